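"""Per-marker and panel-level diversity statistics.

For a marker with allele frequencies p_i (counted over non-missing diploid
calls, a heterozygote contributing one copy of each allele):

* gene diversity (expected heterozygosity)  GD = 1 - sum(p_i^2)
* polymorphism information content (Botstein et al. 1980)
  PIC = 1 - sum(p_i^2) - sum_{i<j} 2 p_i^2 p_j^2
  (biallelic: 2pq - 2 p^2 q^2, maximum 0.375 at p = q = 0.5)
* MAF = min(p_i); observed heterozygosity = het calls / non-missing calls.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from importlib import resources
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix, MISSING


def allele_frequencies(calls: Sequence[str]) -> dict[str, float]:
    """Allele frequencies at one marker from diploid two-letter calls."""
    counts: dict[str, int] = {}
    for call in calls:
        if call == MISSING:
            continue
        for a in call:
            counts[a] = counts.get(a, 0) + 1
    total = sum(counts.values())
    if total == 0:
        raise ValueError("no data: all calls missing at this marker")
    return {a: c / total for a, c in sorted(counts.items())}


def minor_allele_frequency(freqs: dict[str, float] | Sequence[float]) -> float:
    vals = list(freqs.values()) if isinstance(freqs, dict) else list(freqs)
    return min(vals) if len(vals) > 1 else 0.0


def gene_diversity(freqs: dict[str, float] | Sequence[float]) -> float:
    """Expected heterozygosity 1 - sum(p_i^2)."""
    vals = np.asarray(list(freqs.values()) if isinstance(freqs, dict) else freqs)
    return float(1.0 - np.sum(vals ** 2))


def pic(freqs: dict[str, float] | Sequence[float]) -> float:
    """Botstein polymorphism information content."""
    vals = np.asarray(list(freqs.values()) if isinstance(freqs, dict) else freqs)
    s2 = np.sum(vals ** 2)
    cross = 0.0
    for i in range(len(vals)):
        for j in range(i + 1, len(vals)):
            cross += 2.0 * vals[i] ** 2 * vals[j] ** 2
    return float(1.0 - s2 - cross)


def observed_heterozygosity(calls: Sequence[str]) -> float:
    """Fraction of non-missing calls that are heterozygous."""
    called = [c for c in calls if c != MISSING]
    if not called:
        raise ValueError("no data: all calls missing at this marker")
    return sum(c[0] != c[1] for c in called) / len(called)


@dataclass
class MarkerStats:
    """One row of the per-marker diversity table."""

    marker_id: str
    chrom: str
    position: int
    variation_type: str
    pic: float
    maf: float
    gene_diversity: float
    heterozygosity: float
    missing_rate: float
    flagged: Optional[str] = None


def marker_stats(matrix: GenotypeMatrix, j: int) -> MarkerStats:
    col = matrix.calls[:, j].tolist()
    chrom, pos = matrix.positions[j]
    n = len(col)
    n_missing = sum(c == MISSING for c in col)
    if n_missing == n:
        return MarkerStats(matrix.marker_ids[j], chrom, pos, "?/?",
                           float("nan"), float("nan"), float("nan"),
                           float("nan"), 1.0, flagged="all calls missing")
    freqs = allele_frequencies(col)
    alleles = sorted(freqs, key=freqs.get, reverse=True)
    vtype = "/".join(alleles) if len(alleles) > 1 else f"{alleles[0]}/-"
    return MarkerStats(
        marker_id=matrix.marker_ids[j], chrom=chrom, position=pos,
        variation_type=vtype,
        pic=pic(freqs), maf=minor_allele_frequency(freqs),
        gene_diversity=gene_diversity(freqs),
        heterozygosity=observed_heterozygosity(col),
        missing_rate=n_missing / n)


def marker_table(matrix: GenotypeMatrix) -> tuple[list[MarkerStats], dict]:
    """Per-marker statistics plus the panel summary.

    All-missing markers are kept as flagged rows but excluded from the
    summary means. Summary reports mean/min/max of each statistic, the
    fraction of markers with PIC > 0.25, and the maximum missing rate.
    """
    import warnings

    rows = [marker_stats(matrix, j) for j in range(matrix.n_markers)]
    ok = [r for r in rows if r.flagged is None]
    if len(ok) < len(rows):
        warnings.warn(f"{len(rows) - len(ok)} all-missing markers excluded from summary")
    if not ok:
        raise ValueError("no marker with any data")

    def stat(attr):
        vals = np.array([getattr(r, attr) for r in ok])
        return {"mean": float(vals.mean()), "min": float(vals.min()),
                "max": float(vals.max())}

    summary = {
        "n_markers": len(rows),
        "n_markers_flagged": len(rows) - len(ok),
        "pic": stat("pic"),
        "maf": stat("maf"),
        "gene_diversity": stat("gene_diversity"),
        "heterozygosity": stat("heterozygosity"),
        "missing_rate": stat("missing_rate"),
        "fraction_pic_above_0.25": float(np.mean([r.pic > 0.25 for r in ok])),
        "max_missing_rate": max(r.missing_rate for r in ok),
    }
    return rows, summary


def marker_table_to_tsv(rows: Sequence[MarkerStats], path: str | Path) -> None:
    df = pd.DataFrame([asdict(r) for r in rows])
    num = ["pic", "maf", "gene_diversity", "heterozygosity", "missing_rate"]
    df[num] = df[num].round(3)
    df.to_csv(path, sep="\t", index=False)


def load_reference_panel() -> pd.DataFrame:
    """Published diversity table for the 32-marker radish KASP panel
    genotyped on 356 accessions (printed at 3 dp)."""
    with resources.files("radfp.data").joinpath("reference_panel.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")
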