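"""KASP assay feasibility from flanking sequence, and post-genotyping marker QC.

A KASP assay is two allele-specific primers (differing only at the 3'
terminal base, the SNP) carrying universal FAM/HEX tails, plus one common
primer on the opposite strand. Feasibility constraints, applied to primer
bodies (tails are universal and do not anneal to target):

* GC fraction < 0.60
* melting temperature in [55, 62] degC (nearest-neighbour thermodynamics,
  SantaLucia 1998 unified parameters, 50 mM Na+, 250 nM primer)
* PCR product size <= 120 bp

The search over primer lengths (18-30 bp) and common-primer placements is
deterministic, so identical flanks always give the identical assay.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from Bio.Seq import Seq
from Bio.SeqUtils import MeltingTemp as mt
from Bio.SeqUtils import gc_fraction

from .genotypes import MISSING
from .variants import VariantRecord

FAM_TAIL = "GAAGGTGACCAAGTTCATGCT"
HEX_TAIL = "GAAGGTCGGGAGTCAACGGATT"

GC_MAX = 0.60
TM_RANGE = (55.0, 62.0)
PRODUCT_MAX = 120
PRIMER_LEN_RANGE = (18, 30)
TM_METHOD = "NN_SantaLucia1998_Na50mM_primer250nM"


def primer_tm(seq: str) -> float:
    """Nearest-neighbour Tm of a primer body."""
    return float(mt.Tm_NN(Seq(seq), nn_table=mt.DNA_NN3, Na=50, dnac1=250, dnac2=0))


def _check_primer(seq: str) -> Optional[str]:
    """First violated constraint for a primer body, or None if it passes."""
    if gc_fraction(seq) >= GC_MAX:
        return "GC content"
    tm = primer_tm(seq)
    if not TM_RANGE[0] <= tm <= TM_RANGE[1]:
        return "Tm"
    return None


@dataclass
class FlankedSite:
    """A biallelic SNP with its upstream and downstream reference flanks."""

    site_id: str
    ref_allele: str
    alt_allele: str
    upstream_seq: str
    downstream_seq: str
    truncated: bool = False

    def __post_init__(self) -> None:
        self.upstream_seq = self.upstream_seq.upper()
        self.downstream_seq = self.downstream_seq.upper()
        for s in (self.upstream_seq, self.downstream_seq,
                  self.ref_allele, self.alt_allele):
            if set(s) - set("ACGT"):
                raise ValueError(f"non-ACGT characters in flanks of {self.site_id}")
        if len(self.upstream_seq) != 100 or len(self.downstream_seq) != 100:
            self.truncated = True


@dataclass
class KaspAssay:
    site_id: str
    feasible: bool
    reason: Optional[str] = None
    fam_primer: Optional[str] = None     # tail + body, body ends on ref allele
    hex_primer: Optional[str] = None     # tail + body, body ends on alt allele
    common_primer: Optional[str] = None
    product_size: Optional[int] = None
    gc: dict = field(default_factory=dict)
    tm: dict = field(default_factory=dict)
    tm_method: str = TM_METHOD


def design_assay(flanked: FlankedSite) -> KaspAssay:
    """Search primer lengths/placements for a feasible KASP assay.

    Allele-specific primer bodies end on the SNP base and extend into the
    upstream flank; the common primer is the reverse complement of a window
    in the downstream flank. The first feasible combination in the
    deterministic search order (allele-primer length ascending, then gap,
    then common length) is returned; otherwise the binding constraint.
    """
    lmin, lmax = PRIMER_LEN_RANGE
    up, down = flanked.upstream_seq, flanked.downstream_seq
    if len(up) < lmin - 1 or len(down) < lmin:
        return KaspAssay(flanked.site_id, False, reason="truncated_flank")

    asp_fail: dict[str, int] = {}
    feasible_asp = []
    for alen in range(lmin, lmax + 1):
        body = up[-(alen - 1):] if alen > 1 else ""
        if len(body) != alen - 1:
            break
        ref_body = body + flanked.ref_allele
        alt_body = body + flanked.alt_allele
        bad = _check_primer(ref_body) or _check_primer(alt_body)
        if bad:
            asp_fail[bad] = asp_fail.get(bad, 0) + 1
            continue
        feasible_asp.append((alen, ref_body, alt_body))
    if not feasible_asp:
        reason = max(asp_fail, key=lambda k: (asp_fail[k], k == "GC content")) \
            if asp_fail else "truncated_flank"
        return KaspAssay(flanked.site_id, False, reason=reason)

    common_fail: dict[str, int] = {}
    for alen, ref_body, alt_body in feasible_asp:
        max_total_down = PRODUCT_MAX - alen - 1  # bases of downstream inside product
        for gap in range(0, max_total_down - lmin + 1):
            for clen in range(lmin, min(lmax, max_total_down - gap) + 1):
                window = down[gap:gap + clen]
                if len(window) < clen:
                    break
                common = str(Seq(window).reverse_complement())
                bad = _check_primer(common)
                if bad:
                    common_fail[bad] = common_fail.get(bad, 0) + 1
                    continue
                product = alen + 1 + gap + clen
                if product > PRODUCT_MAX:
                    common_fail["product size"] = common_fail.get("product size", 0) + 1
                    continue
                return KaspAssay(
                    flanked.site_id, True,
                    fam_primer=FAM_TAIL + ref_body,
                    hex_primer=HEX_TAIL + alt_body,
                    common_primer=common,
                    product_size=product,
                    gc={"fam": gc_fraction(ref_body), "hex": gc_fraction(alt_body),
                        "common": gc_fraction(common)},
                    tm={"fam": primer_tm(ref_body), "hex": primer_tm(alt_body),
                        "common": primer_tm(common)})
    reason = max(common_fail, key=lambda k: (common_fail[k], k == "GC content")) \
        if common_fail else "product size"
    return KaspAssay(flanked.site_id, False, reason=reason)


# -- marker QC ------------------------------------------------------------------

NO_CALL_MAX = 0.10  # strict: > 10% no-call is excluded


@dataclass
class MarkerQCVerdict:
    category: str          # typable | untypable | monomorphic | high_no_call
    no_call_rate: float
    n_genotype_clusters: int


def classify_marker(calls: Sequence[str]) -> MarkerQCVerdict:
    """QC category for one marker from its per-accession genotype calls.

    untypable: every call missing; high_no_call: no-call fraction > 0.10
    (strict); monomorphic: a single genotype class among called samples;
    typable otherwise.
    """
    calls = list(calls)
    if not calls:
        raise ValueError("empty call vector")
    n = len(calls)
    n_nc = sum(c == MISSING for c in calls)
    classes = {c if c[0] <= c[1] else c[1] + c[0] for c in calls if c != MISSING}
    rate = n_nc / n
    if n_nc == n:
        return MarkerQCVerdict("untypable", 1.0, 0)
    if rate > NO_CALL_MAX:
        return MarkerQCVerdict("high_no_call", rate, len(classes))
    if len(classes) == 1:
        return MarkerQCVerdict("monomorphic", rate, 1)
    return MarkerQCVerdict("typable", rate, len(classes))


# -- candidate panel selection ---------------------------------------------------

def select_candidate_panel(sites: Sequence[tuple[str, str, int]],
                           per_chrom_range: tuple[int, int] = (8, 12)
                           ) -> list[str]:
    """Pick per-chromosome candidates maximizing physical spacing.

    ``sites`` are (site_id, chrom, pos). Per chromosome the target count is
    the range maximum (capped at availability); sites are chosen by greedy
    farthest-point dispersion, ties broken toward the lowest position. A
    chromosome with fewer sites than the range minimum contributes all of
    them with a warning.
    """
    import warnings

    lo, hi = per_chrom_range
    if not 1 <= lo <= hi:
        raise ValueError(f"bad per-chromosome range {per_chrom_range}")
    by_chrom: dict[str, list[tuple[int, str]]] = {}
    for sid, chrom, pos in sites:
        by_chrom.setdefault(chrom, []).append((pos, sid))
    chosen: list[str] = []
    for chrom in sorted(by_chrom):
        pts = sorted(by_chrom[chrom])
        if len(pts) < lo:
            warnings.warn(f"{chrom}: only {len(pts)} sites (< minimum {lo}); taking all")
            chosen.extend(sid for _, sid in pts)
            continue
        k = min(hi, len(pts))
        pos = np.array([p for p, _ in pts])
        picked = [0, len(pts) - 1] if len(pts) > 1 else [0]
        while len(picked) < k:
            dmin = np.min(np.abs(pos[:, None] - pos[picked][None, :]), axis=1)
            dmin[picked] = -1
            best = int(np.argmax(dmin))  # argmax takes lowest index (lowest pos) on ties
            picked.append(best)
        chosen.extend(pts[i][1] for i in sorted(picked))
    return chosen


# -- flank FASTA I/O --------------------------------------------------------------

AMBIG = {"R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC"}


def read_flanks_fasta(path: str | Path) -> list[FlankedSite]:
    """Read flanked sites: SNP as an IUPAC ambiguity code at position 101, or
    ref/alt given in the header as ``ref=X alt=Y``."""
    from Bio import SeqIO

    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        desc = dict(kv.split("=") for kv in rec.description.split()[1:] if "=" in kv)
        amb_pos = next((i for i, b in enumerate(seq) if b in AMBIG), None)
        if amb_pos is None:
            raise ValueError(f"{rec.id}: no IUPAC ambiguity base found")
        alleles = AMBIG[seq[amb_pos]]
        ref = desc.get("ref", alleles[0])
        alt = desc.get("alt", alleles[1] if alleles[0] == ref else alleles[0])
        out.append(FlankedSite(rec.id, ref, alt, seq[:amb_pos], seq[amb_pos + 1:]))
    return out


def assays_to_tsv(assays: Sequence[KaspAssay], path: str | Path) -> None:
    import pandas as pd

    rows = []
    for a in assays:
        rows.append({
            "site_id": a.site_id, "feasible": a.feasible, "reason": a.reason or "",
            "fam_primer": a.fam_primer or "", "hex_primer": a.hex_primer or "",
            "common_primer": a.common_primer or "",
            "product_size": a.product_size if a.product_size else "",
            "gc_fam": round(a.gc.get("fam", float("nan")), 3) if a.gc else "",
            "gc_common": round(a.gc.get("common", float("nan")), 3) if a.gc else "",
            "tm_fam": round(a.tm.get("fam", float("nan")), 2) if a.tm else "",
            "tm_common": round(a.tm.get("common", float("nan")), 2) if a.tm else "",
            "tm_method": a.tm_method})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
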