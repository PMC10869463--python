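"""Core-collection construction and its diversity evaluation.

Distances between accessions use the per-accession allele-frequency
convention ({1} for a homozygote, {0.5, 0.5} for a heterozygote) with
pairwise deletion over loci called in both accessions:

* modified Rogers  MR = sqrt( (1/2L) sum_loci sum_alleles (p_a - q_a)^2 )
* Cavalli-Sforza & Edwards (Core Hunter convention)
  CE = sqrt( (1/2L) sum_loci sum_alleles (sqrt p_a - sqrt q_a)^2 );
  the 1967 chord distance (2/pi arc factor) is available via ``chord=True``.

Panel metrics for a subset: MR/CE = mean over subset pairs; HE = mean over
markers of 1 - sum p^2; NE = mean of 1/sum p^2; PIC = mean Botstein PIC;
SH = Shannon index over the pooled allele-frequency list (each marker's
alleles weighted 1/L, so 32 balanced biallelic loci give ln 64); CV =
fraction of the reference collection's alleles present in the subset.

Selection is two-phase: a greedy sweep maximizing allele coverage, then a
seeded steepest-ascent swap search on the weighted objective (default mean
MR) that never lets coverage drop.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .genotypes import GenotypeMatrix, MISSING
from .diversity import allele_frequencies, pic


# -- pairwise distances -----------------------------------------------------

def _dosage_planes(matrix: GenotypeMatrix) -> tuple[np.ndarray, np.ndarray]:
    d = matrix.dosages()
    return d, ~np.isnan(d)


def modified_rogers_matrix(matrix: GenotypeMatrix) -> np.ndarray:
    """Full pairwise modified-Rogers distance matrix (pairwise deletion)."""
    d, called = _dosage_planes(matrix)
    d0 = np.nan_to_num(d)
    cal = called.astype(float)
    shared = cal @ cal.T
    # per locus: sum_alleles (p-q)^2 = (d_i - d_j)^2 / 2 for biallelic dosages
    sq = np.zeros_like(shared)
    for jm in range(matrix.n_markers):
        col = d0[:, jm]
        m = cal[:, jm]
        dd = (col[:, None] - col[None, :]) ** 2 * (m[:, None] * m[None, :])
        sq += dd
    with np.errstate(invalid="ignore", divide="ignore"):
        vals = np.sqrt(sq / 2.0 / (2.0 * shared))
    np.fill_diagonal(vals, 0.0)
    return vals


def cavalli_edwards_matrix(matrix: GenotypeMatrix, chord: bool = False) -> np.ndarray:
    """Full pairwise Cavalli-Sforza & Edwards distance matrix.

    Default is the Euclidean-on-sqrt-frequencies form; ``chord=True`` applies
    the 1967 chord distance 2/pi * sqrt(2 (1 - cos theta)) per locus instead.
    """
    d, called = _dosage_planes(matrix)
    d0 = np.nan_to_num(d)
    cal = called.astype(float)
    s_alt = np.sqrt(d0 / 2.0)
    s_ref = np.sqrt(1.0 - d0 / 2.0)
    shared = cal @ cal.T
    sq = np.zeros_like(shared)
    for jm in range(matrix.n_markers):
        m = cal[:, jm]
        w = m[:, None] * m[None, :]
        if chord:
            cos = (s_ref[:, jm][:, None] * s_ref[:, jm][None, :]
                   + s_alt[:, jm][:, None] * s_alt[:, jm][None, :])
            per_locus = (2.0 / math.pi) ** 2 * 2.0 * (1.0 - np.clip(cos, -1, 1))
            sq += per_locus * w * 2.0  # rescale so the 1/(2L) outer factor matches
        else:
            dd = ((s_ref[:, jm][:, None] - s_ref[:, jm][None, :]) ** 2
                  + (s_alt[:, jm][:, None] - s_alt[:, jm][None, :]) ** 2)
            sq += dd * w
    with np.errstate(invalid="ignore", divide="ignore"):
        vals = np.sqrt(sq / (2.0 * shared))
    np.fill_diagonal(vals, 0.0)
    return vals


def modified_rogers(matrix: GenotypeMatrix, i: int | str, j: int | str) -> float:
    ia = matrix.accession_ids.index(i) if isinstance(i, str) else i
    ja = matrix.accession_ids.index(j) if isinstance(j, str) else j
    return float(modified_rogers_matrix(matrix)[ia, ja])


def cavalli_edwards(matrix: GenotypeMatrix, i: int | str, j: int | str,
                    chord: bool = False) -> float:
    ia = matrix.accession_ids.index(i) if isinstance(i, str) else i
    ja = matrix.accession_ids.index(j) if isinstance(j, str) else j
    return float(cavalli_edwards_matrix(matrix, chord=chord)[ia, ja])


# -- panel metrics -----------------------------------------------------------

@dataclass
class CoreSelection:
    selected: list[str]
    size_fraction: float
    metrics: dict
    warning: Optional[str] = None


def _allele_sets(matrix: GenotypeMatrix) -> list[set[str]]:
    """Observed alleles per marker."""
    out = []
    for j in range(matrix.n_markers):
        alleles = set()
        for call in matrix.calls[:, j]:
            if call != MISSING:
                alleles.update(call)
        out.append(alleles)
    return out


def panel_metrics(matrix: GenotypeMatrix, subset: Sequence[str],
                  reference: Optional[GenotypeMatrix] = None) -> dict:
    """Core-collection evaluation metrics for an accession subset."""
    if not list(subset):
        raise ValueError("empty subset")
    reference = reference if reference is not None else matrix
    sub = matrix.subset_accessions(list(subset))

    mr = modified_rogers_matrix(sub)
    ce = cavalli_edwards_matrix(sub)
    iu = np.triu_indices(sub.n_accessions, k=1)
    mean_mr = float(np.nanmean(mr[iu])) if iu[0].size else 0.0
    mean_ce = float(np.nanmean(ce[iu])) if iu[0].size else 0.0

    he_vals, ne_vals, pic_vals, pooled = [], [], [], []
    n_loci_used = 0
    for j in range(sub.n_markers):
        try:
            freqs = allele_frequencies(sub.calls[:, j].tolist())
        except ValueError:
            continue
        s2 = sum(f ** 2 for f in freqs.values())
        he_vals.append(1.0 - s2)
        ne_vals.append(1.0 / s2)
        pic_vals.append(pic(freqs))
        pooled.append(list(freqs.values()))
        n_loci_used += 1
    if n_loci_used == 0:
        raise ValueError("subset has no marker with data")
    flat = np.concatenate([np.asarray(f) / n_loci_used for f in pooled])
    flat = flat[flat > 0]
    sh = float(-(flat * np.log(flat)).sum())

    ref_alleles = _allele_sets(reference)
    sub_alleles = _allele_sets(sub)
    n_ref = sum(len(a) for a in ref_alleles)
    n_hit = sum(len(r & s) for r, s in zip(ref_alleles, sub_alleles))
    cv = n_hit / n_ref if n_ref else 1.0

    return {"n": sub.n_accessions, "MR": mean_mr, "CE": mean_ce, "SH": sh,
            "HE": float(np.mean(he_vals)), "NE": float(np.mean(ne_vals)),
            "PIC": float(np.mean(pic_vals)), "CV": cv}


def _coverage_state(matrix: GenotypeMatrix) -> tuple[np.ndarray, int]:
    """(accessions x distinct-allele columns) presence matrix and total alleles."""
    cols = []
    for j in range(matrix.n_markers):
        alleles = sorted(set("".join(c for c in matrix.calls[:, j] if c != MISSING)))
        for a in alleles:
            has = np.array([a in call and call != MISSING
                            for call in matrix.calls[:, j]])
            cols.append(has)
    presence = np.array(cols).T if cols else np.zeros((matrix.n_accessions, 0), bool)
    return presence, presence.shape[1]


def select_core(matrix: GenotypeMatrix, target_fraction: float = 0.20,
                seed: int = 0, max_sweeps: int = 30) -> CoreSelection:
    """Two-phase core selection: greedy allele coverage, then swap ascent on mean MR.

    Phase 1 adds the accession contributing the most uncovered alleles (ties:
    lowest index) until full coverage or the target size; remaining slots are
    filled greedily by the accession maximizing the subset's mean
    modified-Rogers distance. Phase 2 is steepest-ascent swapping under the
    constraint that allele coverage never decreases. Deterministic under seed.
    """
    if not 0 < target_fraction <= 1:
        raise ValueError("target_fraction outside (0, 1]")
    n = matrix.n_accessions
    target = max(int(round(target_fraction * n)), 1)
    if target >= n:
        sel = list(matrix.accession_ids)
        return CoreSelection(sel, 1.0, panel_metrics(matrix, sel))

    rng = np.random.default_rng(np.random.SeedSequence([seed, 11]))
    presence, n_alleles = _coverage_state(matrix)
    dist = modified_rogers_matrix(matrix)
    dist = np.nan_to_num(dist)

    covered = np.zeros(n_alleles, dtype=bool)
    selected: list[int] = []
    # phase 1: allele coverage
    while len(selected) < target and not covered.all():
        gains = presence[:, ~covered].sum(axis=1)
        gains[selected] = -1
        selected.append(int(np.argmax(gains)))
        covered |= presence[selected[-1]]
    warning = None
    if not covered.all():
        warning = (f"target size {target} too small for full allele coverage "
                   f"({covered.sum()}/{n_alleles} alleles)")
    # fill to target by max mean distance
    while len(selected) < target:
        in_sel = np.zeros(n, dtype=bool)
        in_sel[selected] = True
        gains = dist[:, selected].sum(axis=1)
        gains[in_sel] = -np.inf
        selected.append(int(np.argmax(gains)))

    # phase 2: steepest-ascent swaps maximizing total within-subset distance,
    # never losing a covered allele
    sel = np.array(sorted(selected))
    in_sel = np.zeros(n, dtype=bool)
    in_sel[sel] = True
    for _ in range(max_sweeps):
        sub = dist[np.ix_(sel, sel)]
        total = sub.sum() / 2.0
        cover_counts = presence[sel].sum(axis=0)
        best_delta, best_swap = 1e-9, None
        outside = np.where(~in_sel)[0]
        row_out = dist[np.ix_(outside, sel)]  # candidates x current members
        for si, member in enumerate(sel):
            lost = dist[member, sel].sum()
            # alleles held only by this member
            critical = presence[member] & (cover_counts == 1) & covered
            gains = row_out.sum(axis=1) - dist[outside, member]
            if critical.any():
                ok = presence[outside][:, critical].all(axis=1)
            else:
                ok = np.ones(len(outside), dtype=bool)
            gains[~ok] = -np.inf
            ci = int(np.argmax(gains))
            delta = gains[ci] - lost
            if delta > best_delta:
                best_delta, best_swap = delta, (si, outside[ci])
        if best_swap is None:
            break
        si, newcomer = best_swap
        in_sel[sel[si]] = False
        in_sel[newcomer] = True
        sel[si] = newcomer
        sel = np.array(sorted(sel))

    ids = [matrix.accession_ids[i] for i in sorted(sel)]
    metrics = panel_metrics(matrix, ids, reference=matrix)
    return CoreSelection(ids, len(ids) / n, metrics, warning)
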