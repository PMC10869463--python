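"""Genetic distances, neighbour-joining tree, PCA and the Evanno ΔK statistic.

Distances between individual accessions treat each accession as a tiny
"population": at a locus its allele-frequency vector is {1} for a homozygote
and {0.5, 0.5} for a heterozygote. Missing data are handled by pairwise
deletion — only loci called in both accessions contribute — so accessions
that differ only by missing calls are at distance zero.

* p-distance: mean per-locus allele-sharing dissimilarity,
  1 - (shared allele count)/2 per locus.
* Nei (1972) standard distance: D = -ln( J_xy / sqrt(J_x J_y) ) with
  J terms the across-loci means of sum(x_i y_i), sum(x_i^2), sum(y_i^2).
* Neighbour joining: Saitou-Nei with the standard Q-criterion,
  lexicographically smallest label pair on ties, negative branch lengths
  clamped to zero (flagged).
* Evanno ΔK: |L''(K)| / sd(L(K)) over replicate log-likelihoods.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix


@dataclass
class DistanceMatrix:
    labels: list[str]
    values: np.ndarray
    metric_name: str
    flagged_pairs: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.labels), len(self.labels)):
            raise ValueError("distance matrix shape does not match labels")
        if not np.allclose(v, v.T, equal_nan=True):
            raise ValueError("distance matrix not symmetric")
        if np.any(np.nan_to_num(np.diag(v)) != 0):
            raise ValueError("distance matrix diagonal not zero")
        self.values = v

    def to_phylip(self, path: str | Path) -> None:
        lines = [f"{len(self.labels)}"]
        for lab, row in zip(self.labels, self.values):
            lines.append(f"{lab:<12}" + " ".join(f"{x:.6f}" for x in row))
        Path(path).write_text("\n".join(lines) + "\n")

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(self.values, index=self.labels,
                     columns=self.labels).to_csv(path, sep="\t")


# -- per-accession frequency encodings ---------------------------------------

def _freq_planes(matrix: GenotypeMatrix) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(x_ref, x_alt, called) planes; frequencies of the two panel alleles
    per accession and locus, NaN-free with a boolean called mask."""
    d = matrix.dosages()
    called = ~np.isnan(d)
    d = np.nan_to_num(d)
    x_alt = d / 2.0
    x_ref = 1.0 - x_alt
    x_alt[~called] = 0.0
    x_ref[~called] = 0.0
    return x_ref, x_alt, called


def p_distance(matrix: GenotypeMatrix, i: int | str, j: int | str) -> float:
    """Allele-sharing p-distance between two accessions (pairwise deletion)."""
    ia = matrix.accession_ids.index(i) if isinstance(i, str) else i
    ja = matrix.accession_ids.index(j) if isinstance(j, str) else j
    d = matrix.dosages()
    both = ~np.isnan(d[ia]) & ~np.isnan(d[ja])
    if not both.any():
        raise ValueError(f"no mutually called locus between "
                         f"{matrix.accession_ids[ia]} and {matrix.accession_ids[ja]}")
    return float(np.mean(np.abs(d[ia, both] - d[ja, both]) / 2.0))


def p_distance_matrix(matrix: GenotypeMatrix) -> DistanceMatrix:
    d = matrix.dosages()
    called = ~np.isnan(d)
    d0 = np.nan_to_num(d)
    n = matrix.n_accessions
    shared = called.astype(float) @ called.astype(float).T
    # sum |di-dj| over shared loci, via per-locus loop kept vectorised in markers
    diff = np.zeros((n, n))
    for jm in range(matrix.n_markers):
        col = d0[:, jm]
        m = called[:, jm].astype(float)
        dd = np.abs(col[:, None] - col[None, :]) * (m[:, None] * m[None, :])
        diff += dd
    with np.errstate(invalid="ignore", divide="ignore"):
        vals = diff / 2.0 / shared
    flagged = [(matrix.accession_ids[a], matrix.accession_ids[b])
               for a, b in zip(*np.where(shared == 0)) if a < b]
    np.fill_diagonal(vals, 0.0)
    return DistanceMatrix(list(matrix.accession_ids), vals, "p_distance", flagged)


def nei1972_distance(matrix: GenotypeMatrix) -> DistanceMatrix:
    """Nei (1972) standard genetic distance between accessions.

    D = -ln I with I = Jxy_bar / sqrt(Jx_bar * Jy_bar); the J-bar terms are
    means across mutually called loci of sum(x y), sum(x^2), sum(y^2) over
    the locus's alleles. I = 0 (fixed opposite homozygotes everywhere) gives
    D = +inf, flagged.
    """
    xr, xa, called = _freq_planes(matrix)
    cal = called.astype(float)
    shared = cal @ cal.T
    sxy = xr @ xr.T + xa @ xa.T
    j_self = xr ** 2 + xa ** 2          # per accession x locus
    jx = j_self @ cal.T                  # sum over loci called in BOTH (row view)
    jy = cal @ j_self.T
    with np.errstate(invalid="ignore", divide="ignore"):
        identity = (sxy / shared) / np.sqrt((jx / shared) * (jy / shared))
        identity = np.clip(identity, 0.0, 1.0)
        vals = -np.log(identity)
    flagged = []
    n = len(matrix.accession_ids)
    for a in range(n):
        for b in range(a + 1, n):
            if shared[a, b] == 0 or not np.isfinite(vals[a, b]):
                flagged.append((matrix.accession_ids[a], matrix.accession_ids[b]))
    np.fill_diagonal(vals, 0.0)
    return DistanceMatrix(list(matrix.accession_ids), vals, "nei1972", flagged)


# -- neighbour joining --------------------------------------------------------

@dataclass
class Tree:
    """Unrooted tree as a Newick string over the accession labels."""

    newick: str
    labels: list[str]
    negative_branches_clamped: int = 0

    def to_skbio(self):
        import io
        from skbio import TreeNode
        return TreeNode.read(io.StringIO(self.newick))

    def write(self, path: str | Path) -> None:
        Path(path).write_text(self.newick + "\n")


def _nwk(label: str, length: float) -> str:
    return f"{label}:{length:.17g}"


def nj_tree(d: DistanceMatrix) -> Tree:
    """Saitou-Nei neighbour joining; exact on additive distances.

    Ties in the Q-criterion are broken by the lexicographically smallest
    (label, label) pair; negative branch lengths are clamped to 0 and counted.
    """
    if len(d.labels) < 3:
        raise ValueError("need >= 3 labels for neighbour joining")
    if not np.all(np.isfinite(d.values)):
        bad = np.argwhere(~np.isfinite(d.values))[0]
        raise ValueError(f"non-finite distance between "
                         f"{d.labels[bad[0]]} and {d.labels[bad[1]]}")
    D = d.values.astype(float).copy()
    # node representations: (sort key, newick fragment)
    nodes = [(lab, lab) for lab in d.labels]
    clamped = 0

    def clamp(x: float) -> float:
        nonlocal clamped
        if x < 0:
            clamped += 1
            return 0.0
        return x

    while len(nodes) > 3:
        n = len(nodes)
        r = D.sum(axis=1)
        q = (n - 2) * D - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        qmin = q.min()
        best = None
        for a, b in zip(*np.where(np.isclose(q, qmin, rtol=0, atol=1e-12))):
            if a >= b:
                continue
            key = tuple(sorted((nodes[a][0], nodes[b][0])))
            if best is None or key < best[0]:
                best = (key, int(a), int(b))
        _, a, b = best
        la = clamp(0.5 * D[a, b] + (r[a] - r[b]) / (2 * (n - 2)))
        lb = clamp(D[a, b] - (0.5 * D[a, b] + (r[a] - r[b]) / (2 * (n - 2))))
        new_frag = f"({_nwk(nodes[a][1], la)},{_nwk(nodes[b][1], lb)})"
        new_key = min(nodes[a][0], nodes[b][0])
        dn = 0.5 * (D[a] + D[b] - D[a, b])
        keep = [k for k in range(n) if k not in (a, b)]
        D = np.vstack([np.hstack([D[np.ix_(keep, keep)],
                                  dn[keep][:, None]]),
                       np.hstack([dn[keep], [0.0]])])
        nodes = [nodes[k] for k in keep] + [(new_key, new_frag)]
    # final three-point join
    (ka, fa), (kb, fb), (kc, fc) = nodes
    dab, dac, dbc = D[0, 1], D[0, 2], D[1, 2]
    la = clamp(0.5 * (dab + dac - dbc))
    lb = clamp(0.5 * (dab + dbc - dac))
    lc = clamp(0.5 * (dac + dbc - dab))
    newick = f"({_nwk(fa, la)},{_nwk(fb, lb)},{_nwk(fc, lc)});"
    return Tree(newick, list(d.labels), clamped)


# -- PCA ----------------------------------------------------------------------

def pca_coordinates(matrix: GenotypeMatrix, n_components: int = 2
                    ) -> tuple[pd.DataFrame, np.ndarray]:
    """PCA of accessions on alternate-allele dosage.

    Missing dosages are imputed with the marker mean; markers are centered;
    the accession covariance is eigendecomposed (via SVD). Sign convention:
    the largest-magnitude marker loading of each component is positive.
    Returns (coordinates DataFrame, explained-variance fractions).
    """
    if n_components > min(matrix.n_accessions, matrix.n_markers):
        raise ValueError("n_components exceeds matrix rank bound")
    d = matrix.dosages()
    col_mean = np.nanmean(d, axis=0)
    col_mean = np.nan_to_num(col_mean)
    idx = np.where(np.isnan(d))
    d[idx] = col_mean[idx[1]]
    x = d - d.mean(axis=0)
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    total_var = (x ** 2).sum()
    explained = (s ** 2) / total_var if total_var > 0 else np.zeros_like(s)
    coords = u * s
    for k in range(min(n_components, vt.shape[0])):
        lead = np.argmax(np.abs(vt[k]))
        if vt[k, lead] < 0:
            coords[:, k] *= -1
            vt[k] *= -1
    df = pd.DataFrame(coords[:, :n_components],
                      index=pd.Index(matrix.accession_ids, name="accession"),
                      columns=[f"PC{k + 1}" for k in range(n_components)])
    return df, explained[:n_components]


# -- Evanno ΔK ----------------------------------------------------------------

@dataclass
class StructureRuns:
    """Replicate log-likelihoods L(K) per number of clusters K."""

    logliks: dict[int, list[float]]

    def __post_init__(self) -> None:
        ks = sorted(self.logliks)
        if len(ks) < 3 or any(b - a != 1 for a, b in zip(ks, ks[1:])):
            raise ValueError("need >= 3 consecutive K values")
        for k, reps in self.logliks.items():
            if len(reps) < 2:
                raise ValueError(f"K={k}: need >= 2 replicates for ΔK")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "StructureRuns":
        df = pd.read_csv(path, sep="\t")
        out: dict[int, list[float]] = {}
        for _, row in df.iterrows():
            out.setdefault(int(row["K"]), []).append(float(row["lnP"]))
        return cls(out)

    def to_tsv(self, path: str | Path) -> None:
        rows = [(k, r, v) for k, reps in sorted(self.logliks.items())
                for r, v in enumerate(reps, 1)]
        pd.DataFrame(rows, columns=["K", "replicate", "lnP"]).to_csv(
            path, sep="\t", index=False)


def evanno_delta_k(runs: StructureRuns) -> tuple[pd.DataFrame, int]:
    """Evanno ΔK table and the argmax K.

    L'(K) = mean L(K) - mean L(K-1); |L''(K)| = |L'(K+1) - L'(K)|;
    ΔK = |L''(K)| / sd(L(K)) with the n-1 sd denominator. ΔK is undefined at
    the endpoints of the K range; sd = 0 gives an infinite ΔK (flagged).
    """
    ks = sorted(runs.logliks)
    mean = {k: float(np.mean(runs.logliks[k])) for k in ks}
    sd = {k: float(np.std(runs.logliks[k], ddof=1)) for k in ks}
    rows = []
    for k in ks:
        lp = mean[k] - mean[k - 1] if k - 1 in mean else np.nan
        if k - 1 in mean and k + 1 in mean:
            lpp = abs((mean[k + 1] - mean[k]) - lp)
            if sd[k] == 0:
                warnings.warn(f"K={k}: zero replicate sd; ΔK infinite")
                dk = math.inf if lpp > 0 else math.nan
            else:
                dk = lpp / sd[k]
        else:
            lpp, dk = np.nan, np.nan
        rows.append({"K": k, "mean_lnP": mean[k], "sd_lnP": sd[k],
                     "L_prime": lp, "abs_L_double_prime": lpp, "delta_K": dk})
    df = pd.DataFrame(rows)
    interior = df.dropna(subset=["delta_K"])
    if interior.empty:
        raise ValueError("no interior K with defined ΔK")
    best = int(interior.loc[interior["delta_K"].idxmax(), "K"])
    return df, best


def structure_pseudo_likelihood(matrix: GenotypeMatrix, k_range: range | Sequence[int],
                                n_replicates: int = 5, seed: int = 0,
                                subsample: float = 0.9) -> StructureRuns:
    """Replicate log-likelihood profile over K from a genotype panel.

    Stands in for an external Bayesian clustering run: per replicate a random
    ``subsample`` fraction of accessions is clustered on imputed dosage with
    k-means, cluster allele frequencies are estimated, and the binomial
    genotype log-likelihood is evaluated and rescaled to full panel size.
    Replicate scatter therefore reflects genuine sampling variation, which is
    what the ΔK denominator expects.
    """
    from scipy.stats import binom
    from sklearn.cluster import KMeans

    rng = np.random.default_rng(np.random.SeedSequence([seed, 7]))
    d = matrix.dosages()
    col_mean = np.nan_to_num(np.nanmean(d, axis=0))
    imputed = d.copy()
    idx = np.where(np.isnan(imputed))
    imputed[idx] = col_mean[idx[1]]
    n = matrix.n_accessions
    m = int(round(subsample * n))
    out: dict[int, list[float]] = {}
    for k in k_range:
        reps = []
        for _ in range(n_replicates):
            rows = rng.choice(n, size=m, replace=False)
            xs = imputed[rows]
            if k == 1:
                labels = np.zeros(m, dtype=int)
            else:
                km = KMeans(n_clusters=k, n_init=3,
                            random_state=int(rng.integers(2 ** 31 - 1)))
                labels = km.fit_predict(xs)
            ll = 0.0
            for c in range(k):
                sel = labels == c
                if not sel.any():
                    continue
                p = xs[sel].mean(axis=0) / 2.0
                eps = 1.0 / (2 * max(sel.sum(), 1) + 2)
                p = np.clip(p, eps, 1 - eps)
                dos = np.round(xs[sel]).clip(0, 2).astype(int)
                ll += float(binom.logpmf(dos, 2, p[None, :]).sum())
            reps.append(ll / subsample)
        out[int(k)] = reps
    return StructureRuns(out)
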