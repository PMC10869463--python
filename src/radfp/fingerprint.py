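"""Minimal discriminating marker sets, fingerprint encoding and duplicate groups.

An accession pair is *resolved* by a marker when both accessions are called
there and their (unordered) genotypes differ; a missing call never resolves a
pair. Finding the smallest marker subset that resolves every resolvable pair
is minimum set cover; a greedy cover (with PIC and genome-position
tie-breaks) is used at scale, with a provably minimal exhaustive solver for
small instances.

Fingerprint codes: AA=1, CC=2, GG=3, TT=4, any heterozygote=5, missing=6,
with the heatmap colour legend yellow/green/blue/purple/grey/white.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix, MISSING
from .diversity import allele_frequencies, pic

CODE_MAP = {"AA": 1, "CC": 2, "GG": 3, "TT": 4}
CODE_COLORS = {1: "yellow", 2: "green", 3: "blue", 4: "purple", 5: "grey", 6: "white"}
HET_CODE = 5
MISSING_CODE = 6


def _pair_index(n: int) -> list[tuple[int, int]]:
    return [(i, j) for i in range(n) for j in range(i + 1, n)]


def _difference_planes(matrix: GenotypeMatrix) -> np.ndarray:
    """Boolean array (n_pairs, n_markers): marker resolves the pair."""
    codes = matrix.genotype_codes()
    n = matrix.n_accessions
    iu, ju = np.triu_indices(n, k=1)
    a = codes[iu]          # n_pairs x markers
    b = codes[ju]
    return (a != b) & (a >= 0) & (b >= 0)


@dataclass
class PairResolution:
    accession_a: str
    accession_b: str
    resolved: bool
    witness_markers: list[str]


def discriminating_pairs(matrix: GenotypeMatrix,
                         subset: Optional[Sequence[str]] = None
                         ) -> tuple[list[PairResolution], float]:
    """Resolution status of every accession pair under a marker subset.

    Returns the per-pair records and the resolved fraction over all pairs.
    An empty subset resolves nothing.
    """
    if subset is None:
        subset = list(matrix.marker_ids)
    sub = matrix.subset_markers(list(subset)) if list(subset) != matrix.marker_ids \
        else matrix
    n = matrix.n_accessions
    pairs = _pair_index(n)
    if not subset:
        res = [PairResolution(matrix.accession_ids[i], matrix.accession_ids[j],
                              False, []) for i, j in pairs]
        return res, 0.0
    diff = _difference_planes(sub)
    out = []
    for p, (i, j) in enumerate(pairs):
        wit = [sub.marker_ids[m] for m in np.where(diff[p])[0]]
        out.append(PairResolution(matrix.accession_ids[i], matrix.accession_ids[j],
                                  bool(wit), wit))
    frac = float(np.mean([r.resolved for r in out])) if out else 1.0
    return out, frac


def minimal_core_set(matrix: GenotypeMatrix,
                     resolvable_pairs_only: bool = True
                     ) -> tuple[list[str], pd.DataFrame, list[tuple[str, str]]]:
    """Greedy set-cover marker selection plus the identification-efficiency curve.

    The universe is the set of accession pairs resolvable by the FULL panel;
    pairs no marker resolves are reported separately (the panel's own
    duplicate groups) rather than failing the run. At each step the marker
    resolving the most still-unresolved pairs is added; ties break toward
    higher PIC, then lower (chromosome, position).

    Returns (ordered marker ids, efficiency-curve DataFrame, unresolvable pairs).
    """
    if matrix.n_markers == 0:
        raise ValueError("no markers")
    diff = _difference_planes(matrix)          # pairs x markers
    pairs = _pair_index(matrix.n_accessions)
    resolvable = diff.any(axis=1)
    unresolvable = [(matrix.accession_ids[i], matrix.accession_ids[j])
                    for p, (i, j) in enumerate(pairs) if not resolvable[p]]
    universe = np.where(resolvable)[0]
    cover = diff[universe]                      # resolvable pairs x markers
    pics = []
    for j in range(matrix.n_markers):
        try:
            pics.append(pic(allele_frequencies(matrix.calls[:, j].tolist())))
        except ValueError:
            pics.append(-1.0)
    order_key = [(-pics[j], matrix.positions[j][0], matrix.positions[j][1])
                 for j in range(matrix.n_markers)]

    uncovered = np.ones(len(universe), dtype=bool)
    selected: list[int] = []
    curve_rows = []
    total = len(universe)
    while uncovered.any():
        gains = cover[uncovered].sum(axis=0)
        gains[selected] = -1
        best_gain = gains.max()
        if best_gain <= 0:
            break  # cannot happen when universe is panel-resolvable
        cand = np.where(gains == best_gain)[0]
        best = min(cand, key=lambda j: order_key[j])
        selected.append(int(best))
        uncovered &= ~cover[:, best]
        curve_rows.append({
            "n_markers": len(selected),
            "marker": matrix.marker_ids[best],
            "pairs_resolved": int(total - uncovered.sum()),
            "resolved_fraction": (total - int(uncovered.sum())) / total if total else 1.0,
        })
    curve = pd.DataFrame(curve_rows)
    return [matrix.marker_ids[j] for j in selected], curve, unresolvable


def exact_minimal_set(matrix: GenotypeMatrix, max_markers: int = 20) -> list[str]:
    """Provably minimum-cardinality marker subset covering all resolvable pairs.

    Exhaustive by subset size; refuses panels larger than ``max_markers``.
    """
    m = matrix.n_markers
    if m > max_markers:
        raise ValueError(f"{m} markers exceed the exhaustive budget "
                         f"({max_markers}); use the greedy cover")
    diff = _difference_planes(matrix)
    resolvable = diff.any(axis=1)
    cover = diff[resolvable]
    if cover.shape[0] == 0:
        return []
    masks = []
    for j in range(m):
        mask = 0
        for p in np.where(cover[:, j])[0]:
            mask |= 1 << int(p)
        masks.append(mask)
    full = (1 << cover.shape[0]) - 1
    for size in range(1, m + 1):
        for combo in itertools.combinations(range(m), size):
            acc = 0
            for j in combo:
                acc |= masks[j]
            if acc == full:
                return [matrix.marker_ids[j] for j in combo]
    raise AssertionError("unreachable: full panel covers its own resolvable pairs")


def encode_fingerprints(matrix: GenotypeMatrix,
                        subset: Optional[Sequence[str]] = None) -> pd.DataFrame:
    """Numeric fingerprint codes (markers as rows, accessions as columns).

    AA=1 (yellow), CC=2 (green), GG=3 (blue), TT=4 (purple), heterozygous=5
    (grey), missing=6 (white). The encoding lumps all heterozygotes, so the
    underlying allele pair is not recoverable from code 5 alone.
    """
    sub = matrix.subset_markers(list(subset)) if subset is not None else matrix
    codes = np.empty(sub.calls.shape, dtype=int)
    for idx, call in np.ndenumerate(sub.calls):
        codes[idx] = encode_call(call)
    return pd.DataFrame(codes.T, index=pd.Index(sub.marker_ids, name="marker"),
                        columns=sub.accession_ids)


def encode_call(call: str) -> int:
    if call == MISSING:
        return MISSING_CODE
    if call[0] != call[1]:
        return HET_CODE
    code = CODE_MAP.get(call)
    if code is None:
        raise ValueError(f"homozygote for a non-ACGT allele: {call!r}")
    return code


def decode_class(code: int) -> str:
    """Genotype class of a fingerprint code: the homozygote, 'het' or 'missing'."""
    if code in (1, 2, 3, 4):
        return {1: "AA", 2: "CC", 3: "GG", 4: "TT"}[code]
    if code == HET_CODE:
        return "het"
    if code == MISSING_CODE:
        return "missing"
    raise ValueError(f"invalid fingerprint code {code}")


def fingerprint_heatmap(codes: pd.DataFrame, path: str | Path) -> None:
    """Render the fingerprint code matrix as a heatmap image.

    Rows are markers, columns are accessions; the colour legend is the
    standard six-class one (AA yellow, CC green, GG blue, TT purple,
    het grey, missing white).
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.colors import BoundaryNorm, ListedColormap
    from matplotlib.patches import Patch

    cmap = ListedColormap(["yellow", "green", "blue", "purple", "grey", "white"])
    norm = BoundaryNorm(np.arange(0.5, 7.5), cmap.N)
    fig, ax = plt.subplots(figsize=(max(6, codes.shape[1] / 12),
                                    max(3, codes.shape[0] / 4)))
    ax.imshow(codes.to_numpy(), aspect="auto", cmap=cmap, norm=norm,
              interpolation="nearest")
    ax.set_yticks(range(codes.shape[0]), codes.index, fontsize=6)
    ax.set_xlabel("accession")
    legend = [Patch(facecolor=CODE_COLORS[c], edgecolor="black",
                    label=f"{c}: {decode_class(c)}") for c in range(1, 7)]
    ax.legend(handles=legend, loc="upper left", bbox_to_anchor=(1.01, 1),
              fontsize=7, frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


@dataclass
class DuplicateReport:
    groups: list[list[str]]                      # components with >= 2 members
    non_clique_components: list[list[str]]       # flagged: compatibility not transitive
    singletons: int


def duplicate_groups(matrix: GenotypeMatrix) -> DuplicateReport:
    """Group accessions by missing-tolerant genotype equality.

    Two accessions are compatible when they agree at every mutually called
    locus. Compatibility is not transitive, so groups are the connected
    components of the compatibility graph; components that are not cliques
    are flagged.
    """
    codes = matrix.genotype_codes()
    n = matrix.n_accessions
    conflicts = np.zeros((n, n), dtype=np.int64)
    for jm in range(matrix.n_markers):
        c = codes[:, jm]
        called = c >= 0
        neq = (c[:, None] != c[None, :]) & called[:, None] & called[None, :]
        conflicts += neq
    compatible = conflicts == 0
    g = nx.Graph()
    g.add_nodes_from(range(n))
    iu, ju = np.where(np.triu(compatible, k=1))
    g.add_edges_from(zip(iu.tolist(), ju.tolist()))
    groups, flagged, singles = [], [], 0
    for comp in nx.connected_components(g):
        comp = sorted(comp)
        if len(comp) == 1:
            singles += 1
            continue
        members = [matrix.accession_ids[i] for i in comp]
        groups.append(members)
        size = len(comp)
        n_edges = g.subgraph(comp).number_of_edges()
        if n_edges < size * (size - 1) // 2:
            flagged.append(members)
    groups.sort(key=lambda ms: (-len(ms), ms))
    return DuplicateReport(groups, flagged, singles)
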