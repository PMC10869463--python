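"""Diploid genotype matrix: the central container for diversity statistics,
distances, fingerprinting and core-collection selection.

Genotypes are unphased two-letter strings over {A, C, G, T} with the alleles
stored in alphabetical order ("AG", never "GA"); missing calls are the
distinguished string ``"NN"``. The panel is assumed biallelic per marker —
at most two distinct alleles may be observed at a locus.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

MISSING = "NN"
VALID_BASES = frozenset("ACGT")


def canonical_call(call: str) -> str:
    """Return the call with alleles in alphabetical order ('GA' -> 'AG')."""
    if call == MISSING:
        return MISSING
    if len(call) != 2 or not set(call) <= VALID_BASES:
        raise ValueError(f"malformed diploid call {call!r}")
    return call if call[0] <= call[1] else call[1] + call[0]


@dataclass
class GenotypeMatrix:
    """Accessions x markers diploid calls with a missing-data mask.

    Parameters
    ----------
    accession_ids : list of str
    marker_ids : list of str
    positions : list of (chrom, pos) pairs, 1-based bp, one per marker
    calls : ndarray of shape (n_accessions, n_markers), dtype ``<U2``
    """

    accession_ids: list[str]
    marker_ids: list[str]
    positions: list[tuple[str, int]]
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype="<U2")
        n_acc, n_mark = self.calls.shape
        if len(self.accession_ids) != n_acc:
            raise ValueError("accession_ids length does not match calls")
        if len(self.marker_ids) != n_mark or len(self.positions) != n_mark:
            raise ValueError("marker metadata length does not match calls")
        # canonicalise het orientation once on construction
        flat = np.vectorize(canonical_call, otypes=["<U2"])
        if n_acc and n_mark:
            self.calls = flat(self.calls)

    # -- basic structure -------------------------------------------------

    @property
    def n_accessions(self) -> int:
        return self.calls.shape[0]

    @property
    def n_markers(self) -> int:
        return self.calls.shape[1]

    def missing_mask(self) -> np.ndarray:
        """Boolean (accessions x markers): True where the call is missing."""
        return self.calls == MISSING

    def het_mask(self) -> np.ndarray:
        """Boolean mask of heterozygous calls (missing counts as False)."""
        called = ~self.missing_mask()
        first = self.calls.view("U1").reshape(*self.calls.shape, 2)
        return called & (first[..., 0] != first[..., 1])

    def marker_alleles(self, j: int) -> list[str]:
        """Sorted distinct alleles observed at marker ``j`` (≤2 for a valid panel)."""
        col = self.calls[:, j]
        alleles = set()
        for call in col:
            if call != MISSING:
                alleles.update(call)
        out = sorted(alleles)
        if len(out) > 2:
            raise ValueError(f"marker {self.marker_ids[j]} has >2 alleles: {out}")
        return out

    def dosages(self) -> np.ndarray:
        """Alternate-allele dosage encoding, float (accessions x markers).

        Per marker the observed alleles are sorted and the dosage counts the
        second (alphabetically later) allele: 0, 1 or 2. Missing is NaN;
        monomorphic markers encode as all-zero.
        """
        out = np.full(self.calls.shape, np.nan)
        for j in range(self.n_markers):
            alleles = self.marker_alleles(j)
            alt = alleles[-1] if len(alleles) > 1 else None
            col = self.calls[:, j]
            called = col != MISSING
            if alt is None:
                out[called, j] = 0.0
                continue
            pairs = np.ascontiguousarray(col).view("U1").reshape(-1, 2)
            out[called, j] = (pairs[called] == alt).sum(axis=1)
        return out

    def genotype_codes(self) -> np.ndarray:
        """Integer genotype-class codes per cell; -1 for missing.

        Codes are only comparable within a marker (equal code <=> equal
        unordered genotype); used by fingerprinting and duplicate detection.
        """
        codes = np.full(self.calls.shape, -1, dtype=np.int64)
        for j in range(self.n_markers):
            col = self.calls[:, j]
            called = col != MISSING
            _, inv = np.unique(col[called], return_inverse=True)
            codes[called, j] = inv
        return codes

    # -- subsetting ------------------------------------------------------

    def subset_accessions(self, ids: list[str]) -> "GenotypeMatrix":
        index = {a: i for i, a in enumerate(self.accession_ids)}
        missing = [a for a in ids if a not in index]
        if missing:
            raise KeyError(f"unknown accessions: {missing[:5]}")
        rows = [index[a] for a in ids]
        return GenotypeMatrix(list(ids), list(self.marker_ids),
                              list(self.positions), self.calls[rows])

    def subset_markers(self, ids: list[str]) -> "GenotypeMatrix":
        index = {m: j for j, m in enumerate(self.marker_ids)}
        missing = [m for m in ids if m not in index]
        if missing:
            raise KeyError(f"unknown markers: {missing[:5]}")
        cols = [index[m] for m in ids]
        return GenotypeMatrix(list(self.accession_ids), list(ids),
                              [self.positions[j] for j in cols],
                              self.calls[:, cols])

    # -- I/O ---------------------------------------------------------------

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.calls, index=pd.Index(self.accession_ids, name="accession"),
                            columns=self.marker_ids)

    def to_csv(self, path: str | Path) -> None:
        """Write the genotype CSV dialect: accession column + one column per
        marker, two-letter genotype strings, ``NN`` for missing."""
        self.to_dataframe().to_csv(path)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame,
                       positions: list[tuple[str, int]] | None = None) -> "GenotypeMatrix":
        if positions is None:
            positions = [("unknown", j + 1) for j in range(df.shape[1])]
        return cls(list(df.index.astype(str)), list(df.columns.astype(str)),
                   positions, df.to_numpy(dtype="<U2"))

    @classmethod
    def from_csv(cls, path: str | Path,
                 positions: list[tuple[str, int]] | None = None) -> "GenotypeMatrix":
        df = pd.read_csv(path, index_col=0, dtype=str)
        if df.isna().any().any():
            bad = df[df.isna().any(axis=1)].index[0]
            raise ValueError(f"ragged or incomplete genotype row for accession {bad!r} in {path}")
        return cls.from_dataframe(df, positions)
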