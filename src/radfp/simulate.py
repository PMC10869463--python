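"""Synthetic genotype panels, annotated variant tables, gene models and
flanking sequences.

The genotype generator emulates a germplasm-panel design: ~356 diploid
accessions genotyped at 32 biallelic SNP markers spread over 9 chromosomes,
two admixed subpopulations, per-marker minor-allele frequencies spanning
0.125-0.482, no-call rates up to ~9%, and small groups of duplicate
accessions that are identical except for missing calls.

Model: ancestral allele frequencies are drawn uniformly from ``maf_range``;
subpopulation frequencies disperse around them by a Balding-Nichols Beta
draw with differentiation ``fst``; each accession gets Dirichlet admixture
proportions, and each of its two allele copies independently picks a source
subpopulation and then an allele (Hardy-Weinberg within the source
subpopulation). Missing calls are injected independently per cell at a
per-marker rate. Duplicate groups are literal copies of a base accession
with extra independent missing calls and no genotype changes.

All randomness flows from a single integer seed through deterministic
sub-streams, so identical configurations give bit-identical output.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .genotypes import GenotypeMatrix, MISSING
from .variants import GeneModel, VariantRecord

BASES = np.array(list("ACGT"))


@dataclass
class SimulationConfig:
    """Study-design parameters for the synthetic genotype panel."""

    n_accessions: int = 356
    n_markers: int = 32
    n_chromosomes: int = 9
    chrom_length: int = 50_000_000
    k_subpops: int = 2
    admixture_alpha: float = 0.5
    maf_range: tuple[float, float] = (0.125, 0.482)
    fst: float = 0.15
    missing_rate_range: tuple[float, float] = (0.0, 0.09)
    n_duplicate_groups: int = 1
    duplicate_group_size: int = 7
    duplicate_missing_rate: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_accessions < 1 or self.n_markers < 1 or self.n_chromosomes < 1:
            raise ValueError("non-positive dimensions")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError(f"maf_range {self.maf_range} outside (0, 0.5]")
        mlo, mhi = self.missing_rate_range
        if not (0 <= mlo <= mhi < 1):
            raise ValueError(f"missing_rate_range {self.missing_rate_range} outside [0, 1)")
        if not 0 <= self.fst < 1:
            raise ValueError(f"fst {self.fst} outside [0, 1)")
        n_dups = self.n_duplicate_groups * max(self.duplicate_group_size - 1, 0)
        if self.n_duplicate_groups and self.duplicate_group_size < 2:
            raise ValueError("duplicate_group_size must be >= 2 when groups are requested")
        if self.n_accessions - n_dups < self.n_duplicate_groups:
            raise ValueError("too many duplicate accessions for n_accessions")


@dataclass
class TruthRecord:
    """Ground truth behind a simulated panel, for parameter-recovery tests."""

    subpop_assignment: list[int]
    admixture_proportions: np.ndarray            # accessions x k
    subpop_allele_freqs: np.ndarray              # k x markers (alt-allele freq)
    ancestral_freqs: np.ndarray                  # markers
    duplicate_groups: list[list[str]]
    marker_missing_rates: np.ndarray
    ref_alleles: list[str] = field(default_factory=list)
    alt_alleles: list[str] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        obj = {
            "subpop_assignment": self.subpop_assignment,
            "admixture_proportions": self.admixture_proportions.tolist(),
            "subpop_allele_freqs": self.subpop_allele_freqs.tolist(),
            "ancestral_freqs": self.ancestral_freqs.tolist(),
            "duplicate_groups": self.duplicate_groups,
            "marker_missing_rates": self.marker_missing_rates.tolist(),
            "ref_alleles": self.ref_alleles,
            "alt_alleles": self.alt_alleles,
        }
        Path(path).write_text(json.dumps(obj, indent=1))


def _substream(seed: int, label: str) -> np.random.Generator:
    """Deterministic named sub-stream of the global seed."""
    h = np.frombuffer(label.encode(), dtype=np.uint8).sum()
    return np.random.default_rng(np.random.SeedSequence([seed, int(h)]))


def simulate_genotypes(config: SimulationConfig) -> tuple[GenotypeMatrix, TruthRecord]:
    """Simulate a diploid biallelic genotype panel with admixture and duplicates."""
    rng = _substream(config.seed, "genotypes")
    m, k = config.n_markers, config.k_subpops
    n_extra = config.n_duplicate_groups * (config.duplicate_group_size - 1)
    n_base = config.n_accessions - n_extra

    # marker placement: markers spread over chromosomes round-robin
    chroms = [f"Chr{1 + j % config.n_chromosomes}" for j in range(m)]
    positions = sorted(
        zip(chroms, rng.integers(1, config.chrom_length, size=m).tolist()))
    marker_ids = [f"{c}-{i + 1:02d}" for i, (c, _) in enumerate(positions)]

    # ancestral frequencies and allele letters
    anc = rng.uniform(config.maf_range[0], config.maf_range[1], size=m)
    allele_idx = np.array([rng.choice(4, size=2, replace=False) for _ in range(m)])
    ref = BASES[allele_idx[:, 0]]
    alt = BASES[allele_idx[:, 1]]

    # Balding-Nichols subpopulation frequencies
    if config.fst > 0 and k > 1:
        a = anc * (1 - config.fst) / config.fst
        b = (1 - anc) * (1 - config.fst) / config.fst
        sub_freqs = rng.beta(a, b, size=(k, m))
        sub_freqs = np.clip(sub_freqs, 1e-6, 1 - 1e-6)
    else:
        sub_freqs = np.tile(anc, (k, 1))

    admix = rng.dirichlet([config.admixture_alpha] * k, size=n_base)
    # per allele copy: source subpop, then allele
    calls = np.empty((n_base, m), dtype="<U2")
    alt_freq = sub_freqs  # alt allele frequency per subpop
    for copy in range(2):
        src = np.array([rng.choice(k, size=m, p=admix[i]) for i in range(n_base)])
        p_alt = alt_freq[src, np.arange(m)[None, :]]
        is_alt = rng.random((n_base, m)) < p_alt
        letters = np.where(is_alt, alt[None, :], ref[None, :])
        if copy == 0:
            first = letters
        else:
            second = letters
    lo = np.where(first <= second, first, second)
    hi = np.where(first <= second, second, first)
    calls = np.char.add(lo, hi)

    # missing calls, independent per cell at a per-marker rate
    miss_rates = rng.uniform(config.missing_rate_range[0],
                             config.missing_rate_range[1], size=m)
    miss = rng.random((n_base, m)) < miss_rates[None, :]
    calls[miss] = MISSING

    accession_ids = [f"Rs{i + 1:03d}" for i in range(n_base)]
    subpop = admix.argmax(axis=1).tolist()

    # duplicate groups: copy a base accession, add independent extra missing
    dup_groups: list[list[str]] = []
    if config.n_duplicate_groups:
        base_choices = rng.choice(n_base, size=config.n_duplicate_groups, replace=False)
        extra_rows, extra_ids = [], []
        next_id = n_base + 1
        for g, b in enumerate(base_choices):
            group = [accession_ids[b]]
            for _ in range(config.duplicate_group_size - 1):
                row = calls[b].copy()
                extra_miss = rng.random(m) < config.duplicate_missing_rate
                row[extra_miss] = MISSING
                extra_rows.append(row)
                aid = f"Rs{next_id:03d}"
                next_id += 1
                extra_ids.append(aid)
                group.append(aid)
                subpop.append(subpop[b])
            dup_groups.append(group)
        if extra_rows:
            calls = np.vstack([calls, np.array(extra_rows)])
            accession_ids += extra_ids
            admix = np.vstack([admix] + [admix[b][None, :]
                                         for b in base_choices
                                         for _ in range(config.duplicate_group_size - 1)])

    matrix = GenotypeMatrix(accession_ids, marker_ids, positions, calls)
    truth = TruthRecord(subpop, admix, sub_freqs, anc, dup_groups, miss_rates,
                        ref.tolist(), alt.tolist())
    return matrix, truth


# -- annotated variant tables ------------------------------------------------

PLANTABLE_RULES = ("QD", "MQ", "MQRankSum", "ReadPosRankSum", "isolation",
                   "max-alleles", "max-missing", "mac", "minQ", "maf", "mean-DP")


def simulate_variant_table(n_sites: int, seed: int = 0,
                           fail_fraction_per_rule: Optional[dict[str, float]] = None,
                           ) -> tuple[list[VariantRecord], dict[str, np.ndarray]]:
    """Emit annotated variant records with controlled planted rule violations.

    Returns the records plus a label dict: rule name -> boolean array marking
    the records planted to violate that rule. Records not planted for a rule
    are safely inside its passing region, so a correct filter recovers the
    planted labels exactly.
    """
    fail = dict(fail_fraction_per_rule or {})
    unknown = set(fail) - set(PLANTABLE_RULES)
    if unknown:
        raise ValueError(f"unknown rules: {sorted(unknown)}")
    for r, f in fail.items():
        if not 0 <= f <= 1:
            raise ValueError(f"fail fraction for {r} outside [0,1]: {f}")
    rng = _substream(seed, "variants")
    n_samples = 356

    # safe annotation values
    qd = rng.uniform(10, 35, n_sites)
    mq = rng.uniform(50, 60, n_sites)
    mqrs = rng.normal(0, 2, n_sites).clip(-10, 10)
    rprs = rng.normal(0, 2, n_sites).clip(-6, 6)
    qual = rng.uniform(100, 1000, n_sites)
    dp = rng.uniform(5, 50, n_sites)
    maf = rng.uniform(0.10, 0.5, n_sites)
    missing = rng.uniform(0.0, 0.3, n_sites)
    n_alt = np.ones(n_sites, dtype=int)

    labels = {r: np.zeros(n_sites, dtype=bool) for r in PLANTABLE_RULES}

    def plant(rule: str, n: int) -> np.ndarray:
        k = int(round(fail.get(rule, 0.0) * n_sites))
        idx = rng.choice(n_sites, size=k, replace=False) if k else np.array([], dtype=int)
        labels[rule][idx] = True
        return idx

    for rule, arr, lo_hi in [("QD", qd, (0.1, 1.9)), ("MQ", mq, (10, 39.5)),
                             ("MQRankSum", mqrs, (-20, -12.6)),
                             ("ReadPosRankSum", rprs, (-15, -8.1)),
                             ("minQ", qual, (1, 29.5)), ("mean-DP", dp, (0.1, 1.1)),
                             ("maf", maf, (0.005, 0.045)),
                             ("max-missing", missing, (0.51, 0.9))]:
        idx = plant(rule, n_sites)
        arr[idx] = rng.uniform(*lo_hi, size=idx.size)
    n_alt[plant("max-alleles", n_sites)] = 2

    # mac derived from maf so the two rules stay consistent; plant mac<3 last
    mac = np.maximum((maf * 2 * n_samples).astype(int), 3)
    mac_idx = plant("mac", n_sites)
    if mac_idx.size:
        mac[mac_idx] = rng.integers(0, 3, size=mac_idx.size)
        maf[mac_idx] = mac[mac_idx] / (2 * n_samples)
        labels["maf"][mac_idx] = maf[mac_idx] < 0.05  # planting mac drags maf down too

    # positions: default spacing is generous; isolation failures are planted
    # as consecutive runs 30 bp apart (pairs, plus one triple if the count is odd)
    iso_k = int(round(fail.get("isolation", 0.0) * n_sites))
    iso_members = rng.choice(n_sites, size=iso_k, replace=False) if iso_k else np.array([], dtype=int)
    labels["isolation"][iso_members] = True
    gaps = rng.integers(200, 1000, size=n_sites)
    order = rng.permutation(n_sites)
    # group planted-isolation records into adjacent runs in the laid-out order
    iso_set = set(iso_members.tolist())
    laid = [i for i in order if i not in iso_set]
    iso_list = [i for i in order if i in iso_set]
    runs: list[list[int]] = []
    while iso_list:
        take = 3 if len(iso_list) % 2 == 1 and len(runs) == 0 and len(iso_list) >= 3 else 2
        if len(iso_list) == 1:  # lone site cannot fail isolation; pair impossible
            raise ValueError("isolation fail fraction yields a single site; need >= 2")
        runs.append(iso_list[:take])
        iso_list = iso_list[take:]
    layout: list[tuple[int, int]] = []  # (record index, gap before it)
    run_iter = iter(runs)
    for i, rec_i in enumerate(laid):
        layout.append((rec_i, int(gaps[rec_i])))
        if (i % max(len(laid) // (len(runs) + 1), 1) == 0) and runs:
            try:
                run = next(run_iter)
            except StopIteration:
                continue
            for j, rr in enumerate(run):
                layout.append((rr, 30 if j > 0 else int(gaps[rr])))
            runs_left = None
    # append any runs not yet placed
    for run in run_iter:
        for j, rr in enumerate(run):
            layout.append((rr, 30 if j > 0 else int(gaps[rr])))

    pos = np.zeros(n_sites, dtype=int)
    cur = 1000
    for rec_i, gap in layout:
        cur += gap
        pos[rec_i] = cur

    # substitution classes are transition-enriched (Ts/Tv ~ 1.17, the typical
    # plant-genome spectrum): each of the 4 transition classes ~13.5%, each
    # of the 8 transversion classes ~5.8%
    ts_fraction = 1.17 / (1 + 1.17)
    classes = [("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")]
    class_p = [ts_fraction / 4] * 4
    for r in "ACGT":
        for a in "ACGT":
            if r != a and (r, a) not in classes:
                classes.append((r, a))
                class_p.append((1 - ts_fraction) / 8)
    class_draw = rng.choice(len(classes), size=n_sites, p=class_p)

    records = []
    for i in range(n_sites):
        ref_b, alt_b = classes[class_draw[i]]
        alts = [alt_b]
        if n_alt[i] > 1:  # triallelic sites planted for the max-alleles rule
            extra = next(b for b in "ACGT" if b not in (ref_b, alt_b))
            alts.append(extra)
        records.append(VariantRecord(
            chrom="Chr1", pos=int(pos[i]), ref_allele=ref_b,
            alt_alleles=tuple(alts),
            qd=float(qd[i]), mq=float(mq[i]), mq_rank_sum=float(mqrs[i]),
            read_pos_rank_sum=float(rprs[i]), qual=float(qual[i]),
            mean_dp=float(dp[i]), mac=int(mac[i]), maf=float(min(maf[i], 0.5)),
            missing_fraction=float(missing[i]), site_id=f"site{i:05d}"))
    return records, labels


# -- gene models --------------------------------------------------------------

def simulate_gene_models(n_genes: int, chrom_length: int, seed: int = 0,
                         chrom: str = "Chr1") -> list[GeneModel]:
    """Non-pathological gene models with exons, introns, UTRs and strand.

    Genes are spaced at least 2.5 kb apart so that their 1-kb flanking
    regions never overlap a neighbouring gene.
    """
    rng = _substream(seed, "genes")
    genes: list[GeneModel] = []
    cursor = 3000
    for gi in range(n_genes):
        n_exons = int(rng.integers(1, 5))
        exon_lens = rng.integers(150, 400, size=n_exons)
        intron_lens = rng.integers(200, 800, size=max(n_exons - 1, 0))
        start = cursor
        exons = []
        p = start
        for k in range(n_exons):
            exons.append((p, p + int(exon_lens[k]) - 1))
            p = exons[-1][1] + 1
            if k < n_exons - 1:
                p += int(intron_lens[k])
        end = exons[-1][1]
        if end + 3500 > chrom_length:
            break
        strand = "+" if rng.random() < 0.5 else "-"
        u5 = int(rng.integers(40, 100))
        u3 = int(rng.integers(40, 100))
        first, last = exons[0], exons[-1]
        if strand == "+":
            utr5 = [(first[0], min(first[0] + u5 - 1, first[1]))]
            utr3 = [(max(last[1] - u3 + 1, last[0]), last[1])]
        else:
            utr5 = [(max(last[1] - u5 + 1, last[0]), last[1])]
            utr3 = [(first[0], min(first[0] + u3 - 1, first[1]))]
        genes.append(GeneModel(f"gene{gi + 1:04d}", chrom, start, end, strand,
                               exons, utr5, utr3))
        cursor = end + int(rng.integers(2500, 6000))
    return genes


# -- flanking sequences -------------------------------------------------------

IUPAC = {frozenset("AG"): "R", frozenset("CT"): "Y", frozenset("GC"): "S",
         frozenset("AT"): "W", frozenset("GT"): "K", frozenset("AC"): "M"}


def simulate_flanks(n_sites: int, seed: int = 0, flank: int = 100,
                    gc_range: tuple[float, float] = (0.3, 0.55)
                    ) -> list[tuple[str, str, str, str, str]]:
    """Random flanked SNP sites: (site_id, upstream, ref, alt, downstream).

    GC content of the flanks is drawn per site from ``gc_range``.
    """
    rng = _substream(seed, "flanks")
    out = []
    for i in range(n_sites):
        gc = rng.uniform(*gc_range)
        p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
        up = "".join(rng.choice(list("ACGT"), size=flank, p=p))
        down = "".join(rng.choice(list("ACGT"), size=flank, p=p))
        ref, alt = rng.choice(list("ACGT"), size=2, replace=False)
        out.append((f"site{i:04d}", up, str(ref), str(alt), down))
    return out


def write_flanks_fasta(flanks: Sequence[tuple[str, str, str, str, str]],
                       path: str | Path) -> None:
    """FASTA of flanked sites, SNP as an IUPAC ambiguity code at position 101."""
    lines = []
    for site_id, up, ref, alt, down in flanks:
        amb = IUPAC[frozenset((ref, alt))]
        lines.append(f">{site_id} ref={ref} alt={alt}")
        lines.append(up + amb + down)
    Path(path).write_text("\n".join(lines) + "\n")
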