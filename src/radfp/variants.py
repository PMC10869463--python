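"""SNP selection cascade and variant summaries.

Three-stage cascade, in fixed order:

1. ``hard_filter`` — GATK-style hard annotation filter. A record fails iff a
   *present* annotation violates QD < 2.0, MQ < 40.0, MQRankSum < -12.5 or
   ReadPosRankSum < -8.0 (strict inequalities; absent annotations never fail).
2. ``isolation_filter`` — a site passes iff no other variant lies within
   ±50 bp on the same chromosome, regardless of that neighbour's own filter
   status (primer design cares about physical sequence context).
3. ``popgen_filter`` — VCFtools-style population filter: biallelic,
   missing fraction ≤ 0.5, minor allele count ≥ 3, site quality ≥ 30,
   MAF ≥ 0.05 and mean depth ≥ 1.2 (inclusive bounds, matching VCFtools'
   documented --maf/--minQ/--mac/--max-missing/--min-meanDP semantics).

Plus the variant-type spectrum (Ts/Tv) and genomic-context annotation of
sites against gene models.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
from intervaltree import IntervalTree

# GATK-style hard-filter thresholds (fail on strict inequality)
HARD_FILTER_THRESHOLDS = {
    "QD": 2.0,
    "MQ": 40.0,
    "MQRankSum": -12.5,
    "ReadPosRankSum": -8.0,
}

ISOLATION_WINDOW = 50  # bp on each side

# VCFtools-style bounds (inclusive)
POPGEN_THRESHOLDS = {
    "max-missing": 0.5,   # missing_fraction <= 0.5
    "mac": 3,             # minor allele count >= 3
    "minQ": 30.0,         # QUAL >= 30
    "maf": 0.05,          # MAF >= 0.05
    "mean-DP": 1.2,       # mean depth >= 1.2
}

TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}
BASES = ("A", "C", "G", "T")
SPECTRUM_CLASSES = [f"{r}/{a}" for r in BASES for a in BASES if r != a]


@dataclass
class VariantRecord:
    """One variant site with QC annotations.

    Annotation fields are optional; an absent annotation can never fail a
    filter (matching GATK hard-filter behaviour on missing INFO keys).
    """

    chrom: str
    pos: int
    ref_allele: str
    alt_alleles: tuple[str, ...]
    qd: Optional[float] = None
    mq: Optional[float] = None
    mq_rank_sum: Optional[float] = None
    read_pos_rank_sum: Optional[float] = None
    qual: Optional[float] = None
    mean_dp: Optional[float] = None
    mac: Optional[int] = None
    maf: Optional[float] = None
    missing_fraction: Optional[float] = None
    site_id: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.chrom or self.pos is None or self.pos < 1:
            raise ValueError(f"malformed record: chrom={self.chrom!r} pos={self.pos!r}")
        if not self.ref_allele or not self.alt_alleles:
            raise ValueError(f"malformed record at {self.chrom}:{self.pos}: missing alleles")
        if self.maf is not None and not 0 <= self.maf <= 0.5:
            raise ValueError(f"MAF {self.maf} outside [0, 0.5] at {self.chrom}:{self.pos}")
        if self.missing_fraction is not None and not 0 <= self.missing_fraction <= 1:
            raise ValueError(f"missing_fraction outside [0,1] at {self.chrom}:{self.pos}")

    @property
    def is_snp(self) -> bool:
        return len(self.ref_allele) == 1 and all(len(a) == 1 for a in self.alt_alleles)

    @property
    def n_alleles(self) -> int:
        return 1 + len(self.alt_alleles)

    @property
    def key(self) -> tuple[str, int]:
        return (self.chrom, self.pos)


@dataclass
class FilterReport:
    """Per-record verdicts for one filter stage.

    ``verdicts`` maps record key -> None (pass) or the name of the first
    failing rule.
    """

    stage: str
    verdicts: dict[tuple[str, int], Optional[str]]
    n_input: int
    n_pass: int

    def passing(self, records: Sequence[VariantRecord]) -> list[VariantRecord]:
        return [r for r in records if self.verdicts[r.key] is None]

    def failures_by_rule(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for rule in self.verdicts.values():
            if rule is not None:
                out[rule] = out.get(rule, 0) + 1
        return out


def hard_filter(records: Sequence[VariantRecord]) -> FilterReport:
    """GATK-style hard filter; fails on strict inequality of present annotations."""
    verdicts: dict[tuple[str, int], Optional[str]] = {}
    for rec in records:
        rule = None
        if rec.qd is not None and rec.qd < HARD_FILTER_THRESHOLDS["QD"]:
            rule = "QD"
        elif rec.mq is not None and rec.mq < HARD_FILTER_THRESHOLDS["MQ"]:
            rule = "MQ"
        elif rec.mq_rank_sum is not None and rec.mq_rank_sum < HARD_FILTER_THRESHOLDS["MQRankSum"]:
            rule = "MQRankSum"
        elif (rec.read_pos_rank_sum is not None
              and rec.read_pos_rank_sum < HARD_FILTER_THRESHOLDS["ReadPosRankSum"]):
            rule = "ReadPosRankSum"
        verdicts[rec.key] = rule
    n_pass = sum(v is None for v in verdicts.values())
    return FilterReport("hard", verdicts, len(records), n_pass)


def isolation_filter(records: Sequence[VariantRecord],
                     window: int = ISOLATION_WINDOW) -> FilterReport:
    """Keep sites with no other variant within ±window bp on the same chromosome.

    All supplied variants count as neighbours, whatever their own filter
    status. Duplicate (chrom, pos) pairs are ambiguous and rejected.
    """
    keys = [r.key for r in records]
    if len(set(keys)) != len(keys):
        seen, dup = set(), None
        for k in keys:
            if k in seen:
                dup = k
                break
            seen.add(k)
        raise ValueError(f"duplicate variant site {dup[0]}:{dup[1]}")
    by_chrom: dict[str, list[int]] = {}
    for r in records:
        by_chrom.setdefault(r.chrom, []).append(r.pos)
    verdicts: dict[tuple[str, int], Optional[str]] = {}
    for chrom, positions in by_chrom.items():
        pos = np.array(sorted(positions))
        gap_left = np.diff(pos, prepend=pos[0] - (window + 1) * 2)
        gap_right = np.diff(pos, append=pos[-1] + (window + 1) * 2)
        isolated = (gap_left > window) & (gap_right > window)
        for p, ok in zip(pos, isolated):
            verdicts[(chrom, int(p))] = None if ok else "isolation"
    n_pass = sum(v is None for v in verdicts.values())
    return FilterReport("isolation", verdicts, len(records), n_pass)


def popgen_filter(records: Sequence[VariantRecord]) -> FilterReport:
    """VCFtools-style filter: biallelic, missingness, MAC, QUAL, MAF, mean depth."""
    verdicts: dict[tuple[str, int], Optional[str]] = {}
    for rec in records:
        rule = None
        if rec.n_alleles != 2:
            rule = "max-alleles" if rec.n_alleles > 2 else "min-alleles"
        elif rec.missing_fraction is not None and rec.missing_fraction > POPGEN_THRESHOLDS["max-missing"]:
            rule = "max-missing"
        elif rec.mac is not None and rec.mac < POPGEN_THRESHOLDS["mac"]:
            rule = "mac"
        elif rec.qual is not None and rec.qual < POPGEN_THRESHOLDS["minQ"]:
            rule = "minQ"
        elif rec.maf is not None and rec.maf < POPGEN_THRESHOLDS["maf"]:
            rule = "maf"
        elif rec.mean_dp is not None and rec.mean_dp < POPGEN_THRESHOLDS["mean-DP"]:
            rule = "mean-DP"
        verdicts[rec.key] = rule
    n_pass = sum(v is None for v in verdicts.values())
    return FilterReport("popgen", verdicts, len(records), n_pass)


def filter_cascade(records: Sequence[VariantRecord],
                   window: int = ISOLATION_WINDOW
                   ) -> tuple[list[VariantRecord], list[FilterReport]]:
    """Run hard -> isolation -> popgen; survivors are monotone non-increasing.

    The isolation stage sees the *full* input as neighbours but only
    hard-filter survivors are candidates for passing onward.
    """
    hard = hard_filter(records)
    survivors = hard.passing(records)
    iso_all = isolation_filter(records, window=window)
    iso_verdicts = {r.key: iso_all.verdicts[r.key] for r in survivors}
    iso = FilterReport("isolation", iso_verdicts, len(survivors),
                       sum(v is None for v in iso_verdicts.values()))
    survivors = iso.passing(survivors)
    pop = popgen_filter(survivors)
    survivors = pop.passing(survivors)
    return survivors, [hard, iso, pop]


# -- variant-type spectrum ------------------------------------------------

def variant_spectrum(records: Sequence[VariantRecord]) -> dict:
    """Counts/fractions of the 12 REF/ALT single-base classes and the Ts/Tv ratio.

    Non-SNP records are skipped and counted. Multiallelic SNPs contribute one
    observation per REF/ALT pair.
    """
    counts = {c: 0 for c in SPECTRUM_CLASSES}
    skipped = 0
    for rec in records:
        if not rec.is_snp:
            skipped += 1
            continue
        for alt in rec.alt_alleles:
            key = f"{rec.ref_allele}/{alt}"
            if key in counts:
                counts[key] += 1
    ts = sum(n for c, n in counts.items() if tuple(c.split("/")) in TRANSITIONS)
    tv = sum(counts.values()) - ts
    total = sum(counts.values())
    if tv == 0:
        ts_tv = float("inf") if ts > 0 else float("nan")
        warnings.warn("no transversions observed; Ts/Tv undefined (reported as inf)")
    else:
        ts_tv = ts / tv
    fractions = {c: (n / total if total else 0.0) for c, n in counts.items()}
    return {"counts": counts, "fractions": fractions, "transitions": ts,
            "transversions": tv, "ts_tv": ts_tv, "skipped_non_snp": skipped}


# -- gene models and genomic context ---------------------------------------

@dataclass
class GeneModel:
    """A gene with exon structure; 1-based closed intervals, GFF3 convention."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str  # '+' or '-'
    exons: list[tuple[int, int]]
    utr5: list[tuple[int, int]] = field(default_factory=list)
    utr3: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for s, e in [(self.start, self.end), *self.exons, *self.utr5, *self.utr3]:
            if e < s:
                raise ValueError(f"feature with end < start in gene {self.gene_id}: ({s},{e})")
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r} for {self.gene_id}")
        self.exons = sorted(self.exons)

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end

    @property
    def tts(self) -> int:
        return self.end if self.strand == "+" else self.start


CONTEXT_PRECEDENCE = ["splice_junction", "utr5", "utr3", "exonic", "intronic",
                      "upstream_1kb", "downstream_1kb", "intergenic"]

SPLICE_WINDOW = 2       # bp around internal exon-intron boundaries
FLANK_WINDOW = 1000     # upstream/downstream of TSS/TTS


def _gene_categories(gene: GeneModel, pos: int) -> set[str]:
    cats: set[str] = set()
    in_gene = gene.start <= pos <= gene.end
    if in_gene:
        # splice junctions: internal exon boundaries only
        internal = []
        for k, (s, e) in enumerate(gene.exons):
            if k > 0:
                internal.append(s)   # acceptor side
            if k < len(gene.exons) - 1:
                internal.append(e)   # donor side
        if any(abs(pos - b) <= SPLICE_WINDOW for b in internal):
            cats.add("splice_junction")
        if any(s <= pos <= e for s, e in gene.utr5):
            cats.add("utr5")
        if any(s <= pos <= e for s, e in gene.utr3):
            cats.add("utr3")
        if any(s <= pos <= e for s, e in gene.exons):
            cats.add("exonic")
        else:
            cats.add("intronic")
    else:
        if gene.strand == "+":
            if gene.start - FLANK_WINDOW <= pos < gene.start:
                cats.add("upstream_1kb")
            if gene.end < pos <= gene.end + FLANK_WINDOW:
                cats.add("downstream_1kb")
        else:
            if gene.end < pos <= gene.end + FLANK_WINDOW:
                cats.add("upstream_1kb")
            if gene.start - FLANK_WINDOW <= pos < gene.start:
                cats.add("downstream_1kb")
    return cats


def annotate_context(records: Sequence[VariantRecord],
                     genes: Sequence[GeneModel]) -> dict:
    """Assign each site exactly one genomic-context category.

    Precedence when a site hits several features (possibly of different
    genes): splice_junction > UTR > exonic > intronic > upstream_1kb >
    downstream_1kb > intergenic.
    """
    trees: dict[str, IntervalTree] = {}
    for g in genes:
        tree = trees.setdefault(g.chrom, IntervalTree())
        # pad by flank window so near-gene sites are retrieved too
        tree.addi(g.start - FLANK_WINDOW, g.end + FLANK_WINDOW + 1, g)
    assignments: dict[tuple[str, int], str] = {}
    for rec in records:
        cats: set[str] = set()
        tree = trees.get(rec.chrom)
        if tree is not None:
            for iv in tree.at(rec.pos):
                cats |= _gene_categories(iv.data, rec.pos)
        chosen = "intergenic"
        for cat in CONTEXT_PRECEDENCE:
            if cat in cats:
                chosen = cat
                break
        assignments[rec.key] = chosen
    counts = {c: 0 for c in CONTEXT_PRECEDENCE}
    for cat in assignments.values():
        counts[cat] += 1
    n = len(assignments)
    fractions = {c: (v / n if n else 0.0) for c, v in counts.items()}
    return {"assignments": assignments, "counts": counts, "fractions": fractions}


# -- VCF / GFF3 I/O ---------------------------------------------------------

VCF_HEADER = """##fileformat=VCFv4.2
##INFO=<ID=QD,Number=1,Type=Float,Description="Quality by depth">
##INFO=<ID=MQ,Number=1,Type=Float,Description="RMS mapping quality">
##INFO=<ID=MQRankSum,Number=1,Type=Float,Description="Mapping-quality rank-sum">
##INFO=<ID=ReadPosRankSum,Number=1,Type=Float,Description="Read-position rank-sum">
##INFO=<ID=MEANDP,Number=1,Type=Float,Description="Mean depth across samples">
##INFO=<ID=AC,Number=A,Type=Integer,Description="Alternate allele count">
##INFO=<ID=AN,Number=1,Type=Integer,Description="Allele number">
##INFO=<ID=FMISS,Number=1,Type=Float,Description="Fraction of samples uncalled">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO
"""


def write_vcf(records: Sequence[VariantRecord], path: str | Path,
              contigs: Sequence[str] | None = None) -> None:
    """Write records as a minimal sites-only VCF v4.2."""
    lines = ["##fileformat=VCFv4.2"]
    if contigs:
        lines += [f"##contig=<ID={c}>" for c in contigs]
    lines += VCF_HEADER.strip().split("\n")[1:]
    an = 712  # 2 x 356 nominal; only AC/AN ratio is consumed downstream
    for rec in sorted(records, key=lambda r: (r.chrom, r.pos)):
        info = []
        for key, val in [("QD", rec.qd), ("MQ", rec.mq), ("MQRankSum", rec.mq_rank_sum),
                         ("ReadPosRankSum", rec.read_pos_rank_sum), ("MEANDP", rec.mean_dp),
                         ("FMISS", rec.missing_fraction)]:
            if val is not None:
                info.append(f"{key}={val:.6g}")
        if rec.mac is not None:
            info.append(f"AC={rec.mac}")
            info.append(f"AN={an}")
        qual = f"{rec.qual:.6g}" if rec.qual is not None else "."
        lines.append("\t".join([rec.chrom, str(rec.pos), rec.site_id or ".",
                                rec.ref_allele, ",".join(rec.alt_alleles),
                                qual, ".", ";".join(info) or "."]))
    Path(path).write_text("\n".join(lines) + "\n")


def read_vcf(path: str | Path) -> list[VariantRecord]:
    """Read a sites-only VCF written by :func:`write_vcf` (or compatible)."""
    import pysam

    records = []
    with pysam.VariantFile(str(path)) as vf:
        for v in vf:
            info = dict(v.info)
            ac = info.get("AC")
            if isinstance(ac, tuple):
                ac = ac[0]
            an = info.get("AN")
            maf = None
            if ac is not None and an:
                f = ac / an
                maf = min(f, 1 - f)
            records.append(VariantRecord(
                chrom=v.chrom, pos=v.pos, ref_allele=v.ref,
                alt_alleles=tuple(v.alts or ()),
                qd=info.get("QD"), mq=info.get("MQ"),
                mq_rank_sum=info.get("MQRankSum"),
                read_pos_rank_sum=info.get("ReadPosRankSum"),
                qual=v.qual, mean_dp=info.get("MEANDP"),
                mac=ac, maf=maf, missing_fraction=info.get("FMISS"),
                site_id=v.id))
    return records


def write_gff3(genes: Sequence[GeneModel], path: str | Path) -> None:
    lines = ["##gff-version 3"]
    for g in genes:
        col9 = f"ID={g.gene_id}"
        lines.append("\t".join([g.chrom, "radfp", "gene", str(g.start), str(g.end),
                                ".", g.strand, ".", col9]))
        mrna = f"{g.gene_id}.t1"
        lines.append("\t".join([g.chrom, "radfp", "mRNA", str(g.start), str(g.end),
                                ".", g.strand, ".", f"ID={mrna};Parent={g.gene_id}"]))
        for kind, ivs in [("exon", g.exons), ("five_prime_UTR", g.utr5),
                          ("three_prime_UTR", g.utr3)]:
            for k, (s, e) in enumerate(ivs, 1):
                lines.append("\t".join([g.chrom, "radfp", kind, str(s), str(e), ".",
                                        g.strand, ".", f"ID={mrna}.{kind}{k};Parent={mrna}"]))
    Path(path).write_text("\n".join(lines) + "\n")


def read_gff3(path: str | Path) -> list[GeneModel]:
    """Parse GFF3 gene/exon/UTR features into GeneModel records."""
    genes: dict[str, GeneModel] = {}
    mrna_parent: dict[str, str] = {}
    rows = []
    for line in Path(path).read_text().splitlines():
        if not line or line.startswith("#"):
            continue
        f = line.split("\t")
        if len(f) != 9:
            raise ValueError(f"malformed GFF3 line: {line!r}")
        attrs = dict(kv.split("=", 1) for kv in f[8].split(";") if "=" in kv)
        rows.append((f[0], f[2], int(f[3]), int(f[4]), f[6], attrs))
    for chrom, kind, start, end, strand, attrs in rows:
        if end < start:
            raise ValueError(f"GFF feature with end < start: {attrs.get('ID')}")
        if kind == "gene":
            genes[attrs["ID"]] = GeneModel(attrs["ID"], chrom, start, end, strand, [])
        elif kind == "mRNA":
            mrna_parent[attrs["ID"]] = attrs["Parent"]
    for chrom, kind, start, end, strand, attrs in rows:
        if kind in ("exon", "five_prime_UTR", "three_prime_UTR"):
            gene_id = mrna_parent.get(attrs.get("Parent", ""), attrs.get("Parent", ""))
            g = genes.get(gene_id)
            if g is None:
                continue
            {"exon": g.exons, "five_prime_UTR": g.utr5,
             "three_prime_UTR": g.utr3}[kind].append((start, end))
    for g in genes.values():
        g.exons.sort()
    return list(genes.values())
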