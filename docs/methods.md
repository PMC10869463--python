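# Methods

This note documents the models, conventions and numerical choices behind
`radfp`, in the order of the analysis chain.

## Synthetic genotype panels

The generator emulates the design of a germplasm fingerprinting study:
~356 diploid accessions typed at 32 biallelic SNPs spread over 9
chromosomes, two subpopulations with gene flow between them, per-marker
minor-allele frequencies in 0.125–0.482, no-call rates up to ~9%, and small
groups of duplicate accessions.

**Model.** Per marker, an ancestral frequency is drawn uniformly from
`maf_range`. Subpopulation frequencies disperse around it by the
Balding–Nichols construction — a Beta draw with mean p and variance
Fst·p(1−p) — with `fst` the single differentiation knob; no generative model
is otherwise implied by the study design, and Balding–Nichols is the
standard minimal choice. Each accession receives admixture proportions from
a symmetric Dirichlet(α); each of its two allele copies independently picks
a source subpopulation from those proportions and then an allele from that
subpopulation's frequency (Hardy–Weinberg within the source). Radish is
self-incompatible and outcrossing, which loosely supports HWE-within-
subpopulation as the mating-system stand-in; no selfing or inbreeding model
is provided.

**Missing data** are injected independently per (accession, marker) cell at
a per-marker rate drawn from `missing_rate_range`. There is no call-rate
correlation structure across accessions — matching the fact that downstream
summaries only consume a per-marker missing rate.

**Duplicate groups** are literal copies of one base accession with extra
independent missing calls at `duplicate_missing_rate` and no genotype
changes, emulating the same variety submitted several times. They are the
ground truth for duplicate detection and for the "distance exactly zero"
behaviour of the missing-tolerant distances.

**Defaults** are the study conditions: 356 accessions, 32 markers,
9 chromosomes, k = 2 subpopulations, α = 0.5 (substantial admixture — the
two groups exchange genes freely), Fst = 0.15, MAF range (0.125, 0.482),
missing range (0, 0.09), one duplicate group of 7. Structure-recovery tests
use Fst = 0.25 with α = 0.05: "well-separated" subpopulations in Wright's
qualitative scale (Fst > 0.25 = very great differentiation) with essentially
unadmixed individuals, because hard truth labels are only meaningful when
individuals are not intermediates.

**Variant tables** carry QD, MQ, MQRankSum, ReadPosRankSum, QUAL, mean
depth, MAC/MAF and missingness annotations. Passing values are sampled well
inside the passing region and violations are planted per rule in disjoint
value ranges, so a correct filter recovers the planted labels *exactly* (a
label equality, not a sampling statement). Isolation failures are planted as
runs of sites 30 bp apart; all other adjacent gaps are ≥ 200 bp.
Substitution classes are drawn transition-enriched at Ts/Tv = 1.17 (each
transition class ~13.5%, each transversion class ~5.8%), the spectrum
typical of plant SNP panels. **Gene models** are non-overlapping (≥ 2.5 kb
apart, so 1-kb flanks never overlap a neighbour), with 1–4 exons, 40–100 bp
UTRs inside the terminal exons, and random strand.

One integer seed drives everything through named, deterministically derived
sub-streams; identical configuration ⇒ bit-identical output.

What the generator does **not** emulate: linkage disequilibrium, genotyping
batch effects, correlated missingness, allele-calling error. Passing tests
therefore demonstrate the correctness of the statistics and algorithms under
the stated model, not robustness to those real-data artefacts.

## Filter cascade

Order is fixed: hard → isolation → population. Thresholds fail on *strict*
inequality for the GATK-style hard filters (QD < 2.0 fails, QD = 2.0
passes), and pass on *inclusive* bounds for the VCFtools-style rules
(MAF = 0.05 passes), mirroring the respective tools' documented semantics.
`max-missing 0.5` follows VCFtools' famously inverted flag: proportion of
data present ≥ 0.5, i.e. missing fraction ≤ 0.5. Absent annotations never
fail a record. The isolation filter counts *all* variants as neighbours,
including ones failing other filters, because primer design cares about
physical sequence context, not filter status; it is symmetric (two sites
30 bp apart both fail; 51 bp apart both pass).

Genomic-context annotation assigns exactly one category per site with the
precedence splice_junction > UTR > exonic > intronic > upstream_1kb >
downstream_1kb > intergenic (precedence is a package convention — fixed so
percentages are reproducible). Splice junctions are ±2 bp around internal
exon boundaries (the canonical splice dinucleotide); upstream/downstream are
1 kb from TSS/TTS respecting strand.

## KASP design

Allele-specific primer bodies end on the SNP base and extend into the
upstream flank; the common primer is the reverse complement of a downstream
window. Constraints: GC < 0.60 and Tm ∈ [55, 62] °C per primer *body*
(the universal FAM/HEX tails do not anneal to target and are excluded —
GC/Tm are applied per primer, not per amplicon), product ≤ 120 bp. Tm uses
nearest-neighbour thermodynamics (SantaLucia 1998 unified parameters,
50 mM Na⁺, 250 nM primer, via Biopython); the Tm method name is recorded in
output because feasibility verdicts depend on it. Primer lengths are
searched over 18–30 bp (standard practice). The search order — allele-primer
length ascending, then common-primer gap, then common-primer length — is
deterministic, so identical flanks give identical assays. Infeasibility
reports the constraint that blocked the most candidates (GC preferred on
ties, it being the most interpretable).

Marker QC: `untypable` (all calls missing) > `high_no_call`
(no-call > 10%, strict) > `monomorphic` (one genotype class among called) >
`typable`. The partition is exhaustive and order-invariant.

Candidate-panel selection picks 8–12 sites per chromosome by greedy
farthest-point dispersion (ties to the lowest position). Greedy
farthest-point guarantees at least half the optimal minimum spacing but does
not always attain it — a 12-site uniform grid with k = 6 is a
counterexample — so tests assert the ½-guarantee, not equality with the
exhaustive optimum.

## Diversity statistics

Allele frequencies are counted over non-missing diploid calls, a
heterozygote contributing one copy of each allele. GD = 1 − Σpᵢ²; PIC is the
Botstein (1980) form, which for a biallelic locus is 2pq − 2p²q² with
maximum 0.375 at p = 0.5. Heterozygosity is the simple observed fraction of
heterozygous calls among called samples (not Nei's unbiased estimator): in
the published reference table the heterozygosity column is not a function of
MAF, confirming an observed rather than expected quantity. No-calls are
excluded from every statistic. Internally everything is computed in full
precision; tables are written at 3 dp.

The published 32-marker reference table ships as package data. Recomputing
GD and PIC from each printed MAF reproduces the printed cells to within
0.001: nine rows differ in the third decimal because the printed MAF is
itself rounded to 3 dp, which is exactly the error one extra half-ULP of
input propagates.

## Distances, trees, structure

Between individual accessions, "allele frequencies" at a locus are {1} for a
homozygote and {0.5, 0.5} for a heterozygote — the natural embedding of an
individual as a two-gene population, adopted because the pairwise distances
are applied between accessions, not populations. All distances use pairwise
deletion (only loci called in both accessions contribute), which is what
makes duplicate accessions sit at distance exactly zero despite missing
calls. p-distance is the mean per-locus allele-sharing dissimilarity
(1 − shared/2 ∈ {0, 0.5, 1}). Nei (1972) D = −ln I with I the ratio of
across-loci mean Σxy to the geometric mean of Σx², Σy²; I = 0 (opposite
fixation everywhere) yields D = +∞ and is flagged rather than fatal.

Neighbour joining is the standard Saitou–Nei Q-criterion agglomeration,
implemented in-package so two details are pinned: ties in Q join the
lexicographically smallest label pair, and negative branch lengths are
clamped to zero with a count reported. NJ is exact on additive matrices
(tested against trees with known branch lengths and against an exhaustive
minimum-evolution enumeration of all 945 seven-leaf topologies with OLS
branch lengths); it also cross-checks against scikit-bio's implementation.

PCA encodes genotypes as alternate-allele dosage {0, 1, 2}, imputes missing
cells with the marker mean (imputation is used for PCA only — never for
distances), centers markers, and eigendecomposes via SVD. The sign
convention — the largest-magnitude loading of each component is positive —
makes coordinates reproducible.

Evanno ΔK consumes replicate log-likelihoods L(K): L′(K) = L̄(K) − L̄(K−1),
|L″(K)| = |L′(K+1) − L′(K)|, ΔK = |L″(K)|/sd(L(K)) with the n−1 sd; ΔK is
undefined at the K-range endpoints, and sd = 0 yields an infinite ΔK with a
warning. No Bayesian clustering sampler is implemented: ΔK reads externally
supplied K/replicate/lnP tables, and for self-contained runs a
pseudo-likelihood generator clusters dosages with k-means per K, scores the
binomial genotype likelihood under the cluster allele frequencies, and
derives replicate scatter from 90% subsampling of accessions (rescaled to
full size) — genuine sampling variation, which is what the ΔK denominator
expects.

## Fingerprinting

A marker resolves an accession pair iff both are called there and their
unordered genotypes differ; a missing call never resolves a pair (the only
reading consistent with treating accessions that differ solely by missing
calls as indistinguishable). Heterozygote orientation is ignored (AG ≡ GA).
Minimal marker-set selection is greedy set cover over the pairs resolvable
by the full panel; pairs no marker resolves are excluded from the universe
up front and reported (the collection's own duplicates), not treated as
failure. Greedy ties break toward higher PIC, then lower (chromosome,
position) — the positional tie-break nudges selections toward even genome
coverage. An exhaustive solver (bitset cover by increasing subset size,
≤ 20 markers) provides the provably minimal answer for tests; greedy size ≥
exact size always, within the classic ln(#pairs)+1 factor.

Fingerprint codes are AA=1, CC=2, GG=3, TT=4, heterozygous=5, missing=6
(yellow, green, blue, purple, grey, white); the encoding is lossy on
heterozygotes, so the genotype matrix remains the authoritative record.
Duplicate detection groups accessions by missing-tolerant equality; the
relation is not transitive, so groups are connected components of the
compatibility graph and non-clique components are flagged.

## Core collection

Pairwise distances: modified Rogers MR = √((1/2L)·Σ_loci Σ_alleles (p−q)²)
and Cavalli-Sforza–Edwards CE = √((1/2L)·Σ Σ (√p−√q)²) (the Euclidean-on-√
convention; the 1967 chord distance with its 2/π factor is available via a
flag since sources disagree). Both are 0 for identical genotypes and 1 for
opposite homozygotes at every locus.

Subset evaluation: MR/CE are means over subset pairs; HE = mean over markers
of 1 − Σp²; NE = mean over markers of 1/Σp² (per locus NE = 1/(1−HE), so
panel means obey Jensen's inequality mean(NE) ≥ 1/(1−mean(HE)), checked in
tests); PIC = mean Botstein PIC; CV = fraction of the reference panel's
alleles present in the subset. SH is the Shannon index over the *pooled*
allele-frequency list, each marker's alleles weighted 1/L — the convention
under which 32 balanced biallelic loci give SH = ln 64 ≈ 4.159; a
per-locus-mean Shannon index would be bounded by ln 2 and is inconsistent
with panel-level SH values above 4. NE as mean-of-per-locus effective allele
numbers is likewise a convention choice; ratio-of-means is equally
defensible but changes little at these frequencies.

Selection is two-phase and deterministic under the seed: phase 1 greedily
adds the accession covering the most still-uncovered alleles until CV = 1 or
the target size; remaining slots fill by the accession maximizing summed MR
to the current subset; phase 2 is steepest-ascent swapping on total
within-subset MR under the constraint that no covered allele is lost
(a swap partner must carry every allele the leaver uniquely holds), capped
at 30 sweeps. This replaces heavier metaheuristics (parallel tempering et
al.) deliberately: for a 32-marker biallelic panel (≤ 64 alleles) greedy
coverage saturates with a handful of accessions and swap ascent reliably
beats random subsets of equal size, which is the property the evaluation
requires. If the target size cannot reach CV = 1 the best achievable
coverage is returned with a warning.

## Pipeline, formats, sizes

The pipeline writes every intermediate as plain text: genotype CSV (two-
letter calls, `NN` missing), sites-only VCF v4.2, GFF3, FASTA flanks (SNP as
IUPAC ambiguity at position 101), PHYLIP square distances, Newick, TSV/JSON
reports, plus a JSON manifest (config, seed, version, stage counts) that
makes a run bit-reproducible. CLI exit codes: 0 success, 2 validation error,
1 runtime failure.

Default problem sizes — 356 × 32 genotypes, 2 000 variant sites, 50 genes,
40 flanks, K ∈ 1..8 with 5 replicates — complete in a few seconds and are
the package's chosen study-scale working set; tests use the same scale or
smaller.

## Known limitations

- Individual-level Nei/MR/CE distances are conventions, not the population
  quantities the original estimators define; they are documented above and
  used consistently.
- The greedy marker set is not always minimum-cardinality (set cover is
  NP-hard); the exhaustive solver bounds the gap on small panels.
- The ΔK pseudo-likelihood is a stand-in for an external Bayesian clustering
  run, adequate for recovering strong two-population structure; it is not an
  admixture estimator.
- No LD, no genotyping error model, no phenotype-aware core selection, no
  bootstrap supports on trees, no fluorescence-cluster calling from raw
  FAM/HEX intensities (genotype calls are inputs).
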