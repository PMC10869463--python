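"""Synthetic-data generators: determinism, frequency recovery, planted structure."""

import numpy as np
import pytest

from radfp import (SimulationConfig, simulate_genotypes, simulate_variant_table,
                   simulate_gene_models, simulate_flanks, annotate_context,
                   hard_filter, isolation_filter, popgen_filter, VariantRecord)
from radfp.diversity import allele_frequencies, observed_heterozygosity
from radfp.genotypes import MISSING


class TestSimulateGenotypes:
    def test_same_seed_identical(self):
        a, _ = simulate_genotypes(SimulationConfig(seed=42))
        b, _ = simulate_genotypes(SimulationConfig(seed=42))
        assert np.array_equal(a.calls, b.calls)
        assert a.accession_ids == b.accession_ids

    def test_different_seed_differs(self):
        a, _ = simulate_genotypes(SimulationConfig(seed=1))
        b, _ = simulate_genotypes(SimulationConfig(seed=2))
        assert not np.array_equal(a.calls, b.calls)

    def test_hwe_at_balanced_frequency(self):
        # one panmictic population fixed at MAF 0.5: observed MAF ~ 0.5 and
        # observed heterozygosity ~ 2pq = 0.5 within sampling error
        cfg = SimulationConfig(n_accessions=2000, n_markers=10, k_subpops=1,
                               fst=0.0, maf_range=(0.5, 0.5),
                               missing_rate_range=(0.0, 0.0),
                               n_duplicate_groups=0, seed=3)
        m, _ = simulate_genotypes(cfg)
        se = 3 * np.sqrt(0.25 / (2 * cfg.n_accessions))
        for j in range(m.n_markers):
            freqs = allele_frequencies(m.calls[:, j].tolist())
            assert min(freqs.values()) == pytest.approx(0.5, abs=se)
            he_se = 3 * np.sqrt(0.25 / cfg.n_accessions)
            assert observed_heterozygosity(m.calls[:, j].tolist()) == pytest.approx(0.5, abs=he_se)

    def test_allele_frequency_recovery(self):
        cfg = SimulationConfig(n_accessions=3000, n_markers=20, k_subpops=1,
                               fst=0.0, missing_rate_range=(0.0, 0.0),
                               n_duplicate_groups=0, seed=4)
        m, truth = simulate_genotypes(cfg)
        n_chrom = 2 * cfg.n_accessions
        for j in range(m.n_markers):
            p = truth.subpop_allele_freqs[0, j]  # frequency of the alt letter
            freqs = allele_frequencies(m.calls[:, j].tolist())
            obs = freqs.get(truth.alt_alleles[j], 0.0)
            se = 3 * np.sqrt(p * (1 - p) / n_chrom)
            assert obs == pytest.approx(p, abs=max(se, 1e-9))

    def test_duplicate_group_identical_modulo_missing(self):
        cfg = SimulationConfig(n_duplicate_groups=1, duplicate_group_size=7, seed=5)
        m, truth = simulate_genotypes(cfg)
        (group,) = truth.duplicate_groups
        assert len(group) == 7
        idx = [m.accession_ids.index(a) for a in group]
        for a in idx:
            for b in idx:
                both = (m.calls[a] != MISSING) & (m.calls[b] != MISSING)
                assert np.array_equal(m.calls[a][both], m.calls[b][both])

    @pytest.mark.parametrize("bad", [
        dict(n_accessions=0),
        dict(maf_range=(0.0, 0.4)),
        dict(maf_range=(0.2, 0.6)),
        dict(missing_rate_range=(-0.1, 0.2)),
        dict(fst=1.0),
        dict(n_duplicate_groups=60, duplicate_group_size=7),
    ])
    def test_config_validation(self, bad):
        with pytest.raises(ValueError):
            SimulationConfig(**bad)


class TestSimulateVariantTable:
    def test_no_planted_failures_all_pass(self):
        recs, _ = simulate_variant_table(300, seed=1)
        assert hard_filter(recs).n_pass == 300
        assert isolation_filter(recs).n_pass == 300
        assert popgen_filter(recs).n_pass == 300

    def test_planted_fractions_recovered_exactly(self):
        fracs = {"QD": 0.2, "MQ": 0.1, "MQRankSum": 0.05, "ReadPosRankSum": 0.05,
                 "isolation": 0.1, "max-alleles": 0.06, "max-missing": 0.04,
                 "mac": 0.04, "minQ": 0.05, "maf": 0.05, "mean-DP": 0.03}
        recs, labels = simulate_variant_table(500, seed=2, fail_fraction_per_rule=fracs)
        # each hard-filter rule: planted set == violating set
        preds = {"QD": lambda r: r.qd < 2.0, "MQ": lambda r: r.mq < 40.0,
                 "MQRankSum": lambda r: r.mq_rank_sum < -12.5,
                 "ReadPosRankSum": lambda r: r.read_pos_rank_sum < -8.0,
                 "max-alleles": lambda r: r.n_alleles > 2,
                 "max-missing": lambda r: r.missing_fraction > 0.5,
                 "mac": lambda r: r.mac < 3, "minQ": lambda r: r.qual < 30,
                 "maf": lambda r: r.maf < 0.05, "mean-DP": lambda r: r.mean_dp < 1.2}
        for rule, pred in preds.items():
            got = {r.site_id for r in recs if pred(r)}
            want = {recs[i].site_id for i in np.where(labels[rule])[0]}
            assert got == want, rule
        iso = isolation_filter(recs)
        iso_fail = {k for k, v in iso.verdicts.items() if v == "isolation"}
        assert iso_fail == {recs[i].key for i in np.where(labels["isolation"])[0]}

    def test_determinism(self):
        a, _ = simulate_variant_table(100, seed=7, fail_fraction_per_rule={"QD": 0.1})
        b, _ = simulate_variant_table(100, seed=7, fail_fraction_per_rule={"QD": 0.1})
        assert [(r.chrom, r.pos, r.qd) for r in a] == [(r.chrom, r.pos, r.qd) for r in b]

    def test_transition_enriched_spectrum(self):
        from radfp import variant_spectrum

        recs, _ = simulate_variant_table(5000, seed=6)
        spec = variant_spectrum(recs)
        # generator draws substitution classes at Ts/Tv 1.17; recovery within
        # multinomial sampling error on 5000 sites
        assert spec["ts_tv"] == pytest.approx(1.17, abs=0.1)

    def test_bad_fraction_rejected(self):
        with pytest.raises(ValueError):
            simulate_variant_table(10, seed=0, fail_fraction_per_rule={"QD": 1.5})
        with pytest.raises(ValueError):
            simulate_variant_table(10, seed=0, fail_fraction_per_rule={"bogus": 0.1})


class TestSimulateGeneModels:
    def test_no_genes_everything_intergenic(self):
        recs, _ = simulate_variant_table(50, seed=1)
        ctx = annotate_context(recs, simulate_gene_models(0, 10**6, seed=1))
        assert all(v == "intergenic" for v in ctx["assignments"].values())

    def test_site_in_exon_annotated_genic(self):
        genes = simulate_gene_models(5, 10**6, seed=2)
        g = genes[0]
        s, e = g.exons[0]
        site = VariantRecord(g.chrom, (s + e) // 2, "A", ("G",))
        ctx = annotate_context([site], genes)
        # mid-exon position may still be UTR or near a splice site by construction
        assert ctx["assignments"][site.key] in {"exonic", "utr5", "utr3", "splice_junction"}

    def test_determinism(self):
        a = simulate_gene_models(20, 10**6, seed=3)
        b = simulate_gene_models(20, 10**6, seed=3)
        assert [(g.start, g.end, g.strand, g.exons) for g in a] == \
               [(g.start, g.end, g.strand, g.exons) for g in b]

    def test_grid_categories_match_interval_arithmetic(self):
        """Dense-grid annotation equals an independent brute-force interval oracle."""
        genes = simulate_gene_models(8, 60_000, seed=4)
        span = max(g.end for g in genes) + 2000
        grid = list(range(1, span, 3))
        recs = [VariantRecord("Chr1", p, "A", ("G",)) for p in grid]
        ctx = annotate_context(recs, genes)

        def oracle(p):
            cats = set()
            for g in genes:
                inside = g.start <= p <= g.end
                if inside:
                    bounds = []
                    for k, (s, e) in enumerate(g.exons):
                        if k > 0:
                            bounds.append(s)
                        if k < len(g.exons) - 1:
                            bounds.append(e)
                    if any(abs(p - b) <= 2 for b in bounds):
                        cats.add("splice_junction")
                    if any(s <= p <= e for s, e in g.utr5):
                        cats.add("utr5")
                    if any(s <= p <= e for s, e in g.utr3):
                        cats.add("utr3")
                    if any(s <= p <= e for s, e in g.exons):
                        cats.add("exonic")
                    else:
                        cats.add("intronic")
                else:
                    before = g.start - 1000 <= p < g.start
                    after = g.end < p <= g.end + 1000
                    if (g.strand == "+" and before) or (g.strand == "-" and after):
                        cats.add("upstream_1kb")
                    if (g.strand == "+" and after) or (g.strand == "-" and before):
                        cats.add("downstream_1kb")
            for c in ["splice_junction", "utr5", "utr3", "exonic", "intronic",
                      "upstream_1kb", "downstream_1kb"]:
                if c in cats:
                    return c
            return "intergenic"

        got = {pos: ctx["assignments"][("Chr1", pos)] for pos in grid}
        assert got == {p: oracle(p) for p in grid}


class TestSimulateFlanks:
    def test_determinism_and_shape(self):
        a = simulate_flanks(10, seed=5)
        b = simulate_flanks(10, seed=5)
        assert a == b
        for _, up, ref, alt, down in a:
            assert len(up) == len(down) == 100
            assert ref != alt and {ref, alt} <= set("ACGT")
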