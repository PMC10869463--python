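"""End-to-end pipeline: simulate -> filter -> KASP -> diversity -> distance /
tree / PCA / ΔK -> fingerprint -> core collection.

Every stage writes its artifact in a standard plain-text format, and each run
writes a JSON manifest (config, seed, package version, per-stage counts)
sufficient to re-run it bit-identically.
"""

from __future__ import annotations

import dataclasses
import json
import platform
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

from . import __version__
from .simulate import (SimulationConfig, simulate_genotypes, simulate_variant_table,
                       simulate_gene_models, simulate_flanks, write_flanks_fasta)
from .variants import (filter_cascade, variant_spectrum, annotate_context,
                       write_vcf, write_gff3)
from .kasp import design_assay, classify_marker, read_flanks_fasta, assays_to_tsv
from .diversity import marker_table, marker_table_to_tsv
from .distance import (nei1972_distance, p_distance_matrix, nj_tree,
                       pca_coordinates, structure_pseudo_likelihood, evanno_delta_k)
from .fingerprint import (minimal_core_set, encode_fingerprints, duplicate_groups)
from .core import select_core


@dataclass
class RunConfig:
    """Pipeline configuration; every threshold defaults to the published value
    (hard-filter QD < 2.0 etc., VCFtools MAF >= 0.05, GC < 60%, Tm 55-62,
    product <= 120 bp, no-call cut 10%, core fraction 20%)."""

    outdir: str = "radfp_run"
    seed: int = 0
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    n_variant_sites: int = 2000
    variant_fail_fractions: dict = field(default_factory=lambda: {
        "QD": 0.05, "MQ": 0.05, "MQRankSum": 0.02, "ReadPosRankSum": 0.02,
        "isolation": 0.10, "max-alleles": 0.05, "max-missing": 0.05,
        "mac": 0.04, "minQ": 0.05, "maf": 0.05, "mean-DP": 0.03})
    n_genes: int = 50
    n_flank_sites: int = 40
    core_target_fraction: float = 0.20
    delta_k_range: tuple[int, int] = (1, 8)
    delta_k_replicates: int = 5
    genotype_csv: Optional[str] = None   # skip simulation, load this panel


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis chain, returning the manifest dict."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package": "radfp", "version": __version__,
        "python": platform.python_version(),
        "seed": config.seed,
        "config": json.loads(json.dumps(asdict(config), default=str)),
        "stages": {},
    }
    stage = "simulate"
    try:
        sim = dataclasses.replace(config.simulation, seed=config.seed)
        if config.genotype_csv:
            from .genotypes import GenotypeMatrix
            matrix = GenotypeMatrix.from_csv(config.genotype_csv)
            truth = None
        else:
            matrix, truth = simulate_genotypes(sim)
            truth.to_json(out / "truth.json")
        matrix.to_csv(out / "genotypes.csv")
        records, labels = simulate_variant_table(
            config.n_variant_sites, seed=config.seed,
            fail_fraction_per_rule=config.variant_fail_fractions)
        write_vcf(records, out / "variants.vcf", contigs=["Chr1"])
        genes = simulate_gene_models(config.n_genes, 10_000_000, seed=config.seed)
        write_gff3(genes, out / "genes.gff3")
        flanks = simulate_flanks(config.n_flank_sites, seed=config.seed)
        write_flanks_fasta(flanks, out / "flanks.fasta")
        manifest["stages"][stage] = {"n_accessions": matrix.n_accessions,
                                     "n_markers": matrix.n_markers,
                                     "n_variant_sites": len(records)}

        stage = "filter"
        survivors, reports = filter_cascade(records)
        counts = {r.stage: r.n_pass for r in reports}
        write_vcf(survivors, out / "variants.filtered.vcf", contigs=["Chr1"])
        verdict_rows = ["site\tstage\tverdict"]
        for rep in reports:
            for key, rule in sorted(rep.verdicts.items()):
                verdict_rows.append(f"{key[0]}:{key[1]}\t{rep.stage}\t{rule or 'PASS'}")
        (out / "filter_report.tsv").write_text("\n".join(verdict_rows) + "\n")
        spectrum = variant_spectrum(records)
        context = annotate_context(survivors, genes)
        (out / "filter_summary.json").write_text(json.dumps({
            "stage_counts": counts, "spectrum": {
                "counts": spectrum["counts"], "ts_tv": spectrum["ts_tv"]},
            "context_fractions": context["fractions"]}, indent=1, default=str))
        manifest["stages"][stage] = {"input": len(records), **counts}

        stage = "kasp"
        flank_sites = read_flanks_fasta(out / "flanks.fasta")
        assays = [design_assay(f) for f in flank_sites]
        assays_to_tsv(assays, out / "kasp_assays.tsv")
        qc_rows = ["marker\tcategory\tno_call_rate\tn_genotype_clusters"]
        for j, mid in enumerate(matrix.marker_ids):
            v = classify_marker(matrix.calls[:, j].tolist())
            qc_rows.append(f"{mid}\t{v.category}\t{v.no_call_rate:.4f}\t{v.n_genotype_clusters}")
        (out / "marker_qc.tsv").write_text("\n".join(qc_rows) + "\n")
        manifest["stages"][stage] = {
            "n_assays": len(assays),
            "n_feasible": sum(a.feasible for a in assays)}

        stage = "diversity"
        rows, summary = marker_table(matrix)
        marker_table_to_tsv(rows, out / "marker_stats.tsv")
        (out / "diversity_summary.json").write_text(json.dumps(summary, indent=1))
        manifest["stages"][stage] = {"mean_pic": round(summary["pic"]["mean"], 4)}

        stage = "distance"
        nei = nei1972_distance(matrix)
        nei.to_phylip(out / "nei1972.phy")
        p_distance_matrix(matrix).to_tsv(out / "p_distance.tsv")
        tree = nj_tree(nei)
        tree.write(out / "nj_tree.nwk")
        coords, explained = pca_coordinates(matrix, n_components=2)
        coords.assign(explained_pc1=explained[0], explained_pc2=explained[1]) \
              .to_csv(out / "pca.tsv", sep="\t")
        runs = structure_pseudo_likelihood(
            matrix, range(config.delta_k_range[0], config.delta_k_range[1] + 1),
            n_replicates=config.delta_k_replicates, seed=config.seed)
        runs.to_tsv(out / "structure_runs.tsv")
        dk_table, best_k = evanno_delta_k(runs)
        dk_table.to_csv(out / "delta_k.tsv", sep="\t", index=False)
        manifest["stages"][stage] = {"best_k": best_k,
                                     "clamped_branches": tree.negative_branches_clamped}

        stage = "fingerprint"
        selected, curve, unresolvable = minimal_core_set(matrix)
        curve.to_csv(out / "efficiency_curve.tsv", sep="\t", index=False)
        (out / "core_markers.tsv").write_text(
            "rank\tmarker\n" + "\n".join(f"{i+1}\t{m}" for i, m in enumerate(selected)) + "\n")
        encode_fingerprints(matrix, selected).to_csv(out / "fingerprints.csv")
        dup = duplicate_groups(matrix)
        dup_rows = ["group\tsize\tmembers\tnon_clique"]
        for gi, members in enumerate(dup.groups, 1):
            flag = members in dup.non_clique_components
            dup_rows.append(f"{gi}\t{len(members)}\t{','.join(members)}\t{flag}")
        (out / "duplicate_groups.tsv").write_text("\n".join(dup_rows) + "\n")
        manifest["stages"][stage] = {"n_core_markers": len(selected),
                                     "n_unresolvable_pairs": len(unresolvable),
                                     "n_duplicate_groups": len(dup.groups)}

        stage = "core"
        core = select_core(matrix, target_fraction=config.core_target_fraction,
                           seed=config.seed)
        (out / "core_accessions.tsv").write_text(
            "accession\n" + "\n".join(core.selected) + "\n")
        (out / "core_metrics.json").write_text(json.dumps({
            "original_size": matrix.n_accessions, "core_size": len(core.selected),
            **{k: (round(v, 4) if isinstance(v, float) else v)
               for k, v in core.metrics.items()},
            "warning": core.warning}, indent=1))
        manifest["stages"][stage] = {"core_size": len(core.selected),
                                     "CV": core.metrics["CV"]}
    except Exception as exc:
        (out / "manifest.partial.json").write_text(json.dumps(manifest, indent=1))
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
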