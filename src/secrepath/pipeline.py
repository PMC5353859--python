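"""End-to-end orchestration: catalogue -> network -> transfer ->
expression -> clustering -> regulator screen -> phenotype correlation ->
overlay, as one configured, logged, seeded run."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from secrepath import clustering, homology, overlay, phenotype, regulators
from secrepath.catalogue import load_catalogue, save_catalogue
from secrepath.expression import (
    adjust_and_flag_de,
    compute_cpm,
    filter_expressed,
    load_counts,
)
from secrepath.network import build_network, export_network, load_interactions

logger = logging.getLogger(__name__)

ALL_STAGES = (
    "network",
    "transfer",
    "expression",
    "clustering",
    "regulators",
    "phenotype",
    "overlay",
)

#: Input paths each stage requires before anything is computed.
STAGE_INPUTS = {
    "network": ("catalogue",),
    "transfer": ("catalogue", "hits"),
    "expression": ("counts",),
    "clustering": ("counts",),
    "regulators": ("counts", "seed_genes"),
    "phenotype": ("counts", "phenotypes", "catalogue"),
    "overlay": ("catalogue", "dge"),
}


class PipelineConfigError(ValueError):
    """Raised when a pipeline configuration fails pre-flight validation."""


@dataclass
class PipelineConfig:
    """Validated configuration of a pipeline run."""

    out_dir: str = "secrepath_out"
    seed: int = 0
    stages: list[str] = field(default_factory=lambda: list(ALL_STAGES))

    catalogue: str | None = None
    interactions: str | None = None
    hits: str | None = None
    counts: str | None = None
    sample_metadata: str | None = None
    dge: str | None = None
    phenotypes: str | None = None
    seed_genes: str | None = None

    drop_isolated: bool = True
    normalization: str = "libsize"
    min_cpm: float = 1.0
    min_samples: int = 2
    fc_cut: float = 2.0
    p_cut: float = 0.05
    fdr_cut: float = 0.05
    high_pident: float = 80.0
    moderate_pident: float = 60.0
    moderate_bitscore: float = 50.0
    moderate_evalue: float = 1e-5
    nboot: int = 1000
    nboot_per_scale: int = 100
    alpha: float = 0.95
    top_k: int = 10
    enrichment_kind: str = "complex"
    max_cluster_genes: int = 400

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        unknown = set(raw) - {f.name for f in cls.__dataclass_fields__.values()}
        if unknown:
            raise PipelineConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def validate(self) -> None:
        """Pre-flight check: stage names, required inputs, file existence."""
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise PipelineConfigError(f"unknown stage(s): {sorted(unknown)}")
        for stage in self.stages:
            for key in STAGE_INPUTS[stage]:
                value = getattr(self, key)
                if value is None:
                    raise PipelineConfigError(
                        f"stage {stage!r} enabled but input {key!r} is not set"
                    )
                if not Path(value).exists():
                    raise PipelineConfigError(
                        f"stage {stage!r}: input file not found: {value}"
                    )


def run_pipeline(config: PipelineConfig) -> dict[str, object]:
    """Run all enabled stages; returns a result dict and writes the report.

    Validation happens before any computation, so a misconfigured run
    leaves no partial outputs. Outputs under ``out_dir`` are deterministic
    given identical inputs and seed.
    """
    config.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    results: dict[str, object] = {}
    run_log: list[str] = [f"seed={config.seed}", f"stages={','.join(config.stages)}"]

    cat = None
    net = None
    if config.catalogue:
        cat = load_catalogue(config.catalogue)
        run_log.append(f"catalogue: {len(cat)} components")

    if "network" in config.stages:
        interactions = (
            load_interactions(config.interactions) if config.interactions else []
        )
        net = build_network(cat, interactions, drop_isolated=config.drop_isolated)
        counts = net.kind_counts()
        run_log.append(
            "network: "
            + ", ".join(f"{k}={v}" for k, v in counts.items())
            + f", edges={len(net.edges)}"
        )
        export_network(net, out_dir, basename="network")
        results["network"] = net

    if "transfer" in config.stages:
        hits = homology.parse_hits(config.hits)
        thresholds = homology.TierThresholds(
            high_pident=config.high_pident,
            moderate_pident=config.moderate_pident,
            moderate_bitscore=config.moderate_bitscore,
            moderate_evalue=config.moderate_evalue,
        )
        assignments = homology.assign_homologs(hits, thresholds)
        target_cat, report = homology.transfer_catalogue(
            cat, assignments, target_species="target"
        )
        save_catalogue(target_cat, out_dir / "transferred_catalogue.tsv")
        pd.DataFrame(
            [(a.reference_id, a.target_id or "", a.tier, a.reason) for a in assignments],
            columns=["reference_id", "target_id", "tier", "reason"],
        ).to_csv(out_dir / "homology_assignments.tsv", sep="\t", index=False)
        run_log.append(
            f"transfer: {len(report.mapped)} mapped, {len(report.unmapped)} unmapped"
        )
        results["transfer"] = (target_cat, report)

    expr = None
    if any(s in config.stages for s in ("expression", "clustering", "regulators", "phenotype")):
        counts_df, _meta = load_counts(config.counts, config.sample_metadata)
        cpm = compute_cpm(counts_df, config.normalization)
        filtered, report = filter_expressed(cpm, config.min_cpm, config.min_samples)
        run_log.append(
            f"expression: kept {report.n_kept}/{report.n_input} genes"
        )
        log_expr = compute_cpm(counts_df, config.normalization, log2=True)
        expr = log_expr.values.loc[filtered.values.index]
        filtered.values.to_csv(out_dir / "cpm_filtered.tsv", sep="\t")
        results["expression"] = filtered

    if "clustering" in config.stages:
        genes = list(expr.index)
        if cat is not None:
            network_genes = [g for g in expr.index if g in cat]
            if network_genes:
                genes = network_genes
        genes = genes[: config.max_cluster_genes]
        tree = clustering.tree_from_values(expr.loc[genes])
        tree = clustering.au_pvalues(
            expr.loc[genes],
            tree,
            nboot_per_scale=config.nboot_per_scale,
            seed=config.seed,
        )
        tree = clustering.bootstrap_support(
            expr.loc[genes], tree, nboot=config.nboot, seed=config.seed + 1
        )
        clusters = clustering.significant_clusters(tree, config.alpha)
        (out_dir / "tree.nwk").write_text(tree.to_newick(), encoding="utf-8")
        clustering.support_table(tree).to_csv(
            out_dir / "cluster_support.tsv", sep="\t", index=False
        )
        run_log.append(
            f"clustering: {len(genes)} genes, "
            f"{len(clusters)} significant clusters at alpha={config.alpha}"
        )
        results["clustering"] = (tree, clusters)

    if "regulators" in config.stages:
        seed_genes = [
            g.strip()
            for g in Path(config.seed_genes).read_text(encoding="utf-8").splitlines()
            if g.strip()
        ]
        scores = regulators.summed_correlation_scores(expr, seed_genes)
        positive, negative = regulators.rank_regulator_candidates(
            scores, config.top_k
        )
        scores.to_csv(out_dir / "regulator_scores.tsv", sep="\t")
        positive.to_csv(out_dir / "regulators_positive.tsv", sep="\t")
        negative.to_csv(out_dir / "regulators_negative.tsv", sep="\t")
        run_log.append(
            f"regulators: scored {len(scores)} genes against {len(seed_genes)} seeds"
        )
        results["regulators"] = (positive, negative)

    if "phenotype" in config.stages:
        pheno_table = pd.read_csv(config.phenotypes, sep="\t", index_col=0)
        network_genes = [g for g in expr.index if g in cat]
        if not network_genes:
            logger.warning(
                "no catalogue genes found in the expression matrix; "
                "correlating all expressed genes"
            )
            network_genes = list(expr.index)
        frames = []
        for column in pheno_table.columns:
            corr = phenotype.correlate_to_phenotype(
                expr.loc[network_genes], pheno_table[column]
            )
            corr.columns = [f"{c}_{column}" for c in corr.columns]
            frames.append(corr)
        combined = pd.concat(frames, axis=1)
        flagged = phenotype.classify_targets(combined)
        flagged.to_csv(out_dir / "phenotype_correlations.tsv", sep="\t")
        n_sig = int(
            flagged[[c for c in flagged.columns if c.startswith("significant_")]]
            .any(axis=1)
            .sum()
        )
        run_log.append(
            f"phenotype: {len(network_genes)} network genes, {n_sig} flagged"
        )
        results["phenotype"] = flagged

    if "overlay" in config.stages:
        if net is None:
            interactions = (
                load_interactions(config.interactions) if config.interactions else []
            )
            net = build_network(cat, interactions, drop_isolated=config.drop_isolated)
        dge_raw = pd.read_csv(config.dge, sep="\t")
        if "FDR" not in dge_raw.columns:
            dge_raw = adjust_and_flag_de(
                dge_raw, config.fc_cut, config.p_cut, config.fdr_cut
            )
        annotations = overlay.annotate_network(net, dge_raw, fdr_cut=config.fdr_cut)
        enrichment = overlay.complex_enrichment(
            net, cat, dge_raw, kind=config.enrichment_kind
        )
        overlay.style_and_export(net, annotations, enrichment, out_dir)
        run_log.append(
            f"overlay: {len(annotations)} nodes annotated, "
            f"{len(enrichment)} enrichment tests"
        )
        results["overlay"] = (annotations, enrichment)

    (out_dir / "run_log.txt").write_text("\n".join(run_log) + "\n", encoding="utf-8")
    (out_dir / "config_echo.yaml").write_text(
        yaml.safe_dump(asdict(config), sort_keys=True), encoding="utf-8"
    )
    results["log"] = run_log
    return results
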