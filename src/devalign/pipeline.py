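"""Config-driven end-to-end runner.

Stage order mirrors the analysis: simulate (or ingest) -> quantile
normalization -> detection filter -> subgroup classification -> group
statistics, pair-wise tests and the exclusivity intersect -> PCA ordination
and centroid distances -> co-expression network, eigengenes, trait and
alignment-order correlations -> optional gene-set over-representation.
Every output is plain text (TSV / Newick), carries the config hash and seed
in a comment header, and is bit-reproducible for a fixed config and seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .classify import ClassifierPanel, classify_by_reference, read_panel
from .enrichment import load_collection, overrepresentation
from .intersect import compute_group_stats, run_all_comparisons, stepwise_exclusive, top_table
from .matrix import ExpressionMatrix, read_expression, write_expression
from .network import (
    NetworkConfig,
    cluster_families,
    control_stage_levels,
    detect_modules,
    module_eigengenes,
    score_alignment_orders,
    select_soft_power,
    subgroup_traits,
    trait_association,
)
from .ordination import group_centroids, hierarchical_cluster, pca
from .preprocess import detection_filter, network_prefilter, quantile_normalize
from .simulate import SimulationParams, paper_cohort_design, simulate_cohort, write_fixture

log = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failure, annotated with the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """Effective parameters of one pipeline run (flat key/value schema)."""

    mode: str = "simulate"                  # "simulate" | "files"
    expression_path: str | None = None
    metadata_path: str | None = None
    reference_expression_path: str | None = None
    reference_metadata_path: str | None = None
    panel_path: str | None = None
    gmt_path: str | None = None
    out_dir: str = "results/pipeline"
    seed: int = 0
    # simulation
    n_genes: int = 1200
    noise_sd: float = 0.5
    gradient_slope: float = 0.5
    marker_effect: float = 2.0
    module_loading_sd: float = 1.0
    n_gradient_modules: int = 5
    genes_per_module: int = 40
    n_exclusive_markers_per_subgroup: int = 25
    fraction_below_detection: float = 0.1
    # differential expression
    alpha: float = 0.05
    k_sigma: float = 2.0
    direction: str = "up"
    t_variant: str = "student"
    # normalization: "auto" applies quantile normalization to file input but
    # not to simulated cohorts (those are generated on a common, already
    # normalized scale and carry planted signal in a large fraction of genes,
    # violating the mostly-non-differential assumption of the transform)
    quantile_normalize: str = "auto"
    # filters
    detection_threshold: float = 200.0
    variance_quantile: float = 0.75
    suffix_list: tuple[str, ...] = ("_x_at",)
    # ordination
    n_pca_components: int = 5
    centroid_components: tuple[int, ...] = (1, 2, 3, 4)
    classifier_components: int = 4
    # network
    candidate_powers: tuple[int, ...] = tuple(range(1, 13))
    signed: str = "unsigned"
    min_module_size: int = 20
    tree_cut_height: float = 0.97
    family_cut_height: float = 0.8
    scale_free_r2_target: float = 0.8
    trait_encoding: str = "rank"
    alignment_orientation: str = "positive"

    def validate(self) -> "PipelineConfig":
        if self.mode not in ("simulate", "files"):
            raise ValueError(f"mode must be 'simulate' or 'files', got {self.mode!r}")
        if self.mode == "files" and not (self.expression_path and self.metadata_path):
            raise ValueError("files mode requires expression_path and metadata_path")
        if not 0 < self.alpha < 1:
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.k_sigma <= 0:
            raise ValueError("k_sigma must be positive")
        if self.direction not in ("up", "down"):
            raise ValueError("direction must be 'up' or 'down'")
        if not 0 <= self.variance_quantile < 1:
            raise ValueError("variance_quantile must be in [0, 1)")
        if self.detection_threshold < 0:
            raise ValueError("detection_threshold must be non-negative")
        if self.seed < 0 or self.seed >= 2**31:
            raise ValueError("seed must be a non-negative 31-bit integer")
        if self.quantile_normalize not in ("auto", "always", "never"):
            raise ValueError("quantile_normalize must be 'auto', 'always' or 'never'")
        self.network_config()  # range-checks the network block
        return self

    def network_config(self) -> NetworkConfig:
        return NetworkConfig(
            candidate_powers=tuple(self.candidate_powers),
            signed=self.signed,
            min_module_size=self.min_module_size,
            tree_cut_height=self.tree_cut_height,
            family_cut_height=self.family_cut_height,
            scale_free_r2_target=self.scale_free_r2_target,
        )

    def simulation_params(self) -> SimulationParams:
        return SimulationParams(
            noise_sd=self.noise_sd,
            gradient_slope=self.gradient_slope,
            marker_effect=self.marker_effect,
            module_loading_sd=self.module_loading_sd,
            n_gradient_modules=self.n_gradient_modules,
            genes_per_module=self.genes_per_module,
            n_exclusive_markers_per_subgroup=self.n_exclusive_markers_per_subgroup,
            fraction_below_detection=self.fraction_below_detection,
            seed=self.seed,
        )

    def config_hash(self) -> str:
        # out_dir is excluded so the same analysis is byte-identical
        # wherever the bundle is written
        payload = {k: v for k, v in asdict(self).items() if k != "out_dir"}
        return hashlib.sha256(json.dumps(payload, sort_keys=True, default=str).encode()).hexdigest()[:12]


def validate_config(path) -> PipelineConfig:
    """Load a YAML config file, rejecting unknown keys and out-of-range values.

    An empty file yields all defaults. The effective parameters are echoed at
    INFO level so no default stays hidden.
    """
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError("config file must contain a mapping of keys to values")
    known = {f.name for f in fields(PipelineConfig)}
    unknown = sorted(set(raw) - known)
    if unknown:
        raise ValueError(f"unknown config keys: {unknown}")
    for key in ("suffix_list", "centroid_components", "candidate_powers"):
        if key in raw and isinstance(raw[key], list):
            raw[key] = tuple(raw[key])
    config = PipelineConfig(**raw).validate()
    for f in fields(config):
        log.info("config %s = %r", f.name, getattr(config, f.name))
    return config


def _write_table(df: pd.DataFrame, path: Path, header: str, index_label: str | None = None) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", newline="\n") as fh:
        for line in header.splitlines():
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", lineterminator="\n", index_label=index_label)


def run_pipeline(config: PipelineConfig) -> dict[str, Path]:
    """Execute every stage; returns the paths of the report bundle.

    Deterministic for a fixed config (the seed drives all randomness). A
    stage failure raises :class:`PipelineError` naming the stage and leaves a
    FAILED marker next to the partial outputs.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()
    header = f"devalign {__version__}\nconfig_hash={chash} seed={config.seed}"
    paths: dict[str, Path] = {}
    summary: dict[str, object] = {"config_hash": chash, "seed": config.seed}
    log_lines = [f"devalign {__version__}", f"config_hash={chash}"] + [
        f"param {f.name}={getattr(config, f.name)!r}" for f in fields(config)
        if f.name != "out_dir"
    ]
    stage = "setup"
    try:
        # -- input -------------------------------------------------------
        stage = "input"
        truth = None
        reference = None
        reference_labels = None
        if config.mode == "simulate":
            design = paper_cohort_design(config.n_genes)
            params = config.simulation_params()
            matrix, truth = simulate_cohort(design, params)
            # independent reference cohort sharing the planted structure,
            # for the classification stage
            ref_seed = int(np.random.SeedSequence(config.seed).generate_state(2)[1] % (2**31))
            reference, _ = simulate_cohort(design, SimulationParams(
                **{**asdict(params), "seed": ref_seed}), truth=truth)
            reference = reference.subset_samples(
                reference.metadata.index[reference.metadata["kind"] == "tumor"])
            reference_labels = reference.metadata["group"]
            fixture_paths = write_fixture(matrix, truth, out / "cohort")
            paths.update({f"cohort_{k}": v for k, v in fixture_paths.items()})
            panel = ClassifierPanel(
                gene_ids=tuple(g for s in truth.marker_sets.values() for g in s),
                source="planted markers",
            )
        else:
            matrix = read_expression(config.expression_path, config.metadata_path)
            if config.reference_expression_path and config.reference_metadata_path:
                reference = read_expression(
                    config.reference_expression_path, config.reference_metadata_path)
                reference_labels = reference.metadata["group"]
            panel = read_panel(config.panel_path) if config.panel_path else None

        # -- normalization and detection filter --------------------------
        stage = "normalize"
        apply_qn = config.quantile_normalize == "always" or (
            config.quantile_normalize == "auto" and config.mode == "files")
        normalized = quantile_normalize(matrix) if apply_qn else matrix
        if not apply_qn:
            log_lines.append("stage normalize skipped: simulated input is already on a common scale")
        write_expression(normalized, out / "normalized_expression.tsv", out / "metadata.tsv", header)
        paths["normalized_expression"] = out / "normalized_expression.tsv"

        stage = "detection_filter"
        filtered, report = detection_filter(normalized, config.detection_threshold)
        _write_table(report.to_frame(), out / "filter_report.tsv", header)
        paths["filter_report"] = out / "filter_report.tsv"
        summary["n_genes_input"] = report.n_input
        summary["n_genes_below_detection"] = report.n_below_detection
        summary["n_genes_detected"] = report.n_retained

        # -- classification ----------------------------------------------
        stage = "classify"
        if reference is not None and panel is not None:
            tumor_samples = filtered.metadata.index[filtered.metadata["kind"] == "tumor"]
            if len(tumor_samples) == 0:
                raise ValueError("no tumour samples to classify")
            query = filtered.subset_samples(tumor_samples)
            assignment = classify_by_reference(
                reference, reference_labels, query, panel,
                n_components=config.classifier_components,
            )
            table = assignment.distances.copy()
            table.insert(0, "assigned", assignment.labels)
            _write_table(table, out / "subgroup_assignments.tsv", header, index_label="sample_id")
            paths["subgroup_assignments"] = out / "subgroup_assignments.tsv"
            true_labels = query.metadata["group"]
            accuracy = float((assignment.labels == true_labels).mean())
            summary["classification_accuracy_vs_metadata"] = round(accuracy, 4)
        else:
            log_lines.append("stage classify skipped: no reference cohort / panel configured")

        # -- intersect differential expression ---------------------------
        stage = "intersect_de"
        stats_table = compute_group_stats(filtered)
        flat = stats_table.table.copy()
        flat.columns = [f"{g}.{stat}" for g, stat in flat.columns]
        _write_table(flat, out / "group_stats.tsv", header, index_label="gene_id")
        paths["group_stats"] = out / "group_stats.tsv"
        comparisons = run_all_comparisons(
            filtered, alpha=config.alpha, k_sigma=config.k_sigma, variant=config.t_variant)
        de_dir = out / "de"
        for res in comparisons:
            _write_table(res.table, de_dir / f"{res.subgroup}_vs_{res.control}.tsv",
                         header, index_label="gene_id")
            tt = top_table(res, n=25, direction=config.direction)
            _write_table(tt, de_dir / f"top_{res.subgroup}_vs_{res.control}.tsv", header)
        calls = stepwise_exclusive(comparisons, direction=config.direction, alpha=config.alpha)
        excl = calls.classes.copy()
        _write_table(excl, out / "exclusivity.tsv", header, index_label="gene_id")
        paths["exclusivity"] = out / "exclusivity.tsv"
        for s in calls.classes.columns:
            summary[f"n_exclusive_{s}"] = len(calls.exclusive_genes(s))

        # -- ordination ---------------------------------------------------
        stage = "ordination"
        ordination = pca(filtered, n_components=config.n_pca_components)
        _write_table(ordination.scores, out / "pca_scores.tsv", header, index_label="sample_id")
        paths["pca_scores"] = out / "pca_scores.tsv"
        comps = tuple(c for c in config.centroid_components if c <= ordination.n_components)
        table = group_centroids(ordination, filtered.metadata, comps)
        _write_table(table.distances, out / "centroid_distances.tsv", header, index_label="group")
        paths["centroid_distances"] = out / "centroid_distances.tsv"
        for s, ranking in table.control_ranking.items():
            summary[f"nearest_control_{s}"] = ranking[0]
        dendro = hierarchical_cluster(filtered)
        (out / "sample_dendrogram.nwk").write_text(dendro.to_newick() + "\n")
        paths["sample_dendrogram"] = out / "sample_dendrogram.nwk"

        # -- co-expression network ---------------------------------------
        stage = "network"
        net_cfg = config.network_config()
        net_matrix, net_report = network_prefilter(
            filtered, suffixes=tuple(config.suffix_list),
            variance_quantile=config.variance_quantile)
        summary["n_network_genes"] = net_matrix.n_genes
        power, fit_table = select_soft_power(net_matrix, net_cfg)
        _write_table(fit_table, out / "soft_power_fit.tsv", header, index_label=None)
        summary["soft_power"] = power
        modules = detect_modules(net_matrix, power, net_cfg)
        _write_table(modules.labels.rename("module").to_frame(), out / "modules.tsv",
                     header, index_label="gene_id")
        paths["modules"] = out / "modules.tsv"
        summary["n_modules"] = len(modules.module_ids)
        if modules.module_ids:
            eigengenes = module_eigengenes(net_matrix, modules)
            _write_table(eigengenes, out / "eigengenes.tsv", header, index_label="module")
            paths["eigengenes"] = out / "eigengenes.tsv"
            if eigengenes.shape[0] >= 2:
                families = cluster_families(eigengenes, cut_height=config.family_cut_height)
                _write_table(families.labels.to_frame(), out / "families.tsv",
                             header, index_label="module")
                (out / "family_tree.nwk").write_text(families.to_newick() + "\n")
                summary["n_families"] = int(families.labels.nunique())
            traits = subgroup_traits(net_matrix.metadata)
            r, p = trait_association(eigengenes, traits)
            _write_table(r, out / "trait_correlation.tsv", header, index_label="module")
            _write_table(p, out / "trait_p.tsv", header, index_label="module")
            paths["trait_correlation"] = out / "trait_correlation.tsv"

            stage = "alignment"
            levels = control_stage_levels(net_matrix) if config.trait_encoding == "control_mean" else None
            hypotheses = score_alignment_orders(
                eigengenes, net_matrix.metadata, orientation=config.alignment_orientation,
                encoding=config.trait_encoding, control_level=levels)
            rows = [{
                "rank": i + 1,
                "order": " < ".join(s for s, _ in sorted(h.stage_map.items(), key=lambda kv: kv[1])),
                **{f"stage_{s}": st for s, st in sorted(h.stage_map.items())},
                "score_r": h.score,
                "best_module": h.best_module,
                "best_module_p": float(h.module_p[h.best_module]),
            } for i, h in enumerate(hypotheses)]
            _write_table(pd.DataFrame(rows).set_index("rank"), out / "alignment_orders.tsv", header,
                         index_label="rank")
            paths["alignment_orders"] = out / "alignment_orders.tsv"
            best = hypotheses[0]
            summary["best_alignment_order"] = rows[0]["order"]
            summary["best_alignment_r"] = round(best.score, 4)

        # -- enrichment ---------------------------------------------------
        stage = "enrichment"
        if config.gmt_path:
            collection = load_collection(config.gmt_path, filtered.gene_ids)
            enr_dir = out / "enrichment"
            for s in calls.classes.columns:
                genes = calls.exclusive_genes(s)
                if not genes:
                    log_lines.append(f"enrichment for {s} skipped: empty exclusive set")
                    continue
                try:
                    table = overrepresentation(genes, collection)
                except ValueError as exc:
                    log_lines.append(f"enrichment for {s} skipped: {exc}")
                    continue
                _write_table(table, enr_dir / f"exclusive_{s}.tsv", header, index_label=None)
            paths["enrichment_dir"] = enr_dir
        else:
            log_lines.append("stage enrichment skipped: no gmt_path configured")

        # -- summary ------------------------------------------------------
        stage = "summary"
        summary_df = pd.DataFrame(sorted(summary.items()), columns=["key", "value"]).set_index("key")
        _write_table(summary_df, out / "summary.tsv", header, index_label="key")
        paths["summary"] = out / "summary.tsv"
        (out / "run_log.txt").write_text("\n".join(log_lines) + "\n")
        paths["run_log"] = out / "run_log.txt"
        return paths
    except PipelineError:
        raise
    except Exception as exc:  # annotate and mark partial outputs
        (out / "FAILED").write_text(f"stage={stage}\nerror={exc}\n")
        raise PipelineError(stage, exc) from exc
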