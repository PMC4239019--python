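"""Synthetic expression cohorts with planted ground truth.

The generator emulates the statistical structure the downstream analyses
assume: a small panel of ordered developmental control groups (one of which
may be a single pooled profile), tumour subgroups whose transcriptomes sit
at latent positions on the same developmental axis, co-expression modules
whose expression is monotone in developmental stage, subgroup-exclusive
over-expressed marker genes, log-normal intensity noise, and a fraction of
probe sets whose intensities fall below the linear detection limit
(200 units).

Everything is simulated in log2 space; the detection rule is applied on the
linear scale (2**x) downstream.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .matrix import ExpressionMatrix, read_expression, write_expression

DETECTION_LIMIT_LINEAR = 200.0
_LOG2_DETECTION = math.log2(DETECTION_LIMIT_LINEAR)


@dataclass(frozen=True)
class CohortDesign:
    """Group structure of a cohort.

    ``control_groups`` is an ordered list of ``(label, n, stage_index)``;
    stage indices must be distinct and cover 1..K. ``tumor_groups`` is a list
    of ``(label, n, true_stage_index)`` giving each subgroup's latent position
    on the same stage axis.
    """

    control_groups: tuple[tuple[str, int, int], ...]
    tumor_groups: tuple[tuple[str, int, int], ...]
    n_genes: int = 1200

    def __post_init__(self):
        object.__setattr__(self, "control_groups", tuple(tuple(g) for g in self.control_groups))
        object.__setattr__(self, "tumor_groups", tuple(tuple(g) for g in self.tumor_groups))
        if not self.control_groups:
            raise ValueError("at least one control group is required")
        k = len(self.control_groups)
        stages = sorted(s for _, _, s in self.control_groups)
        if stages != list(range(1, k + 1)):
            raise ValueError(f"control stage indices must be distinct and cover 1..{k}, got {stages}")
        labels = [g for g, _, _ in self.control_groups] + [g for g, _, _ in self.tumor_groups]
        if len(set(labels)) != len(labels):
            raise ValueError("group labels must be unique")
        for label, n, _ in self.control_groups + self.tumor_groups:
            if n < 1:
                raise ValueError(f"group {label!r} must have n >= 1")
        for label, _, s in self.tumor_groups:
            if not 1 <= s <= k:
                raise ValueError(f"tumor group {label!r} stage {s} outside 1..{k}")
        if self.n_genes < 1:
            raise ValueError("n_genes must be positive")

    @property
    def n_stages(self) -> int:
        return len(self.control_groups)

    @property
    def stage_map(self) -> dict[str, int]:
        return {label: stage for label, _, stage in self.tumor_groups}

    @property
    def n_samples(self) -> int:
        return sum(n for _, n, _ in self.control_groups) + sum(n for _, n, _ in self.tumor_groups)


@dataclass(frozen=True)
class SimulationParams:
    """Tunable knobs of the generative model (log2 units throughout)."""

    baseline_log2_mean: float = 9.0
    baseline_log2_sd: float = 0.8
    noise_sd: float = 0.5
    n_gradient_modules: int = 5
    genes_per_module: int = 40
    gradient_slope: float = 0.5
    n_exclusive_markers_per_subgroup: int = 25
    marker_effect: float = 2.0
    module_loading_sd: float = 1.0
    fraction_below_detection: float = 0.1
    fraction_cross_hyb: float = 0.05
    seed: int = 0

    def __post_init__(self):
        for name in ("baseline_log2_sd", "noise_sd", "module_loading_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.marker_effect <= 0:
            raise ValueError("marker_effect must be positive")
        if not 0 <= self.fraction_below_detection < 1:
            raise ValueError("fraction_below_detection must be in [0, 1)")
        if not 0 <= self.fraction_cross_hyb < 1:
            raise ValueError("fraction_cross_hyb must be in [0, 1)")
        for name in ("n_gradient_modules", "genes_per_module", "n_exclusive_markers_per_subgroup"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass
class PlantedTruth:
    """Ground truth of one simulated cohort.

    ``module_membership`` maps every gene to a module id (0 = none);
    ``marker_sets`` maps each tumour subgroup to its planted exclusive
    markers; ``stage_map`` records each subgroup's latent stage.
    """

    module_membership: pd.Series
    marker_sets: dict[str, list[str]]
    stage_map: dict[str, int]
    below_detection: list[str]
    baselines: pd.Series
    marker_effect: float
    gradient_slope: float

    def __post_init__(self):
        all_markers = [g for s in self.marker_sets.values() for g in s]
        if len(set(all_markers)) != len(all_markers):
            raise ValueError("marker sets must be pairwise disjoint")
        module_genes = set(self.module_membership.index[self.module_membership > 0])
        if module_genes & set(all_markers):
            raise ValueError("module genes must be disjoint from marker genes")

    @property
    def module_genes(self) -> list[str]:
        return list(self.module_membership.index[self.module_membership > 0])

    @property
    def marker_genes(self) -> list[str]:
        return [g for s in self.marker_sets.values() for g in s]


def paper_cohort_design(n_genes: int = 1200) -> CohortDesign:
    """The study-realistic default design.

    Controls: NSC (n=3, stage 1), NPC (n=3, stage 2), NFGM (n=2, stage 3) and
    the single pooled NFB profile (n=1, stage 4). Tumour subgroups: WNT (n=8),
    SHH (n=21), Group 3 (n=22) and Group 4 (n=14), with latent stages mirroring
    the WNT < SHH < Group 3 < Group 4 differentiation continuum.
    """
    return CohortDesign(
        control_groups=(("NSC", 3, 1), ("NPC", 3, 2), ("NFGM", 2, 3), ("NFB", 1, 4)),
        tumor_groups=(("WNT", 8, 1), ("SHH", 21, 2), ("Group3", 22, 3), ("Group4", 14, 4)),
        n_genes=n_genes,
    )


def _sample_table(design: CohortDesign) -> pd.DataFrame:
    rows = []
    for label, n, stage in design.control_groups:
        for i in range(n):
            rows.append((f"{label}_{i + 1}", label, "control", float(stage), stage))
    for label, n, stage in design.tumor_groups:
        for i in range(n):
            rows.append((f"{label}_{i + 1}", label, "tumor", np.nan, stage))
    df = pd.DataFrame(rows, columns=["sample_id", "group", "kind", "stage_index", "latent_stage"])
    return df.set_index("sample_id")


def simulate_cohort(
    design: CohortDesign,
    params: SimulationParams,
    truth: PlantedTruth | None = None,
) -> tuple[ExpressionMatrix, PlantedTruth]:
    """Draw one cohort from the generative model.

    When ``truth`` is given (from a previous call with a compatible design),
    the gene roles, baselines and stage map are reused and only the noise and
    per-module latent factors are redrawn — producing an independent cohort
    that shares the planted structure (e.g. a labelled reference cohort for
    classification).
    """
    rng = np.random.default_rng(params.seed)
    n_modules = params.n_gradient_modules
    n_module_genes = n_modules * params.genes_per_module
    subgroups = [label for label, _, _ in design.tumor_groups]
    n_marker_genes = params.n_exclusive_markers_per_subgroup * len(subgroups)
    if n_module_genes + n_marker_genes > design.n_genes:
        raise ValueError(
            f"gene budget exceeded: {n_module_genes} module + {n_marker_genes} marker genes "
            f"> n_genes = {design.n_genes}"
        )

    samples = _sample_table(design)
    n_samples = len(samples)
    latent_stage = samples["latent_stage"].to_numpy(float)

    if truth is None:
        gene_ids = np.array([f"{200000 + i}_at" for i in range(design.n_genes)], dtype=object)
        order = rng.permutation(design.n_genes)

        module_of = np.zeros(design.n_genes, dtype=int)
        role = np.array(["background"] * design.n_genes, dtype=object)
        pos = 0
        for m in range(1, n_modules + 1):
            idx = order[pos : pos + params.genes_per_module]
            module_of[idx] = m
            role[idx] = "module"
            pos += params.genes_per_module
        marker_sets_idx: dict[str, np.ndarray] = {}
        for label in subgroups:
            idx = order[pos : pos + params.n_exclusive_markers_per_subgroup]
            marker_sets_idx[label] = idx
            role[idx] = "marker"
            pos += params.n_exclusive_markers_per_subgroup

        background = np.flatnonzero(role == "background")
        n_below = int(round(params.fraction_below_detection * len(background)))
        below_idx = background[: n_below]  # background order is already rng-permuted
        role[below_idx] = "below_detection"
        remaining = np.flatnonzero(role == "background")
        n_xat = int(round(params.fraction_cross_hyb * len(remaining)))
        for i in remaining[:n_xat]:
            gene_ids[i] = gene_ids[i].replace("_at", "_x_at")

        baselines = rng.normal(params.baseline_log2_mean, params.baseline_log2_sd, design.n_genes)
        # keep planted-signal and ordinary background genes above the
        # detection floor so detectability is governed by one parameter
        baselines = np.maximum(baselines, _LOG2_DETECTION + 0.2)
        baselines[below_idx] = rng.uniform(4.0, 6.0, n_below)

        membership = pd.Series(module_of, index=gene_ids, name="module")
        marker_sets = {label: [gene_ids[i] for i in idx] for label, idx in marker_sets_idx.items()}
        truth = PlantedTruth(
            module_membership=membership,
            marker_sets=marker_sets,
            stage_map=dict(design.stage_map),
            below_detection=[gene_ids[i] for i in below_idx],
            baselines=pd.Series(baselines, index=gene_ids, name="baseline_log2"),
            marker_effect=params.marker_effect,
            gradient_slope=params.gradient_slope,
        )
    else:
        gene_ids = np.asarray(truth.module_membership.index, dtype=object)
        if len(gene_ids) != design.n_genes:
            raise ValueError("reused truth does not match design.n_genes")

    gene_index = pd.Index(gene_ids)
    baselines = truth.baselines.loc[gene_index].to_numpy(float)
    module_of = truth.module_membership.loc[gene_index].to_numpy(int)

    expected = np.tile(baselines[:, None], (1, n_samples))
    in_module = module_of > 0
    expected[in_module, :] += truth.gradient_slope * latent_stage[None, :]
    group_arr = samples["group"].to_numpy(object)
    for label, markers in truth.marker_sets.items():
        gidx = gene_index.get_indexer(markers)
        sidx = np.flatnonzero(group_arr == label)
        expected[np.ix_(gidx, sidx)] += truth.marker_effect

    values = expected.copy()
    if params.module_loading_sd > 0 and in_module.any():
        factors = rng.normal(0.0, 1.0, (n_modules, n_samples))
        for m in range(1, n_modules + 1):
            values[module_of == m, :] += params.module_loading_sd * factors[m - 1][None, :]
    else:
        rng.normal(0.0, 1.0, (n_modules, n_samples))  # keep the draw order stable
    values += params.noise_sd * rng.standard_normal((design.n_genes, n_samples))

    meta = samples.drop(columns="latent_stage")
    matrix = ExpressionMatrix(
        pd.DataFrame(values, index=gene_index, columns=samples.index), meta, scale="log2"
    )
    return matrix, truth


# -- fixture I/O ---------------------------------------------------------------

TRUTH_FILES = {
    "modules": "truth_modules.tsv",
    "markers": "truth_markers.tsv",
    "stage_map": "truth_stage_map.tsv",
    "below_detection": "truth_below_detection.tsv",
    "baselines": "truth_baselines.tsv",
    "effects": "truth_effects.tsv",
}


def write_fixture(matrix: ExpressionMatrix, truth: PlantedTruth, directory) -> dict[str, Path]:
    """Write expression, metadata and ground-truth tables as TSV; returns paths."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "expression": directory / "expression.tsv",
        "metadata": directory / "metadata.tsv",
    }
    write_expression(matrix, paths["expression"], paths["metadata"])
    for key, fname in TRUTH_FILES.items():
        paths[key] = directory / fname
    truth.module_membership.rename_axis("gene_id").to_csv(paths["modules"], sep="\t")
    marker_rows = [(s, g) for s, genes in truth.marker_sets.items() for g in genes]
    pd.DataFrame(marker_rows, columns=["subgroup", "gene_id"]).to_csv(paths["markers"], sep="\t", index=False)
    pd.DataFrame(
        sorted(truth.stage_map.items()), columns=["subgroup", "stage_index"]
    ).to_csv(paths["stage_map"], sep="\t", index=False)
    pd.DataFrame({"gene_id": truth.below_detection}).to_csv(paths["below_detection"], sep="\t", index=False)
    truth.baselines.rename_axis("gene_id").to_csv(paths["baselines"], sep="\t")
    pd.DataFrame(
        [("marker_effect", truth.marker_effect), ("gradient_slope", truth.gradient_slope)],
        columns=["parameter", "value"],
    ).to_csv(paths["effects"], sep="\t", index=False)
    return paths


def read_fixture(directory) -> tuple[ExpressionMatrix, PlantedTruth]:
    """Read back a fixture written by :func:`write_fixture` (lossless round trip)."""
    directory = Path(directory)
    matrix = read_expression(directory / "expression.tsv", directory / "metadata.tsv")
    membership = pd.read_csv(directory / TRUTH_FILES["modules"], sep="\t", index_col=0)["module"]
    membership.index = membership.index.astype(str)
    markers_df = pd.read_csv(directory / TRUTH_FILES["markers"], sep="\t")
    marker_sets: dict[str, list[str]] = {}
    for subgroup, sub in markers_df.groupby("subgroup", sort=False):
        marker_sets[str(subgroup)] = [str(g) for g in sub["gene_id"]]
    stage_df = pd.read_csv(directory / TRUTH_FILES["stage_map"], sep="\t")
    stage_map = {str(r.subgroup): int(r.stage_index) for r in stage_df.itertuples()}
    below = pd.read_csv(directory / TRUTH_FILES["below_detection"], sep="\t")
    baselines = pd.read_csv(directory / TRUTH_FILES["baselines"], sep="\t", index_col=0)["baseline_log2"]
    baselines.index = baselines.index.astype(str)
    effects = pd.read_csv(directory / TRUTH_FILES["effects"], sep="\t").set_index("parameter")["value"]
    truth = PlantedTruth(
        module_membership=membership.astype(int),
        marker_sets=marker_sets,
        stage_map=stage_map,
        below_detection=[str(g) for g in below["gene_id"]] if len(below) else [],
        baselines=baselines.astype(float),
        marker_effect=float(effects["marker_effect"]),
        gradient_slope=float(effects["gradient_slope"]),
    )
    return matrix, truth
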