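"""Study-scale recovery experiments on the synthetic cohort.

These functions run the pipeline's stages against cohorts drawn at the
study's group sizes (WNT 8, SHH 21, Group 3 22, Group 4 14 tumours; NSC 3,
NPC 3, NFGM 2, NFB 1 controls) and measure how well the planted structure is
recovered: exclusive-marker precision/recall, module adjusted Rand index,
alignment-order top-1 rate, centroid nearest-control recovery, and the
permutation calibration of the trait-association test. They back both the
acceptance script and the heavier end of the test suite.

Per-replicate seeds are spawned deterministically from one base seed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from .intersect import run_all_comparisons, stepwise_exclusive
from .network import (
    NetworkConfig, detect_modules, module_eigengenes, score_alignment_orders, select_soft_power,
)
from .ordination import group_centroids, pca
from .preprocess import detection_filter, network_prefilter
from .simulate import PlantedTruth, SimulationParams, paper_cohort_design, simulate_cohort


def spawn_seeds(base_seed: int, n: int) -> list[int]:
    """n reproducible 31-bit child seeds from one base seed."""
    ss = np.random.SeedSequence(base_seed)
    return [int(s % (2**31)) for s in ss.generate_state(n, dtype=np.uint64)]


def _default_cohort(seed: int, **overrides) -> tuple:
    design = paper_cohort_design()
    params = SimulationParams(seed=seed, **overrides)
    return simulate_cohort(design, params)


# -- marker recovery -----------------------------------------------------------

@dataclass
class MarkerRecovery:
    precision: list[float]
    recall: list[float]

    @property
    def median_precision(self) -> float:
        return float(np.median(self.precision))

    @property
    def median_recall(self) -> float:
        return float(np.median(self.recall))


def marker_recovery(n_seeds: int = 50, base_seed: int = 0, noise_sd: float = 0.5,
                    marker_effect: float = 2.0, alpha: float = 0.05) -> MarkerRecovery:
    """Precision/recall of exclusivity calls against the planted marker sets.

    For each replicate cohort: detection filter, all pair-wise comparisons,
    the step-wise exclusivity intersect (direction up), then pooled
    precision/recall of the per-subgroup exclusive sets against the planted
    markers.
    """
    precisions, recalls = [], []
    for seed in spawn_seeds(base_seed, n_seeds):
        matrix, truth = _default_cohort(seed, noise_sd=noise_sd, marker_effect=marker_effect)
        filtered, _ = detection_filter(matrix)
        calls = stepwise_exclusive(run_all_comparisons(filtered, alpha=alpha), direction="up",
                                   alpha=alpha)
        tp = fp = fn = 0
        for s in calls.classes.columns:
            called = set(calls.exclusive_genes(s))
            planted = set(truth.marker_sets[s]) & set(filtered.gene_ids)
            tp += len(called & planted)
            fp += len(called - planted)
            fn += len(planted - called)
        precisions.append(tp / (tp + fp) if tp + fp else 0.0)
        recalls.append(tp / (tp + fn) if tp + fn else 0.0)
    return MarkerRecovery(precision=precisions, recall=recalls)


# -- module recovery -----------------------------------------------------------

def module_recovery(n_seeds: int = 20, base_seed: int = 1, noise_sd: float = 0.5,
                    config: NetworkConfig = NetworkConfig()) -> list[float]:
    """Adjusted Rand index between detected modules and the planted 5-module
    partition, evaluated on planted-module genes surviving the prefilter."""
    aris = []
    for seed in spawn_seeds(base_seed, n_seeds):
        matrix, truth = _default_cohort(seed, noise_sd=noise_sd)
        filtered, _ = detection_filter(matrix)
        net, _ = network_prefilter(filtered)
        power, _ = select_soft_power(net, config)
        modules = detect_modules(net, power, config)
        planted = truth.module_membership
        eval_genes = [g for g in net.gene_ids if planted.get(g, 0) > 0]
        detected = modules.labels.loc[eval_genes].to_numpy()
        aris.append(float(adjusted_rand_score(planted.loc[eval_genes].to_numpy(), detected)))
    return aris


# -- alignment-order recovery --------------------------------------------------

def _planted_eigengenes(matrix, truth: PlantedTruth):
    """Eigengenes computed from the planted module memberships."""
    from .network import ModuleSet

    members = truth.module_membership.loc[[g for g in matrix.gene_ids]]
    modules = ModuleSet(labels=members.astype(int), power=0, linkage=np.empty((0, 4)), cut_height=0.0)
    return module_eigengenes(matrix, modules)


def alignment_recovery(n_seeds: int = 100, base_seed: int = 2, gradient_slope: float = 1.5,
                       noise_sd: float = 0.5) -> dict:
    """How often the planted subgroup -> stage map ranks first among all 24
    injective alignment orders, scored on planted-module eigengenes."""
    hits = 0
    best_rs = []
    for seed in spawn_seeds(base_seed, n_seeds):
        matrix, truth = _default_cohort(seed, noise_sd=noise_sd, gradient_slope=gradient_slope)
        eigengenes = _planted_eigengenes(matrix, truth)
        hypotheses = score_alignment_orders(eigengenes, matrix.metadata)
        if hypotheses[0].stage_map == truth.stage_map:
            hits += 1
        best_rs.append(hypotheses[0].score)
    return {"top1_rate": hits / n_seeds, "n_seeds": n_seeds,
            "mean_best_r": float(np.mean(best_rs))}


def noise_free_alignment(seed: int = 0, gradient_slope: float = 1.5) -> dict:
    """The noise-free limit: the planted map must score r = 1 and rank first."""
    matrix, truth = _default_cohort(seed, noise_sd=0.0, module_loading_sd=0.0,
                                    gradient_slope=gradient_slope)
    eigengenes = _planted_eigengenes(matrix, truth)
    hypotheses = score_alignment_orders(eigengenes, matrix.metadata)
    return {"recovered": hypotheses[0].stage_map == truth.stage_map,
            "score": hypotheses[0].score}


# -- centroid nearest-control recovery ----------------------------------------

def centroid_recovery(n_seeds: int = 100, base_seed: int = 3, gradient_slope: float = 1.5,
                      noise_sd: float = 0.5, components=(1, 2, 3, 4)) -> dict:
    """How often the nearest-control ranking recovers the planted stage for
    every tumour subgroup simultaneously."""
    hits = 0
    for seed in spawn_seeds(base_seed, n_seeds):
        matrix, truth = _default_cohort(seed, noise_sd=noise_sd, gradient_slope=gradient_slope)
        filtered, _ = detection_filter(matrix)
        ordination = pca(filtered, n_components=max(components))
        table = group_centroids(ordination, filtered.metadata, components)
        stage_of_control = {filtered.stage_of_group(c): c
                            for c in filtered.groups(kind="control")}
        ok = all(
            table.nearest_control(s) == stage_of_control[truth.stage_map[s]]
            for s in filtered.groups(kind="tumor")
        )
        hits += ok
    return {"recovery_rate": hits / n_seeds, "n_seeds": n_seeds}


# -- trait-association calibration ---------------------------------------------

def trait_typeI_error(n_draws: int = 10_000, seed: int = 4, alpha: float = 0.05) -> dict:
    """Empirical type-I error of the trait-association p-value under a
    permutation null.

    One standard-normal pseudo-eigengene over the cohort's samples is held
    fixed; the binary subgroup trait is permuted ``n_draws`` times and the
    t-approximation p-value recomputed each time. The rejection rate at
    ``alpha`` estimates the test's size.
    """
    from .network import _cor_and_p

    design = paper_cohort_design()
    n = design.n_samples
    rng = np.random.default_rng(seed)
    e = rng.standard_normal(n)
    n1 = [size for _, size, _ in design.tumor_groups][2]  # Group 3, n = 22
    base_trait = np.zeros(n)
    base_trait[:n1] = 1.0
    rejections = 0
    for _ in range(n_draws):
        t = rng.permutation(base_trait)
        _, p = _cor_and_p(e, t)
        rejections += p < alpha
    return {"type_i_error": rejections / n_draws, "n_draws": n_draws}
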