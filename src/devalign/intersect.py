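"""Developmental intersect analysis: per-comparison statistics and the
step-wise exclusivity classifier.

Each tumour subgroup is compared pair-wise to every control group. Groups
with n > 1 are compared by a per-gene two-sided t test (pooled-variance
Student by default, Welch by flag) with fold changes reported as linear
ratios of group means. A single-profile control is compared by its sigma-fold
deviation from the subgroup distribution, with membership decided by a
standard-deviation cutoff. The step-wise intersect then classifies each gene,
per subgroup, as exclusive ("$"), shared ("∧") or none: exclusive means
significantly differential in the requested direction against every
multi-sample control, and in no other subgroup.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

DEFAULT_ALPHA = 0.05
DEFAULT_K_SIGMA = 2.0


@dataclass
class GroupStats:
    """Per-gene, per-group moments: mean, stdev, median, variance (log2 units)."""

    table: pd.DataFrame  # MultiIndex columns (group, statistic)
    group_sizes: dict[str, int]

    def for_group(self, group: str) -> pd.DataFrame:
        return self.table[group]


def compute_group_stats(matrix) -> GroupStats:
    """Exact per-group moments; single-sample groups report NaN stdev/variance."""
    pieces = {}
    sizes = {}
    for group in matrix.groups():
        sub = matrix.group_values(group)
        if sub.shape[1] == 0:
            raise ValueError(f"group {group!r} is empty")
        sizes[group] = sub.shape[1]
        pieces[group] = pd.DataFrame(
            {
                "mean": sub.mean(axis=1),
                "stdev": sub.std(axis=1, ddof=1),  # NaN for n = 1
                "median": sub.median(axis=1),
                "variance": sub.var(axis=1, ddof=1),
                "n": sub.shape[1],
            }
        )
    table = pd.concat(pieces, axis=1)
    return GroupStats(table=table, group_sizes=sizes)


@dataclass
class DEComparisonResult:
    """Per-gene statistics for one (subgroup, control) comparison.

    ``kind`` is ``"ttest"`` for multi-sample controls (columns t, p,
    fold_change, direction) or ``"sigma"`` for a single-profile control
    (columns sigma_fold, membership, direction). Fold change is the linear
    ratio 2**(mean_A - mean_B); direction is from A's point of view.
    """

    subgroup: str
    control: str
    kind: str
    table: pd.DataFrame
    alpha: float = DEFAULT_ALPHA
    k_sigma: float = DEFAULT_K_SIGMA
    n_subgroup: int = 0
    n_control: int = 0


def _student_t(mean_a, mean_b, var_a, var_b, na, nb):
    df = na + nb - 2
    sp2 = ((na - 1) * var_a + (nb - 1) * var_b) / df
    se = np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    return (mean_a - mean_b), se, np.full_like(se, float(df))


def _welch_t(mean_a, mean_b, var_a, var_b, na, nb):
    va, vb = var_a / na, var_b / nb
    se = np.sqrt(va + vb)
    with np.errstate(divide="ignore", invalid="ignore"):
        df = (va + vb) ** 2 / (va**2 / (na - 1) + vb**2 / (nb - 1))
    return (mean_a - mean_b), se, df


def pairwise_test(matrix, group_a: str, group_b: str, alpha: float = DEFAULT_ALPHA,
                  variant: str = "student") -> DEComparisonResult:
    """Two-sided per-gene t test of group A versus group B.

    Degenerate genes (zero variance in both groups) get t = 0, p = 1 when the
    means are equal, and p = 0 with the sign of the difference otherwise.
    """
    a = matrix.group_values(group_a).to_numpy(float)
    b = matrix.group_values(group_b).to_numpy(float)
    na, nb = a.shape[1], b.shape[1]
    if na < 2 or nb < 2:
        raise ValueError(
            f"pairwise_test needs n >= 2 in both groups (got {na} and {nb}); "
            "use single_reference_membership for single-profile references"
        )
    if variant not in ("student", "welch"):
        raise ValueError(f"unknown t-test variant {variant!r}")
    mean_a, mean_b = a.mean(axis=1), b.mean(axis=1)
    var_a, var_b = a.var(axis=1, ddof=1), b.var(axis=1, ddof=1)
    diff, se, df = (_student_t if variant == "student" else _welch_t)(
        mean_a, mean_b, var_a, var_b, na, nb
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / se
        p = 2.0 * stats.t.sf(np.abs(t), df)
    degenerate = se == 0
    if degenerate.any():
        equal = degenerate & (diff == 0)
        t[equal], p[equal] = 0.0, 1.0
        unequal = degenerate & (diff != 0)
        t[unequal] = np.sign(diff[unequal]) * np.inf
        p[unequal] = 0.0
    fold_change = np.power(2.0, diff) if matrix.scale == "log2" else mean_a / mean_b
    direction = np.where(p < alpha, np.where(diff > 0, "up", "down"), "ns")
    direction = np.where((p < alpha) & (diff == 0), "ns", direction)
    table = pd.DataFrame(
        {"t": t, "p": p, "fold_change": fold_change, "mean_diff": diff, "direction": direction},
        index=matrix.values.index,
    )
    return DEComparisonResult(
        subgroup=group_a, control=group_b, kind="ttest", table=table,
        alpha=alpha, n_subgroup=na, n_control=nb,
    )


def single_reference_membership(matrix, subgroup: str, reference_group: str,
                                k: float = DEFAULT_K_SIGMA) -> DEComparisonResult:
    """Sigma-fold membership test of a single reference profile.

    ``sigma_fold = (x_ref - mean_S) / stdev_S``; the reference is *inside* the
    subgroup distribution iff |sigma_fold| <= k. Direction is from the
    subgroup's point of view: ``up`` (S over-expressed relative to the
    reference) iff the reference lies more than k standard deviations below
    the subgroup mean. A zero-stdev gene is inside iff exactly equal.
    """
    s = matrix.group_values(subgroup).to_numpy(float)
    ref = matrix.group_values(reference_group).to_numpy(float)
    if s.shape[1] < 2:
        raise ValueError(f"subgroup {subgroup!r} needs n >= 2")
    if ref.shape[1] != 1:
        raise ValueError(f"reference group {reference_group!r} must hold a single sample")
    x_ref = ref[:, 0]
    mean_s = s.mean(axis=1)
    sd_s = s.std(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        sigma_fold = (x_ref - mean_s) / sd_s
    zero_sd = sd_s == 0
    sigma_fold[zero_sd] = np.where(x_ref[zero_sd] == mean_s[zero_sd], 0.0,
                                   np.sign(x_ref[zero_sd] - mean_s[zero_sd]) * np.inf)
    inside = np.abs(sigma_fold) <= k
    direction = np.where(sigma_fold < -k, "up", np.where(sigma_fold > k, "down", "ns"))
    fold_change = (
        np.power(2.0, mean_s - x_ref) if matrix.scale == "log2"
        else mean_s / x_ref
    )
    table = pd.DataFrame(
        {
            "sigma_fold": sigma_fold,
            "membership": np.where(inside, "inside", "outside"),
            "fold_change": fold_change,
            "mean_diff": mean_s - x_ref,
            "direction": direction,
        },
        index=matrix.values.index,
    )
    return DEComparisonResult(
        subgroup=subgroup, control=reference_group, kind="sigma", table=table,
        k_sigma=k, n_subgroup=s.shape[1], n_control=1,
    )


@dataclass
class ExclusivityCall:
    """Cross-comparison classification: gene x subgroup -> class and support.

    ``classes`` holds ``exclusive`` ("$"), ``shared`` ("∧") or ``none``;
    ``corroborated`` records whether every single-profile control also lay
    outside the subgroup distribution in the same direction (supporting, but
    never required, evidence).
    """

    classes: pd.DataFrame
    corroborated: pd.DataFrame
    direction: str
    alpha: float

    def exclusive_genes(self, subgroup: str) -> list[str]:
        col = self.classes[subgroup]
        return list(col.index[col == "exclusive"])

    def shared_genes(self, subgroup: str) -> list[str]:
        col = self.classes[subgroup]
        return list(col.index[col == "shared"])


def stepwise_exclusive(results: list[DEComparisonResult], direction: str = "up",
                       alpha: float | None = None) -> ExclusivityCall:
    """The step-wise intersect protocol.

    Step 1 — a gene passes for subgroup S iff p < alpha with the stated
    direction against *every* control with n > 1 (single-profile controls
    contribute corroboration only). Step 2 — a passing gene is ``exclusive``
    for S iff no other subgroup also passed, otherwise ``shared``; genes
    failing step 1 are ``none``.
    """
    if direction not in ("up", "down"):
        raise ValueError("direction must be 'up' or 'down'")
    if not results:
        raise ValueError("no comparison results provided (cohort without tumour groups?)")
    subgroups = list(dict.fromkeys(r.subgroup for r in results))
    controls_t = list(dict.fromkeys(r.control for r in results if r.kind == "ttest"))
    controls_s = list(dict.fromkeys(r.control for r in results if r.kind == "sigma"))
    by_pair = {(r.subgroup, r.control): r for r in results}
    missing = [
        (s, c) for s in subgroups for c in controls_t + controls_s if (s, c) not in by_pair
    ]
    if missing:
        raise ValueError(f"missing comparisons for pairs: {missing}")
    genes = results[0].table.index
    if alpha is None:
        alpha = results[0].alpha

    passed = pd.DataFrame(True, index=genes, columns=subgroups)
    for s in subgroups:
        for c in controls_t:
            tab = by_pair[(s, c)].table
            ok = (tab["p"].to_numpy() < alpha) & (
                np.sign(tab["mean_diff"].to_numpy()) == (1 if direction == "up" else -1)
            )
            passed[s] &= ok
    corroborated = pd.DataFrame(True, index=genes, columns=subgroups)
    for s in subgroups:
        for c in controls_s:
            tab = by_pair[(s, c)].table
            corroborated[s] &= (tab["membership"] == "outside").to_numpy() & (
                tab["direction"] == direction
            ).to_numpy()

    n_passing = passed.sum(axis=1)
    classes = pd.DataFrame("none", index=genes, columns=subgroups, dtype=object)
    for s in subgroups:
        classes.loc[passed[s] & (n_passing == 1), s] = "exclusive"
        classes.loc[passed[s] & (n_passing > 1), s] = "shared"
    return ExclusivityCall(classes=classes, corroborated=corroborated, direction=direction, alpha=alpha)


def signed_fold(ratio: np.ndarray | float):
    """Render a linear fold ratio as a signed fold: r for r >= 1, -1/r below."""
    ratio = np.asarray(ratio, dtype=float)
    out = np.where(ratio >= 1.0, ratio, -1.0 / ratio)
    return out if out.ndim else float(out)


def top_table(result: DEComparisonResult, n: int | None = None, direction: str = "up",
              alpha: float | None = None) -> pd.DataFrame:
    """Ranked over- or under-expressed genes for one comparison.

    Genes significant in the requested direction, sorted by |fold change|
    descending (ties by gene id). Down-regulated genes are reported with a
    signed fold (-1/ratio), matching the convention of negative fold-change
    columns in published top tables.
    """
    if alpha is None:
        alpha = result.alpha
    tab = result.table
    if result.kind == "ttest":
        sig = (tab["p"] < alpha) & (np.sign(tab["mean_diff"]) == (1 if direction == "up" else -1))
    else:
        sig = tab["direction"] == direction
    sel = tab.loc[sig].copy()
    sel["fch"] = signed_fold(sel["fold_change"].to_numpy())
    sel["abs_fch"] = np.abs(sel["fch"])
    sel = sel.sort_values(["abs_fch"], ascending=False, kind="stable")
    # deterministic tie-break on gene id
    sel = sel.iloc[np.lexsort((sel.index.to_numpy(), -sel["abs_fch"].to_numpy()), )]
    sel = sel.drop(columns="abs_fch")
    if n is not None and n < len(sel):
        sel = sel.iloc[:n]
    return sel.rename_axis("gene_id")


def run_all_comparisons(matrix, alpha: float = DEFAULT_ALPHA, k_sigma: float = DEFAULT_K_SIGMA,
                        variant: str = "student") -> list[DEComparisonResult]:
    """All (tumour subgroup, control) comparisons, routing n = 1 controls to
    the sigma-fold membership test."""
    results = []
    group_n = matrix.metadata.groupby("group", sort=False).size()
    for s in matrix.groups(kind="tumor"):
        for c in matrix.groups(kind="control"):
            if group_n[c] > 1:
                results.append(pairwise_test(matrix, s, c, alpha=alpha, variant=variant))
            else:
                results.append(single_reference_membership(matrix, s, c, k=k_sigma))
    return results
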