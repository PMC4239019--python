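"""Weighted co-expression network: soft-threshold selection by scale-free
fit, topological-overlap module detection, module eigengenes, eigengene
cluster families, binary-trait association and developmental
alignment-order scoring.

The network follows the weighted-correlation-network construction: the
adjacency between genes i and j is |cor(i, j)|**beta (unsigned, the default)
or ((1 + cor)/2)**beta (signed); beta is chosen as the smallest candidate
power whose connectivity distribution approximates a scale-free topology
(log-log regression R^2 above a target), falling back to the best-fitting
power. Modules are branches of an average-linkage tree on 1 - TOM cut at a
static height; each module is summarised by its eigengene (the unit-norm
first principal component of its standardized member genes).

Alignment-order scoring is the network analogue of asking "in which order do
the tumour subgroups continue the developmental control series?": every
injective map of subgroups onto control stages induces a per-sample stage
trait (controls keep their own stage), each eigengene is correlated with
that trait, and a candidate order is scored by its most descriptive module.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from skbio import TreeNode


@dataclass(frozen=True)
class NetworkConfig:
    candidate_powers: tuple[int, ...] = tuple(range(1, 13))
    signed: str = "unsigned"
    min_module_size: int = 20
    tree_cut_height: float = 0.97
    family_cut_height: float = 0.8
    scale_free_r2_target: float = 0.8
    n_bins: int = 10

    def __post_init__(self):
        if any(p < 1 for p in self.candidate_powers):
            raise ValueError("candidate powers must be >= 1")
        if self.signed not in ("signed", "unsigned"):
            raise ValueError("signed must be 'signed' or 'unsigned'")
        if not 0 < self.tree_cut_height <= 1:
            raise ValueError("tree_cut_height must be in (0, 1]")
        if not 0 < self.scale_free_r2_target <= 1:
            raise ValueError("scale_free_r2_target must be in (0, 1]")


def adjacency(matrix, power: float, signed: str = "unsigned") -> pd.DataFrame:
    """Soft-thresholded Pearson adjacency (genes x genes, unit diagonal)."""
    x = matrix.values.to_numpy(float)
    r = np.corrcoef(x)
    r = np.clip(r, -1.0, 1.0)
    a = np.abs(r) ** power if signed == "unsigned" else ((1.0 + r) / 2.0) ** power
    np.fill_diagonal(a, 1.0)
    return pd.DataFrame(a, index=matrix.gene_ids, columns=matrix.gene_ids)


def connectivity(adj: pd.DataFrame) -> pd.Series:
    """Whole-network connectivity k_i = sum_{j != i} a_ij."""
    a = adj.to_numpy(float)
    return pd.Series(a.sum(axis=1) - np.diag(a), index=adj.index, name="k")


def scale_free_fit(k: np.ndarray, n_bins: int = 10) -> tuple[float, float]:
    """Scale-free topology fit of a connectivity distribution.

    Bins k into equal-width bins, regresses log10(frequency per bin) on
    log10(mean k per bin) and returns (R^2, slope). Undefined fits (fewer
    than 3 populated bins, or zero spread) return (nan, nan).
    """
    k = np.asarray(k, dtype=float)
    k = k[k > 0]
    if k.size < 3 or np.ptp(k) == 0:
        return float("nan"), float("nan")
    counts, edges = np.histogram(k, bins=n_bins)
    sums, _ = np.histogram(k, bins=edges, weights=k)
    mask = counts > 0
    if mask.sum() < 3:
        return float("nan"), float("nan")
    mean_k = sums[mask] / counts[mask]
    freq = counts[mask] / counts.sum()
    x, y = np.log10(mean_k), np.log10(freq)
    if np.ptp(x) == 0:
        return float("nan"), float("nan")
    fit = stats.linregress(x, y)
    return float(fit.rvalue**2), float(fit.slope)


def select_soft_power(matrix, config: NetworkConfig = NetworkConfig()) -> tuple[int, pd.DataFrame]:
    """Pick the soft power: smallest candidate with R^2 >= target, else the
    argmax-R^2 fallback (with a warning). Returns the full fit table."""
    if matrix.n_genes < 3:
        raise ValueError("soft power selection needs at least 3 genes")
    rows = []
    for beta in config.candidate_powers:
        adj = adjacency(matrix, beta, config.signed)
        k = connectivity(adj).to_numpy()
        r2, slope = scale_free_fit(k, config.n_bins)
        rows.append({"power": beta, "scale_free_r2": r2, "slope": slope, "mean_k": float(k.mean())})
    table = pd.DataFrame(rows)
    # signed fit: a scale-free degree distribution has a *decreasing* log-log
    # frequency, so positive-slope fits count against a power
    signed_r2 = np.where(table["slope"] < 0, table["scale_free_r2"], -table["scale_free_r2"])
    table["signed_r2"] = signed_r2
    ok = table[table["signed_r2"] >= config.scale_free_r2_target]
    if len(ok):
        power = int(ok.iloc[0]["power"])
    else:
        if table["scale_free_r2"].isna().all():
            warnings.warn("scale-free fit undefined for every candidate power; using the smallest")
            power = int(table.iloc[0]["power"])
        else:
            warnings.warn(
                f"no candidate power reached scale-free R^2 >= {config.scale_free_r2_target}; "
                "falling back to the best-fitting power"
            )
            power = int(table.loc[table["signed_r2"].idxmax(), "power"])
    return power, table


def topological_overlap(adj: pd.DataFrame) -> pd.DataFrame:
    """Topological overlap matrix of a weighted adjacency (unit diagonal).

    TOM_ij = (sum_{u != i,j} a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij).
    """
    a = adj.to_numpy(float)
    np.fill_diagonal(a := a.copy(), 1.0)
    k = a.sum(axis=1) - 1.0
    l = a @ a - 2.0 * a  # sum over u != i,j of a_iu * a_uj (unit diagonal)
    num = l + a
    den = np.minimum.outer(k, k) + 1.0 - a
    with np.errstate(divide="ignore", invalid="ignore"):
        tom = np.where(den > 0, num / den, 0.0)
    np.fill_diagonal(tom, 1.0)
    tom = np.clip((tom + tom.T) / 2.0, 0.0, 1.0)
    return pd.DataFrame(tom, index=adj.index, columns=adj.columns)


@dataclass
class ModuleSet:
    """Gene -> module label (0 = unassigned), with the clustering artefacts."""

    labels: pd.Series
    power: int
    linkage: np.ndarray
    cut_height: float

    @property
    def module_ids(self) -> list[int]:
        return sorted(set(self.labels) - {0})

    @property
    def sizes(self) -> pd.Series:
        return self.labels[self.labels > 0].value_counts().sort_index()

    def genes_in(self, module: int) -> list[str]:
        return list(self.labels.index[self.labels == module])


def detect_modules(matrix, power: int, config: NetworkConfig = NetworkConfig()) -> ModuleSet:
    """Modules as static-height branches of the average-linkage 1 - TOM tree.

    Clusters smaller than ``min_module_size`` are relegated to label 0;
    surviving modules are relabelled 1..M by decreasing size (ties by the
    lexicographically smallest member gene id, so labels do not depend on
    gene order).
    """
    adj = adjacency(matrix, power, config.signed)
    tom = topological_overlap(adj)
    dissim = 1.0 - tom.to_numpy()
    np.fill_diagonal(dissim, 0.0)
    z = hierarchy.linkage(squareform(dissim, checks=False), method="average")
    raw = hierarchy.fcluster(z, t=config.tree_cut_height, criterion="distance")
    genes = tom.index
    labels = pd.Series(raw, index=genes)
    kept = [c for c, size in labels.value_counts().items() if size >= config.min_module_size]
    if not kept:
        warnings.warn("no cluster reached min_module_size; all genes unassigned")
    order = sorted(kept, key=lambda c: (-int((labels == c).sum()), min(genes[labels == c])))
    remap = {c: i + 1 for i, c in enumerate(order)}
    final = labels.map(lambda c: remap.get(c, 0)).astype(int)
    if len(order) == 1:
        warnings.warn("all assigned genes fall in a single module")
    return ModuleSet(labels=final, power=power, linkage=z, cut_height=config.tree_cut_height)


def module_eigengenes(matrix, modules: ModuleSet) -> pd.DataFrame:
    """Eigengene per module: unit-norm first right singular vector of the
    standardized member-gene submatrix, sign-fixed so the mean correlation
    with member genes is non-negative. Returns modules x samples."""
    if not modules.module_ids:
        raise ValueError("module set is empty")
    x = matrix.values
    rows = {}
    for m in modules.module_ids:
        sub = x.loc[modules.genes_in(m)].to_numpy(float)
        mu = sub.mean(axis=1, keepdims=True)
        sd = sub.std(axis=1, ddof=1, keepdims=True)
        sd[sd == 0] = 1.0
        z = (sub - mu) / sd
        _, _, vt = np.linalg.svd(z, full_matrices=False)
        v = vt[0]
        v = v / np.linalg.norm(v)
        member_cor = np.array([_pearson(v, row) for row in z])
        if np.nanmean(member_cor) < 0:
            v = -v
        rows[f"ME{m}"] = v
    return pd.DataFrame(rows, index=matrix.sample_ids).T


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    denom = np.linalg.norm(a) * np.linalg.norm(b)
    return float(a @ b / denom) if denom > 0 else float("nan")


@dataclass
class FamilySet:
    """Eigengene cluster families: module -> family label, with the tree."""

    labels: pd.Series           # "ME<m>" -> family int label
    linkage: np.ndarray
    eigengene_ids: list[str]
    cut_height: float

    @property
    def family_names(self) -> dict[int, str]:
        # letters A, B, ... in label order, for display
        return {f: chr(ord("A") + i) for i, f in enumerate(sorted(set(self.labels)))}

    def to_newick(self) -> str:
        tree = TreeNode.from_linkage_matrix(self.linkage, self.eigengene_ids)
        return str(tree).strip()


def cluster_families(eigengenes: pd.DataFrame, cut_height: float = 0.8) -> FamilySet:
    """Average-linkage families on the eigengene correlation distance
    1 - cor(E_i, E_j)."""
    if eigengenes.shape[0] < 2:
        raise ValueError("cluster families need at least 2 modules")
    e = eigengenes.to_numpy(float)
    r = np.clip(np.corrcoef(e), -1.0, 1.0)
    d = 1.0 - r
    np.fill_diagonal(d, 0.0)
    d = np.clip((d + d.T) / 2.0, 0.0, None)
    z = hierarchy.linkage(squareform(d, checks=False), method="average")
    raw = hierarchy.fcluster(z, t=cut_height, criterion="distance")
    labels = pd.Series(raw, index=eigengenes.index, name="family")
    return FamilySet(labels=labels, linkage=z, eigengene_ids=list(eigengenes.index), cut_height=cut_height)


def _cor_and_p(e: np.ndarray, t: np.ndarray) -> tuple[float, float]:
    r = _pearson(e, t)
    if np.isnan(r):
        return r, float("nan")
    n = len(e)
    r_ = min(max(r, -1.0), 1.0)
    if abs(r_) == 1.0:
        return r_, 0.0
    tstat = r_ * np.sqrt((n - 2) / (1.0 - r_**2))
    return r_, float(2.0 * stats.t.sf(abs(tstat), n - 2))


def trait_association(eigengenes: pd.DataFrame, traits: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pearson r and two-sided p (t approximation, df = n - 2) for every
    (module eigengene, binary trait) pair. Constant traits give NaN."""
    bad = [c for c in traits.columns if not set(np.unique(traits[c])) <= {0, 1}]
    if bad:
        raise ValueError(f"traits must be 0/1 vectors; offending columns: {bad}")
    traits = traits.loc[list(eigengenes.columns)]
    r = pd.DataFrame(index=eigengenes.index, columns=traits.columns, dtype=float)
    p = r.copy()
    for me in eigengenes.index:
        e = eigengenes.loc[me].to_numpy(float)
        for trait in traits.columns:
            r.loc[me, trait], p.loc[me, trait] = _cor_and_p(e, traits[trait].to_numpy(float))
    return r, p


def subgroup_traits(metadata: pd.DataFrame) -> pd.DataFrame:
    """Binary membership matrix (samples x tumour subgroups)."""
    tumors = list(dict.fromkeys(metadata.loc[metadata["kind"] == "tumor", "group"]))
    return pd.DataFrame(
        {g: (metadata["group"] == g).astype(int) for g in tumors}, index=metadata.index
    )


@dataclass
class AlignmentHypothesis:
    """One candidate subgroup -> stage map with its per-module correlations."""

    stage_map: dict[str, int]
    module_r: pd.Series
    module_p: pd.Series
    score: float
    best_module: str

    def describe(self) -> str:
        order = " < ".join(s for s, _ in sorted(self.stage_map.items(), key=lambda kv: kv[1]))
        return f"{order} (r = {self.score:.3f} via {self.best_module})"


def induced_stage_trait(metadata: pd.DataFrame, stage_map: dict[str, int],
                        encoding: str = "rank", control_level: pd.Series | None = None) -> pd.Series:
    """Per-sample trait induced by a candidate alignment order.

    Control samples keep their own stage; tumour samples take their mapped
    stage. ``rank`` encoding uses the stage index itself; ``control_mean``
    replaces each stage by the corresponding control group's mean intensity
    (``control_level``: stage -> level).
    """
    values = np.empty(len(metadata), dtype=float)
    for i, (sample, row) in enumerate(metadata.iterrows()):
        stage = row["stage_index"] if row["kind"] == "control" else stage_map[row["group"]]
        if np.isnan(stage):
            raise ValueError(f"control sample {sample} lacks a stage_index")
        stage = int(stage)
        if encoding == "rank":
            values[i] = stage
        elif encoding == "control_mean":
            if control_level is None:
                raise ValueError("control_mean encoding requires control_level")
            values[i] = control_level[stage]
        else:
            raise ValueError(f"unknown trait encoding {encoding!r}")
    return pd.Series(values, index=metadata.index, name="stage_trait")


def control_stage_levels(matrix) -> pd.Series:
    """Mean intensity of each control group, indexed by its stage."""
    levels = {}
    for g in matrix.groups(kind="control"):
        levels[matrix.stage_of_group(g)] = float(matrix.group_values(g).to_numpy().mean())
    return pd.Series(levels).sort_index()


def enumerate_stage_maps(subgroups: list[str], stages: list[int]) -> list[dict[str, int]]:
    """All injective maps of subgroups onto stages (4 subgroups x 4 stages -> 24)."""
    if len(subgroups) != len(stages):
        raise ValueError("alignment enumeration expects as many subgroups as stages")
    return [dict(zip(subgroups, perm)) for perm in itertools.permutations(stages)]


def score_alignment_orders(eigengenes: pd.DataFrame, metadata: pd.DataFrame,
                           candidate_maps: list[dict[str, int]] | None = None,
                           orientation: str = "positive",
                           encoding: str = "rank",
                           control_level: pd.Series | None = None) -> list[AlignmentHypothesis]:
    """Score every candidate alignment order and rank them.

    A hypothesis' score is the correlation of its most descriptive module:
    max over eigengenes of r (``orientation='positive'``, which resolves the
    reversal ambiguity by demanding expression increase with stage) or of |r|
    (``orientation='absolute'``). Returns hypotheses sorted by descending
    score; ties break deterministically on the stage map.
    """
    if orientation not in ("positive", "absolute"):
        raise ValueError("orientation must be 'positive' or 'absolute'")
    subgroups = list(dict.fromkeys(metadata.loc[metadata["kind"] == "tumor", "group"]))
    stages = sorted(int(s) for s in metadata.loc[metadata["kind"] == "control", "stage_index"].dropna().unique())
    if candidate_maps is None:
        candidate_maps = enumerate_stage_maps(subgroups, stages)
    hypotheses = []
    for stage_map in candidate_maps:
        if len(set(stage_map.values())) != len(stage_map):
            raise ValueError(f"stage map is not injective: {stage_map}")
        trait = induced_stage_trait(metadata, stage_map, encoding, control_level)
        t = trait.loc[list(eigengenes.columns)].to_numpy(float)
        rs, ps = {}, {}
        for me in eigengenes.index:
            rs[me], ps[me] = _cor_and_p(eigengenes.loc[me].to_numpy(float), t)
        module_r = pd.Series(rs)
        module_p = pd.Series(ps)
        scored = module_r if orientation == "positive" else module_r.abs()
        best = scored.idxmax()
        hypotheses.append(AlignmentHypothesis(
            stage_map=dict(stage_map), module_r=module_r, module_p=module_p,
            score=float(scored[best]), best_module=str(best),
        ))
    hypotheses.sort(key=lambda h: (-h.score, tuple(sorted(h.stage_map.items()))))
    return hypotheses
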