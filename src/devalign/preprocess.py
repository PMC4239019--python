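"""Normalization and the detection-limit / probe-suffix / variance filters.

Quantile normalization stands in for the cross-array component of RMA at
probe-set-matrix level: every sample is mapped onto the common distribution
of row means of order statistics. The detection filter drops probe sets
whose linear-scale intensity never reaches the 200-unit detection limit in
any sample; the network prefilter drops cross-hybridizing ``_x_at`` probe
sets and low-variance genes ahead of co-expression analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .matrix import ExpressionMatrix

DEFAULT_DETECTION_THRESHOLD = 200.0
DEFAULT_SUFFIXES = ("_x_at",)


@dataclass
class FilterReport:
    """Accounting for one filtering step.

    Each removed gene is counted once, in the first filter that removed it;
    ``flags`` maps every input gene to ``retained`` or its removal reason.
    """

    n_input: int
    n_below_detection: int = 0
    n_suffix_removed: int = 0
    n_low_variance_removed: int = 0
    flags: pd.Series | None = None

    @property
    def n_retained(self) -> int:
        return self.n_input - self.n_below_detection - self.n_suffix_removed - self.n_low_variance_removed

    def validate(self) -> None:
        assert self.flags is not None and len(self.flags) == self.n_input
        counts = self.flags.value_counts()
        assert int(counts.get("retained", 0)) == self.n_retained

    def to_frame(self) -> pd.DataFrame:
        return self.flags.rename("filter_flag").rename_axis("gene_id").to_frame()


def quantile_normalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Force every sample onto the common distribution of mean order statistics.

    After normalization every column holds an identical sorted value vector.
    Ties within a column are broken by row order (stable ranks), which makes
    the transform idempotent. A single-sample matrix is returned unchanged
    with a warning.
    """
    if matrix.n_samples < 2:
        warnings.warn("quantile normalization with a single sample is the identity transform")
        return ExpressionMatrix(matrix.values.copy(), matrix.metadata.copy(), matrix.scale)
    x = matrix.values.to_numpy(float)
    order = np.argsort(x, axis=0, kind="stable")
    sorted_x = np.take_along_axis(x, order, axis=0)
    reference = sorted_x.mean(axis=1)
    out = np.empty_like(x)
    for j in range(x.shape[1]):
        out[order[:, j], j] = reference
    values = pd.DataFrame(out, index=matrix.values.index, columns=matrix.values.columns)
    return ExpressionMatrix(values, matrix.metadata.copy(), matrix.scale)


def detection_filter(
    matrix: ExpressionMatrix, threshold_linear: float = DEFAULT_DETECTION_THRESHOLD
) -> tuple[ExpressionMatrix, FilterReport]:
    """Drop genes never reaching ``threshold_linear`` intensity in any sample.

    The rule uses the maximum across samples so that a gene detected in any
    single group survives (per-subgroup over-expression queries must still be
    able to see it). Thresholds are on the linear scale regardless of the
    matrix's own scale tag.
    """
    if threshold_linear < 0:
        raise ValueError("detection threshold must be non-negative")
    linear_max = matrix.linear_values().max(axis=1)
    keep = linear_max >= threshold_linear
    flags = pd.Series(
        np.where(keep, "retained", "below_detection"), index=matrix.values.index, dtype=object
    )
    report = FilterReport(n_input=matrix.n_genes, n_below_detection=int((~keep).sum()), flags=flags)
    report.validate()
    filtered = ExpressionMatrix(matrix.values.loc[keep], matrix.metadata.copy(), matrix.scale)
    return filtered, report


def network_prefilter(
    matrix: ExpressionMatrix,
    suffixes: tuple[str, ...] = DEFAULT_SUFFIXES,
    variance_quantile: float = 0.75,
) -> tuple[ExpressionMatrix, FilterReport]:
    """Drop suffix-matching probe sets, then low-variance genes.

    ``variance_quantile`` q removes the floor(q * n) lowest-variance genes of
    the n suffix-surviving genes (q = 0 keeps all of them). Ties in variance
    are broken deterministically by gene id: among tied genes the
    lexicographically smaller id is kept first. Gene order of the input is
    preserved in the output.
    """
    if not 0 <= variance_quantile < 1:
        raise ValueError("variance_quantile must be in [0, 1)")
    gene_ids = matrix.values.index
    suffix_hit = gene_ids.str.endswith(tuple(suffixes)) if len(suffixes) else np.zeros(len(gene_ids), bool)
    flags = pd.Series("retained", index=gene_ids, dtype=object)
    flags[suffix_hit] = "suffix"

    survivors = gene_ids[~suffix_hit]
    n_drop = int(np.floor(variance_quantile * len(survivors)))
    if n_drop > 0 and len(survivors):
        variances = matrix.values.loc[survivors].var(axis=1, ddof=1)
        ranking = sorted(survivors, key=lambda g: (-variances[g], g))
        dropped = ranking[len(survivors) - n_drop :]
        flags[dropped] = "low_variance"

    keep = flags == "retained"
    report = FilterReport(
        n_input=matrix.n_genes,
        n_suffix_removed=int((flags == "suffix").sum()),
        n_low_variance_removed=int((flags == "low_variance").sum()),
        flags=flags,
    )
    report.validate()
    if report.n_retained == 0:
        warnings.warn("network prefilter removed every gene")
    filtered = ExpressionMatrix(matrix.values.loc[keep], matrix.metadata.copy(), matrix.scale)
    return filtered, report
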