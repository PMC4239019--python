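"""Expression matrix container and tab-delimited I/O.

The :class:`ExpressionMatrix` is the common currency of the pipeline: a
genes x samples table of intensities (log2 by default) together with a
per-sample metadata table (group label, tumour/control kind and, for
control groups, an ordinal developmental stage index).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

VALID_SCALES = ("log2", "linear")
VALID_KINDS = ("tumor", "control")

METADATA_COLUMNS = ["group", "kind", "stage_index"]


@dataclass
class ExpressionMatrix:
    """Genes x samples intensity matrix with validated sample metadata.

    Parameters
    ----------
    values
        DataFrame indexed by gene id with one column per sample id.
    metadata
        DataFrame indexed by sample id with columns ``group``,
        ``kind`` (``tumor``/``control``) and ``stage_index`` (nullable;
        meaningful for control groups only).
    scale
        ``"log2"`` (default) or ``"linear"``.
    """

    values: pd.DataFrame
    metadata: pd.DataFrame
    scale: str = "log2"

    def __post_init__(self) -> None:
        if self.scale not in VALID_SCALES:
            raise ValueError(f"unknown scale {self.scale!r}; expected one of {VALID_SCALES}")
        if self.values.index.has_duplicates:
            dup = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene ids: {dup[:5]}")
        if self.values.columns.has_duplicates:
            dup = self.values.columns[self.values.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids: {dup[:5]}")
        missing = [s for s in self.values.columns if s not in self.metadata.index]
        if missing:
            raise ValueError(f"samples missing from metadata: {missing}")
        extra = [s for s in self.metadata.index if s not in self.values.columns]
        if extra:
            raise ValueError(f"metadata samples absent from matrix: {extra}")
        for col in ("group", "kind"):
            if col not in self.metadata.columns:
                raise ValueError(f"metadata lacks required column {col!r}")
        if "stage_index" not in self.metadata.columns:
            self.metadata = self.metadata.assign(stage_index=np.nan)
        bad_kind = sorted(set(self.metadata["kind"]) - set(VALID_KINDS))
        if bad_kind:
            raise ValueError(f"unknown sample kinds {bad_kind}; expected {VALID_KINDS}")
        if self.metadata["group"].isna().any():
            raise ValueError("every sample must have a group label")
        vals = self.values.to_numpy()
        if vals.size and not np.isfinite(vals).all():
            raise ValueError("expression values must be finite")
        # align metadata row order with the matrix columns; canonical axis names
        self.metadata = self.metadata.loc[list(self.values.columns)]
        self.values.index.name = "gene_id"
        self.values.columns.name = None
        self.metadata.index.name = "sample_id"

    # -- convenience accessors -------------------------------------------------

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def groups(self, kind: str | None = None) -> list[str]:
        """Group labels in first-appearance order, optionally restricted by kind."""
        meta = self.metadata if kind is None else self.metadata[self.metadata["kind"] == kind]
        return list(dict.fromkeys(meta["group"]))

    def samples_in_group(self, group: str) -> list[str]:
        sel = self.metadata.index[self.metadata["group"] == group]
        if len(sel) == 0:
            raise KeyError(f"unknown group {group!r}")
        return list(sel)

    def group_values(self, group: str) -> pd.DataFrame:
        return self.values[self.samples_in_group(group)]

    def stage_of_group(self, group: str) -> int:
        stages = self.metadata.loc[self.metadata["group"] == group, "stage_index"].dropna().unique()
        if len(stages) != 1:
            raise ValueError(f"group {group!r} has no unique stage_index")
        return int(stages[0])

    def subset_genes(self, gene_ids) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.loc[list(gene_ids)], self.metadata.copy(), self.scale)

    def subset_samples(self, sample_ids) -> "ExpressionMatrix":
        sample_ids = list(sample_ids)
        return ExpressionMatrix(self.values[sample_ids], self.metadata.loc[sample_ids].copy(), self.scale)

    def linear_values(self) -> pd.DataFrame:
        """Values on the linear intensity scale (2**x for log2 data)."""
        if self.scale == "linear":
            return self.values
        return np.power(2.0, self.values)

    def to_log2(self) -> "ExpressionMatrix":
        if self.scale == "log2":
            return self
        vals = self.values.where(self.values > 0)
        if vals.isna().any().any():
            raise ValueError("non-positive linear intensities cannot be log2 transformed")
        return ExpressionMatrix(np.log2(vals), self.metadata.copy(), "log2")


def _read_tsv(path: Path) -> pd.DataFrame:
    # comment='#' tolerates provenance header lines; python engine handles
    # stray CRLF / surrounding whitespace dialects.
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0, skipinitialspace=True)
    df.index = df.index.astype(str).str.strip()
    df.columns = [str(c).strip() for c in df.columns]
    return df


def read_expression(expression_path, metadata_path, scale: str = "log2") -> ExpressionMatrix:
    """Read an expression TSV and its sample metadata TSV.

    The expression table has gene ids in the first column and one column per
    sample; the metadata table has sample_id, group, kind and (for controls)
    stage_index. Sample ids must match between the two files.
    """
    expression_path, metadata_path = Path(expression_path), Path(metadata_path)
    for p in (expression_path, metadata_path):
        if not p.exists():
            raise FileNotFoundError(p)
    values = _read_tsv(expression_path)
    meta = _read_tsv(metadata_path)
    missing_meta = [s for s in values.columns if s not in meta.index]
    missing_expr = [s for s in meta.index if s not in values.columns]
    if missing_meta or missing_expr:
        raise ValueError(
            "sample ids differ between expression and metadata; "
            f"absent from metadata: {missing_meta}; absent from expression: {missing_expr}"
        )
    if "stage_index" in meta.columns:
        meta["stage_index"] = pd.to_numeric(meta["stage_index"], errors="coerce")
    for col in ("group", "kind"):
        if col in meta.columns:
            meta[col] = meta[col].astype(str).str.strip()
    return ExpressionMatrix(values.astype(float), meta, scale=scale)


def write_expression(matrix: ExpressionMatrix, expression_path, metadata_path, header: str | None = None) -> None:
    """Write the matrix and metadata as TSV; ``header`` lines are prefixed with '#'."""
    for path, table, label in (
        (Path(expression_path), matrix.values, "gene_id"),
        (Path(metadata_path), matrix.metadata, "sample_id"),
    ):
        path.parent.mkdir(parents=True, exist_ok=True)
        with open(path, "w", newline="\n") as fh:
            if header:
                for line in header.splitlines():
                    fh.write(f"# {line}\n")
            table.rename_axis(label).to_csv(fh, sep="\t", lineterminator="\n")
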