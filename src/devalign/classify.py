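"""Molecular subgroup classification by PCA projection onto a labelled
reference cohort.

A classifier gene panel (by default the 20 subgroup-classifier genes
available on the U133A array) restricts the gene space; PCA is fitted on the
reference cohort only, query samples are projected into that fixed geometry,
and each query sample takes the label of the nearest reference-label
centroid (Euclidean distance on the first ``n_components`` components).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

log = logging.getLogger(__name__)

DEFAULT_N_COMPONENTS = 4


@dataclass(frozen=True)
class ClassifierPanel:
    """A named list of classifier gene ids (one gene per line on disk)."""

    gene_ids: tuple[str, ...]
    source: str = ""

    def __post_init__(self):
        if not self.gene_ids:
            raise ValueError("classifier panel is empty")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("classifier panel contains duplicate gene ids")


def read_panel(path) -> ClassifierPanel:
    lines = [ln.strip() for ln in Path(path).read_text().splitlines()]
    genes = tuple(ln for ln in lines if ln and not ln.startswith("#"))
    return ClassifierPanel(gene_ids=genes, source=str(path))


def default_panel() -> ClassifierPanel:
    """The 20-gene subgroup classifier panel shipped as a package resource."""
    text = resources.files("devalign.data").joinpath("classifier_panel_20.txt").read_text()
    genes = tuple(ln.strip() for ln in text.splitlines() if ln.strip() and not ln.startswith("#"))
    return ClassifierPanel(gene_ids=genes, source="builtin:classifier_panel_20")


@dataclass
class SubgroupAssignment:
    """Per-sample label and the distance to every reference-label centroid."""

    labels: pd.Series               # sample -> assigned label
    distances: pd.DataFrame         # sample x label centroid distances
    missing_panel_genes: tuple[str, ...]
    n_components: int

    def __post_init__(self):
        # the assigned label must attain the minimum distance
        assert (self.distances.idxmin(axis=1) == self.labels).all()


def classify_by_reference(reference, reference_labels: pd.Series, query,
                          panel: ClassifierPanel | None = None,
                          n_components: int = DEFAULT_N_COMPONENTS) -> SubgroupAssignment:
    """Assign each query sample to the nearest reference-label centroid in
    reference PC space.

    ``reference_labels`` maps reference sample ids to subgroup labels. Panel
    genes absent from the matrix are logged and skipped (mirroring panels
    whose remaining members are not represented on the array); classification
    errors out only if no panel gene is present or the reference carries
    fewer than two labels.
    """
    if panel is None:
        panel = default_panel()
    labels = reference_labels.loc[reference.sample_ids]
    if labels.nunique() < 2:
        raise ValueError("reference must contain at least 2 labels")
    present = [g for g in panel.gene_ids if g in reference.values.index]
    missing = tuple(g for g in panel.gene_ids if g not in reference.values.index)
    if not present:
        raise ValueError("no classifier panel gene present in the reference matrix")
    if missing:
        msg = f"{len(missing)} panel genes absent from the matrix: {', '.join(missing)}"
        log.warning(msg)
        warnings.warn(msg)
    absent_query = [g for g in present if g not in query.values.index]
    if absent_query:
        raise ValueError(f"query matrix lacks panel genes present in reference: {absent_query}")

    n_components = min(n_components, len(present), reference.n_samples - 1)
    ref_x = reference.values.loc[present].to_numpy(float).T
    qry_x = query.values.loc[present].to_numpy(float).T
    model = PCA(n_components=n_components, svd_solver="full")
    ref_scores = model.fit_transform(ref_x)
    qry_scores = model.transform(qry_x)

    label_names = list(dict.fromkeys(labels))
    centroids = np.vstack([
        ref_scores[(labels == name).to_numpy()].mean(axis=0) for name in label_names
    ])
    d = np.linalg.norm(qry_scores[:, None, :] - centroids[None, :, :], axis=2)
    distances = pd.DataFrame(d, index=query.sample_ids, columns=label_names)
    assigned = distances.idxmin(axis=1).rename("subgroup")
    return SubgroupAssignment(
        labels=assigned, distances=distances, missing_panel_genes=missing,
        n_components=n_components,
    )
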