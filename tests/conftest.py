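import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import devalign as dv

settings.register_profile(
    "ci", derandomize=True, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_design():
    """A compact cohort: 3 control stages (one single-profile), 2 subgroups."""
    return dv.CohortDesign(
        control_groups=(("CtlA", 3, 1), ("CtlB", 3, 2), ("CtlC", 1, 3)),
        tumor_groups=(("TumX", 6, 1), ("TumY", 7, 3)),
        n_genes=300,
    )


@pytest.fixture(scope="session")
def small_params():
    return dv.SimulationParams(
        seed=11, n_gradient_modules=2, genes_per_module=20,
        n_exclusive_markers_per_subgroup=10,
    )


@pytest.fixture(scope="session")
def small_cohort(small_design, small_params):
    return dv.simulate_cohort(small_design, small_params)


@pytest.fixture(scope="session")
def paper_cohort():
    """One study-sized cohort at the default generative settings."""
    return dv.simulate_cohort(dv.paper_cohort_design(), dv.SimulationParams(seed=5))


def make_matrix(values, groups, kinds=None, stages=None, gene_ids=None, scale="log2"):
    """Hand-build an ExpressionMatrix from a plain array and group labels."""
    values = np.asarray(values, dtype=float)
    n_genes, n_samples = values.shape
    gene_ids = gene_ids or [f"g{i}" for i in range(n_genes)]
    sample_ids = [f"s{j}" for j in range(n_samples)]
    kinds = kinds or ["tumor"] * n_samples
    meta = pd.DataFrame(
        {"group": groups, "kind": kinds,
         "stage_index": stages if stages is not None else [np.nan] * n_samples},
        index=sample_ids,
    )
    return dv.ExpressionMatrix(
        pd.DataFrame(values, index=gene_ids, columns=sample_ids), meta, scale=scale
    )
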