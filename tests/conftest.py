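"""Shared fixtures: tiny hand-built matrices and the desk-scale fixture runs."""

from __future__ import annotations

import warnings

import anndata as ad
import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from retrotag.pipeline import PipelineConfig, run_pipeline_mem
from retrotag.simulate import default_config, simulate


def make_adata(
    counts: np.ndarray, classes: list[str] | None = None,
    var_names: list[str] | None = None,
) -> ad.AnnData:
    """AnnData from a dense cells x features array with feature classes."""
    counts = np.asarray(counts)
    n_cells, n_feats = counts.shape
    if classes is None:
        classes = ["endogenous"] * n_feats
    if var_names is None:
        var_names = [f"g{i}" for i in range(n_feats)]
    var = pd.DataFrame(
        {"name": var_names, "feature_class": classes}, index=var_names
    )
    obs = pd.DataFrame(index=[f"c{i}" for i in range(n_cells)])
    return ad.AnnData(X=sp.csr_matrix(counts.astype(np.int64)), obs=obs, var=var)


@pytest.fixture(scope="session")
def fixture_run():
    """One full pipeline run on the default synthetic fixture (seed 0)."""
    adata, truth = simulate(default_config(0))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        result = run_pipeline_mem(adata, truth, config=PipelineConfig(seed=0))
    return result, truth


@pytest.fixture(scope="session")
def recovery_runs():
    """Twenty seeded pipeline runs on the default fixture (shared by the
    parameter-recovery and calibration checks)."""
    runs = []
    for seed in range(20):
        adata, truth = simulate(default_config(seed))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            result = run_pipeline_mem(
                adata, truth, config=PipelineConfig(seed=seed))
        runs.append((result, truth))
    return runs
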