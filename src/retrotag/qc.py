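"""Per-cell QC and the normalization stack.

The stack mirrors standard droplet preprocessing: per-cell metric
computation, threshold filtering (gene/count bounds chosen per dataset,
5% mitochondrial ceiling, precomputed doublet flags), depth normalization to
10^4 followed by log1p, optional TF-IDF weighting, highly-variable-gene
selection (top 2000), and unit-variance scaling.

TF-IDF treats each cell as a document and each gene as a term:
``weight(g, c) = TF(g, c) * ln(N / n_g)`` with N the number of cells and
n_g the number of cells in which gene g appears (count > 0). A gene seen in
every cell gets weight 0 everywhere — the weighting emphasises genes that
vary across the population rather than ubiquitous, highly expressed ones.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp

from .errors import QCError

#: Per-dataset QC presets (genes low/high, counts low/high, mito ceiling):
#: cortical single-cell ("v1"), collicular single-nucleus ("sc"),
#: ventral-midbrain single-nucleus ("vm").
QC_PRESETS: dict[str, "QCBounds"] = {}


@dataclass(frozen=True)
class QCBounds:
    min_genes: int = 200
    max_genes: int = 6_000
    min_counts: int = 750
    max_counts: int = 30_000
    max_mito_fraction: float = 0.05

    def __post_init__(self) -> None:
        if self.min_genes > self.max_genes or self.min_counts > self.max_counts:
            raise ValueError("lower QC bound exceeds upper bound")
        if not 0 <= self.max_mito_fraction <= 1:
            raise ValueError("max_mito_fraction must be in [0, 1]")


QC_PRESETS["v1"] = QCBounds(200, 6_000, 750, 30_000, 0.05)
QC_PRESETS["sc"] = QCBounds(300, 9_000, 750, 50_000, 0.05)
QC_PRESETS["vm"] = QCBounds(300, 5_000, 500, 20_000, 0.05)
# mito-and-doublet-only filtering, for desk-scale synthetic matrices whose
# depth is far below a real droplet run
QC_PRESETS["permissive"] = QCBounds(0, 10**9, 0, 10**9, 0.05)


def _classes(adata: ad.AnnData) -> pd.Series:
    if "feature_class" not in adata.var:
        raise QCError("adata.var['feature_class'] missing; classify features first")
    return adata.var["feature_class"]


def compute_qc_metrics(adata: ad.AnnData) -> pd.DataFrame:
    """Per-cell QC metrics: genes_detected, total_counts, mito_fraction.

    ``genes_detected`` counts endogenous + transgene features with count > 0
    (mitochondrial features are a fraction, not a complexity signal).
    All-zero cells get mito_fraction 0 and ``zero_total=True``.
    Results are also written into ``adata.obs``.
    """
    cls = _classes(adata)
    X = sp.csr_matrix(adata.X)
    total = np.asarray(X.sum(axis=1)).ravel()
    mito_mask = (cls == "mito").values
    mito = np.asarray(X[:, mito_mask].sum(axis=1)).ravel()
    nonmito_mask = ~mito_mask
    genes = np.asarray((X[:, nonmito_mask] > 0).sum(axis=1)).ravel()
    zero = total == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_frac = np.where(zero, 0.0, mito / np.where(zero, 1, total))
    metrics = pd.DataFrame(
        {
            "genes_detected": genes.astype(int),
            "total_counts": total.astype(int),
            "mito_fraction": mito_frac,
            "zero_total": zero,
        },
        index=adata.obs_names,
    )
    for col in metrics:
        adata.obs[col] = metrics[col]
    return metrics


def qc_filter(
    adata: ad.AnnData,
    bounds: QCBounds = QC_PRESETS["v1"],
    doublet_flags: pd.Series | np.ndarray | None = None,
) -> tuple[ad.AnnData, pd.DataFrame]:
    """Filter cells by QC bounds and (optional) precomputed doublet flags.

    Doublet detection itself is upstream (e.g. Scrublet); this stage only
    honours the flags. Returns the filtered AnnData (a copy) and a report of
    removal counts per criterion (a cell can fail several). Raises
    :class:`QCError` if nothing survives.
    """
    if "genes_detected" not in adata.obs:
        compute_qc_metrics(adata)
    obs = adata.obs
    fails = {
        "low_genes": obs["genes_detected"] < bounds.min_genes,
        "high_genes": obs["genes_detected"] > bounds.max_genes,
        "low_counts": obs["total_counts"] < bounds.min_counts,
        "high_counts": obs["total_counts"] > bounds.max_counts,
        "high_mito": obs["mito_fraction"] > bounds.max_mito_fraction,
    }
    if doublet_flags is not None:
        flags = np.asarray(doublet_flags, dtype=bool)
        if len(flags) != adata.n_obs:
            raise QCError("doublet flags length mismatch")
        fails["doublet"] = pd.Series(flags, index=obs.index)
    keep = ~np.logical_or.reduce([f.values for f in fails.values()])
    report = pd.DataFrame(
        {
            "criterion": list(fails) + ["retained", "initial"],
            "n_cells": [int(f.sum()) for f in fails.values()]
            + [int(keep.sum()), adata.n_obs],
        }
    )
    if keep.sum() == 0:
        raise QCError(f"QC bounds removed all cells; report:\n{report}")
    return adata[keep].copy(), report


def normalize_log(adata: ad.AnnData, scale: float = 1e4) -> ad.AnnData:
    """Depth-normalize each cell to ``scale`` total counts, then log1p.

    value = ln(1 + scale * count / cell_total). Stores the result in
    ``layers["lognorm"]`` and returns the same AnnData. Zero-total cells are
    a hard error — they should have been removed by QC.
    """
    X = sp.csr_matrix(adata.X, dtype=float)
    total = np.asarray(X.sum(axis=1)).ravel()
    if np.any(total == 0):
        raise QCError("zero-total cell reached normalization; run qc_filter first")
    norm = sp.diags(scale / total) @ X
    norm.data = np.log1p(norm.data)
    adata.layers["lognorm"] = norm.tocsr()
    return adata


def tfidf(adata: ad.AnnData, layer: str | None = None) -> ad.AnnData:
    """TF-IDF weighting: weight(g,c) = TF(g,c) * ln(N / n_g).

    Natural log, no smoothing. Genes appearing in no cell (n_g = 0) get
    weight 0 everywhere. Stores the result in ``layers["tfidf"]``.
    """
    X = sp.csr_matrix(adata.X if layer is None else adata.layers[layer], dtype=float)
    N = X.shape[0]
    n_g = np.asarray((X > 0).sum(axis=0)).ravel()
    idf = np.zeros(X.shape[1])
    present = n_g > 0
    idf[present] = np.log(N / n_g[present])
    adata.layers["tfidf"] = (X @ sp.diags(idf)).tocsr()
    return adata


def select_hvg(
    adata: ad.AnnData, n_top: int = 2000, layer: str = "lognorm", n_bins: int = 20
) -> np.ndarray:
    """Select highly variable genes on the log-normalized layer.

    Dispersion (variance/mean of the log values) is z-normalized within 20
    equal-frequency mean bins and genes ranked by that normalized dispersion,
    descending, ties broken by gene index. Transgene (and mitochondrial)
    features never enter the ranking. If fewer eligible genes than ``n_top``
    exist, all are returned with a warning. Returns a boolean var mask, also
    stored as ``var["highly_variable"]``.
    """
    cls = _classes(adata)
    eligible = (cls == "endogenous").values
    X = sp.csr_matrix(adata.layers[layer])[:, eligible]
    mean = np.asarray(X.mean(axis=0)).ravel()
    sq = np.asarray(X.multiply(X).mean(axis=0)).ravel()
    var = sq - mean**2
    with np.errstate(invalid="ignore", divide="ignore"):
        disp = np.where(mean > 0, var / mean, 0.0)

    n_eligible = eligible.sum()
    if n_top >= n_eligible:
        warnings.warn(
            f"n_top={n_top} >= {n_eligible} eligible genes; keeping all",
            stacklevel=2,
        )
        mask = eligible.copy()
        adata.var["highly_variable"] = mask
        return mask

    order = np.argsort(mean, kind="stable")
    bins = np.array_split(order, n_bins)
    norm_disp = np.zeros_like(disp)
    for b in bins:
        if len(b) == 0:
            continue
        mu, sd = disp[b].mean(), disp[b].std()
        norm_disp[b] = (disp[b] - mu) / (sd if sd > 0 else 1.0)
    # rank descending; ties broken by lower gene index
    rank = np.lexsort((np.arange(len(norm_disp)), -norm_disp))
    chosen_local = np.zeros(n_eligible, dtype=bool)
    chosen_local[rank[:n_top]] = True
    mask = np.zeros(adata.n_vars, dtype=bool)
    mask[np.flatnonzero(eligible)] = chosen_local
    adata.var["highly_variable"] = mask
    return mask


def scale_unit(values: np.ndarray | sp.spmatrix) -> np.ndarray:
    """Zero-center and scale each column (gene) to unit variance.

    Zero-variance genes become all-zero columns. Returns a dense array
    (centering destroys sparsity).
    """
    X = np.asarray(values.todense() if sp.issparse(values) else values, dtype=float)
    mean = X.mean(axis=0)
    sd = X.std(axis=0)
    sd_safe = np.where(sd > 0, sd, 1.0)
    out = (X - mean) / sd_safe
    out[:, sd == 0] = 0.0
    return out
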