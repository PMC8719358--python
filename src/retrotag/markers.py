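"""Marker ranking, Jaccard cluster merging, final marker selection.

Markers are ranked one-vs-rest per cluster with the Mann-Whitney U test
(tie-corrected normal approximation for the usual cell numbers, exact
enumeration when both sides are tiny), Benjamini-Hochberg adjusted within
each cluster's comparison. The top-50 sets drive cluster merging: clusters
whose top sets overlap above the cutoff (Jaccard 0.8 by default) are the
same transcriptomic type split by over-clustering, and are merged by
transitive closure.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats
from scipy.sparse.csgraph import connected_components
from statsmodels.stats.multitest import multipletests

#: Largest per-side sample size routed through exact enumeration.
EXACT_MAX_N = 10


def mann_whitney(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Two-sided Mann-Whitney U test of x vs y.

    Returns ``(U_x, z, p)`` where U_x counts (x > y) pairs (+ half ties) and
    z is the tie-corrected standardized U (positive when x tends larger).
    Exact enumeration when both samples have <= 10 values and no ties span
    the groups; tie-corrected normal approximation (no continuity
    correction) otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    m, n = len(x), len(y)
    if m == 0 or n == 0:
        raise ValueError("both samples must be nonempty")
    combined = np.concatenate([x, y])
    ranks = stats.rankdata(combined)
    u_x = ranks[:m].sum() - m * (m + 1) / 2
    mu = m * n / 2
    _, counts = np.unique(combined, return_counts=True)
    N = m + n
    tie_term = (counts**3 - counts).sum() / (N * (N - 1))
    var = m * n / 12 * (N + 1 - tie_term)
    z = 0.0 if var == 0 else (u_x - mu) / np.sqrt(var)

    no_ties = len(counts) == N
    if m <= EXACT_MAX_N and n <= EXACT_MAX_N and no_ties:
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method="exact")
        p = float(res.pvalue)
    else:
        p = 1.0 if var == 0 else 2 * stats.norm.sf(abs(z))
    return float(u_x), float(z), min(p, 1.0)


def _dense(layer) -> np.ndarray:
    return np.asarray(layer.todense() if sp.issparse(layer) else layer, dtype=float)


def rank_markers(
    adata: ad.AnnData,
    labels: np.ndarray,
    n_top: int = 50,
    layer: str = "lognorm",
    min_cells: int = 3,
) -> pd.DataFrame:
    """One-vs-rest Mann-Whitney marker table, top ``n_top`` genes per cluster.

    Only endogenous features are tested. Per cluster, genes are ranked by
    descending standardized U (positive = enriched in the cluster) and BH
    adjustment is applied across all tested genes of that cluster's
    comparison. Expression fractions come from raw counts; ``log_fold`` is
    the log2 ratio of mean depth-normalized expression. Clusters smaller
    than ``min_cells`` are skipped with a warning.
    """
    labels = np.asarray(labels)
    if len(labels) != adata.n_obs:
        raise ValueError("labels length mismatch")
    cluster_ids = np.unique(labels)
    if len(cluster_ids) < 2:
        raise ValueError("need at least 2 clusters to rank markers")

    endo = (adata.var["feature_class"] == "endogenous").values
    genes = adata.var_names[endo]
    vals = _dense(adata.layers[layer][:, endo])
    raw = sp.csr_matrix(adata.X)[:, endo]
    present = raw > 0

    n_cells, n_genes = vals.shape
    ranks = stats.rankdata(vals, axis=0)
    # per-gene tie correction over the full comparison (same for every
    # one-vs-rest split of the same cells)
    tie_term = np.zeros(n_genes)
    for g in range(n_genes):
        _, counts = np.unique(vals[:, g], return_counts=True)
        tie_term[g] = (counts**3 - counts).sum()
    tie_term /= n_cells * (n_cells - 1)

    frames = []
    for c in cluster_ids:
        mask = labels == c
        m = int(mask.sum())
        n = n_cells - m
        if m < min_cells:
            warnings.warn(f"cluster {c} has {m} < {min_cells} cells; skipped",
                          stacklevel=2)
            continue
        if m <= EXACT_MAX_N and n <= EXACT_MAX_N:
            stats_rows = [mann_whitney(vals[mask, g], vals[~mask, g])
                          for g in range(n_genes)]
            z = np.array([r[1] for r in stats_rows])
            p = np.array([r[2] for r in stats_rows])
        else:
            u = ranks[mask].sum(axis=0) - m * (m + 1) / 2
            var = m * n / 12 * (n_cells + 1 - tie_term)
            with np.errstate(invalid="ignore", divide="ignore"):
                z = np.where(var > 0, (u - m * n / 2) / np.sqrt(var), 0.0)
            p = np.where(var > 0, 2 * stats.norm.sf(np.abs(z)), 1.0)
        q = multipletests(p, method="fdr_bh")[1]
        frac_in = np.asarray(present[mask].mean(axis=0)).ravel()
        frac_out = np.asarray(present[~mask].mean(axis=0)).ravel()
        mean_in = np.expm1(vals[mask]).mean(axis=0)
        mean_out = np.expm1(vals[~mask]).mean(axis=0)
        eps = 1e-9
        log_fold = np.log2((mean_in + eps) / (mean_out + eps))
        df = pd.DataFrame(
            {
                "gene": genes,
                "cluster": c,
                "z_score": z,
                "p": p,
                "q": q,
                "frac_in": frac_in,
                "frac_out": frac_out,
                "log_fold": log_fold,
            }
        )
        # descending z, ties broken by gene order for determinism
        df = df.sort_values(
            ["z_score", "gene"], ascending=[False, True], kind="stable"
        ).head(min(n_top, n_genes))
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def jaccard_topsets(table: pd.DataFrame, mode: str = "jaccard") -> pd.DataFrame:
    """Pairwise similarity matrix between per-cluster top marker sets.

    ``mode="jaccard"``: |A∩B| / |A∪B| (default). ``mode="overlap"``:
    |A∩B| / max(|A|, |B|) — the raw mutual-presence reading of the cutoff.
    Diagonal is 1.
    """
    if mode not in ("jaccard", "overlap"):
        raise ValueError("mode must be 'jaccard' or 'overlap'")
    sets = {c: set(g["gene"]) for c, g in table.groupby("cluster", observed=True)}
    ids = sorted(sets)
    mat = np.eye(len(ids))
    for i, a in enumerate(ids):
        for j in range(i + 1, len(ids)):
            b = ids[j]
            inter = len(sets[a] & sets[b])
            if mode == "jaccard":
                denom = len(sets[a] | sets[b])
            else:
                denom = max(len(sets[a]), len(sets[b]))
            mat[i, j] = mat[j, i] = inter / denom if denom else 0.0
    return pd.DataFrame(mat, index=ids, columns=ids)


@dataclass
class MergeMap:
    """Cluster-merge result: old label -> merged label, plus provenance."""

    mapping: dict[int, int]
    similarity: pd.DataFrame
    threshold: float

    def apply(self, labels: np.ndarray) -> np.ndarray:
        return np.array([self.mapping[int(c)] for c in labels])

    @property
    def n_merged(self) -> int:
        return len(set(self.mapping.values()))


def merge_by_jaccard(
    similarity: pd.DataFrame, threshold: float = 0.8
) -> MergeMap:
    """Merge clusters whose top-set similarity reaches ``threshold``.

    Pairs at or above the threshold define a graph; its connected components
    (transitive closure) become the merged clusters, relabeled contiguously
    in order of each component's smallest member label.
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    mat = similarity.values
    if mat.shape[0] != mat.shape[1] or not np.allclose(mat, mat.T):
        raise ValueError("similarity matrix must be square and symmetric")
    adj = sp.csr_matrix(mat >= threshold)
    _, comp = connected_components(adj, directed=False)
    ids = list(similarity.index)
    # relabel components by smallest member label
    comp_min = {}
    for lab, c in zip(ids, comp):
        comp_min[c] = min(comp_min.get(c, lab), lab)
    order = {c: r for r, c in enumerate(
        sorted(comp_min, key=lambda c: comp_min[c]))}
    mapping = {int(lab): order[c] for lab, c in zip(ids, comp)}
    return MergeMap(mapping=mapping, similarity=similarity, threshold=threshold)


def select_final_markers(
    table: pd.DataFrame,
    min_frac_in: float = 0.5,
    max_frac_out: float = 0.2,
) -> pd.DataFrame:
    """Final marker list: highly expressed, majority-expressed, unique.

    Keeps genes with ``frac_in >= min_frac_in`` and
    ``frac_out <= max_frac_out`` that survive in exactly one cluster's list
    ("unique"), ranked by descending standardized U within each cluster.
    May be empty (warned).
    """
    surviving = table[
        (table["frac_in"] >= min_frac_in) & (table["frac_out"] <= max_frac_out)
    ]
    counts = surviving["gene"].value_counts()
    unique_genes = set(counts[counts == 1].index)
    final = surviving[surviving["gene"].isin(unique_genes)].copy()
    final = final.sort_values(
        ["cluster", "z_score", "gene"], ascending=[True, False, True],
        kind="stable",
    ).reset_index(drop=True)
    if final.empty:
        warnings.warn("no genes pass the final marker filters", stacklevel=2)
    return final
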