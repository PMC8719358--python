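"""Cluster the fixture, rank markers, merge redundant clusters.

Endogenous genes only feed PCA / kNN / Leiden; the marker table drives
Jaccard-based merging and the final unique-marker selection.
"""

import numpy as np

from retrotag import cluster as cl
from retrotag import markers, qc
from retrotag.simulate import default_config, simulate

adata, truth = simulate(default_config(seed=0))
adata, _ = qc.qc_filter(adata, qc.QC_PRESETS["v1"], truth["doublet"])
qc.normalize_log(adata)
hvg = qc.select_hvg(adata, n_top=2000)

scaled = qc.scale_unit(adata.layers["lognorm"][:, hvg])
emb = cl.pca_embed(scaled, n_pcs=50, seed=0, adata=adata, feature_mask=hvg)
graph = cl.knn_graph(emb, k=15)
labels = cl.community_cluster(graph, resolution=0.6, seed=0)
print(f"{labels.n_clusters} clusters from {adata.n_obs} cells")
print(f"top PC explains {emb.explained_variance_ratio[0]:.1%} of variance")

table = markers.rank_markers(adata, labels.labels, n_top=50)
sim = markers.jaccard_topsets(table)
merge = markers.merge_by_jaccard(sim, threshold=0.8)
print(f"after merging at Jaccard >= 0.8: {merge.n_merged} clusters")

final = markers.select_final_markers(table)
print("\nfinal unique markers per cluster (top 3):")
print(final.groupby("cluster").head(3)[
    ["cluster", "gene", "z_score", "frac_in", "frac_out"]
].to_string(index=False))

print("\ndendrogram:",
      cl.cluster_dendrogram(emb, cl.ClusterLabels(
          merge.apply(labels.labels), 0.6, 0)))
# Leaves are cluster ids; merge heights are 1 - Pearson r between cluster
# centroids in PC space, so near-zero heights mean transcriptomic twins.
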