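"""Per-cell QC, filtering, normalization and feature selection.

Shows the metric computation, the bounds-based filter report (including
doublet removal from precomputed flags), depth/log normalization, TF-IDF
weighting and highly-variable-gene selection.
"""

import numpy as np

from retrotag import qc
from retrotag.simulate import default_config, simulate

adata, truth = simulate(default_config(seed=0))

metrics = qc.compute_qc_metrics(adata)
print("QC metrics (first 3 cells):")
print(metrics.head(3).to_string())

filtered, report = qc.qc_filter(
    adata, qc.QC_PRESETS["v1"], doublet_flags=truth["doublet"])
print("\nfilter report:")
print(report.to_string(index=False))

qc.normalize_log(filtered)
qc.tfidf(filtered, layer="lognorm")
hvg = qc.select_hvg(filtered, n_top=500)
print(f"\nselected {hvg.sum()} highly variable genes "
      f"(of {(filtered.var['feature_class'] == 'endogenous').sum()} endogenous)")

# TF-IDF downweights broadly detected genes: ln(N/n_g) -> 0 as a gene
# approaches ubiquity, regardless of how highly it is expressed
w = filtered.layers["tfidf"]
n_cells_per_gene = np.asarray((filtered.layers["lognorm"] > 0).sum(0)).ravel()
broadest = int(np.argmax(n_cells_per_gene))
idf = np.log(filtered.n_obs / n_cells_per_gene[broadest])
print(f"broadest gene ({filtered.var_names[broadest]}) is detected in "
      f"{n_cells_per_gene[broadest]}/{filtered.n_obs} cells; "
      f"its IDF factor is {idf:.4f}")
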