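"""The core readout: overlay transgene barcodes on clusters.

Runs the whole pipeline on the fixture, then walks through the three
diagnostics: projection assignment by hypergeometric enrichment, the
ambient-contamination verdict, and the ground-state perturbation check.
"""

import warnings

warnings.filterwarnings("ignore")

import retrotag as rt
from retrotag.overlay import perturbation_check
from retrotag.simulate import default_config, simulate

adata, truth = simulate(default_config(seed=0))
result = rt.run_pipeline_mem(adata, truth, config=rt.PipelineConfig(seed=0))

print("assigned projection identities:")
print(result.enrichment.query("assigned")[
    ["transgene", "cluster", "n_pos", "fraction", "q"]].to_string(index=False))

print("\ncontamination verdicts:")
for t, v in result.verdicts.items():
    print(f"  {t}: {v.verdict} (breadth {v.breadth:.2f}, "
          f"one-sided p {v.p_one_sided:.3g})")
# GFP and Cre positives are confined to one cluster each and depleted of
# the non-neuronal compartment -> consistent with retrograde labeling.
# tdTomato appears in every cluster and equally across compartments ->
# ambient RNA from the dissection, not a projection label.

gfp_cluster = int(result.enrichment.query(
    "transgene == 'GFP' and assigned")["cluster"].iloc[0])
res = perturbation_check(
    result.adata, result.labels, result.calls, gfp_cluster, "GFP")
print(f"\nperturbation check in cluster {gfp_cluster}: "
      f"{res.n_significant} of {res.n_tested} endogenous genes differ "
      f"between GFP+ and GFP- cells (q < 0.05)")
# Zero significant genes: infection status does not skew the endogenous
# transcriptome, so clusters reflect cellular ground states.
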