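# Methods

This note documents the models, procedures and numerical choices behind
`retrotag`, in the order the pipeline applies them, together with what the
bundled simulator does and does not emulate.

## Problem setting and assumptions

A retrogradely infecting virus injected into a target structure delivers a
transgene to the neurons projecting there; the transgene mRNA is captured in
droplet RNA-seq like any transcript and quantified against a reference
augmented with one contig per transgene. The overlay logic assumes:

* transgene counts are honest per-cell observations once ambient
  contamination is excluded (no model-based decontamination is attempted —
  contamination is *diagnosed*, not removed);
* viral infection does not reshape the endogenous transcriptome, so
  clusters computed from endogenous genes alone represent cell types, not
  infection states (this assumption is itself checked, see
  "perturbation check");
* retrograde viruses label neurons; free ambient RNA lands in droplets
  independently of cell identity. The neuronal / non-neuronal partition is
  therefore informative about a barcode's provenance.

## Reference augmentation and barcode discriminability

Each transgene becomes a contig with a single gene/transcript/exon spanning
1..len on the + strand (1-based closed intervals, `gene_id`/`transcript_id`
equal to the record name), the layout standard aligner toolchains accept
for custom references. Percent identity between two barcodes uses global
alignment with match +1, mismatch −1, linear gap −2, identity =
matches / alignment-length; positions involving `N` never match. The scheme
is arbitrary but fixed and documented — an identity percentage is only
reproducible together with its scoring. Discriminability is screened at
k = 90 (order of a read length, configurable): a single shared k-mer means a
read could align to either contig, so any sharing raises a warning.

## Synthetic droplet model

Endogenous counts are negative binomial, NB(mean, φ) with variance
mean + φ·mean², the standard droplet overdispersion model, with

* per-gene baseline mean ~ LogNormal(0, 1);
* per-cell size factor ~ LogNormal(0, 0.3);
* dispersion φ = 0.5;
* marker genes: fold > 1 inside their population and suppressed to a
  background factor 0.2 of baseline outside it. Cluster markers in real
  tissue are population-restricted; without the suppression the simulated
  transcriptome contains no gene that is both common inside a population
  and rare outside, and the final-marker selection stage would have nothing
  it could ever legitimately return.

A cell of population P is retrogradely labeled for transgene t with P's
labeling probability; labeled cells draw NB(size-factor × 8, φ) transgene
counts. Every cell additionally draws Poisson(ambient-rate × size-factor)
ambient counts per transgene. Mitochondrial features draw their counts so
the per-cell mito fraction (Beta(2, 98), mean ≈ 2%) holds in expectation.
Doublets (4% by default) are appended as sums of two freshly drawn singlet
profiles from uniformly chosen populations; the doublet inherits the
population and compartment of the parent with the larger endogenous total
(ties → first parent). All draws flow from one `numpy` Generator seeded by
`SimConfig.seed`; identical seed gives byte-identical output.

The default fixture is desk-scale: 5 populations (excitatory-like 600,
inhibitory-like 450, deep-neuronal 350 cells; glia 400 and endothelial 200
as the non-neuronal compartment), 1,500 endogenous genes with 20 markers
per population at fold 6, 10 mitochondrial features, and 3 transgenes —
`GFP` labeling the excitatory population at 0.4, `Cre` labeling the
inhibitory population at 0.35, and `tdTomato` with zero labeling and a
uniform ambient rate of 0.4 expected counts/cell, emulating an
injection-site contamination scenario. The labeling probabilities and the
ambient rate are illustrative round numbers chosen once (no empirical
estimate of either exists to copy); they produce per-transgene positive
fractions of a few hundred cells per fixture, comparable in order to the
real datasets' thousands in tens of thousands.

What the simulator does **not** emulate: batch effects, UMI collisions,
gene–gene correlation beyond the population structure, empty droplets, and
depth gradients between cell types. Passing recovery tests on this fixture
shows the pipeline's statistics behave as designed under their own model
assumptions; it does not certify performance on real tissue.

## QC and normalization

Per-cell metrics: genes detected (endogenous + transgene features with
count > 0), total counts, mito fraction (mito counts / total, defined as 0
with a flag for all-zero cells; such cells are a hard error if they reach
normalization). Bounds presets mirror the three study datasets
(200–6,000 genes / 750–30,000 counts; 300–9,000 / 750–50,000;
300–5,000 / 500–20,000; all with a 5% mito ceiling) plus a `permissive`
preset (mito + doublets only) for desk-scale synthetic matrices whose depth
is far below a real run. Doublet flags are inputs — detection itself
(Scrublet-style) is out of scope. Filtering is idempotent.

Normalization: counts scaled to 10⁴ per cell, then ln(1 + ·). TF-IDF,
`weight(g,c) = TF(g,c) · ln(N/n_g)` with natural log and no smoothing, is
available as an optional stage off the main path (the main path feeds
log-normalized values to HVG selection and scaling). HVG selection ranks
genes by dispersion (variance/mean of log values) z-normalized within 20
equal-frequency mean bins, descending, ties broken by gene index —
deterministic by construction; transgene and mitochondrial features never
enter the ranking. Selected genes are zero-centered and scaled to unit
variance (constant genes → all zeros).

## Clustering

PCA with the arpack solver (50 components, seeded; component signs fixed by
the largest-loading convention so reruns are byte-identical), 15-NN graph
by Euclidean distance in PC space symmetrized by edge union (unweighted),
Leiden communities (RBConfiguration modularity, resolution 0.6, seeded,
labels contiguous from 0). Transgene features are excluded from every one
of these inputs and the exclusion is asserted, not trusted: letting the
barcode shape the clusters would make the overlay circular. Dendrograms:
complete linkage on 1 − Pearson r between cluster-centroid PC vectors,
emitted as Newick.

## Markers and merging

One-vs-rest Mann–Whitney U per endogenous gene. For the usual cell numbers
the tie-corrected normal approximation (no continuity correction) gives the
standardized U; when both sides have ≤ 10 observations and no ties the
p-value comes from exact enumeration instead, which is also the regime the
test suite can verify against full permutation enumeration to 1e-9. BH is
applied per cluster across genes (one family per one-vs-rest comparison).
The top 50 genes by standardized U form each cluster's marker set.

Merging: pairs of clusters with top-set Jaccard ≥ 0.8 are connected; the
connected components (transitive closure) become merged clusters, labels
renumbered by smallest member. The cutoff can alternatively be applied to
raw mutual overlap |A∩B| / max(|A|,|B|) via `mode="overlap"` — the wording
of an "80% cutoff on mutual presence via Jaccard" is ambiguous between the
two, so both are supported with Jaccard the default. After merging, markers
are re-ranked and the final list keeps genes with in-cluster expression
fraction ≥ 0.5 ("expressed in the majority"), out-of-cluster fraction
≤ 0.2 ("unique"), surviving in exactly one cluster's list, ranked by
standardized U. The 0.5 / 0.2 quantification of "majority" and "unique" is
a package choice, configurable.

## Overlay and diagnostics

Positivity: raw transgene count ≥ θ, default θ = 1 (any aligned read).
Enrichment: upper-tail hypergeometric probability of the observed positive
count per cluster, BH across clusters within each transgene; assignment
requires q < 0.05 and cluster fraction > global fraction.

Contamination verdict per transgene: build the 2×2 of positivity ×
compartment — default rows transgene⁺ vs transgene⁻ (`versus_negative`,
independent rows; `versus_total` available), columns non-neuronal vs
neuronal; the one-sided depletion p-value is Φ(z) with z the signed square
root of the Pearson χ² (equivalently a two-proportion z-test; no
continuity correction by default, Yates available). Depletion at α = 0.05
→ `retrograde_consistent`; no depletion *and* breadth (fraction of
clusters containing ≥ 1 positive) ≥ 0.9 → `ambient_suspect`; no positives
→ `undetected`. Narrow compartment-neutral detection deliberately does not
trigger `ambient_suspect`: the ambient signature is breadth plus
compartment neutrality, and a sparsely detected barcode simply lacks power.

Perturbation check: within an assigned cluster, Mann–Whitney per endogenous
gene between transgene⁺ and transgene⁻ cells, BH across tested genes;
a clean ground state yields zero significant genes at q < 0.05. Fewer than
10 positives or negatives returns an explicit insufficient-data result
rather than a silent pass. Genes constant within the cluster are skipped
(no information, p = 1).

Contingency statistics for in-situ co-expression use the same Pearson χ²
closed form, N(ad−bc)²/((a+b)(c+d)(a+c)(b+d)), df = 1, no continuity
correction. Percentages round half-up at the reported precision (integer
for co-expression rates, 1–2 decimals for composition fractions).

## Numerical and reproducibility choices

* All TSV floats are written at 6 significant digits; JSON keys sorted;
  Newick branch lengths at 6 significant digits — a rerun with the same
  seed is byte-identical, and the test suite asserts this at the file
  level.
* Ties everywhere break deterministically (gene index, smallest label,
  first parent).
* Each stage takes one integer seed; the pipeline passes its single
  configured seed to PCA and Leiden.
* The hypergeometric, χ², normal and Mann–Whitney tail computations come
  from SciPy; the closed-form χ² is evaluated directly and cross-checked
  against `scipy.stats.chi2_contingency` in the tests.

## Problem sizes used by the verification scripts

The acceptance script and test suite run the full pipeline on the 2,000-cell
default fixture across 20 seeded replicates for recovery metrics, 500
reduced replicates (300 cells, 30 genes) for the ambient-null calibration
of the one-sided compartment test, and 20 permutation replicates for the
perturbation-check null — sizes at which the whole verification completes
in minutes on one CPU while keeping Monte-Carlo error small relative to the
asserted margins.

## Known limitations

* The compartment diagnostic needs both compartments present and labeled;
  it is undefined on single-compartment data and returns an error there.
* The one-sided depletion test falsely rejects at rate ≈ α under a pure
  ambient null, so an ambient barcode is expected to be mis-flagged
  `retrograde_consistent` in about 5% of datasets; α is configurable.
* Exact Mann–Whitney enumeration is used only at ≤ 10 per side without
  ties; log-normalized expression values in real clusters are heavily tied,
  where the tie-corrected approximation is the operative path.
* The published contamination p-values for the collicular dataset are not
  exactly reproducible from the printed counts under any single obvious
  2×2 construction; the package's default (`versus_negative`, no
  correction) is the statistically defensible choice, documented rather
  than fitted.
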