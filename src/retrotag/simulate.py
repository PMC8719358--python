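"""Synthetic droplet simulator with known ground truth.

Generates cells x features count matrices with the statistical structure the
overlay method assumes: discrete populations with over-expressed marker
genes, negative-binomial endogenous counts with per-cell library-size
variation, per-population retrograde labeling probabilities for each
transgene, a uniform ambient-leakage rate per transgene (free RNA released
during dissociation lands in droplets regardless of cell type), mitochondrial
features, and doublets. Every downstream stage is testable against the
returned truth table without any external data.

Model
-----
* endogenous gene g in cell c:  NB(mean = s_c * m_g * fold_{pop(c),g}, phi)
  where s_c ~ LogNormal (library size factor), m_g ~ LogNormal (baseline),
  and variance = mean + phi * mean^2.
* transgene t in cell c:  NB(s_c * transgene_mean, phi) if the cell drew a
  retrograde label for t (Bernoulli with its population's probability),
  plus Poisson(ambient_rate_t * s_c) in *every* cell.
* mitochondrial features: per-cell fraction f_c ~ Beta; mito counts drawn
  Poisson so that mito/(mito+endo) = f_c in expectation.
* doublets: extra droplets appended, each the sum of two freshly drawn
  singlet profiles from two uniformly chosen populations; the doublet
  inherits the compartment and population of the parent with the larger
  endogenous total (ties -> first parent).

Same seed, same config => byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp

from .io import read_counts_dir, write_counts_dir  # noqa: F401  (re-export)

__all__ = [
    "PopulationSpec",
    "SimConfig",
    "simulate",
    "default_config",
    "write_counts_dir",
    "read_counts_dir",
]


@dataclass
class PopulationSpec:
    """One simulated cell population.

    ``marker_genes`` maps gene index -> fold enrichment (> 1) over baseline.
    ``transgene_labeling`` maps transgene name -> probability that a cell of
    this population carries the retrograde label.
    """

    name: str
    n_cells: int
    compartment: str  # "neuronal" | "non_neuronal"
    marker_genes: list[tuple[int, float]] = field(default_factory=list)
    transgene_labeling: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise ValueError(f"population {self.name}: n_cells must be >= 1")
        if self.compartment not in ("neuronal", "non_neuronal"):
            raise ValueError(f"population {self.name}: bad compartment")
        for g, fold in self.marker_genes:
            if fold <= 1:
                raise ValueError(
                    f"population {self.name}: marker fold must be > 1 (gene {g})"
                )
        for t, p in self.transgene_labeling.items():
            if not 0 <= p <= 1:
                raise ValueError(
                    f"population {self.name}: labeling prob for {t} outside [0,1]"
                )


@dataclass
class SimConfig:
    """Full simulation configuration; ``seed`` fixes the entire output."""

    populations: list[PopulationSpec]
    n_genes: int = 1500
    n_mito_genes: int = 10
    baseline_mean_log_mu: float = 0.0
    baseline_mean_log_sigma: float = 1.0
    libsize_log_mu: float = 0.0
    libsize_log_sigma: float = 0.3
    dispersion: float = 0.5
    marker_background: float = 0.2
    transgene_mean: float = 8.0
    ambient_rate: dict[str, float] = field(default_factory=dict)
    mito_beta_a: float = 2.0
    mito_beta_b: float = 98.0
    doublet_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.populations:
            raise ValueError("need at least one population")
        if not 0 <= self.doublet_rate < 1:
            raise ValueError("doublet_rate must be in [0, 1)")
        if self.dispersion < 0 or self.transgene_mean < 0:
            raise ValueError("rates must be >= 0")
        for t, r in self.ambient_rate.items():
            if r < 0:
                raise ValueError(f"ambient rate for {t} must be >= 0")
        max_marker = max(
            (g for p in self.populations for g, _ in p.marker_genes), default=-1
        )
        if max_marker >= self.n_genes:
            raise ValueError(
                f"marker gene index {max_marker} >= n_genes={self.n_genes}"
            )

    @classmethod
    def from_json(cls, path) -> "SimConfig":
        """Load a configuration from JSON; ``marker_genes`` entries are
        ``[gene_index, fold]`` pairs. Unknown keys are rejected."""
        import dataclasses
        import json
        from pathlib import Path

        raw = json.loads(Path(path).read_text())
        pop_fields = {f.name for f in dataclasses.fields(PopulationSpec)}
        cfg_fields = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - cfg_fields
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        pops = []
        for p in raw.get("populations", []):
            bad = set(p) - pop_fields
            if bad:
                raise ValueError(f"unknown population keys: {sorted(bad)}")
            p = dict(p)
            p["marker_genes"] = [tuple(m) for m in p.get("marker_genes", [])]
            pops.append(PopulationSpec(**p))
        raw["populations"] = pops
        return cls(**raw)

    @property
    def transgenes(self) -> list[str]:
        names: list[str] = []
        for pop in self.populations:
            for t in pop.transgene_labeling:
                if t not in names:
                    names.append(t)
        for t in self.ambient_rate:
            if t not in names:
                names.append(t)
        return names


def _nb(rng: np.random.Generator, mean: np.ndarray, phi: float) -> np.ndarray:
    """NB(mean, dispersion) with variance mean + phi*mean^2; phi=0 -> Poisson."""
    mean = np.asarray(mean, dtype=float)
    if phi == 0:
        return rng.poisson(mean)
    out = np.zeros(mean.shape, dtype=np.int64)
    pos = mean > 0
    n = 1.0 / phi
    p = n / (n + mean[pos])
    out[pos] = rng.negative_binomial(n, p)
    return out


def _singlet_profiles(
    rng: np.random.Generator,
    cfg: SimConfig,
    pop_idx: np.ndarray,
    base_mean: np.ndarray,
    fold: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Draw endogenous, transgene, mito counts and labels for given cells."""
    n = len(pop_idx)
    sf = rng.lognormal(cfg.libsize_log_mu, cfg.libsize_log_sigma, size=n)
    mean = sf[:, None] * base_mean[None, :] * fold[pop_idx]
    endo = _nb(rng, mean, cfg.dispersion)

    transgenes = cfg.transgenes
    labels = np.zeros((n, len(transgenes)), dtype=bool)
    tg = np.zeros((n, len(transgenes)), dtype=np.int64)
    for j, t in enumerate(transgenes):
        prob = np.array(
            [cfg.populations[i].transgene_labeling.get(t, 0.0) for i in pop_idx]
        )
        labels[:, j] = rng.random(n) < prob
        lab_mean = np.where(labels[:, j], sf * cfg.transgene_mean, 0.0)
        tg[:, j] = _nb(rng, lab_mean, cfg.dispersion)
        amb = cfg.ambient_rate.get(t, 0.0)
        if amb > 0:
            tg[:, j] += rng.poisson(amb * sf)

    frac = rng.beta(cfg.mito_beta_a, cfg.mito_beta_b, size=n)
    endo_tot = endo.sum(axis=1)
    mito_mean = endo_tot * frac / (1.0 - frac) / cfg.n_mito_genes
    mito = rng.poisson(np.repeat(mito_mean[:, None], cfg.n_mito_genes, axis=1))
    return endo, tg, mito, labels


def simulate(config: SimConfig) -> tuple[ad.AnnData, pd.DataFrame]:
    """Run the generative model; returns (counts AnnData, truth table).

    The AnnData is cells x features with ``var["feature_class"]`` in
    {endogenous, mito, transgene}; the truth table records per cell the
    population, compartment, doublet flag, and one ``labeled_<t>`` column
    per transgene.
    """
    rng = np.random.default_rng(config.seed)
    pops = config.populations
    transgenes = config.transgenes

    base_mean = rng.lognormal(
        config.baseline_mean_log_mu, config.baseline_mean_log_sigma, config.n_genes
    )
    # marker genes are on/off: enriched in their population, suppressed to
    # a background level everywhere else (real cluster markers are
    # population-restricted, not uniformly expressed genes with a bump)
    fold = np.ones((len(pops), config.n_genes))
    is_marker = np.zeros(config.n_genes, dtype=bool)
    for pop in pops:
        for g, _ in pop.marker_genes:
            is_marker[g] = True
    fold[:, is_marker] = config.marker_background
    for i, pop in enumerate(pops):
        for g, f in pop.marker_genes:
            fold[i, g] = f

    pop_idx = np.repeat(np.arange(len(pops)), [p.n_cells for p in pops])
    endo, tg, mito, labels = _singlet_profiles(rng, config, pop_idx, base_mean, fold)

    n_singlets = len(pop_idx)
    n_doub = int(round(config.doublet_rate * n_singlets))
    doublet = np.zeros(n_singlets + n_doub, dtype=bool)
    if n_doub:
        pa = rng.integers(0, len(pops), size=n_doub)
        pb = rng.integers(0, len(pops), size=n_doub)
        ea, ta, ma, la = _singlet_profiles(rng, config, pa, base_mean, fold)
        eb, tb, mb, lb = _singlet_profiles(rng, config, pb, base_mean, fold)
        # doublet identity follows the parent with more endogenous counts;
        # ties go to the first parent
        bigger_b = eb.sum(axis=1) > ea.sum(axis=1)
        d_pop = np.where(bigger_b, pb, pa)
        pop_idx = np.concatenate([pop_idx, d_pop])
        endo = np.vstack([endo, ea + eb])
        tg = np.vstack([tg, ta + tb])
        mito = np.vstack([mito, ma + mb])
        labels = np.vstack([labels, la | lb])
        doublet[n_singlets:] = True

    n_cells = len(pop_idx)
    X = sp.csr_matrix(
        np.hstack([endo, mito, tg]).astype(np.int64)
    )
    gene_ids = [f"gene{g}" for g in range(config.n_genes)]
    mito_ids = [f"mt-gene{g}" for g in range(config.n_mito_genes)]
    var = pd.DataFrame(
        {
            "name": gene_ids + mito_ids + list(transgenes),
            "feature_class": ["endogenous"] * config.n_genes
            + ["mito"] * config.n_mito_genes
            + ["transgene"] * len(transgenes),
        },
        index=gene_ids + mito_ids + list(transgenes),
    )
    barcodes = [f"cell{i:05d}" for i in range(n_cells)]
    adata = ad.AnnData(X=X, obs=pd.DataFrame(index=barcodes), var=var)

    truth = pd.DataFrame(
        {
            "population": [pops[i].name for i in pop_idx],
            "compartment": [pops[i].compartment for i in pop_idx],
            "doublet": doublet,
        },
        index=pd.Index(barcodes, name="barcode"),
    )
    for j, t in enumerate(transgenes):
        truth[f"labeled_{t}"] = labels[:, j]
    return adata, truth


def default_config(seed: int = 0) -> SimConfig:
    """The bundled desk-scale fixture: 5 populations, 2,000 cells,
    1,500 genes, 3 transgenes.

    Three neuronal populations (one excitatory-like, one inhibitory-like,
    one mixed deep-layer-like) and two non-neuronal (glia-like, endothelial-
    like). ``GFP`` retrogradely labels the excitatory population, ``Cre`` the
    inhibitory one; ``tdTomato`` has zero labeling everywhere and a uniform
    ambient leak — the injection-site contamination scenario the compartment
    diagnostic is built to catch.
    """

    def markers(start: int, n: int = 20, fold: float = 6.0):
        return [(g, fold) for g in range(start, start + n)]

    pops = [
        PopulationSpec(
            "excitatory", 600, "neuronal", markers(0),
            {"GFP": 0.4, "tdTomato": 0.0},
        ),
        PopulationSpec(
            "inhibitory", 450, "neuronal", markers(20), {"Cre": 0.35}
        ),
        PopulationSpec("deep_neuronal", 350, "neuronal", markers(40)),
        PopulationSpec("glia", 400, "non_neuronal", markers(60)),
        PopulationSpec("endothelial", 200, "non_neuronal", markers(80)),
    ]
    return SimConfig(
        populations=pops,
        n_genes=1500,
        ambient_rate={"tdTomato": 0.4},
        doublet_rate=0.04,
        seed=seed,
    )
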