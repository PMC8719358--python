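"""Transgene overlay: projection-identity calls, enrichment, diagnostics.

The core readout: a cell whose droplet contains >= theta reads of a virally
delivered transgene is called positive for that barcode, and clusters where
positives concentrate beyond chance (hypergeometric enrichment, BH across
clusters) are assigned to the corresponding projection target.

Two confound checks travel with the assignment:

* **Ambient contamination.** Free transgene RNA released at dissociation
  lands in droplets uniformly, so an ambient barcode is detected across
  (nearly) all clusters and equally in neuronal and non-neuronal nuclei.
  A genuinely retrograde barcode is depleted of the non-neuronal
  compartment (viruses label neurons). The verdict combines a one-sided
  compartment test with detection breadth across clusters.
* **Ground-state perturbation.** If infection skewed transcription,
  transgene-positive cells would separate from negative cells within their
  cluster; a within-cluster differential test (positives vs negatives over
  endogenous genes) should find nothing.

The 2x2 contingency machinery (Pearson chi-square, df=1) also serves the
in-situ co-expression specificity comparisons.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from math import floor

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .markers import mann_whitney


# ---------------------------------------------------------------------------
# positivity calls

@dataclass
class TransgeneCalls:
    """Per-cell boolean positivity per transgene at read threshold theta."""

    calls: pd.DataFrame  # cells x transgenes, bool
    theta: int

    @property
    def transgenes(self) -> list[str]:
        return list(self.calls.columns)

    def n_positive(self) -> pd.Series:
        return self.calls.sum(axis=0)


def call_positive(adata: ad.AnnData, theta: int = 1) -> TransgeneCalls:
    """Call transgene-positive cells by raw read count >= theta.

    theta=1 (any aligned read) is the default; raise it for noisy data.
    """
    if theta < 1:
        raise ValueError("theta must be >= 1")
    mask = (adata.var["feature_class"] == "transgene").values
    if not mask.any():
        raise ValueError("no transgene features in matrix")
    X = sp.csr_matrix(adata.X)[:, mask]
    names = list(adata.var_names[mask])
    calls = pd.DataFrame(
        np.asarray((X >= theta).todense()),
        index=adata.obs_names,
        columns=names,
    )
    return TransgeneCalls(calls=calls, theta=theta)


# ---------------------------------------------------------------------------
# cluster enrichment -> projection assignment

def cluster_enrichment(
    calls: TransgeneCalls,
    labels: np.ndarray,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Hypergeometric enrichment of transgene-positive cells per cluster.

    p = P(>= n_pos positives in the cluster | cluster size, global positives)
    under random placement; BH across clusters within each transgene. A
    cluster is ``assigned`` to the transgene's projection target when
    q < alpha and its positive fraction exceeds the global fraction.
    """
    labels = np.asarray(labels)
    if len(labels) != len(calls.calls):
        raise ValueError("labels must cover all called cells")
    N = len(labels)
    cluster_ids = np.unique(labels)
    rows = []
    for t in calls.transgenes:
        pos = calls.calls[t].values
        K = int(pos.sum())
        for c in cluster_ids:
            mask = labels == c
            n = int(mask.sum())
            if n == 0:
                warnings.warn(f"cluster {c} empty; skipped", stacklevel=2)
                continue
            k = int(pos[mask].sum())
            p = float(stats.hypergeom.sf(k - 1, N, K, n)) if K else 1.0
            rows.append(
                {
                    "transgene": t,
                    "cluster": int(c),
                    "n_cells": n,
                    "n_pos": k,
                    "fraction": k / n,
                    "global_fraction": K / N,
                    "p": p,
                }
            )
    df = pd.DataFrame(rows)
    df["q"] = np.nan
    for t in calls.transgenes:
        m = df["transgene"] == t
        if m.any():
            df.loc[m, "q"] = multipletests(df.loc[m, "p"], method="fdr_bh")[1]
    df["assigned"] = (df["q"] < alpha) & (df["fraction"] > df["global_fraction"])
    return df


# ---------------------------------------------------------------------------
# 2x2 contingency machinery

@dataclass
class ContingencyTable:
    """2x2 table: rows = groups, columns = (outcome-positive, negative)."""

    a: int
    b: int
    c: int
    d: int

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    def margins_positive(self) -> bool:
        return min(self.a + self.b, self.c + self.d,
                   self.a + self.c, self.b + self.d) > 0


def chisq_2x2(
    table: ContingencyTable, correction: str = "none"
) -> tuple[float, float]:
    """Pearson chi-square (df=1) of a 2x2 table.

    ``correction="none"`` evaluates the closed form
    N(ad-bc)^2 / ((a+b)(c+d)(a+c)(b+d)); ``"yates"`` subtracts the
    continuity correction N/2 from |ad-bc|. Zero margins are an error
    (use an exact test there).
    """
    if correction not in ("none", "yates"):
        raise ValueError("correction must be 'none' or 'yates'")
    if not table.margins_positive():
        raise ValueError("zero margin: chi-square undefined, use an exact test")
    a, b, c, d = (float(x) for x in (table.a, table.b, table.c, table.d))
    N = a + b + c + d
    det = abs(a * d - b * c)
    if correction == "yates":
        det = max(det - N / 2, 0.0)
    chi2 = N * det**2 / ((a + b) * (c + d) * (a + c) * (b + d))
    return float(chi2), float(stats.chi2.sf(chi2, df=1))


def compartment_table(
    calls: TransgeneCalls,
    compartments: pd.Series | np.ndarray,
    transgene: str,
    reference: str = "versus_negative",
) -> ContingencyTable:
    """2x2 table of transgene positivity against cell compartment.

    Rows: transgene-positive cells vs either transgene-negative cells
    (``versus_negative``, independent rows) or all cells (``versus_total``).
    Columns: non-neuronal, neuronal. A degenerate table (no positives) is
    returned with a warning.
    """
    if reference not in ("versus_negative", "versus_total"):
        raise ValueError("reference must be versus_negative or versus_total")
    comp = np.asarray(compartments)
    if len(comp) != len(calls.calls):
        raise ValueError("compartment labels must cover all cells")
    valid = {"neuronal", "non_neuronal"}
    if set(comp) - valid:
        raise ValueError(f"compartment labels must be in {valid}")
    pos = calls.calls[transgene].values
    nonneu = comp == "non_neuronal"
    a = int((pos & nonneu).sum())
    b = int((pos & ~nonneu).sum())
    if reference == "versus_negative":
        c = int((~pos & nonneu).sum())
        d = int((~pos & ~nonneu).sum())
    else:
        c = int(nonneu.sum())
        d = int((~nonneu).sum())
    if a + b == 0:
        warnings.warn(f"no {transgene}-positive cells: degenerate table",
                      stacklevel=2)
    return ContingencyTable(a, b, c, d)


# ---------------------------------------------------------------------------
# ambient-contamination verdict

@dataclass
class ContaminationVerdict:
    transgene: str
    verdict: str  # retrograde_consistent | ambient_suspect | undetected
    breadth: float
    table: ContingencyTable
    p_one_sided: float


def breadth(calls: TransgeneCalls, labels: np.ndarray, transgene: str) -> float:
    """Fraction of clusters containing >= 1 positive cell."""
    labels = np.asarray(labels)
    pos = calls.calls[transgene].values
    cluster_ids = np.unique(labels)
    with_pos = sum(1 for c in cluster_ids if pos[labels == c].any())
    return with_pos / len(cluster_ids)


def contamination_verdict(
    calls: TransgeneCalls,
    compartments: pd.Series | np.ndarray,
    labels: np.ndarray,
    transgene: str,
    alpha: float = 0.05,
    breadth_cut: float = 0.9,
    reference: str = "versus_negative",
) -> ContaminationVerdict:
    """Classify a transgene as retrograde-consistent, ambient-suspect, or
    undetected.

    The one-sided two-proportion test asks whether positive cells are
    *depleted* of the non-neuronal compartment relative to the reference
    rows (z = signed sqrt of the Pearson chi-square). Depletion at
    ``alpha`` -> retrograde_consistent. No depletion plus detection breadth
    >= ``breadth_cut`` across clusters -> ambient_suspect; otherwise the
    verdict stays retrograde_consistent (narrow, compartment-neutral
    detection is not the ambient signature). Zero positives -> undetected.
    """
    comp = np.asarray(compartments)
    if len(set(comp)) < 2:
        raise ValueError("single-compartment dataset: diagnostic undefined")
    table = compartment_table(calls, comp, transgene, reference)
    if table.a + table.b == 0:
        return ContaminationVerdict(
            transgene, "undetected", 0.0, table, float("nan")
        )
    p1 = table.a / (table.a + table.b)  # non-neuronal fraction among positives
    p2 = table.c / (table.c + table.d)
    try:
        chi2, _ = chisq_2x2(table, correction="none")
        z = np.sign(p1 - p2) * np.sqrt(chi2)
        p_one = float(stats.norm.cdf(z))  # small when positives depleted
    except ValueError:  # zero margin
        p_one = float("nan")
    br = breadth(calls, labels, transgene)
    if not np.isnan(p_one) and p_one < alpha:
        verdict = "retrograde_consistent"
    elif br >= breadth_cut:
        verdict = "ambient_suspect"
    else:
        verdict = "retrograde_consistent"
    return ContaminationVerdict(transgene, verdict, br, table, p_one)


# ---------------------------------------------------------------------------
# ground-state perturbation check

@dataclass
class PerturbationResult:
    n_tested: int
    n_significant: int
    genes: list[str]
    sufficient: bool


def perturbation_check(
    adata: ad.AnnData,
    labels: np.ndarray,
    calls: TransgeneCalls,
    cluster: int,
    transgene: str,
    q_cut: float = 0.05,
    min_pos: int = 10,
    layer: str = "lognorm",
) -> PerturbationResult:
    """Within-cluster differential test: transgene+ vs transgene- cells.

    Mann-Whitney per endogenous gene, BH across tested genes. A clean
    ground state returns zero significant genes. With fewer than
    ``min_pos`` positives (or negatives) the result is explicitly
    insufficient rather than a silent pass.
    """
    labels = np.asarray(labels)
    mask = labels == cluster
    pos = calls.calls[transgene].values & mask
    neg = ~calls.calls[transgene].values & mask
    if pos.sum() < min_pos or neg.sum() < min_pos:
        return PerturbationResult(0, 0, [], sufficient=False)
    endo = (adata.var["feature_class"] == "endogenous").values
    vals = adata.layers[layer][:, endo]
    vals = np.asarray(vals.todense() if sp.issparse(vals) else vals)
    genes = adata.var_names[endo]
    pvals = np.ones(vals.shape[1])
    for g in range(vals.shape[1]):
        col = vals[:, g]
        if np.all(col[pos | neg] == col[pos | neg][0]):
            continue  # constant within the cluster: no information
        _, _, pvals[g] = mann_whitney(col[pos], col[neg])
    q = multipletests(pvals, method="fdr_bh")[1]
    sig = q < q_cut
    return PerturbationResult(
        n_tested=int(vals.shape[1]),
        n_significant=int(sig.sum()),
        genes=list(genes[sig]),
        sufficient=True,
    )


# ---------------------------------------------------------------------------
# in-situ co-expression arithmetic

def round_half_up(x: float) -> int:
    return int(floor(x + 0.5))


@dataclass(frozen=True)
class CoexpressionRecord:
    """FISH-style co-expression count: probe+ cells, double+ cells."""

    n_probe_pos: int
    n_double_pos: int

    def __post_init__(self) -> None:
        if self.n_double_pos > self.n_probe_pos:
            raise ValueError("double-positives cannot exceed probe-positives")


def coexpression_rate(record: CoexpressionRecord) -> int:
    """Integer co-expression percentage, rounded half-up."""
    if record.n_probe_pos < 1:
        raise ValueError("need at least one probe-positive cell")
    return round_half_up(100.0 * record.n_double_pos / record.n_probe_pos)


def percent(numerator: float, denominator: float, decimals: int = 2) -> float:
    """Percentage rounded half-up at the given number of decimals."""
    if denominator == 0:
        raise ValueError("zero denominator")
    scale = 10**decimals
    return floor(100.0 * numerator / denominator * scale + 0.5) / scale
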