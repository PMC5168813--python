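"""Relating the global seed metabolic profile to germination vigor.

Three complementary views of the same question — does the dry-seed
metabolome predict germination?

* PCA of the (centered, unit-scaled) log RMC matrix, with plots colored by
  germination downstream;
* k-means clustering of plots in metabolite space, followed by a chi-square
  test of whether the non / intermediate / well germination groups distribute
  differently across clusters than in the population;
* per-metabolite Welch contrasts of well- vs non-germinating plots, with
  permissive-Bonferroni multiplicity and linear-scale fold differences.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

from .qtl import MultiplicityRule, welch_t_test

__all__ = [
    "PCAResult",
    "ClusterEnrichment",
    "run_pca",
    "kmeans_plots",
    "cluster_germination_enrichment",
    "germination_group_contrasts",
]


@dataclass
class PCAResult:
    scores: pd.DataFrame            # plots x components
    loadings: pd.DataFrame          # metabolites x components
    variance_explained: np.ndarray  # fractions, non-increasing


def run_pca(
    log_rmc: pd.DataFrame,
    center: bool = True,
    scale: bool = True,
    n_components: int | None = None,
) -> PCAResult:
    """PCA of the complete (imputed) log RMC matrix.

    Metabolites are centered and, by default, scaled to unit variance so
    that heterogeneous metabolite variances do not dominate.  Component sign
    is fixed by making each loading vector's largest-magnitude entry
    positive, so results are fully deterministic.
    """
    if log_rmc.isna().any().any():
        raise ValueError("PCA requires a complete (imputed) matrix")
    if len(log_rmc) < 2:
        raise ValueError("need at least 2 plots")
    x = log_rmc.to_numpy(dtype=float)
    if center:
        x = x - x.mean(axis=0)
    if scale:
        sd = x.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        x = x / sd
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(x)
    loadings = pca.components_.T
    # deterministic sign convention
    for j in range(loadings.shape[1]):
        i = np.argmax(np.abs(loadings[:, j]))
        if loadings[i, j] < 0:
            loadings[:, j] *= -1
            scores[:, j] *= -1
    comp = [f"PC{i + 1}" for i in range(loadings.shape[1])]
    return PCAResult(
        scores=pd.DataFrame(scores, index=log_rmc.index, columns=comp),
        loadings=pd.DataFrame(loadings, index=log_rmc.columns, columns=comp),
        variance_explained=pca.explained_variance_ratio_,
    )


def kmeans_plots(
    log_rmc: pd.DataFrame,
    k: int = 3,
    n_restarts: int = 50,
    rng_seed: int = 0,
) -> pd.Series:
    """Euclidean k-means of plots in metabolite space.

    ``n_restarts`` random initializations; the assignment with the lowest
    within-cluster sum of squares is kept.  Deterministic given the seed.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > len(log_rmc):
        raise ValueError("k cannot exceed the number of plots")
    if log_rmc.isna().any().any():
        raise ValueError("k-means requires a complete (imputed) matrix")
    km = KMeans(n_clusters=k, n_init=n_restarts, random_state=rng_seed & 0x7FFFFFFF)
    labels = km.fit_predict(log_rmc.to_numpy(dtype=float))
    return pd.Series(labels, index=log_rmc.index, name="cluster")


@dataclass
class ClusterEnrichment:
    """Chi-square test of germination-group composition across clusters."""

    contingency: pd.DataFrame       # clusters x groups, counts
    composition: pd.DataFrame       # % of each group within each cluster
    overall: pd.Series              # % of each group in all plots
    chi_square: float
    df: int
    p_value: float
    low_expected: bool              # any expected cell < 1


def cluster_germination_enrichment(
    assignment: pd.Series,
    germ_groups: pd.Series,
) -> ClusterEnrichment:
    """Pearson chi-square of independence between cluster and group."""
    groups = germ_groups.loc[assignment.index]
    if groups.isna().any():
        raise ValueError("every clustered plot needs a germination group")
    table = pd.crosstab(assignment, groups)
    chi2, p, dof, expected = stats.chi2_contingency(table.to_numpy(),
                                                    correction=False)
    composition = table.div(table.sum(axis=1), axis=0) * 100.0
    overall = table.sum(axis=0) / table.to_numpy().sum() * 100.0
    return ClusterEnrichment(
        contingency=table,
        composition=composition,
        overall=overall,
        chi_square=float(chi2),
        df=int(dof),
        p_value=float(p),
        low_expected=bool((expected < 1).any()),
    )


def germination_group_contrasts(
    log_rmc: pd.DataFrame,
    germ_groups: pd.Series,
    rule: MultiplicityRule | None = None,
) -> pd.DataFrame:
    """Per-metabolite Welch contrast of well- vs non-germinating plots.

    Fold differences are ratios of back-transformed (linear-scale) group
    means, reported both ways (non/well and well/non); the intermediate
    group's mean is carried along for the three-bar profile.  Multiplicity
    uses ``rule`` (default permissive Bonferroni at alpha 0.05) with n equal
    to the number of metabolites tested.
    """
    rule = rule or MultiplicityRule(alpha=0.05, variant="permissive_bonferroni")
    groups = germ_groups.loc[log_rmc.index]
    well = log_rmc[groups == "well"]
    non = log_rmc[groups == "non"]
    inter = log_rmc[groups == "intermediate"]
    if len(well) < 2 or len(non) < 2:
        raise ValueError("need >= 2 plots in both the well and non groups")
    linear = np.exp(log_rmc)
    rows = []
    for met in log_rmc.columns:
        t, _, p = welch_t_test(well[met].dropna(), non[met].dropna())
        mean_well = float(linear.loc[well.index, met].mean())
        mean_non = float(linear.loc[non.index, met].mean())
        mean_inter = (float(linear.loc[inter.index, met].mean())
                      if len(inter) else np.nan)
        rows.append({
            "metabolite": met,
            "mean_rmc_non": mean_non,
            "mean_rmc_intermediate": mean_inter,
            "mean_rmc_well": mean_well,
            "fold_non_over_well": mean_non / mean_well if mean_well else np.nan,
            "fold_well_over_non": mean_well / mean_non if mean_non else np.nan,
            "t": t,
            "p_value": p,
        })
    out = pd.DataFrame(rows).set_index("metabolite")
    out["significant"] = out["p_value"] < rule.cutoff(len(out))
    return out
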