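"""Ground-truth recovery scoring for synthetic datasets.

Given a synthetic experiment with known structure, run the analysis exactly
as the pipeline does and score how well it recovers what was planted: the
ms1/ms2 metabolite bipartition (adjusted Rand index against the latent set
assignment), the consistency of germination-trait edges with the set labels,
the concentration of non-germinating plots in one metabolite-based cluster,
and the sensitivity of the QTL scan to planted effects.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from .germination import classify_germination_group, germination_traits_table, \
    plates_from_frame
from .integrate import cluster_germination_enrichment, kmeans_plots
from .network import (adjust_p_matrix, assemble_metabolite_sets, build_network,
                      germination_edge_report, signed_bipartition,
                      spearman_matrix, walktrap_communities)
from .normalize import PeakTable, impute_missing, log_transform, normalize_peaks
from .qtl import MultiplicityRule, detect_trait_qtls
from .synthetic import SynthConfig, SyntheticDataset, generate_dataset

__all__ = ["evaluate_dataset", "qtl_recovery_sensitivity"]

GERM_TRAIT_NODES = ("percent", "t50", "sd_plate")
PLOT_KEY = ["line", "treatment", "season", "plot"]


def _sets_for_condition(imputed_values, meta, germ_keyed, condition,
                        q=0.05, r_min=0.4, steps=4):
    mask = meta["treatment"] == condition
    mat = imputed_values[mask]
    key = pd.MultiIndex.from_frame(meta.loc[mask, PLOT_KEY])
    traits = germ_keyed.reindex(key)
    traits.index = mat.index
    r, p = spearman_matrix(pd.concat([mat, traits], axis=1))
    net = build_network(r, adjust_p_matrix(p), r_min=r_min, q=q)
    met_nodes = [v for v in net.nodes() if v not in GERM_TRAIT_NODES]
    met_net = net.subgraph(met_nodes)
    partition = walktrap_communities(met_net, steps=steps)
    bipartitions = {}
    for cid in sorted(set(partition.values())):
        members = [v for v, c in partition.items() if c == cid]
        bipartitions[cid] = signed_bipartition(met_net.subgraph(members))
    sets = assemble_metabolite_sets(partition, bipartitions, net,
                                    germination_percent_node="percent")
    report = germination_edge_report(net, sets)
    return sets, report


def evaluate_dataset(
    config: SynthConfig | None = None,
    dataset: SyntheticDataset | None = None,
) -> dict[str, float]:
    """Run the analysis on one synthetic dataset and score recovery.

    Returns per-condition adjusted Rand indices of the ms1/ms2 assignment
    against the planted sets, germination-edge consistency scores, and the
    chi-square p-value of germination-group enrichment across k-means
    clusters together with the share of non-germinating plots captured by
    the cluster holding most of them.
    """
    if dataset is None:
        dataset = generate_dataset(config or SynthConfig())
    cfg = dataset.config
    peaks = PeakTable(
        meta=dataset.peaks[["line", "treatment", "season", "plot",
                            "run_block", "seed_mass_extracted"]],
        peaks=dataset.peaks[cfg.metabolites])
    imputed = impute_missing(log_transform(normalize_peaks(peaks)))
    meta = peaks.meta.copy()
    meta["season"] = meta["season"].astype(str)

    germ_traits = germination_traits_table(
        plates_from_frame(dataset.germination))
    germ_traits["season"] = germ_traits["season"].astype(str)
    germ_keyed = germ_traits.set_index(PLOT_KEY)[list(GERM_TRAIT_NODES)]

    truth = dataset.truth.set_assignment
    metrics: dict[str, float] = {}
    for cond in ("SDF", "SDS"):
        sets, report = _sets_for_condition(imputed.values, meta, germ_keyed,
                                           cond)
        assigned = [m for m in cfg.metabolites
                    if sets.assignment.get(m, "unassigned") != "unassigned"]
        if assigned:
            ari = adjusted_rand_score([truth[m] for m in assigned],
                                      [sets.assignment[m] for m in assigned])
        else:
            ari = 0.0
        metrics[f"ari_{cond}"] = float(ari)
        metrics[f"assigned_frac_{cond}"] = len(assigned) / cfg.n_metabolites
        metrics[f"germination_edge_consistency_{cond}"] = (
            float(report["consistent"].mean()) if len(report) else np.nan)

    # k-means cluster enrichment of germination groups (both conditions)
    clusters = kmeans_plots(imputed.values, k=3, n_restarts=50,
                            rng_seed=cfg.rng_seed)
    percent = germ_traits.set_index(PLOT_KEY)["percent"].reindex(
        pd.MultiIndex.from_frame(meta[PLOT_KEY]))
    groups = pd.Series(percent.to_numpy(), index=meta.index).dropna().map(
        classify_germination_group)
    common = clusters.index.intersection(groups.index)
    enr = cluster_germination_enrichment(clusters.loc[common],
                                         groups.loc[common])
    metrics["enrichment_chi_square"] = enr.chi_square
    metrics["enrichment_p"] = enr.p_value
    if "non" in enr.contingency.columns:
        non_counts = enr.contingency["non"]
        metrics["non_germinating_in_top_cluster"] = float(
            non_counts.max() / non_counts.sum()) if non_counts.sum() else np.nan
    return metrics


def qtl_recovery_sensitivity(
    seed: int,
    n_lines: int = 72,
    n_planted: int = 15,
    effect: float = 0.5,
    sigma: float = 0.15,
    n_reps: int = 5,
    rule: MultiplicityRule | None = None,
) -> float:
    """Sensitivity of the IL-vs-control scans to planted trait shifts.

    Simulates ``n_lines`` ILs plus a control at plot-level noise ``sigma``
    with ``n_planted`` lines carrying an additive shift of ``effect``
    (random sign) present under both growth conditions — the generator
    plants line QTLs irrespective of treatment.  Both per-condition scans
    are run under the permissive Bonferroni rule, and a planted effect
    counts as recovered when either condition's map calls it with the
    correct direction, matching how putative QTLs are read off the two
    condition maps.
    """
    rule = rule or MultiplicityRule(0.05, "permissive_bonferroni")
    rng = np.random.default_rng(seed)
    lines = ["M82"] + [f"IL{i:02d}" for i in range(1, n_lines + 1)]
    planted = rng.choice(lines[1:], size=n_planted, replace=False)
    signs = rng.choice([-1.0, 1.0], size=n_planted)
    shift = dict(zip(planted, signs * effect))
    rows = []
    for line in lines:
        for treatment in ("SDF", "SDS"):
            for plot in range(1, n_reps + 1):
                rows.append({"line": line, "treatment": treatment,
                             "season": "I", "plot": plot,
                             "trait": rng.normal(shift.get(line, 0.0), sigma)})
    table = pd.DataFrame(rows)
    called: set[str] = set()
    for condition in ("SDF", "SDS"):
        rec = detect_trait_qtls(table, "M82", condition, rule=rule)
        hits = rec[rec["significant"]]
        for _, row in hits.iterrows():
            expected = "+" if shift.get(row["line"], 0.0) >= 0 else "-"
            if row["direction"] == expected:
                called.add(row["line"])
    return sum(line in called for line in planted) / n_planted
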