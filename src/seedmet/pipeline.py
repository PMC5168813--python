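"""End-to-end orchestration: inputs -> RMC -> traits -> QTLs -> network -> vigor.

A :class:`PipelineConfig` points either at the three standard input tables
(peaks.tsv, morphology.tsv, germination.tsv) or at a simulate block that
generates them; the stages then run in order

    normalize -> germination traits -> QTL scans -> correlation network
    -> vigor integration

writing every stage artifact as TSV into one output directory together with
a run manifest (package versions, configuration hash, seed).  All randomness
flows from the single top-level seed, so a rerun with the same configuration
is bit-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .germination import (classify_germination_group, germination_traits_table,
                          maturation_percent, plates_from_frame,
                          salinity_fold_change)
from .integrate import (cluster_germination_enrichment,
                        germination_group_contrasts, kmeans_plots, run_pca)
from .network import (adjust_p_matrix, assemble_metabolite_sets, build_network,
                      germination_edge_report, network_attributes,
                      signed_bipartition, spearman_matrix,
                      walktrap_communities)
from .normalize import (PeakTable, impute_missing, log_transform,
                        normalize_peaks, read_peak_table)
from .qtl import (MultiplicityRule, detect_fc_qtls, detect_trait_qtls,
                  detect_treatment_effects)
from .synthetic import SynthConfig, generate_dataset

log = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline"]

GERM_TRAIT_NODES = ("percent", "t50", "sd_plate")
PLOT_KEY = ["line", "treatment", "season", "plot"]


@dataclass
class PipelineConfig:
    """Structured configuration of one pipeline run."""

    # exactly one of: input paths, or a simulate block
    peaks_path: str | None = None
    morphology_path: str | None = None
    germination_path: str | None = None
    simulate: SynthConfig | None = None

    control_line: str = "M82"
    seed: int = 0

    # normalization / imputation
    impute_components: int = 5
    impute_tol: float = 1e-6
    impute_max_iter: int = 1000

    # multiplicity rules per scan
    qtl_rule: MultiplicityRule = field(
        default_factory=lambda: MultiplicityRule(0.05, "permissive_bonferroni"))
    metabolite_qtl_rule: MultiplicityRule = field(
        default_factory=lambda: MultiplicityRule(0.05, "bonferroni"))
    treatment_rule: MultiplicityRule = field(
        default_factory=lambda: MultiplicityRule(0.01, "raw"))
    fc_rule: MultiplicityRule = field(
        default_factory=lambda: MultiplicityRule(0.05, "bonferroni"))

    # network
    network_q: float = 0.05
    network_r_min: float = 0.4
    walktrap_steps: int = 4

    # integration
    kmeans_k: int = 3
    kmeans_restarts: int = 50
    well_min_percent: float = 95.0

    def __post_init__(self) -> None:
        has_paths = any([self.peaks_path, self.morphology_path,
                         self.germination_path])
        if has_paths and self.simulate is not None:
            raise ValueError("config must name input paths or a simulate "
                             "block, not both")
        if not has_paths and self.simulate is None:
            self.simulate = SynthConfig(rng_seed=self.seed)
        if self.simulate is not None:
            self.simulate = SynthConfig(**{**asdict(self.simulate),
                                           "rng_seed": self.seed})
            self.simulate.weight_qtl_lines = dict(self.simulate.weight_qtl_lines)
        for name, lo, hi in (("network_q", 0.0, 1.0),
                             ("network_r_min", 0.0, 1.0),
                             ("well_min_percent", 0.0, 100.0)):
            v = getattr(self, name)
            if not lo <= v <= hi:
                raise ValueError(f"{name} out of range [{lo}, {hi}]: {v}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "simulate" in raw and isinstance(raw["simulate"], dict):
            sim = dict(raw["simulate"])
            if "set_sizes" in sim:
                sim["set_sizes"] = tuple(sim["set_sizes"])
            if "treatment_mets" in sim:
                sim["treatment_mets"] = tuple(sim["treatment_mets"])
            raw["simulate"] = SynthConfig(**sim)
        for key in ("qtl_rule", "metabolite_qtl_rule", "treatment_rule",
                    "fc_rule"):
            if key in raw and isinstance(raw[key], dict):
                raw[key] = MultiplicityRule(**raw[key])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = asdict(self)
        if d.get("simulate"):
            d["simulate"]["set_sizes"] = list(d["simulate"]["set_sizes"])
            d["simulate"]["treatment_mets"] = list(d["simulate"]["treatment_mets"])
            d["simulate"]["weight_qtl_lines"] = dict(
                d["simulate"]["weight_qtl_lines"])
        return d

    @property
    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _write(df: pd.DataFrame, path: Path, config_hash: str, **kwargs) -> None:
    with open(path, "w") as fh:
        fh.write(f"# config_hash={config_hash}\n")
        df.to_csv(fh, sep="\t", na_rep="NA", **kwargs)


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> dict[str, Path]:
    """Execute every stage and return the map of written artifacts."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    chash = config.config_hash
    artifacts: dict[str, Path] = {}

    def save(name: str, df: pd.DataFrame, **kw) -> None:
        path = outdir / f"{name}.tsv"
        _write(df, path, chash, **kw)
        artifacts[name] = path

    # ---- inputs -----------------------------------------------------------
    if config.simulate is not None:
        log.info("stage simulate: generating synthetic dataset (seed=%d)",
                 config.seed)
        ds = generate_dataset(config.simulate)
        input_dir = outdir / "inputs"
        for k, v in ds.write(input_dir).items():
            artifacts[f"input_{k}"] = v
        peaks = PeakTable(
            meta=ds.peaks[
                ["line", "treatment", "season", "plot", "run_block",
                 "seed_mass_extracted"]],
            peaks=ds.peaks[ds.config.metabolites],
        )
        morphology = ds.morphology
        germination = ds.germination
    else:
        log.info("stage ingest: reading input tables")
        peaks = read_peak_table(config.peaks_path)
        morphology = pd.read_csv(config.morphology_path, sep="\t",
                                 index_col="sample_id")
        germination = pd.read_csv(config.germination_path, sep="\t")

    # ---- normalization ----------------------------------------------------
    log.info("stage normalize: %d samples x %d metabolites",
             len(peaks.meta), len(peaks.metabolites))
    rmc = normalize_peaks(peaks)
    save("rmc", pd.concat([rmc.meta, rmc.values], axis=1),
         index_label="sample_id")
    log_rmc = log_transform(rmc)
    imputed = impute_missing(log_rmc, n_components=config.impute_components,
                             max_iter=config.impute_max_iter,
                             tol=config.impute_tol)
    save("log_rmc_imputed",
         pd.concat([imputed.meta, imputed.values], axis=1),
         index_label="sample_id")
    report = pd.DataFrame({
        "metabolite": list(log_rmc.values.columns),
        "n_missing": log_rmc.values.isna().sum().to_numpy(),
        "excluded": [m in imputed.excluded_metabolites
                     for m in log_rmc.values.columns],
    })
    save("imputation_report", report, index=False)

    # ---- germination and morphology traits --------------------------------
    log.info("stage germination traits")
    plates = plates_from_frame(germination)
    germ_traits = germination_traits_table(plates)
    germ_traits["season"] = germ_traits["season"].astype(str)
    save("germ_traits", germ_traits, index=False)

    morph = morphology.copy()
    morph["season"] = morph["season"].astype(str)
    morph["maturation_percent"] = [
        maturation_percent(int(m), int(a))
        for m, a in zip(morph["mature"], morph["aborted"])
    ]
    save("morphology_traits", morph, index=False)

    fc_table = salinity_fold_change(germ_traits, rule=config.qtl_rule)
    save("germination_salinity_fc", fc_table)

    # ---- QTL scans --------------------------------------------------------
    log.info("stage QTL scans")
    meta_for_log = rmc.meta[["line", "treatment", "season", "plot"]].copy()
    meta_for_log["season"] = meta_for_log["season"].astype(str)
    log_table = pd.concat([meta_for_log, log_rmc.values], axis=1)
    scans: list[pd.DataFrame] = []

    for cond, tag in (("SDF", "f_qtl"), ("SDS", "s_qtl")):
        rec = detect_trait_qtls(log_table, config.control_line, cond,
                                rule=config.metabolite_qtl_rule)
        rec["scan"] = tag
        scans.append(rec)

    morph_table = morph[PLOT_KEY + ["avg_seed_weight", "maturation_percent"]]
    for cond in ("SDF", "SDS"):
        rec = detect_trait_qtls(morph_table, config.control_line, cond,
                                rule=config.qtl_rule)
        rec["scan"] = f"morphology_qtl_{cond}"
        scans.append(rec)

    germ_table = germ_traits[PLOT_KEY + list(GERM_TRAIT_NODES)]
    for cond in ("SDF", "SDS"):
        rec = detect_trait_qtls(germ_table, config.control_line, cond,
                                rule=config.qtl_rule)
        rec["scan"] = f"germination_qtl_{cond}"
        scans.append(rec)

    rec = detect_treatment_effects(log_table, rule=config.treatment_rule)
    rec["scan"] = "treatment_effect"
    scans.append(rec)

    rec = detect_fc_qtls(log_table, config.control_line, rule=config.fc_rule)
    rec["scan"] = "fc_qtl"
    scans.append(rec)

    qtl_records = pd.concat(scans, ignore_index=True)
    save("qtl_records", qtl_records, index=False)

    # ---- correlation networks (per condition) -----------------------------
    log.info("stage network")
    imputed_table = pd.concat([meta_for_log, imputed.values], axis=1)
    germ_keyed = germ_traits.set_index(PLOT_KEY)[list(GERM_TRAIT_NODES)]
    net_results = {}
    attr_rows = []
    for cond in ("SDF", "SDS"):
        sub = imputed_table[imputed_table["treatment"] == cond]
        mat = sub.drop(columns=PLOT_KEY)
        key = pd.MultiIndex.from_frame(sub[PLOT_KEY])
        traits = germ_keyed.reindex(key)
        traits.index = mat.index
        corr_input = pd.concat([mat, traits], axis=1)
        r, p = spearman_matrix(corr_input)
        p_adj = adjust_p_matrix(p)
        net = build_network(r, p_adj, r_min=config.network_r_min,
                            q=config.network_q)
        if net.number_of_nodes() == 0:
            log.warning("condition %s: empty network", cond)
            continue
        attrs = network_attributes(net)
        attr_rows.append({"condition": cond, **attrs.to_dict()})

        met_nodes = [v for v in net.nodes() if v not in GERM_TRAIT_NODES]
        met_net = net.subgraph(met_nodes)
        partition = walktrap_communities(met_net,
                                         steps=config.walktrap_steps)
        bipartitions = {}
        for cid in sorted(set(partition.values())):
            members = [v for v, c in partition.items() if c == cid]
            bipartitions[cid] = signed_bipartition(met_net.subgraph(members))
        sets = assemble_metabolite_sets(partition, bipartitions, net,
                                        germination_percent_node="percent")
        germ_report = germination_edge_report(net, sets)
        net_results[cond] = (net, partition, sets, germ_report)

        edges = pd.DataFrame(
            [(u, v, d["r"], d["p_adj"], d["sign"])
             for u, v, d in sorted(net.edges(data=True))],
            columns=["u", "v", "r", "p_adj", "sign"])
        save(f"edges_{cond}", edges, index=False)
        save(f"communities_{cond}", pd.DataFrame(
            sorted(partition.items()), columns=["node", "community"]),
            index=False)
        save(f"sets_{cond}", pd.DataFrame(
            sorted(sets.assignment.items()), columns=["node", "set"]),
            index=False)
        save(f"germination_edges_{cond}", germ_report, index=False)
    save("attributes", pd.DataFrame(attr_rows), index=False)

    # ---- vigor integration ------------------------------------------------
    log.info("stage integrate")
    pca = run_pca(imputed.values)
    save("pca_scores", pca.scores, index_label="sample_id")
    save("pca_loadings", pca.loadings, index_label="metabolite")
    save("pca_variance", pd.DataFrame({
        "component": pca.scores.columns,
        "variance_explained": pca.variance_explained}), index=False)

    clusters = kmeans_plots(imputed.values, k=config.kmeans_k,
                            n_restarts=config.kmeans_restarts,
                            rng_seed=config.seed)
    save("clusters", clusters.to_frame(), index_label="sample_id")

    germ_keyed_all = germ_traits.set_index(PLOT_KEY)["percent"]
    sample_key = pd.MultiIndex.from_frame(meta_for_log[PLOT_KEY])
    percent = pd.Series(germ_keyed_all.reindex(sample_key).to_numpy(),
                        index=meta_for_log.index)
    groups = percent.dropna().map(
        lambda v: classify_germination_group(v, well_min=config.well_min_percent))
    enrichment = None
    common = clusters.index.intersection(groups.index)
    if len(common) and groups.loc[common].nunique() > 1:
        enrichment = cluster_germination_enrichment(clusters.loc[common],
                                                    groups.loc[common])
        enr = enrichment.composition.copy()
        enr["chi_square"] = enrichment.chi_square
        enr["df"] = enrichment.df
        enr["p_value"] = enrichment.p_value
        save("enrichment", enr, index_label="cluster")

    contrasts = None
    if {"well", "non"} <= set(groups.unique()):
        sub = imputed.values.loc[groups.index]
        contrasts = germination_group_contrasts(sub, groups,
                                                rule=config.qtl_rule)
        save("group_contrasts", contrasts)

    # ---- manifest ---------------------------------------------------------
    import scipy
    import sklearn
    import igraph

    manifest = {
        "package": "seedmet",
        "version": __version__,
        "config": config.to_dict(),
        "config_hash": chash,
        "seed": config.seed,
        "elapsed_s": round(time.time() - t0, 2),
        "versions": {
            "numpy": np.__version__, "scipy": scipy.__version__,
            "pandas": pd.__version__, "scikit-learn": sklearn.__version__,
            "igraph": igraph.__version__,
        },
        "artifacts": {k: str(v) for k, v in sorted(artifacts.items())},
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    artifacts["manifest"] = outdir / "manifest.json"
    log.info("pipeline complete in %.1fs, %d artifacts",
             time.time() - t0, len(artifacts))
    return artifacts
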