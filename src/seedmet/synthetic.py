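"""Synthetic introgression-line (IL) seed metabolomics dataset generator.

Emulates the statistical structure of a tomato IL field experiment: ~72 ILs
plus the recurrent-parent control (M82), grown under fresh-water (SDF) and
saline (SDS) irrigation with five replicate plots per line x treatment.  Each
plot yields

* GC-MS peak heights for ~65 annotated metabolites, organised into two latent,
  mutually anti-correlated metabolite sets (S1 and S2) with run-block
  multiplicative effects, line-specific QTL shifts and optional salinity
  shifts;
* seed morphology (average seed weight, mature / aborted counts per fruit);
* germination plate records (seeds sown, daily cumulative germinated counts)
  whose vigor is driven by the plot's metabolic balance score
  (mean latent S2 minus mean latent S1).

Ground truth (set assignment, planted QTL effects, balance scores) is carried
alongside every dataset so downstream recovery can be scored.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.special import expit

__all__ = [
    "SynthConfig",
    "GroundTruth",
    "SyntheticDataset",
    "substream",
    "generate_metabolite_latents",
    "latents_to_peaks",
    "generate_germination",
    "generate_morphology",
    "generate_dataset",
]

CONTROL_LINE = "M82"
MAX_GERMINATION_DAY = 14


def substream(seed: int, name: str) -> np.random.Generator:
    """Named, reproducible child RNG of a single top-level seed.

    All generator components draw from ``substream(seed, component_name)`` so
    that regenerating one component (or the whole dataset) with the same seed
    is bit-identical, independent of call order.
    """
    return np.random.default_rng([seed & 0x7FFFFFFF, zlib.crc32(name.encode())])


@dataclass
class SynthConfig:
    """Study-design and effect-size parameters of the simulated experiment.

    Defaults mirror the design of the emulated field trial: 72 ILs + M82,
    5 replicate plots per line x treatment, 65 annotated metabolites split
    into two anti-correlated sets, 3 plates x 50 seeds per germination test.
    """

    n_ils: int = 72
    n_plots: int = 5
    n_metabolites: int = 65
    set_sizes: tuple[int, int] = (40, 25)
    rho_within: float = 0.6
    rho_between: float = -0.4
    noise_sigma: float = 0.3          # log-scale SD of latent metabolite levels
    n_blocks: int = 4
    block_sigma: float = 0.3          # log-scale SD of block x metabolite factor
    load_sigma: float = 0.2           # log-scale SD of per-sample load factor
    missing_frac: float = 0.05
    # metabolite QTLs
    qtl_lines_frac: float = 0.15
    qtl_mets_per_line: int = 3
    # |log-scale shift| per planted QTL; ~3.3-fold, the magnitude detected
    # metabolite loci show against replicate noise in IL populations
    qtl_effect: float = 1.2
    # salinity effect on metabolites (near-null by default: the emulated
    # experiment saw ~1% of SDS-vs-SDF comparisons significant at p<0.01,
    # indistinguishable from the null rate)
    treatment_effect: float = 0.0
    treatment_mets: tuple[int, ...] = ()
    # deteriorated plots: a small fraction of plots with a strong S1-up /
    # S2-down metabolic shift and consequently (near-)zero germination
    deteriorated_frac: float = 0.10
    deterioration_shift: float = 1.5
    # morphology
    seed_weight_base: float = 2.5     # mg
    seed_weight_sigma: float = 0.15
    weight_qtl_lines: Mapping[str, float] = field(
        default_factory=lambda: {
            "IL03": -0.4, "IL12": 0.5, "IL27": 0.45,
            "IL44": -0.35, "IL58": 0.4, "IL66": 0.45,
        }
    )
    fruits_per_plot: int = 2
    seeds_per_fruit: int = 60
    abortion_base: float = 0.10
    abortion_salinity_effect: float = 0.08
    # germination link
    germ_beta0: float = 2.5           # baseline log-odds of germination
    germ_beta: float = 2.5            # slope on the S2-S1 balance score
    t50_mu0: float = 3.0              # baseline expected germination day
    t50_gamma: float = 0.5            # day decrease per unit balance score
    day_dispersion: float = 6.0       # negative-binomial size of the day law
    seeds_per_plate: int = 50
    n_plates: int = 3
    # peak-table plumbing
    seed_mass_mean: float = 50.0      # mg of seed extracted per sample
    seed_mass_sd: float = 5.0
    season: str = "I"
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if sum(self.set_sizes) != self.n_metabolites:
            raise ValueError("set_sizes must sum to n_metabolites")
        if not (self.rho_within > 0 > self.rho_between):
            raise ValueError("require rho_within > 0 > rho_between")
        if self.noise_sigma <= 0:
            raise ValueError("noise_sigma must be > 0")
        for name in ("seed_weight_sigma", "seed_mass_sd", "block_sigma",
                     "load_sigma"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("missing_frac", "deteriorated_frac", "abortion_base",
                     "qtl_lines_frac"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")

    @property
    def lines(self) -> list[str]:
        return [CONTROL_LINE] + [f"IL{i:02d}" for i in range(1, self.n_ils + 1)]

    @property
    def metabolites(self) -> list[str]:
        return [f"met{i:02d}" for i in range(1, self.n_metabolites + 1)]


@dataclass
class GroundTruth:
    """Planted structure of one synthetic dataset."""

    set_assignment: dict[str, str]            # metabolite -> {"S1", "S2"}
    qtl_map: dict[tuple[str, str], float]     # (line, trait) -> log-scale effect
    balance_score: pd.Series                  # per sample: mean S2 - mean S1
    deteriorated: pd.Series                   # per sample: bool

    def to_frame(self) -> pd.DataFrame:
        rows = [("set", m, s) for m, s in self.set_assignment.items()]
        rows += [("qtl", f"{ln}|{tr}", str(e)) for (ln, tr), e in self.qtl_map.items()]
        rows += [("balance", s, repr(float(v))) for s, v in self.balance_score.items()]
        rows += [("deteriorated", s, str(bool(v))) for s, v in self.deteriorated.items()]
        return pd.DataFrame(rows, columns=["kind", "key", "value"])


def _sample_frame(config: SynthConfig) -> pd.DataFrame:
    """One row per plot (sample): line, treatment, season, plot, run block.

    Blocks are assigned round-robin within the season, mirroring an analytic
    run order interleaved across the field design.
    """
    rows = []
    for line in config.lines:
        for treatment in ("SDF", "SDS"):
            for plot in range(1, config.n_plots + 1):
                rows.append((f"{line}_{treatment}_{plot}", line, treatment,
                             config.season, plot))
    meta = pd.DataFrame(
        rows, columns=["sample_id", "line", "treatment", "season", "plot"]
    ).set_index("sample_id")
    meta["run_block"] = [f"B{i % config.n_blocks + 1}" for i in range(len(meta))]
    return meta


def _correlation_matrix(config: SynthConfig) -> np.ndarray:
    n1, n2 = config.set_sizes
    m = config.n_metabolites
    r = np.full((m, m), config.rho_between)
    r[:n1, :n1] = config.rho_within
    r[n1:, n1:] = config.rho_within
    np.fill_diagonal(r, 1.0)
    return r


def generate_metabolite_latents(
    config: SynthConfig, rng: np.random.Generator | None = None
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Draw the plot x metabolite latent (log-scale) abundance matrix.

    Latents are multivariate normal with within-set correlation
    ``rho_within`` and between-set correlation ``rho_between``, plus planted
    line-QTL shifts, optional salinity shifts, and the deteriorated-plot
    S1-up / S2-down shift.  Returns ``(meta, latents, truth)``.

    Raises ``ValueError`` for correlation targets that yield a
    non-positive-definite matrix ("infeasible correlation structure").
    """
    if rng is None:
        rng = substream(config.rng_seed, "latents")
    meta = _sample_frame(config)
    corr = _correlation_matrix(config)
    # eigen-factorization tolerates the singular (perfect-correlation) edge
    # cases while still rejecting genuinely indefinite targets
    eigval, eigvec = np.linalg.eigh(corr)
    if eigval.min() < -1e-8:
        raise ValueError(
            "infeasible correlation structure: the (rho_within, rho_between, "
            "set_sizes) targets do not form a positive semidefinite matrix"
        )
    factor = eigvec * np.sqrt(np.clip(eigval, 0.0, None))

    n = len(meta)
    z = rng.standard_normal((n, config.n_metabolites))
    latents = pd.DataFrame(
        z @ factor.T * config.noise_sigma, index=meta.index,
        columns=config.metabolites,
    )

    n1 = config.set_sizes[0]
    mets = config.metabolites
    set_assignment = {m: ("S1" if i < n1 else "S2") for i, m in enumerate(mets)}

    # planted metabolite QTLs: a fraction of ILs each shift a few metabolites
    qtl_rng = substream(config.rng_seed, "qtl-map")
    ils = config.lines[1:]
    n_qtl_lines = int(round(config.qtl_lines_frac * len(ils)))
    qtl_lines = qtl_rng.choice(ils, size=n_qtl_lines, replace=False)
    qtl_map: dict[tuple[str, str], float] = {}
    for line in qtl_lines:
        hit = qtl_rng.choice(mets, size=config.qtl_mets_per_line, replace=False)
        for met in hit:
            # heterogeneous locus strengths: magnitude drawn around the
            # configured scale so a scan sees both clear and marginal QTLs
            effect = (config.qtl_effect * qtl_rng.uniform(0.5, 2.0)
                      * qtl_rng.choice([-1.0, 1.0]))
            qtl_map[(str(line), str(met))] = effect
            latents.loc[meta["line"] == line, met] += effect

    # salinity shift on a configured metabolite subset (default: none)
    if config.treatment_effect != 0.0 and config.treatment_mets:
        sds = meta["treatment"] == "SDS"
        for j in config.treatment_mets:
            latents.loc[sds, mets[j]] += config.treatment_effect

    # deteriorated plots: strong shift toward S1, away from S2
    det_rng = substream(config.rng_seed, "deterioration")
    deteriorated = pd.Series(
        det_rng.random(n) < config.deteriorated_frac, index=meta.index
    )
    if deteriorated.any():
        latents.loc[deteriorated, mets[:n1]] += config.deterioration_shift
        latents.loc[deteriorated, mets[n1:]] -= config.deterioration_shift

    balance = latents[mets[n1:]].mean(axis=1) - latents[mets[:n1]].mean(axis=1)
    truth = GroundTruth(set_assignment, qtl_map, balance, deteriorated)
    return meta, latents, truth


def latents_to_peaks(
    latents: pd.DataFrame,
    meta: pd.DataFrame,
    config: SynthConfig,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Convert latent log-abundances into a raw GC-MS peak-height table.

    peak = exp(latent) * seed_mass_extracted * block_factor * load_factor,
    where the block factor is a per (run block, metabolite) multiplicative
    effect and the load factor a per-sample injection/extraction factor.
    A ``missing_frac`` fraction of entries is removed completely at random.
    The returned frame carries the metadata columns needed for normalization
    to undo every non-biological factor.
    """
    if rng is None:
        rng = substream(config.rng_seed, "peaks")
    mets = list(latents.columns)
    blocks = sorted(meta["run_block"].unique())
    block_factor = pd.DataFrame(
        np.exp(rng.normal(0.0, config.block_sigma, (len(blocks), len(mets)))),
        index=blocks, columns=mets,
    )
    load = np.exp(rng.normal(0.0, config.load_sigma, len(meta)))
    seed_mass = rng.normal(config.seed_mass_mean, config.seed_mass_sd, len(meta))
    seed_mass = np.clip(seed_mass, 1.0, None)

    values = np.exp(latents.to_numpy())
    values = values * block_factor.loc[meta["run_block"]].to_numpy()
    values = values * load[:, None] * seed_mass[:, None]

    if config.missing_frac > 0:
        mask = rng.random(values.shape) < config.missing_frac
        values = np.where(mask, np.nan, values)

    peaks = meta.copy()
    peaks["seed_mass_extracted"] = seed_mass
    peaks[mets] = values
    return peaks


def generate_germination(
    balance_scores: pd.Series,
    meta: pd.DataFrame,
    config: SynthConfig,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Simulate germination plate records from per-plot balance scores.

    Each sown seed germinates with probability
    ``logistic(germ_beta0 + germ_beta * score)``; germination day follows a
    shifted negative binomial on days 1..14 whose mean is
    ``max(1.5, t50_mu0 - t50_gamma * score)``.  Returns a long frame with one
    row per plate and day: plate_id, plot key, seeds_sown, day, cumulative.
    """
    if rng is None:
        rng = substream(config.rng_seed, "germination")
    rows = []
    days = np.arange(1, MAX_GERMINATION_DAY + 1)
    for sample_id, score in balance_scores.items():
        line, treatment, season, plot = (
            meta.loc[sample_id, "line"], meta.loc[sample_id, "treatment"],
            meta.loc[sample_id, "season"], meta.loc[sample_id, "plot"],
        )
        p_germ = float(expit(config.germ_beta0 + config.germ_beta * score))
        mean_day = max(1.5, config.t50_mu0 - config.t50_gamma * score)
        mu = mean_day - 1.0  # shifted NB: day = 1 + NB count
        size = config.day_dispersion
        p_nb = size / (size + mu) if mu > 0 else 1.0
        for plate in range(1, config.n_plates + 1):
            k = int(rng.binomial(config.seeds_per_plate, p_germ))
            if k > 0:
                seed_days = 1 + rng.negative_binomial(size, p_nb, k)
                seed_days = np.minimum(seed_days, MAX_GERMINATION_DAY)
                cumulative = np.cumsum(np.bincount(
                    seed_days, minlength=MAX_GERMINATION_DAY + 1)[1:])
            else:
                cumulative = np.zeros(MAX_GERMINATION_DAY, dtype=int)
            plate_id = f"{sample_id}_P{plate}"
            for d, c in zip(days, cumulative):
                rows.append((plate_id, line, treatment, season, plot,
                             config.seeds_per_plate, int(d), int(c)))
    return pd.DataFrame(rows, columns=[
        "plate_id", "line", "treatment", "season", "plot",
        "seeds_sown", "day", "cumulative",
    ])


def generate_morphology(
    meta: pd.DataFrame,
    config: SynthConfig,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Per-plot seed weight and mature/aborted counts.

    Seed weight is line base plus any planted weight QTL plus noise and is
    unaffected by treatment; abortion probability rises by
    ``abortion_salinity_effect`` under SDS.
    """
    if rng is None:
        rng = substream(config.rng_seed, "morphology")
    n = len(meta)
    weight_shift = meta["line"].map(
        lambda ln: config.weight_qtl_lines.get(ln, 0.0)).to_numpy()
    weight = (config.seed_weight_base + weight_shift
              + rng.normal(0.0, config.seed_weight_sigma, n))
    p_abort = np.where(
        meta["treatment"].to_numpy() == "SDS",
        config.abortion_base + config.abortion_salinity_effect,
        config.abortion_base,
    )
    total = rng.poisson(config.seeds_per_fruit * config.fruits_per_plot, n)
    total = np.maximum(total, 1)
    aborted = rng.binomial(total, np.clip(p_abort, 0.0, 1.0))
    morph = meta[["line", "treatment", "season", "plot"]].copy()
    morph["avg_seed_weight"] = weight
    morph["mature"] = total - aborted
    morph["aborted"] = aborted
    return morph


@dataclass
class SyntheticDataset:
    """A full synthetic experiment plus its ground truth."""

    config: SynthConfig
    meta: pd.DataFrame
    peaks: pd.DataFrame
    morphology: pd.DataFrame
    germination: pd.DataFrame
    truth: GroundTruth

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Write the standard pipeline input files plus ground truth."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "peaks": outdir / "peaks.tsv",
            "morphology": outdir / "morphology.tsv",
            "germination": outdir / "germination.tsv",
            "ground_truth": outdir / "ground_truth.tsv",
            "config": outdir / "synth_config.yaml",
        }
        self.peaks.to_csv(paths["peaks"], sep="\t", na_rep="NA",
                          index_label="sample_id")
        self.morphology.to_csv(paths["morphology"], sep="\t",
                               index_label="sample_id")
        self.germination.to_csv(paths["germination"], sep="\t", index=False)
        self.truth.to_frame().to_csv(paths["ground_truth"], sep="\t", index=False)
        import yaml

        cfg = asdict(self.config)
        cfg["weight_qtl_lines"] = dict(cfg["weight_qtl_lines"])
        cfg["set_sizes"] = list(cfg["set_sizes"])
        cfg["treatment_mets"] = list(cfg["treatment_mets"])
        paths["config"].write_text(yaml.safe_dump(cfg, sort_keys=True))
        return paths


def generate_dataset(config: SynthConfig | None = None) -> SyntheticDataset:
    """Generate a complete synthetic dataset from one top-level seed."""
    config = config or SynthConfig()
    meta, latents, truth = generate_metabolite_latents(config)
    peaks = latents_to_peaks(latents, meta, config)
    germination = generate_germination(truth.balance_score, meta, config)
    morphology = generate_morphology(meta, config)
    return SyntheticDataset(config, meta, peaks, morphology, germination, truth)
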