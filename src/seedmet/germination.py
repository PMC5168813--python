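"""Germination vigor and seed morphology traits.

Vigor measures per germination plate:

* final germination percent (of seeds sown),
* T50 — the first day on which cumulative germination reaches 50% of the
  seeds that eventually germinated in the plate (undefined for 0 germinated),
* SD-plate — the sample standard deviation of individual seeds' germination
  day (a uniformity measure; undefined for fewer than 2 germinated seeds).

Plates are aggregated to the field plot (the analysis unit) by unweighted
means of the defined per-plate values.  The salinity response of a line is
the ratio of its trait means in SDS over SDF, with a Welch t-test on the
plot-level values.  Undefined values propagate as missing, never as zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .qtl import welch_t_test, MultiplicityRule

__all__ = [
    "PlateGermination",
    "GerminationTraits",
    "plate_percent",
    "plate_t50",
    "plate_sd",
    "aggregate_plot",
    "plates_from_frame",
    "germination_traits_table",
    "salinity_fold_change",
    "fold_change_table",
    "classify_germination_group",
    "maturation_percent",
]

GERMINATION_TRAITS = ("percent", "t50", "sd_plate")


@dataclass(frozen=True)
class PlateGermination:
    """Cumulative daily germination counts of one plate of sown seeds."""

    plate_id: str
    line: str
    treatment: str
    season: str
    plot: int
    seeds_sown: int
    cumulative: tuple[int, ...]  # indexed by day, day 1 first

    def __post_init__(self) -> None:
        c = self.cumulative
        if any(b < a for a, b in zip(c, c[1:])):
            raise ValueError(f"{self.plate_id}: cumulative counts decrease")
        if c and c[-1] > self.seeds_sown:
            raise ValueError(f"{self.plate_id}: germinated > seeds sown")

    @property
    def final_count(self) -> int:
        return self.cumulative[-1] if self.cumulative else 0

    @property
    def increments(self) -> np.ndarray:
        return np.diff(np.concatenate([[0], self.cumulative]))


@dataclass
class GerminationTraits:
    """Plot-level germination vigor (means over plates, with SEs)."""

    line: str
    treatment: str
    season: str
    plot: int
    percent: float
    t50: float | None
    sd_plate: float | None
    n_plates: int
    percent_se: float | None = None
    t50_se: float | None = None
    sd_plate_se: float | None = None


def plate_percent(plate: PlateGermination) -> float:
    """Final germination percent of seeds sown."""
    if plate.seeds_sown <= 0:
        raise ValueError("seeds_sown must be > 0")
    return 100.0 * plate.final_count / plate.seeds_sown


def plate_t50(plate: PlateGermination) -> int | None:
    """First day on which cumulative germination reaches half the final count.

    The 50% threshold refers to the seeds that eventually germinated, not to
    the seeds sown.  Undefined (None) when no seed germinated.
    """
    final = plate.final_count
    if final == 0:
        return None
    half = 0.5 * final
    for day, count in enumerate(plate.cumulative, start=1):
        if count >= half:
            return day
    raise AssertionError("unreachable: final count reaches its own half")


def plate_sd(plate: PlateGermination) -> float | None:
    """Sample SD of per-seed germination days; None for < 2 germinated."""
    inc = plate.increments
    n = int(inc.sum())
    if n < 2:
        return None
    days = np.repeat(np.arange(1, len(inc) + 1), inc)
    return float(np.std(days, ddof=1))


def _mean_se(values: list[float]) -> tuple[float | None, float | None]:
    if not values:
        return None, None
    mean = float(np.mean(values))
    se = float(np.std(values, ddof=1) / math.sqrt(len(values))) \
        if len(values) > 1 else 0.0
    return mean, se


def aggregate_plot(plates: list[PlateGermination]) -> GerminationTraits:
    """Unweighted plate means of percent, T50 and SD-plate for one plot."""
    if not plates:
        raise ValueError("at least one plate required")
    first = plates[0]
    pct, pct_se = _mean_se([plate_percent(p) for p in plates])
    t50, t50_se = _mean_se([t for p in plates if (t := plate_t50(p)) is not None])
    sd, sd_se = _mean_se([s for p in plates if (s := plate_sd(p)) is not None])
    return GerminationTraits(
        line=first.line, treatment=first.treatment, season=first.season,
        plot=first.plot, percent=pct, t50=t50, sd_plate=sd,
        n_plates=len(plates), percent_se=pct_se, t50_se=t50_se,
        sd_plate_se=sd_se,
    )


def plates_from_frame(df: pd.DataFrame) -> list[PlateGermination]:
    """Build plate records from a germination.tsv table (either dialect).

    Long dialect: columns plate_id, line, treatment, season, plot,
    seeds_sown, day, cumulative — one row per plate and day.  Wide dialect:
    one row per plate with cumulative-count columns day1, day2, ...
    """
    plates = []
    if "day" in df.columns and "cumulative" in df.columns:
        for plate_id, grp in df.groupby("plate_id", sort=True):
            grp = grp.sort_values("day")
            row = grp.iloc[0]
            plates.append(PlateGermination(
                plate_id=str(plate_id), line=str(row["line"]),
                treatment=str(row["treatment"]), season=str(row["season"]),
                plot=int(row["plot"]), seeds_sown=int(row["seeds_sown"]),
                cumulative=tuple(int(c) for c in grp["cumulative"]),
            ))
        return plates
    day_cols = sorted((c for c in df.columns if c.startswith("day")
                       and c[3:].isdigit()), key=lambda c: int(c[3:]))
    if not day_cols:
        raise ValueError("germination table matches neither the long "
                         "(day/cumulative) nor the wide (day1..dayN) dialect")
    for _, row in df.iterrows():
        plates.append(PlateGermination(
            plate_id=str(row["plate_id"]), line=str(row["line"]),
            treatment=str(row["treatment"]), season=str(row["season"]),
            plot=int(row["plot"]), seeds_sown=int(row["seeds_sown"]),
            cumulative=tuple(int(row[c]) for c in day_cols),
        ))
    return plates


def germination_traits_table(plates: list[PlateGermination]) -> pd.DataFrame:
    """Aggregate all plates to one row per plot."""
    rows = []
    key = lambda p: (p.line, p.treatment, p.season, p.plot)
    groups: dict[tuple, list[PlateGermination]] = {}
    for p in plates:
        groups.setdefault(key(p), []).append(p)
    for k in sorted(groups):
        t = aggregate_plot(groups[k])
        rows.append({
            "line": t.line, "treatment": t.treatment, "season": t.season,
            "plot": t.plot, "percent": t.percent, "t50": t.t50,
            "sd_plate": t.sd_plate, "n_plates": t.n_plates,
            "percent_se": t.percent_se, "t50_se": t.t50_se,
            "sd_plate_se": t.sd_plate_se,
        })
    return pd.DataFrame(rows)


def fold_change_table(means_sdf: pd.DataFrame, means_sds: pd.DataFrame) -> pd.DataFrame:
    """Per-line SDS/SDF ratios of germination trait means.

    Inputs are line-indexed frames of trait means (columns from
    ``GERMINATION_TRAITS``).  A zero SDF mean leaves the ratio undefined.
    """
    lines = means_sdf.index.intersection(means_sds.index)
    out = {}
    for trait in GERMINATION_TRAITS:
        if trait in means_sdf.columns and trait in means_sds.columns:
            denom = means_sdf.loc[lines, trait].replace(0.0, np.nan)
            out[f"fc_{trait}"] = means_sds.loc[lines, trait] / denom
    return pd.DataFrame(out, index=lines)


def salinity_fold_change(
    traits: pd.DataFrame,
    rule: MultiplicityRule | None = None,
) -> pd.DataFrame:
    """Salinity response of each line: trait ratios SDS/SDF plus t-tests.

    ``traits`` is plot-level (one row per plot, as from
    ``germination_traits_table``).  For each line and trait the fold change
    is the ratio of the line's SDS mean to its SDF mean; a Welch t-test on
    the plot values tests the treatment difference, with significance marked
    by ``rule`` (permissive Bonferroni over all line x trait tests by
    default).
    """
    rule = rule or MultiplicityRule(alpha=0.05, variant="permissive_bonferroni")
    rows = []
    for line, grp in traits.groupby("line", sort=True):
        sdf = grp[grp["treatment"] == "SDF"]
        sds = grp[grp["treatment"] == "SDS"]
        if sdf.empty or sds.empty:
            continue
        row: dict = {"line": line}
        for trait in GERMINATION_TRAITS:
            x = sdf[trait].dropna().to_numpy(dtype=float)
            y = sds[trait].dropna().to_numpy(dtype=float)
            mean_f = float(np.mean(x)) if len(x) else np.nan
            mean_s = float(np.mean(y)) if len(y) else np.nan
            row[f"fc_{trait}"] = mean_s / mean_f if mean_f else np.nan
            if len(x) >= 2 and len(y) >= 2:
                _, _, p = welch_t_test(y, x)
            else:
                p = np.nan
            row[f"p_{trait}"] = p
        rows.append(row)
    out = pd.DataFrame(rows).set_index("line")
    n_tests = int(out[[f"p_{t}" for t in GERMINATION_TRAITS]].notna().sum().sum())
    cutoff = rule.cutoff(max(n_tests, 1))
    for trait in GERMINATION_TRAITS:
        out[f"significant_{trait}"] = out[f"p_{trait}"] < cutoff
    return out


def classify_germination_group(
    percent: float,
    well_min: float = 95.0,
) -> str:
    """Assign a plot to the non / intermediate / well germination group.

    0% is non-germinating; at or above ``well_min`` (default 95%) is
    well-germinating; anything between is intermediate.
    """
    if not 0.0 <= percent <= 100.0:
        raise ValueError("percent must be in [0, 100]")
    if percent == 0.0:
        return "non"
    if percent >= well_min:
        return "well"
    return "intermediate"


def maturation_percent(mature: int, aborted: int) -> float | None:
    """Mature seeds as a percentage of all (mature + aborted) seeds."""
    if mature < 0 or aborted < 0:
        raise ValueError("counts must be non-negative")
    total = mature + aborted
    if total == 0:
        return None
    return 100.0 * mature / total
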