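"""Putative QTL calling by IL-vs-control and within-line treatment contrasts.

An introgression line (IL) carries a single defined wild-species chromosome
segment in the control background, so a significant trait difference between
an IL and the control maps the trait to that segment — a putative QTL.  Three
scans are provided:

* ``detect_trait_qtls`` — IL vs control per condition (metabolite f-/s-QTLs on
  log RMC; seed weight, maturation percent and germination QTLs on raw
  trait values);
* ``detect_treatment_effects`` — SDS vs SDF within each line;
* ``detect_fc_qtls`` — fold-change QTLs: the salinity response of an IL
  compared with the control's, estimated as the log-scale interaction
  contrast over the four line x treatment cells.

All tests are Welch (unequal-variance) two-sample t-tests.  Multiplicity is
handled by Bonferroni or the permissive Bonferroni variant (cutoff alpha
divided by the square root of the number of comparisons, "Bcp"), with n taken
per scan.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

__all__ = [
    "MultiplicityRule",
    "QTLRecord",
    "permissive_bonferroni_cutoff",
    "welch_t_test",
    "detect_trait_qtls",
    "detect_treatment_effects",
    "detect_fc_qtls",
]

META_COLUMNS = ("line", "treatment", "season", "plot", "run_block",
                "seed_mass_extracted")

QTL_RECORD_COLUMNS = ["line", "trait", "contrast", "direction", "estimate",
                      "p_value", "threshold_rule", "significant"]


def permissive_bonferroni_cutoff(alpha: float, n: int) -> float:
    """Permissive Bonferroni cutoff: alpha / sqrt(n)."""
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    if n < 1:
        raise ValueError("n must be >= 1")
    return alpha / math.sqrt(n)


@dataclass(frozen=True)
class MultiplicityRule:
    """A per-scan multiple-testing rule.

    ``variant`` is "bonferroni" (cutoff alpha/n), "permissive_bonferroni"
    (alpha/sqrt(n), the Bcp rule) or "raw" (cutoff alpha, no adjustment).
    """

    alpha: float = 0.05
    variant: str = "permissive_bonferroni"

    def __post_init__(self) -> None:
        if self.variant not in ("bonferroni", "permissive_bonferroni", "raw"):
            raise ValueError(f"unknown variant {self.variant!r}")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")

    def cutoff(self, n: int) -> float:
        if n < 1:
            raise ValueError("n must be >= 1")
        if self.variant == "bonferroni":
            return self.alpha / n
        if self.variant == "permissive_bonferroni":
            return permissive_bonferroni_cutoff(self.alpha, n)
        return self.alpha

    @property
    def name(self) -> str:
        tag = {"bonferroni": "Bc", "permissive_bonferroni": "Bcp",
               "raw": "raw"}[self.variant]
        return f"{tag}_{str(self.alpha).replace('0.', '')}"


@dataclass(frozen=True)
class QTLRecord:
    """One putative QTL call."""

    line: str
    trait: str
    contrast: str
    direction: str
    estimate: float
    p_value: float
    threshold_rule: str
    significant: bool


def welch_t_test(x, y) -> tuple[float, float, float]:
    """Welch two-sample t-test.

    Returns ``(t, df, p)`` with the Welch-Satterthwaite degrees of freedom
    and a two-sided p-value.  When both groups have zero variance and equal
    means the difference is exactly zero and ``(0, df, 1)`` is returned.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    nx, ny = len(x), len(y)
    if nx < 2 or ny < 2:
        raise ValueError("each group needs at least 2 values")
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    se2 = vx / nx + vy / ny
    diff = x.mean() - y.mean()
    if se2 == 0.0:
        if diff == 0.0:
            return 0.0, float(nx + ny - 2), 1.0
        return math.copysign(math.inf, diff), float(nx + ny - 2), 0.0
    t = diff / math.sqrt(se2)
    df = se2**2 / ((vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1))
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), float(df), float(p)


def _split(trait_table: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    meta_cols = [c for c in trait_table.columns if c in META_COLUMNS]
    traits = [c for c in trait_table.columns if c not in META_COLUMNS]
    return trait_table[meta_cols], traits


def _records_frame(records: list[QTLRecord]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in records],
                        columns=QTL_RECORD_COLUMNS)


def detect_trait_qtls(
    trait_table: pd.DataFrame,
    control_line: str,
    condition: str,
    rule: MultiplicityRule | None = None,
) -> pd.DataFrame:
    """Scan every IL x trait for differences from the control in one condition.

    ``trait_table`` holds plot-level values: metadata columns (at least
    ``line`` and ``treatment``) plus one column per trait (log RMC for
    metabolites, raw values for morphology / germination traits).  Each IL is
    compared with the control by a Welch t-test; significance is marked by
    ``rule`` with n equal to the number of comparisons performed in the scan.
    """
    rule = rule or MultiplicityRule()
    meta, traits = _split(trait_table)
    sub = trait_table[meta["treatment"] == condition]
    control = sub[sub["line"] == control_line]
    if len(control) < 2:
        raise ValueError(f"control line {control_line!r} needs >= 2 replicates "
                         f"in condition {condition!r}")
    records: list[QTLRecord] = []
    contrast = f"IL_vs_control@{condition}"
    for line, grp in sub.groupby("line", sort=True):
        if line == control_line:
            continue
        for trait in traits:
            x = grp[trait].dropna().to_numpy(dtype=float)
            y = control[trait].dropna().to_numpy(dtype=float)
            if len(x) < 2 or len(y) < 2:
                log.warning("skipped %s/%s in %s: <2 replicates",
                            line, trait, condition)
                continue
            t, _, p = welch_t_test(x, y)
            est = float(np.mean(x) - np.mean(y))
            records.append(QTLRecord(
                line=str(line), trait=trait, contrast=contrast,
                direction="+" if est >= 0 else "-", estimate=est,
                p_value=p, threshold_rule=rule.name, significant=False,
            ))
    return _finalize(records, rule)


def detect_treatment_effects(
    trait_table: pd.DataFrame,
    rule: MultiplicityRule | None = None,
) -> pd.DataFrame:
    """SDS-vs-SDF Welch t-test per line x trait.

    The emulated analysis reported these at raw p < 0.01, so the default
    rule is unadjusted alpha = 0.01; pass any ``MultiplicityRule`` to change
    that.
    """
    rule = rule or MultiplicityRule(alpha=0.01, variant="raw")
    meta, traits = _split(trait_table)
    records: list[QTLRecord] = []
    for line, grp in trait_table.groupby("line", sort=True):
        sds = grp[grp["treatment"] == "SDS"]
        sdf = grp[grp["treatment"] == "SDF"]
        if len(sds) < 2 or len(sdf) < 2:
            log.warning("skipped line %s: missing a treatment", line)
            continue
        for trait in traits:
            x = sds[trait].dropna().to_numpy(dtype=float)
            y = sdf[trait].dropna().to_numpy(dtype=float)
            if len(x) < 2 or len(y) < 2:
                continue
            t, _, p = welch_t_test(x, y)
            est = float(np.mean(x) - np.mean(y))
            records.append(QTLRecord(
                line=str(line), trait=trait, contrast="SDS_vs_SDF_within_line",
                direction="+" if est >= 0 else "-", estimate=est,
                p_value=p, threshold_rule=rule.name, significant=False,
            ))
    return _finalize(records, rule)


def detect_fc_qtls(
    log_rmc: pd.DataFrame,
    control_line: str,
    rule: MultiplicityRule | None = None,
) -> pd.DataFrame:
    """Fold-change QTLs: IL salinity response vs control salinity response.

    On the log scale the contrast is the interaction
    ``(mean IL,SDS - mean IL,SDF) - (mean control,SDS - mean control,SDF)``,
    whose sign equals the sign of log(FC_IL / FC_control) computed from cell
    means.  The standard error pools the four cell variances
    (sqrt of the sum of s_i^2/n_i) with Welch-Satterthwaite degrees of
    freedom.  Default rule: plain Bonferroni at alpha = 0.05.
    """
    rule = rule or MultiplicityRule(alpha=0.05, variant="bonferroni")
    meta, traits = _split(log_rmc)
    control = log_rmc[meta["line"] == control_line]
    records: list[QTLRecord] = []
    ctrl_cells = {
        cond: control[control["treatment"] == cond] for cond in ("SDF", "SDS")
    }
    for line, grp in log_rmc.groupby("line", sort=True):
        if line == control_line:
            continue
        cells = {cond: grp[grp["treatment"] == cond] for cond in ("SDF", "SDS")}
        for trait in traits:
            groups = [
                cells["SDS"][trait].dropna().to_numpy(dtype=float),
                cells["SDF"][trait].dropna().to_numpy(dtype=float),
                ctrl_cells["SDS"][trait].dropna().to_numpy(dtype=float),
                ctrl_cells["SDF"][trait].dropna().to_numpy(dtype=float),
            ]
            if any(len(g) < 2 for g in groups):
                log.warning("skipped FC contrast %s/%s: empty or singleton cell",
                            line, trait)
                continue
            means = [g.mean() for g in groups]
            est = (means[0] - means[1]) - (means[2] - means[3])
            comps = [g.var(ddof=1) / len(g) for g in groups]
            se2 = sum(comps)
            if se2 == 0.0:
                p = 1.0 if est == 0.0 else 0.0
            else:
                df = se2**2 / sum(c**2 / (len(g) - 1)
                                  for c, g in zip(comps, groups))
                t = est / math.sqrt(se2)
                p = float(2.0 * stats.t.sf(abs(t), df))
            records.append(QTLRecord(
                line=str(line), trait=trait, contrast="FC_vs_control",
                direction="+" if est >= 0 else "-", estimate=float(est),
                p_value=p, threshold_rule=rule.name, significant=False,
            ))
    return _finalize(records, rule)


def _finalize(records: list[QTLRecord], rule: MultiplicityRule) -> pd.DataFrame:
    """Apply the multiplicity rule with n = comparisons in this scan."""
    df = _records_frame(records)
    if len(df):
        df["significant"] = df["p_value"] < rule.cutoff(len(df))
    return df
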