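"""Reading raw GC-MS peak tables and computing relative metabolite content.

The relative metabolite content (RMC) of a sample is its peak height after
three normalization steps applied in order:

1. division by the sample's extracted seed mass,
2. division by the sum of the sample's (weight-normalized, non-missing) peaks,
3. division, per metabolite, by the median of that metabolite across the
   samples of the same analytic run block.

RMC is dimensionless with per-block per-metabolite median exactly 1.  A
natural-log transform is applied before statistical testing, and missing
values are completed by an iterative low-rank (probabilistic-PCA-style)
reconstruction before correlation / PCA / clustering stages only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

log = logging.getLogger(__name__)

METADATA_COLUMNS = ["line", "treatment", "season", "plot", "run_block",
                    "seed_mass_extracted"]

__all__ = [
    "PeakTable",
    "RMCTable",
    "SchemaError",
    "read_peak_table",
    "normalize_peaks",
    "log_transform",
    "impute_missing",
]


class SchemaError(ValueError):
    """Input table does not match the documented schema."""


@dataclass
class PeakTable:
    """Raw peak heights plus per-sample metadata.

    ``meta`` is indexed by sample_id and holds line, treatment, season, plot,
    run_block and seed_mass_extracted (mg); ``peaks`` shares the index with
    one non-negative (or missing) column per annotated metabolite.
    """

    meta: pd.DataFrame
    peaks: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.meta.index.equals(self.peaks.index):
            raise ValueError("meta and peaks must share the sample index")
        if (self.meta["seed_mass_extracted"] <= 0).any():
            bad = self.meta.index[self.meta["seed_mass_extracted"] <= 0]
            raise ValueError(f"seed_mass_extracted must be > 0: {list(bad)}")
        key = self.meta[["line", "treatment", "season", "plot"]]
        if key.duplicated().any():
            raise ValueError("duplicate (line, treatment, season, plot) rows")

    @property
    def metabolites(self) -> list[str]:
        return list(self.peaks.columns)


@dataclass
class RMCTable:
    """Relative metabolite content with provenance flags."""

    meta: pd.DataFrame
    values: pd.DataFrame
    log_transformed: bool = False
    imputed_mask: pd.DataFrame | None = None
    excluded_metabolites: list[str] = field(default_factory=list)

    @property
    def metabolites(self) -> list[str]:
        return list(self.values.columns)

    def write(self, path: str | Path) -> None:
        out = pd.concat([self.meta, self.values], axis=1)
        out.to_csv(path, sep="\t", na_rep="NA", index_label="sample_id")


def read_peak_table(path: str | Path) -> PeakTable:
    """Read a peaks.tsv file (tab-separated, "NA" for missing).

    Mandatory columns: sample_id plus the metadata columns; every remaining
    column is taken to be an annotated metabolite and must be numeric.
    """
    df = pd.read_csv(path, sep="\t", na_values=["NA"], keep_default_na=False)
    if "sample_id" not in df.columns:
        raise SchemaError("missing mandatory column: sample_id")
    df = df.set_index("sample_id")
    for col in METADATA_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"missing mandatory column: {col}")
    met_cols = [c for c in df.columns if c not in METADATA_COLUMNS]
    peaks = pd.DataFrame(index=df.index)
    for col in met_cols:
        try:
            peaks[col] = pd.to_numeric(df[col], errors="raise")
        except (ValueError, TypeError) as exc:
            bad = df[col][pd.to_numeric(df[col], errors="coerce").isna()
                          & df[col].notna()]
            row = bad.index[0] if len(bad) else "?"
            raise SchemaError(
                f"non-numeric peak value in column {col!r}, row {row!r}"
            ) from exc
    meta = df[METADATA_COLUMNS].copy()
    meta["seed_mass_extracted"] = pd.to_numeric(meta["seed_mass_extracted"])
    log.info("read %d samples x %d metabolites from %s",
             len(df), len(met_cols), path)
    return PeakTable(meta=meta, peaks=peaks)


def normalize_peaks(peaks: PeakTable) -> RMCTable:
    """Normalize raw peak heights to relative metabolite content.

    In order: per-sample seed mass, per-sample total sum (over non-missing
    metabolites), per-block per-metabolite median.  Missing values stay
    missing throughout; a metabolite entirely missing within a block is left
    missing there with a logged warning; a zero sample sum is an error.
    """
    v = peaks.peaks.astype(float)
    v = v.div(peaks.meta["seed_mass_extracted"], axis=0)
    sums = v.sum(axis=1, skipna=True)
    if (sums <= 0).any():
        bad = list(sums.index[sums <= 0])
        raise ValueError(f"zero or negative total peak sum for samples: {bad}")
    v = v.div(sums, axis=0)
    for block, idx in peaks.meta.groupby("run_block").groups.items():
        sub = v.loc[idx]
        med = sub.median(axis=0, skipna=True)
        dead = med.index[med.isna()]
        if len(dead):
            log.warning("block %s: metabolites entirely missing, left missing: %s",
                        block, list(dead))
        v.loc[idx] = sub.div(med, axis=1)
    return RMCTable(meta=peaks.meta.copy(), values=v)


def log_transform(rmc: RMCTable) -> RMCTable:
    """Natural-log transform of all non-missing RMC values."""
    if rmc.log_transformed:
        raise ValueError("table is already log-transformed")
    bad = (rmc.values <= 0)
    if bad.any().any():
        cells = [(r, c) for c in rmc.values.columns
                 for r in rmc.values.index[bad[c]]]
        raise ValueError(f"non-positive RMC values cannot be log-transformed: "
                         f"{cells[:10]}{'...' if len(cells) > 10 else ''}")
    return replace(rmc, values=np.log(rmc.values),
                   log_transformed=True)


def impute_missing(
    rmc: RMCTable,
    n_components: int = 5,
    max_iter: int = 1000,
    tol: float = 1e-6,
    max_missing_frac: float = 0.5,
) -> RMCTable:
    """Complete missing cells by iterative low-rank reconstruction.

    Probabilistic-PCA-style completion: missing cells are initialized at the
    column mean, then the matrix is alternately fitted with ``n_components``
    principal components and the missing cells replaced by the reconstruction,
    until the largest absolute change falls below ``tol`` or ``max_iter``
    iterations.  Observed cells are never altered.  Metabolites with more
    than ``max_missing_frac`` missing are excluded from the model and listed
    in ``excluded_metabolites``.
    """
    if not rmc.log_transformed:
        raise ValueError("impute_missing expects a log-transformed table")
    values = rmc.values.copy()
    frac = values.isna().mean(axis=0)
    excluded = list(frac.index[frac > max_missing_frac])
    if excluded:
        log.warning("excluded from imputation (>%.0f%% missing): %s",
                    100 * max_missing_frac, excluded)
    cols = [c for c in values.columns if c not in excluded]
    x = values[cols].to_numpy(dtype=float)
    mask = np.isnan(x)
    if not mask.any():
        return replace(rmc, imputed_mask=values.isna(),
                       excluded_metabolites=excluded)

    col_means = np.nanmean(x, axis=0)
    filled = np.where(mask, col_means[None, :], x)
    k = min(n_components, filled.shape[0] - 1, filled.shape[1])
    for _ in range(max_iter):
        pca = PCA(n_components=k, svd_solver="full")
        scores = pca.fit_transform(filled)
        recon = pca.inverse_transform(scores)
        new = np.where(mask, recon, x)
        delta = np.max(np.abs(new - filled)) if mask.any() else 0.0
        filled = new
        if delta < tol:
            break
    out = values.copy()
    out[cols] = filled
    return replace(rmc, values=out, imputed_mask=rmc.values.isna(),
                   excluded_metabolites=excluded)
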