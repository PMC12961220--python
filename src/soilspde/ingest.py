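"""Survey-table cleaning and covariate preparation.

Steps mirror the survey-harmonization stage of the mapping workflow:
detection-limit substitution (LLD/2), programmatic outlier masking,
"N.S." (not sampled) handling, horizon averaging with coalesce semantics,
collinearity screening at |r| > 0.7, and covariate standardization with a
reusable scaling record.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ScalingRecord",
    "CleaningReport",
    "substitute_below_lld",
    "mask_outliers",
    "drop_not_sampled",
    "merge_horizons",
    "screen_collinear",
    "standardize_covariates",
    "clean_survey",
]

HORIZONS = ("top5", "ahorizon")
NOT_SAMPLED = "N.S."


@dataclass
class CleaningReport:
    """Counts of rows/values affected at each cleaning step."""

    counts: dict[str, int] = field(default_factory=dict)

    def add(self, step: str, n: int) -> None:
        self.counts[step] = self.counts.get(step, 0) + int(n)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.counts, indent=2))


@dataclass
class ScalingRecord:
    """Per-covariate means and SDs used for standardization.

    Applying the record to new data reuses the stored statistics; the
    transform is never re-estimated.
    """

    means: dict[str, float]
    sds: dict[str, float]

    def __post_init__(self) -> None:
        for name, sd in self.sds.items():
            if not sd > 0:
                raise ValueError(f"covariate {name!r} has non-positive SD")

    @property
    def names(self) -> list[str]:
        return list(self.means)

    def apply(self, table: pd.DataFrame) -> pd.DataFrame:
        out = table.copy()
        for name in self.means:
            out[name] = (out[name] - self.means[name]) / self.sds[name]
        return out

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({"means": self.means, "sds": self.sds}))

    @classmethod
    def from_json(cls, path: str | Path) -> "ScalingRecord":
        rec = json.loads(Path(path).read_text())
        return cls(means=rec["means"], sds=rec["sds"])


def read_survey_csv(path: str | Path) -> pd.DataFrame:
    """Read a survey table (comma-separated, header row, UTF-8; the literal
    "N.S." in lab-id columns marks not-sampled horizons)."""
    table = pd.read_csv(path, encoding="utf-8")
    for hz in HORIZONS:
        flag = f"below_lld_{hz}"
        if flag in table.columns:
            table[flag] = table[flag].astype(bool)
    return table


def write_survey_csv(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, index=False, encoding="utf-8")


def substitute_below_lld(
    table: pd.DataFrame, report: CleaningReport | None = None
) -> pd.DataFrame:
    """Replace below-detection concentrations with half the detection limit."""
    out = table.copy()
    n_changed = 0
    for hz in HORIZONS:
        conc, flag = f"conc_{hz}", f"below_lld_{hz}"
        if conc not in out.columns or flag not in out.columns:
            continue
        flagged = out[flag].fillna(False).astype(bool) & out[conc].notna()
        if flagged.any() and out.loc[flagged, "lld"].isna().any():
            bad = out.loc[flagged & out["lld"].isna(), "site_id"].tolist()
            raise ValueError(f"below-LLD flag without an LLD at sites {bad}")
        out.loc[flagged, conc] = out.loc[flagged, "lld"] / 2.0
        n_changed += int(flagged.sum())
    if report is not None:
        report.add("below_lld_substituted", n_changed)
    return out


def mask_outliers(
    table: pd.DataFrame,
    site_ids: list[str],
    report: CleaningReport | None = None,
) -> pd.DataFrame:
    """Set concentrations at user-identified outlier sites to missing.

    Rows are retained; each masking is logged.  Unknown site ids warn
    rather than fail.
    """
    out = table.copy()
    n_masked = 0
    known = set(out["site_id"])
    for sid in site_ids:
        if sid not in known:
            logger.warning("mask_outliers: unknown site_id %r ignored", sid)
            continue
        row = out["site_id"] == sid
        for hz in HORIZONS:
            col = f"conc_{hz}"
            if col in out.columns:
                out.loc[row, col] = np.nan
        logger.info("mask_outliers: masked concentrations at site %s", sid)
        n_masked += 1
    if report is not None:
        report.add("outlier_sites_masked", n_masked)
    return out


def drop_not_sampled(
    table: pd.DataFrame, report: CleaningReport | None = None
) -> pd.DataFrame:
    """Void horizon values labelled "N.S." and drop sites with no horizon left."""
    out = table.copy()
    for hz in HORIZONS:
        lab, conc = f"lab_id_{hz}", f"conc_{hz}"
        if lab in out.columns:
            ns = out[lab].astype(str).str.strip() == NOT_SAMPLED
            out.loc[ns, conc] = np.nan
    have_any = pd.Series(False, index=out.index)
    for hz in HORIZONS:
        conc = f"conc_{hz}"
        if conc in out.columns:
            have_any |= out[conc].notna()
    n_dropped = int((~have_any).sum())
    if n_dropped:
        logger.info("drop_not_sampled: dropped %d sites with no observed horizon", n_dropped)
    if report is not None:
        report.add("not_sampled_sites_dropped", n_dropped)
    return out.loc[have_any].reset_index(drop=True)


def merge_horizons(
    table: pd.DataFrame, report: CleaningReport | None = None
) -> pd.DataFrame:
    """Collapse the two depth horizons to one ``conc`` column per site.

    Both horizons present: arithmetic mean (the 0-25 cm composite); one
    present: that value (coalesce); both missing: site dropped with a log
    entry.
    """
    out = table.copy()
    vals = out[[f"conc_{hz}" for hz in HORIZONS]]
    conc = vals.mean(axis=1, skipna=True)
    missing = vals.isna().all(axis=1)
    if missing.any():
        for sid in out.loc[missing, "site_id"]:
            logger.info("merge_horizons: site %s dropped (no horizon value)", sid)
    if report is not None:
        report.add("merge_dropped_sites", int(missing.sum()))
    out["conc"] = conc
    out = out.loc[~missing].reset_index(drop=True)
    return out.drop(columns=[f"conc_{hz}" for hz in HORIZONS])


def screen_collinear(
    covariates: pd.DataFrame, threshold: float = 0.7
) -> tuple[list[str], pd.DataFrame]:
    """Drop the later-listed member of every covariate pair with |r| > threshold.

    The inequality is strict: a pair at exactly |r| == threshold is retained.
    Zero-variance covariates are dropped with a warning.  Returns the retained
    names (input order) and the full Pearson correlation matrix.
    """
    if covariates.shape[1] < 2:
        raise ValueError("need at least 2 covariates to screen")
    if covariates.dropna().shape[0] < 3:
        raise ValueError("need at least 3 complete rows")
    names = list(covariates.columns)
    sds = covariates.std(ddof=1)
    degenerate = [n for n in names if not sds[n] > 0]
    for n in degenerate:
        logger.warning("screen_collinear: zero-variance covariate %r dropped", n)
    names = [n for n in names if n not in degenerate]
    corr = covariates[names].corr(method="pearson")
    retained: list[str] = []
    for j, name in enumerate(names):
        clash = any(
            abs(corr.loc[name, earlier]) > threshold for earlier in retained
        )
        if clash:
            logger.info("screen_collinear: dropping %r (|r| > %.2f)", name, threshold)
        else:
            retained.append(name)
    return retained, corr


def standardize_covariates(
    table: pd.DataFrame, names: list[str] | None = None
) -> tuple[pd.DataFrame, ScalingRecord]:
    """Center/scale each covariate to mean 0, sample SD 1; return the record."""
    names = list(names if names is not None else table.columns)
    means, sds = {}, {}
    for name in names:
        sd = float(table[name].std(ddof=1))
        if not sd > 0:
            raise ValueError(f"covariate {name!r} has zero SD; cannot standardize")
        means[name] = float(table[name].mean())
        sds[name] = sd
    record = ScalingRecord(means=means, sds=sds)
    return record.apply(table), record


def clean_survey(
    table: pd.DataFrame,
    outlier_sites: list[str] | None = None,
    report: CleaningReport | None = None,
) -> pd.DataFrame:
    """Full cleaning chain: N.S. handling, LLD substitution, outlier masking,
    horizon merge, duplicate-site removal."""
    report = report if report is not None else CleaningReport()
    out = drop_not_sampled(table, report)
    out = substitute_below_lld(out, report)
    out = mask_outliers(out, outlier_sites or [], report)
    out = merge_horizons(out, report)
    n_dup = int(out["site_id"].duplicated().sum())
    if n_dup:
        logger.info("clean_survey: removed %d duplicated site ids", n_dup)
    report.add("duplicate_sites_removed", n_dup)
    out = out.loc[~out["site_id"].duplicated()].reset_index(drop=True)
    out = out.loc[out["conc"].notna()].reset_index(drop=True)
    return out
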