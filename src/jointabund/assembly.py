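"""Build the joint abundance-index analysis table.

Survey responses from the three sources are aligned with one-year-lagged
covariates, restricted to complete cases for the predictors in play, and
standardized within survey type so that harvest totals, route counts, and
station counts become commensurable. The per-survey standardization
parameters are retained in ``DataFrame.attrs`` so that fitted slopes can be
mapped back to the latent (pre-standardization) scale.
"""

from __future__ import annotations

import warnings
from itertools import combinations

import numpy as np
import pandas as pd

from .errors import DegenerateSurveyError, EmptyDatasetError

ID_COLUMNS = ["county_id", "region_id", "year"]


def lag_covariates(panel: pd.DataFrame, lag: int = 1) -> pd.DataFrame:
    """Shift covariates forward so the row for year t carries year t-lag.

    Years with no donor year in the input get missing covariates. The set of
    (county, year) rows is unchanged.
    """
    if lag < 0:
        raise ValueError("lag must be >= 0")
    if lag == 0:
        return panel.copy()
    covs = [c for c in panel.columns if c not in ID_COLUMNS]
    donor = panel[["county_id", "year"] + covs].copy()
    donor["year"] = donor["year"] + lag
    out = panel[ID_COLUMNS].merge(donor, on=["county_id", "year"], how="left")
    return out[panel.columns.tolist()]


def standardize_response(
    records: pd.DataFrame, transform: str = "log1p"
) -> pd.DataFrame:
    """Z-score the response within each survey type.

    ``transform`` is applied first ("log1p" or "none"); the z-score uses the
    survey type's mean and sample SD over the rows present, so re-running on
    the restricted dataset of each analysis keeps the index calibrated to
    that dataset. Standardization parameters land in
    ``out.attrs["standardization"]`` as {survey: (mean, sd)}.
    """
    if transform not in ("none", "log1p"):
        raise ValueError(f"unknown transform: {transform!r}")
    out = records.copy()
    vals = out["response"].to_numpy(float)
    t = np.log1p(vals) if transform == "log1p" else vals
    out["_t_response"] = t
    z = np.full(len(out), np.nan)
    params = {}
    for s, idx in out.groupby("survey_type", observed=True).groups.items():
        x = out.loc[idx, "_t_response"].to_numpy(float)
        mu, sd = float(np.mean(x)), float(np.std(x, ddof=1)) if len(x) > 1 else 0.0
        if not np.isfinite(sd) or sd <= 1e-12 * max(1.0, abs(mu)):
            raise DegenerateSurveyError(
                f"survey type {s!r} has zero response variance; cannot standardize"
            )
        params[s] = (mu, sd)
        z[out.index.get_indexer(idx)] = (x - mu) / sd
    out["z_response"] = z
    out.attrs["standardization"] = params
    out.attrs["transform"] = transform
    out.attrs["response_mean_transformed"] = float(np.mean(t))
    return out


def _normalize_year_range(year_range):
    """Accept (lo, hi) or a list of (lo, hi) windows; None = no restriction."""
    if year_range is None:
        return None
    if len(year_range) == 2 and np.isscalar(year_range[0]):
        return [tuple(year_range)]
    return [tuple(w) for w in year_range]


def build_joint_table(
    records: pd.DataFrame,
    panel: pd.DataFrame,
    covariates: list,
    year_range=None,
    transform: str = "log1p",
    lag: int = 1,
) -> pd.DataFrame:
    """Join lagged covariates to survey records and standardize.

    Rows with any missing value among ``covariates`` are dropped (complete
    cases), then the response is z-scored per survey type over the surviving
    set. ``year_range`` may be a single (lo, hi) or a list of windows whose
    union defines the restriction.
    """
    missing_cols = [c for c in covariates if c not in panel.columns]
    if missing_cols:
        raise KeyError(f"covariates absent from panel: {missing_cols}")
    lagged = lag_covariates(panel, lag)
    merged = records.merge(
        lagged[["county_id", "year"] + list(covariates)],
        on=["county_id", "year"],
        how="left",
    )
    windows = _normalize_year_range(year_range)
    if windows is not None:
        keep = np.zeros(len(merged), dtype=bool)
        for lo, hi in windows:
            keep |= (merged["year"] >= lo) & (merged["year"] <= hi)
        merged = merged.loc[keep]
    if covariates:
        merged = merged.dropna(subset=list(covariates))
    if len(merged) == 0:
        raise EmptyDatasetError(
            "no analysis rows survive the year/complete-case restriction"
        )
    merged = merged.reset_index(drop=True)
    table = standardize_response(merged, transform=transform)
    table.attrs["covariates"] = list(covariates)
    table.attrs["n_input_records"] = len(records)
    return table


def standardization_sds(table: pd.DataFrame) -> dict:
    """Per-survey SDs used in the z-scoring of ``table``."""
    return {s: sd for s, (_, sd) in table.attrs["standardization"].items()}


def latent_scale(table: pd.DataFrame, value: float) -> float:
    """Map a z-scale quantity (slope or SE) back to the transformed response
    scale using the mean of the per-survey standardization SDs."""
    sds = list(standardization_sds(table).values())
    return value * float(np.mean(sds))


def correlation_screen(
    table: pd.DataFrame, covariates: list, threshold: float = 0.65
) -> set:
    """Unordered covariate pairs with |Pearson r| >= threshold (inclusive).

    Constant covariates have undefined correlation and are conservatively
    forbidden with every partner, with a warning. Interaction terms inherit
    the prohibitions of their components at enumeration time.
    """
    if len(table) < 3:
        raise ValueError("need at least 3 rows to screen correlations")
    sub = table[list(covariates)].astype(float)
    constant = [c for c in covariates if sub[c].nunique(dropna=True) <= 1]
    if constant:
        warnings.warn(
            f"constant covariates with undefined correlation treated as "
            f"forbidden with all partners: {constant}"
        )
    corr = sub.corr()
    forbidden = set()
    for a, b in combinations(covariates, 2):
        if a in constant or b in constant:
            forbidden.add(frozenset((a, b)))
            continue
        r = corr.loc[a, b]
        if np.isnan(r) or abs(r) >= threshold:
            forbidden.add(frozenset((a, b)))
    return forbidden
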