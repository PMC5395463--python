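"""Effect summaries from fitted models.

Turns a fitted mixed model into the quantities the analysis reports:
interaction surfaces (index vs. a covariate across years), pesticide
percentile slices of a three-way interaction, percent-change crop effects,
and the single-variable crop comparison. All predictions hold the other
model terms at their data means, average over the survey-type contrasts at
their observed proportions, and take 95% intervals from the fixed-effect
covariance only (random effects enter through neither the point prediction
nor the interval).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import MissingTermError
from .mixedmodel import FitResult, ModelSpec, fit_lmm
from .terms import canonical

Z95 = 1.959963984540054  # two-sided 95% normal quantile


def _design_row(fit: FitResult, assignments: dict) -> np.ndarray:
    """One fixed-design row with ``assignments`` (component -> value) set
    and everything else at its data mean.

    A column is recomputed from its component/center metadata when any of
    its components is assigned (unassigned components sit at their centers,
    zeroing their centered contribution); untouched columns keep their
    observed means, which for survey dummies averages the contrasts at the
    data proportions.
    """
    row = fit.col_means.copy()
    for col, pairs in fit.col_components.items():
        if not pairs:
            continue
        comps = [c for c, _ in pairs]
        if not any(c in assignments for c in comps):
            continue
        val = 1.0
        for c, center in pairs:
            val *= assignments.get(c, center) - center
        row[col] = val
    return row.to_numpy(float)


def predict_linear(fit: FitResult, assignments: dict):
    """Point prediction and SE of the fixed linear predictor."""
    x = _design_row(fit, assignments)
    beta = fit.beta.to_numpy(float)
    mean = float(x @ beta)
    se = float(np.sqrt(x @ fit.cov_fixed.to_numpy(float) @ x))
    return mean, se


@dataclass(frozen=True)
class EffectSurface:
    """Rectangular (covariate x year) grid of predicted joint-index means."""

    x_term: str
    year_term: str
    grid: pd.DataFrame  # columns: x, year, mean, lower95, upper95


def predict_surface(
    fit: FitResult, x_term: str, year_term: str, x_grid, year_grid
) -> EffectSurface:
    """Predicted index over an (x, year) grid from an interaction model."""
    inter = canonical(f"{x_term}:{year_term}")
    for t in (x_term, year_term, inter):
        if canonical(t) not in fit.spec.effect_terms:
            raise MissingTermError(f"fitted model lacks term {t!r}")
    recs = []
    for yr in year_grid:
        for x in x_grid:
            m, se = predict_linear(fit, {x_term: float(x), year_term: float(yr)})
            recs.append(
                {
                    "x": float(x),
                    "year": float(yr),
                    "mean": m,
                    "lower95": m - Z95 * se,
                    "upper95": m + Z95 * se,
                }
            )
    return EffectSurface(x_term=x_term, year_term=year_term, grid=pd.DataFrame(recs))


@dataclass(frozen=True)
class PesticideClasses:
    """Low/high pesticide thresholds (empirical quantiles, kg/ha/yr) and the
    early/late year eras used to illustrate the three-way interaction."""

    low_threshold: float
    high_threshold: float
    early_span: tuple
    late_span: tuple

    @property
    def era_midpoints(self) -> dict:
        return {
            "early": (self.early_span[0] + self.early_span[1]) / 2.0,
            "late": (self.late_span[0] + self.late_span[1]) / 2.0,
        }


def pesticide_classes(
    panel: pd.DataFrame,
    low_q: float = 0.10,
    high_q: float = 0.90,
    era_split: int = 2001,
) -> PesticideClasses:
    """Percentile thresholds and era partition for pesticide slices.

    Thresholds are linear-interpolation empirical quantiles of the
    nonmissing pesticide values; the eras split the pesticide years at
    ``era_split``, with the first analysis year one past the first data
    year (the one-year lag consumes it).
    """
    vals = panel["pesticide_total"].dropna().to_numpy(float)
    if len(vals) == 0:
        raise ValueError("pesticide column is entirely missing")
    if not low_q <= high_q:
        raise ValueError("low_q must be <= high_q")
    lo = float(np.quantile(vals, low_q))
    hi = float(np.quantile(vals, high_q))
    years = panel.loc[panel["pesticide_total"].notna(), "year"]
    y0, y1 = int(years.min()), int(years.max())
    return PesticideClasses(
        low_threshold=lo,
        high_threshold=hi,
        early_span=(y0 + 1, era_split - 1),
        late_span=(era_split, y1),
    )


def three_way_slices(
    fit: FitResult,
    crop_term: str,
    classes: PesticideClasses,
    crop_grid,
    pesticide_term: str = "pesticide_total",
    year_term: str = "year",
) -> pd.DataFrame:
    """Four predicted index-vs-cropland curves: low/high pesticide x era.

    Pesticide is pinned at the percentile thresholds and year at the era
    midpoint (both remain continuous in the model); other terms sit at
    their means. Long format: x, pesticide_level, era, mean, lower95,
    upper95.
    """
    three = canonical(f"{crop_term}:{pesticide_term}:{year_term}")
    if three not in fit.spec.effect_terms:
        raise MissingTermError(f"fitted model lacks three-way term {three!r}")
    recs = []
    for era, mid in classes.era_midpoints.items():
        for level, pest in (
            ("low", classes.low_threshold),
            ("high", classes.high_threshold),
        ):
            for x in crop_grid:
                m, se = predict_linear(
                    fit,
                    {
                        crop_term: float(x),
                        pesticide_term: float(pest),
                        year_term: float(mid),
                    },
                )
                recs.append(
                    {
                        "x": float(x),
                        "pesticide_level": level,
                        "era": era,
                        "mean": m,
                        "lower95": m - Z95 * se,
                        "upper95": m + Z95 * se,
                    }
                )
    return pd.DataFrame(recs)


def percent_change(
    fit: FitResult, term: str, delta_x: float = 1.0, reference: float | None = None
):
    """Percent change of the joint index per ``delta_x`` in ``term``.

    The standardized-index slope is converted to a percentage of a
    reference index level, by default the mean pre-standardization
    (transformed) joint index of the fitted dataset; CI endpoints come from
    beta +/- 1.96 SE. This back-transform is an interpretive convention and
    the reference is deliberately configurable.
    """
    t = canonical(term)
    if t not in fit.beta.index:
        raise MissingTermError(f"fitted model lacks term {term!r}")
    if reference is None:
        reference = fit.reference_mean
    if not np.isfinite(reference) or reference <= 0:
        raise ValueError(f"reference must be positive, got {reference!r}")
    b, s = float(fit.beta[t]), float(fit.se[t])
    scale = 100.0 * delta_x / reference
    est = b * scale
    lo, hi = sorted(((b - Z95 * s) * scale, (b + Z95 * s) * scale))
    return est, lo, hi


def crop_posthoc(table: pd.DataFrame, crop_terms: list) -> pd.DataFrame:
    """Single-variable crop comparison on a common complete-case table.

    Each crop is fit alone (plus survey type and random effects) on the
    same rows; the percent-change effect and its CI are reported, with
    support flagged when the CI excludes zero. Zero-variance crops are
    skipped with a warning.
    """
    recs = []
    for crop in crop_terms:
        if table[crop].nunique(dropna=True) <= 1:
            warnings.warn(f"crop {crop!r} has zero variance; skipped")
            continue
        fit = fit_lmm(table, ModelSpec.from_candidates([crop]))
        est, lo, hi = percent_change(fit, crop, delta_x=1.0)
        # a NaN SE (non-PD covariance at a variance boundary) gives no
        # usable interval: never claim support from it
        ok = np.isfinite(lo) and np.isfinite(hi) and not (lo <= 0.0 <= hi)
        recs.append(
            {
                "crop": crop,
                "estimate_pct": est,
                "lower95_pct": lo,
                "upper95_pct": hi,
                "supported": ok,
                "aicc": fit.aicc,
            }
        )
    return pd.DataFrame(recs)
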