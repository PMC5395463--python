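"""Constrained model-set analysis.

Enumerates every hierarchy-complete candidate model subject to the
analysis constraints (at most four effects per model, a fixed-parameter
cap, exclusion of correlated predictor pairs), fits each by ML, and ranks
models by AICc with Akaike weights. Per-covariate importance is reported
two ways: the raw weight sum, and a representation-adjusted probability
that corrects for covariates appearing in unequal numbers of models —
contrasting the mean weight of models containing a covariate against the
mean weight of those without it, then mapping the contrast to an odds
("adjusted evidence ratio").
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from . import assembly
from .errors import UnknownCovariateError
from .mixedmodel import FitResult, ModelSpec, fit_lmm
from .terms import all_components, canonical, expand_terms

ER_CAP = 100.0  # evidence ratios beyond this render as ">100"


def enumerate_models(
    candidates: list,
    max_effects: int = 4,
    forbidden_pairs: set = frozenset(),
    mandatory: tuple = ("survey_type",),
    max_fixed_params: int | None = 8,
    random_spec: str = "county_in_region",
    n_survey_levels: int = 3,
) -> list:
    """All deduplicated specs from subsets of 0..max_effects candidates.

    Each candidate counts as one effect even when it is an interaction; the
    spec it contributes is hierarchy-complete (an interaction brings its
    mains and lower-order interactions, shared mains counted once toward
    the fixed-parameter cap). Specs containing both members of a forbidden
    covariate pair — as mains or inside interactions — are excluded, as are
    specs whose fixed parameter count exceeds ``max_fixed_params`` (pass
    None to lift the cap, as in the pesticide analysis with three-way
    interactions). Survey type is mandatory in every model.
    """
    if not candidates:
        raise ValueError("candidate list is empty")
    include_survey = "survey_type" in mandatory
    forbidden = {frozenset(p) for p in forbidden_pairs}
    seen, specs = set(), []
    for k in range(0, max_effects + 1):
        for subset in combinations(candidates, k):
            term_set = expand_terms(subset)
            comps = all_components(term_set)
            if any(p <= comps for p in forbidden):
                continue
            spec = ModelSpec(
                effect_terms=term_set,
                random_spec=random_spec,
                include_survey=include_survey,
            )
            if (
                max_fixed_params is not None
                and spec.fixed_param_count(n_survey_levels) > max_fixed_params
            ):
                continue
            key = frozenset(term_set)
            if key in seen:
                continue
            seen.add(key)
            specs.append(spec)
    return specs


@dataclass
class ModelSetSummary:
    """Fitted model set: per-model table, fits, and importance scores."""

    models: pd.DataFrame          # terms, aicc, loglik, k, n, delta, weight
    fits: list = field(default_factory=list)
    importance: pd.DataFrame = None
    candidates: list = field(default_factory=list)

    @property
    def top(self) -> FitResult:
        return self.fits[int(self.models["delta"].idxmin())]


def akaike_weights(aicc_values) -> np.ndarray:
    a = np.asarray(aicc_values, dtype=float)
    delta = a - a.min()
    w = np.exp(-delta / 2.0)
    return w / w.sum()


def fit_model_set(
    table: pd.DataFrame, specs: list, candidates: list | None = None
) -> ModelSetSummary:
    """Fit every spec on the identical row set and fill delta / weights.

    ``table`` must already be complete-case for the union of candidate
    covariates so all models see the same rows. Non-converged fits are
    excluded with a warning.
    """
    if not specs:
        raise ValueError("no model specs to fit")
    needed = all_components(
        t for s in specs for t in s.effect_terms
    ) - {"year"}
    absent = [c for c in needed if c not in table.columns]
    if absent:
        raise UnknownCovariateError(f"table lacks covariates: {absent}")
    fits, dropped = [], 0
    for spec in specs:
        fit = fit_lmm(table, spec)
        if not fit.converged or not np.isfinite(fit.aicc):
            dropped += 1
            warnings.warn(f"model excluded (no convergence): {spec.formula()}")
            continue
        fits.append(fit)
    if dropped:
        warnings.warn(f"{dropped} of {len(specs)} models excluded for non-convergence")
    rows = pd.DataFrame(
        {
            "terms": [" + ".join(f.spec.effect_terms) or "(survey only)" for f in fits],
            "n_terms": [len(f.spec.effect_terms) for f in fits],
            "k": [f.k for f in fits],
            "k_fixed": [f.k_fixed for f in fits],
            "n": [f.n for f in fits],
            "loglik": [f.loglik for f in fits],
            "aicc": [f.aicc for f in fits],
            "r2c": [f.r2c for f in fits],
        }
    )
    rows["delta"] = rows["aicc"] - rows["aicc"].min()
    rows["weight"] = akaike_weights(rows["aicc"])
    summary = ModelSetSummary(
        models=rows, fits=fits, candidates=list(candidates or [])
    )
    return summary


def evidence_ratio(w_a: float, w_b: float) -> float:
    """Ratio of two Akaike weights; infinite when the denominator is zero."""
    if w_b == 0:
        return float("inf")
    return w_a / w_b


def format_er(er: float) -> str:
    """Render an evidence ratio, using the ">100" convention beyond 100."""
    if not np.isfinite(er) or er > ER_CAP:
        return ">100"
    return f"{er:.2f}"


def adjusted_importance(
    summary: ModelSetSummary, scored_terms: list | None = None
) -> pd.DataFrame:
    """Representation-adjusted importance per candidate covariate.

    For covariate j present in m_j of the M models with weights w_i:
    A_j = (sum of w_i over models containing j) / m_j and B_j the analogous
    mean over models without j; the adjusted probability is
    p_j = A_j / (A_j + B_j) and the adjusted evidence ratio its odds
    p_j / (1 - p_j). Covariates in every model get p_j = 1 (ER rendered
    ">100"); covariates in no model are not scored. Ranks sort by
    descending p_j, ties broken by descending raw weight sum then name.
    """
    if scored_terms is None:
        scored_terms = summary.candidates
    if not scored_terms:
        raise ValueError("no covariates to score")
    w = summary.models["weight"].to_numpy(float)
    M = len(summary.fits)
    recs = []
    for term in scored_terms:
        t = canonical(term)
        mask = np.array([f.spec.contains(t) for f in summary.fits])
        m_j = int(mask.sum())
        if m_j == 0:
            continue
        raw = float(w[mask].sum())
        if m_j == M:
            p = 1.0
            er = float("inf")
        else:
            a = raw / m_j
            b = float(w[~mask].sum()) / (M - m_j)
            p = a / (a + b) if (a + b) > 0 else np.nan
            er = p / (1.0 - p) if p < 1 else float("inf")
        recs.append(
            {
                "covariate": term,
                "m_models": m_j,
                "raw_weight_sum": raw,
                "adj_probability": p,
                "adj_er": er,
            }
        )
    out = pd.DataFrame(recs)
    out = out.sort_values(
        by=["adj_probability", "raw_weight_sum", "covariate"],
        ascending=[False, False, True],
        kind="mergesort",
    ).reset_index(drop=True)
    out.insert(0, "rank", np.arange(1, len(out) + 1))
    return out


def variable_reduction(
    records: pd.DataFrame,
    panel: pd.DataFrame,
    groups: dict,
    year_range=None,
    transform: str = "log1p",
    support_margin: float = 2.0,
    random_spec: str = "county_in_region",
    lag: int = 1,
) -> dict:
    """Grouped screening stage: carry forward terms with real support.

    Each group of thematically related candidates (climate, land use, ...)
    is evaluated on its own complete-case dataset, so long-running
    covariates are not truncated to the span of short-running ones. Within
    a group, each candidate (single term or designated interaction,
    hierarchy-expanded) is fit alongside the baseline (survey type only)
    and null (random effects only) models; candidates whose AICc beats the
    baseline by ``support_margin`` and the null outright are carried
    forward. Higher-order candidates that pass are carried forward as
    interactions (their mains come along at enumeration).

    Returns {"carried_forward": [...], "groups": {name: DataFrame}}.
    """
    carried, per_group = [], {}
    for name, cands in groups.items():
        if not cands:
            warnings.warn(f"group {name!r} has no candidates; skipped")
            continue
        covs = sorted(all_components(cands) - {"year"})
        tbl = assembly.build_joint_table(
            records, panel, covs, year_range=year_range, transform=transform, lag=lag
        )
        base = fit_lmm(tbl, ModelSpec(random_spec=random_spec))
        null = fit_lmm(
            tbl, ModelSpec(random_spec=random_spec, include_survey=False)
        )
        rows = []
        for cand in cands:
            fit = fit_lmm(tbl, ModelSpec.from_candidates([cand], random_spec=random_spec))
            ok = fit.converged and (
                fit.aicc <= base.aicc - support_margin and fit.aicc < null.aicc
            )
            rows.append(
                {
                    "candidate": cand,
                    "aicc": fit.aicc,
                    "baseline_aicc": base.aicc,
                    "null_aicc": null.aicc,
                    "n": fit.n,
                    "supported": ok,
                }
            )
            if ok and canonical(cand) not in {canonical(c) for c in carried}:
                carried.append(cand)
        per_group[name] = pd.DataFrame(rows)
    return {"carried_forward": carried, "groups": per_group}
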