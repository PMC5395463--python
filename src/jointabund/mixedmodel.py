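"""Linear mixed model underlying every candidate in the model set.

All candidates are Gaussian identity-link mixed models of the standardized
joint index with survey type as a mandatory fixed factor and random
intercepts of county nested within region (or county only, in regional
re-analyses). Estimation is by maximum likelihood, not REML: the model set
compares fits that differ in their fixed effects, and ML log-likelihoods
are the ones AICc can legitimately rank.

The design parametrization matters for interpretation and is fixed here:
main effects enter in their original units, calendar year is centered at
the dataset mean, and interaction columns are products of mean-centered
components. Each fitted model retains enough design metadata (component
centers, column means, fixed-effect covariance) for downstream effect
surfaces and percent-change back-transforms.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from statsmodels.tools.sm_exceptions import ConvergenceWarning

from .errors import SampleTooSmallError, SingularDesignError
from .terms import canonical, components, expand_terms

SURVEY_REFERENCE = "AGTS"  # treatment-contrast reference level (alphabetical)


@dataclass(frozen=True)
class ModelSpec:
    """A candidate fixed-effect structure.

    ``effect_terms`` must be hierarchy-complete (use ``from_candidates``);
    ``random_spec`` is ``"county_in_region"`` (two variance components) or
    ``"county"`` (regional analyses). ``include_survey`` is False only for
    the null model (random effects only).
    """

    effect_terms: tuple = ()
    random_spec: str = "county_in_region"
    include_survey: bool = True
    include_intercept: bool = True

    def __post_init__(self):
        object.__setattr__(
            self, "effect_terms", expand_terms(self.effect_terms)
        )
        if self.random_spec not in ("county_in_region", "county"):
            raise ValueError(f"unknown random_spec: {self.random_spec!r}")

    @classmethod
    def from_candidates(cls, candidates, **kw) -> "ModelSpec":
        return cls(effect_terms=tuple(candidates), **kw)

    def fixed_param_count(self, n_survey_levels: int = 3) -> int:
        """Number of estimated fixed parameters (intercept + survey-type
        contrasts + one slope per term, shared mains counted once)."""
        p = 1 if self.include_intercept else 0
        if self.include_survey:
            p += n_survey_levels - 1
        return p + len(self.effect_terms)

    def contains(self, term: str) -> bool:
        return canonical(term) in self.effect_terms

    def formula(self) -> str:
        rand = (
            "(1|region/county)"
            if self.random_spec == "county_in_region"
            else "(1|county)"
        )
        parts = (["survey"] if self.include_survey else []) + [
            t.replace(":", "*") if ":" not in t else t for t in self.effect_terms
        ]
        fixed = " + ".join(parts) if parts else "1"
        return f"z ~ {fixed} + {rand}"


@dataclass
class FitResult:
    """Summary of one fitted mixed model plus design metadata."""

    spec: ModelSpec
    beta: pd.Series
    se: pd.Series
    cov_fixed: pd.DataFrame
    loglik: float
    k: int                      # all estimated parameters (fixed + variance)
    k_fixed: int                # fixed parameters only (the <=8 cap applies here)
    n: int
    varcomp: dict
    aicc: float
    r2c: float
    converged: bool
    col_components: dict = field(default_factory=dict)  # col -> ((comp, center), ...)
    col_means: pd.Series = None
    reference_mean: float = np.nan  # mean pre-standardization (transformed) index
    survey_levels: tuple = ()

    @property
    def sigma2_fixed(self) -> float:
        return self._sigma2_fixed

    def formula(self) -> str:
        return self.spec.formula()


def build_design(table: pd.DataFrame, spec: ModelSpec):
    """Fixed-effect design matrix and per-column component/center metadata.

    Returns (X, col_components) where every slope column is described by a
    tuple of (component, center) pairs whose product (value - center)
    reproduces the column; intercept and survey-dummy columns map to ().
    """
    n = len(table)
    cols, data, meta = [], [], {}
    if spec.include_intercept:
        cols.append("Intercept")
        data.append(np.ones(n))
        meta["Intercept"] = ()
    levels = tuple(sorted(table["survey_type"].unique())) if spec.include_survey else ()
    if spec.include_survey:
        for lev in levels:
            if lev == levels[0]:
                continue  # reference level absorbed by the intercept
            name = f"survey_{lev}"
            cols.append(name)
            data.append((table["survey_type"] == lev).to_numpy(float))
            meta[name] = ()
    year_center = float(table["year"].mean()) if "year" in table.columns else 0.0
    centers = {"year": year_center}
    for term in spec.effect_terms:
        comps = components(term)
        for c in comps:
            if c == "year":
                continue
            if c not in table.columns:
                raise KeyError(f"term {term!r} needs column {c!r} absent from table")
            centers.setdefault(c, float(table[c].mean()))
        if len(comps) == 1:
            c = comps[0]
            center = year_center if c == "year" else 0.0
            vals = table["year" if c == "year" else c].to_numpy(float) - center
            meta[term] = ((c, center),)
        else:
            vals = np.ones(n)
            pairs = []
            for c in comps:
                center = centers[c]
                vals = vals * (table[c].to_numpy(float) - center)
                pairs.append((c, center))
            meta[term] = tuple(pairs)
        cols.append(term)
        data.append(vals)
    X = pd.DataFrame(dict(zip(cols, data)), index=table.index)
    return X, meta, levels


def _check_rank(X: pd.DataFrame):
    arr = X.to_numpy(float)
    rank = np.linalg.matrix_rank(arr)
    if rank < X.shape[1]:
        # identify aliased columns greedily by growing an independent set
        aliased, kept = [], []
        for j, name in enumerate(X.columns):
            trial = arr[:, [X.columns.get_loc(k) for k in kept] + [j]]
            if np.linalg.matrix_rank(trial) == len(kept) + 1:
                kept.append(name)
            else:
                aliased.append(name)
        raise SingularDesignError(aliased)


_SAFE = {":": "_x_"}


def _safe_name(col: str) -> str:
    out = col
    for a, b in _SAFE.items():
        out = out.replace(a, b)
    return out


def fit_lmm(table: pd.DataFrame, spec: ModelSpec) -> FitResult:
    """Fit one candidate by ML and package its selection statistics.

    A boundary fit (a variance component estimated at zero) is valid and
    returns ``converged=True``; genuine optimizer failure returns
    ``converged=False`` and the model-set stage excludes the model.
    """
    X, meta, levels = build_design(table, spec)
    _check_rank(X)
    df = pd.DataFrame(
        {_safe_name(c): X[c].to_numpy() for c in X.columns if c != "Intercept"}
    )
    df["z_response"] = table["z_response"].to_numpy(float)
    df["region_id"] = table["region_id"].to_numpy()
    df["county_id"] = table["county_id"].to_numpy()
    rhs = " + ".join([_safe_name(c) for c in X.columns if c != "Intercept"]) or "1"
    formula = f"z_response ~ {rhs}"
    n_vc = 2 if spec.random_spec == "county_in_region" else 1
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        warnings.simplefilter("ignore", RuntimeWarning)
        warnings.simplefilter("ignore", UserWarning)
        if spec.random_spec == "county_in_region":
            model = smf.mixedlm(
                formula,
                df,
                groups="region_id",
                re_formula="1",
                vc_formula={"county": "0 + C(county_id)"},
            )
        else:
            model = smf.mixedlm(formula, df, groups="county_id", re_formula="1")
        # variance components at the boundary routinely trip the default
        # optimizer; cascade through optimizers, preferring the first
        # converged fit with a usable (positive-diagonal) fixed-effect
        # covariance, then any converged fit, then the best log-likelihood
        n_fe = len(df.columns) - 3 + 1  # fixed columns incl. intercept
        res, fallback, best = None, None, None
        for method in (None, "lbfgs", "powell", "nm"):
            kwargs = {"method": method} if method else {}
            try:
                attempt = model.fit(reml=False, **kwargs)
            except (np.linalg.LinAlgError, ValueError):
                continue
            if best is None or attempt.llf > best.llf:
                best = attempt
            if attempt.converged:
                if fallback is None:
                    fallback = attempt
                d = np.diag(attempt.cov_params().to_numpy())[:n_fe]
                if np.all(np.isfinite(d)) and np.all(d >= 0):
                    res = attempt
                    break
        if res is None:
            res = fallback if fallback is not None else best
        if res is None:
            raise RuntimeError("all mixed-model optimizers failed")
    fe_names_safe = [_safe_name(c) if c != "Intercept" else "Intercept" for c in X.columns]
    rename = dict(zip(fe_names_safe, X.columns))
    beta = res.fe_params.rename(index=rename).reindex(X.columns)
    cov = res.cov_params().iloc[: len(X.columns), : len(X.columns)]
    cov = cov.rename(index=rename, columns=rename).reindex(
        index=X.columns, columns=X.columns
    )
    diag = np.diag(cov.to_numpy())
    # a non-PD Hessian at a variance boundary can yield negative variances;
    # report those SEs as NaN rather than fabricating a number
    se = pd.Series(
        np.where(diag >= 0, np.sqrt(np.abs(diag)), np.nan), index=X.columns
    )
    if spec.random_spec == "county_in_region":
        var_region = float(res.cov_re.iloc[0, 0])
        var_county = float(res.vcomp[0]) if len(res.vcomp) else 0.0
    else:
        var_region = 0.0
        var_county = float(res.cov_re.iloc[0, 0])
    var_resid = float(res.scale)
    k_fixed = X.shape[1]
    k = k_fixed + n_vc + 1
    n = len(table)
    llf = float(res.llf)
    crit = aicc(llf, k, n) if np.isfinite(llf) else np.inf
    fitted_fixed = X.to_numpy(float) @ beta.to_numpy(float)
    s2_fixed = float(np.var(fitted_fixed, ddof=1)) if n > 1 else 0.0
    denom = s2_fixed + var_region + var_county + var_resid
    r2c = (s2_fixed + var_region + var_county) / denom if denom > 0 else np.nan
    fit = FitResult(
        spec=spec,
        beta=beta,
        se=se,
        cov_fixed=cov,
        loglik=llf,
        k=k,
        k_fixed=k_fixed,
        n=n,
        varcomp={
            "sigma2_region": var_region,
            "sigma2_county": var_county,
            "sigma2_resid": var_resid,
        },
        aicc=crit,
        r2c=r2c,
        converged=bool(res.converged),
        col_components=meta,
        col_means=X.mean(),
        reference_mean=float(table.attrs.get("response_mean_transformed", np.nan)),
        survey_levels=levels,
    )
    fit._sigma2_fixed = s2_fixed
    return fit


def aicc(loglik: float, k: int, n: int) -> float:
    """Small-sample-corrected AIC: -2 logL + 2k + 2k(k+1)/(n-k-1)."""
    if n - k - 1 <= 0:
        raise SampleTooSmallError(f"AICc undefined for n={n}, k={k}")
    return -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


def conditional_r2(fit: FitResult, fixed_variance: float) -> float:
    """Proportion of variance explained by fixed plus random effects.

    Returns NaN (the error flag) when every variance component and the
    fixed-predictor variance are zero.
    """
    vr = fit.varcomp["sigma2_region"]
    vc = fit.varcomp["sigma2_county"]
    ve = fit.varcomp["sigma2_resid"]
    if min(fixed_variance, vr, vc, ve) < 0:
        raise ValueError("variances must be >= 0")
    denom = fixed_variance + vr + vc + ve
    if denom == 0:
        return float("nan")
    return (fixed_variance + vr + vc) / denom


def support_check(
    candidate_aicc: float, baseline_aicc: float, null_aicc: float
) -> bool:
    """Supported iff at least 2 AICc units below the baseline (survey-type
    only) model and below the null (random effects only) model."""
    for v in (candidate_aicc, baseline_aicc, null_aicc):
        if not np.isfinite(v):
            raise ValueError("AICc values must be finite")
    return candidate_aicc <= baseline_aicc - 2.0 and candidate_aicc < null_aicc
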