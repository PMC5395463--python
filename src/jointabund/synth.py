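"""Synthetic county x year survey and covariate generator.

Emulates the statistical structure assumed by the joint abundance-index
analysis: a latent log-scale county abundance driven by lagged environmental
covariates, observed through three survey types (hunter harvest totals,
breeding-season route counts, winter station counts) with distinct
observation scales and disjoint year spans, on top of county-within-region
random structure.

The generator is first-class, tested code: parameter-recovery and
type-I-error experiments downstream rely on the documented generative model

    log lambda_{c,t} = intercept + u_region + u_county
                       + sum_j beta_j * x_j(c, t-1) + eps_{c,t}

with interaction terms formed as products of mean-centered components and a
one-year lag between covariates and abundance (mirrored by the assembly
stage). Survey responses are Poisson (route/station counts) or negative
binomial (harvest totals) around q_s * lambda.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InvalidDesignError, UnknownCovariateError

SURVEY_TYPES = ("AGTS", "BBS", "CBC")

LAND_USE_COVARIATES = [
    "harvested_cropland_pct",
    "unharvested_cropland_pct",
    "cropland_pasture_pct",
    "crp_pct",
]
CROP_COVARIATES = [
    "barley",
    "sugar_beets",
    "nut_trees",
    "winter_wheat",
    "sorghum",
    "vegetable_seed",
    "rice",
    "cotton",
    "grapes",
    "hay",
    "corn",
    "wheat",
    "oats",
    "fruit_trees",
]
CLIMATE_COVARIATES = [
    "tmin_breeding",
    "tmin_brood",
    "tmin_winter",
    "precip_breeding",
    "precip_brood",
    "precip_winter",
]
AVIAN_COVARIATES = ["corvid", "raptor", "turkey"]
PESTICIDE_COVARIATES = ["pesticide_total"]

ALL_COVARIATES = (
    LAND_USE_COVARIATES
    + CROP_COVARIATES
    + CLIMATE_COVARIATES
    + AVIAN_COVARIATES
    + PESTICIDE_COVARIATES
)

# Mean seasonal minimum temperature (deg C) and precipitation (mm) around
# which county means are drawn; chosen as plausible Central Valley values.
_CLIMATE_MEANS = {
    "tmin_breeding": (9.0, 1.5),   # (statewide mean, between/within-county SD)
    "tmin_brood": (14.0, 1.5),
    "tmin_winter": (3.0, 1.5),
    "precip_breeding": (60.0, 20.0),
    "precip_brood": (15.0, 8.0),
    "precip_winter": (250.0, 60.0),
}


@dataclass(frozen=True)
class SurveyDesign:
    """Spatial/temporal layout and coverage of the three survey types.

    ``year_span`` holds the first and last calendar year each survey ran
    (defaults emulate long-running harvest, breeding, and winter-count
    programs with disjoint spans); ``coverage`` is the probability that a
    county-year inside the span is actually observed.
    """

    n_regions: int = 4
    counties_per_region: int = 8
    year_span: dict = field(
        default_factory=lambda: {
            "AGTS": (1948, 2010),
            "BBS": (1974, 2012),
            "CBC": (1914, 2013),
        }
    )
    coverage: dict = field(
        default_factory=lambda: {"AGTS": 0.9, "BBS": 0.85, "CBC": 0.8}
    )
    pesticide_start: int = 1990
    crop_start: int = 1980

    def __post_init__(self):
        if self.n_regions <= 0 or self.counties_per_region <= 0:
            raise InvalidDesignError(
                "n_regions and counties_per_region must be positive"
            )
        for s, (lo, hi) in self.year_span.items():
            if hi < lo:
                raise InvalidDesignError(f"empty year span for {s}: ({lo}, {hi})")
        for s, c in self.coverage.items():
            if not 0 < c <= 1:
                raise InvalidDesignError(f"coverage for {s} must be in (0, 1]")

    @property
    def years(self) -> range:
        lo = min(a for a, _ in self.year_span.values())
        hi = max(b for _, b in self.year_span.values())
        return range(lo, hi + 1)

    @property
    def counties(self) -> list:
        return [
            (f"R{r:02d}", f"R{r:02d}C{c:02d}")
            for r in range(self.n_regions)
            for c in range(self.counties_per_region)
        ]


@dataclass(frozen=True)
class SimTruth:
    """Known parameters of the latent abundance process.

    ``beta_true`` maps covariate or interaction terms (colon-separated
    components, e.g. ``"harvested_cropland_pct:year"``) to latent-log-scale
    effects per predictor unit. ``q_survey`` are detectability/scaling
    multipliers per survey type; ``dispersion`` is the negative-binomial
    size parameter for harvest counts (larger = closer to Poisson).
    """

    beta_true: dict = field(default_factory=dict)
    sigma_region: float = 0.3
    sigma_county: float = 0.4
    sigma_resid: float = 0.3
    q_survey: dict = field(
        default_factory=lambda: {"AGTS": 12.0, "BBS": 1.0, "CBC": 2.5}
    )
    dispersion: float = 5.0
    intercept: float = 3.0
    seed: int = 20170315

    def __post_init__(self):
        if min(self.sigma_region, self.sigma_county, self.sigma_resid) < 0:
            raise InvalidDesignError("standard deviations must be >= 0")
        if any(q <= 0 for q in self.q_survey.values()):
            raise InvalidDesignError("q_survey multipliers must be > 0")
        if self.dispersion <= 0:
            raise InvalidDesignError("dispersion must be > 0")

    def replace(self, **kw) -> "SimTruth":
        return dataclasses.replace(self, **kw)


def _county_rng(seed: int, stream: int) -> np.random.Generator:
    # Distinct, reproducible substreams keyed on (seed, stream).
    return np.random.default_rng(np.random.SeedSequence([int(seed), int(stream)]))


def generate_covariate_panel(design: SurveyDesign, seed: int) -> pd.DataFrame:
    """Generate one covariate row per county-year over the union of spans.

    Land-use percentages follow county-specific linear-plus-noise trends;
    pesticide is structurally missing before ``design.pesticide_start`` and
    increases on average afterwards; per-crop percentages are Dirichlet
    shares of harvested cropland (so their sum never exceeds it) and are
    missing before ``design.crop_start``; climate draws vary around county
    means; corvid/raptor/turkey are nonnegative integer counts with a mild
    upward trend.
    """
    rng = _county_rng(seed, 0)
    years = np.array(design.years)
    ny = len(years)
    yc = years - years.mean()
    frames = []
    for region_id, county_id in design.counties:
        row = {"county_id": county_id, "region_id": region_id, "year": years}
        harv = np.clip(
            rng.uniform(20, 60)
            + rng.normal(0, 0.15) * yc
            + rng.normal(0, 2.0, ny),
            0.5,
            95.0,
        )
        unharv = np.clip(
            rng.uniform(2, 15) + rng.normal(0, 0.05) * yc + rng.normal(0, 1.0, ny),
            0.0,
            40.0,
        )
        pasture = np.clip(
            rng.uniform(1, 10) + rng.normal(0, 0.03) * yc + rng.normal(0, 0.8, ny),
            0.0,
            30.0,
        )
        crp = np.clip(
            rng.uniform(0, 5) + rng.normal(0, 0.02) * yc + rng.normal(0, 0.5, ny),
            0.0,
            20.0,
        )
        row.update(
            harvested_cropland_pct=harv,
            unharvested_cropland_pct=unharv,
            cropland_pasture_pct=pasture,
            crp_pct=crp,
        )

        # Crop shares: county-level Dirichlet base perturbed per year,
        # scaled so the 14 crop percentages sum to <= harvested cropland.
        base = rng.dirichlet(np.full(len(CROP_COVARIATES), 0.6))
        shares = rng.dirichlet(base * 50 + 0.1, size=ny)  # year-to-year wobble
        crop_vals = shares * (0.85 * harv)[:, None]
        crop_vals[years < design.crop_start] = np.nan
        for j, crop in enumerate(CROP_COVARIATES):
            row[crop] = crop_vals[:, j]

        for name, (mu, sd) in _CLIMATE_MEANS.items():
            county_mean = rng.normal(mu, sd)
            if name.startswith("precip"):
                county_mean = max(county_mean, 1.0)
                shape = 4.0
                row[name] = rng.gamma(shape, county_mean / shape, ny)
            else:
                row[name] = rng.normal(county_mean, sd, ny)

        for name, (lo, hi) in (("corvid", (20, 60)), ("raptor", (5, 20)), ("turkey", (1, 10))):
            base_count = rng.uniform(lo, hi)
            trend = np.exp(0.01 * (years - years[0]))
            row[name] = rng.poisson(base_count * trend / trend.mean())

        pest = np.full(ny, np.nan)
        mask = years >= design.pesticide_start
        if mask.any():
            t = years[mask] - design.pesticide_start
            mean = 0.8 + 0.18 * t
            shape = 1.1
            pest[mask] = rng.gamma(shape, mean / shape)
        row["pesticide_total"] = pest

        frames.append(pd.DataFrame(row))
    panel = pd.concat(frames, ignore_index=True)
    return panel[["county_id", "region_id", "year"] + ALL_COVARIATES]


def _split_term(term: str) -> list:
    return term.split(":")


def _term_values(panel_lagged: pd.DataFrame, term: str, centers: dict) -> np.ndarray:
    comps = _split_term(term)
    if len(comps) == 1:
        c = comps[0]
        if c == "year":
            return panel_lagged["year"].to_numpy(float) - centers["year"]
        return panel_lagged[c].to_numpy(float)
    val = np.ones(len(panel_lagged))
    for c in comps:
        val = val * (panel_lagged[c].to_numpy(float) - centers[c])
    return val


def generate_latent_abundance(
    panel: pd.DataFrame,
    truth: SimTruth,
    lag: int = 1,
    zero_fill: tuple = ("pesticide_total",),
) -> pd.DataFrame:
    """Latent log-abundance per county-year from lagged covariate effects.

    The row for year ``t`` uses the panel covariates of year ``t - lag``
    (abundance responds to the previous year's conditions); main effects
    enter on their original scale except ``year``, which is centered at the
    panel midpoint, and interaction products use mean-centered components
    (only the highest-order coefficient of an interaction family is
    invariant to the centering choice). Rows whose donor year is absent, or
    whose needed covariates are missing, are omitted — except exposure
    covariates listed in ``zero_fill``, whose structural missingness means
    "not applied" and contributes zero rather than truncating the series.
    """
    needed = sorted({c for t in truth.beta_true for c in _split_term(t) if c != "year"})
    missing = [c for c in needed if c not in panel.columns]
    if missing:
        raise UnknownCovariateError(f"terms reference unknown covariates: {missing}")

    work = panel.copy()
    donor = work[["county_id", "year"] + needed].copy()
    donor["year"] = donor["year"] + lag
    lagged = work[["county_id", "region_id", "year"]].merge(
        donor, on=["county_id", "year"], how="left"
    )
    for c in needed:
        if c in zero_fill:
            lagged[c] = lagged[c].fillna(0.0)
    strict = [c for c in needed if c not in zero_fill]
    if strict:
        lagged = lagged.dropna(subset=strict)
    # drop rows whose donor year precedes the panel (no covariates at all)
    if needed:
        first_year = int(panel["year"].min()) + lag
        lagged = lagged[lagged["year"] >= first_year]

    centers = {"year": float(panel["year"].mean())}
    for c in needed:
        centers[c] = float(lagged[c].mean())

    rng = _county_rng(truth.seed, 1)
    counties = sorted(panel["county_id"].unique())
    regions = sorted(panel["region_id"].unique())
    u_region = dict(zip(regions, rng.normal(0, truth.sigma_region, len(regions))))
    u_county = dict(zip(counties, rng.normal(0, truth.sigma_county, len(counties))))

    log_lam = np.full(len(lagged), truth.intercept)
    log_lam += lagged["region_id"].map(u_region).to_numpy(float)
    log_lam += lagged["county_id"].map(u_county).to_numpy(float)
    for term, beta in truth.beta_true.items():
        log_lam += beta * _term_values(lagged, term, centers)
    log_lam += rng.normal(0, truth.sigma_resid, len(lagged))

    out = lagged[["county_id", "region_id", "year"]].copy()
    out["log_lambda"] = log_lam
    return out.reset_index(drop=True)


def generate_surveys(
    latent: pd.DataFrame,
    truth: SimTruth,
    design: SurveyDesign,
    seed: int | None = None,
) -> pd.DataFrame:
    """Draw survey responses around ``q_s * lambda`` for covered county-years.

    Route/station counts (BBS, CBC) are Poisson; harvest totals (AGTS) are
    negative binomial with size ``truth.dispersion``. County-years outside a
    survey's span, or dropped by its coverage probability, are absent.
    """
    rng = _county_rng(truth.seed if seed is None else seed, 2)
    lam = np.exp(latent["log_lambda"].to_numpy(float))
    frames = []
    for s in SURVEY_TYPES:
        lo, hi = design.year_span[s]
        in_span = (latent["year"] >= lo) & (latent["year"] <= hi)
        sub = latent.loc[in_span, ["county_id", "region_id", "year"]].copy()
        mu = truth.q_survey[s] * lam[in_span.to_numpy()]
        keep = rng.random(len(sub)) < design.coverage[s]
        sub, mu = sub.loc[keep], mu[keep]
        if s == "AGTS":
            k = truth.dispersion
            with np.errstate(divide="ignore", invalid="ignore"):
                p = np.where(mu > 0, k / (k + mu), 1.0)
            resp = rng.negative_binomial(k, p)
        else:
            resp = rng.poisson(mu)
        sub["survey_type"] = s
        sub["response"] = resp.astype(float)
        frames.append(sub)
    out = pd.concat(frames, ignore_index=True)
    return out[["survey_type", "region_id", "county_id", "year", "response"]]
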