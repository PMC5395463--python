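import warnings

import numpy as np
import pandas as pd
import pytest

from jointabund import synth


@pytest.fixture(autouse=True)
def _quiet_convergence():
    # boundary variance-component fits emit harmless optimizer chatter
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message=".*converge.*")
        warnings.filterwarnings("ignore", message=".*boundary.*")
        warnings.filterwarnings("ignore", message=".*Hessian.*")
        yield


@pytest.fixture(scope="session")
def small_design():
    return synth.SurveyDesign(
        n_regions=2,
        counties_per_region=4,
        year_span={"AGTS": (1980, 2010), "BBS": (1985, 2012), "CBC": (1975, 2013)},
        coverage={"AGTS": 1.0, "BBS": 1.0, "CBC": 1.0},
    )


@pytest.fixture(scope="session")
def small_panel(small_design):
    return synth.generate_covariate_panel(small_design, seed=42)


@pytest.fixture(scope="session")
def small_truth():
    return synth.SimTruth(
        beta_true={"tmin_breeding": 0.2, "corvid": -0.01},
        sigma_region=0.2,
        sigma_county=0.3,
        sigma_resid=0.1,
        q_survey={"AGTS": 4.0, "BBS": 1.0, "CBC": 2.0},
        intercept=2.5,
        dispersion=10.0,
        seed=42,
    )


@pytest.fixture(scope="session")
def small_records(small_design, small_panel, small_truth):
    latent = synth.generate_latent_abundance(small_panel, small_truth)
    return synth.generate_surveys(latent, small_truth, small_design)


@pytest.fixture()
def toy_records():
    """Hand-sized survey table: 2 regions x 2 counties x 6 years x 3 surveys."""
    rng = np.random.default_rng(0)
    rows = []
    for r, c in [("R0", "R0C0"), ("R0", "R0C1"), ("R1", "R1C0"), ("R1", "R1C1")]:
        for year in range(2000, 2006):
            for s, scale in (("AGTS", 50), ("BBS", 5), ("CBC", 12)):
                rows.append(
                    {
                        "survey_type": s,
                        "region_id": r,
                        "county_id": c,
                        "year": year,
                        "response": float(rng.poisson(scale)),
                    }
                )
    return pd.DataFrame(rows)


@pytest.fixture()
def toy_panel():
    rng = np.random.default_rng(1)
    rows = []
    for r, c in [("R0", "R0C0"), ("R0", "R0C1"), ("R1", "R1C0"), ("R1", "R1C1")]:
        for year in range(1999, 2006):
            rows.append(
                {
                    "county_id": c,
                    "region_id": r,
                    "year": year,
                    "x1": rng.normal(10, 2),
                    "x2": rng.normal(0, 1),
                    "x3": rng.uniform(0, 100),
                }
            )
    return pd.DataFrame(rows)
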