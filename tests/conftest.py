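"""Shared fixtures: small simulated surveys and session-scoped model fits."""

import pandas as pd
import pytest

import weeddyn as wd
from weeddyn.clmm import FitOptions, ModelSpec, projection_spec


@pytest.fixture(scope="session")
def small_dataset():
    """A compact mixed-management survey (25 sites x 8 years, capped truth)."""
    cfg = wd.SimulationConfig(
        n_sites=25,
        years=(2001, 2008),
        true_model=wd.default_true_model(sigma=1.0, cap_paddy=True),
        management=wd.ManagementProcess(
            land_use_probs={"wheat": 0.6, "barley": 0.1, "other_crop": 0.1,
                            "paddy_rice": 0.1, "fallow_managed": 0.05,
                            "fallow_unmanaged": 0.05},
            irrigation_rate=0.2, delayed_rate=0.2,
        ),
        initial_level_distribution=(0.3, 0.3, 0.2, 0.2),
        missing_rate=0.1,
        seed=11,
    )
    ds, truth = wd.simulate_dataset(cfg)
    return cfg, ds, truth


@pytest.fixture(scope="session")
def toy_model():
    """Hand-set parameters for exact probability checks."""
    return wd.make_true_model(
        thresholds=(-1.0, 0.0, 1.0),
        alpha=(0.5, 1.0, 1.5),
        coefs={"irrigation": -1.0, "land_use[barley]": 0.3,
               "land_use[other_crop]": -2.0, "land_use[paddy_rice]": -8.0,
               "land_use[fallow_managed]": -1.0, "land_use[fallow_unmanaged]": -0.5},
        sigma=1.0,
    )


@pytest.fixture(scope="session")
def toy_site_pairs():
    """Three transitions at one site, for quadrature oracle checks."""
    return pd.DataFrame({
        "site_id": ["A"] * 3,
        "year": [2001, 2002, 2003],
        "from_level": [0, 1, 2],
        "to_level": [1, 2, 1],
        "land_use": ["wheat", "barley", "wheat"],
        "irrigation": [0, 1, 0],
        "delayed_sowing": [0, 0, 0],
        "temp_dec_apr": [6.8, 7.0, 6.5],
        "gap": [1, 1, 1],
    })


# ---- campaign-scale emulation, fitted once per session ----------------------

ACCEPTANCE_SEED = 1


@pytest.fixture(scope="session")
def survey_emulation():
    cfg = wd.emulated_survey_config(seed=ACCEPTANCE_SEED)
    ds, truth = wd.simulate_dataset(cfg)
    pairs = wd.build_transition_pairs(ds)
    return cfg, ds, truth, pairs


@pytest.fixture(scope="session")
def projection_fit(survey_emulation):
    _, _, _, pairs = survey_emulation
    return wd.fit_model(pairs, projection_spec(), FitOptions(n_starts=1))


@pytest.fixture(scope="session")
def candidate_fits(survey_emulation):
    """The candidate models of the selection ladder, fitted on the emulation."""
    _, _, _, pairs = survey_emulation
    full = frozenset(
        {"prev_coverage", "irrigation", "delayed_sowing", "land_use", "temperature"})
    specs = {
        "full": full,
        "no_delayed": full - {"delayed_sowing"},
        "no_temp": full - {"temperature"},
        "projection": full - {"delayed_sowing", "temperature"},
        "no_prev": full - {"prev_coverage"},
    }
    opts = FitOptions(n_starts=1)
    return {
        name: wd.fit_model(pairs, ModelSpec(terms=t), opts)
        for name, t in specs.items()
    }
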