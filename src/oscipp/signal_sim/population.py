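"""Synthetic population tables for hypertension-screening experiments.

Columns mirror a health-survey extract: ``age, sex, race, bmi, smoking,
sbp, dbp, hr`` plus derived ``pp`` and the two label columns
``systolic_htn`` (SBP >= 130) and ``general_htn`` (SBP >= 130 or DBP >= 80).
Continuous variables are tied together with a Gaussian copula; DBP tracks
SBP linearly with residual scatter so SBP and PP are strongly positively
correlated at the default settings.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from importlib import resources

import numpy as np
import pandas as pd
import yaml
from scipy.stats import norm

__all__ = ["PopulationConfig", "simulate_population", "POPULATION_COLUMNS"]

POPULATION_COLUMNS = [
    "age", "sex", "race", "bmi", "smoking", "sbp", "dbp", "hr",
    "pp", "systolic_htn", "general_htn",
]

SYSTOLIC_THRESHOLD_MMHG = 130.0
DIASTOLIC_THRESHOLD_MMHG = 80.0
AGE_CUTOFF_YEARS = 65.0


def _load_defaults() -> dict:
    text = resources.files("oscipp.data").joinpath("population.yaml").read_text()
    return yaml.safe_load(text)


_DEFAULTS = _load_defaults()


@dataclass(frozen=True)
class PopulationConfig:
    """Size, seed, and distribution parameters of a synthetic population.

    Distribution defaults live in ``oscipp/data/population.yaml``; any key
    there may be overridden via ``params``.
    """

    n_people: int = 1000
    seed: int = 0
    params: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.n_people < 0:
            raise ValueError("n_people must be non-negative")
        unknown = set(self.params) - set(_DEFAULTS)
        if unknown:
            raise ValueError(f"unknown population parameters: {sorted(unknown)}")

    def resolved(self) -> dict:
        out = dict(_DEFAULTS)
        out.update(self.params)
        return out

    def with_(self, **kw) -> "PopulationConfig":
        return replace(self, **kw)


def _latent_correlation(p: dict) -> np.ndarray:
    # order: age, bmi, sbp, hr, dbp-residual (residual independent)
    r = np.eye(5)
    r[0, 1] = r[1, 0] = p["corr_age_bmi"]
    r[0, 2] = r[2, 0] = p["corr_age_sbp"]
    r[0, 3] = r[3, 0] = p["corr_age_hr"]
    r[1, 2] = r[2, 1] = p["corr_bmi_sbp"]
    r[1, 3] = r[3, 1] = p["corr_bmi_hr"]
    r[2, 3] = r[3, 2] = p["corr_sbp_hr"]
    return r


def simulate_population(config: PopulationConfig) -> pd.DataFrame:
    """Draw a seeded synthetic population table.

    Ages are strictly below 65 (the screening target population), PP is
    bounded away from zero, labels are computed from the stored (possibly
    measurement-noise-corrupted) BP columns, and the same seed reproduces
    the table exactly.
    """
    p = config.resolved()
    n = config.n_people
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7]))

    if n == 0:
        return pd.DataFrame(columns=POPULATION_COLUMNS)

    corr = _latent_correlation(p)
    # cholesky also validates positive definiteness of the configured matrix
    chol = np.linalg.cholesky(corr)
    z = rng.standard_normal((n, 5)) @ chol.T

    age = p["age_min"] + (p["age_max"] - p["age_min"]) * norm.cdf(z[:, 0])
    bmi = np.clip(np.exp(p["bmi_log_mean"] + p["bmi_log_sd"] * z[:, 1]),
                  p["bmi_min"], p["bmi_max"])
    sbp = p["sbp_mean"] + p["sbp_sd"] * z[:, 2]
    hr = np.clip(p["hr_mean"] + p["hr_sd"] * z[:, 3], p["hr_min"], p["hr_max"])
    dbp = p["dbp_intercept"] + p["dbp_slope"] * sbp + p["dbp_resid_sd"] * z[:, 4]
    dbp = np.minimum(dbp, sbp - p["min_pp"])  # keep PP physiological

    sex = rng.choice(p["sex_levels"], size=n, p=p["sex_probs"])
    race = rng.choice(p["race_levels"], size=n, p=p["race_probs"])
    smoking = rng.choice(p["smoking_levels"], size=n, p=p["smoking_probs"])

    noise_mean = p["measurement_noise_mean"]
    noise_sd = p["measurement_noise_sd"]
    if noise_mean != 0.0 or noise_sd != 0.0:
        sbp = sbp + rng.normal(noise_mean, noise_sd, size=n)
        dbp = dbp + rng.normal(noise_mean, noise_sd, size=n)
        dbp = np.minimum(dbp, sbp - 1.0)

    df = pd.DataFrame({
        "age": age, "sex": sex, "race": race, "bmi": bmi, "smoking": smoking,
        "sbp": sbp, "dbp": dbp, "hr": hr,
    })
    df["pp"] = df["sbp"] - df["dbp"]
    df["systolic_htn"] = (df["sbp"] >= SYSTOLIC_THRESHOLD_MMHG).astype(int)
    df["general_htn"] = (
        (df["sbp"] >= SYSTOLIC_THRESHOLD_MMHG)
        | (df["dbp"] >= DIASTOLIC_THRESHOLD_MMHG)
    ).astype(int)
    return df
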