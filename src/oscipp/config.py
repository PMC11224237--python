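"""Run configuration: one hierarchical YAML file, flag-overridable.

Defaults live in ``oscipp/data/defaults.yaml`` and round-trip through
:meth:`RunConfig.to_yaml` / :meth:`RunConfig.from_yaml` identically.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from importlib import resources

import yaml

__all__ = ["RunConfig", "PhysicsConfig", "AlgorithmConfig",
           "ValidityConfig", "ScreeningConfig"]


def _defaults() -> dict:
    text = resources.files("oscipp.data").joinpath("defaults.yaml").read_text()
    return yaml.safe_load(text)


_D = _defaults()


@dataclass
class PhysicsConfig:
    rho_blood_kg_m3: float = _D["physics"]["rho_blood_kg_m3"]
    g_m_s2: float = _D["physics"]["g_m_s2"]
    pa_per_mmhg: float = _D["physics"]["pa_per_mmhg"]


@dataclass
class AlgorithmConfig:
    filter_lo_hz: float = _D["algorithm"]["filter_lo_hz"]
    filter_hi_hz: float = _D["algorithm"]["filter_hi_hz"]
    prominence_frac: float = _D["algorithm"]["prominence_frac"]
    smooth_window: int = _D["algorithm"]["smooth_window"]
    normalize_after_smooth: bool = _D["algorithm"]["normalize_after_smooth"]
    fit_tol: float = _D["algorithm"]["fit_tol"]
    fit_start_widths: list = field(
        default_factory=lambda: list(_D["algorithm"]["fit_start_widths"]))
    pp_grid_points: int = _D["algorithm"]["pp_grid_points"]

    @staticmethod
    def ppg_rate_of(session) -> float:
        """Sampling rate of a session's PPG channel (metadata, else inferred)."""
        rate = session.metadata.get("ppg_rate_hz")
        if rate:
            return float(rate)
        import numpy as np

        dt = np.median(np.diff(session.t_ppg))
        return 1.0 / float(dt)


@dataclass
class ValidityConfig:
    contact_area_max_frac: float = _D["validity"]["contact_area_max_frac"]
    limb_max_frac: float = _D["validity"]["limb_max_frac"]
    linearity_min_r2: float = _D["validity"]["linearity_min_r2"]
    monotone_min_frac: float = _D["validity"]["monotone_min_frac"]
    percent_increase: float = _D["validity"]["percent_increase"]
    raise_min_s: float = _D["validity"]["raise_min_s"]
    raise_max_s: float = _D["validity"]["raise_max_s"]


@dataclass
class ScreeningConfig:
    train_frac: float = _D["screening"]["train_frac"]
    hidden_units: int = _D["screening"]["hidden_units"]
    lbfgs_tol: float = _D["screening"]["lbfgs_tol"]
    max_iter: int = _D["screening"]["max_iter"]
    noise_mean_mmhg: float = _D["screening"]["noise_mean_mmhg"]
    noise_sd_mmhg: float = _D["screening"]["noise_sd_mmhg"]
    n_realizations: int = _D["screening"]["n_realizations"]


@dataclass
class RunConfig:
    physics: PhysicsConfig = field(default_factory=PhysicsConfig)
    algorithm: AlgorithmConfig = field(default_factory=AlgorithmConfig)
    validity: ValidityConfig = field(default_factory=ValidityConfig)
    screening: ScreeningConfig = field(default_factory=ScreeningConfig)
    seed: int = _D["seed"]

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        return cls(
            physics=PhysicsConfig(**d.get("physics", {})),
            algorithm=AlgorithmConfig(**d.get("algorithm", {})),
            validity=ValidityConfig(**d.get("validity", {})),
            screening=ScreeningConfig(**d.get("screening", {})),
            seed=d.get("seed", _D["seed"]),
        )

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=False)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})
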