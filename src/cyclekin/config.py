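"""Simulation configuration: generative parameters, validation, TOML IO.

Cycle times are lognormal.  On the log scale a cell at depth k in tree tau
has

    log T = m(k) + F_tau + G_tau * k + B_div + eps

with independent zero-mean normal components: F per tree (family), G per
tree (generational drift, scaled by depth), B per division (shared by the
two daughters it creates) and eps per cell.  Component variances are
expressed as fractions of the depth-1 total log-variance V1, and V1 is
calibrated so the arithmetic mean and s.d. of complete cycle times pooled
over the measured depths match the configured per-generation targets
(13.4 +/- 5.4 h for sorted generation 1, 14.3 +/- 4.4 h for generation 3).
The per-depth location m(k) = log(mean) - V(k)/2 keeps the arithmetic mean
flat across depths.
"""

from __future__ import annotations

import hashlib
import json
import math
import tomllib
from dataclasses import asdict, dataclass, field, replace

from scipy.optimize import brentq

__all__ = ["SimulationConfig", "GenParams", "ConfigError", "load_config", "dump_toml"]

MIN_PER_H = 60.0


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class GenParams:
    """Resolved lognormal parameters for one sorted generation's FAST state."""

    mean_min: float
    v1: float            # total log-variance at depth 1
    var_family: float
    var_drift: float     # multiplies depth^2
    var_division: float
    var_individual: float

    def total_logvar(self, depth: int) -> float:
        return self.v1 + (depth * depth - 1) * self.var_drift

    def location(self, depth: int) -> float:
        # arithmetic mean is mean_min at every depth
        return math.log(self.mean_min) - self.total_logvar(depth) / 2.0


def _calibrate(
    mean_min: float,
    sd_min: float,
    frac_drift: float,
    depth_weights: dict[int, float],
) -> float:
    """Solve for V1 so the pooled (across measured depths) arithmetic
    variance matches sd_min^2, given the drift fraction of V1."""
    cv2 = (sd_min / mean_min) ** 2

    def f(v1: float) -> float:
        pooled = sum(
            w * math.exp(v1 + (k * k - 1) * frac_drift * v1)
            for k, w in depth_weights.items()
        )
        return pooled - (1.0 + cv2)

    return brentq(f, 0.0, 5.0)


@dataclass
class SimulationConfig:
    seed: int = 0
    generation_offset: int = 1
    n_founders: int = 100

    # imaging
    window_lo_min: float = 3960.0       # 66 h
    window_hi_min: float = 5400.0       # 90 h
    frame_lo_min: float = 3.0
    frame_hi_min: float = 4.0
    max_depth: int = 3                  # division rounds tracked past the founder

    # per-generation cycle-time targets (arithmetic, hours)
    gen1_mean_h: float = 13.4
    gen1_sd_h: float = 5.4
    gen3_mean_h: float = 14.3
    gen3_sd_h: float = 4.4
    # generation 8 FAST cells reuse the generation-3 parameters (no printed
    # summary exists for generation-8 fast cyclers)

    # heritability variance fractions of V1 (must sum to 1)
    frac_family: float = 0.05
    frac_drift: float = 0.06
    frac_division: float = 0.79
    frac_individual: float = 0.10

    # slow/no-division state
    g_onset: int = 8
    p_on: float = 0.25
    p_stay: float = 0.8
    p_arrest: float = 0.35
    slow_median_min: float = 1800.0
    slow_sigma_log: float = 0.45

    # reporter kinetics
    plateau_au: float = 1000.0
    ko_high_plateau_au: float = 2500.0
    rise_min: float = 8.0
    decay_min: float = 8.0
    noise_cv: float = 0.05
    dn_duration_min: float = 60.0
    g1_frac_fast: float = 0.25
    g1_frac_slow: float = 0.7

    # CTV dye
    ctv_founder_au: float = 10000.0
    ctv_cv: float = 0.15
    ctv_floor_generation: int = 9

    # BrdU
    f_s: float = 0.6

    # misc
    death_hazard_per_min: float = 0.0
    activation_lag_min: float = 1440.0

    _gen_params: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.validate()

    # -- validation -------------------------------------------------------
    def validate(self) -> None:
        if self.generation_offset not in (1, 3, 8):
            raise ConfigError(f"generation_offset must be 1, 3 or 8, got {self.generation_offset}")
        if self.n_founders < 1:
            raise ConfigError("n_founders must be >= 1")
        if not (0 < self.window_lo_min <= self.window_hi_min):
            raise ConfigError("imaging window bounds invalid")
        if not (0 < self.frame_lo_min <= self.frame_hi_min):
            raise ConfigError("frame interval bounds invalid")
        if self.max_depth < 1:
            raise ConfigError("max_depth must be >= 1")
        fracs = (self.frac_family, self.frac_drift, self.frac_division, self.frac_individual)
        if any(f < 0 for f in fracs):
            raise ConfigError("variance fractions must be nonnegative")
        if abs(sum(fracs) - 1.0) > 1e-9:
            raise ConfigError(f"variance fractions must sum to 1, got {sum(fracs)}")
        for name in ("p_on", "p_stay", "p_arrest", "noise_cv", "ctv_cv"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ConfigError(f"{name} must be in [0, 1], got {v}")
        for name in ("g1_frac_fast", "g1_frac_slow"):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise ConfigError(f"{name} must be in (0, 1), got {v}")
        if not (0.0 < self.f_s <= 1.0):
            raise ConfigError(f"f_s must be in (0, 1], got {self.f_s}")
        if self.slow_median_min <= 1440.0:
            raise ConfigError("slow_median_min must exceed 1440 (median > 24 h)")
        for name in ("gen1_mean_h", "gen1_sd_h", "gen3_mean_h", "gen3_sd_h",
                     "plateau_au", "dn_duration_min", "slow_sigma_log"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if self.death_hazard_per_min < 0:
            raise ConfigError("death_hazard_per_min must be >= 0")

    # -- resolved distribution parameters ---------------------------------
    def _measured_depth_weights(self) -> dict[int, float]:
        # complete cycles are measured at depths 1 .. max_depth-1 of a
        # (near-)complete binary tree: weights proportional to 2^k
        depths = list(range(1, max(self.max_depth, 2)))
        total = sum(2.0 ** k for k in depths)
        return {k: 2.0 ** k / total for k in depths}

    def gen_params(self, sorted_generation: int) -> GenParams:
        """Lognormal FAST-state parameters for a sorted generation (1/3/8)."""
        key = sorted_generation
        if key not in self._gen_params:
            if sorted_generation == 1:
                mean_h, sd_h = self.gen1_mean_h, self.gen1_sd_h
            else:  # generations 3 and 8 share the generation-3 targets
                mean_h, sd_h = self.gen3_mean_h, self.gen3_sd_h
            mean_min = mean_h * MIN_PER_H
            sd_min = sd_h * MIN_PER_H
            v1 = _calibrate(mean_min, sd_min, self.frac_drift, self._measured_depth_weights())
            self._gen_params[key] = GenParams(
                mean_min=mean_min,
                v1=v1,
                var_family=self.frac_family * v1,
                var_drift=self.frac_drift * v1,
                var_division=self.frac_division * v1,
                var_individual=self.frac_individual * v1,
            )
        return self._gen_params[key]

    @property
    def slow_mu_log(self) -> float:
        return math.log(self.slow_median_min)

    # -- serialization ----------------------------------------------------
    _TOML_SECTIONS = {
        "run": ("seed", "generation_offset", "n_founders"),
        "imaging": ("window_lo_min", "window_hi_min", "frame_lo_min", "frame_hi_min",
                    "max_depth", "activation_lag_min"),
        "distributions": ("gen1_mean_h", "gen1_sd_h", "gen3_mean_h", "gen3_sd_h",
                          "slow_median_min", "slow_sigma_log"),
        "heritability": ("frac_family", "frac_drift", "frac_division", "frac_individual"),
        "slow_state": ("g_onset", "p_on", "p_stay", "p_arrest"),
        "reporter": ("plateau_au", "ko_high_plateau_au", "rise_min", "decay_min",
                     "noise_cv", "dn_duration_min", "g1_frac_fast", "g1_frac_slow"),
        "ctv": ("ctv_founder_au", "ctv_cv", "ctv_floor_generation"),
        "brdu": ("f_s",),
        "death": ("death_hazard_per_min",),
    }

    def to_dict(self) -> dict:
        d = asdict(self)
        d.pop("_gen_params", None)
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def with_overrides(self, **kw) -> "SimulationConfig":
        return replace(self, _gen_params={}, **kw)

    @classmethod
    def from_dict(cls, data: dict) -> "SimulationConfig":
        flat: dict = {}
        for key, value in data.items():
            if isinstance(value, dict):
                flat.update(value)
            else:
                flat[key] = value
        known = {f for fields in cls._TOML_SECTIONS.values() for f in fields}
        unknown = set(flat) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**flat)


def load_config(path) -> SimulationConfig:
    with open(path, "rb") as fh:
        data = tomllib.load(fh)
    return SimulationConfig.from_dict(data)


def dump_toml(config: SimulationConfig) -> str:
    """Render a config as TOML text (sections as in the shipped default)."""
    lines = []
    for section, keys in SimulationConfig._TOML_SECTIONS.items():
        lines.append(f"[{section}]")
        for key in keys:
            value = getattr(config, key)
            if isinstance(value, bool):
                rendered = "true" if value else "false"
            elif isinstance(value, float):
                rendered = repr(value)
            else:
                rendered = str(value)
            lines.append(f"{key} = {rendered}")
        lines.append("")
    return "\n".join(lines)
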