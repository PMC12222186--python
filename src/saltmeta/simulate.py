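"""Synthetic study corpora with the structure the meta-analysis assumes.

The generator emulates a literature corpus: per experimental setting a number
of studies, each with a low-salinity control and one to a few saline
treatment levels, reporting study-mean values for a set of variables.  The
true dose-response of the relative value is a modified discount curve

    r(x) = 1 / (1 + (x / c50)^shape),

the standard sigmoidal salt-tolerance form: r(0) = 1, r(c50) = 0.5, strictly
decreasing.  Observed responses are the curve times multiplicative lognormal
noise; a small contamination fraction is multiplied (or divided) by a large
factor to create the gross outliers the Hampel filter targets.  Study counts
per setting are imbalanced by default, mirroring a literature dominated by
greenhouse experiments.

All randomness flows from a single seed through per-stage derived streams,
so identical configs give byte-identical corpora.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .io import (
    ObservationRecord,
    SalinityMeasure,
    SalinityUnit,
    Setting,
    Stage,
    Variable,
    VariableKey,
    EC_PER_MOLAR_NACL,
)

__all__ = [
    "SettingResponseParams",
    "SyntheticCorpusConfig",
    "FactorialConfig",
    "mean_response",
    "generate_corpus",
    "generate_factorial",
    "default_config",
    "null_config",
]


@dataclass(frozen=True)
class SettingResponseParams:
    """True dose-response and noise parameters of one setting."""

    setting: Setting
    c50: float  # dS/m at which the relative response halves
    shape: float = 2.0  # steepness of the discount curve
    sigma_noise: float = 0.2  # log-scale SD of multiplicative noise
    contamination_rate: float = 0.05
    contamination_scale: float = 4.0

    def __post_init__(self) -> None:
        if self.c50 <= 0 or self.shape <= 0:
            raise ValueError("c50 and shape must be positive")
        if not (0 <= self.contamination_rate < 0.5):
            raise ValueError("contamination_rate must be in [0, 0.5)")
        if self.sigma_noise < 0 or self.contamination_scale <= 0:
            raise ValueError("noise parameters must be non-negative")


#: Default study counts: imbalanced, greenhouse-heavy.  With an average of
#: two stress levels per study these reproduce a literature composition of
#: roughly 117 field : 77 outdoor-pot : 296 greenhouse : 49 climate-chamber
#: stress observations per variable.
DEFAULT_STUDIES_PER_SETTING = {
    Setting.FIELD: 58,
    Setting.OUTDOOR_POTS: 38,
    Setting.GREENHOUSE: 148,
    Setting.CLIMATE_CHAMBER: 25,
}

#: Default true c50 per setting (dS/m): field crops tolerate far more added
#: salinity than greenhouse pots before halving their response.
DEFAULT_C50 = {
    Setting.FIELD: 30.0,
    Setting.OUTDOOR_POTS: 20.0,
    Setting.GREENHOUSE: 12.0,
    Setting.CLIMATE_CHAMBER: 14.0,
}

DEFAULT_VARIABLES = (
    VariableKey(Variable.GRAIN_YIELD),
    VariableKey(Variable.SHOOT_DW, Stage.REPRODUCTIVE),
)


@dataclass(frozen=True)
class SyntheticCorpusConfig:
    """Full parameterization of a synthetic corpus."""

    params: dict[Setting, SettingResponseParams]
    studies_per_setting: dict[Setting, int]
    ec_range: tuple[float, float] = (4.0, 30.0)
    control_ec_range: tuple[float, float] = (0.0, 2.0)
    duration_range: tuple[float, float] = (14.0, 60.0)
    variables: tuple[VariableKey, ...] = DEFAULT_VARIABLES
    max_levels_per_study: int = 3
    baseline_log_mean: float = math.log(50.0)
    baseline_log_sd: float = 0.5
    molar_unit_every: int = 5  # every k-th study reports salinity in mM
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.params or not self.studies_per_setting:
            raise ValueError("config must cover at least one setting")
        lo, hi = self.ec_range
        if not (0 < lo < hi <= 60):
            raise ValueError("ec_range must satisfy 0 < lo < hi <= 60")
        if any(n < 1 for n in self.studies_per_setting.values()):
            raise ValueError("studies_per_setting must be >= 1 per setting")
        missing = set(self.studies_per_setting) - set(self.params)
        if missing:
            raise ValueError(f"no response params for settings {missing}")


def default_config(seed: int = 0, **overrides) -> SyntheticCorpusConfig:
    """The default study conditions: four settings with setting-specific
    c50, greenhouse-heavy study counts, 20% multiplicative noise and 5%
    outlier contamination."""
    params = {
        s: SettingResponseParams(s, c50=DEFAULT_C50[s])
        for s in Setting
    }
    cfg = SyntheticCorpusConfig(
        params=params,
        studies_per_setting=dict(DEFAULT_STUDIES_PER_SETTING),
        seed=seed,
    )
    return replace(cfg, **overrides) if overrides else cfg


def null_config(seed: int = 0, c50: float = 18.0, **overrides) -> SyntheticCorpusConfig:
    """A null-hypothesis corpus: all four settings share identical response
    parameters, so any detected setting difference is a false positive."""
    params = {s: SettingResponseParams(s, c50=c50) for s in Setting}
    cfg = SyntheticCorpusConfig(
        params=params,
        studies_per_setting=dict(DEFAULT_STUDIES_PER_SETTING),
        seed=seed,
    )
    return replace(cfg, **overrides) if overrides else cfg


def mean_response(axis_value: float, params: SettingResponseParams) -> float:
    """True relative response at a stress-axis value: the discount curve
    ``1 / (1 + (x/c50)^shape)``."""
    x = np.asarray(axis_value, dtype=float)
    if np.any(x < 0):
        raise ValueError("stress-axis value must be non-negative")
    r = 1.0 / (1.0 + (x / params.c50) ** params.shape)
    return float(r) if np.isscalar(axis_value) else r


def _stage_seed(base: int, tag: str) -> int:
    return (int(base) ^ zlib.crc32(tag.encode())) % (2**31 - 1)


def generate_corpus(config: SyntheticCorpusConfig) -> list[ObservationRecord]:
    """Draw a full synthetic corpus of observation records.

    Per study: a control EC near zero, 1..max_levels stress levels across
    ``ec_range`` (as relative EC added on top of the control), a per-study
    lognormal baseline per variable, and

        stress_value = control_value * r(axis) * exp(sigma * Z),

    where the axis is the relative EC, or relative EC x duration for
    vegetative-stage growth variables (whose effective c50 is scaled by the
    mean duration so the curve lives on the integral scale).  With
    probability ``contamination_rate`` the stress value is multiplied or
    divided by ``contamination_scale``.  Noise is independent per row, so
    the response ratio carries no study-level random effect.
    """
    records: list[ObservationRecord] = []
    mean_duration = float(np.mean(config.duration_range))
    for setting in sorted(config.studies_per_setting, key=lambda s: s.value):
        n_studies = config.studies_per_setting[setting]
        params = config.params[setting]
        rng = np.random.default_rng(
            _stage_seed(config.seed, f"corpus|{setting.value}")
        )
        for i in range(n_studies):
            study_id = f"{setting.value}-S{i + 1:03d}"
            control_ec = float(rng.uniform(*config.control_ec_range))
            n_levels = int(rng.integers(1, config.max_levels_per_study + 1))
            rel_ecs = np.sort(rng.uniform(*config.ec_range, size=n_levels))
            duration = float(rng.uniform(*config.duration_range))
            in_molar = (
                config.molar_unit_every > 0
                and i % config.molar_unit_every == config.molar_unit_every - 1
            )
            for var in config.variables:
                control_value = float(
                    rng.lognormal(config.baseline_log_mean, config.baseline_log_sd)
                )
                vegetative = var.is_growth and var.stage is Stage.VEGETATIVE
                for level, rel_ec in enumerate(rel_ecs, start=1):
                    if vegetative:
                        axis = rel_ec * duration
                        eff = replace(params, c50=params.c50 * mean_duration)
                    else:
                        axis = rel_ec
                        eff = params
                    noise = float(rng.lognormal(0.0, params.sigma_noise))
                    value = control_value * mean_response(axis, eff) * noise
                    if rng.random() < params.contamination_rate:
                        sign = 1.0 if rng.random() < 0.5 else -1.0
                        value *= params.contamination_scale**sign
                    stress_ec = control_ec + float(rel_ec)
                    if in_molar:
                        control_sal = SalinityMeasure(
                            control_ec / EC_PER_MOLAR_NACL,
                            SalinityUnit.MOL_PER_L_NACL,
                        )
                        stress_sal = SalinityMeasure(
                            stress_ec / EC_PER_MOLAR_NACL,
                            SalinityUnit.MOL_PER_L_NACL,
                        )
                    else:
                        control_sal = SalinityMeasure(
                            control_ec, SalinityUnit.DS_PER_M
                        )
                        stress_sal = SalinityMeasure(
                            stress_ec, SalinityUnit.DS_PER_M
                        )
                    records.append(
                        ObservationRecord(
                            study_id=study_id,
                            experiment_id="E1",
                            setting=setting,
                            variable=var,
                            control_salinity=control_sal,
                            stress_salinity=stress_sal,
                            control_value=control_value,
                            stress_value=value,
                            stress_duration_days=(
                                duration if vegetative else None
                            ),
                        )
                    )
    return records


@dataclass(frozen=True)
class FactorialConfig:
    """Parameterization of a synthetic factorial (stress x setting)
    experiment in long format."""

    baseline: float = 100.0
    stress_effect: float = 0.6  # multiplier on the response under salt
    setting_effects: dict[Setting, float] = field(
        default_factory=lambda: {s: 1.0 for s in Setting}
    )
    interaction_effects: dict[Setting, float] = field(
        default_factory=dict
    )  # extra multiplier on salt cells of a setting
    noise: str = "gaussian"  # gaussian | lognormal | t
    sigma: float = 0.1  # noise scale relative to baseline
    t_df: float = 2.0
    reps_per_cell: int = 6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise not in ("gaussian", "lognormal", "t"):
            raise ValueError("noise must be gaussian, lognormal or t")
        if self.reps_per_cell < 1 or self.baseline <= 0 or self.sigma < 0:
            raise ValueError("invalid factorial config")


def generate_factorial(config: FactorialConfig) -> pd.DataFrame:
    """Long-format (value, stress, setting) table for the factorial tests.

    Cell means are baseline x stress effect x setting effect x an optional
    interaction multiplier on the salt cells of chosen settings; gaussian
    noise is additive and homoscedastic, lognormal and t noise are
    multiplicative around the cell mean.
    """
    rng = np.random.default_rng(_stage_seed(config.seed, "factorial"))
    rows = []
    for setting in sorted(config.setting_effects, key=lambda s: s.value):
        for stress in ("control", "salt"):
            mu = config.baseline * config.setting_effects[setting]
            if stress == "salt":
                mu *= config.stress_effect
                mu *= config.interaction_effects.get(setting, 1.0)
            for _ in range(config.reps_per_cell):
                if config.noise == "gaussian":
                    value = mu + config.baseline * config.sigma * rng.standard_normal()
                elif config.noise == "lognormal":
                    value = mu * math.exp(config.sigma * rng.standard_normal())
                else:
                    value = mu + config.baseline * config.sigma * rng.standard_t(
                        config.t_df
                    )
                rows.append(
                    {
                        "value": value,
                        "stress": stress,
                        "setting": setting.value,
                    }
                )
    return pd.DataFrame(rows, columns=["value", "stress", "setting"])
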