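"""Seeded synthetic home-cage cohorts with circadian structure.

The generator emulates the statistical shape of an HCA (home cage automated
monitoring) study of a murine controlled-cortical-impact model: a naive
baseline group recorded for one week and injured / sham-craniotomy groups
recorded weekly after intervention. Each behavioural channel follows a
cosinor (cosine circadian) model

    x(t) = mesor + amplitude * cos(2*pi * (t - acrophase) / period)

plus channel noise. Injury is modelled as per-group, per-week multiplicative
factors on amplitude and mesor: injured animals show a strongly blunted
circadian rhythm and depressed activity in week 1 with gradual partial
recovery; sham animals show a milder, faster-recovering effect.

All randomness is driven by a single integer seed, so equal configurations
produce bitwise-identical cohorts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import yaml

from .records import CHANNELS, GROUPS, SAMPLE_INTERVAL_MIN, AnimalRecord

MINUTES_PER_DAY = 1440.0


@dataclass(frozen=True)
class CircadianParams:
    """Cosinor parameters of one behavioural channel.

    mesor
        Rhythm-adjusted mean (channel units).
    amplitude
        Half peak-to-trough range (channel units), >= 0.
    acrophase_min
        Time of peak, minutes since session start.
    period_min
        Rhythm period in minutes (default one day).
    """

    mesor: float
    amplitude: float
    acrophase_min: float
    period_min: float = MINUTES_PER_DAY

    def __post_init__(self) -> None:
        if self.period_min <= 0:
            raise ValueError("period must be positive")
        if self.amplitude < 0:
            raise ValueError("amplitude must be non-negative")


@dataclass(frozen=True)
class InjuryEffect:
    """Week-indexed multiplicative factors applied to one channel.

    ``amplitude[w-1]`` and ``mesor[w-1]`` scale the corresponding cosinor
    parameter in week ``w``; weeks beyond the listed schedule reuse the last
    factor (a plateau of the recovery trajectory).
    """

    amplitude: tuple[float, ...]
    mesor: tuple[float, ...]

    def __post_init__(self) -> None:
        for seq in (self.amplitude, self.mesor):
            if not seq:
                raise ValueError("factor schedule must be non-empty")
            if any(not 0.0 <= f <= 2.0 for f in seq):
                raise ValueError("effect factors must lie in [0, 2]")
            if any(b < a for a, b in zip(seq, seq[1:])):
                raise ValueError("effect factors must be non-decreasing (recovery)")

    def for_week(self, week: int) -> tuple[float, float]:
        i = min(week, len(self.amplitude)) - 1
        j = min(week, len(self.mesor)) - 1
        return self.amplitude[i], self.mesor[j]


@dataclass
class SyntheticConfig:
    """Full description of a synthetic cohort."""

    group_sizes: dict[str, int]
    weeks: dict[str, tuple[int, ...]]
    circadian: dict[str, CircadianParams]
    injury_effects: dict[str, dict[str, InjuryEffect]]
    noise_sd: dict[str, float]
    samples_per_week: int = 290
    sample_interval_min: float = SAMPLE_INTERVAL_MIN
    seed: int = 0

    def __post_init__(self) -> None:
        for group, n in self.group_sizes.items():
            if group not in GROUPS:
                raise ValueError(f"unknown group {group!r}")
            if n < 1:
                raise ValueError(f"group {group!r} must have >= 1 animal")
            if group not in self.weeks or not self.weeks[group]:
                raise ValueError(f"group {group!r} has no weeks configured")
        if self.samples_per_week < 1:
            raise ValueError("samples_per_week must be >= 1")
        if set(self.circadian) != set(CHANNELS):
            raise ValueError(f"circadian params required for all channels {CHANNELS}")
        for channel, sd in self.noise_sd.items():
            if sd < 0:
                raise ValueError(f"noise_sd for {channel!r} must be >= 0")


def circadian_signal(
    t: np.ndarray | float,
    mesor: float,
    amplitude: float,
    acrophase: float,
    period: float = MINUTES_PER_DAY,
) -> np.ndarray | float:
    """Evaluate the cosinor model at time ``t`` (minutes).

    Returns ``mesor + amplitude * cos(2*pi*(t - acrophase)/period)``.
    """
    if period <= 0:
        raise ValueError("period must be positive")
    if amplitude < 0:
        raise ValueError("amplitude must be non-negative")
    return mesor + amplitude * np.cos(2.0 * math.pi * (np.asarray(t) - acrophase) / period)


def apply_injury_effect(
    base: dict[str, CircadianParams],
    group: str,
    week: int,
    effects: dict[str, dict[str, InjuryEffect]],
) -> dict[str, CircadianParams]:
    """Scale per-channel cosinor parameters by the group/week injury factors.

    Naive parameters are returned unchanged; injured and sham channels have
    amplitude and mesor multiplied by the configured week factors.
    """
    if group not in GROUPS:
        raise ValueError(f"unknown group {group!r}; expected one of {GROUPS}")
    if group == "naive" or group not in effects:
        return dict(base)
    out: dict[str, CircadianParams] = {}
    for channel, params in base.items():
        effect = effects[group].get(channel)
        if effect is None:
            out[channel] = params
            continue
        amp_f, mesor_f = effect.for_week(week)
        out[channel] = replace(
            params, amplitude=params.amplitude * amp_f, mesor=params.mesor * mesor_f
        )
    return out


def generate_cohort(config: SyntheticConfig) -> list[AnimalRecord]:
    """Generate one :class:`AnimalRecord` per (animal, week) in the config.

    Continuous channels are cosinor signal + Gaussian noise (distance and
    separation clipped at zero; temperature clipped to the physiological
    range 30–42 °C, which the parameter defaults never reach in practice).
    Transitions are Poisson counts with the cosinor as rate, or the rounded
    rate when that channel's noise is disabled.
    """
    rng = np.random.default_rng(config.seed)
    t = np.arange(config.samples_per_week, dtype=float) * config.sample_interval_min
    records: list[AnimalRecord] = []
    for group in GROUPS:
        if group not in config.group_sizes:
            continue
        for animal_idx in range(config.group_sizes[group]):
            animal_id = f"{group}_{animal_idx + 1:02d}"
            for week in config.weeks[group]:
                params = apply_injury_effect(
                    config.circadian, group, week, config.injury_effects
                )
                values = np.empty((config.samples_per_week, len(CHANNELS)))
                for ci, channel in enumerate(CHANNELS):
                    p = params[channel]
                    signal = circadian_signal(
                        t, p.mesor, p.amplitude, p.acrophase_min, p.period_min
                    )
                    sd = config.noise_sd.get(channel, 0.0)
                    if channel == "transitions":
                        rate = np.clip(signal, 0.0, None)
                        if sd > 0:
                            values[:, ci] = rng.poisson(rate).astype(float)
                        else:
                            values[:, ci] = np.rint(rate)
                    else:
                        x = signal + (rng.normal(0.0, sd, signal.shape) if sd > 0 else 0.0)
                        if channel in ("distance_mm", "separation_mm"):
                            x = np.clip(x, 0.0, None)
                        elif channel == "temperature_c":
                            x = np.clip(x, 30.0, 42.0)
                        values[:, ci] = x
                records.append(
                    AnimalRecord(
                        animal_id=animal_id,
                        group=group,
                        week=week,
                        timestamps=t.copy(),
                        values=values,
                    )
                )
    return records


# ---------------------------------------------------------------------------
# Default study conditions
# ---------------------------------------------------------------------------

_DEFAULT_CIRCADIAN = {
    "distance_mm": CircadianParams(mesor=8000.0, amplitude=5000.0, acrophase_min=780.0),
    "temperature_c": CircadianParams(mesor=36.8, amplitude=1.0, acrophase_min=780.0),
    "separation_mm": CircadianParams(mesor=150.0, amplitude=60.0, acrophase_min=780.0),
    "transitions": CircadianParams(mesor=30.0, amplitude=18.0, acrophase_min=780.0),
}

# Noise: 10% of mesor for the activity-scale channels; a physiological
# 0.2 degC for body temperature; transitions carry Poisson noise (the value
# acts as an on/off switch for that channel).
_DEFAULT_NOISE = {
    "distance_mm": 800.0,
    "temperature_c": 0.2,
    "separation_mm": 15.0,
    "transitions": 1.0,
}

# Injury trajectories over weeks 1..5. Injured: strong week-1 blunting
# (amplitude x0.3, mesor x0.5) with partial recovery; sham: milder transient
# craniotomy effect. Factors are non-decreasing (recovery) and the injured
# week-1 amplitude factor is below the sham one.
_INJURED_ACTIVITY = InjuryEffect(
    amplitude=(0.30, 0.45, 0.60, 0.70, 0.80), mesor=(0.50, 0.60, 0.70, 0.80, 0.85)
)
_SHAM_ACTIVITY = InjuryEffect(
    amplitude=(0.70, 0.80, 0.85, 0.90, 0.95), mesor=(0.85, 0.90, 0.92, 0.94, 0.96)
)
_DEFAULT_EFFECTS = {
    "injured": {
        "distance_mm": _INJURED_ACTIVITY,
        "separation_mm": _INJURED_ACTIVITY,
        "transitions": _INJURED_ACTIVITY,
        "temperature_c": InjuryEffect(
            amplitude=(0.30, 0.45, 0.60, 0.70, 0.80),
            mesor=(0.99, 0.995, 1.0, 1.0, 1.0),
        ),
    },
    "sham": {
        "distance_mm": _SHAM_ACTIVITY,
        "separation_mm": _SHAM_ACTIVITY,
        "transitions": _SHAM_ACTIVITY,
        "temperature_c": InjuryEffect(
            amplitude=(0.70, 0.80, 0.85, 0.90, 0.95),
            mesor=(1.0, 1.0, 1.0, 1.0, 1.0),
        ),
    },
}


def default_config(seed: int = 0) -> SyntheticConfig:
    """Default cohort: 4 naive x 1 week, 6 injured x 5 weeks, 6 sham x 5 weeks.

    64 animal-week records of 290 samples each; 384 observations after
    6-binning.
    """
    return SyntheticConfig(
        group_sizes={"naive": 4, "injured": 6, "sham": 6},
        weeks={
            "naive": (1,),
            "injured": (1, 2, 3, 4, 5),
            "sham": (1, 2, 3, 4, 5),
        },
        circadian=dict(_DEFAULT_CIRCADIAN),
        injury_effects={g: dict(e) for g, e in _DEFAULT_EFFECTS.items()},
        noise_sd=dict(_DEFAULT_NOISE),
        seed=seed,
    )


def study_shape_config(seed: int = 0) -> SyntheticConfig:
    """Cohort matching the published dataset's class structure.

    16 naive, 54 injured and 48 sham animal-weeks, which after 6-binning
    give 96 / 324 / 288 observations (708 in total).
    """
    cfg = default_config(seed)
    cfg.group_sizes = {"naive": 16, "injured": 9, "sham": 8}
    cfg.weeks = {"naive": (1,), "injured": tuple(range(1, 7)), "sham": tuple(range(1, 7))}
    return cfg


# ---------------------------------------------------------------------------
# Plain-text config file support
# ---------------------------------------------------------------------------

def load_config(path: str) -> SyntheticConfig:
    """Load a :class:`SyntheticConfig` from a YAML file.

    Only keys that override the defaults need to be present; ``seed``,
    ``group_sizes``, ``weeks``, ``samples_per_week``, ``noise_sd``,
    ``circadian`` and ``injury_effects`` are recognised.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    cfg = default_config(int(raw.get("seed", 0)))
    if "group_sizes" in raw:
        cfg.group_sizes = {str(k): int(v) for k, v in raw["group_sizes"].items()}
    if "weeks" in raw:
        cfg.weeks = {str(k): tuple(int(w) for w in v) for k, v in raw["weeks"].items()}
    if "samples_per_week" in raw:
        cfg.samples_per_week = int(raw["samples_per_week"])
    if "noise_sd" in raw:
        cfg.noise_sd.update({str(k): float(v) for k, v in raw["noise_sd"].items()})
    if "circadian" in raw:
        for channel, kv in raw["circadian"].items():
            cfg.circadian[str(channel)] = CircadianParams(**{k: float(v) for k, v in kv.items()})
    if "injury_effects" in raw:
        for group, per_channel in raw["injury_effects"].items():
            cfg.injury_effects.setdefault(str(group), {})
            for channel, kv in per_channel.items():
                cfg.injury_effects[str(group)][str(channel)] = InjuryEffect(
                    amplitude=tuple(float(f) for f in kv["amplitude"]),
                    mesor=tuple(float(f) for f in kv["mesor"]),
                )
    cfg.__post_init__()
    return cfg
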