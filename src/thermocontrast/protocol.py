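"""Thermal stimulation protocol for the offset-analgesia / onset-hyperalgesia paradigm.

The paradigm delivers a three-phase contact-heat stimulus: a ramp from a
non-painful baseline (38 °C) to an individually calibrated plateau (the T1
temperature, producing about NRS 5), a brief temperature excursion of ±1 or
±2 °C (T2, 6.5–12 s), a return to the T1 plateau (T3, 12–33 s), and finally a
ramp back to baseline.  Offset-analgesia (OA) conditions step the temperature
*up* during T2 and back down; onset-hyperalgesia (OH) conditions step *down*
and back up; the control condition holds the plateau constant.  All ramps run
at a fixed rate of 5 °C/s.

This module builds the commanded temperature time courses for the five
conditions and the per-participant randomized session schedule.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CONDITION_NAMES",
    "ConditionSpec",
    "ProtocolConstants",
    "TemperatureTrace",
    "SessionSchedule",
    "make_condition_spec",
    "build_temperature_trace",
    "build_session_schedule",
]

#: Signed T2 temperature change (°C) for each condition.
_CONDITION_DELTAS: dict[str, float] = {
    "control": 0.0,
    "OA1": 1.0,
    "OA2": 2.0,
    "OH1": -1.0,
    "OH2": -2.0,
}

CONDITION_NAMES: tuple[str, ...] = tuple(_CONDITION_DELTAS)


@dataclass(frozen=True)
class ConditionSpec:
    """One of the five stimulation conditions.

    ``delta_t`` is the signed temperature change (°C) applied during T2,
    relative to the calibrated T1 plateau: positive for OA (brief increase,
    then offset back down), negative for OH (brief decrease, then onset back
    up), zero for the constant-temperature control.
    """

    name: str
    delta_t: float

    def __post_init__(self) -> None:
        expected = _CONDITION_DELTAS.get(self.name)
        if expected is None:
            raise ValueError(
                f"unknown condition {self.name!r}; expected one of {CONDITION_NAMES}"
            )
        if self.delta_t != expected:
            raise ValueError(
                f"condition {self.name!r} requires delta_t={expected:+g}, "
                f"got {self.delta_t:+g}"
            )


def make_condition_spec(name: str) -> ConditionSpec:
    """Return the :class:`ConditionSpec` for a condition name.

    Raises ``ValueError`` for unknown names.
    """
    if name not in _CONDITION_DELTAS:
        raise ValueError(
            f"unknown condition {name!r}; expected one of {CONDITION_NAMES}"
        )
    return ConditionSpec(name=name, delta_t=_CONDITION_DELTAS[name])


@dataclass(frozen=True)
class ProtocolConstants:
    """Fixed protocol timings and temperatures.

    Units: temperatures in °C, times in seconds, ramp_rate in °C/s.
    Phase boundaries are the nominal values 6.5 / 12 / 33 s, with each ramp
    occurring inside the destination phase.
    """

    baseline_temp: float = 38.0
    ramp_rate: float = 5.0
    t2_start: float = 6.5
    t3_start: float = 12.0
    stim_end: float = 33.0
    post_record: float = 10.0
    iti: float = 50.0
    nrs_min: float = 0.0
    nrs_max: float = 10.0

    def __post_init__(self) -> None:
        if not (0.0 < self.t2_start < self.t3_start < self.stim_end):
            raise ValueError("phase boundaries must satisfy 0 < t2_start < t3_start < stim_end")
        if self.ramp_rate <= 0:
            raise ValueError("ramp_rate must be positive")


@dataclass
class TemperatureTrace:
    """Commanded thermode temperature sampled on a uniform time grid."""

    times: np.ndarray
    temps: np.ndarray
    condition: str
    t1_temp: float

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.temps = np.asarray(self.temps, dtype=float)
        if self.times.shape != self.temps.shape:
            raise ValueError("times and temps must have equal length")

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0])

    def to_frame(self, trial_id: int = 0) -> pd.DataFrame:
        """Long-format representation (trial_id, condition, time_s, temperature_c)."""
        return pd.DataFrame(
            {
                "trial_id": trial_id,
                "condition": self.condition,
                "time_s": self.times,
                "temperature_c": self.temps,
            }
        )


def build_temperature_trace(
    spec: ConditionSpec,
    t1_temp: float,
    constants: ProtocolConstants | None = None,
    sample_rate: float = 10.0,
) -> TemperatureTrace:
    """Construct the commanded temperature time course for one trial.

    The trace ramps from baseline to ``t1_temp`` at ``ramp_rate`` starting at
    t = 0, holds until ``t2_start``, ramps to ``t1_temp + delta_t``, holds
    until ``t3_start``, ramps back to ``t1_temp``, holds until ``stim_end``,
    then ramps down to baseline and records ``post_record`` further seconds
    at baseline.

    Parameters
    ----------
    spec : condition to build (determines the signed T2 excursion).
    t1_temp : calibrated plateau temperature, °C; must exceed baseline and
        not exceed 50 °C.
    sample_rate : sampling frequency in Hz; the sampling interval must
        resolve the shortest ramp of the trace.
    """
    c = constants if constants is not None else ProtocolConstants()
    if not (c.baseline_temp < t1_temp <= 50.0):
        raise ValueError(
            f"t1_temp must lie in ({c.baseline_temp}, 50] °C, got {t1_temp}"
        )
    if sample_rate <= 0:
        raise ValueError("sample_rate must be positive")

    dt = 1.0 / sample_rate
    rise = (t1_temp - c.baseline_temp) / c.ramp_rate
    step = abs(spec.delta_t) / c.ramp_rate

    ramps = [rise] + ([step] if spec.delta_t != 0.0 else [])
    if dt > min(ramps):
        raise ValueError(
            f"sampling interval {dt:g} s cannot resolve the shortest ramp "
            f"({min(ramps):g} s); increase sample_rate"
        )

    t2_temp = t1_temp + spec.delta_t
    # Piecewise-linear knots; every segment slope is 0 or ±ramp_rate.
    knot_t = np.array(
        [
            0.0,
            rise,
            c.t2_start,
            c.t2_start + step,
            c.t3_start,
            c.t3_start + step,
            c.stim_end,
            c.stim_end + rise,
        ]
    )
    knot_temp = np.array(
        [
            c.baseline_temp,
            t1_temp,
            t1_temp,
            t2_temp,
            t2_temp,
            t1_temp,
            t1_temp,
            c.baseline_temp,
        ]
    )
    end = c.stim_end + rise + c.post_record
    n = int(round(end * sample_rate)) + 1
    times = np.arange(n) * dt
    temps = np.interp(times, knot_t, knot_temp)
    return TemperatureTrace(times=times, temps=temps, condition=spec.name, t1_temp=t1_temp)


@dataclass
class SessionSchedule:
    """Randomized order of the five conditions for one participant.

    Each trial is followed by an inter-trial baseline interval of ``iti``
    seconds at the baseline temperature.
    """

    conditions: list[ConditionSpec]
    iti: float
    seed: int

    def __len__(self) -> int:
        return len(self.conditions)


def build_session_schedule(
    subject_seed: int, constants: ProtocolConstants | None = None
) -> SessionSchedule:
    """Draw a uniformly random permutation of the five conditions.

    Reproducible from ``subject_seed``; every condition appears exactly once.
    """
    c = constants if constants is not None else ProtocolConstants()
    rng = np.random.default_rng(subject_seed)
    order = rng.permutation(len(CONDITION_NAMES))
    conditions = [make_condition_spec(CONDITION_NAMES[i]) for i in order]
    return SessionSchedule(conditions=conditions, iti=c.iti, seed=int(subject_seed))
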