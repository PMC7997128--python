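"""Synthetic participants for the offset-analgesia / onset-hyperalgesia paradigm.

No raw continuous-rating data accompany the study design this package
implements, so this module generates rating traces with the statistical
structure the downstream analysis assumes: individually calibrated plateau
temperatures (population mean 47.1 °C, SD 1.4 °C), lagged perception of the
commanded temperature, condition-dependent hypo-/hyperalgesic modulation
that scales with the stimulus range, between-subject heterogeneity (and
correlation) of the modulation gains, smooth additive rating noise, and an
optional sex effect on the hyperalgesia gain.

The latent response model for a subject is

    rating(t) = clip( 5 + k · (T_eff(t) − t50) + m(t) + ε(t), 0, 10 )

where ``T_eff`` is a first-order low-pass filter of the commanded
temperature (time constant ``lag_tau``), ``m(t)`` is the modulation evoked
by the T2→T3 return step — rising with time constant ``mod_tau`` to
``−gain_oa·|ΔT|`` after a downward return step (OA) or ``+gain_oh·|ΔT|``
after an upward one (OH), zero for control — and ``ε`` is white Gaussian
noise smoothed by the same low-pass filter, scaled to standard deviation
``noise_sd``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields as dc_fields

import numpy as np
import pandas as pd

from .calibration import ResponseOracle, calibrate_subject
from .protocol import (
    ConditionSpec,
    ProtocolConstants,
    TemperatureTrace,
    build_session_schedule,
    build_temperature_trace,
)

__all__ = [
    "SubjectParams",
    "PopulationConfig",
    "RatingTrace",
    "sample_population",
    "effective_temperature",
    "simulate_rating_trace",
    "make_response_oracle",
    "simulate_experiment",
    "simulate_window_means",
]

NRS_MID = 5.0


@dataclass
class SubjectParams:
    """Latent psychophysical parameters of one simulated participant.

    t50 : °C producing a latent pain of NRS 5.
    slope_k : NRS per °C of the static temperature→pain transduction.
    lag_tau : s, time constant of perceived (effective) temperature.
    mod_tau : s, rise time of the post-return-step modulation.
    gain_oa : NRS of extra hypoalgesia per °C of downward return step;
        may be negative for subjects with reversed responses.
    gain_oh : NRS of extra hyperalgesia per °C of upward return step.
    noise_sd : NRS, standard deviation of the smoothed rating noise.
    decay_tau : s, optional decay of the modulation after the return step;
        ``None`` means the modulation is sustained through T3.
    """

    t50: float = 47.1
    slope_k: float = 1.0
    lag_tau: float = 1.0
    mod_tau: float = 2.0
    gain_oa: float = 0.75
    gain_oh: float = 0.4
    noise_sd: float = 0.5
    sex: str = "F"
    decay_tau: float | None = None

    def __post_init__(self) -> None:
        if self.slope_k <= 0:
            raise ValueError("slope_k must be positive")
        if self.lag_tau < 0 or self.mod_tau < 0:
            raise ValueError("time constants must be non-negative")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.sex not in ("F", "M", "unreported"):
            raise ValueError("sex must be 'F', 'M' or 'unreported'")


@dataclass
class PopulationConfig:
    """Population distribution of :class:`SubjectParams` plus design shape.

    Gains are drawn jointly bivariate-normal with correlation
    ``gain_correlation_rho``; female subjects receive an additive shift
    ``sex_effect_oh`` on ``gain_oh``.  ``n_unreported_sex`` subjects carry no
    sex label and are excluded from sex comparisons downstream.
    """

    n_subjects: int = 21
    proportion_female: float = 1.0
    n_unreported_sex: int = 0
    t50_mean: float = 47.1
    t50_sd: float = 1.4
    slope_mean: float = 1.0
    slope_sd: float = 0.15
    lag_tau_mean: float = 1.0
    lag_tau_sd: float = 0.2
    mod_tau_mean: float = 2.0
    mod_tau_sd: float = 0.3
    gain_oa_mean: float = 0.75
    gain_oa_sd: float = 0.5
    gain_oh_mean: float = 0.4
    gain_oh_sd: float = 0.5
    gain_correlation_rho: float = 0.27
    sex_effect_oh: float = 0.3
    # rating noise is a measurement property, kept homogeneous by default:
    # subject-level noise heterogeneity biases the extremum-based subtracted
    # effects of both paradigms together and would induce spurious
    # offset-onset correlation
    noise_sd_mean: float = 0.5
    noise_sd_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not -1.0 <= self.gain_correlation_rho <= 1.0:
            raise ValueError("gain_correlation_rho must lie in [-1, 1]")
        for f in dc_fields(self):
            if f.name.endswith("_sd") and getattr(self, f.name) < 0:
                raise ValueError(f"{f.name} must be non-negative")
        if not 0.0 <= self.proportion_female <= 1.0:
            raise ValueError("proportion_female must lie in [0, 1]")
        if not 0 <= self.n_unreported_sex <= self.n_subjects:
            raise ValueError("n_unreported_sex must lie in [0, n_subjects]")


@dataclass
class RatingTrace:
    """Continuous 0–10 NRS rating time series on the stimulus time grid."""

    times: np.ndarray
    ratings: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.ratings = np.asarray(self.ratings, dtype=float)
        if self.times.shape != self.ratings.shape:
            raise ValueError("times and ratings must have equal length")


def _assign_sexes(config: PopulationConfig) -> list[str]:
    n_rep = config.n_subjects - config.n_unreported_sex
    n_f = int(round(config.proportion_female * n_rep))
    return ["F"] * n_f + ["M"] * (n_rep - n_f) + ["unreported"] * config.n_unreported_sex


def sample_population(
    config: PopulationConfig, rng: np.random.Generator | None = None
) -> list[SubjectParams]:
    """Draw a cohort of subjects; reproducible from ``config.seed``.

    Positive-by-nature parameters (transduction slope, time constants,
    noise SD) are truncated at small positive floors; the modulation gains
    are unconstrained in sign.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n = config.n_subjects
    cov = np.array(
        [
            [config.gain_oa_sd**2,
             config.gain_correlation_rho * config.gain_oa_sd * config.gain_oh_sd],
            [config.gain_correlation_rho * config.gain_oa_sd * config.gain_oh_sd,
             config.gain_oh_sd**2],
        ]
    )
    gains = rng.multivariate_normal(
        [config.gain_oa_mean, config.gain_oh_mean], cov, size=n,
        check_valid="ignore", method="svd",
    )
    t50 = rng.normal(config.t50_mean, config.t50_sd, n)
    slope = np.clip(rng.normal(config.slope_mean, config.slope_sd, n), 0.05, None)
    lag = np.clip(rng.normal(config.lag_tau_mean, config.lag_tau_sd, n), 0.05, None)
    mod = np.clip(rng.normal(config.mod_tau_mean, config.mod_tau_sd, n), 0.05, None)
    noise = np.clip(rng.normal(config.noise_sd_mean, config.noise_sd_sd, n), 0.0, None)
    sexes = _assign_sexes(config)
    subjects = []
    for i in range(n):
        g_oh = gains[i, 1] + (config.sex_effect_oh if sexes[i] == "F" else 0.0)
        subjects.append(
            SubjectParams(
                t50=float(t50[i]),
                slope_k=float(slope[i]),
                lag_tau=float(lag[i]),
                mod_tau=float(mod[i]),
                gain_oa=float(gains[i, 0]),
                gain_oh=float(g_oh),
                noise_sd=float(noise[i]),
                sex=sexes[i],
            )
        )
    return subjects


def _lowpass(x: np.ndarray, tau: float, dt: float) -> np.ndarray:
    """Exact zero-order-hold discretization of dy/dt = (x − y)/tau, y(0)=x(0)."""
    if tau < dt:
        return x.copy()
    a = np.exp(-dt / tau)
    from scipy.signal import lfilter

    return x[0] + lfilter([0.0, 1.0 - a], [1.0, -a], x - x[0])


def effective_temperature(trace: TemperatureTrace, lag_tau: float) -> TemperatureTrace:
    """Perceived temperature: first-order low-pass of the commanded trace.

    Models the delayed perception of contact heat.  Time constants shorter
    than one sampling interval pass the input through unchanged.  Requires a
    uniform time grid.
    """
    dts = np.diff(trace.times)
    if dts.size and not np.allclose(dts, dts[0], rtol=0, atol=1e-9):
        raise ValueError("effective_temperature requires a uniform time grid")
    temps = _lowpass(trace.temps, lag_tau, trace.dt)
    return TemperatureTrace(
        times=trace.times.copy(), temps=temps,
        condition=trace.condition, t1_temp=trace.t1_temp,
    )


def _modulation(
    times: np.ndarray, spec: ConditionSpec, subject: SubjectParams, t_onset: float
) -> np.ndarray:
    if spec.delta_t == 0.0:
        return np.zeros_like(times)
    magnitude = abs(spec.delta_t)
    level = -subject.gain_oa * magnitude if spec.delta_t > 0 else subject.gain_oh * magnitude
    rel = np.clip(times - t_onset, 0.0, None)
    active = times >= t_onset
    if subject.mod_tau <= 0:
        m = np.where(active, level, 0.0)
    else:
        m = np.where(active, level * (1.0 - np.exp(-rel / subject.mod_tau)), 0.0)
    if subject.decay_tau is not None:
        m = m * np.where(active, np.exp(-rel / subject.decay_tau), 1.0)
    return m


def _smoothed_noise(
    n: int, noise_sd: float, tau: float, dt: float, rng: np.random.Generator
) -> np.ndarray:
    """White noise low-pass filtered, rescaled so the stationary SD is noise_sd."""
    if noise_sd == 0.0:
        return np.zeros(n)
    if tau < dt:
        return rng.normal(0.0, noise_sd, n)
    a = np.exp(-dt / tau)
    # stationary var of y[i] = a·y[i-1] + (1-a)·x[i-1] is (1-a)/(1+a)·var(x)
    sigma_x = noise_sd * np.sqrt((1.0 + a) / (1.0 - a))
    white = rng.normal(0.0, sigma_x, n)
    return _lowpass(white, tau, dt)


def simulate_rating_trace(
    temp_trace: TemperatureTrace,
    spec: ConditionSpec,
    subject: SubjectParams,
    rng: np.random.Generator | None = None,
    constants: ProtocolConstants | None = None,
) -> RatingTrace:
    """Simulate one continuous rating trace for a subject and condition."""
    if temp_trace.condition != spec.name:
        raise ValueError(
            f"temperature trace was built for {temp_trace.condition!r}, "
            f"not {spec.name!r}"
        )
    c = constants if constants is not None else ProtocolConstants()
    if rng is None:
        rng = np.random.default_rng()
    t_eff = _lowpass(temp_trace.temps, subject.lag_tau, temp_trace.dt)
    latent = NRS_MID + subject.slope_k * (t_eff - subject.t50)
    latent += _modulation(temp_trace.times, spec, subject, c.t3_start)
    latent += _smoothed_noise(
        temp_trace.times.size, subject.noise_sd, subject.lag_tau, temp_trace.dt, rng
    )
    return RatingTrace(
        times=temp_trace.times.copy(),
        ratings=np.clip(latent, c.nrs_min, c.nrs_max),
    )


def make_response_oracle(subject: SubjectParams) -> ResponseOracle:
    """Noise-free steady-state response used for the calibration loop.

    Calibration stimuli (≥5 s) are long relative to the perceptual lag, so
    the peak rating is taken at the static transduction fixed point.
    """

    def oracle(temp_c: float, duration_s: float) -> float:
        return float(
            np.clip(NRS_MID + subject.slope_k * (temp_c - subject.t50), 0.0, 10.0)
        )

    return oracle


def simulate_experiment(
    config: PopulationConfig,
    constants: ProtocolConstants | None = None,
    sample_rate: float = 10.0,
) -> pd.DataFrame:
    """Simulate a full experiment: calibration, randomized order, one trial
    per condition per subject.

    Returns a long-format DataFrame with columns ``subject_id``, ``sex``,
    ``condition``, ``time_s``, ``temperature_c``, ``rating_nrs`` and
    ``t1_temp_c``; fully reproducible from ``config.seed``.
    """
    c = constants if constants is not None else ProtocolConstants()
    root = np.random.SeedSequence(config.seed)
    pop_seq, *subj_seqs = root.spawn(1 + config.n_subjects)
    subjects = sample_population(config, rng=np.random.default_rng(pop_seq))

    cols: dict[str, list] = {k: [] for k in (
        "subject_id", "sex", "condition", "time_s", "temperature_c",
        "rating_nrs", "t1_temp_c",
    )}
    for i, (subject, seq) in enumerate(zip(subjects, subj_seqs)):
        rng = np.random.default_rng(seq)
        outcome = calibrate_subject(make_response_oracle(subject))
        if outcome.success:
            t1 = outcome.t1_temp
        else:
            # rare extreme subject: keep the last attempted (clamped) temperature
            t1 = outcome.history[-1][0] if outcome.history else 47.1
        schedule = build_session_schedule(int(rng.integers(2**31)), c)
        sid = f"S{i:03d}"
        for spec in schedule.conditions:
            trace = build_temperature_trace(spec, t1, c, sample_rate)
            rating = simulate_rating_trace(trace, spec, subject, rng, c)
            n = trace.times.size
            cols["subject_id"].append(np.repeat(sid, n))
            cols["sex"].append(np.repeat(subject.sex, n))
            cols["condition"].append(np.repeat(spec.name, n))
            cols["time_s"].append(trace.times)
            cols["temperature_c"].append(trace.temps)
            cols["rating_nrs"].append(rating.ratings)
            cols["t1_temp_c"].append(np.repeat(t1, n))
    return pd.DataFrame({k: np.concatenate(v) for k, v in cols.items()})


def simulate_window_means(
    config: PopulationConfig,
    conditions: tuple[str, ...] = ("control", "OA1", "OA2", "OH1", "OH2"),
    constants: ProtocolConstants | None = None,
    sample_rate: float = 10.0,
    window: tuple[float, float] = (20.0, 33.0),
) -> pd.DataFrame:
    """Fast path for simulation studies: last-13-s window means only.

    Simulates the requested conditions for every subject with the same
    per-subject seeding scheme as :func:`simulate_experiment` and returns an
    n_subjects × len(conditions) DataFrame of window-mean ratings (plus a
    ``sex`` column), skipping the long-format trace assembly.  The generator
    is condition-order invariant, so the session schedule draw is omitted.
    """
    from .effects import windowed_mean
    from .protocol import make_condition_spec

    c = constants if constants is not None else ProtocolConstants()
    root = np.random.SeedSequence(config.seed)
    pop_seq, *subj_seqs = root.spawn(1 + config.n_subjects)
    subjects = sample_population(config, rng=np.random.default_rng(pop_seq))
    specs = [make_condition_spec(name) for name in conditions]
    rows = []
    for subject, seq in zip(subjects, subj_seqs):
        rng = np.random.default_rng(seq)
        outcome = calibrate_subject(make_response_oracle(subject))
        t1 = outcome.t1_temp if outcome.success else (
            outcome.history[-1][0] if outcome.history else 47.1
        )
        row = {}
        for spec in specs:
            trace = build_temperature_trace(spec, t1, c, sample_rate)
            rating = simulate_rating_trace(trace, spec, subject, rng, c)
            row[spec.name] = windowed_mean(rating.times, rating.ratings, window)
        row["sex"] = subject.sex
        rows.append(row)
    return pd.DataFrame(rows)
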