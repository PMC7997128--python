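"""Individual pain calibration.

Before the experiment each participant's T1 temperature — the plateau
producing a pain rating of about NRS 5 — is estimated from graded 5-s heat
stimuli between 38 and 50 °C, then verified with a 15-s stimulus.  If the
peak rating of the verification stimulus falls within the closed band
[4, 6] NRS the temperature is accepted; otherwise the temperature is stepped
0.5 °C up or down and verified again, up to an iteration budget.

The prediction step fits an ordinary least-squares line of peak rating on
stimulus temperature and inverts it at NRS 5 (the simplest monotone model
consistent with the up/down adjustment loop).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np

__all__ = [
    "CalibrationData",
    "CalibrationFit",
    "CalibrationOutcome",
    "fit_calibration_curve",
    "verify_t1",
    "calibrate_subject",
    "DEFAULT_CALIBRATION_GRID",
]

#: Default graded-stimulus temperatures (°C) presented during calibration.
DEFAULT_CALIBRATION_GRID: tuple[float, ...] = tuple(np.arange(38.0, 50.0 + 1e-9, 2.0))

TEMP_MIN, TEMP_MAX = 38.0, 50.0
TARGET_NRS = 5.0
ACCEPT_LOW, ACCEPT_HIGH = 4.0, 6.0
ADJUST_STEP = 0.5
CALIB_STIM_S = 5.0
VERIFY_STIM_S = 15.0

#: An oracle maps (temperature °C, stimulus duration s) -> peak NRS rating.
ResponseOracle = Callable[[float, float], float]


@dataclass
class CalibrationData:
    """Pairs of (stimulus temperature °C, peak NRS rating) from graded stimuli."""

    temps: np.ndarray
    ratings: np.ndarray

    def __post_init__(self) -> None:
        self.temps = np.asarray(self.temps, dtype=float)
        self.ratings = np.asarray(self.ratings, dtype=float)
        if self.temps.shape != self.ratings.shape or self.temps.ndim != 1:
            raise ValueError("temps and ratings must be 1-D arrays of equal length")
        if np.unique(self.temps).size < 2:
            raise ValueError("calibration needs at least 2 distinct temperatures")
        if np.any((self.ratings < 0) | (self.ratings > 10)):
            raise ValueError("ratings must lie in [0, 10]")

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[float, float]]) -> "CalibrationData":
        arr = np.asarray(list(pairs), dtype=float)
        return cls(temps=arr[:, 0], ratings=arr[:, 1])


@dataclass(frozen=True)
class CalibrationFit:
    """OLS line of peak rating on temperature and the implied NRS-5 temperature."""

    slope: float
    intercept: float
    predicted_t1: float
    calibratable: bool


def fit_calibration_curve(data: CalibrationData) -> CalibrationFit:
    """Least-squares line of peak rating on stimulus temperature.

    ``predicted_t1`` is the temperature at which the fitted line crosses
    NRS 5, clamped to [38, 50] °C and rounded to 0.1 °C.  A non-positive
    slope (pain not increasing with temperature) is flagged as
    non-calibratable; the prediction is then undefined (NaN).
    """
    slope, intercept = np.polyfit(data.temps, data.ratings, 1)
    if slope <= 0:
        return CalibrationFit(float(slope), float(intercept), float("nan"), False)
    t1 = (TARGET_NRS - intercept) / slope
    t1 = float(np.clip(t1, TEMP_MIN, TEMP_MAX))
    return CalibrationFit(float(slope), float(intercept), round(t1, 1), True)


def verify_t1(peak_rating: float) -> str:
    """Decision for the 15-s verification stimulus.

    Returns ``"accept"`` when 4 ≤ rating ≤ 6 (closed band), ``"lower"`` above
    it, ``"raise"`` below it.
    """
    if not 0.0 <= peak_rating <= 10.0:
        raise ValueError(f"rating must lie in [0, 10], got {peak_rating}")
    if peak_rating > ACCEPT_HIGH:
        return "lower"
    if peak_rating < ACCEPT_LOW:
        return "raise"
    return "accept"


@dataclass
class CalibrationOutcome:
    """Accepted T1 temperature (or failure) plus the full iteration log."""

    t1_temp: float
    success: bool
    fit: CalibrationFit
    history: list[tuple[float, float, str]] = field(default_factory=list)


def _fit_temps_ratings(temps: np.ndarray, ratings: np.ndarray) -> CalibrationFit:
    """Fit, excluding floor/ceiling ratings when enough interior points remain.

    Ratings pinned at the scale limits (0 or 10) carry no gradient
    information; they are dropped from the line fit provided at least two
    distinct interior temperatures remain.
    """
    interior = (ratings > 0.0) & (ratings < 10.0)
    if np.unique(temps[interior]).size >= 2:
        temps, ratings = temps[interior], ratings[interior]
    return fit_calibration_curve(CalibrationData(temps=temps, ratings=ratings))


def calibrate_subject(
    response_oracle: ResponseOracle,
    max_iter: int = 10,
    grid: Sequence[float] = DEFAULT_CALIBRATION_GRID,
) -> CalibrationOutcome:
    """Run the full calibration loop against a response oracle.

    The oracle stands in for the participant: it returns the peak NRS rating
    for a stimulus of given temperature and duration.  Graded 5-s stimuli on
    ``grid`` seed the regression; the predicted NRS-5 temperature is then
    verified with 15-s stimuli, stepping ±0.5 °C until the rating falls in
    [4, 6] or ``max_iter`` verifications are exhausted.
    """
    temps = np.asarray(grid, dtype=float)
    ratings = np.array([response_oracle(t, CALIB_STIM_S) for t in temps], dtype=float)
    fit = _fit_temps_ratings(temps, ratings)
    if not fit.calibratable:
        return CalibrationOutcome(float("nan"), False, fit)

    temp = fit.predicted_t1
    history: list[tuple[float, float, str]] = []
    for _ in range(max_iter):
        rating = float(response_oracle(temp, VERIFY_STIM_S))
        decision = verify_t1(rating)
        history.append((temp, rating, decision))
        if decision == "accept":
            return CalibrationOutcome(round(temp, 1), True, fit, history)
        delta = -ADJUST_STEP if decision == "lower" else ADJUST_STEP
        temp = round(float(np.clip(temp + delta, TEMP_MIN, TEMP_MAX)), 1)
    return CalibrationOutcome(float("nan"), False, fit, history)
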