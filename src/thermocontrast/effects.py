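"""Windowed summaries of continuous rating traces.

Three quantities feed the inference chain:

* the per-condition mean rating over the last 13 s of stimulation
  (20–33 s), where the conditions have re-converged on the T1 plateau;
* control-subtracted difference traces per stimulus range, with the OA
  difference sign-inverted so that the canonical hypoalgesic response is
  positive (diff_offset = −(OA − control), diff_onset = OH − control);
* the subtracted offset/onset effect: the span between the maximum of the
  difference trace during T3 (20–33 s) and its minimum during T2 (9–20 s,
  extended backwards to absorb the perceptual lag).

Windows are half-open ``[start, end)``; the sample at the shared 20-s
boundary belongs to T3.  The effect is computed as max(T3) − min(T2), the
positive-going convention; its magnitude is unchanged if the opposite order
is preferred.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "AnalysisWindows",
    "windowed_mean",
    "condition_mean_table",
    "subtract_and_invert",
    "subtracted_effect",
    "subtracted_effect_table",
    "hypo_hyper_responses",
]

#: (paradigm, stimulus range °C) -> experimental condition name
_RANGE_CONDITIONS = {
    ("offset", 1): "OA1",
    ("offset", 2): "OA2",
    ("onset", 1): "OH1",
    ("onset", 2): "OH2",
}


@dataclass(frozen=True)
class AnalysisWindows:
    """Half-open analysis windows in seconds from trial start."""

    t2_window: tuple[float, float] = (9.0, 20.0)
    t3_window: tuple[float, float] = (20.0, 33.0)

    def __post_init__(self) -> None:
        for w in (self.t2_window, self.t3_window):
            if not w[0] < w[1]:
                raise ValueError(f"window {w} must have start < end")
        if self.t2_window[1] != self.t3_window[0]:
            raise ValueError("t2_window must end where t3_window starts")

    @property
    def mean_window(self) -> tuple[float, float]:
        """Window for per-condition mean ratings (last 13 s of stimulation)."""
        return self.t3_window


def _window_mask(times: np.ndarray, window: tuple[float, float]) -> np.ndarray:
    # tiny tolerance so float grids (e.g. 0.1-s steps) hit nominal boundaries
    eps = 1e-9
    return (times >= window[0] - eps) & (times < window[1] - eps)


def windowed_mean(times: np.ndarray, values: np.ndarray, window: tuple[float, float]) -> float:
    """Arithmetic mean of samples with window.start ≤ t < window.end."""
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    mask = _window_mask(times, window)
    if not mask.any():
        raise ValueError(f"trace does not cover window {window}")
    return float(values[mask].mean())


def condition_mean_table(
    dataset: pd.DataFrame, windows: AnalysisWindows | None = None
) -> pd.DataFrame:
    """Last-13-s mean rating per subject × condition.

    Expects a long-format dataset with one trace per subject × condition
    (columns ``subject_id``, ``condition``, ``time_s``, ``rating_nrs``).
    Duplicate subject × condition traces are rejected.
    """
    w = windows if windows is not None else AnalysisWindows()
    sub = dataset[_window_mask(dataset["time_s"].to_numpy(), w.mean_window)]
    if sub.empty:
        raise ValueError(f"dataset does not cover the mean window {w.mean_window}")
    counts = sub.groupby(["subject_id", "condition"], sort=True)["time_s"].nunique()
    sizes = sub.groupby(["subject_id", "condition"], sort=True).size()
    if (sizes != counts).any():
        dup = sizes[sizes != counts].index.tolist()
        raise ValueError(f"duplicate traces for subject × condition: {dup}")
    out = (
        sub.groupby(["subject_id", "condition"], sort=True)["rating_nrs"]
        .mean()
        .rename("window_mean")
        .reset_index()
    )
    return out


def subtract_and_invert(dataset: pd.DataFrame) -> pd.DataFrame:
    """Per-subject control-subtracted difference traces, OA sign-inverted.

    Returns a long DataFrame with columns ``subject_id``, ``paradigm``
    (offset/onset), ``range`` (1 or 2 °C), ``time_s`` and ``diff`` where
    diff_offset(t) = −(OA(t) − control(t)) and diff_onset(t) = OH(t) −
    control(t).  All traces of a subject must share one time grid.
    """
    pieces = []
    for sid, g in dataset.groupby("subject_id", sort=True):
        wide = g.pivot(index="time_s", columns="condition", values="rating_nrs")
        if wide.isna().any().any():
            raise ValueError(f"subject {sid}: traces are not on a common time grid")
        if "control" not in wide:
            raise ValueError(f"subject {sid}: missing control condition")
        for (paradigm, rng_c), cond in _RANGE_CONDITIONS.items():
            if cond not in wide:
                continue
            diff = wide[cond] - wide["control"]
            if paradigm == "offset":
                diff = -diff
            pieces.append(
                pd.DataFrame(
                    {
                        "subject_id": sid,
                        "paradigm": paradigm,
                        "range": rng_c,
                        "time_s": wide.index.to_numpy(),
                        "diff": diff.to_numpy(),
                    }
                )
            )
    return pd.concat(pieces, ignore_index=True)


def subtracted_effect(
    times: np.ndarray, diff: np.ndarray, windows: AnalysisWindows | None = None
) -> float:
    """Span of a difference trace: max over T3 minus min over T2.

    Positive values correspond to the canonical offset/onset response.  The
    statistic is invariant to adding a constant to the whole trace.
    """
    w = windows if windows is not None else AnalysisWindows()
    times = np.asarray(times, dtype=float)
    diff = np.asarray(diff, dtype=float)
    m2 = _window_mask(times, w.t2_window)
    m3 = _window_mask(times, w.t3_window)
    if not m2.any() or not m3.any():
        raise ValueError("difference trace does not cover the T2 and T3 windows")
    return float(diff[m3].max() - diff[m2].min())


def subtracted_effect_table(
    dataset: pd.DataFrame, windows: AnalysisWindows | None = None
) -> pd.DataFrame:
    """Subtracted offset/onset effect per subject, paradigm and stimulus range."""
    w = windows if windows is not None else AnalysisWindows()
    diffs = subtract_and_invert(dataset)
    rows = []
    for (sid, paradigm, rng_c), g in diffs.groupby(
        ["subject_id", "paradigm", "range"], sort=True
    ):
        eff = subtracted_effect(g["time_s"].to_numpy(), g["diff"].to_numpy(), w)
        rows.append(
            {"subject_id": sid, "paradigm": paradigm, "range": rng_c,
             "subtracted_effect": eff}
        )
    return pd.DataFrame(rows)


def hypo_hyper_responses(mean_table: pd.DataFrame) -> pd.DataFrame:
    """Control-subtracted window means per subject and experimental condition.

    A hypoalgesic response appears as a negative (OA − control) difference
    and a hyperalgesic one as a positive (OH − control) difference.
    Subjects lacking a control mean are excluded.
    """
    wide = mean_table.pivot(index="subject_id", columns="condition", values="window_mean")
    missing_control = wide.index[wide.get("control", pd.Series(dtype=float)).isna()] \
        if "control" in wide else wide.index
    if "control" not in wide:
        raise ValueError("mean table has no control condition")
    wide = wide.drop(index=missing_control)
    rows = []
    for cond in ("OA1", "OA2", "OH1", "OH2"):
        if cond not in wide:
            continue
        sub = wide[[cond, "control"]].dropna()
        for sid, (v, ctrl) in sub.iterrows():
            rows.append(
                {"subject_id": sid, "condition": cond, "response": v - ctrl}
            )
    return pd.DataFrame(rows)
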