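"""Pupil-trace cleaning and tonic (pre-stimulus) measures.

Blink/dropout samples are padded, short gaps linearly interpolated, and
the mean diameter in the second before each target onset is extracted as
the tonic effort index; its time-on-task slope is an OLS fit against
elapsed minutes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd


@dataclass
class PupilTrace:
    """Sampled pupil-diameter series with per-sample validity.

    ``raw_valid`` preserves the validity mask as recorded, so the
    preprocessing (which pads and interpolates around *raw* blinks) is
    idempotent.
    """

    time_s: np.ndarray
    diameter_mm: np.ndarray
    valid: np.ndarray
    sampling_rate: float
    raw_valid: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.diameter_mm = np.asarray(self.diameter_mm, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.time_s.size == 0:
            raise ValueError("empty trace")
        if not (self.time_s.size == self.diameter_mm.size == self.valid.size):
            raise ValueError("time, diameter and valid must have equal length")
        if np.any(np.diff(self.time_s) <= 0):
            raise ValueError("time must be strictly increasing")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if self.raw_valid is None:
            self.raw_valid = self.valid.copy()
        else:
            self.raw_valid = np.asarray(self.raw_valid, dtype=bool)

    @property
    def duration_s(self) -> float:
        return float(self.time_s[-1] - self.time_s[0])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"time_s": self.time_s, "diameter_mm": self.diameter_mm,
             "valid": self.valid}
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame, sampling_rate: float) -> "PupilTrace":
        return cls(
            time_s=df["time_s"].to_numpy(),
            diameter_mm=df["diameter_mm"].to_numpy(),
            valid=df["valid"].to_numpy(dtype=bool),
            sampling_rate=sampling_rate,
        )


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open [start, stop) index ranges of True runs."""
    if not mask.any():
        return []
    padded = np.concatenate([[False], mask, [False]])
    edges = np.flatnonzero(np.diff(padded.astype(int)))
    return list(zip(edges[::2], edges[1::2]))


def preprocess(
    trace: PupilTrace,
    pad_ms: float = 100.0,
    max_gap_ms: float = 500.0,
    smooth_ms: float = 0.0,
) -> PupilTrace:
    """Clean a trace: pad invalid runs, interpolate short gaps.

    Raw invalid runs are dilated by ``pad_ms`` on each side (blink edges
    are unreliable); padded gaps no longer than ``max_gap_ms`` plus the
    padding are linearly interpolated from their valid neighbours and
    marked valid, longer gaps stay invalid (NaN).  With ``smooth_ms`` > 0
    a centred moving average is applied afterwards (this step breaks
    idempotence and is off by default).  Sample count is unchanged.
    """
    assert trace.raw_valid is not None
    if not trace.raw_valid.any():
        raise ValueError("trace has no valid samples")
    fs = trace.sampling_rate
    pad_n = int(round(pad_ms / 1000.0 * fs))
    max_run = (max_gap_ms + 2 * pad_ms) / 1000.0 * fs

    invalid = ~trace.raw_valid
    padded = invalid.copy()
    for start, stop in _runs(invalid):
        padded[max(0, start - pad_n):min(len(padded), stop + pad_n)] = True

    diameter = trace.diameter_mm.copy()
    valid = ~padded
    # anchor values: samples outside every padded run keep raw values
    anchor_t = trace.time_s[valid]
    anchor_d = diameter[valid]
    for start, stop in _runs(padded):
        interior = start > 0 and stop < len(padded)
        if (stop - start) <= max_run and interior:
            diameter[start:stop] = np.interp(
                trace.time_s[start:stop], anchor_t, anchor_d
            )
            valid[start:stop] = True
        else:
            diameter[start:stop] = np.nan

    if smooth_ms > 0:
        w = max(1, int(round(smooth_ms / 1000.0 * fs)))
        kernel = np.ones(w) / w
        filled = np.where(valid, diameter, 0.0)
        norm = np.convolve(valid.astype(float), kernel, mode="same")
        smoothed = np.convolve(filled, kernel, mode="same")
        with np.errstate(invalid="ignore", divide="ignore"):
            diameter = np.where(valid & (norm > 0), smoothed / norm, diameter)

    return PupilTrace(
        time_s=trace.time_s.copy(),
        diameter_mm=diameter,
        valid=valid,
        sampling_rate=fs,
        raw_valid=trace.raw_valid.copy(),
    )


def extract_prestim(
    trace: PupilTrace,
    onsets: Sequence[float],
    conditions: Sequence[str] | None = None,
    window_s: float = 1.0,
    min_valid_frac: float = 0.5,
) -> pd.DataFrame:
    """Tonic pre-stimulus epochs: mean valid diameter in
    ``[onset - window_s, onset)`` per target.

    An epoch is usable when at least ``min_valid_frac`` of its in-window
    samples are valid (and it has any samples at all).
    """
    onsets = np.asarray(onsets, dtype=float)
    if conditions is None:
        conditions = ["all"] * onsets.size
    if len(conditions) != onsets.size:
        raise ValueError("conditions must match onsets")
    t = trace.time_s
    if onsets.size and (onsets.min() < t[0] or onsets.max() > t[-1]):
        raise ValueError("onsets must lie within the trace span")
    rows = []
    for onset, cond in zip(onsets, conditions):
        in_win = (t >= onset - window_s) & (t < onset)
        n_total = int(in_win.sum())
        n_valid = int((in_win & trace.valid).sum())
        usable = n_total > 0 and n_valid / max(n_total, 1) >= min_valid_frac
        mean = (
            float(np.mean(trace.diameter_mm[in_win & trace.valid]))
            if n_valid
            else np.nan
        )
        rows.append(
            dict(
                onset_s=float(onset),
                condition=cond,
                prestim_mean_mm=mean,
                n_samples=n_total,
                n_valid=n_valid,
                usable=bool(usable),
            )
        )
    return pd.DataFrame(rows)


def subject_inclusion(
    epochs: pd.DataFrame,
    min_trials: int = 23,
    conditions: Sequence[str] | None = None,
) -> bool:
    """Gate: include a subject iff every condition has at least
    ``min_trials`` usable epochs."""
    if conditions is None:
        conditions = sorted(epochs["condition"].unique())
    counts = epochs[epochs["usable"]].groupby("condition").size()
    return all(int(counts.get(c, 0)) >= min_trials for c in conditions)


def pupil_tot_slope(epochs: pd.DataFrame, min_epochs: int = 3) -> pd.DataFrame:
    """Per-condition OLS slope (mm per minute) of the tonic measure on
    elapsed time."""
    rows = []
    for cond, grp in epochs[epochs["usable"]].groupby("condition", sort=True):
        if len(grp) < min_epochs:
            raise ValueError(
                f"condition {cond!r} has {len(grp)} usable epochs; need {min_epochs}"
            )
        minutes = grp["onset_s"].to_numpy() / 60.0
        slope = np.polyfit(minutes, grp["prestim_mean_mm"].to_numpy(), 1)[0]
        rows.append(dict(condition=cond, slope_mm_per_min=float(slope),
                         n_epochs=len(grp)))
    return pd.DataFrame(rows)
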