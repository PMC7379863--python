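"""Scoring of vigilance and N-Back sessions.

Vigilance metrics: response speed (1/RT), the baseline-median RT
criterion, percentage of responses faster than criterion, and linear
time-on-task slopes.  N-Back runs are tabulated into signal-detection
counts, from which d-prime and the likelihood-ratio bias are computed
with a 1/(2N) correction for perfect or empty cells.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

FALSE_START_MS = 100.0  # responses faster than this are invalid anticipations

GAIN_CENTS = {"target": 6, "nontarget": 2}
LOSS_ENDOWMENT_CENTS = 200


def response_speed(rt_ms):
    """Response speed in 1/s from RT in ms (vectorized)."""
    rt = np.asarray(rt_ms, dtype=float)
    if np.any(rt <= 0):
        raise ValueError("RT must be positive")
    out = 1000.0 / rt
    return float(out) if out.ndim == 0 else out


def _clean_rts(rt_ms, valid=None, min_rt_ms: float = FALSE_START_MS) -> np.ndarray:
    rt = np.asarray(rt_ms, dtype=float)
    mask = np.ones(rt.shape, dtype=bool) if valid is None else np.asarray(valid, bool)
    mask = mask & (rt >= min_rt_ms)
    return rt[mask]


def rt_criterion(rt_ms, valid=None, min_rt_ms: float = FALSE_START_MS) -> float:
    """Median RT over valid baseline trials (false starts excluded)."""
    rts = _clean_rts(rt_ms, valid, min_rt_ms)
    if rts.size == 0:
        raise ValueError("no valid baseline trials")
    return float(np.median(rts))


def pct_faster(rt_ms, criterion: float, valid=None,
               min_rt_ms: float = FALSE_START_MS) -> float:
    """Percentage of valid responses strictly faster than the criterion.

    Ties count as not-faster so the rule is deterministic at millisecond
    resolution.
    """
    if criterion <= 0:
        raise ValueError("criterion must be positive")
    rts = _clean_rts(rt_ms, valid, min_rt_ms)
    if rts.size == 0:
        raise ValueError("no valid trials")
    return float(100.0 * np.mean(rts < criterion))


def tot_slope(values, minutes) -> float:
    """OLS slope of a measure on elapsed minutes (time-on-task)."""
    y = np.asarray(values, dtype=float)
    x = np.asarray(minutes, dtype=float)
    if y.size != x.size:
        raise ValueError("values and minutes must have equal length")
    if y.size < 3:
        raise ValueError("need at least 3 points for a slope")
    if np.ptp(x) == 0:
        raise ValueError("time vector is constant")
    return float(np.polyfit(x, y, 1)[0])


def score_vigilance(
    trials: pd.DataFrame,
    criterion_ms: float | None = None,
    min_rt_ms: float = FALSE_START_MS,
) -> pd.DataFrame:
    """Per-condition vigilance metrics for one subject's trial table.

    Columns required: onset_s, condition, rt_ms (optional valid).  If no
    criterion is supplied it is taken from the table's own baseline
    condition.
    """
    df = trials.copy()
    if "valid" not in df:
        df["valid"] = True
    df["valid"] = df["valid"] & (df["rt_ms"] >= min_rt_ms)
    if criterion_ms is None:
        base = df[df["condition"] == "baseline"]
        criterion_ms = rt_criterion(base["rt_ms"], base["valid"], min_rt_ms)
    rows = []
    for cond, grp in df[df["valid"]].groupby("condition", sort=True):
        rows.append(
            dict(
                condition=cond,
                n_trials=len(grp),
                mean_speed=float(np.mean(response_speed(grp["rt_ms"]))),
                median_rt_ms=float(np.median(grp["rt_ms"])),
                pct_faster=pct_faster(grp["rt_ms"], criterion_ms),
                speed_tot_slope=tot_slope(
                    response_speed(grp["rt_ms"]), grp["onset_s"] / 60.0
                ),
                rt_tot_slope=tot_slope(grp["rt_ms"], grp["onset_s"] / 60.0),
            )
        )
    out = pd.DataFrame(rows)
    out["criterion_ms"] = criterion_ms
    return out


# ---------------------------------------------------------------------------
# signal detection


@dataclass(frozen=True)
class SDTCounts:
    hits: int
    misses: int
    false_alarms: int
    correct_rejections: int
    load: int | None = None
    frame: str | None = None

    def __post_init__(self) -> None:
        for v in (self.hits, self.misses, self.false_alarms,
                  self.correct_rejections):
            if v < 0:
                raise ValueError("counts must be non-negative")

    @property
    def n_signal(self) -> int:
        return self.hits + self.misses

    @property
    def n_noise(self) -> int:
        return self.false_alarms + self.correct_rejections


@dataclass(frozen=True)
class SDTMetrics:
    hit_rate: float
    fa_rate: float
    d_prime: float
    beta_bias: float


def _corrected_rate(count: int, n: int) -> float:
    # 1/(2N) adjustment only at the boundary cells
    if count == 0:
        return 1.0 / (2 * n)
    if count == n:
        return 1.0 - 1.0 / (2 * n)
    return count / n


def sdt_metrics(counts: SDTCounts) -> SDTMetrics:
    """d' and likelihood-ratio bias from a 2x2 count table.

    ``d' = z(H) - z(F)``; ``beta = exp((z(F)^2 - z(H)^2) / 2)`` with z the
    inverse standard-normal CDF and rates corrected by the 1/(2N) rule
    at 0 or 1.
    """
    if counts.n_signal == 0 or counts.n_noise == 0:
        raise ValueError("both signal and noise denominators must be positive")
    h = _corrected_rate(counts.hits, counts.n_signal)
    f = _corrected_rate(counts.false_alarms, counts.n_noise)
    zh, zf = stats.norm.ppf(h), stats.norm.ppf(f)
    return SDTMetrics(
        hit_rate=h,
        fa_rate=f,
        d_prime=float(zh - zf),
        beta_bias=float(np.exp((zf**2 - zh**2) / 2.0)),
    )


def score_nback(
    trials: pd.DataFrame,
    max_missing_frac: float = 0.10,
) -> pd.DataFrame:
    """SDT counts, metrics and earnings per subject x load x frame.

    A "target" response to a target is a hit; any other behaviour on a
    target (non-target press or non-response) is a miss, and symmetrically
    for non-targets, so denominators stay fixed.  Earnings follow the
    2 cent / 6 cent payoff: in the gain frame correct responses earn, in
    the loss frame errors and non-responses deduct from a $2 endowment.
    Cells where more than ``max_missing_frac`` of responses are missing
    are flagged.
    """
    df = trials.copy()
    resp = df["response"].astype(object).where(df["response"].notna(), "none")
    df["_press_target"] = resp == "target"
    df["_press_nontarget"] = resp == "nontarget"
    df["_missing"] = ~(df["_press_target"] | df["_press_nontarget"])

    rows = []
    for (subj, load, frame), grp in df.groupby(["subject", "load", "frame"],
                                               sort=True):
        tgt = grp["is_target"].astype(bool)
        hits = int((tgt & grp["_press_target"]).sum())
        misses = int((tgt & ~grp["_press_target"]).sum())
        fas = int((~tgt & grp["_press_target"]).sum())
        crs = int((~tgt & ~grp["_press_target"]).sum())
        counts = SDTCounts(hits, misses, fas, crs, load=load, frame=frame)
        m = sdt_metrics(counts)

        correct_tgt_press = int((tgt & grp["_press_target"]).sum())
        correct_nt_press = int((~tgt & grp["_press_nontarget"]).sum())
        gain_cents = GAIN_CENTS["target"] * correct_tgt_press \
            + GAIN_CENTS["nontarget"] * correct_nt_press
        wrong_tgt = int((tgt & ~grp["_press_target"]).sum())
        wrong_nt = int((~tgt & ~grp["_press_nontarget"]).sum())
        loss_cents = GAIN_CENTS["target"] * wrong_tgt \
            + GAIN_CENTS["nontarget"] * wrong_nt
        rows.append(
            dict(
                subject=subj,
                load=load,
                frame=frame,
                hits=hits,
                misses=misses,
                false_alarms=fas,
                correct_rejections=crs,
                hit_rate=m.hit_rate,
                fa_rate=m.fa_rate,
                d_prime=m.d_prime,
                beta_bias=m.beta_bias,
                gain_earnings_cents=gain_cents,
                loss_deduction_cents=loss_cents,
                loss_remaining_cents=LOSS_ENDOWMENT_CENTS - loss_cents,
                missing_frac=float(grp["_missing"].mean()),
                flagged=bool(grp["_missing"].mean() > max_missing_frac),
            )
        )
    return pd.DataFrame(rows)
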