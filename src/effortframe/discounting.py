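"""Effort-discounting models: subjective value, likelihoods, model fits,
BIC comparison, AUC summaries and paired gain/loss contrasts.

Five discount function families map a monetary amount ``M`` and an effort
level ``E`` to a subjective value:

==============  =============================================
hyperbolic      ``M / (1 + kE)``
exponential     ``M * exp(-kE)``
linear          ``M * (1 - kE)``
quadratic       ``M * (1 - kE^2)``
sigmoid         ``M * (1 - (s(E) - s(0)) / (1 - s(0)))`` with
                ``s(E) = 1 / (1 + exp(-k (E - p)))``
==============  =============================================

All families are clipped at zero (a task cannot be worth less than
nothing in this design) and satisfy ``SV(M, 0) = M``.  Choices are
modelled with a softmax rule ``P(high) = logistic(beta * (SV_high -
SV_low))`` where amounts are always net outcomes, so one value function
serves both frames with frame-specific ``k``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import expit

from .staircase import HIGH, LOW, ChoiceTrial

FAMILIES = ("hyperbolic", "exponential", "linear", "quadratic", "sigmoid")

N_PARAMS = {
    "hyperbolic": 2,
    "exponential": 2,
    "linear": 2,
    "quadratic": 2,
    "sigmoid": 3,
}

#: upper bound on k used by the multi-start optimizer, per family
K_MAX = {
    "hyperbolic": 10.0,
    "exponential": 2.0,
    "linear": 1.0,
    "quadratic": 1.0,
    "sigmoid": 5.0,
}

BETA_BOUNDS = (0.01, 100.0)


def subjective_value(family, amount, effort, k, p_sigmoid=None):
    """Subjective value of ``amount`` at ``effort`` under a discount family.

    Accepts scalars or numpy arrays for ``amount`` and ``effort``; the
    result is floored at zero.
    """
    if family not in FAMILIES:
        raise ValueError(f"unknown family {family!r}")
    amount = np.asarray(amount, dtype=float)
    effort = np.asarray(effort, dtype=float)
    if np.any(amount < 0):
        raise ValueError("amount must be non-negative")
    if np.any(effort < 0):
        raise ValueError("effort must be non-negative")
    if k < 0:
        raise ValueError("k must be non-negative")

    if family == "hyperbolic":
        sv = amount / (1.0 + k * effort)
    elif family == "exponential":
        sv = amount * np.exp(-k * effort)
    elif family == "linear":
        sv = amount * (1.0 - k * effort)
    elif family == "quadratic":
        sv = amount * (1.0 - k * effort**2)
    else:
        if p_sigmoid is None:
            raise ValueError("sigmoid family requires p_sigmoid")
        s = expit(k * (effort - p_sigmoid))
        s0 = expit(-k * p_sigmoid)
        denom = 1.0 - s0
        if denom <= 0:  # k == 0 exactly: no discounting
            sv = amount * np.ones_like(effort)
        else:
            sv = amount * (1.0 - (s - s0) / denom)
    out = np.maximum(sv, 0.0)
    return float(out) if out.ndim == 0 else out


def _trials_to_arrays(trials: Sequence[ChoiceTrial]) -> dict[str, np.ndarray]:
    return {
        "m_low": np.array([t.net_low for t in trials], dtype=float),
        "m_high": np.array([t.net_high for t in trials], dtype=float),
        "e_low": np.array([t.effort_low for t in trials], dtype=float),
        "e_high": np.array([t.effort_high for t in trials], dtype=float),
    }


def _chose_high(choices: Sequence) -> np.ndarray:
    arr = np.asarray(choices)
    if arr.dtype.kind in "USO":
        bad = ~np.isin(arr, (LOW, HIGH))
        if bad.any():
            raise ValueError(f"unknown choice labels: {set(arr[bad])}")
        return arr == HIGH
    return arr.astype(bool)


def choice_loglik(
    trials: Sequence[ChoiceTrial],
    choices: Sequence,
    family: str,
    k: float,
    beta: float,
    p_sigmoid: float | None = None,
) -> float:
    """Natural-log likelihood of observed choices under the softmax model."""
    if len(trials) == 0:
        raise ValueError("at least one trial is required")
    if len(trials) != len(choices):
        raise ValueError("trials and choices must have equal length")
    arrs = _trials_to_arrays(trials)
    chose_high = _chose_high(choices)
    sv_low = subjective_value(family, arrs["m_low"], arrs["e_low"], k, p_sigmoid)
    sv_high = subjective_value(family, arrs["m_high"], arrs["e_high"], k, p_sigmoid)
    dsv = np.asarray(sv_high - sv_low)
    # log P(high) = -log(1 + exp(-beta dsv)); stable in both tails
    lp_high = -np.logaddexp(0.0, -beta * dsv)
    lp_low = -np.logaddexp(0.0, beta * dsv)
    return float(np.sum(np.where(chose_high, lp_high, lp_low)))


@dataclass
class DiscountFit:
    subject_id: str
    frame: str
    family: str
    k: float
    beta: float
    loglik: float
    n_trials: int
    bic: float
    p_sigmoid: float | None = None
    converged: bool = True

    @property
    def n_params(self) -> int:
        return N_PARAMS[self.family]


def _start_grid(family: str, k_max: float, e_max: float) -> list[np.ndarray]:
    k_starts = np.concatenate([[0.0], np.geomspace(k_max * 1e-4, k_max * 0.5, 5)])
    beta_starts = (1.0, 10.0)
    starts = []
    for k0 in k_starts:
        for b0 in beta_starts:
            if family == "sigmoid":
                for p0 in (0.3 * e_max, 0.7 * e_max):
                    starts.append(np.array([k0, b0, p0]))
            else:
                starts.append(np.array([k0, b0]))
    return starts


def fit_model(
    trials: Sequence[ChoiceTrial],
    choices: Sequence,
    family: str,
    *,
    subject_id: str = "s01",
    frame: str = "gain",
    k_max: float | None = None,
    beta_bounds: tuple[float, float] = BETA_BOUNDS,
) -> DiscountFit:
    """Maximum-likelihood fit of one family to one subject x frame cell.

    Deterministic multi-start bounded L-BFGS-B over ``k in [0, k_max]``,
    ``beta in beta_bounds`` (and the inflection ``p`` for the sigmoid).
    A fit where no start converges is returned flagged, never as silent
    NaN.
    """
    if family not in FAMILIES:
        raise ValueError(f"unknown family {family!r}")
    n_par = N_PARAMS[family]
    if len(trials) < n_par + 1:
        raise ValueError(f"need at least {n_par + 1} trials to fit {family}")
    if k_max is None:
        k_max = K_MAX[family]
    e_max = max(t.effort_high for t in trials)

    arrs = _trials_to_arrays(trials)
    chose_high = _chose_high(choices)

    def nll(x: np.ndarray) -> float:
        k, beta = x[0], x[1]
        p = x[2] if family == "sigmoid" else None
        sv_low = subjective_value(family, arrs["m_low"], arrs["e_low"], k, p)
        sv_high = subjective_value(family, arrs["m_high"], arrs["e_high"], k, p)
        dsv = np.asarray(sv_high - sv_low)
        lp_high = -np.logaddexp(0.0, -beta * dsv)
        lp_low = -np.logaddexp(0.0, beta * dsv)
        return -float(np.sum(np.where(chose_high, lp_high, lp_low)))

    bounds = [(0.0, k_max), beta_bounds]
    if family == "sigmoid":
        bounds.append((1e-6, 2.0 * e_max))

    best = None
    any_ok = False
    for x0 in _start_grid(family, k_max, e_max):
        x0 = np.clip(x0, [b[0] for b in bounds], [b[1] for b in bounds])
        res = optimize.minimize(nll, x0, method="L-BFGS-B", bounds=bounds)
        any_ok = any_ok or bool(res.success)
        if best is None or res.fun < best.fun - 1e-12:
            best = res

    assert best is not None
    k_hat, beta_hat = float(best.x[0]), float(best.x[1])
    p_hat = float(best.x[2]) if family == "sigmoid" else None
    loglik = -float(best.fun)
    n = len(trials)
    bic = n_par * math.log(n) - 2.0 * loglik
    return DiscountFit(
        subject_id=subject_id,
        frame=frame,
        family=family,
        k=k_hat,
        beta=beta_hat,
        p_sigmoid=p_hat,
        loglik=loglik,
        n_trials=n,
        bic=bic,
        converged=any_ok,
    )


def fit_all_families(trials, choices, **kwargs) -> list[DiscountFit]:
    return [fit_model(trials, choices, fam, **kwargs) for fam in FAMILIES]


@dataclass
class ModelComparison:
    per_subject: pd.DataFrame  # subject, frame, family, k, beta, loglik, bic, winner
    group: pd.DataFrame  # family, total_bic, n_winner
    winner: str  # family with lowest summed BIC


def compare_models(fits: Iterable[DiscountFit]) -> ModelComparison:
    """Per-subject and group-level BIC comparison across the five families.

    Per-subject winner is the lowest BIC; ties break toward fewer
    parameters, then the fixed family order.  All five families must be
    fitted on identical trial sets for every subject x frame cell.
    """
    fits = list(fits)
    rows = [
        dict(
            subject=f.subject_id,
            frame=f.frame,
            family=f.family,
            k=f.k,
            beta=f.beta,
            loglik=f.loglik,
            n_trials=f.n_trials,
            bic=f.bic,
        )
        for f in fits
    ]
    df = pd.DataFrame(rows)
    order = {fam: i for i, fam in enumerate(FAMILIES)}

    winners = []
    for (subj, frame), cell in df.groupby(["subject", "frame"], sort=True):
        if sorted(cell["family"]) != sorted(FAMILIES):
            raise ValueError(f"cell ({subj}, {frame}) is missing families")
        if cell["n_trials"].nunique() != 1:
            raise ValueError(
                f"cell ({subj}, {frame}) was fitted on mismatched trial sets"
            )
        best = min(
            cell.itertuples(),
            key=lambda r: (r.bic, N_PARAMS[r.family], order[r.family]),
        )
        winners.append(dict(subject=subj, frame=frame, winner=best.family))
    win_df = pd.DataFrame(winners)
    df = df.merge(win_df, on=["subject", "frame"])

    group = (
        df.groupby("family")
        .agg(total_bic=("bic", "sum"))
        .reindex(list(FAMILIES))
        .reset_index()
    )
    counts = win_df["winner"].value_counts()
    group["n_winner"] = group["family"].map(counts).fillna(0).astype(int)
    overall = min(
        group.itertuples(),
        key=lambda r: (r.total_bic, N_PARAMS[r.family], order[r.family]),
    ).family
    return ModelComparison(per_subject=df, group=group, winner=overall)


def compute_auc(
    effort_levels: Sequence[float],
    indifference: Sequence[float],
    amount_high: float = 10.0,
    reference_level: float = 1.0,
) -> float:
    """Normalized area under the discounting curve for one subject x frame.

    Effort is normalized by its maximum (the reference level anchors the
    curve at y = 1), values by the fixed high-effort amount; the
    trapezoidal area over ``[x_first, x_last]`` is divided by the x-range
    so the result lies in ``[0, 1]`` and larger values denote less
    discounting.
    """
    levels = np.asarray(effort_levels, dtype=float)
    vals = np.asarray(indifference, dtype=float)
    if levels.shape != vals.shape or levels.size == 0:
        raise ValueError("effort_levels and indifference must match and be non-empty")
    if np.any(np.diff(levels) <= 0):
        raise ValueError("effort_levels must be strictly increasing")
    if np.any(np.isnan(vals)):
        raise ValueError("missing indifference point")
    if levels[0] <= reference_level:
        raise ValueError("effort levels must exceed the reference level")
    if np.any(vals < 0) or np.any(vals > amount_high):
        raise ValueError("indifference points must lie in [0, amount_high]")

    x = np.concatenate([[reference_level], levels]) / levels[-1]
    y = np.concatenate([[1.0], vals / amount_high])
    area = np.trapezoid(y, x)
    return float(area / (x[-1] - x[0]))


def auc_table(indifference: pd.DataFrame, amount_high: float = 10.0,
              reference_level: float = 1.0) -> pd.DataFrame:
    """AUC per subject x frame from a tidy indifference table
    (columns subject, frame, effort_level, indifference)."""
    rows = []
    for (subj, frame), cell in indifference.groupby(["subject", "frame"], sort=True):
        cell = cell.sort_values("effort_level")
        rows.append(
            dict(
                subject=subj,
                frame=frame,
                auc=compute_auc(
                    cell["effort_level"].to_numpy(),
                    cell["indifference"].to_numpy(),
                    amount_high=amount_high,
                    reference_level=reference_level,
                ),
            )
        )
    return pd.DataFrame(rows)


@dataclass
class ContrastResult:
    """Paired loss-vs-gain contrast on a per-subject metric."""

    n: int
    differences: np.ndarray  # loss - gain, per subject
    mean_difference: float
    t: float
    df: int
    p: float
    degenerate: bool = False


def gain_loss_contrast(
    gain: Sequence[float],
    loss: Sequence[float],
    transform: str | None = None,
) -> ContrastResult:
    """Paired two-sided t test of loss vs gain values (loss - gain).

    ``transform="sqrt"`` square-root-transforms both sides first (used
    for discount rates, which are right-skewed).  Zero-variance non-zero
    differences are flagged degenerate with an infinite t rather than
    returned as NaN.
    """
    g = np.asarray(gain, dtype=float)
    l = np.asarray(loss, dtype=float)
    if g.shape != l.shape:
        raise ValueError("gain and loss must be paired")
    n = g.size
    if n < 3:
        raise ValueError("need at least 3 paired observations")
    if transform == "sqrt":
        if np.any(g < 0) or np.any(l < 0):
            raise ValueError("sqrt transform requires non-negative values")
        g, l = np.sqrt(g), np.sqrt(l)
    elif transform is not None:
        raise ValueError(f"unknown transform {transform!r}")

    d = l - g
    mean_d = float(np.mean(d))
    if np.allclose(np.std(d, ddof=1), 0.0):
        if math.isclose(mean_d, 0.0, abs_tol=1e-300):
            return ContrastResult(n, d, 0.0, 0.0, n - 1, 1.0, degenerate=True)
        t = math.inf if mean_d > 0 else -math.inf
        return ContrastResult(n, d, mean_d, t, n - 1, 0.0, degenerate=True)
    res = stats.ttest_rel(l, g)
    return ContrastResult(
        n=n,
        differences=d,
        mean_difference=mean_d,
        t=float(res.statistic),
        df=n - 1,
        p=float(res.pvalue),
    )
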