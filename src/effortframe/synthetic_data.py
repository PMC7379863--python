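"""Synthetic agents and task sessions.

Generates everything the analysis stages consume: softmax discounting
agents, vigilance RT sessions (blocked or intermixed incentive cues),
pupil-diameter traces with blinks, and N-Back letter runs with exact
target counts.  All randomness flows from an explicit seed per generator
call; a fixed seed gives bit-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .discounting import FAMILIES, subjective_value
from .staircase import HIGH, LOW, ChoiceTrial, StaircaseConfig
from .pupillometry import PupilTrace

VIGILANCE_COLUMNS = ["subject", "trial", "onset_s", "condition", "rt_ms", "valid"]
NBACK_COLUMNS = ["subject", "load", "frame", "trial", "letter", "is_target",
                 "response", "correct"]
PUPIL_COLUMNS = ["time_s", "diameter_mm", "valid"]

#: consonant pool for N-Back letter streams (vowels excluded to limit
#: chunking strategies; the original pool is unspecified)
LETTER_POOL = tuple("BCDFGHJKLMNPQRSTVWXZ")


@dataclass
class AgentParams:
    """Generative model of one simulated subject."""

    subject_id: str
    family: str
    k_gain: float
    k_loss: float
    beta: float = math.inf
    p_sigmoid: float | None = None
    rng_seed: int = 0
    _rng: np.random.Generator | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        if self.k_gain < 0 or self.k_loss < 0:
            raise ValueError("discount rates must be non-negative")
        if self.beta < 0:
            raise ValueError("beta must be non-negative")
        if self.family == "sigmoid" and self.p_sigmoid is None:
            raise ValueError("sigmoid family requires p_sigmoid")

    @property
    def rng(self) -> np.random.Generator:
        """The agent's own seeded stream (created lazily, then persistent)."""
        if self._rng is None:
            self._rng = np.random.default_rng(self.rng_seed)
        return self._rng


def simulate_choice(agent: AgentParams, trial: ChoiceTrial, rng=None) -> str:
    """Sample one choice from the agent's softmax rule.

    ``P(high_effort) = logistic(beta * (SV_high - SV_low))`` on net
    outcomes with the frame-appropriate discount rate.  With infinite
    beta the higher-valued option is chosen deterministically and exact
    ties resolve to ``low_effort``.
    """
    k = agent.k_gain if trial.frame == "gain" else agent.k_loss
    sv_low = subjective_value(agent.family, trial.net_low, trial.effort_low,
                              k, agent.p_sigmoid)
    sv_high = subjective_value(agent.family, trial.net_high, trial.effort_high,
                               k, agent.p_sigmoid)
    if math.isinf(agent.beta):
        return HIGH if sv_high > sv_low else LOW
    p_high = 1.0 / (1.0 + math.exp(-agent.beta * (sv_high - sv_low)))
    if rng is None:
        rng = agent.rng
    return HIGH if rng.random() < p_high else LOW


# ---------------------------------------------------------------------------
# vigilance sessions


@dataclass
class VigilanceSimConfig:
    n_trials: int = 80
    run_duration: float = 600.0
    isi_range: tuple[float, float] = (5.0, 10.0)
    rt_mu: float = 350.0  # median RT in ms (log-normal location)
    rt_sigma: float = 0.2  # log-scale spread
    incentive_speedup: float = 0.1
    loss_extra_speedup: float = 0.0
    tot_slowing: float = 5.0  # additive ms per minute on task
    lapse_prob: float = 0.0
    design: str = "intermixed"
    max_consecutive: int = 3
    conditions: tuple[str, ...] = ("gain", "loss", "neutral")

    def __post_init__(self) -> None:
        lo, hi = self.isi_range
        if not 0 < lo <= hi:
            raise ValueError("isi_range must satisfy 0 < min <= max")
        if self.design not in ("blocked", "intermixed"):
            raise ValueError(f"unknown design {self.design!r}")


def intermixed_sequence(
    n: int,
    conditions: Sequence[str],
    max_consecutive: int,
    rng: np.random.Generator,
    max_restarts: int = 1000,
) -> list[str]:
    """Pseudo-random condition sequence with balanced counts (within one)
    and no run longer than ``max_consecutive``."""
    base, extra = divmod(n, len(conditions))
    for _ in range(max_restarts):
        counts = {c: base for c in conditions}
        for c in rng.permutation(np.asarray(conditions, dtype=object))[:extra]:
            counts[c] += 1
        seq: list[str] = []
        ok = True
        for _ in range(n):
            run_len = 0
            for c in reversed(seq):
                if c == seq[-1]:
                    run_len += 1
                else:
                    break
            allowed = [
                c for c in conditions
                if counts[c] > 0
                and not (seq and c == seq[-1] and run_len >= max_consecutive)
            ]
            if not allowed:
                ok = False
                break
            weights = np.array([counts[c] for c in allowed], dtype=float)
            pick = allowed[rng.choice(len(allowed), p=weights / weights.sum())]
            seq.append(pick)
            counts[pick] -= 1
        if ok:
            return seq
    raise RuntimeError("could not build a constrained condition sequence")


def generate_vigilance_session(
    config: VigilanceSimConfig,
    seed,
    subject: str = "s01",
    condition: str | None = None,
) -> pd.DataFrame:
    """Simulate one vigilance run.

    Target onsets accumulate uniform ISIs until the run duration is
    exhausted.  RTs are log-normal around ``rt_mu`` with multiplicative
    incentive speed-ups and an additive time-on-task slowing.
    """
    lo, hi = config.isi_range
    expected = config.run_duration / ((lo + hi) / 2.0)
    if abs(expected - config.n_trials) > 0.25 * config.n_trials:
        raise ValueError(
            f"isi_range {config.isi_range} yields ~{expected:.0f} trials in "
            f"{config.run_duration}s; incompatible with n_trials={config.n_trials}"
        )
    rng = np.random.default_rng(seed)

    onsets = []
    t = float(rng.uniform(lo, hi))
    while t < config.run_duration:
        onsets.append(t)
        t += float(rng.uniform(lo, hi))
    onsets = np.asarray(onsets)
    n = len(onsets)

    if config.design == "blocked":
        if condition is None:
            raise ValueError("blocked design requires an explicit condition")
        seq = [condition] * n
    else:
        seq = intermixed_sequence(n, config.conditions, config.max_consecutive, rng)

    mult = np.ones(n)
    for i, c in enumerate(seq):
        if c in ("gain", "loss"):
            mult[i] *= 1.0 - config.incentive_speedup
        if c == "loss":
            mult[i] *= 1.0 - config.loss_extra_speedup
    base = config.rt_mu * np.exp(config.rt_sigma * rng.standard_normal(n))
    rt = base * mult + config.tot_slowing * onsets / 60.0
    if config.lapse_prob > 0:
        lapses = rng.random(n) < config.lapse_prob
        rt[lapses] *= rng.uniform(2.0, 3.0, size=int(lapses.sum()))
    return pd.DataFrame(
        {
            "subject": subject,
            "trial": np.arange(n),
            "onset_s": onsets,
            "condition": seq,
            "rt_ms": rt,
            "valid": True,
        }
    )


# ---------------------------------------------------------------------------
# pupil traces


@dataclass
class PupilSimConfig:
    sampling_rate: float = 60.0
    baseline_mm: float = 4.0
    incentive_dilation_mm: float = 0.25
    drift_mm_per_min: float = -0.05  # signed tonic drift (negative = decline)
    blink_rate: float = 8.0  # blinks per minute
    blink_duration_ms: tuple[float, float] = (100.0, 300.0)
    noise_sd_mm: float = 0.05
    cue_lead_s: float = 1.5  # incentive cue precedes the target onset

    def __post_init__(self) -> None:
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if self.baseline_mm <= 0:
            raise ValueError("baseline_mm must be positive")


def generate_pupil_trace(
    config: PupilSimConfig,
    events: pd.DataFrame | Sequence[tuple[float, str]],
    duration_s: float,
    seed,
) -> PupilTrace:
    """Simulate a tonic pupil-diameter series.

    ``events`` holds (onset_s, condition) rows of *target* onsets; the
    incentive cue precedes each target by ``cue_lead_s``, so the tonic
    level is ``baseline + dilation * [condition is incentivized] + drift
    * minutes + noise`` from the cue until the next cue.  Blinks arrive
    as a Poisson process and are flagged invalid.
    """
    if isinstance(events, pd.DataFrame):
        ev = list(zip(events["onset_s"], events["condition"]))
    else:
        ev = list(events)
    ev.sort(key=lambda x: x[0])
    if ev and (ev[0][0] < 0 or ev[-1][0] > duration_s):
        raise ValueError("event onsets must lie within the trace duration")
    rng = np.random.default_rng(seed)

    n = int(round(duration_s * config.sampling_rate)) + 1
    t = np.arange(n) / config.sampling_rate
    level = np.full(n, config.baseline_mm)
    starts = [max(0.0, o - config.cue_lead_s) for o, _ in ev]
    bounds = starts + [np.inf]
    for (onset, cond), start, nxt in zip(ev, starts, bounds[1:]):
        if cond in ("gain", "loss"):
            level[(t >= start) & (t < nxt)] += config.incentive_dilation_mm
    level = level + config.drift_mm_per_min * t / 60.0
    if config.noise_sd_mm > 0:
        level = level + config.noise_sd_mm * rng.standard_normal(n)

    valid = np.ones(n, dtype=bool)
    n_blinks = rng.poisson(config.blink_rate * duration_s / 60.0)
    starts = np.sort(rng.uniform(0, duration_s, size=n_blinks))
    durs = rng.uniform(*config.blink_duration_ms, size=n_blinks) / 1000.0
    for s, d in zip(starts, durs):
        valid[(t >= s) & (t < s + d)] = False
    diameter = np.where(valid, level, np.nan)
    return PupilTrace(
        time_s=t,
        diameter_mm=diameter,
        valid=valid,
        sampling_rate=config.sampling_rate,
    )


# ---------------------------------------------------------------------------
# N-Back sessions


def _default_hit_rates() -> dict[tuple[int, str], float]:
    gain = {1: 0.95, 2: 0.88, 3: 0.78, 4: 0.60}
    loss = {1: 0.95, 2: 0.88, 3: 0.80, 4: 0.68}
    return {(l, "gain"): gain[l] for l in gain} | {(l, "loss"): loss[l] for l in loss}


def _default_fa_rates() -> dict[tuple[int, str], float]:
    gain = {1: 0.02, 2: 0.04, 3: 0.06, 4: 0.08}
    loss = {1: 0.02, 2: 0.04, 3: 0.06, 4: 0.07}
    return {(l, "gain"): gain[l] for l in gain} | {(l, "loss"): loss[l] for l in loss}


@dataclass
class NBackSimConfig:
    loads: tuple[int, ...] = (1, 2, 3, 4)
    n_stimuli: int = 64
    n_targets: int = 16
    hit_rate_by_load_frame: Mapping[tuple[int, str], float] = field(
        default_factory=_default_hit_rates
    )
    fa_rate_by_load_frame: Mapping[tuple[int, str], float] = field(
        default_factory=_default_fa_rates
    )

    def __post_init__(self) -> None:
        for p in list(self.hit_rate_by_load_frame.values()) + list(
            self.fa_rate_by_load_frame.values()
        ):
            if not 0.0 <= p <= 1.0:
                raise ValueError("hit/FA rates must lie in [0, 1]")


def generate_nback_session(
    config: NBackSimConfig,
    load: int,
    frame: str,
    seed,
    subject: str = "s01",
) -> pd.DataFrame:
    """Simulate one N-Back run at a given load and frame.

    The letter stream contains *exactly* ``n_targets`` lag-``load``
    matches: target letters copy the letter ``load`` positions back, and
    every other letter is sampled to differ from it, so accidental
    matches cannot occur and SDT denominators are fixed.
    """
    if load not in config.loads:
        raise ValueError(f"load {load} not in configured loads {config.loads}")
    if frame not in ("gain", "loss"):
        raise ValueError(f"unknown frame {frame!r}")
    if config.n_targets > config.n_stimuli - load:
        raise ValueError("too many targets for this load and run length")
    rng = np.random.default_rng(seed)

    n = config.n_stimuli
    target_pos = set(
        rng.choice(np.arange(load, n), size=config.n_targets, replace=False).tolist()
    )
    pool = list(LETTER_POOL)
    letters: list[str] = []
    for i in range(n):
        if i in target_pos:
            letters.append(letters[i - load])
        elif i >= load:
            banned = letters[i - load]
            choices = [c for c in pool if c != banned]
            letters.append(choices[rng.integers(len(choices))])
        else:
            letters.append(pool[rng.integers(len(pool))])

    is_target = np.array([i in target_pos for i in range(n)])
    hit_p = config.hit_rate_by_load_frame[(load, frame)]
    fa_p = config.fa_rate_by_load_frame[(load, frame)]
    u = rng.random(n)
    press_target = np.where(is_target, u < hit_p, u < fa_p)
    response = np.where(press_target, "target", "nontarget")
    correct = press_target == is_target
    return pd.DataFrame(
        {
            "subject": subject,
            "load": load,
            "frame": frame,
            "trial": np.arange(n),
            "letter": letters,
            "is_target": is_target,
            "response": response,
            "correct": correct,
        }
    )


# ---------------------------------------------------------------------------
# agent populations and choice datasets


def generate_agent_population(
    n_subjects: int,
    seed,
    family: str = "quadratic",
    k_log10_mean: float = -2.7,
    k_log10_sd: float = 0.4,
    k_loss_ratio: float = 0.7,
    beta: float = 10.0,
    p_sigmoid: float | None = None,
) -> list[AgentParams]:
    """Draw a population of agents with log-normal gain discount rates and
    ``k_loss = k_loss_ratio * k_gain``."""
    rng = np.random.default_rng(seed)
    agents = []
    for i in range(n_subjects):
        k_gain = 10.0 ** (k_log10_mean + k_log10_sd * rng.standard_normal())
        agents.append(
            AgentParams(
                subject_id=f"s{i + 1:03d}",
                family=family,
                k_gain=k_gain,
                k_loss=k_loss_ratio * k_gain,
                beta=beta,
                p_sigmoid=p_sigmoid,
                rng_seed=int(rng.integers(2**31)),
            )
        )
    return agents


def generate_choice_dataset(
    agents: Sequence[AgentParams],
    effort_levels: Sequence[float],
    config: StaircaseConfig | None = None,
    *,
    seed=0,
    effort_low: float = 1.0,
    frames: Sequence[str] = ("gain", "loss"),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run titration sessions for a whole population.

    Returns ``(choices, indifference)`` tidy tables.  Choices carry every
    staircase trial (net amounts) so the discounting models can be fitted
    directly; indifference rows feed the AUC summary.
    """
    from .staircase import _as_seed_key, run_staircase

    if config is None:
        config = StaircaseConfig()
    seed_key = _as_seed_key(seed)
    choice_rows = []
    indiff_rows = []
    for ai, agent in enumerate(agents):
        for fi, frame in enumerate(frames):
            for li, level in enumerate(effort_levels):
                res = run_staircase(
                    agent, level, frame, config,
                    seed=seed_key + [ai, fi, li], effort_low=effort_low,
                )
                for trial, choice in zip(res.trials, res.choices):
                    choice_rows.append(
                        dict(
                            subject=agent.subject_id,
                            frame=frame,
                            effort_low=trial.effort_low,
                            effort_high=trial.effort_high,
                            amount_low=trial.amount_low,
                            amount_high=trial.amount_high,
                            choice=choice,
                        )
                    )
                indiff_rows.append(
                    dict(
                        subject=agent.subject_id,
                        frame=frame,
                        effort_level=level,
                        indifference=res.indifference,
                    )
                )
    return pd.DataFrame(choice_rows), pd.DataFrame(indiff_rows)


def trials_from_frame(df: pd.DataFrame) -> tuple[list[ChoiceTrial], list[str]]:
    """Rebuild ChoiceTrial objects (+ choices) from a choices CSV table."""
    trials, choices = [], []
    for row in df.itertuples():
        endowment = row.amount_high if row.frame == "loss" else None
        trials.append(
            ChoiceTrial(
                effort_low=row.effort_low,
                effort_high=row.effort_high,
                amount_low=row.amount_low,
                amount_high=row.amount_high,
                frame=row.frame,
                endowment=endowment,
            )
        )
        choices.append(row.choice)
    return trials, choices
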