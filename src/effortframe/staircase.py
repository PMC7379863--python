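"""Adaptive staircase titration of effort-indifference points.

Each titration run is a midpoint bisection on the offer interval
``[0, amount_high]``: choosing the low-effort option means the current
offer was acceptable (upper bound moves down), choosing the high-effort
option means it was not (lower bound moves up).  After ``max_iterations``
choices the indifference point is taken as the midpoint of the final
interval; estimates are averaged across runs.

Loss-framed trials are *pegged* to gain trials: the participant starts
from an endowment equal to the fixed high-effort amount and loses
``endowment - amount_low`` when choosing the low-effort option, so the
net outcomes of the two frames are identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np

FRAMES = ("gain", "loss")
LOW, HIGH = "low_effort", "high_effort"


@dataclass(frozen=True)
class ChoiceTrial:
    """One titration choice between a variable low-effort and a fixed
    high-effort option.

    Amounts are stored as *net outcomes* in both frames; for loss-framed
    trials the displayed loss amounts are derived properties.
    """

    effort_low: float
    effort_high: float
    amount_low: float
    amount_high: float
    frame: str = "gain"
    endowment: float | None = None

    def __post_init__(self) -> None:
        if self.frame not in FRAMES:
            raise ValueError(f"unknown frame {self.frame!r}")
        if self.amount_low < 0 or self.amount_high < 0:
            raise ValueError("amounts must be non-negative")
        if self.amount_low > self.amount_high:
            raise ValueError("amount_low must not exceed amount_high")
        if not self.effort_low < self.effort_high:
            raise ValueError("effort_low must be smaller than effort_high")
        if self.frame == "loss":
            if self.endowment is None:
                raise ValueError("loss-framed trial requires an endowment")
            if self.amount_low > self.endowment:
                raise ValueError("amount_low exceeds the endowment")

    @property
    def net_low(self) -> float:
        """Net outcome of the low-effort option (identical across frames)."""
        return self.amount_low

    @property
    def net_high(self) -> float:
        return self.amount_high

    @property
    def loss_low(self) -> float:
        """Displayed loss for the low-effort option (loss frame only)."""
        if self.frame != "loss":
            raise ValueError("loss_low is defined for loss-framed trials only")
        assert self.endowment is not None
        return self.endowment - self.amount_low

    @property
    def loss_high(self) -> float:
        if self.frame != "loss":
            raise ValueError("loss_high is defined for loss-framed trials only")
        return 0.0


def peg_loss_trial(gain_trial: ChoiceTrial, endowment: float) -> ChoiceTrial:
    """Construct the loss-framed trial whose net outcomes equal ``gain_trial``'s.

    The endowment must equal the gain trial's fixed high-effort amount so
    that losing nothing (high effort) nets the same as earning it.
    """
    if gain_trial.frame != "gain":
        raise ValueError("peg_loss_trial expects a gain-framed trial")
    if endowment != gain_trial.amount_high:
        raise ValueError("endowment must equal the gain trial's amount_high")
    if gain_trial.amount_low > endowment:
        raise ValueError("amount_low exceeds the endowment")
    return replace(gain_trial, frame="loss", endowment=endowment)


def unpeg_loss_trial(loss_trial: ChoiceTrial) -> ChoiceTrial:
    """Inverse of :func:`peg_loss_trial`; recovers the gain trial exactly."""
    if loss_trial.frame != "loss":
        raise ValueError("unpeg_loss_trial expects a loss-framed trial")
    return replace(loss_trial, frame="gain", endowment=None)


@dataclass
class StaircaseState:
    lower_bound: float
    upper_bound: float
    current_offer: float
    iteration: int = 0
    max_iterations: int = 5
    history: list[tuple[float, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.lower_bound <= self.current_offer <= self.upper_bound:
            raise ValueError("current_offer outside [lower_bound, upper_bound]")

    @property
    def estimate(self) -> float:
        """Midpoint of the current interval."""
        return 0.5 * (self.lower_bound + self.upper_bound)

    @property
    def done(self) -> bool:
        return self.iteration >= self.max_iterations


def init_staircase(amount_high: float = 10.0, max_iterations: int = 5) -> StaircaseState:
    return StaircaseState(
        lower_bound=0.0,
        upper_bound=amount_high,
        current_offer=amount_high / 2.0,
        max_iterations=max_iterations,
    )


def update_staircase(state: StaircaseState, choice: str) -> StaircaseState:
    """One bisection step.

    ``low_effort`` lowers the upper bound to the current offer,
    ``high_effort`` raises the lower bound; the next offer is the midpoint
    of the updated interval.
    """
    if state.done:
        raise ValueError("staircase already ran for max_iterations trials")
    if choice not in (LOW, HIGH):
        raise ValueError(f"unknown choice {choice!r}")
    lower, upper = state.lower_bound, state.upper_bound
    if choice == LOW:
        upper = state.current_offer
    else:
        lower = state.current_offer
    return StaircaseState(
        lower_bound=lower,
        upper_bound=upper,
        current_offer=0.5 * (lower + upper),
        iteration=state.iteration + 1,
        max_iterations=state.max_iterations,
        history=state.history + [(state.current_offer, choice)],
    )


@dataclass
class StaircaseConfig:
    amount_high: float = 10.0
    n_iterations: int = 5
    n_runs: int = 2


@dataclass
class StaircaseResult:
    indifference: float
    run_estimates: list[float]
    trials: list[ChoiceTrial]
    choices: list[str]


def _as_seed_key(seed) -> list[int]:
    if isinstance(seed, (int, np.integer)):
        return [int(seed)]
    return [int(s) for s in seed]


def run_staircase(
    agent,
    effort_level: float,
    frame: str,
    config: StaircaseConfig | None = None,
    *,
    seed=0,
    effort_low: float = 1.0,
    choices: Sequence[str] | None = None,
) -> StaircaseResult:
    """Run the full titration for one (agent, effort level, frame) cell.

    ``config.n_runs`` independent bisection runs of ``config.n_iterations``
    trials each are executed; the returned indifference point is the mean
    of the per-run terminal midpoints.

    Choice noise for run ``r`` is drawn from ``default_rng([*seed, r])``
    regardless of frame, so two frames run with equal discount rates and
    the same seed produce identical estimates, and interleaving trials
    across staircases cannot alter any staircase's outcome.

    In replay mode a recorded flat ``choices`` sequence (run-major) is
    consumed instead of simulating the agent.
    """
    from .synthetic_data import simulate_choice  # deferred: avoids an import cycle

    if config is None:
        config = StaircaseConfig()
    if frame not in FRAMES:
        raise ValueError(f"unknown frame {frame!r}")
    if choices is not None and len(choices) != config.n_runs * config.n_iterations:
        raise ValueError("replay sequence length must equal n_runs * n_iterations")

    seed_key = _as_seed_key(seed)
    estimates: list[float] = []
    all_trials: list[ChoiceTrial] = []
    all_choices: list[str] = []
    for run in range(config.n_runs):
        rng = np.random.default_rng(seed_key + [run])
        state = init_staircase(config.amount_high, config.n_iterations)
        for i in range(config.n_iterations):
            trial = ChoiceTrial(
                effort_low=effort_low,
                effort_high=effort_level,
                amount_low=state.current_offer,
                amount_high=config.amount_high,
            )
            if frame == "loss":
                trial = peg_loss_trial(trial, config.amount_high)
            if choices is not None:
                choice = choices[run * config.n_iterations + i]
                if choice not in (LOW, HIGH):
                    raise ValueError(f"unknown choice {choice!r} in replay sequence")
            else:
                choice = simulate_choice(agent, trial, rng=rng)
            state = update_staircase(state, choice)
            all_trials.append(trial)
            all_choices.append(choice)
        estimates.append(state.estimate)
    return StaircaseResult(
        indifference=float(np.mean(estimates)),
        run_estimates=estimates,
        trials=all_trials,
        choices=all_choices,
    )


def run_titration_session(
    agent,
    effort_levels: Sequence[float],
    config: StaircaseConfig | None = None,
    *,
    seed=0,
    effort_low: float = 1.0,
    frames: Sequence[str] = FRAMES,
    design: str = "blocked",
    frame_seed_offset: bool = True,
) -> "pd.DataFrame":
    """Titrate every (frame, effort level) cell for one agent.

    ``design="interleaved"`` presents trials from all active staircases in
    a shuffled order while each staircase updates separately, mirroring
    the intermixed task variant; per-frame estimates are identical to the
    blocked schedule because every staircase owns its noise stream.

    With ``frame_seed_offset`` (default) gain and loss staircases consume
    distinct noise; disable it to make framing value-neutral under equal
    discount rates.
    """
    import pandas as pd

    if config is None:
        config = StaircaseConfig()
    if design not in ("blocked", "interleaved"):
        raise ValueError(f"unknown design {design!r}")
    seed_key = _as_seed_key(seed)

    cells = [(f, lev) for f in frames for lev in effort_levels]
    cell_seed = {
        (f, lev): seed_key + ([fi] if frame_seed_offset else []) + [li]
        for fi, f in enumerate(frames)
        for li, lev in enumerate(effort_levels)
    }

    if design == "blocked":
        order = list(cells)
    else:
        # genuine interleaving: one pending trial slot per staircase trial,
        # scheduled in shuffled order
        slots = [
            cell
            for cell in cells
            for _ in range(config.n_runs * config.n_iterations)
        ]
        sched_rng = np.random.default_rng(seed_key + [997])
        sched_rng.shuffle(slots)

    rows = []
    if design == "blocked":
        for frame, level in order:
            res = run_staircase(
                agent, level, frame, config,
                seed=cell_seed[(frame, level)], effort_low=effort_low,
            )
            rows.append((frame, level, res.indifference))
    else:
        # per-cell generator state: run index, state, rng
        runs_done: dict[tuple, int] = {c: 0 for c in cells}
        states: dict[tuple, StaircaseState | None] = {c: None for c in cells}
        rngs: dict[tuple, np.random.Generator] = {}
        run_estimates: dict[tuple, list[float]] = {c: [] for c in cells}
        from .synthetic_data import simulate_choice

        for frame, level in slots:
            cell = (frame, level)
            if states[cell] is None:
                r = runs_done[cell]
                states[cell] = init_staircase(config.amount_high, config.n_iterations)
                rngs[cell] = np.random.default_rng(cell_seed[cell] + [r])
            state = states[cell]
            trial = ChoiceTrial(
                effort_low=effort_low,
                effort_high=level,
                amount_low=state.current_offer,
                amount_high=config.amount_high,
            )
            if frame == "loss":
                trial = peg_loss_trial(trial, config.amount_high)
            choice = simulate_choice(agent, trial, rng=rngs[cell])
            state = update_staircase(state, choice)
            if state.done:
                run_estimates[cell].append(state.estimate)
                runs_done[cell] += 1
                states[cell] = None
            else:
                states[cell] = state
        for frame, level in cells:
            rows.append((frame, level, float(np.mean(run_estimates[(frame, level)]))))

    subject = getattr(agent, "subject_id", "s01")
    return pd.DataFrame(rows, columns=["frame", "effort_level", "indifference"]).assign(
        subject=subject
    )[["subject", "frame", "effort_level", "indifference"]]
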