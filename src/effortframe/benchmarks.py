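"""Desk-scale recovery benchmarks.

Each function runs one self-contained validation study against an
independent oracle (bisection bound, fine-grid quadrature, root-finding
CDF inversion, Monte-Carlo calibration) and returns plain numbers.  The
acceptance test suite asserts thresholds on these; the reporting script
dumps them as JSON.  Everything is seeded and CPU-cheap.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import optimize, special, stats as sps

from . import discounting, performance, pipeline, pupillometry, synthetic_data
from .staircase import StaircaseConfig, run_staircase, unpeg_loss_trial
from .synthetic_data import AgentParams, generate_agent_population


# ---------------------------------------------------------------------------
# staircase convergence


def staircase_convergence(n_thresholds: int = 100, seed: int = 0) -> dict:
    """Max |estimate - truth| over deterministic threshold agents whose true
    indifference points lie on a grid in (0, 10)."""
    config = StaircaseConfig()
    level, e_low, m = 10.0, 1.0, 10.0
    thresholds = np.linspace(0.05, 9.95, n_thresholds)
    errors = []
    for thr in thresholds:
        # linear-family agent whose true indifference point at this level
        # is exactly thr: thr (1 - k e_low) = m (1 - k level)
        k = (m - thr) / (m * level - thr * e_low)
        agent = AgentParams(
            subject_id="thr", family="linear", k_gain=k, k_loss=k,
            beta=np.inf, rng_seed=0,
        )
        res = run_staircase(agent, level, "gain", config, seed=seed)
        errors.append(abs(res.indifference - thr))
    errors = np.asarray(errors)
    bound = config.amount_high / 2**config.n_iterations
    return {
        "max_abs_error": float(errors.max()),
        "bound": bound,
        "fraction_within_bound": float(np.mean(errors <= bound)),
        "n": n_thresholds,
    }


# ---------------------------------------------------------------------------
# AUC vs quadrature oracle


def auc_oracle_agreement(n_tables: int = 1000, seed: int = 0) -> dict:
    """Max |trapezoid AUC - fine-grid quadrature| over random monotone
    indifference tables."""
    rng = np.random.default_rng(seed)
    levels = np.array([5.0, 10.0, 20.0, 30.0])
    ref = 1.0
    errs = []
    for _ in range(n_tables):
        vals = np.sort(rng.uniform(0, 10, size=levels.size))[::-1]
        auc = discounting.compute_auc(levels, vals, amount_high=10.0,
                                      reference_level=ref)
        # oracle: dense sampling of the piecewise-linear curve
        x = np.concatenate([[ref], levels]) / levels[-1]
        y = np.concatenate([[1.0], vals / 10.0])
        grid = np.linspace(x[0], x[-1], 200_001)
        fine = np.interp(grid, x, y)
        oracle = np.trapezoid(fine, grid) / (x[-1] - x[0])
        errs.append(abs(auc - oracle))
    return {"max_abs_error": float(np.max(errs)), "n": n_tables}


# ---------------------------------------------------------------------------
# parameter / model recovery


def _recovery_battery(n_agents: int = 30, seed: int = 0):
    """Quadratic agents, k log-uniform over two decades, beta=10, 40
    staircase choice trials each (duration effort levels)."""
    rng = np.random.default_rng(seed)
    levels = (5.0, 10.0, 20.0, 30.0)
    agents = []
    for i in range(n_agents):
        k = 10.0 ** rng.uniform(-4, -2)
        agents.append(
            AgentParams(
                subject_id=f"s{i + 1:03d}", family="quadratic",
                k_gain=k, k_loss=k, beta=10.0,
                rng_seed=int(rng.integers(2**31)),
            )
        )
    choices, _ = synthetic_data.generate_choice_dataset(
        agents, levels, seed=seed + 1, frames=("gain",)
    )
    return agents, choices


def parameter_recovery(n_agents: int = 30, seed: int = 0,
                       battery=None) -> dict:
    """Spearman correlation and median relative error of fitted vs true
    quadratic discount rates."""
    agents, choices = battery if battery is not None else _recovery_battery(
        n_agents, seed
    )
    true_k, fit_k = [], []
    for agent in agents:
        cell = choices[choices["subject"] == agent.subject_id]
        trials, ch = synthetic_data.trials_from_frame(cell)
        fit = discounting.fit_model(trials, ch, "quadratic",
                                    subject_id=agent.subject_id)
        true_k.append(agent.k_gain)
        fit_k.append(fit.k)
    true_k, fit_k = np.asarray(true_k), np.asarray(fit_k)
    rel_err = np.abs(fit_k - true_k) / true_k
    rho = sps.spearmanr(true_k, fit_k).statistic
    return {
        "spearman": float(rho),
        "median_relative_error": float(np.median(rel_err)),
        "n": len(agents),
    }


def model_selection_recovery(n_agents: int = 30, seed: int = 0,
                             battery=None) -> dict:
    """Fit all five families to quadratic-generated data; BIC comparison."""
    agents, choices = battery if battery is not None else _recovery_battery(
        n_agents, seed
    )
    fits = []
    for agent in agents:
        cell = choices[choices["subject"] == agent.subject_id]
        trials, ch = synthetic_data.trials_from_frame(cell)
        fits.extend(
            discounting.fit_all_families(trials, ch,
                                         subject_id=agent.subject_id)
        )
    comp = discounting.compare_models(fits)
    winners = comp.per_subject.drop_duplicates(["subject", "frame"])["winner"]
    frac_quadratic = float((winners == "quadratic").mean())
    return {
        "group_winner": comp.winner,
        "group_winner_is_quadratic": comp.winner == "quadratic",
        "per_subject_quadratic_fraction": frac_quadratic,
        "n": len(agents),
    }


# ---------------------------------------------------------------------------
# end-to-end loss-aversion power


def loss_aversion_power(
    n_replicates: int = 200,
    n_subjects: int = 30,
    k_loss_ratio: float = 0.7,
    seed: int = 0,
    alpha: float = 0.05,
) -> dict:
    """Fraction of pipeline replicates whose paired loss-vs-gain AUC
    contrast is significant (load-effort titration, quadratic agents)."""
    levels = (2.0, 3.0, 4.0)
    rejections = 0
    mean_diffs = []
    for rep in range(n_replicates):
        agents = generate_agent_population(
            n_subjects,
            seed=[seed, rep, 0],
            family="quadratic",
            k_log10_mean=-1.3,
            k_log10_sd=0.3,
            k_loss_ratio=k_loss_ratio,
            beta=10.0,
        )
        _, indiff = synthetic_data.generate_choice_dataset(
            agents, levels, seed=[seed, rep, 1]
        )
        auc = discounting.auc_table(indiff)
        wide = auc.pivot(index="subject", columns="frame", values="auc")
        contrast = discounting.gain_loss_contrast(wide["gain"], wide["loss"])
        rejections += contrast.p < alpha
        mean_diffs.append(contrast.mean_difference)
    return {
        "rejection_rate": rejections / n_replicates,
        "mean_auc_difference": float(np.mean(mean_diffs)),
        "n": n_replicates,
    }


# ---------------------------------------------------------------------------
# SDT oracle


def _ppf_oracle(q: float) -> float:
    """Inverse standard-normal CDF by bracketed root finding on the exact
    CDF (independent of scipy's ppf implementation)."""
    return optimize.brentq(
        lambda x: special.ndtr(x) - q, -12.0, 12.0, xtol=1e-13, rtol=1e-14
    )


def sdt_oracle_agreement() -> dict:
    """Max discrepancy between sdt_metrics and closed forms evaluated with
    root-finding CDF inversion, over a grid of count tables including
    corrected 0/1 cells."""
    n_sig, n_noise = 16, 48
    errs = []
    for hits in range(0, n_sig + 1, 2):
        for fas in range(0, n_noise + 1, 4):
            counts = performance.SDTCounts(
                hits, n_sig - hits, fas, n_noise - fas
            )
            m = performance.sdt_metrics(counts)
            h = hits / n_sig if 0 < hits < n_sig else (
                1 / (2 * n_sig) if hits == 0 else 1 - 1 / (2 * n_sig)
            )
            f = fas / n_noise if 0 < fas < n_noise else (
                1 / (2 * n_noise) if fas == 0 else 1 - 1 / (2 * n_noise)
            )
            zh, zf = _ppf_oracle(h), _ppf_oracle(f)
            errs.append(abs(m.d_prime - (zh - zf)))
            errs.append(abs(m.beta_bias - np.exp((zf**2 - zh**2) / 2)))
    return {"max_abs_error": float(np.max(errs)), "n": len(errs) // 2}


# ---------------------------------------------------------------------------
# pegging invariant


def pegging_invariant(n_agents: int = 20, seed: int = 0) -> dict:
    """Exhaustive check that every loss-frame staircase trial nets exactly
    what its unpegged gain twin nets."""
    agents = generate_agent_population(n_agents, seed=seed, beta=5.0)
    n_checked, n_equal = 0, 0
    for ai, agent in enumerate(agents):
        for li, level in enumerate((5.0, 10.0, 20.0, 30.0)):
            res = run_staircase(agent, level, "loss", seed=[seed, ai, li])
            for trial in res.trials:
                twin = unpeg_loss_trial(trial)
                n_checked += 1
                n_equal += (
                    trial.net_low == twin.amount_low
                    and trial.net_high == twin.amount_high
                    and trial.loss_low == trial.endowment - twin.amount_low
                )
    return {
        "fraction_exact": n_equal / n_checked,
        "n": n_checked,
    }


# ---------------------------------------------------------------------------
# time-on-task slope recovery


def slope_recovery(n_replicates: int = 1000, seed: int = 0) -> dict:
    """Bias of vigilance RT and pupil tonic time-on-task slope estimators
    against the generating drifts, in Monte-Carlo standard errors."""
    vcfg = synthetic_data.VigilanceSimConfig(
        design="blocked", tot_slowing=5.0, rt_sigma=0.15,
        incentive_speedup=0.0,
    )
    vig_slopes = []
    for rep in range(n_replicates):
        df = synthetic_data.generate_vigilance_session(
            vcfg, [seed, 1, rep], condition="neutral"
        )
        vig_slopes.append(
            performance.tot_slope(df["rt_ms"], df["onset_s"] / 60.0)
        )
    vig_slopes = np.asarray(vig_slopes)
    vig_se = vig_slopes.std(ddof=1) / np.sqrt(n_replicates)
    vig_z = (vig_slopes.mean() - vcfg.tot_slowing) / vig_se

    pcfg = synthetic_data.PupilSimConfig(
        drift_mm_per_min=-0.05, noise_sd_mm=0.05, blink_rate=6.0,
        incentive_dilation_mm=0.0,
    )
    duration = 300.0
    onsets = np.arange(8.0, duration - 4.0, 7.5)
    events = [(float(o), "neutral") for o in onsets]
    pup_slopes = []
    for rep in range(n_replicates):
        trace = synthetic_data.generate_pupil_trace(
            pcfg, events, duration, [seed, 2, rep]
        )
        clean = pupillometry.preprocess(trace)
        ep = pupillometry.extract_prestim(clean, onsets)
        sl = pupillometry.pupil_tot_slope(ep)
        pup_slopes.append(float(sl["slope_mm_per_min"].iloc[0]))
    pup_slopes = np.asarray(pup_slopes)
    pup_se = pup_slopes.std(ddof=1) / np.sqrt(n_replicates)
    pup_z = (pup_slopes.mean() - pcfg.drift_mm_per_min) / pup_se

    return {
        "vigilance_mean_slope": float(vig_slopes.mean()),
        "vigilance_true_slope": vcfg.tot_slowing,
        "vigilance_bias_z": float(vig_z),
        "pupil_mean_slope": float(pup_slopes.mean()),
        "pupil_true_slope": pcfg.drift_mm_per_min,
        "pupil_bias_z": float(pup_z),
        "n": n_replicates,
    }


# ---------------------------------------------------------------------------
# ANOVA calibration


def anova_calibration(
    n_replicates: int = 2000,
    n_subjects: int = 20,
    n_conditions: int = 3,
    seed: int = 0,
    alpha: float = 0.05,
) -> dict:
    """Type-I error of rm_anova and mixed_anova_order under a Gaussian
    null."""
    rng = np.random.default_rng(seed)
    rm_rej = 0
    for _ in range(n_replicates):
        x = rng.standard_normal((n_subjects, n_conditions))
        rm_rej += pipeline.rm_anova(x).p < alpha
    groups = np.array(["a"] * (n_subjects // 2) + ["b"] * (n_subjects - n_subjects // 2))
    mx_rej = 0
    for _ in range(n_replicates):
        x = rng.standard_normal((n_subjects, 2))
        mx_rej += pipeline.mixed_anova_order(x, groups).p < alpha
    return {
        "rm_anova_type1": rm_rej / n_replicates,
        "mixed_anova_type1": mx_rej / n_replicates,
        "n": n_replicates,
    }
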