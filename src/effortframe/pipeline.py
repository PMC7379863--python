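"""End-to-end experiment orchestration and the repeated-measures statistics.

``run_experiment`` composes the generators and scorers into the four
experiment layouts (blocked vigilance + duration discounting; intermixed
vigilance; incentivized N-Back; load-based discounting) and emits tidy
CSV intermediates plus a versioned JSON report.  Every statistic in the
report is recomputable from an intermediate file.

Statistical conventions: all p values are two-sided, no sphericity
correction is applied by default, and with the balanced designs produced
here Type II and Type III sums of squares coincide.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import discounting, performance, pupillometry, synthetic_data
from .staircase import StaircaseConfig
from .synthetic_data import (
    NBackSimConfig,
    PupilSimConfig,
    VigilanceSimConfig,
    generate_agent_population,
    generate_choice_dataset,
)

REPORT_SCHEMA_VERSION = "1.0"

DURATION_LEVELS = (5.0, 10.0, 20.0, 30.0)
NBACK_LEVELS = (2.0, 3.0, 4.0)


@dataclass
class StatResult:
    name: str
    statistic: float
    df: tuple[float, float] | tuple[float]
    p: float
    direction: str | None = None
    extra: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "statistic": self.statistic,
            "df": list(self.df),
            "p": self.p,
            "direction": self.direction,
            **({"extra": self.extra} if self.extra else {}),
        }


def rm_anova(values: np.ndarray, name: str = "rm_anova") -> StatResult:
    """One-way repeated-measures ANOVA on an (n subjects x c conditions)
    complete matrix; df = (c-1, (c-1)(n-1))."""
    x = np.asarray(values, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError("values must be a 2-D subjects x conditions matrix")
    if np.any(np.isnan(x)):
        raise ValueError("missing cells are not allowed")
    n, c = x.shape
    grand = x.mean()
    ss_cond = n * np.sum((x.mean(axis=0) - grand) ** 2)
    ss_subj = c * np.sum((x.mean(axis=1) - grand) ** 2)
    ss_total = np.sum((x - grand) ** 2)
    ss_err = ss_total - ss_cond - ss_subj
    df1, df2 = c - 1, (c - 1) * (n - 1)
    ms_err = ss_err / df2
    if ss_cond <= 0:
        return StatResult(name, 0.0, (df1, df2), 1.0)
    if ms_err <= 0:
        return StatResult(name, math.inf, (df1, df2), 0.0,
                          extra={"degenerate": True})
    f = (ss_cond / df1) / ms_err
    p = float(sps.f.sf(f, df1, df2))
    return StatResult(name, float(f), (df1, df2), p)


def paired_t(a, b, name: str = "paired_t") -> StatResult:
    """Two-sided paired t test of a vs b (statistic for a - b)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.size < 2:
        raise ValueError("paired samples required")
    d = a - b
    if np.allclose(np.std(d, ddof=1), 0):
        if np.allclose(d.mean(), 0):
            return StatResult(name, 0.0, (a.size - 1,), 1.0,
                              extra={"degenerate": True})
        t = math.inf if d.mean() > 0 else -math.inf
        return StatResult(name, t, (a.size - 1,), 0.0, extra={"degenerate": True})
    res = sps.ttest_rel(a, b)
    return StatResult(name, float(res.statistic), (a.size - 1,),
                      float(res.pvalue))


def mixed_anova_order(
    values: np.ndarray,
    groups: Sequence,
    name: str = "incentive_x_order",
) -> StatResult:
    """Incentive x Order interaction from a 2 (within) x 2 (between) mixed
    design.

    ``values`` is (n subjects x 2 conditions); ``groups`` assigns each
    subject to one of two order groups.  For a 2x2 design the interaction
    F equals the squared two-sample t on the within-subject difference
    scores, df = (1, n-2).  Within-group paired t follow-ups are attached.
    """
    x = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    if x.ndim != 2 or x.shape[1] != 2:
        raise ValueError("values must be n x 2 (two within-subject conditions)")
    if groups.shape[0] != x.shape[0]:
        raise ValueError("one group label per subject required")
    levels = np.unique(groups)
    if levels.size != 2:
        raise ValueError("exactly two order groups required")
    d = x[:, 1] - x[:, 0]
    d1, d2 = d[groups == levels[0]], d[groups == levels[1]]
    if d1.size < 2 or d2.size < 2:
        raise ValueError("each order group needs at least 2 subjects")
    n = x.shape[0]
    pooled_var = (
        np.sum((d1 - d1.mean()) ** 2) + np.sum((d2 - d2.mean()) ** 2)
    ) / (n - 2)
    if pooled_var <= 0:
        # zero within-group variance of difference scores
        f = 0.0 if np.isclose(d1.mean(), d2.mean()) else math.inf
        p = 1.0 if f == 0.0 else 0.0
        t_res = None
    else:
        t_res = sps.ttest_ind(d1, d2, equal_var=True)
        f = float(t_res.statistic**2)
        p = float(t_res.pvalue)
    followups = {}
    for lev in levels:
        sub = x[groups == lev]
        r = paired_t(sub[:, 1], sub[:, 0], name=f"within_{lev}")
        followups[str(lev)] = r.to_dict()
    return StatResult(
        name,
        f,
        (1, n - 2),
        p,
        extra={"followups": followups},
    )


# ---------------------------------------------------------------------------
# experiment configuration


@dataclass
class ExperimentConfig:
    experiment: str = "exp3b"
    n_subjects: int = 30
    family: str = "quadratic"
    k_log10_mean: float | None = None  # default depends on the effort scale
    k_log10_sd: float = 0.4
    k_loss_ratio: float = 0.7
    beta: float = 10.0
    p_sigmoid: float | None = None
    staircase: StaircaseConfig = field(default_factory=StaircaseConfig)
    vigilance: VigilanceSimConfig = field(default_factory=VigilanceSimConfig)
    pupil: PupilSimConfig = field(default_factory=PupilSimConfig)
    nback: NBackSimConfig = field(default_factory=NBackSimConfig)
    min_pupil_trials: int = 23
    fit_models: bool = False
    master_seed: int = 0

    def __post_init__(self) -> None:
        if self.experiment not in ("exp1", "exp2", "exp3a", "exp3b"):
            raise ValueError(f"unknown experiment {self.experiment!r}")
        if self.n_subjects < 3:
            raise ValueError("n_subjects must be at least 3")
        if self.k_log10_mean is None:
            # duration effort runs to 30 min, load effort to 4-back
            self.k_log10_mean = -1.3 if self.experiment == "exp3b" else -2.7

    @property
    def effort_levels(self) -> tuple[float, ...]:
        return NBACK_LEVELS if self.experiment == "exp3b" else DURATION_LEVELS


def load_experiment_config(path) -> ExperimentConfig:
    """Build an ExperimentConfig from a YAML mapping mirroring the dataclass."""
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    for key, cls in (
        ("staircase", StaircaseConfig),
        ("vigilance", VigilanceSimConfig),
        ("pupil", PupilSimConfig),
        ("nback", NBackSimConfig),
    ):
        if key in raw and isinstance(raw[key], dict):
            sub = raw[key]
            for k, v in sub.items():
                if isinstance(v, list):
                    sub[k] = tuple(v)
            raw[key] = cls(**sub)
    return ExperimentConfig(**raw)


# ---------------------------------------------------------------------------
# stage runners


def _discounting_stage(config: ExperimentConfig, seed_tag: int) -> dict:
    agents = generate_agent_population(
        config.n_subjects,
        seed=[config.master_seed, seed_tag, 0],
        family=config.family,
        k_log10_mean=config.k_log10_mean,
        k_log10_sd=config.k_log10_sd,
        k_loss_ratio=config.k_loss_ratio,
        beta=config.beta,
        p_sigmoid=config.p_sigmoid,
    )
    choices, indiff = generate_choice_dataset(
        agents,
        config.effort_levels,
        config.staircase,
        seed=[config.master_seed, seed_tag, 1],
    )
    auc = discounting.auc_table(indiff, amount_high=config.staircase.amount_high)
    wide = auc.pivot(index="subject", columns="frame", values="auc")
    contrast = discounting.gain_loss_contrast(wide["gain"], wide["loss"])
    out = {
        "agents": agents,
        "choices": choices,
        "indifference": indiff,
        "auc": auc,
        "auc_contrast": contrast,
    }
    if config.fit_models:
        fits = []
        for subj, frame_df in choices.groupby("subject"):
            for frame, cell in frame_df.groupby("frame"):
                trials, ch = synthetic_data.trials_from_frame(cell)
                fits.extend(
                    discounting.fit_all_families(
                        trials, ch, subject_id=subj, frame=frame
                    )
                )
        comparison = discounting.compare_models(fits)
        out["model_comparison"] = comparison
        k_wide = (
            comparison.per_subject.query("family == @comparison.winner")
            .pivot(index="subject", columns="frame", values="k")
        )
        out["k_contrast"] = discounting.gain_loss_contrast(
            k_wide["gain"], k_wide["loss"], transform="sqrt"
        )
    return out


def _vigilance_stage(config: ExperimentConfig) -> dict:
    """Vigilance + pupillometry for exp1 (blocked runs) or exp2 (intermixed)."""
    blocked = config.experiment == "exp1"
    vcfg = config.vigilance
    all_trials, metric_rows, pupil_rows, included = [], [], [], []
    for i in range(config.n_subjects):
        subj = f"s{i + 1:03d}"
        sessions = []
        if blocked:
            run_conditions = ["baseline", "gain", "loss"]
            for ri, cond in enumerate(run_conditions):
                from dataclasses import replace as _rep

                cfg = _rep(vcfg, design="blocked")
                df = synthetic_data.generate_vigilance_session(
                    cfg, [config.master_seed, 10, i, ri], subject=subj,
                    condition=cond,
                )
                df["run"] = ri
                sessions.append(df)
        else:
            base_cfg = VigilanceSimConfig(
                **{**asdict(vcfg), "design": "blocked"}
            )
            df = synthetic_data.generate_vigilance_session(
                base_cfg, [config.master_seed, 10, i, 0], subject=subj,
                condition="baseline",
            )
            df["run"] = 0
            sessions.append(df)
            for ri in (1, 2):
                df = synthetic_data.generate_vigilance_session(
                    vcfg, [config.master_seed, 10, i, ri], subject=subj,
                )
                df["run"] = ri
                sessions.append(df)
        trials = pd.concat(sessions, ignore_index=True)
        all_trials.append(trials)

        base = trials[trials["condition"] == "baseline"]
        criterion = performance.rt_criterion(base["rt_ms"], base["valid"])
        scored = performance.score_vigilance(trials, criterion_ms=criterion)
        scored["subject"] = subj
        metric_rows.append(scored)

        # pupil: one trace per run (baseline included)
        epochs_all = []
        for ri, sess in enumerate(sessions):
            events = sess[["onset_s", "condition"]]
            trace = synthetic_data.generate_pupil_trace(
                config.pupil,
                events,
                duration_s=vcfg.run_duration,
                seed=[config.master_seed, 11, i, ri],
            )
            clean = pupillometry.preprocess(trace)
            ep = pupillometry.extract_prestim(
                clean, events["onset_s"].to_numpy(),
                events["condition"].tolist(),
            )
            ep["run"] = ri
            epochs_all.append(ep)
        epochs = pd.concat(epochs_all, ignore_index=True)
        epochs["subject"] = subj
        include = pupillometry.subject_inclusion(
            epochs, min_trials=config.min_pupil_trials
        )
        included.append(include)
        pupil_rows.append(epochs)

    trials_df = pd.concat(all_trials, ignore_index=True)
    metrics_df = pd.concat(metric_rows, ignore_index=True)
    epochs_df = pd.concat(pupil_rows, ignore_index=True)
    return {
        "trials": trials_df,
        "metrics": metrics_df,
        "epochs": epochs_df,
        "included": included,
    }


def _nback_stage(config: ExperimentConfig) -> dict:
    frames = ("gain", "loss")
    tables = []
    for i in range(config.n_subjects):
        subj = f"s{i + 1:03d}"
        for load in config.nback.loads:
            for fi, frame in enumerate(frames):
                tables.append(
                    synthetic_data.generate_nback_session(
                        config.nback, load, frame,
                        seed=[config.master_seed, 20, i, load, fi],
                        subject=subj,
                    )
                )
    trials = pd.concat(tables, ignore_index=True)
    scores = performance.score_nback(trials)
    return {"trials": trials, "scores": scores}


# ---------------------------------------------------------------------------
# report assembly


def _contrast_dict(c: discounting.ContrastResult) -> dict:
    return {
        "n": c.n,
        "mean_difference": c.mean_difference,
        "t": c.t,
        "df": c.df,
        "p": c.p,
        "degenerate": c.degenerate,
    }


def run_experiment(config: ExperimentConfig, outdir: str | Path | None = None) -> dict:
    """Run one experiment end to end; returns (and optionally writes) the
    report.  Deterministic under ``config.master_seed``."""
    report: dict = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "experiment": config.experiment,
        "n_subjects": config.n_subjects,
        "master_seed": config.master_seed,
        "stats": {},
    }
    files: dict[str, pd.DataFrame] = {}

    if config.experiment in ("exp1", "exp2", "exp3b"):
        disc = _discounting_stage(config, seed_tag=1)
        files["choices.csv"] = disc["choices"]
        files["indifference.csv"] = disc["indifference"]
        files["auc.csv"] = disc["auc"]
        report["stats"]["auc_loss_minus_gain"] = _contrast_dict(disc["auc_contrast"])
        if config.fit_models:
            comp = disc["model_comparison"]
            files["model_fits.csv"] = comp.per_subject
            files["model_group_bic.csv"] = comp.group
            report["stats"]["model_winner"] = comp.winner
            report["stats"]["sqrt_k_loss_minus_gain"] = _contrast_dict(
                disc["k_contrast"]
            )

    if config.experiment in ("exp1", "exp2"):
        vig = _vigilance_stage(config)
        files["vigilance_trials.csv"] = vig["trials"]
        files["vigilance_metrics.csv"] = vig["metrics"]
        files["pupil_epochs.csv"] = vig["epochs"]

        conds = (
            ["baseline", "gain", "loss"]
            if config.experiment == "exp1"
            else ["neutral", "gain", "loss"]
        )
        speed = vig["metrics"].pivot(
            index="subject", columns="condition", values="mean_speed"
        )[conds].to_numpy()
        report["stats"]["speed_rm_anova"] = rm_anova(
            speed, name="speed_incentive"
        ).to_dict()
        report["stats"]["speed_gain_vs_loss"] = paired_t(
            speed[:, 1], speed[:, 2], name="speed_gain_vs_loss"
        ).to_dict()
        pctf = vig["metrics"].pivot(
            index="subject", columns="condition", values="pct_faster"
        )
        report["stats"]["pct_faster_gain_mean"] = float(pctf["gain"].mean())
        report["stats"]["pct_faster_loss_mean"] = float(pctf["loss"].mean())

        ep = vig["epochs"]
        ep_ok = ep[ep["usable"] & ep["condition"].isin(conds)]
        prestim = (
            ep_ok.groupby(["subject", "condition"])["prestim_mean_mm"]
            .mean()
            .unstack()[conds]
        )
        mask = np.asarray(vig["included"])
        report["n_pupil_included"] = int(mask.sum())
        if mask.sum() >= 3:
            report["stats"]["pupil_rm_anova"] = rm_anova(
                prestim.to_numpy()[mask], name="pupil_incentive"
            ).to_dict()

        if config.experiment == "exp1":
            # alternating counterbalanced order groups
            groups = np.array(
                ["gain_first" if i % 2 == 0 else "loss_first"
                 for i in range(config.n_subjects)]
            )
            report["stats"]["speed_incentive_x_order"] = mixed_anova_order(
                speed[:, 1:3], groups
            ).to_dict()
            auc_wide = disc["auc"].pivot(
                index="subject", columns="frame", values="auc"
            )[["gain", "loss"]].to_numpy()
            report["stats"]["auc_incentive_x_order"] = mixed_anova_order(
                auc_wide, groups
            ).to_dict()

    if config.experiment == "exp3a":
        nb = _nback_stage(config)
        files["nback_trials.csv"] = nb["trials"]
        files["nback_scores.csv"] = nb["scores"]
        scores = nb["scores"]
        dp = scores.pivot_table(
            index="subject", columns=["frame", "load"], values="d_prime"
        )
        loads = sorted(config.nback.loads)
        gain_mat = dp["gain"][loads].to_numpy()
        loss_mat = dp["loss"][loads].to_numpy()
        report["stats"]["dprime_load_rm_anova_gain"] = rm_anova(
            gain_mat, name="dprime_load_gain"
        ).to_dict()
        per_load = {}
        for j, load in enumerate(loads):
            per_load[str(load)] = paired_t(
                loss_mat[:, j], gain_mat[:, j], name=f"dprime_loss_vs_gain_{load}"
            ).to_dict()
        report["stats"]["dprime_loss_vs_gain_by_load"] = per_load
        hr = scores.pivot_table(
            index="subject", columns=["frame", "load"], values="hit_rate"
        )
        top = max(loads)
        report["stats"]["hit_rate_loss_vs_gain_top_load"] = paired_t(
            hr["loss"][top], hr["gain"][top], name="hit_rate_top_load"
        ).to_dict()

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for fname, df in files.items():
            df.to_csv(outdir / fname, index=False)
        with open(outdir / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
    return report
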