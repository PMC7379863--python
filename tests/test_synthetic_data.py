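import math

import numpy as np
import pandas as pd
import pytest

from effortframe.staircase import HIGH, LOW, ChoiceTrial
from effortframe.synthetic_data import (
    AgentParams,
    NBackSimConfig,
    PupilSimConfig,
    VigilanceSimConfig,
    generate_agent_population,
    generate_nback_session,
    generate_pupil_trace,
    generate_vigilance_session,
    intermixed_sequence,
    simulate_choice,
)


class TestAgentParams:
    def test_rejects_negative_k(self):
        with pytest.raises(ValueError):
            AgentParams("s", "linear", -0.1, 0.1)

    def test_rejects_negative_beta(self):
        with pytest.raises(ValueError):
            AgentParams("s", "linear", 0.1, 0.1, beta=-1.0)

    def test_rejects_unknown_family(self):
        with pytest.raises(ValueError):
            AgentParams("s", "cubic", 0.1, 0.1)

    def test_sigmoid_needs_inflection(self):
        with pytest.raises(ValueError):
            AgentParams("s", "sigmoid", 0.1, 0.1)


class TestSimulateChoice:
    def test_deterministic_limit_prefers_higher_sv(self):
        agent = AgentParams("s", "linear", 0.0, 0.0, beta=math.inf)
        trial = ChoiceTrial(1, 30, 3.0, 10.0)  # k=0: SV_high=10 > SV_low=3
        assert simulate_choice(agent, trial) == HIGH

    def test_tie_resolves_low_effort(self):
        agent = AgentParams("s", "linear", 0.0, 0.0, beta=math.inf)
        trial = ChoiceTrial(1, 30, 10.0, 10.0)
        assert simulate_choice(agent, trial) == LOW

    def test_symmetric_choice_half_probability(self):
        agent = AgentParams("s", "linear", 0.0, 0.0, beta=2.0, rng_seed=0)
        trial = ChoiceTrial(1, 30, 10.0, 10.0)
        rng = np.random.default_rng(0)
        picks = [simulate_choice(agent, trial, rng=rng) for _ in range(4000)]
        assert np.mean([p == HIGH for p in picks]) == pytest.approx(0.5, abs=0.03)

    def test_quadratic_k_zero_always_high_below_ten(self):
        agent = AgentParams("s", "quadratic", 0.0, 0.0, beta=math.inf)
        for amount in np.linspace(0, 9.99, 20):
            assert simulate_choice(agent, ChoiceTrial(1, 30, amount, 10.0)) == HIGH

    def test_frame_selects_k(self):
        # k_loss=0: loss-framed high option keeps full value
        agent = AgentParams("s", "quadratic", 1.0, 0.0, beta=math.inf)
        gain = ChoiceTrial(1, 30, 5.0, 10.0)
        loss = ChoiceTrial(1, 30, 5.0, 10.0, frame="loss", endowment=10.0)
        assert simulate_choice(agent, gain) == LOW  # gain k huge -> SV_high 0
        assert simulate_choice(agent, loss) == HIGH

    def test_agent_stream_is_consumed(self):
        agent = AgentParams("s", "linear", 0.0, 0.0, beta=0.5, rng_seed=5)
        trial = ChoiceTrial(1, 30, 9.9, 10.0)
        seq1 = [simulate_choice(agent, trial) for _ in range(20)]
        agent2 = AgentParams("s", "linear", 0.0, 0.0, beta=0.5, rng_seed=5)
        seq2 = [simulate_choice(agent2, trial) for _ in range(20)]
        assert seq1 == seq2


class TestVigilanceSession:
    def test_intermixed_no_four_in_a_row(self):
        cfg = VigilanceSimConfig()
        for seed in range(5):
            df = generate_vigilance_session(cfg, seed)
            conds = df["condition"].tolist()
            for i in range(len(conds) - 3):
                assert len(set(conds[i : i + 4])) > 1

    def test_intermixed_counts_balanced_within_one(self):
        df = generate_vigilance_session(VigilanceSimConfig(), 7)
        counts = df["condition"].value_counts()
        assert counts.max() - counts.min() <= 1

    def test_degenerate_config_constant_rt(self):
        cfg = VigilanceSimConfig(
            rt_sigma=0.0, incentive_speedup=0.0, tot_slowing=0.0, lapse_prob=0.0
        )
        df = generate_vigilance_session(cfg, 3)
        assert np.allclose(df["rt_ms"], cfg.rt_mu)

    def test_mean_trial_count_near_target(self):
        cfg = VigilanceSimConfig()
        counts = [
            len(generate_vigilance_session(cfg, [1, i])) for i in range(400)
        ]
        assert abs(np.mean(counts) - cfg.n_trials) <= 5

    def test_incompatible_isi_raises(self):
        with pytest.raises(ValueError):
            generate_vigilance_session(
                VigilanceSimConfig(isi_range=(1.0, 2.0)), 0
            )

    def test_blocked_requires_condition(self):
        cfg = VigilanceSimConfig(design="blocked")
        with pytest.raises(ValueError):
            generate_vigilance_session(cfg, 0)
        df = generate_vigilance_session(cfg, 0, condition="baseline")
        assert (df["condition"] == "baseline").all()

    def test_reproducible(self):
        cfg = VigilanceSimConfig()
        a = generate_vigilance_session(cfg, 11)
        b = generate_vigilance_session(cfg, 11)
        pd.testing.assert_frame_equal(a, b)

    def test_incentive_speedup_lowers_rt(self):
        cfg = VigilanceSimConfig(rt_sigma=0.0, tot_slowing=0.0,
                                 incentive_speedup=0.2)
        df = generate_vigilance_session(cfg, 2)
        gain_rt = df.query("condition == 'gain'")["rt_ms"].mean()
        neutral_rt = df.query("condition == 'neutral'")["rt_ms"].mean()
        assert gain_rt == pytest.approx(0.8 * neutral_rt)


def test_intermixed_sequence_constraints():
    rng = np.random.default_rng(0)
    seq = intermixed_sequence(60, ("gain", "loss", "neutral"), 3, rng)
    assert len(seq) == 60
    counts = pd.Series(seq).value_counts()
    assert counts.max() - counts.min() <= 1
    for i in range(len(seq) - 3):
        assert len(set(seq[i : i + 4])) > 1


class TestPupilTraceGeneration:
    def test_constant_trace_without_noise(self):
        cfg = PupilSimConfig(noise_sd_mm=0.0, blink_rate=0.0, drift_mm_per_min=0.0)
        trace = generate_pupil_trace(cfg, [], 60.0, 0)
        assert np.allclose(trace.diameter_mm, cfg.baseline_mm)
        assert trace.valid.all()

    def test_linear_drift_arithmetic(self):
        cfg = PupilSimConfig(noise_sd_mm=0.0, blink_rate=0.0,
                             drift_mm_per_min=-0.05)
        trace = generate_pupil_trace(cfg, [], 600.0, 0)
        assert trace.diameter_mm[-1] == pytest.approx(cfg.baseline_mm - 0.5)

    def test_blink_fraction_matches_expectation(self):
        cfg = PupilSimConfig(blink_rate=10.0, blink_duration_ms=(200.0, 200.0))
        fracs = [
            1.0 - generate_pupil_trace(cfg, [], 120.0, [2, i]).valid.mean()
            for i in range(200)
        ]
        # 10 blinks/min x 0.2 s each = 2 s invalid per 60 s
        assert np.mean(fracs) == pytest.approx(2.0 / 60.0, abs=0.005)

    def test_incentive_dilation_applied_between_events(self):
        cfg = PupilSimConfig(noise_sd_mm=0.0, blink_rate=0.0, drift_mm_per_min=0.0,
                             incentive_dilation_mm=0.4, cue_lead_s=0.0)
        events = [(10.0, "gain"), (20.0, "neutral")]
        trace = generate_pupil_trace(cfg, events, 30.0, 0)
        t = trace.time_s
        assert np.allclose(
            trace.diameter_mm[(t >= 10) & (t < 20)], cfg.baseline_mm + 0.4
        )
        assert np.allclose(trace.diameter_mm[t < 10], cfg.baseline_mm)

    def test_event_outside_duration_rejected(self):
        with pytest.raises(ValueError):
            generate_pupil_trace(PupilSimConfig(), [(100.0, "gain")], 60.0, 0)

    def test_nonpositive_sampling_rate_rejected(self):
        with pytest.raises(ValueError):
            PupilSimConfig(sampling_rate=0.0)


class TestNBackSession:
    @pytest.mark.parametrize("load", [1, 2, 3, 4])
    def test_exact_target_count_every_seed(self, load):
        cfg = NBackSimConfig()
        for seed in range(10):
            df = generate_nback_session(cfg, load, "gain", seed)
            letters = df["letter"].tolist()
            matches = sum(
                letters[i] == letters[i - load] for i in range(load, len(letters))
            )
            assert matches == cfg.n_targets
            assert df["is_target"].sum() == cfg.n_targets

    def test_perfect_rates_score_perfectly(self):
        cfg = NBackSimConfig(
            hit_rate_by_load_frame={(2, "gain"): 1.0},
            fa_rate_by_load_frame={(2, "gain"): 0.0},
            loads=(2,),
        )
        df = generate_nback_session(cfg, 2, "gain", 0)
        tgt = df["is_target"]
        assert (df.loc[tgt, "response"] == "target").all()
        assert (df.loc[~tgt, "response"] == "nontarget").all()

    def test_empirical_hit_rate_converges(self):
        cfg = NBackSimConfig()
        hits = []
        for i in range(1000):
            df = generate_nback_session(cfg, 4, "loss", [3, i])
            tgt = df[df["is_target"]]
            hits.append((tgt["response"] == "target").mean())
        assert np.mean(hits) == pytest.approx(0.68, abs=0.02)

    def test_invalid_load_rejected(self):
        with pytest.raises(ValueError):
            generate_nback_session(NBackSimConfig(loads=(1, 2)), 3, "gain", 0)

    def test_infeasible_target_count_rejected(self):
        cfg = NBackSimConfig(loads=(60,), n_stimuli=64, n_targets=16,
                             hit_rate_by_load_frame={(60, "gain"): 0.5},
                             fa_rate_by_load_frame={(60, "gain"): 0.1})
        with pytest.raises(ValueError):
            generate_nback_session(cfg, 60, "gain", 0)

    def test_reproducible(self):
        cfg = NBackSimConfig()
        a = generate_nback_session(cfg, 3, "gain", 42)
        b = generate_nback_session(cfg, 3, "gain", 42)
        pd.testing.assert_frame_equal(a, b)

    def test_rate_bounds_validated(self):
        with pytest.raises(ValueError):
            NBackSimConfig(hit_rate_by_load_frame={(1, "gain"): 1.2})


def test_agent_population_structure():
    agents = generate_agent_population(10, seed=0, k_loss_ratio=0.7)
    assert len(agents) == 10
    for a in agents:
        assert a.k_loss == pytest.approx(0.7 * a.k_gain)
        assert a.k_gain > 0
    assert len({a.subject_id for a in agents}) == 10
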