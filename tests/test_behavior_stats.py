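"""Behavioral statistics: oracles, calibration and cross-checks."""

import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest

from tonelearn import behavior_stats, synthgen


def _toy_trials(outcomes_by_block, n_stimuli=4, participant="P1", group="Control"):
    """Trial table for one participant; outcomes_by_block[b] = set of correct
    stimulus indices in block b (1-based blocks)."""
    rows = []
    trial = 0
    for block, correct in outcomes_by_block.items():
        for i in range(n_stimuli):
            trial += 1
            rows.append(
                {
                    "participant": participant,
                    "group": group,
                    "phase": "training",
                    "block": block,
                    "trial": trial,
                    "syllable": f"s{i}",
                    "talker": "t1",
                    "tone": "T1",
                    "response": "T1" if i in correct else "T2",
                    "outcome": int(i in correct),
                    "stimulated": 0,
                }
            )
    return pd.DataFrame(rows)


class TestRetention:
    def test_hand_enumerated_half_overlap(self):
        trials = _toy_trials({1: {0, 1, 2}, 2: {1, 2, 3}})
        table = behavior_stats.compute_retention(trials)
        assert list(table["block"]) == [2]
        assert table["retention"].iloc[0] == pytest.approx(50.0)

    def test_full_and_zero_overlap_bounds(self):
        full = behavior_stats.compute_retention(
            _toy_trials({1: {0, 1, 2, 3}, 2: {0, 1, 2, 3}})
        )
        assert full["retention"].iloc[0] == pytest.approx(100.0)
        disjoint = behavior_stats.compute_retention(
            _toy_trials({1: {0, 1}, 2: {2, 3}})
        )
        assert disjoint["retention"].iloc[0] == pytest.approx(0.0)

    def test_missing_stimulus_in_block_rejected(self):
        trials = _toy_trials({1: {0}, 2: {0}})
        trials = trials.drop(index=trials.index[-1])  # block 2 incomplete
        with pytest.raises(ValueError):
            behavior_stats.compute_retention(trials)

    def test_retention_bounded_on_simulated_cohort(self, small_cohort):
        table = behavior_stats.compute_retention(small_cohort)
        assert table["retention"].between(0, 100).all()
        # defined for blocks 2..n_blocks only
        assert table["block"].min() == 2

    def test_lmm_intercept_is_control_block2_mean_when_balanced(self, small_cohort):
        retention = behavior_stats.compute_retention(small_cohort)
        fit = behavior_stats.fit_retention_lmm(retention)
        control_b2 = retention.query("group == 'Control' and block == 2")[
            "retention"
        ].mean()
        assert fit.params["Intercept"] == pytest.approx(control_b2, abs=1e-6)


class TestImprovement:
    def test_arithmetic_oracle(self):
        # per-block accuracies 30,40,...,80% over 10-trial blocks
        blocks = {b: set(range(3 + (b - 1))) for b in range(1, 7)}
        trials = _toy_trials(blocks, n_stimuli=10)
        imp = behavior_stats.mean_accuracy_improvement(trials)
        assert imp.iloc[0] == pytest.approx(np.mean([10, 20, 30, 40, 50]))

    def test_constant_accuracy_gives_zero(self):
        trials = _toy_trials({1: {0, 1}, 2: {0, 1}, 3: {2, 3}})
        imp = behavior_stats.mean_accuracy_improvement(trials)
        assert imp.iloc[0] == pytest.approx(0.0)

    def test_last_minus_first_variant(self):
        blocks = {b: set(range(3 + (b - 1))) for b in range(1, 7)}
        trials = _toy_trials(blocks, n_stimuli=10)
        imp = behavior_stats.mean_accuracy_improvement(trials, method="last_minus_first")
        assert imp.iloc[0] == pytest.approx(50.0)


class TestFalsePositives:
    def test_perfect_responder_zero(self):
        trials = _make_fp_table(lambda tone: tone)
        fp = behavior_stats.false_positive_rate(trials)
        assert (fp["fp_pct"] == 0).all()

    def test_always_t1_responder_is_total(self):
        trials = _make_fp_table(lambda tone: "T1")
        fp = behavior_stats.false_positive_rate(trials)
        assert (fp["fp_pct"] == 100.0).all()

    def test_uniform_responder_near_analytic_half(self):
        rng = np.random.default_rng(0)
        tones = ["T1", "T2", "T3", "T4"]
        trials = _make_fp_table(lambda tone: tones[rng.integers(4)], reps=250)
        fp = behavior_stats.false_positive_rate(trials)
        assert fp["fp_pct"].iloc[0] == pytest.approx(50.0, abs=7.0)


def _make_fp_table(responder, reps=5):
    rows = []
    trial = 0
    for rep in range(reps):
        for tone in ("T1", "T2", "T3", "T4"):
            trial += 1
            resp = responder(tone)
            rows.append(
                {
                    "participant": "P1",
                    "group": "Control",
                    "phase": "training",
                    "block": 1,
                    "trial": trial,
                    "syllable": "s",
                    "talker": "t",
                    "tone": tone,
                    "response": resp,
                    "outcome": int(resp == tone),
                    "stimulated": 0,
                }
            )
    return pd.DataFrame(rows)


@pytest.fixture(scope="module")
def aggregate():
    return synthgen.simulate_aggregate_dataset(
        120, 4, synthgen.AggregateConfig(seed=2)
    )


class TestMonteCarlo:
    def test_unreachable_group_mean_gives_zero(self, aggregate):
        top = behavior_stats.aggregate_improvement(aggregate).max()
        p = behavior_stats.monte_carlo_group_p(aggregate, top + 10, seed=0)
        assert p == 0.0

    def test_fixed_seed_is_deterministic(self, aggregate):
        p1 = behavior_stats.monte_carlo_group_p(aggregate, 5.0, seed=11)
        p2 = behavior_stats.monte_carlo_group_p(aggregate, 5.0, seed=11)
        assert p1 == p2

    def test_monotone_nonincreasing_in_group_mean(self, aggregate):
        ps = [
            behavior_stats.monte_carlo_group_p(aggregate, m, seed=3)
            for m in (-20.0, 0.0, 5.0, 10.0, 30.0)
        ]
        assert all(a >= b for a, b in zip(ps, ps[1:]))

    def test_oversized_group_rejected(self, aggregate):
        with pytest.raises(ValueError):
            behavior_stats.monte_carlo_group_p(aggregate, 0.0, group_size=10_000)


class TestPsychometric:
    def test_slope_recovery_over_seeds(self):
        beta_true, hits = 1.5, 0
        steps = np.repeat(np.arange(1, 8), 20)
        for seed in range(10):
            rng = np.random.default_rng(seed)
            p = 1 / (1 + np.exp(-beta_true * (steps - 4)))
            resp = (rng.random(steps.size) < p).astype(int)
            fit = behavior_stats.fit_psychometric_slope(
                pd.DataFrame({"step": steps, "response": resp})
            )
            hits += abs(fit.slope - beta_true) <= 0.5
        assert hits >= 8

    def test_flat_responding_gives_near_zero_slope(self):
        steps = np.repeat(np.arange(1, 8), 10)
        resp = np.tile([0, 1], steps.size // 2)
        fit = behavior_stats.fit_psychometric_slope(
            pd.DataFrame({"step": steps, "response": resp})
        )
        assert fit.slope < 0.2

    def test_step_function_flags_separation(self):
        steps = np.repeat(np.arange(1, 8), 10)
        resp = (steps > 4).astype(int)
        fit = behavior_stats.fit_psychometric_slope(
            pd.DataFrame({"step": steps, "response": resp})
        )
        assert not fit.converged
        assert any("separation" in d or "bound" in d for d in fit.diagnostics)


class TestClassicalTests:
    def test_f_equals_t_squared_for_two_groups(self):
        rng = np.random.default_rng(4)
        a, b = rng.normal(0, 1, 15), rng.normal(0.5, 1, 15)
        res = behavior_stats.oneway_anova(
            np.concatenate([a, b]), np.array(["a"] * 15 + ["b"] * 15)
        )
        t, p_t, df = behavior_stats.two_sample_t(a, b)
        assert res.F == pytest.approx(t**2, rel=1e-10)
        assert res.p == pytest.approx(p_t, rel=1e-10)
        assert (res.df_between, res.df_within) == (1, 28)
        assert df == 28

    def test_three_group_sums_of_squares_oracle(self):
        values = np.array([3.0, 4, 5, 6, 7, 2, 3, 4, 5, 6, 8, 9, 10, 11, 12])
        labels = np.repeat(["g1", "g2", "g3"], 5)
        # brute-force decomposition
        grand = values.mean()
        ss_b = sum(
            5 * (values[labels == g].mean() - grand) ** 2 for g in ("g1", "g2", "g3")
        )
        ss_w = sum(
            ((values[labels == g] - values[labels == g].mean()) ** 2).sum()
            for g in ("g1", "g2", "g3")
        )
        f_oracle = (ss_b / 2) / (ss_w / 12)
        res = behavior_stats.oneway_anova(values, labels)
        assert res.F == pytest.approx(f_oracle, rel=1e-10)

    def test_identical_groups_give_zero_f(self):
        values = np.tile([1.0, 2.0, 3.0], 2)
        labels = np.repeat(["a", "b"], 3)
        res = behavior_stats.oneway_anova(values, labels)
        assert res.F == pytest.approx(0.0, abs=1e-12)

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            behavior_stats.oneway_anova(np.arange(4.0), np.repeat("a", 4))


class TestTrialGlmm:
    def test_all_correct_raises_separation_diagnostic(self, small_cohort):
        trials = small_cohort.copy()
        trials["outcome"] = 1
        fit = behavior_stats.fit_trial_glmm(trials)
        assert not fit.converged
        assert any("separation" in d for d in fit.diagnostics)

    def test_matches_lme4_glmer_on_shared_data(self, tmp_path):
        """Independent cross-check of the Laplace fit against lme4."""
        cfg = synthgen.CohortConfig(n_per_group=6, n_blocks=3, seed=7)
        trials = synthgen.simulate_learner_cohort(cfg)
        fit = behavior_stats.fit_trial_glmm(trials)
        csv = tmp_path / "trials.csv"
        trials[trials["phase"] == "training"].to_csv(csv, index=False)
        r_code = textwrap.dedent(
            f"""
            suppressMessages(library(lme4))
            d <- read.csv("{csv}")
            d$group <- relevel(factor(d$group), ref="Control")
            m <- glmer(outcome ~ group*trial + (1|participant) + (1|tone),
                       data=d, family=binomial)
            co <- summary(m)$coefficients
            write.csv(co, "{tmp_path / 'lme4.csv'}")
            """
        )
        proc = subprocess.run(
            ["Rscript", "-e", r_code], capture_output=True, text=True, timeout=300
        )
        assert proc.returncode == 0, proc.stderr
        ref = pd.read_csv(tmp_path / "lme4.csv", index_col=0)
        mapping = {
            "Intercept": "(Intercept)",
            "group[tVNS-easy]": "grouptVNS-easy",
            "group[tVNS-hard]": "grouptVNS-hard",
            "trial": "trial",
            "group[tVNS-easy]:trial": "grouptVNS-easy:trial",
            "group[tVNS-hard]:trial": "grouptVNS-hard:trial",
        }
        for ours, theirs in mapping.items():
            assert fit.params[ours] == pytest.approx(
                ref.loc[theirs, "Estimate"], abs=0.02
            )
            assert fit.z[ours] == pytest.approx(ref.loc[theirs, "z value"], rel=0.05)


class TestGeneralizationGlmm:
    def test_block_effect_near_zero_when_distributions_match(self):
        cfg = synthgen.CohortConfig(
            n_per_group=8,
            n_blocks=2,
            trial_slope_per_group={"tVNS-easy": 0.0, "tVNS-hard": 0.0, "Control": 0.0},
            seed=21,
        )
        trials = synthgen.simulate_learner_cohort(cfg)
        fit = behavior_stats.fit_generalization_glmm(trials)
        assert abs(fit.params["blockcat[gen]"]) < 3 * fit.bse["blockcat[gen]"] + 0.1

    def test_requires_generalization_block(self, small_cohort):
        with pytest.raises(ValueError):
            behavior_stats.fit_generalization_glmm(
                small_cohort[small_cohort["phase"] == "training"]
            )
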