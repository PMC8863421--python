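"""Profile scores: selection, scoring arithmetic, R2 evaluation, sweeps."""

import numpy as np
import pandas as pd
import pytest

from stressmwas import (evaluate_binary, evaluate_continuous, profile_score,
                        select_sites, threshold_sweep)
from stressmwas.scoring import DEFAULT_THRESHOLDS


def _stats_table(rng, n=1000):
    return pd.DataFrame({"cpg_id": [f"cg{i}" for i in range(n)],
                         "effect": rng.standard_normal(n),
                         "p": rng.random(n)})


class TestSelection:
    def test_uniform_null_fraction(self, rng):
        sel = select_sites(_stats_table(rng), 0.1)
        assert len(sel) == pytest.approx(100, abs=35)

    def test_below_minimum_empty(self, rng):
        stats_df = _stats_table(rng)
        sel = select_sites(stats_df, stats_df["p"].min() / 2)
        assert sel.empty

    def test_default_thresholds_nested(self, rng):
        stats_df = _stats_table(rng)
        sets = [set(select_sites(stats_df, t)["cpg_id"])
                for t in DEFAULT_THRESHOLDS]
        for smaller, larger in zip(sets, sets[1:]):
            assert smaller <= larger


class TestProfileScore:
    def _target(self, values, samples=None):
        p, n = values.shape
        return pd.DataFrame(values, index=[f"cg{i}" for i in range(p)],
                            columns=samples or [f"T{i}" for i in range(n)])

    def test_single_term_product(self):
        target = self._target(np.array([[1.5]]))
        effects = pd.Series({"cg0": 2.0})
        ps = profile_score(effects, target)
        assert ps.scores.iloc[0] == pytest.approx(3.0)

    def test_additivity(self):
        target = self._target(np.array([[1.5], [0.5]]))
        effects = pd.Series({"cg0": 2.0, "cg1": -1.0})
        ps = profile_score(effects, target)
        assert ps.scores.iloc[0] == pytest.approx(2.5)

    def test_linearity_in_effects(self, rng):
        target = self._target(rng.standard_normal((10, 5)))
        effects = pd.Series(rng.standard_normal(10),
                            index=[f"cg{i}" for i in range(10)])
        s1 = profile_score(effects, target).scores
        s2 = profile_score(2.0 * effects, target).scores
        assert np.allclose(2.0 * s1, s2)

    def test_order_invariance(self, rng):
        target = self._target(rng.standard_normal((6, 4)))
        effects = pd.Series(rng.standard_normal(6),
                            index=[f"cg{i}" for i in range(6)])
        shuffled = effects.sample(frac=1.0, random_state=1)
        assert np.allclose(profile_score(effects, target).scores,
                           profile_score(shuffled, target).scores)

    def test_missing_cpgs_skipped_with_count(self, rng):
        target = self._target(rng.standard_normal((3, 4)))
        effects = pd.Series({"cg0": 1.0, "cg1": 1.0, "nope": 5.0})
        ps = profile_score(effects, target)
        assert ps.n_cpgs == 2
        assert ps.n_missing == 1

    def test_zero_overlap_rejected(self, rng):
        target = self._target(rng.standard_normal((2, 3)))
        with pytest.raises(ValueError, match="present"):
            profile_score(pd.Series({"x": 1.0}), target)

    def test_leakage_guard(self, rng):
        target = self._target(rng.standard_normal((2, 3)),
                              samples=["A", "B", "C"])
        effects = pd.Series({"cg0": 1.0})
        with pytest.raises(ValueError, match="overlap"):
            profile_score(effects, target, discovery_samples=["B", "Z"])


class TestEvaluation:
    def test_independent_score_binary_null(self, rng):
        n = 5000
        score = rng.standard_normal(n)
        outcome = (rng.random(n) < 0.2).astype(float)
        ev = evaluate_binary(score, outcome)
        assert ev.r2 < 0.002

    def test_liability_score_matches_logistic_oracle(self, rng):
        # score = the liability's heritable part; compare the Nagelkerke
        # increment with a direct statsmodels fit (independent route)
        import statsmodels.api as sm
        n, h2 = 4000, 0.3
        g = rng.standard_normal(n)
        liab = np.sqrt(h2) * g + np.sqrt(1 - h2) * rng.standard_normal(n)
        outcome = (liab > np.quantile(liab, 0.8)).astype(float)
        ev = evaluate_binary(g, outcome)
        X0 = np.ones((n, 1))
        X1 = np.column_stack([X0, g])
        ll0 = sm.Logit(outcome, X0).fit(disp=False).llf
        ll1 = sm.Logit(outcome, X1).fit(disp=False).llf
        r2_oracle = (1 - np.exp(2 / n * (ll0 - ll1))) / (1 - np.exp(2 / n * ll0))
        assert ev.r2 == pytest.approx(r2_oracle, rel=1e-6)
        assert ev.r2 > 0.05

    def test_constant_score_zero_r2(self, rng):
        outcome = (rng.random(200) < 0.3).astype(float)
        ev = evaluate_binary(np.ones(200), outcome)
        assert ev.r2 == 0.0
        assert ev.p == 1.0

    def test_outcome_equals_score_perfect_adjusted_r2(self, rng):
        score = rng.standard_normal(300)
        ev = evaluate_continuous(score, score)
        assert ev.r2 == pytest.approx(1.0, abs=1e-10)

    def test_independent_score_adjusted_r2_near_zero(self, rng):
        ev = evaluate_continuous(rng.standard_normal(2000),
                                 rng.standard_normal(2000))
        assert abs(ev.r2) < 0.005

    def test_planted_r2_recovered(self):
        ests = []
        for rep in range(60):
            rng = np.random.default_rng(8000 + rep)
            n, r2 = 4000, 0.01
            score = rng.standard_normal(n)
            outcome = np.sqrt(r2) * score + np.sqrt(1 - r2) * rng.standard_normal(n)
            ests.append(evaluate_continuous(score, outcome).r2)
        assert 0.007 <= np.mean(ests) <= 0.013

    def test_zero_variance_outcome_rejected(self, rng):
        with pytest.raises(ValueError, match="variance"):
            evaluate_continuous(rng.standard_normal(50), np.ones(50))


class TestThresholdSweep:
    def test_family_gate_is_six_point_two_five_e_minus_three(self, rng):
        stats_df = _stats_table(rng, 200)
        target = pd.DataFrame(rng.standard_normal((200, 100)),
                              index=stats_df["cpg_id"],
                              columns=[f"T{i}" for i in range(100)])
        outcome = pd.Series(rng.standard_normal(100), index=target.columns)
        out = threshold_sweep(stats_df, target, outcome,
                              thresholds=(0.5,), alpha_family=0.05,
                              n_phenotypes=8)
        # the gate itself: a P just above 6.25e-3 is not significant
        assert out["significant"].iloc[0] == (out["p"].iloc[0] < 6.25e-3)

    def test_contributing_counts_monotone(self, rng):
        stats_df = _stats_table(rng)
        target = pd.DataFrame(rng.standard_normal((1000, 60)),
                              index=stats_df["cpg_id"],
                              columns=[f"T{i}" for i in range(60)])
        outcome = pd.Series(rng.standard_normal(60), index=target.columns)
        out = threshold_sweep(stats_df, target, outcome)
        counts = out["n_cpgs"].to_numpy()
        assert np.all(np.diff(counts) >= 0)
        assert out["best"].sum() == 1

    def test_null_sweep_best_p_rarely_passes_gate(self):
        passes = 0
        for rep in range(25):
            rng = np.random.default_rng(9000 + rep)
            stats_df = _stats_table(rng, 400)
            target = pd.DataFrame(rng.standard_normal((400, 150)),
                                  index=stats_df["cpg_id"],
                                  columns=[f"T{i}" for i in range(150)])
            outcome = pd.Series(rng.standard_normal(150), index=target.columns)
            out = threshold_sweep(stats_df, target, outcome,
                                  thresholds=(1e-3, 1e-2, 1e-1))
            best = out.loc[out["best"], "p"]
            if not best.empty and best.iloc[0] < 6.25e-3:
                passes += 1
        assert passes <= 3          # selection optimism exists but is bounded

    def test_external_weights_mode(self, rng):
        # scoring from a supplied site list, no discovery stage
        target = pd.DataFrame(rng.standard_normal((5, 40)),
                              index=[f"cg{i}" for i in range(5)],
                              columns=[f"T{i}" for i in range(40)])
        weights = pd.Series({"cg0": 0.5, "cg3": -0.2})
        ps = profile_score(weights, target)
        expect = 0.5 * target.loc["cg0"] - 0.2 * target.loc["cg3"]
        assert np.allclose(ps.scores, expect)
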