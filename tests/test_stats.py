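import itertools

import numpy as np
import pytest

from archbar.stats import (
    InsufficientDataError,
    InsufficientVariationError,
    StrategyGroup,
    assign_letters,
    bonferroni_threshold,
    brown_forsythe,
    build_report,
    check_letter_soundness,
    ci95_from_moments,
    compare_precision,
    ComparisonResult,
    kruskal_wallis,
    mann_whitney,
    pairwise_mannwhitney,
    summarize,
)
from archbar.stats import test_normality as normality_check
from archbar.cli import records_to_frame
from archbar.synthetic import null_profiles, simulate_strategy_study

from oracles import kruskal_wallis_oracle, mann_whitney_exact_oracle


def g(sid, values, param="deltaL_um"):
    return StrategyGroup(sid, param, np.asarray(values, dtype=float))


class TestSummarize:
    def test_constant_sample(self):
        s = summarize([3.0] * 10)
        assert s.M == s.MED == 3.0
        assert s.SD == 0.0
        assert s.CI95_lower == s.CI95_upper == 3.0

    @pytest.mark.parametrize("mean,sd,lo,hi", [
        # printed full-arch study values: group means/SDs with n=25 and the
        # published confidence bounds they imply
        (-64.94, 58.84, -89.23, -40.65),
        (-66.59, 92.73, -104.87, -28.31),
        (-49.94, 46.27, -69.04, -30.84),
    ])
    def test_ci_from_printed_moments(self, mean, sd, lo, hi):
        got_lo, got_hi = ci95_from_moments(mean, sd, 25)
        assert got_lo == pytest.approx(lo, abs=0.01)
        assert got_hi == pytest.approx(hi, abs=0.01)

    def test_summary_invariants(self, rng):
        v = rng.normal(10, 3, 40)
        s = summarize(v)
        assert s.MIN <= s.MED <= s.MAX
        assert s.CI95_lower <= s.M <= s.CI95_upper
        assert s.SD == pytest.approx(np.std(v, ddof=1))

    def test_insufficient_data(self):
        with pytest.raises(InsufficientDataError):
            summarize([1.0])


class TestNormality:
    def test_normal_sample_rarely_rejected(self):
        flags = []
        for seed in range(200):
            v = np.random.default_rng(seed).standard_normal(25)
            flags.append(normality_check(v)["non_normal"])
        assert np.mean(flags) <= 0.10

    def test_bimodal_sample_rejected(self):
        hits = []
        for seed in range(100):
            r = np.random.default_rng(10_000 + seed)
            v = np.concatenate([r.normal(-5, 1, 13), r.normal(5, 1, 12)])
            hits.append(normality_check(v)["non_normal"])
        assert np.mean(hits) >= 0.95

    def test_constant_sample_raises(self):
        with pytest.raises(InsufficientVariationError):
            normality_check([2.0] * 25)


class TestKruskalWallis:
    def test_hand_computed_example(self):
        """Groups {1,2,3},{4,5,6},{7,8,9}: ranks are 1..9 and the rank
        formula gives H = 7.2 exactly."""
        groups = [g("a", [1, 2, 3]), g("b", [4, 5, 6]), g("c", [7, 8, 9])]
        res = kruskal_wallis(groups)
        assert res.statistic == pytest.approx(7.2, abs=1e-9)
        h, p = kruskal_wallis_oracle([gr.values for gr in groups])
        assert res.statistic == pytest.approx(h, abs=1e-9)
        assert res.p_value == pytest.approx(p, abs=1e-12)

    def test_identical_constant_groups_vacuous(self):
        groups = [g(s, [5.0, 5.0, 5.0]) for s in "abc"]
        res = kruskal_wallis(groups)
        assert res.statistic == 0.0 and res.p_value == 1.0
        assert not res.significant

    def test_matches_oracle_on_small_inputs(self, rng):
        """Tie-corrected H and chi-square p agree with the longhand rank
        oracle on every random input with total n <= 10, ties included."""
        for trial in range(60):
            sizes = rng.integers(2, 4, size=rng.integers(2, 4))
            while sizes.sum() > 10:
                sizes = sizes[:-1]
            if len(sizes) < 2:
                continue
            vals = rng.integers(0, 5, size=int(sizes.sum())).astype(float)
            groups, start = [], 0
            for i, n in enumerate(sizes):
                groups.append(g(f"g{i}", vals[start:start + n]))
                start += n
            if np.ptp(vals) == 0:
                continue
            res = kruskal_wallis(groups)
            h, p = kruskal_wallis_oracle([gr.values for gr in groups])
            assert res.statistic == pytest.approx(h, abs=1e-9)
            assert res.p_value == pytest.approx(p, abs=1e-9)


class TestMannWhitney:
    def test_bonferroni_threshold(self):
        assert bonferroni_threshold(0.05, 3) == 0.017
        assert bonferroni_threshold(0.05, 1) == 0.05
        # monotone: more comparisons never raise the threshold
        ths = [bonferroni_threshold(0.05, m) for m in range(1, 12)]
        assert all(a >= b for a, b in zip(ths, ths[1:]))

    def test_exact_enumeration_example(self):
        u, p = mann_whitney([1, 2, 3], [4, 5, 6])
        assert u == 0.0
        assert p == pytest.approx(0.1, abs=1e-12)

    def test_identical_groups_not_significant(self):
        res = pairwise_mannwhitney([g("a", [1, 2, 3, 4]),
                                    g("b", [1, 2, 3, 4])])
        assert res[0].p_value > 0.9
        assert not res[0].significant

    def test_matches_exhaustive_oracle_no_ties(self, rng):
        """Exact two-sided p equals full enumeration over all
        C(n1+n2, n1) group assignments, for every tie-free input with
        total n <= 10."""
        for trial in range(40):
            n1 = int(rng.integers(2, 6))
            n2 = int(rng.integers(2, 6))
            if n1 + n2 > 10:
                continue
            vals = rng.permutation(np.arange(1.0, n1 + n2 + 1))
            a, b = vals[:n1], vals[n1:]
            u, p = mann_whitney(a, b)
            u_o, p_o = mann_whitney_exact_oracle(a, b)
            assert u == pytest.approx(max(u_o, n1 * n2 - u_o), abs=1e-9) \
                or u == pytest.approx(u_o, abs=1e-9)
            assert p == pytest.approx(p_o, abs=1e-9)

    def test_threshold_applied(self):
        res = pairwise_mannwhitney(
            [g("a", np.arange(10.0)), g("b", np.arange(10.0) + 100)],
            family_alpha=0.05, m=3)
        assert res[0].threshold == 0.017
        assert res[0].significant


class TestPrecision:
    def test_shifted_groups_equal_dispersion(self):
        a = np.array([1.0, 2.0, 4.0, 8.0, 9.5])
        res = compare_precision([g("a", a), g("b", a + 100.0)])
        assert res[0].p_value == 1.0
        assert not res[0].significant

    def test_group_vs_itself(self):
        a = np.array([1.0, 2.0, 4.0, 8.0])
        w, p = brown_forsythe(a, a.copy())
        assert w == 0.0 and p == 1.0

    def test_power_against_5x_sd(self):
        hits = []
        for seed in range(200):
            r = np.random.default_rng(seed)
            res = compare_precision([g("a", r.normal(0, 1, 25)),
                                     g("b", r.normal(0, 5, 25))],
                                    family_alpha=0.05, m=1)
            hits.append(res[0].p_value < 0.05)
        assert np.mean(hits) >= 0.90


class TestLetters:
    def _results(self, ids, sig_pairs):
        out = []
        for a, b in itertools.combinations(ids, 2):
            s = {a, b} in [set(p) for p in sig_pairs]
            out.append(ComparisonResult("mwu", (a, b), 0.0,
                                        0.001 if s else 0.9, 0.017, s))
        return out

    def test_no_significant_pairs_single_letter(self):
        ids = ["FL", "FZ", "FC"]
        res = self._results(ids, [])
        letters = assign_letters(ids, res)
        assert all(v == "A" for v in letters.values())

    def test_one_group_isolated(self):
        ids = ["a", "b", "c"]
        res = self._results(ids, [("a", "c"), ("b", "c")])
        letters = assign_letters(ids, res, uppercase=False)
        assert letters["a"] == letters["b"]
        assert set(letters["c"]) & set(letters["a"]) == set()
        assert check_letter_soundness(letters, res)

    def test_all_pairs_significant_distinct_letters(self):
        ids = ["a", "b", "c", "d"]
        res = self._results(ids, list(itertools.combinations(ids, 2)))
        letters = assign_letters(ids, res)
        assert len({v for v in letters.values()}) == 4
        assert check_letter_soundness(letters, res)

    def test_soundness_on_random_patterns(self, rng):
        ids = [f"g{i}" for i in range(6)]
        for _ in range(50):
            sig_pairs = [p for p in itertools.combinations(ids, 2)
                         if rng.random() < 0.4]
            res = self._results(ids, sig_pairs)
            letters = assign_letters(ids, res)
            assert check_letter_soundness(letters, res)
            assert all(letters[i] for i in ids)


@pytest.fixture(scope="module")
def study_frame():
    recs = simulate_strategy_study(n_per_group=25, seed=99)
    return records_to_frame(recs)


class TestBuildReport:
    def test_report_shape_and_soundness(self, study_frame):
        rep = build_report(study_frame)
        assert len(rep.strategies) == 9
        lin = rep.linear_table()
        ang = rep.angular_table()
        assert len(lin) == len(ang) == 9
        assert "deltaL_um_MED" in lin.columns
        assert "alpha_overall_deg_letters" in ang.columns
        # every pairwise family threshold is the published 0.017
        for param, comps in rep.trueness_pairwise.items():
            assert all(c.threshold == 0.017 for c in comps)

    def test_null_study_mostly_homogeneous(self):
        homogeneous = 0
        for seed in range(10):
            recs = simulate_strategy_study(null_profiles(), n_per_group=25,
                                           seed=3000 + seed)
            rep = build_report(records_to_frame(recs))
            letters = rep.trueness_letters["VE_x_um"]
            homogeneous += int(len(set(letters.values())) == 1)
        # Bonferroni-corrected pairwise tests under the null: most runs
        # produce a single shared letter
        assert homogeneous >= 7

    def test_inflated_variance_strategy_isolated(self):
        """A 5x SD strategy separates, in the precision letters, from every
        group it is compared with (comparisons run within factor-level
        families, so only those pairs can ever separate)."""
        profs = null_profiles()
        from dataclasses import replace
        profs["SZ"] = replace(profs["SZ"],
                              translation_scale_um=np.asarray(
                                  profs["SZ"].translation_scale_um) * 5.0)
        compared_with_sz = {"SL", "SC", "FZ", "HZ"}
        hits = 0
        for seed in range(10):
            recs = simulate_strategy_study(profs, n_per_group=25,
                                           seed=4000 + seed)
            rep = build_report(records_to_frame(recs))
            letters = rep.precision_letters["VE_x_um"]
            separated = all(
                not (set(letters["SZ"]) & set(letters[s]))
                for s in compared_with_sz)
            hits += int(separated)
        assert hits >= 8

    def test_single_strategy_rejected(self, study_frame):
        one = study_frame[study_frame["strategy"] == "FL"]
        with pytest.raises(InsufficientDataError):
            build_report(one)

    def test_missing_column_named(self, study_frame):
        broken = study_frame.drop(columns=["alpha_axial_deg"])
        with pytest.raises(ValueError, match="alpha_axial_deg"):
            build_report(broken)
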