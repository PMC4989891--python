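"""SAM statistic, s0 search, permutation null, delta calling and log2FC."""

import math
from itertools import combinations

import numpy as np
import pytest

from conftest import make_matrix
from mirnetppi import diffexpr as de
from mirnetppi.diffexpr import SamConfig
from mirnetppi.io_formats import ConfigError


def oracle_d_s(matrix, s0):
    """Direct per-feature recomputation of the pooled-SE formula."""
    c1, c2 = matrix.classes
    x1, x2 = matrix.class_values(c1), matrix.class_values(c2)
    n1, n2 = x1.shape[1], x2.shape[1]
    d, s = [], []
    for i in range(x1.shape[0]):
        m1, m2 = x1[i].mean(), x2[i].mean()
        ss = ((x1[i] - m1) ** 2).sum() + ((x2[i] - m2) ** 2).sum()
        si = math.sqrt((1 / n1 + 1 / n2) * ss / (n1 + n2 - 2))
        s.append(si)
        d.append((m2 - m1) / (si + s0))
    return np.array(d), np.array(s)


class TestSamStatistic:
    def test_identical_classes_give_zero_d(self):
        m = make_matrix([[5, 6, 5, 6]], ["f"], ["a", "b", "c", "d"], ["WT", "WT", "KO", "KO"])
        d, s = de.sam_statistic(m, s0=1.0)
        assert d[0] == 0.0

    def test_zero_variance_closed_form(self):
        # class1=(1,1), class2=(3,3), s0=1 -> s=0, d=(3-1)/1=2
        m = make_matrix([[1, 1, 3, 3]], ["f"], ["a", "b", "c", "d"], ["WT", "WT", "KO", "KO"])
        d, s = de.sam_statistic(m, s0=1.0)
        assert s[0] == 0.0 and d[0] == 2.0

    def test_random_matrix_matches_formula_oracle(self):
        rng = np.random.default_rng(4)
        samples = [f"s{i}" for i in range(8)]
        m = make_matrix(rng.normal(size=(20, 8)), [f"f{i}" for i in range(20)],
                        samples, ["WT"] * 4 + ["KO"] * 4)
        d, s = de.sam_statistic(m, s0=0.3)
        od, os_ = oracle_d_s(m, 0.3)
        np.testing.assert_allclose(d, od, rtol=1e-12)
        np.testing.assert_allclose(s, os_, rtol=1e-12)

    def test_shift_invariance_and_scale_equivariance(self):
        rng = np.random.default_rng(9)
        samples = [f"s{i}" for i in range(6)]
        base = rng.normal(size=(10, 6))
        m = make_matrix(base, [f"f{i}" for i in range(10)], samples, ["WT"] * 3 + ["KO"] * 3)
        shifted = make_matrix(base + 7.5, [f"f{i}" for i in range(10)], samples, ["WT"] * 3 + ["KO"] * 3)
        d0, _ = de.sam_statistic(m, 0.4)
        d1, _ = de.sam_statistic(shifted, 0.4)
        np.testing.assert_allclose(d0, d1, atol=1e-10)
        scaled = make_matrix(base * 3.0, [f"f{i}" for i in range(10)], samples, ["WT"] * 3 + ["KO"] * 3)
        d2, _ = de.sam_statistic(scaled, 0.0)
        np.testing.assert_allclose(d2, de.sam_statistic(m, 0.0)[0], atol=1e-10)

    def test_empty_class_rejected(self):
        with pytest.raises(Exception):
            make_matrix([[1, 2]], ["f"], ["a", "b"], ["WT", "WT"])


class TestChooseS0:
    def test_deterministic_and_matches_independent_search(self, two_class_matrix):
        got = de.choose_s0(two_class_matrix)
        assert got == de.choose_s0(two_class_matrix)

        # independent plain-loop re-implementation of the percentile search
        _, s = oracle_d_s(two_class_matrix, 0.0)
        c1, c2 = two_class_matrix.classes
        x1 = two_class_matrix.class_values(c1)
        x2 = two_class_matrix.class_values(c2)
        num = x2.mean(axis=1) - x1.mean(axis=1)
        order = np.argsort(s, kind="mergesort")
        windows = np.array_split(order, min(100, len(s)))
        best, best_cv = None, np.inf
        for s0 in np.percentile(s, np.arange(0, 101, 5)):
            d = num / (s + s0)
            mads = []
            for w in windows:
                vals = d[w]
                mads.append(np.median(np.abs(vals - np.median(vals))))
            mads = np.array(mads)
            cv = np.inf if mads.mean() == 0 else mads.std() / mads.mean()
            if best is None or cv < best_cv - 1e-12:
                best, best_cv = float(s0), cv
        assert got == pytest.approx(best)

    def test_simulated_variance_dependent_scale(self):
        rng = np.random.default_rng(31)
        samples = [f"s{i}" for i in range(8)]
        sds = rng.uniform(0.2, 3.0, size=500)
        vals = rng.normal(0, 1, size=(500, 8)) * sds[:, None]
        m = make_matrix(vals, [f"f{i}" for i in range(500)], samples, ["WT"] * 4 + ["KO"] * 4)
        assert de.choose_s0(m) == de.choose_s0(m)  # reproducible

    def test_all_zero_s_returns_zero_with_warning(self):
        m = make_matrix([[1, 1, 2, 2], [0, 0, 5, 5]], ["a", "b"],
                        ["s1", "s2", "s3", "s4"], ["WT", "WT", "KO", "KO"])
        with pytest.warns(UserWarning):
            assert de.choose_s0(m) == 0.0

    def test_fixed_mode(self, two_class_matrix):
        assert de.choose_s0(two_class_matrix, SamConfig(s0_method="fixed", s0_fixed=0.7)) == 0.7


class TestPermutationNull:
    def test_one_vs_one_exhaustive(self):
        m = make_matrix([[1.0, 3.0], [2.0, 2.5]], ["a", "b"], ["s1", "s2"], ["WT", "KO"])
        d_exp, perm = de.sam_permutation_null(m, s0=1.0, config=SamConfig(n_permutations=10))
        assert perm.shape[0] == 2  # only 2 label assignments
        np.testing.assert_allclose(d_exp, perm.mean(axis=0))

    def test_three_vs_three_equals_exhaustive_enumeration(self):
        rng = np.random.default_rng(12)
        samples = [f"s{i}" for i in range(6)]
        m = make_matrix(rng.normal(size=(15, 6)), [f"f{i}" for i in range(15)],
                        samples, ["WT"] * 3 + ["KO"] * 3)
        d_exp, perm = de.sam_permutation_null(m, s0=0.2, config=SamConfig(n_permutations=1000))
        assert perm.shape[0] == 20  # C(6,3)

        X = m.values.to_numpy()
        rows = []
        for idx in combinations(range(6), 3):
            mask = np.zeros(6, dtype=bool)
            mask[list(idx)] = True
            x1, x2 = X[:, mask], X[:, ~mask]
            dd, _ = oracle_d_s(
                make_matrix(np.hstack([x1, x2]), m.feature_ids, samples,
                            ["WT"] * 3 + ["KO"] * 3), 0.2
            )
            rows.append(np.sort(dd))
        np.testing.assert_allclose(d_exp, np.vstack(rows).mean(axis=0), rtol=1e-12)

    def test_null_centering(self):
        rng = np.random.default_rng(42)
        samples = [f"s{i}" for i in range(8)]
        m = make_matrix(rng.normal(size=(200, 8)), [f"f{i}" for i in range(200)],
                        samples, ["WT"] * 4 + ["KO"] * 4)
        fit = de.sam_fit(m, SamConfig(n_permutations=1000, rng_seed=1))
        gap = np.mean(np.sort(fit.d) - fit.d_expected)
        assert abs(gap) < 0.05  # Monte-Carlo-scale centering

    def test_sampled_mode_is_seed_reproducible(self):
        rng = np.random.default_rng(8)
        samples = [f"s{i}" for i in range(12)]
        m = make_matrix(rng.normal(size=(30, 12)), [f"f{i}" for i in range(30)],
                        samples, ["WT"] * 6 + ["KO"] * 6)
        cfg = SamConfig(n_permutations=50, rng_seed=99)
        a = de.sam_permutation_null(m, 0.1, cfg)
        b = de.sam_permutation_null(m, 0.1, cfg)
        np.testing.assert_array_equal(a[1], b[1])


class TestSamCall:
    def test_huge_delta_calls_nothing(self, two_class_matrix):
        fit = de.sam_fit(two_class_matrix)
        res = de.sam_call(fit, SamConfig(delta=1e6))
        assert res.n_called == 0 and res.fdr_median is None

    def test_delta_nesting(self, two_class_matrix):
        fit = de.sam_fit(two_class_matrix)
        called = {}
        for delta in (0.0, 0.5, 1.0, 2.0):
            res = de.sam_call(fit, SamConfig(delta=delta))
            called[delta] = {c.feature_id for c in res.calls if c.called}
        assert called[2.0] <= called[1.0] <= called[0.5] <= called[0.0]

    def test_directions_follow_sign(self, two_class_matrix):
        fit = de.sam_fit(two_class_matrix)
        res = de.sam_call(fit, SamConfig(delta=de.tune_delta(fit, 2)))
        by_id = {c.feature_id: c for c in res.calls}
        assert by_id["f0"].called and by_id["f0"].direction == "up"
        assert by_id["f1"].called and by_id["f1"].direction == "down"

    def test_planted_simulation_calibration(self):
        """Planted 200-feature studies: recovery and median-FDR realism."""
        n_rep = 50
        realized, estimated = [], []
        recovered = 0
        for rep in range(n_rep):
            rng = np.random.default_rng(700 + rep)
            samples = [f"s{i}" for i in range(8)]
            vals = rng.normal(0, 1, size=(200, 8))
            vals[:10, 4:] += 3.0
            vals[10:15, 4:] -= 3.0
            m = make_matrix(vals, [f"f{i}" for i in range(200)], samples,
                            ["WT"] * 4 + ["KO"] * 4)
            fit = de.sam_fit(m, SamConfig(rng_seed=rep))
            delta = de.tune_delta(fit, 15)
            res = de.sam_call(fit, SamConfig(delta=delta))
            called = {c.feature_id for c in res.calls if c.called}
            planted = {f"f{i}" for i in range(15)}
            recovered += len(called & planted) / 15
            if called:
                realized.append(len(called - planted) / len(called))
                estimated.append(res.fdr_median)
        assert recovered / n_rep >= 0.8
        # median-FDR estimate tracks the realized false-call proportion
        assert abs(np.mean(realized) - np.mean(estimated)) <= 0.1

    def test_zero_feature_calls_edge(self):
        m = make_matrix([[1, 1, 1, 1]] * 3, ["a", "b", "c"],
                        ["s1", "s2", "s3", "s4"], ["WT", "WT", "KO", "KO"])
        with pytest.warns(UserWarning):
            fit = de.sam_fit(m)
        res = de.sam_call(fit)
        assert res.n_called == 0 and res.calls[0].direction == "none"


class TestLog2fc:
    def test_equal_means_score_zero_direction_none(self):
        m = make_matrix([[4, 4, 4, 4]], ["g"], ["a", "b", "c", "d"],
                        ["WT", "WT", "KO", "KO"], mode="fpkm")
        (call,) = de.log2fc_table(m)
        assert call.score == 0.0 and call.direction == "none" and not call.called

    def test_closed_form(self):
        m = make_matrix([[2, 2, 8, 8]], ["g"], ["a", "b", "c", "d"],
                        ["WT", "WT", "KO", "KO"], mode="fpkm")
        (call,) = de.log2fc_table(m, pseudocount=0.0)
        assert call.score == 2.0 and call.direction == "up" and call.called

    def test_random_table_matches_independent_recomputation(self):
        rng = np.random.default_rng(6)
        vals = rng.uniform(0, 50, size=(30, 6))
        samples = [f"s{i}" for i in range(6)]
        m = make_matrix(vals, [f"g{i}" for i in range(30)], samples,
                        ["WT"] * 3 + ["KO"] * 3, mode="fpkm")
        calls = de.log2fc_table(m, pseudocount=1.0)
        for i, c in enumerate(calls):
            expect = math.log2((vals[i, 3:].mean() + 1) / (vals[i, :3].mean() + 1))
            assert c.score == pytest.approx(expect, rel=1e-12)

    def test_negative_values_are_domain_error(self):
        m = make_matrix([[-1, 2, 3, 4]], ["g"], ["a", "b", "c", "d"],
                        ["WT", "WT", "KO", "KO"], mode="intensity")
        with pytest.raises(ValueError):
            de.log2fc_table(m)


class TestCallsRoundtrip:
    def test_write_read(self, tmp_path, two_class_matrix):
        fit = de.sam_fit(two_class_matrix)
        res = de.sam_call(fit, SamConfig(delta=0.5))
        p = tmp_path / "calls.tsv"
        de.write_calls(res.calls, p)
        assert de.read_calls(p) == res.calls
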