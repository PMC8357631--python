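"""Two-sample testing and the permutation FDR estimator.

The exhaustive-permutation oracle here is an independent brute force: it
enumerates every distinct label assignment with plain itertools and
scipy's ttest_ind, builds the null from the non-observed assignments,
and applies the estimator definition (mean permuted exceedance count over
observed count, capped at 1, step-down monotone envelope) with explicit
loops.
"""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from conftest import make_quant_table
from ubage.differential import (
    ContrastSpec,
    permutation_fdr,
    run_contrast,
    summarize_counts,
    two_sample_t,
)
from ubage.io_tables import ValidationError


def brute_force_qvalues(matrix: pd.DataFrame, group_a, group_b) -> np.ndarray:
    """Independent enumeration of the permutation-FDR q-values."""
    combined = sorted(set(group_a) | set(group_b))
    k = min(len(group_a), len(group_b))
    small = set(group_a) if len(group_a) <= len(group_b) else set(group_b)
    balanced = 2 * k == len(combined)

    def abs_t(cols_x, cols_y):
        out = []
        for _, row in matrix.iterrows():
            t, _ = stats.ttest_ind(row[list(cols_x)], row[list(cols_y)], equal_var=True)
            out.append(abs(t))
        return out

    obs = abs_t(group_a, group_b)

    null_values = []
    for idx in combinations(range(len(combined)), k):
        chosen = {combined[i] for i in idx}
        if chosen == small or (balanced and chosen == set(combined) - small):
            continue  # the observed assignment is not a shuffle
        rest = [s for s in combined if s not in chosen]
        null_values.extend(abs_t(sorted(chosen), rest))
    n_perm = len(null_values) // len(matrix)

    fdr = []
    for c in obs:
        numerator = sum(v >= c for v in null_values) / n_perm
        denominator = sum(o >= c for o in obs)
        fdr.append(min(1.0, numerator / denominator))

    order = np.argsort([-o for o in obs], kind="stable")
    q = np.empty(len(obs))
    running = 0.0
    for i in order:
        running = max(running, fdr[i])
        q[i] = running
    return q


class TestTwoSampleT:
    def test_closed_form_example(self):
        fc, t, p = two_sample_t([1, 2, 3], [4, 5, 6], s0=0)
        assert fc == pytest.approx(-3.0)
        assert t == pytest.approx(-3.674, abs=1e-3)
        assert p == pytest.approx(0.0213, abs=1e-4)

    def test_identical_groups(self):
        assert two_sample_t([2, 2, 2], [2, 2, 2]) == (0.0, 0.0, 1.0)

    def test_degenerate_variance_different_means(self):
        fc, t, p = two_sample_t([1, 1], [2, 2])
        assert fc == -1.0
        assert np.isinf(t) and t < 0
        assert p == 0.0

    def test_large_s0_kills_statistic(self):
        _, t, p = two_sample_t([1, 2, 3], [7, 8, 9], s0=1e9)
        assert abs(t) < 1e-6
        assert p > 0.999

    def test_matches_scipy_student(self):
        rng = np.random.default_rng(1)
        a, b = rng.normal(0, 1, 5), rng.normal(1, 1, 7)
        fc, t, p = two_sample_t(a, b)
        ref_t, ref_p = stats.ttest_ind(a, b, equal_var=True)
        assert t == pytest.approx(ref_t)
        assert p == pytest.approx(ref_p)

    def test_missing_values_rejected(self):
        with pytest.raises(ValidationError):
            two_sample_t([1, np.nan, 3], [4, 5, 6])


class TestPermutationFdr:
    def _matrix(self, n_features=6, seed=0, samples=6, effect_rows=()):
        rng = np.random.default_rng(seed)
        values = rng.normal(25, 1, (n_features, samples))
        for r in effect_rows:
            values[r, : samples // 2] += 5
        cols = [f"a{i}" for i in range(samples // 2)] + [f"b{i}" for i in range(samples - samples // 2)]
        return pd.DataFrame(values, columns=cols, index=[f"F{i}" for i in range(n_features)])

    @pytest.mark.parametrize("effect_rows", [(), (0,), (0, 3)])
    def test_exhaustive_matches_brute_force_3v3(self, effect_rows):
        mat = self._matrix(effect_rows=effect_rows)
        spec = ContrastSpec("toy", ["a0", "a1", "a2"], ["b0", "b1", "b2"],
                            n_permutations="exhaustive")
        q = permutation_fdr(mat, spec)
        expected = brute_force_qvalues(mat, spec.group_a, spec.group_b)
        assert np.allclose(q.to_numpy(), expected)

    def test_exhaustive_matches_brute_force_unbalanced(self):
        mat = self._matrix(samples=7, effect_rows=(1,))
        spec = ContrastSpec("toy", ["a0", "a1", "a2"], ["b0", "b1", "b2", "b3"],
                            n_permutations="exhaustive")
        q = permutation_fdr(mat, spec)
        expected = brute_force_qvalues(mat, spec.group_a, spec.group_b)
        assert np.allclose(q.to_numpy(), expected)

    def test_requested_count_above_distinct_uses_exhaustive(self):
        mat = self._matrix(effect_rows=(0,))
        spec_int = ContrastSpec("toy", ["a0", "a1", "a2"], ["b0", "b1", "b2"],
                                n_permutations=250)
        spec_ex = ContrastSpec("toy", ["a0", "a1", "a2"], ["b0", "b1", "b2"],
                               n_permutations="exhaustive")
        assert np.allclose(permutation_fdr(mat, spec_int), permutation_fdr(mat, spec_ex))

    def test_constant_features_all_q_one(self):
        mat = pd.DataFrame(np.full((4, 6), 25.0),
                           columns=["a0", "a1", "a2", "b0", "b1", "b2"])
        spec = ContrastSpec("null", ["a0", "a1", "a2"], ["b0", "b1", "b2"],
                            n_permutations="exhaustive")
        q = permutation_fdr(mat, spec)
        assert (q == 1.0).all()

    def test_separated_feature_gets_q_zero(self):
        mat = self._matrix(n_features=8, effect_rows=(2,))
        mat.iloc[2, :3] += 100  # |t| beyond anything a shuffle can reach
        spec = ContrastSpec("sep", ["a0", "a1", "a2"], ["b0", "b1", "b2"],
                            n_permutations="exhaustive")
        q = permutation_fdr(mat, spec)
        assert q.iloc[2] == 0.0

    def test_q_monotone_in_abs_t(self):
        rng = np.random.default_rng(3)
        mat = pd.DataFrame(rng.normal(0, 1, (40, 8)),
                           columns=[f"a{i}" for i in range(4)] + [f"b{i}" for i in range(4)])
        spec = ContrastSpec("m", [f"a{i}" for i in range(4)], [f"b{i}" for i in range(4)],
                            n_permutations="exhaustive")
        q = permutation_fdr(mat, spec)
        t = np.abs([stats.ttest_ind(mat.loc[i, spec.group_a], mat.loc[i, spec.group_b],
                                    equal_var=True)[0] for i in mat.index])
        order = np.argsort(-t)
        assert (np.diff(q.to_numpy()[order]) >= -1e-12).all()

    def test_seeded_subsampling_deterministic(self):
        rng = np.random.default_rng(4)
        cols = [f"a{i}" for i in range(6)] + [f"b{i}" for i in range(6)]
        mat = pd.DataFrame(rng.normal(0, 1, (20, 12)), columns=cols)
        spec = ContrastSpec("s", cols[:6], cols[6:], n_permutations=100, seed=5)
        q1 = permutation_fdr(mat, spec)
        q2 = permutation_fdr(mat, spec)
        pd.testing.assert_series_equal(q1, q2)


class TestRunContrast:
    def _table(self, seed=0, n=50, effect=0.0):
        rng = np.random.default_rng(seed)
        values = rng.normal(25, 0.35, (n, 8))
        values[0, :4] += effect
        samples = [f"d15_{i}" for i in range(4)] + [f"d5_{i}" for i in range(4)]
        return make_quant_table(values, samples), samples

    def test_orientation_contract(self):
        table, samples = self._table(effect=2.0)
        spec = ContrastSpec("aged", samples[:4], samples[4:], n_permutations="exhaustive")
        diff = run_contrast(table, spec)
        # the feature higher at day 15 has a positive fold change
        assert diff["log2_fc"].iloc[0] > 0

    def test_swapping_groups_negates_fc_keeps_q(self):
        table, samples = self._table(seed=2, effect=1.5)
        fwd = ContrastSpec("f", samples[:4], samples[4:], n_permutations="exhaustive")
        rev = ContrastSpec("r", samples[4:], samples[:4], n_permutations="exhaustive")
        df, dr = run_contrast(table, fwd), run_contrast(table, rev)
        assert np.allclose(df["log2_fc"], -dr["log2_fc"])
        assert np.allclose(df["t_stat"], -dr["t_stat"])
        assert np.allclose(df["p_value"], dr["p_value"])
        assert np.allclose(df["q_value"], dr["q_value"])

    def test_planted_effect_recovered_across_seeds(self):
        """A 1.5 log2 effect at noise 0.35, n = 4, is found with fold
        change in [1.0, 2.0] for the vast majority of affected features."""
        rates = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            n, n_eff = 200, 30
            values = rng.normal(25, 0.35, (n, 8))
            values[:n_eff, :4] += 1.5
            samples = [f"d15_{i}" for i in range(4)] + [f"d5_{i}" for i in range(4)]
            table = make_quant_table(values, samples)
            spec = ContrastSpec("planted", samples[:4], samples[4:],
                                n_permutations="exhaustive", seed=seed)
            diff = run_contrast(table, spec)
            planted = diff.iloc[:n_eff]
            rates.append(
                float((planted["significant"] & planted["log2_fc"].between(1.0, 2.0)).mean())
            )
        assert sum(r >= 0.75 for r in rates) >= 9
        assert np.mean(rates) >= 0.85

    def test_significant_iff_q_below_threshold(self):
        table, samples = self._table(seed=3, n=100, effect=2.0)
        spec = ContrastSpec("c", samples[:4], samples[4:], n_permutations="exhaustive")
        diff = run_contrast(table, spec)
        assert (diff["significant"] == (diff["q_value"] < spec.fdr_threshold)).all()

    def test_weak_observed_evidence_not_called(self):
        table, samples = self._table(seed=4, n=30, effect=3.0)
        observed = pd.DataFrame(
            {"n_valid_a": 4, "n_valid_b": 4}, index=table.intensities.index
        )
        observed.iloc[0] = [4, 1]  # group b of the planted feature mostly imputed
        spec = ContrastSpec("g", samples[:4], samples[4:], n_permutations="exhaustive")
        diff = run_contrast(table, spec, observed_counts=observed)
        assert not diff["significant"].iloc[0]
        assert diff["q_value"].iloc[0] == 1.0

    def test_overlapping_groups_rejected(self):
        table, samples = self._table()
        with pytest.raises(ValidationError):
            ContrastSpec("bad", samples[:4], samples[3:]).validate(samples)


class TestSummarizeCounts:
    def test_counts_and_percentages(self):
        diff = pd.DataFrame(
            {
                "log2_fc": [1.0, 2.0, 0.5, -1.0, 0.3],
                "significant": [True, True, True, True, False],
            }
        )
        out = summarize_counts({"c": diff})
        row = out.loc["c"]
        assert (row["up"], row["down"]) == (3, 1)
        assert row["up_pct"] == pytest.approx(75.0)
        assert row["down_pct"] == pytest.approx(25.0)
        assert row["up_pct"] + row["down_pct"] == pytest.approx(100.0)

    def test_no_significant_reports_nan_percentages(self):
        diff = pd.DataFrame({"log2_fc": [1.0], "significant": [False]})
        row = summarize_counts({"c": diff}).loc["c"]
        assert (row["up"], row["down"]) == (0, 0)
        assert np.isnan(row["up_pct"]) and np.isnan(row["down_pct"])

    def test_multi_contrast_enumeration(self):
        tables = {}
        expected = {}
        rng = np.random.default_rng(8)
        for name in ("w", "x", "y", "z"):
            fc = rng.normal(0, 1, 20)
            sig = rng.random(20) < 0.4
            tables[name] = pd.DataFrame({"log2_fc": fc, "significant": sig})
            expected[name] = (int(((fc > 0) & sig).sum()), int(((fc < 0) & sig).sum()))
        out = summarize_counts(tables)
        for name, (up, down) in expected.items():
            assert (out.loc[name, "up"], out.loc[name, "down"]) == (up, down)
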