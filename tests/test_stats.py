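"""Statistics: omnibus tests, post-hocs, correlations, cohort report."""
import numpy as np
import pandas as pd
import pytest
from scipy.integrate import quad
from scipy.stats import norm
from scipy.stats import tukey_hsd as scipy_tukey

from picov.stats import (kruskal_wallis, nemenyi_posthoc, pearson_corr,
                         run_cohort_stats, tukey_posthoc)


def _sr_sf_integral(q_val, k):
    """Studentized-range survival function via its integral form."""
    f = lambda z: norm.pdf(z) * (norm.cdf(z) - norm.cdf(z - q_val)) ** (k - 1)
    return 1.0 - k * quad(f, -np.inf, np.inf)[0]


class TestKruskalWallis:
    def test_textbook_example(self):
        # integer data 1..11 are their own ranks: rank sums 15, 31, 20
        a, b, c = [1, 2, 5, 7], [4, 8, 9, 10], [3, 6, 11]
        res = kruskal_wallis([a, b, c])
        n = 11
        h = 12 / (n * (n + 1)) * (15 ** 2 / 4 + 31 ** 2 / 4 + 20 ** 2 / 3) \
            - 3 * (n + 1)
        assert res.statistic == pytest.approx(h, abs=1e-10)

    def test_identical_groups_not_significant(self):
        res = kruskal_wallis([[1.0, 1.0], [1.0, 1.0], [1.0, 1.0]])
        assert res.statistic == 0.0
        assert res.p_value == 1.0
        assert not res.significant

    def test_separated_groups_significant(self, rng):
        groups = [rng.normal(i, 0.1, 8) for i in range(3)]
        assert kruskal_wallis(groups).significant

    def test_needs_two_groups(self):
        with pytest.raises(ValueError):
            kruskal_wallis([[1, 2, 3]])


class TestNemenyi:
    def test_matches_integral_oracle(self, rng):
        groups = [rng.normal(i * 0.7, 1.0, 6) for i in range(4)]
        res = nemenyi_posthoc(groups)
        pooled = np.concatenate(groups)
        n = pooled.size
        ranks = np.array([1 + np.sum(pooled < x)
                          + 0.5 * (np.sum(pooled == x) - 1) for x in pooled])
        mean_ranks, start = [], 0
        for g in groups:
            mean_ranks.append(ranks[start:start + len(g)].mean())
            start += len(g)
        k = len(groups)
        for i in range(k):
            for j in range(i + 1, k):
                se = np.sqrt(n * (n + 1) / 12 * (1 / 6 + 1 / 6))
                q = abs(mean_ranks[i] - mean_ranks[j]) / se * np.sqrt(2)
                assert res.pairwise.iloc[i, j] == pytest.approx(
                    _sr_sf_integral(q, k), abs=1e-6)

    def test_symmetric_with_unit_diagonal(self, rng):
        groups = [rng.normal(i, 1, 5) for i in range(3)]
        m = nemenyi_posthoc(groups).pairwise.to_numpy()
        assert np.allclose(m, m.T)
        assert np.allclose(np.diag(m), 1.0)

    def test_duplicated_group_pair_not_significant(self):
        g = [1.0, 2.0, 3.0, 4.0]
        res = nemenyi_posthoc([g, list(g), [10.0, 11.0, 12.0, 13.0]])
        assert res.pairwise.iloc[0, 1] > 0.95

    def test_needs_three_groups(self):
        with pytest.raises(ValueError):
            nemenyi_posthoc([[1, 2], [3, 4]])


class TestTukey:
    def test_matches_scipy(self, rng):
        groups = [rng.normal(i * 0.5, 1.0, 7) for i in range(4)]
        ours = tukey_posthoc(groups).pairwise.to_numpy()
        ref = scipy_tukey(*groups).pvalue
        assert np.max(np.abs(ours - ref)) < 1e-6

    def test_unbalanced_matches_scipy(self, rng):
        groups = [rng.normal(0, 1, n) for n in (5, 9, 4)]
        ours = tukey_posthoc(groups).pairwise.to_numpy()
        ref = scipy_tukey(*groups).pvalue
        assert np.max(np.abs(ours - ref)) < 1e-6

    def test_identical_groups_p_one(self):
        g = [[1.0, 2.0], [1.0, 2.0], [1.0, 2.0]]
        m = tukey_posthoc(g).pairwise.to_numpy()
        off = m[~np.eye(3, dtype=bool)]
        assert np.allclose(off, 1.0)

    def test_named_pairwise_frame(self, rng):
        groups = [rng.normal(0, 1, 5) for _ in range(3)]
        res = tukey_posthoc(groups, names=("a", "b", "c"))
        assert list(res.pairwise.index) == ["a", "b", "c"]
        assert res.pairwise.loc["a", "b"] == res.pairwise.loc["b", "a"]


class TestPearson:
    def test_perfect_line(self):
        r, p = pearson_corr([1, 2, 3, 4], [2, 4, 6, 8])
        assert r == pytest.approx(1.0)
        assert p < 1e-6

    def test_sign(self):
        r, _ = pearson_corr([1, 2, 3, 4], [5, 3, 2, 0])
        assert r < -0.9

    def test_zero_variance_is_nan(self):
        r, p = pearson_corr([1, 1, 1], [1, 2, 3])
        assert np.isnan(r) and np.isnan(p)


def _toy_table(rng, shift_by_group=0.0, quad_shift=0.0):
    rows = []
    groups = ["control", "noDR", "mild", "mod-severe"]
    for layer in ("SVC", "DVC"):
        for gi, g in enumerate(groups):
            for e in range(6):
                base = 0.1 + shift_by_group * gi + rng.normal(0, 0.005)
                rows.append({
                    "eye_id": f"e{gi}{e}", "layer": layer, "group": g,
                    "picov": base,
                    "picov_ST": base + quad_shift,
                    "picov_SN": base,
                    "picov_IT": base + quad_shift,
                    "picov_IN": base,
                    "mean_PD": 0.55 - base, "sd_PD": 0.01,
                    "mean_VD": 0.3 - base / 2, "sd_VD": 0.01,
                })
    return pd.DataFrame(rows)


class TestCohortReport:
    def test_missing_columns_rejected(self):
        with pytest.raises(ValueError, match="missing columns"):
            run_cohort_stats(pd.DataFrame({"picov": [1.0]}))

    def test_null_table_gates_posthocs(self, rng):
        report = run_cohort_stats(_toy_table(rng), group_order=None)
        for layer, res in report.layers.items():
            if not res["kruskal_wallis"].significant:
                assert res["nemenyi"] is None

    def test_graded_table_flags_extremes(self, rng):
        report = run_cohort_stats(_toy_table(rng, shift_by_group=0.04))
        for res in report.layers.values():
            assert res["kruskal_wallis"].significant
            pm = res["nemenyi"].pairwise
            assert pm.loc["control", "mod-severe"] == pm.min().min()
            # negative PICoV-density correlation built into the table
            assert res["picov_correlations"]["mean_PD"]["r"] < -0.9

    def test_quadrant_pools_present(self, rng):
        report = run_cohort_stats(_toy_table(rng, quad_shift=0.05))
        for res in report.layers.values():
            for tag in ("quadrant_all_groups", "quadrant_dr_only"):
                assert res[tag] is not None
                assert res[tag]["kruskal_wallis"].significant

    def test_report_serializes(self, rng):
        import json
        report = run_cohort_stats(_toy_table(rng, shift_by_group=0.04))
        d = report.to_dict()
        json.dumps(d)  # must be JSON-clean
        assert set(d["layers"]) == {"SVC", "DVC"}
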