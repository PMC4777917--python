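import itertools

import numpy as np
import pandas as pd
import pytest

from foxgate.cohort import (SampleSummary, bonferroni, compare_cohort,
                            kruskal_test, mww_test, summaries_frame)


def mww_exact_oracle(x, y):
    """Two-sided exact MWW p by full enumeration of group assignments
    (no ties assumed); independent of scipy."""
    x, y = list(x), list(y)
    combined = x + y
    n1 = len(x)
    ranks = {v: r for r, v in enumerate(sorted(combined), start=1)}
    def u_of(subset):
        r1 = sum(ranks[v] for v in subset)
        return r1 - n1 * (n1 + 1) / 2
    u_obs = u_of(x)
    mean_u = n1 * len(y) / 2
    dev = abs(u_obs - mean_u)
    count = total = 0
    for subset in itertools.combinations(combined, n1):
        total += 1
        if abs(u_of(subset) - mean_u) >= dev - 1e-12:
            count += 1
    return count / total


class TestMww:
    def test_small_example_third(self):
        u, p = mww_test([1, 2], [3, 4])
        assert p == pytest.approx(1 / 3)

    def test_three_vs_three(self):
        _, p = mww_test([1, 2, 3], [4, 5, 6])
        assert p == pytest.approx(0.1)

    def test_identical_multisets_give_one(self):
        _, p = mww_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert p == pytest.approx(1.0)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            mww_test([], [1.0])

    @pytest.mark.parametrize("case", range(10))
    def test_matches_enumeration_oracle(self, case):
        rng = np.random.default_rng(400 + case)
        n1 = int(rng.integers(2, 6))
        n2 = int(rng.integers(2, 11 - n1))
        vals = rng.permutation(np.arange(1.0, n1 + n2 + 1))
        x, y = vals[:n1], vals[n1:]
        _, p = mww_test(x, y)
        assert p == pytest.approx(mww_exact_oracle(x, y), abs=1e-12)


class TestKruskal:
    def test_identical_constants_give_zero(self):
        h, p = kruskal_test([[5.0, 5.0], [5.0, 5.0], [5.0, 5.0]])
        assert h == 0.0 and p == 1.0

    def test_hand_computed_example(self):
        groups = [[1.0, 2.0, 3.0], [4.0, 5.0, 6.0], [7.0, 8.0, 9.0]]
        # textbook formula without ties:
        # H = 12/(N(N+1)) * sum n_i (Rbar_i - (N+1)/2)^2
        n = 9
        rbars = [2.0, 5.0, 8.0]
        h_oracle = 12 / (n * (n + 1)) * sum(
            3 * (rb - (n + 1) / 2) ** 2 for rb in rbars)
        h, _ = kruskal_test(groups)
        assert h == pytest.approx(h_oracle)

    def test_permutation_invariant(self):
        groups = [[1.0, 4.0], [2.0, 9.0], [3.0, 5.0, 7.0]]
        h1, _ = kruskal_test(groups)
        h2, _ = kruskal_test(groups[::-1])
        assert h1 == pytest.approx(h2)

    def test_fewer_than_three_groups_rejected(self):
        with pytest.raises(ValueError):
            kruskal_test([[1.0], [2.0]])


class TestBonferroni:
    def test_scaling_and_cap(self):
        np.testing.assert_allclose(bonferroni([0.01], m=3), [0.03])
        np.testing.assert_allclose(bonferroni([0.5], m=3), [1.0])
        np.testing.assert_allclose(bonferroni([0.2], m=1), [0.2])

    def test_monotone_and_at_least_raw(self):
        p = np.array([0.001, 0.04, 0.2, 0.9])
        adj = bonferroni(p)
        assert np.all(adj >= p)
        assert np.all(np.diff(adj[np.argsort(p)]) >= 0)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bonferroni([1.2])


def _summaries(effector_by_status, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    i = 0
    for status, (center, n) in effector_by_status.items():
        for _ in range(n):
            eff = center + rng.normal(0, 0.3)
            rows.append(SampleSummary(
                f"s{i}", status,
                {"effector_treg_like": max(eff, 0.0),
                 "naive_treg_like": max(3 + rng.normal(0, 0.3), 0),
                 "non_treg_like": max(3 + rng.normal(0, 0.3), 0)}))
            i += 1
    return rows


class TestCompareCohort:
    def test_two_group_layout(self):
        res = compare_cohort(_summaries({"HC": (2, 8), "mel": (6, 8)}))
        assert len(res) == 3
        assert (res["m"] == 3).all()
        assert np.all(res["p_adj"] >= res["p_raw"])
        eff = res[res.subpopulation == "effector_treg_like"].iloc[0]
        assert eff["p_adj"] < 0.05

    def test_staged_layout(self):
        res = compare_cohort(
            _summaries({"HC": (2, 6), "I-II": (2.5, 5), "III": (5, 5),
                        "IV": (6, 5)}),
            design="staged")
        kw = res[res.test == "Kruskal-Wallis"]
        pw = res[res.test == "MWW (pairwise)"]
        assert len(kw) == 3
        assert len(pw) == 9     # 3 subpopulations x 3 stage-vs-HC pairs
        assert (pw["m"] == 3).all()

    def test_all_pairs_family(self):
        res = compare_cohort(
            _summaries({"HC": (2, 5), "I-II": (3, 5), "III": (5, 5)}),
            design="staged", pairwise_family="all_pairs")
        pw = res[res.test == "MWW (pairwise)"]
        assert (pw["m"] == 3).all() and len(pw) == 9

    def test_single_sample_group_rejected(self):
        with pytest.raises(ValueError):
            compare_cohort(_summaries({"HC": (2, 1), "mel": (6, 5)}))

    def test_summaries_frame_round_trip(self):
        rows = _summaries({"HC": (2, 3), "mel": (6, 3)})
        df = summaries_frame(rows)
        assert set(df["status"]) == {"HC", "mel"}
        res = compare_cohort(df)
        assert len(res) == 3
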