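"""Bray-Curtis, inverse Simpson, turnover series and group comparisons."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import braycurtis as scipy_braycurtis
from scipy.stats import rankdata

from gutresidency import (
    CountMatrix,
    beta_time_trend,
    bray_curtis,
    consecutive_series,
    dunn_test,
    inverse_simpson,
    participant_dissimilarity_test,
    within_between_comparison,
)
from gutresidency.diversity import DissimilaritySeries, compact_letter_display


class TestBrayCurtis:
    def test_identical_vectors_zero(self):
        assert bray_curtis([2, 1, 5], [2, 1, 5]) == 0.0

    def test_disjoint_supports_one(self):
        assert bray_curtis([3, 0, 0], [0, 2, 7]) == 1.0

    def test_hand_computed_value(self):
        assert bray_curtis([2, 1, 0], [1, 1, 1]) == pytest.approx(1 - 4 / 6)

    def test_both_zero_undefined(self):
        with pytest.raises(ValueError, match="all-zero"):
            bray_curtis([0, 0], [0, 0])

    def test_symmetric_bounded_and_matches_scipy(self, rng):
        for _ in range(100):
            a = rng.integers(0, 50, size=12)
            b = rng.integers(0, 50, size=12)
            if a.sum() == 0 or b.sum() == 0:
                continue
            d = bray_curtis(a, b)
            assert d == pytest.approx(bray_curtis(b, a))
            assert 0.0 <= d <= 1.0
            assert d == pytest.approx(scipy_braycurtis(a, b), abs=1e-12)


class TestInverseSimpson:
    def test_uniform_equals_richness(self):
        assert inverse_simpson([5, 5, 5, 5]) == pytest.approx(4.0)

    def test_hand_computed_value(self):
        # p = (0.5, 0.25, 0.25) -> 1 / (0.25 + 0.0625 + 0.0625)
        assert inverse_simpson([2, 1, 1]) == pytest.approx(1 / 0.375)

    def test_single_taxon_is_one(self):
        assert inverse_simpson([0, 9, 0]) == pytest.approx(1.0)

    def test_scale_invariant(self, rng):
        a = rng.integers(1, 100, size=10)
        assert inverse_simpson(a) == pytest.approx(inverse_simpson(a * 17))

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            inverse_simpson([0, 0])


def _matrix_meta(columns, days, subject="P1"):
    taxa = [f"t{i}" for i in range(len(columns[0]))]
    ids = [f"{subject}_s{i}" for i in range(len(columns))]
    m = CountMatrix(pd.DataFrame(np.array(columns).T, index=taxa, columns=ids))
    meta = pd.DataFrame({"sample_id": ids, "subject_id": subject, "date": days})
    return m, meta


class TestConsecutiveSeries:
    def test_two_samples_one_pair(self):
        m, meta = _matrix_meta([[5, 1], [1, 5]], [0, 9])
        s = consecutive_series(m, meta, "P1")
        assert len(s.pairs) == 1
        assert s.pairs[0][:2] == (0, 9)

    def test_identical_consecutive_samples_zero(self):
        m, meta = _matrix_meta([[3, 3], [3, 3], [3, 3]], [0, 5, 11])
        assert consecutive_series(m, meta, "P1").values.tolist() == [0.0, 0.0]

    def test_matches_pairwise_bruteforce(self, rng):
        cols = rng.integers(1, 60, size=(6, 8)).tolist()
        m, meta = _matrix_meta(cols, [0, 4, 9, 15, 22, 30])
        s = consecutive_series(m, meta, "P1")
        arr = np.array(cols)
        for i, (_, _, v) in enumerate(s.pairs):
            assert v == pytest.approx(bray_curtis(arr[i], arr[i + 1]))


class TestBetaTimeTrend:
    def test_monotone_drift_positive_r(self):
        # communities drifting steadily: dissimilarity grows with lag
        cols = [[100 - 10 * i, 10 * i + 1, 50] for i in range(8)]
        m, meta = _matrix_meta(cols, list(range(0, 80, 10)))
        r, p, slope = beta_time_trend(m, meta, "P1")
        assert r > 0.5 and slope > 0

    def test_constant_dissimilarity_zero_r(self):
        m, meta = _matrix_meta([[5, 2]] * 4, [0, 7, 14, 21])
        r, p, slope = beta_time_trend(m, meta, "P1")
        assert r == 0.0 and slope == 0.0

    def test_anchor_first_uses_first_sample_pairs_only(self):
        cols = [[50, 1], [40, 11], [30, 21], [20, 31]]
        m, meta = _matrix_meta(cols, [0, 10, 20, 30])
        r_all, _, _ = beta_time_trend(m, meta, "P1")
        r_anchor, _, _ = beta_time_trend(m, meta, "P1", anchor_first=True)
        assert r_anchor > 0.99  # strictly increasing from the first sample
        assert r_all > 0

    def test_simulated_drift_positive_in_most_replicates(self, rng):
        wins = 0
        n_rep = 100
        for _ in range(n_rep):
            base = rng.integers(50, 150, size=20).astype(float)
            cols, state = [], base.copy()
            for _ in range(10):
                state = np.clip(state + rng.normal(0, 8, size=20), 1, None)
                cols.append(state.astype(int) + 1)
            m, meta = _matrix_meta(cols, list(range(0, 100, 10)))
            r, _, _ = beta_time_trend(m, meta, "P1")
            wins += r > 0
        assert wins / n_rep >= 0.95


class TestWithinBetween:
    def _two_subject_data(self, cols_a, cols_b, days_a, days_b):
        taxa = [f"t{i}" for i in range(len(cols_a[0]))]
        ids_a = [f"A_s{i}" for i in range(len(cols_a))]
        ids_b = [f"B_s{i}" for i in range(len(cols_b))]
        m = CountMatrix(pd.DataFrame(
            np.array(cols_a + cols_b).T, index=taxa, columns=ids_a + ids_b))
        meta = pd.DataFrame({
            "sample_id": ids_a + ids_b,
            "subject_id": ["A"] * len(ids_a) + ["B"] * len(ids_b),
            "date": days_a + days_b,
        })
        return m, meta

    def test_identical_communities_p_near_one(self):
        col = [10, 20, 30]
        m, meta = self._two_subject_data([col] * 3, [col] * 3,
                                         [0, 7, 14], [0, 7, 14])
        within, between, p = within_between_comparison(m, meta, "A", "B")
        assert p == pytest.approx(1.0)

    def test_disjoint_communities_small_p(self):
        a = [[10, 20, 0, 0], [12, 18, 0, 0], [9, 21, 0, 0], [11, 19, 0, 0]]
        b = [[0, 0, 15, 15], [0, 0, 14, 16], [0, 0, 16, 14], [0, 0, 13, 17]]
        m, meta = self._two_subject_data(a, b, [0, 7, 14, 21], [0, 7, 14, 21])
        within, between, p = within_between_comparison(m, meta, "A", "B")
        assert (between == 1.0).all()
        assert p < 0.01

    def test_between_pair_count_combinatorial(self, rng):
        a = (rng.integers(1, 40, size=(5, 6))).tolist()
        b = (rng.integers(1, 40, size=(7, 6))).tolist()
        m, meta = self._two_subject_data(a, b, list(range(0, 50, 10)),
                                         list(range(0, 70, 10)))
        within, between, _ = within_between_comparison(m, meta, "A", "B")
        assert len(between) == 5 * 7
        assert len(within) == 10 + 21


class TestParticipantTest:
    def _series(self, subject, values):
        pairs = tuple((i * 7, (i + 1) * 7, v) for i, v in enumerate(values))
        return DissimilaritySeries(subject, pairs)

    def test_identical_distributions_share_letter(self, rng):
        vals = rng.uniform(0.2, 0.4, size=20)
        series = [self._series(s, vals) for s in ("A", "B", "C")]
        h, p, pairs, letters = participant_dissimilarity_test(series)
        assert len(set(letters.values())) == 1

    def test_shifted_subject_gets_distinct_letter(self, rng):
        base = rng.uniform(0.2, 0.3, size=30)
        series = [self._series("A", base),
                  self._series("B", base + rng.uniform(-0.01, 0.01, size=30)),
                  self._series("C", base + 0.5)]
        h, p, pairs, letters = participant_dissimilarity_test(series)
        assert p < 0.001
        assert letters["C"] != letters["A"]
        assert set(letters["A"]) & set(letters["B"])

    def test_dunn_ranks_match_bruteforce_midranks(self, rng):
        groups = {g: rng.uniform(0, 1, size=n).round(1)  # force ties
                  for g, n in (("A", 12), ("B", 15), ("C", 9))}
        table = dunn_test(groups)
        # independent recomputation of one z value
        pooled = np.concatenate(list(groups.values()))
        ranks = rankdata(pooled)
        n = len(pooled)
        r_a = ranks[:12].mean()
        r_b = ranks[12:27].mean()
        _, counts = np.unique(pooled, return_counts=True)
        tie = (counts**3 - counts).sum() / (12 * (n - 1))
        se = np.sqrt((n * (n + 1) / 12 - tie) * (1 / 12 + 1 / 15))
        z_expected = (r_a - r_b) / se
        row = table[(table.group_a == "A") & (table.group_b == "B")].iloc[0]
        assert row.z == pytest.approx(z_expected, abs=1e-10)

    def test_letters_consistent_with_significance(self):
        pairs = pd.DataFrame([
            {"group_a": "A", "group_b": "B", "p_adj": 0.8},
            {"group_a": "A", "group_b": "C", "p_adj": 0.001},
            {"group_a": "B", "group_b": "C", "p_adj": 0.001},
        ])
        letters = compact_letter_display(["A", "B", "C"], pairs)
        assert set(letters["A"]) & set(letters["B"])
        assert not set(letters["A"]) & set(letters["C"])
        assert not set(letters["B"]) & set(letters["C"])
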