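"""Clone screening, residency, group comparisons and contingency tests."""

from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from gutresidency import (
    AnalysisConfig,
    CloneRecord,
    PresenceSeries,
    SamplingSchedule,
    beyond_study_contingency,
    call_residency,
    clone_residency,
    fisher_exact_2x2,
    group_residence_comparison,
    screen_candidate_residents,
)
from gutresidency.clones import clones_from_table, pool_small_groups

CFG = AnalysisConfig()
SCHED = SamplingSchedule("P1", tuple(range(0, 101, 10)))


def isolate_table(rows):
    return pd.DataFrame(rows, columns=["subject_id", "group_label", "day"])


class TestScreen:
    def test_span_over_threshold_is_candidate(self):
        t = isolate_table([("P1", "A", 0), ("P1", "A", 20)])
        out = screen_candidate_residents(t, CFG)
        assert out.candidate_resident.tolist() == [True]

    def test_single_sample_label_is_one_transient_clone(self):
        t = isolate_table([("P1", "E", 5), ("P1", "E", 5), ("P1", "E", 5)])
        out = screen_candidate_residents(t, CFG)
        row = out.iloc[0]
        assert not row.candidate_resident
        assert row.n_provisional_transient_clones == 1  # same sample, same group

    def test_empty_table_no_candidates(self):
        assert screen_candidate_residents(isolate_table([]), CFG).empty

    def test_span_exactly_threshold_qualifies(self):
        t = isolate_table([("P1", "B1", 0), ("P1", "B1", 14)])
        assert screen_candidate_residents(t, CFG).candidate_resident.all()


class TestCloneResidency:
    def test_boundary_clone_beyond_study(self):
        clone = CloneRecord("c1", "P1", "A", (0, 20, 40, 60, 80, 100))
        (cr,) = clone_residency([clone], {"P1": SCHED}, CFG)
        assert cr.beyond_study
        assert cr.calls["min"].always_resident

    def test_interior_short_clone_transient_under_min(self):
        clone = CloneRecord("c2", "P1", "B1", (40, 50))
        (cr,) = clone_residency([clone], {"P1": SCHED}, CFG)
        assert not cr.beyond_study
        assert cr.calls["min"].status == "transient"
        assert cr.observed_days("min") == 10

    def test_date_outside_schedule_rejected(self):
        clone = CloneRecord("c3", "P1", "A", (0, 33))
        with pytest.raises(ValueError, match="not in"):
            clone_residency([clone], {"P1": SCHED}, CFG)

    def test_reuses_taxon_episode_machinery(self):
        # identical presence pattern gives identical episodes either way
        dates = (20, 60, 90)
        clone = CloneRecord("c4", "P1", "F", dates)
        (cr,) = clone_residency([clone], {"P1": SCHED}, CFG)
        series = PresenceSeries("c4", SCHED, tuple(d in dates for d in SCHED.dates))
        for est in ("min", "ave", "max"):
            assert cr.calls[est].episodes == call_residency(series, CFG, est).episodes

    def test_clones_from_table_groups_by_fingerprint(self):
        df = pd.DataFrame({
            "subject_id": ["P1"] * 3 + ["P2"],
            "clone_id": ["c1", "c1", "c2", "c1"],
            "group_label": ["A", "A", "B1", "F"],
            "day": [0, 20, 10, 5],
        })
        recs = clones_from_table(df)
        assert {(r.subject_id, r.clone_id) for r in recs} == {
            ("P1", "c1"), ("P1", "c2"), ("P2", "c1")}
        (c1,) = [r for r in recs if r.subject_id == "P1" and r.clone_id == "c1"]
        assert c1.observation_dates == (0, 20)


_ids = iter(range(10**6))


def _cr(group, days_observed, boundary=False):
    """CloneResidency with one episode of min-span ``days_observed``.

    ``boundary`` puts the first observation on the subject's first sample,
    which makes the clone a beyond-study clone.
    """
    d = max(int(days_observed), 0)
    start = 0 if boundary else 30
    obs = tuple(sorted({start + x for x in range(0, d, 25)} | {start + d}))
    dates = tuple(sorted({0, *obs, obs[-1] + 97}))
    sched = SamplingSchedule("P1", dates)
    clone = CloneRecord(f"{group}-{next(_ids)}", "P1", group, obs)
    (cr,) = clone_residency([clone], {"P1": sched}, CFG)
    return cr


class TestGroupComparison:
    def test_hand_anova_on_toy_groups(self):
        # log10(days+1) values {1,2,3} vs {2,3,4}: hand ANOVA gives
        # SSB = 1.5, MSW = 1 -> F = 1.5 on (1, 4) df
        crs = ([_cr("L", 10 ** v - 1) for v in (1, 2, 3)]
               + [_cr("S", 10 ** v - 1) for v in (2, 3, 4)])
        f, p, means, pairs = group_residence_comparison(crs, "min", min_group_size=2)
        assert f == pytest.approx(1.5, rel=1e-9)
        assert p == pytest.approx(float(stats.f.sf(1.5, 1, 4)), rel=1e-9)
        assert means["L"] == pytest.approx(2.0)
        assert means["S"] == pytest.approx(3.0)

    def test_identical_groups_f_zero(self):
        crs = [_cr(g, d) for g in ("X", "Y") for d in (20, 40, 80)]
        f, p, means, pairs = group_residence_comparison(crs, "min", min_group_size=2)
        assert f == pytest.approx(0.0, abs=1e-12)
        assert means["X"] == pytest.approx(means["Y"])

    def test_small_groups_pool_into_other(self):
        crs = [_cr("big", d) for d in (20, 30, 40, 50, 60, 70, 80)] \
            + [_cr("tiny1", 20), _cr("tiny2", 30)]
        pooled = pool_small_groups(crs, min_group_size=6)
        assert set(pooled) == {"big", "Other"}
        assert len(pooled["Other"]) == 2

    def test_fewer_than_two_groups_rejected(self):
        crs = [_cr("only", d) for d in (20, 30, 40)]
        with pytest.raises(ValueError, match=">= 2 groups"):
            group_residence_comparison(crs, "min", min_group_size=1)

    def test_shifted_groups_detected_with_power(self, rng):
        """A 1.5-log10 residence shift between groups is detected nearly always."""
        from gutresidency.simulate import CloneGroupSpec, SimulationConfig, \
            simulate_clones
        sched = SamplingSchedule("P1", tuple(range(0, 512, 8)))
        cfg = SimulationConfig(clone_groups={
            "long": CloneGroupSpec(15, 2.0, 0.4),
            "short": CloneGroupSpec(15, 0.5, 0.4),
        })
        hits = 0
        n_rep = 200
        for _ in range(n_rep):
            recs, _ = simulate_clones(cfg, sched, rng)
            crs = clone_residency(recs, {"P1": sched}, CFG)
            if len({c.clone.group_label for c in crs}) < 2:
                continue
            _, p, _, _ = group_residence_comparison(crs, "ave", min_group_size=2)
            hits += p < 0.05
        assert hits / n_rep >= 0.9


def fisher_oracle(table):
    """Full enumeration over all 2x2 tables at the observed margins, exact
    rational arithmetic (independent of the implementation's k-scan)."""
    (a, b), (c, d) = table
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    denom = comb(n, c1)
    p_obs = Fraction(comb(r1, a) * comb(r2, c), denom)
    total = Fraction(0)
    for aa in range(0, min(r1, c1) + 1):
        cc = c1 - aa
        if cc < 0 or cc > r2:
            continue
        p = Fraction(comb(r1, aa) * comb(r2, cc), denom)
        if p <= p_obs:
            total += p
    return float(total)


class TestContingency:
    def test_fisher_diagonal_table_enumeration(self):
        t = [[10, 0], [0, 10]]
        p = fisher_exact_2x2(np.array(t))
        assert p == pytest.approx(fisher_oracle(t), rel=1e-12)
        assert p == pytest.approx(2 / comb(20, 10), rel=1e-12)

    def test_fisher_independent_table_p_one(self):
        assert fisher_exact_2x2(np.array([[5, 5], [5, 5]])) == pytest.approx(1.0)

    def test_fisher_matches_scipy_on_random_tables(self, rng):
        for _ in range(200):
            t = rng.integers(0, 25, size=(2, 2))
            if t.sum(axis=0).min() == 0 or t.sum(axis=1).min() == 0:
                continue
            ours = fisher_exact_2x2(t)
            _, ref = stats.fisher_exact(t)
            assert ours == pytest.approx(ref, abs=1e-9)

    def test_empty_margin_rejected(self):
        with pytest.raises(ValueError, match="margin"):
            fisher_exact_2x2(np.array([[0, 0], [3, 4]]))

    def test_tables_and_chi_square_match_hand_computation(self):
        # resident clones (80 d span) on the boundary, transients interior:
        # both 2x2 tables come out [[20,10],[10,20]], E = 15 everywhere,
        # chi2 = 4 * 25/15 = 6.6667
        crs = ([_cr("A", 80, boundary=True) for _ in range(20)]
               + [_cr("A", 5) for _ in range(10)]
               + [_cr("B1", 80, boundary=True) for _ in range(10)]
               + [_cr("B1", 5) for _ in range(20)])
        chi2, chi2_p, t_beyond, fisher_p, t_res = beyond_study_contingency(
            crs, long_lived_groups={"A"}, estimator="min")
        assert t_beyond.tolist() == [[20, 10], [10, 20]]
        assert t_res.tolist() == [[20, 10], [10, 20]]
        assert chi2 == pytest.approx(4 * 25 / 15, rel=1e-12)
        assert fisher_p == pytest.approx(fisher_oracle([[20, 10], [10, 20]]), rel=1e-12)

    def test_anova_type_one_error_calibrated(self, rng):
        """Null simulation: rejection rate at alpha=0.05 stays near 0.05."""
        rejections = 0
        n_rep = 2000
        for _ in range(n_rep):
            g1 = rng.normal(1.0, 0.4, size=12)
            g2 = rng.normal(1.0, 0.4, size=12)
            g3 = rng.normal(1.0, 0.4, size=12)
            _, p = stats.f_oneway(g1, g2, g3)
            rejections += p < 0.05
        assert abs(rejections / n_rep - 0.05) <= 0.02
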