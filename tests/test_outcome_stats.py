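"""Fertilization accounting, median ± MAD, and the signed-rank test vs its oracle."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from spermfx.outcome_stats import (
    CycleRecord,
    PairedCohort,
    build_report,
    cycles_to_cohort,
    fertilization_rate,
    median_mad,
    signed_rank_test,
    significance_tier,
    wilcoxon_paired,
)
from spermfx.synthetic_data import CohortSpec, make_cohort


def oracle_two_sided_p(x, y):
    """Independent brute-force oracle: full 2^n sign enumeration."""
    d = np.asarray(x, dtype=float) - np.asarray(y, dtype=float)
    d = d[d != 0]
    n = d.size
    ranks = stats.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    ws = np.array([
        sum(r for s, r in zip(signs, ranks) if s)
        for signs in itertools.product([0, 1], repeat=n)
    ])
    sf = np.mean(ws >= w_obs - 1e-9)
    cdf = np.mean(ws <= w_obs + 1e-9)
    return min(1.0, 2.0 * min(sf, cdf))


class TestFertilizationRate:
    def test_direct_ratio(self):
        rec = CycleRecord("c1", "DGC", "IVF", 10, 7, 0, 3, 0)
        assert fertilization_rate(rec) == pytest.approx(70.0)

    def test_triploid_stays_in_denominator(self):
        rec = CycleRecord("c1", "DGC", "IVF", 10, 6, 1, 3, 0)
        assert fertilization_rate(rec) == pytest.approx(60.0)

    def test_zero_zygotes(self):
        rec = CycleRecord("c1", "CA0", "ICSI", 8, 0, 0, 7, 1)
        assert fertilization_rate(rec) == 0.0

    def test_zero_denominator_rejected(self):
        with pytest.raises(ValueError):
            fertilization_rate(CycleRecord("c1", "DGC", "IVF", 0, 0))

    def test_outcomes_cannot_exceed_inseminated(self):
        with pytest.raises(ValueError):
            CycleRecord("c1", "DGC", "IVF", 5, 4, 2, 0, 0)

    def test_rate_always_in_0_100(self, rng):
        for _ in range(100):
            n = int(rng.integers(1, 20))
            z = int(rng.integers(0, n + 1))
            rate = fertilization_rate(CycleRecord("c", "DGC", "IVF", n, z))
            assert 0.0 <= rate <= 100.0


class TestMedianMad:
    @pytest.mark.parametrize(
        "values, med, mad",
        [([5, 5, 5], 5, 0), ([1, 2, 3, 4, 100], 3, 1), ([7.5], 7.5, 0)],
    )
    def test_examples(self, values, med, mad):
        mm = median_mad(values)
        assert mm.median == pytest.approx(med)
        assert mm.mad == pytest.approx(mad)
        assert mm.n == len(values)

    def test_mad_is_unscaled(self, rng):
        v = rng.normal(size=101)
        assert median_mad(v).mad == pytest.approx(
            np.median(np.abs(v - np.median(v)))
        )

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            median_mad([])


class TestSignedRank:
    def test_five_positive_pairs_exact(self):
        # only the all-positive and all-negative sign patterns are as extreme
        res = signed_rank_test([2, 3, 4, 5, 6], [1, 1, 1, 1, 1])
        assert res.mode == "exact"
        assert res.statistic_w == 15.0
        assert res.p_two_sided == pytest.approx(2 / 32)

    def test_all_zero_differences_degenerate(self):
        res = signed_rank_test([1, 2, 3], [1, 2, 3])
        assert res.mode == "degenerate"
        assert res.p_two_sided == 1.0

    def test_exact_matches_enumeration_oracle(self, rng):
        # integer-valued pairs force ties and zero differences
        for _ in range(60):
            n = int(rng.integers(3, 13))
            x = rng.integers(0, 6, size=n).astype(float)
            y = rng.integers(0, 6, size=n).astype(float)
            if np.all(x == y):
                continue
            res = signed_rank_test(x, y)
            assert res.p_two_sided == pytest.approx(oracle_two_sided_p(x, y), abs=1e-12)

    def test_exact_matches_scipy_without_ties(self, rng):
        for _ in range(20):
            n = int(rng.integers(6, 18))
            d = rng.normal(size=n)  # continuous: no ties, no zeros
            x = d + 10.0
            y = np.full(n, 10.0)
            res = signed_rank_test(x, y)
            ref = stats.wilcoxon(x, y, alternative="two-sided", method="exact")
            assert res.p_two_sided == pytest.approx(ref.pvalue, abs=1e-12)

    def test_normal_approx_matches_scipy(self, rng):
        x = rng.normal(size=50)
        y = rng.normal(size=50)
        res = signed_rank_test(x, y, exact_limit=20)
        assert res.mode == "normal_approx"
        ref = stats.wilcoxon(x, y, alternative="two-sided", method="approx",
                             correction=True)
        assert res.p_two_sided == pytest.approx(ref.pvalue, abs=1e-9)

    def test_arm_swap_antisymmetry(self, rng):
        for _ in range(20):
            n = int(rng.integers(4, 15))
            x = rng.normal(size=n)
            y = rng.normal(size=n)
            a = signed_rank_test(x, y)
            b = signed_rank_test(y, x)
            assert a.p_two_sided == b.p_two_sided
            assert b.statistic_w == pytest.approx(
                a.n_used * (a.n_used + 1) / 2 - a.statistic_w
            )

    @given(st.floats(min_value=-50, max_value=50),
           st.floats(min_value=0.1, max_value=20))
    @settings(max_examples=30, derandomize=True)
    def test_invariance_under_shift_and_positive_scaling(self, shift, scale):
        rng = np.random.default_rng(12)
        x = rng.normal(size=10)
        y = rng.normal(size=10)
        base = signed_rank_test(x, y)
        moved = signed_rank_test(scale * (x + shift), scale * (y + shift))
        assert moved.p_two_sided == base.p_two_sided
        assert moved.statistic_w == base.statistic_w

    def test_w_within_bounds(self, rng):
        for _ in range(20):
            n = int(rng.integers(2, 25))
            res = signed_rank_test(rng.normal(size=n), rng.normal(size=n))
            assert 0 <= res.statistic_w <= res.n_used * (res.n_used + 1) / 2
            assert 0 < res.p_two_sided <= 1


class TestReport:
    def _cohort(self, dgc, ca0, variable="v", sample_class="Nz", group="other"):
        n = len(dgc)
        return PairedCohort(variable=variable, units="u", sample_class=sample_class,
                            subject_id=tuple(f"s{i}" for i in range(n)),
                            dgc=dgc, ca0=ca0, group=group)

    def test_identical_arms_not_significant(self):
        c = self._cohort([1.0, 2, 3, 4], [1.0, 2, 3, 4])
        tables = build_report([c])
        row = tables["summary"].iloc[0]
        assert row["significance"] == "NS"
        assert row["p_two_sided"] == 1.0

    def test_cohort_at_count_medians_reports_medians_within_mad(self):
        spec = CohortSpec(
            n_subjects=12, sample_class="Nz", variable="sperm_count",
            units="1e6 cells", dgc_median=36.0, dgc_mad=9.0,
            ca0_median=52.0, ca0_mad=13.0, seed=4, group="counts",
        )
        tables = build_report([make_cohort(spec)])
        row = tables["summary"].iloc[0]
        assert row["dgc_median"] == pytest.approx(36.0, abs=9.0)
        assert row["ca0_median"] == pytest.approx(52.0, abs=13.0)

    def test_incomplete_pairs_excluded(self):
        c = self._cohort([1.0, 2, np.nan, 4], [2.0, 1, 3, np.nan])
        assert c.complete().n_subjects == 2
        assert wilcoxon_paired(c).n_used == 2

    def test_no_cycles_omits_fertilization_table(self, tmp_path):
        c = self._cohort([1.0, 2, 3, 4], [2.0, 3, 1, 5])
        tables = build_report([c], cycles=(), out_dir=tmp_path)
        assert "table_fertilization" not in tables
        assert (tmp_path / "summary.csv").exists()

    def test_cycles_paired_by_cycle_id(self):
        cycles = [
            CycleRecord("c1", "DGC", "IVF", 10, 7),
            CycleRecord("c1", "CA0", "IVF", 10, 6),
            CycleRecord("c2", "DGC", "IVF", 8, 4),
            CycleRecord("c2", "CA0", "IVF", 8, 6),
            CycleRecord("c3", "DGC", "ICSI", 6, 3),  # no CA0 arm: dropped
        ]
        cohort = cycles_to_cohort(cycles, "IVF")
        assert cohort.n_subjects == 2
        np.testing.assert_allclose(cohort.dgc, [70.0, 50.0])
        np.testing.assert_allclose(cohort.ca0, [60.0, 75.0])
        with pytest.raises(ValueError):
            cycles_to_cohort(cycles, "ICSI")

    @pytest.mark.parametrize(
        "p, tier",
        [(0.2, "NS"), (0.05, "P<=0.05"), (0.01, "P<=0.01"), (0.0005, "P<=0.001")],
    )
    def test_significance_tiers(self, p, tier):
        assert significance_tier(p) == tier
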