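import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from cardiogate import (InvalidInputError, alt_accuracy, awareness,
                        confidence_mean, flag_overestimator, insight,
                        profile_cohort, profile_subject, sensibility,
                        std_accuracy, tipe)


class TestAccuracy:
    def test_perfect_report(self):
        assert std_accuracy([50, 40], [50, 40]) == 1.0
        assert alt_accuracy([50, 40], [50, 40]) == 1.0

    def test_std_hand_values(self):
        assert std_accuracy([50], [40]) == pytest.approx(0.8)
        # beyond 2x over-reporting the standard score goes negative
        assert std_accuracy([50], [110]) == pytest.approx(-0.2)
        assert flag_overestimator([50], [110])

    def test_alt_hand_values(self):
        assert alt_accuracy([50], [40]) == pytest.approx(1 - 10 / 45)
        assert alt_accuracy([60], [10]) == pytest.approx(1 - 50 / 35)

    def test_zero_real_rejected(self):
        with pytest.raises(InvalidInputError):
            std_accuracy([0], [5])

    @settings(deadline=None, derandomize=True)
    @given(st.lists(st.tuples(st.integers(1, 200), st.integers(0, 600)),
                    min_size=1, max_size=10))
    def test_alt_accuracy_bounded(self, pairs):
        real = [p[0] for p in pairs]
        rep = [p[1] for p in pairs]
        if all(r + q > 0 for r, q in pairs):
            assert -1.0 <= alt_accuracy(real, rep) <= 1.0
            assert std_accuracy(real, rep) <= 1.0

    @settings(deadline=None, derandomize=True)
    @given(st.lists(st.tuples(st.integers(20, 80), st.integers(0, 250)),
                    min_size=2, max_size=6))
    def test_negative_std_implies_some_overestimation(self, pairs):
        """std accuracy < 0 on a trial iff reported > 2x real on that trial;
        the subject-level rule is consistent with the per-trial algebra."""
        real = np.array([p[0] for p in pairs], dtype=float)
        rep = np.array([p[1] for p in pairs], dtype=float)
        per_trial = 1 - np.abs(real - rep) / real
        np.testing.assert_array_equal(per_trial < 0, rep > 2 * real)


class TestInsight:
    def test_perfect_alignment(self):
        assert insight([50] * 3, [40] * 3, [8] * 3) == pytest.approx(0.0)

    def test_high_performance_low_confidence(self):
        assert insight([100] * 2, [90] * 2, [4] * 2) == pytest.approx(0.5)

    def test_low_performance_high_confidence(self):
        # accuracy 0.3, confidence 8 -> signed score is negative
        assert insight([100] * 2, [30] * 2, [8] * 2) == pytest.approx(-0.5)

    def test_antisymmetry(self):
        """Swapping the roles of accuracy and rescaled confidence flips
        the sign of the discrepancy."""
        real, rep, conf = [100, 100, 100], [90, 70, 85], [6.0, 8.0, 5.0]
        forward = insight(real, rep, conf)
        # construct trials whose accuracy equals the old confidence/10 and
        # whose confidence equals the old accuracy*10
        acc = 1 - np.abs(np.array(real) - np.array(rep)) / np.array(real)
        swapped = insight([100] * 3, (np.array(conf) * 10).astype(int),
                          (acc * 10))
        assert swapped == pytest.approx(-forward)


class TestAwareness:
    def test_exact_linear_positive(self):
        real = [60, 60, 60, 60, 60, 60]
        rep = [30, 36, 42, 48, 54, 60]
        acc = 1 - np.abs(np.array(real) - np.array(rep)) / ((np.array(real) + np.array(rep)) / 2)
        conf = 10 * (acc - acc.min()) / (acc.max() - acc.min())
        assert awareness(real, rep, conf) == pytest.approx(1.0)
        assert awareness(real, rep, 10 - conf) == pytest.approx(-1.0)

    def test_matches_pearson_oracle(self):
        real = np.array([40, 45, 50, 55, 60, 65])
        rep = np.array([20, 30, 38, 47, 55, 65])
        conf = [2, 4, 3, 7, 6, 9]
        acc = 1 - np.abs(real - rep) / ((real + rep) / 2)
        assert awareness(real, rep, conf) == pytest.approx(
            np.corrcoef(acc, conf)[0, 1])

    def test_frozen_pearson_value(self):
        # Pearson of (0.5..1.0 in steps of .1) vs (2,4,3,7,6,9)
        acc = [0.5, 0.6, 0.7, 0.8, 0.9, 1.0]
        conf = [2, 4, 3, 7, 6, 9]
        assert np.corrcoef(acc, conf)[0, 1] == pytest.approx(0.9113097, abs=1e-6)

    def test_degenerate_returns_none(self):
        assert awareness([50] * 6, [50] * 6, [3, 4, 5, 6, 7, 8]) is None
        assert awareness([50, 60, 70], [40, 50, 60], [5, 5, 5]) is None

    @settings(deadline=None, derandomize=True)
    @given(st.floats(0.1, 5.0), st.floats(-3.0, 3.0))
    def test_affine_confidence_invariance(self, a, b):
        """Awareness is invariant under positive affine rescaling of
        confidence (Pearson property)."""
        real = [50, 55, 60, 65, 70, 75]
        rep = [40, 50, 45, 60, 72, 70]
        conf = np.array([2.0, 5.0, 3.0, 7.0, 9.0, 6.0])
        base = awareness(real, rep, conf)
        scaled = awareness(real, rep, a * conf + b)
        assert scaled == pytest.approx(base, abs=1e-9)


def test_confidence_mean():
    assert confidence_mean([5.0] * 6) == 5.0
    assert confidence_mean([2, 4, 6, 8, 10, 0]) == 5.0


class TestSensibility:
    def test_constant_items(self):
        assert sensibility([3] * 45) == 3.0
        assert sensibility([5] * 45) == 5.0

    def test_mixed_items(self):
        items = [1] * 22 + [5] * 22 + [3]
        assert sensibility(items) == pytest.approx(3.0)

    def test_out_of_range_rejected(self):
        with pytest.raises(InvalidInputError):
            sensibility([3] * 44 + [6])


class TestTipe:
    def test_identical_z_vectors_cancel(self):
        # both columns are exact linear ramps: z-scores coincide
        out = tipe([0.2, 0.5, 0.8], [2.0, 3.0, 4.0])
        np.testing.assert_allclose(out, 0.0, atol=1e-12)

    def test_cohort_mean_zero_and_unit_sd(self, rng):
        acc = rng.normal(0.6, 0.2, 30)
        sens = rng.normal(2.5, 0.6, 30)
        out = tipe(acc, sens)
        assert np.mean(out) == pytest.approx(0.0, abs=1e-9)
        for col in (acc, sens):
            z = (col - col.mean()) / col.std(ddof=1)
            assert z.std(ddof=1) == pytest.approx(1.0, abs=1e-9)

    def test_subject_at_cohort_mean(self):
        acc = np.array([0.4, 0.6, 0.5])
        sens = np.array([2.0, 4.0, 3.0])
        assert tipe(acc, sens)[2] == pytest.approx(0.0, abs=1e-12)


class TestOverestimatorFlag:
    def test_exact_report_not_flagged(self):
        assert not flag_overestimator([30, 40], [30, 40])

    def test_totals_rule(self):
        assert flag_overestimator([100, 100], [220, 230])   # 450 > 400
        assert not flag_overestimator([100, 100], [200, 200])

    def test_cohort_with_one_overestimator(self):
        """An injected over-estimator keeps alternative-based indices only,
        so the standard-accuracy column has one fewer entry."""
        rows = []
        for s in range(5):
            for t in range(6):
                real = 40 + t
                rep = real * 3 if s == 0 else real - 5
                rows.append({"subject_id": f"s{s}", "trial_index": t,
                             "nbeats_real": real, "nbeats_reported": rep,
                             "confidence": 5.0 + t})
        prof = profile_cohort(pd.DataFrame(rows))
        assert prof["overestimator"].sum() == 1
        assert prof["std_accuracy"].notna().sum() == 4
        assert prof["insight"].notna().sum() == 4
        assert prof["alt_accuracy"].notna().sum() == 5


def test_profile_subject_assembles_indices():
    p = profile_subject("s1", [50, 60, 70], [40, 50, 60], [4, 5, 6],
                        bpq=[3] * 45)
    assert p.std_accuracy == pytest.approx(np.mean([0.8, 1 - 10 / 60, 1 - 10 / 70]))
    assert p.sensibility == 3.0
    assert not p.overestimator
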