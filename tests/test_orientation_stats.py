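"""Angle binning and the group-comparison statistics."""

import dataclasses
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from epistrat.orientation_stats import (
    BIN_NAMES,
    BinProportions,
    bin_angles,
    chi_squared_bins,
    compare_group_means,
    ks_two_sample,
    proportions_anova,
    radial_histogram,
)
from epistrat.synthetic_data import default_config


class TestBinAngles:
    @pytest.mark.parametrize(
        "angles,expected",
        [
            ([0, 15, 29.9], (3, 0, 0)),
            ([10, 45, 80], (1, 1, 1)),
            ([30, 60, 90], (0, 1, 2)),  # half-open convention; 90 included
        ],
    )
    def test_bin_assignment(self, angles, expected):
        assert bin_angles(angles).counts == expected

    def test_out_of_range_identified(self):
        with pytest.raises(ValueError, match="position"):
            bin_angles([10.0, 95.0])

    @given(st.lists(st.floats(0, 90), min_size=1, max_size=200))
    @settings(max_examples=50, derandomize=True)
    def test_partition_conserves_counts(self, angles):
        bp = bin_angles(angles)
        assert bp.n == len(angles)
        assert sum(bp.proportions) == pytest.approx(1.0)


class TestRadialHistogram:
    def test_empty_input_all_zero(self):
        df = radial_histogram([])
        assert (df["count"] == 0).all()
        assert len(df) == 9

    def test_point_mass_in_first_bin(self):
        df = radial_histogram([5.0] * 7)
        assert df["count"].iloc[0] == 7
        assert df["count"].sum() == 7

    def test_uniform_sample_fills_bins_evenly(self):
        rng = np.random.default_rng(0)
        angles = rng.uniform(0, 90, size=9000)
        df = radial_histogram(angles)
        se = math.sqrt(9000 * (1 / 9) * (8 / 9))
        assert (np.abs(df["count"] - 1000) < 3 * se).all()

    def test_angle_90_lands_in_last_bin(self):
        df = radial_histogram([90.0])
        assert df["count"].iloc[-1] == 1

    def test_non_divisor_width_rejected(self):
        with pytest.raises(ValueError):
            radial_histogram([10.0], bin_width_deg=7.0)


class TestChiSquared:
    def test_identical_counts_give_zero_statistic(self):
        res = chi_squared_bins((10, 20, 30), (10, 20, 30))
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_hand_computed_statistic(self):
        # expected counts (35, 30, 35) per group; Pearson X² = 25.714...
        res = chi_squared_bins((50, 30, 20), (20, 30, 50))
        assert res.statistic == pytest.approx(2 * (15**2 / 35 + 0 + 15**2 / 35))
        assert res.df == 2

    def test_symmetric_in_group_order(self):
        a = chi_squared_bins((5, 10, 40), (12, 9, 7))
        b = chi_squared_bins((12, 9, 7), (5, 10, 40))
        assert a.statistic == pytest.approx(b.statistic)

    def test_statistic_scales_with_counts(self):
        # documented behaviour: chi-squared is NOT invariant to count scaling
        a = chi_squared_bins((5, 3, 2), (2, 3, 5))
        b = chi_squared_bins((50, 30, 20), (20, 30, 50))
        assert b.statistic == pytest.approx(10 * a.statistic)

    def test_empty_column_dropped_with_reduced_df(self):
        with pytest.warns(UserWarning, match="dropped"):
            res = chi_squared_bins((10, 0, 30), (20, 0, 5))
        assert res.df == 1

    def test_low_expected_counts_flagged(self):
        res = chi_squared_bins((2, 2, 2), (1, 2, 3))
        assert any("expected" in w for w in res.warnings)

    def test_type_I_error_near_nominal(self):
        """Under the null (same mixture both groups) rejection at α=0.05
        occurs in 5% ± 2% of simulated datasets."""
        mix = default_config().angle_mixtures[("control", 16.5)]
        rng = np.random.default_rng(2024)
        n_sim, n_per_group = 1000, 100
        rejections = 0
        for _ in range(n_sim):
            a = bin_angles(mix.sample(n_per_group, rng))
            b = bin_angles(mix.sample(n_per_group, rng))
            if chi_squared_bins(a.counts, b.counts).p_value < 0.05:
                rejections += 1
        assert rejections / n_sim == pytest.approx(0.05, abs=0.02)

    def test_power_for_preset_separation(self):
        """Control (~40% perpendicular) vs mutant (~60%) at n=100/group is
        detected in >80% of datasets at α=0.05."""
        cfg = default_config()
        ctrl = cfg.angle_mixtures[("control", 16.5)]
        mut = cfg.angle_mixtures[("mutant", 16.5)]
        rng = np.random.default_rng(7)
        n_sim = 400
        rejections = sum(
            chi_squared_bins(
                bin_angles(ctrl.sample(100, rng)).counts,
                bin_angles(mut.sample(100, rng)).counts,
            ).p_value
            < 0.05
            for _ in range(n_sim)
        )
        assert rejections / n_sim > 0.8


class TestKolmogorovSmirnov:
    def test_identical_samples(self):
        res = ks_two_sample([10, 20, 30], [10, 20, 30])
        assert res.statistic == 0.0

    def test_disjoint_samples(self):
        res = ks_two_sample([1, 2, 3], [50, 60, 70])
        assert res.statistic == 1.0
        assert res.p_value < 0.05

    def test_ecdf_enumeration_case(self):
        res = ks_two_sample([10, 20, 30], [10, 20, 30, 70])
        assert res.statistic == pytest.approx(0.25)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            ks_two_sample([], [1.0])


def _bp(props, group="g"):
    counts = tuple(int(round(p * 100)) for p in props)
    return BinProportions(group=group, counts=counts, proportions=tuple(props))


class TestProportionsAnova:
    def test_identical_animals_give_p_one(self):
        per_animal = [
            (g, f"{g}{i}", _bp((0.4, 0.3, 0.3)))
            for g in ("control", "mutant")
            for i in range(4)
        ]
        res = proportions_anova(per_animal)
        assert res.p_value == pytest.approx(1.0)

    def test_deterministic_separation_detected(self):
        per_animal = [
            ("control", f"c{i}", _bp((0.4, 0.2, 0.4))) for i in range(5)
        ] + [
            ("mutant", f"m{i}", _bp((0.17, 0.23, 0.60))) for i in range(5)
        ]
        res = proportions_anova(per_animal)
        assert res.p_value < 1e-6  # below any fixed α; zero-variance handled

    def test_single_animal_genotype_rejected(self):
        per_animal = [
            ("control", "c1", _bp((0.4, 0.3, 0.3))),
            ("control", "c2", _bp((0.4, 0.3, 0.3))),
            ("mutant", "m1", _bp((0.2, 0.3, 0.5))),
        ]
        with pytest.raises(ValueError, match="mutant"):
            proportions_anova(per_animal)

    def test_null_p_values_roughly_uniform(self):
        """Permuting genotype labels under the null keeps the interaction
        p-value approximately uniform (checked by rejection rate)."""
        mix = default_config().angle_mixtures[("control", 16.5)]
        rng = np.random.default_rng(11)
        pvals = []
        for _ in range(200):
            per_animal = [
                (g, f"{g}{i}", bin_angles(mix.sample(30, rng)))
                for g in ("a", "b")
                for i in range(5)
            ]
            pvals.append(proportions_anova(per_animal).p_value)
        pvals = np.asarray(pvals)
        # coarse uniformity: rejection near nominal at two thresholds
        assert np.mean(pvals < 0.05) == pytest.approx(0.05, abs=0.05)
        assert np.mean(pvals < 0.5) == pytest.approx(0.5, abs=0.15)


class TestGroupMeans:
    def test_identical_groups(self):
        res = compare_group_means([1, 2, 3], [1, 2, 3])
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_constant_equal_groups(self):
        res = compare_group_means([2, 2, 2], [2, 2, 2])
        assert res.p_value == 1.0

    def test_separation_limit(self):
        for eps in (1e-2, 1e-4):
            a = np.array([0.0, eps, -eps, 0.0])
            b = np.array([1.0, 1 + eps, 1 - eps, 1.0])
            assert compare_group_means(a, b).p_value < eps

    def test_too_small_group_rejected(self):
        with pytest.raises(ValueError):
            compare_group_means([1.0], [1.0, 2.0])
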