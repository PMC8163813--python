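"""Statistical structure and determinism of the synthetic measurement tables."""

import dataclasses
import math

import numpy as np
import pytest

from epistrat.synthetic_data import (
    AngleMixture,
    AxisGrowth,
    DensityCurve,
    GeneratorConfig,
    GeneratorConfigError,
    default_config,
    generate_angle_dataset,
    generate_density_table,
    generate_edu_table,
    generate_growth_table,
)
from epistrat.orientation_stats import bin_angles


class TestGrowthTable:
    def test_noise_free_lengths_follow_the_line(self):
        cfg = GeneratorConfig(
            stages=(12.5,),
            embryos_per_stage=3,
            growth={
                "sagittal": AxisGrowth(1.0, 1.0, 0.0),
                "orthogonal": AxisGrowth(1.0, 1.0, 0.0),
            },
        )
        df = generate_growth_table(cfg)
        sag = df[df["axis"] == "sagittal"]
        assert (sag["length_mm"] == 13.5).all()

    def test_same_seed_reproduces_table(self, config):
        assert generate_growth_table(config).equals(generate_growth_table(config))

    def test_large_sample_mean_near_expected(self):
        cfg = GeneratorConfig(
            seed=5,
            stages=(14.5,),
            embryos_per_stage=10_000,
            growth={
                "sagittal": AxisGrowth(2.0, 1.0, 0.8),
                "orthogonal": AxisGrowth(1.0, 0.5, 0.4),
            },
        )
        df = generate_growth_table(cfg)
        sag = df[df["axis"] == "sagittal"]["length_mm"]
        expected = 2.0 + 1.0 * 14.5
        se = 0.8 / math.sqrt(len(sag))
        assert abs(sag.mean() - expected) < 3 * se

    def test_non_positive_expected_length_rejected(self):
        with pytest.raises(GeneratorConfigError):
            GeneratorConfig(
                stages=(12.5,),
                growth={"sagittal": AxisGrowth(-100.0, 1.0, 0.0)},
            )

    def test_non_positive_slope_rejected(self):
        with pytest.raises(GeneratorConfigError):
            GeneratorConfig(
                stages=(12.5,),
                growth={"sagittal": AxisGrowth(10.0, -1.0, 0.0)},
            )


class TestDensityTable:
    def test_noise_free_matches_curve_exactly(self, noise_free_config):
        df = generate_density_table(noise_free_config)
        for (layer, axis), curve in noise_free_config.density_curves.items():
            sub = df[(df["layer"] == layer) & (df["axis"] == axis)]
            for stage, expected in curve.values.items():
                got = sub[sub["stage"] == stage]["density_per_100um"]
                assert np.allclose(got, expected)

    def test_suprabasal_absent_at_E12_5(self, tables):
        early = tables["density"][
            (tables["density"]["stage"] == 12.5)
            & (tables["density"]["layer"] == "suprabasal")
        ]
        assert (early["density_per_100um"] == 0.0).all()

    def test_parity_at_E15_5(self, tables):
        d = tables["density"]
        at = d[d["stage"] == 15.5].groupby("layer")["density_per_100um"].mean()
        assert at["suprabasal"] / at["basal"] == pytest.approx(1.0, abs=0.1)

    def test_determinism(self, config):
        assert generate_density_table(config).equals(generate_density_table(config))


class TestEdUTable:
    @pytest.mark.parametrize("fraction,expect", [(0.0, 0), (1.0, 100)])
    def test_degenerate_fractions(self, config, fraction, expect):
        curves = {
            layer: dataclasses.replace(
                c, values={s: fraction for s in c.values}
            )
            for layer, c in config.edu_curves.items()
        }
        cfg = dataclasses.replace(config, edu_curves=curves)
        df = generate_edu_table(cfg)
        assert (df["n_positive"] == expect).all()

    def test_binomial_pooled_fraction(self):
        cfg = dataclasses.replace(
            default_config(seed=3),
            stages=(13.5,),
            animals_per_stage=100,
            edu_cells_per_animal=1000,
        )
        curves = {
            layer: dataclasses.replace(c, values={13.5: 0.27})
            for layer, c in cfg.edu_curves.items()
        }
        cfg = dataclasses.replace(cfg, edu_curves=curves)
        df = generate_edu_table(cfg)
        basal = df[df["layer"] == "basal"]
        pooled = basal["n_positive"].sum() / basal["n_total"].sum()
        se = math.sqrt(0.27 * 0.73 / basal["n_total"].sum())
        assert abs(pooled - 0.27) < 3 * se

    def test_suprabasal_labeling_collapses_after_E15_5(self, tables):
        edu = tables["edu"]
        sup = edu[edu["layer"] == "suprabasal"]
        frac = sup.groupby("stage").apply(
            lambda g: g["n_positive"].sum() / g["n_total"].sum(),
            include_groups=False,
        )
        assert frac[14.5] > 0.3
        assert frac[16.5] < 0.1

    def test_fraction_outside_unit_interval_rejected(self, config):
        curves = dict(config.edu_curves)
        curves["basal"] = dataclasses.replace(
            curves["basal"], values={s: 1.2 for s in curves["basal"].values}
        )
        with pytest.raises(GeneratorConfigError):
            dataclasses.replace(config, edu_curves=curves)


class TestAngleDataset:
    def test_degenerate_mixture_bins_parallel(self, config):
        mix = AngleMixture(weights=(1.0, 0.0, 0.0), means=(0.0, 45.0, 78.0),
                           sds=(1e-6, 10.0, 9.0))
        cfg = dataclasses.replace(config, angle_mixtures={("g", 15.5): mix})
        df = generate_angle_dataset(cfg)
        bp = bin_angles(df["angle_deg"].to_numpy())
        assert bp.counts == (bp.n, 0, 0)

    def test_flat_mixture_gives_equal_thirds(self, config):
        # the E15.5 presets are solved for equal bin masses
        mix = config.angle_mixtures[("control", 15.5)]
        assert np.allclose(mix.bin_masses(), [1 / 3, 1 / 3, 1 / 3], atol=1e-9)

    def test_mutant_perpendicular_mass_matches_analytic(self):
        cfg = dataclasses.replace(
            default_config(seed=17), animals_per_stage=1, angles_per_animal=10_000
        )
        df = generate_angle_dataset(cfg, groups=[("mutant", 16.5)])
        bp = bin_angles(df["angle_deg"].to_numpy())
        target = cfg.angle_mixtures[("mutant", 16.5)].bin_masses()[2]
        assert bp.proportions[2] == pytest.approx(target, abs=0.02)

    def test_preset_perpendicular_targets(self, config):
        assert config.angle_mixtures[("control", 16.5)].bin_masses()[2] == pytest.approx(0.40, abs=1e-9)
        assert config.angle_mixtures[("mutant", 16.5)].bin_masses()[2] == pytest.approx(0.60, abs=1e-9)

    def test_missing_group_names_the_group(self, config):
        with pytest.raises(GeneratorConfigError, match="wt.*E14.5"):
            generate_angle_dataset(config, groups=[("wt", 14.5)])

    def test_determinism(self, config):
        assert generate_angle_dataset(config).equals(generate_angle_dataset(config))


class TestConfigValidation:
    def test_stages_must_increase(self):
        with pytest.raises(GeneratorConfigError):
            GeneratorConfig(stages=(13.5, 12.5))

    def test_empty_stages_rejected(self):
        with pytest.raises(GeneratorConfigError):
            GeneratorConfig(stages=())

    def test_mixture_weights_must_sum_to_one(self, config):
        bad = AngleMixture(weights=(0.5, 0.5, 0.5))
        with pytest.raises(GeneratorConfigError):
            dataclasses.replace(config, angle_mixtures={("g", 1.5): bad})

    def test_negative_density_knot_rejected(self, config):
        bad = {("basal", "sagittal"): DensityCurve(values={12.5: -1.0})}
        with pytest.raises(GeneratorConfigError):
            GeneratorConfig(stages=(12.5,), density_curves=bad)

    def test_tables_regenerable_independently(self, config, tables):
        # the angles substream is independent of whether other tables were drawn
        assert generate_angle_dataset(config).equals(tables["angles"])
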