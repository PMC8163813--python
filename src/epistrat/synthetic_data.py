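"""Synthetic measurement tables emulating embryonic back-skin microscopy data.

Four tables are generated, matching the quantities a sectioning/immunostaining
study measures between E12.5 and E18.5:

* per-embryo body-axis lengths (crown-rump / dorso-ventral), growing linearly;
* per-animal basal and suprabasal cell densities (cells per 100 µm) along both
  axes, with the suprabasal layer absent at E12.5 and reaching density parity
  with the basal layer at E15.5;
* per-animal EdU-positive / total cell counts per layer, with suprabasal
  labeling high during E13.5-E15.5 and collapsing from E16.5;
* per-animal division-orientation angles with genotype- and stage-specific
  truncated-normal mixtures (e.g. ~40% vs ~60% perpendicular at E16.5 for
  control vs mutant).

Default density curves are derived from the two-phase lineage trajectory
divided by the linear-growth area proxy, so the reconstructed cell-number
index reproduces the model's phase folds (≈7.2x over E12.5-E15.5, ≈2x over
E15.5-E18.5) by construction.  A single master seed spawns independent,
stable substreams per table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from .lineage_model import LineageParams, two_phase_trajectory

__all__ = [
    "GeneratorConfigError",
    "AxisGrowth",
    "DensityCurve",
    "EdUCurve",
    "AngleMixture",
    "GeneratorConfig",
    "default_config",
    "generate_growth_table",
    "generate_density_table",
    "generate_edu_table",
    "generate_angle_dataset",
    "generate_all_tables",
]

DEFAULT_STAGES = (12.5, 13.5, 14.5, 15.5, 16.5, 17.5, 18.5)
AXES = ("sagittal", "orthogonal")
LAYERS = ("basal", "suprabasal")

# substream identifiers: stable across runs, so each table can be
# regenerated independently from the master seed
_STREAMS = {"growth": 0, "density": 1, "edu": 2, "angles": 3}

_LENGTH_FLOOR_MM = 0.1


class GeneratorConfigError(ValueError):
    """Raised when a generator configuration violates its invariants."""


@dataclass(frozen=True)
class AxisGrowth:
    """Linear growth law length = intercept + slope * stage (mm, days)."""

    intercept_mm: float
    slope_mm_per_day: float
    noise_sd_mm: float = 0.0

    def expected(self, stage: float) -> float:
        return self.intercept_mm + self.slope_mm_per_day * stage


@dataclass(frozen=True)
class DensityCurve:
    """Per-stage density knots (cells per 100 µm) plus Gaussian noise SD."""

    values: dict[float, float]
    noise_sd: float = 0.0


@dataclass(frozen=True)
class EdUCurve:
    """Per-stage EdU-positive fraction knots."""

    values: dict[float, float]


@dataclass(frozen=True)
class AngleMixture:
    """Three-component truncated-normal mixture on [0, 90] degrees."""

    weights: tuple[float, float, float]
    means: tuple[float, float, float] = (12.0, 45.0, 78.0)
    sds: tuple[float, float, float] = (9.0, 10.0, 9.0)

    def _components(self):
        for w, mu, sd in zip(self.weights, self.means, self.sds):
            a, b = (0.0 - mu) / sd, (90.0 - mu) / sd
            yield w, truncnorm(a, b, loc=mu, scale=sd)

    def bin_masses(self, edges=(0.0, 30.0, 60.0, 90.0)) -> np.ndarray:
        """Analytic probability mass of the mixture in each angle bin."""
        masses = np.zeros(len(edges) - 1)
        for w, tn in self._components():
            cdf = tn.cdf(edges)
            masses += w * np.diff(cdf)
        return masses

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        comps = list(self._components())
        ks = rng.choice(len(comps), size=n, p=[c[0] for c in comps])
        out = np.empty(n)
        for k, (_, tn) in enumerate(comps):
            mask = ks == k
            if mask.any():
                out[mask] = tn.rvs(size=int(mask.sum()), random_state=rng)
        return np.clip(out, 0.0, 90.0)


@dataclass(frozen=True)
class GeneratorConfig:
    seed: int = 0
    stages: tuple[float, ...] = DEFAULT_STAGES
    embryos_per_stage: int = 10
    animals_per_stage: int = 5
    growth: dict[str, AxisGrowth] = field(default_factory=dict)
    density_curves: dict[tuple[str, str], DensityCurve] = field(default_factory=dict)
    edu_curves: dict[str, EdUCurve] = field(default_factory=dict)
    edu_cells_per_animal: int = 100
    angle_mixtures: dict[tuple[str, float], AngleMixture] = field(default_factory=dict)
    angles_per_animal: int = 30

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if len(self.stages) == 0:
            raise GeneratorConfigError("stages must be non-empty")
        if any(b <= a for a, b in zip(self.stages, self.stages[1:])):
            raise GeneratorConfigError("stages must be strictly increasing")
        if self.embryos_per_stage < 1 or self.animals_per_stage < 1:
            raise GeneratorConfigError("replicate counts must be positive")
        if self.edu_cells_per_animal < 1 or self.angles_per_animal < 1:
            raise GeneratorConfigError("per-animal counts must be positive")
        for axis, g in self.growth.items():
            if g.slope_mm_per_day <= 0:
                raise GeneratorConfigError(f"{axis} growth slope must be positive")
            bad = [s for s in self.stages if g.expected(s) <= 0]
            if bad:
                raise GeneratorConfigError(
                    f"{axis} growth law gives non-positive expected length "
                    f"at stages {bad}"
                )
            if g.noise_sd_mm < 0:
                raise GeneratorConfigError("growth noise SD must be non-negative")
        for key, curve in self.density_curves.items():
            for s, v in curve.values.items():
                if v < 0:
                    raise GeneratorConfigError(f"negative density at {key}, E{s}")
            if curve.noise_sd < 0:
                raise GeneratorConfigError("density noise SD must be non-negative")
        for layer, curve in self.edu_curves.items():
            for s, v in curve.values.items():
                if not 0.0 <= v <= 1.0:
                    raise GeneratorConfigError(
                        f"EdU fraction for {layer} at E{s} outside [0, 1]: {v}"
                    )
        for key, mix in self.angle_mixtures.items():
            w = np.asarray(mix.weights, dtype=float)
            if (w < -1e-12).any() or abs(w.sum() - 1.0) > 1e-9:
                raise GeneratorConfigError(
                    f"mixture weights for {key} must be non-negative and sum to 1"
                )
            if any(sd <= 0 for sd in mix.sds):
                raise GeneratorConfigError(f"mixture SDs for {key} must be positive")

    def rng(self, table: str) -> np.random.Generator:
        """Deterministic per-table substream of the master seed."""
        ss = np.random.SeedSequence(self.seed, spawn_key=(_STREAMS[table],))
        return np.random.default_rng(ss)


# ---------------------------------------------------------------------------
# default study conditions


_DEFAULT_GROWTH = {
    # crown-rump 8.5 -> 22.0 mm and dorso-ventral 5.0 -> 12.0 mm over E12.5-E18.5
    "sagittal": AxisGrowth(intercept_mm=8.5 - 2.25 * 12.5, slope_mm_per_day=2.25,
                           noise_sd_mm=0.5),
    "orthogonal": AxisGrowth(intercept_mm=5.0 - (7.0 / 6.0) * 12.5,
                             slope_mm_per_day=7.0 / 6.0, noise_sd_mm=0.3),
}

# suprabasal share of total cells: absent at E12.5, parity from E15.5
_DEFAULT_SUPRABASAL_FRACTION = {
    12.5: 0.0, 13.5: 0.15, 14.5: 0.35, 15.5: 0.5, 16.5: 0.5, 17.5: 0.5, 18.5: 0.5,
}

_DEFAULT_EDU_FRACTIONS = {
    # basal labeling ~50% through the amplification phase, dropping ~40% after;
    # suprabasal labeling high E13.5-E15.5, near zero from E16.5
    "basal": {12.5: 0.5, 13.5: 0.5, 14.5: 0.5, 15.5: 0.45,
              16.5: 0.3, 17.5: 0.3, 18.5: 0.3},
    "suprabasal": {12.5: 0.0, 13.5: 0.45, 14.5: 0.45, 15.5: 0.35,
                   16.5: 0.03, 17.5: 0.02, 18.5: 0.02},
}

# target orientation-bin proportions (parallel, oblique, perpendicular)
_ANGLE_TARGETS = {
    ("control", 15.5): (1 / 3, 1 / 3, 1 / 3),
    ("mutant", 15.5): (1 / 3, 1 / 3, 1 / 3),
    ("control", 16.5): (0.42, 0.18, 0.40),
    ("mutant", 16.5): (0.17, 0.23, 0.60),
    ("control", 17.5): (0.42, 0.18, 0.40),
    ("mutant", 17.5): (0.17, 0.23, 0.60),
}


def _mixture_for_targets(targets: tuple[float, float, float]) -> AngleMixture:
    """Solve component weights so analytic bin masses equal the targets."""
    probe = AngleMixture(weights=(1.0, 0.0, 0.0))
    cols = []
    for k in range(3):
        w = [0.0, 0.0, 0.0]
        w[k] = 1.0
        cols.append(replace(probe, weights=tuple(w)).bin_masses())
    M = np.column_stack(cols)
    w = np.linalg.solve(M, np.asarray(targets, dtype=float))
    w = np.clip(w, 0.0, None)
    w /= w.sum()
    return AngleMixture(weights=tuple(float(x) for x in w))


def _default_density_curves(
    params: LineageParams,
    stages: tuple[float, ...],
    growth: dict[str, AxisGrowth],
    suprabasal_fraction: dict[float, float],
    basal_density_start: float = 12.0,
    noise_sd: float = 0.8,
) -> dict[tuple[str, str], DensityCurve]:
    """Density knots consistent with the two-phase trajectory.

    The layer's cell-number curve n_layer(t) (two-phase model x suprabasal
    share) is spread over the area proxy a(t) = l_s(t) * l_o(t); assigning
    each axis the square root keeps the reconstructed index proportional to
    n_layer(t), so downstream phase folds match the model exactly in the
    noise-free limit.
    """
    traj = two_phase_trajectory(params, n0=1.0, time_grid=np.asarray(stages))
    total = traj["total"].to_numpy()
    area = np.array(
        [growth["sagittal"].expected(s) * growth["orthogonal"].expected(s)
         for s in stages]
    )
    scale = basal_density_start / math.sqrt(
        (1.0 - suprabasal_fraction[stages[0]]) * total[0] / area[0]
    )
    curves: dict[tuple[str, str], DensityCurve] = {}
    for layer in LAYERS:
        knots = {}
        for i, s in enumerate(stages):
            frac = suprabasal_fraction[s]
            share = frac if layer == "suprabasal" else 1.0 - frac
            knots[s] = scale * math.sqrt(share * total[i] / area[i])
        for axis in AXES:
            curves[(layer, axis)] = DensityCurve(values=dict(knots), noise_sd=noise_sd)
    return curves


def default_config(
    seed: int = 0, params: LineageParams = LineageParams()
) -> GeneratorConfig:
    """The default study conditions, calibrated to the two-phase model."""
    stages = DEFAULT_STAGES
    return GeneratorConfig(
        seed=seed,
        stages=stages,
        growth=dict(_DEFAULT_GROWTH),
        density_curves=_default_density_curves(
            params, stages, _DEFAULT_GROWTH, _DEFAULT_SUPRABASAL_FRACTION
        ),
        edu_curves={k: EdUCurve(values=dict(v)) for k, v in _DEFAULT_EDU_FRACTIONS.items()},
        angle_mixtures={k: _mixture_for_targets(t) for k, t in _ANGLE_TARGETS.items()},
    )


# ---------------------------------------------------------------------------
# generators


def generate_growth_table(config: GeneratorConfig) -> pd.DataFrame:
    """Per-embryo axis lengths: linear trend plus truncated Gaussian noise."""
    if not config.growth:
        raise GeneratorConfigError("no growth laws configured")
    rng = config.rng("growth")
    rows = []
    for stage in config.stages:
        for i in range(config.embryos_per_stage):
            embryo = f"E{stage}_emb{i + 1}"
            for axis in AXES:
                g = config.growth[axis]
                length = g.expected(stage) + rng.normal(0.0, g.noise_sd_mm)
                rows.append((embryo, stage, axis, max(length, _LENGTH_FLOOR_MM)))
    df = pd.DataFrame(rows, columns=["embryo_id", "stage", "axis", "length_mm"])
    assert (df["length_mm"] > 0).all()
    assert not df.duplicated(["embryo_id", "stage", "axis"]).any()
    return df


def generate_density_table(config: GeneratorConfig) -> pd.DataFrame:
    """Per-animal layer densities around the configured stage curves.

    Noise is suppressed where a knot is exactly zero (a layer that does not
    exist yet has no cells to miscount).
    """
    if not config.density_curves:
        raise GeneratorConfigError("no density curves configured")
    rng = config.rng("density")
    rows = []
    for stage in config.stages:
        for i in range(config.animals_per_stage):
            animal = f"E{stage}_an{i + 1}"
            for layer in LAYERS:
                for axis in AXES:
                    curve = config.density_curves[(layer, axis)]
                    if stage not in curve.values:
                        raise GeneratorConfigError(
                            f"density curve {(layer, axis)} missing stage {stage}"
                        )
                    mu = curve.values[stage]
                    val = 0.0 if mu == 0.0 else max(
                        0.0, mu + rng.normal(0.0, curve.noise_sd)
                    )
                    rows.append((animal, stage, layer, axis, val))
    df = pd.DataFrame(
        rows, columns=["animal_id", "stage", "layer", "axis", "density_per_100um"]
    )
    assert (df["density_per_100um"] >= 0).all()
    return df


def generate_edu_table(config: GeneratorConfig) -> pd.DataFrame:
    """Per-animal binomial EdU counts at the configured stage/layer fractions."""
    if not config.edu_curves:
        raise GeneratorConfigError("no EdU curves configured")
    rng = config.rng("edu")
    n_total = config.edu_cells_per_animal
    rows = []
    for stage in config.stages:
        for i in range(config.animals_per_stage):
            animal = f"E{stage}_an{i + 1}"
            for layer in LAYERS:
                curve = config.edu_curves[layer]
                if stage not in curve.values:
                    raise GeneratorConfigError(
                        f"EdU curve for {layer} missing stage {stage}"
                    )
                n_pos = int(rng.binomial(n_total, curve.values[stage]))
                rows.append((animal, stage, layer, n_pos, n_total))
    df = pd.DataFrame(
        rows, columns=["animal_id", "stage", "layer", "n_positive", "n_total"]
    )
    assert (df["n_positive"] <= df["n_total"]).all()
    return df


def generate_angle_dataset(
    config: GeneratorConfig,
    groups: list[tuple[str, float]] | None = None,
) -> pd.DataFrame:
    """Per-animal division-orientation angles from the configured mixtures."""
    if not config.angle_mixtures:
        raise GeneratorConfigError("no angle mixtures configured")
    rng = config.rng("angles")
    if groups is None:
        groups = sorted(config.angle_mixtures)
    rows = []
    for genotype, stage in groups:
        if (genotype, stage) not in config.angle_mixtures:
            raise GeneratorConfigError(
                f"no angle mixture configured for group ({genotype!r}, E{stage})"
            )
        mix = config.angle_mixtures[(genotype, stage)]
        for i in range(config.animals_per_stage):
            animal = f"{genotype}_E{stage}_an{i + 1}"
            angles = mix.sample(config.angles_per_animal, rng)
            for a in angles:
                rows.append((animal, genotype, stage, float(a)))
    df = pd.DataFrame(rows, columns=["animal_id", "genotype", "stage", "angle_deg"])
    assert df["angle_deg"].between(0.0, 90.0).all()
    return df


def generate_all_tables(config: GeneratorConfig) -> dict[str, pd.DataFrame]:
    """All four measurement tables from their independent substreams."""
    return {
        "growth": generate_growth_table(config),
        "density": generate_density_table(config),
        "edu": generate_edu_table(config),
        "angles": generate_angle_dataset(config),
    }
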