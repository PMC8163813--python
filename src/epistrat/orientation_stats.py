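"""Division-orientation angle binning and group comparisons.

Angles are measured between the division axis of a late-anaphase/telophase
basal cell and the basement membrane, folded into [0, 90] degrees upstream.
They are categorised as parallel (0-29°), oblique (30-59°) or perpendicular
(60-90°); for continuous angles the bins are realised as the half-open
partition [0, 30), [30, 60), [60, 90].

Group comparisons follow standard practice for such data: Pearson chi-squared
on the 2x3 bin table, the two-sample Kolmogorov-Smirnov test on raw angles,
a two-way ANOVA (genotype x bin, per-animal proportions, interaction term)
and plain two-sample t-tests for scalar summaries.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
import statsmodels.formula.api as smf

__all__ = [
    "BIN_NAMES",
    "BinProportions",
    "TestResult",
    "bin_angles",
    "radial_histogram",
    "chi_squared_bins",
    "ks_two_sample",
    "proportions_anova",
    "compare_group_means",
]

BIN_NAMES = ("parallel", "oblique", "perpendicular")
_BIN_EDGES = (0.0, 30.0, 60.0, 90.0)


@dataclass(frozen=True)
class BinProportions:
    """Counts and proportions of angles in the three orientation bins."""

    group: str
    counts: tuple[int, int, int]
    proportions: tuple[float, float, float]

    @property
    def n(self) -> int:
        return sum(self.counts)


@dataclass(frozen=True)
class TestResult:
    name: str
    statistic: float
    p_value: float
    df: float | None = None
    sample_sizes: tuple[int, ...] = ()
    warnings: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not (np.isnan(self.p_value) or 0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p_value outside [0, 1]: {self.p_value}")


def _check_angles(angles: np.ndarray) -> np.ndarray:
    angles = np.asarray(angles, dtype=float)
    bad = np.where((angles < 0) | (angles > 90) | ~np.isfinite(angles))[0]
    if bad.size:
        raise ValueError(
            f"angles outside [0, 90] degrees at positions {bad[:10].tolist()}: "
            f"{angles[bad[:10]].tolist()}"
        )
    return angles


def bin_angles(angles, group: str = "") -> BinProportions:
    """Assign angles to parallel [0, 30) / oblique [30, 60) / perpendicular [60, 90]."""
    angles = _check_angles(angles)
    counts, _ = np.histogram(angles, bins=_BIN_EDGES)  # last bin closed at 90
    total = int(counts.sum())
    props = tuple(c / total for c in counts) if total else (0.0, 0.0, 0.0)
    return BinProportions(group=group, counts=tuple(int(c) for c in counts), proportions=props)


def radial_histogram(angles, bin_width_deg: float = 10.0) -> pd.DataFrame:
    """Histogram counts over [0, 90] for radial plotting; last bin closed."""
    if bin_width_deg <= 0 or abs(90.0 / bin_width_deg - round(90.0 / bin_width_deg)) > 1e-9:
        raise ValueError(f"bin width {bin_width_deg} must divide 90 exactly")
    angles = _check_angles(angles)
    edges = np.linspace(0.0, 90.0, int(round(90.0 / bin_width_deg)) + 1)
    counts, _ = np.histogram(angles, bins=edges)
    return pd.DataFrame(
        {"bin_start": edges[:-1], "bin_end": edges[1:], "count": counts.astype(int)}
    )


def chi_squared_bins(counts_a, counts_b) -> TestResult:
    """Pearson chi-squared test on the 2x3 genotype-by-bin contingency table.

    Bins empty in both groups are dropped (with a warning and reduced df);
    expected counts below 5 set a warning flag but do not alter the test.
    """
    a = np.asarray(counts_a, dtype=int)
    b = np.asarray(counts_b, dtype=int)
    if a.shape != (3,) or b.shape != (3,):
        raise ValueError("each group must supply exactly three bin counts")
    if a.sum() == 0 or b.sum() == 0:
        raise ValueError("each group must have a positive total count")
    table = np.vstack([a, b])
    notes = []
    keep = table.sum(axis=0) > 0
    if not keep.all():
        dropped = [BIN_NAMES[i] for i in np.where(~keep)[0]]
        notes.append(f"empty bins dropped: {dropped}; df reduced")
        warnings.warn(notes[-1], stacklevel=2)
        table = table[:, keep]
    stat, p, df, expected = stats.chi2_contingency(table, correction=False)
    if (expected < 5).any():
        notes.append("expected counts < 5: chi-squared approximation unreliable")
    return TestResult(
        name="chi_squared",
        statistic=float(stat),
        p_value=float(p),
        df=float(df),
        sample_sizes=(int(a.sum()), int(b.sum())),
        warnings=tuple(notes),
    )


def ks_two_sample(angles_a, angles_b) -> TestResult:
    """Two-sample Kolmogorov-Smirnov test on raw angle distributions."""
    a = _check_angles(angles_a)
    b = _check_angles(angles_b)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    res = stats.ks_2samp(a, b, method="asymp")
    return TestResult(
        name="kolmogorov_smirnov",
        statistic=float(res.statistic),
        p_value=float(min(1.0, res.pvalue)),
        sample_sizes=(a.size, b.size),
    )


def proportions_anova(per_animal: list[tuple[str, str, BinProportions]]) -> TestResult:
    """Two-way ANOVA on per-animal bin proportions: genotype x bin interaction.

    Each record is (genotype, animal_id, BinProportions).  Because proportions
    sum to one within an animal, the genotype main effect is structurally null;
    a genotype-dependent shift of the orientation distribution appears as the
    genotype x bin interaction, whose p-value is reported.

    Because each animal's three proportions sum to one exactly, an animal
    contributes only two independent residual dimensions; the residual degrees
    of freedom are corrected accordingly (2 x Σ_genotype (n_animals - 1))
    before the F test — the naive OLS count would understate the residual
    mean square by a third and inflate the type-I error rate by half.

    Degenerate zero-residual designs (identical animals within genotype) are
    resolved by limits: interaction SS > 0 gives p -> 0, otherwise p = 1.
    """
    genotypes: dict[str, int] = {}
    for g, _, _ in per_animal:
        genotypes[g] = genotypes.get(g, 0) + 1
    if len(genotypes) < 2:
        raise ValueError("need at least two genotypes")
    single = [g for g, n in genotypes.items() if n < 2]
    if single:
        raise ValueError(f"genotypes with fewer than two animals: {single}")
    rows = []
    for genotype, animal, bp in per_animal:
        for name, prop in zip(BIN_NAMES, bp.proportions):
            rows.append((genotype, animal, name, prop))
    df = pd.DataFrame(rows, columns=["genotype", "animal", "bin", "proportion"])
    model = smf.ols("proportion ~ C(genotype) * C(bin)", data=df).fit()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # zero-residual designs emit RuntimeWarnings
        table = sm.stats.anova_lm(model, typ=2)
    inter = table.loc["C(genotype):C(bin)"]
    ss_inter = float(inter["sum_sq"])
    df_inter = float(inter["df"])
    ss_resid = float(table.loc["Residual"]["sum_sq"])
    # sum-to-one constraint: only (n_bins - 1) free residual dims per animal
    df_resid = (len(BIN_NAMES) - 1) * sum(n - 1 for n in genotypes.values())
    notes: tuple[str, ...] = ()
    if ss_resid < 1e-12:
        # zero within-group variance: exact separation or exact equality
        p = 0.0 if ss_inter > 1e-12 else 1.0
        f_stat = np.inf if ss_inter > 1e-12 else 0.0
        notes = ("zero residual variance: p-value taken as the degenerate limit",)
    else:
        f_stat = (ss_inter / df_inter) / (ss_resid / df_resid)
        p = float(stats.f.sf(f_stat, df_inter, df_resid))
    return TestResult(
        name="two_way_anova_interaction",
        statistic=float(f_stat),
        p_value=p,
        df=df_inter,
        sample_sizes=tuple(genotypes.values()),
        warnings=notes,
    )


def compare_group_means(group_a, group_b) -> TestResult:
    """Two-tailed two-sample t-test (pooled variance)."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least two values")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # near-constant data
        res = stats.ttest_ind(a, b, equal_var=True)
    stat, p = float(res.statistic), float(res.pvalue)
    if np.isnan(stat):
        # both groups constant: equal means -> no evidence of difference
        if np.isclose(a.mean(), b.mean()):
            stat, p = 0.0, 1.0
        else:
            stat, p = np.inf, 0.0
    return TestResult(
        name="t_test",
        statistic=stat,
        p_value=p,
        df=float(a.size + b.size - 2),
        sample_sizes=(a.size, b.size),
    )
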