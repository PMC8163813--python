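"""Tissue-scale reconstruction of relative epidermal cell numbers.

Absolute cell counts are not measurable from sections, but the product of
per-length cell density and body-axis length along two orthogonal axes is
proportional to the layer's total cell number:

    n(t) ∝ ρ_sagittal(t)·l_sagittal(t) × ρ_orthogonal(t)·l_orthogonal(t)

Only ratios of this index across stages are meaningful.  Phase behaviour
(exponential amplification vs linear-trend maintenance growth) is classified
by comparing a log-linear and a linear fit of the index against stage.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "cell_number_index",
    "build_cell_number_series",
    "summarize_phase",
    "PhaseSummary",
]

AXES = ("sagittal", "orthogonal")
LAYERS = ("basal", "suprabasal")


def cell_number_index(
    density_sagittal: float,
    density_orthogonal: float,
    length_sagittal: float,
    length_orthogonal: float,
) -> float:
    """Relative cell-number index: ρ_s·l_s × ρ_o·l_o (arbitrary units)."""
    args = (density_sagittal, density_orthogonal, length_sagittal, length_orthogonal)
    if any(a < 0 for a in args):
        raise ValueError("densities and lengths must be non-negative")
    return (
        density_sagittal * length_sagittal * density_orthogonal * length_orthogonal
    )


def _group_mean_se(values: np.ndarray) -> tuple[float, float]:
    values = np.asarray(values, dtype=float)
    mean = float(values.mean())
    if values.size < 2:
        return mean, 0.0
    return mean, float(values.std(ddof=1) / math.sqrt(values.size))


def build_cell_number_series(
    densities: pd.DataFrame, growth: pd.DataFrame
) -> pd.DataFrame:
    """Per-stage relative cell-number index for each layer, plus a total row.

    Stage means of axis lengths and per-layer densities are combined through
    the index; the standard error is propagated to first order (delta method)
    treating the four group means as independent:

        Var(I) ≈ Σ_x (∂I/∂x)² SE_x²

    Returns a frame with columns ``stage, layer, index, index_se`` where
    ``layer`` includes ``basal``, ``suprabasal`` and ``total`` (the exact sum
    of the two layer indices, SE combined in quadrature).
    """
    d_stages = set(densities["stage"].unique())
    g_stages = set(growth["stage"].unique())
    if d_stages != g_stages:
        missing = sorted(d_stages.symmetric_difference(g_stages))
        raise ValueError(
            f"density and growth tables must cover the same stages; "
            f"unmatched stages: {missing}"
        )
    rows = []
    for stage in sorted(d_stages):
        lens, len_ses = {}, {}
        for axis in AXES:
            sub = growth[(growth["stage"] == stage) & (growth["axis"] == axis)]
            if sub.empty:
                raise ValueError(f"no {axis} lengths at stage {stage}")
            lens[axis], len_ses[axis] = _group_mean_se(sub["length_mm"].to_numpy())
        layer_idx = {}
        for layer in LAYERS:
            rho, rho_se = {}, {}
            for axis in AXES:
                sub = densities[
                    (densities["stage"] == stage)
                    & (densities["layer"] == layer)
                    & (densities["axis"] == axis)
                ]
                if sub.empty:
                    raise ValueError(f"no {layer}/{axis} densities at stage {stage}")
                rho[axis], rho_se[axis] = _group_mean_se(
                    sub["density_per_100um"].to_numpy()
                )
            idx = cell_number_index(
                rho["sagittal"], rho["orthogonal"], lens["sagittal"], lens["orthogonal"]
            )
            # delta method on the product of four independent means
            terms = [
                (rho["orthogonal"] * lens["sagittal"] * lens["orthogonal"])
                * rho_se["sagittal"],
                (rho["sagittal"] * lens["sagittal"] * lens["orthogonal"])
                * rho_se["orthogonal"],
                (rho["sagittal"] * rho["orthogonal"] * lens["orthogonal"])
                * len_ses["sagittal"],
                (rho["sagittal"] * rho["orthogonal"] * lens["sagittal"])
                * len_ses["orthogonal"],
            ]
            se = math.sqrt(sum(t * t for t in terms))
            layer_idx[layer] = (idx, se)
            rows.append((stage, layer, idx, se))
        total = sum(v[0] for v in layer_idx.values())
        total_se = math.sqrt(sum(v[1] ** 2 for v in layer_idx.values()))
        rows.append((stage, "total", total, total_se))
    return pd.DataFrame(rows, columns=["stage", "layer", "index", "index_se"])


@dataclass(frozen=True)
class PhaseSummary:
    """Fold change and trend classification of one growth phase."""

    phase_start: float
    phase_end: float
    layer: str
    fold_change: float
    trend: str  # "exponential" | "linear"
    trend_score: float  # AIC(linear) - AIC(exponential); > 0 favours exponential


_SIGMA2_FLOOR = 1e-300  # guards log-likelihood of exact fits


def _gaussian_aic(resid: np.ndarray, k_params: int) -> float:
    n = resid.size
    sigma2 = max(float(np.mean(resid**2)), _SIGMA2_FLOOR)
    loglik = -0.5 * n * (math.log(2 * math.pi * sigma2) + 1.0)
    return 2 * k_params - 2 * loglik


def summarize_phase(
    series: pd.DataFrame,
    layer: str = "total",
    phase_start: float = 12.5,
    phase_end: float = 15.5,
) -> PhaseSummary:
    """Fold change across a phase and exponential-vs-linear trend call.

    The fold is index(phase_end)/index(phase_start).  Trend is chosen by AIC:
    a Gaussian linear model index ~ stage versus a log-normal model
    log(index) ~ stage (AIC corrected by the Jacobian term 2·Σ log index so
    the two likelihoods are on the same scale).  Ties break to linear.
    """
    sub = series[
        (series["layer"] == layer)
        & (series["stage"] >= phase_start - 1e-9)
        & (series["stage"] <= phase_end + 1e-9)
    ].sort_values("stage")
    if len(sub) < 3:
        raise ValueError(
            f"need >= 3 stages in [{phase_start}, {phase_end}], got {len(sub)}"
        )
    stages = sub["stage"].to_numpy(dtype=float)
    idx = sub["index"].to_numpy(dtype=float)
    for bound, name in ((phase_start, "phase_start"), (phase_end, "phase_end")):
        if not np.any(np.isclose(stages, bound)):
            raise ValueError(f"{name} {bound} has no row in the series")
    i0 = idx[np.isclose(stages, phase_start)][0]
    i1 = idx[np.isclose(stages, phase_end)][0]
    if i0 <= 0:
        raise ValueError("index at phase_start must be positive")
    fold = i1 / i0

    X = sm.add_constant(stages)
    lin = sm.OLS(idx, X).fit()
    aic_lin = _gaussian_aic(lin.resid, k_params=3)
    if np.any(idx <= 0):
        trend, score = "linear", -math.inf
    else:
        logfit = sm.OLS(np.log(idx), X).fit()
        # Jacobian of y -> log y puts the log-normal AIC on the y scale
        aic_exp = _gaussian_aic(logfit.resid, k_params=3) + 2.0 * float(
            np.sum(np.log(idx))
        )
        score = aic_lin - aic_exp
        trend = "exponential" if score > 0 else "linear"
    return PhaseSummary(
        phase_start=phase_start,
        phase_end=phase_end,
        layer=layer,
        fold_change=fold,
        trend=trend,
        trend_score=score if math.isfinite(score) else math.copysign(1e12, score),
    )
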