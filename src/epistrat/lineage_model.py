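"""Two-phase lineage kinetics of the embryonic epidermis.

Phase 1 (E12.5-E15.5): a single equipotent progenitor pool ``p`` duplicates
at a constant per-cell rate λ (``p -> p + p``), giving exponential growth.

Phase 2 (E15.5-E18.5): basal progenitors ``b`` fire at rate λ and either
duplicate (probability 1-r) or convert into a post-mitotic suprabasal cell
``s`` (probability r), so that

    db/dt = λ(1-2r) b,    ds/dt = λ r b.

Proportionate expansion of the two layers (db/dt = ds/dt) pins r = 1/3, in
which case b(t) = s(t) whenever the phase starts at parity.

Both phases are available as closed-form mean solutions and as exact
(Gillespie) stochastic simulations of the underlying Markov jump process.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "LineageParams",
    "phase1_closed_form",
    "simulate_phase1",
    "phase2_closed_form",
    "simulate_phase2",
    "two_phase_trajectory",
]


@dataclass(frozen=True)
class LineageParams:
    """Kinetic parameters of the two-phase model.

    Parameters
    ----------
    lambda_phase1 : float
        Per-cell division rate during the amplification phase (per day).
    lambda_phase2 : float
        Per-cell event rate during the maintenance phase (per day).
    r : float
        Per-event probability that a basal cell stratifies instead of
        duplicating. ``r = 1/3`` yields proportionate basal/suprabasal growth.
    t_start, t_switch, t_end : float
        Phase boundaries in absolute embryonic days.
    basal_fraction_at_switch : float
        Fraction of the phase-1 progenitor pool assigned to the basal
        compartment when phase 2 begins (default 1/2: density parity).
    """

    lambda_phase1: float = 0.66
    lambda_phase2: float = 0.7
    r: float = 1.0 / 3.0
    t_start: float = 12.5
    t_switch: float = 15.5
    t_end: float = 18.5
    basal_fraction_at_switch: float = 0.5

    def __post_init__(self) -> None:
        if self.lambda_phase1 <= 0 or self.lambda_phase2 <= 0:
            raise ValueError("division rates must be positive")
        if not 0.0 <= self.r <= 1.0:
            raise ValueError(f"r must lie in [0, 1], got {self.r}")
        if not self.t_start < self.t_switch < self.t_end:
            raise ValueError("phase boundaries must satisfy t_start < t_switch < t_end")
        if not 0.0 <= self.basal_fraction_at_switch <= 1.0:
            raise ValueError("basal_fraction_at_switch must lie in [0, 1]")


def phase1_closed_form(n0: float, lam: float, dt: float) -> float:
    """Expected progenitor count after ``dt`` days of pure duplication.

    Returns ``n0 * exp(lam * dt)``, the mean of the Yule process started
    from ``n0`` cells.
    """
    if n0 <= 0:
        raise ValueError("n0 must be positive")
    if lam < 0:
        raise ValueError("lam must be non-negative")
    if dt < 0:
        raise ValueError("dt must be non-negative")
    return n0 * math.exp(lam * dt)


def phase2_closed_form(
    b0: float, s0: float, lam: float, r: float, dt: float
) -> tuple[float, float]:
    """Mean basal and suprabasal counts under the duplication/stratification rules.

    ``b(dt) = b0 exp(λ(1-2r) dt)``; the suprabasal compartment integrates the
    stratification flux λ r b.  At ``r = 1/2`` the basal exponent vanishes and
    the continuity limit ``s = s0 + λ r b0 dt`` applies.
    """
    if b0 <= 0:
        raise ValueError("b0 must be positive")
    if s0 < 0:
        raise ValueError("s0 must be non-negative")
    if not 0.0 <= r <= 1.0:
        raise ValueError(f"r must lie in [0, 1], got {r}")
    if lam < 0 or dt < 0:
        raise ValueError("lam and dt must be non-negative")
    g = lam * (1.0 - 2.0 * r)
    b = b0 * math.exp(g * dt)
    if abs(1.0 - 2.0 * r) < 1e-12:
        s = s0 + lam * r * b0 * dt
    else:
        s = s0 + (r / (1.0 - 2.0 * r)) * b0 * (math.exp(g * dt) - 1.0)
    return b, s


def _sample_grid(dt: float, grid_dt: float) -> np.ndarray:
    n = int(round(dt / grid_dt))
    grid = np.linspace(0.0, n * grid_dt, n + 1)
    if grid[-1] < dt - 1e-12:
        grid = np.append(grid, dt)
    else:
        grid[-1] = dt
    return grid


def simulate_phase1(
    n0: int,
    lam: float,
    dt: float,
    n_replicates: int = 1,
    seed: int | np.random.SeedSequence | None = None,
    grid_dt: float = 0.1,
) -> pd.DataFrame:
    """Exact stochastic simulation of the pure-duplication (Yule) process.

    The waiting time from ``k`` to ``k+1`` cells is Exponential(λk), so a
    replicate's full event-time sequence is the cumulative sum of independent
    exponentials — simulated here vectorised, with chunked extension until the
    horizon ``dt`` is passed.

    Returns a tidy frame with columns ``replicate, time, b, s, total`` sampled
    on a fixed grid; ``s`` is identically 0 (no suprabasal compartment in
    phase 1).  ``n0 = 0`` yields a frozen all-zero trajectory.
    """
    if n0 < 0 or n_replicates < 1 or dt < 0:
        raise ValueError("n0, dt must be non-negative and n_replicates >= 1")
    rng = np.random.default_rng(seed)
    grid = _sample_grid(dt, grid_dt)
    frames = []
    for rep in range(n_replicates):
        if n0 == 0 or lam == 0.0:
            counts = np.full(grid.size, n0, dtype=np.int64)
        else:
            event_times = np.empty(0)
            k = n0
            t_last = 0.0
            while t_last < dt:
                chunk = max(256, int(0.5 * k))
                rates = lam * np.arange(k, k + chunk)
                waits = rng.exponential(1.0, size=chunk) / rates
                new_times = t_last + np.cumsum(waits)
                event_times = np.concatenate([event_times, new_times])
                k += chunk
                t_last = new_times[-1]
            counts = n0 + np.searchsorted(event_times, grid, side="right")
        frames.append(
            pd.DataFrame(
                {
                    "replicate": rep,
                    "time": grid,
                    "b": counts,
                    "s": 0,
                    "total": counts,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def simulate_phase2(
    b0: int,
    s0: int,
    lam: float,
    r: float,
    dt: float,
    n_replicates: int = 1,
    seed: int | np.random.SeedSequence | None = None,
    grid_dt: float = 0.1,
) -> pd.DataFrame:
    """Exact Gillespie simulation of the duplication/stratification process.

    Events fire at total rate λb; each is a duplication (b -> b+1) with
    probability 1-r, otherwise a direct conversion (b -> b-1, s -> s+1).
    A replicate whose basal pool hits zero is absorbed (frozen thereafter).
    """
    if b0 < 1:
        raise ValueError("b0 must be >= 1")
    if s0 < 0:
        raise ValueError("s0 must be non-negative")
    if not 0.0 <= r <= 1.0:
        raise ValueError(f"r must lie in [0, 1], got {r}")
    rng = np.random.default_rng(seed)
    grid = _sample_grid(dt, grid_dt)
    frames = []
    # pre-drawn randomness in chunks: per-event unit exponential + fate uniform
    chunk = 4096
    for rep in range(n_replicates):
        b, s = b0, s0
        t = 0.0
        gi = 0
        bs_on_grid = np.empty((grid.size, 2), dtype=np.int64)
        exps = rng.exponential(1.0, size=chunk)
        fates = rng.random(size=chunk)
        ei = 0
        while True:
            if b == 0 or lam == 0.0:
                t_next = math.inf
            else:
                if ei == chunk:
                    exps = rng.exponential(1.0, size=chunk)
                    fates = rng.random(size=chunk)
                    ei = 0
                t_next = t + exps[ei] / (lam * b)
            while gi < grid.size and grid[gi] <= t_next:
                bs_on_grid[gi] = (b, s)
                gi += 1
            if gi == grid.size:
                break
            if fates[ei] < r:
                b -= 1
                s += 1
            else:
                b += 1
            ei += 1
            t = t_next
        frames.append(
            pd.DataFrame(
                {
                    "replicate": rep,
                    "time": grid,
                    "b": bs_on_grid[:, 0],
                    "s": bs_on_grid[:, 1],
                    "total": bs_on_grid.sum(axis=1),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def two_phase_trajectory(
    params: LineageParams = LineageParams(),
    n0: float = 1.0,
    time_grid: np.ndarray | None = None,
    grid_dt: float = 0.1,
) -> pd.DataFrame:
    """Deterministic mean trajectory of the full two-phase model.

    Up to ``t_switch`` all cells are undifferentiated progenitors (reported in
    the ``b`` column, ``s = 0``).  At the switch the pool is split
    ``basal_fraction_at_switch : 1 - basal_fraction_at_switch`` between the
    basal and suprabasal compartments and evolved by the phase-2 closed form;
    the total count is continuous at the switch.

    Returns a frame with columns ``time, b, s, total``.
    """
    p = params
    if time_grid is None:
        time_grid = _sample_grid(p.t_end - p.t_start, grid_dt) + p.t_start
    time_grid = np.asarray(time_grid, dtype=float)
    if time_grid.min() < p.t_start - 1e-9 or time_grid.max() > p.t_end + 1e-9:
        raise ValueError("time_grid must lie within [t_start, t_end]")
    n_switch = phase1_closed_form(n0, p.lambda_phase1, p.t_switch - p.t_start)
    b_sw = p.basal_fraction_at_switch * n_switch
    s_sw = n_switch - b_sw
    rows = []
    for t in time_grid:
        if t < p.t_switch:
            n = phase1_closed_form(n0, p.lambda_phase1, t - p.t_start)
            rows.append((t, n, 0.0, n))
        else:
            b, s = phase2_closed_form(b_sw, s_sw, p.lambda_phase2, p.r, t - p.t_switch)
            rows.append((t, b, s, b + s))
    return pd.DataFrame(rows, columns=["time", "b", "s", "total"])
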