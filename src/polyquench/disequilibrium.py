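"""Disequilibrium distances R_L and R_T and the formation-temperature scan.

An observed length distribution is compared against the two equilibrium
predictions of :mod:`polyquench.equilibrium` through Euclidean distances in
occupancy space,

    R = sqrt( Σ_L (n_L − n̄_L)² / (2 ρ v_p) ),

with n̄_L the bath prediction (R_T, a function of the assumed bath
temperature) or the isolated prediction (R_L, temperature-independent).
Scanning R_T over assumed βΔ and locating its dip identifies the apparent
formation temperature of the distribution: data frozen in by a quench from a
hot bath show their minimum at the *hot* βΔ, not at the ambient one, and at
the dip R_T is essentially equal to R_L.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .equilibrium import (
    EnsembleConfig,
    EquilibriumSolution,
    ObservedState,
    solve_bath_equilibrium,
    solve_isolated_equilibrium,
)
from .errors import FeasibilityError, PolyquenchError, SolverError

logger = logging.getLogger(__name__)

__all__ = ["RTCurve", "distance_to_bath", "distance_to_isolated", "rt_scan"]


@dataclass
class RTCurve:
    """Result of an R_T scan over assumed bath βΔ values.

    ``rt_values`` holds NaN at grid points excluded as infeasible (listed in
    ``excluded``).  ``argmin`` is the feasible grid point with the smallest
    R_T; ties break toward smaller |βΔ| (the hotter interpretation).
    """

    grid: np.ndarray
    rt_values: np.ndarray
    rl_value: float
    argmin: float
    rt_min: float
    isolated: EquilibriumSolution | None = None
    excluded: list[tuple[float, str]] = field(default_factory=list)


def _euclidean(obs: np.ndarray, pred: np.ndarray, rho_vp: float) -> float:
    n = max(obs.size, pred.size)
    o = np.zeros(n)
    p = np.zeros(n)
    o[: obs.size] = obs
    p[: pred.size] = pred
    return float(np.sqrt(np.sum((o - p) ** 2) / (2.0 * rho_vp)))


def distance_to_bath(
    observed: ObservedState, beta_delta: float, config: EnsembleConfig
) -> float:
    """R_T: distance from the bath equilibrium at assumed βΔ and observed ρv_p."""
    lmax = max(config.lmax, observed.lmax)
    cfg = EnsembleConfig(
        b=config.b, lmax=lmax, nu=config.nu, dilution=config.dilution, delta=config.delta
    )
    sol = solve_bath_equilibrium(beta_delta, observed.rho_vp, cfg)
    return _euclidean(observed.occupancies, sol.occupancies, observed.rho_vp)


def distance_to_isolated(
    observed: ObservedState, config: EnsembleConfig
) -> tuple[float, EquilibriumSolution]:
    """R_L: distance from the self-equilibrated state fixed by the observed moments."""
    sol = solve_isolated_equilibrium(observed, config)
    rl = _euclidean(observed.occupancies, sol.occupancies, observed.rho_vp)
    return rl, sol


def rt_scan(
    observed: ObservedState, grid: np.ndarray, config: EnsembleConfig
) -> RTCurve:
    """Scan R_T over a grid of assumed βΔ and locate the dip.

    Infeasible grid points (nonnegative βΔ, or failed bath solves) are flagged
    and excluded rather than aborting the scan.
    """
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise FeasibilityError("scan grid is empty")
    rt = np.full(grid.size, np.nan)
    excluded: list[tuple[float, str]] = []
    for i, bd in enumerate(grid):
        if bd >= 0:
            excluded.append((float(bd), "beta_delta must be negative"))
            continue
        try:
            rt[i] = distance_to_bath(observed, float(bd), config)
        except (FeasibilityError, SolverError) as exc:
            excluded.append((float(bd), str(exc)))
            logger.warning("grid point beta_delta=%g excluded: %s", bd, exc)
    if np.all(np.isnan(rt)):
        raise FeasibilityError("every grid point was infeasible")

    finite = np.where(np.isfinite(rt))[0]
    best = finite[0]
    for i in finite[1:]:
        if rt[i] < rt[best] or (rt[i] == rt[best] and abs(grid[i]) < abs(grid[best])):
            best = i

    try:
        rl, iso = distance_to_isolated(observed, config)
    except PolyquenchError as exc:
        logger.warning("isolated solve failed during scan: %s", exc)
        rl, iso = np.nan, None
    return RTCurve(
        grid=grid,
        rt_values=rt,
        rl_value=float(rl),
        argmin=float(grid[best]),
        rt_min=float(rt[best]),
        isolated=iso,
        excluded=excluded,
    )
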