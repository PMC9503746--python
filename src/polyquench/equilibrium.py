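"""Entropy-maximizing polymer length distributions.

A dilute solution of linear polymers built from ``b`` monomer species is coarse
grained down to its length histogram ``{N_L}``.  Every bond carries the same
energy ``-Δ`` (Δ < 0: the bonded state lies above the unbonded one, as for
peptide bonds), so a chain of length ``L`` has energy ``-(L-1)Δ`` and the state
of the system is fully specified by the histogram.  The number of ways to
realize a histogram is a product over lengths of binomial factors with
degeneracy

    G_L = b^L · V / v_L,        v_L = l_p^3 · L^{3ν},

where ``l_p`` is the persistence length and ``ν`` the Flory exponent (0.588 for
a self-avoiding walk).  Maximizing ``ln W = Σ_L ln[(N_L+G_L-1)!/(N_L!(G_L-1)!)]``
at fixed polymer number and bond energy yields Bose-form mean occupancies

    n̄_L = (b^L / L^{3ν}) / (exp(-βμ - βΔ(L-1)) - 1),

written here in the dimensionless occupancy variable ``n_L = N_L·(v_p/V)`` with
``v_p = l_p^3``.  (The additive ``-v_p/V`` correction to the degeneracy is
negligible and dropped.)

Two equilibria are distinguished:

* **bath** equilibrium — βΔ is set by an external bath temperature, and βμ is
  solved from the polymer-density constraint ``Σ_L n̄_L = ρ·v_p``;
* **isolated** (self-)equilibrium — both βΔ and βμ are solved from the
  system's own moments ``(ρ·v_p, e·v_p)``, where ``e·v_p = Σ_L (L-1) n_L`` is
  the dimensionless bond density.  Its βΔ defines an *effective* temperature
  that can differ from the current bath's if the system has not re-equilibrated
  (e.g. after a quench).

All sums are evaluated in log space so that ``b^L`` never overflows.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq
from scipy.special import logsumexp

from .errors import FeasibilityError, SolverError

logger = logging.getLogger(__name__)

__all__ = [
    "EnsembleConfig",
    "LengthDistribution",
    "ObservedState",
    "EquilibriumSolution",
    "occupancy_distribution",
    "solve_bath_equilibrium",
    "solve_bath_monomer_density",
    "solve_isolated_equilibrium",
    "solve_isolated_from_moments",
    "state_moments",
    "log_occupancies",
]

# brentq cannot go tighter than ~4 machine epsilons in relative terms
_BRENTQ_RTOL = 8.9e-16


@dataclass(frozen=True)
class EnsembleConfig:
    """Ensemble parameters of the length-distribution model.

    Parameters
    ----------
    b:
        Number of monomer species available for inclusion in polymers.
    lmax:
        Largest length carried in sums and solves.
    nu:
        Flory exponent ν entering the entropic volume ``v_L = l_p^3 L^{3ν}``.
        Default 0.588, the self-avoiding-walk value measured for denatured
        proteins.
    dilution:
        ``v_p/V`` — the (tiny) ratio of the persistence-length volume to the
        solution volume; converts counts to dimensionless occupancies.
    delta:
        Bond energy Δ in k_B·kelvin, Δ < 0 (bonded state is higher in energy).
        Used only when converting between kelvin and βΔ.
    """

    b: int
    lmax: int
    nu: float = 0.588
    dilution: float = 1e-6
    delta: float = -3000.0

    def __post_init__(self) -> None:
        if self.b < 1:
            raise FeasibilityError(f"b must be >= 1, got {self.b}")
        if not 0.0 <= self.nu <= 1.0:
            raise FeasibilityError(f"nu must lie in [0, 1], got {self.nu}")
        if not 0.0 < self.dilution < 1.0:
            raise FeasibilityError(f"dilution must lie in (0, 1), got {self.dilution}")
        if self.delta >= 0:
            raise FeasibilityError(f"delta must be < 0, got {self.delta}")
        if self.lmax < 1:
            raise FeasibilityError(f"lmax must be >= 1, got {self.lmax}")

    def log_degeneracy(self, lmax: int | None = None) -> np.ndarray:
        """``ln G_L`` up to the V/v_p factor: ``L ln b − 3ν ln L`` for L=1..lmax."""
        L = np.arange(1, (lmax or self.lmax) + 1, dtype=float)
        return L * np.log(self.b) - 3.0 * self.nu * np.log(L)

    def beta_delta_at(self, temperature: float) -> float:
        """βΔ for a bath at ``temperature`` kelvin."""
        if temperature <= 0:
            raise FeasibilityError("temperature must be positive")
        return self.delta / temperature


@dataclass
class LengthDistribution:
    """Counts of polymers per length L >= 1."""

    counts: dict[int, float]

    def __post_init__(self) -> None:
        for L, n in self.counts.items():
            if L < 1 or int(L) != L:
                raise FeasibilityError(f"length must be a positive integer, got {L}")
            if n < 0:
                raise FeasibilityError(f"count for L={L} must be >= 0, got {n}")

    @classmethod
    def from_array(cls, arr: np.ndarray) -> "LengthDistribution":
        """Build from an array indexed by L-1 (index 0 holds monomers)."""
        return cls({L + 1: float(c) for L, c in enumerate(arr) if c > 0})

    @property
    def n_total(self) -> float:
        return float(sum(self.counts.values()))

    @property
    def max_length(self) -> int:
        return max(self.counts) if self.counts else 0

    def to_array(self, lmax: int | None = None) -> np.ndarray:
        lmax = lmax or self.max_length
        arr = np.zeros(lmax)
        for L, c in self.counts.items():
            if L <= lmax:
                arr[L - 1] = c
        return arr

    def occupancies(self, dilution: float, lmax: int | None = None) -> np.ndarray:
        """Dimensionless ``n_L = N_L·(v_p/V)`` as an array over L=1..lmax."""
        return self.to_array(lmax) * dilution

    def merged(self, other: "LengthDistribution") -> "LengthDistribution":
        out = dict(self.counts)
        for L, c in other.counts.items():
            out[L] = out.get(L, 0.0) + c
        return LengthDistribution(out)


@dataclass
class ObservedState:
    """An observed length distribution reduced to dimensionless occupancies."""

    occupancies: np.ndarray  # n_L for L = 1..len

    def __post_init__(self) -> None:
        self.occupancies = np.asarray(self.occupancies, dtype=float)
        if self.occupancies.ndim != 1 or self.occupancies.size == 0:
            raise FeasibilityError("occupancies must be a nonempty 1-D array")
        if np.any(self.occupancies < 0):
            raise FeasibilityError("occupancies must be nonnegative")
        if self.rho_vp <= 0:
            raise FeasibilityError("total polymer density must be positive")

    @property
    def lmax(self) -> int:
        return self.occupancies.size

    @property
    def rho_vp(self) -> float:
        """Dimensionless polymer number density ``Σ_L n_L``."""
        return float(self.occupancies.sum())

    @property
    def e_vp(self) -> float:
        """Dimensionless bond-energy density ``Σ_L (L-1) n_L`` in |Δ| units."""
        L = np.arange(1, self.lmax + 1)
        return float(((L - 1) * self.occupancies).sum())

    @property
    def mean_bonds(self) -> float:
        """Mean number of bonds per polymer, ``e_vp / rho_vp``."""
        return self.e_vp / self.rho_vp


@dataclass
class EquilibriumSolution:
    """A solved (βΔ, βμ) pair with its predicted occupancies."""

    beta_delta: float
    beta_mu: float
    occupancies: np.ndarray
    residuals: dict[str, float] = field(default_factory=dict)

    @property
    def rho_vp(self) -> float:
        return float(self.occupancies.sum())

    @property
    def e_vp(self) -> float:
        L = np.arange(1, self.occupancies.size + 1)
        return float(((L - 1) * self.occupancies).sum())

    @property
    def mean_length(self) -> float:
        L = np.arange(1, self.occupancies.size + 1)
        return float((L * self.occupancies).sum() / self.occupancies.sum())


def _log_expm1(x: np.ndarray) -> np.ndarray:
    """``log(exp(x) - 1)`` for x > 0, stable at both ends."""
    x = np.asarray(x, dtype=float)
    small = x < 0.6931471805599453  # ln 2
    out = np.empty_like(x)
    out[small] = np.log(np.expm1(x[small]))
    xl = x[~small]
    out[~small] = xl + np.log1p(-np.exp(-xl))
    return out


def log_occupancies(log_g: np.ndarray, beta_mu: float, beta_delta: float) -> np.ndarray:
    """``ln n̄_L`` for the Bose-form occupancy with degeneracies ``exp(log_g)``.

    Raises
    ------
    FeasibilityError
        If the Bose exponent ``-βμ - βΔ(L-1)`` is nonpositive for some L,
        which would make an occupancy negative or divergent; the message names
        the first offending length.
    """
    lmax = len(log_g)
    L = np.arange(1, lmax + 1, dtype=float)
    x = -beta_mu - beta_delta * (L - 1)
    if np.any(x <= 0):
        bad = int(L[np.argmax(x <= 0)])
        raise FeasibilityError(
            f"nonpositive Bose exponent at L={bad} "
            f"(beta_mu={beta_mu:g}, beta_delta={beta_delta:g})"
        )
    return log_g - _log_expm1(x)


def occupancy_distribution(
    beta_mu: float, beta_delta: float, config: EnsembleConfig
) -> np.ndarray:
    """Mean occupancies ``n̄_L`` for L = 1..config.lmax at given (βμ, βΔ).

    Evaluates ``n̄_L = (b^L/L^{3ν}) / (exp(-βμ - βΔ(L-1)) - 1)`` in log space.
    """
    return np.exp(log_occupancies(config.log_degeneracy(), beta_mu, beta_delta))


def _mu_upper(beta_delta: float, lmax: int) -> float:
    """Supremum of feasible βμ: all Bose exponents must stay positive."""
    return min(0.0, -beta_delta * (lmax - 1))


def _solve_mu(
    log_g: np.ndarray,
    beta_delta: float,
    log_target: float,
    log_weights: np.ndarray | None = None,
) -> float:
    """Solve ``logsumexp(ln n̄_L [+ ln w_L]) = log_target`` for βμ.

    The weighted occupancy sum is strictly increasing in βμ on the feasible
    interval and diverges at its upper end, so a bracketed Brent solve on an
    expanding interval always succeeds when the target is reachable.
    """
    lmax = len(log_g)
    mu_sup = _mu_upper(beta_delta, lmax)

    def f(mu: float) -> float:
        logn = log_occupancies(log_g, mu, beta_delta)
        if log_weights is not None:
            logn = logn + log_weights
        return logsumexp(logn) - log_target

    hi = mu_sup - 1e-13 * max(1.0, abs(mu_sup))
    f_hi = f(hi)
    if f_hi < 0:
        raise FeasibilityError(
            f"target density exp({log_target:g}) exceeds the occupancy-sum "
            f"supremum reachable at beta_delta={beta_delta:g}"
        )
    step = 1.0
    lo = hi - step
    while f(lo) > 0:
        step *= 2.0
        lo = hi - step
        if step > 1e8:
            raise SolverError("failed to bracket beta_mu from below")
    mu = brentq(f, lo, hi, xtol=1e-14, rtol=_BRENTQ_RTOL)
    logger.debug("solved beta_mu=%.15g at beta_delta=%g (f=%.3g)", mu, beta_delta, f(mu))
    return float(mu)


def solve_bath_equilibrium(
    beta_delta: float, rho_vp: float, config: EnsembleConfig
) -> EquilibriumSolution:
    """Bath equilibrium: fix βΔ from the bath, solve βμ so ``Σ n̄_L = ρv_p``.

    Parameters
    ----------
    beta_delta:
        Δ/(k_B T) of the assumed bath, < 0.
    rho_vp:
        Observed dimensionless polymer density to match.
    """
    if rho_vp <= 0:
        raise FeasibilityError("rho_vp must be positive")
    if beta_delta >= 0:
        raise FeasibilityError("beta_delta must be negative (delta < 0, T > 0)")
    log_g = config.log_degeneracy()
    mu = _solve_mu(log_g, beta_delta, np.log(rho_vp))
    occ = np.exp(log_occupancies(log_g, mu, beta_delta))
    resid = abs(occ.sum() - rho_vp) / rho_vp
    if resid > 1e-10:
        raise SolverError(f"bath solve residual {resid:g} exceeds 1e-10")
    return EquilibriumSolution(
        beta_delta=float(beta_delta),
        beta_mu=mu,
        occupancies=occ,
        residuals={"rho": resid},
    )


def solve_bath_monomer_density(
    beta_delta: float, monomer_vp: float, config: EnsembleConfig
) -> EquilibriumSolution:
    """Bath equilibrium constrained by *monomer* density ``Σ L·n̄_L = m·v_p``.

    Used when the conserved quantity is total monomer content (as in the
    reaction-network simulator) rather than polymer number.
    """
    if monomer_vp <= 0:
        raise FeasibilityError("monomer_vp must be positive")
    log_g = config.log_degeneracy()
    logL = np.log(np.arange(1, config.lmax + 1, dtype=float))
    mu = _solve_mu(log_g, beta_delta, np.log(monomer_vp), log_weights=logL)
    occ = np.exp(log_occupancies(log_g, mu, beta_delta))
    L = np.arange(1, config.lmax + 1)
    resid = abs((L * occ).sum() - monomer_vp) / monomer_vp
    if resid > 1e-10:
        raise SolverError(f"monomer-density solve residual {resid:g} exceeds 1e-10")
    return EquilibriumSolution(
        beta_delta=float(beta_delta),
        beta_mu=mu,
        occupancies=occ,
        residuals={"monomer": resid},
    )


def solve_isolated_from_moments(
    log_g: np.ndarray, rho: float, bonds: float
) -> EquilibriumSolution:
    """Solve both (βΔ, βμ) from a polymer total and a bond total.

    ``rho`` and ``bonds`` may be dimensionless densities or raw counts — the
    equations are homogeneous in the degeneracy normalization only through
    ``log_g``, so any consistent unit works.  Nested 1-D solves: the outer
    Brent iteration adjusts βΔ to match the bond total, with βμ re-solved for
    the polymer total at every trial βΔ (the bond total is strictly increasing
    in βΔ at fixed polymer total).
    """
    lmax = len(log_g)
    if lmax < 2:
        raise FeasibilityError("isolated solve needs lmax >= 2")
    if rho <= 0 or bonds <= 0:
        raise FeasibilityError("polymer and bond totals must be positive")
    mean_bonds = bonds / rho
    if not 0.0 < mean_bonds < lmax - 1:
        raise FeasibilityError(
            f"mean bonds per polymer {mean_bonds:g} must lie strictly inside "
            f"(0, {lmax - 1})"
        )
    log_rho = np.log(rho)
    log_bonds = np.log(bonds)
    with np.errstate(divide="ignore"):
        logw = np.log(np.arange(0, lmax, dtype=float))  # ln(L-1); -inf at L=1

    def g(bd: float) -> float:
        mu = _solve_mu(log_g, bd, log_rho)
        logn = log_occupancies(log_g, mu, bd)
        return logsumexp(logn[1:] + logw[1:]) - log_bonds

    lo, hi = -1.0, 1.0
    while g(lo) > 0:
        lo *= 2.0
        if lo < -1e4:
            raise SolverError("failed to bracket beta_delta from below")
    while g(hi) < 0:
        hi *= 2.0
        if hi > 1e4:
            raise SolverError("failed to bracket beta_delta from above")
    bd = brentq(g, lo, hi, xtol=1e-13, rtol=_BRENTQ_RTOL)
    mu = _solve_mu(log_g, bd, log_rho)
    occ = np.exp(log_occupancies(log_g, mu, bd))
    L = np.arange(1, lmax + 1)
    resid_rho = abs(occ.sum() - rho) / rho
    resid_e = abs(((L - 1) * occ).sum() - bonds) / bonds
    if max(resid_rho, resid_e) > 1e-8:
        raise SolverError(
            f"isolated solve residuals rho={resid_rho:g}, bonds={resid_e:g} "
            "exceed 1e-8"
        )
    return EquilibriumSolution(
        beta_delta=float(bd),
        beta_mu=float(mu),
        occupancies=occ,
        residuals={"rho": resid_rho, "bonds": resid_e},
    )


def solve_isolated_equilibrium(
    observed: ObservedState, config: EnsembleConfig
) -> EquilibriumSolution:
    """Self-equilibrated (isolated) solution matching the observed moments.

    The returned βΔ fixes the *effective* temperature implied by the system's
    own polymer and bond densities, with no reference to an external bath.
    """
    lmax = max(config.lmax, observed.lmax)
    return solve_isolated_from_moments(
        config.log_degeneracy(lmax), observed.rho_vp, observed.e_vp
    )


def state_moments(
    distribution: LengthDistribution, config: EnsembleConfig
) -> ObservedState:
    """Reduce a length distribution to its dimensionless occupancy moments."""
    if not distribution.counts:
        raise FeasibilityError("distribution is empty")
    lmax = max(config.lmax, distribution.max_length)
    return ObservedState(distribution.occupancies(config.dilution, lmax))
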