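"""Closed-form kinetics of the quench transition.

Scission/ligation reactions proceed at Arrhenius rates ``f_a·v`` with
``v = exp(-Δa/k_B T)``.  Activation energies Δa are disordered: each reaction
draws its own Δa from a Gaussian centered on the experimental mean Δ̄a with
width σ, truncated to Δa >= 0.  The width convention here is

    dP/dΔa ∝ exp(-(Δa - Δ̄a)² / σ²),

i.e. σ absorbs the usual √2, so that with ξ = Δ̄a/σ the fraction of reactions
fast enough to fire within an observation window t_expt,

    f_a · v >= 1/t_expt   ⟺   Δa <= k_B·T·ln(f_a·t_expt) = Δ̄a·T/T_c,

has the exact closed form

    p_eff(T) = [erf(ξ) − erf((1 − T/T_c)·ξ)] / [erf(ξ) + 1],

with critical temperature T_c = (Δ̄a/k_B)/ln(t_expt·f_a).  p_eff switches
sharply from ~1 above T_c to ~0 below it — the kinetic realization of the
Kauffman network-sparsity parameter p, and the mechanism by which a sudden
hot→cold quench freezes a hot length distribution into the cold phase.

All energies are in k_B·kelvin (see :mod:`polyquench.units`).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.special import erf, erfinv

from .errors import FeasibilityError
from .units import seconds_to_years

__all__ = [
    "KineticParams",
    "critical_temperature",
    "dwell_time",
    "p_effective",
    "uniform_length_temperature",
    "sample_activation_energies",
    "activation_energy_from_uniform",
    "activation_threshold",
]


@dataclass(frozen=True)
class KineticParams:
    """Kinetic disorder parameters.

    Parameters
    ----------
    delta_a_mean:
        Mean activation energy Δ̄a/k_B in kelvin (e.g. 1.2e4 K for
        glycine–glycine peptide-bond hydrolysis).
    sigma:
        Gaussian width σ in kelvin under the ``exp(-(Δa-Δ̄a)²/σ²)``
        convention (so the standard deviation is σ/√2).
    fa:
        Arrhenius attempt frequency, s⁻¹ (~1.3e7 s⁻¹ for peptide hydrolysis).
    texpt:
        Observation/dwell time, seconds.
    T:
        Optional ambient temperature, kelvin.
    """

    delta_a_mean: float
    sigma: float
    fa: float
    texpt: float
    T: float | None = None

    def __post_init__(self) -> None:
        if self.delta_a_mean <= 0:
            raise FeasibilityError("delta_a_mean must be positive")
        if self.sigma <= 0:
            raise FeasibilityError("sigma must be positive")
        if self.fa <= 0:
            raise FeasibilityError("fa must be positive")
        if self.texpt <= 0:
            raise FeasibilityError("texpt must be positive")
        if self.T is not None and self.T < 0:
            raise FeasibilityError("T must be >= 0")

    @property
    def xi(self) -> float:
        """Disorder sharpness ξ = Δ̄a/σ."""
        return self.delta_a_mean / self.sigma

    @property
    def tc(self) -> float:
        """Critical temperature, kelvin."""
        return critical_temperature(self)

    def with_texpt(self, texpt: float) -> "KineticParams":
        return replace(self, texpt=texpt)


def critical_temperature(params: KineticParams) -> float:
    """T_c = (Δ̄a/k_B) / ln(t_expt·f_a); requires t_expt·f_a > 1."""
    tf = params.texpt * params.fa
    if tf <= 1.0:
        raise FeasibilityError(
            f"texpt*fa = {tf:g} must exceed 1 for a positive critical temperature"
        )
    return params.delta_a_mean / np.log(tf)


def dwell_time(params: KineticParams, tc: float) -> float:
    """Dwell time t_expt = f_a⁻¹·exp(Δ̄a/(k_B·T_c)) implied by a target T_c.

    Returns seconds; divide by :data:`polyquench.units.SECONDS_PER_YEAR` (or
    use :func:`polyquench.units.seconds_to_years`) for years.  Exact algebraic
    inverse of :func:`critical_temperature`.
    """
    if tc <= 0:
        raise FeasibilityError("target critical temperature must be positive")
    return float(np.exp(params.delta_a_mean / tc) / params.fa)


def dwell_time_years(params: KineticParams, tc: float) -> float:
    return seconds_to_years(dwell_time(params, tc))


def activation_threshold(T: float, params: KineticParams) -> float:
    """Largest Δa (kelvin) that still fires within t_expt at temperature T.

    ``Δa* = k_B·T·ln(f_a·t_expt) = Δ̄a·T/T_c``.
    """
    return T * np.log(params.fa * params.texpt)


def p_effective(T: float | np.ndarray, params: KineticParams) -> float | np.ndarray:
    """Fraction of reactions fast enough to occur within t_expt at temperature T.

    Nondecreasing in T, 0 at T=0, → 1 as T → ∞, with a sigmoidal transition at
    T_c whose width shrinks as ξ grows.
    """
    xi = params.xi
    tc = params.tc
    T = np.asarray(T, dtype=float)
    num = erf(xi) - erf((1.0 - T / tc) * xi)
    p = np.clip(num / (erf(xi) + 1.0), 0.0, 1.0)
    return float(p) if p.ndim == 0 else p


def uniform_length_temperature(delta: float, b: int) -> float:
    """Temperature ``T_u = -Δ/(k_B ln b)`` at which the equilibrium length
    distribution is flat (each extra bond costs exactly the ln b entropy of an
    extra monomer choice).  For b = 20 and peptide-scale Δ this lands near the
    boiling point of water.
    """
    if b <= 1:
        raise FeasibilityError("b must be >= 2 (ln b must be positive)")
    if delta >= 0:
        raise FeasibilityError("delta must be < 0")
    return -delta / np.log(b)


def sample_activation_energies(
    params: KineticParams, n: int, seed: int | np.random.Generator | None = None
) -> np.ndarray:
    """Draw n activation energies from the truncated Gaussian disorder law.

    Rejection sampling from the untruncated normal N(Δ̄a, σ/√2); the
    acceptance probability is (1+erf(ξ))/2 >= 1/2 for ξ >= 0, ample for
    physically relevant ξ (peptides: ξ ≈ 7.7).  Deterministic under a seed.
    """
    if n < 1:
        raise FeasibilityError("n must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    std = params.sigma / np.sqrt(2.0)
    out = np.empty(n)
    filled = 0
    while filled < n:
        draw = rng.normal(params.delta_a_mean, std, size=2 * (n - filled))
        draw = draw[draw >= 0.0]
        take = min(draw.size, n - filled)
        out[filled : filled + take] = draw[:take]
        filled += take
    return out


def activation_energy_from_uniform(
    u: np.ndarray, params: KineticParams
) -> np.ndarray:
    """Inverse CDF of the truncated Gaussian: maps u ∈ (0,1) to Δa >= 0.

    Lets activation energies be assigned reproducibly from per-reaction hash
    values (see :func:`polyquench.reaction_network.build_network`).
    """
    u = np.asarray(u, dtype=float)
    xi = params.xi
    arg = u * (1.0 + erf(xi)) - erf(xi)
    return params.delta_a_mean + params.sigma * erfinv(arg)
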