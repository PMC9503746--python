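# Methods

This note records the model conventions, numerical choices and study sizes
behind polyquench, in the spirit of a simulator's model documentation: enough
detail to reproduce or deliberately change any of it.

## Ensemble model

The state of a polymer solution is its length histogram `{N_L}`. The number
of microstates is taken as the **product** over lengths of binomial factors,

    W = Π_L (N_L + G_L − 1)! / (N_L! (G_L − 1)!),
    G_L = b^L · (V/v_p) / L^{3ν},

so that `ln W` is extensive and its maximization under fixed polymer count and
bond count yields the Bose-form occupancies used everywhere else. (A sum over
L in place of the product would not reproduce that stationarity condition; the
product is the convention here.) Degeneracies combine the `b^L` sequence count
with the entropic volume `v_L = l_p³·L^{3ν}` of a chain of length L.

Parameters, units, defaults:

| parameter | meaning | default | notes |
|---|---|---|---|
| `b` | monomer alphabet size | 20 | amino acids |
| `ν` | Flory exponent | 0.588 | self-avoiding walk, as measured for denatured proteins; configurable |
| `v_p/V` (`dilution`) | persistence volume / solution volume | 1e−6 | not fixed by the physics here; every scan result is conditional on it and reports should state it |
| `Δ` | bond energy, k_B·kelvin, Δ<0 | −3000 K | only used to convert kelvin ↔ βΔ; dimensionless analyses never touch it |
| `lmax` | largest length in sums | data-driven | defaults to the maximum observed length in data paths |

All energies are internally in k_B·kelvin (k_B = 1); kelvin appears only at
interfaces. Occupancies are always computed in log space
(`ln n̄_L = ln G_L − ln(e^x − 1)`, `x = −βμ − βΔ(L−1)`), so `b^L` never
overflows even for L in the thousands; the additive `−v_p/V` correction to
`G_L` is dropped (it is smaller than `b^L/L^{3ν}` by many orders of magnitude
in any regime of interest) while the `−1` in the Bose denominator is kept.

### Solvers

Both equilibrium solves are bracketed Brent iterations on monotone functions:

* **bath**: `Σ n̄_L` is strictly increasing in `βμ` on the feasible interval
  `βμ < min(0, −βΔ(lmax−1))` and diverges at its upper end, so the 1-D root is
  bracketed by expanding the lower end geometrically. Residual tolerance
  1e−10 (relative), enforced post hoc.
* **isolated**: nested 1-D — the outer iteration adjusts `βΔ` to match the
  bond total (strictly increasing in `βΔ` at fixed polymer total), re-solving
  `βμ` at each trial. Residual tolerance 1e−8 on both constraints. Inputs
  must have a mean bond count strictly inside `(0, lmax−1)`.

Both solvers accept arbitrary positive degeneracies, which is what lets a
brute-force integer-composition maximization of the exact `ln W` (small
`G_L`, `N ≤ 8`) serve as an oracle for the continuous solution in the tests.

## Disequilibrium distances

`R = sqrt(Σ_L (n_L − n̄_L)²/(2ρv_p))`. The square root makes the quantity an
actual Euclidean distance (per its name); since the transformation is
monotone it moves no dip location. Scans run over `βΔ` (dimensionless);
kelvin axes require a user-supplied `Δ`. The dip is the global grid minimum,
no interpolation, ties broken toward smaller `|βΔ|` (the hotter reading).
Infeasible grid points are excluded and flagged rather than fatal.

A caution established while validating the method: for data sampled *exactly*
from the model, both `R_T(argmin)` and `R_L` sit at the multinomial noise
floor, and their ratio is an O(1) random variable — it does **not** converge
to 1 with sample size, because the two statistics project the same noise onto
different constraint sets. When the generating distribution is concentrated
in a few length bins (which happens whenever `|βΔ| < ln b`, the
growing-distribution regime), the relative gap between them fluctuates at the
tens-of-percent level; only for distributions spread over many lengths
(`βΔ ≈ −ln b`, the near-uniform regime) do the two reliably agree to a few
percent. On real data, whose model misfit dwarfs sampling noise, the two
distances track each other closely — which is the regime the close-agreement
observation comes from. Passing or failing a tight `R_T≈R_L` check on
synthetic model-drawn data therefore says more about projection geometry than
about the method.

## Quench kinetics

The disorder law for activation energies is

    dP/dΔa ∝ exp(−(Δa − Δ̄a)²/σ²),  Δa ≥ 0,

i.e. σ absorbs the usual √2 (standard deviation σ/√2). This convention is
what makes the closed form for `p_eff` with `ξ = Δ̄a/σ` *exact* — the
truncated-Gaussian probability below the Arrhenius threshold
`Δa ≤ k_B·T·ln(f_a·t_expt) = Δ̄a·T/T_c` integrates to exactly
`[erf(ξ) − erf((1−T/T_c)ξ)]/[erf(ξ)+1]`, which the tests verify against
quadrature to 1e−12. The threshold form is the rate condition
`f_a·v ≥ 1/t_expt` with `v = e^{−Δa/k_BT}` restated in energy.

Year ↔ second conversion is fixed at 3.156×10⁷ s/yr. The standalone sampler
uses rejection from the untruncated normal (acceptance ≥ 1/2 for ξ ≥ 0; the
peptide regime has ξ ≈ 7.7 where truncation is irrelevant). Network
construction instead assigns `Δa` through the truncated-Gaussian inverse CDF
applied to a 64-bit hash of `(seed, parent sequence, cut position)`: the
assignment is then a pure function of the reaction identity and the formation
seed, independent of enumeration order, and shared by the forward and reverse
directions (one transition state per reaction).

The packaged peptide parameters (`Δ̄a/k_B = 1.2e4 K`, `f_a = 1.3e7 s⁻¹`,
dwell 0.3 yr ⇒ `T_c ≈ 370 K`) and the drying/quench-fit parameters
(`Δa = 99.7 kcal/mol`, `f_a = 5.96e−7 s⁻¹`, `σ = 0.13·Δa`) are both usable as
named configurations; note the two sets are mutually inconsistent as quoted
(the kcal/mol set converts to a very different `Δ̄a/k_B`) and no attempt is
made to reconcile them — conversions use 503.2 K per kcal/mol.

## Reaction networks and dynamics

Species are all sequences up to `lmax` over the first `b` letters of the
amino-acid alphabet (enumeration guarded at `b^lmax ≤ 1e6`); every bond of
every sequence is one reversible reaction, `Σ_{L≤lmax} b^L(L−1)` in total.
Equilibrium ratios use sequence-resolved reference abundances
`n̄_s = n̄_{L(s)}/b^{L(s)}` (equal-energy coarse graining spreads each
length's occupancy uniformly over its sequences), so
`k_d² = n̄₂n̄₃/n̄₁` depends only on the fragment lengths.

Dynamics are exact Gillespie (direct method) on copy numbers with physical
propensities `f_a·v·k_d·N₁` (scission) and `f_a·v·N₂N₃/(k_d·Ω)` (ligation),
`Ω = V/v_p` the system size converting densities to counts (default 1e4
monomers unless stated). Two combinatorial conventions are forced by exact
detailed balance against the reference equilibrium and by conservation:

* identical-fragment ligation uses `N(N−1)`, not `N(N−1)/2` — the density
  rate law `v·n₂n₃/k_d` carries no ½ for identical reactants, and with the
  ½ convention every palindromic reaction would violate detailed balance by a
  factor 2 (this was caught as a systematic monomer excess against the
  equilibrium solver before the convention was fixed);
* scission of a palindromic parent credits its fragment twice.

Monomer content is conserved identically at every event; a `check_conservation`
mode asserts it per event. Under a quench protocol the network is formed once
(activation energies are *reused* across the switch, having been drawn at
network formation); the Arrhenius factors, the kinetic-trap filter
(`f_a·v ≥ 1/t_expt` with the protocol's `t_expt`) and the `k_d` table (from
the bath equilibrium at the new temperature and the current monomer density)
are rebuilt at the hot→cold switch. Checkpoint histograms default to
caller-specified times; every stochastic output records its seed, and reruns
with the same manifest are bit-identical.

The state summary reports the combinatorial entropy
`S/k_B = Σ_L ln[(N_L+G_L−1)!/(N_L!(G_L−1)!)]` through log-gamma (switching to
the `N·ln G` asymptotic once `G` exceeds ~1e12), and the even–odd index
`O = (Σ_{even L≥2} N_L − Σ_{odd L≥3} N_L)/Σ_{L≥2} N_L ∈ [−1,1]` used to
quantify the even–odd length oscillations that quench simulations produce.

## Synthetic data

The generators emulate the quench hypothesis read generatively: protein
lengths are multinomial draws from the normalized bath-equilibrium
occupancies at a formation `βΔ_hot` (support truncated at the smallest length
window holding all but 1e−9 of the mass, capped at 1e4), with an ambient-`βΔ`
variant as the null. Sequences are filled with uniform random residues purely
so the FASTA path is exercised; the analysis is composition-blind. Default
draw: `ρv_p = 1e−3`, 5×10⁴ proteins, one organism; organism sets draw
per-organism sizes with optional uniform jitter and no cross-organism
correlation. Everything is a pure function of (spec, seed).

What the generator deliberately does **not** emulate: real proteome length
distributions (lognormal-like bodies, ORF-calling artifacts, genetic-code
era constraints). Passing recovery tests on synthetic data validates the
pipeline's statistics, not the biological hypothesis.

## Study sizes

The standard sizes used by the tests and by `scripts/acceptance.py`, chosen
as the smallest giving comfortably resolved statistics for each check:

* formation-temperature recovery: 5×10⁴ proteins, `b = 20`, `lmax = 60`,
  grid `βΔ ∈ [−3, −1]` step 0.025;
* `p_eff` realization: the 25 488-reaction `b = 4`, `lmax = 6` network,
  filtered once at `T_c` with `ξ = 2`;
* detailed balance: `b = 2`, `lmax = 4`, `Ω = 5×10⁵`, 2×10⁴ monomers,
  5×10⁵ events with time-averaging after a burn-in of 50 model seconds;
* quench memory: `b = 2`, `lmax = 4`, `Ω = 8×10³`, 2×10³ monomers, 600 K →
  300 K across `T_c ≈ 370 K`, 10 seeds, 1.5×10⁵-event budget per run (the
  hot phase equilibrates well inside it; the cold phase is frozen by
  construction).

## Known limitations

* No spatial structure, diffusion or explicit solvent; the reactor is
  well-mixed by construction.
* All bonds share a single `Δ`; no composition-dependent energetics,
  secondary structure or folding.
* Explicit species enumeration caps practical alphabets/lengths at
  `b^lmax ≤ 1e6`; larger systems need an on-the-fly species representation
  that is not implemented.
* The `v_p/V` dilution is a free parameter; kelvin-space statements
  additionally require a user-supplied `Δ`.
* Replication/autocatalysis variants of the network model are out of scope.
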