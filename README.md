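# polyquench

Tools for asking a thermometer-like question of polymer length distributions:
**at what temperature was this collection of polymers assembled?** The package
implements the statistical-mechanical machinery behind the hypothesis that the
first proteins were formed in hot fluids (near the boiling point of water) and
then *quenched* — plunged into cold surroundings fast enough that the
hot-equilibrium length distribution froze in. It is aimed at researchers in
prebiotic chemistry and systems biology who want to run this analysis on
proteome length histograms, simulate coarse-grained ligation/scission
chemistry through quenches, or reproduce the rare-event arithmetic that frames
the problem.

## The model

A dilute solution of linear polymers over `b` monomer types is coarse grained
to its length histogram `{N_L}`. Every bond carries one energy `−Δ` (Δ < 0),
so entropy maximization at fixed polymer density `ρ·v_p` and bond density
`e·v_p` gives Bose-form mean occupancies

    n̄_L = (b^L / L^{3ν}) / (exp(−βμ − βΔ(L−1)) − 1),

with `ν` the Flory exponent (0.588, self-avoiding walk) and `v_p = l_p³` the
persistence-length volume. Two equilibria are distinguished: **bath**
equilibrium, where `βΔ` comes from an external temperature and `βμ` is solved
from `Σ n̄_L = ρv_p`; and **isolated** (self-)equilibrium, where both
parameters come from the system's own moments. An observed histogram is
compared to each through Euclidean distances

    R = sqrt( Σ_L (n_L − n̄_L)² / (2 ρv_p) ),

giving `R_T` (a function of the assumed bath temperature) and `R_L`
(temperature-independent). Scanning `R_T` over assumed `βΔ` and locating its
dip reads off the apparent formation temperature: data frozen by a quench dip
at the *hot* `βΔ`, not the ambient one.

The kinetic side: scission/ligation reactions fire at Arrhenius rates
`f_a·e^{−Δa/k_BT}` with activation energies drawn from a Gaussian of mean
`Δ̄a` and width `σ` (truncated at 0). The fraction fast enough to act within a
dwell time `t_expt`,

    p_eff(T) = [erf(ξ) − erf((1 − T/T_c)ξ)] / [erf(ξ) + 1],
    ξ = Δ̄a/σ,   T_c = (Δ̄a/k_B) / ln(t_expt·f_a),

switches sharply from ~1 to ~0 as T crosses `T_c` — for peptide-bond
hydrolysis (`Δ̄a/k_B ≈ 1.2×10⁴ K`, `f_a ≈ 1.3×10⁷ s⁻¹`, dwell ≈ 0.3 yr) that
transition sits near 370 K. A Gillespie simulator over explicitly enumerated
sequence species realizes this: networks are built with per-reaction `Δa` and
equilibrium ratios `k_d` (`k_d² = n̄₂n̄₃/n̄₁`), kinetically trapped reactions
are filtered out, and hot→cold protocols show the post-quench histogram
remembering the hot bath.

## Worked example

Order-of-magnitude arithmetic for assembling one specific 209-residue protein
from ~500 candidate amino acids:

```
$ polyquench estimate prion-protein
sequence space  10^564
search time     10^526 years (at assumed flux 10^40/yr)
computed flux   10^31.8/yr
workable forms  10^514
```

A sequence space of 10⁵⁶⁴ candidates worked through at the historically quoted
monomer flux of 10⁴⁰/yr takes 10⁵²⁶ years; even a workable fraction of 10⁻⁵⁰
leaves 10⁵¹⁴ viable "exotic" chemistries. (The flux computed honestly from
10¹³ kg/yr of rift water at 10⁻⁵ molar is 10³¹·⁸/yr — both figures are
printed.)

The kinetic transition for peptide parameters:

```
$ polyquench quench --delta-a 1.2e4 --sigma 1560 --fa 1.3e7 --texpt 0.3 --years
T_c     369.869 K       xi      7.69231
T_kelvin        p_eff
300     0.01993991252
360     0.385802306
380     0.6171337851
440     0.9804283142
```

At 300 K only ~2% of bond-breaking reactions can act within the dwell time; by
440 K essentially all can — a quench across 370 K freezes the chemistry.

End-to-end formation-temperature recovery on a synthetic proteome of 20 000
proteins generated at `βΔ_hot = −2.0`:

```
$ polyquench make-synthetic --beta-delta -2.0 --n-proteins 20000 --seed 7 \
      --out-dir demo --lmax 60
$ polyquench lengths demo/syn001.fasta --out demo/syn001.tsv
$ polyquench rt-scan --table demo/syn001.tsv --grid-start -3.0 --grid-stop -1.0 \
      --grid-step 0.05 --dilution 5e-8
argmin  -2      RT_min  5.95809e-05     RL      5.8846e-05
```

The scan's dip lands exactly on the generating `βΔ = −2.0`, and the dip depth
is close to the isolated-equilibrium distance `R_L` — the signature the method
looks for in real proteomes.

Other subcommands: `equilibrium` (bath solve for a histogram),
`simulate-quench` (Gillespie hot→cold protocol with checkpoint histograms and
a run manifest), `pipeline` (multi-organism scan with aggregate mean/SD
curves). See `polyquench --help`.

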