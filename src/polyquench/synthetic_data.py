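"""Synthetic proteomes and simulator fixtures.

The quench hypothesis reads the equilibrium model generatively: proteins were
assembled while the system was bath-equilibrated at a *hot* formation
temperature, and that length distribution was frozen in by the quench.  The
generators here emulate exactly that — protein lengths are drawn multinomially
from the normalized bath-equilibrium occupancies at a formation βΔ, and
sequences are filled with uniform random residues over the 20-letter amino
acid alphabet (residue identities are irrelevant to the equal-Δ analysis but
are emitted so the FASTA path is exercised end to end).  An ambient variant
equilibrated at a cold βΔ serves as the null for contrast.

Every generator is a pure function of its spec and seed; truth manifests
record the generating parameters.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from .equilibrium import EnsembleConfig, LengthDistribution, solve_bath_equilibrium
from .errors import FeasibilityError
from .proteome_io import ProteomeRecord
from .reaction_network import ALPHABET, SimState, enumerate_species

__all__ = [
    "SyntheticSpec",
    "generation_probabilities",
    "generate_quenched_proteome",
    "generate_ambient_proteome",
    "generate_organism_set",
    "generate_sim_fixture",
    "write_fasta",
]

#: lengths with cumulative probability below this tail mass are dropped
_TAIL_MASS = 1e-9
_LMAX_CAP = 10**4


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of a synthetic proteome draw.

    ``beta_delta`` is the formation bath βΔ (hot for the quench scenario,
    ambient for the null); ``rho_vp`` the dimensionless polymer density the
    bath solve targets; ``n_proteins`` the multinomial sample size.
    """

    beta_delta: float
    rho_vp: float = 1e-3
    n_proteins: int = 50_000
    n_organisms: int = 1
    n_proteins_jitter: float = 0.0  # uniform relative jitter on per-organism size
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_proteins < 1:
            raise FeasibilityError("n_proteins must be >= 1")
        if self.n_organisms < 1:
            raise FeasibilityError("n_organisms must be >= 1")
        if not 0.0 <= self.n_proteins_jitter < 1.0:
            raise FeasibilityError("jitter must lie in [0, 1)")


def generation_probabilities(
    spec: SyntheticSpec, config: EnsembleConfig
) -> np.ndarray:
    """Normalized length probabilities ``N̄_L/N̄`` at the formation bath.

    The support is truncated to the smallest length window holding all but a
    1e-9 tail of the mass, capped at min(config.lmax, 1e4).
    """
    lmax = min(config.lmax, _LMAX_CAP)
    cfg = EnsembleConfig(
        b=config.b, lmax=lmax, nu=config.nu, dilution=config.dilution, delta=config.delta
    )
    sol = solve_bath_equilibrium(spec.beta_delta, spec.rho_vp, cfg)
    p = sol.occupancies / sol.occupancies.sum()
    cum = np.cumsum(p)
    support = int(np.searchsorted(cum, 1.0 - _TAIL_MASS) + 1)
    p = p[:support]
    return p / p.sum()


def _sample_lengths(
    p: np.ndarray, n: int, rng: np.random.Generator
) -> LengthDistribution:
    counts = rng.multinomial(n, p)
    return LengthDistribution.from_array(counts.astype(float))


def _fill_sequences(
    distribution: LengthDistribution, rng: np.random.Generator
) -> list[str]:
    seqs: list[str] = []
    for L in sorted(distribution.counts):
        k = int(distribution.counts[L])
        draws = rng.integers(0, len(ALPHABET), size=(k, L))
        seqs.extend("".join(ALPHABET[j] for j in row) for row in draws)
    return seqs


def write_fasta(organism_id: str, sequences: list[str], path: Path) -> None:
    with open(path, "w") as fh:
        for i, s in enumerate(sequences, start=1):
            fh.write(f">{organism_id}_{i:06d}\n")
            for j in range(0, len(s), 60):
                fh.write(s[j : j + 60] + "\n")


def generate_quenched_proteome(
    spec: SyntheticSpec,
    config: EnsembleConfig,
    out_dir: str | Path | None = None,
    organism_id: str = "syn001",
) -> tuple[ProteomeRecord, dict]:
    """Draw one proteome frozen at the formation bath of ``spec.beta_delta``.

    Returns the record plus a truth manifest; when ``out_dir`` is given, also
    writes ``<organism_id>.fasta`` and ``truth.json`` there.  Infeasible specs
    raise before any file is written.
    """
    p = generation_probabilities(spec, config)  # raises if infeasible
    rng = np.random.default_rng(spec.seed)
    dist = _sample_lengths(p, spec.n_proteins, rng)
    record = ProteomeRecord(organism_id, dist)
    manifest = {
        "organism_id": organism_id,
        "beta_delta": spec.beta_delta,
        "rho_vp": spec.rho_vp,
        "n_proteins": spec.n_proteins,
        "seed": spec.seed,
        "b": config.b,
        "nu": config.nu,
        "lmax_support": int(p.size),
    }
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_fasta(organism_id, _fill_sequences(dist, rng), out_dir / f"{organism_id}.fasta")
        with open(out_dir / "truth.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
    return record, manifest


def generate_ambient_proteome(
    spec: SyntheticSpec,
    config: EnsembleConfig,
    out_dir: str | Path | None = None,
    organism_id: str = "amb001",
) -> tuple[ProteomeRecord, dict]:
    """Null variant: a proteome equilibrated at the (cold) ambient βΔ.

    Identical machinery to :func:`generate_quenched_proteome`; only the
    interpretation of ``spec.beta_delta`` differs.
    """
    return generate_quenched_proteome(spec, config, out_dir, organism_id)


def generate_organism_set(
    spec: SyntheticSpec,
    config: EnsembleConfig,
    out_dir: str | Path | None = None,
    prefix: str = "syn",
) -> tuple[list[ProteomeRecord], dict]:
    """A set of organisms drawn independently at the same formation bath.

    Per-organism sample sizes are jittered uniformly by up to
    ``spec.n_proteins_jitter`` (relative); no correlation structure between
    organisms is modeled.
    """
    p = generation_probabilities(spec, config)
    rng = np.random.default_rng(spec.seed)
    records = []
    for i in range(1, spec.n_organisms + 1):
        n = spec.n_proteins
        if spec.n_proteins_jitter > 0:
            n = max(1, int(round(n * (1.0 + spec.n_proteins_jitter * rng.uniform(-1, 1)))))
        dist = _sample_lengths(p, n, rng)
        records.append(ProteomeRecord(f"{prefix}{i:03d}", dist))
    manifest = {**asdict(spec), "organisms": [r.organism_id for r in records]}
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for rec in records:
            write_fasta(
                rec.organism_id,
                _fill_sequences(rec.distribution, rng),
                out_dir / f"{rec.organism_id}.fasta",
            )
        with open(out_dir / "truth.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
    return records, manifest


def generate_sim_fixture(
    b: int, lmax: int, monomer_count: int, seed: int = 0, omega: float = 1e4
) -> SimState:
    """All-monomer initial state: ``monomer_count`` monomers split as evenly
    as possible across the b monomer species (remainder assigned by seed)."""
    species = enumerate_species(b, lmax)
    counts = np.zeros(len(species), dtype=np.int64)
    base, rem = divmod(monomer_count, b)
    counts[:b] = base
    if rem:
        rng = np.random.default_rng(seed)
        counts[rng.choice(b, size=rem, replace=False)] += 1
    return SimState(species=species, copy_numbers=counts, omega=omega)
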