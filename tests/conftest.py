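import numpy as np
import pytest

from polyquench.equilibrium import EnsembleConfig
from polyquench.quench_theory import KineticParams


@pytest.fixture
def protein_config() -> EnsembleConfig:
    """Amino-acid-like ensemble: b=20, self-avoiding-walk ν."""
    return EnsembleConfig(b=20, lmax=60, nu=0.588, dilution=1e-6, delta=-3000.0)


@pytest.fixture
def peptide_kinetics() -> KineticParams:
    """Peptide-bond hydrolysis kinetics: Δ̄a/k_B = 1.2e4 K, f_a = 1.3e7 /s,
    dwell time ≈ 0.3 yr (so T_c ≈ 370 K)."""
    return KineticParams(delta_a_mean=1.2e4, sigma=1560.0, fa=1.3e7, texpt=9.468e6)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20_220_828)
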