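"""Shared fixtures: small synthetic inputs built at test time."""

import numpy as np
import pytest

from memphys import dib, synthetic
from memphys.constants import nacl_osmolarity_mol_m3
from memphys.dib import DropletPairState, TransportParams


@pytest.fixture
def control_state():
    """Two 100 um droplets: pure water vs 0.1 M NaCl."""
    v2 = dib.volume_from_radius(50e-6)
    osm2 = nacl_osmolarity_mol_m3(0.1)
    return DropletPairState.from_radii_um(50.0, 50.0, n1=0.0, n2=osm2 * v2)


@pytest.fixture
def control_params():
    return TransportParams(pf_um_s=73.0)


@pytest.fixture
def t_grid():
    return np.arange(0.0, 300.5, 1.0)


@pytest.fixture
def noise_free_trajectory():
    return synthetic.gen_trajectory(
        synthetic.TrajectoryConfig(seed=1, sigma_r_um=0.0))


@pytest.fixture
def control_thermogram_clean():
    """Noise-free, drift-free control endotherm (single Gaussian)."""
    return synthetic.gen_thermogram(synthetic.ThermogramConfig(
        seed=0, snr=float("inf"), drift=(0.0,)))


@pytest.fixture
def ftir_clean():
    return synthetic.gen_spectrum(synthetic.SpectrumConfig(
        seed=0, kind="ATR-FTIR", snr=float("inf")))


@pytest.fixture
def raman_clean():
    return synthetic.gen_spectrum(synthetic.SpectrumConfig(
        seed=0, kind="Raman", snr=float("inf")))
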