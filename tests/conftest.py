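import numpy as np
import pytest

from bspa.chem import ProductTarget
from bspa.qc import ChromatogramRun, QCConfig, SpectrumScan


@pytest.fixture
def qc_config():
    return QCConfig()


@pytest.fixture
def simple_target():
    """A mid-sized product: neutral monoisotopic mass 313.1426 Da."""
    return ProductTarget(
        id="T1",
        smiles="CC1CN(C(=O)c2ccco2)CCN1C(=O)Nc1ccccc1",
        formula="C17H19N3O3",
        mono_mass=313.1426,
        avg_mass=313.36,
        expected_ions=(("[M+H]+", 314.149876, 1),),
    )


def make_run(tic_profile, base_mz=200.0, sample_id="toy"):
    """A run whose scans each hold one signal, so the TIC equals the profile."""
    scans = tuple(
        SpectrumScan(rt=float(5 * i), mz=np.array([base_mz]),
                     intensity=np.array([float(v)]), ms_level=1)
        for i, v in enumerate(tic_profile)
    )
    return ChromatogramRun(sample_id=sample_id, scans=scans)


@pytest.fixture
def gaussian_tic():
    x = np.arange(61, dtype=float)
    return 1e5 * np.exp(-((x - 30) ** 2) / (2 * 4.0**2))
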