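import numpy as np
import pytest

from liquidlens import genome_cni as gc
from liquidlens import synthetic_data as sd


@pytest.fixture(scope="session")
def toy_windows() -> gc.GenomeWindows:
    """One 100 bp chromosome tiled into ten 10 bp windows."""
    return gc.partition_genome({"chr1": 100}, n_windows=None, span_bp=10)


@pytest.fixture(scope="session")
def hg19_windows() -> gc.GenomeWindows:
    return gc.partition_genome(gc.load_packaged_chrom_sizes())


@pytest.fixture(scope="session")
def null_cfdna() -> sd.CfdnaSim:
    """A simulated normal panel plus 20 null samples (no aberrations)."""
    return sd.gen_cfdna(sd.CfdnaSimParams(n_samples=20, seed=101))


@pytest.fixture(scope="session")
def null_panel(null_cfdna) -> gc.ReferencePanel:
    profiles = [
        gc.log2_ratio_profile(c, null_cfdna.windows) for c in null_cfdna.panel
    ]
    return gc.build_reference(profiles)


@pytest.fixture(scope="session")
def small_raman():
    """A reduced spectral dataset for fast classifier tests."""
    params = sd.RamanSimParams(
        n_cancer_participants=6, n_control_participants=6, n_points=301,
        seed=77,
    )
    return sd.gen_raman(params)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
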