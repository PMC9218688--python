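import numpy as np
import pytest

from tendonswe import (KernelConfig, SweepConfig, TendonPhantom, VoxelGridSpec,
                       compound, pixel_world_positions, simulate_sweep)


@pytest.fixture(scope="session")
def phantom():
    """Default straight 46 mm phantom with regions (9.5, 9.0, 10.0) m/s."""
    return TendonPhantom()


@pytest.fixture(scope="session")
def noisefree_sweep(phantom):
    """Dense noise-free transverse sweep covering the whole tendon."""
    cfg = SweepConfig(n_frames=112, frame_rows=14, frame_cols=56,
                      pixel_spacing=0.5, seed=7)
    return simulate_sweep(phantom, cfg)


@pytest.fixture(scope="session")
def noisefree_recon(phantom, noisefree_sweep):
    """Compounded SWE and B-mode volumes of the noise-free sweep."""
    pts = np.concatenate([pixel_world_positions(f).reshape(-1, 3)
                          for f in noisefree_sweep])
    spec = VoxelGridSpec.bounding(pts, 0.5)
    swe, bmode = compound(noisefree_sweep, spec, KernelConfig())
    return spec, swe, bmode
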