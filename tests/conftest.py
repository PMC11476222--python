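import numpy as np
import pytest

from gangliotk.simulate import SimConfig, default_panel, simulate_run


@pytest.fixture(scope="session")
def clean_run():
    """Noise-free default-panel run, densely sampled (dt = sigma/10), with
    its truth table.  Session-scoped: read-only in tests."""
    cfg = SimConfig(species=default_panel(), scan_interval=0.005, seed=11)
    run, truth = simulate_run(cfg)
    return run, truth, cfg


@pytest.fixture()
def single_gaussian_xic():
    """A synthetic Gaussian trace as a bare Chromatogram (sigma 0.05 min,
    apex 1e6 at 10 min) plus its analytic area."""
    from gangliotk.xic import Chromatogram

    sigma, apex, center = 0.05, 1.0e6, 10.0
    rts = np.arange(8.0, 12.0, sigma / 10)
    y = apex * np.exp(-0.5 * ((rts - center) / sigma) ** 2)
    xic = Chromatogram(rts=rts, intensities=y, mz=1000.0, tolerance_ppm=10.0)
    true_area = apex * sigma * np.sqrt(2 * np.pi)
    return xic, true_area, center, sigma
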