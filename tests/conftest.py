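import numpy as np
import pytest

from cytodiff.synthetic import SyntheticHistologySpec, gen_histology


@pytest.fixture(scope="session")
def default_tile():
    """One default-regime synthetic CC3 tile with its ground truth."""
    spec = SyntheticHistologySpec(seed=0)
    img, truth = gen_histology(spec)
    return spec, img, truth


@pytest.fixture(scope="session")
def small_tile():
    """A small, quick tile for CLI and plumbing tests."""
    spec = SyntheticHistologySpec(
        height=128, width=128, n_blue_nuclei=28, n_brown_cells=5, seed=2
    )
    img, truth = gen_histology(spec)
    return spec, img, truth


def dice(a: np.ndarray, b: np.ndarray) -> float:
    return 2.0 * np.logical_and(a, b).sum() / (a.sum() + b.sum())
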