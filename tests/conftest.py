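import numpy as np
import pytest

from macromorph import synthdata


@pytest.fixture(scope="session")
def class_specs_small():
    """Six-phenotype specs scaled to ~5% of the study's cell counts."""
    return synthdata.dataset1_class_specs(scale=0.05)


@pytest.fixture(scope="session")
def cohort_small(class_specs_small):
    return synthdata.make_tabular_cohort(class_specs_small, seed=7)


@pytest.fixture(scope="session")
def full_cohort():
    """The full-size six-class cohort (9304 cells), shared across tests."""
    return synthdata.make_tabular_cohort(synthdata.dataset1_class_specs(), seed=11)


def disk_mask(radius: int, pad: int = 10) -> np.ndarray:
    n = 2 * (radius + pad)
    yy, xx = np.mgrid[:n, :n]
    c = n / 2 - 0.5
    return (yy - c) ** 2 + (xx - c) ** 2 <= (radius + 0.4) ** 2


def ellipse_mask(a: int, b: int, pad: int = 10) -> np.ndarray:
    """Axis-aligned digitized ellipse with semi-axes a >= b."""
    h, w = 2 * (b + pad), 2 * (a + pad)
    yy, xx = np.mgrid[:h, :w]
    cy, cx = h / 2 - 0.5, w / 2 - 0.5
    return ((xx - cx) / (a + 0.4)) ** 2 + ((yy - cy) / (b + 0.4)) ** 2 <= 1.0
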