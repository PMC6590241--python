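import numpy as np
import pytest

from msiqc.core import MassSpectrum, MSIDataset
from msiqc.phantom import PhantomSpec, default_analytes, generate_phantom


def make_dataset(mz, rows, n_cols, n_rows, coords=None, **kwargs):
    """Tiny continuous-mode dataset from explicit per-pixel intensity rows."""
    rows = np.asarray(rows, dtype=np.float64)
    if coords is None:
        coords = [(i % n_cols, i // n_cols) for i in range(rows.shape[0])]
    return MSIDataset.from_matrix(np.asarray(mz, float), rows, coords, n_cols, n_rows, **kwargs)


def small_phantom_spec(**overrides):
    """Scaled-down two-region phantom: 32x32 grid, m/z 800-1300, both region
    markers plus three shared peptides."""
    defaults = dict(
        n_cols=32,
        n_rows=32,
        mz_min=800.0,
        mz_max=1300.0,
        analytes=default_analytes(800.0, 1300.0),
        seed=0,
    )
    defaults.update(overrides)
    return PhantomSpec(**defaults)


@pytest.fixture(scope="session")
def small_phantom():
    """One deterministic scaled-down phantom shared across read-only tests."""
    spec = small_phantom_spec()
    dataset, truth = generate_phantom(spec)
    return dataset, truth
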