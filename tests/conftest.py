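import numpy as np
import pandas as pd
import pytest

from comorbinet import Cohort, default_spec, generate, load_codebook


@pytest.fixture(scope="session")
def codebook():
    return load_codebook()


@pytest.fixture(scope="session")
def default_cohort():
    """One calibrated synthetic cohort at study scale, with true labels."""
    cohort, labels = generate(default_spec(n=3171, seed=1))
    return cohort, labels


def make_cohort(flags, codebook, *, age=50.0, sep=0.0, rng=None):
    """Build a minimal valid cohort around a given disease-flag matrix."""
    flags = np.atleast_2d(np.asarray(flags, dtype=int))
    n = flags.shape[0]
    rng = rng or np.random.default_rng(0)
    frame = pd.DataFrame({
        "patient_id": [f"T{i:04d}" for i in range(n)],
        "age": np.full(n, age, dtype=float),
        "sex": np.where(rng.random(n) < 0.5, "female", "male"),
        "sep": np.full(n, sep, dtype=float),
        "smoking": rng.integers(0, 2, n),
        "n_teeth": np.full(n, 26),
        "n_pockets_ge6": np.full(n, 20),
        "bop_pct": np.full(n, 50.0),
        "pisa_mm2": np.full(n, 1300.0),
    })
    for j, d in enumerate(codebook.diseases):
        frame[d] = flags[:, j]
    return Cohort(frame, codebook)


@pytest.fixture
def cohort_builder(codebook):
    return lambda flags, **kw: make_cohort(flags, codebook, **kw)
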