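import numpy as np
import pandas as pd
import pytest

from epifidelity.datatypes import TagCountMatrix
from epifidelity.simulate import SimConfig


@pytest.fixture
def small_config():
    """Scaled-down study design for fast end-to-end runs."""
    return SimConfig(
        n_loci=60,
        n_tags=80,
        n_true_dmrs=8,
        lib_size_range=(2_000, 3_000),
        seed=42,
    )


def make_null_matrix(seed, n_tags=500, n_per_group=3, phi=0.2, mean_log=3.8):
    """NB count matrix with no condition effect (helper, not a fixture)."""
    rng = np.random.default_rng(seed)
    n = 2 * n_per_group
    mu = rng.lognormal(mean_log, 1.0, n_tags)
    lib_scale = rng.uniform(0.8, 1.2, n)
    m = mu[:, None] * lib_scale[None, :]
    if phi > 0:
        lam = rng.gamma(1 / phi, m * phi)
    else:
        lam = m
    counts = pd.DataFrame(
        rng.poisson(lam),
        index=[f"t{i:04d}" for i in range(n_tags)],
        columns=[f"s{i}" for i in range(n)],
    )
    meta = pd.DataFrame(
        {
            "variety": "V",
            "condition": ["field"] * n_per_group + ["in_vitro"] * n_per_group,
            "tissue": "root",
            "replicate": list(range(n_per_group)) * 2,
        },
        index=counts.columns,
    )
    return TagCountMatrix(counts, meta), meta["condition"]
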