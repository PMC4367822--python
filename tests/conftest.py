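import numpy as np
import pandas as pd
import pytest

from modulome.synthetic_data import CohortSpec, generate_cohort


@pytest.fixture(scope="session")
def reference_cohort():
    """Complete reference cohort: n=200, 4 modules x 15 features + 40 noise,
    within-module correlation 0.7, fixed seed; metabolites on log10 scale."""
    spec = CohortSpec(seed=3, mcar_rate=0.0, censor_rate=0.0, batch_sd=0.0)
    pheno, metab, transcripts, truth = generate_cohort(spec)
    logv = np.log10(metab.values)
    return pheno, logv, transcripts, truth


@pytest.fixture(scope="session")
def noisy_cohort():
    """Default cohort with batch effects and missingness, fixed seed."""
    spec = CohortSpec(seed=1)
    return generate_cohort(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def tiny_block_frame(n=120, sizes=(6, 7), cor=0.9, seed=0, noise=0):
    """Small block-correlated frame for clustering tests."""
    r = np.random.default_rng(seed)
    cols, data = [], []
    for b, s in enumerate(sizes, start=1):
        L = r.normal(size=n)
        for j in range(s):
            cols.append(f"B{b}F{j}")
            data.append(np.sqrt(cor) * L + np.sqrt(1 - cor) * r.normal(size=n))
    for j in range(noise):
        cols.append(f"N{j}")
        data.append(r.normal(size=n))
    return pd.DataFrame(np.column_stack(data),
                        index=[f"S{i}" for i in range(n)], columns=cols)
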