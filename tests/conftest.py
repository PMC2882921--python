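import numpy as np
import pandas as pd
import pytest

import mgfscreen as m


@pytest.fixture
def cfg():
    return m.AnalysisConfig()


def make_dataset(signal, calls, populations, probes=None, samples=None):
    """Build a small ExpressionDataset from plain lists."""
    signal = np.asarray(signal, dtype=float)
    n_probes, n_samples = signal.shape
    probes = probes or [f"p{i + 1}" for i in range(n_probes)]
    samples = samples or [f"s{j + 1}" for j in range(n_samples)]
    return m.ExpressionDataset(
        signal=pd.DataFrame(signal, index=probes, columns=samples),
        call=pd.DataFrame(np.asarray(calls, dtype=object), index=probes, columns=samples),
        populations=pd.Series(list(populations), index=samples),
    )


@pytest.fixture
def tiny_dataset():
    return make_dataset(
        signal=[[2.0, 4.0, 6.0], [1.0, 1.0, 1.0]],
        calls=[["P", "P", "A"], ["A", "A", "A"]],
        populations=["MMC", "MMC", "MMC"],
    )


#: Reduced sample sizes for unit tests that only need the populations to exist.
SMALL_SIZES = {
    "MMC": 12, "CD3": 4, "CD14": 4, "PMN": 4, "BMSC": 4, "OC": 5,
    "MB": 4, "PPC": 4, "BMPC": 4, "WBM": 0,
}


def small_synthetic(genes, seed=0, sd=0.3, **kwargs):
    """Small, fast synthetic dataset with the given planted genes."""
    cfg = m.SyntheticConfig(
        population_sizes=dict(SMALL_SIZES),
        genes=tuple(genes),
        within_pop_log2_sd=sd,
        n_background_probes=kwargs.pop("n_background_probes", 300),
        seed=seed,
        **kwargs,
    )
    return m.generate_dataset(cfg)
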