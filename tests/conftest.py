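import numpy as np
import pandas as pd
import pytest

import chromdomains as cd


@pytest.fixture(scope="session")
def small_cohort():
    """A small but fully structured cohort shared by read-only tests."""
    cfg = cd.SimConfig(
        n_samples=150,
        n_cases=70,
        n_chromosomes=2,
        peaks_per_chromosome=120,
        crd_sizes=(8, 10, 12, 8, 10, 12),
        n_trds=3,
        disease_effect_size=1.0,
        fraction_affected_peaks=0.1,
        n_cells=300,
        n_variants=500,
        seed=11,
    )
    peaks, m, truth = cd.simulate_bulk(cfg)
    return cfg, peaks, m, truth


@pytest.fixture()
def toy_peaks():
    return cd.PeakSet.from_arrays(
        ["chr1", "chr1", "chr1", "chr2"],
        [100, 500, 900, 50],
        [200, 700, 1400, 150],
        ["pA", "pB", "pC", "pD"],
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
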