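"""Shared helpers: labelled RNG streams and multiple-testing wrappers."""

from __future__ import annotations

import numpy as np
from statsmodels.stats.multitest import multipletests

# Fixed stream labels: each simulated object draws from its own stream derived
# from the master seed, so e.g. adding cells never perturbs the bulk matrix.
_STREAMS = {
    "layout": 0,
    "bulk": 1,
    "severity": 2,
    "genotypes": 3,
    "cells": 4,
    "celltype_truth": 5,
    "diagnosis": 6,
    "covariates": 7,
}


def stream_rng(seed: int, label: str) -> np.random.Generator:
    """Independent, reproducible RNG stream for one simulated object."""
    if label not in _STREAMS:
        raise KeyError(f"unknown RNG stream label: {label!r}")
    ss = np.random.SeedSequence(entropy=int(seed), spawn_key=(_STREAMS[label],))
    return np.random.Generator(np.random.PCG64(ss))


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


def standardize(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    sd = x.std(ddof=0)
    if sd == 0:
        raise ValueError("cannot standardize a constant vector")
    return (x - x.mean()) / sd
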