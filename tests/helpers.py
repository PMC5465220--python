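"""Shared test utilities and independent oracles."""

import math

import numpy as np
import pandas as pd

from pufstress import CountMatrix


def matrix_from(counts: np.ndarray, strains=None, timepoints=None, batches=None):
    n_genes, n_samples = counts.shape
    genes = [f"g{i}" for i in range(n_genes)]
    samples = [f"s{j}" for j in range(n_samples)]
    meta = pd.DataFrame(
        {
            "strain": strains or ["WT-a"] * n_samples,
            "timepoint": timepoints or ["T0"] * n_samples,
            "replicate_batch": batches or ["R1"] * n_samples,
        },
        index=samples,
    )
    return CountMatrix(counts=pd.DataFrame(counts, index=genes, columns=samples),
                       samples=meta)


def brute_force_size_factors(counts: np.ndarray) -> np.ndarray:
    """Independent median-of-ratios oracle by direct enumeration."""
    ref_rows = [g for g in range(counts.shape[0]) if all(c > 0 for c in counts[g])]
    factors = []
    for j in range(counts.shape[1]):
        ratios = []
        for g in ref_rows:
            geomean = math.prod(int(c) for c in counts[g]) ** (1.0 / counts.shape[1])
            ratios.append(counts[g, j] / geomean)
        factors.append(float(np.median(ratios)))
    return np.array(factors)
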