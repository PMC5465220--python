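"""Count-matrix handling: background filtering, median-of-ratios
normalization, per-replicate log2 ratio profiles, and replicate QC.

The container is :class:`CountMatrix`, a genes x samples integer table with
per-sample metadata (strain, timepoint in {T0, T45, Tend}, replicate_batch).
Normalization reimplements the DESeq2 median-of-ratios size factor:

    s_j = median over reference genes g of  count[g, j] / geomean_g

where geomean_g is the geometric mean of gene g across samples and the
reference set is the genes with nonzero counts in every sample.  Ratio
profiles are log2((num + pc) / (den + pc)) on normalized counts, pairing
the two samples of a contrast within the same replicate batch — each
biological repeat is treated separately, never pooled.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CountMatrix",
    "RatioProfile",
    "read_counts",
    "filter_background",
    "size_factors",
    "normalize",
    "log_ratio",
    "replicate_qc",
    "compare_measurements",
]

logger = logging.getLogger(__name__)

TIMEPOINTS = ("T0", "T45", "Tend")
METADATA_COLUMNS = ("strain", "timepoint", "replicate_batch")


@dataclass
class CountMatrix:
    """Gene x sample raw counts with sample metadata.

    ``counts`` is a genes x samples DataFrame of non-negative integers;
    ``samples`` is indexed by sample id with columns strain, timepoint and
    replicate_batch.
    """

    counts: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        if self.counts.index.has_duplicates:
            raise ValueError("duplicate gene ids")
        if self.counts.columns.has_duplicates:
            raise ValueError("duplicate sample ids")
        missing_cols = [c for c in METADATA_COLUMNS if c not in self.samples.columns]
        if missing_cols:
            raise ValueError(f"sample metadata missing column(s): {missing_cols}")
        missing = set(self.counts.columns) - set(self.samples.index)
        if missing:
            raise ValueError(f"samples without metadata: {sorted(missing)[:5]}")
        if self.samples.loc[list(self.counts.columns), list(METADATA_COLUMNS)].isna().any().any():
            raise ValueError("incomplete sample metadata")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("negative counts")
        self.samples = self.samples.loc[list(self.counts.columns)]

    @property
    def gene_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.counts.columns

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]


@dataclass(frozen=True)
class RatioProfile:
    """Per-gene log2 ratio of one contrast for one strain x replicate batch."""

    strain: str
    replicate_batch: str
    contrast: str  # "T45/T0" or "Tend/T0"
    log2_ratio: pd.Series  # indexed by gene id

    @property
    def gene_ids(self) -> pd.Index:
        return self.log2_ratio.index


def read_counts(counts_path, metadata_path) -> CountMatrix:
    """Load a counts TSV (first column gene id, header sample ids) plus a
    metadata TSV (first column sample id; strain, timepoint, replicate_batch)."""
    counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    samples = pd.read_csv(metadata_path, sep="\t", index_col=0, dtype=str)
    return CountMatrix(counts=counts, samples=samples)


def filter_background(m: CountMatrix, min_reads: int = 100) -> CountMatrix:
    """Keep genes with count strictly greater than ``min_reads`` in at least
    one sample (gene order preserved); the study's background filter."""
    keep = (m.counts > min_reads).any(axis=1)
    if not keep.any():
        raise ValueError("no genes pass filter")
    return CountMatrix(counts=m.counts.loc[keep].copy(), samples=m.samples.copy())


def size_factors(m: CountMatrix | pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors, one per sample.

    Reference genes are those with nonzero counts in all samples; each
    sample's factor is the median over reference genes of its count divided
    by the gene's across-sample geometric mean.
    """
    counts = m.counts if isinstance(m, CountMatrix) else m
    arr = counts.to_numpy(dtype=float)
    ref = (arr > 0).all(axis=1)
    if not ref.any():
        raise ValueError("no reference genes: every gene has a zero count in some sample")
    logs = np.log(arr[ref])
    log_geomean = logs.mean(axis=1, keepdims=True)
    factors = np.exp(np.median(logs - log_geomean, axis=0))
    return pd.Series(factors, index=counts.columns, name="size_factor")


def normalize(m: CountMatrix | pd.DataFrame, factors: pd.Series | None = None) -> pd.DataFrame:
    """Divide counts column-wise by per-sample size factors.

    Computes median-of-ratios factors when none are given.
    """
    counts = m.counts if isinstance(m, CountMatrix) else m
    if factors is None:
        factors = size_factors(counts)
    if len(factors) != counts.shape[1]:
        raise ValueError("one size factor per sample required")
    factors = pd.Series(factors, index=counts.columns) if not isinstance(factors, pd.Series) else factors
    if (factors <= 0).any():
        raise ValueError("size factors must be positive")
    return counts / factors


def _find_sample(samples: pd.DataFrame, strain: str, timepoint: str, batch: str) -> str:
    hit = samples[
        (samples["strain"] == strain)
        & (samples["timepoint"] == timepoint)
        & (samples["replicate_batch"].astype(str) == str(batch))
    ]
    if len(hit) == 0:
        raise KeyError(f"no sample for strain={strain}, timepoint={timepoint}, batch={batch}")
    if len(hit) > 1:
        raise KeyError(f"multiple samples for strain={strain}, timepoint={timepoint}, batch={batch}")
    return hit.index[0]


def log_ratio(
    norm: pd.DataFrame,
    samples: pd.DataFrame,
    strain: str,
    batch: str,
    contrast: str = "T45/T0",
    pseudocount: float = 1.0,
) -> RatioProfile:
    """Per-gene log2 ratio for one strain x replicate batch contrast.

    ``contrast`` is "T45/T0" or "Tend/T0"; the numerator and denominator are
    the batch's own samples.  A pseudocount bounds ratios when a zero count
    survives the background filter.
    """
    num_tp, den_tp = contrast.split("/")
    num = norm[_find_sample(samples, strain, num_tp, batch)]
    den = norm[_find_sample(samples, strain, den_tp, batch)]
    ratio = np.log2((num + pseudocount) / (den + pseudocount))
    return RatioProfile(strain=strain, replicate_batch=str(batch),
                        contrast=contrast, log2_ratio=ratio.rename("log2_ratio"))


def replicate_qc(
    norm: pd.DataFrame,
    samples: pd.DataFrame | None = None,
    threshold: float = 0.9,
) -> tuple[pd.DataFrame, list[tuple[str, str, float]]]:
    """Pairwise Spearman correlation of samples over genes.

    Returns the symmetric coefficient matrix and the list of flagged pairs:
    same-condition replicate pairs (same strain and timepoint, different
    batches) whose correlation falls below ``threshold`` — in the study only
    one of 49 replicate pairs fell below 0.9.  Without metadata all pairs
    below threshold are flagged.
    """
    if norm.shape[1] < 2:
        raise ValueError("need at least two samples for replicate QC")
    if (norm.nunique(axis=0) <= 1).any():
        bad = norm.columns[(norm.nunique(axis=0) <= 1)].tolist()
        raise ValueError(f"constant column(s), Spearman undefined: {bad}")
    rho = norm.corr(method="spearman")
    flagged: list[tuple[str, str, float]] = []
    cols = list(norm.columns)
    for i, a in enumerate(cols):
        for b in cols[i + 1:]:
            if samples is not None:
                sa, sb = samples.loc[a], samples.loc[b]
                same_cond = (
                    sa["strain"] == sb["strain"]
                    and sa["timepoint"] == sb["timepoint"]
                    and str(sa["replicate_batch"]) != str(sb["replicate_batch"])
                )
                if not same_cond:
                    continue
            if rho.loc[a, b] < threshold:
                flagged.append((a, b, float(rho.loc[a, b])))
    return rho, flagged


def compare_measurements(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """Pearson r and two-sided t-distribution p-value between two per-gene
    measurement vectors (e.g. northern-blot vs RNA-seq T45/T0 ratios)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("vectors must cover the same genes")
    if a.size < 3:
        raise ValueError("need n >= 3")
    if np.std(a) == 0 or np.std(b) == 0:
        raise ValueError("zero variance")
    r, p = stats.pearsonr(a, b)
    return float(r), float(p)
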