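"""Conventional global-scaling normalizers: UQ, RLE and TMM size factors.

These are independent from-scratch implementations of the three count-based
normalizers the spike-in method is compared against:

* **UQ** — per-sample 75th percentile of counts over genes expressed in at
  least one sample, scaled by library size;
* **RLE** — per-sample median of count ratios to the per-gene geometric
  mean, over genes with all-positive counts;
* **TMM** — per-sample weighted mean of gene-wise log2 ratios (M values)
  against a reference sample, after doubly trimming extreme M and extreme
  average abundance (A), with inverse-delta-method-variance weights.

All three return factors renormalized to geometric mean 1; counts are never
modified, only scaled on demand by :func:`normalize_matrix`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .errors import FormatError, SnvSpikeError

DEFAULT_TRIM_M = 0.30
DEFAULT_TRIM_A = 0.05


class CountMatrix:
    """A rectangular gene x sample matrix of non-negative integer counts."""

    def __init__(self, df: pd.DataFrame):
        if df.index.has_duplicates:
            raise SnvSpikeError("duplicate gene ids in count matrix")
        if df.columns.has_duplicates:
            raise SnvSpikeError("duplicate sample ids in count matrix")
        values = df.to_numpy()
        if values.size == 0:
            raise SnvSpikeError("empty count matrix")
        if not np.issubdtype(values.dtype, np.number):
            raise SnvSpikeError("count matrix must be numeric")
        if (values < 0).any():
            raise SnvSpikeError("count matrix has negative entries")
        self.df = df.astype(np.int64) if np.issubdtype(values.dtype, np.integer) \
            else df

    @property
    def genes(self) -> list[str]:
        return list(self.df.index)

    @property
    def samples(self) -> list[str]:
        return list(self.df.columns)

    def library_sizes(self) -> pd.Series:
        return self.df.sum(axis=0)

    def to_tsv(self, path) -> None:
        self.df.to_csv(path, sep="\t", index_label="gene")

    @classmethod
    def from_tsv(cls, path) -> "CountMatrix":
        try:
            df = pd.read_csv(path, sep="\t", index_col=0)
        except Exception as e:  # pragma: no cover - pandas error text varies
            raise FormatError(f"cannot parse count matrix: {e}", str(path)) from e
        return cls(df)


@dataclass
class SizeFactors:
    """Per-sample positive scaling factors (geometric mean 1)."""

    factors: pd.Series
    method: str

    def __post_init__(self):
        if (self.factors <= 0).any():
            raise SnvSpikeError("size factors must be positive")


def _as_matrix(m) -> CountMatrix:
    return m if isinstance(m, CountMatrix) else CountMatrix(pd.DataFrame(m))


def _geomean_one(f: pd.Series, method: str) -> SizeFactors:
    f = f / np.exp(np.log(f).mean())
    return SizeFactors(factors=f, method=method)


def size_factors_uq(m) -> SizeFactors:
    """Upper-quartile size factors."""
    m = _as_matrix(m)
    counts = m.df.to_numpy(dtype=float)
    expressed = counts[counts.sum(axis=1) > 0]
    if expressed.size == 0:
        raise SnvSpikeError("all-zero count matrix")
    libsize = counts.sum(axis=0)
    if (libsize <= 0).any():
        raise SnvSpikeError("sample with zero library size")
    q75 = np.quantile(expressed, 0.75, axis=0)
    if (q75 <= 0).any():
        raise SnvSpikeError("zero upper quartile; too sparse for UQ")
    return _geomean_one(pd.Series(q75 / libsize, index=m.samples), "UQ")


def size_factors_rle(m) -> SizeFactors:
    """Relative-log-expression (median-of-ratios) size factors.

    Genes with a zero in any sample are excluded (their geometric mean is
    undefined at 0).  The per-sample median of count ratios to the per-gene
    geometric mean absorbs sequencing depth; dividing it by library size
    yields a depth-free factor, so ``counts / (libsize x factor)`` equals
    median-of-ratios-normalized counts up to one global constant, on the
    same convention as UQ and TMM.
    """
    m = _as_matrix(m)
    counts = m.df.to_numpy(dtype=float)
    allpos = counts[(counts > 0).all(axis=1)]
    if allpos.size == 0:
        raise SnvSpikeError("no gene with positive counts in every sample")
    log_geomean = np.log(allpos).mean(axis=1, keepdims=True)
    ratios = allpos / np.exp(log_geomean)
    factors = np.median(ratios, axis=0) / counts.sum(axis=0)
    return _geomean_one(pd.Series(factors, index=m.samples), "RLE")


def _tmm_pair(
    obs: np.ndarray, ref: np.ndarray, n_obs: float, n_ref: float,
    trim_m: float, trim_a: float,
) -> float:
    both = (obs > 0) & (ref > 0)
    if not both.any():
        raise SnvSpikeError("no gene expressed in both sample and reference")
    y, r = obs[both], ref[both]
    m_vals = np.log2((y / n_obs) / (r / n_ref))
    a_vals = 0.5 * np.log2((y / n_obs) * (r / n_ref))
    w = 1.0 / (1.0 / y - 1.0 / n_obs + 1.0 / r - 1.0 / n_ref)

    n = m_vals.size
    lo_m = int(np.floor(n * trim_m)) + 1
    hi_m = n + 1 - lo_m
    lo_a = int(np.floor(n * trim_a)) + 1
    hi_a = n + 1 - lo_a
    rank_m = rankdata(m_vals)
    rank_a = rankdata(a_vals)
    keep = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if not keep.any():
        raise SnvSpikeError("no genes survive TMM trimming")
    return float(2 ** (np.sum(m_vals[keep] * w[keep]) / np.sum(w[keep])))


def size_factors_tmm(
    m,
    ref_sample: str = "auto",
    trim_m: float = DEFAULT_TRIM_M,
    trim_a: float = DEFAULT_TRIM_A,
) -> SizeFactors:
    """Trimmed-mean-of-M-values size factors.

    With ``ref_sample="auto"`` the reference is the sample whose upper
    quartile over library size is closest to the mean of that quantity.
    """
    m = _as_matrix(m)
    counts = m.df.to_numpy(dtype=float)
    libsize = counts.sum(axis=0)
    if (libsize <= 0).any():
        raise SnvSpikeError("sample with zero library size")
    if ref_sample == "auto":
        expressed = counts[counts.sum(axis=1) > 0]
        f75 = np.quantile(expressed, 0.75, axis=0) / libsize
        ref_idx = int(np.argmin(np.abs(f75 - f75.mean())))
    else:
        if ref_sample not in m.samples:
            raise SnvSpikeError(f"unknown reference sample {ref_sample!r}")
        ref_idx = m.samples.index(ref_sample)

    factors = np.ones(len(m.samples))
    for j in range(len(m.samples)):
        if j == ref_idx:
            continue
        factors[j] = _tmm_pair(
            counts[:, j], counts[:, ref_idx], libsize[j], libsize[ref_idx],
            trim_m, trim_a,
        )
    return _geomean_one(pd.Series(factors, index=m.samples), "TMM")


def normalize_matrix(m, f: SizeFactors) -> pd.DataFrame:
    """CPM-style normalized values: counts / (libsize x factor) x 1e6.

    Row order is preserved; samples must match the factors' index.
    """
    m = _as_matrix(m)
    if list(f.factors.index) != m.samples:
        raise SnvSpikeError("size-factor samples do not match matrix samples")
    libsize = m.library_sizes().to_numpy(dtype=float)
    scale = libsize * f.factors.to_numpy(dtype=float)
    return m.df / scale * 1e6


def write_factors_tsv(f: SizeFactors, path) -> None:
    with open(path, "w") as fh:
        fh.write("sample\tfactor\tmethod\n")
        for s, v in f.factors.items():
            fh.write(f"{s}\t{v:.10g}\t{f.method}\n")
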