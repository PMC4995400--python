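"""Evaluation statistics: CV, replicate agreement, correlation, coverage
flattening, discordance counts and the housekeeping-gene CV comparison.

All statistics exclude ND values and report the number of items actually
used.  The flattening metric (within-transcript CV of per-locus normalized
values versus CV of raw per-position coverage) is an artifact-defined scalar
for what the source experiments assess visually: if biases are shared by
target and standard, the per-locus ratios should be flat where the raw
coverage is not.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .baselines import (
    CountMatrix,
    normalize_matrix,
    size_factors_rle,
    size_factors_tmm,
    size_factors_uq,
)
from .counting import AlleleCounts
from .discovery import InformativePosition
from .errors import SnvSpikeError
from .normalize import is_nd, locus_ratio
from .pileup import Pileup

DEFAULT_DISCORDANCE_FACTOR = 2.0


def cv(values) -> float:
    """Coefficient of variation as percent: 100 x sample sd (n-1) / mean."""
    arr = np.asarray(list(values), dtype=float)
    if arr.size < 2:
        raise SnvSpikeError("cv requires at least 2 values")
    mean = arr.mean()
    if mean == 0:
        raise SnvSpikeError("cv undefined for zero mean")
    return float(100.0 * arr.std(ddof=1) / mean)


@dataclass(frozen=True)
class AgreementSummary:
    """Mean and CV of per-gene value ratios between two samples."""

    n_genes: int
    mean_ratio: float
    cv: float


def _shared_defined(
    values1: Mapping[str, float], values2: Mapping[str, float]
) -> tuple[list[str], np.ndarray, np.ndarray]:
    keys = [
        k for k in values1
        if k in values2 and not is_nd(values1[k]) and not is_nd(values2[k])
    ]
    v1 = np.array([values1[k] for k in keys], dtype=float)
    v2 = np.array([values2[k] for k in keys], dtype=float)
    return keys, v1, v2


def agreement(
    values1: Mapping[str, float], values2: Mapping[str, float]
) -> AgreementSummary:
    """Per-gene ratio v1/v2 over shared defined genes; mean and CV of the
    ratios."""
    keys, v1, v2 = _shared_defined(values1, values2)
    usable = v2 != 0
    if usable.sum() < 2:
        raise SnvSpikeError("agreement requires >= 2 shared defined genes")
    ratios = v1[usable] / v2[usable]
    return AgreementSummary(
        n_genes=int(usable.sum()),
        mean_ratio=float(ratios.mean()),
        cv=cv(ratios),
    )


def correlation(
    values1: Mapping[str, float],
    values2: Mapping[str, float],
    log_transform: bool = False,
) -> tuple[float, float]:
    """Pearson r and r^2 over shared defined pairs; an optional log10
    transform drops nonpositive pairs first."""
    _, v1, v2 = _shared_defined(values1, values2)
    if log_transform:
        pos = (v1 > 0) & (v2 > 0)
        v1, v2 = np.log10(v1[pos]), np.log10(v2[pos])
    if v1.size < 3:
        raise SnvSpikeError("correlation requires >= 3 shared finite pairs")
    if v1.std() == 0 or v2.std() == 0:
        raise SnvSpikeError("correlation undefined at zero variance")
    r = float(stats.pearsonr(v1, v2).statistic)
    return r, r * r


@dataclass(frozen=True)
class FlatnessReport:
    """Within-transcript CVs of raw coverage vs per-locus normalized values."""

    transcript_id: str
    n_loci: int
    raw_cv: float
    snv_cv: float


def flatten_profile(
    mixed: Pileup,
    positions: Sequence[InformativePosition],
    allele_counts: Sequence[AlleleCounts],
) -> tuple[list[FlatnessReport], pd.DataFrame]:
    """Quantify coverage flattening per transcript.

    ``raw_cv`` is the CV of total per-position depth over all covered
    positions of the transcript; ``snv_cv`` is the CV of defined per-locus
    normalized values.  Transcripts with fewer than 2 usable loci are
    skipped.  Also returns a long-form profile table (position, depth,
    locus ratio) for plotting.
    """
    by_tid: dict[str, list[AlleleCounts]] = {}
    for c in allele_counts:
        by_tid.setdefault(c.transcript_id, []).append(c)

    reports: list[FlatnessReport] = []
    rows: list[tuple] = []
    for tid in sorted(by_tid):
        depth = mixed.depth_array(tid)
        covered = depth[depth > 0]
        ratios = [
            (c.pos0, locus_ratio(c).value) for c in by_tid[tid]
        ]
        defined = [v for _, v in ratios if not is_nd(v)]
        for pos in np.flatnonzero(depth):
            rows.append((tid, int(pos), int(depth[pos]), math.nan))
        for pos, v in ratios:
            rows.append((tid, pos, int(depth[pos]) if pos < depth.size else 0, v))
        if len(defined) < 2 or covered.size < 2:
            continue
        reports.append(
            FlatnessReport(
                transcript_id=tid,
                n_loci=len(defined),
                raw_cv=cv(covered),
                snv_cv=cv(defined),
            )
        )
    profile = pd.DataFrame(
        rows, columns=["transcript", "pos0", "depth", "locus_ratio"]
    )
    return reports, profile


def discordance_count(
    folds1: Mapping[str, float],
    folds2: Mapping[str, float],
    factor: float = DEFAULT_DISCORDANCE_FACTOR,
) -> int:
    """Number of shared defined keys whose two fold estimates differ by
    strictly more than ``factor`` (a 2-fold boundary is not counted)."""
    if factor <= 0:
        raise SnvSpikeError("discordance factor must be > 0")
    _, v1, v2 = _shared_defined(folds1, folds2)
    usable = (v1 > 0) & (v2 > 0)
    v1, v2 = v1[usable], v2[usable]
    return int(np.sum(np.maximum(v1 / v2, v2 / v1) > factor))


@dataclass(frozen=True)
class CvSummary:
    """Five-number summary of a per-gene CV distribution."""

    method: str
    n_genes: int
    minimum: float
    q1: float
    median: float
    q3: float
    maximum: float

    @classmethod
    def from_values(cls, method: str, values: np.ndarray) -> "CvSummary":
        q1, med, q3 = np.percentile(values, [25, 50, 75])
        return cls(method, int(values.size), float(values.min()), float(q1),
                   float(med), float(q3), float(values.max()))


def housekeeping_cv_compare(
    matrix: CountMatrix,
    snv_values: Sequence[Mapping[str, float]],
    hk_genes: Iterable[str],
    methods: Sequence[str] = ("UQ", "RLE", "TMM", "SNV"),
) -> dict[str, CvSummary]:
    """Per-method housekeeping-gene CV distributions across replicates.

    ``matrix`` holds replicate samples as columns (conventional methods
    normalize these counts); ``snv_values`` holds one per-gene mapping of
    SNV-normalized transcript values per replicate.  For each method the
    CV across replicates is computed per housekeeping gene and summarized
    as quartiles and whiskers.  Methods are compared only through their own
    CVs, never through cross-method values.
    """
    hk = list(dict.fromkeys(hk_genes))
    if not hk:
        raise SnvSpikeError("empty housekeeping gene list")
    out: dict[str, CvSummary] = {}
    factor_fns = {
        "UQ": size_factors_uq,
        "RLE": size_factors_rle,
        "TMM": size_factors_tmm,
    }
    for method in methods:
        if method == "SNV":
            if len(snv_values) < 2:
                raise SnvSpikeError("SNV comparison requires >= 2 replicates")
            cvs = []
            for g in hk:
                vals = [rep.get(g, float("nan")) for rep in snv_values]
                if any(is_nd(v) for v in vals):
                    continue
                arr = np.array(vals, dtype=float)
                if arr.mean() > 0:
                    cvs.append(100.0 * arr.std(ddof=1) / arr.mean())
            values = np.array(cvs)
        else:
            if len(matrix.samples) < 2:
                raise SnvSpikeError("conventional comparison requires >= 2 replicates")
            norm = normalize_matrix(matrix, factor_fns[method](matrix))
            shared = [g for g in hk if g in norm.index]
            sub = norm.loc[shared].to_numpy(dtype=float)
            means = sub.mean(axis=1)
            usable = means > 0
            values = 100.0 * sub[usable].std(axis=1, ddof=1) / means[usable]
        if values.size == 0:
            raise SnvSpikeError(
                f"no usable housekeeping genes for method {method!r}"
            )
        out[method] = CvSummary.from_values(method, values)
    return out


# ---------------------------------------------------------------------------
# optional plots
# ---------------------------------------------------------------------------


def plot_flatness(profile: pd.DataFrame, transcript_id: str, path) -> None:
    """Coverage profile with per-locus normalized values for one transcript."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    sub = profile[profile["transcript"] == transcript_id]
    cov = sub[sub["locus_ratio"].isna()]
    loci = sub.dropna(subset=["locus_ratio"])
    fig, ax1 = plt.subplots(figsize=(8, 3))
    ax1.fill_between(cov["pos0"], cov["depth"], color="0.8", label="raw depth")
    ax1.set_xlabel(f"{transcript_id} position (bp)")
    ax1.set_ylabel("read depth")
    ax2 = ax1.twinx()
    ax2.stem(loci["pos0"], loci["locus_ratio"], basefmt=" ")
    ax2.set_ylabel("SNV-normalized value")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def plot_cv_boxes(summaries: Mapping[str, CvSummary], path) -> None:
    """Box-and-whisker plot of per-method housekeeping CV distributions."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    stats_list = [
        {
            "label": s.method,
            "whislo": s.minimum,
            "q1": s.q1,
            "med": s.median,
            "q3": s.q3,
            "whishi": s.maximum,
            "fliers": [],
        }
        for s in summaries.values()
    ]
    ax.bxp(stats_list, showfliers=False)
    ax.set_ylabel("housekeeping-gene CV (%)")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
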