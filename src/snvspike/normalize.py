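"""SNV-normalized expression values and differential expression.

The normalized value of a locus is the human allele count divided by the
chimpanzee allele count; per transcript, counts over all informative loci
are discriminatively summed first and the sums divided (sum-then-divide,
not mean of per-locus ratios).  Because both species' reads of a transcript
share every processing step, any multiplicative per-sample or per-locus
efficiency cancels in the ratio — the core spike-in property.

``ND`` (not determined) is the typed missing value produced whenever a
denominator is zero; it propagates through fold changes and is excluded
from all summary statistics, never coerced to 0 or infinity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping

from .counting import AlleleCounts
from .errors import FormatError, SnvSpikeError

ND = float("nan")
ND_TOKEN = "ND"

DEFAULT_COUNT_CUTOFF = 40


def is_nd(x: float) -> bool:
    """True for the ND (not determined) missing value."""
    return isinstance(x, float) and math.isnan(x)


def _fmt(x: float) -> str:
    return ND_TOKEN if is_nd(x) else f"{x:.6g}"


def _parse_value(s: str) -> float:
    return ND if s == ND_TOKEN else float(s)


@dataclass(frozen=True)
class SnvRatio:
    """An SNV-normalized expression value at locus or transcript scope."""

    transcript_id: str
    n_human: int
    n_chimp: int
    pos0: int | None = None  # None => transcript scope

    @property
    def scope(self) -> str:
        return "transcript" if self.pos0 is None else "locus"

    @property
    def value(self) -> float:
        if self.n_chimp == 0:
            return ND
        return self.n_human / self.n_chimp


@dataclass(frozen=True)
class DiffExpression:
    """Fold change of SNV-normalized values between two samples."""

    transcript_id: str
    ratio_sample1: float
    ratio_sample2: float

    @property
    def fold(self) -> float:
        if is_nd(self.ratio_sample1) or is_nd(self.ratio_sample2):
            return ND
        if self.ratio_sample2 <= 0:
            return ND
        return self.ratio_sample1 / self.ratio_sample2


def locus_ratio(c: AlleleCounts) -> SnvRatio:
    """Per-locus normalized value: n_human / n_chimp (ND when n_chimp = 0)."""
    return SnvRatio(c.transcript_id, c.n_human, c.n_chimp, pos0=c.pos0)


def transcript_ratio(
    counts: Iterable[AlleleCounts], transcript_id: str | None = None
) -> SnvRatio:
    """Sum human and chimp reads over a transcript's informative loci, then
    divide the sums.  An empty locus set yields ND with zero counts (the
    transcript id must then be supplied explicitly)."""
    counts = list(counts)
    if not counts:
        if transcript_id is None:
            raise SnvSpikeError(
                "empty locus set: pass transcript_id to get the ND ratio"
            )
        return SnvRatio(transcript_id, 0, 0, pos0=None)
    tids = {c.transcript_id for c in counts}
    if transcript_id is not None:
        tids.add(transcript_id)
    if len(tids) != 1:
        raise SnvSpikeError(f"loci span multiple transcripts: {sorted(tids)}")
    n_h = sum(c.n_human for c in counts)
    n_c = sum(c.n_chimp for c in counts)
    return SnvRatio(counts[0].transcript_id, n_h, n_c, pos0=None)


def transcript_ratios(counts: Iterable[AlleleCounts]) -> dict[str, SnvRatio]:
    """Group per-locus counts by transcript and compute each sum-then-divide
    ratio; transcript order follows first appearance."""
    grouped: dict[str, list[AlleleCounts]] = {}
    for c in counts:
        grouped.setdefault(c.transcript_id, []).append(c)
    return {tid: transcript_ratio(cc) for tid, cc in grouped.items()}


def apply_cutoff(
    ratios: Iterable[SnvRatio], threshold: int = DEFAULT_COUNT_CUTOFF
) -> list[SnvRatio]:
    """Retain ratios whose human AND chimp summed counts reach the threshold
    (boundary inclusive).  Guards both the numerator and the denominator
    against low-count noise."""
    if threshold < 0:
        raise SnvSpikeError("cutoff threshold must be >= 0")
    return [r for r in ratios if min(r.n_human, r.n_chimp) >= threshold]


def differential_expression(
    r1: Mapping[str, SnvRatio] | Iterable[SnvRatio],
    r2: Mapping[str, SnvRatio] | Iterable[SnvRatio],
) -> list[DiffExpression]:
    """Per-transcript fold of sample-1 over sample-2 normalized values.

    ND propagates; transcripts present on only one side get ND on the
    missing side.  Output is sorted by transcript id.
    """
    d1 = _as_map(r1)
    d2 = _as_map(r2)
    out = []
    for tid in sorted(set(d1) | set(d2)):
        v1 = d1[tid].value if tid in d1 else ND
        v2 = d2[tid].value if tid in d2 else ND
        out.append(DiffExpression(tid, v1, v2))
    return out


def _as_map(r) -> dict[str, SnvRatio]:
    if isinstance(r, Mapping):
        return dict(r)
    out = {}
    for x in r:
        if x.transcript_id in out:
            raise SnvSpikeError(f"duplicate transcript {x.transcript_id!r}")
        out[x.transcript_id] = x
    return out


def unnormalized_fold(
    count1: float, count2: float, libsize1: float, libsize2: float
) -> float:
    """Naive library-size-scaled fold change: (c1/N1)/(c2/N2); ND if c2 = 0."""
    if libsize1 <= 0 or libsize2 <= 0:
        raise SnvSpikeError("library sizes must be > 0")
    if count2 == 0:
        return ND
    return (count1 / libsize1) / (count2 / libsize2)


def rpkm(count: float, transcript_length: int, total_mapped: int) -> float:
    """Reads per kilobase of transcript per million mapped reads."""
    if transcript_length <= 0 or total_mapped <= 0:
        raise SnvSpikeError("length and total_mapped must be > 0")
    return 1e9 * count / (transcript_length * total_mapped)


# ---------------------------------------------------------------------------
# TSV I/O
# ---------------------------------------------------------------------------

RATIO_HEADER = "transcript\tn_human\tn_chimp\tsnv_ratio"
FOLD_HEADER = "transcript\tratio_s1\tratio_s2\tfold"


def write_ratios_tsv(ratios: Iterable[SnvRatio], path) -> None:
    with open(path, "w") as fh:
        fh.write(RATIO_HEADER + "\n")
        for r in ratios:
            fh.write(f"{r.transcript_id}\t{r.n_human}\t{r.n_chimp}\t"
                     f"{_fmt(r.value)}\n")


def read_ratios_tsv(path) -> dict[str, SnvRatio]:
    out: dict[str, SnvRatio] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
        if header != RATIO_HEADER:
            raise FormatError(f"bad ratio header {header!r}", str(path), 1)
        for lineno, line in enumerate(fh, start=2):
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 4:
                raise FormatError("expected 4 tab-separated fields",
                                  str(path), lineno)
            tid, nh, nc, _ = fields
            try:
                out[tid] = SnvRatio(tid, int(nh), int(nc))
            except ValueError as e:
                raise FormatError(str(e), str(path), lineno) from e
    return out


def write_folds_tsv(folds: Iterable[DiffExpression], path) -> None:
    with open(path, "w") as fh:
        fh.write(FOLD_HEADER + "\n")
        for f in folds:
            fh.write(f"{f.transcript_id}\t{_fmt(f.ratio_sample1)}\t"
                     f"{_fmt(f.ratio_sample2)}\t{_fmt(f.fold)}\n")


def read_folds_tsv(path) -> list[DiffExpression]:
    out: list[DiffExpression] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
        if header != FOLD_HEADER:
            raise FormatError(f"bad fold header {header!r}", str(path), 1)
        for lineno, line in enumerate(fh, start=2):
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 4:
                raise FormatError("expected 4 tab-separated fields",
                                  str(path), lineno)
            tid, r1, r2, _ = fields
            try:
                out.append(DiffExpression(tid, _parse_value(r1), _parse_value(r2)))
            except ValueError as e:
                raise FormatError(str(e), str(path), lineno) from e
    return out
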