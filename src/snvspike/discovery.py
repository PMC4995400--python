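"""Discovery of informative interspecies positions from single-species pileups.

An informative position is a transcript coordinate where two independent
human sources (here called HF and HI, after fibroblast and iPSC libraries)
and one chimpanzee source (CL) are each effectively homozygous — major
allele at >= 90% of a column with depth >= 10 — with the two human sources
agreeing and the chimpanzee source differing.  Reads in a spiked mixture can
then be assigned to species by the base they carry at such positions.

Discovery operates directly on pileup columns; for substitution-only data
this is equivalent to variant calling followed by the same depth/frequency
filters, without genotype-likelihood machinery.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable

import numpy as np

from ._codec import BASES
from .errors import FormatError, SnvSpikeError
from .pileup import Pileup, PileupColumn

DEFAULT_MIN_DEPTH = 10
DEFAULT_HOMOZYGOSITY = 0.90

_BED_NAME = re.compile(r"^([ACGT])>([ACGT])$")


@dataclass(frozen=True, order=True)
class InformativePosition:
    """A transcript coordinate with its diagnostic human/chimp alleles."""

    transcript_id: str
    pos0: int
    human_base: str
    chimp_base: str

    def __post_init__(self):
        if self.human_base not in BASES or self.chimp_base not in BASES:
            raise SnvSpikeError(
                f"invalid bases {self.human_base!r}/{self.chimp_base!r}"
            )
        if self.human_base == self.chimp_base:
            raise SnvSpikeError(
                f"human and chimp bases must differ at "
                f"{self.transcript_id}:{self.pos0}"
            )


def major_allele(column: PileupColumn) -> tuple[str, float]:
    """The base with maximal count and its frequency; ties break A<C<G<T."""
    if column.depth == 0:
        raise SnvSpikeError(
            f"major_allele undefined at zero depth "
            f"({column.transcript_id}:{column.pos0})"
        )
    idx = int(np.argmax(column.counts))  # argmax takes the first max: A<C<G<T
    return BASES[idx], column.counts[idx] / column.depth


def passes_homozygosity(
    column: PileupColumn, threshold: float = DEFAULT_HOMOZYGOSITY
) -> bool:
    """True iff the column is covered and its major allele reaches the
    threshold frequency (boundary inclusive, tolerating sequencing error)."""
    if column.depth == 0:
        return False
    _, freq = major_allele(column)
    return freq >= threshold


def find_informative(
    hf: Pileup,
    hi: Pileup,
    cl: Pileup,
    min_depth: int = DEFAULT_MIN_DEPTH,
    homozygosity: float = DEFAULT_HOMOZYGOSITY,
) -> list[InformativePosition]:
    """Scan three single-species pileups for informative positions.

    A position is emitted iff all three columns have depth >= ``min_depth``
    and pass homozygosity, the two human sources share their major allele,
    and the chimpanzee major allele differs from it.
    """
    out: list[InformativePosition] = []
    shared = sorted(set(hf.transcripts()) & set(hi.transcripts()) & set(cl.transcripts()))
    for tid in shared:
        mats = [p._mat[tid] for p in (hf, hi, cl)]
        length = min(m.shape[0] for m in mats)
        depths = [m[:length].sum(axis=1) for m in mats]
        majors = [m[:length].argmax(axis=1) for m in mats]
        maxima = [m[:length].max(axis=1) for m in mats]
        ok = np.ones(length, dtype=bool)
        for d, mx in zip(depths, maxima):
            ok &= d >= max(min_depth, 1)
            # major frequency >= threshold, in integer arithmetic
            ok &= mx >= homozygosity * d
        ok &= majors[0] == majors[1]
        ok &= majors[2] != majors[0]
        for pos in np.flatnonzero(ok):
            out.append(
                InformativePosition(
                    tid, int(pos), BASES[majors[0][pos]], BASES[majors[2][pos]]
                )
            )
    return out


def write_informative_bed(positions: Iterable[InformativePosition], path) -> None:
    """Write positions as 0-based half-open BED with ``HUMAN>CHIMP`` names."""
    with open(path, "w") as fh:
        for p in sorted(positions):
            fh.write(f"{p.transcript_id}\t{p.pos0}\t{p.pos0 + 1}\t"
                     f"{p.human_base}>{p.chimp_base}\n")


def read_informative_bed(path) -> list[InformativePosition]:
    """Parse an informative-position BED; malformed rows raise with line numbers."""
    out: list[InformativePosition] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise FormatError("expected 4 BED fields", str(path), lineno)
            tid, start_s, end_s, name = fields[:4]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as e:
                raise FormatError(str(e), str(path), lineno) from e
            if end != start + 1 or start < 0:
                raise FormatError(
                    f"informative position must span one base, got "
                    f"[{start}, {end})", str(path), lineno,
                )
            m = _BED_NAME.match(name)
            if not m:
                raise FormatError(
                    f"name field must be HUMANBASE>CHIMPBASE, got {name!r}",
                    str(path), lineno,
                )
            if m.group(1) == m.group(2):
                raise FormatError(
                    f"human and chimp bases must differ, got {name!r}",
                    str(path), lineno,
                )
            out.append(InformativePosition(tid, start, m.group(1), m.group(2)))
    return out
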