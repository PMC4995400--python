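"""Species-resolved allele counting at informative positions of a mixed sample.

Classification is per position, not per read: a read overlapping k
informative positions contributes k allele observations.  Bases matching
neither diagnostic allele are tallied as ``n_other`` (sequencing errors) and
excluded from all downstream ratios.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from ._codec import BASES
from .discovery import InformativePosition
from .errors import FormatError
from .pileup import Pileup

COUNTS_HEADER = (
    "transcript\tpos0\thuman_base\tchimp_base\tn_human\tn_chimp\tn_other"
)


@dataclass(frozen=True)
class AlleleCounts:
    """Human/chimp/other read tallies at one informative position."""

    transcript_id: str
    pos0: int
    human_base: str
    chimp_base: str
    n_human: int
    n_chimp: int
    n_other: int

    @property
    def depth(self) -> int:
        return self.n_human + self.n_chimp + self.n_other


def count_alleles(
    mixed: Pileup, positions: Iterable[InformativePosition]
) -> list[AlleleCounts]:
    """Count diagnostic alleles at each informative position of a mixed pileup.

    Positions with no coverage (including transcripts absent from the
    pileup) yield (0, 0, 0).
    """
    out: list[AlleleCounts] = []
    for p in positions:
        mat = mixed._mat.get(p.transcript_id)
        if mat is None or p.pos0 >= mat.shape[0]:
            counts = (0, 0, 0, 0)
        else:
            counts = tuple(int(c) for c in mat[p.pos0])
        hi = BASES.index(p.human_base)
        ci = BASES.index(p.chimp_base)
        n_h = counts[hi]
        n_c = counts[ci]
        n_o = sum(counts) - n_h - n_c
        out.append(
            AlleleCounts(p.transcript_id, p.pos0, p.human_base, p.chimp_base,
                         n_h, n_c, n_o)
        )
    return out


def write_counts_tsv(counts: Sequence[AlleleCounts], path) -> None:
    with open(path, "w") as fh:
        fh.write(COUNTS_HEADER + "\n")
        for c in counts:
            fh.write(
                f"{c.transcript_id}\t{c.pos0}\t{c.human_base}\t{c.chimp_base}"
                f"\t{c.n_human}\t{c.n_chimp}\t{c.n_other}\n"
            )


def read_counts_tsv(path) -> list[AlleleCounts]:
    out: list[AlleleCounts] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
        if header != COUNTS_HEADER:
            raise FormatError(f"bad counts header {header!r}", str(path), 1)
        for lineno, line in enumerate(fh, start=2):
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 7:
                raise FormatError("expected 7 tab-separated fields",
                                  str(path), lineno)
            tid, pos_s, hb, cb, nh, nc, no = fields
            try:
                out.append(AlleleCounts(tid, int(pos_s), hb, cb,
                                        int(nh), int(nc), int(no)))
            except ValueError as e:
                raise FormatError(str(e), str(path), lineno) from e
    return out
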