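"""Per-position base-count pileups built directly from read placements.

This replaces the external ``samtools mpileup`` step: with the simulator's
ungapped, unambiguous placements there is no CIGAR, mapping-quality or depth
cap to honor, so a pileup is simply the per-position tally of observed read
bases over each transcript.  Coordinates are 0-based throughout; columns
with zero depth are omitted on output.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator, Mapping, Union

import numpy as np

from ._codec import BASES, encode
from .errors import FormatError, SnvSpikeError
from .simulate import Placement, ReadSet

PILEUP_HEADER = "transcript\tpos0\tA\tC\tG\tT"


@dataclass(frozen=True)
class PileupColumn:
    """Base counts for one transcript position of one sample source."""

    transcript_id: str
    pos0: int
    counts: tuple[int, int, int, int]  # A, C, G, T

    @property
    def depth(self) -> int:
        return int(sum(self.counts))

    def count(self, base: str) -> int:
        return self.counts[BASES.index(base)]

    def as_dict(self) -> dict[str, int]:
        return dict(zip(BASES, self.counts))


class Pileup:
    """Base-count matrices keyed by transcript.

    Internally one ``(length, 4)`` int64 array per covered transcript;
    reference lengths bound the coordinate space.
    """

    def __init__(self, ref_lengths: Mapping[str, int]):
        self.ref_lengths = dict(ref_lengths)
        self._mat: dict[str, np.ndarray] = {}

    # ---- accumulation ---------------------------------------------------

    def matrix(self, transcript_id: str) -> np.ndarray:
        if transcript_id not in self.ref_lengths:
            raise SnvSpikeError(f"unknown transcript {transcript_id!r}")
        if transcript_id not in self._mat:
            self._mat[transcript_id] = np.zeros(
                (self.ref_lengths[transcript_id], 4), dtype=np.int64
            )
        return self._mat[transcript_id]

    def add_read(self, transcript_id: str, start0: int, codes: np.ndarray) -> None:
        mat = self.matrix(transcript_id)
        end = start0 + len(codes)
        if start0 < 0 or end > mat.shape[0]:
            raise SnvSpikeError(
                f"read at {transcript_id}:{start0} (length {len(codes)}) "
                f"exceeds transcript length {mat.shape[0]}"
            )
        np.add.at(mat, (np.arange(start0, end), codes), 1)

    # ---- queries --------------------------------------------------------

    def transcripts(self) -> list[str]:
        return sorted(self._mat)

    def column(self, transcript_id: str, pos0: int) -> PileupColumn:
        mat = self._mat.get(transcript_id)
        if mat is None or not 0 <= pos0 < mat.shape[0]:
            return PileupColumn(transcript_id, pos0, (0, 0, 0, 0))
        return PileupColumn(transcript_id, pos0, tuple(int(c) for c in mat[pos0]))

    def depth_array(self, transcript_id: str) -> np.ndarray:
        mat = self._mat.get(transcript_id)
        if mat is None:
            return np.zeros(self.ref_lengths.get(transcript_id, 0), dtype=np.int64)
        return mat.sum(axis=1)

    def columns(self) -> Iterator[PileupColumn]:
        """Yield covered columns, ordered by transcript id then position."""
        for tid in self.transcripts():
            mat = self._mat[tid]
            for pos in np.flatnonzero(mat.sum(axis=1)):
                yield PileupColumn(tid, int(pos), tuple(int(c) for c in mat[pos]))

    def total_base_count(self) -> int:
        return int(sum(m.sum() for m in self._mat.values()))

    def __eq__(self, other) -> bool:
        if not isinstance(other, Pileup):
            return NotImplemented
        keys = set(self._mat) | set(other._mat)
        for tid in keys:
            a = self._mat.get(tid)
            b = other._mat.get(tid)
            if a is None:
                a = np.zeros_like(b)
            if b is None:
                b = np.zeros_like(a)
            if a.shape != b.shape or not np.array_equal(a, b):
                return False
        return True

    # ---- I/O ------------------------------------------------------------

    def write_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(PILEUP_HEADER + "\n")
            for tid in self.transcripts():
                mat = self._mat[tid]
                for pos in np.flatnonzero(mat.sum(axis=1)):
                    a, c, g, t = (int(x) for x in mat[pos])
                    fh.write(f"{tid}\t{pos}\t{a}\t{c}\t{g}\t{t}\n")

    @classmethod
    def read_tsv(cls, path, ref_lengths: Mapping[str, int] | None = None) -> "Pileup":
        rows: dict[str, list[tuple[int, tuple[int, int, int, int]]]] = {}
        with open(path) as fh:
            header = fh.readline().rstrip("\n")
            if header != PILEUP_HEADER:
                raise FormatError(f"bad pileup header {header!r}", str(path), 1)
            for lineno, line in enumerate(fh, start=2):
                fields = line.rstrip("\n").split("\t")
                if len(fields) != 6:
                    raise FormatError(
                        "expected 6 tab-separated fields", str(path), lineno
                    )
                tid = fields[0]
                try:
                    pos = int(fields[1])
                    counts = tuple(int(x) for x in fields[2:])
                except ValueError as e:
                    raise FormatError(str(e), str(path), lineno) from e
                if pos < 0 or any(c < 0 for c in counts):
                    raise FormatError("negative position or count", str(path), lineno)
                rows.setdefault(tid, []).append((pos, counts))
        if ref_lengths is None:
            ref_lengths = {
                tid: max(p for p, _ in rr) + 1 for tid, rr in rows.items()
            }
        pu = cls(ref_lengths)
        for tid, rr in rows.items():
            mat = pu.matrix(tid)
            for pos, counts in rr:
                if pos >= mat.shape[0]:
                    raise FormatError(
                        f"position {pos} beyond length of {tid}", str(path)
                    )
                mat[pos] += np.array(counts, dtype=np.int64)
        return pu


PlacementsLike = Union[ReadSet, Iterable[Placement]]


def _ref_lengths(reference) -> dict[str, int]:
    # accepts Transcriptome, {id: sequence-str}, or {id: length}
    if hasattr(reference, "as_length_map"):
        return reference.as_length_map()
    out = {}
    for tid, val in reference.items():
        out[tid] = val if isinstance(val, int) else len(val)
    return out


def build_pileup(placements: PlacementsLike, reference) -> Pileup:
    """Tally observed read bases per position over the reference.

    ``reference`` supplies transcript lengths (a :class:`Transcriptome`, a
    mapping id -> sequence, or id -> length); bases are counted from the
    reads themselves, so substituted bases land where they were observed.
    """
    pu = Pileup(_ref_lengths(reference))
    if isinstance(placements, ReadSet):
        _accumulate_readset(pu, placements)
        return pu
    for p in placements:
        pu.add_read(p.transcript, p.start0, encode(p.seq))
    return pu


def _accumulate_readset(pu: Pileup, reads: ReadSet) -> None:
    rl = reads.read_length
    order = np.argsort(reads.transcript_idx, kind="stable")
    t_sorted = reads.transcript_idx[order]
    bounds = np.flatnonzero(np.diff(t_sorted)) + 1
    groups = np.split(order, bounds)
    offsets = np.arange(rl)
    for grp in groups:
        if grp.size == 0:
            continue
        tid = reads.transcript_ids[reads.transcript_idx[grp[0]]]
        mat = pu.matrix(tid)
        length = mat.shape[0]
        starts = reads.start0[grp]
        if starts.min() < 0 or int(starts.max()) + rl > length:
            raise SnvSpikeError(
                f"read placement exceeds transcript length on {tid!r}"
            )
        pos = starts[:, None] + offsets
        flat = pos.astype(np.int64) * 4 + reads.bases[grp]
        mat += np.bincount(flat.ravel(), minlength=length * 4).reshape(length, 4)


def merge_pileups(p1: Pileup, p2: Pileup) -> Pileup:
    """Element-wise sum of two pileups over the same reference."""
    for tid in set(p1.ref_lengths) & set(p2.ref_lengths):
        if p1.ref_lengths[tid] != p2.ref_lengths[tid]:
            raise SnvSpikeError(f"reference length mismatch for {tid!r}")
    merged = Pileup({**p2.ref_lengths, **p1.ref_lengths})
    for src in (p1, p2):
        for tid, mat in src._mat.items():
            merged.matrix(tid)[:] += mat
    return merged


def placements_from_sam(path, sample: str = "S") -> list[Placement]:
    """Read ungapped single-end alignments from a SAM file as placements.

    Convenience for externally aligned reads; alignments whose CIGAR is not
    a single match run are rejected (this model has no indels or clipping).
    """
    import pysam

    out: list[Placement] = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for aln in sam:
            if aln.is_unmapped:
                continue
            cig = aln.cigartuples
            if cig is None or len(cig) != 1 or cig[0][0] != 0:
                raise FormatError(
                    f"gapped or clipped alignment for read {aln.query_name!r}; "
                    "only ungapped placements are supported",
                    str(path),
                )
            out.append(
                Placement(
                    aln.query_name,
                    "unknown",
                    aln.reference_name,
                    aln.reference_start,
                    aln.query_length,
                    aln.query_sequence.upper(),
                )
            )
    return out
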