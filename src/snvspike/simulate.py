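"""Simulator of paired human/chimpanzee transcriptomes and spiked RNA-seq reads.

The spike-in design under study mixes chimpanzee RNA (the internal standard)
into human samples before library preparation, so that every downstream bias
— positional preference of library chemistry, 3'-ward enrichment after
partial degradation, sequencing depth — acts identically on both species'
molecules of the same transcript.  This module generates that world with
full ground truth:

* a human transcriptome and a chimpanzee counterpart differing only by
  homozygous single-nucleotide substitutions placed Bernoulli(snv_rate) per
  base (about one per 210 bp by default, matching the human/chimp divergence
  the method exploits);
* log-normal relative abundances, with optional per-gene fold changes
  between samples A and B, and a shared-batch spike profile;
* single-end read placements drawn from a multinomial over
  (species, transcript, start) cells whose weights combine molar abundance,
  a positional bias profile and an exponential 3'-degradation survival term;
* uniform base-call errors at a configurable substitution rate.

Everything is driven by one ``numpy`` Generator per operation so that equal
seeds give byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Callable, Iterator, NamedTuple

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from ._codec import BASES, decode, encode
from .errors import ConfigError

HUMAN, CHIMP = 0, 1
SPECIES_NAMES = ("human", "chimp")

# ---------------------------------------------------------------------------
# positional bias profiles
# ---------------------------------------------------------------------------


def _bias_uniform(x: np.ndarray) -> np.ndarray:
    return np.ones_like(x)


def _bias_hexamer_like(x: np.ndarray) -> np.ndarray:
    # random-hexamer priming chemistry: mid-body hump, depleted ends
    return 0.3 + 1.4 * np.exp(-0.5 * ((x - 0.5) / 0.15) ** 2)


def _bias_nextera_like(x: np.ndarray) -> np.ndarray:
    # tagmentation-style chemistry: mild 5' ramp
    return 0.4 + 1.2 * (1.0 - x)


BIAS_PROFILES: dict[str, Callable[[np.ndarray], np.ndarray]] = {
    "uniform": _bias_uniform,
    "hexamer-like": _bias_hexamer_like,
    "nextera-like": _bias_nextera_like,
}


def degradation_weight(d, rate: float):
    """Survival probability of a fragment whose 3' side lies ``d`` bp from
    the transcript 3' end, under per-bp cut rate ``rate``.

    Oligo-dT capture requires an intact path from the fragment to the poly-A
    tail, so the fragment survives selection only if none of the ``d``
    downstream bases was cut: ``exp(-rate * d)``.
    """
    d = np.asarray(d, dtype=float)
    if (d < 0).any():
        raise ValueError("distance to 3' end must be >= 0")
    if rate < 0:
        raise ValueError("degradation rate must be >= 0")
    return np.exp(-rate * d)


def degradation_rate_for_loss(loss_fraction: float, length: float) -> float:
    """Per-bp cut rate at which a ``length``-bp 5'-terminal fragment loses
    oligo-dT capture with probability ``loss_fraction``."""
    if not 0 <= loss_fraction < 1:
        raise ValueError("loss_fraction must be in [0, 1)")
    return -math.log(1.0 - loss_fraction) / float(length)


# ---------------------------------------------------------------------------
# configuration and truth containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SimConfig:
    """Study-condition knobs for one simulated experiment.

    Defaults mirror the spike-in study's conditions: ~1 SNV per 210 bp of
    human/chimp divergence, 150-bp reads, a 1:1 (mass) chimpanzee spike from
    a single batch, log-normal expression and a typical Illumina-like
    substitution error rate.
    """

    n_transcripts: int = 200
    length_dist: tuple[float, float] = (2000.0, 700.0)  # mean, sd in bp
    snv_rate: float = 1.0 / 210.0
    expression_dist: tuple[float, float] = (0.0, 1.0)  # lognormal mu, sigma
    de_spec: tuple[tuple[int, float], ...] = ()  # (gene index, fold B/A)
    spike_fraction: float = 1.0  # chimp:human mass ratio
    total_reads: int = 200_000
    read_length: int = 150
    error_rate: float = 0.005
    bias_profile: str = "uniform"
    degradation_rate: float = 0.0  # per-bp cut probability
    spike_profile: str = "match_A"  # "match_A" | "lognormal"
    seed: int = 0

    def __post_init__(self):
        if not 0 <= self.snv_rate < 1:
            raise ConfigError("snv_rate must be in [0, 1)")
        if self.spike_fraction < 0:
            raise ConfigError("spike_fraction must be >= 0")
        if not 0 <= self.error_rate < 0.5:
            raise ConfigError("error_rate must be in [0, 0.5)")
        for name in ("n_transcripts", "total_reads", "read_length"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be > 0")
        if self.bias_profile not in BIAS_PROFILES:
            raise ConfigError(
                f"unknown bias_profile {self.bias_profile!r}; "
                f"choose from {sorted(BIAS_PROFILES)}"
            )
        if self.spike_profile not in ("match_A", "lognormal"):
            raise ConfigError("spike_profile must be 'match_A' or 'lognormal'")
        if self.degradation_rate < 0:
            raise ConfigError("degradation_rate must be >= 0")

    def replace(self, **kw) -> "SimConfig":
        return dataclasses.replace(self, **kw)


@dataclass
class Transcriptome:
    """An ordered set of transcript sequences (uint8-coded internally)."""

    ids: list[str]
    seqs: list[np.ndarray]

    @property
    def lengths(self) -> np.ndarray:
        return np.array([len(s) for s in self.seqs], dtype=np.int64)

    def sequence(self, transcript_id: str) -> str:
        return decode(self.seqs[self.ids.index(transcript_id)])

    def as_length_map(self) -> dict[str, int]:
        return {t: len(s) for t, s in zip(self.ids, self.seqs)}

    def to_fasta(self, path) -> None:
        records = (
            SeqRecord(Seq(decode(s)), id=t, description="")
            for t, s in zip(self.ids, self.seqs)
        )
        SeqIO.write(records, str(path), "fasta")

    @classmethod
    def from_fasta(cls, path) -> "Transcriptome":
        ids, seqs = [], []
        for rec in SeqIO.parse(str(path), "fasta"):
            ids.append(rec.id)
            seqs.append(encode(str(rec.seq)))
        return cls(ids, seqs)


@dataclass
class SimTruth:
    """Ground truth of one simulated transcriptome pair.

    ``snv_positions`` maps transcript id to a list of
    ``(pos0, human_base, chimp_base)`` tuples; abundances are relative molar
    quantities (arbitrary scale); ``fold_changes[g]`` is exactly
    ``abundance_B[g] / abundance_A[g]``.
    """

    ids: list[str]
    snv_positions: dict[str, list[tuple[int, str, str]]]
    abundance_A: np.ndarray
    abundance_B: np.ndarray
    abundance_spike: np.ndarray
    fold_changes: np.ndarray

    def n_snvs(self) -> np.ndarray:
        return np.array([len(self.snv_positions[t]) for t in self.ids])

    def write_snv_bed(self, path) -> None:
        with open(path, "w") as fh:
            for t in self.ids:
                for pos, hb, cb in self.snv_positions[t]:
                    fh.write(f"{t}\t{pos}\t{pos + 1}\t{hb}>{cb}\n")

    def write_tables(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(
                "transcript\tn_snvs\tabundance_A\tabundance_B\t"
                "abundance_spike\tfold_change\n"
            )
            for i, t in enumerate(self.ids):
                fh.write(
                    f"{t}\t{len(self.snv_positions[t])}\t"
                    f"{self.abundance_A[i]:.6g}\t{self.abundance_B[i]:.6g}\t"
                    f"{self.abundance_spike[i]:.6g}\t{self.fold_changes[i]:.6g}\n"
                )


@dataclass
class MixtureWeights:
    """Per-(species, transcript) molar sampling weights for one spiked sample."""

    sample: str
    human: np.ndarray
    chimp: np.ndarray


class Placement(NamedTuple):
    """One read placed on a transcript, with its truth origin."""

    read_id: str
    species: str  # "human" | "chimp"
    transcript: str
    start0: int
    length: int
    seq: str


@dataclass
class ReadSet:
    """Column-oriented container of simulated read placements.

    Each row carries its truth origin (species, transcript, 0-based start)
    alongside the possibly error-bearing base calls.
    """

    transcript_ids: list[str]
    species: np.ndarray  # uint8: 0 human, 1 chimp
    transcript_idx: np.ndarray  # int32 index into transcript_ids
    start0: np.ndarray  # int32
    bases: np.ndarray  # (n_reads, read_length) uint8
    sample: str = "S"

    def __len__(self) -> int:
        return len(self.species)

    @property
    def read_length(self) -> int:
        return self.bases.shape[1]

    def read_id(self, i: int) -> str:
        return f"{self.sample}.r{i:08d}"

    def __iter__(self) -> Iterator[Placement]:
        for i in range(len(self)):
            yield Placement(
                self.read_id(i),
                SPECIES_NAMES[self.species[i]],
                self.transcript_ids[self.transcript_idx[i]],
                int(self.start0[i]),
                self.read_length,
                decode(self.bases[i]),
            )

    # ---- I/O ------------------------------------------------------------

    def write_placements_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("read_id\tspecies\ttranscript\tstart0\tlength\tseq\n")
            for p in self:
                fh.write(
                    f"{p.read_id}\t{p.species}\t{p.transcript}\t"
                    f"{p.start0}\t{p.length}\t{p.seq}\n"
                )

    def write_fastq(self, path, error_rate: float = 0.0) -> None:
        # constant Sanger-scaled quality implied by the substitution rate
        q = 40 if error_rate <= 0 else min(40, round(-10 * math.log10(error_rate)))
        qline = chr(q + 33) * self.read_length
        with open(path, "w") as fh:
            for i in range(len(self)):
                fh.write(
                    f"@{self.read_id(i)}\n{decode(self.bases[i])}\n+\n{qline}\n"
                )


def read_placements_tsv(path) -> list[Placement]:
    """Read a placements TSV back into row records (toy/CLI scale)."""
    from .errors import FormatError

    out: list[Placement] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
        expected = "read_id\tspecies\ttranscript\tstart0\tlength\tseq"
        if header != expected:
            raise FormatError(f"bad placements header {header!r}", str(path), 1)
        for lineno, line in enumerate(fh, start=2):
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 6:
                raise FormatError("expected 6 tab-separated fields", str(path), lineno)
            rid, sp, tx, s0, ln, seq = fields
            try:
                out.append(Placement(rid, sp, tx, int(s0), int(ln), seq))
            except ValueError as e:
                raise FormatError(str(e), str(path), lineno) from e
    return out


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------


def gen_transcriptome(
    config: SimConfig,
) -> tuple[Transcriptome, Transcriptome, SimTruth]:
    """Generate the paired references and full ground truth.

    The chimpanzee sequence of each transcript differs from the human one at
    exactly the truth SNV positions (substitutions only); transcripts drawn
    shorter than one read length are rejected and redrawn.
    """
    rng = np.random.default_rng([config.seed, 1])
    mean_len, sd_len = config.length_dist
    mu, sigma = config.expression_dist

    ids: list[str] = []
    human_seqs: list[np.ndarray] = []
    chimp_seqs: list[np.ndarray] = []
    snv_positions: dict[str, list[tuple[int, str, str]]] = {}

    for g in range(config.n_transcripts):
        length = 0
        while length < config.read_length:
            length = int(round(rng.normal(mean_len, sd_len)))
        tid = f"tx{g + 1:05d}"
        hseq = rng.integers(0, 4, size=length).astype(np.uint8)
        cseq = hseq.copy()
        snvs: list[tuple[int, str, str]] = []
        if config.snv_rate > 0:
            pos = np.flatnonzero(rng.random(length) < config.snv_rate)
            if pos.size:
                shift = rng.integers(1, 4, size=pos.size).astype(np.uint8)
                cseq[pos] = (hseq[pos] + shift) % 4
                snvs = [
                    (int(p), BASES[hseq[p]], BASES[cseq[p]]) for p in pos
                ]
        ids.append(tid)
        human_seqs.append(hseq)
        chimp_seqs.append(cseq)
        snv_positions[tid] = snvs

    abundance_A = rng.lognormal(mu, sigma, size=config.n_transcripts)
    fold = np.ones(config.n_transcripts)
    for gene_idx, fc in config.de_spec:
        if not 0 <= gene_idx < config.n_transcripts:
            raise ConfigError(f"de_spec gene index {gene_idx} out of range")
        if fc <= 0:
            raise ConfigError("de_spec fold changes must be > 0")
        fold[gene_idx] = fc
    abundance_B = abundance_A * fold
    if config.spike_profile == "match_A":
        abundance_spike = abundance_A.copy()
    else:
        abundance_spike = rng.lognormal(mu, sigma, size=config.n_transcripts)

    truth = SimTruth(
        ids=ids,
        snv_positions=snv_positions,
        abundance_A=abundance_A,
        abundance_B=abundance_B,
        abundance_spike=abundance_spike,
        fold_changes=fold,
    )
    return Transcriptome(ids, human_seqs), Transcriptome(ids, chimp_seqs), truth


def gen_mixture(truth: SimTruth, config: SimConfig, sample: str) -> MixtureWeights:
    """Molar sampling weights for one spiked sample (``"A"`` or ``"B"``).

    Equal amounts of each human sample are analyzed (human weights are
    normalized to total 1), and the chimpanzee standard comes from one batch
    shared by every sample: its per-transcript weights are identical between
    A and B and its total is ``spike_fraction`` times the human total.
    """
    if sample not in ("A", "B"):
        raise ConfigError(f"sample must be 'A' or 'B', got {sample!r}")
    human = (truth.abundance_A if sample == "A" else truth.abundance_B).astype(float)
    human = human / human.sum()
    spike = truth.abundance_spike.astype(float)
    total_spike = spike.sum()
    if total_spike <= 0 or config.spike_fraction == 0:
        chimp = np.zeros_like(spike)
    else:
        chimp = spike * (config.spike_fraction / total_spike)
    return MixtureWeights(sample=sample, human=human, chimp=chimp)


def start_weights(length: int, config: SimConfig) -> np.ndarray:
    """Unnormalized sampling weight for each valid read start on a transcript.

    Combines the positional bias profile (a function of relative start
    position) with the 3'-degradation survival term for the fragment's
    distance to the transcript 3' end.
    """
    n_starts = length - config.read_length + 1
    if n_starts <= 0:
        raise ConfigError("transcript shorter than read length")
    starts = np.arange(n_starts)
    x = starts / max(n_starts - 1, 1)
    w = BIAS_PROFILES[config.bias_profile](x.astype(float))
    if config.degradation_rate > 0:
        d = length - (starts + config.read_length)
        w = w * degradation_weight(d, config.degradation_rate)
    return w


def sample_reads(
    references: tuple[Transcriptome, Transcriptome],
    weights: MixtureWeights,
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> ReadSet:
    """Draw exactly ``config.total_reads`` single-end reads from the mixture.

    Start positions are multinomial over (species, transcript, start) cells
    with weight mixture x bias x degradation survival; each base is then
    substituted independently with probability ``config.error_rate`` to a
    uniformly chosen different base.  Every read keeps its truth origin.
    """
    human_ref, chimp_ref = references
    if human_ref.ids != chimp_ref.ids:
        raise ConfigError("human and chimp references must share transcript ids")
    if rng is None:
        rng = np.random.default_rng(
            [config.seed, 2, {"A": 1, "B": 2}.get(weights.sample, 99)]
        )
    n = len(human_ref.ids)
    rl = config.read_length

    svecs = [start_weights(len(s), config) for s in human_ref.seqs]
    stot = np.array([v.sum() for v in svecs])
    cell = np.empty((2, n))
    cell[HUMAN] = weights.human * stot
    cell[CHIMP] = weights.chimp * stot
    total_w = cell.sum()
    if total_w <= 0:
        raise ConfigError("all sampling weights are zero")
    counts = rng.multinomial(config.total_reads, (cell / total_w).ravel()).reshape(2, n)

    total = config.total_reads
    species = np.empty(total, dtype=np.uint8)
    t_idx = np.empty(total, dtype=np.int32)
    start0 = np.empty(total, dtype=np.int32)
    bases = np.empty((total, rl), dtype=np.uint8)

    offsets = np.arange(rl)
    out = 0
    for sp in (HUMAN, CHIMP):
        seqs = human_ref.seqs if sp == HUMAN else chimp_ref.seqs
        for t in range(n):
            c = int(counts[sp, t])
            if c == 0:
                continue
            v = svecs[t]
            per_start = rng.multinomial(c, v / v.sum())
            starts = np.repeat(
                np.arange(v.size, dtype=np.int32), per_start
            )
            block = seqs[t][starts[:, None] + offsets]
            if config.error_rate > 0:
                mask = rng.random(block.shape) < config.error_rate
                k = int(mask.sum())
                if k:
                    block[mask] = (
                        block[mask] + rng.integers(1, 4, size=k).astype(np.uint8)
                    ) % 4
            sl = slice(out, out + c)
            species[sl] = sp
            t_idx[sl] = t
            start0[sl] = starts
            bases[sl] = block
            out += c
    assert out == total
    return ReadSet(
        transcript_ids=list(human_ref.ids),
        species=species,
        transcript_idx=t_idx,
        start0=start0,
        bases=bases,
        sample=weights.sample,
    )


def expected_informative_depth(
    references: tuple[Transcriptome, Transcriptome],
    truth: SimTruth,
    weights: MixtureWeights,
    config: SimConfig,
) -> tuple[np.ndarray, np.ndarray]:
    """Expected per-transcript summed read depth over truth SNV positions,
    for each species, at ``config.total_reads`` total reads.

    The expectation of the depth at position p is the total read count times
    the summed sampling probability of starts covering p; summing over a
    transcript's informative loci gives the expected discriminatively-summed
    allele count used by the per-transcript SNV ratio.  Useful for Poisson
    technical-replicate resampling without a full read draw.
    """
    human_ref, _ = references
    n = len(human_ref.ids)
    rl = config.read_length
    svecs = [start_weights(len(s), config) for s in human_ref.seqs]
    stot = np.array([v.sum() for v in svecs])
    total_w = (weights.human * stot).sum() + (weights.chimp * stot).sum()
    exp_h = np.zeros(n)
    exp_c = np.zeros(n)
    for t, tid in enumerate(human_ref.ids):
        snvs = truth.snv_positions[tid]
        if not snvs:
            continue
        v = svecs[t]
        cum = np.concatenate(([0.0], np.cumsum(v)))
        cov = 0.0
        for pos, _, _ in snvs:
            lo = max(0, pos - rl + 1)
            hi = min(v.size - 1, pos)
            if hi >= lo:
                cov += cum[hi + 1] - cum[lo]
        exp_h[t] = weights.human[t] * cov
        exp_c[t] = weights.chimp[t] * cov
    scale = config.total_reads / total_w
    return exp_h * scale, exp_c * scale
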