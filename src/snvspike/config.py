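"""Pipeline configuration, the end-to-end runner and format validation.

The pipeline chains the stages on a simulated experiment:
simulate -> pileup -> discover -> count -> normalize -> evaluate,
writing every intermediate as headered TSV (plus FASTA/BED/FASTQ where those
are the natural formats) and a JSON manifest recording parameters, seed and
output digests.  One seed determines every stochastic choice.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .baselines import CountMatrix
from .counting import count_alleles, write_counts_tsv
from .discovery import (
    DEFAULT_HOMOZYGOSITY,
    DEFAULT_MIN_DEPTH,
    find_informative,
    read_informative_bed,
    write_informative_bed,
)
from .errors import ConfigError, FormatError
from .evaluate import DEFAULT_DISCORDANCE_FACTOR, flatten_profile
from .normalize import (
    DEFAULT_COUNT_CUTOFF,
    apply_cutoff,
    differential_expression,
    transcript_ratios,
    write_folds_tsv,
    write_ratios_tsv,
)
from .pileup import Pileup, build_pileup
from .simulate import MixtureWeights, SimConfig, gen_mixture, gen_transcriptome, sample_reads

log = logging.getLogger("snvspike")


@dataclass(frozen=True)
class PipelineConfig:
    """Parameters of a full pipeline run; unknown YAML keys are rejected."""

    simulate: SimConfig = field(default_factory=SimConfig)
    min_depth: int = DEFAULT_MIN_DEPTH
    homozygosity_threshold: float = DEFAULT_HOMOZYGOSITY
    count_cutoff: int = DEFAULT_COUNT_CUTOFF
    discordance_factor: float = DEFAULT_DISCORDANCE_FACTOR
    seed: int | None = None  # overrides simulate.seed when set
    log_level: str = "INFO"

    def __post_init__(self):
        if self.min_depth < 1:
            raise ConfigError("min_depth must be >= 1")
        if not 0.5 < self.homozygosity_threshold <= 1:
            raise ConfigError("homozygosity_threshold must be in (0.5, 1]")
        if self.count_cutoff < 0:
            raise ConfigError("count_cutoff must be >= 0")
        if self.discordance_factor <= 0:
            raise ConfigError("discordance_factor must be > 0")

    def effective_sim(self) -> SimConfig:
        if self.seed is None:
            return self.simulate
        return self.simulate.replace(seed=self.seed)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ConfigError(f"config root must be a mapping, got {type(raw)}")
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        raw = dict(raw)
        sim_raw = raw.pop("simulate", {})
        known = {f.name for f in dataclasses.fields(cls)} - {"simulate"}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        sim_known = {f.name for f in dataclasses.fields(SimConfig)}
        sim_unknown = set(sim_raw) - sim_known
        if sim_unknown:
            raise ConfigError(f"unknown simulate keys: {sorted(sim_unknown)}")
        if "length_dist" in sim_raw:
            sim_raw["length_dist"] = tuple(sim_raw["length_dist"])
        if "expression_dist" in sim_raw:
            sim_raw["expression_dist"] = tuple(sim_raw["expression_dist"])
        if "de_spec" in sim_raw:
            sim_raw["de_spec"] = tuple(tuple(x) for x in sim_raw["de_spec"])
        return cls(simulate=SimConfig(**sim_raw), **raw)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig, outdir) -> dict:
    """Run the full simulated pipeline into ``outdir``; returns the manifest.

    Stages: generate the paired transcriptomes; sequence three pure
    single-species libraries (two human samples and the chimpanzee
    standard) and two spiked mixtures; build pileups; discover informative
    positions from the pure libraries; count alleles in the mixtures;
    compute cutoff-filtered transcript ratios and the differential-
    expression table; emit per-transcript flatness reports.
    """
    logging.basicConfig(level=config.log_level)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sim = config.effective_sim()

    stage = "simulate"
    try:
        human_ref, chimp_ref, truth = gen_transcriptome(sim)
        human_ref.to_fasta(outdir / "human.fasta")
        chimp_ref.to_fasta(outdir / "chimp.fasta")
        truth.write_snv_bed(outdir / "truth_snvs.bed")
        truth.write_tables(outdir / "truth.tsv")

        refs = (human_ref, chimp_ref)
        zeros = np.zeros(len(truth.ids))
        norm_a = truth.abundance_A / truth.abundance_A.sum()
        norm_b = truth.abundance_B / truth.abundance_B.sum()
        spike = truth.abundance_spike / truth.abundance_spike.sum()
        pure = {
            "HF": MixtureWeights("A", norm_a, zeros),
            "HI": MixtureWeights("B", norm_b, zeros),
            "CL": MixtureWeights("A", zeros, spike),
        }
        libraries: dict[str, Pileup] = {}
        for i, (name, w) in enumerate(pure.items()):
            rng = np.random.default_rng([sim.seed, 10 + i])
            reads = sample_reads(refs, w, sim, rng=rng)
            reads.sample = name
            libraries[name] = build_pileup(reads, human_ref)
            libraries[name].write_tsv(outdir / f"{name}.pileup.tsv")
        mixed: dict[str, Pileup] = {}
        for i, sample in enumerate(("A", "B")):
            rng = np.random.default_rng([sim.seed, 20 + i])
            reads = sample_reads(refs, gen_mixture(truth, sim, sample), sim, rng=rng)
            reads.write_placements_tsv(outdir / f"mixed_{sample}.placements.tsv")
            mixed[sample] = build_pileup(reads, human_ref)
            mixed[sample].write_tsv(outdir / f"mixed_{sample}.pileup.tsv")

        stage = "discover"
        informative = find_informative(
            libraries["HF"], libraries["HI"], libraries["CL"],
            min_depth=config.min_depth,
            homozygosity=config.homozygosity_threshold,
        )
        write_informative_bed(informative, outdir / "informative.bed")
        log.info("discovered %d informative positions", len(informative))

        stage = "count"
        counts = {s: count_alleles(mixed[s], informative) for s in ("A", "B")}
        for s in ("A", "B"):
            write_counts_tsv(counts[s], outdir / f"counts_{s}.tsv")

        stage = "normalize"
        ratios = {s: transcript_ratios(counts[s]) for s in ("A", "B")}
        kept = {
            s: {r.transcript_id: r
                for r in apply_cutoff(ratios[s].values(), config.count_cutoff)}
            for s in ("A", "B")
        }
        for s in ("A", "B"):
            write_ratios_tsv(kept[s].values(), outdir / f"ratios_{s}.tsv")
        folds = differential_expression(kept["B"], kept["A"])
        write_folds_tsv(folds, outdir / "folds_B_vs_A.tsv")

        stage = "evaluate"
        reports, profile = flatten_profile(mixed["A"], informative, counts["A"])
        with open(outdir / "flatness_A.tsv", "w") as fh:
            fh.write("transcript\tn_loci\traw_cv\tsnv_cv\n")
            for r in reports:
                fh.write(f"{r.transcript_id}\t{r.n_loci}\t"
                         f"{r.raw_cv:.4f}\t{r.snv_cv:.4f}\n")
        profile.to_csv(outdir / "profile_A.tsv", sep="\t", index=False)
    except Exception as e:
        raise ConfigError(f"pipeline stage {stage!r} failed: {e}") from e

    manifest = {
        "tool": "snvspike",
        "version": __version__,
        "seed": sim.seed,
        "parameters": {
            "simulate": dataclasses.asdict(sim),
            "min_depth": config.min_depth,
            "homozygosity_threshold": config.homozygosity_threshold,
            "count_cutoff": config.count_cutoff,
            "discordance_factor": config.discordance_factor,
        },
        "n_informative_positions": len(informative),
        "outputs": {
            p.name: _sha256(p)
            for p in sorted(outdir.iterdir())
            if p.is_file() and p.name != "manifest.json"
        },
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest


# ---------------------------------------------------------------------------
# format validation
# ---------------------------------------------------------------------------


@dataclass
class ValidationReport:
    path: str
    kind: str
    valid: bool
    messages: list[str]


def validate_formats(path, kind: str) -> ValidationReport:
    """Check a file against its schema and invariants.

    Supported kinds: fasta, bed, pileup, counts, matrix.  Diagnostics carry
    line numbers where the underlying parsers provide them.
    """
    path = str(path)
    if kind not in ("fasta", "bed", "pileup", "counts", "matrix"):
        raise ConfigError(f"unknown format kind {kind!r}")
    messages: list[str] = []
    try:
        if kind == "fasta":
            from .simulate import Transcriptome

            tr = Transcriptome.from_fasta(path)
            if not tr.ids:
                messages.append("no sequences found")
            if len(set(tr.ids)) != len(tr.ids):
                messages.append("duplicate sequence ids")
        elif kind == "bed":
            read_informative_bed(path)
        elif kind == "pileup":
            Pileup.read_tsv(path)
        elif kind == "counts":
            from .counting import read_counts_tsv

            for c in read_counts_tsv(path):
                if c.human_base == c.chimp_base:
                    messages.append(
                        f"{c.transcript_id}:{c.pos0}: human and chimp base equal"
                    )
        elif kind == "matrix":
            CountMatrix.from_tsv(path)
    except FileNotFoundError:
        raise  # unreadable file is an I/O error, not an invalid format
    except (FormatError, ConfigError, ValueError) as e:
        messages.append(str(e))
    return ValidationReport(path, kind, valid=not messages, messages=messages)
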