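"""Pre-packaged simulation studies of the spike-in normalization design.

Each function runs one self-contained in-silico experiment mirroring a
condition of the spike-in study — quarter-spike ratio recovery, technical
replicate agreement, in-process degradation, shared positional bias,
coverage flattening, housekeeping-gene stability — and returns the summary
statistics a bench scientist would report.  They are the building blocks of
the example scripts and the reproduction script, and keep the study
conditions (sample sizes, depths, rates) in one place.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .counting import count_alleles
from .discovery import InformativePosition, find_informative
from .evaluate import CvSummary, agreement, cv, housekeeping_cv_compare
from .normalize import SnvRatio, apply_cutoff, transcript_ratios
from .pileup import Pileup, build_pileup
from .simulate import (
    HUMAN,
    MixtureWeights,
    SimConfig,
    SimTruth,
    Transcriptome,
    degradation_rate_for_loss,
    expected_informative_depth,
    gen_mixture,
    gen_transcriptome,
    sample_reads,
)


def _truth_positions(truth: SimTruth) -> list[InformativePosition]:
    return [
        InformativePosition(tid, p, hb, cb)
        for tid in truth.ids
        for p, hb, cb in truth.snv_positions[tid]
    ]


def _mixed_ratios(
    refs: tuple[Transcriptome, Transcriptome],
    truth: SimTruth,
    cfg: SimConfig,
    sample: str,
    rng: np.random.Generator,
) -> tuple[dict[str, SnvRatio], np.ndarray]:
    """Sequence one spiked mixture and return per-transcript SNV ratios plus
    per-transcript human-origin read counts (the unnormalized comparator)."""
    reads = sample_reads(refs, gen_mixture(truth, cfg, sample), cfg, rng=rng)
    human_counts = np.bincount(
        reads.transcript_idx[reads.species == HUMAN], minlength=len(truth.ids)
    )
    pu = build_pileup(reads, refs[0])
    counts = count_alleles(pu, _truth_positions(truth))
    return transcript_ratios(counts), human_counts


@dataclass(frozen=True)
class SpikeRatioResult:
    mean_ratio: float
    cv_percent: float
    n_transcripts: int
    mean_human_depth: float
    mean_chimp_depth: float


def quarter_spike_experiment(
    seed: int,
    n_transcripts: int = 2000,
    total_reads: int = 2_800_000,
    min_loci: int = 5,
    cutoff: int = 40,
) -> SpikeRatioResult:
    """Recovery of the 1:0.25 spike design.

    One quarter as much standard as target RNA makes every per-transcript
    SNV-normalized value estimate 1/0.25 = 4.  Simulates one spiked
    mixture, counts alleles at the known informative loci and averages the
    sum-then-divide ratios of transcripts with at least ``min_loci`` loci
    passing the read cutoff on both species.
    """
    cfg = SimConfig(
        n_transcripts=n_transcripts,
        spike_fraction=0.25,
        total_reads=total_reads,
        seed=seed,
    )
    refs = gen_transcriptome(cfg)
    human, chimp, truth = refs
    ratios, _ = _mixed_ratios((human, chimp), truth, cfg, "A",
                              np.random.default_rng([seed, 3]))
    kept = [
        r for r in apply_cutoff(ratios.values(), cutoff)
        if len(truth.snv_positions[r.transcript_id]) >= min_loci
    ]
    values = np.array([r.value for r in kept])
    return SpikeRatioResult(
        mean_ratio=float(values.mean()),
        cv_percent=cv(values),
        n_transcripts=len(kept),
        mean_human_depth=float(np.mean([r.n_human for r in ratios.values()])),
        mean_chimp_depth=float(np.mean([r.n_chimp for r in ratios.values()])),
    )


@dataclass(frozen=True)
class ReplicateAgreementResult:
    mean_ratio: float
    cv_percent: float
    n_genes: int
    mean_depth_per_species: float


def replicate_agreement_experiment(
    seed: int,
    n_transcripts: int = 2000,
    total_reads: int = 1_200_000,
    cutoff: int = 40,
) -> ReplicateAgreementResult:
    """Technical-replicate agreement of SNV-normalized values.

    One 1:1 spiked library is resequenced in silico: each transcript's
    expected summed human and chimpanzee allele counts are resampled
    independently as Poisson for two replicates.  Reports the mean and CV
    of per-transcript replicate-1/replicate-2 ratios over transcripts
    passing the read cutoff in both replicates.
    """
    cfg = SimConfig(
        n_transcripts=n_transcripts, spike_fraction=1.0,
        total_reads=total_reads, seed=seed,
    )
    human, chimp, truth = gen_transcriptome(cfg)
    w = gen_mixture(truth, cfg, "A")
    exp_h, exp_c = expected_informative_depth((human, chimp), truth, w, cfg)
    rng = np.random.default_rng([seed, 4])
    reps = []
    for _ in range(2):
        h = rng.poisson(exp_h)
        c = rng.poisson(exp_c)
        ratios = [
            SnvRatio(tid, int(h[i]), int(c[i]))
            for i, tid in enumerate(truth.ids)
        ]
        reps.append({r.transcript_id: r for r in apply_cutoff(ratios, cutoff)})
    values = [
        {tid: r.value for tid, r in rep.items()} for rep in reps
    ]
    s = agreement(values[0], values[1])
    return ReplicateAgreementResult(
        mean_ratio=s.mean_ratio,
        cv_percent=s.cv,
        n_genes=s.n_genes,
        mean_depth_per_species=float((exp_h.mean() + exp_c.mean()) / 2),
    )


@dataclass(frozen=True)
class BiasCancellationResult:
    mean_ratio: float
    se_ratio: float
    truth_ratio: float
    n_transcripts: int


def bias_cancellation_experiment(
    seed: int,
    n_transcripts: int = 300,
    total_reads: int = 600_000,
    bias_profile: str = "hexamer-like",
    cutoff: int = 40,
) -> BiasCancellationResult:
    """Shared positional bias leaves per-transcript ratios unbiased.

    Both species of a transcript are sampled through the same positional
    weight function, so the bias cancels locus by locus; with a 1:1 spike
    mirroring the sample, every true ratio is 1.
    """
    cfg = SimConfig(
        n_transcripts=n_transcripts, spike_fraction=1.0,
        total_reads=total_reads, bias_profile=bias_profile, seed=seed,
    )
    human, chimp, truth = gen_transcriptome(cfg)
    ratios, _ = _mixed_ratios((human, chimp), truth, cfg, "A",
                              np.random.default_rng([seed, 5]))
    values = np.array([r.value for r in apply_cutoff(ratios.values(), cutoff)])
    return BiasCancellationResult(
        mean_ratio=float(values.mean()),
        se_ratio=float(values.std(ddof=1) / math.sqrt(values.size)),
        truth_ratio=1.0,
        n_transcripts=values.size,
    )


@dataclass(frozen=True)
class DegradationComparisonResult:
    rmse_log2_snv: float
    rmse_log2_unnormalized: float
    n_transcripts: int
    degradation_rate: float


def degradation_comparison_experiment(
    seed: int,
    n_transcripts: int = 300,
    total_reads: int = 3_600_000,
    n_de: int = 30,
    de_fold: float = 3.0,
    degraded_loss: float = 0.7,
    cutoff: int = 40,
) -> DegradationComparisonResult:
    """Fold-change accuracy when one sample is partially degraded.

    Sample A is processed normally; sample B suffers 3'-biased degradation
    (the standard was spiked before the degradation step, so it degrades
    with its sample).  Compares log2 RMSE against the true compositional
    fold changes for the SNV method versus library-size-scaled human
    counts.  Symmetric differential expression: ``n_de`` genes up by
    ``de_fold`` and ``n_de`` genes down by 1/``de_fold``.
    """
    de = tuple((g, de_fold) for g in range(n_de)) + tuple(
        (n_de + g, 1.0 / de_fold) for g in range(n_de)
    )
    base = SimConfig(
        n_transcripts=n_transcripts, spike_fraction=1.0,
        total_reads=total_reads, de_spec=de, seed=seed,
    )
    human, chimp, truth = gen_transcriptome(base)
    mean_len = float(np.mean([len(s) for s in human.seqs]))
    lam = degradation_rate_for_loss(degraded_loss, mean_len)
    degraded = base.replace(degradation_rate=lam)

    ratios_a, counts_a = _mixed_ratios((human, chimp), truth, base, "A",
                                       np.random.default_rng([seed, 6]))
    ratios_b, counts_b = _mixed_ratios((human, chimp), truth, degraded, "B",
                                       np.random.default_rng([seed, 7]))

    # measured folds estimate relative-composition changes, so compare to
    # fold x (total_A / total_B)
    comp = truth.abundance_A.sum() / truth.abundance_B.sum()
    truth_fold = {
        tid: truth.fold_changes[i] * comp for i, tid in enumerate(truth.ids)
    }

    keep_a = {r.transcript_id for r in apply_cutoff(ratios_a.values(), cutoff)}
    keep_b = {r.transcript_id for r in apply_cutoff(ratios_b.values(), cutoff)}
    idx = {tid: i for i, tid in enumerate(truth.ids)}
    err_snv, err_raw = [], []
    lib_a, lib_b = counts_a.sum(), counts_b.sum()
    for tid in sorted(keep_a & keep_b):
        i = idx[tid]
        if counts_a[i] == 0 or counts_b[i] == 0:
            continue
        snv_fold = ratios_b[tid].value / ratios_a[tid].value
        raw_fold = (counts_b[i] / lib_b) / (counts_a[i] / lib_a)
        err_snv.append(math.log2(snv_fold / truth_fold[tid]))
        err_raw.append(math.log2(raw_fold / truth_fold[tid]))
    err_snv = np.array(err_snv)
    err_raw = np.array(err_raw)
    return DegradationComparisonResult(
        rmse_log2_snv=float(np.sqrt(np.mean(err_snv**2))),
        rmse_log2_unnormalized=float(np.sqrt(np.mean(err_raw**2))),
        n_transcripts=err_snv.size,
        degradation_rate=lam,
    )


@dataclass(frozen=True)
class FlatteningResult:
    fraction_flattened: float
    n_transcripts: int
    median_raw_cv: float
    median_snv_cv: float


def flattening_experiment(
    seed: int,
    n_transcripts: int = 200,
    total_reads: int = 1_000_000,
    bias_profile: str = "hexamer-like",
    min_loci: int = 5,
) -> FlatteningResult:
    """Within-transcript flattening of biased coverage by SNV normalization.

    Under a strong shared positional bias, raw coverage is skewed along
    each transcript while per-locus normalized values are flat up to
    counting noise; reports the fraction of transcripts (with at least
    ``min_loci`` usable loci) whose normalized CV is below the raw
    coverage CV.
    """
    from .evaluate import flatten_profile

    cfg = SimConfig(
        n_transcripts=n_transcripts, spike_fraction=1.0,
        total_reads=total_reads, bias_profile=bias_profile, seed=seed,
    )
    human, chimp, truth = gen_transcriptome(cfg)
    reads = sample_reads((human, chimp), gen_mixture(truth, cfg, "A"), cfg,
                         rng=np.random.default_rng([seed, 8]))
    pu = build_pileup(reads, human)
    positions = _truth_positions(truth)
    counts = count_alleles(pu, positions)
    reports, _ = flatten_profile(pu, positions, counts)
    rich = [r for r in reports if r.n_loci >= min_loci]
    flags = np.array([r.snv_cv < r.raw_cv for r in rich])
    return FlatteningResult(
        fraction_flattened=float(flags.mean()),
        n_transcripts=len(rich),
        median_raw_cv=float(np.median([r.raw_cv for r in rich])),
        median_snv_cv=float(np.median([r.snv_cv for r in rich])),
    )


def housekeeping_cv_experiment(
    seed: int,
    n_transcripts: int = 400,
    total_reads: int = 1_200_000,
    degraded_loss: float = 0.7,
    cutoff: int = 40,
) -> dict[str, CvSummary]:
    """Housekeeping-gene CV comparison across normalization methods.

    Two technical replicates of one 1:1 spiked sample are sequenced, the
    second after partial 3' degradation.  Conventional methods normalize
    the per-transcript human read counts; the SNV method uses transcript
    ratios.  All genes are housekeeping by construction (no differential
    expression between replicates of the same sample).
    """
    import pandas as pd

    from .baselines import CountMatrix

    base = SimConfig(
        n_transcripts=n_transcripts, spike_fraction=1.0,
        total_reads=total_reads, seed=seed,
    )
    human, chimp, truth = gen_transcriptome(base)
    mean_len = float(np.mean([len(s) for s in human.seqs]))
    degraded = base.replace(
        degradation_rate=degradation_rate_for_loss(degraded_loss, mean_len)
    )
    snv_values, columns = [], {}
    for name, cfg, tag in (("rep1", base, 30), ("rep2", degraded, 31)):
        ratios, counts = _mixed_ratios((human, chimp), truth, cfg, "A",
                                       np.random.default_rng([seed, tag]))
        kept = apply_cutoff(ratios.values(), cutoff)
        snv_values.append({r.transcript_id: r.value for r in kept})
        columns[name] = counts
    matrix = CountMatrix(pd.DataFrame(columns, index=truth.ids))
    return housekeeping_cv_compare(matrix, snv_values, truth.ids)


@dataclass(frozen=True)
class DiscoveryFidelityResult:
    n_truth: int
    n_qualified: int
    n_found: int
    n_false_positive: int


def discovery_fidelity_experiment(
    seed: int,
    n_transcripts: int = 60,
    mean_depth: float = 100.0,
    error_rate: float = 0.01,
    min_depth: int = 10,
) -> DiscoveryFidelityResult:
    """Discovery against ground truth at realistic error rates.

    Three equal-abundance single-species libraries (two human, one
    chimpanzee) at roughly ``mean_depth`` coverage are scanned for
    informative positions; reports truth recovery restricted to positions
    meeting the depth filter in all libraries, and false discoveries.
    """
    length = 1200.0
    total_reads = int(n_transcripts * length * mean_depth / 150)
    cfg = SimConfig(
        n_transcripts=n_transcripts, length_dist=(length, 300.0),
        total_reads=total_reads, error_rate=error_rate, seed=seed,
    )
    human, chimp, truth = gen_transcriptome(cfg)
    flat = np.ones(n_transcripts)
    zeros = np.zeros(n_transcripts)
    libs = {
        "HF": MixtureWeights("A", flat, zeros),
        "HI": MixtureWeights("B", flat, zeros),
        "CL": MixtureWeights("A", zeros, flat),
    }
    pus: dict[str, Pileup] = {}
    for i, (name, w) in enumerate(libs.items()):
        rng = np.random.default_rng([seed, 40 + i])
        pus[name] = build_pileup(sample_reads((human, chimp), w, cfg, rng=rng),
                                 human)
    found = set(find_informative(pus["HF"], pus["HI"], pus["CL"],
                                 min_depth=min_depth))
    truth_set = set(_truth_positions(truth))
    qualified = {
        p for p in truth_set
        if all(pus[k].depth_array(p.transcript_id)[p.pos0] >= min_depth
               for k in pus)
    }
    return DiscoveryFidelityResult(
        n_truth=len(truth_set),
        n_qualified=len(qualified),
        n_found=len(found),
        n_false_positive=len(found - truth_set),
    )
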