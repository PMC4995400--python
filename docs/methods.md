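# Methods

This note documents the model behind `snvspike`: what the simulator
emulates and deliberately omits, the statistical procedures, the defaults
and the numerical conventions.

## The measurement model

A spiked sample contains human RNA from sample *s* and chimpanzee standard
RNA from a single shared batch.  At an informative position of transcript
*g*, the expected read counts are

```
E[h_gs] = D_s · β_gp · a_gs            (human)
E[c_gs] = D_s · β_gp · φ · q_g         (chimpanzee standard)
```

where `D_s` collects every sample-level efficiency (depth, enrichment,
PCR), `β_gp` every locus-level efficiency (positional bias, degradation
survival, local sequence effects), `a_gs` the human relative abundance,
`q_g` the standard's composition and `φ` the spike fraction.  Both factors
cancel in the ratio `h/c`, leaving `a_gs / (φ q_g)` — per-locus, per-sample
normalization with no modeling of `D` or `β` at all.  Dividing two samples'
ratios cancels `φ q_g` too and estimates the fold change of *relative*
abundance (each sample contributes an equal analyzed amount, so folds are
compositional; evaluations against simulator truth therefore multiply true
per-gene folds by `Σa_A / Σa_B`).

Per transcript, counts are summed over loci first and divided once
(sum-then-divide).  This weighs loci by their information content and
rescues loci whose chimpanzee count is zero; the mean of per-locus ratios
is deliberately not used (it is biased at low counts and undefined at any
ND locus) and appears only inside the flattening diagnostic.

## Simulator

`simulate` generates the full study world with ground truth:

* **References.**  Human transcript sequences are i.i.d. uniform bases;
  lengths are Normal(mean, sd) rounded, redrawn while shorter than one
  read.  The chimpanzee sequence differs by substitutions placed
  Bernoulli(`snv_rate`) per base — default 1/210, the observed
  human/chimpanzee mRNA divergence — with the alternate base uniform among
  the other three.  No indels, no isoforms: the informative-position
  method is substitution-based, and isoform structure would only add
  bookkeeping, not change the ratio arithmetic.
* **Abundances.**  Log-normal (default μ=0, σ=1, a typical bulk RNA-seq
  dynamic range); differential expression is a per-gene multiplicative
  fold.  The standard's composition mirrors sample A by default
  (`spike_profile="match_A"`, the matched-tissue ideal the original design
  recommends) or is an independent log-normal draw.
* **Mixtures.**  Human weights are normalized to total 1 per sample (equal
  analyzed amounts); the chimpanzee batch is shared by all samples and
  scaled to `spike_fraction` times the human total.
* **Reads.**  Single-end, fixed 150 bp, sense strand.  A read start is one
  multinomial draw over (species, transcript, start) cells with weight
  mixture × bias × degradation survival, so per-transcript counts,
  positional skew and species balance all emerge from one sampling law.
  Base-call errors are i.i.d. substitutions (default 0.005, Illumina-like)
  to a uniform different base.  Paired ends, quality-dependent errors, PCR
  duplicates and rRNA are not modeled; none interact with the ratio
  arithmetic being tested.
* **Positional bias.**  Three fixed smooth profiles of relative start
  position: `uniform`; `hexamer-like`, a mid-body Gaussian hump with
  depleted ends (0.3 + 1.4·exp(−(x−0.5)²/2·0.15²)), standing in for
  random-hexamer chemistry; `nextera-like`, a mild 5′ ramp
  (0.4 + 1.2(1−x)), standing in for tagmentation.  The real chemistry
  differences are known only qualitatively, so all conclusions drawn from
  these profiles are before/after-normalization comparisons, never
  absolute bias shapes.
* **Degradation.**  Each fragment survives oligo-dT selection only if the
  path from its 3′ side to the transcript 3′ end is uncut:
  survival = exp(−λ·d).  λ is calibrated via
  `degradation_rate_for_loss(loss, length)`; the degradation scenarios use
  loss = 0.7 at the mean transcript length, mirroring the ~70% ribosomal
  degradation of the motivating bench protocol.
* **Determinism.**  Every operation takes or derives a `numpy` Generator
  from the config seed; identical configs give byte-identical outputs.

What passing tests on this simulator do **not** show: robustness to
alignment/mapping artifacts (placements are truth), to within-species
polymorphism (humans are one haplotype), to isoform-specific expression,
or to real chemistry bias shapes.  They do show the core cancellation
property, which is independent of the particular bias inserted.

## Pipeline conventions

* Coordinates are 0-based internally; BED output is 0-based half-open with
  name `HUMANBASE>CHIMPBASE`.  All tables are headered TSV, UTF-8, with
  `ND` as the single missing-value token.
* Pileups tally *observed* read bases with no depth cap and no quality
  filtering (simulated reads carry none; unique placement replaces the
  mapping-quality filter an aligner would need).
* Homozygosity is operationalized purely as major-allele frequency ≥ 0.90
  (boundary inclusive) at depth ≥ 10 in all three discovery libraries;
  ties in the major allele break A<C<G<T and necessarily fail the
  frequency test.
* The read cutoff (default 40, boundary inclusive) applies to **both**
  species' summed counts.  The source protocol states only "counts over
  40"; requiring the chimpanzee side too guards the denominator, and
  inclusivity is fixed for testability.
* `n_other` (bases matching neither diagnostic allele) is recorded but
  excluded from every ratio; no threshold is applied to it.

## Baselines

UQ, RLE and TMM are independent from-scratch implementations (validated in
the tests against hand-coded oracles and against edgeR/DESeq2 through
Rscript).  All three return factors with geometric mean 1 on a *depth-free*
convention: normalized values are `counts/(libsize × factor) × 1e6`.  For
RLE this means the per-sample median of count ratios to per-gene geometric
means (computed over genes positive in every sample) is divided by library
size; the product factor × libsize reproduces the DESeq size factor up to
one global constant.  TMM uses the published defaults — 30% two-sided trim
on M, 5% on A, delta-method inverse-variance weights, reference = sample
whose Q75/libsize is closest to the mean — all configurable.

## Evaluation statistics

* `cv` is 100·sd/mean with the n−1 denominator; all statistics drop ND
  values and report the n actually used.
* Replicate agreement is the mean and CV of per-gene value ratios (mean of
  ratios, matching how agreement plots are constructed gene by gene — not
  the ratio of means).
* Flatness had to be given a scalar definition (the source assesses it
  visually): per transcript, the CV of defined per-locus ratios versus the
  CV of per-position total coverage.  It is labeled artifact-defined.
* Discordance counts fold pairs differing by *strictly* more than the
  factor (an exactly 2-fold difference does not count).
* The housekeeping comparison is structural: each method is scored only by
  the CVs of its own normalized quantities across replicates, never by
  cross-method value comparison.  The simulator's housekeeping list is the
  set of genes with fold change 1.

## Study problem sizes

The packaged studies in `snvspike.experiments` run at desk scale, chosen
so that the statistic of interest is resolved well above its Monte-Carlo
noise: 2,000 transcripts at 2.8 M reads for the quarter-spike design
(summed depth ≈ 800 human / 200 chimp per transcript), 2,000 transcripts
with Poisson-resampled expected counts (mean ≈ 210 per species) for
replicate agreement, 300 transcripts at 3.6 M reads per sample for the
degradation fold-accuracy comparison (SNV counting noise well below the
degradation bias it is compared against), 200 transcripts at 1 M reads for
flattening, and 400 transcripts at 1.2 M reads per replicate for the
housekeeping CV contrast.  The original experiments used 22–26 M reads
over ~10,000 transcripts; per-transcript depths here are comparable or
deeper, sample counts smaller.

## Known limitations

* Single-haplotype species: heterozygosity within human samples (the
  reason the discovery filter demands two concordant human sources) never
  arises in simulation, so condition (iii) is exercised only by
  constructed fixtures.
* The compositional nature of spike-normalized folds (see above) is
  inherent to equal-mass loading, not an artifact; absolute folds require
  the standard's `φ q_g` to be known.
* Fold-change significance testing is out of scope; the method yields
  ratios, and count-model inference on them would need a dedicated error
  model for ratio statistics.
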