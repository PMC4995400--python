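"""Simulator: divergence placement, mixture invariants, read sampling laws."""

from __future__ import annotations

import numpy as np
import pytest
from scipy import stats

import snvspike as sv
from snvspike._codec import decode
from snvspike.errors import ConfigError


class TestGenTranscriptome:
    def test_snv_density_matches_rate(self):
        # rate 1/210 on ~2.1-kb transcripts -> about 10 SNVs per transcript
        cfg = sv.SimConfig(
            n_transcripts=1000, length_dist=(2100.0, 0.001), snv_rate=1 / 210,
            seed=2,
        )
        _, _, truth = sv.gen_transcriptome(cfg)
        n = truth.n_snvs()
        expected = 2100 / 210
        se = np.sqrt(expected) / np.sqrt(len(n))  # Poisson-binomial scale
        assert abs(n.mean() - expected) < 3 * se

    def test_chimp_differs_exactly_at_truth_positions(self, small_world):
        _, human, chimp, truth = small_world
        for i, tid in enumerate(truth.ids):
            diff = np.flatnonzero(human.seqs[i] != chimp.seqs[i])
            truth_pos = np.array([p for p, _, _ in truth.snv_positions[tid]], dtype=int)
            assert np.array_equal(diff, truth_pos)
            for p, hb, cb in truth.snv_positions[tid]:
                assert hb != cb
                assert decode(human.seqs[i][p : p + 1]) == hb
                assert decode(chimp.seqs[i][p : p + 1]) == cb

    def test_zero_rate_gives_identical_references(self):
        cfg = sv.SimConfig(n_transcripts=10, snv_rate=0.0, seed=4)
        human, chimp, truth = sv.gen_transcriptome(cfg)
        for h, c in zip(human.seqs, chimp.seqs):
            assert np.array_equal(h, c)
        assert truth.n_snvs().sum() == 0

    def test_same_seed_identical_fasta_bytes(self, tmp_path):
        cfg = sv.SimConfig(n_transcripts=15, seed=9)
        for run in ("a", "b"):
            human, _, _ = sv.gen_transcriptome(cfg)
            human.to_fasta(tmp_path / f"{run}.fasta")
        assert (tmp_path / "a.fasta").read_bytes() == (tmp_path / "b.fasta").read_bytes()

    def test_short_transcripts_are_redrawn(self):
        cfg = sv.SimConfig(
            n_transcripts=50, length_dist=(160.0, 80.0), read_length=150, seed=3
        )
        human, _, _ = sv.gen_transcriptome(cfg)
        assert (human.lengths >= 150).all()

    def test_fold_changes_exact(self):
        cfg = sv.SimConfig(n_transcripts=10, de_spec=((2, 4.0), (5, 0.25)), seed=1)
        _, _, truth = sv.gen_transcriptome(cfg)
        np.testing.assert_allclose(
            truth.fold_changes, truth.abundance_B / truth.abundance_A
        )
        assert truth.fold_changes[2] == 4.0 and truth.fold_changes[5] == 0.25

    def test_fasta_round_trip(self, tmp_path, small_world):
        _, human, _, _ = small_world
        human.to_fasta(tmp_path / "h.fasta")
        back = sv.Transcriptome.from_fasta(tmp_path / "h.fasta")
        assert back.ids == human.ids
        assert all(np.array_equal(a, b) for a, b in zip(back.seqs, human.seqs))


class TestGenMixture:
    @pytest.mark.parametrize("frac", [1.0, 0.25, 0.0])
    def test_spike_fraction_sets_total_weight(self, small_world, frac):
        cfg, _, _, truth = small_world
        w = sv.gen_mixture(truth, cfg.replace(spike_fraction=frac), "A")
        assert w.chimp.sum() == pytest.approx(frac * w.human.sum())

    def test_chimp_weights_identical_between_samples(self, small_world):
        cfg, _, _, truth = small_world
        wa = sv.gen_mixture(truth, cfg, "A")
        wb = sv.gen_mixture(truth, cfg, "B")
        np.testing.assert_array_equal(wa.chimp, wb.chimp)

    def test_symmetric_mix_equal_weights(self):
        cfg = sv.SimConfig(n_transcripts=8, spike_fraction=1.0, seed=6)
        _, _, truth = sv.gen_transcriptome(cfg)
        w = sv.gen_mixture(truth, cfg, "A")
        # spike profile mirrors sample A, so per-transcript weights match
        np.testing.assert_allclose(w.human, w.chimp)

    def test_invalid_sample_label_rejected(self, small_world):
        cfg, _, _, truth = small_world
        with pytest.raises(ConfigError):
            sv.gen_mixture(truth, cfg, "C")

    def test_negative_spike_fraction_rejected(self):
        with pytest.raises(ConfigError):
            sv.SimConfig(spike_fraction=-0.1)


class TestDegradation:
    def test_zero_rate_unit_weight(self):
        assert sv.degradation_weight(np.arange(0, 5000, 100), 0.0).min() == 1.0

    def test_three_prime_terminal_fragment_survives(self):
        assert sv.degradation_weight(0, 0.01) == 1.0

    def test_closed_form_calibration(self):
        lam = sv.degradation_rate_for_loss(0.7, 2000)
        assert lam == pytest.approx(-np.log(0.3) / 2000)
        assert sv.degradation_weight(2000, lam) == pytest.approx(0.3)
        w = sv.degradation_weight(np.arange(0, 3000), lam)
        assert (np.diff(w) < 0).all()


class TestSampleReads:
    def test_exact_read_count_and_origins(self, small_world):
        cfg, human, chimp, truth = small_world
        reads = sv.sample_reads((human, chimp), sv.gen_mixture(truth, cfg, "A"), cfg)
        assert len(reads) == cfg.total_reads
        assert reads.bases.shape == (cfg.total_reads, cfg.read_length)

    def test_noiseless_reads_match_reference(self):
        cfg = sv.SimConfig(n_transcripts=6, total_reads=2000, error_rate=0.0, seed=8)
        human, chimp, truth = sv.gen_transcriptome(cfg)
        reads = sv.sample_reads((human, chimp), sv.gen_mixture(truth, cfg, "A"), cfg)
        seqs = [human.seqs, chimp.seqs]
        for i in range(0, len(reads), 97):
            src = seqs[reads.species[i]][reads.transcript_idx[i]]
            s = int(reads.start0[i])
            assert np.array_equal(reads.bases[i], src[s : s + cfg.read_length])

    def test_same_seed_identical_reads(self, small_world):
        cfg, human, chimp, truth = small_world
        w = sv.gen_mixture(truth, cfg, "A")
        r1 = sv.sample_reads((human, chimp), w, cfg)
        r2 = sv.sample_reads((human, chimp), w, cfg)
        assert np.array_equal(r1.bases, r2.bases)
        assert np.array_equal(r1.start0, r2.start0)
        assert np.array_equal(r1.species, r2.species)

    def test_uniform_equal_weights_multinomial(self):
        # equal weights over 10 equal-length transcripts: per-transcript
        # counts consistent with Multinomial(n, 1/10)
        cfg = sv.SimConfig(
            n_transcripts=10, length_dist=(500.0, 0.001), total_reads=100_000,
            snv_rate=0.0, error_rate=0.0, seed=12,
        )
        human, chimp, _ = sv.gen_transcriptome(cfg)
        w = sv.MixtureWeights("A", np.ones(10), np.zeros(10))
        reads = sv.sample_reads((human, chimp), w, cfg)
        counts = np.bincount(reads.transcript_idx, minlength=10)
        chi2 = ((counts - 10_000.0) ** 2 / 10_000.0).sum()
        assert stats.chi2.sf(chi2, df=9) > 0.001

    def test_spike_conservation(self, small_world):
        cfg, human, chimp, truth = small_world
        cfg = cfg.replace(spike_fraction=0.25)
        reads = sv.sample_reads((human, chimp), sv.gen_mixture(truth, cfg, "A"), cfg)
        p = 0.25 / 1.25
        frac = (reads.species == 1).mean()
        se = np.sqrt(p * (1 - p) / len(reads))
        assert abs(frac - p) < 3 * se

    def test_zero_spike_no_chimp_reads(self, small_world):
        cfg, human, chimp, truth = small_world
        cfg = cfg.replace(spike_fraction=0.0)
        reads = sv.sample_reads((human, chimp), sv.gen_mixture(truth, cfg, "A"), cfg)
        assert (reads.species == 0).all()

    def test_empty_weights_rejected(self, small_world):
        cfg, human, chimp, truth = small_world
        n = len(truth.ids)
        with pytest.raises(ConfigError):
            sv.sample_reads(
                (human, chimp),
                sv.MixtureWeights("A", np.zeros(n), np.zeros(n)),
                cfg,
            )

    def test_batch_identity_of_chimp_counts(self, small_world):
        # chimp per-transcript expected counts are equal between samples A
        # and B up to sampling noise (shared-batch standard)
        cfg, human, chimp, truth = small_world
        ca, cb = [], []
        for sample, store in (("A", ca), ("B", cb)):
            reads = sv.sample_reads(
                (human, chimp), sv.gen_mixture(truth, cfg, sample), cfg
            )
            sel = reads.species == 1
            store.append(np.bincount(reads.transcript_idx[sel], minlength=len(truth.ids)))
        ca, cb = ca[0], cb[0]
        tot = ca + cb
        keep = tot >= 50
        z = (ca[keep] - cb[keep]) / np.sqrt(tot[keep])  # binomial split z-scores
        assert np.abs(z).mean() < 2.0
        assert (np.abs(z) < 5).all()


class TestPlacementsIO:
    def test_placements_tsv_round_trip(self, tmp_path):
        cfg = sv.SimConfig(n_transcripts=4, total_reads=50, seed=13)
        human, chimp, truth = sv.gen_transcriptome(cfg)
        reads = sv.sample_reads((human, chimp), sv.gen_mixture(truth, cfg, "A"), cfg)
        path = tmp_path / "p.tsv"
        reads.write_placements_tsv(path)
        back = sv.simulate.read_placements_tsv(path)
        assert [p for p in reads] == back

    def test_fastq_well_formed(self, tmp_path):
        cfg = sv.SimConfig(n_transcripts=3, total_reads=20, seed=14)
        human, chimp, truth = sv.gen_transcriptome(cfg)
        reads = sv.sample_reads((human, chimp), sv.gen_mixture(truth, cfg, "A"), cfg)
        path = tmp_path / "r.fastq"
        reads.write_fastq(path, cfg.error_rate)
        from Bio import SeqIO

        records = list(SeqIO.parse(str(path), "fastq"))
        assert len(records) == 20
        assert all(len(r.seq) == cfg.read_length for r in records)


class TestExpectedDepth:
    def test_expected_matches_sampled_depth(self):
        cfg = sv.SimConfig(n_transcripts=30, total_reads=300_000, seed=17,
                           error_rate=0.0)
        human, chimp, truth = sv.gen_transcriptome(cfg)
        w = sv.gen_mixture(truth, cfg, "A")
        exp_h, exp_c = sv.expected_informative_depth((human, chimp), truth, w, cfg)
        reads = sv.sample_reads((human, chimp), w, cfg)
        pu = sv.build_pileup(reads, human)
        from conftest import truth_positions

        counts = sv.count_alleles(pu, truth_positions(truth))
        ratios = sv.transcript_ratios(counts)
        obs_h = np.array([ratios[t].n_human if t in ratios else 0 for t in truth.ids])
        keep = exp_h > 50
        z = (obs_h[keep] - exp_h[keep]) / np.sqrt(exp_h[keep])
        assert np.abs(z).mean() < 2.0
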