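from __future__ import annotations

import numpy as np
import pytest

import snvspike as sv


def make_column(counts: dict[str, int], tid: str = "tx00001", pos: int = 0):
    """PileupColumn from a base->count dict."""
    full = tuple(counts.get(b, 0) for b in "ACGT")
    return sv.PileupColumn(tid, pos, full)


@pytest.fixture(scope="session")
def small_world():
    """A 40-transcript world with references, truth and mixture weights."""
    cfg = sv.SimConfig(
        n_transcripts=40,
        length_dist=(1200.0, 300.0),
        total_reads=150_000,
        seed=11,
    )
    human, chimp, truth = sv.gen_transcriptome(cfg)
    return cfg, human, chimp, truth


def pure_weights(truth: sv.SimTruth) -> dict[str, sv.MixtureWeights]:
    """Single-species sampling weights for the three discovery libraries."""
    zeros = np.zeros(len(truth.ids))
    return {
        "HF": sv.MixtureWeights("A", truth.abundance_A / truth.abundance_A.sum(), zeros),
        "HI": sv.MixtureWeights("B", truth.abundance_B / truth.abundance_B.sum(), zeros),
        "CL": sv.MixtureWeights(
            "A", zeros, truth.abundance_spike / truth.abundance_spike.sum()
        ),
    }


@pytest.fixture(scope="session")
def pure_pileups(small_world):
    cfg, human, chimp, truth = small_world
    pus = {}
    for i, (name, w) in enumerate(pure_weights(truth).items()):
        rng = np.random.default_rng([cfg.seed, 100 + i])
        reads = sv.sample_reads((human, chimp), w, cfg, rng=rng)
        pus[name] = sv.build_pileup(reads, human)
    return pus


def truth_positions(truth: sv.SimTruth) -> list[sv.InformativePosition]:
    return [
        sv.InformativePosition(tid, p, hb, cb)
        for tid in truth.ids
        for p, hb, cb in truth.snv_positions[tid]
    ]
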