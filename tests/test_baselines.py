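"""Size-factor baselines against independent oracles and invariants."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import snvspike as sv
from snvspike.baselines import (
    CountMatrix,
    normalize_matrix,
    size_factors_rle,
    size_factors_tmm,
    size_factors_uq,
)

ALL_METHODS = [size_factors_uq, size_factors_rle, size_factors_tmm]


# ---------------------------------------------------------------------------
# independent, deliberately naive oracle implementations
# ---------------------------------------------------------------------------


def oracle_uq(df: pd.DataFrame) -> np.ndarray:
    keep = df.loc[df.sum(axis=1) > 0]
    factors = []
    for col in df.columns:
        vals = sorted(keep[col].tolist())
        # quartile by linear interpolation, coded by hand
        h = 0.75 * (len(vals) - 1)
        lo, hi = int(np.floor(h)), int(np.ceil(h))
        q = vals[lo] + (h - lo) * (vals[hi] - vals[lo])
        factors.append(q / df[col].sum())
    f = np.array(factors, dtype=float)
    return f / np.exp(np.mean(np.log(f)))


def oracle_rle(df: pd.DataFrame) -> np.ndarray:
    rows = [r for _, r in df.iterrows() if (r > 0).all()]
    ratios = {c: [] for c in df.columns}
    for r in rows:
        gm = float(np.exp(np.mean([np.log(v) for v in r])))
        for c in df.columns:
            ratios[c].append(r[c] / gm)
    f = np.array(
        [float(np.median(ratios[c])) / df[c].sum() for c in df.columns]
    )
    return f / np.exp(np.mean(np.log(f)))


def _rank_average(values):
    order = sorted(range(len(values)), key=lambda i: values[i])
    ranks = [0.0] * len(values)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and values[order[j + 1]] == values[order[i]]:
            j += 1
        avg = (i + j) / 2 + 1
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def oracle_tmm(df: pd.DataFrame, trim_m=0.30, trim_a=0.05) -> np.ndarray:
    libsize = df.sum(axis=0)
    expressed = df.loc[df.sum(axis=1) > 0]
    f75 = np.array([np.quantile(expressed[c], 0.75) / libsize[c] for c in df.columns])
    ref = df.columns[int(np.argmin(np.abs(f75 - f75.mean())))]
    factors = []
    for col in df.columns:
        if col == ref:
            factors.append(1.0)
            continue
        ms, as_, ws = [], [], []
        for g in df.index:
            y, r = df.at[g, col], df.at[g, ref]
            if y > 0 and r > 0:
                ms.append(np.log2((y / libsize[col]) / (r / libsize[ref])))
                as_.append(0.5 * np.log2((y / libsize[col]) * (r / libsize[ref])))
                ws.append(
                    1.0
                    / (
                        1 / y - 1 / libsize[col] + 1 / r - 1 / libsize[ref]
                    )
                )
        n = len(ms)
        lo_m = int(np.floor(n * trim_m)) + 1
        lo_a = int(np.floor(n * trim_a)) + 1
        rank_m, rank_a = _rank_average(ms), _rank_average(as_)
        num = den = 0.0
        for i in range(n):
            if lo_m <= rank_m[i] <= n + 1 - lo_m and lo_a <= rank_a[i] <= n + 1 - lo_a:
                num += ms[i] * ws[i]
                den += ws[i]
        factors.append(2 ** (num / den))
    f = np.array(factors)
    return f / np.exp(np.mean(np.log(f)))


def random_matrix(seed, n_genes=200, n_samples=4):
    rng = np.random.default_rng(seed)
    lam = rng.lognormal(3.0, 1.0, size=n_genes)
    depth = rng.uniform(0.5, 2.0, size=n_samples)
    counts = rng.poisson(lam[:, None] * depth[None, :])
    return pd.DataFrame(
        counts,
        index=[f"g{i:04d}" for i in range(n_genes)],
        columns=[f"s{j}" for j in range(n_samples)],
    )


# ---------------------------------------------------------------------------


class TestInvariants:
    @pytest.mark.parametrize("fn", ALL_METHODS)
    def test_identical_samples_unit_factors(self, fn):
        df = random_matrix(0)[["s0"]]
        df = pd.concat([df] * 3, axis=1)
        df.columns = ["a", "b", "c"]
        np.testing.assert_allclose(fn(df).factors.to_numpy(), 1.0, atol=1e-12)

    @pytest.mark.parametrize("fn", ALL_METHODS)
    def test_pure_library_size_scaling_cancels(self, fn):
        # sample2 = 3 x sample1 is a pure depth change: factors stay 1
        df = random_matrix(1)[["s0"]].copy()
        df["s1"] = df["s0"] * 3
        np.testing.assert_allclose(fn(df).factors.to_numpy(), 1.0, atol=1e-10)

    @pytest.mark.parametrize("fn", ALL_METHODS)
    def test_geometric_mean_one(self, fn):
        f = fn(random_matrix(2)).factors.to_numpy()
        assert abs(np.log(f).mean()) < 1e-12

    @pytest.mark.parametrize("fn", ALL_METHODS)
    def test_sample_permutation_equivariance(self, fn):
        df = random_matrix(3)
        perm = ["s2", "s0", "s3", "s1"]
        f = fn(df).factors
        g = fn(df[perm]).factors
        np.testing.assert_allclose(g.to_numpy(), f[perm].to_numpy(), rtol=1e-12)

    def test_rle_excludes_genes_with_zeros(self):
        # a gene with a zero must not influence the median of ratios: the
        # effective scales (factor x libsize, geomean-1) are identical
        # whether the gene is present or dropped entirely
        def eff(df):
            e = (size_factors_rle(df).factors * df.sum(axis=0)).to_numpy()
            return e / np.exp(np.log(e).mean())

        df = random_matrix(4)
        df.iloc[0, 0] = 0
        np.testing.assert_allclose(eff(df), eff(df.iloc[1:]), rtol=1e-12)

    def test_all_zero_matrix_rejected(self):
        df = pd.DataFrame(np.zeros((5, 3), dtype=int),
                          index=list("abcde"), columns=list("xyz"))
        with pytest.raises(sv.SnvSpikeError):
            size_factors_uq(df)
        with pytest.raises(sv.SnvSpikeError):
            size_factors_rle(df)

    def test_negative_counts_rejected(self):
        df = pd.DataFrame({"a": [1, -2]}, index=["g1", "g2"])
        with pytest.raises(sv.SnvSpikeError):
            CountMatrix(df)


class TestOracles:
    @pytest.mark.parametrize("seed", [10, 11, 12])
    def test_uq_matches_hand_coded_quartile(self, seed):
        df = random_matrix(seed, n_genes=50, n_samples=3)
        np.testing.assert_allclose(
            size_factors_uq(df).factors.to_numpy(), oracle_uq(df), atol=1e-10
        )

    @pytest.mark.parametrize("seed", [13, 14, 15])
    def test_rle_matches_hand_coded_median_of_ratios(self, seed):
        df = random_matrix(seed)
        np.testing.assert_allclose(
            size_factors_rle(df).factors.to_numpy(), oracle_rle(df), atol=1e-10
        )

    @pytest.mark.parametrize("seed", [16, 17, 18])
    def test_tmm_matches_loop_implementation(self, seed):
        df = random_matrix(seed)
        np.testing.assert_allclose(
            size_factors_tmm(df).factors.to_numpy(), oracle_tmm(df), atol=1e-4
        )

    def test_rle_exact_scaling_effective_sizes(self):
        # sample2 = 2 x sample1: the median-of-ratios depth estimate
        # (factor x libsize) is in ratio 2:1, while the depth-free factors
        # themselves stay at 1
        df = random_matrix(19)[["s0"]].copy()
        df["s1"] = df["s0"] * 2
        f = size_factors_rle(df).factors
        np.testing.assert_allclose(f.to_numpy(), 1.0, atol=1e-12)
        eff = f * df.sum(axis=0)
        assert eff["s1"] / eff["s0"] == pytest.approx(2.0)


class TestNormalizeMatrix:
    def test_unit_factors_proportional_to_input(self):
        df = random_matrix(20)
        f = size_factors_uq(df)
        norm = normalize_matrix(df, f)
        assert list(norm.index) == list(df.index)
        col = df.columns[0]
        ratio = norm[col] / df[col].replace(0, np.nan)
        assert ratio.dropna().std() < 1e-9

    def test_doubling_counts_and_factor_cancels(self):
        df = random_matrix(21)
        f = size_factors_uq(df)
        norm1 = normalize_matrix(df, f)
        df2 = df.copy()
        df2["s0"] = df2["s0"] * 2  # doubles libsize; same factor => same CPM
        norm2 = normalize_matrix(df2, f)
        np.testing.assert_allclose(norm1["s0"], norm2["s0"], rtol=1e-12)

    def test_matrix_tsv_round_trip(self, tmp_path):
        m = CountMatrix(random_matrix(22))
        path = tmp_path / "m.tsv"
        m.to_tsv(path)
        back = CountMatrix.from_tsv(path)
        pd.testing.assert_frame_equal(back.df, m.df, check_names=False)
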