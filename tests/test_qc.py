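import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cagekit.qc import (
    NormalizedMatrix,
    classical_mds,
    leading_logfc_distances,
    mds_coordinates,
    spearman_matrix,
    tmm_factors,
)


def oracle_tmm(counts: np.ndarray, trim_m=0.30, trim_a=0.05) -> np.ndarray:
    """Step-by-step TMM recomputation, written independently of cagekit.qc."""
    lib = counts.sum(axis=0)
    f75 = np.array([np.quantile(counts[:, j] / lib[j], 0.75) for j in range(counts.shape[1])])
    ref = int(np.argmin(np.abs(f75 - f75.mean())))
    logf = np.zeros(counts.shape[1])
    for j in range(counts.shape[1]):
        if j == ref:
            continue
        x, r = counts[:, j].astype(float), counts[:, ref].astype(float)
        keep = (x > 0) & (r > 0)
        x, r = x[keep], r[keep]
        m = np.log2(x / lib[j]) - np.log2(r / lib[ref])
        a = (np.log2(x / lib[j]) + np.log2(r / lib[ref])) / 2
        v = (lib[j] - x) / (lib[j] * x) + (lib[ref] - r) / (lib[ref] * r)
        if np.max(np.abs(m)) < 1e-6:
            continue
        n = len(m)
        lo_m, hi_m = np.floor(n * trim_m) + 1, n - np.floor(n * trim_m)
        lo_a, hi_a = np.floor(n * trim_a) + 1, n - np.floor(n * trim_a)
        rm = stats.rankdata(m)
        ra = stats.rankdata(a)
        keep2 = (rm >= lo_m) & (rm <= hi_m) & (ra >= lo_a) & (ra <= hi_a)
        if keep2.any():
            logf[j] = np.sum(m[keep2] / v[keep2]) / np.sum(1.0 / v[keep2])
    logf -= logf.mean()
    return 2.0 ** logf


class TestTmm:
    def test_identical_columns(self):
        c = pd.DataFrame({"a": [10, 20, 30], "b": [10, 20, 30]})
        assert tmm_factors(c).to_numpy() == pytest.approx([1.0, 1.0])

    def test_pure_depth_scaling(self):
        col = np.array([5, 50, 500, 17, 3, 80, 41, 9, 230, 12])
        c = pd.DataFrame({"a": col, "b": 2 * col})
        assert tmm_factors(c).to_numpy() == pytest.approx([1.0, 1.0])

    def test_composition_shift_matches_hand_oracle(self):
        # generic-position counts (distinct M values) with one gene's count
        # carrying a strong composition shift in sample b
        col = np.array([5, 50, 500, 17, 3, 80, 41, 9, 230, 12])
        col2 = np.array([7, 41, 390, 22, 2, 90, 36, 11, 280, 1200])
        c = pd.DataFrame({"a": col, "b": col2})
        got = tmm_factors(c).to_numpy()
        expected = oracle_tmm(c.to_numpy())
        assert not np.allclose(got, 1.0)
        assert got == pytest.approx(expected, abs=1e-9)

    def test_oracle_on_random_matrices(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            mat = rng.negative_binomial(4, 0.05, size=(50, 4)) + rng.integers(0, 2, (50, 4))
            df = pd.DataFrame(mat, columns=list("wxyz"))
            assert tmm_factors(df).to_numpy() == pytest.approx(oracle_tmm(mat), abs=1e-9)

    def test_geometric_mean_one(self):
        rng = np.random.default_rng(4)
        df = pd.DataFrame(rng.poisson(40, size=(100, 5)))
        f = tmm_factors(df).to_numpy()
        assert np.exp(np.log(f).mean()) == pytest.approx(1.0)

    def test_all_zero_column_rejected(self):
        c = pd.DataFrame({"a": [1, 2], "bad": [0, 0]})
        with pytest.raises(ValueError, match="bad"):
            tmm_factors(c)

    def test_scale_invariance_of_normalized_values(self):
        rng = np.random.default_rng(5)
        counts = pd.DataFrame(rng.poisson(50, size=(200, 3)), columns=list("abc"))
        scaled = counts.copy()
        scaled["b"] = scaled["b"] * 7
        n1 = NormalizedMatrix.from_counts(counts)
        n2 = NormalizedMatrix.from_counts(scaled)
        # near-invariance only: TMM precision weights depend weakly on depth,
        # so pure depth scaling perturbs the factor at the ~1e-3 level
        assert n2.normalized["b"].to_numpy() == pytest.approx(
            n1.normalized["b"].to_numpy(), rel=5e-3
        )


class TestSpearman:
    def test_identical(self):
        df = pd.DataFrame({"a": [1, 2, 3], "b": [1, 2, 3]})
        assert spearman_matrix(df).loc["a", "b"] == pytest.approx(1.0)

    def test_reversed(self):
        df = pd.DataFrame({"a": [1, 2, 3], "b": [3, 2, 1]})
        assert spearman_matrix(df).loc["a", "b"] == pytest.approx(-1.0)

    def test_ties_equal_rank_then_pearson(self):
        a, b = [1.0, 2.0, 2.0, 4.0], [1.0, 2.0, 3.0, 4.0]
        df = pd.DataFrame({"a": a, "b": b})
        got = spearman_matrix(df).loc["a", "b"]
        expected = stats.pearsonr(stats.rankdata(a), stats.rankdata(b)).statistic
        assert got == pytest.approx(expected)

    def test_constant_column_nan_with_warning(self, caplog):
        df = pd.DataFrame({"a": [1, 2, 3], "b": [5, 5, 5]})
        with caplog.at_level("WARNING"):
            m = spearman_matrix(df)
        assert np.isnan(m.loc["a", "b"])
        assert "constant" in caplog.text

    def test_symmetric_unit_diagonal(self):
        rng = np.random.default_rng(6)
        df = pd.DataFrame(rng.poisson(9, size=(30, 4)))
        m = spearman_matrix(df)
        assert np.allclose(m, m.T)
        assert np.allclose(np.diag(m), 1.0)


class TestMds:
    def test_identical_samples_zero_distance(self):
        df = pd.DataFrame({"a": [1.0, 2.0], "b": [1.0, 2.0], "c": [9.0, 1.0]})
        d = leading_logfc_distances(df, top_n=2)
        assert d.loc["a", "b"] == 0.0
        assert d.loc["a", "a"] == 0.0

    def test_symmetry(self):
        rng = np.random.default_rng(7)
        df = pd.DataFrame(rng.poisson(30, size=(40, 4)).astype(float))
        d = leading_logfc_distances(df)
        assert np.allclose(d, d.T)

    def test_hand_built_distance_and_eigen(self):
        df = pd.DataFrame(
            {"a": [4.0, 8.0, 16.0], "b": [8.0, 8.0, 16.0], "c": [4.0, 8.0, 64.0]}
        )
        d = leading_logfc_distances(df, top_n=2, prior_count=0.0)
        # brute-force gene-wise logFC enumeration
        logs = np.log2(df.to_numpy())
        for i, ci in enumerate(df.columns):
            for j, cj in enumerate(df.columns):
                if i == j:
                    continue
                lfc = np.sort(np.abs(logs[:, i] - logs[:, j]))[-2:]
                assert d.loc[ci, cj] == pytest.approx(np.sqrt(np.mean(lfc**2)))
        coords = classical_mds(d, dims=2)
        # with 3 points the 2-D embedding reproduces the distances exactly
        for ci in df.columns:
            for cj in df.columns:
                emb = np.linalg.norm(coords.loc[ci] - coords.loc[cj])
                assert emb == pytest.approx(d.loc[ci, cj], abs=1e-9)
        # eigenvalues agree with a direct eigendecomposition
        n = 3
        jmat = np.eye(n) - np.ones((n, n)) / n
        b = -0.5 * jmat @ (d.to_numpy() ** 2) @ jmat
        evals = np.sort(np.linalg.eigvalsh(b))[::-1]
        recon = (coords.to_numpy() ** 2).sum(axis=0)
        assert recon == pytest.approx(evals[:2], abs=1e-9)

    def test_dims_bound(self):
        df = pd.DataFrame(np.ones((5, 3)))
        with pytest.raises(ValueError):
            mds_coordinates(df, dims=3)

    def test_replicate_groups_cluster(self, default_generator, default_libraries):
        from cagekit.peaks import identify_peaks, quantify_peak_expression

        peaks = identify_peaks(default_libraries)
        counts, _ = quantify_peak_expression(peaks, default_libraries)
        rho = spearman_matrix(counts)
        groups = default_generator.ground_truth.sample_groups
        cols = list(counts.columns)
        within, between = [], []
        for i, a in enumerate(cols):
            for b in cols[i + 1:]:
                (within if groups[a] == groups[b] else between).append(rho.loc[a, b])
        assert min(within) > max(between)
        norm = NormalizedMatrix.from_counts(counts)
        coords = mds_coordinates(norm.normalized, top_n=100)
        for a in cols:
            for b in cols:
                if a == b or groups[a] != groups[b]:
                    continue
                mate = np.linalg.norm(coords.loc[a] - coords.loc[b])
                others = [
                    np.linalg.norm(coords.loc[a] - coords.loc[c])
                    for c in cols if groups[c] != groups[a]
                ]
                assert mate < min(others)
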