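import numpy as np
import pytest

from triproj.exceptions import DataError
from triproj.latent_factor import ScoreMatrix
from triproj.projection import (
    FusionConfig,
    disease_projection,
    fuse,
    lncrna_projection,
    project_and_fuse,
)
from triproj.similarity import SimilarityMatrix


def sim(values, names=None, kind="integrated"):
    values = np.asarray(values, dtype=float)
    names = names or [f"x{i}" for i in range(values.shape[0])]
    return SimilarityMatrix(names, values, kind)


def scores(values, rows=None, cols=None, stage="reconstructed"):
    values = np.asarray(values, dtype=float)
    rows = rows or [f"x{i}" for i in range(values.shape[0])]
    cols = cols or [f"y{j}" for j in range(values.shape[1])]
    return ScoreMatrix(rows, cols, values, stage=stage)


def naive_pipeline(ils, ids, psi, omega):
    """Triple-loop transliteration of the projection/fusion formulas —
    the independent oracle for the vectorized implementation."""
    m, e = psi.shape
    lp = np.zeros((m, e))
    for i in range(m):
        norm = np.sqrt(sum(ils[i, j] ** 2 for j in range(m)))
        for c in range(e):
            acc = sum(ils[i, j] * psi[j, c] for j in range(m))
            lp[i, c] = acc / norm if norm > 0 else 0.0
    dp = np.zeros((m, e))
    for j in range(e):
        norm = np.sqrt(sum(ids[i, j] ** 2 for i in range(e)))
        for r in range(m):
            acc = sum(ids[i, j] * psi[r, i] for i in range(e))
            dp[r, j] = acc / norm if norm > 0 else 0.0
    out = np.zeros((m, e))
    for i in range(m):
        ni = np.sqrt(sum(ils[i, j] ** 2 for j in range(m)))
        for j in range(e):
            nj = np.sqrt(sum(ids[i2, j] ** 2 for i2 in range(e)))
            denom = ni + nj
            num = omega * lp[i, j] + (1 - omega) * dp[i, j]
            out[i, j] = num / denom if denom > 0 else 0.0
    return lp, dp, out


class TestLncrnaProjection:
    def test_identity_similarity(self):
        psi = scores([[1.0, 2.0], [3.0, 4.0]])
        lp = lncrna_projection(sim(np.eye(2), psi.lncrna_names), psi)
        np.testing.assert_allclose(lp.values, psi.values)

    def test_all_ones_similarity(self):
        psi = scores([[1.0, 0.0], [0.0, 1.0]])
        lp = lncrna_projection(sim(np.ones((2, 2)), psi.lncrna_names), psi)
        np.testing.assert_allclose(lp.values, np.full((2, 2), 1 / np.sqrt(2)))

    def test_zero_similarity_row(self):
        psi = scores([[1.0, 2.0], [3.0, 4.0]])
        s = sim([[0.0, 0.0], [0.0, 1.0]], psi.lncrna_names)
        lp = lncrna_projection(s, psi)
        np.testing.assert_array_equal(lp.values[0], [0.0, 0.0])

    def test_name_mismatch(self):
        psi = scores([[1.0]])
        with pytest.raises(DataError):
            lncrna_projection(sim([[1.0]], ["other"]), psi)


class TestDiseaseProjection:
    def test_identity_similarity(self):
        psi = scores([[1.0, 2.0], [3.0, 4.0]])
        dp = disease_projection(sim(np.eye(2), psi.disease_names), psi)
        np.testing.assert_allclose(dp.values, psi.values)

    def test_all_ones_similarity(self):
        psi = scores([[1.0, 0.0], [0.0, 1.0]])
        dp = disease_projection(sim(np.ones((2, 2)), psi.disease_names), psi)
        np.testing.assert_allclose(dp.values, np.full((2, 2), 1 / np.sqrt(2)))

    @pytest.mark.parametrize("seed", range(4))
    def test_transposition_symmetry(self, seed):
        rng = np.random.default_rng(seed)
        m, e = rng.integers(2, 6, size=2)
        psi_values = rng.normal(size=(m, e))
        s_values = rng.uniform(size=(e, e))
        s_values = (s_values + s_values.T) / 2
        dnames = [f"d{j}" for j in range(e)]
        psi = scores(psi_values, cols=dnames)
        psi_t = scores(psi_values.T, rows=dnames, cols=psi.lncrna_names)
        dp = disease_projection(sim(s_values, dnames), psi)
        lp_t = lncrna_projection(sim(s_values, dnames), psi_t)
        np.testing.assert_allclose(dp.values, lp_t.values.T, atol=1e-12)


class TestFuse:
    def _parts(self, psi_values, ils_values, ids_values, omega):
        psi = scores(psi_values)
        ils = sim(ils_values, psi.lncrna_names)
        ids = sim(ids_values, psi.disease_names)
        lp = lncrna_projection(ils, psi)
        dp = disease_projection(ids, psi)
        return fuse(lp, dp, ils, ids, FusionConfig(omega)), psi

    def test_identity_similarities_halve_psi(self):
        rng = np.random.default_rng(0)
        psi_values = rng.normal(size=(3, 4))
        out, psi = self._parts(psi_values, np.eye(3), np.eye(4), omega=0.3)
        np.testing.assert_allclose(out.values, psi.values / 2.0, atol=1e-12)

    def test_omega_endpoints(self):
        rng = np.random.default_rng(1)
        psi_values = rng.uniform(size=(3, 3))
        s = rng.uniform(size=(3, 3))
        s = (s + s.T) / 2
        psi = scores(psi_values, rows=list("abc"), cols=list("xyz"))
        ils, ids = sim(s, list("abc")), sim(s, list("xyz"))
        lp = lncrna_projection(ils, psi)
        dp = disease_projection(ids, psi)
        row_n = np.linalg.norm(ils.values, axis=1)[:, None]
        col_n = np.linalg.norm(ids.values, axis=0)[None, :]
        only_lp = fuse(lp, dp, ils, ids, FusionConfig(1.0))
        only_dp = fuse(lp, dp, ils, ids, FusionConfig(0.0))
        np.testing.assert_allclose(only_lp.values, lp.values / (row_n + col_n))
        np.testing.assert_allclose(only_dp.values, dp.values / (row_n + col_n))

    def test_default_omega(self):
        assert FusionConfig().omega == 0.3

    @pytest.mark.parametrize("omega", [-0.1, 1.5])
    def test_omega_out_of_range(self, omega):
        with pytest.raises(DataError):
            FusionConfig(omega)

    def test_linearity_in_projections(self):
        rng = np.random.default_rng(2)
        psi = scores(rng.normal(size=(3, 4)))
        ils = sim(rng.uniform(size=(3, 3)), psi.lncrna_names)
        ids = sim(rng.uniform(size=(4, 4)), psi.disease_names)
        lp = lncrna_projection(ils, psi)
        dp = disease_projection(ids, psi)
        base = fuse(lp, dp, ils, ids, FusionConfig(0.4)).values
        a = 2.5
        lp_s = ScoreMatrix(lp.lncrna_names, lp.disease_names, a * lp.values,
                           stage="lncrna_projection")
        dp_s = ScoreMatrix(dp.lncrna_names, dp.disease_names, a * dp.values,
                           stage="disease_projection")
        scaled = fuse(lp_s, dp_s, ils, ids, FusionConfig(0.4)).values
        np.testing.assert_allclose(scaled, a * base, atol=1e-12)

    @pytest.mark.parametrize("omega", [0.0, 0.3, 0.7, 1.0])
    def test_bounded_by_projections(self, omega):
        rng = np.random.default_rng(3)
        psi = scores(rng.normal(size=(4, 5)))
        ils = sim(rng.uniform(size=(4, 4)), psi.lncrna_names)
        ids = sim(rng.uniform(size=(5, 5)), psi.disease_names)
        lp = lncrna_projection(ils, psi)
        dp = disease_projection(ids, psi)
        out = fuse(lp, dp, ils, ids, FusionConfig(omega)).values
        denom = (np.linalg.norm(ils.values, axis=1)[:, None]
                 + np.linalg.norm(ids.values, axis=0)[None, :])
        lo = np.minimum(lp.values, dp.values) / denom
        hi = np.maximum(lp.values, dp.values) / denom
        assert (out >= lo - 1e-12).all() and (out <= hi + 1e-12).all()


class TestBruteForceOracle:
    @pytest.mark.parametrize("seed", range(10))
    def test_matches_naive_loops(self, seed):
        rng = np.random.default_rng(seed)
        m, e = rng.integers(2, 7, size=2)
        psi_values = rng.normal(size=(m, e))
        ils_values = rng.uniform(size=(m, m))
        ils_values = (ils_values + ils_values.T) / 2
        ids_values = rng.uniform(size=(e, e))
        ids_values = (ids_values + ids_values.T) / 2
        # occasionally zero out a similarity row/column to hit the
        # zero-denominator branch
        if seed % 3 == 0:
            ils_values[0, :] = ils_values[:, 0] = 0.0
            ids_values[-1, :] = ids_values[:, -1] = 0.0
        omega = float(rng.uniform())

        psi = scores(psi_values)
        ils = sim(ils_values, psi.lncrna_names)
        ids = sim(ids_values, psi.disease_names)
        lp = lncrna_projection(ils, psi)
        dp = disease_projection(ids, psi)
        out = fuse(lp, dp, ils, ids, FusionConfig(omega))

        lp_n, dp_n, out_n = naive_pipeline(ils_values, ids_values, psi_values, omega)
        np.testing.assert_allclose(lp.values, lp_n, atol=1e-12)
        np.testing.assert_allclose(dp.values, dp_n, atol=1e-12)
        np.testing.assert_allclose(out.values, out_n, atol=1e-12)


class TestProjectAndFuse:
    def test_identity_ranking_preserved(self):
        rng = np.random.default_rng(4)
        psi = scores(rng.normal(size=(5, 6)))
        ils = sim(np.eye(5), psi.lncrna_names)
        ids = sim(np.eye(6), psi.disease_names)
        out = project_and_fuse(ils, ids, psi, FusionConfig(0.3))
        np.testing.assert_array_equal(
            np.argsort(out.values, axis=None), np.argsort(psi.values, axis=None)
        )

    def test_ncp_style_single_normalization(self):
        rng = np.random.default_rng(5)
        psi = scores(rng.uniform(size=(3, 3)))
        s = rng.uniform(size=(3, 3))
        s = (s + s.T) / 2
        ils = sim(s, psi.lncrna_names)
        ids = sim(s, psi.disease_names)
        out = project_and_fuse(ils, ids, psi, FusionConfig(0.3), style="ncp")
        lp_raw = ils.values @ psi.values
        dp_raw = psi.values @ ids.values
        denom = (np.linalg.norm(ils.values, axis=1)[:, None]
                 + np.linalg.norm(ids.values, axis=0)[None, :])
        expected = (0.3 * lp_raw + 0.7 * dp_raw) / denom
        np.testing.assert_allclose(out.values, expected, atol=1e-12)

    def test_unknown_style(self):
        psi = scores([[1.0]])
        ils = sim([[1.0]], psi.lncrna_names)
        ids = sim([[1.0]], psi.disease_names)
        with pytest.raises(DataError):
            project_and_fuse(ils, ids, psi, style="other")
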