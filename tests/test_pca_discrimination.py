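import numpy as np
import pandas as pd
import pytest

from hepamark import fixed_score as fs
from hepamark import normalization as nm
from hepamark import pca_discrimination as pca
from hepamark import synthetic_data as sd
from hepamark.errors import DataValidationError, NumericError
from hepamark.table_io import MARKER_GENES


def _frame(rng, n=20):
    return pd.DataFrame(rng.normal(0, 1, size=(n, 12)),
                        columns=list(MARKER_GENES),
                        index=[f"p{i}" for i in range(n)])


class TestStandardize:
    def test_columns_become_mean0_sd1(self, rng):
        z, mu, sigma = pca.standardize(_frame(rng))
        assert z.mean(axis=0).abs().max() <= 1e-12
        np.testing.assert_allclose(z.std(axis=0, ddof=1), 1.0, atol=1e-12)

    def test_duplicated_rows_raise_zero_variance(self):
        rows = pd.DataFrame([[1.0] * 12] * 5, columns=list(MARKER_GENES))
        with pytest.raises(NumericError, match="zero-variance gene"):
            pca.standardize(rows)

    def test_fewer_than_three_rows_rejected(self, rng):
        with pytest.raises(DataValidationError, match="at least 3 rows"):
            pca.standardize(_frame(rng, n=2))

    def test_hand_oracle_small_matrix(self, rng):
        rows = _frame(rng, n=4)
        z, mu, sigma = pca.standardize(rows)
        for g in MARKER_GENES:
            col = rows[g].to_numpy()
            m, s = col.mean(), col.std(ddof=1)
            np.testing.assert_allclose(z[g].to_numpy(), (col - m) / s)
            assert mu[g] == pytest.approx(m)
            assert sigma[g] == pytest.approx(s)


class TestFitPca:
    def _labels(self, index, pattern=("GTHC", "NGTHC")):
        reps = [pattern[i % len(pattern)] for i in range(len(index))]
        return pd.Series(reps, index=index)

    def test_rank_one_matrix_has_unit_pc1_variance(self):
        pattern = np.linspace(-1, 1, 12)
        scale = np.array([3.0, -1.0, 2.0, 0.5, -2.0])
        z = pd.DataFrame(np.outer(scale, pattern), columns=list(MARKER_GENES),
                         index=[f"p{i}" for i in range(5)])
        result = pca.fit_pca(z, self._labels(z.index))
        assert result.explained_variance_ratio[0] == pytest.approx(1.0)

    def test_loadings_are_unit_norm(self, rng):
        z, mu, sigma = pca.standardize(_frame(rng))
        result = pca.fit_pca(z, self._labels(z.index))
        norms = np.linalg.norm(result.loadings.to_numpy(), axis=0)
        np.testing.assert_allclose(norms, 1.0, atol=1e-12)

    def test_scores_equal_z_times_loadings(self, rng):
        z, mu, sigma = pca.standardize(_frame(rng))
        result = pca.fit_pca(z, self._labels(z.index))
        recomputed = z.to_numpy() @ result.loadings.to_numpy()
        np.testing.assert_allclose(result.score_matrix().to_numpy(),
                                   recomputed, atol=1e-9)

    def test_score_covariance_is_diagonal_eigenvalue_spectrum(self, rng):
        z, _, _ = pca.standardize(_frame(rng, n=30))
        result = pca.fit_pca(z, self._labels(z.index), n_components=2)
        S = result.score_matrix().to_numpy()
        cov = S.T @ S / (len(S) - 1)
        assert abs(cov[0, 1]) <= 1e-10
        # eigenvalues of the correlation matrix, descending
        eig = np.linalg.eigvalsh(np.corrcoef(z.to_numpy(), rowvar=False))[::-1]
        np.testing.assert_allclose(np.diag(cov), eig[:2], atol=1e-8)

    def test_explained_variance_fractions_valid(self, rng):
        z, _, _ = pca.standardize(_frame(rng))
        result = pca.fit_pca(z, self._labels(z.index))
        evr = result.explained_variance_ratio
        assert ((evr >= 0) & (evr <= 1)).all()
        assert (np.diff(evr) <= 1e-12).all()

    def test_orientation_puts_gthc_low_on_pc1(self, reference_panel):
        result = pca.fit_panel_pca(reference_panel)
        scores = result.scores
        gthc = scores.loc[scores["class"] == "GTHC", "PC1"].mean()
        non = scores.loc[scores["class"] != "GTHC", "PC1"].mean()
        assert gthc < non

    def test_pc2_largest_loading_is_positive(self, reference_panel):
        result = pca.fit_panel_pca(reference_panel)
        pc2 = result.loadings["PC2"].to_numpy()
        assert pc2[np.argmax(np.abs(pc2))] > 0

    def test_row_permutation_invariance(self, rng):
        z, _, _ = pca.standardize(_frame(rng, n=25))
        labels = self._labels(z.index)
        result = pca.fit_pca(z, labels)
        perm = rng.permutation(len(z))
        zp = z.iloc[perm]
        result_p = pca.fit_pca(zp, labels.iloc[perm])
        np.testing.assert_allclose(result.loadings.to_numpy(),
                                   result_p.loadings.to_numpy(), atol=1e-9)
        np.testing.assert_allclose(
            result.score_matrix().loc[zp.index].to_numpy(),
            result_p.score_matrix().to_numpy(), atol=1e-9)

    def test_unlabeled_fit_warns_and_skips_orientation(self, rng, caplog):
        z, _, _ = pca.standardize(_frame(rng))
        labels = pd.Series("QUERY", index=z.index)
        with caplog.at_level("WARNING"):
            result = pca.fit_pca(z, labels)
        assert result.orientation["pc1_flipped"] is None

    def test_synthetic_panel_fully_separated_on_pc1(self):
        cfg = sd.PanelSimulationConfig(
            n_points={"GTHC": 15, "NGTHC": 21, "NGTNHC": 26}, seed=8)
        panel = sd.simulate_reference_panel(cfg)  # 124 points
        result = pca.fit_panel_pca(panel)
        scores = result.scores
        assert scores.loc[scores["class"] == "GTHC", "PC1"].max() < \
            scores.loc[scores["class"] != "GTHC", "PC1"].min()


def _manual_result(pc1_by_class):
    """Build a minimal PCAResult with given {(point, class): pc1} scores."""
    records = [(pid, cls, v) for (pid, cls), v in pc1_by_class.items()]
    scores = pd.DataFrame(
        {"PC1": [v for _, _, v in records],
         "PC2": 0.0,
         "class": [c for _, c, _ in records]},
        index=[p for p, _, _ in records])
    loadings = pd.DataFrame(
        {"PC1": np.full(12, 1 / np.sqrt(12)), "PC2": np.full(12, 1 / np.sqrt(12))},
        index=list(MARKER_GENES))
    return pca.PCAResult(
        loadings=loadings, scores=scores,
        explained_variance_ratio=np.array([0.7, 0.2]),
        mu=pd.Series(0.0, index=list(MARKER_GENES)),
        sigma=pd.Series(1.0, index=list(MARKER_GENES)))


class TestPc1Border:
    def test_published_flanking_points_give_midpoint(self):
        result = _manual_result({
            ("DEN24L", "GTHC"): -0.637, ("other", "GTHC"): -5.0,
            ("FEN24M", "NGTHC"): -0.159, ("far", "NGTNHC"): 3.0,
        })
        border = pca.pc1_border(result)
        assert border.border == pytest.approx(-0.398)
        assert border.gthc_flank == "DEN24L"
        assert border.non_gthc_flank == "FEN24M"
        assert border.separable

    def test_symmetric_toy_border_is_zero(self):
        result = _manual_result({
            ("a", "GTHC"): -1.0, ("b", "NGTHC"): 1.0, ("c", "NGTNHC"): 2.0,
        })
        assert pca.pc1_border(result).border == 0.0

    def test_overlap_flags_not_separable(self):
        result = _manual_result({
            ("a", "GTHC"): 0.5, ("b", "NGTHC"): -0.5,
        })
        border = pca.pc1_border(result)
        assert not border.separable
        assert border.border == pytest.approx(0.0)

    def test_absent_class_fatal(self):
        result = _manual_result({("a", "NGTHC"): 0.5, ("b", "NGTNHC"): 1.0})
        with pytest.raises(DataValidationError, match="required"):
            pca.pc1_border(result)


class TestClassifyByPca:
    def test_below_border_is_gthc_like(self):
        result = _manual_result({("q", "QUERY"): -1.5, ("a", "GTHC"): -1.0,
                                 ("b", "NGTHC"): 1.0})
        calls = pca.classify_by_pca(result, -0.5, ["q"])
        assert calls["q"] == "GTHC-like"

    def test_exactly_at_border_is_non_gthc_like(self):
        result = _manual_result({("q", "QUERY"): -0.5})
        calls = pca.classify_by_pca(result, -0.5, ["q"])
        assert calls["q"] == "non-GTHC-like"

    def test_unknown_query_fatal(self):
        result = _manual_result({("a", "GTHC"): -1.0})
        with pytest.raises(DataValidationError, match="unknown query"):
            pca.classify_by_pca(result, 0.0, ["nope"])

    def test_end_to_end_synthetic_query(self, reference_panel, study_ratio):
        prof = nm.condition_profile(study_ratio, "AAF")
        queries = pd.DataFrame([prof.values], index=["AAF-mean"])
        result = pca.fit_panel_pca(reference_panel, queries=queries)
        border = pca.pc1_border(result)
        calls = pca.classify_by_pca(result, border.border, ["AAF-mean"])
        assert calls["AAF-mean"] == "GTHC-like"


class TestProjectOnly:
    def test_projected_queries_use_reference_standardization(self, reference_panel):
        queries = pd.DataFrame(
            [np.zeros(12)], columns=list(MARKER_GENES), index=["q0"])
        result = pca.fit_panel_pca(reference_panel, queries=queries,
                                   project_only=True)
        assert "q0" in result.scores.index
        assert result.scores.loc["q0", "class"] == "QUERY"
        z = (queries.iloc[0] - result.mu) / result.sigma
        expected = float(z.to_numpy() @ result.loadings["PC1"].to_numpy())
        assert result.scores.loc["q0", "PC1"] == pytest.approx(expected)

    def test_reference_scores_unchanged_by_projection(self, reference_panel):
        base = pca.fit_panel_pca(reference_panel)
        queries = pd.DataFrame([np.ones(12)], columns=list(MARKER_GENES),
                               index=["q0"])
        proj = pca.fit_panel_pca(reference_panel, queries=queries,
                                 project_only=True)
        ids = reference_panel.data.index
        np.testing.assert_allclose(
            base.scores.loc[ids, ["PC1", "PC2"]].to_numpy(),
            proj.scores.loc[ids, ["PC1", "PC2"]].to_numpy(), atol=1e-12)

    def test_colliding_query_ids_rejected(self, reference_panel):
        pid = reference_panel.data.index[0]
        queries = pd.DataFrame([np.zeros(12)], columns=list(MARKER_GENES),
                               index=[pid])
        with pytest.raises(DataValidationError, match="collide"):
            pca.fit_panel_pca(reference_panel, queries=queries)


class TestExtractFixedConstants:
    def test_round_trip_reproduces_pc1_scores(self, reference_panel):
        result = pca.fit_panel_pca(reference_panel)
        border = pca.pc1_border(result)
        constants = pca.extract_fixed_constants(result, border=border.border)
        ratios = reference_panel.ratios()
        for pid in ratios.index:
            prof = nm.Log2RatioProfile(values=ratios.loc[pid], label=str(pid))
            y1 = fs.approximate_pc1(prof, constants)
            assert abs(y1 - result.scores.loc[pid, "PC1"]) <= 1e-9

    def test_loadings_vector_unit_norm(self, reference_panel):
        constants = pca.extract_fixed_constants(
            pca.fit_panel_pca(reference_panel))
        assert np.sum(np.square(constants.a)) == pytest.approx(1.0, abs=1e-9)

    def test_loadings_correlate_with_published_vector(self, reference_panel):
        constants = pca.extract_fixed_constants(
            pca.fit_panel_pca(reference_panel))
        published = fs.default_constants()
        rho = np.corrcoef(constants.a, published.a)[0, 1]
        assert rho > 0.9
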