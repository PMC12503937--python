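"""Flight-style filtering, Gower/PCoA embedding, Mahalanobis distinctiveness
and the ecological regressions."""

import itertools

import numpy as np
import pandas as pd
import pytest

import wingleg as wl


def _table(rows, columns=None):
    rows = np.asarray(rows)
    return pd.DataFrame(
        rows,
        index=pd.Index([f"s{i}" for i in range(rows.shape[0])], name="species"),
        columns=columns or [f"style_{j}" for j in range(rows.shape[1])],
    )


class TestFilterFlight:
    def test_single_style_row_removed(self):
        rows = np.zeros((7, 4), dtype=int)
        rows[:, 0] = 1
        rows[1:, 1] = 1  # s0 has a single style
        rows[2, 2] = rows[3, 3] = 1
        out = wl.filter_flight(_table(rows))
        assert "s0" not in out.index
        assert len(out) == 6

    def test_two_style_row_retained(self):
        rows = np.zeros((6, 4), dtype=int)
        rows[:, :2] = 1
        rows[0, 2] = rows[1, 3] = 1
        out = wl.filter_flight(_table(rows))
        assert len(out) == 6

    def test_too_few_survivors_rejected(self):
        rows = np.eye(6, dtype=int)  # everyone has exactly one style
        with pytest.raises(ValueError, match="too few"):
            wl.filter_flight(_table(rows))

    def test_non_binary_rejected(self):
        with pytest.raises(ValueError, match="binary"):
            wl.filter_flight(_table(np.full((6, 3), 2)))

    def test_dead_columns_dropped_with_warning(self):
        rows = np.zeros((6, 4), dtype=int)
        rows[:, :2] = 1
        with pytest.warns(UserWarning, match="constant-zero"):
            out = wl.filter_flight(_table(rows))
        assert out.shape[1] == 2


class TestFlightDistance:
    def test_identical_rows_zero(self):
        rows = np.tile([1, 0, 1, 1, 0], (6, 1))
        D = wl.flight_distance(_table(rows))
        np.testing.assert_allclose(D.to_numpy(), 0.0, atol=1e-12)

    def test_four_mismatches_give_two(self):
        a = np.array([[1, 1, 1, 1, 0], [0, 0, 0, 0, 0]])
        D = wl.flight_distance(_table(a))
        assert D.iloc[0, 1] == pytest.approx(2.0)

    def test_matches_mismatch_count_oracle(self):
        rng = np.random.default_rng(0)
        rows = rng.integers(0, 2, (8, 5))
        D = wl.flight_distance(_table(rows)).to_numpy()
        for i in range(8):
            for j in range(8):
                mismatches = int(np.sum(rows[i] != rows[j]))
                assert D[i, j] == pytest.approx(np.sqrt(mismatches))

    def test_metric_axioms_exhaustive(self):
        rng = np.random.default_rng(1)
        for _ in range(5):
            rows = rng.integers(0, 2, (6, 6))
            D = wl.flight_distance(_table(rows)).to_numpy()
            np.testing.assert_allclose(D, D.T, atol=1e-12)
            np.testing.assert_allclose(np.diag(D), 0.0, atol=1e-12)
            for i, j, k in itertools.permutations(range(6), 3):
                assert D[i, j] <= D[i, k] + D[k, j] + 1e-12


class TestPcoa:
    def test_collinear_points_one_axis(self):
        D = pd.DataFrame(
            [[0.0, 1.0, 2.0], [1.0, 0.0, 1.0], [2.0, 1.0, 0.0]],
            index=list("abc"),
            columns=list("abc"),
        )
        scores = wl.pcoa(D)
        assert scores.shape[1] == 1
        x = scores.iloc[:, 0].to_numpy()
        np.testing.assert_allclose(
            np.abs(np.diff(np.sort(x))), [1.0, 1.0], atol=1e-10
        )

    def test_recovers_planted_geometry(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(10, 2))
        from scipy.spatial.distance import pdist, squareform

        D = pd.DataFrame(squareform(pdist(X)), index=range(10), columns=range(10))
        scores = wl.pcoa(D, threshold=0.01).to_numpy()[:, :2]
        Xc = X - X.mean(axis=0)
        # optimal orthogonal alignment (Procrustes)
        U, _, Vt = np.linalg.svd(scores.T @ Xc)
        R = U @ Vt
        assert np.abs(scores @ R - Xc).max() < 1e-8

    def test_equilateral_symmetry(self):
        D = pd.DataFrame(1.0 - np.eye(3), index=list("abc"), columns=list("abc"))
        scores = wl.pcoa(D, threshold=0.05)
        lam = scores.attrs["proportion_explained"]
        assert lam[0] == pytest.approx(lam[1], rel=1e-9)

    def test_scores_centred(self):
        rng = np.random.default_rng(3)
        rows = rng.integers(0, 2, (9, 6))
        scores = wl.pcoa(wl.flight_distance(_table(rows)))
        np.testing.assert_allclose(scores.mean(axis=0), 0.0, atol=1e-9)

    def test_threshold_too_high_rejected(self):
        D = pd.DataFrame(1.0 - np.eye(3), index=list("abc"), columns=list("abc"))
        with pytest.raises(ValueError, match="no axis"):
            wl.pcoa(D, threshold=0.9)

    def test_matches_skbio_reference(self):
        """Cross-check coordinates against the scikit-bio implementation."""
        from skbio.stats.ordination import pcoa as skbio_pcoa

        rng = np.random.default_rng(4)
        rows = rng.integers(0, 2, (12, 6))
        D = wl.flight_distance(_table(rows))
        ours = wl.pcoa(D, threshold=0.0)
        ref = skbio_pcoa(D.to_numpy(), number_of_dimensions=ours.shape[1])
        for k in range(ours.shape[1]):
            a = ours.iloc[:, k].to_numpy()
            b = ref.samples.iloc[:, k].to_numpy()
            agree = min(np.abs(a - b).max(), np.abs(a + b).max())
            assert agree < 1e-8


class TestMahalanobis:
    def test_centroid_species_zero(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(10, 2))
        X[0] = X[1:].mean(axis=0) * 0  # place one species at the raw origin
        scores = pd.DataFrame(X - X.mean(axis=0), index=[f"s{i}" for i in range(10)])
        fd = wl.mahalanobis_mflight(scores)
        at_centroid = np.abs(scores.to_numpy()).sum(axis=1).argmin()
        assert fd.m_flight.iloc[at_centroid] == fd.m_flight.min()

    def test_isotropic_equals_euclidean(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(400, 3))
        scores = pd.DataFrame(X, index=[f"s{i}" for i in range(400)])
        fd = wl.mahalanobis_mflight(scores)
        Xc = X - X.mean(axis=0)
        cov = Xc.T @ Xc / len(X)
        expected = np.sqrt(np.einsum("ij,ji->i", Xc, np.linalg.solve(cov, Xc.T)))
        np.testing.assert_allclose(fd.m_flight.to_numpy(), expected, atol=1e-10)

    def test_affine_invariance(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(15, 3))
        M = rng.normal(size=(3, 3)) + 3 * np.eye(3)
        a = wl.mahalanobis_mflight(pd.DataFrame(X, index=range(15)))
        b = wl.mahalanobis_mflight(pd.DataFrame(X @ M.T, index=range(15)))
        assert np.abs(a.m_flight.to_numpy() - b.m_flight.to_numpy()).max() < 1e-8

    def test_mean_d2_equals_axis_count(self, medium_dataset):
        fd = wl.flight_distinctiveness(medium_dataset["dataset"].flight_styles)
        assert fd.d2.mean() == pytest.approx(fd.scores.shape[1], abs=1e-6)

    def test_too_few_species_rejected(self):
        scores = pd.DataFrame(np.eye(3), index=list("abc"))
        with pytest.raises(ValueError, match="axes"):
            wl.mahalanobis_mflight(scores)


class TestEcologyModels:
    def test_exact_quadratic_perfect_fit(self):
        x = np.linspace(-1, 1, 12)
        y = 0.4 - 0.8 * x + 2.5 * x**2
        fit = wl.fit_ecology_models(
            pd.Series(y, index=range(12)), pd.Series(x, index=range(12)), "quadratic"
        )
        assert fit.adj_r2 == pytest.approx(1.0)
        assert fit.coefficients["delta2"] == pytest.approx(2.5, rel=1e-10)

    def test_permutation_type_one_error(self):
        """With response permuted (no association), the quadratic term
        rejects at the nominal rate."""
        rng = np.random.default_rng(8)
        n = 100
        x = rng.normal(size=n)
        y = rng.normal(size=n)
        idx = range(n)
        rej = 0
        reps = 1000
        for _ in range(reps):
            yp = rng.permutation(y)
            fit = wl.fit_ecology_models(
                pd.Series(yp, index=idx), pd.Series(x, index=idx), "quadratic"
            )
            rej += fit.pvalues["delta2"] < 0.05
        assert 0.03 <= rej / reps <= 0.07

    def test_rank_deficiency_rejected(self):
        x = np.zeros(10)
        y = np.arange(10.0)
        with pytest.raises(ValueError, match="rank"):
            wl.fit_ecology_models(
                pd.Series(y, index=range(10)), pd.Series(x, index=range(10)), "linear"
            )

    def test_linear_formula_coefficients(self):
        x = np.linspace(0, 1, 10)
        y = 1.0 + 2.0 * x
        fit = wl.fit_ecology_models(
            pd.Series(y, index=range(10)), pd.Series(x, index=range(10)), "linear"
        )
        assert fit.coefficients["delta"] == pytest.approx(2.0, rel=1e-10)
        assert fit.n == 10


class TestEndToEndCouplings:
    def test_altricial_quadratic_signal_present(self, medium_dataset):
        ds = medium_dataset["dataset"]
        fd = wl.flight_distinctiveness(ds.flight_styles)
        dev = ds.traits["dev_class"]
        alt = fd.m_flight.index.intersection(dev.index[dev == "altricial2"])
        fit = wl.fit_ecology_models(
            fd.m_flight.loc[alt], medium_dataset["scores"].scores, "quadratic"
        )
        assert fit.pvalues["delta2"] < 0.05
        assert fit.coefficients["delta2"] > 0
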