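"""MVAR fitting, spectral evaluation, interaction measures, vectorisation."""

import numpy as np
import pytest

from neurodecline.connectivity import (
    BANDS,
    DEFAULT_FREQS,
    MEASURES,
    MVARModel,
    band_average,
    compute_measure,
    fit_mvar,
    residuals,
    spectral_set,
    vectorize,
)


def simulate_mvar(coeffs, n, rng, sigma=None):
    p, m, _ = coeffs.shape
    sigma = sigma if sigma is not None else np.eye(m)
    chol = np.linalg.cholesky(sigma)
    burn = 500
    x = np.zeros((m, n + burn))
    e = chol @ rng.standard_normal((m, n + burn))
    for t in range(p, n + burn):
        acc = e[:, t]
        for k in range(1, p + 1):
            acc = acc + coeffs[k - 1] @ x[:, t - k]
        x[:, t] = acc
    return x[:, burn:]


class TestFitMVAR:
    def test_ar1_coefficient_recovered(self, rng):
        coeffs = np.array([[[0.6]]])
        x = simulate_mvar(coeffs, 10_000, rng)
        model = fit_mvar(x, order=1)
        assert abs(model.coeffs[0, 0, 0] - 0.6) < 0.02
        assert abs(model.sigma[0, 0] - 1.0) < 0.05

    def test_white_noise_gives_vanishing_structure(self, rng):
        x = rng.standard_normal((3, 20_000))
        model = fit_mvar(x, order=3)
        assert np.abs(model.coeffs).max() < 0.05
        off = model.sigma[~np.eye(3, dtype=bool)]
        assert np.abs(off).max() < 0.05

    def test_default_order_is_ten(self, rng):
        x = rng.standard_normal((2, 600))
        model = fit_mvar(x)
        assert model.order == 10

    def test_residual_covariance_matches_sigma(self, rng):
        coeffs = np.zeros((2, 2, 2))
        coeffs[0] = [[0.5, 0.0], [0.3, 0.4]]
        coeffs[1] = [[-0.2, 0.0], [0.0, -0.2]]
        x = simulate_mvar(coeffs, 50_000, rng)
        model = fit_mvar(x, order=2)
        res = residuals(model, x)
        assert np.allclose(np.cov(res), model.sigma, atol=0.02)

    def test_constant_channel_reported(self, rng):
        x = rng.standard_normal((3, 1000))
        x[1] = 4.2
        with pytest.raises(ValueError, match="channel index 1"):
            fit_mvar(x, order=2)

    def test_agrees_with_least_squares_var_at_large_n(self, rng):
        # independent estimator (statsmodels OLS VAR) as cross-check
        from statsmodels.tsa.vector_ar.var_model import VAR

        coeffs = np.zeros((1, 2, 2))
        coeffs[0] = [[0.5, 0.2], [-0.1, 0.4]]
        x = simulate_mvar(coeffs, 30_000, rng)
        lattice = fit_mvar(x, order=1)
        ols = VAR(x.T).fit(maxlags=1, trend="n")
        assert np.allclose(lattice.coeffs[0], ols.coefs[0], atol=0.01)


class TestSpectralSet:
    def test_zero_coefficients_give_identity_transfer(self):
        sigma = np.array([[2.0, 0.3], [0.3, 1.0]])
        model = MVARModel(coeffs=np.zeros((1, 2, 2)), sigma=sigma, fs=500.0)
        sset = spectral_set(model)
        assert np.allclose(sset.transfer, np.eye(2))
        assert np.allclose(sset.spectrum, sigma)

    def test_default_grid_has_124_frequencies(self):
        model = MVARModel(coeffs=np.zeros((1, 2, 2)), sigma=np.eye(2), fs=500.0)
        sset = spectral_set(model)
        assert len(sset.freqs) == 124
        assert sset.freqs[0] == 2.0 and sset.freqs[-1] == 125.0

    def test_ar1_spectrum_matches_closed_form(self):
        a, fs = 0.9, 500.0
        model = MVARModel(coeffs=np.full((1, 1, 1), a), sigma=np.eye(1), fs=fs)
        sset = spectral_set(model)

        def analytic(f):
            return 1.0 / np.abs(1 - a * np.exp(-2j * np.pi * f / fs)) ** 2

        ratio_est = sset.spectrum[0, 0, 0].real / sset.spectrum[-1, 0, 0].real
        ratio_true = analytic(2.0) / analytic(125.0)
        assert abs(ratio_est - ratio_true) < 1e-6 * ratio_true

    def test_transfer_inverts_polynomial(self, rng):
        x = simulate_mvar(np.array([[[0.5]]]), 5000, rng)
        model = fit_mvar(np.vstack([x, rng.standard_normal((1, 5000))]), order=2)
        sset = spectral_set(model)
        prod = sset.transfer @ sset.abar
        assert np.allclose(prod, np.eye(2), atol=1e-8)


@pytest.fixture(scope="module")
def coupled_sset():
    rng = np.random.default_rng(7)
    coeffs = np.zeros((2, 2, 2))
    coeffs[0] = [[0.55, 0.0], [0.4, 0.55]]
    coeffs[1] = [[-0.8, 0.0], [0.0, -0.8]]
    x = simulate_mvar(coeffs, 50_000, rng)
    model = fit_mvar(x, order=2, fs=100.0)
    return spectral_set(model, freqs=np.arange(1, 50, dtype=float))


class TestMeasures:
    def test_independence_gives_zero_cross_measures(self):
        model = MVARModel(coeffs=np.zeros((1, 2, 2)), sigma=np.eye(2), fs=500.0)
        sset = spectral_set(model)
        for name in ("coherence_complex", "PDC", "DTF", "GGC"):
            t = compute_measure(sset, name)
            assert np.abs(t[:, 0, 1]).max() < 1e-12
            assert np.abs(t[:, 1, 0]).max() < 1e-12
        coh = compute_measure(sset, "coherence_complex")
        assert np.allclose(np.abs(coh[:, 0, 0]), 1.0)

    def test_pdc_column_normalisation(self, coupled_sset):
        pdc = compute_measure(coupled_sset, "PDC")
        sums = (pdc**2).sum(axis=1)
        assert np.allclose(sums, 1.0, atol=1e-12)

    def test_dtf_row_normalisation(self, coupled_sset):
        dtf = compute_measure(coupled_sset, "DTF")
        sums = (dtf**2).sum(axis=2)
        assert np.allclose(sums, 1.0, atol=1e-12)

    def test_ffdtf_global_normalisation(self, coupled_sset):
        ff = compute_measure(coupled_sset, "ffDTF")
        sums = (ff**2).sum(axis=(0, 2))
        assert np.allclose(sums, 1.0, atol=1e-12)

    def test_directionality_of_planted_coupling(self, coupled_sset):
        pdc = compute_measure(coupled_sset, "PDC")
        assert pdc[:, 1, 0].mean() > 5 * pdc[:, 0, 1].mean()

    def test_squared_measures_bounded_and_ggc_nonnegative(self, coupled_sset):
        for name in ("PDC", "gPDC", "DTF", "dDTF", "ffDTF"):
            t = compute_measure(coupled_sset, name)
            assert t.min() >= 0.0 and t.max() <= 1.0 + 1e-9
        assert compute_measure(coupled_sset, "GGC").min() >= 0.0

    def test_direct_causality_aliases_ddtf(self, coupled_sset):
        assert np.allclose(
            compute_measure(coupled_sset, "direct_causality"),
            compute_measure(coupled_sset, "dDTF"),
        )

    def test_directionality_monte_carlo(self):
        # planted 1 -> 2 coupling dominates the reverse direction in the
        # resonant band for almost all short-segment fits
        coeffs = np.zeros((2, 2, 2))
        coeffs[0] = [[0.55, 0.0], [0.5, 0.55]]
        coeffs[1] = [[-0.8, 0.0], [0.0, -0.8]]
        wins = 0
        n_trials = 100
        for seed in range(n_trials):
            rng = np.random.default_rng(1000 + seed)
            x = simulate_mvar(coeffs, 500, rng)
            model = fit_mvar(x, order=2, fs=500.0)
            sset = spectral_set(model, freqs=np.arange(2, 126, dtype=float))
            pdc = compute_measure(sset, "PDC")
            banded, names = band_average(pdc, sset.freqs)
            # generator resonates near 10 Hz at fs 500 (pole angle ~14 Hz here)
            alpha = banded[names.index("alpha")]
            wins += alpha[1, 0] > alpha[0, 1]
        assert wins >= 95


class TestBandAverage:
    def test_delta_is_mean_of_2_3_4(self):
        freqs = DEFAULT_FREQS
        tensor = freqs[:, None, None] * np.ones((1, 1))
        banded, names = band_average(tensor, freqs)
        assert banded[names.index("delta"), 0, 0] == pytest.approx(3.0)

    def test_alpha_of_identity_measure_is_10_5(self):
        freqs = DEFAULT_FREQS
        tensor = freqs[:, None, None] * np.ones((1, 1))
        banded, names = band_average(tensor, freqs)
        assert banded[names.index("alpha"), 0, 0] == pytest.approx(10.5)

    def test_constant_measure_preserved_in_every_band(self, rng):
        tensor = np.full((124, 3, 3), 0.77)
        banded, _ = band_average(tensor, DEFAULT_FREQS)
        assert np.allclose(banded, 0.77)


class TestVectorize:
    def test_symmetric_17ch_has_136_pairs_per_band(self):
        banded = np.zeros((6, 17, 17))
        v, ids = vectorize(banded, "pCOH", [f"c{i}" for i in range(17)])
        assert len(v) == 136 * 6 == 816

    def test_directed_17ch_has_272_pairs_per_band(self):
        banded = np.zeros((6, 17, 17))
        v, ids = vectorize(banded, "PDC", [f"c{i}" for i in range(17)])
        assert len(v) == 272 * 6 == 1632

    def test_two_channel_symmetric_gives_one_value_per_band(self):
        banded = np.zeros((6, 2, 2))
        v, ids = vectorize(banded, "pCOH", ["a", "b"])
        assert len(v) == 6
        assert ids[0] == "pCOH:delta:a<->b"

    def test_complex_measure_emits_re_im_pairs(self):
        banded = np.full((6, 2, 2), 1 + 2j)
        v, ids = vectorize(banded, "coherence_complex", ["a", "b"])
        assert len(v) == 12
        assert ids[0].endswith(":re") and ids[1].endswith(":im")

    def test_channel_relabeling_permutes_identifiers_consistently(self, rng):
        banded = rng.normal(size=(6, 3, 3))
        names = ["x", "y", "z"]
        v1, ids1 = vectorize(banded, "PDC", names)
        perm = [2, 0, 1]
        permuted = banded[:, perm][:, :, perm]
        v2, ids2 = vectorize(permuted, "PDC", [names[i] for i in perm])
        lookup = dict(zip(ids2, v2))
        assert all(np.isclose(lookup[i], val) for i, val in zip(ids1, v1))

    def test_spectrum_keeps_diagonal(self):
        banded = np.zeros((6, 3, 3))
        v, ids = vectorize(banded, "spectrum", ["a", "b", "c"])
        assert len(v) == 6 * 6  # upper triangle incl. diagonal: 6 entries
        assert any(":a<->a" in i for i in ids)

    def test_all_declared_measures_have_conventions(self):
        for name, info in MEASURES.items():
            assert "directed" in info and "diagonal" in info
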