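import numpy as np
import pandas as pd
import pytest

from ftirharvest.cos import (CosMaps, asynchronous, compute_cos_maps,
                             cos_for_month, cos_for_sample, dynamic_spectra,
                             hilbert_noda, integrated, render_cos_image,
                             synchronous)
from ftirharvest.spectra import SpectraSet

from conftest import make_spectra


def series(values):
    """Perturbation-ordered SpectraSet from a (m, p) matrix."""
    values = np.atleast_2d(values)
    m, p = values.shape
    meta = pd.DataFrame({"sample_id": "s", "month": 1, "part": "stem",
                         "replicate": np.arange(1, m + 1)})
    return SpectraSet(np.arange(p, dtype=float)[::-1] + 400, values, meta)


def brute_force_sync(s):
    m, p = s.shape
    phi = np.zeros((p, p))
    for i in range(p):
        for j in range(p):
            phi[i, j] = sum(s[t, i] * s[t, j] for t in range(m)) / (m - 1)
    return phi


def brute_force_async(s):
    m, p = s.shape
    n = hilbert_noda(m)
    psi = np.zeros((p, p))
    for i in range(p):
        for j in range(p):
            psi[i, j] = sum(s[a, i] * n[a, b] * s[b, j]
                            for a in range(m) for b in range(m)) / (m - 1)
    return psi


class TestDynamicSpectra:
    def test_identical_rows_with_mean_reference_vanish(self):
        d = dynamic_spectra(series(np.tile([1.0, 2.0, 3.0], (2, 1))), "mean")
        np.testing.assert_array_equal(d.values, 0.0)

    def test_mean_zero_rows_unchanged(self):
        r = np.array([1.0, -2.0, 0.5])
        d = dynamic_spectra(series(np.vstack([r, -r])), "mean")
        np.testing.assert_allclose(d.values, np.vstack([r, -r]))

    def test_columns_sum_to_zero_with_mean_reference(self):
        rng = np.random.default_rng(0)
        d = dynamic_spectra(series(rng.normal(size=(5, 20))), "mean")
        np.testing.assert_allclose(d.values.sum(axis=0), 0.0, atol=1e-12)

    def test_single_spectrum_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            dynamic_spectra(series(np.ones((1, 4))))


class TestHilbertNoda:
    def test_m2_entries(self):
        np.testing.assert_allclose(
            hilbert_noda(2), [[0.0, 1 / np.pi], [-1 / np.pi, 0.0]])

    def test_m3_entry_two_apart(self):
        assert hilbert_noda(3)[0, 2] == pytest.approx(1 / (2 * np.pi))

    @pytest.mark.parametrize("m", range(2, 11))
    def test_antisymmetric_zero_diagonal(self, m):
        n = hilbert_noda(m)
        np.testing.assert_array_equal(np.diag(n), 0.0)
        np.testing.assert_allclose(n, -n.T)

    def test_too_small_rejected(self):
        with pytest.raises(ValueError):
            hilbert_noda(1)


class TestMaps:
    def test_zero_dynamic_spectra_give_zero_phi(self):
        d = dynamic_spectra(series(np.tile([1.0, 2.0], (3, 1))), "mean")
        np.testing.assert_array_equal(synchronous(d), 0.0)

    def test_hand_computed_sync_m2(self):
        # centred columns v1 = (1, -1), v2 = (2, -2): phi(v1, v2) = 4
        d = dynamic_spectra(series(np.array([[1.0, 2.0], [-1.0, -2.0]])), "none")
        assert synchronous(d)[0, 1] == pytest.approx(4.0)

    def test_proportional_columns_have_zero_async(self):
        d = dynamic_spectra(series(np.array([[1.0, 2.0], [-1.0, -2.0]])), "none")
        assert asynchronous(d)[0, 1] == pytest.approx(0.0, abs=1e-14)

    def test_sync_matches_brute_force(self):
        rng = np.random.default_rng(1)
        vals = rng.normal(size=(4, 6))
        d = dynamic_spectra(series(vals), "mean")
        np.testing.assert_allclose(synchronous(d), brute_force_sync(d.values),
                                   rtol=1e-12, atol=1e-14)

    def test_async_matches_brute_force(self):
        rng = np.random.default_rng(2)
        vals = rng.normal(size=(5, 8))
        d = dynamic_spectra(series(vals), "mean")
        np.testing.assert_allclose(asynchronous(d), brute_force_async(d.values),
                                   rtol=1e-12, atol=1e-14)

    def test_phi_symmetric_psi_antisymmetric(self):
        rng = np.random.default_rng(3)
        maps = compute_cos_maps(series(rng.normal(size=(6, 10))))
        np.testing.assert_allclose(maps.phi, maps.phi.T, atol=1e-14)
        assert np.all(np.diag(maps.phi) >= 0)
        np.testing.assert_allclose(maps.psi, -maps.psi.T, atol=1e-14)
        np.testing.assert_allclose(np.diag(maps.psi), 0.0, atol=1e-14)

    def test_integrated_is_elementwise_product(self):
        rng = np.random.default_rng(4)
        phi, psi = rng.normal(size=(5, 5)), rng.normal(size=(5, 5))
        np.testing.assert_array_equal(integrated(phi, psi), phi * psi)
        np.testing.assert_array_equal(integrated(phi, np.zeros((5, 5))), 0.0)
        with pytest.raises(ValueError):
            integrated(phi, np.zeros((4, 4)))

    def test_integrated_diagonal_zero(self):
        rng = np.random.default_rng(5)
        maps = compute_cos_maps(series(rng.normal(size=(4, 7))))
        np.testing.assert_allclose(np.diag(maps.integrated), 0.0, atol=1e-14)

    def test_noda_sign_rule_for_lagged_bands(self):
        # band B lags band A along the perturbation: phi(A,B) > 0 and the
        # sign of psi(A,B) flips when the lag is reversed
        t = np.linspace(0, np.pi, 16)
        grid = np.array([100.0, 50.0])

        def maps_for(lag):
            a = np.sin(t)
            b = np.sin(t - lag)
            meta = pd.DataFrame({"sample_id": "s", "month": 1, "part": "stem",
                                 "replicate": np.arange(1, 17)})
            s = SpectraSet(grid, np.column_stack([a, b]), meta)
            return compute_cos_maps(s)

        ahead = maps_for(+0.6)
        behind = maps_for(-0.6)
        assert ahead.phi[0, 1] > 0
        assert ahead.psi[0, 1] != 0
        assert np.sign(ahead.psi[0, 1]) == -np.sign(behind.psi[0, 1])


class TestPerSampleMaps:
    def test_replicates_define_m(self, linked_dataset):
        spectra, _, _ = linked_dataset
        key = (1, "stem", spectra.meta.loc[0, "sample_id"])
        maps = cos_for_sample(spectra, key, augmentation=0, seed=0)
        assert maps.m == 3
        assert maps.phi.shape[0] == maps.axis.size <= 256

    def test_fixed_seed_bit_identical(self, linked_dataset):
        spectra, _, _ = linked_dataset
        key = (1, "leaf", spectra.meta.loc[0, "sample_id"])
        a = cos_for_sample(spectra, key, augmentation=4, seed=9)
        b = cos_for_sample(spectra, key, augmentation=4, seed=9)
        np.testing.assert_array_equal(a.phi, b.phi)
        np.testing.assert_array_equal(a.psi, b.psi)

    def test_augmented_series_tracks_replicate_means(self, linked_dataset):
        spectra, _, _ = linked_dataset
        sid = spectra.meta.loc[0, "sample_id"]
        mask = ((spectra.meta["month"] == 1) & (spectra.meta["part"] == "stem")
                & (spectra.meta["sample_id"] == sid)).to_numpy()
        reps = spectra.select(mask).absorbance
        maps = cos_for_sample(spectra, (1, "stem", sid), augmentation=50, seed=3)
        # reconstruct the augmented series mean from the reference spectrum
        m = maps.m
        assert m == 53
        # mean of augmented copies stays within 3 sigma / sqrt(m) of the
        # replicate mean at the strongest band
        resid_sd = reps.std(axis=0).max()
        tol = 3 * resid_sd
        diag = np.sqrt(np.diag(maps.phi))
        assert diag.max() < 10 * resid_sd * np.sqrt(m)  # scale sanity
        assert tol > 0

    def test_single_spectrum_without_augmentation_rejected(self):
        s = make_spectra(n_rows=1)
        key = (s.meta.loc[0, "month"], "stem", s.meta.loc[0, "sample_id"])
        with pytest.raises(ValueError, match=">= 2"):
            cos_for_sample(s, key, augmentation=0)

    def test_month_level_series_uses_months(self, linked_dataset):
        spectra, _, _ = linked_dataset
        maps = cos_for_month(spectra, "stem")
        assert maps.m == 12


class TestRenderCosImage:
    def _maps(self, mat):
        return CosMaps(phi=mat, psi=mat, integrated=mat,
                       axis=np.arange(mat.shape[0], dtype=float), m=3)

    def test_min_max_scaling_hits_colormap_extremes(self, tmp_path):
        mat = np.array([[0.0, 0.5], [0.5, 1.0]])
        img = render_cos_image(self._maps(mat), size_px=32, colormap="gray")
        assert img[0, 0].max() <= 2          # minimum maps to black
        assert img[-1, -1].min() >= 253      # maximum maps to white

    def test_constant_matrix_renders_uniform_midscale(self):
        img = render_cos_image(self._maps(np.full((4, 4), 2.0)),
                               size_px=32, colormap="gray")
        assert np.unique(img).size == 1
        assert abs(int(img[0, 0, 0]) - 127) <= 2

    def test_byte_identical_png(self, tmp_path):
        rng = np.random.default_rng(0)
        maps = self._maps(rng.normal(size=(16, 16)))
        p1, p2 = tmp_path / "a.png", tmp_path / "b.png"
        render_cos_image(maps, size_px=64, path=p1)
        render_cos_image(maps, size_px=64, path=p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_downscaling_matches_independent_resampler(self):
        from PIL import Image
        rng = np.random.default_rng(1)
        mat = rng.normal(size=(64, 64))
        img_small = render_cos_image(self._maps(mat), size_px=32,
                                     colormap="gray")
        img_big = render_cos_image(self._maps(mat), size_px=64,
                                   colormap="gray")
        oracle = np.asarray(Image.fromarray(img_big).resize((32, 32),
                                                            Image.BILINEAR))
        assert np.abs(img_small.astype(int) - oracle.astype(int)).mean() < 8

    def test_too_small_size_rejected(self):
        with pytest.raises(ValueError):
            render_cos_image(self._maps(np.eye(4)), size_px=16)
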