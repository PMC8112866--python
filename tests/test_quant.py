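"""Calibration and cluster-counting accuracy against generator truth."""

import numpy as np
import pytest

from microdomain.core import CalibrationError, DegenerateFieldError, ImageField, ParameterError
from microdomain import simgen as sg
from microdomain.quant import (
    QuantParams,
    calibrate_single_molecule,
    detect_spots,
    estimate_background,
    quantify_field,
)


def _field(seed, **kw):
    return sg.simulate_dslb_field(sg.FieldSimParams(seed=seed, **kw))


class TestBackground:
    def test_constant_image(self):
        img = ImageField(np.full((64, 64), 7.0), 0.1)
        bg, _ = estimate_background(img)
        assert bg == 7.0

    def test_constant_plus_bright_spot(self):
        px = np.full((64, 64), 5.0)
        px[30:33, 30:33] = 500.0
        bg, _ = estimate_background(ImageField(px, 0.1))
        assert bg == 5.0

    def test_simulated_field_noise_free(self):
        img, _ = _field(1, n_singles=50, background_level=120.0, noise_model="none")
        bg, _ = estimate_background(img)
        assert bg == pytest.approx(120.0, rel=0.01)

    def test_annulus_method_returns_per_spot_values(self):
        px = np.full((64, 64), 10.0)
        px[20:24, 20:24] = 300.0
        from skimage.measure import label

        labels = label(px > 100)
        bg, per_spot = estimate_background(ImageField(px, 0.1), "annulus", labels=labels)
        assert bg == 10.0
        assert per_spot == {1: 10.0}


class TestCalibration:
    def test_noise_free_recovers_mean_within_2pct(self, calibration):
        assert calibration.single_intensity_mean == pytest.approx(1000.0, rel=0.02)
        assert calibration.n_spots >= 100

    def test_empty_field_raises(self):
        img, _ = _field(2, noise_model="none")
        with pytest.raises(CalibrationError):
            calibrate_single_molecule(img)

    def test_noisy_cv_field_within_10pct(self):
        img, _ = _field(
            3, field_size_px=(512, 512), n_singles=200, single_intensity_cv=0.2
        )
        calib = calibrate_single_molecule(img)
        assert calib.single_intensity_mean == pytest.approx(1000.0, rel=0.10)

    def test_result_validates_spot_count(self):
        from microdomain.quant import CalibrationResult

        with pytest.raises(CalibrationError):
            CalibrationResult(single_intensity_mean=100.0, single_intensity_sd=1.0, n_spots=5)


class TestDetectSpots:
    def test_blank_field_yields_no_spots(self, calibration):
        img, _ = _field(4, noise_model="none")
        assert detect_spots(img, calibration) == []

    def test_single_50_molecule_cluster_noise_free(self, calibration):
        img, _ = _field(
            5,
            n_clusters=1,
            cluster_fixed_molecules=50,
            noise_model="none",
            single_intensity_cv=0.0,
        )
        spots = detect_spots(img, calibration)
        assert len(spots) == 1
        assert spots[0].molecules == pytest.approx(50.0, rel=0.10)
        assert spots[0].is_cluster

    def test_trimer_field_recovers_three_molecules(self, calibration):
        img, _ = _field(6, field_size_px=(512, 512), n_trimers=80)
        spots = detect_spots(
            img, calibration, QuantParams(threshold_molecules=1.0)
        )
        mols = np.array([s.molecules for s in spots])
        assert len(mols) >= 50
        assert mols.mean() == pytest.approx(3.0, rel=0.10)

    def test_raising_threshold_never_adds_spots(self, calibration):
        img, _ = _field(7, n_singles=150, n_trimers=40, n_clusters=10)
        n_prev = None
        for k in (1.0, 2.0, 4.0, 8.0):
            n = len(detect_spots(img, calibration, QuantParams(threshold_molecules=k)))
            if n_prev is not None:
                assert n <= n_prev
            n_prev = n

    def test_linearity_doubling_molecules(self, calibration):
        """Doubling every emitter's molecule count doubles the estimates."""
        common = dict(
            n_clusters=12, noise_model="none", single_intensity_cv=0.0
        )
        img1, _ = _field(8, cluster_fixed_molecules=20, **common)
        img2, _ = _field(8, cluster_fixed_molecules=40, **common)
        m1 = np.sort([s.molecules for s in detect_spots(img1, calibration)])
        m2 = np.sort([s.molecules for s in detect_spots(img2, calibration)])
        assert len(m1) == len(m2) == 12
        assert np.allclose(m2 / m1, 2.0, rtol=0.02)

    def test_threshold_above_cluster_min_warns(self):
        with pytest.warns(UserWarning):
            QuantParams(threshold_molecules=15.0, cluster_min=10.0)


class TestQuantifyField:
    def test_no_spots_above_threshold_means_zero_fraction(self, calibration):
        img, _ = _field(9, n_singles=80)  # singles sit below the 5-molecule level
        q = quantify_field(img, calibration)
        assert q.clustered_fraction == 0.0

    def test_pure_cluster_field_fraction_near_one(self, calibration):
        img, _ = _field(
            10,
            n_clusters=20,
            cluster_fixed_molecules=30,
            noise_model="none",
            single_intensity_cv=0.0,
        )
        q = quantify_field(img, calibration)
        assert q.clustered_fraction == pytest.approx(1.0, abs=0.02)

    def test_60pct_clustered_recovered_at_default_snr(self, calibration):
        img, truth = _field(
            11, n_singles=600, n_trimers=120, n_clusters=48, cluster_fixed_molecules=30
        )
        q = quantify_field(img, calibration)
        truth_frac = truth.molecules_in_clusters / truth.total_molecules
        assert truth_frac == pytest.approx(0.6, abs=0.01)
        assert q.clustered_fraction == pytest.approx(truth_frac, abs=0.05)

    def test_adding_a_cluster_never_lowers_fraction(self, calibration):
        common = dict(
            n_singles=100,
            n_trimers=20,
            cluster_fixed_molecules=30,
            noise_model="none",
            single_intensity_cv=0.0,
        )
        img1, _ = _field(12, n_clusters=2, **common)
        img2, _ = _field(12, n_clusters=3, **common)
        f1 = quantify_field(img1, calibration).clustered_fraction
        f2 = quantify_field(img2, calibration).clustered_fraction
        assert f2 >= f1

    def test_degenerate_field_raises(self, calibration):
        img = ImageField(np.full((64, 64), 50.0), 0.1)
        with pytest.raises(DegenerateFieldError):
            quantify_field(img, calibration)

    def test_invariant_clustered_not_above_total(self, calibration):
        img, _ = _field(13, n_singles=100, n_clusters=20, cluster_fixed_molecules=40)
        q = quantify_field(img, calibration)
        assert 0.0 <= q.clustered_fraction <= 1.0
        assert q.clustered_intensity <= q.total_intensity + 1e-9

    def test_molecule_recovery_median_error_for_large_clusters(self, calibration):
        """Across seeded fields at default SNR, clusters of >= 20 molecules
        are counted with a median relative error well under 15%."""
        errs = []
        for seed in range(20):
            img, truth = _field(
                200 + seed, n_clusters=6, cluster_fixed_molecules=25
            )
            spots = [s for s in detect_spots(img, calibration) if s.is_cluster]
            errs.extend(abs(s.molecules - 25) / 25 for s in spots)
        assert np.median(errs) < 0.15
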