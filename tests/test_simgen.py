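"""Generator contracts: determinism, flux conservation, distributional truth."""

import math

import numpy as np
import pytest
from scipy import stats as sps
from scipy.special import erf

from microdomain.core import ParameterError, SizingError
from microdomain import simgen as sg

SQRT2 = math.sqrt(2.0)


def _analytic_field_flux(truth: sg.EmitterTruth, shape, sigma: float) -> float:
    """Independent oracle: total rendered flux = sum over emitters of the
    analytic Gaussian mass inside the field rectangle."""
    h, w = shape
    total = 0.0
    s = sigma * SQRT2
    for row in truth.emitters.itertuples():
        mr = 0.5 * (erf((h - row.row_px) / s) - erf((0 - row.row_px) / s))
        mc = 0.5 * (erf((w - row.col_px) / s) - erf((0 - row.col_px) / s))
        total += row.flux * mr * mc
    return total


class TestDslbField:
    def test_empty_field_is_flat_background(self):
        p = sg.FieldSimParams(seed=0, background_level=42.0, noise_model="none")
        image, truth = sg.simulate_dslb_field(p)
        assert np.all(image.pixels == 42.0)
        assert truth.emitters.empty
        assert truth.total_molecules == 0

    def test_same_seed_bit_identical(self):
        p = sg.FieldSimParams(seed=7, n_singles=50, n_trimers=10, n_clusters=5)
        img1, t1 = sg.simulate_dslb_field(p)
        img2, t2 = sg.simulate_dslb_field(p)
        assert np.array_equal(img1.pixels, img2.pixels)
        assert t1.emitters.equals(t2.emitters)

    def test_flux_conservation_against_analytic_oracle(self):
        p = sg.FieldSimParams(
            seed=3,
            n_singles=60,
            n_trimers=15,
            n_clusters=8,
            background_level=0.0,
            noise_model="none",
        )
        image, truth = sg.simulate_dslb_field(p)
        expected = _analytic_field_flux(truth, image.shape, p.psf_sigma_px)
        assert image.pixels.sum() == pytest.approx(expected, rel=1e-3)

    def test_truth_totals_are_consistent(self):
        p = sg.FieldSimParams(seed=5, n_singles=20, n_trimers=10, n_clusters=4)
        _, truth = sg.simulate_dslb_field(p)
        df = truth.emitters
        assert truth.total_molecules == int(df.molecule_count.sum())
        in_cl = int(df.loc[df.cluster_id.notna(), "molecule_count"].sum())
        assert truth.molecules_in_clusters == in_cl
        assert truth.total_molecules == 20 + 30 + in_cl

    def test_emitters_inside_field(self):
        p = sg.FieldSimParams(seed=9, field_size_px=(64, 64), n_singles=40, n_clusters=3)
        _, truth = sg.simulate_dslb_field(p)
        assert truth.emitters.row_px.between(0, 64).all()
        assert truth.emitters.col_px.between(0, 64).all()

    @pytest.mark.parametrize(
        "bad",
        [
            dict(field_size_px=(16, 64)),
            dict(single_intensity_mean=-1.0),
            dict(single_intensity_cv=1.5),
            dict(psf_sigma_px=0.0),
            dict(noise_model="salt"),
            dict(n_singles=-1),
            dict(cluster_min_molecules=0),
        ],
    )
    def test_invalid_params_rejected(self, bad):
        with pytest.raises(ParameterError):
            sg.FieldSimParams(seed=0, **bad)


class TestClusterSizeLaw:
    def test_truncation_redraws_below_minimum(self):
        p = sg.FieldSimParams(seed=11)
        counts = sg.sample_cluster_molecule_counts(p, 500)
        assert counts.min() >= p.cluster_min_molecules

    def test_default_law_median_and_mean(self):
        # the untruncated high-cholesterol law: median 25, arithmetic mean 38
        p = sg.FieldSimParams(seed=0)
        assert math.exp(p.cluster_logmu) == pytest.approx(25.0)
        assert math.exp(p.cluster_logmu + p.cluster_logsigma**2 / 2) == pytest.approx(38.0)

    def test_continuous_draws_match_truncated_lognormal(self):
        """KS of the sampler's continuous draws against the generating
        truncated law (conditioned on >= cluster_min)."""
        p = sg.FieldSimParams(seed=13)
        draws = sg.sample_cluster_molecule_counts(p, 1000, integer=False)
        lo = p.cluster_min_molecules
        base = sps.lognorm(s=p.cluster_logsigma, scale=math.exp(p.cluster_logmu))
        p_lo = base.cdf(lo)

        def trunc_cdf(x):
            return (base.cdf(x) - p_lo) / (1.0 - p_lo)

        res = sps.kstest(draws, trunc_cdf)
        assert res.pvalue > 0.01


class TestGuvSet:
    def test_zero_rate_gives_zero_counts(self):
        p = sg.GUVSimParams(seed=1, n_liposomes=12, lambda_clusters=0.0)
        pairs, truth = sg.simulate_guv_set(p)
        assert (truth.counts == 0).all()
        assert truth.clusters.empty

    def test_single_liposome_single_ring(self):
        p = sg.GUVSimParams(seed=2, n_liposomes=1, lambda_clusters=0.0, noise_model="none")
        pairs, truth = sg.simulate_guv_set(p)
        assert len(truth.liposomes) == 1
        mem = pairs[0][0].pixels
        from skimage.measure import label

        lab = label(mem > mem.mean() + 2 * mem.std(), connectivity=2)
        assert lab.max() == 1

    def test_counts_follow_poisson_law(self):
        p = sg.GUVSimParams(seed=3, n_liposomes=1000, lambda_clusters=0.72)
        _, truth = sg.simulate_guv_set(p)
        counts = truth.counts
        assert abs(counts.mean() - 0.72) < 3 * math.sqrt(0.72 / 1000)
        # chi-square GOF against the generating law (known lambda)
        kmax = counts.max()
        obs = np.bincount(counts, minlength=kmax + 2).astype(float)
        exp = 1000 * sps.poisson.pmf(np.arange(kmax + 2), 0.72)
        exp[-1] = 1000 * sps.poisson.sf(kmax, 0.72)
        while exp[-1] < 5:
            exp[-2] += exp[-1]
            obs[-2] += obs[-1]
            exp, obs = exp[:-1], obs[:-1]
        chi2 = float(((obs - exp) ** 2 / exp).sum())
        assert sps.chi2.sf(chi2, len(exp) - 1) > 0.01

    def test_field_too_small_raises(self):
        with pytest.raises(SizingError):
            sg.simulate_guv_set(
                sg.GUVSimParams(seed=4, n_liposomes=1, field_size_px=(48, 48),
                                radius_um_range=(4.0, 5.0))
            )

    def test_determinism(self):
        p = sg.GUVSimParams(seed=5, n_liposomes=10, lambda_clusters=0.5)
        (pairs1, t1), (pairs2, t2) = sg.simulate_guv_set(p), sg.simulate_guv_set(p)
        assert np.array_equal(pairs1[0][1].pixels, pairs2[0][1].pixels)
        assert t1.liposomes.equals(t2.liposomes)


class TestColocPair:
    def test_full_overlap_every_b_on_a(self):
        p = sg.ColocSimParams(seed=1, overlap_fraction=1.0)
        _, _, truth = sg.simulate_coloc_pair(p)
        assert truth.puncta_B.copositioned.all()
        a = truth.puncta_A[["row_px", "col_px"]].to_numpy()
        for row in truth.puncta_B.itertuples():
            d = np.hypot(a[:, 0] - row.row_px, a[:, 1] - row.col_px)
            assert d.min() == 0.0

    def test_zero_overlap_keeps_b_away_from_a(self):
        p = sg.ColocSimParams(seed=2, overlap_fraction=0.0)
        _, _, truth = sg.simulate_coloc_pair(p)
        a = truth.puncta_A[["row_px", "col_px"]].to_numpy()
        for row in truth.puncta_B.itertuples():
            d = np.hypot(a[:, 0] - row.row_px, a[:, 1] - row.col_px)
            assert d.min() > 2 * p.psf_sigma_px

    def test_copositioned_count_is_exact(self):
        # 480 px field at 0.1 um/px = 2304 um^2; density 200/2304 -> 200 puncta
        p = sg.ColocSimParams(
            seed=3,
            field_size_px=(480, 480),
            density_A=200 / 2304,
            density_B=200 / 2304,
            overlap_fraction=0.5,
        )
        _, _, truth = sg.simulate_coloc_pair(p)
        assert len(truth.puncta_B) == 200
        assert int(truth.puncta_B.copositioned.sum()) == 100

    def test_overcrowded_request_rejected(self):
        with pytest.raises(ParameterError):
            sg.simulate_coloc_pair(
                sg.ColocSimParams(seed=4, density_A=5.0, density_B=5.0)
            )


class TestFrapTrace:
    def test_full_recovery_returns_to_one(self):
        p = sg.FRAPSimParams(seed=1, mobile_fraction=1.0, tau_s=2.0, n_frames=200,
                             frame_interval_s=0.5, noise_sd=0.0)
        trace, _ = sg.simulate_frap_trace(p)
        assert trace.bleach_roi[-1] == pytest.approx(1.0, abs=1e-6)

    def test_immobile_trace_stays_at_floor(self):
        p = sg.FRAPSimParams(seed=1, mobile_fraction=0.0, bleach_depth=0.8, noise_sd=0.0)
        trace, _ = sg.simulate_frap_trace(p)
        post = trace.bleach_roi[trace.bleach_frame_index:]
        assert np.allclose(post, 0.2)

    def test_closed_form_value_at_one_tau(self):
        p = sg.FRAPSimParams(seed=1, mobile_fraction=0.74, tau_s=5.0,
                             frame_interval_s=1.0, bleach_depth=0.9, noise_sd=0.0)
        trace, _ = sg.simulate_frap_trace(p)
        idx = trace.bleach_frame_index + 5  # t = 5 s after bleach
        expected = 0.1 + 0.9 * 0.74 * (1.0 - math.exp(-1.0))
        assert trace.bleach_roi[idx] == pytest.approx(expected, abs=1e-12)

    def test_prebleach_mean_is_one(self):
        p = sg.FRAPSimParams(seed=2, noise_sd=0.0)
        trace, _ = sg.simulate_frap_trace(p)
        assert trace.bleach_roi[: trace.bleach_frame_index].mean() == pytest.approx(1.0)

    def test_invalid_prebleach_raises(self):
        with pytest.raises(ParameterError):
            sg.FRAPSimParams(seed=1, n_frames=10, prebleach_frames=10)
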