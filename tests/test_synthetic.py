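"""Tests for the synthetic data generator."""

import math

import numpy as np
import pytest
from scipy import stats

import toccsl
from toccsl.synthetic import (
    Aperture,
    CameraModel,
    GroundTruth,
    MonomerBrightnessLaw,
    ToccslTiming,
    generate_mixture_spots,
    generate_monomer_brightness,
    render_image,
    simulate_frap_trace,
    simulate_repeated_runs,
    simulate_toccsl_run,
)


class TestGroundTruthValidation:
    def test_fractions_must_sum_to_one(self, law):
        with pytest.raises(ValueError, match="sum to 1"):
            GroundTruth(fractions=(0.6, 0.3), monomer_law=law)

    def test_negative_fraction_rejected(self, law):
        with pytest.raises(ValueError):
            GroundTruth(fractions=(1.2, -0.2), monomer_law=law)

    def test_active_prob_bounds(self, law):
        with pytest.raises(ValueError, match="active_prob"):
            GroundTruth(fractions=(1.0,), monomer_law=law, active_prob=1.5)

    def test_nonpositive_scale_rejected(self):
        with pytest.raises(ValueError):
            MonomerBrightnessLaw(median=-5.0)
        with pytest.raises(ValueError):
            MonomerBrightnessLaw(median=100.0, geometric_sd=0.9)


class TestGenerateMonomerBrightness:
    def test_degenerate_law_returns_constant(self, degenerate_law):
        out = generate_monomer_brightness(degenerate_law, 3, seed=0)
        assert np.array_equal(out, [100.0, 100.0, 100.0])

    def test_same_seed_identical(self, law):
        a = generate_monomer_brightness(law, 1000, seed=42)
        b = generate_monomer_brightness(law, 1000, seed=42)
        assert np.array_equal(a, b)

    def test_different_seed_differs(self, law):
        a = generate_monomer_brightness(law, 1000, seed=1)
        b = generate_monomer_brightness(law, 1000, seed=2)
        assert not np.array_equal(a, b)

    def test_lognormal_mean_matches_closed_form(self, law):
        # closed-form lognormal mean: median * exp(sigma_log^2 / 2)
        expected = 100.0 * math.exp(0.5 * math.log(1.4) ** 2)
        sample = generate_monomer_brightness(law, 10**5, seed=7)
        assert sample.mean() == pytest.approx(expected, rel=0.01)

    def test_n_below_one_rejected(self, law):
        with pytest.raises(ValueError, match="n must be >= 1"):
            generate_monomer_brightness(law, 0, seed=0)

    def test_all_positive(self, law):
        assert np.all(generate_monomer_brightness(law, 10**4, seed=3) > 0)


class TestGenerateMixtureSpots:
    def test_pure_monomer(self, law):
        truth = GroundTruth(fractions=(1.0,), monomer_law=law)
        spots = generate_mixture_spots(truth, 500, seed=0)
        assert (spots["true_order"] == 1).all()
        assert (spots["active_count"] == 1).all()
        assert spots["visible"].all()

    def test_dimer_active_counts_binomial(self, law):
        # Binomial(2, 0.5) -> pmf (0.25, 0.5, 0.25)
        truth = GroundTruth(fractions=(0.0, 1.0), monomer_law=law,
                            active_prob=0.5)
        n = 10**5
        spots = generate_mixture_spots(truth, n, seed=1)
        for k, p in [(0, 0.25), (1, 0.5), (2, 0.25)]:
            count = int((spots["active_count"] == k).sum())
            sd = math.sqrt(n * p * (1 - p))
            assert abs(count - n * p) < 3 * sd

    def test_degenerate_mixture_brightness_values(self, degenerate_law):
        truth = GroundTruth(fractions=(0.6, 0.4), monomer_law=degenerate_law)
        n = 20000
        spots = generate_mixture_spots(truth, n, seed=2)
        values = set(np.unique(spots["brightness"]))
        assert values == {100.0, 200.0}
        frac_mono = (spots["brightness"] == 100.0).mean()
        assert frac_mono == pytest.approx(0.6, abs=0.02)

    def test_zero_active_invisible(self, law):
        truth = GroundTruth(fractions=(1.0,), monomer_law=law, active_prob=0.3)
        spots = generate_mixture_spots(truth, 5000, seed=3)
        dark = spots[spots["active_count"] == 0]
        assert len(dark) > 0
        assert (dark["brightness"] == 0).all()
        assert (~dark["visible"]).all()

    def test_brightness_is_sum_of_monomer_draws(self, degenerate_law):
        # invariant on the degenerate law: n-mer brightness == n * 100 exactly
        truth = GroundTruth(fractions=(0.3, 0.3, 0.4),
                            monomer_law=degenerate_law)
        spots = generate_mixture_spots(truth, 2000, seed=4)
        assert np.array_equal(spots["brightness"],
                              100.0 * spots["true_order"])


class TestRenderImage:
    def test_blank_equals_offset(self, camera):
        cam = CameraModel(offset=100.0, inverse_gain=4.0, read_noise_sd=0.0,
                          pixel_size=0.16)
        img = render_image([], [], [], 1.2, cam, (32, 32), seed=0, noise=False)
        assert img.dtype == np.uint16
        assert np.all(img == 100)

    def test_single_spot_photon_sum(self, fine_camera):
        img = render_image([16.0], [16.0], [500.0], 1.2, fine_camera,
                           (33, 33), seed=0, noise=False)
        photons = np.clip(img.astype(float) - 100.0, 0, None) * 0.1
        assert photons.sum() == pytest.approx(500.0, rel=0.005)

    def test_same_seed_bit_identical(self, camera):
        a = render_image([10.0], [10.0], [300.0], 1.2, camera, (24, 24),
                         seed=9, noise=True)
        b = render_image([10.0], [10.0], [300.0], 1.2, camera, (24, 24),
                         seed=9, noise=True)
        assert np.array_equal(a, b)

    def test_shape_validation(self, camera):
        with pytest.raises(ValueError, match="shape"):
            render_image([], [], [], 1.2, camera, (0, 10), seed=0)

    def test_positions_outside_frame_rejected(self, camera):
        with pytest.raises(ValueError, match="inside the frame"):
            render_image([100.0], [5.0], [100.0], 1.2, camera, (32, 32), seed=0)


class TestSimulateToccslRun:
    @pytest.fixture
    def setup(self, wildtype_truth, camera):
        aperture = Aperture(20, 60, 20, 60)
        return wildtype_truth, ToccslTiming(), aperture, camera

    def test_no_diffusion_no_reentry(self, setup):
        truth, timing, aperture, camera = setup
        _, _, table = simulate_toccsl_run(
            truth, timing, 0.0, aperture, camera, (80, 80), 1.2, seed=5,
            noise=False,
        )
        reentered = table[table["rendered_post"]]
        assert len(reentered) == 0

    def test_bleaching_reduces_aperture_spots(self, setup):
        truth, timing, aperture, camera = setup
        _, _, table = simulate_toccsl_run(
            truth, timing, 0.5, aperture, camera, (80, 80), 1.2, seed=6,
            noise=False,
        )
        pre_in = aperture.contains(table["x_px"].to_numpy(),
                                   table["y_px"].to_numpy()).sum()
        post_active = table["rendered_post"].sum()
        assert post_active < pre_in

    def test_prebleach_count_poisson(self, law, camera):
        # density 1/um^2 over (62.5px * 0.16)^2 = 100 um^2 -> mean 100
        truth = GroundTruth(fractions=(1.0,), monomer_law=law, density=1.0)
        timing = ToccslTiming()
        aperture = Aperture(10, 50, 10, 50)
        shape = (63, 63)  # 63*0.16 = 10.08 um per side
        area = shape[0] * shape[1] * 0.16**2
        _, _, table = simulate_toccsl_run(
            truth, timing, 0.1, aperture, camera, shape, 1.2, seed=8,
            noise=False,
        )
        mean = truth.density * area
        assert abs(len(table) - mean) < 3 * math.sqrt(mean)

    def test_aperture_outside_frame_rejected(self, setup):
        truth, timing, _, camera = setup
        with pytest.raises(ValueError, match="aperture"):
            simulate_toccsl_run(truth, timing, 0.1, Aperture(20, 120, 20, 60),
                                camera, (80, 80), 1.2, seed=0)

    def test_determinism(self, setup):
        truth, timing, aperture, camera = setup
        out1 = simulate_toccsl_run(truth, timing, 0.3, aperture, camera,
                                   (80, 80), 1.2, seed=11)
        out2 = simulate_toccsl_run(truth, timing, 0.3, aperture, camera,
                                   (80, 80), 1.2, seed=11)
        assert np.array_equal(out1[0], out2[0])
        assert np.array_equal(out1[1], out2[1])
        assert out1[2].equals(out2[2])

    def test_poisson_count_gof(self, law, camera):
        """Chi-square goodness of fit of prebleach counts over 200 fields."""
        truth = GroundTruth(fractions=(1.0,), monomer_law=law, density=0.4)
        timing = ToccslTiming()
        aperture = Aperture(10, 40, 10, 40)
        shape = (50, 50)
        mean = truth.density * shape[0] * shape[1] * 0.16**2  # 25.6
        counts = []
        for seed in range(200):
            _, _, table = simulate_toccsl_run(
                truth, timing, 0.0, aperture, camera, shape, 1.2, seed=seed,
                noise=False,
            )
            counts.append(len(table))
        counts = np.asarray(counts)
        # bin into quantile-ish ranges with expected counts >= 5
        edges = stats.poisson.ppf([0.0, 0.2, 0.4, 0.6, 0.8, 1.0], mean)
        edges[0], edges[-1] = -0.5, np.inf
        observed, _ = np.histogram(counts, bins=edges)
        cdf = stats.poisson.cdf(edges[1:-1], mean)
        probs = np.diff(np.concatenate([[0.0], cdf, [1.0]]))
        expected = probs * counts.size
        chi2 = ((observed - expected) ** 2 / expected).sum()
        p = stats.chi2.sf(chi2, df=len(observed) - 1)
        assert p > 0.001


class TestSimulateRepeatedRuns:
    def test_no_exchange_ratio_preserved(self, law):
        truth = GroundTruth(fractions=(0.6, 0.4), monomer_law=law)
        df = simulate_repeated_runs(truth, 0.6, exchange=False, runs=3,
                                    seed=0, n_spots=20000)
        for r in range(3):
            vis = df[(df["run"] == r) & df["visible"]]
            dimer_frac = (vis["active_count"] == 2).mean()
            assert dimer_frac == pytest.approx(0.4, abs=0.02)

    def test_survival_one_all_runs_identical(self, law):
        truth = GroundTruth(fractions=(0.6, 0.4), monomer_law=law)
        df = simulate_repeated_runs(truth, 1.0, exchange=True, runs=3,
                                    seed=1, n_spots=500)
        run0 = df[df["run"] == 0]["active_count"].to_numpy()
        for r in (1, 2):
            assert np.array_equal(
                df[df["run"] == r]["active_count"].to_numpy(), run0
            )

    def test_exchange_dimer_fraction_matches_enumeration(self, law):
        """Oracle: enumerate active-count outcomes for dimers at q = s^r."""
        s = 0.6
        truth = GroundTruth(fractions=(0.6, 0.4), monomer_law=law)
        df = simulate_repeated_runs(truth, s, exchange=True, runs=3, seed=2,
                                    n_spots=60000)
        for r in range(3):
            q = s**r
            # enumeration over per-fluorophore states
            vis_mono = 0.6 * q
            vis_dim_1 = 0.4 * 2 * q * (1 - q)
            vis_dim_2 = 0.4 * q * q
            expected = vis_dim_2 / (vis_mono + vis_dim_1 + vis_dim_2)
            vis = df[(df["run"] == r) & df["visible"]]
            observed = (vis["active_count"] == 2).mean()
            sd = math.sqrt(expected * (1 - expected) / len(vis))
            assert abs(observed - expected) < 4 * sd

    def test_apparent_monomer_fraction_nondecreasing(self, law):
        truth = GroundTruth(fractions=(0.5, 0.5), monomer_law=law)
        df = simulate_repeated_runs(truth, 0.5, exchange=True, runs=4, seed=3,
                                    n_spots=50000)
        fracs = []
        for r in range(4):
            vis = df[(df["run"] == r) & df["visible"]]
            fracs.append((vis["active_count"] == 1).mean())
        assert all(b >= a - 0.01 for a, b in zip(fracs, fracs[1:]))

    def test_invalid_args(self, wildtype_truth):
        with pytest.raises(ValueError):
            simulate_repeated_runs(wildtype_truth, 1.2, False, 3, 0)
        with pytest.raises(ValueError):
            simulate_repeated_runs(wildtype_truth, 0.5, False, 0, 0)


class TestSimulateFrapTrace:
    def test_zero_at_t0(self):
        trace = simulate_frap_trace(0.89, 0.02, [0.0], noise_sd=0.0)
        assert trace[0] == 0.0

    def test_plateau(self):
        # K*t = 20 -> plateau at mf
        trace = simulate_frap_trace(0.89, 0.02, [1000.0], noise_sd=0.0)
        assert trace[0] == pytest.approx(0.89, abs=1e-8)

    def test_characteristic_time(self):
        # t = 1/K: mf * (1 - 1/e)
        trace = simulate_frap_trace(0.8, 0.02, [50.0], noise_sd=0.0)
        assert trace[0] == pytest.approx(0.8 * (1 - math.exp(-1)), abs=1e-12)

    def test_negative_times_rejected(self):
        with pytest.raises(ValueError, match="nonnegative"):
            simulate_frap_trace(0.5, 0.1, [-1.0, 0.0])

    def test_seeded_noise_reproducible(self):
        t = np.arange(0, 100, 10.0)
        a = simulate_frap_trace(0.9, 0.02, t, noise_sd=0.02, seed=5)
        b = simulate_frap_trace(0.9, 0.02, t, noise_sd=0.02, seed=5)
        assert np.array_equal(a, b)
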