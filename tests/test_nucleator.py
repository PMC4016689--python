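"""Nucleator rays, somal-volume aggregation, shrinkage correction."""

import math

import numpy as np
import pytest
from scipy import stats

from stereovol.nucleator import (
    RaySampleSet,
    correct_for_shrinkage,
    nucleator_mean_volume,
    sample_rays,
    sample_rays_study,
    shrinkage,
    sine_weighted_alpha,
    tissue_volume_before_cm3,
)
from stereovol.phantom import PhantomParams, generate_phantom
from stereovol.sectioning import SectionPlan, cut_vertical_sections


def vertical_setup(phantom, seed, n_blocks=2):
    return cut_vertical_sections(
        phantom, SectionPlan(thickness_um=2.0), n_blocks=n_blocks, seed=seed
    )


class TestRays:
    def test_sphere_centered_rays_equal_radius(self, mono_phantom):
        blocks = vertical_setup(mono_phantom, seed=1)
        r = mono_phantom.semi_axes[0, 0]
        rs = sample_rays(
            mono_phantom, blocks[0], 0, n_rays=6, rng=np.random.default_rng(2)
        )
        assert np.allclose(rs.lengths_um, r)
        assert rs.volume_um3 == pytest.approx(4 / 3 * math.pi * r**3)

    def test_two_rays_one_antipodal_pair(self, mono_phantom):
        blocks = vertical_setup(mono_phantom, seed=1)
        rs = sample_rays(
            mono_phantom, blocks[0], 0, n_rays=2, rng=np.random.default_rng(3)
        )
        assert len(rs.lengths_um) == 2
        assert rs.alphas[1] == pytest.approx(math.pi - rs.alphas[0])

    def test_odd_ray_count_rejected(self, mono_phantom):
        blocks = vertical_setup(mono_phantom, seed=1)
        with pytest.raises(ValueError):
            sample_rays(mono_phantom, blocks[0], 0, n_rays=3, rng=np.random.default_rng(0))

    def test_sine_weighted_density(self):
        # oracle: the sine CDF (1 - cos a)/2, KS at alpha = 0.01
        a = sine_weighted_alpha(np.random.default_rng(7), 10_000)
        ks = stats.kstest(a, lambda x: (1 - np.cos(x)) / 2)
        assert ks.pvalue > 0.01

    def test_number_weighted_sampling_fraction(self, default_phantom):
        rng = np.random.default_rng(11)
        counts = []
        for _ in range(30):
            blocks = vertical_setup(default_phantom, seed=rng, n_blocks=4)
            s = sample_rays_study(default_phantom, blocks, period=5, n_rays=2, rng=rng)
            counts.append(len(s))
        mean = np.mean(counts)
        expected = default_phantom.true_cell_count / 5
        assert abs(mean - expected) < 3 * np.std(counts, ddof=1) / math.sqrt(len(counts))


class TestMeanVolume:
    def test_sphere_closed_form(self):
        rs = RaySampleSet(cell_id=0, lengths_um=np.array([3.0, 3.0]), alphas=np.zeros(2))
        est = nucleator_mean_volume([rs])
        assert est.mean_volume_um3 == pytest.approx(4 / 3 * math.pi * 27)

    def test_zero_lengths(self):
        rs = RaySampleSet(cell_id=0, lengths_um=np.zeros(4), alphas=np.zeros(4))
        assert nucleator_mean_volume([rs]).mean_volume_um3 == 0.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            nucleator_mean_volume([])

    def test_mean_equals_mean_of_cells(self):
        sets = [
            RaySampleSet(cell_id=i, lengths_um=np.array([l, l]), alphas=np.zeros(2))
            for i, l in enumerate((2.0, 3.0, 4.0))
        ]
        est = nucleator_mean_volume(sets)
        assert est.mean_volume_um3 == pytest.approx(np.mean(est.cell_volumes_um3))
        assert est.n_cells == 3

    def test_histogram_spans_range(self):
        sets = [
            RaySampleSet(cell_id=i, lengths_um=np.array([l, l]), alphas=np.zeros(2))
            for i, l in enumerate(np.linspace(1, 5, 30))
        ]
        est = nucleator_mean_volume(sets)
        assert est.histogram_counts.sum() == 30
        assert len(est.histogram_counts) >= 10

    def test_vertical_pipeline_unbiased_for_spheres(self, default_phantom):
        # oracle: analytic mean of the configured volume distribution
        rng = np.random.default_rng(21)
        means = []
        for _ in range(40):
            blocks = vertical_setup(default_phantom, seed=rng, n_blocks=4)
            s = sample_rays_study(default_phantom, blocks, period=4, n_rays=2, rng=rng)
            means.append(nucleator_mean_volume(s).mean_volume_um3)
        means = np.asarray(means)
        se = means.std(ddof=1) / math.sqrt(len(means))
        assert abs(means.mean() - default_phantom.true_mean_somal_volume_um3) < 3 * se

    def test_uniform_ray_weighting_biased_on_anisotropic_cells(self):
        # documented negative control: uniform in-plane angles overestimate
        # cells elongated along the vertical axis
        p = generate_phantom(
            PhantomParams(
                n_cells=250,
                somal_cv=0.0,
                shape="ellipsoid",
                aspect=(1.0, 1.0, 2.5),
                region_size_um=(250.0, 160.0, 260.0),
            ),
            seed=6,
        )
        rng = np.random.default_rng(9)
        est = {}
        for w in ("sine", "uniform"):
            vals = []
            for _ in range(10):
                blocks = vertical_setup(p, seed=rng, n_blocks=4)
                s = sample_rays_study(
                    p, blocks, period=1, n_rays=8, rng=rng, weighting=w
                )
                vals.append(nucleator_mean_volume(s).mean_volume_um3)
            est[w] = np.asarray(vals)
        truth = p.true_mean_somal_volume_um3
        z_sine = abs(est["sine"].mean() - truth) / (
            est["sine"].std(ddof=1) / math.sqrt(10)
        )
        z_unif = (est["uniform"].mean() - truth) / (
            est["uniform"].std(ddof=1) / math.sqrt(10)
        )
        assert z_sine < 4.0
        assert z_unif > 10.0


class TestShrinkage:
    def test_paper_average(self):
        assert shrinkage(1.0, 0.85) == pytest.approx(0.15)

    def test_no_change(self):
        assert shrinkage(0.7, 0.7) == 0.0

    def test_swelling_warns_not_raises(self):
        with pytest.warns(UserWarning, match="swelling"):
            s = shrinkage(1.0, 1.1)
        assert s == pytest.approx(-0.1)

    def test_weight_conversion(self):
        assert tissue_volume_before_cm3(0.5) == pytest.approx(0.52)

    def test_correction_identity_and_doubling(self):
        rs = RaySampleSet(cell_id=0, lengths_um=np.array([3.0, 3.0]), alphas=np.zeros(2))
        est = nucleator_mean_volume([rs])
        assert correct_for_shrinkage(est, 0.0).mean_volume_um3 == pytest.approx(
            est.mean_volume_um3
        )
        assert correct_for_shrinkage(est, 0.5).mean_volume_um3 == pytest.approx(
            2 * est.mean_volume_um3
        )

    def test_correction_monotone_in_shrinkage(self):
        rs = RaySampleSet(cell_id=0, lengths_um=np.array([3.0, 3.0]), alphas=np.zeros(2))
        est = nucleator_mean_volume([rs])
        vols = [
            correct_for_shrinkage(est, s).mean_volume_um3
            for s in (0.0, 0.1, 0.2, 0.4)
        ]
        assert all(b > a for a, b in zip(vols, vols[1:]))

    def test_full_shrinkage_rejected(self):
        rs = RaySampleSet(cell_id=0, lengths_um=np.array([3.0, 3.0]), alphas=np.zeros(2))
        est = nucleator_mean_volume([rs])
        with pytest.raises(ValueError):
            correct_for_shrinkage(est, 1.0)

    def test_roundtrip_recovers_unshrunk_measurement(self, default_phantom):
        # measuring shrunken tissue then correcting reproduces the unshrunk
        # measurement exactly when the same design randomness is used
        s = 0.15
        f_lin = (1 - s) ** (1 / 3)
        blocks = vertical_setup(default_phantom, seed=31, n_blocks=4)
        raw = sample_rays_study(
            default_phantom, blocks, period=4, n_rays=2,
            rng=np.random.default_rng(32),
        )
        shrunk = sample_rays_study(
            default_phantom, blocks, period=4, n_rays=2,
            rng=np.random.default_rng(32), shrink_linear=f_lin,
        )
        est_raw = nucleator_mean_volume(raw)
        est_corr = correct_for_shrinkage(nucleator_mean_volume(shrunk), s)
        assert est_corr.mean_volume_um3 == pytest.approx(est_raw.mean_volume_um3)
        assert np.allclose(est_corr.cell_volumes_um3, est_raw.cell_volumes_um3)
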