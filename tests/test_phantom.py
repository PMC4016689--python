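"""Phantom generation: ground-truth bookkeeping, packing rule, study draws."""

import math

import numpy as np
import pytest

from stereovol.phantom import (
    Cell,
    PackingError,
    PhantomParams,
    StudyScenario,
    generate_phantom,
    generate_study,
    lognormal_radius_params,
)


class TestCellInvariants:
    def test_nucleolus_must_be_inside(self):
        with pytest.raises(ValueError, match="nucleolus"):
            Cell(0, (0, 0, 0), (2, 2, 2), (3, 0, 0))

    def test_semi_axes_positive(self):
        with pytest.raises(ValueError, match="semi-axes"):
            Cell(0, (0, 0, 0), (2, 0.0, 2), (0, 0, 0))

    def test_sphere_volume(self):
        c = Cell(0, (0, 0, 0), (3.0, 3.0, 3.0), (0, 0, 0))
        assert c.volume_um3 == pytest.approx(4 / 3 * math.pi * 27)


class TestGenerate:
    def test_zero_count_rejected(self):
        with pytest.raises(ValueError, match="count"):
            generate_phantom(PhantomParams(n_cells=0), seed=0)

    def test_negative_cv_rejected(self):
        with pytest.raises(ValueError, match="CV"):
            generate_phantom(PhantomParams(somal_cv=-0.1), seed=0)

    def test_monodisperse_mean_volume_exact(self):
        r = (3 * 3588.0 / (4 * math.pi)) ** (1 / 3)
        p = generate_phantom(PhantomParams(n_cells=40, somal_cv=0.0), seed=3)
        assert p.true_mean_somal_volume_um3 == pytest.approx(4 / 3 * math.pi * r**3)
        assert np.allclose(p.semi_axes, r)

    def test_lognormal_mean_within_3se(self):
        # oracle: the configured log-normal volume distribution itself
        params = PhantomParams(n_cells=500, somal_cv=0.3)
        p = generate_phantom(params, seed=10)
        v = p.cell_volumes_um3
        se = v.std(ddof=1) / math.sqrt(v.size)
        assert abs(v.mean() - params.mean_somal_volume_um3) < 3 * se

    def test_lognormal_radius_params_roundtrip(self):
        mu, sigma = lognormal_radius_params(3000.0, 0.25)
        rng = np.random.default_rng(0)
        r = rng.lognormal(mu, sigma, size=200_000)
        v = 4 / 3 * math.pi * r**3
        assert v.mean() == pytest.approx(3000.0, rel=0.01)
        assert v.std() / v.mean() == pytest.approx(0.25, rel=0.02)

    def test_ground_truth_matches_contents(self, default_phantom):
        p = default_phantom
        assert p.true_cell_count == p.centers.shape[0]
        assert p.true_layer_volume_mm3 == float(np.prod(p.region_size_um)) / 1e9
        v = 4 / 3 * np.pi * np.prod(p.semi_axes, axis=1)
        assert p.true_mean_somal_volume_um3 == float(v.mean())

    def test_seed_determinism(self):
        a = generate_phantom(PhantomParams(n_cells=60), seed=11)
        b = generate_phantom(PhantomParams(n_cells=60), seed=11)
        assert np.array_equal(a.centers, b.centers)
        assert np.array_equal(a.semi_axes, b.semi_axes)
        assert np.array_equal(a.nucleoli, b.nucleoli)

    def test_cells_inside_region_with_z_containment(self, default_phantom):
        p = default_phantom
        L = np.asarray(p.region_size_um)
        assert np.all(p.centers >= 0) and np.all(p.centers <= L)
        assert np.all(p.centers[:, 2] - p.semi_axes[:, 2] >= 0)
        assert np.all(p.centers[:, 2] + p.semi_axes[:, 2] <= L[2])

    def test_no_cell_contains_anothers_nucleolus(self, default_phantom):
        p = default_phantom
        L = np.asarray(p.region_size_um)
        delta = p.nucleoli[:, None, :] - p.centers[None, :, :]
        for k in (0, 1):
            delta[:, :, k] -= L[k] * np.round(delta[:, :, k] / L[k])
        q2 = ((delta / p.semi_axes[None, :, :]) ** 2).sum(axis=2)
        np.fill_diagonal(q2, np.inf)
        assert not np.any(q2 < 1.0)

    def test_infeasible_packing_raises(self):
        params = PhantomParams(
            n_cells=200,
            region_size_um=(40.0, 40.0, 40.0),
            min_center_spacing_um=20.0,
            max_attempts_per_cell=5,
        )
        with pytest.raises(PackingError):
            generate_phantom(params, seed=0)

    def test_eccentric_nucleoli_strictly_inside(self):
        p = generate_phantom(
            PhantomParams(n_cells=200, nucleolus_eccentricity=0.8), seed=5
        )
        q = (p.nucleoli - p.centers) / p.semi_axes
        assert np.all((q**2).sum(axis=1) < 1.0)

    def test_cv_fidelity_over_many_phantoms(self):
        # pooled somal-volume CV over >=100 phantoms within 10% of configured
        target = 0.25
        vols = []
        for s in range(100):
            p = generate_phantom(PhantomParams(n_cells=60, somal_cv=target), seed=s)
            vols.append(p.cell_volumes_um3)
        v = np.concatenate(vols)
        cv = v.std(ddof=1) / v.mean()
        assert abs(cv - target) / target < 0.10

    def test_json_roundtrip(self):
        from stereovol.phantom import Phantom

        p = generate_phantom(PhantomParams(n_cells=15), seed=4)
        q = Phantom.from_json(p.to_json())
        assert np.allclose(p.centers, q.centers)
        assert q.true_cell_count == p.true_cell_count
        assert q.true_layer_volume_mm3 == pytest.approx(p.true_layer_volume_mm3)


class TestStudy:
    def test_zero_between_cv_identical_params(self):
        params = PhantomParams(n_cells=30)
        sc = StudyScenario(
            n_per_group=2,
            control_params=params,
            treated_params=params,
            between_animal_cv=0.0,
        )
        animals = generate_study(sc, seed=0)
        counts = {a.phantom.true_cell_count for a in animals}
        assert counts == {30}
        vols = {round(a.phantom.true_layer_volume_mm3, 12) for a in animals}
        assert len(vols) == 1

    def test_groups_balanced_and_labelled(self):
        sc = StudyScenario(
            n_per_group=3,
            control_params=PhantomParams(n_cells=20),
            treated_params=PhantomParams(n_cells=20),
        )
        animals = generate_study(sc, seed=1)
        labels = [a.group_label for a in animals]
        assert labels.count("control") == 3 and labels.count("treated") == 3

    def test_effect_direction_recovered_from_phantoms(self):
        # oracle: recompute group ground-truth means from emitted phantoms
        control = PhantomParams(n_cells=40, mean_somal_volume_um3=3588.0)
        treated = PhantomParams(n_cells=40, mean_somal_volume_um3=3037.0)
        sc = StudyScenario(
            n_per_group=8,
            control_params=control,
            treated_params=treated,
            between_animal_cv=0.05,
        )
        animals = generate_study(sc, seed=2)
        mean = {
            g: np.mean(
                [
                    a.phantom.true_mean_somal_volume_um3
                    for a in animals
                    if a.group_label == g
                ]
            )
            for g in ("control", "treated")
        }
        assert mean["treated"] < mean["control"]

    def test_study_determinism(self):
        sc = StudyScenario(
            n_per_group=2,
            control_params=PhantomParams(n_cells=25),
            treated_params=PhantomParams(n_cells=25),
        )
        a = generate_study(sc, seed=9)
        b = generate_study(sc, seed=9)
        for x, y in zip(a, b):
            assert x.animal_id == y.animal_id
            assert np.array_equal(x.phantom.centers, y.phantom.centers)

    def test_n_per_group_minimum(self):
        with pytest.raises(ValueError):
            StudyScenario(n_per_group=1).validate()
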