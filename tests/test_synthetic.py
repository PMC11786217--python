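"""Synthetic cohort generator: determinism, geometry, noise structure."""

import numpy as np
import pytest
from scipy import ndimage, stats

from bmrano.mask_ops import longest_axial_diameter, volume_mm3
from bmrano.synthetic import (
    CohortConfig,
    ConfigurationError,
    TrueLesionState,
    default_analysis_config,
    generate_cohort,
    perturb_contour,
    render_lesion_mask,
    simulate_manual_diameter,
    simulate_trajectory,
)
from bmrano.stability import temporal_monotonicity

from conftest import sphere_state


def small_config(**kw):
    defaults = dict(n_patients=4, lesions_per_patient=(2, 3), seed=9)
    defaults.update(kw)
    return CohortConfig(**defaults)


class TestGenerateCohort:
    def test_zero_patients_empty_cohort(self):
        cohort = generate_cohort(small_config(n_patients=0))
        assert cohort.n_lesions == 0

    def test_same_seed_identical_cohorts(self):
        c1 = generate_cohort(small_config())
        c2 = generate_cohort(small_config())
        assert c1.table().equals(c2.table())
        for t1, t2 in zip(c1.trajectories, c2.trajectories):
            for o1, o2 in zip(t1.observations, t2.observations):
                assert o1.manual_diameter_mm == o2.manual_diameter_mm
                for src in o1.masks:
                    assert np.array_equal(o1.masks[src].occupancy, o2.masks[src].occupancy)

    def test_different_seed_differs(self):
        c1 = generate_cohort(small_config(seed=9))
        c2 = generate_cohort(small_config(seed=10))
        assert not c1.table().equals(c2.table())

    def test_radionecrosis_fraction_binomial(self, default_cohort):
        # Bernoulli(0.109) per lesion: observed fraction within the 99% CI
        flags = [t.radionecrosis for t in default_cohort.trajectories]
        n, p = len(flags), 0.109
        lo, hi = stats.binom.ppf([0.005, 0.995], n, p) / n
        assert lo <= np.mean(flags) <= hi

    def test_every_lesion_has_baseline_and_followup(self, default_cohort):
        for traj in default_cohort.trajectories:
            assert traj.observations[0].time_days == 0
            assert len(traj.observations) >= 2
            first = traj.observations[0]
            assert set(first.masks) == {"manual", "automatic"}

    def test_schedule_shared_within_patient(self, default_cohort):
        by_patient = {}
        for traj in default_cohort.trajectories:
            by_patient.setdefault(traj.patient_id, set()).add(traj.times)
        assert all(len(v) == 1 for v in by_patient.values())

    def test_table_bookkeeping_matches_objects(self, default_cohort):
        table = default_cohort.table()
        assert table.lesion_id.nunique() == default_cohort.n_lesions
        assert table.patient_id.nunique() == len(
            {t.patient_id for t in default_cohort.trajectories}
        )

    def test_invalid_config_rejected(self):
        with pytest.raises(ConfigurationError):
            CohortConfig(trajectory_mix={"shrink": 0.5})
        with pytest.raises(ConfigurationError):
            CohortConfig(radionecrosis_fraction=1.5)
        with pytest.raises(ConfigurationError):
            CohortConfig(grid_spacing=0)
        with pytest.raises(ConfigurationError):
            CohortConfig(lesions_per_patient=(3, 2))


class TestSimulateTrajectory:
    def rng(self):
        return np.random.default_rng(5)

    def test_stable_noise_free_constant(self):
        times = np.array([0.0, 60, 120])
        v = simulate_trajectory(1000.0, "stable", times, 0.0, self.rng())
        assert np.allclose(v, 1000.0)

    def test_shrink_noise_free_strictly_decreasing(self):
        times = np.array([0.0, 60, 120, 180, 240])
        v = simulate_trajectory(1000.0, "shrink", times, 0.0, self.rng())
        assert np.all(np.diff(v) < 0)
        assert temporal_monotonicity(times=times, values=v) == pytest.approx(1.0)

    def test_grow_noise_free_strictly_increasing(self):
        times = np.array([0.0, 60, 120, 180])
        v = simulate_trajectory(1000.0, "grow", times, 0.0, self.rng())
        assert np.all(np.diff(v) > 0)

    def test_pseudo_progression_rise_then_fall(self):
        times = np.array([0.0, 60, 120, 180, 240])
        v = simulate_trajectory(1000.0, "pseudo_progression", times, 0.0, self.rng())
        d = np.diff(v)
        assert (d > 0).any() and (d < 0).any()
        assert np.argmax(v) not in (0,)  # the peak is a local rise

    def test_complete_response_suffix_of_zeros(self):
        times = np.array([0.0, 60, 120, 180])
        v = simulate_trajectory(1000.0, "complete_response", times, 0.1, self.rng())
        zero = np.flatnonzero(v == 0)
        assert len(zero) >= 1
        assert np.all(v[zero[0] :] == 0)
        assert v[0] == 1000.0

    def test_non_increasing_times_rejected(self):
        with pytest.raises(ValueError):
            simulate_trajectory(1.0, "stable", np.array([0.0, 60, 60]), 0.0, self.rng())
        with pytest.raises(ValueError):
            simulate_trajectory(1.0, "stable", np.array([10.0, 60]), 0.0, self.rng())


class TestRenderLesionMask:
    def test_sphere_volume_1mm_within_2pct(self, sphere_mask):
        assert volume_mm3(sphere_mask) == pytest.approx(4 / 3 * np.pi * 1e3, rel=0.02)

    def test_sphere_volume_quartermm_within_halfpct(self):
        mask = render_lesion_mask(sphere_state(10.0), spacing=0.25)
        analytic = 4 / 3 * np.pi * 1e3
        assert mask.n_voxels * 0.25**3 == pytest.approx(analytic, rel=0.005)

    def test_subvoxel_lesion_nonempty(self):
        state = TrueLesionState((0, 0, 0), (0.6, 0.6, 0.6), (0, 0, 0), 1.0, 0.0)
        mask = render_lesion_mask(state, spacing=1.0)
        assert mask.n_voxels >= 1

    def test_ellipsoid_volume_converges(self):
        state = TrueLesionState((0, 0, 0), (8, 6, 4), (20, 0, 40), 1.0, 0.0)
        analytic = 4 / 3 * np.pi * 8 * 6 * 4
        errs = []
        for spacing in (1.0, 0.5):
            mask = render_lesion_mask(state, spacing=spacing)
            errs.append(abs(mask.n_voxels * spacing**3 - analytic) / analytic)
        assert errs[1] < errs[0]  # O(spacing) surface error
        assert errs[0] < 0.03

    def test_too_small_grid_raises(self):
        with pytest.raises(ValueError, match="exceeds"):
            render_lesion_mask(sphere_state(10.0), spacing=1.0, extent_mm=8.0)


class TestPerturbContour:
    def test_amplitude_zero_identity(self, sphere_mask):
        rng = np.random.default_rng(0)
        for style in ("manual", "automatic"):
            out = perturb_contour(sphere_mask, style, 0.0, rng)
            assert np.array_equal(out.occupancy, sphere_mask.occupancy)

    def test_negative_amplitude_raises(self, sphere_mask):
        with pytest.raises(ValueError):
            perturb_contour(sphere_mask, "manual", -1.0, np.random.default_rng(0))

    def test_empty_mask_raises(self):
        from bmrano.mask_ops import Mask3D

        with pytest.raises(ValueError):
            perturb_contour(
                Mask3D(np.zeros((3, 3, 3), dtype=bool)), "manual", 1.0, np.random.default_rng(0)
            )

    @pytest.mark.parametrize("style", ["manual", "automatic"])
    def test_morphological_envelope(self, sphere_mask, style):
        # every changed voxel lies within `amplitude` of the original boundary
        amplitude = 1.0
        out = perturb_contour(sphere_mask, style, amplitude, np.random.default_rng(2))
        changed = out.occupancy ^ sphere_mask.occupancy
        inside = ndimage.distance_transform_edt(sphere_mask.occupancy)
        outside = ndimage.distance_transform_edt(~sphere_mask.occupancy)
        surf_dist = np.where(sphere_mask.occupancy, inside - 0.5, outside - 0.5)
        assert np.all(surf_dist[changed] <= amplitude + 1e-9)

    def test_manual_sawtooth_rougher_across_slices_than_automatic(self, sphere_mask):
        # per-slice equivalent radii: slice-to-slice variation is larger for
        # the sawtooth (independent per-slice) noise than the smooth 3D one
        def slice_roughness(mask):
            zs = np.unique(np.nonzero(mask.occupancy)[2])
            radii = np.array(
                [np.sqrt(mask.occupancy[:, :, z].sum() / np.pi) for z in zs]
            )
            return np.diff(radii).std()

        wins = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            man = perturb_contour(sphere_mask, "manual", 1.0, rng)
            auto = perturb_contour(sphere_mask, "automatic", 1.0, rng)
            wins += slice_roughness(man) > slice_roughness(auto)
        assert wins >= 18  # strictly higher variance in (almost) every seed


class TestSimulateManualDiameter:
    def test_bias_one_no_noise_identity(self, sphere_mask):
        d = simulate_manual_diameter(sphere_mask, 1.0, 0.0, np.random.default_rng(0))
        assert d == pytest.approx(longest_axial_diameter(sphere_mask))

    def test_bias_arithmetic(self, sphere_mask):
        lad = longest_axial_diameter(sphere_mask)
        d = simulate_manual_diameter(sphere_mask, 0.75, 0.0, np.random.default_rng(0))
        assert d == pytest.approx(0.75 * lad)
        assert 0.75 * 10.64 == pytest.approx(7.98)

    def test_mean_over_seeds_clt_bound(self, sphere_mask):
        lad = longest_axial_diameter(sphere_mask)
        noise_sd = 0.5
        draws = [
            simulate_manual_diameter(sphere_mask, 0.75, noise_sd, np.random.default_rng(s))
            for s in range(1000)
        ]
        sem = noise_sd / np.sqrt(1000)
        assert abs(np.mean(draws) - 0.75 * lad) < 3 * sem

    def test_empty_mask_raises(self):
        from bmrano.mask_ops import Mask3D

        with pytest.raises(ValueError):
            simulate_manual_diameter(
                Mask3D(np.zeros((2, 2, 2), dtype=bool)), 0.75, 0.0, np.random.default_rng(0)
            )


def test_noise_free_monotone_cohort_recovers_monotonicity():
    """Trajectory recovery: measured sizes of noise-free shrink/grow lesions
    are perfectly monotone in time for every lesion and method."""
    from bmrano.synthetic import ShapeConfig

    cfg = CohortConfig(
        n_patients=6,
        lesions_per_patient=(3, 4),
        n_followups=(2, 4),
        trajectory_mix={"shrink": 0.6, "grow": 0.4},
        volume_noise_sd=0.0,
        manual_contour_noise=0.0,
        auto_contour_noise=0.0,
        manual_diam_noise_sd=0.0,
        radionecrosis_fraction=0.0,
        shape=ShapeConfig(surface_noise=0.0),
        seed=21,
    )
    cohort = generate_cohort(cfg)
    assert cohort.n_lesions > 10
    for traj in cohort.trajectories:
        if len(traj.observations) < 3:
            continue
        # volumes: thousands of voxels change per step, so measured volumes
        # are strictly monotone and recover |Spearman| = 1 exactly
        for method in ("vol-manseg", "vol-autoseg"):
            series = traj.size_series(method)
            assert temporal_monotonicity(series) == pytest.approx(1.0), (
                traj.lesion_id,
                method,
                series.values,
            )
        # diameters: voxel quantisation can tie consecutive time points on
        # small lesions, so we require weak monotonicity (no reversal)
        for method in ("diam-manseg", "diam-autoseg"):
            values = np.array(traj.size_series(method).values)
            diffs = np.diff(values)
            assert np.all(diffs <= 0) or np.all(diffs >= 0), (
                traj.lesion_id,
                method,
                values,
            )
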