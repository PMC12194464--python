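"""Profile cleaning, windowing, normalization and group averaging."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from waxstrace import (
    CohortSpec,
    Profile1D,
    clean_profiles,
    group_average_profiles,
    l1_normalize,
    remove_nan,
    restrict_q,
    simulate_cohort,
    subtract_background,
)
from waxstrace.pipeline import preprocess_profiles


def make_profile(q, intensity, sigma=None, **meta):
    return Profile1D(
        q=q,
        intensity=np.asarray(intensity, dtype=float),
        sigma=np.zeros(len(q)) if sigma is None else np.asarray(sigma, dtype=float),
        **meta,
    )


class TestSubtractBackground:
    def test_zero_background_is_identity(self, noisy_profile_factory):
        prof = noisy_profile_factory(0)
        zero = prof.replace(intensity=np.zeros(len(prof)), sigma=np.zeros(len(prof)))
        out = subtract_background(prof, zero)
        np.testing.assert_array_equal(out.intensity, prof.intensity)

    def test_self_subtraction_quadrature(self, noisy_profile_factory):
        prof = noisy_profile_factory(1)
        out = subtract_background(prof, prof)
        assert np.allclose(out.intensity, 0.0)
        np.testing.assert_allclose(out.sigma, prof.sigma * np.sqrt(2))

    def test_subtract_then_add_roundtrip(self, noisy_profile_factory):
        prof, bg = noisy_profile_factory(2), noisy_profile_factory(3)
        back = subtract_background(prof, bg).replace()
        restored = back.replace(intensity=back.intensity + bg.intensity)
        np.testing.assert_allclose(restored.intensity, prof.intensity, atol=1e-12)

    def test_grid_mismatch_rejected(self, noisy_profile_factory):
        prof = noisy_profile_factory(0)
        shifted = prof.replace(q=prof.q + 0.1)
        with pytest.raises(ValueError):
            subtract_background(prof, shifted)


class TestRemoveNan:
    def test_finite_profile_unchanged(self, noisy_profile_factory):
        prof = noisy_profile_factory(0)
        assert remove_nan(prof) is prof

    def test_single_bad_row_dropped_and_idempotent(self, q_grid):
        intensity = np.ones_like(q_grid)
        intensity[100] = np.nan
        prof = make_profile(q_grid, intensity)
        once = remove_nan(prof)
        assert len(once) == len(q_grid) - 1
        assert np.all(np.diff(once.q) > 0)
        assert len(remove_nan(once)) == len(once)

    def test_all_bad_rejected(self, q_grid):
        prof = make_profile(q_grid, np.full_like(q_grid, np.nan))
        with pytest.raises(ValueError):
            remove_nan(prof)


class TestRestrictQ:
    def test_full_window_unchanged(self, q_grid):
        prof = make_profile(q_grid, np.ones_like(q_grid))
        assert len(restrict_q(prof, 0.0, 100.0)) == len(prof)

    def test_default_grid_retained_in_analysis_window(self, q_grid):
        prof = make_profile(q_grid, np.ones_like(q_grid))
        assert len(restrict_q(prof, 3.25, 21.0)) == 414

    def test_biomarker_window_count_matches_brute_force(self, q_grid):
        prof = make_profile(q_grid, np.ones_like(q_grid))
        expected = sum(1 for q in q_grid if 10.0 <= q <= 20.5)
        assert len(restrict_q(prof, 10.0, 20.5)) == expected

    def test_empty_result_rejected(self, q_grid):
        prof = make_profile(q_grid, np.ones_like(q_grid))
        with pytest.raises(ValueError):
            restrict_q(prof, 30.0, 40.0)


class TestL1Normalize:
    def test_arithmetic_example(self):
        prof = make_profile(np.array([1.0, 2.0]), [1.0, 3.0])
        out = l1_normalize(prof)
        np.testing.assert_allclose(out.intensity, [0.25, 0.75])

    def test_unit_mass_within_tolerance(self, noisy_profile_factory):
        out = l1_normalize(noisy_profile_factory(0))
        assert abs(np.abs(out.intensity).sum() - 1.0) < 1e-12

    def test_idempotent(self, noisy_profile_factory):
        once = l1_normalize(noisy_profile_factory(1))
        twice = l1_normalize(once)
        np.testing.assert_allclose(twice.intensity, once.intensity, rtol=1e-14)

    @given(st.floats(min_value=1e-6, max_value=1e6))
    def test_scale_invariance(self, alpha):
        q = np.linspace(1, 10, 20)
        base = make_profile(q, np.linspace(1, 5, 20), sigma=np.ones(20))
        scaled = base.replace(intensity=base.intensity * alpha, sigma=base.sigma * alpha)
        a, b = l1_normalize(base), l1_normalize(scaled)
        np.testing.assert_allclose(a.intensity, b.intensity, rtol=1e-9)
        np.testing.assert_allclose(a.sigma, b.sigma, rtol=1e-9)

    def test_zero_mass_rejected(self):
        prof = make_profile(np.array([1.0, 2.0]), [0.0, 0.0])
        with pytest.raises(ValueError):
            l1_normalize(prof)


class TestCleanProfiles:
    def test_nominal_cohort_retention(self):
        """Default criteria retain >= 99% of a nominal default-noise cohort."""
        profiles, _ = simulate_cohort(CohortSpec(seed=11))
        retained, report = clean_profiles(profiles)
        assert len(report.entries) == len(profiles)
        assert report.n_retained / len(profiles) >= 0.99

    def test_zero_mass_rejected_with_reason(self, q_grid):
        good = [
            make_profile(q_grid, np.random.default_rng(s).poisson(50, len(q_grid)),
                         sigma=np.ones(len(q_grid)), group="g", lobe="left")
            for s in range(3)
        ]
        bad = make_profile(q_grid, np.zeros(len(q_grid)), group="g", lobe="left")
        _, report = clean_profiles(good + [bad])
        entry = report.entries[-1]
        assert not entry.retained
        assert "non-positive mass" in entry.reasons

    def test_injected_shape_outlier_caught_by_mad_rule(self, control_params, q_grid):
        from waxstrace import simulate_profile

        profiles = []
        for s in range(12):
            p, _ = simulate_profile(control_params, q_grid, seed=s)
            profiles.append(p.replace(group="g", lobe="left", subject_id=f"m{s}"))
        outlier = profiles[0].replace(subject_id="weird")
        boosted = outlier.intensity.copy()
        boosted[: len(boosted) // 2] *= 100.0
        profiles.append(outlier.replace(intensity=boosted))
        _, report = clean_profiles(profiles)
        assert not report.entries[-1].retained
        assert any("MAD" in r for r in report.entries[-1].reasons)
        assert all(e.retained for e in report.entries[:-1])

    def test_every_input_accounted_once(self, q_grid):
        profiles = [
            make_profile(q_grid, np.ones(len(q_grid)), group="a", lobe="left")
            for _ in range(5)
        ]
        _, report = clean_profiles(profiles)
        assert sorted(e.index for e in report.entries) == list(range(5))


class TestGroupAverage:
    def test_single_profile_is_itself_with_zero_sem(self, noisy_profile_factory):
        prof = noisy_profile_factory(0).replace(group="Control", lobe="left")
        out = group_average_profiles([prof])[("Control", "left")]
        np.testing.assert_array_equal(out.intensity, prof.intensity)
        assert np.all(out.sigma == 0.0)

    def test_identical_profiles_zero_sem(self, noisy_profile_factory):
        prof = noisy_profile_factory(1).replace(group="g", lobe="left")
        out = group_average_profiles([prof, prof.replace()])[("g", "left")]
        np.testing.assert_array_equal(out.intensity, prof.intensity)
        assert np.allclose(out.sigma, 0.0)

    def test_permutation_invariance(self, noisy_profile_factory):
        profs = [
            noisy_profile_factory(s).replace(group="g", lobe="left") for s in range(4)
        ]
        a = group_average_profiles(profs)[("g", "left")]
        b = group_average_profiles(profs[::-1])[("g", "left")]
        np.testing.assert_allclose(a.intensity, b.intensity)

    def test_grid_mismatch_rejected(self, noisy_profile_factory):
        a = noisy_profile_factory(0).replace(group="g", lobe="left")
        b = a.replace(q=a.q + 0.01)
        with pytest.raises(ValueError):
            group_average_profiles([a, b])

    def test_day16_left_lobe_regions_shift_as_generated(self):
        """Day16 left-lobe group mean: water region up, lipid region down."""
        spec = CohortSpec(seed=21, n_per_group=3, positions_per_lobe=4)
        profiles, _ = simulate_cohort(spec)
        retained, _ = preprocess_profiles(profiles)
        means = group_average_profiles(retained)
        ctrl = means[("Control", "left")]
        day16 = means[("Day16", "left")]
        water = (ctrl.q >= 17.0) & (ctrl.q <= 19.0)
        lipid = (ctrl.q >= 12.5) & (ctrl.q <= 14.5)
        assert day16.intensity[water].mean() > ctrl.intensity[water].mean()
        assert day16.intensity[lipid].mean() < ctrl.intensity[lipid].mean()


class TestPipelineOrder:
    def test_declared_stage_order_output(self, control_params, q_grid):
        """remove_nan -> restrict -> L1: the composed output is reproduced."""
        from waxstrace import simulate_profile

        prof, _ = simulate_profile(control_params, q_grid, seed=5)
        dirty = prof.intensity.copy()
        dirty[7] = np.nan
        prof = prof.replace(intensity=dirty)
        retained, report = preprocess_profiles([prof])
        assert report.n_retained == 1
        manual = l1_normalize(restrict_q(remove_nan(prof), 3.25, 21.0))
        np.testing.assert_array_equal(retained[0].intensity, manual.intensity)
        assert abs(np.abs(retained[0].intensity).sum() - 1.0) < 1e-12
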