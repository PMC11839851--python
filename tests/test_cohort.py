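"""Synthetic cohort generator: phantom rendering, reader panel, OOD profiles."""

import numpy as np
import pytest

from spectvote.cohort import (
    OOD_SHIFTS,
    SMOOTHING_LEVELS_MM,
    CohortConfig,
    OODProfile,
    PhantomParams,
    ReaderModel,
    ReaderVotes,
    SeverityMixture,
    background_roi_mask,
    generate_cohort,
    generate_ood_cohort,
    generate_phantom,
    load_cohort,
    render_template,
    save_cohort,
    simulate_readers,
    striatal_mask,
)


class TestPhantom:
    def test_severity_monotone_striatal_signal(self):
        """Noise-free striatal ROI mean strictly decreases with severity."""
        mask = striatal_mask()
        means = [
            render_template(PhantomParams(severity=s, noise_sd=0.0))[mask].mean()
            for s in np.linspace(0.0, 1.0, 11)
        ]
        assert all(a > b for a, b in zip(means, means[1:]))

    def test_seeded_determinism(self):
        p = PhantomParams(severity=0.4)
        a = generate_phantom(p, "ASC", 12.0, seed=42)
        b = generate_phantom(p, "ASC", 12.0, seed=42)
        np.testing.assert_array_equal(a.pixels, b.pixels)

    def test_contrast_matches_configuration(self):
        """Measured striatum/background mean ratio equals the configured
        contrast on the unconvolved, noise-free template."""
        p = PhantomParams(
            severity=0.0, noise_sd=0.0, intrinsic_fwhm_mm=0.0, striatal_contrast_normal=4.0
        )
        img = generate_phantom(p, "ASC", 0.0, seed=0).pixels
        ratio = img[striatal_mask()].mean() / img[background_roi_mask()].mean()
        assert ratio == pytest.approx(4.0, rel=0.01)

    def test_variants_differ_by_fixed_transform(self):
        from spectvote.cohort import Variant

        p = PhantomParams(severity=0.2, noise_sd=0.0)
        asc = render_template(p, Variant.ASC)
        noasc = render_template(p, Variant.NOASC)
        bg = background_roi_mask()
        assert noasc[bg].mean() == pytest.approx(1.25 * asc[bg].mean())

    @pytest.mark.parametrize(
        "kwargs", [dict(severity=-0.1), dict(severity=1.5), dict(severity=0.5, noise_sd=-1.0)]
    )
    def test_invalid_params_rejected(self, kwargs):
        with pytest.raises(ValueError):
            PhantomParams(**kwargs)

    def test_non_member_smoothing_level_rejected(self):
        with pytest.raises(ValueError):
            generate_phantom(PhantomParams(severity=0.1), "ASC", 11.0, seed=0)

    def test_images_finite_nonnegative(self):
        img = generate_phantom(PhantomParams(severity=0.9, noise_sd=2.0), "NOASC", 18.0, 5)
        assert np.all(np.isfinite(img.pixels)) and np.all(img.pixels >= 0)


class TestReaders:
    def test_deterministic_threshold(self):
        model = ReaderModel(thresholds=(0.5, 0.5, 0.5), noise_sds=(0.0, 0.0, 0.0))
        assert simulate_readers(0.9, model, seed=0).votes == (1, 1, 1)
        assert simulate_readers(0.1, model, seed=0).votes == (0, 0, 0)

    @pytest.mark.parametrize("severity", [0.0, 0.3, 0.5, 0.7, 1.0])
    def test_identical_noise_free_readers_are_unanimous(self, severity):
        model = ReaderModel(thresholds=(0.5, 0.5, 0.5), noise_sds=(0.0, 0.0, 0.0))
        assert simulate_readers(severity, model, seed=1).unanimous

    def test_votes_reproducible(self):
        model = ReaderModel()
        assert simulate_readers(0.5, model, 11).votes == simulate_readers(0.5, model, 11).votes

    def test_no_discrepancy_beyond_noise_bound(self):
        """Perceptual noise is bounded: scans farther than twice the largest
        noise sd from the boundary always get unanimous votes."""
        model = ReaderModel()
        mix = SeverityMixture()
        rng = np.random.default_rng(3)
        bound = 2.0 * max(model.noise_sds)
        n_checked = 0
        for i in range(20_000):
            s = mix.sample(rng)
            if abs(s - 0.5) <= bound:
                continue
            n_checked += 1
            assert simulate_readers(s, model, seed=i).unanimous
        assert n_checked > 15_000


class TestCohort:
    def test_counts_and_structure(self, small_cohort):
        assert len(small_cohort) == 40
        for rec in small_cohort:
            assert len(rec.instances) == 12
            variants = {(i.variant.value, i.smoothing_fwhm_mm) for i in rec.instances}
            assert len(variants) == 12
            assert {i.smoothing_fwhm_mm for i in rec.instances} == set(SMOOTHING_LEVELS_MM)
            assert all(i.scan_id == rec.scan_id for i in rec.instances)
            assert len(rec.votes) == 3

    def test_seeded_reproducibility(self, small_cohort):
        again = generate_cohort(CohortConfig(n_scans=40, seed=7))
        for a, b in zip(small_cohort, again):
            assert a.severity == b.severity and a.votes.votes == b.votes.votes
            np.testing.assert_array_equal(a.instances[5].pixels, b.instances[5].pixels)

    def test_too_few_scans_rejected(self):
        with pytest.raises(ValueError):
            CohortConfig(n_scans=5)

    def test_round_trip_persistence(self, small_cohort, tmp_path):
        save_cohort(small_cohort[:10], tmp_path / "c")
        loaded = load_cohort(tmp_path / "c")
        assert len(loaded) == 10
        orig = {r.scan_id: r for r in small_cohort[:10]}
        for rec in loaded:
            ref = orig[rec.scan_id]
            assert rec.votes.votes == ref.votes.votes
            np.testing.assert_allclose(
                rec.instances[3].pixels, ref.instances[3].pixels, rtol=1e-6
            )


class TestOOD:
    def test_single_instance_per_scan(self):
        recs = generate_ood_cohort(
            CohortConfig(n_scans=10, seed=1, ood_profile=OODProfile.MPH_LIKE)
        )
        assert len(recs) == 10
        assert all(len(r.instances) == 1 for r in recs)
        assert all(len(r.votes) == 1 for r in recs)

    def test_in_dist_profile_rejected(self):
        with pytest.raises(ValueError):
            generate_ood_cohort(CohortConfig(n_scans=10, seed=1))

    def test_profile_ordering(self):
        mph = OOD_SHIFTS[OODProfile.MPH_LIKE]
        ppmi = OOD_SHIFTS[OODProfile.PPMI_LIKE]
        assert mph["contrast_gain"] > 1.0 and mph["noise_gain"] < 1.0
        assert mph["intrinsic_fwhm_mm"] < 8.0 < ppmi["intrinsic_fwhm_mm"]

    def test_ppmi_like_prevalence(self):
        n = 645
        recs = generate_ood_cohort(
            CohortConfig(n_scans=n, seed=2, ood_profile=OODProfile.PPMI_LIKE)
        )
        frac = np.mean([r.true_class for r in recs])
        half_ci = 1.96 * np.sqrt(0.679 * 0.321 / n)
        assert abs(frac - 0.679) < half_ci

    def test_mph_contrast_higher_noise_lower(self):
        base = CohortConfig(n_scans=10, seed=3)
        mph = generate_ood_cohort(
            CohortConfig(n_scans=10, seed=3, ood_profile=OODProfile.MPH_LIKE)
        )
        indist = generate_cohort(base)
        sm, bm = striatal_mask(), background_roi_mask()

        def contrast(rec_img):
            return rec_img[sm].mean() / rec_img[bm].mean()

        # compare the unsmoothed in-distribution instance of normal scans
        mph_normals = [r.instances[0].pixels for r in mph if r.true_class == 0]
        ind_normals = [
            r.instances[0].pixels for r in indist if r.true_class == 0
        ]
        assert np.mean([contrast(i) for i in mph_normals]) > np.mean(
            [contrast(i) for i in ind_normals]
        )


class TestVotePattern:
    def test_empty_votes_rejected(self):
        with pytest.raises(ValueError):
            ReaderVotes(())

    def test_non_binary_votes_rejected(self):
        with pytest.raises(ValueError):
            ReaderVotes((0, 2, 1))
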