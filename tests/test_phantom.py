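"""Phantom generator: determinism, tissue composition, score sampling."""

import numpy as np
import pytest

from ctamuscle.phantom import (
    DSA_PARAMS,
    PhantomSpec,
    SubjectRecord,
    TISSUE_LABELS,
    TissueParams,
    generate_cohort,
    generate_phantom,
    sample_runoff_scores,
    cohort_table,
)

from conftest import homogeneous_spec, small_spec


class TestSpecValidation:
    def test_rejects_bad_values(self):
        with pytest.raises(ValueError):
            PhantomSpec(grid_shape=(4, 64, 64))
        with pytest.raises(ValueError):
            PhantomSpec(imf_fraction=1.5)
        with pytest.raises(ValueError):
            PhantomSpec(spacing=(0.0, 3.0, 5.0))
        with pytest.raises(ValueError):
            TissueParams(10.0, -1.0)

    def test_subject_record_group_score_consistency(self):
        with pytest.raises(ValueError):
            SubjectRecord("x", "mild", dsa_score=9.0, cta_score=5.0)
        with pytest.raises(ValueError):
            SubjectRecord("x", "severe", dsa_score=3.0, cta_score=5.0)
        with pytest.raises(ValueError):
            SubjectRecord("x", "mild", dsa_score=-1.0, cta_score=5.0)

    def test_leg_too_big_for_grid_names_structure(self, mild_subject):
        spec = PhantomSpec(grid_shape=(8, 8, 8))
        with pytest.raises(ValueError, match="leg outline"):
            generate_phantom(spec, mild_subject)


class TestGeneratePhantom:
    def test_constant_muscle_hu(self, mild_subject):
        """With all randomness off, every muscle voxel equals the set mean."""
        tissues = dict(
            muscle_mild=TissueParams(45.0, 0.0),
            muscle_severe=TissueParams(45.0, 0.0),
            subcutaneous_fat=TissueParams(-100.0, 0.0),
            intramuscular_fat=TissueParams(0.0, 0.0),
            cortical_bone=TissueParams(1200.0, 0.0),
            marrow=TissueParams(30.0, 0.0),
            artery_contrast=TissueParams(300.0, 0.0),
            vein=TissueParams(90.0, 0.0),
        )
        spec = homogeneous_spec(tissue_params=tissues)
        vol, labels = generate_phantom(spec, mild_subject, return_labels=True)
        muscle = labels == TISSUE_LABELS["muscle"]
        assert muscle.sum() > 0
        assert (vol.hu[muscle] == 45).all()

    def test_muscle_mean_matches_group_parameter(self, mild_subject):
        """>= 1e4 muscle voxels: sample mean near 44.6 HU (no subject offset)."""
        spec = homogeneous_spec(grid_shape=(64, 64, 60))
        vol, labels = generate_phantom(spec, mild_subject, return_labels=True)
        muscle = labels == TISSUE_LABELS["muscle"]
        assert muscle.sum() >= 10_000
        assert abs(vol.hu[muscle].mean() - 44.6) < 0.5
        assert abs(vol.hu[muscle].std() - 16.0) < 0.5

    def test_determinism(self, mild_subject):
        spec = small_spec()
        a = generate_phantom(spec, mild_subject)
        b = generate_phantom(spec, mild_subject)
        assert np.array_equal(a.hu, b.hu)

    def test_contains_expected_tissues(self, small_phantom):
        _, labels = small_phantom
        for tissue in ("muscle", "subcutaneous_fat", "cortical_bone", "marrow",
                       "artery_contrast", "vein"):
            assert (labels == TISSUE_LABELS[tissue]).any(), tissue

    def test_hu_within_ct_range(self, small_phantom):
        vol, _ = small_phantom
        assert vol.hu.min() >= -1024 and vol.hu.max() <= 3071

    def test_severe_distal_gradient_lowers_ankle_hu(self, severe_subject):
        spec = homogeneous_spec(
            grid_shape=(48, 48, 40), distal_gradient=-8.0, distal_gradient_sd=0.0
        )
        vol, labels = generate_phantom(spec, severe_subject, return_labels=True)
        muscle = labels == TISSUE_LABELS["muscle"]
        nz = vol.shape[2]
        knee = vol.hu[muscle & (np.arange(nz)[None, None, :] < nz // 4)]
        ankle = vol.hu[muscle & (np.arange(nz)[None, None, :] >= 3 * nz // 4)]
        assert knee.mean() - ankle.mean() > 3.0  # ~6 HU tilt across the leg


class TestRunoffScores:
    def test_mild_always_at_most_seven(self, rng):
        for _ in range(500):
            dsa, cta = sample_runoff_scores("mild", rng)
            assert 0.0 <= dsa <= 7.0
            assert 0.0 <= cta <= 19.0

    def test_severe_always_above_seven(self, rng):
        for _ in range(500):
            dsa, _ = sample_runoff_scores("severe", rng)
            assert 7.0 < dsa <= 19.0

    def test_zero_sd_gives_group_mean(self, monkeypatch):
        monkeypatch.setitem(DSA_PARAMS, "mild", (3.3, 0.0))
        dsa, _ = sample_runoff_scores("mild", 0)
        assert dsa == pytest.approx(3.3)

    def test_severe_mean_matches_truncated_normal(self):
        """Monte-Carlo mean of the severe DSA sampler stays near 12.3."""
        rng = np.random.default_rng(7)
        draws = [sample_runoff_scores("severe", rng)[0] for _ in range(10_000)]
        assert abs(np.mean(draws) - 12.3) < 0.3

    def test_group_cta_means_reproduce_reported_values(self):
        rng = np.random.default_rng(11)
        mild = [sample_runoff_scores("mild", rng)[1] for _ in range(10_000)]
        severe = [sample_runoff_scores("severe", rng)[1] for _ in range(10_000)]
        assert abs(np.mean(mild) - 6.1) < 0.3
        assert abs(np.mean(severe) - 11.8) < 0.3

    def test_unknown_group_rejected(self):
        with pytest.raises(ValueError):
            sample_runoff_scores("moderate", 0)


class TestGenerateCohort:
    def test_counts_and_labels(self):
        recs, vols = generate_cohort(1, 1, spec=small_spec(), seed=3)
        assert len(recs) == len(vols) == 2
        assert {r.group for r in recs} == {"mild", "severe"}

    def test_default_cohort_size_is_56(self):
        recs, _ = generate_cohort(2, 2, spec=small_spec(), seed=0)
        # full-size default is 36 + 20; here just check the table layout
        df = cohort_table(recs)
        assert list(df.columns) == ["subject_id", "group", "dsa_score", "cta_score"]

    def test_same_seed_same_cohort(self):
        r1, v1 = generate_cohort(2, 1, spec=small_spec(), seed=5)
        r2, v2 = generate_cohort(2, 1, spec=small_spec(), seed=5)
        assert cohort_table(r1).equals(cohort_table(r2))
        for a, b in zip(v1, v2):
            assert np.array_equal(a.hu, b.hu)

    def test_writes_volumes_and_csv(self, tmp_path):
        generate_cohort(1, 1, spec=small_spec(), seed=1, out_dir=tmp_path)
        assert (tmp_path / "subjects.csv").exists()
        assert len(list(tmp_path.glob("*.nii.gz"))) == 2

    def test_group_separation_in_muscle_mean(self):
        """Mild cohorts have higher mean muscle HU than severe ones."""
        wins = 0
        n_cohorts = 10
        for seed in range(n_cohorts):
            recs, vols = generate_cohort(6, 4, spec=small_spec(), seed=seed)
            means = {"mild": [], "severe": []}
            for rec, vol in zip(recs, vols):
                _, labels = generate_phantom(
                    small_spec(seed=seed), rec, return_labels=True
                )
                means[rec.group].append(vol.hu[labels == TISSUE_LABELS["muscle"]].mean())
            if np.mean(means["mild"]) > np.mean(means["severe"]):
                wins += 1
        assert wins >= 0.95 * n_cohorts
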