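import numpy as np
import pandas as pd
import pytest

from asbestoscreen.phantoms import (
    PhantomSpec,
    draw_severities,
    generate_cohort,
    generate_volume,
    simulate_cohort_table,
    simulate_lung_function,
    simulate_panel,
)


class TestPhantomSpec:
    def test_rejects_bad_inputs(self):
        with pytest.raises(ValueError):
            PhantomSpec(lesion_kind="emphysema")
        with pytest.raises(ValueError):
            PhantomSpec(severity_img=1.5)
        with pytest.raises(ValueError):
            PhantomSpec(grid_shape=(4, 48, 24))
        with pytest.raises(ValueError):
            PhantomSpec(noise_sd=-1.0)


class TestGenerateVolume:
    def test_zero_severity_means_no_lesion(self):
        _, lesion = generate_volume(PhantomSpec(lesion_kind="asbestosis_fibrosis", severity_img=0.0, seed=1))
        assert lesion.sum() == 0

    def test_seeded_determinism_is_bitwise(self):
        spec = PhantomSpec(lesion_kind="asbestosis_fibrosis", severity_img=0.5, seed=42)
        v1, l1 = generate_volume(spec)
        v2, l2 = generate_volume(spec)
        assert np.array_equal(v1.values, v2.values)
        assert np.array_equal(l1, l2)

    def test_lesion_burden_monotone_in_severity(self):
        counts = []
        for sev in (0.0, 0.2, 0.5, 0.8, 1.0):
            _, lesion = generate_volume(
                PhantomSpec(lesion_kind="asbestosis_fibrosis", severity_img=sev, seed=9)
            )
            counts.append(int(lesion.sum()))
        assert counts == sorted(counts)
        assert counts[3] > counts[1]  # strictly larger at 0.8 than at 0.2

    def test_lesion_confined_to_lungs(self, fibrotic_phantom):
        from asbestoscreen.phantoms import _lung_geometry

        spec, _, lesion = fibrotic_phantom
        _, lungs = _lung_geometry(spec.grid_shape)
        assert np.all(lungs[lesion])

    def test_plaques_raise_pleural_attenuation_without_parenchymal_lesion(self):
        spec = PhantomSpec(lesion_kind="plaques_only", severity_img=0.7, seed=3)
        vol, lesion = generate_volume(spec)
        assert lesion.sum() == 0
        base, _ = generate_volume(PhantomSpec(lesion_kind="none", severity_img=0.0, seed=3))
        assert (vol.values > 120).sum() > (base.values > 120).sum()

    def test_lungs_darker_than_body(self, healthy_phantom):
        from asbestoscreen.phantoms import _lung_geometry

        spec, vol, _ = healthy_phantom
        body, lungs = _lung_geometry(spec.grid_shape)
        assert vol.values[lungs].mean() < -600
        assert vol.values[body & ~lungs].mean() > -100


class TestClinicalSimulators:
    def test_lung_function_formula_limits(self):
        rec = simulate_lung_function(0.0, 0.0, seed=1, dlco_noise_sd=0, fvc_noise_sd=0, vc_noise_sd=0)
        assert rec.dlco_pct == 100.0 and rec.fvc_pct == 100.0 and rec.vc_pct == 100.0
        rec = simulate_lung_function(1.0, 1.0, seed=1, dlco_slope=55.0, dlco_noise_sd=0, fvc_noise_sd=0, vc_noise_sd=0)
        assert rec.dlco_pct == pytest.approx(45.0)

    def test_lung_function_clipped_to_physiological_range(self):
        rec = simulate_lung_function(1.0, 1.0, seed=7, dlco_slope=120.0, dlco_noise_sd=0)
        assert rec.dlco_pct == 15.0

    def test_panel_votes_at_the_extremes_without_noise(self):
        assert simulate_panel(1.0, 1.0, seed=0, noise_scale=0.0).votes == (1, 1, 1)
        assert simulate_panel(0.0, 0.0, seed=0, noise_scale=0.0).votes == (0, 0, 0)

    def test_severity_decomposition_mixes_an_independent_latent(self, rng):
        s_img, s_func = draw_severities(2000, rng)
        assert ((0 <= s_img) & (s_img <= 1)).all()
        assert ((0 <= s_func) & (s_func <= 1)).all()
        # the functional severity is correlated with, but not determined by, imaging
        r = np.corrcoef(s_img, s_func)[0, 1]
        assert 0.3 < r < 0.95


class TestCohortCalibration:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_envelopes_at_n500(self, seed):
        df = simulate_cohort_table(500, seed=seed)
        votes = df[["vote1", "vote2", "vote3"]].to_numpy()
        k = votes.sum(axis=1)
        prevalence = np.mean(k >= 2)
        unanimity = np.mean((k == 0) | (k == 3))
        r2 = np.corrcoef(df["dlco_pct"], df["severity_img"])[0, 1] ** 2
        assert 0.38 <= prevalence <= 0.54
        assert 0.70 <= unanimity <= 0.85
        assert 0.1 <= r2 <= 0.4

    def test_table_is_reproducible(self):
        a = simulate_cohort_table(100, seed=5)
        b = simulate_cohort_table(100, seed=5)
        pd.testing.assert_frame_equal(a, b)

    def test_prevalence_tracks_the_target(self):
        df = simulate_cohort_table(500, prevalence_target=0.30, seed=3)
        k = df[["vote1", "vote2", "vote3"]].sum(axis=1)
        assert abs(np.mean(k >= 2) - 0.30) <= 0.08


class TestGenerateCohort:
    def test_single_case_writes_one_volume_and_one_row(self, tmp_path):
        cases = generate_cohort(1, seed=2, out_dir=tmp_path)
        assert len(cases) == 1
        assert (tmp_path / "case_0000.nii.gz").exists()
        assert len(pd.read_csv(tmp_path / "cohort.csv")) == 1

    def test_repeat_runs_write_identical_csv(self, tmp_path):
        generate_cohort(3, seed=8, out_dir=tmp_path / "a")
        generate_cohort(3, seed=8, out_dir=tmp_path / "b")
        assert (tmp_path / "a" / "cohort.csv").read_bytes() == (tmp_path / "b" / "cohort.csv").read_bytes()

    def test_cases_carry_aligned_ground_truth(self):
        cases = generate_cohort(4, seed=13)
        for case in cases:
            assert case.volume.shape == case.lesion_mask.shape == case.lung_mask.shape
            assert np.all(case.lung_mask[case.lesion_mask])
            assert case.votes.verdict in (True, False)
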