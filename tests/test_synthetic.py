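"""Phantom generator: determinism, geometry, and calibration to cohort means."""

import numpy as np
import pandas as pd
import pytest

from rnfl_quant import (
    PhantomSpec,
    corrupt_mask,
    make_dataset,
    render_bscan,
    tsnit_profile,
)
from rnfl_quant.errors import ConfigurationError
from rnfl_quant.synthetic import (
    GROUP_TARGET_AVG_UM,
    HUMP_CENTERS_DEG,
    noise_free_profile,
    splitmix64,
)


class TestTsnitProfile:
    def test_flat_case_is_exactly_constant(self):
        spec = PhantomSpec(
            baseline_um=100.0, hump_amplitude_um=0.0, scale_sd=0.0, jitter_um=0.0
        )
        profile = tsnit_profile(spec, seed=7)
        assert profile.n_ascans == 256
        np.testing.assert_array_equal(profile.values_um, np.full(256, 100.0))

    def test_every_value_at_least_baseline_without_jitter(self):
        spec = PhantomSpec(scale_sd=0.0, jitter_um=0.0)
        profile = tsnit_profile(spec, seed=3)
        assert np.all(profile.values_um >= spec.baseline_um - 1e-12)

    def test_deterministic_given_spec_and_seed(self, control_spec):
        a = tsnit_profile(control_spec, seed=42)
        b = tsnit_profile(control_spec, seed=42)
        np.testing.assert_array_equal(a.values_um, b.values_um)
        c = tsnit_profile(control_spec, seed=43)
        assert not np.array_equal(a.values_um, c.values_um)

    def test_hump_peaks_sit_at_configured_centres(self):
        # closed-form check: with jitter off, local maxima of the profile
        # coincide with the columns nearest the two bundle-peak angles
        spec = PhantomSpec(hump_amplitude_um=40.0, scale_sd=0.0, jitter_um=0.0)
        values = tsnit_profile(spec, seed=0).values_um
        n = spec.width_ascans
        expected_cols = {round(c / (360.0 / n)) % n for c in HUMP_CENTERS_DEG}
        # the two humps are symmetric; find the argmax in each half-circle
        top = set(np.argsort(values)[-2:])
        # each of the two highest columns must be within one column of a centre
        for col in top:
            assert min(abs(col - e) for e in expected_cols) <= 1

    def test_invalid_spec_names_violated_invariant(self):
        with pytest.raises(ConfigurationError, match="baseline_um"):
            PhantomSpec(baseline_um=900.0, hump_amplitude_um=200.0)
        with pytest.raises(ConfigurationError, match="hump_width_deg"):
            PhantomSpec(hump_width_deg=0.0)

    @pytest.mark.parametrize("group", ["control", "NAION", "ON"])
    def test_noise_free_average_matches_group_target(self, group):
        spec = PhantomSpec.for_group(group)
        avg = float(noise_free_profile(spec).mean())
        assert avg == pytest.approx(GROUP_TARGET_AVG_UM[group], abs=1e-9)


class TestRenderBscan:
    def test_noise_free_template_has_three_intensities(self, control_spec):
        import dataclasses

        spec = dataclasses.replace(control_spec, speckle_shape=0.0)
        profile = tsnit_profile(spec, seed=1)
        image, _ = render_bscan(spec, profile, seed=2)
        assert set(np.unique(image.pixels)) == {
            spec.background_level,
            spec.band_level,
            spec.deep_level,
        }

    def test_mask_column_counts_match_profile_within_one_pixel(self, control_spec):
        profile = tsnit_profile(control_spec, seed=5)
        _, truth = render_bscan(control_spec, profile, seed=6)
        counts_um = truth.mask.pixels.sum(axis=0) * control_spec.axial_spacing_um
        diff_px = np.abs(counts_um - profile.values_um) / control_spec.axial_spacing_um
        assert np.all(diff_px <= 1.0)

    def test_mask_columns_are_single_runs_starting_at_ilm(self, control_spec):
        profile = tsnit_profile(control_spec, seed=8)
        _, truth = render_bscan(control_spec, profile, seed=9)
        for col in range(control_spec.width_ascans):
            rows = np.flatnonzero(truth.mask.pixels[:, col])
            assert rows.size > 0
            assert rows[0] == truth.ilm_row_per_column[col]
            assert np.array_equal(rows, np.arange(rows[0], rows[0] + rows.size))

    def test_bit_identical_for_same_inputs(self, control_spec):
        profile = tsnit_profile(control_spec, seed=11)
        img1, t1 = render_bscan(control_spec, profile, seed=12)
        img2, t2 = render_bscan(control_spec, profile, seed=12)
        np.testing.assert_array_equal(img1.pixels, img2.pixels)
        np.testing.assert_array_equal(t1.mask.pixels, t2.mask.pixels)

    def test_band_exceeding_frame_raises(self):
        spec = PhantomSpec(height_px=64, axial_spacing_um=3.87, ilm_depth_px=30)
        profile = tsnit_profile(spec, seed=1)
        with pytest.raises(ConfigurationError, match="frame"):
            render_bscan(spec, profile, seed=2)

    def test_artifacts_change_only_the_image_not_the_mask(self, control_spec):
        import dataclasses

        profile = tsnit_profile(control_spec, seed=13)
        plain_img, plain_truth = render_bscan(control_spec, profile, seed=14)
        art_spec = dataclasses.replace(control_spec, erm=True, pvd=True)
        art_img, art_truth = render_bscan(art_spec, profile, seed=14)
        np.testing.assert_array_equal(
            plain_truth.mask.pixels, art_truth.mask.pixels
        )
        assert not np.array_equal(plain_img.pixels, art_img.pixels)


class TestMakeDataset:
    def test_file_and_row_counts(self, control_spec, tmp_path):
        manifest = make_dataset(10, control_spec, seed=1, out_dir=tmp_path / "d")
        assert len(manifest.frame) == 10
        assert len(list((tmp_path / "d").glob("*.png"))) == 20

    def test_same_seed_reproduces_manifest(self, control_spec, tmp_path):
        m1 = make_dataset(5, control_spec, seed=9, out_dir=tmp_path / "a")
        m2 = make_dataset(5, control_spec, seed=9, out_dir=tmp_path / "b")
        pd.testing.assert_frame_equal(m1.frame, m2.frame)
        assert (tmp_path / "a" / "manifest.csv").read_bytes() == (
            tmp_path / "b" / "manifest.csv"
        ).read_bytes()

    def test_naion_dataset_mean_near_cohort_mean(self, tmp_path):
        spec = PhantomSpec.for_group("NAION")
        manifest = make_dataset(50, spec, seed=21, out_dir=tmp_path / "n")
        assert manifest.frame.true_avg_um.mean() == pytest.approx(69.7, abs=5.0)


class TestCorruptMask:
    def test_removes_requested_arc_fraction(self, control_spec):
        profile = tsnit_profile(control_spec, seed=2)
        _, truth = render_bscan(control_spec, profile, seed=3)
        corrupted = corrupt_mask(truth.mask, seed=4, arc_fraction=0.25)
        empty_cols = int((corrupted.pixels.sum(axis=0) == 0).sum())
        assert empty_cols == round(0.25 * control_spec.width_ascans)
        kept = corrupted.pixels.sum()
        assert 0 < kept < truth.mask.pixels.sum()


def test_splitmix_child_seeds_are_stable_and_spread():
    seeds = [splitmix64(1, i) for i in range(100)]
    assert seeds == [splitmix64(1, i) for i in range(100)]
    assert len(set(seeds)) == 100
    assert all(0 <= s < 2**31 for s in seeds)
    assert splitmix64(1, 0) != splitmix64(2, 0)
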