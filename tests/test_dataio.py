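"""I/O, normalisation, grid fitting, windows, folds, bias correction."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from eatseg import analysis, dataio, phantom
from eatseg.dataio import (
    CineSeries,
    LabelStack,
    bias_correct,
    extract_windows,
    fit_to_grid,
    invert_fit,
    normalize_intensity,
    read_subject,
    split_folds,
    write_subject,
)


def _flat_phantom(**kw):
    """Phantom with identical tissue intensities: a flat signal field."""
    means = {k: 0.5 for k in ("background", "myocardium", "blood", "fat",
                              "fascia")}
    means["fat"] = 0.5 + 1e-9  # keep fat > myocardium validation happy
    params = phantom.PhantomParams(intensity_means=means, noise_sigma=0.0,
                                   n_frames=5, seed=3, **kw)
    series, *_ = phantom.render_cine(params)
    return series


class TestReadWrite:
    def test_round_trip_identity(self, tmp_path, small_cohort):
        s = small_cohort[0]
        write_subject(tmp_path, s.subject_id, s.series, s.labels)
        series, labels = read_subject(
            tmp_path / f"{s.subject_id}_cine.nii.gz",
            tmp_path / f"{s.subject_id}_labels.nii.gz",
        )
        assert np.allclose(series.frames, s.series.frames, atol=1e-6)
        assert np.array_equal(labels.masks, s.labels.masks)
        assert series.pixel_spacing == pytest.approx(s.series.pixel_spacing)

    def test_unknown_label_code_names_code_and_frame(self, tmp_path):
        frames = np.zeros((3, 8, 8))
        masks = np.zeros((3, 8, 8), dtype=np.int16)
        masks[1, 4, 4] = 5
        series = CineSeries(frames, (1.0, 1.0), "bad")
        with pytest.raises(ValueError, match="code 5 in frame 1"):
            LabelStack(masks)
        # and through the NIfTI reader
        import nibabel as nib
        good = LabelStack(np.zeros((3, 8, 8), dtype=np.int16))
        write_subject(tmp_path, "bad", series, good)
        img = nib.load(tmp_path / "bad_labels.nii.gz")
        data = np.asarray(img.dataobj).copy()
        data[4, 4, 0, 1] = 5
        nib.save(nib.Nifti1Image(data, img.affine, img.header),
                 tmp_path / "bad_labels.nii.gz")
        with pytest.raises(ValueError, match="code 5 in frame 1"):
            read_subject(tmp_path / "bad_cine.nii.gz",
                         tmp_path / "bad_labels.nii.gz")

    def test_header_spacing_propagates_to_areas(self, tmp_path):
        frames = np.random.default_rng(0).random((3, 20, 20))
        masks = np.zeros((3, 20, 20), dtype=np.int16)
        masks[:, :10, :10] = 1  # 100 pixels
        write_subject(tmp_path, "sp", CineSeries(frames, (1.5, 1.5), "sp"),
                      LabelStack(masks))
        series, labels = read_subject(tmp_path / "sp_cine.nii.gz",
                                      tmp_path / "sp_labels.nii.gz")
        area = analysis.area_cm2(labels.masks[0] == 1, series.pixel_spacing)
        assert area == pytest.approx(2.25)

    def test_grid_mismatch_rejected(self, tmp_path):
        frames = np.zeros((3, 8, 8))
        write_subject(tmp_path, "a", CineSeries(frames, (1, 1), "a"),
                      LabelStack(np.zeros((3, 8, 8), dtype=np.int16)))
        write_subject(tmp_path, "b",
                      CineSeries(np.zeros((3, 10, 10)), (1, 1), "b"),
                      LabelStack(np.zeros((3, 10, 10), dtype=np.int16)))
        with pytest.raises(ValueError, match="does not match"):
            read_subject(tmp_path / "a_cine.nii.gz",
                         tmp_path / "b_labels.nii.gz")


class TestNormalize:
    def test_affine_map(self):
        frames = np.array([[[10.0, 20.0]], [[30.0, 20.0]], [[10.0, 30.0]]])
        out = normalize_intensity(CineSeries(frames, (1, 1), "x"))
        assert set(np.round(np.unique(out.frames), 6)) == {0.0, 0.5, 1.0}
        assert out.frames.min() == 0.0 and out.frames.max() == 1.0

    def test_idempotent(self, small_cohort):
        once = normalize_intensity(small_cohort[0].series)
        twice = normalize_intensity(once)
        assert np.allclose(once.frames, twice.frames)

    def test_constant_series_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            normalize_intensity(CineSeries(np.ones((3, 4, 4)), (1, 1), "c"))


class TestFitToGrid:
    def test_pad_centering(self):
        arr = np.ones((200, 150))
        fitted, placement = fit_to_grid(arr, (256, 192))
        assert fitted.shape == (256, 192)
        assert placement.pad_before == (28, 21)
        assert fitted[:28].sum() == 0 and fitted[-28:].sum() == 0
        assert fitted[:, :21].sum() == 0 and fitted[:, -21:].sum() == 0

    def test_crop_centering(self):
        arr = np.arange(300 * 192).reshape(300, 192)
        fitted, placement = fit_to_grid(arr, (256, 192))
        assert placement.crop_before == (22, 0)
        assert np.array_equal(fitted, arr[22:278])

    def test_fit_then_invert_restores(self, rng):
        for shape in [(200, 150), (300, 250), (100, 300)]:
            arr = rng.random(shape)
            fitted, placement = fit_to_grid(arr, (256, 192))
            back = invert_fit(fitted, placement)
            rows = slice(placement.crop_before[0],
                         placement.crop_before[0]
                         + min(shape[0], 256))
            cols = slice(placement.crop_before[1],
                         placement.crop_before[1]
                         + min(shape[1], 192))
            assert np.array_equal(back[rows, cols], arr[rows, cols])

    def test_label_count_preserved_without_crop(self, rng):
        mask = (rng.random((100, 80)) < 0.2).astype(np.int16)
        fitted, _ = fit_to_grid(mask, (256, 192))
        assert fitted.sum() == mask.sum()

    @given(h=st.integers(10, 300), w=st.integers(10, 300))
    @settings(max_examples=30, deadline=None)
    def test_shape_contract_property(self, h, w):
        fitted, placement = fit_to_grid(np.ones((h, w)), (64, 48))
        assert fitted.shape == (64, 48)
        assert invert_fit(fitted, placement).shape == (h, w)


class TestExtractWindows:
    def test_cyclic_windows_25_frames(self, small_cohort):
        s = small_cohort[0]
        samples = extract_windows(s.series, s.labels)
        assert len(samples) == 25
        first = samples[0]
        assert np.array_equal(first.window[0], s.series.frames[24])
        assert np.array_equal(first.window[1], s.series.frames[0])
        assert np.array_equal(first.window[2], s.series.frames[1])
        for t, sample in enumerate(samples):
            assert sample.frame_index == t
            assert np.array_equal(sample.target, s.labels.masks[t])

    def test_three_frame_enumeration(self):
        frames = np.arange(3 * 4 * 4, dtype=float).reshape(3, 4, 4)
        series = CineSeries(frames, (1, 1), "t3")
        labels = LabelStack(np.zeros((3, 4, 4), dtype=np.int16))
        samples = extract_windows(series, labels)
        got = [tuple(int(w[0, 0] // 16) for w in s.window) for s in samples]
        assert got == [(2, 0, 1), (0, 1, 2), (1, 2, 0)]

    def test_too_few_frames_rejected(self):
        with pytest.raises(ValueError):
            CineSeries(np.zeros((2, 4, 4)), (1, 1), "x")


def _manifest(counts=(21, 12, 67)):
    rows = []
    for group, n in zip(("healthy", "obese", "diabetic"), counts):
        rows += [{"subject_id": f"{group[:1]}{i:03d}", "group": group}
                 for i in range(n)]
    return pd.DataFrame(rows)


class TestSplitFolds:
    def test_partition_and_stratification(self):
        man = _manifest()
        split = split_folds(man, seed=3)
        all_ids = [sid for sub in split.subsets for sid in sub]
        assert len(all_ids) == 100 and len(set(all_ids)) == 100
        for subset in split.subsets:
            assert len(subset) == 20
            groups = man.set_index("subject_id").loc[subset, "group"]
            assert abs((groups == "healthy").sum() - 4.2) <= 1
            assert abs((groups == "obese").sum() - 2.4) <= 1
            assert abs((groups == "diabetic").sum() - 13.4) <= 1

    def test_rotations_are_60_20(self):
        split = split_folds(_manifest(), seed=3)
        assert len(split.train_val_assignments) == 4
        val_sets = []
        for train, val in split.train_val_assignments:
            assert len(train) == 60 and len(val) == 20
            assert not set(train) & set(val)
            assert not set(train) & set(split.test_subjects)
            val_sets.append(set(val))
        # every non-test subject validates exactly once
        assert set().union(*val_sets) == set(
            sid for s in split.subsets[1:] for sid in s)

    def test_deterministic_under_seed(self):
        a = split_folds(_manifest(), seed=9)
        b = split_folds(_manifest(), seed=9)
        assert a.subsets == b.subsets

    def test_small_group_warns(self):
        man = _manifest(counts=(3, 12, 67))
        with pytest.warns(UserWarning, match="healthy"):
            split_folds(man, seed=0)


class TestBiasCorrect:
    def test_none_is_identity(self, small_cohort):
        s = small_cohort[0].series
        out = bias_correct(s, "none")
        assert np.array_equal(out.frames, s.frames)

    def test_flat_field_passes_through(self):
        series = _flat_phantom(bias_field_amplitude=0.0)
        out = bias_correct(series, "polynomial_surrogate")
        rms = np.sqrt(np.mean((out.frames - series.frames) ** 2))
        assert rms / np.sqrt(np.mean(series.frames**2)) < 0.01

    def test_polynomial_bias_recovery(self):
        clean = _flat_phantom(bias_field_amplitude=0.0)
        biased = _flat_phantom(bias_field_amplitude=0.3)
        corrected = bias_correct(biased, "polynomial_surrogate")
        rms_before = np.sqrt(np.mean((biased.frames - clean.frames) ** 2))
        rms_after = np.sqrt(np.mean((corrected.frames - clean.frames) ** 2))
        assert rms_after < rms_before

    def test_external_n4_runs(self):
        pytest.importorskip("SimpleITK")
        biased = _flat_phantom(bias_field_amplitude=0.3)
        out = bias_correct(biased, "external_n4")
        assert out.frames.shape == biased.frames.shape

    def test_unknown_method_rejected(self, small_cohort):
        with pytest.raises(ValueError, match="unknown method"):
            bias_correct(small_cohort[0].series, "magic")
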