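"""Volume containers, NIfTI/DICOM reading, HU windowing and normalization."""

import numpy as np
import pytest
import pydicom
from pydicom.dataset import FileDataset, FileMetaDataset
from pydicom.uid import ExplicitVRLittleEndian, generate_uid

from ctdense import (CTVolume, NormalizedVolume, LabelVolume, clip_hu,
                     normalize, denormalize, read_volume, write_volume,
                     read_labels, write_labels)


def _ramp_volume(shape=(5, 6, 7)):
    z = np.arange(shape[0], dtype=np.float32)[:, None, None]
    return CTVolume(voxels=np.broadcast_to(z * 100 - 200, shape).copy(),
                    spacing=(2.5, 1.0, 1.0))


class TestNiftiRoundTrip:
    def test_voxels_and_spacing_preserved(self, tmp_path):
        vol = _ramp_volume()
        path = tmp_path / "vol.nii.gz"
        write_volume(vol, path)
        back = read_volume(path)
        np.testing.assert_allclose(back.voxels, vol.voxels, rtol=1e-6)
        assert back.spacing == pytest.approx(vol.spacing)

    def test_slice_axis_is_largest_spacing(self, tmp_path):
        # write with the thick axis first; re-read and confirm it stays axis 0
        vol = _ramp_volume()
        path = tmp_path / "vol.nii"
        write_volume(vol, path)
        assert read_volume(path).voxels.shape[0] == 5

    def test_labels_round_trip(self, tmp_path):
        codes = np.zeros((4, 5, 5), dtype=np.int16)
        codes[1:3, 1:3, 1:3] = 1
        labels = LabelVolume(codes=codes)
        path = tmp_path / "labels.nii.gz"
        write_labels(labels, path)
        np.testing.assert_array_equal(read_labels(path).codes, codes)

    def test_missing_file(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            read_volume(tmp_path / "nope.nii")


def _write_dicom_slice(path, z, pixels, thickness=1.0):
    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = pydicom.uid.CTImageStorage
    meta.MediaStorageSOPInstanceUID = generate_uid()
    meta.TransferSyntaxUID = ExplicitVRLittleEndian
    ds = FileDataset(str(path), {}, file_meta=meta, preamble=b"\0" * 128)
    ds.SOPClassUID = meta.MediaStorageSOPClassUID
    ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
    ds.Modality = "CT"
    ds.Rows, ds.Columns = pixels.shape
    ds.PixelSpacing = [1.0742, 1.0742]
    ds.SliceThickness = thickness
    ds.ImagePositionPatient = [0.0, 0.0, float(z)]
    ds.ImageOrientationPatient = [1, 0, 0, 0, 1, 0]
    ds.RescaleSlope = 1.0
    ds.RescaleIntercept = -1024.0
    ds.BitsAllocated = 16
    ds.BitsStored = 16
    ds.HighBit = 15
    ds.PixelRepresentation = 0
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.PixelData = pixels.astype(np.uint16).tobytes()
    ds.save_as(str(path), enforce_file_format=True)


class TestDicomSeries:
    def test_slice_gap_defines_longitudinal_spacing(self, tmp_path):
        # thickness 1 mm but 2.5 mm between positions: increment wins
        pixels = np.full((4, 4), 1024, dtype=np.uint16)
        for i, z in enumerate([0.0, 2.5, 5.0]):
            _write_dicom_slice(tmp_path / f"s{i}.dcm", z, pixels)
        vol = read_volume(tmp_path)
        assert vol.spacing[0] == pytest.approx(2.5)
        assert vol.voxels.shape == (3, 4, 4)
        # rescale applied: 1024 - 1024 = 0 HU
        np.testing.assert_allclose(vol.voxels, 0.0)

    def test_inconsistent_spacing_rejected(self, tmp_path):
        pixels = np.zeros((4, 4), dtype=np.uint16)
        for i, z in enumerate([0.0, 2.5, 6.0]):
            _write_dicom_slice(tmp_path / f"s{i}.dcm", z, pixels)
        with pytest.raises(ValueError, match="spacing"):
            read_volume(tmp_path)


class TestHuWindow:
    def test_clip_examples(self):
        vol = CTVolume(voxels=np.array([[[1500.0, 40.0]], [[-2000.0, 0.0]]]),
                       spacing=(2.5, 1, 1))
        clipped = clip_hu(vol)
        assert clipped.voxels[0, 0, 0] == 1000.0
        assert clipped.voxels[0, 0, 1] == 40.0
        assert clipped.voxels.min() >= -1000.0

    def test_clip_idempotent(self, rng):
        vol = CTVolume(voxels=rng.uniform(-3000, 3000, (4, 5, 5)), spacing=(2.5, 1, 1))
        once = clip_hu(vol)
        np.testing.assert_array_equal(clip_hu(once).voxels, once.voxels)

    def test_bad_window(self):
        vol = _ramp_volume()
        with pytest.raises(ValueError):
            clip_hu(vol, 100, -100)

    @pytest.mark.parametrize("hu,expected", [(-1000, 0.0), (1000, 1.0), (0, 0.5)])
    def test_normalize_window_points(self, hu, expected):
        vol = CTVolume(voxels=np.full((2, 2, 2), float(hu)), spacing=(2.5, 1, 1))
        assert normalize(vol).voxels[0, 0, 0] == pytest.approx(expected)

    def test_normalize_requires_clipping(self):
        vol = CTVolume(voxels=np.full((2, 2, 2), 1500.0), spacing=(2.5, 1, 1))
        with pytest.raises(ValueError, match="clip"):
            normalize(vol)

    def test_denormalize_inverse(self, rng):
        vol = CTVolume(voxels=rng.uniform(-1000, 1000, (4, 6, 6)), spacing=(2.5, 1, 1))
        back = denormalize(normalize(clip_hu(vol)))
        np.testing.assert_allclose(back.voxels, clip_hu(vol).voxels, atol=1e-3)

    def test_denormalize_examples(self):
        vol = NormalizedVolume(voxels=np.array([[[0.5, 0.4]], [[0.0, 1.0]]]))
        hu = denormalize(vol).voxels
        assert hu[0, 0, 0] == pytest.approx(0.0)
        assert hu[0, 0, 1] == pytest.approx(-200.0, abs=1e-3)


class TestInvariants:
    def test_spacing_must_be_positive(self):
        with pytest.raises(ValueError):
            CTVolume(voxels=np.zeros((3, 3, 3)), spacing=(0.0, 1, 1))

    def test_normalized_range_enforced(self):
        with pytest.raises(ValueError):
            NormalizedVolume(voxels=np.full((2, 2, 2), 1.5))

    def test_label_codes_must_be_known(self):
        with pytest.raises(ValueError, match="organ_map"):
            LabelVolume(codes=np.full((2, 2, 2), 9, dtype=np.int16))
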