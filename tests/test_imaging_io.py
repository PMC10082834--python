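"""SUV conversion arithmetic and volume round trips."""

from datetime import datetime, timedelta

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from petquant import (
    AcquisitionMeta,
    ActivityVolume,
    ConfigurationError,
    LesionMask,
    SUVImage,
    VolumeFormatError,
    read_mask,
    read_volume,
    to_suv,
    write_volume,
)
from petquant.imaging_io import F18_HALF_LIFE_MIN

META = AcquisitionMeta(injected_activity_bq=4e6, body_weight_g=20.0)


def test_suv_formula_hand_values():
    vol = ActivityVolume(np.full((3, 3, 3), 1000.0), spacing=(0.5, 0.5, 0.5))
    suv = to_suv(vol, META)
    # 1000 Bq/mL / 4e6 Bq * 20 g = 0.005
    assert np.allclose(suv.voxels, 0.005)

    zero = ActivityVolume(np.zeros((2, 2, 2)), spacing=(1, 1, 1))
    assert np.all(to_suv(zero, META).voxels == 0)


def test_decay_correction_one_half_life():
    t0 = datetime(2024, 1, 1, 9, 0, 0)
    meta = AcquisitionMeta(
        4e6, 20.0, injection_time=t0,
        scan_time=t0 + timedelta(minutes=F18_HALF_LIFE_MIN),
    )
    vol = ActivityVolume(np.full((2, 2, 2), 1000.0), spacing=(0.5, 0.5, 0.5))
    assert np.allclose(to_suv(vol, meta, decay_correct=True).voxels, 0.010)
    # without the flag the raw injected activity is used
    assert np.allclose(to_suv(vol, meta, decay_correct=False).voxels, 0.005)


def test_decay_correction_requires_timestamps():
    vol = ActivityVolume(np.ones((2, 2, 2)), spacing=(1, 1, 1))
    with pytest.raises(ConfigurationError):
        to_suv(vol, META, decay_correct=True)


@given(st.floats(min_value=0.0, max_value=1e4, allow_nan=False))
def test_suv_linearity(c):
    base = np.arange(8.0).reshape(2, 2, 2)
    scaled = to_suv(ActivityVolume(c * base, spacing=(1, 1, 1)), META)
    ref = to_suv(ActivityVolume(base, spacing=(1, 1, 1)), META)
    assert np.allclose(scaled.voxels, c * ref.voxels, rtol=1e-12)


def test_uniform_volume_stays_uniform():
    suv = to_suv(ActivityVolume(np.full((4, 5, 6), 37.0), spacing=(0.5, 0.4, 0.3)), META)
    assert np.ptp(suv.voxels) == 0


def test_meta_invariants():
    with pytest.raises(ValueError):
        AcquisitionMeta(0.0, 20.0)
    with pytest.raises(ValueError):
        AcquisitionMeta(4e6, -1.0)
    t0 = datetime(2024, 1, 1)
    meta = AcquisitionMeta(4e6, 20.0, injection_time=t0,
                           scan_time=t0 - timedelta(minutes=5))
    with pytest.raises(ValueError):
        meta.uptake_minutes()


def test_volume_invariants():
    with pytest.raises(ValueError):
        ActivityVolume(np.full((2, 2, 2), -1.0), spacing=(1, 1, 1))
    with pytest.raises(ValueError):
        ActivityVolume(np.ones((2, 2, 2)), spacing=(0.0, 1, 1))
    with pytest.raises(ValueError):
        ActivityVolume(np.ones((0, 2, 2)), spacing=(1, 1, 1))
    with pytest.raises(ValueError):
        ActivityVolume(np.full((2, 2, 2), np.nan), spacing=(1, 1, 1))


def test_nifti_round_trip_scalar(tmp_path):
    rng = np.random.default_rng(7)
    vol = ActivityVolume(rng.random((4, 5, 6)) * 100, spacing=(0.5, 0.4, 0.3),
                         origin=(1.0, 2.0, 3.0))
    p = tmp_path / "vol.nii.gz"
    write_volume(vol, p)
    back = read_volume(p)
    assert np.array_equal(back.voxels, vol.voxels)
    assert back.spacing == pytest.approx(vol.spacing)
    assert back.origin == pytest.approx(vol.origin)


def test_nifti_round_trip_mask_bit_exact(tmp_path):
    rng = np.random.default_rng(3)
    mask = LesionMask(rng.random((6, 6, 6)) > 0.5, spacing=(0.5, 0.5, 0.5))
    p = tmp_path / "mask.nii"
    write_volume(mask, p)
    back = read_mask(p)
    assert np.array_equal(back.voxels, mask.voxels)
    assert back.spacing == pytest.approx((0.5, 0.5, 0.5))


def test_suv_round_trip_preserves_spacing(tmp_path):
    suv = SUVImage(np.ones((3, 3, 3)), spacing=(0.5, 0.5, 0.5), meta=META)
    p = tmp_path / "suv.nii.gz"
    write_volume(suv, p)
    assert read_volume(p).spacing == (0.5, 0.5, 0.5)


def test_write_to_missing_directory_fails(tmp_path):
    vol = ActivityVolume(np.ones((2, 2, 2)), spacing=(1, 1, 1))
    with pytest.raises(IOError):
        write_volume(vol, tmp_path / "nope" / "x.nii")


def test_read_garbage_is_format_error(tmp_path):
    p = tmp_path / "bad.nii"
    p.write_bytes(b"this is not a nifti file")
    with pytest.raises(VolumeFormatError):
        read_volume(p)
    with pytest.raises(VolumeFormatError):
        read_volume(tmp_path / "missing.nii")


def test_negative_voxels_on_disk_rejected(tmp_path):
    import nibabel as nib

    data = -np.ones((2, 2, 2), dtype=np.float64)
    nib.save(nib.Nifti1Image(data, np.eye(4)), str(tmp_path / "neg.nii"))
    with pytest.raises(VolumeFormatError):
        read_volume(tmp_path / "neg.nii")


def _write_dicom_series(dirpath, n_slices=3, shape=(4, 4), spacing=0.5, slope=2.0):
    import pydicom
    from pydicom.dataset import FileDataset, FileMetaDataset
    from pydicom.uid import ExplicitVRLittleEndian, generate_uid

    series_uid = generate_uid()
    for i in range(n_slices):
        meta = FileMetaDataset()
        meta.MediaStorageSOPClassUID = pydicom.uid.SecondaryCaptureImageStorage
        meta.MediaStorageSOPInstanceUID = generate_uid()
        meta.TransferSyntaxUID = ExplicitVRLittleEndian
        ds = FileDataset(None, {}, file_meta=meta, preamble=b"\0" * 128)
        ds.SOPClassUID = meta.MediaStorageSOPClassUID
        ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
        ds.SeriesInstanceUID = series_uid
        ds.Modality = "PT"
        ds.Rows, ds.Columns = shape
        ds.PixelSpacing = [spacing, spacing]
        ds.SliceThickness = spacing
        ds.ImagePositionPatient = [0.0, 0.0, i * spacing]
        ds.ImageOrientationPatient = [1, 0, 0, 0, 1, 0]
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.BitsAllocated = 16
        ds.BitsStored = 16
        ds.HighBit = 15
        ds.PixelRepresentation = 0
        ds.RescaleSlope = slope
        ds.RescaleIntercept = 0.0
        arr = np.full(shape, 10 + i, dtype="<u2")
        ds.PixelData = arr.tobytes()
        ds.save_as(str(dirpath / f"slice{i:03d}.dcm"), enforce_file_format=True)


def test_dicom_series_import(tmp_path):
    _write_dicom_series(tmp_path)
    vol = read_volume(tmp_path, format="dicom_series")
    assert vol.shape == (3, 4, 4)
    assert vol.spacing == pytest.approx((0.5, 0.5, 0.5))
    # rescale slope applied, slices ordered by position
    assert np.all(vol.voxels[0] == 20.0)
    assert np.all(vol.voxels[2] == 24.0)
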