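"""Volume I/O, reformatting, and z-axis chunk/stitch round trips."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import thinslice as ts
from thinslice.volume import ChunkConfigError, VolumeFormatError


class TestNifti:
    def test_round_trip_identity(self, small_volume, tmp_path):
        p = tmp_path / "vol.nii.gz"
        ts.write_volume(small_volume, p)
        back = ts.read_volume(p)
        np.testing.assert_allclose(back.voxels, small_volume.voxels,
                                   atol=0.5)
        assert back.spacing == small_volume.spacing

    def test_spacing_header_pass_through(self, tmp_path, rng):
        vol = ts.CTVolume(rng.uniform(-800, 100, (5, 4, 3)),
                          spacing=(4.0, 0.7, 0.7))
        p = tmp_path / "v.nii.gz"
        ts.write_volume(vol, p)
        assert ts.read_volume(p).spacing == (4.0, 0.7, 0.7)

    def test_single_slice_survives(self, tmp_path, rng):
        vol = ts.CTVolume(rng.uniform(-100, 100, (1, 6, 7)),
                          spacing=(1.0, 1.0, 1.0))
        p = tmp_path / "one.nii"
        ts.write_volume(vol, p)
        back = ts.read_volume(p)
        assert back.shape == (1, 6, 7)
        np.testing.assert_allclose(back.voxels, vol.voxels, atol=0.5)

    def test_unreadable_file_raises(self, tmp_path):
        p = tmp_path / "junk.nii"
        p.write_bytes(b"not a nifti")
        with pytest.raises(VolumeFormatError):
            ts.read_volume(p)


def _write_dicom_series(dirpath, stored, spacing=(2.0, 0.7, 0.7),
                        slope=1.0, intercept=-1024.0):
    """Create a minimal CT DICOM series from uint16 stored values."""
    import pydicom
    from pydicom.dataset import FileDataset, FileMetaDataset
    from pydicom.uid import ExplicitVRLittleEndian, generate_uid

    dz, dy, dx = spacing
    series_uid = generate_uid()
    for k in range(stored.shape[0]):
        meta = FileMetaDataset()
        meta.MediaStorageSOPClassUID = pydicom.uid.CTImageStorage
        meta.MediaStorageSOPInstanceUID = generate_uid()
        meta.TransferSyntaxUID = ExplicitVRLittleEndian
        ds = FileDataset(None, {}, file_meta=meta, preamble=b"\0" * 128)
        ds.SOPClassUID = meta.MediaStorageSOPClassUID
        ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
        ds.SeriesInstanceUID = series_uid
        ds.Modality = "CT"
        ds.InstanceNumber = k + 1
        ds.ImagePositionPatient = [0.0, 0.0, k * dz]
        ds.PixelSpacing = [dy, dx]
        ds.SliceThickness = dz
        ds.RescaleSlope = slope
        ds.RescaleIntercept = intercept
        ds.Rows, ds.Columns = stored.shape[1:]
        ds.BitsAllocated = 16
        ds.BitsStored = 16
        ds.HighBit = 15
        ds.PixelRepresentation = 0
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.PixelData = stored[k].astype(np.uint16).tobytes()
        ds.save_as(dirpath / f"slice{k:03d}.dcm", enforce_file_format=True)


class TestDicom:
    def test_rescale_slope_intercept(self, tmp_path):
        stored = np.full((3, 4, 4), 1024, dtype=np.uint16)
        _write_dicom_series(tmp_path, stored, slope=1.0, intercept=-1024.0)
        vol = ts.read_volume(tmp_path, format="dicom_series")
        # stored 1024 with slope 1, intercept -1024 -> 0 HU
        np.testing.assert_allclose(vol.voxels, 0.0)
        assert vol.spacing == (2.0, 0.7, 0.7)

    def test_non_uniform_spacing_names_slice(self, tmp_path):
        stored = np.zeros((4, 4, 4), dtype=np.uint16)
        _write_dicom_series(tmp_path, stored)
        # corrupt one slice position
        import pydicom
        bad = tmp_path / "slice002.dcm"
        ds = pydicom.dcmread(bad)
        ds.ImagePositionPatient = [0.0, 0.0, 7.7]
        ds.save_as(bad, enforce_file_format=True)
        with pytest.raises(VolumeFormatError):
            ts.read_volume(tmp_path, format="dicom_series")


class TestReformat:
    def test_axial_is_identity(self, small_volume):
        out = ts.reformat(small_volume, "axial")
        np.testing.assert_array_equal(out.voxels, small_volume.voxels)
        assert out.spacing == small_volume.spacing

    def test_involution_through_axial(self, small_volume):
        for plane in ("coronal", "sagittal"):
            out = ts.reformat(ts.reformat(small_volume, plane), "axial")
            np.testing.assert_array_equal(out.voxels, small_volume.voxels)
            assert out.spacing == small_volume.spacing

    def test_coronal_shape_and_spacing_permutation(self, rng):
        vol = ts.CTVolume(rng.uniform(-500, 100, (16, 512 // 8, 500 // 4)),
                          spacing=(1.0, 0.7, 0.7))
        cor = ts.reformat(vol, "coronal")
        assert cor.shape == (vol.shape[1], vol.shape[0], vol.shape[2])
        assert cor.spacing == (0.7, 1.0, 0.7)

    def test_voxel_multiset_preserved(self, small_volume):
        for plane in ("coronal", "sagittal"):
            out = ts.reformat(small_volume, plane)
            np.testing.assert_array_equal(
                np.sort(out.voxels, axis=None),
                np.sort(small_volume.voxels, axis=None))


class TestChunkStitch:
    def test_offsets_stride_and_padding_75(self, rng):
        vol = ts.CTVolume(rng.uniform(-500, 100, (75, 6, 5)),
                          spacing=(4.0, 0.7, 0.7))
        segments, plan = ts.chunk_z(vol, 16, 2)
        # stride = 16 - 2 = 14; offsets step by 14 until covered
        assert plan.segment_offsets == [0, 14, 28, 42, 56, 70]
        assert plan.pad_z == 70 + 16 - 75
        out = ts.stitch_z(segments, plan, r=1)
        assert out.z_len == 75
        np.testing.assert_allclose(out.voxels, vol.voxels, rtol=1e-6)

    def test_exact_single_segment_identity(self, rng):
        vol = ts.CTVolume(rng.uniform(-500, 100, (16, 4, 4)),
                          spacing=(1.0, 1.0, 1.0))
        segments, plan = ts.chunk_z(vol, 16, 0)
        assert plan.segment_count == 1 and plan.pad_z == 0
        np.testing.assert_array_equal(segments[0].voxels, vol.voxels)

    def test_short_volume_padded(self, rng):
        vol = ts.CTVolume(rng.uniform(-500, 100, (5, 4, 4)),
                          spacing=(1.0, 1.0, 1.0))
        segments, plan = ts.chunk_z(vol, 16, 2)
        assert plan.segment_count == 1
        assert plan.pad_z == 11
        # edge replication
        np.testing.assert_array_equal(segments[0].voxels[5:],
                                      np.repeat(vol.voxels[-1:], 11, axis=0))
        out = ts.stitch_z(segments, plan, r=1)
        np.testing.assert_allclose(out.voxels, vol.voxels, rtol=1e-6)

    def test_overlap_too_large_rejected(self, small_volume):
        with pytest.raises(ChunkConfigError):
            ts.chunk_z(small_volume, 16, 8)

    def test_constant_segments_stitch_constant(self):
        vol = ts.CTVolume(np.full((30, 3, 3), 7.0), spacing=(1, 1, 1))
        segments, plan = ts.chunk_z(vol, 16, 2)
        out = ts.stitch_z(segments, plan, r=1)
        np.testing.assert_allclose(out.voxels, 7.0, rtol=1e-6)

    def test_cross_fade_is_linear_ramp(self):
        """Two overlapping constant segments 0 and 1 blend as a ramp."""
        vol = ts.CTVolume(np.zeros((30, 2, 2), np.float32),
                          spacing=(1, 1, 1))
        segments, plan = ts.chunk_z(vol, 16, 2)
        assert plan.segment_count == 2
        a = segments[0].copy()
        b = segments[1].copy()
        a.voxels[:] = 0.0
        b.voxels[:] = 1.0
        out = ts.stitch_z([a, b], plan, r=1)
        ov0 = plan.segment_offsets[1]          # overlap start = 14
        ov1 = plan.segment_offsets[0] + 16     # overlap end = 16
        # closed form: weights (i+1)/(n+1) against (n-i)/(n+1)
        expected = np.array([1 / 3, 2 / 3])
        np.testing.assert_allclose(out.voxels[ov0:ov1, 0, 0], expected,
                                   rtol=1e-6)
        np.testing.assert_allclose(out.voxels[:ov0], 0.0, atol=1e-7)
        np.testing.assert_allclose(out.voxels[ov1:], 1.0, rtol=1e-6)

    def test_segment_count_mismatch_rejected(self, rng):
        vol = ts.CTVolume(rng.uniform(0, 1, (30, 3, 3)), spacing=(1, 1, 1))
        segments, plan = ts.chunk_z(vol, 16, 2)
        with pytest.raises(ValueError):
            ts.stitch_z(segments[:1], plan, r=1)

    @settings(max_examples=25, deadline=None)
    @given(z=st.integers(1, 60), seg=st.integers(4, 20),
           ov=st.integers(0, 4), seed=st.integers(0, 10))
    def test_chunk_stitch_identity_property(self, z, seg, ov, seed):
        """chunk_z then stitch_z with r=1 is the identity for any z_len."""
        if ov >= seg / 2:
            ov = 0
        vox = np.random.default_rng(seed).uniform(-1000, 1000, (z, 3, 2))
        vol = ts.CTVolume(vox, spacing=(1.0, 1.0, 1.0))
        segments, plan = ts.chunk_z(vol, seg, ov)
        out = ts.stitch_z(segments, plan, r=1)
        np.testing.assert_allclose(out.voxels, vol.voxels, rtol=1e-5,
                                   atol=1e-3)
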