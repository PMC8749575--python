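"""Shared fixtures: tiny images and file-based study inputs built at test time."""

from __future__ import annotations

import numpy as np
import pytest

from echotex.image_io import GreyImage


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)


@pytest.fixture
def grey_image_factory():
    """Build a GreyImage from an integer array (optionally pre-normalized)."""

    def make(pixels, normalized=False, plane=None, source_id="test"):
        return GreyImage(pixels=np.asarray(pixels, dtype=np.uint8),
                         normalized=normalized, plane=plane, source_id=source_id)

    return make


@pytest.fixture
def dicom_factory(tmp_path):
    """Write a minimal single-frame DICOM file and return its path."""
    import pydicom
    from pydicom.dataset import Dataset, FileMetaDataset
    from pydicom.uid import ExplicitVRLittleEndian, SecondaryCaptureImageStorage, generate_uid

    def make(pixels, photometric="MONOCHROME2", name="scan.dcm", n_frames=None):
        pixels = np.asarray(pixels, dtype=np.uint8)
        frame_shape = pixels.shape[1:] if n_frames else pixels.shape
        meta = FileMetaDataset()
        meta.MediaStorageSOPClassUID = SecondaryCaptureImageStorage
        meta.MediaStorageSOPInstanceUID = generate_uid()
        meta.TransferSyntaxUID = ExplicitVRLittleEndian
        ds = Dataset()
        ds.file_meta = meta
        ds.SOPClassUID = meta.MediaStorageSOPClassUID
        ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
        ds.Modality = "US"
        ds.Rows, ds.Columns = frame_shape[:2]
        ds.SamplesPerPixel = 3 if (pixels.ndim == 3 and not n_frames) else 1
        if ds.SamplesPerPixel == 3:
            ds.PlanarConfiguration = 0
        ds.PhotometricInterpretation = photometric
        ds.BitsAllocated = 8
        ds.BitsStored = 8
        ds.HighBit = 7
        ds.PixelRepresentation = 0
        if n_frames is not None:
            ds.NumberOfFrames = n_frames
        ds.PixelData = pixels.tobytes()
        path = tmp_path / name
        ds.save_as(path, enforce_file_format=True)
        return path

    return make
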