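"""Reading and writing slices, templates and measurement tables.

Slices travel as 16-bit NIfTI (stored value = HU + 1024, recorded in the
header description) or as DICOM secondary capture with the equivalent
rescale intercept; measurement tables as long-format CSV.
"""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import pydicom
from pydicom.dataset import Dataset, FileMetaDataset
from pydicom.uid import ExplicitVRLittleEndian, SecondaryCaptureImageStorage, generate_uid

from .phantom import SliceImage

__all__ = [
    "write_slice_nifti",
    "read_slice_nifti",
    "write_slice_dicom",
    "read_slice_dicom",
    "read_slice",
    "write_measurements_csv",
    "read_measurements_csv",
]

HU_OFFSET = 1024
_CSV_FLOAT_FORMAT = "%.10g"

MEASUREMENT_COLUMNS = [
    "config", "reconstruction", "omar", "recon_key", "label",
    "mean_hu", "noise_hu", "snr", "cnr", "n_pixels", "category",
]


def write_slice_nifti(image: SliceImage, path) -> None:
    """16-bit NIfTI with stored value = HU + 1024 (offset noted in descrip)."""
    data = np.rint(np.clip(image.pixels, -HU_OFFSET, 32767 - HU_OFFSET)) + HU_OFFSET
    dx, dy = image.pixel_spacing_mm
    affine = np.diag([dx, dy, 1.0, 1.0])
    img = nib.Nifti1Image(data.astype(np.int16), affine)
    img.header["descrip"] = b"stored = HU + 1024"
    img.header.set_zooms((dx, dy))
    nib.save(img, str(path))


def read_slice_nifti(path) -> SliceImage:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float) - HU_OFFSET
    zooms = img.header.get_zooms()[:2]
    return SliceImage(data, (float(zooms[0]), float(zooms[1])), provenance=str(path))


def write_slice_dicom(image: SliceImage, path) -> None:
    """Minimal DICOM secondary-capture export (RescaleIntercept -1024)."""
    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = SecondaryCaptureImageStorage
    meta.MediaStorageSOPInstanceUID = generate_uid()
    meta.TransferSyntaxUID = ExplicitVRLittleEndian

    ds = Dataset()
    ds.file_meta = meta
    ds.SOPClassUID = SecondaryCaptureImageStorage
    ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
    ds.Modality = "OT"
    ds.Rows, ds.Columns = image.pixels.shape
    ds.PixelSpacing = [float(image.pixel_spacing_mm[1]), float(image.pixel_spacing_mm[0])]
    ds.BitsAllocated = 16
    ds.BitsStored = 16
    ds.HighBit = 15
    ds.PixelRepresentation = 0
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.RescaleIntercept = -HU_OFFSET
    ds.RescaleSlope = 1
    stored = np.rint(np.clip(image.pixels, -HU_OFFSET, 65535 - HU_OFFSET)) + HU_OFFSET
    ds.PixelData = stored.astype(np.uint16).tobytes()
    ds.save_as(str(path), enforce_file_format=True)


def read_slice_dicom(path) -> SliceImage:
    ds = pydicom.dcmread(str(path))
    slope = float(getattr(ds, "RescaleSlope", 1.0))
    intercept = float(getattr(ds, "RescaleIntercept", 0.0))
    data = ds.pixel_array.astype(float) * slope + intercept
    spacing = getattr(ds, "PixelSpacing", [1.0, 1.0])
    return SliceImage(
        data, (float(spacing[1]), float(spacing[0])), provenance=str(path)
    )


def read_slice(path) -> SliceImage:
    """Dispatch on extension: .nii/.nii.gz or .dcm."""
    p = Path(path)
    name = p.name.lower()
    if name.endswith((".nii", ".nii.gz")):
        return read_slice_nifti(p)
    if name.endswith(".dcm"):
        return read_slice_dicom(p)
    raise ValueError(f"unsupported image format: {p.name}")


def write_measurements_csv(df: pd.DataFrame, path) -> None:
    """Deterministic long-format measurement export (stable column order)."""
    cols = [c for c in MEASUREMENT_COLUMNS if c in df.columns]
    cols += [c for c in df.columns if c not in cols]
    df[cols].to_csv(path, index=False, float_format=_CSV_FLOAT_FORMAT)


def read_measurements_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "omar" in df.columns:
        df["omar"] = df["omar"].astype(bool)
    return df
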