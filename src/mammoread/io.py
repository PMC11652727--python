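"""Reading and writing the pipeline's external formats.

Images travel as 16-bit PNG with a JSON sidecar carrying the pixel
spacing and the intensity window used for integer encoding (or as
single-frame DICOM when requested); annotations, lesion truths and
area tables are plain CSV with documented column names.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .annotations import ANNOTATION_COLUMNS, LESION_COLUMNS


def write_image(path, array: np.ndarray, spacing: float,
                fmt: str = "png") -> Path:
    """Write a grey-scale image as 16-bit PNG (+ JSON spacing sidecar)
    or as a single-frame DICOM file."""
    path = Path(path)
    arr = np.asarray(array, dtype=float)
    lo, hi = float(arr.min()), float(arr.max())
    scale = (hi - lo) if hi > lo else 1.0
    encoded = np.round((arr - lo) / scale * 65535).astype(np.uint16)
    if fmt == "png":
        Image.fromarray(encoded).save(path)  # uint16 -> 16-bit greyscale
        sidecar = {"pixel_spacing_mm": spacing, "intensity_min": lo,
                   "intensity_max": hi, "dtype": "uint16"}
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))
    elif fmt == "dicom":
        _write_dicom(path, encoded, spacing, lo, hi)
    else:
        raise ValueError(f"unsupported image format: {fmt}")
    return path


def _write_dicom(path, encoded, spacing, lo, hi):
    import pydicom
    from pydicom.dataset import FileMetaDataset
    from pydicom.uid import ExplicitVRLittleEndian, generate_uid

    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = pydicom.uid.SecondaryCaptureImageStorage
    meta.MediaStorageSOPInstanceUID = generate_uid()
    meta.TransferSyntaxUID = ExplicitVRLittleEndian
    ds = pydicom.Dataset()
    ds.file_meta = meta
    ds.SOPClassUID = meta.MediaStorageSOPClassUID
    ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
    ds.Modality = "MG"
    ds.Rows, ds.Columns = encoded.shape
    ds.PixelSpacing = [spacing, spacing]
    ds.BitsAllocated = 16
    ds.BitsStored = 16
    ds.HighBit = 15
    ds.PixelRepresentation = 0
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.RescaleIntercept = lo
    ds.RescaleSlope = (hi - lo) / 65535 if hi > lo else 1.0
    ds.PixelData = encoded.tobytes()
    ds.save_as(path, enforce_file_format=True)


def read_image(path):
    """Load an image written by :func:`write_image`.

    Returns ``(array, spacing_mm)`` with the original intensity scale
    restored from the sidecar (PNG) or rescale tags (DICOM).
    """
    path = Path(path)
    if path.suffix.lower() in {".dcm", ".dicom"}:
        import pydicom

        ds = pydicom.dcmread(path)
        arr = ds.pixel_array.astype(float)
        arr = arr * float(ds.RescaleSlope) + float(ds.RescaleIntercept)
        return arr, float(ds.PixelSpacing[0])
    encoded = np.asarray(Image.open(path), dtype=float)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    lo, hi = sidecar["intensity_min"], sidecar["intensity_max"]
    arr = encoded / 65535 * (hi - lo) + lo
    return arr, float(sidecar["pixel_spacing_mm"])


def write_case_set(case_set, out_dir) -> Path:
    """Persist a synthetic case set: PNGs plus truth CSVs."""
    out_dir = Path(out_dir)
    img_dir = out_dir / "images"
    img_dir.mkdir(parents=True, exist_ok=True)
    for (case_id, view, side), arr in case_set.images.items():
        write_image(img_dir / f"{case_id}_{view}_{side}.png", arr,
                    case_set.pixel_spacing)
    case_set.lesion_truths.to_csv(out_dir / "lesions.csv", index=False)
    case_set.planted_area_truths.to_csv(out_dir / "area_truths.csv",
                                        index=False)
    return out_dir


def read_annotations(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in ANNOTATION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"annotation CSV missing columns: {missing}")
    return df


def read_lesions(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in LESION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"lesion CSV missing columns: {missing}")
    return df
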