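"""NIfTI and CSV input/output.

Label volumes travel as NIfTI files (integer data, spacing in the header)
with a JSON sidecar (``<file>.json``) carrying the label legend, knee side
and any per-scan metadata such as patient id and timepoint.  Tables are
tidy CSV (UTF-8, header row, period decimal separator).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

import nibabel as nib
import numpy as np
import pandas as pd

from .volume import LABEL_LEGEND, LabelVolume

__all__ = [
    "FormatError",
    "read_label_volume",
    "write_label_volume",
    "write_metrics_csv",
    "read_metrics_csv",
    "METRICS_COLUMNS",
]

METRICS_COLUMNS = ["patient_id", "timepoint_weeks", "bone", "region", "metric", "value"]


class FormatError(ValueError):
    """Raised when an input file violates the expected format."""


def _sidecar_path(path: Path) -> Path:
    return Path(str(path) + ".json")


def write_label_volume(volume: LabelVolume, path, metadata: Optional[dict] = None) -> Path:
    """Write a label volume as NIfTI plus a JSON sidecar; returns the path."""
    path = Path(path)
    affine = np.diag(list(volume.spacing_mm) + [1.0])
    img = nib.Nifti1Image(volume.data.astype(np.int16), affine)
    img.header.set_zooms(volume.spacing_mm)
    nib.save(img, path)
    sidecar = {
        "legend": {str(k): v for k, v in LABEL_LEGEND.items()},
        "knee_side": volume.knee_side,
        "canonical": volume.canonical,
    }
    if metadata:
        sidecar.update(metadata)
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=1, sort_keys=True))
    return path


def read_label_volume(path) -> tuple[LabelVolume, dict]:
    """Read a NIfTI label volume; returns (volume, sidecar metadata).

    Raises :class:`FormatError` naming the offending field for non-integer
    data, unknown labels or non-positive spacing.
    """
    path = Path(path)
    img = nib.load(path)
    data = np.asanyarray(img.dataobj)
    if not np.issubdtype(data.dtype, np.integer):
        if not np.allclose(data, np.round(data)):
            raise FormatError(f"{path}: data is not integer-valued (dtype {data.dtype})")
        data = np.round(data).astype(np.int16)
    # nibabel silently "repairs" non-positive pixdims on load, so validate
    # the raw, unchecked header field instead of the sanitized zooms
    with nib.openers.ImageOpener(str(path), "rb") as f:
        raw_hdr = nib.Nifti1Header.from_fileobj(f, check=False)
    raw_pixdim = tuple(float(z) for z in raw_hdr["pixdim"][1:4])
    if any(not np.isfinite(z) or z <= 0 for z in raw_pixdim):
        raise FormatError(f"{path}: spacing must be positive, header pixdim is {raw_pixdim}")
    zooms = img.header.get_zooms()[:3]
    unknown = sorted(set(np.unique(data)) - set(LABEL_LEGEND))
    if unknown:
        raise FormatError(f"{path}: unknown labels {unknown} (legend: {sorted(LABEL_LEGEND)})")
    meta: dict = {}
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    volume = LabelVolume(
        data=data.astype(np.int16),
        spacing_mm=tuple(float(z) for z in zooms),
        knee_side=meta.get("knee_side", "right"),
    )
    volume.canonical = bool(meta.get("canonical", False))
    return volume, meta


def write_metrics_csv(df: pd.DataFrame, path) -> Path:
    """Deterministic CSV writer (fixed float format, sorted rows)."""
    path = Path(path)
    sort_cols = [c for c in METRICS_COLUMNS if c in df.columns] or list(df.columns)
    out = df.sort_values(sort_cols).reset_index(drop=True)
    out.to_csv(path, index=False, float_format="%.10g")
    return path


def read_metrics_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"patient_id": str})
    missing = set(METRICS_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: metrics CSV lacks columns {sorted(missing)}")
    return df
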