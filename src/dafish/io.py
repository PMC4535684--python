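"""File formats: multi-page TIFF images, TSV tables, JSON configs.

All tables are TSV with a header row, UTF-8, '.' decimal.  Images are written
as 16-bit multi-page TIFF; values exceeding the 16-bit range are divided by a
scale factor recorded in the page description (JSON), and restored on read.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .quantify import CellMeasurement
from .segmentation import Contour

__all__ = [
    "read_image_stack",
    "write_image_stack",
    "write_table",
    "read_table",
    "contours_to_table",
    "contours_from_table",
    "measurements_to_table",
    "measurements_from_table",
]

_U16_MAX = 65535


def write_image_stack(path, array: np.ndarray, metadata: dict | None = None) -> None:
    """Write a 2D image or 3D stack (section, row, col) as 16-bit TIFF.

    Non-negative data only.  A ``scale_factor`` (original = stored * factor)
    is stored in the TIFF description together with any user metadata.
    """
    arr = np.asarray(array)
    if arr.ndim not in (2, 3):
        raise ValueError("expected a 2D image or a 3D stack")
    if arr.size and float(arr.min()) < 0:
        raise ValueError("photon-count images must be non-negative")
    peak = float(arr.max()) if arr.size else 0.0
    scale = peak / _U16_MAX if peak > _U16_MAX else 1.0
    stored = np.round(arr / scale).astype(np.uint16)
    desc = dict(metadata or {})
    desc["scale_factor"] = scale
    tifffile.imwrite(str(path), stored, description=json.dumps(desc))


def read_image_stack(path):
    """Read a TIFF as ``(array, metadata)``.

    Multi-page files come back as ``(section, row, col)``; single-page as 2D.
    Pages of inconsistent shape are a format error.  The stored scale factor,
    if any, is applied (so round trips of in-range integer data are exact).
    """
    path = Path(path)
    try:
        with tifffile.TiffFile(str(path)) as tif:
            shapes = {p.shape for p in tif.pages}
            if len(shapes) > 1:
                raise ValueError(f"inconsistent page shapes in {path}: {sorted(shapes)}")
            arr = tif.asarray()
            desc = tif.pages[0].description
    except tifffile.TiffFileError as exc:
        raise ValueError(f"{path} is not a readable TIFF: {exc}") from exc
    metadata: dict = {}
    if desc:
        try:
            metadata = json.loads(desc)
        except (json.JSONDecodeError, TypeError):
            metadata = {"description": desc}
    scale = float(metadata.get("scale_factor", 1.0))
    if scale != 1.0:
        arr = arr.astype(float) * scale
    return arr, metadata


def write_table(path, frame: pd.DataFrame) -> None:
    frame.to_csv(path, sep="\t", index=False)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def contours_to_table(contours: dict) -> pd.DataFrame:
    """``{(cell_id, homolog): Contour}`` -> long table of vertices."""
    rows = []
    for (cell_id, homolog), contour in contours.items():
        for i, (r, c) in enumerate(contour.vertices):
            rows.append(
                {
                    "cell_id": cell_id,
                    "homolog": homolog,
                    "vertex_index": i,
                    "row": r,
                    "col": c,
                }
            )
    return pd.DataFrame(rows)


def contours_from_table(frame: pd.DataFrame) -> dict:
    out = {}
    for (cell_id, homolog), grp in frame.groupby(["cell_id", "homolog"], sort=True):
        grp = grp.sort_values("vertex_index")
        out[(cell_id, homolog)] = Contour(grp[["row", "col"]].to_numpy(float))
    return out


def measurements_to_table(measurements) -> pd.DataFrame:
    rows = []
    for m in measurements:
        rows.append(
            {
                "cell_id": m.cell_id,
                "locus_id": m.locus_id,
                "I_A": m.intensity_a,
                "I_B": m.intensity_b,
                "d": m.normalized_difference,
                "weaker": m.weaker_homolog,
                "qc_flags": ";".join(m.qc_flags),
            }
        )
    return pd.DataFrame(rows)


def measurements_from_table(frame: pd.DataFrame):
    out = []
    for row in frame.itertuples(index=False):
        flags = getattr(row, "qc_flags", "")
        flags = tuple(str(flags).split(";")) if isinstance(flags, str) and flags else ()
        out.append(
            CellMeasurement(
                cell_id=str(row.cell_id),
                locus_id=str(row.locus_id),
                intensity_a=float(row.I_A),
                intensity_b=float(row.I_B),
                normalized_difference=float(row.d),
                weaker_homolog=str(row.weaker),
                qc_flags=flags,
            )
        )
    return out
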