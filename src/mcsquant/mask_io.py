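"""Reading and writing masks, polygon annotations, grayscale images and reports.

Conventions
-----------
* Arrays are indexed ``(row, col)``, 0-based.
* Region masks are boolean grids; instance masks are non-negative integer
  grids where 0 is background and any positive value is an instance id.
  Instance ids need not be consecutive and are preserved verbatim.
* Polygon vertices are ``(x, y) = (col, row)``, the Labelme convention.
  A pixel belongs to a polygon iff its center lies inside under the
  even-odd rule.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, fields as dc_fields
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
import tifffile
from PIL import Image

from ._errors import ConsistencyError, IOFormatError

__all__ = [
    "GrayImage",
    "PolygonAnnotation",
    "ReportRow",
    "read_gray_image",
    "read_label_image",
    "write_label_image",
    "read_labelme",
    "write_labelme",
    "polygons_to_mask",
    "write_report",
    "read_report",
]

_TIFF_SUFFIXES = {".tif", ".tiff"}


@dataclass
class GrayImage:
    """A 2D grayscale raster with a known physical pixel size in nm."""

    pixels: np.ndarray
    pixel_size_nm: float

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2 or self.pixels.shape[0] < 1 or self.pixels.shape[1] < 1:
            raise IOFormatError("grayscale image must be a non-empty 2D grid")
        if not self.pixel_size_nm > 0:
            raise IOFormatError("pixel_size_nm must be positive")

    @property
    def shape(self) -> tuple:
        return self.pixels.shape


@dataclass
class PolygonAnnotation:
    """A labeled polygon in image space, vertices as (x, y) = (col, row)."""

    label: str
    vertices: np.ndarray

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, dtype=float)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 2 or len(self.vertices) < 3:
            raise IOFormatError("polygon needs at least 3 (x, y) vertices")


def _read_raster(path) -> np.ndarray:
    path = Path(path)
    if not path.exists():
        raise IOFormatError(f"no such file: {path}")
    if path.stat().st_size == 0:
        raise IOFormatError(f"empty file: {path}")
    try:
        if path.suffix.lower() in _TIFF_SUFFIXES:
            arr = tifffile.imread(path)
        else:
            arr = np.asarray(Image.open(path))
    except (OSError, ValueError) as exc:
        raise IOFormatError(f"cannot read raster {path}: {exc}") from exc
    return arr


def read_gray_image(path, pixel_size_nm: float) -> GrayImage:
    """Load a grayscale image and tag it with its native resolution."""
    arr = _read_raster(path)
    if arr.ndim == 3:  # collapse an RGB(A) PNG to luminance
        arr = arr[..., :3].mean(axis=-1)
    return GrayImage(arr, pixel_size_nm)


def read_label_image(path, mode: str = "instances") -> np.ndarray:
    """Load a label raster as a region (binary) or instance mask.

    Parameters
    ----------
    path : path-like
        PNG (8/16-bit) or TIFF file holding an integer-valued raster.
    mode : {"binary", "instances"}
        ``"binary"`` collapses every non-zero pixel to True;
        ``"instances"`` preserves the integer labels verbatim.
    """
    if mode not in ("binary", "instances"):
        raise ValueError(f"mode must be 'binary' or 'instances', got {mode!r}")
    arr = _read_raster(path)
    if arr.ndim == 3:
        # palette/RGB label PNGs: only accept if all channels agree
        if not (arr[..., 0] == arr[..., 1]).all() or arr.shape[-1] < 3:
            raise IOFormatError(f"{path}: multi-channel raster is not a label image")
        arr = arr[..., 0]
    if arr.dtype == bool:
        arr = arr.astype(np.uint8)
    if not np.issubdtype(arr.dtype, np.integer):
        raise IOFormatError(f"{path}: label image must be integer-valued, got {arr.dtype}")
    if (arr < 0).any():
        raise IOFormatError(f"{path}: negative labels are not valid instance ids")
    if mode == "binary":
        return arr != 0
    return arr.astype(np.int64, copy=False)


def write_label_image(mask: np.ndarray, path) -> None:
    """Write a region or instance mask as PNG (8/16-bit as needed) or TIFF."""
    path = Path(path)
    arr = np.asarray(mask)
    if arr.dtype == bool:
        arr = arr.astype(np.uint8)
    if path.suffix.lower() in _TIFF_SUFFIXES:
        tifffile.imwrite(path, arr.astype(np.int32, copy=False))
        return
    vmax = int(arr.max()) if arr.size else 0
    if vmax > 65535:
        raise IOFormatError("instance ids exceed 16-bit PNG range; use TIFF")
    if vmax > 255:
        Image.fromarray(arr.astype(np.uint16)).save(path)
    else:
        Image.fromarray(arr.astype(np.uint8), mode="L").save(path)


def read_labelme(path) -> list:
    """Parse a Labelme-style JSON file into PolygonAnnotation objects."""
    path = Path(path)
    try:
        payload = json.loads(path.read_text())
    except (OSError, json.JSONDecodeError) as exc:
        raise IOFormatError(f"cannot parse annotation file {path}: {exc}") from exc
    shapes = payload.get("shapes")
    if shapes is None:
        raise IOFormatError(f"{path}: missing top-level 'shapes' list")
    annotations = []
    for shape in shapes:
        pts = shape.get("points", [])
        if len(pts) < 3:
            continue  # degenerate shapes (points, lines) carry no area
        annotations.append(PolygonAnnotation(label=shape.get("label", ""), vertices=pts))
    return annotations


def write_labelme(annotations: Iterable[PolygonAnnotation], path,
                  image_shape: Optional[tuple] = None) -> None:
    payload = {
        "shapes": [
            {
                "label": a.label,
                "points": np.asarray(a.vertices, dtype=float).tolist(),
                "shape_type": "polygon",
            }
            for a in annotations
        ],
    }
    if image_shape is not None:
        payload["imageHeight"] = int(image_shape[0])
        payload["imageWidth"] = int(image_shape[1])
    Path(path).write_text(json.dumps(payload, indent=1))


def _even_odd_inside(vertices: np.ndarray, xs: np.ndarray, ys: np.ndarray) -> np.ndarray:
    """Even-odd (crossing-number) point-in-polygon test on a pixel-center grid.

    Edges are treated half-open in y so that boundary points are classified
    consistently (a point exactly on the maximal-x/maximal-y edge falls
    outside, matching half-open raster semantics).
    """
    X, Y = np.meshgrid(xs, ys)
    inside = np.zeros(X.shape, dtype=bool)
    v = np.asarray(vertices, dtype=float)
    n = len(v)
    for k in range(n):
        x1, y1 = v[k]
        x2, y2 = v[(k + 1) % n]
        if y1 == y2:
            continue  # horizontal edges never cross a horizontal ray transversally
        straddles = (y1 > Y) != (y2 > Y)
        with np.errstate(invalid="ignore"):
            x_cross = x1 + (Y - y1) * (x2 - x1) / (y2 - y1)
        inside ^= straddles & (X < x_cross)
    return inside


def polygons_to_mask(annotations: Sequence[PolygonAnnotation], shape: tuple,
                     label_filter=None) -> np.ndarray:
    """Rasterize polygons onto a boolean mask by pixel-center containment.

    A pixel (row i, col j) has center (x=j, y=i); it is set iff the center
    lies inside any polygon whose label passes ``label_filter`` (a string, a
    collection of strings, or None for all labels). Self-intersecting
    polygons are filled under the even-odd rule. If no polygon matches, an
    empty mask is returned and a warning is emitted.
    """
    H, W = shape
    if isinstance(label_filter, str):
        wanted = {label_filter}
    elif label_filter is None:
        wanted = None
    else:
        wanted = set(label_filter)
    selected = [a for a in annotations if wanted is None or a.label in wanted]
    mask = np.zeros((H, W), dtype=bool)
    if not selected:
        warnings.warn(f"no polygon matches label filter {label_filter!r}; returning empty mask",
                      stacklevel=2)
        return mask
    xs = np.arange(W, dtype=float)
    ys = np.arange(H, dtype=float)
    for poly in selected:
        mask |= _even_odd_inside(poly.vertices, xs, ys)
    return mask


# ---------------------------------------------------------------------------
# Tabular reports
# ---------------------------------------------------------------------------

AGGREGATE_PATCH_ID = "aggregate"


@dataclass
class ReportRow:
    """One row of the quantification report: a patch or a per-image aggregate.

    ``length_per_bin`` holds the contacting mitochondria boundary length
    (boundary-pixel count) per integer width bin 0..T, bin 0 being overlap.
    ``ratio_per_bin`` is each length divided by the total mitochondria
    boundary length; it is None (flagged undefined) when the patch contains
    no mitochondria boundary. ``cumulative_ratio`` sums ratios over bins
    0..cumulative_cut (default cut 3 = contacts up to 30 nm at 10 nm/px).
    """

    image_id: str
    patch_id: str
    pair: str
    n_instances: int
    total_perimeter_px: float
    mean_perimeter_px: Optional[float]
    total_area_px: float
    mean_elongation: Optional[float]
    len_mito_px: int
    n_contact_px: int
    n_contact_segments: int
    length_per_bin: tuple
    ratio_per_bin: Optional[tuple]
    cumulative_cut: int
    cumulative_ratio: Optional[float] = field(default=None)

    def __post_init__(self):
        self.length_per_bin = tuple(int(v) for v in self.length_per_bin)
        if any(v < 0 for v in self.length_per_bin):
            raise ConsistencyError("per-bin contact lengths must be non-negative")
        if self.ratio_per_bin is not None:
            self.ratio_per_bin = tuple(float(v) for v in self.ratio_per_bin)
            if len(self.ratio_per_bin) != len(self.length_per_bin):
                raise ConsistencyError("length and ratio bin counts differ")
            if any(not 0.0 <= v <= 1.0 for v in self.ratio_per_bin):
                raise ConsistencyError("contact ratios must lie in [0, 1]")
            if self.cumulative_ratio is None:
                self.cumulative_ratio = self.cumulative_ratio_at(self.cumulative_cut)

    @property
    def threshold(self) -> int:
        return len(self.length_per_bin) - 1

    def cumulative_ratio_at(self, k: int) -> Optional[float]:
        """Summed contact ratio over width bins 0..k (overlap through k px)."""
        if self.ratio_per_bin is None:
            return None
        return float(sum(self.ratio_per_bin[: k + 1]))


def _report_columns(T: int) -> list:
    scalar = [f.name for f in dc_fields(ReportRow)
              if f.name not in ("length_per_bin", "ratio_per_bin")]
    return (scalar
            + [f"len_bin_{b}" for b in range(T + 1)]
            + [f"ratio_bin_{b}" for b in range(T + 1)])


def _rows_to_frame(rows: Sequence[ReportRow]) -> pd.DataFrame:
    thresholds = {r.threshold for r in rows}
    if len(thresholds) > 1:
        raise ConsistencyError(f"rows mix bin counts (thresholds {sorted(thresholds)})")
    T = thresholds.pop() if thresholds else 10
    records = []
    for r in rows:
        rec = {f.name: getattr(r, f.name) for f in dc_fields(ReportRow)
               if f.name not in ("length_per_bin", "ratio_per_bin")}
        for b in range(T + 1):
            rec[f"len_bin_{b}"] = r.length_per_bin[b]
            rec[f"ratio_bin_{b}"] = None if r.ratio_per_bin is None else r.ratio_per_bin[b]
        records.append(rec)
    return pd.DataFrame.from_records(records, columns=_report_columns(T))


def write_report(rows: Sequence[ReportRow], path, format: Optional[str] = None) -> None:
    """Write rows to CSV or JSON with a deterministic column order.

    All rows must share one bin count T. Floats are written with the
    shortest round-trippable representation, so write-then-read reproduces
    values exactly.
    """
    path = Path(path)
    if format is None:
        format = "json" if path.suffix.lower() == ".json" else "csv"
    if format not in ("csv", "json"):
        raise ValueError(f"format must be 'csv' or 'json', got {format!r}")
    df = _rows_to_frame(rows)
    if format == "csv":
        df.to_csv(path, index=False)
    else:
        records = df.to_dict(orient="records")
        clean = [{k: (None if isinstance(v, float) and np.isnan(v) else v)
                  for k, v in rec.items()} for rec in records]
        path.write_text(json.dumps({"columns": list(df.columns), "rows": clean}, indent=1))


def read_report(path, format: Optional[str] = None) -> list:
    """Read a report back into ReportRow objects (inverse of write_report)."""
    path = Path(path)
    if format is None:
        format = "json" if path.suffix.lower() == ".json" else "csv"
    if format == "csv":
        df = pd.read_csv(path, float_precision="round_trip")
    else:
        payload = json.loads(path.read_text())
        df = pd.DataFrame(payload["rows"], columns=payload["columns"])
    len_cols = [c for c in df.columns if c.startswith("len_bin_")]
    T = len(len_cols) - 1
    rows = []
    for _, rec in df.iterrows():
        lengths = tuple(int(rec[f"len_bin_{b}"]) for b in range(T + 1))
        ratios = [rec[f"ratio_bin_{b}"] for b in range(T + 1)]
        has_ratios = not any(r is None or (isinstance(r, float) and np.isnan(r)) for r in ratios)

        def _opt(v):
            if v is None or (isinstance(v, float) and np.isnan(v)):
                return None
            return float(v)

        rows.append(ReportRow(
            image_id=str(rec["image_id"]),
            patch_id=str(rec["patch_id"]),
            pair=str(rec["pair"]),
            n_instances=int(rec["n_instances"]),
            total_perimeter_px=float(rec["total_perimeter_px"]),
            mean_perimeter_px=_opt(rec["mean_perimeter_px"]),
            total_area_px=float(rec["total_area_px"]),
            mean_elongation=_opt(rec["mean_elongation"]),
            len_mito_px=int(rec["len_mito_px"]),
            n_contact_px=int(rec["n_contact_px"]),
            n_contact_segments=int(rec["n_contact_segments"]),
            length_per_bin=lengths,
            ratio_per_bin=tuple(float(r) for r in ratios) if has_ratios else None,
            cumulative_cut=int(rec["cumulative_cut"]),
            cumulative_ratio=_opt(rec["cumulative_ratio"]),
        ))
    return rows
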