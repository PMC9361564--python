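"""Seeded generator of organelle-like scenes with known contact geometry.

Scenes emulate what a segmenter would emit for a 2D EM patch: disk- or
blob-like mitochondria and lipid droplets as instance masks, and the
ribbon-like ER network as a single region mask, placed at controlled gap
widths so the contact profile is known analytically or by exhaustive
enumeration. Fixtures can be written in the exact formats the real
pipeline reads (label PNG + Labelme-style polygon JSON), so I/O,
preprocessing and quantification are exercised end-to-end without EM data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Tuple

import numpy as np

from ._errors import ConfigError
from . import mask_io

__all__ = [
    "Primitive",
    "SceneSpec",
    "render_scene",
    "parallel_bar_scene",
    "random_blob_scene",
    "write_scene",
]

_ORGANELLES = ("mito", "er", "ld")
_KINDS = ("disk", "bar", "ribbon", "blob")


@dataclass(frozen=True)
class Primitive:
    """One geometric primitive of a synthetic scene.

    kind/params:
      disk   — center (row, col), radius r: pixels with (dr^2 + dc^2) <= r^2
      bar    — top, left, height, width: a filled axis-aligned rectangle
      ribbon — points [(row, col), ...], half_width: pixels within
               half_width (Euclidean) of the polyline
      blob   — center, n_steps, r, seed: union of disks along a seeded
               random walk
    """

    kind: str
    organelle: str
    params: dict
    instance_id: int = 1

    def __post_init__(self):
        if self.kind not in _KINDS:
            raise ConfigError(f"unknown primitive kind {self.kind!r}")
        if self.organelle not in _ORGANELLES:
            raise ConfigError(f"unknown organelle class {self.organelle!r}")


@dataclass
class SceneSpec:
    """Shape, primitives and seed fully describing one synthetic scene."""

    shape: Tuple[int, int]
    primitives: List[Primitive] = field(default_factory=list)
    rng_seed: int = 0


def _grid(shape):
    rows = np.arange(shape[0], dtype=float)
    cols = np.arange(shape[1], dtype=float)
    return np.meshgrid(rows, cols, indexing="ij")


def _render_disk(shape, center, radius) -> np.ndarray:
    R, C = _grid(shape)
    return (R - center[0]) ** 2 + (C - center[1]) ** 2 <= radius ** 2


def _render_bar(shape, top, left, height, width) -> np.ndarray:
    m = np.zeros(shape, dtype=bool)
    m[top:top + height, left:left + width] = True
    return m


def _point_segment_dist2(R, C, p, q):
    # squared distance from every pixel center to segment p-q
    pr, pc = p
    qr, qc = q
    dr, dc = qr - pr, qc - pc
    L2 = dr * dr + dc * dc
    if L2 == 0:
        return (R - pr) ** 2 + (C - pc) ** 2
    t = np.clip(((R - pr) * dr + (C - pc) * dc) / L2, 0.0, 1.0)
    return (R - (pr + t * dr)) ** 2 + (C - (pc + t * dc)) ** 2


def _render_ribbon(shape, points, half_width) -> np.ndarray:
    R, C = _grid(shape)
    d2 = np.full(shape, np.inf)
    pts = [tuple(map(float, p)) for p in points]
    for p, q in zip(pts[:-1], pts[1:]):
        d2 = np.minimum(d2, _point_segment_dist2(R, C, p, q))
    return d2 <= half_width ** 2


def _render_blob(shape, center, n_steps, radius, seed) -> np.ndarray:
    rng = np.random.default_rng(seed)
    m = np.zeros(shape, dtype=bool)
    r, c = float(center[0]), float(center[1])
    for _ in range(max(1, int(n_steps))):
        m |= _render_disk(shape, (r, c), radius)
        r = float(np.clip(r + rng.normal(0, radius / 2), radius, shape[0] - 1 - radius))
        c = float(np.clip(c + rng.normal(0, radius / 2), radius, shape[1] - 1 - radius))
    return m


def _render_primitive(shape, prim: Primitive) -> np.ndarray:
    p = prim.params
    if prim.kind == "disk":
        return _render_disk(shape, p["center"], p["radius"])
    if prim.kind == "bar":
        return _render_bar(shape, p["top"], p["left"], p["height"], p["width"])
    if prim.kind == "ribbon":
        return _render_ribbon(shape, p["points"], p["half_width"])
    return _render_blob(shape, p["center"], p.get("n_steps", 5),
                        p["radius"], p.get("seed", 0))


def render_scene(spec: SceneSpec):
    """Rasterize a scene into (mito InstanceMask, er RegionMask, ld InstanceMask).

    Deterministic given the spec; a primitive whose mask is entirely
    out of bounds (renders empty despite non-empty geometry) raises.
    """
    H, W = spec.shape
    mito = np.zeros((H, W), dtype=np.int32)
    ld = np.zeros((H, W), dtype=np.int32)
    er = np.zeros((H, W), dtype=bool)
    seen_ids = {"mito": set(), "ld": set()}
    for prim in spec.primitives:
        m = _render_primitive((H, W), prim)
        if not m.any():
            raise ConfigError(f"primitive {prim.kind} ({prim.organelle}) is out of bounds")
        if prim.organelle == "er":
            er |= m
        else:
            target = mito if prim.organelle == "mito" else ld
            ids = seen_ids[prim.organelle]
            if prim.instance_id in ids:
                raise ConfigError(
                    f"duplicate instance id {prim.instance_id} in class {prim.organelle}")
            ids.add(prim.instance_id)
            target[m] = prim.instance_id
    return mito, er, ld


def parallel_bar_scene(gap_px: int, height: int, threshold: int,
                       margin: int = 4):
    """Two facing 1-px-wide vertical bars with ``gap_px`` background columns.

    Returns (mito InstanceMask, er RegionMask, expected length_per_bin).
    The facing edges are gap_px + 1 apart center-to-center; with equal,
    aligned bar extents every mitochondria boundary pixel contacts at
    exactly that distance, so the expected profile puts all ``height``
    pixels in bin gap_px + 1 (empty when gap_px + 1 > threshold).
    """
    if gap_px < 0 or height < 1:
        raise ConfigError("gap_px must be >= 0 and height >= 1")
    T = int(threshold)
    H = height + 2 * margin
    W = gap_px + 2 + 2 * margin
    spec = SceneSpec(shape=(H, W), primitives=[
        Primitive("bar", "mito", dict(top=margin, left=margin, height=height, width=1)),
        Primitive("bar", "er",
                  dict(top=margin, left=margin + 1 + gap_px, height=height, width=1)),
    ])
    mito, er, _ = render_scene(spec)
    expected = np.zeros(T + 1, dtype=np.int64)
    if gap_px + 1 <= T:
        expected[gap_px + 1] = height
    return mito, er, expected


def random_blob_scene(n_mito: int = 5, er_density: float = 0.5, rng_seed: int = 0,
                      shape: Tuple[int, int] = (128, 128),
                      n_ld: int = 0) -> SceneSpec:
    """A seeded scene of disk/blob mitochondria and ribbon/bar ER.

    ``er_density`` in [0, 1] scales the number of ER ribbons (0 gives an
    empty ER). Organelle overlap is allowed, as segmenter outputs may
    overlap; scenes are used for oracle-equivalence sweeps.
    """
    if n_mito < 0 or n_ld < 0 or er_density < 0:
        raise ConfigError("scene parameters must be non-negative")
    rng = np.random.default_rng(rng_seed)
    H, W = shape
    prims: List[Primitive] = []
    for k in range(n_mito):
        r = int(rng.integers(3, max(4, min(H, W) // 10)))
        center = (int(rng.integers(r, H - r)), int(rng.integers(r, W - r)))
        if rng.random() < 0.5:
            prims.append(Primitive("disk", "mito", dict(center=center, radius=r),
                                   instance_id=k + 1))
        else:
            prims.append(Primitive(
                "blob", "mito",
                dict(center=center, n_steps=int(rng.integers(2, 5)), radius=max(2, r // 2),
                     seed=int(rng.integers(0, 2 ** 31 - 1))),
                instance_id=k + 1))
    n_er = int(round(er_density * 6))
    for _ in range(n_er):
        n_pts = int(rng.integers(2, 5))
        pts = np.column_stack([rng.integers(2, H - 2, n_pts),
                               rng.integers(2, W - 2, n_pts)]).astype(float)
        prims.append(Primitive("ribbon", "er",
                               dict(points=pts.tolist(),
                                    half_width=float(rng.uniform(1.0, 2.5)))))
    for k in range(n_ld):
        r = int(rng.integers(2, max(3, min(H, W) // 16)))
        center = (int(rng.integers(r, H - r)), int(rng.integers(r, W - r)))
        prims.append(Primitive("disk", "ld", dict(center=center, radius=r),
                               instance_id=k + 1))
    return SceneSpec(shape=shape, primitives=prims, rng_seed=rng_seed)


def _mask_to_polygons(mask: np.ndarray, label: str) -> list:
    """Trace each connected component's filled bounding outline as a polygon.

    Used only to emit Labelme-style fixtures; outlines are taken from
    skimage marching squares on a padded mask, shifted to (x, y) order.
    """
    from skimage import measure

    annotations = []
    padded = np.pad(np.asarray(mask).astype(float), 1)
    for contour in measure.find_contours(padded, 0.5):
        # contour is (row, col) on the padded grid; shift back and flip to (x, y)
        verts = np.column_stack([contour[:, 1] - 1.0, contour[:, 0] - 1.0])
        if len(verts) >= 3:
            annotations.append(mask_io.PolygonAnnotation(label=label, vertices=verts))
    return annotations


def write_scene(scene_dir, mito: np.ndarray, er: np.ndarray,
                ld: Optional[np.ndarray] = None,
                roi_polygon: Optional[np.ndarray] = None,
                pixel_nm: float = 10.0) -> dict:
    """Write a scene in the formats the pipeline reads.

    Emits mito.png / er.png (/ ld.png) label images, annotations.json with
    polygon outlines (plus an optional plasma-membrane RoI polygon), and a
    meta.json recording the pixel size. Returns the path map.
    """
    scene_dir = Path(scene_dir)
    scene_dir.mkdir(parents=True, exist_ok=True)
    paths = {}
    mask_io.write_label_image(np.asarray(mito), scene_dir / "mito.png")
    paths["mito"] = scene_dir / "mito.png"
    mask_io.write_label_image(np.asarray(er), scene_dir / "er.png")
    paths["er"] = scene_dir / "er.png"
    if ld is not None:
        mask_io.write_label_image(np.asarray(ld), scene_dir / "ld.png")
        paths["ld"] = scene_dir / "ld.png"
    annotations = (_mask_to_polygons(np.asarray(mito) > 0, "mito")
                   + _mask_to_polygons(np.asarray(er) > 0, "er"))
    if roi_polygon is not None:
        annotations.append(mask_io.PolygonAnnotation(label="plasma_membrane",
                                                     vertices=roi_polygon))
    mask_io.write_labelme(annotations, scene_dir / "annotations.json",
                          image_shape=np.asarray(mito).shape)
    paths["annotations"] = scene_dir / "annotations.json"
    (scene_dir / "meta.json").write_text(json.dumps({"pixel_size_nm": pixel_nm}))
    paths["meta"] = scene_dir / "meta.json"
    return paths
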