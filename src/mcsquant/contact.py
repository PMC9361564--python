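"""Membrane-contact-site quantification between organelle boundary pixels.

Given a mitochondria (or lipid-droplet) mask and an ER region mask on the
same pixel grid, the pipeline is:

1. extract the inner boundary of each mask;
2. mark the overlap region (pixels claimed by both masks);
3. for every non-overlap ER boundary pixel, record the minimum Euclidean
   distance to a non-overlap mitochondria boundary pixel within the contact
   range T (``MinDistance``);
4. for every non-overlap mitochondria boundary pixel, record the minimum
   distance to an ER boundary pixel among *admissible* candidates — an ER
   pixel is admissible only if the pair distance is less than that ER
   pixel's MinDistance + 1 px. This near-one-to-one rule reflects the
   biology: a tethering site on one membrane communicates with a unique
   site on the other, but at 10 nm/px the strict one-to-one constraint is
   relaxed by one pixel;
5. mitochondria boundary pixels inside the overlap get distance 0;
6. bin distances into integer pixel-width bins 0..T (bin b = distances d
   with ceil(d) = b; bin 0 = overlap) and divide by the total mitochondria
   boundary length to obtain per-width contact ratios.

``brute_force_contact`` re-derives the whole profile by exhaustive
all-pairs enumeration with no search window and serves as the oracle for
the optimized KD-tree path.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from ._errors import (
    ConsistencyError,
    ShapeMismatchError,
    UndefinedRatioError,
)
from .mask_io import AGGREGATE_PATCH_ID, ReportRow
from . import morphometrics

__all__ = [
    "ContactConfig",
    "DistanceGrid",
    "ContactProfile",
    "ContactRatios",
    "extract_boundary",
    "compute_overlap",
    "compute_min_distance",
    "compute_distance_map",
    "profile_contacts",
    "contact_ratio",
    "brute_force_contact",
    "contact_pipeline",
    "quantify_patch",
    "aggregate_image",
]

_EIGHT_CONNECTED = np.ones((3, 3), dtype=bool)


@dataclass(frozen=True)
class ContactConfig:
    """Contact-analysis parameters.

    threshold_px : maximum pixel distance counted as a contact (default 10,
        i.e. 0-100 nm at the 10 nm/px analysis standard).
    pixel_nm : physical pixel size, used only for labeling outputs.
    cumulative_cut : width bin at which the default cumulative ratio is
        reported; 3 bins = contacts up to 30 nm, the convention used for
        LD-mitochondria contacts.
    """

    threshold_px: int = 10
    pixel_nm: float = 10.0
    cumulative_cut: int = 3

    def __post_init__(self):
        if int(self.threshold_px) != self.threshold_px or self.threshold_px < 1:
            raise ValueError("threshold_px must be an integer >= 1")
        if not self.pixel_nm > 0:
            raise ValueError("pixel_nm must be positive")
        if not 0 <= self.cumulative_cut <= self.threshold_px:
            raise ValueError("cumulative_cut must lie in [0, threshold_px]")


@dataclass
class DistanceGrid:
    """Per-pixel contact distances (pixel units) with sentinel threshold+1.

    Non-sentinel values occur only on the relevant edge pixels: on ER edges
    for MinDistance, on mitochondria edges for the final distance map
    (where 0 marks overlap edge pixels).
    """

    values: np.ndarray
    threshold: int

    @property
    def sentinel(self) -> float:
        return float(self.threshold + 1)


@dataclass
class ContactProfile:
    """Width-binned contact lengths for one mitochondria/ER scene.

    length_per_bin[b] counts mitochondria boundary pixels whose contact
    distance rounds up to b pixels (bin 0 = overlap). len_con is the total
    contacting boundary length, len_mito the total mitochondria boundary
    length, n_con the count of non-overlap contacting pixels, and
    n_segments the number of 8-connected contacting runs (discrete contact
    sites).
    """

    length_per_bin: np.ndarray
    len_con: int
    n_con: int
    n_segments: int
    len_mito: int

    def __post_init__(self):
        self.length_per_bin = np.asarray(self.length_per_bin, dtype=np.int64)
        if self.length_per_bin.sum() != self.len_con:
            raise ConsistencyError("per-bin lengths do not sum to len_con")
        if self.len_con > self.len_mito:
            raise ConsistencyError("contacting length exceeds boundary length")

    @property
    def threshold(self) -> int:
        return len(self.length_per_bin) - 1


@dataclass
class ContactRatios:
    """Per-bin and cumulative contact ratios derived from a ContactProfile."""

    per_bin: np.ndarray
    cumulative: np.ndarray

    def at(self, k: int) -> float:
        """Cumulative ratio over bins 0..k."""
        return float(self.cumulative[k])


def extract_boundary(mask: np.ndarray) -> np.ndarray:
    """Inner boundary of a binary mask.

    A pixel is a boundary pixel iff it is foreground and has a background
    4-neighbor or lies on the image border. The boundary-pixel count is the
    perimeter measure used throughout.
    """
    m = np.asarray(mask).astype(bool)
    if m.size == 0 or not m.any():
        return np.zeros_like(m)
    p = np.pad(m, 1, constant_values=False)
    interior = p[:-2, 1:-1] & p[2:, 1:-1] & p[1:-1, :-2] & p[1:-1, 2:]
    return m & ~interior


def compute_overlap(mito: np.ndarray, er: np.ndarray) -> np.ndarray:
    """Pixels claimed by both masks; excluded from distance candidate sets."""
    mito = np.asarray(mito).astype(bool)
    er = np.asarray(er).astype(bool)
    if mito.shape != er.shape:
        raise ShapeMismatchError(f"mask shapes differ: {mito.shape} vs {er.shape}")
    return mito & er


def compute_min_distance(edge_er: np.ndarray, edge_mito: np.ndarray,
                         overlap: np.ndarray, threshold: int) -> DistanceGrid:
    """MinDistance: per non-overlap ER edge pixel, the minimum Euclidean
    center-to-center distance to any non-overlap mitochondria edge pixel
    within contact range; sentinel threshold+1 when none is in range.
    """
    T = int(threshold)
    sentinel = float(T + 1)
    values = np.full(np.asarray(edge_er).shape, sentinel)
    er_pts = np.argwhere(edge_er & ~overlap)
    mito_pts = np.argwhere(edge_mito & ~overlap)
    if len(er_pts) and len(mito_pts):
        tree = cKDTree(mito_pts)
        # distances are sqrt of integers: a bound of T + 1e-9 returns exactly d <= T
        d, _ = tree.query(er_pts, k=1, distance_upper_bound=T + 1e-9)
        d = np.where(np.isfinite(d), d, sentinel)
        values[er_pts[:, 0], er_pts[:, 1]] = d
    return DistanceGrid(values, T)


def compute_distance_map(edge_mito: np.ndarray, edge_er: np.ndarray,
                         overlap: np.ndarray, min_distance: DistanceGrid,
                         threshold: int) -> DistanceGrid:
    """Distance map on mitochondria edges under the one-to-one relaxation.

    Each non-overlap mitochondria edge pixel receives the minimum distance
    over ER edge candidates (x, y) in range satisfying
    ``d < MinDistance[x, y] + 1``; mitochondria edge pixels inside the
    overlap are set to 0; everything else holds the sentinel threshold+1.
    """
    T = int(threshold)
    if min_distance.threshold != T:
        raise ConsistencyError(
            f"MinDistance was computed at threshold {min_distance.threshold}, expected {T}")
    sentinel = float(T + 1)
    values = np.full(np.asarray(edge_mito).shape, sentinel)
    mito_pts = np.argwhere(edge_mito & ~overlap)
    er_pts = np.argwhere(edge_er & ~overlap)
    if len(mito_pts) and len(er_pts):
        pairs = cKDTree(mito_pts).sparse_distance_matrix(
            cKDTree(er_pts), T + 1e-9, output_type="ndarray")
        if len(pairs):
            md = min_distance.values[er_pts[pairs["j"], 0], er_pts[pairs["j"], 1]]
            ok = pairs["v"] < md + 1.0
            best = np.full(len(mito_pts), sentinel)
            np.minimum.at(best, pairs["i"][ok], pairs["v"][ok])
            values[mito_pts[:, 0], mito_pts[:, 1]] = best
    values[overlap & np.asarray(edge_mito).astype(bool)] = 0.0
    return DistanceGrid(values, T)


def _bin_distances(d: np.ndarray, T: int) -> np.ndarray:
    """Histogram positive contact distances into bins 1..T by ceil(d)."""
    bins = np.zeros(T + 1, dtype=np.int64)
    if d.size:
        b = np.ceil(d).astype(np.int64)
        b = b[(b >= 1) & (b <= T)]
        bins[1:] = np.bincount(b, minlength=T + 1)[1:]
    return bins


def profile_contacts(distance_map: DistanceGrid, edge_mito: np.ndarray,
                     threshold: Optional[int] = None) -> ContactProfile:
    """Bin the distance map into the 0..T width profile.

    Bin 0 counts overlap edge pixels (distance 0); bin b in 1..T counts
    pixels with ceil(distance) = b. A pixel contacts iff ceil(d) <= T.
    """
    T = distance_map.threshold if threshold is None else int(threshold)
    if distance_map.threshold != T:
        raise ConsistencyError(
            f"distance map at threshold {distance_map.threshold}, expected {T}")
    edge = np.asarray(edge_mito).astype(bool)
    d = distance_map.values[edge]
    bins = _bin_distances(d[d > 0], T)
    bins[0] = int((d == 0).sum())
    contact_set = edge & (distance_map.values <= T)
    n_con = int(((d > 0) & (d <= T)).sum())
    _, n_segments = ndimage.label(contact_set, structure=_EIGHT_CONNECTED)
    return ContactProfile(
        length_per_bin=bins,
        len_con=int(bins.sum()),
        n_con=n_con,
        n_segments=int(n_segments),
        len_mito=int(edge.sum()),
    )


def contact_ratio(profile: ContactProfile) -> ContactRatios:
    """Per-bin contact ratios length_per_bin / len_mito and their cumsum.

    The ratio is contacting mitochondria boundary length over total
    mitochondria boundary length; a scene with no mitochondria boundary has
    no defined ratio and raises rather than silently reporting 0.
    """
    if profile.len_mito == 0:
        raise UndefinedRatioError("no mitochondria boundary: contact ratio undefined")
    per_bin = profile.length_per_bin / profile.len_mito
    return ContactRatios(per_bin=per_bin, cumulative=np.cumsum(per_bin))


def brute_force_contact(mito: np.ndarray, er: np.ndarray, threshold: int) -> ContactProfile:
    """Windowless exhaustive reference for the contact profile.

    Enumerates all boundary-pixel pairs (no search window), applies the same
    overlap and one-to-one rules, and bins with exact integer arithmetic
    (ceil of sqrt of the integer squared distance). Intended for small
    scenes (<= 256x256); the optimized pipeline must agree bin-for-bin.
    """
    T = int(threshold)
    mito_b = np.asarray(mito) > 0
    er_b = np.asarray(er).astype(bool)
    if mito_b.shape != er_b.shape:
        raise ShapeMismatchError(f"mask shapes differ: {mito_b.shape} vs {er_b.shape}")
    overlap = mito_b & er_b

    # independent boundary route: erosion with a 4-connected structuring element
    cross = ndimage.generate_binary_structure(2, 1)

    def boundary(m):
        return m & ~ndimage.binary_erosion(m, structure=cross, border_value=0)

    edge_mito = boundary(mito_b)
    edge_er = boundary(er_b)
    M = np.argwhere(edge_mito & ~overlap)
    E = np.argwhere(edge_er & ~overlap)
    bins = np.zeros(T + 1, dtype=np.int64)
    contact_set = overlap & edge_mito
    bins[0] = int(contact_set.sum())
    n_con = 0
    if len(M) and len(E):
        d2 = ((M[:, None, :] - E[None, :, :]) ** 2).sum(axis=-1)  # integer squared distances
        d = np.sqrt(d2.astype(float))
        min_er = d.min(axis=0)  # global minimum per ER pixel, no window
        admissible = d < (min_er[None, :] + 1.0)
        d_adm = np.where(admissible, d, np.inf)
        dmap = d_adm.min(axis=1)
        d2_best = np.where(np.isfinite(dmap),
                           np.take_along_axis(d2, d_adm.argmin(axis=1)[:, None], axis=1)[:, 0],
                           -1)
        for idx, (r, c) in enumerate(M):
            if d2_best[idx] < 0:
                continue
            b = math.isqrt(int(d2_best[idx]))
            if b * b < d2_best[idx]:
                b += 1
            if 1 <= b <= T:
                bins[b] += 1
                n_con += 1
                contact_set[r, c] = True
    _, n_segments = ndimage.label(contact_set, structure=_EIGHT_CONNECTED)
    return ContactProfile(
        length_per_bin=bins,
        len_con=int(bins.sum()),
        n_con=n_con,
        n_segments=int(n_segments),
        len_mito=int(edge_mito.sum()),
    )


def contact_pipeline(mito: np.ndarray, er: np.ndarray, threshold: int):
    """Run boundary/overlap/MinDistance/DistanceMap/profile in one call.

    Returns (profile, distance_map, edge_mito) so callers can reuse the
    grids for visualization.
    """
    T = int(threshold)
    mito_b = np.asarray(mito) > 0
    er_b = np.asarray(er).astype(bool)
    overlap = compute_overlap(mito_b, er_b)
    edge_mito = extract_boundary(mito_b)
    edge_er = extract_boundary(er_b)
    min_distance = compute_min_distance(edge_er, edge_mito, overlap, T)
    distance_map = compute_distance_map(edge_mito, edge_er, overlap, min_distance, T)
    profile = profile_contacts(distance_map, edge_mito, T)
    return profile, distance_map, edge_mito


def quantify_patch(mito: np.ndarray, er: np.ndarray, config: ContactConfig,
                   image_id: str = "image", patch_id: str = "patch",
                   pair: str = "ER-Mito") -> ReportRow:
    """Quantify one standardized patch: morphometrics + contact profile.

    ``mito`` may be an instance mask (labels preserved) or a binary mask
    (instances then found by 8-connected components); ``er`` is a region
    mask. Ratios are flagged undefined (None) when the patch holds no
    mitochondria boundary.
    """
    mito = np.asarray(mito)
    er = np.asarray(er)
    if mito.shape != er.shape:
        raise ShapeMismatchError(f"mask shapes differ: {mito.shape} vs {er.shape}")
    labels = morphometrics.ensure_instances(mito)
    profile, _, _ = contact_pipeline(labels, er, config.threshold_px)
    stats = morphometrics.instance_stats(labels)
    summary = morphometrics.summarize(stats)
    if profile.len_mito > 0:
        ratios = contact_ratio(profile)
        ratio_per_bin = tuple(float(v) for v in ratios.per_bin)
        cumulative = ratios.at(config.cumulative_cut)
    else:
        ratio_per_bin = None
        cumulative = None
    return ReportRow(
        image_id=image_id,
        patch_id=patch_id,
        pair=pair,
        n_instances=summary.count,
        total_perimeter_px=summary.total_perimeter,
        mean_perimeter_px=summary.mean_perimeter,
        total_area_px=summary.total_area,
        mean_elongation=summary.mean_elongation,
        len_mito_px=profile.len_mito,
        n_contact_px=profile.n_con,
        n_contact_segments=profile.n_segments,
        length_per_bin=tuple(int(v) for v in profile.length_per_bin),
        ratio_per_bin=ratio_per_bin,
        cumulative_cut=config.cumulative_cut,
        cumulative_ratio=cumulative,
    )


def aggregate_image(rows: Sequence[ReportRow]) -> ReportRow:
    """Per-image aggregate across patches: sum, then recompute ratios.

    The image-level contact ratio is the summed contacting boundary length
    over the summed total boundary length across patches — not the mean of
    per-patch ratios, which would weight sparse patches equally with dense
    ones.
    """
    rows = list(rows)
    if not rows:
        raise ConsistencyError("cannot aggregate an empty row list")
    image_ids = {r.image_id for r in rows}
    if len(image_ids) > 1:
        raise ConsistencyError(f"rows mix image ids: {sorted(image_ids)}")
    thresholds = {r.threshold for r in rows}
    if len(thresholds) > 1:
        raise ConsistencyError(f"rows mix thresholds: {sorted(thresholds)}")
    T = thresholds.pop()
    lengths = np.sum([r.length_per_bin for r in rows], axis=0).astype(np.int64)
    len_mito = sum(r.len_mito_px for r in rows)
    n_instances = sum(r.n_instances for r in rows)
    total_perimeter = float(sum(r.total_perimeter_px for r in rows))
    total_area = float(sum(r.total_area_px for r in rows))
    elong_sum = sum(r.mean_elongation * r.n_instances for r in rows
                    if r.mean_elongation is not None)
    cut = rows[0].cumulative_cut
    if len_mito > 0:
        ratio_per_bin = tuple(float(v) for v in lengths / len_mito)
    else:
        ratio_per_bin = None
    return ReportRow(
        image_id=rows[0].image_id,
        patch_id=AGGREGATE_PATCH_ID,
        pair=rows[0].pair,
        n_instances=n_instances,
        total_perimeter_px=total_perimeter,
        mean_perimeter_px=total_perimeter / n_instances if n_instances else None,
        total_area_px=total_area,
        mean_elongation=elong_sum / n_instances if n_instances else None,
        len_mito_px=int(len_mito),
        n_contact_px=sum(r.n_contact_px for r in rows),
        n_contact_segments=sum(r.n_contact_segments for r in rows),
        length_per_bin=tuple(int(v) for v in lengths),
        ratio_per_bin=ratio_per_bin,
        cumulative_cut=cut,
    )
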