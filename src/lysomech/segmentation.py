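"""Label-mask ingestion, object filtering, boundary tracing and tracking.

The curvature pipeline consumes per-frame integer label masks (0 =
background) produced by an external pixel classifier. This module turns
those masks into :class:`LabeledObject` records, applies the
object-inclusion filters (membrane-marker intensity and size), extracts
each object's boundary pixels as an ordered closed contour, and links
objects across frames by nearest-centroid tracking.

Boundary semantics: a boundary pixel is an object pixel with at least one
4-neighbor outside the object. The ordered contour is obtained by
Moore-neighbor tracing (8-connected walk around the object) and then
restricted to the 4-boundary pixel set; orientation is normalized so the
contour runs counter-clockwise (positive shoelace area in (x, y) = (col,
row) coordinates), which puts the object interior to the left of the
direction of travel.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage


class DegenerateObjectError(ValueError):
    """Object too small, line-like, or multi-component for boundary tracing."""


@dataclass
class LabeledObject:
    """One segmented object in one frame.

    ``coords`` are (row, col) pixel coordinates; ``mean_morphology_intensity``
    is the mean of the membrane-marker channel over the object's pixels
    (the intensity the inclusion filter tests).
    """

    object_id: int
    frame: int
    coords: np.ndarray
    area_px: int
    mean_morphology_intensity: float
    centroid: tuple[float, float]

    def mask(self, shape: tuple[int, int]) -> np.ndarray:
        """Render the object as a boolean mask of the given image shape."""
        m = np.zeros(shape, dtype=bool)
        m[self.coords[:, 0], self.coords[:, 1]] = True
        return m


@dataclass
class Boundary:
    """Ordered closed contour of one object.

    ``points`` is an (n, 2) array of (row, col) coordinates traversed
    counter-clockwise; the first and last points are 8-adjacent (closure is
    implicit, the first point is not repeated).
    """

    object_id: int
    frame: int
    points: np.ndarray

    @property
    def n_points(self) -> int:
        return len(self.points)

    def signed_area(self) -> float:
        """Shoelace area in (x, y) = (col, row) coordinates; > 0 for CCW."""
        x = self.points[:, 1].astype(float)
        y = self.points[:, 0].astype(float)
        return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def extract_objects(
    label_image: np.ndarray,
    intensity_image: np.ndarray | None = None,
    frame: int = 0,
) -> list[LabeledObject]:
    """Convert an integer label mask into LabeledObject records.

    ``intensity_image`` is the morphology (membrane-marker) channel; when
    omitted, mean intensity is reported as NaN and the intensity filter
    cannot be applied meaningfully.
    """
    label_image = np.asarray(label_image)
    objects: list[LabeledObject] = []
    for lab in np.unique(label_image):
        if lab == 0:
            continue
        rr, cc = np.nonzero(label_image == lab)
        coords = np.column_stack([rr, cc])
        if intensity_image is not None:
            mean_int = float(np.mean(intensity_image[rr, cc]))
        else:
            mean_int = float("nan")
        objects.append(
            LabeledObject(
                object_id=int(lab),
                frame=frame,
                coords=coords,
                area_px=len(coords),
                mean_morphology_intensity=mean_int,
                centroid=(float(rr.mean()), float(cc.mean())),
            )
        )
    return objects


def filter_objects(
    objects: list[LabeledObject],
    min_intensity: float = 300.0,
    min_area_px: int = 200,
) -> list[LabeledObject]:
    """Apply the object-inclusion rule, preserving order.

    An object is retained when its mean morphology-channel intensity is
    strictly over ``min_intensity`` AND its pixel count is strictly over
    ``min_area_px``. Defaults reproduce the published rule (intensity over
    300 a.u., size over 200 pixels).
    """
    return [
        o
        for o in objects
        if o.mean_morphology_intensity > min_intensity and o.area_px > min_area_px
    ]


_MOORE_OFFSETS = np.array(
    [(-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1)]
)
# clockwise scan order starting from "north", used by the Moore walk


_OFFSET_INDEX = {tuple(o): k for k, o in enumerate(_MOORE_OFFSETS)}


def _moore_trace(mask: np.ndarray) -> np.ndarray:
    """Moore-neighbor tracing with Jacob's stopping criterion.

    ``mask`` must contain a single 8-connected object not touching the
    array edge (callers pad). Returns ordered (row, col) boundary pixels;
    the walk terminates when the start pixel is re-entered from the same
    direction as the initial entry, so the full outer contour is traversed
    exactly once.
    """
    rows, cols = np.nonzero(mask)
    # start at topmost-then-leftmost object pixel; the pixel to its left is
    # guaranteed background and serves as the initial backtrack
    start_idx = np.lexsort((cols, rows))[0]
    start = (int(rows[start_idx]), int(cols[start_idx]))
    b0 = (start[0], start[1] - 1)

    def scan(cur, back):
        # clockwise scan of cur's Moore ring starting just after `back`;
        # returns the first object pixel and the background pixel scanned
        # immediately before it (the new backtrack, adjacent to both)
        k0 = _OFFSET_INDEX[(back[0] - cur[0], back[1] - cur[1])]
        prev_bg = back
        for j in range(1, 9):
            off = _MOORE_OFFSETS[(k0 + j) % 8]
            cand = (cur[0] + int(off[0]), cur[1] + int(off[1]))
            if mask[cand]:
                return cand, prev_bg
            prev_bg = cand
        return None, None

    contour: list[tuple[int, int]] = []
    cur, back = start, b0
    max_steps = 8 * len(rows) + 8
    while True:
        contour.append(cur)
        nxt, new_back = scan(cur, back)
        if nxt is None:  # isolated pixel (cannot occur for area >= 5, 1 comp)
            break
        cur, back = nxt, new_back
        if cur == start and back == b0:
            break
        if len(contour) > max_steps:  # safety; should be unreachable
            break
    return np.array(contour, dtype=int)


def boundary_pixel_set(mask: np.ndarray) -> np.ndarray:
    """Boolean mask of object pixels with at least one 4-neighbor outside."""
    eroded = ndimage.binary_erosion(
        mask, structure=ndimage.generate_binary_structure(2, 1), border_value=0
    )
    return mask & ~eroded


def trace_boundary(obj: LabeledObject, image_shape: tuple[int, int] | None = None) -> Boundary:
    """Extract the ordered closed boundary of one object.

    Interior holes are filled before tracing (holes in an organelle mask
    are segmentation noise). Raises :class:`DegenerateObjectError` for
    objects with fewer than 5 pixels, multiple 8-connected components, or
    line-like (width-1) geometry that has no 2x2 solid block.
    """
    if obj.area_px < 5:
        raise DegenerateObjectError(
            f"object {obj.object_id} (frame {obj.frame}): {obj.area_px} px < 5"
        )
    r0, c0 = obj.coords.min(axis=0)
    r1, c1 = obj.coords.max(axis=0)
    h, w = r1 - r0 + 1, c1 - c0 + 1
    local = np.zeros((h + 2, w + 2), dtype=bool)  # 1-px pad for tracing
    local[obj.coords[:, 0] - r0 + 1, obj.coords[:, 1] - c0 + 1] = True

    n_comp = ndimage.label(local, structure=np.ones((3, 3), dtype=int))[1]
    if n_comp != 1:
        raise DegenerateObjectError(
            f"object {obj.object_id} (frame {obj.frame}): {n_comp} connected components"
        )
    # width-1 / line-like test: a non-degenerate blob contains a 2x2 block
    has_block = np.any(local[:-1, :-1] & local[1:, :-1] & local[:-1, 1:] & local[1:, 1:])
    if not has_block:
        raise DegenerateObjectError(
            f"object {obj.object_id} (frame {obj.frame}): line-like (no 2x2 block)"
        )

    local = ndimage.binary_fill_holes(local)
    traced = _moore_trace(local)
    bset = boundary_pixel_set(local)
    keep = bset[traced[:, 0], traced[:, 1]]
    pts = traced[keep]
    # drop consecutive duplicates (Moore walk can revisit along spurs)
    if len(pts) > 1:
        dup = np.all(pts == np.roll(pts, 1, axis=0), axis=1)
        dup[0] = False
        pts = pts[~dup]
    pts = pts + np.array([r0 - 1, c0 - 1])
    b = Boundary(object_id=obj.object_id, frame=obj.frame, points=pts)
    if b.signed_area() < 0:
        b.points = b.points[::-1].copy()
    return b


@dataclass
class Track:
    track_id: int
    members: list[tuple[int, int]] = field(default_factory=list)  # (frame, local id)


def track_objects(
    objects_by_frame: dict[int, list[LabeledObject]],
    max_displacement_px: float = 10.0,
) -> dict[tuple[int, int], int]:
    """Greedy nearest-centroid tracking across consecutive frames.

    Returns a mapping (frame, frame-local object_id) -> persistent track id.
    Links longer than ``max_displacement_px`` are not made; a track that
    loses its object ends, and a reappearing object starts a new track
    (no gap bridging).
    """
    frames = sorted(objects_by_frame)
    assignment: dict[tuple[int, int], int] = {}
    next_id = 0
    prev_tracks: dict[int, LabeledObject] = {}  # track id -> object in prev frame

    prev_frame = None
    for f in frames:
        objs = objects_by_frame[f]
        current: dict[int, LabeledObject] = {}
        if prev_frame is not None and f == prev_frame + 1 and prev_tracks:
            # candidate links sorted by distance, greedy
            cands = []
            for tid, pobj in prev_tracks.items():
                for o in objs:
                    d = float(np.hypot(
                        o.centroid[0] - pobj.centroid[0],
                        o.centroid[1] - pobj.centroid[1],
                    ))
                    if d <= max_displacement_px:
                        cands.append((d, tid, o))
            cands.sort(key=lambda t: t[0])
            used_tracks: set[int] = set()
            used_objs: set[int] = set()
            for d, tid, o in cands:
                if tid in used_tracks or id(o) in used_objs:
                    continue
                assignment[(f, o.object_id)] = tid
                current[tid] = o
                used_tracks.add(tid)
                used_objs.add(id(o))
        for o in objs:
            if (f, o.object_id) not in assignment:
                assignment[(f, o.object_id)] = next_id
                current[next_id] = o
                next_id += 1
        prev_tracks = current
        prev_frame = f
    return assignment


def objects_table(objects: list[LabeledObject]) -> "pandas.DataFrame":
    """Per-object summary table (frame, object_id, area, intensity, centroid)."""
    import pandas as pd

    return pd.DataFrame(
        {
            "frame": [o.frame for o in objects],
            "object_id": [o.object_id for o in objects],
            "area_px": [o.area_px for o in objects],
            "mean_intensity": [o.mean_morphology_intensity for o in objects],
            "centroid_y": [o.centroid[0] for o in objects],
            "centroid_x": [o.centroid[1] for o in objects],
        }
    )
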