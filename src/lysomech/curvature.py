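"""Local boundary curvature and curvature-calcium coupling statistics.

The core measurement: at every boundary sampling point of a tracked
organelle, estimate the signed local curvature and the mean intensity of
each channel in a small window restricted to the object, normalize the
calcium signal by the membrane-marker signal, and correlate curvature with
normalized calcium across the sampling points of one frame. Per-frame
correlation coefficients of one organelle are averaged over time into a
single frame-averaged coefficient, the per-lysosome summary statistic.

Curvature estimator
-------------------
Signed Menger curvature: at point ``p_i`` the curvature is the reciprocal
circumradius of the circle through ``(p_{i-k}, p_i, p_{i+k})`` (indices
cyclic, ``k`` boundary steps to each side), with positive sign where the
contour bulges outward (convex) for a counter-clockwise contour. Collinear
triples give exactly 0. An optional circular moving-average smoothing of
the contour coordinates suppresses pixel-lattice jitter before the
three-point circle is fit; it is on by default because raw rasterized
contours carry half-pixel noise comparable to the curvature signal of
micron-scale organelles.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from lysomech.segmentation import (
    Boundary,
    LabeledObject,
    extract_objects,
    filter_objects,
    trace_boundary,
    track_objects,
)

logger = logging.getLogger(__name__)


class ContourTooShortError(ValueError):
    pass


class NoEligiblePixelsError(ValueError):
    pass


def smooth_contour(points: np.ndarray, window: int = 5) -> np.ndarray:
    """Circular moving average of contour coordinates.

    ``window`` must be odd; window 1 is the identity. Returns float
    coordinates; the contour remains closed and ordered.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError("smoothing window must be odd and >= 1")
    if window == 1:
        return points.astype(float)
    kernel = np.ones(window) / window
    out = np.empty(points.shape, dtype=float)
    for d in range(2):
        out[:, d] = ndimage.convolve1d(points[:, d].astype(float), kernel, mode="wrap")
    return out


def local_curvature(
    boundary: Boundary | np.ndarray,
    window_k: int = 5,
    smooth_window: int = 3,
) -> np.ndarray:
    """Signed local curvature (px^-1) at every boundary point.

    Positive where the object bulges outward. ``window_k`` is the
    half-window in boundary steps; ``smooth_window`` the contour-coordinate
    smoothing window (odd; 1 disables smoothing).
    """
    pts = boundary.points if isinstance(boundary, Boundary) else np.asarray(boundary)
    n = len(pts)
    if window_k < 1:
        raise ValueError("window_k must be >= 1")
    if n <= 2 * window_k:
        raise ContourTooShortError(
            f"contour has {n} points, need more than {2 * window_k}"
        )
    p = smooth_contour(pts, smooth_window)
    # (x, y) = (col, row); sign convention matches CCW-normalized contours
    xy = p[:, ::-1]
    a = np.roll(xy, window_k, axis=0)   # p_{i-k}
    c = np.roll(xy, -window_k, axis=0)  # p_{i+k}
    d1 = xy - a
    d2 = c - xy
    d3 = c - a
    cross = d1[:, 0] * d2[:, 1] - d1[:, 1] * d2[:, 0]
    denom = (
        np.linalg.norm(d1, axis=1)
        * np.linalg.norm(d2, axis=1)
        * np.linalg.norm(d3, axis=1)
    )
    kappa = np.zeros(n)
    ok = denom > 0
    kappa[ok] = 2.0 * cross[ok] / denom[ok]
    return kappa


def select_sampling_points(kappa: np.ndarray) -> np.ndarray:
    """Boolean mask of points retained for correlation: kappa >= 0.

    Only non-negative-curvature points enter the analysis; they are the
    bulged (convex) regions of the organelle. Order is preserved.
    """
    return np.asarray(kappa) >= 0


def local_intensity(
    channel: np.ndarray,
    point: tuple[int, int],
    object_mask: np.ndarray,
    window_px: int = 5,
) -> tuple[float, int]:
    """Mean channel intensity in a window restricted to the object.

    A ``window_px`` x ``window_px`` region (odd size) is centred on the
    sampling point, clipped at the image border, and intersected with the
    filled object mask so that only boundary and interior pixels
    contribute; exterior pixels would dilute the membrane-proximal signal.
    Returns (mean, number of pixels used). Raises
    :class:`NoEligiblePixelsError` when no pixel qualifies.
    """
    if window_px % 2 == 0 or window_px < 1:
        raise ValueError("window_px must be odd and >= 1")
    h = window_px // 2
    r, c = int(round(point[0])), int(round(point[1]))
    r0, r1 = max(r - h, 0), min(r + h + 1, channel.shape[0])
    c0, c1 = max(c - h, 0), min(c + h + 1, channel.shape[1])
    sub = channel[r0:r1, c0:c1]
    m = object_mask[r0:r1, c0:c1]
    n = int(m.sum())
    if n == 0:
        raise NoEligiblePixelsError(f"no eligible pixels at point ({r}, {c})")
    return float(sub[m].mean()), n


def sampling_point_table(
    boundary: Boundary,
    morphology: np.ndarray,
    calcium: np.ndarray,
    object_mask: np.ndarray,
    pixel_size_um: float,
    window_k: int = 5,
    window_px: int = 5,
    smooth_window: int = 3,
    min_eligible_px: int = 6,
) -> pd.DataFrame:
    """Per-sampling-point measurements for one object in one frame.

    Computes curvature at every boundary point, keeps the non-negative-
    curvature points, samples both channels in the object-restricted
    window, and forms the normalized calcium intensity (local calcium mean
    over local morphology mean). Points whose window retains fewer than
    ``min_eligible_px`` pixels, or whose morphology mean is not positive,
    are dropped with a logged count.
    """
    kappa_px = local_curvature(boundary, window_k=window_k, smooth_window=smooth_window)
    keep = select_sampling_points(kappa_px)
    rows = []
    n_dropped = 0
    for i in np.nonzero(keep)[0]:
        pt = boundary.points[i]
        try:
            ca, n_ca = local_intensity(calcium, pt, object_mask, window_px)
            mo, _ = local_intensity(morphology, pt, object_mask, window_px)
        except NoEligiblePixelsError:
            n_dropped += 1
            continue
        if n_ca < min_eligible_px or mo <= 0:
            n_dropped += 1
            continue
        rows.append(
            {
                "frame": boundary.frame,
                "object_id": boundary.object_id,
                "y_px": int(pt[0]),
                "x_px": int(pt[1]),
                "kappa_per_px": kappa_px[i],
                "kappa_per_um": kappa_px[i] / pixel_size_um,
                "local_calcium": ca,
                "local_morphology": mo,
                "normalized_calcium": ca / mo,
                "n_window_px": n_ca,
            }
        )
    if n_dropped:
        logger.info(
            "object %d frame %d: dropped %d sampling points (window/morphology)",
            boundary.object_id,
            boundary.frame,
            n_dropped,
        )
    cols = [
        "frame", "object_id", "y_px", "x_px", "kappa_per_px", "kappa_per_um",
        "local_calcium", "local_morphology", "normalized_calcium", "n_window_px",
    ]
    return pd.DataFrame(rows, columns=cols)


def frame_correlation(
    kappa: np.ndarray,
    normalized_calcium: np.ndarray,
    method: str = "pearson",
) -> float:
    """Correlation between curvature and normalized calcium for one frame.

    Pearson product-moment by default; ``method='spearman'`` for the
    rank-based variant. Returns NaN ("undefined", excluded from frame
    averaging) when fewer than 3 points are supplied or either variable
    has zero variance.
    """
    kappa = np.asarray(kappa, dtype=float)
    y = np.asarray(normalized_calcium, dtype=float)
    if len(kappa) < 3 or np.ptp(kappa) == 0 or np.ptp(y) == 0:
        return float("nan")
    if method == "pearson":
        return float(np.corrcoef(kappa, y)[0, 1])
    if method == "spearman":
        return float(stats.spearmanr(kappa, y).statistic)
    raise ValueError(f"unknown correlation method: {method}")


def average_over_frames(per_frame_r: "list[float] | np.ndarray") -> tuple[float, int]:
    """Frame-averaged correlation coefficient for one organelle.

    Unweighted arithmetic mean over frames with a defined (non-NaN)
    coefficient; returns (r_bar, n_frames_used). Raises ValueError when no
    frame has a defined coefficient.
    """
    r = np.asarray(per_frame_r, dtype=float)
    ok = ~np.isnan(r)
    if not ok.any():
        raise ValueError("no frame has a defined correlation coefficient")
    return float(r[ok].mean()), int(ok.sum())


def analyze_movie(
    movie: np.ndarray,
    labels: np.ndarray,
    pixel_size_um: float,
    window_k: int = 5,
    window_px: int = 5,
    smooth_window: int = 3,
    min_intensity: float = 300.0,
    min_area_px: int = 200,
    max_displacement_px: float = 10.0,
    method: str = "pearson",
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Full curvature-calcium pipeline on a two-channel movie.

    Parameters
    ----------
    movie : array, shape (T, 2, H, W)
        Channel 0 is morphology (membrane marker), channel 1 calcium.
    labels : array, shape (T, H, W)
        Integer label mask per frame (0 = background).

    Returns
    -------
    points : DataFrame
        One row per retained sampling point.
    per_frame : DataFrame
        (track_id, frame, r, n_points) per object per frame.
    per_lysosome : DataFrame
        (track_id, r_bar, n_frames_used) — the frame-averaged coefficient.
    """
    movie = np.asarray(movie)
    labels = np.asarray(labels)
    if movie.ndim != 4 or movie.shape[1] != 2:
        raise ValueError("movie must have shape (T, 2, H, W)")
    if labels.shape != (movie.shape[0],) + movie.shape[2:]:
        raise ValueError("labels shape must match movie frames")

    n_frames = movie.shape[0]
    objects_by_frame: dict[int, list[LabeledObject]] = {}
    for f in range(n_frames):
        objs = extract_objects(labels[f], intensity_image=movie[f, 0], frame=f)
        objects_by_frame[f] = filter_objects(objs, min_intensity, min_area_px)
    track_of = track_objects(objects_by_frame, max_displacement_px)

    point_tables = []
    frame_rows = []
    for f in range(n_frames):
        for obj in objects_by_frame[f]:
            boundary = trace_boundary(obj)
            mask = np.zeros(labels.shape[1:], dtype=bool)
            mask[obj.coords[:, 0], obj.coords[:, 1]] = True
            mask = ndimage.binary_fill_holes(mask)
            tbl = sampling_point_table(
                boundary,
                morphology=movie[f, 0],
                calcium=movie[f, 1],
                object_mask=mask,
                pixel_size_um=pixel_size_um,
                window_k=window_k,
                window_px=window_px,
                smooth_window=smooth_window,
            )
            tid = track_of[(f, obj.object_id)]
            tbl.insert(0, "track_id", tid)
            point_tables.append(tbl)
            r = frame_correlation(
                tbl["kappa_per_um"].to_numpy(),
                tbl["normalized_calcium"].to_numpy(),
                method=method,
            )
            frame_rows.append(
                {"track_id": tid, "frame": f, "r": r, "n_points": len(tbl)}
            )

    points = (
        pd.concat(point_tables, ignore_index=True)
        if point_tables
        else pd.DataFrame()
    )
    per_frame = pd.DataFrame(
        frame_rows, columns=["track_id", "frame", "r", "n_points"]
    )
    lyso_rows = []
    for tid, grp in per_frame.groupby("track_id"):
        try:
            r_bar, n_used = average_over_frames(grp["r"].to_numpy())
        except ValueError:
            r_bar, n_used = float("nan"), 0
        lyso_rows.append({"track_id": tid, "r_bar": r_bar, "n_frames_used": n_used})
    per_lysosome = pd.DataFrame(
        lyso_rows, columns=["track_id", "r_bar", "n_frames_used"]
    )
    return points, per_frame, per_lysosome
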