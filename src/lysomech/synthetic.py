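"""Synthetic inputs with analytically known ground truth.

Every input the analysis pipeline consumes can be generated here:

* star-convex organelle shapes defined in polar form, with exact signed
  curvature from the polar-curve formula;
* two-channel movies (membrane-marker ring + curvature-coupled calcium
  channel) with per-frame label masks and a ground-truth table;
* cell layouts with designed peripheral/central organelle placement;
* whole-cell calcium traces with a step fold change at a known onset;
* pressure-clamp sweep ensembles generated by a binomial N-channel gating
  model under a stepwise suction protocol.

Randomness: every generator takes a single seed and derives independent
substreams (one per frame / sweep block) via ``numpy`` seed sequences, so
extending a movie by frames does not perturb earlier frames.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree
from skimage import draw

from lysomech.ephys import PressureProtocol, SweepEnsemble

#: default pixel pitch (um/px) implied by a 5x5-pixel sampling window
#: covering 0.11 um^2: sqrt(0.11 / 25)
DEFAULT_PIXEL_SIZE_UM = math.sqrt(0.11 / 25.0)


# --------------------------------------------------------------------------
# analytic shapes


@dataclass
class ShapeSpec:
    """Star-convex shape in polar form about its centroid.

    r(theta) = r0 * (1 + sum_k a_k cos(k theta + phi_k)); the harmonic
    amplitudes must satisfy sum |a_k| < 1 so the radius stays positive and
    the curve remains simple.
    """

    r0_um: float
    harmonics: list[tuple[int, float, float]] = field(default_factory=list)
    n_theta: int = 2000

    def __post_init__(self):
        if self.r0_um <= 0:
            raise ValueError("base radius must be positive")
        if sum(abs(a) for _, a, _ in self.harmonics) >= 1:
            raise ValueError("harmonic amplitudes must satisfy sum|a_k| < 1")
        if self.n_theta < 16:
            raise ValueError("n_theta too small")


@dataclass
class AnalyticBoundary:
    """Densely sampled closed curve with exact curvature at every point.

    Points are ordered counter-clockwise; ``kappa_per_um`` is the exact
    signed curvature (positive on convex-outward arcs).
    """

    x_um: np.ndarray
    y_um: np.ndarray
    kappa_per_um: np.ndarray

    @property
    def n_points(self) -> int:
        return len(self.x_um)

    def arc_lengths_um(self) -> np.ndarray:
        """Segment length from each point to the next (closed)."""
        dx = np.roll(self.x_um, -1) - self.x_um
        dy = np.roll(self.y_um, -1) - self.y_um
        return np.hypot(dx, dy)

    def perimeter_um(self) -> float:
        return float(self.arc_lengths_um().sum())

    def turning_integral(self) -> float:
        """Closed-contour integral of kappa ds; 2*pi for a simple curve."""
        ds = self.arc_lengths_um()
        k_mid = 0.5 * (self.kappa_per_um + np.roll(self.kappa_per_um, -1))
        return float(np.sum(k_mid * ds))


def make_shape(spec: ShapeSpec) -> AnalyticBoundary:
    """Evaluate a polar-harmonic shape and its exact curvature.

    Uses the polar-curve curvature
    kappa = (r^2 + 2 r'^2 - r r'') / (r^2 + r'^2)^(3/2),
    which is positive everywhere the curve is convex outward for the
    counter-clockwise parameterization.
    """
    th = np.linspace(0.0, 2.0 * np.pi, spec.n_theta, endpoint=False)
    r = np.full_like(th, spec.r0_um)
    r1 = np.zeros_like(th)
    r2 = np.zeros_like(th)
    for k, a, phi in spec.harmonics:
        r += spec.r0_um * a * np.cos(k * th + phi)
        r1 += -spec.r0_um * a * k * np.sin(k * th + phi)
        r2 += -spec.r0_um * a * k * k * np.cos(k * th + phi)
    if np.any(r <= 0):
        raise ValueError("radius non-positive; reduce harmonic amplitudes")
    kappa = (r**2 + 2 * r1**2 - r * r2) / (r**2 + r1**2) ** 1.5
    return AnalyticBoundary(x_um=r * np.cos(th), y_um=r * np.sin(th), kappa_per_um=kappa)


def make_ellipse(a_um: float, b_um: float, n_theta: int = 2000) -> AnalyticBoundary:
    """Exact ellipse boundary with analytic curvature.

    Parameterized as (a cos t, b sin t); kappa(t) = a b / (a^2 sin^2 t +
    b^2 cos^2 t)^(3/2), equal to a/b^2 at the major-axis vertices.
    """
    if a_um <= 0 or b_um <= 0:
        raise ValueError("semi-axes must be positive")
    t = np.linspace(0.0, 2.0 * np.pi, n_theta, endpoint=False)
    kappa = a_um * b_um / (a_um**2 * np.sin(t) ** 2 + b_um**2 * np.cos(t) ** 2) ** 1.5
    return AnalyticBoundary(x_um=a_um * np.cos(t), y_um=b_um * np.sin(t), kappa_per_um=kappa)


# --------------------------------------------------------------------------
# two-channel movie rendering


@dataclass
class CouplingSpec:
    """Linear curvature-to-calcium coupling with additive Gaussian noise.

    The clean local calcium level at a boundary point with exact curvature
    kappa is ``alpha + beta * kappa``; noise of s.d. ``sigma`` is added on
    top. With sigma = 0 and beta != 0 the point-wise correlation between
    curvature and calcium is exactly +/-1.
    """

    alpha: float = 200.0
    beta_um: float = 0.0
    sigma: float = 0.0
    membrane_intensity: float = 800.0
    seed: int = 0

    def __post_init__(self):
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")
        if self.membrane_intensity <= 0:
            raise ValueError("membrane intensity must be positive")


def coupling_for_correlation(
    boundary: AnalyticBoundary,
    rho: float,
    sigma: float = 30.0,
    alpha: float = 200.0,
    membrane_intensity: float = 800.0,
    seed: int = 0,
) -> CouplingSpec:
    """Coupling spec whose theoretical point-wise correlation is ``rho``.

    The correlation is computed over the analysis population — points with
    non-negative exact curvature — so beta is scaled by the curvature s.d.
    of that subset: beta = sigma * rho / (sd_kappa * sqrt(1 - rho^2)).
    """
    if not -1 < rho < 1:
        raise ValueError("rho must be in (-1, 1)")
    if rho == 0:
        beta = 0.0
    else:
        kk = boundary.kappa_per_um[boundary.kappa_per_um >= 0]
        sd = float(np.std(kk))
        if sd == 0:
            raise ValueError("shape has constant curvature; rho != 0 unreachable")
        beta = sigma * rho / (sd * math.sqrt(1.0 - rho**2))
    return CouplingSpec(
        alpha=alpha,
        beta_um=beta,
        sigma=sigma,
        membrane_intensity=membrane_intensity,
        seed=seed,
    )


@dataclass
class MovieFixture:
    """Rendered synthetic movie plus everything needed to verify it."""

    movie: np.ndarray  # (T, 2, H, W) float; channel 0 morphology, 1 calcium
    labels: np.ndarray  # (T, H, W) uint16
    truth: pd.DataFrame  # frame, object_id, point_idx, x_px, y_px, kappa, clean
    pixel_size_um: float


def render_movie(
    shape: ShapeSpec | AnalyticBoundary,
    coupling: CouplingSpec,
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM,
    n_frames: int = 1,
    drift_um_per_frame: tuple[float, float] = (0.0, 0.0),
    noise_block_px: float = 5.0,
    image_pad_px: int = 12,
) -> MovieFixture:
    """Render a two-channel movie of one organelle with known ground truth.

    The morphology channel is a ring along the contour over a filled
    interior at the membrane intensity; the calcium channel assigns every
    object pixel the clean level ``alpha + beta * kappa`` of its nearest
    analytic boundary point plus Gaussian noise. The noise is drawn per
    contour block of arc length ``noise_block_px`` pixels (not per pixel),
    so its spatial correlation length matches the intensity-sampling
    window and the designed point-wise correlation survives window
    averaging. The label mask marks the filled object; the ground-truth
    table lists each analytic point's pixel position, exact curvature and
    clean calcium level per frame.
    """
    if pixel_size_um <= 0:
        raise ValueError("pixel size must be positive")
    if n_frames < 1:
        raise ValueError("need at least one frame")
    ab = make_shape(shape) if isinstance(shape, ShapeSpec) else shape

    r_extent = float(np.hypot(ab.x_um, ab.y_um).max()) / pixel_size_um
    drift_px = (
        drift_um_per_frame[0] / pixel_size_um,
        drift_um_per_frame[1] / pixel_size_um,
    )
    pad = image_pad_px + math.ceil(
        max(abs(drift_px[0]), abs(drift_px[1])) * (n_frames - 1)
    )
    half = math.ceil(r_extent) + pad
    size = 2 * half + 1
    if size < 16:
        raise ValueError("rendered object underflows the minimum image size")

    movie = np.zeros((n_frames, 2, size, size), dtype=float)
    labels = np.zeros((n_frames, size, size), dtype=np.uint16)
    truth_rows = []

    # contour blocks sharing one noise draw, indexed by cumulative arc
    arc_px = np.cumsum(ab.arc_lengths_um()) / pixel_size_um
    arc_px = np.concatenate([[0.0], arc_px[:-1]])
    block_of_point = np.floor(arc_px / noise_block_px).astype(int)
    n_blocks = int(block_of_point.max()) + 1

    streams = np.random.SeedSequence(coupling.seed).spawn(n_frames)
    clean = coupling.alpha + coupling.beta_um * ab.kappa_per_um

    for f in range(n_frames):
        rng = np.random.default_rng(streams[f])
        cy = half + drift_px[1] * f
        cx = half + drift_px[0] * f
        cols = ab.x_um / pixel_size_um + cx
        rows = ab.y_um / pixel_size_um + cy
        rr, cc = draw.polygon(rows, cols, shape=(size, size))
        mask = np.zeros((size, size), dtype=bool)
        mask[rr, cc] = True
        # ensure the rasterized contour pixels themselves are included
        mask[np.round(rows).astype(int), np.round(cols).astype(int)] = True
        mask = ndimage.binary_fill_holes(mask)
        labels[f][mask] = 1

        movie[f, 0][mask] = coupling.membrane_intensity

        obj_rr, obj_cc = np.nonzero(mask)
        tree = cKDTree(np.column_stack([rows, cols]))
        _, nearest = tree.query(np.column_stack([obj_rr, obj_cc]))
        block_noise = (
            rng.normal(0.0, coupling.sigma, size=n_blocks)
            if coupling.sigma > 0
            else np.zeros(n_blocks)
        )
        movie[f, 1][obj_rr, obj_cc] = (
            clean[nearest] + block_noise[block_of_point[nearest]]
        )

        truth_rows.append(
            pd.DataFrame(
                {
                    "frame": f,
                    "object_id": 1,
                    "point_idx": np.arange(ab.n_points),
                    "x_px": cols,
                    "y_px": rows,
                    "kappa_true_per_um": ab.kappa_per_um,
                    "clean_calcium": clean,
                }
            )
        )
    truth = pd.concat(truth_rows, ignore_index=True)
    return MovieFixture(
        movie=movie, labels=labels, truth=truth, pixel_size_um=pixel_size_um
    )


# --------------------------------------------------------------------------
# cell layouts for peripheral-fraction analysis


@dataclass
class CellLayout:
    cell_mask: np.ndarray
    labels: np.ndarray
    truth: pd.DataFrame  # object_id, y_px, x_px, is_peripheral
    pixel_size_um: float


def make_cell_layout(
    cell_radius_um: float = 50.0,
    n_peripheral: int = 4,
    n_central: int = 4,
    shell_depth_um: float = 5.0,
    pixel_size_um: float = 0.2,
    lysosome_radius_um: float = 1.5,
    seed: int = 0,
    max_attempts: int = 20000,
) -> CellLayout:
    """Circular cell with organelles placed at designed depths.

    Exactly ``n_peripheral`` organelle centroids fall strictly within
    ``shell_depth_um`` of the cell outline and ``n_central`` strictly
    deeper; a safety margin of two pixels keeps the designed flags
    unambiguous under rasterization. Placement is rejection sampling with
    a non-overlap constraint; raises when the requested counts cannot be
    packed.
    """
    if shell_depth_um >= cell_radius_um:
        raise ValueError("shell depth must be smaller than the cell radius")
    if n_peripheral + n_central < 1:
        raise ValueError("need at least one organelle")
    margin = 2.0 * pixel_size_um
    lyso_r = lysosome_radius_um
    # radial bands for the centroids (distances from the cell centre)
    peri_lo = cell_radius_um - shell_depth_um + margin
    peri_hi = cell_radius_um - lyso_r - margin
    cent_hi = cell_radius_um - shell_depth_um - margin
    if peri_lo >= peri_hi and n_peripheral > 0:
        raise ValueError("shell too thin for the organelle radius")
    if cent_hi <= lyso_r and n_central > 0:
        raise ValueError("no room for central organelles")

    rng = np.random.default_rng(seed)
    half = int(round(cell_radius_um / pixel_size_um)) + 2
    size = 2 * half + 1
    yy, xx = np.mgrid[0:size, 0:size]
    cell_mask = (yy - half) ** 2 + (xx - half) ** 2 <= (
        cell_radius_um / pixel_size_um
    ) ** 2

    placed: list[tuple[float, float, bool]] = []  # (y_um, x_um, peripheral)
    min_sep = 2 * lyso_r + 2 * pixel_size_um
    want = [(True, n_peripheral), (False, n_central)]
    for is_peri, count in want:
        done = 0
        attempts = 0
        while done < count:
            attempts += 1
            if attempts > max_attempts:
                raise ValueError(
                    "cannot pack the requested organelle counts without overlap"
                )
            if is_peri:
                rad = rng.uniform(peri_lo, peri_hi)
            else:
                rad = rng.uniform(0.0, cent_hi)
            ang = rng.uniform(0.0, 2.0 * np.pi)
            y, x = rad * np.sin(ang), rad * np.cos(ang)
            if all(np.hypot(y - py, x - px) > min_sep for py, px, _ in placed):
                placed.append((y, x, is_peri))
                done += 1

    labels = np.zeros((size, size), dtype=np.uint16)
    rows_truth = []
    r_px = lyso_r / pixel_size_um
    for oid, (y, x, is_peri) in enumerate(placed, start=1):
        cy, cx = half + y / pixel_size_um, half + x / pixel_size_um
        rr, cc = draw.disk((cy, cx), r_px, shape=(size, size))
        labels[rr, cc] = oid
        rows_truth.append(
            {
                "object_id": oid,
                "y_px": cy,
                "x_px": cx,
                "is_peripheral": is_peri,
            }
        )
    truth = pd.DataFrame(rows_truth, columns=["object_id", "y_px", "x_px", "is_peripheral"])
    return CellLayout(
        cell_mask=cell_mask, labels=labels, truth=truth, pixel_size_um=pixel_size_um
    )


# --------------------------------------------------------------------------
# whole-cell calcium traces


def simulate_calcium_trace(
    baseline: float = 100.0,
    fold_change: float = 2.0,
    onset_frame: int = 150,
    n_frames: int = 1500,
    noise_sd: float = 0.0,
    background: float = 20.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Raw fluorescence trace with a step fold change at a known onset.

    Pre-onset raw mean is background + baseline; post-onset it is
    background + baseline * fold_change. Defaults emulate a 10-minute
    acquisition at 0.4 s per frame with the challenge applied after one
    minute. Returns (raw, background_series).
    """
    if not baseline > background >= 0:
        raise ValueError("need baseline > background >= 0")
    if not 0 <= onset_frame <= n_frames:
        raise ValueError("onset frame outside the trace")
    rng = np.random.default_rng(seed)
    signal = np.full(n_frames, baseline)
    signal[onset_frame:] = baseline * fold_change
    raw = background + signal
    if noise_sd > 0:
        raw = raw + rng.normal(0.0, noise_sd, size=n_frames)
    return raw, np.full(n_frames, float(background))


# --------------------------------------------------------------------------
# pressure-clamp sweep ensembles


@dataclass
class GatingSpec:
    """Binomial N-channel gating model under suction.

    Open probability follows a Boltzmann in pressure magnitude,
    p(P) = 1 / (1 + exp((p50 - |P|)/slope)); at every sample the number of
    open channels is an independent binomial draw (gating treated as fast
    relative to the effective sampling), so the ensemble variance of the
    gating component at open probability p is exactly N i^2 p (1 - p).
    """

    n_channels: int = 100
    unitary_current_pa: float = 0.1
    p50_mmhg: float = 45.0
    slope_mmhg: float = 6.0
    noise_sd_pa: float = 0.0
    sample_rate_hz: float = 10000.0

    def __post_init__(self):
        if self.n_channels < 1:
            raise ValueError("need at least one channel")
        if self.slope_mmhg <= 0 or self.sample_rate_hz <= 0:
            raise ValueError("slope and sample rate must be positive")

    def p_open(self, pressure_mmhg: "float | np.ndarray") -> np.ndarray:
        from scipy.special import expit  # overflow-safe logistic

        return expit((np.abs(pressure_mmhg) - self.p50_mmhg) / self.slope_mmhg)


def simulate_sweeps(
    gating: GatingSpec,
    protocol: PressureProtocol,
    n_sweeps: int = 10,
    seed: int = 0,
) -> SweepEnsemble:
    """Generate a sweep ensemble from the binomial gating model.

    current(t) = i * Binomial(N, p(P(t))) + Gaussian recording noise.
    Ensemble mean and variance at a step with open probability p converge
    to N i p and N i^2 p (1-p) + noise_sd^2. Each sweep uses an
    independent substream of the master seed.
    """
    if n_sweeps < 2:
        raise ValueError("need at least 2 sweeps for ensemble analysis")
    pressure = protocol.pressure_series(gating.sample_rate_hz)
    p = gating.p_open(pressure)
    n_samples = len(pressure)
    sweeps = np.empty((n_sweeps, n_samples))
    streams = np.random.SeedSequence(seed).spawn(n_sweeps)
    for s in range(n_sweeps):
        rng = np.random.default_rng(streams[s])
        counts = rng.binomial(gating.n_channels, p)
        cur = gating.unitary_current_pa * counts
        if gating.noise_sd_pa > 0:
            cur = cur + rng.normal(0.0, gating.noise_sd_pa, size=n_samples)
        sweeps[s] = cur
    return SweepEnsemble(
        sweeps=sweeps, sample_rate_hz=gating.sample_rate_hz, protocol=protocol
    )
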