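"""Cell-boundary kymograph analysis: curvature waves and the leading edge.

A movie of single-cell binary masks is converted to a series of 500 equally
spaced boundary points whose indices are propagated between frames by the
cyclic alignment that minimizes the mean squared inter-point distance.  From
the indexed points we build space-time kymographs of the local curvature
``c_i(t)`` (1/um, protrusions positive) and of the boundary velocity
projected on the outward normal ``u_i(t)`` (um/s, protrusion positive).

High-curvature ("protrusive") arcs are segmented by a three-class Otsu
threshold of the whole curvature kymograph, linked across frames by index
overlap, and summarized by the typical angular velocity ``omega_c`` of their
outward normals and the typical lifetime ``tau_d`` of the leading edge (the
wave whose normal points closest to the centroid velocity).  A 1D persistent
random walk of the velocity angle with step time ``tau_d`` and step size
``omega_c * tau_d`` then predicts the decay time of the direction
autocorrelation, ``T_est = 4 / (omega_c^2 tau_d)``.

Contours are handled in (x, y) = (column, row) pixel coordinates scaled to
micrometres; traversal is oriented so the enclosed (signed, shoelace) area is
positive, which makes the tangent angle gain +2*pi per loop, the curvature of
a convex arc positive and the outward normal the tangent rotated by -pi/2.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter1d
from skimage import measure
from skimage.filters import threshold_multiotsu

__all__ = [
    "extract_and_resample",
    "link_frames",
    "ContourSeries",
    "build_contour_series",
    "Kymographs",
    "kymographs",
    "FrontRearFit",
    "fit_front_rear",
    "WaveTrack",
    "classify_and_track_waves",
    "leading_edge_lifetimes",
    "estimate_persistence_time",
    "contour_area",
    "wrap_angle",
]

N_POINTS = 500  # boundary points per frame


def wrap_angle(a):
    """Map angles to (-pi, pi]."""
    return np.pi - np.mod(np.pi - np.asarray(a), 2.0 * np.pi)


def contour_area(points: np.ndarray) -> float:
    """Signed shoelace area of a closed polygon (positive for our orientation)."""
    x, y = points[:, 0], points[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def _single_component_contour(mask: np.ndarray) -> np.ndarray:
    """Closed sub-pixel boundary polygon of a single-component mask, in px."""
    mask = np.asarray(mask).astype(bool)
    if not mask.any():
        raise ValueError("empty mask: no foreground pixels")
    n_comp = measure.label(mask, connectivity=2).max()
    if n_comp != 1:
        raise ValueError(f"mask must contain exactly one component, found {n_comp}")
    padded = np.pad(mask, 1).astype(float)
    contours = measure.find_contours(padded, 0.5)
    contour = max(contours, key=len) - 1.0  # undo padding
    # rows/cols -> (x, y); drop duplicated closing vertex if present
    pts = contour[:, ::-1].copy()
    if np.allclose(pts[0], pts[-1]):
        pts = pts[:-1]
    if contour_area(pts) < 0:
        pts = pts[::-1]
    # start at the upper-left-most boundary point (min row, then min column)
    start = np.lexsort((pts[:, 0], pts[:, 1]))[0]
    return np.roll(pts, -start, axis=0)


def _resample_equal_arc(pts: np.ndarray, n_points: int) -> np.ndarray:
    closed = np.vstack([pts, pts[:1]])
    seg = np.linalg.norm(np.diff(closed, axis=0), axis=1)
    arclen = np.concatenate([[0.0], np.cumsum(seg)])
    targets = np.arange(n_points) * arclen[-1] / n_points
    x = np.interp(targets, arclen, closed[:, 0])
    y = np.interp(targets, arclen, closed[:, 1])
    return np.column_stack([x, y])


def extract_and_resample(mask: np.ndarray, n_points: int = N_POINTS,
                         pixel_size: float = 1.0,
                         smooth_points: float = 3.0) -> np.ndarray:
    """Boundary polygon of a binary mask resampled to equal arc-length points.

    The raw pixel-level boundary is stair-stepped, which would dominate any
    curvature estimate, so the polygon is lightly smoothed: resampled
    uniformly, coordinate-filtered with a circular Gaussian of
    ``smooth_points`` (in units of the n-point index; 0 disables), and
    re-resampled to equal arc length.  Returns an (n_points, 2) array of
    (x, y) positions in micrometres, starting at the upper-left-most boundary
    point, oriented with positive enclosed area.  Raises on empty or
    multi-component masks.
    """
    pts = _single_component_contour(mask) * float(pixel_size)
    out = _resample_equal_arc(pts, n_points)
    if smooth_points > 0:
        out = np.column_stack([
            gaussian_filter1d(out[:, 0], smooth_points, mode="wrap"),
            gaussian_filter1d(out[:, 1], smooth_points, mode="wrap")])
        out = _resample_equal_arc(out, n_points)
    return out


def link_frames(prev: np.ndarray, curr: np.ndarray) -> tuple[int, np.ndarray]:
    """Optimal orientation-preserving cyclic shift between two contour frames.

    Finds the shift ``s`` minimizing ``sum_i |prev[i] - curr[(i+s) % n]|^2``
    via FFT cross-correlation and returns ``(s, curr_reindexed)`` where
    ``curr_reindexed[i] = curr[(i+s) % n]`` (the point linked to previous
    index 0 becomes index 0).
    """
    if len(prev) != len(curr):
        raise ValueError("frames must have the same number of points")
    zp = prev[:, 0] + 1j * prev[:, 1]
    zc = curr[:, 0] + 1j * curr[:, 1]
    # corr[s] = sum_i Re(conj(zp[i]) * zc[(i+s) % n])
    corr = np.fft.ifft(np.conj(np.fft.fft(zp)) * np.fft.fft(zc)).real
    shift = int(np.argmax(corr))
    return shift, np.roll(curr, -shift, axis=0)


def _tangent_angles(points: np.ndarray) -> np.ndarray:
    """Unwrapped tangent angle at each vertex (central difference on the ring)."""
    fwd = np.roll(points, -1, axis=0) - np.roll(points, 1, axis=0)
    theta = np.unwrap(np.arctan2(fwd[:, 1], fwd[:, 0]))
    return theta


def _curvature(points: np.ndarray, window: int = 5,
               smooth_sigma: float = 15.0) -> np.ndarray:
    """Curvature from the tangent-angle derivative over a +-window vertex span.

    The windowed central difference telescopes so that the discrete
    circulation sum(c_i) * ds equals exactly 2*pi, and the wrap-mode Gaussian
    smoothing preserves that sum.
    """
    n = len(points)
    closed = np.vstack([points, points[:1]])
    ds = float(np.sum(np.linalg.norm(np.diff(closed, axis=0), axis=1))) / n
    theta = _tangent_angles(points)
    ext = np.concatenate([theta[-window:] - 2.0 * np.pi, theta,
                          theta[:window] + 2.0 * np.pi])
    c = (ext[2 * window:] - ext[:-2 * window]) / (2.0 * window * ds)
    if smooth_sigma > 0:
        c = gaussian_filter1d(c, smooth_sigma, mode="wrap")
    return c


def _normal_angles(points: np.ndarray) -> np.ndarray:
    """Outward normal angle (tangent angle - pi/2), wrapped to (-pi, pi]."""
    return wrap_angle(_tangent_angles(points) - 0.5 * np.pi)


@dataclass
class ContourSeries:
    """Linked boundary-point series of a mask movie.

    ``points`` is (T, n, 2) in um with frame-to-frame index linkage already
    applied; ``curvature``/``normal_angle`` are (T, n); ``normal_velocity``
    is (T-1, n) (displacement of same-index points projected on the frame-t
    outward normal, per frame interval); ``psi`` (T-1,) is the centroid
    velocity angle (NaN where the centroid does not move).
    """

    points: np.ndarray
    curvature: np.ndarray
    normal_angle: np.ndarray
    normal_velocity: np.ndarray
    centroid: np.ndarray
    psi: np.ndarray
    frame_interval: float
    pixel_size: float
    shifts: np.ndarray

    @property
    def n_frames(self) -> int:
        return self.points.shape[0]

    @property
    def n_points(self) -> int:
        return self.points.shape[1]


def build_contour_series(masks, frame_interval: float = 1.0,
                         pixel_size: float = 1.0, n_points: int = N_POINTS,
                         curvature_window: int = 5,
                         smooth_sigma: float = 15.0) -> ContourSeries:
    """Extract, link and differentiate the boundary of a mask movie."""
    masks = np.asarray(masks)
    if masks.ndim != 3 or masks.shape[0] < 2:
        raise ValueError("need a (T, H, W) stack with at least 2 frames")
    T = masks.shape[0]
    pts = np.empty((T, n_points, 2))
    shifts = np.zeros(T, dtype=int)
    pts[0] = extract_and_resample(masks[0], n_points, pixel_size)
    for t in range(1, T):
        raw = extract_and_resample(masks[t], n_points, pixel_size)
        shifts[t], pts[t] = link_frames(pts[t - 1], raw)

    curv = np.stack([_curvature(pts[t], curvature_window, smooth_sigma)
                     for t in range(T)])
    phi = np.stack([_normal_angles(pts[t]) for t in range(T)])
    normal = np.stack([np.cos(phi), np.sin(phi)], axis=-1)
    disp = np.diff(pts, axis=0)
    u = np.einsum("tij,tij->ti", disp, normal[:-1]) / frame_interval

    centroid = np.empty((T, 2))
    for t in range(T):
        ys, xs = np.nonzero(masks[t])
        centroid[t] = (xs.mean() * pixel_size, ys.mean() * pixel_size)
    dc = np.diff(centroid, axis=0)
    psi = np.arctan2(dc[:, 1], dc[:, 0])
    psi[np.linalg.norm(dc, axis=1) == 0] = np.nan
    return ContourSeries(points=pts, curvature=curv, normal_angle=phi,
                         normal_velocity=u, centroid=centroid, psi=psi,
                         frame_interval=frame_interval, pixel_size=pixel_size,
                         shifts=shifts)


@dataclass(frozen=True)
class Kymographs:
    """Curvature and normal-velocity kymographs (rows = boundary index)."""

    curvature: np.ndarray        # (n_points, T)
    normal_velocity: np.ndarray  # (n_points, T-1)
    normal_angle: np.ndarray     # (n_points, T)
    frame_interval: float


def kymographs(series: ContourSeries) -> Kymographs:
    return Kymographs(curvature=series.curvature.T,
                      normal_velocity=series.normal_velocity.T,
                      normal_angle=series.normal_angle.T,
                      frame_interval=series.frame_interval)


# ---------------------------------------------------------------------------
# Front/rear joint-cosine fit of a velocity profile
# ---------------------------------------------------------------------------

def _region_center(i1: int, i2: int, n: int) -> float:
    """Center of the arc from i1 to i2 under periodic index arithmetic."""
    if i1 <= i2:
        c = (i1 + i2) / 2.0
    elif i1 + i2 <= n:
        c = (i1 + i2 + n) / 2.0
    else:
        c = (i1 + i2 - n) / 2.0
    return c % n


@dataclass(frozen=True)
class FrontRearFit:
    """Joint-cosine decomposition of one frame's normal-velocity profile.

    The front region I = [i1, i2] (periodic) carries a positive half-cosine
    of amplitude A1 centered at ``center_front``; the complement carries a
    negative half-cosine of amplitude A2 centered at ``center_rear``.
    """

    i1: int
    i2: int
    A1: float
    A2: float
    length: int
    center_front: float
    center_rear: float
    rss: float
    degenerate: bool = False


def _front_rear_templates(L: int, n: int):
    front = np.zeros(n)
    d = np.arange(L + 1)
    front[:L + 1] = np.cos(np.pi * (d - L / 2.0) / L)
    rear = np.zeros(n)
    e = np.arange(1, n - L)
    rear[L + 1:] = -np.cos(np.pi * (e - (n - L) / 2.0) / (n - L))
    return front, rear


def _scan_length(u: np.ndarray, L: int):
    """Best shift and amplitudes for a fixed front length via FFT correlation."""
    n = len(u)
    front, rear = _front_rear_templates(L, n)
    fu = np.fft.fft(u)
    # corr[s] = sum_d tmpl[d] * u[(s+d) % n]
    c1 = np.fft.ifft(fu * np.conj(np.fft.fft(front))).real
    c2 = np.fft.ifft(fu * np.conj(np.fft.fft(rear))).real
    n11 = float(front @ front)
    n22 = float(rear @ rear)
    A1 = np.clip(c1 / n11, 0.0, None)
    A2 = np.clip(c2 / n22, 0.0, None)
    rss = (u @ u) - 2 * A1 * c1 - 2 * A2 * c2 + A1 ** 2 * n11 + A2 ** 2 * n22
    s = int(np.argmin(rss))
    return rss[s], s, float(A1[s]), float(A2[s])


def fit_front_rear(u_profile: np.ndarray, coarse_stride: int = 5) -> FrontRearFit:
    """Least-squares fit of the periodic front/rear joint-cosine model.

    Searches front lengths on a coarse grid (all start indices are scanned
    exactly via FFT correlation), then refines the length locally.  The model
    is linear in the nonnegative amplitudes, which are profiled out in closed
    form (the front and rear templates have disjoint support).
    """
    u = np.asarray(u_profile, dtype=float)
    n = len(u)
    if not np.any(u):
        return FrontRearFit(i1=0, i2=0, A1=0.0, A2=0.0, length=0,
                            center_front=0.0, center_rear=_region_center(0, 0, n),
                            rss=0.0, degenerate=True)
    lengths = list(range(4, n - 3, coarse_stride))
    best = min((_scan_length(u, L) + (L,) for L in lengths))
    L0 = best[-1]
    refine = [L for L in range(max(4, L0 - coarse_stride + 1),
                               min(n - 4, L0 + coarse_stride)) ]
    best = min((_scan_length(u, L) + (L,) for L in refine), default=best)
    rss, i1, A1, A2, L = best
    i2 = (i1 + L) % n
    return FrontRearFit(i1=i1, i2=i2, A1=A1, A2=A2, length=L,
                        center_front=_region_center(i1, i2, n),
                        center_rear=_region_center(i2, i1, n), rss=rss)


# ---------------------------------------------------------------------------
# Curvature-wave classification, tracking and the leading edge
# ---------------------------------------------------------------------------

def _circular_runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Contiguous True runs (iL, iR) on a ring, merging across the wrap."""
    n = len(mask)
    if mask.all():
        return [(0, n - 1)]
    if not mask.any():
        return []
    m = mask.astype(int)
    starts = np.flatnonzero(m & ~np.roll(m, 1))
    ends = np.flatnonzero(m & ~np.roll(m, -1))
    runs = []
    for s in starts:
        e = ends[ends >= s][0] if np.any(ends >= s) else ends[0]
        runs.append((int(s), int(e)))
    return runs


def _run_indices(iL: int, iR: int, n: int) -> np.ndarray:
    if iL <= iR:
        return np.arange(iL, iR + 1)
    return np.concatenate([np.arange(iL, n), np.arange(0, iR + 1)])


@dataclass
class WaveTrack:
    """Protrusive curvature-wave fragments, their links and angular velocities."""

    c1: float
    c2: float
    fragments: list                    # per frame: list of (iL, iR)
    centers: list                      # per frame: list of int center indices
    center_angles: list                # per frame: normal angle at each center
    links: list = field(default_factory=list)    # (t, j, j') index-overlap links
    omegas: np.ndarray = field(default_factory=lambda: np.empty(0))
    omega_c: float = float("nan")
    dt: float = 1.0
    n_points: int = N_POINTS

    @property
    def n_frames(self) -> int:
        return len(self.fragments)


def _exponential_scale(values: np.ndarray, min_value: float = 0.0,
                       method: str = "mle") -> float:
    """Scale of an exponential law fitted to values >= min_value.

    ``mle``: for left-truncated exponential data the maximum-likelihood scale
    is ``mean(x[x >= m]) - m``.  ``histogram``: least-squares fit of
    ``a * exp(-x / scale)`` to a histogram, closer to the plotted-fit recipe.
    """
    sel = np.asarray(values, dtype=float)
    sel = sel[np.isfinite(sel) & (sel >= min_value)]
    if len(sel) == 0:
        return float("nan")
    if method == "mle":
        return float(np.mean(sel) - min_value)
    if method == "histogram":
        from scipy.optimize import curve_fit
        counts, edges = np.histogram(sel, bins="auto")
        mids = 0.5 * (edges[:-1] + edges[1:])
        keep = counts > 0
        if keep.sum() < 2:
            return float(np.mean(sel) - min_value)
        p0 = (counts.max(), max(np.mean(sel) - min_value, 1e-6))
        try:
            popt, _ = curve_fit(lambda x, a, s: a * np.exp(-x / s),
                                mids[keep], counts[keep], p0=p0,
                                maxfev=10000)
            return float(abs(popt[1]))
        except RuntimeError:
            return float(np.mean(sel) - min_value)
    raise ValueError(f"unknown method {method!r}")


def classify_and_track_waves(curvature_kymo: np.ndarray,
                             normal_angle_kymo: np.ndarray,
                             dt: float = 1.0,
                             omega_method: str = "mle") -> WaveTrack:
    """Three-class Otsu segmentation of the curvature kymograph + wave tracking.

    Thresholds ``c1 < c2`` are computed once over the whole kymograph;
    positions with curvature above ``c2`` are protrusive.  Contiguous
    protrusive arcs (periodic) are linked between consecutive frames whenever
    their index sets overlap; each link contributes an angular velocity
    ``omega = wrap(phi_center(t+1) - phi_center(t)) / dt`` and the
    representative ``omega_c`` is the exponential scale of ``|omega|``.
    """
    curv = np.asarray(curvature_kymo, dtype=float)
    phi = np.asarray(normal_angle_kymo, dtype=float)
    if curv.shape != phi.shape:
        raise ValueError("curvature and normal-angle kymographs must align")
    n, T = curv.shape
    flat = curv.ravel()
    if np.ptp(flat) < 1e-12 or len(np.unique(flat)) < 3:
        warnings.warn("degenerate curvature kymograph: no waves detected")
        return WaveTrack(c1=float("nan"), c2=float("nan"),
                         fragments=[[] for _ in range(T)],
                         centers=[[] for _ in range(T)],
                         center_angles=[[] for _ in range(T)],
                         dt=dt, n_points=n)
    c1, c2 = (float(x) for x in threshold_multiotsu(flat, classes=3))

    fragments, centers, center_angles = [], [], []
    masks_per_frame = []
    for t in range(T):
        runs = _circular_runs(curv[:, t] > c2)
        fragments.append(runs)
        cs, angs, bmasks = [], [], []
        for iL, iR in runs:
            c = _region_center(iL, iR, n)
            cs.append(c)
            # circular interpolation of the normal angle at the (possibly
            # half-integer) fragment center
            lo = int(np.floor(c)) % n
            hi = (lo + 1) % n
            frac = c - np.floor(c)
            ang = phi[lo, t] + frac * wrap_angle(phi[hi, t] - phi[lo, t])
            angs.append(float(wrap_angle(ang)))
            bm = np.zeros(n, dtype=bool)
            bm[_run_indices(iL, iR, n)] = True
            bmasks.append(bm)
        centers.append(cs)
        center_angles.append(angs)
        masks_per_frame.append(bmasks)

    links, omegas = [], []
    for t in range(T - 1):
        for j, bm in enumerate(masks_per_frame[t]):
            for jp, bmp in enumerate(masks_per_frame[t + 1]):
                if np.any(bm & bmp):
                    links.append((t, j, jp))
                    dphi = wrap_angle(center_angles[t + 1][jp]
                                      - center_angles[t][j])
                    omegas.append(dphi / dt)
    omegas = np.asarray(omegas)
    omega_c = (_exponential_scale(np.abs(omegas), 0.0, omega_method)
               if len(omegas) else float("nan"))
    return WaveTrack(c1=c1, c2=c2, fragments=fragments, centers=centers,
                     center_angles=center_angles, links=links, omegas=omegas,
                     omega_c=omega_c, dt=dt, n_points=n)


def leading_edge_lifetimes(track: WaveTrack, psi: np.ndarray,
                           tau_method: str = "mle"):
    """Dominant (leading-edge) wave per frame and its lifetime statistics.

    The leading wave minimizes the circular distance between its center's
    outward-normal angle and the centroid-velocity angle ``psi(t)``.  Break
    times are frames where the leading wave is not linked to the next frame's
    leading wave; lifetimes are the intervals between consecutive break
    times minus one frame interval.  Frames without fragments or with
    undefined ``psi`` split the record and lifetimes never bridge the gap.

    Returns ``(j_d, lifetimes, tau_d)`` where ``j_d[t]`` is the leading
    fragment index (-1 where undefined).
    """
    T = track.n_frames
    psi = np.asarray(psi, dtype=float)
    if len(psi) < T:  # velocity angle has one sample fewer than frames
        psi = np.concatenate([psi, [np.nan] * (T - len(psi))])
    dt = track.dt
    j_d = np.full(T, -1, dtype=int)
    for t in range(T):
        angs = track.center_angles[t]
        if len(angs) == 0 or not np.isfinite(psi[t]):
            continue
        dist = np.abs(wrap_angle(np.asarray(angs) - psi[t]))
        j_d[t] = int(np.argmin(dist))

    link_set = set(track.links)
    lifetimes = []
    t = 0
    while t < T:
        if j_d[t] < 0:
            t += 1
            continue
        run_start = t
        while t + 1 < T and j_d[t + 1] >= 0:
            t += 1
        run_end = t
        breaks = [run_start * dt - dt]
        for s in range(run_start, run_end):
            if (s, j_d[s], j_d[s + 1]) not in link_set:
                breaks.append(s * dt)
        breaks.append(run_end * dt)
        lifetimes.extend(np.diff(breaks) - dt)
        t += 1
    lifetimes = np.asarray(lifetimes, dtype=float)
    tau_d = (_exponential_scale(lifetimes, dt, tau_method)
             if len(lifetimes) else float("nan"))
    return j_d, lifetimes, tau_d


def estimate_persistence_time(omega_c: float, tau_d: float) -> float:
    """Predicted decay time of the centroid-direction autocorrelation.

    For a velocity angle performing a 1D persistent random walk with step
    time ``tau_d`` and step size ``omega_c * tau_d`` the direction
    autocorrelation decays as ``exp(-omega_c^2 tau_d t / 4)``, giving
    ``T_est = 4 / (omega_c^2 tau_d)``.
    """
    if not (omega_c > 0 and tau_d > 0):
        raise ValueError("omega_c and tau_d must be positive")
    return 4.0 / (omega_c ** 2 * tau_d)
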