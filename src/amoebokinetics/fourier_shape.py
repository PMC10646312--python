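"""Elliptic-Fourier shape spectra, power-spectrum PCA and mode couplings.

The cell outline is sampled at 160 equal arc-length points, rescaled by
``3000 * A / (160 * L)`` (A = mask pixel count, L = outline length in px),
centred on the centroid, and Fourier transformed; the power spectrum
``S_k = |q_tilde_k|^2`` is start-point and rotation invariant and is the
input to a PCA fitted once on a reference set and then applied frozen to all
data.  Shapes are reconstructed from scores through the zero-phase inverse
transform of the (clipped-nonnegative) spectrum.

Signed deformation modes follow the convention ``C_n = q_tilde_n`` for
``n >= 1`` and ``C_-n = q_tilde_{160-n}`` (the centred spectrum has
``q_tilde_0 ~ 0``, so indexing from the first harmonic keeps conjugate pairs
aligned); an elongated outline splits its power between ``C_1`` and ``C_-1``.
The velocity-deformation coupling ``C_nm = Cdot_-n C_m - C_-n Cdot_m`` with
``-n + m = 1`` rotates like the centroid velocity and is compared against it
through circular and componentwise linear statistics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .boundary_dynamics import _single_component_contour, wrap_angle

__all__ = [
    "ShapeSpectrum",
    "elliptic_fourier",
    "SpectrumPCA",
    "fit_spectrum_pca",
    "project",
    "reconstruct",
    "pc_autocorrelation",
    "mode_autocorrelation",
    "CouplingResult",
    "deformation_velocity_coupling",
]

N_MODES = 160


@dataclass(frozen=True)
class ShapeSpectrum:
    """Elliptic-Fourier description of one mask outline.

    ``samples`` are the 160 rescaled, centred outline points; ``modes`` the
    complex DFT coefficients q_tilde_k; ``power`` the spectrum S_k.
    """

    samples: np.ndarray     # (160, 2)
    modes: np.ndarray       # (160,) complex
    power: np.ndarray       # (160,)
    perimeter: float        # px
    area: float             # px count

    def mode(self, n: int) -> complex:
        """Signed deformation mode C_n (n >= 1) or C_-n = q_tilde_{160-n}."""
        if n == 0:
            raise ValueError("signed modes are indexed from +-1")
        k = n if n > 0 else N_MODES + n
        return self.modes[k]


def _resample_closed(points: np.ndarray, n: int) -> np.ndarray:
    closed = np.vstack([points, points[:1]])
    seg = np.linalg.norm(np.diff(closed, axis=0), axis=1)
    arclen = np.concatenate([[0.0], np.cumsum(seg)])
    targets = np.arange(n) * arclen[-1] / n
    return np.column_stack([np.interp(targets, arclen, closed[:, 0]),
                            np.interp(targets, arclen, closed[:, 1])])


def elliptic_fourier(mask: np.ndarray, n_points: int = N_MODES,
                     rescale: str = "paper") -> ShapeSpectrum:
    """Elliptic-Fourier spectrum of a single-component binary mask.

    ``rescale='paper'`` multiplies the outline by ``3000 * A / (n * L)``
    (a per-mask uniform scalar that makes the spectrum roughly
    size-normalized); ``'unit'`` scales the perimeter to 1 instead.
    """
    mask = np.asarray(mask).astype(bool)
    outline = _single_component_contour(mask)  # px, validated single component
    closed = np.vstack([outline, outline[:1]])
    perimeter = float(np.sum(np.linalg.norm(np.diff(closed, axis=0), axis=1)))
    area = float(mask.sum())
    pts = _resample_closed(outline, n_points)
    if rescale == "paper":
        factor = 3000.0 * area / (n_points * perimeter)
    elif rescale == "unit":
        factor = 1.0 / perimeter
    else:
        raise ValueError(f"unknown rescale {rescale!r}")
    pts = pts * factor
    pts = pts - pts.mean(axis=0)
    z = pts[:, 0] + 1j * pts[:, 1]
    modes = np.fft.fft(z)  # rotation-matrix DFT == complex DFT of x + i y
    return ShapeSpectrum(samples=pts, modes=modes,
                         power=np.abs(modes) ** 2,
                         perimeter=perimeter, area=area)


@dataclass(frozen=True)
class SpectrumPCA:
    """Frozen PCA of power-spectrum vectors (mean, eigenvalues, eigenvectors).

    ``components[m]`` is the m-th orthonormal eigenvector of the unbiased
    covariance matrix, eigenvalues sorted descending.  Eigenvector signs are
    fixed so the largest-magnitude loading of each component is positive.
    """

    mean: np.ndarray          # (160,)
    eigenvalues: np.ndarray   # (160,) descending
    components: np.ndarray    # (160, 160), rows are eigenvectors

    @property
    def explained_variance_ratio(self) -> np.ndarray:
        tot = self.eigenvalues.sum()
        return self.eigenvalues / tot if tot > 0 else self.eigenvalues


def _as_power(x) -> np.ndarray:
    return x.power if isinstance(x, ShapeSpectrum) else np.asarray(x, dtype=float)


def fit_spectrum_pca(spectra) -> SpectrumPCA:
    """Fit the power-spectrum PCA on a reference set of spectra."""
    S = np.stack([_as_power(s) for s in spectra])
    if len(S) < 2:
        raise ValueError("need >= 2 spectra to fit a PCA")
    if len(S) <= S.shape[1]:
        warnings.warn("fewer samples than spectrum dimensions: "
                      "covariance is rank deficient", stacklevel=2)
    mean = S.mean(axis=0)
    cov = np.cov(S, rowvar=False, ddof=1)
    vals, vecs = np.linalg.eigh(cov)
    order = np.argsort(vals)[::-1]
    vals = np.clip(vals[order], 0.0, None)
    comps = vecs[:, order].T
    # deterministic sign: largest-|loading| entry positive
    for m in range(comps.shape[0]):
        j = np.argmax(np.abs(comps[m]))
        if comps[m, j] < 0:
            comps[m] = -comps[m]
    return SpectrumPCA(mean=mean, eigenvalues=vals, components=comps)


def project(spectrum, pca: SpectrumPCA, n_components: int | None = None) -> np.ndarray:
    """Scores ``PC_m = (S - S_mean) . e_m`` for one spectrum or a stack."""
    S = _as_power(spectrum)
    comps = pca.components if n_components is None else pca.components[:n_components]
    return (S - pca.mean) @ comps.T


def reconstruct(scores: np.ndarray, pca: SpectrumPCA,
                n_points: int = N_MODES, as_mask: bool = False):
    """Zero-phase shape reconstruction from PCA scores.

    Rebuilds ``S = S_mean + sum_m PC_m e_m`` (negative entries clipped to 0
    with a warning), then the contour ``q_i = (1/n) sum_k S_k e^{2 pi i k i / n}``.
    Returns the (n_points, 2) contour, or a binary boundary image when
    ``as_mask`` is true (edge pixels set, as in the reconstruction figures).
    """
    scores = np.asarray(scores, dtype=float)
    S = pca.mean + scores @ pca.components[: len(scores)]
    if np.any(S < 0):
        warnings.warn("reconstructed spectrum has negative entries; clipping to 0",
                      stacklevel=2)
        S = np.clip(S, 0.0, None)
    z = np.fft.ifft(S)  # includes the 1/n factor
    contour = np.column_stack([z.real, z.imag])
    if not as_mask:
        return contour
    # the rescaled spectrum units put the contour far off the pixel scale;
    # normalize the rendering so the boundary image stays a sensible raster
    extent = np.abs(contour).max()
    render = contour * (150.0 / extent) if extent > 512 else contour
    pix = np.rint(render).astype(int)
    pix -= pix.min(axis=0) - 2
    img = np.zeros((pix[:, 1].max() + 3, pix[:, 0].max() + 3), dtype=bool)
    img[pix[:, 1], pix[:, 0]] = True
    return img


def pc_autocorrelation(pc1, pc2, max_lag_steps: int | None = None) -> np.ndarray:
    """Symmetric averaged autocorrelation of per-cell-centred PC1/PC2 series.

    ``pc1``/``pc2`` are lists of equally long 1D score series (one per cell)
    or single series.  Each series is centred on its own mean; the statistic
    is ``0.5 * <PC1~(t) PC1~(t+m) + PC2~(t) PC2~(t+m)>`` over cells and times.
    """
    if np.ndim(pc1) == 1:
        pc1, pc2 = [np.asarray(pc1)], [np.asarray(pc2)]
    pc1 = [np.asarray(p, dtype=float) for p in pc1]
    pc2 = [np.asarray(p, dtype=float) for p in pc2]
    if max_lag_steps is None:
        max_lag_steps = max(len(p) for p in pc1) - 1
    sums = np.zeros(max_lag_steps + 1)
    counts = np.zeros(max_lag_steps + 1, dtype=np.int64)
    for p1, p2 in zip(pc1, pc2):
        a = p1 - p1.mean()
        b = p2 - p2.mean()
        n = len(a)
        for m in range(min(max_lag_steps, n - 1) + 1):
            sums[m] += 0.5 * (np.dot(a[: n - m], a[m:]) + np.dot(b[: n - m], b[m:]))
            counts[m] += n - m
    with np.errstate(invalid="ignore"):
        out = sums / counts
    out[counts == 0] = np.nan
    return out


def mode_autocorrelation(series: np.ndarray, dt: float = 1.0,
                         max_lag_steps: int | None = None):
    """Normalized autocorrelation of a complex mode series and its decay time.

    Returns ``(ac, decay_time)`` where
    ``ac(m) = Re<C~(t) conj(C~(t+m))> / <|C~|^2>`` after per-series mean
    removal.  The decay time comes from a log-linear fit to the *modulus* of
    the complex autocorrelation (robust to a rotating phase) over its initial
    above-noise stretch; a series whose correlation never falls below 1/e
    within the lag range is flagged with ``inf``.
    """
    c = np.asarray(series, dtype=complex)
    c = c - c.mean()
    n = len(c)
    if max_lag_steps is None:
        max_lag_steps = n - 1
    max_lag_steps = min(max_lag_steps, n - 1)
    ac_c = np.empty(max_lag_steps + 1, dtype=complex)
    for m in range(max_lag_steps + 1):
        ac_c[m] = np.mean(c[: n - m] * np.conj(c[m:]))
    norm = ac_c[0].real
    if norm <= 0:
        return np.full(max_lag_steps + 1, np.nan), float("nan")
    ac = ac_c.real / norm
    mod = np.abs(ac_c) / norm
    if mod[1:].min(initial=np.inf) > np.exp(-1):
        return ac, float("inf")
    stop = 1
    while stop <= max_lag_steps and mod[stop] > 0.05:
        stop += 1
    if stop < 3:
        return ac, float(dt)  # decorrelates within one frame interval
    slope = np.polyfit(np.arange(stop) * dt, np.log(mod[:stop]), 1)[0]
    return ac, (float(-1.0 / slope) if slope < 0 else float("inf"))


@dataclass(frozen=True)
class CouplingResult:
    """Coupling of two deformation modes against the centroid velocity.

    ``c_nm(t) = Cdot_-n(t) C_m(t) - C_-n(t) Cdot_m(t)`` by forward
    differences; ``angle_correlation`` is the mean cosine between
    ``arg(C_nm)`` and the velocity angle, ``slope_x``/``slope_y`` the
    through-origin proportionality of Re/Im parts to v_x/v_y with their
    Pearson correlations ``r_x``/``r_y``.  ``defined`` is False when the
    coupling is numerically zero throughout (static shape).
    """

    c_nm: np.ndarray
    angle_correlation: float
    slope_x: float
    slope_y: float
    r_x: float
    r_y: float
    defined: bool


def deformation_velocity_coupling(minus_n_series, m_series, velocities,
                                  dt: float = 1.0, n: int = 3, m: int = 4,
                                  floor: float = 1e-12) -> CouplingResult:
    """Compare the mode coupling C_nm with the centroid velocity.

    Parameters are the complex time series of ``C_-n`` and ``C_m``
    (``-n + m`` must equal 1) and the (T-1, 2) or (T, 2) centroid velocity
    aligned to the same frames.  Samples with ``|C_nm|`` below ``floor``
    are excluded from the angle statistic.
    """
    if -n + m != 1:
        raise ValueError("mode coupling requires -n + m = 1")
    cm_n = np.asarray(minus_n_series, dtype=complex)
    cm = np.asarray(m_series, dtype=complex)
    if len(cm_n) != len(cm):
        raise ValueError("mode series must be aligned")
    d_n = np.diff(cm_n) / dt
    d_m = np.diff(cm) / dt
    c_nm = d_n * cm[:-1] - cm_n[:-1] * d_m

    vel = np.asarray(velocities, dtype=float)
    vel = vel[: len(c_nm)]
    if len(vel) != len(c_nm):
        raise ValueError("velocity series shorter than the coupling series")

    mag = np.abs(c_nm)
    if np.all(mag < floor):
        return CouplingResult(c_nm=c_nm, angle_correlation=float("nan"),
                              slope_x=float("nan"), slope_y=float("nan"),
                              r_x=float("nan"), r_y=float("nan"), defined=False)
    ok = mag >= floor
    v_ang = np.arctan2(vel[:, 1], vel[:, 0])
    ang_corr = float(np.mean(np.cos(wrap_angle(np.angle(c_nm[ok]) - v_ang[ok]))))

    def through_origin(x, y):
        denom = float(x @ x)
        slope = float(x @ y) / denom if denom > 0 else float("nan")
        r = (float(np.corrcoef(x, y)[0, 1])
             if np.std(x) > 0 and np.std(y) > 0 else float("nan"))
        return slope, r

    slope_x, r_x = through_origin(c_nm.real, vel[:, 0])
    slope_y, r_y = through_origin(c_nm.imag, vel[:, 1])
    return CouplingResult(c_nm=c_nm, angle_correlation=ang_corr,
                          slope_x=slope_x, slope_y=slope_y, r_x=r_x, r_y=r_y,
                          defined=True)
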