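"""Defocusing-microscopy z-tracking of fluorescent beads.

An out-of-focus fluorescent bead images as a set of concentric diffraction
rings; the radius of the outer ring reports the distance between the bead
and the focal plane.  This module synthesises such ring patterns (sums of
Gaussian annuli), measures the outer ring radius with sub-pixel precision
by fitting Gaussians to the first and last peak of a diametric intensity
profile, converts radius changes to z via a piezo-stage calibration, and
tracks bead height through an image stack with nanometre-scale precision.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, optimize, signal, stats

from .estimators import BeadTrace

__all__ = [
    "RingImage",
    "Calibration",
    "TrackingError",
    "synthesize_ring_image",
    "outer_ring_radius",
    "calibrate",
    "track_stack",
]


class TrackingError(RuntimeError):
    """Raised when rings cannot be detected."""


@dataclass
class RingImage:
    """A defocused-bead frame: pixel data plus (for synthetic frames) truth.

    ``pixels`` is the 2D intensity array; ``pixel_size`` the sampling
    [um/px].  Ground truth (centre, outer radius, ring width, contrast,
    noise sigma) is stored separately from the pixels and never consulted
    by the tracker.
    """

    pixels: np.ndarray
    pixel_size: float = 0.1
    truth: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2:
            raise ValueError("pixels must be a 2D array")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("pixel intensities must be finite")


@dataclass
class Calibration:
    """Linear radius -> z mapping from piezo steps: z = slope * radius + intercept."""

    slope: float  # um of z per px of radius
    intercept: float  # um
    r2: float
    source_z: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.slope == 0:
            raise ValueError("calibration slope must be non-zero")

    def z_of_radius(self, radius_px: float) -> float:
        return self.slope * radius_px + self.intercept


def synthesize_ring_image(
    outer_radius: float,
    n_rings: int = 3,
    width: float = 1.5,
    contrast: float = 100.0,
    noise_sigma: float = 0.0,
    seed: int | np.random.Generator = 0,
    shape: tuple[int, int] = (128, 128),
    centre: tuple[float, float] | None = None,
    background: float = 10.0,
    pixel_size: float = 0.1,
) -> RingImage:
    """Synthetic concentric-ring bead image.

    The pattern is a sum of ``n_rings`` Gaussian annuli of the given
    ``width`` [px], the outermost at ``outer_radius`` [px] and the rest
    evenly spaced inward, over a flat background, with additive Gaussian
    noise of standard deviation ``noise_sigma`` (absolute intensity units).
    Deterministic for a given seed.
    """
    if outer_radius < 3.0 * width:
        raise ValueError("outer_radius must be at least 3x the ring width")
    ny, nx = shape
    if centre is None:
        centre = ((nx - 1) / 2.0, (ny - 1) / 2.0)
    cx, cy = centre
    margin = outer_radius + 3.0 * width
    if cx - margin < 0 or cx + margin > nx - 1 or cy - margin < 0 or cy + margin > ny - 1:
        raise ValueError("outer ring does not fit inside the frame")
    y, x = np.mgrid[0:ny, 0:nx]
    rho = np.hypot(x - cx, y - cy)
    # rings spaced inward from the outer one; spacing wide enough that
    # neighbouring annuli stay resolved at any radius
    spacing = max(outer_radius / n_rings, 4.0 * width)
    radii = outer_radius - spacing * np.arange(n_rings)
    radii = radii[radii >= 2.0 * width]
    img = np.full((ny, nx), float(background))
    for r0 in radii:
        amp = contrast * (0.6 + 0.4 * (r0 / outer_radius))  # outer rings brighter
        img += amp * np.exp(-((rho - r0) ** 2) / (2.0 * width**2))
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if noise_sigma > 0:
        img = img + rng.normal(0.0, noise_sigma, img.shape)
    truth = dict(
        centre=centre, outer_radius=float(outer_radius), width=float(width),
        contrast=float(contrast), noise_sigma=float(noise_sigma), n_rings=int(n_rings),
    )
    return RingImage(pixels=img, pixel_size=pixel_size, truth=truth)


def _gaussian(x, amp, mu, sig, off):
    return off + amp * np.exp(-((x - mu) ** 2) / (2.0 * sig**2))


def _fit_peak(profile: np.ndarray, i_peak: int, half_window: int = 5):
    """Sub-pixel peak position by local Gaussian fit; returns (mu, sigma_mu)."""
    lo = max(i_peak - half_window, 0)
    hi = min(i_peak + half_window + 1, len(profile))
    x = np.arange(lo, hi, dtype=float)
    y = profile[lo:hi]
    off0 = float(y.min())
    p0 = (float(y[i_peak - lo] - off0), float(i_peak), 1.5, off0)
    try:
        popt, pcov = optimize.curve_fit(_gaussian, x, y, p0=p0, maxfev=5000)
    except RuntimeError:
        return float(i_peak), np.inf
    err = float(np.sqrt(pcov[1, 1])) if np.all(np.isfinite(pcov)) else np.inf
    return float(popt[1]), err


def outer_ring_radius(
    image: RingImage,
    centre: tuple[float, float] | None = None,
    band_halfwidth: int = 1,
    min_prominence_frac: float = 0.25,
) -> tuple[float, float]:
    """Outer ring radius [px] with uncertainty, by diametric profile fitting.

    A horizontal intensity profile through the ring centre (averaged over a
    band of ``2*band_halfwidth + 1`` rows to suppress noise) shows the outer
    ring as its first and last peak; each is located sub-pixel by a local
    Gaussian fit and the radius is half the distance between the two fitted
    centres.  The centre defaults to the intensity centroid.  Raises
    :class:`TrackingError` when no peak rises above the noise floor.
    """
    img = image.pixels
    ny, nx = img.shape
    if centre is None:
        total = img.sum()
        cy = float((img.sum(axis=1) * np.arange(ny)).sum() / total)
        cx = float((img.sum(axis=0) * np.arange(nx)).sum() / total)
    else:
        cx, cy = centre
    if not (0 <= cx <= nx - 1 and 0 <= cy <= ny - 1):
        raise ValueError("centre outside frame")
    iy = int(round(cy))
    lo, hi = max(iy - band_halfwidth, 0), min(iy + band_halfwidth + 1, ny)
    profile = img[lo:hi].mean(axis=0)

    # peak finding on a lightly smoothed profile (noise spikes otherwise
    # masquerade as outer peaks); the sub-pixel Gaussian fits use raw data
    smooth = ndimage.gaussian_filter1d(profile, 1.0)
    span = float(smooth.max() - smooth.min())
    noise = float(np.median(np.abs(np.diff(profile)))) + 1e-12
    if span < 5.0 * noise:
        raise TrackingError("no ring detected: profile is flat relative to noise")
    peaks, _ = signal.find_peaks(smooth, prominence=min_prominence_frac * span)
    peaks = peaks[np.abs(peaks - cx) > 1.5]  # exclude the central maximum
    left = peaks[peaks < cx]
    right = peaks[peaks > cx]
    if len(left) == 0 or len(right) == 0:
        raise TrackingError("no ring detected on both sides of the centre")
    mu_l, e_l = _fit_peak(profile, int(left[0]))
    mu_r, e_r = _fit_peak(profile, int(right[-1]))
    radius = 0.5 * (mu_r - mu_l)
    err = 0.5 * float(np.hypot(e_l, e_r))
    if radius <= 0:
        raise TrackingError("degenerate peak geometry")
    return radius, err


def calibrate(radii_px: np.ndarray, z_steps_um: np.ndarray) -> Calibration:
    """Least-squares linear radius -> z map from known piezo z-steps.

    Needs at least 3 paired points with strictly monotone z; a constant
    radius sequence is degenerate and rejected.
    """
    radii = np.asarray(radii_px, dtype=float)
    z = np.asarray(z_steps_um, dtype=float)
    if len(radii) != len(z) or len(radii) < 3:
        raise ValueError("need at least 3 paired (radius, z) points")
    dz = np.diff(z)
    if not (np.all(dz > 0) or np.all(dz < 0)):
        raise ValueError("z steps must be strictly monotone")
    if np.ptp(radii) < 1e-12:
        raise ValueError("degenerate calibration: radius does not vary")
    lin = stats.linregress(radii, z)
    return Calibration(
        slope=float(lin.slope), intercept=float(lin.intercept),
        r2=float(lin.rvalue**2), source_z=z,
    )


def track_stack(
    images: list[RingImage],
    calibration: Calibration,
    centre: tuple[float, float] | None = None,
    times: np.ndarray | None = None,
    frame_interval: float = 0.1,
    max_failed_frac: float = 0.5,
    distance: float = np.nan,
) -> BeadTrace:
    """Track bead height through a stack of defocused frames.

    Per frame the outer ring radius is converted to z through the linear
    calibration; the first successfully tracked frame defines the baseline.
    Frames where detection fails are carried as NaN gaps (never silently
    interpolated); if more than ``max_failed_frac`` of the frames fail the
    whole stack is rejected.
    """
    if len(images) == 0:
        raise ValueError("empty stack")
    z = np.full(len(images), np.nan)
    for i, im in enumerate(images):
        try:
            radius, _ = outer_ring_radius(im, centre=centre)
        except TrackingError:
            continue
        z[i] = calibration.z_of_radius(radius)
    failed = np.isnan(z)
    if failed.mean() > max_failed_frac:
        raise TrackingError(
            f"{failed.sum()}/{len(z)} frames failed detection"
        )
    baseline = z[~failed][0]
    z = z - baseline
    if times is None:
        times = np.arange(len(images)) * frame_interval
    return BeadTrace(t=np.asarray(times, dtype=float), z=z, distance=distance)
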