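"""Machine-vision measurement of the sensing-tube tip.

The tube tip is located in microscope frames by binarization (Otsu),
one round of 3x3 grayscale dilation to suppress segmentation speckle,
and Harris corner detection; the corner of maximal x inside the tube
component is taken as the tip, because the free end is the rightmost
point of the horizontal tube.  Pixel coordinates convert to microns via
the camera field of view divided by the objective magnification factor.

A synthetic frame renderer stands in for the camera so the whole
pipeline can be exercised and its pixel-level error quantified without
hardware.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.feature import corner_harris, corner_peaks
from skimage.filters import threshold_otsu
from skimage.measure import label
from skimage.morphology import dilation, footprint_rectangle

__all__ = [
    "OpticsSpec",
    "TipObservation",
    "TipDetectionError",
    "render_tube_image",
    "detect_tip",
    "pixel_to_micron",
    "TipNoiseSampler",
    "tip_noise_sampler",
]


class TipDetectionError(RuntimeError):
    """Raised when no plausible tube tip is found in a frame."""


@dataclass(frozen=True)
class OpticsSpec:
    """Camera resolution, field of view, and objective factor.

    ``micron_per_pixel = (fov_width_mm / width_px) * 1000 / objective_factor``.
    The default matches a 1600x1200 camera imaging 7.04 mm x 5.28 mm
    through a 4x objective with a 0.5x adapter (factor 2).
    """

    width_px: int = 1600
    height_px: int = 1200
    fov_width_mm: float = 7.04
    fov_height_mm: float = 5.28
    objective_factor: float = 4 * 0.5

    def __post_init__(self) -> None:
        for name in (
            "width_px",
            "height_px",
            "fov_width_mm",
            "fov_height_mm",
            "objective_factor",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")

    @property
    def micron_per_pixel(self) -> float:
        return self.fov_width_mm * 1000.0 / self.width_px / self.objective_factor


@dataclass(frozen=True)
class TipObservation:
    x_t: float  # px
    y_t: float  # px
    u_tip_um: float | None = None  # (x_t - x_o) * micron_per_pixel when origin known

    def with_origin(self, x_o: float, optics: OpticsSpec) -> "TipObservation":
        return TipObservation(
            self.x_t, self.y_t, (self.x_t - x_o) * optics.micron_per_pixel
        )


def render_tube_image(
    tip_px: tuple[int, int],
    tube_width_px: int = 9,
    noise_level: float = 0.0,
    seed: int | None = 0,
    shape: tuple[int, int] = (300, 400),
    background: int = 220,
    tube_gray: int = 40,
) -> np.ndarray:
    """Synthetic grayscale frame of a dark horizontal tube on a bright field.

    The tube runs from the left edge to ``tip_px = (x, y)``; the rendered
    band occupies rows [y, y + tube_width) so the given point is the
    tube's upper-right corner (the Harris feature the detector reports).
    ``noise_level`` is the additive Gaussian sigma as a fraction of the
    8-bit dynamic range.  Deterministic for a fixed seed.
    """
    h, w = shape
    x, y = tip_px
    margin = tube_width_px
    if not (margin <= x < w - margin and margin <= y < h - margin - tube_width_px):
        raise ValueError(f"tip {tip_px} too close to the frame edge for shape {shape}")
    img = np.full(shape, float(background))
    img[y : y + tube_width_px, : x + 1] = tube_gray
    if noise_level > 0:
        rng = np.random.default_rng(seed)
        img += rng.normal(0.0, noise_level * 255.0, shape)
    return np.clip(img, 0, 255).astype(np.uint8)


def detect_tip(
    image: np.ndarray,
    harris_k: float = 0.04,
    harris_sigma: float = 1.0,
    min_distance: int = 5,
) -> TipObservation:
    """Locate the tube tip: Otsu binarization, 3x3 dilation, Harris corners.

    Among the detected corners lying on the tube component, the one of
    maximal x is returned; ties within one pixel column are broken by
    Harris response.  Raises :class:`TipDetectionError` when the frame
    has no dark component or no corner.
    """
    img = np.asarray(image)
    if img.ndim != 2:
        raise ValueError("expected a single-channel grayscale image")
    imgf = img.astype(float)
    if np.ptp(imgf) < 1e-9:
        raise TipDetectionError("blank frame: no contrast to segment")
    thr = threshold_otsu(imgf)
    binary = imgf < thr  # tube is dark on a bright background
    if not binary.any():
        raise TipDetectionError("no dark component after binarization")
    binary = dilation(binary, footprint_rectangle((3, 3)))

    labels = label(binary)
    sizes = np.bincount(labels.ravel())
    sizes[0] = 0
    tube = labels == int(np.argmax(sizes))

    response = corner_harris(binary.astype(float), k=harris_k, sigma=harris_sigma)
    peaks = corner_peaks(response, min_distance=min_distance, threshold_rel=0.05)
    if peaks.size == 0:
        raise TipDetectionError("no Harris corner found")
    on_tube = [rc for rc in peaks if tube[rc[0], rc[1]]]
    if not on_tube:
        raise TipDetectionError("no corner on the tube component")
    xmax = max(c for _, c in on_tube)
    candidates = [rc for rc in on_tube if xmax - rc[1] <= 1]
    r, c = max(candidates, key=lambda rc: response[rc[0], rc[1]])
    return TipObservation(x_t=float(c), y_t=float(r))


def pixel_to_micron(px: float, optics: OpticsSpec) -> float:
    """Convert a pixel distance to microns for the given optics."""
    return px * optics.micron_per_pixel


class TipNoiseSampler:
    """Stream of tip-position noise in microns.

    Models the frame-to-frame jitter of the detected tip corner (caused
    by fluid fluctuation around the immersed tube) as Gaussian pixel
    noise with standard deviation ``sigma_px``, converted to microns
    through the optics.  In practice ``sigma_px`` is estimated as the
    Bessel-corrected (n-1 denominator) sample standard deviation of a
    recorded pixel track of the stationary tip.
    """

    def __init__(self, sigma_px: float, optics: OpticsSpec, seed: int | None = 0):
        if sigma_px < 0:
            raise ValueError("sigma_px must be >= 0")
        self.sigma_px = sigma_px
        self.optics = optics
        self._rng = np.random.default_rng(seed)

    @property
    def sigma_um(self) -> float:
        return self.sigma_px * self.optics.micron_per_pixel

    def draw(self, n: int) -> np.ndarray:
        if self.sigma_px == 0:
            return np.zeros(n)
        return self._rng.normal(0.0, self.sigma_um, n)

    def __iter__(self):
        while True:
            yield float(self.draw(1)[0])


def tip_noise_sampler(
    sigma_px: float, optics: OpticsSpec, seed: int | None = 0
) -> TipNoiseSampler:
    """Convenience constructor for :class:`TipNoiseSampler`."""
    return TipNoiseSampler(sigma_px, optics, seed)
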