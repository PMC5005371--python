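"""Radiometric image processing: emissivity handling, sharpening,
histogram thresholding, edge removal, and per-day aggregation.

The processing chain mirrors a greenhouse monitoring platform in which a
potted conifer seedling stands between black heating plates (held near
40 degC, hotter than any transpiring canopy) with fixed wet and dry
reference targets in every frame.  Plant tissue is separated from the
heated background by intermodes histogram thresholding of an
unsharp-masked image; mixed pixels along the needle edges are removed via
a gradient-magnitude cut; median temperatures per region are then read
from the *original* raster and emissivity-corrected.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

ABSOLUTE_ZERO_C = -273.15

__all__ = [
    "ThermalImage",
    "SegmentationConfig",
    "SegmentationResult",
    "estimate_emissivity",
    "correct_emissivity",
    "unsharp_mask",
    "intermodes_threshold",
    "detect_edges",
    "segment_scene",
    "aggregate_daily",
    "read_thermal_image",
    "write_thermal_image",
]


@dataclass
class ThermalImage:
    """Single-band surface-temperature raster in degC.

    ``capture_emissivity`` is the emission coefficient the camera was set
    to at acquisition (1.0 in the monitoring protocol; per-region
    correction happens later in :func:`segment_scene`).
    """

    grid: np.ndarray
    capture_emissivity: float = 1.0
    timestamp: Optional[str] = None

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        if self.grid.ndim != 2 or min(self.grid.shape) < 32:
            raise ValueError("temperature grid must be 2-D and at least 32x32")
        if not np.isfinite(self.grid).all():
            raise ValueError("temperature grid contains non-finite values")
        if not (0 < self.capture_emissivity <= 1):
            raise ValueError("capture emissivity must lie in (0, 1]")


@dataclass
class SegmentationConfig:
    unsharp_radius: float = 2.0
    unsharp_weight: float = 0.9
    edge_dilation_px: int = 1
    histogram_bins: int = 256
    #: per-region emission coefficients (wet/dry references and pine canopy)
    emissivities: Mapping[str, float] = field(
        default_factory=lambda: {"canopy": 0.90, "wet": 0.95, "dry": 0.93}
    )
    min_region_pixels: int = 25
    #: minimum plant/background temperature span; the heated plates are held
    #: ~10 degC above any transpiring canopy, so a scene without at least
    #: this much contrast cannot be segmented
    min_contrast_c: float = 2.0

    def __post_init__(self) -> None:
        if not (0 < self.unsharp_weight < 1):
            raise ValueError("unsharp weight must lie in (0, 1)")
        if self.unsharp_radius <= 0:
            raise ValueError("unsharp radius must be positive")
        if self.edge_dilation_px < 0:
            raise ValueError("edge dilation must be >= 0")
        for region, eps in self.emissivities.items():
            if not (0 < eps <= 1):
                raise ValueError(f"emissivity for {region!r} must lie in (0, 1]")


@dataclass
class SegmentationResult:
    """Masks and emissivity-corrected median temperatures per region.

    ``threshold_used`` is on the scale of the sharpened image the masks
    were built from (``threshold_scale``); medians are always read from
    the original raster.  Regions with fewer than the configured minimum
    pixel count are listed in ``flags``.
    """

    canopy_mask: np.ndarray
    wet_mask: np.ndarray
    dry_mask: np.ndarray
    background_mask: np.ndarray
    median_temps: Mapping[str, float]
    threshold_used: float
    n_pixels: Mapping[str, int]
    flags: tuple = ()
    threshold_scale: str = "sharpened"


def estimate_emissivity(t_contact: float, t_image: float) -> float:
    """Apparent emissivity from a contact-thermocouple / image temperature pair.

    Computed as the quotient of the two temperatures on the kelvin scale,
    ``(t_contact + 273.15) / (t_image + 273.15)`` — a temperature ratio is
    only physically meaningful in kelvin.  Values outside (0.5, 1.2] are
    flagged as suspect with a warning.
    """
    if not (np.isfinite(t_contact) and np.isfinite(t_image)):
        raise ValueError("non-finite temperature input")
    if t_contact < ABSOLUTE_ZERO_C or t_image <= ABSOLUTE_ZERO_C:
        raise ValueError("temperature below absolute zero")
    eps = (t_contact - ABSOLUTE_ZERO_C) / (t_image - ABSOLUTE_ZERO_C)
    if not (0.5 < eps <= 1.2):
        warnings.warn(f"suspect emissivity estimate {eps:.3f}", stacklevel=2)
    return eps


def correct_emissivity(image_or_value, emissivity: float):
    """Correct apparent temperature(s) acquired at unit emissivity.

    The emission coefficient is the contact/image kelvin quotient from
    :func:`estimate_emissivity`, so the correction is the inverse of that
    calibration: corrected kelvin temperature = apparent kelvin
    temperature times the coefficient; result returned in degC.  Identity
    at emissivity 1, monotone increasing in the apparent temperature, and
    ``correct(t_image, estimate(t_contact, t_image)) == t_contact``
    exactly.
    """
    if emissivity <= 0:
        raise ValueError("emissivity must be positive")
    t = np.asarray(image_or_value, dtype=float)
    out = (t - ABSOLUTE_ZERO_C) * emissivity + ABSOLUTE_ZERO_C
    return out if out.ndim else float(out)


def unsharp_mask(image: np.ndarray, radius: float = 2.0, weight: float = 0.9) -> np.ndarray:
    """Sharpen by subtracting a weighted Gaussian blur.

    ``S = (I - w * G_sigma(I)) / (1 - w)`` with ``sigma = radius`` and
    reflective boundary handling; this is the standard definition of the
    unsharp-mask command of common image-analysis tools.  Constant images
    are unchanged.
    """
    if not (0 < weight < 1):
        raise ValueError("mask weight must lie in (0, 1)")
    if radius <= 0:
        raise ValueError("radius must be positive")
    img = np.asarray(image, dtype=float)
    blurred = ndimage.gaussian_filter(img, sigma=radius, mode="reflect")
    return (img - weight * blurred) / (1.0 - weight)


def _run_maxima(h) -> list:
    """Local-maximum positions of a histogram; an equal-valued plateau
    counts once, at its central bin."""
    n = len(h)
    maxima = []
    i = 0
    while i < n:
        j = i
        while j + 1 < n and h[j + 1] == h[i]:
            j += 1
        left = h[i - 1] if i > 0 else -1
        right = h[j + 1] if j + 1 < n else -1
        if h[i] > left and h[i] > right and h[i] > 0:
            maxima.append((i + j) // 2)
        i = j + 1
    return maxima


def intermodes_threshold(values, bins: int = 256, max_iter: int = 10_000) -> float:
    """Intermodes histogram threshold.

    The histogram (``bins`` equal-width bins over the data range) is
    repeatedly smoothed with the (1, 2, 1)/4 kernel until exactly two
    local maxima remain; the threshold is the midpoint of the two mode
    bin centers.  Smoothing is carried out in exact (unnormalized)
    integer arithmetic, so the mode positions are free of floating-point
    round-off at any iteration depth.  Raises ``ValueError("not
    bimodal")`` when the histogram collapses to a single mode (or never
    reaches two within the iteration cap), and on constant input.
    """
    vals = np.asarray(values, dtype=float).ravel()
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise ValueError("no finite values to threshold")
    lo, hi = vals.min(), vals.max()
    if hi <= lo:
        raise ValueError("constant input: histogram has zero range")
    hist, edges = np.histogram(vals, bins=bins, range=(lo, hi))
    centers = 0.5 * (edges[:-1] + edges[1:])

    def smooth(hh):
        return [
            (hh[i - 1] if i > 0 else 0) + 2 * hh[i] + (hh[i + 1] if i + 1 < len(hh) else 0)
            for i in range(len(hh))
        ]

    # a two-mode state must survive further smoothing passes, so transient
    # noise maxima in a unimodal histogram are not mistaken for genuine
    # bimodality (genuinely bimodal histograms stay two-mode for hundreds
    # of passes before their lobes merge)
    stability = 50
    h = [int(x) for x in hist]
    for _ in range(max_iter):
        modes = _run_maxima(h)
        if len(modes) < 2:
            raise ValueError("not bimodal")
        if len(modes) == 2:
            probe = h
            stable = True
            for _ in range(stability):
                probe = smooth(probe)
                if len(_run_maxima(probe)) != 2:
                    stable = False
                    break
            if stable:
                return float(0.5 * (centers[modes[0]] + centers[modes[1]]))
        h = smooth(h)
    raise ValueError("not bimodal")


def detect_edges(image: np.ndarray) -> np.ndarray:
    """Sobel gradient magnitude ``sqrt(Gx^2 + Gy^2)``, reflective boundaries."""
    img = np.asarray(image, dtype=float)
    if img.ndim != 2 or min(img.shape) < 3:
        raise ValueError("image must be 2-D and at least 3x3")
    gx = ndimage.sobel(img, axis=1, mode="reflect")
    gy = ndimage.sobel(img, axis=0, mode="reflect")
    return np.hypot(gx, gy)


def _rect_mask(shape, rect) -> np.ndarray:
    r0, c0, r1, c1 = (int(v) for v in rect)
    if not (0 <= r0 < r1 <= shape[0] and 0 <= c0 < c1 <= shape[1]):
        raise ValueError(f"reference rectangle {rect} outside image of shape {shape}")
    m = np.zeros(shape, dtype=bool)
    m[r0:r1, c0:c1] = True
    return m


def _reference_median(grid: np.ndarray, mask: np.ndarray) -> float:
    # discard the upper temperature decile to drop rims and shadows
    px = grid[mask]
    keep = px[px <= np.quantile(px, 0.9)]
    return float(np.median(keep if keep.size else px))


def segment_scene(
    image: ThermalImage,
    config: SegmentationConfig,
    region_layout: Mapping[str, Sequence[int]],
    *,
    remove_edges: bool = True,
) -> SegmentationResult:
    """Segment canopy / wet / dry / background and extract median temperatures.

    ``region_layout`` gives the fixed rectangles ``{"wet": (r0, c0, r1, c1),
    "dry": ...}`` of the reference hardware (row/col, half-open).  The canopy
    is searched everywhere outside those rectangles: the sharpened image is
    intermodes-thresholded, pixels *below* the threshold are kept (the
    heated plates are hotter than any transpiring canopy), and — when
    ``remove_edges`` — pixels under the dilated high-gradient mask (Otsu
    split of gradient magnitudes within the kept set) are discarded as
    plant/background mixtures.  Medians are read from the original raster
    and emissivity-corrected per region.  Reference medians drop the upper
    temperature decile of their rectangle first.
    """
    grid = image.grid
    wet_mask = _rect_mask(grid.shape, region_layout["wet"])
    dry_mask = _rect_mask(grid.shape, region_layout["dry"])
    if (wet_mask & dry_mask).any():
        raise ValueError("wet and dry reference rectangles overlap")
    search = ~(wet_mask | dry_mask)

    sharp = unsharp_mask(grid, config.unsharp_radius, config.unsharp_weight)
    # Saturate unsharp overshoot at the radiometric range of the original
    # raster before histogramming, as an 8-bit display-scaled conversion
    # would: overshoot beyond the measured temperature range carries no
    # information and would otherwise dominate the histogram span.
    lo, hi = float(grid[search].min()), float(grid[search].max())
    if hi - lo < config.min_contrast_c:
        raise ValueError(
            "not bimodal: search region spans "
            f"{hi - lo:.2f} degC, below the {config.min_contrast_c:.2f} degC "
            "plant/background contrast the segmentation assumes"
        )
    sharp = np.clip(sharp, lo, hi)
    threshold = intermodes_threshold(sharp[search], config.histogram_bins)
    candidate = search & (sharp < threshold)
    if not candidate.any():
        raise ValueError("no plant pixels below threshold")

    canopy_mask = candidate
    if remove_edges:
        grad = detect_edges(sharp)
        cand_grads = grad[candidate]
        if np.ptp(cand_grads) > 0:
            cut = threshold_otsu(cand_grads)
            high = grad > cut
            if config.edge_dilation_px > 0:
                high = ndimage.binary_dilation(high, iterations=config.edge_dilation_px)
            canopy_mask = candidate & ~high
    if not canopy_mask.any():
        raise ValueError("no plant pixels after edge removal")

    eps = config.emissivities
    medians = {
        "canopy": float(
            correct_emissivity(np.median(grid[canopy_mask]), eps.get("canopy", 1.0))
        ),
        "wet": float(correct_emissivity(_reference_median(grid, wet_mask), eps.get("wet", 1.0))),
        "dry": float(correct_emissivity(_reference_median(grid, dry_mask), eps.get("dry", 1.0))),
    }
    n_pixels = {
        "canopy": int(canopy_mask.sum()),
        "wet": int(wet_mask.sum()),
        "dry": int(dry_mask.sum()),
    }
    flags = tuple(
        f"{region}: only {n} pixels"
        for region, n in n_pixels.items()
        if n < config.min_region_pixels
    )
    background = ~(canopy_mask | wet_mask | dry_mask)
    return SegmentationResult(
        canopy_mask=canopy_mask,
        wet_mask=wet_mask,
        dry_mask=dry_mask,
        background_mask=background,
        median_temps=medians,
        threshold_used=threshold,
        n_pixels=n_pixels,
        flags=flags,
    )


def aggregate_daily(replicate_results: Sequence[Optional[SegmentationResult]]) -> dict:
    """Per-day mean of replicate median temperatures per region.

    Each measuring day contributes 1-3 replicate images of the same tree;
    failed replicates may be passed as ``None`` and are skipped with a
    warning.  Raises if no usable replicate remains.
    """
    usable = [r for r in replicate_results if r is not None]
    n_skipped = len(replicate_results) - len(usable)
    if n_skipped:
        warnings.warn(f"skipped {n_skipped} failed replicate(s)", stacklevel=2)
    if not usable:
        raise ValueError("no usable replicates for daily aggregation")
    if len(replicate_results) > 3:
        raise ValueError("at most 3 replicates per tree and day")
    regions = usable[0].median_temps.keys()
    out = {
        region: float(np.mean([r.median_temps[region] for r in usable]))
        for region in regions
    }
    out["n_replicates"] = len(usable)
    return out


def read_thermal_image(path) -> ThermalImage:
    """Read a single-band floating-point TIFF or CSV temperature grid (degC)."""
    path = str(path)
    if path.endswith((".tif", ".tiff")):
        import tifffile

        grid = tifffile.imread(path).astype(float)
    else:
        grid = np.loadtxt(path, delimiter=",")
    return ThermalImage(grid=grid)


def write_thermal_image(image_or_grid, path) -> None:
    """Write a temperature grid as 32-bit float TIFF (or CSV by extension)."""
    grid = image_or_grid.grid if isinstance(image_or_grid, ThermalImage) else image_or_grid
    grid = np.asarray(grid, dtype=np.float32)
    path = str(path)
    if path.endswith((".tif", ".tiff")):
        import tifffile

        tifffile.imwrite(path, grid)
    else:
        np.savetxt(path, grid, delimiter=",", fmt="%.4f")
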