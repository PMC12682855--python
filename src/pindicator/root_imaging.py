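"""Rhizotron image chain: panorama, denoise, segment, clean, measure.

Rotating cylindrical rhizotrons are photographed from six angles at 60
degree intervals; the views are registered by horizontal translation and
merged into a 360-degree panorama.  The panorama is denoised by truncated
SVD (best low-rank approximation), roots are segmented by a Laplacian of
Gaussian (LoG) band-pass at a chosen scale binarized with Otsu's threshold,
artefacts are removed by keeping the largest connected component anchored
at the top of the image (roots grow downward from the seed), and the
projected root area is the count of foreground pixels times the square of
a pixel-size coefficient.

The default coefficient is 0.0042 length-units per pixel, kept configurable;
note that at a true 600 dpi resolution the physical pixel pitch would be
25.4/600 ~ 0.0423 mm, an order of magnitude larger.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, interpolate
from skimage.filters import threshold_otsu
from skimage.measure import label

__all__ = [
    "ViewStack",
    "RootAreaSeries",
    "GrowthSpline",
    "estimate_view_offsets",
    "stitch_panorama",
    "svd_denoise",
    "segment_roots",
    "clean_top_connected",
    "projected_area",
    "measure_root_area",
    "fit_growth_spline",
]

#: Default pixel-to-length conversion coefficient (length units per pixel).
DEFAULT_PIXEL_COEFF = 0.0042


@dataclass
class ViewStack:
    """Six grayscale views of one tube at 60-degree intervals.

    Views are float arrays with intensities in [0, 1] and identical shape.
    """

    views: tuple[np.ndarray, ...]
    tube_id: str = ""
    timestamp: float = 0.0
    pixel_coeff: float = DEFAULT_PIXEL_COEFF

    def __post_init__(self) -> None:
        views = tuple(np.asarray(v, dtype=float) for v in self.views)
        if len(views) != 6:
            raise ValueError(f"expected exactly six views, got {len(views)}")
        shape = views[0].shape
        if any(v.shape != shape for v in views):
            raise ValueError("views must share dimensions")
        for v in views:
            if v.min() < 0 or v.max() > 1:
                raise ValueError("view intensities must lie in [0, 1]")
        object.__setattr__(self, "views", views)


@dataclass
class RootAreaSeries:
    """Projected root area of one tube over time.

    ``areas_px`` are foreground pixel counts; ``areas`` the converted
    areas (``count * coeff^2``).  Times must be strictly increasing.
    """

    tube_id: str
    times: np.ndarray
    areas_px: np.ndarray
    pixel_coeff: float = DEFAULT_PIXEL_COEFF

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.areas_px = np.asarray(self.areas_px, dtype=float)
        if self.times.shape != self.areas_px.shape:
            raise ValueError("times and areas must align")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.areas_px < 0):
            raise ValueError("areas must be >= 0")

    @property
    def areas(self) -> np.ndarray:
        return self.areas_px * self.pixel_coeff**2


def _column_profile(image: np.ndarray) -> np.ndarray:
    return np.asarray(image, dtype=float).mean(axis=0)


def _overlap_between(left: np.ndarray, right: np.ndarray, max_overlap: int) -> int:
    """Best overlap (px) between adjacent views by 1-D normalized x-corr.

    Correlates the trailing columns of ``left`` with the leading columns of
    ``right`` over candidate overlaps; returns 0 when no candidate shows a
    meaningful correlation (e.g. featureless views).
    """
    a = _column_profile(left)
    b = _column_profile(right)
    min_overlap = 8  # NCC on shorter windows is not discriminative
    scores = {}
    for o in range(min_overlap, max_overlap + 1):
        sa, sb = a[-o:], b[:o]
        va, vb = sa.std(), sb.std()
        if va == 0 or vb == 0:
            continue
        scores[o] = float(np.mean((sa - sa.mean()) * (sb - sb.mean())) / (va * vb))
    if not scores:
        return 0  # featureless strips: fall back to plain concatenation
    best_c = max(scores.values())
    if best_c < 0.30:  # nothing resembling a real overlap
        return 0
    # among near-ties prefer the largest overlap: with genuinely repeated
    # columns every sub-window of the true overlap also correlates highly
    return max(o for o, c in scores.items() if c >= best_c - 0.02)


def estimate_view_offsets(views, max_overlap: int | None = None) -> np.ndarray:
    """Horizontal start positions of each view on the panorama canvas."""
    views = [np.asarray(v, dtype=float) for v in views]
    w = views[0].shape[1]
    if any(v.shape != views[0].shape for v in views):
        raise ValueError("views must share dimensions")
    if max_overlap is None:
        max_overlap = w // 2
    offsets = [0]
    for left, right in zip(views, views[1:]):
        o = _overlap_between(left, right, max_overlap)
        offsets.append(offsets[-1] + w - o)
    return np.asarray(offsets, dtype=int)


def stitch_panorama(stack: ViewStack | list, max_overlap: int | None = None) -> np.ndarray:
    """Merge six rotational views into one panorama.

    Offsets come from :func:`estimate_view_offsets`; overlapping columns
    are averaged.  With zero estimated overlap this degenerates to plain
    concatenation.  Deterministic.
    """
    views = stack.views if isinstance(stack, ViewStack) else [np.asarray(v, float) for v in stack]
    if len(views) != 6:
        raise ValueError("a panorama is built from exactly six views")
    h, w = views[0].shape
    offsets = estimate_view_offsets(views, max_overlap=max_overlap)
    width = int(offsets[-1]) + w
    acc = np.zeros((h, width))
    cnt = np.zeros((h, width))
    for off, v in zip(offsets, views):
        acc[:, off:off + w] += v
        cnt[:, off:off + w] += 1
    return acc / np.maximum(cnt, 1)


def svd_denoise(image: np.ndarray, rank: int) -> np.ndarray:
    """Best rank-``rank`` approximation of the image, clipped to [0, 1].

    By the Eckart-Young theorem this is the least-squares optimal low-rank
    reconstruction; approximation error is nonincreasing in rank.
    """
    image = np.asarray(image, dtype=float)
    if rank < 1:
        raise ValueError("rank must be >= 1")
    if rank > min(image.shape):
        raise ValueError("rank exceeds min(height, width)")
    u, s, vt = np.linalg.svd(image, full_matrices=False)
    approx = (u[:, :rank] * s[:rank]) @ vt[:rank]
    return np.clip(approx, 0.0, 1.0)


def segment_roots(
    image: np.ndarray,
    sigma: float = 2.0,
    threshold: str | float = "otsu",
    dark_roots: bool = True,
) -> np.ndarray:
    """Binary root mask from a LoG band-pass at scale ``sigma``.

    The LoG response of a grayscale image is positive on structures darker
    than their surroundings at the filter scale (the usual contrast of
    roots against a backlit tube); set ``dark_roots=False`` for inverted
    contrast — the response is negated, so an inverted image yields an
    identical mask.  Binarization is Otsu's threshold on the response, or
    a fixed numeric threshold.
    """
    image = np.asarray(image, dtype=float)
    if not np.isfinite(image).all():
        raise ValueError("non-finite pixels in input")
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    response = ndimage.gaussian_laplace(image, sigma=sigma)
    if not dark_roots:
        response = -response
    if np.ptp(response) == 0:  # featureless image: nothing to segment
        return np.zeros(image.shape, dtype=bool)
    if threshold == "otsu":
        thr = threshold_otsu(response)
    elif isinstance(threshold, (int, float)):
        thr = float(threshold)
    else:
        raise ValueError(f"unknown threshold method {threshold!r}")
    return response > thr


def clean_top_connected(
    mask: np.ndarray, top_fraction: float = 0.10, bridge_px: int = 3
) -> np.ndarray:
    """Keep the largest 8-connected component anchored in the top band.

    A component is "anchored" when its topmost pixel lies within the top
    ``top_fraction`` of rows — root systems hang from the seed at the top
    of the tube, while specks and reflections float lower.  Everything
    else is removed; the output is always a subset of the input.

    Thresholded masks of real root systems fragment at branch junctions;
    ``bridge_px`` closes gaps up to that many pixels when deciding
    connectivity (components are identified on a dilated copy, but output
    pixels come only from the input mask, so the subset property holds).
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return np.zeros_like(mask)
    support = (
        ndimage.binary_dilation(mask, structure=np.ones((3, 3), bool),
                                iterations=bridge_px)
        if bridge_px > 0
        else mask
    )
    labels = label(support, connectivity=2)
    band = max(1, int(np.ceil(top_fraction * mask.shape[0])))
    top_hits = np.unique(labels[:band][mask[:band]])
    top_hits = top_hits[top_hits != 0]
    if top_hits.size == 0:
        return np.zeros_like(mask)
    sizes = np.bincount(labels.ravel(), weights=mask.ravel().astype(float))
    keep = top_hits[np.argmax(sizes[top_hits])]
    return mask & (labels == keep)


def projected_area(mask: np.ndarray, coeff: float = DEFAULT_PIXEL_COEFF) -> tuple[int, float]:
    """Foreground pixel count and its converted area (count * coeff^2)."""
    if coeff <= 0:
        raise ValueError("coeff must be > 0")
    count = int(np.count_nonzero(np.asarray(mask, dtype=bool)))
    return count, count * coeff * coeff


def measure_root_area(
    image: np.ndarray,
    sigma: float = 2.0,
    rank: int | None = None,
    coeff: float = DEFAULT_PIXEL_COEFF,
    dark_roots: bool = True,
    top_fraction: float = 0.10,
) -> tuple[int, float, np.ndarray]:
    """Full chain on one image: optional denoise, segment, clean, measure.

    Returns (pixel count, converted area, cleaned mask).  SVD denoising
    (``rank`` not None) suppresses structured sensor noise, but thin
    oblique roots are themselves far from low-rank, so it is off by
    default and should only be enabled with a generous rank.
    """
    if rank is not None:
        image = svd_denoise(image, min(rank, min(image.shape)))
    mask = segment_roots(image, sigma=sigma, dark_roots=dark_roots)
    mask = clean_top_connected(mask, top_fraction=top_fraction)
    count, area = projected_area(mask, coeff)
    return count, area, mask


@dataclass
class GrowthSpline:
    """Least-squares B-spline fit of a root-area time series."""

    spline: interpolate.BSpline
    t_min: float
    t_max: float

    def __call__(self, t) -> np.ndarray:
        return self.spline(np.asarray(t, dtype=float))

    def derivative(self, t) -> np.ndarray:
        return self.spline.derivative()(np.asarray(t, dtype=float))


def fit_growth_spline(series: RootAreaSeries, df: int = 6, degree: int = 3) -> GrowthSpline:
    """Descriptive B-spline fit of projected area over time.

    ``df`` is the basis dimension (number of B-spline coefficients);
    interior knots are placed at quantiles of the observation times.
    Requires at least ``df + 1`` observations.
    """
    t, y = series.times, series.areas_px.astype(float)
    if df <= degree:
        raise ValueError(f"df must exceed the spline degree ({degree})")
    if t.size < df + 1:
        raise ValueError(f"need at least df+1={df + 1} time points, got {t.size}")
    n_interior = df - degree - 1
    if n_interior > 0:
        qs = np.linspace(0, 1, n_interior + 2)[1:-1]
        interior = np.quantile(t, qs)
    else:
        interior = np.array([])
    knots = np.concatenate([np.repeat(t[0], degree + 1), interior,
                            np.repeat(t[-1], degree + 1)])
    spl = interpolate.make_lsq_spline(t, y, knots, k=degree)
    return GrowthSpline(spline=spl, t_min=float(t[0]), t_max=float(t[-1]))
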