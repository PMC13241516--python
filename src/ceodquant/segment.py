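"""Two-channel segmentation of extract-in-oil droplets and their condensates.

Droplets ("mothers") are detected on the reporter channel that fills every
droplet: Gaussian smoothing, intensity threshold (fixed or Otsu), hole
filling and connected-component labelling.  Condensates ("children") are
detected on the marker channel: median-filter denoising, rolling-ball
background subtraction and a fixed intensity threshold interpreted on an
8-bit-equivalent scale.  Each condensate is then attributed to the droplet
that contains it.

Conventions
-----------
Images are 2-D, row-major, 0-based, with pixel centers at integer
coordinates.  Physical measurements are expressed in micrometres through
the grid's ``pixel_size_um``.  Connected components use 8-connectivity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import ndimage as ndi
from skimage import filters, measure, morphology, segmentation as skseg

logger = logging.getLogger(__name__)

#: Sentinel parent label for a condensate that overlaps no droplet.
ORPHAN = -1


class SegmentationError(ValueError):
    """Raised for invalid segmentation inputs or parameters."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class PixelGrid:
    """A 2-D intensity image with a physical pixel size.

    Parameters
    ----------
    values
        Non-negative intensity array, shape ``(height, width)``.
    pixel_size_um
        Side length of one pixel in micrometres (> 0).
    bit_depth
        Storage bit depth, 8 or 16.  Fixed thresholds quoted on the
        conventional 8-bit display scale are rescaled according to this.
    """

    values: np.ndarray
    pixel_size_um: float
    bit_depth: int = 16

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2 or min(self.values.shape) < 1:
            raise SegmentationError(
                f"expected a 2-D image, got shape {self.values.shape}"
            )
        if self.pixel_size_um <= 0:
            raise SegmentationError("pixel_size_um must be > 0")
        if self.bit_depth not in (8, 16):
            raise SegmentationError("bit_depth must be 8 or 16")
        vmax = float(self.values.max(initial=0.0))
        if float(self.values.min(initial=0.0)) < 0 or vmax > 2 ** self.bit_depth - 1:
            raise SegmentationError(
                f"intensities must lie in [0, {2 ** self.bit_depth - 1}]"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape  # type: ignore[return-value]


@dataclass
class SegmentationParams:
    """Tunable parameters of the two-channel segmentation.

    ``condensate_threshold`` follows the convention of quoting condensate
    thresholds on an 8-bit display scale (default 60); it is rescaled by
    257 = (2^16-1)/(2^8-1) for 16-bit input so that the same setting is
    comparable across bit depths.
    """

    droplet_gaussian_sigma_px: float = 2.0
    droplet_threshold: float | str = "auto"
    droplet_min_area_um2: float = 50.0
    exclude_border: bool = True
    condensate_denoise_radius_px: int = 2
    rolling_ball_radius_px: int = 50
    condensate_threshold: float = 60.0
    condensate_min_area_px: int = 5
    threshold_scale: str = "8bit"   # "8bit" (rescale for 16-bit input) or "raw"

    def __post_init__(self) -> None:
        if self.droplet_gaussian_sigma_px < 0:
            raise SegmentationError("droplet_gaussian_sigma_px must be >= 0")
        if self.droplet_min_area_um2 < 0 or self.condensate_min_area_px < 0:
            raise SegmentationError("minimum areas must be >= 0")
        if self.condensate_denoise_radius_px < 0:
            raise SegmentationError("condensate_denoise_radius_px must be >= 0")
        if self.rolling_ball_radius_px <= 0:
            raise SegmentationError("rolling_ball_radius_px must be > 0")
        if self.threshold_scale not in ("8bit", "raw"):
            raise SegmentationError("threshold_scale must be '8bit' or 'raw'")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SegmentationParams":
        return cls(**d)

    def condensate_threshold_for(self, grid: PixelGrid) -> float:
        """Condensate threshold on the grid's native intensity scale."""
        if self.threshold_scale == "raw" or grid.bit_depth == 8:
            return float(self.condensate_threshold)
        return float(self.condensate_threshold) * (2 ** 16 - 1) / (2 ** 8 - 1)


@dataclass
class LabelMap:
    """Integer label image: 0 = background, k > 0 = object k.

    Labels are consecutive ``1..K`` in top-left scan order of each object's
    first pixel; every object is 8-connected.
    """

    labels: np.ndarray
    pixel_size_um: float

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise SegmentationError("label map must be 2-D")
        if self.pixel_size_um <= 0:
            raise SegmentationError("pixel_size_um must be > 0")

    @property
    def n_labels(self) -> int:
        return int(self.labels.max(initial=0))

    @property
    def label_ids(self) -> list[int]:
        return list(range(1, self.n_labels + 1))


@dataclass
class ParentMap:
    """Mapping from condensate (child) label to droplet (parent) label.

    A child that overlaps no droplet maps to :data:`ORPHAN`.
    """

    child_to_parent: dict[int, int] = field(default_factory=dict)

    def parent_of(self, child: int) -> int:
        return self.child_to_parent[child]

    @property
    def n_orphans(self) -> int:
        return sum(1 for p in self.child_to_parent.values() if p == ORPHAN)


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def _drop_small_components(binary: np.ndarray, min_area_px: float) -> np.ndarray:
    """Remove 8-connected components with pixel count < ``min_area_px``."""
    lab = measure.label(binary, connectivity=2)
    if lab.max() == 0:
        return binary
    sizes = np.bincount(lab.ravel())
    keep = sizes >= min_area_px
    keep[0] = False
    return keep[lab]


def _relabel_scan_order(binary_or_labels: np.ndarray) -> np.ndarray:
    """Label 8-connected components, numbered by first-pixel scan order.

    ``skimage.measure.label`` already assigns labels in raster-scan order of
    each component's first-encountered pixel, but after object removal the
    numbering can have gaps; this compacts it.
    """
    lab = measure.label(binary_or_labels > 0, connectivity=2)
    return lab.astype(np.int32)


def _disk_rank_filter(img: np.ndarray, radius: int, minimum: bool) -> np.ndarray:
    """Exact flat-disk grayscale erosion (``minimum=True``) or dilation.

    The disk footprint {(dy, dx): dy² + dx² <= r²} is a union of horizontal
    segments, one per row, so the 2-D min/max decomposes into one 1-D
    sliding min/max per row offset followed by a vertical reduction.  This
    is O(r) fast 1-D passes instead of an O(r²) neighbourhood per pixel,
    and pixels outside the image are ignored (identity-padding), matching a
    brute-force in-bounds neighbourhood scan.
    """
    h = img.shape[0]
    pad = np.inf if minimum else -np.inf
    filt = ndi.minimum_filter1d if minimum else ndi.maximum_filter1d
    reduce_ = np.minimum if minimum else np.maximum
    out = np.full_like(img, pad)
    for dy in range(-radius, radius + 1):
        wx = int(np.floor(np.sqrt(radius * radius - dy * dy)))
        row = filt(img, size=2 * wx + 1, axis=1, mode="constant", cval=pad)
        if dy >= 0:
            reduce_(out[: h - dy], row[dy:], out=out[: h - dy])
        else:
            reduce_(out[-dy:], row[: h + dy], out=out[-dy:])
    return out


def subtract_background_rolling_ball(grid: PixelGrid, radius_px: int) -> PixelGrid:
    """Remove smooth background by a rolling-ball correction.

    The background is estimated as the grayscale morphological opening of
    the image by a disk structuring element of the given radius (erosion
    then dilation) and subtracted; bright structures narrower than the ball
    survive with their height above local background, while any structure
    the ball can roll under (including a constant offset) is removed
    entirely.

    The output is non-negative and everywhere ``<=`` the input.
    """
    radius_px = int(radius_px)
    if radius_px < 1:
        raise SegmentationError("rolling-ball radius must be >= 1 px")
    h, w = grid.shape
    if 2 * radius_px + 1 > 2 * max(h, w):
        raise SegmentationError(
            f"rolling-ball radius {radius_px} px exceeds image extent {grid.shape}"
        )
    img = grid.values.astype(np.float64)
    background = _disk_rank_filter(
        _disk_rank_filter(img, radius_px, minimum=True), radius_px, minimum=False
    )
    out = img - background
    # Opening is anti-extensive, so the residual is >= 0 up to float round-off.
    np.clip(out, 0.0, None, out=out)
    return PixelGrid(out, grid.pixel_size_um, grid.bit_depth)


def segment_droplets(reporter: PixelGrid, params: SegmentationParams) -> LabelMap:
    """Detect droplets on the reporter channel.

    Gaussian smoothing, intensity threshold (Otsu when ``"auto"``), hole
    filling, 8-connected labelling, then removal of components smaller than
    ``droplet_min_area_um2`` and, when ``exclude_border`` is set, of
    components touching the image border (truncated droplets bias area
    fractions).  An all-background result is an empty map, not an error.
    """
    img = reporter.values.astype(np.float64)
    if params.droplet_gaussian_sigma_px > 0:
        img = ndi.gaussian_filter(img, sigma=params.droplet_gaussian_sigma_px)

    if params.droplet_threshold == "auto":
        if np.ptp(img) == 0:
            return LabelMap(np.zeros(reporter.shape, np.int32), reporter.pixel_size_um)
        thr = filters.threshold_otsu(img)
    else:
        thr = float(params.droplet_threshold)  # type: ignore[arg-type]
        if not 0 <= thr <= 2 ** reporter.bit_depth - 1:
            raise SegmentationError(
                f"droplet threshold {thr} outside intensity range of "
                f"{reporter.bit_depth}-bit data"
            )

    binary = img > thr
    binary = ndi.binary_fill_holes(binary)
    if params.exclude_border:
        binary = skseg.clear_border(binary)

    min_area_px = params.droplet_min_area_um2 / reporter.pixel_size_um ** 2
    if min_area_px > 0:
        binary = _drop_small_components(binary, min_area_px)
    return LabelMap(_relabel_scan_order(binary), reporter.pixel_size_um)


def segment_condensates(marker: PixelGrid, params: SegmentationParams) -> LabelMap:
    """Detect condensates on the marker channel.

    Median-filter denoising, rolling-ball background subtraction, then a
    fixed intensity threshold (quoted on the 8-bit-equivalent scale and
    rescaled for 16-bit input) and 8-connected labelling; components below
    ``condensate_min_area_px`` are discarded.  Condensates may be thin or
    irregular, so no hole filling is applied.
    """
    grid = marker
    if params.condensate_denoise_radius_px > 0:
        den = ndi.median_filter(
            grid.values.astype(np.float64),
            footprint=morphology.disk(params.condensate_denoise_radius_px),
        )
        grid = PixelGrid(den, grid.pixel_size_um, grid.bit_depth)
    grid = subtract_background_rolling_ball(grid, params.rolling_ball_radius_px)

    thr = params.condensate_threshold_for(marker)
    binary = grid.values > thr
    if params.condensate_min_area_px > 0:
        binary = _drop_small_components(binary, params.condensate_min_area_px)
    return LabelMap(_relabel_scan_order(binary), marker.pixel_size_um)


def assign_condensates(droplet_labels: LabelMap, condensate_labels: LabelMap) -> ParentMap:
    """Attribute each condensate to the droplet that contains it.

    The parent is the droplet label under the condensate's (intensity-
    unweighted) centroid pixel; when that pixel is background the droplet
    with the largest pixel overlap is used instead, and a condensate with
    no overlap at all is mapped to :data:`ORPHAN`.  Each child receives
    exactly one parent.
    """
    if droplet_labels.labels.shape != condensate_labels.labels.shape:
        raise SegmentationError(
            f"dimension mismatch: droplets {droplet_labels.labels.shape} vs "
            f"condensates {condensate_labels.labels.shape}"
        )
    drop = droplet_labels.labels
    cond = condensate_labels.labels
    mapping: dict[int, int] = {}
    for child in condensate_labels.label_ids:
        rows, cols = np.nonzero(cond == child)
        cy = int(round(float(rows.mean())))
        cx = int(round(float(cols.mean())))
        parent = int(drop[cy, cx])
        if parent == 0:
            overlapped = drop[rows, cols]
            overlapped = overlapped[overlapped > 0]
            if overlapped.size:
                counts = np.bincount(overlapped)
                parent = int(counts.argmax())
            else:
                parent = ORPHAN
        mapping[child] = parent
    return ParentMap(mapping)
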