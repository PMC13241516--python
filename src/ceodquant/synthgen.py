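"""Synthetic two-channel emulsion micrographs with ground truth.

Emulates equatorial-plane fluorescence images of water-in-oil droplets that
encapsulate translation-competent cytosolic extract: the reporter channel
shows a uniform fill in every droplet (brighter in larger droplets, matching
the observed positive intensity-diameter correlation), and the marker
channel shows a dim droplet fill plus bright irregular condensates in a
stress-dependent fraction of droplets.  Droplet diameters are log-normal
with a median of ~25.3 um under the default parameters.  Every scene comes
with exact ground truth (droplet discs, condensate pixel masks) so the
segmentation, assignment and morphometry stages can be tested end to end
without any external data.

All randomness flows from a single seed in :class:`SceneConfig`; for a fixed
seed every output is bit-reproducible.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from scipy import ndimage as ndi
from skimage import draw, measure

from .segment import PixelGrid

logger = logging.getLogger(__name__)


class SceneError(ValueError):
    """Raised for invalid generator configuration or infeasible scenes."""


# ---------------------------------------------------------------------------
# Configuration and ground-truth records
# ---------------------------------------------------------------------------

@dataclass
class SceneConfig:
    """Parameters of one synthetic scene.

    Defaults describe a stressed condition at 20x-objective scale: a
    512x512 field at 0.65 um/px, droplet diameters log-normal with median
    ``exp(diam_log_mu)`` = 25.3 um and log-sd 0.45, reporter fill intensity
    increasing linearly with diameter, and 80% of droplets carrying one or
    more bright irregular condensates with target perimeters in 15-34 um.
    Intensities are on a 16-bit scale.
    """

    image_height_px: int = 512
    image_width_px: int = 512
    pixel_size_um: float = 0.65
    n_droplets: int = 25
    diam_log_mu: float = 3.2308       # exp(3.2308) = 25.30 um median diameter
    diam_log_sigma: float = 0.45
    intensity_base: float = 6000.0
    intensity_diameter_slope: float = 150.0   # a.u. per um of diameter
    fill_jitter_sd: float = 500.0
    condensate_prob: float = 0.8
    condensates_per_droplet_mean: float = 1.5
    condensate_perimeter_range_um: tuple[float, float] = (15.0, 34.0)
    condensate_intensity: float = 30000.0
    marker_fill_intensity: float = 3000.0
    background_level: float = 500.0
    noise_gaussian_sd: float = 100.0
    noise_poisson_scale: float = 0.05
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if min(self.image_height_px, self.image_width_px) < 1:
            raise SceneError("image dimensions must be positive")
        if self.pixel_size_um <= 0:
            raise SceneError("pixel_size_um must be > 0")
        if self.n_droplets < 0:
            raise SceneError("n_droplets must be >= 0")
        if self.diam_log_sigma < 0:
            raise SceneError("diam_log_sigma must be >= 0")
        if not 0.0 <= self.condensate_prob <= 1.0:
            raise SceneError("condensate_prob must lie in [0, 1]")
        if self.condensates_per_droplet_mean <= 0:
            raise SceneError("condensates_per_droplet_mean must be > 0")
        lo, hi = self.condensate_perimeter_range_um
        if not 0 < lo <= hi:
            raise SceneError("condensate_perimeter_range_um must satisfy 0 < low <= high")
        if self.noise_gaussian_sd < 0 or self.noise_poisson_scale < 0:
            raise SceneError("noise parameters must be >= 0")

    def to_json(self) -> str:
        d = asdict(self)
        d["condensate_perimeter_range_um"] = list(d["condensate_perimeter_range_um"])
        return json.dumps(d, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "SceneConfig":
        d = json.loads(text)
        if "condensate_perimeter_range_um" in d:
            d["condensate_perimeter_range_um"] = tuple(d["condensate_perimeter_range_um"])
        return cls(**d)


@dataclass
class DropletGroundTruth:
    """True position, size and fill of one generated droplet."""

    droplet_id: int
    center_x_um: float
    center_y_um: float
    radius_um: float
    fill_intensity: float
    condensate_ids: list[int] = field(default_factory=list)


@dataclass
class CondensateGroundTruth:
    """True pixel mask and morphology of one generated condensate."""

    condensate_id: int
    parent_droplet_id: int
    pixel_mask: set[tuple[int, int]]
    area_um2: float
    perimeter_um: float


@dataclass
class ChannelPair:
    """The two channels of one scene: reporter (droplet fill) and marker."""

    reporter: PixelGrid
    marker: PixelGrid

    def __post_init__(self) -> None:
        if self.reporter.shape != self.marker.shape:
            raise SceneError("reporter and marker channels must share dimensions")
        if self.reporter.pixel_size_um != self.marker.pixel_size_um:
            raise SceneError("reporter and marker channels must share pixel size")


@dataclass
class FrapTraceGroundTruth:
    """A simulated FRAP acquisition plus the parameters that generated it."""

    times_s: np.ndarray
    bleach_roi_intensity: np.ndarray
    reference_intensity: np.ndarray
    n_prebleach_frames: int
    true_rate_k_per_s: float
    true_plateau: float
    true_post_bleach_level: float


# ---------------------------------------------------------------------------
# Droplet and condensate sampling
# ---------------------------------------------------------------------------

def sample_droplets(
    config: SceneConfig, rng: np.random.Generator | None = None
) -> list[DropletGroundTruth]:
    """Place ``n_droplets`` non-overlapping droplet discs inside the image.

    Diameters are drawn log-normal(diam_log_mu, diam_log_sigma) in um; the
    per-droplet reporter fill is ``intensity_base + slope * diameter`` plus
    Gaussian jitter.  Placement is rejection sampling, largest droplet
    first; droplets are kept strictly inside the field with a small margin
    so no object is border-truncated.
    """
    rng = np.random.default_rng(config.rng_seed) if rng is None else rng
    if config.n_droplets == 0:
        return []

    h_um = config.image_height_px * config.pixel_size_um
    w_um = config.image_width_px * config.pixel_size_um
    margin_um = 2.0 * config.pixel_size_um
    gap_um = 2.0

    diameters = np.exp(rng.normal(config.diam_log_mu, config.diam_log_sigma,
                                  size=config.n_droplets))
    jitter = rng.normal(0.0, config.fill_jitter_sd, size=config.n_droplets)
    order = np.argsort(diameters)[::-1]   # pack large droplets first

    placed: list[tuple[float, float, float, float]] = []  # (cx, cy, r, fill)
    max_tries = 2000
    for idx in order:
        r = diameters[idx] / 2.0
        if 2 * r + 2 * margin_um >= min(h_um, w_um):
            raise SceneError(
                f"scene too crowded: droplet of diameter {2 * r:.1f} um does not "
                f"fit a {w_um:.0f} x {h_um:.0f} um field ({len(placed)} of "
                f"{config.n_droplets} placed)"
            )
        fill = config.intensity_base + config.intensity_diameter_slope * 2 * r + jitter[idx]
        fill = max(fill, config.background_level + 1.0)
        for _ in range(max_tries):
            cx = rng.uniform(r + margin_um, w_um - r - margin_um)
            cy = rng.uniform(r + margin_um, h_um - r - margin_um)
            if all(
                math.hypot(cx - ox, cy - oy) >= r + orr + gap_um
                for ox, oy, orr, _ in placed
            ):
                placed.append((cx, cy, r, fill))
                break
        else:
            raise SceneError(
                f"scene too crowded: placed {len(placed)} of {config.n_droplets} "
                "droplets within the retry budget"
            )
    return [
        DropletGroundTruth(
            droplet_id=i + 1, center_x_um=cx, center_y_um=cy,
            radius_um=r, fill_intensity=fill,
        )
        for i, (cx, cy, r, fill) in enumerate(placed)
    ]


def _perturbed_polygon_mask(
    shape_px: tuple[int, int],
    center_px: tuple[float, float],
    base_radius_px: float,
    rng: np.random.Generator,
    amplitude: float = 0.6,
    n_vertices: int = 72,
) -> np.ndarray:
    """Rasterize an irregular blob: a circle with random radial Fourier modes.

    The radial perturbation ``r(theta) = r0 * (1 + sum a_m cos(m theta + phi_m))``
    over modes m = 2..6 produces connected, lobed shapes whose circularity
    falls well below 1, matching the irregular outlines of stress-induced
    condensates.
    """
    modes = np.arange(2, 7)
    amps = rng.uniform(0.0, amplitude, size=modes.size) / np.sqrt(modes)
    phases = rng.uniform(0.0, 2 * np.pi, size=modes.size)
    theta = np.linspace(0.0, 2 * np.pi, n_vertices, endpoint=False)
    radial = 1.0 + sum(a * np.cos(m * theta + p) for a, m, p in zip(amps, modes, phases))
    radial = np.clip(radial, 0.3, None)
    r = base_radius_px * radial
    cy, cx = center_px
    rows = cy + r * np.sin(theta)
    cols = cx + r * np.cos(theta)
    rr, cc = draw.polygon(rows, cols, shape=shape_px)
    mask = np.zeros(shape_px, bool)
    mask[rr, cc] = True
    # keep the largest connected component (extreme perturbations can pinch off)
    lab, n = ndi.label(mask, structure=np.ones((3, 3), int))
    if n > 1:
        sizes = ndi.sum_labels(mask, lab, index=np.arange(1, n + 1))
        mask = lab == (1 + int(np.argmax(sizes)))
    return mask


def inject_condensates(
    droplets: list[DropletGroundTruth],
    config: SceneConfig,
    rng: np.random.Generator | None = None,
) -> list[CondensateGroundTruth]:
    """Give each droplet condensates with probability ``condensate_prob``.

    A selected droplet receives ``1 + Poisson(mean - 1)`` condensates.  Each
    condensate is an irregular radial-perturbation polygon whose target
    perimeter is drawn uniformly from ``condensate_perimeter_range_um``,
    rasterized strictly inside the parent disc; a condensate that cannot fit
    is shrunk and retried, then skipped with a warning.  Recorded area and
    perimeter are measured on the rasterized mask itself (4-direction
    Crofton perimeter), so ground truth and pipeline measurements share one
    geometry.
    """
    rng = np.random.default_rng(config.rng_seed + 1) if rng is None else rng
    px = config.pixel_size_um
    shape_px = (config.image_height_px, config.image_width_px)
    occupied = np.zeros(shape_px, bool)   # all accepted condensate masks
    out: list[CondensateGroundTruth] = []
    next_id = 1
    for drop in droplets:
        if rng.uniform() >= config.condensate_prob:
            continue
        n_cond = 1 + int(rng.poisson(max(config.condensates_per_droplet_mean - 1.0, 0.0)))
        r_drop_px = drop.radius_um / px
        cy_drop, cx_drop = drop.center_y_um / px, drop.center_x_um / px
        for _ in range(n_cond):
            perim_target = rng.uniform(*config.condensate_perimeter_range_um)
            # the radial perturbation lengthens the outline by ~1.34x at the
            # default amplitude; shrink the base circle so the realized
            # Crofton perimeter tracks the target interval
            r0_px = perim_target / (2 * np.pi) / 1.34 / px
            mask = None
            for attempt in range(60):
                r_eff = r0_px * 0.85 ** (attempt // 15)   # shrink-and-retry
                rho_max = r_drop_px - 2.0 - r_eff
                if rho_max <= 0:
                    continue
                rho = rho_max * math.sqrt(rng.uniform())
                ang = rng.uniform(0.0, 2 * np.pi)
                cy = cy_drop + rho * math.sin(ang)
                cx = cx_drop + rho * math.cos(ang)
                cand = _perturbed_polygon_mask(shape_px, (cy, cx), r_eff, rng)
                if cand.sum() < 4:
                    continue
                rows, cols = np.nonzero(cand)
                # exact containment: every pixel strictly inside the parent disc
                if np.max(np.hypot(rows - cy_drop, cols - cx_drop)) > r_drop_px - 1.0:
                    continue
                # keep siblings separable: 2-px dilated mask must stay clear
                dil = ndi.binary_dilation(cand, np.ones((3, 3), bool), iterations=2)
                if np.any(dil & occupied):
                    continue
                mask = cand
                break
            if mask is None:
                logger.warning(
                    "condensate does not fit droplet %d (radius %.1f um); skipped",
                    drop.droplet_id, drop.radius_um,
                )
                continue
            occupied |= mask
            area_um2 = float(mask.sum()) * px ** 2
            perim_um = float(measure.perimeter_crofton(mask, directions=4)) * px
            out.append(
                CondensateGroundTruth(
                    condensate_id=next_id,
                    parent_droplet_id=drop.droplet_id,
                    pixel_mask={(int(r), int(c)) for r, c in zip(*np.nonzero(mask))},
                    area_um2=area_um2,
                    perimeter_um=perim_um,
                )
            )
            drop.condensate_ids.append(next_id)
            next_id += 1
    return out


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------

def render_scene(
    droplets: list[DropletGroundTruth],
    condensates: list[CondensateGroundTruth],
    config: SceneConfig,
    rng: np.random.Generator | None = None,
) -> ChannelPair:
    """Render the two noisy channels from ground truth.

    Reporter: background plus each droplet's uniform fill.  Marker:
    background, a dim fill in every droplet and the bright condensate
    masks.  Both channels get a 1-px Gaussian optical blur, Poisson-scaled
    shot noise and additive Gaussian read noise, then are clipped to the
    16-bit range (clipping is logged).
    """
    rng = np.random.default_rng(config.rng_seed + 2) if rng is None else rng
    px = config.pixel_size_um
    shape = (config.image_height_px, config.image_width_px)
    reporter = np.full(shape, config.background_level, np.float64)
    marker = np.full(shape, config.background_level, np.float64)

    for drop in droplets:
        rr, cc = draw.disk(
            (drop.center_y_um / px, drop.center_x_um / px),
            drop.radius_um / px, shape=shape,
        )
        reporter[rr, cc] = drop.fill_intensity
        marker[rr, cc] = config.marker_fill_intensity
    for cond in condensates:
        rows = np.fromiter((r for r, _ in cond.pixel_mask), int, len(cond.pixel_mask))
        cols = np.fromiter((c for _, c in cond.pixel_mask), int, len(cond.pixel_mask))
        marker[rows, cols] = config.condensate_intensity

    out = []
    for clean in (reporter, marker):
        img = ndi.gaussian_filter(clean, sigma=1.0)
        if config.noise_poisson_scale > 0:
            img = rng.poisson(img * config.noise_poisson_scale) / config.noise_poisson_scale
        img = img + rng.normal(0.0, config.noise_gaussian_sd, size=shape)
        n_clip = int(np.sum((img < 0) | (img > 65535)))
        if n_clip:
            logger.info("clipped %d pixels to the 16-bit range", n_clip)
        img = np.clip(img, 0, 65535)
        out.append(PixelGrid(img, px, bit_depth=16))
    return ChannelPair(reporter=out[0], marker=out[1])


def generate_scene(
    config: SceneConfig,
) -> tuple[ChannelPair, list[DropletGroundTruth], list[CondensateGroundTruth]]:
    """Sample, inject and render one complete scene from the config's seed."""
    rng = np.random.default_rng(config.rng_seed)
    droplets = sample_droplets(config, rng)
    condensates = inject_condensates(droplets, config, rng)
    channels = render_scene(droplets, condensates, config, rng)
    return channels, droplets, condensates


# ---------------------------------------------------------------------------
# FRAP trace simulation
# ---------------------------------------------------------------------------

def simulate_frap_trace(
    rate_k_per_s: float,
    pre_bleach_level: float = 100.0,
    post_bleach_level: float = 20.0,
    plateau: float = 90.0,
    dt_s: float = 0.5,
    duration_s: float = 180.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    n_prebleach_frames: int = 5,
    reference_level: float = 1000.0,
) -> FrapTraceGroundTruth:
    """Simulate a FRAP acquisition with single-exponential recovery.

    The trace holds ``n_prebleach_frames`` at ``pre_bleach_level`` followed
    by ``I(t) = plateau - (plateau - post_bleach_level) * exp(-k t)`` sampled
    every ``dt_s`` for ``duration_s`` (t = 0 at the first post-bleach frame),
    with optional additive Gaussian noise, plus a constant reference-region
    series for normalization.
    """
    if rate_k_per_s < 0:
        raise ValueError("rate constant must be >= 0")
    if dt_s <= 0 or duration_s < dt_s:
        raise ValueError("need dt_s > 0 and duration_s >= dt_s")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    t_post = np.arange(0.0, duration_s + 0.5 * dt_s, dt_s)
    recovery = plateau - (plateau - post_bleach_level) * np.exp(-rate_k_per_s * t_post)
    pre = np.full(n_prebleach_frames, pre_bleach_level, float)
    bleach = np.concatenate([pre, recovery])
    if noise_sd > 0:
        bleach = bleach + rng.normal(0.0, noise_sd, size=bleach.size)
    times = np.arange(bleach.size, dtype=float) * dt_s
    reference = np.full(bleach.size, reference_level, float)
    return FrapTraceGroundTruth(
        times_s=times,
        bleach_roi_intensity=bleach * reference_level / 100.0,
        reference_intensity=reference,
        n_prebleach_frames=n_prebleach_frames,
        true_rate_k_per_s=rate_k_per_s,
        true_plateau=plateau,
        true_post_bleach_level=post_bleach_level,
    )


# ---------------------------------------------------------------------------
# Export
# ---------------------------------------------------------------------------

def export_scene(
    channels: ChannelPair,
    droplets: list[DropletGroundTruth],
    condensates: list[CondensateGroundTruth],
    directory: str | Path,
) -> dict[str, Path]:
    """Write a scene to disk: 16-bit TIFF per channel plus ground-truth CSVs.

    Intensities are rounded to integers and clipped to the 16-bit range
    before writing (clipping is logged); read-back reproduces the written
    arrays exactly.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for name, grid in (("reporter", channels.reporter), ("marker", channels.marker)):
        vals = np.rint(grid.values)
        n_clip = int(np.sum((vals < 0) | (vals > 65535)))
        if n_clip:
            logger.info("%s channel: clipped %d pixels to 16-bit", name, n_clip)
        path = directory / f"{name}.tif"
        tifffile.imwrite(path, np.clip(vals, 0, 65535).astype(np.uint16))
        paths[name] = path

    drop_df = pd.DataFrame(
        [
            {
                "id": d.droplet_id,
                "cx_um": d.center_x_um,
                "cy_um": d.center_y_um,
                "radius_um": d.radius_um,
                "fill_intensity": d.fill_intensity,
                "n_condensates": len(d.condensate_ids),
            }
            for d in droplets
        ],
        columns=["id", "cx_um", "cy_um", "radius_um", "fill_intensity", "n_condensates"],
    )
    cond_df = pd.DataFrame(
        [
            {
                "id": c.condensate_id,
                "parent_id": c.parent_droplet_id,
                "area_um2": c.area_um2,
                "perimeter_um": c.perimeter_um,
            }
            for c in condensates
        ],
        columns=["id", "parent_id", "area_um2", "perimeter_um"],
    )
    paths["droplets_csv"] = directory / "droplets_truth.csv"
    paths["condensates_csv"] = directory / "condensates_truth.csv"
    drop_df.to_csv(paths["droplets_csv"], index=False)
    cond_df.to_csv(paths["condensates_csv"], index=False)
    return paths
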