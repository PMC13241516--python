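"""FRAP trace normalization and single-exponential recovery fitting.

Fluorescence recovery after photobleaching reports molecular exchange
between a condensate and the surrounding cytosol.  The bleach-region signal
is first divided by a non-bleached reference region of the same droplet or
extract (cancelling illumination drift and acquisition bleaching), then
scaled so the pre-bleach mean is 100%.  Recovery is modelled as

    I(t) = P - (P - I0) * exp(-k * t)

with time re-zeroed at the first post-bleach frame; the reported half-time
is t1/2 = ln 2 / k and the mobile fraction is (P - I0)/(100 - I0).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

logger = logging.getLogger(__name__)


class FrapError(ValueError):
    """Raised for invalid FRAP inputs."""


class FrapFitError(RuntimeError):
    """Raised when the recovery fit fails to converge; carries diagnostics."""


@dataclass
class FrapTrace:
    """Raw bleach-region and reference-region intensities over time."""

    times_s: np.ndarray
    bleach_roi_intensity: np.ndarray
    reference_intensity: np.ndarray
    n_prebleach_frames: int

    def __post_init__(self) -> None:
        self.times_s = np.asarray(self.times_s, float)
        self.bleach_roi_intensity = np.asarray(self.bleach_roi_intensity, float)
        self.reference_intensity = np.asarray(self.reference_intensity, float)
        n = len(self.times_s)
        if not (len(self.bleach_roi_intensity) == len(self.reference_intensity) == n):
            raise FrapError("times, bleach and reference series must have equal length")
        if np.any(np.diff(self.times_s) <= 0):
            raise FrapError("times must be strictly increasing")
        if not 1 <= self.n_prebleach_frames < n:
            raise FrapError("need >= 1 pre-bleach frame and >= 1 post-bleach frame")
        bad = np.nonzero(self.reference_intensity <= 0)[0]
        if bad.size:
            raise FrapError(
                f"reference intensity must be > 0 at every frame; "
                f"first violation at frame {int(bad[0])}"
            )


@dataclass
class FrapFit:
    """Fitted single-exponential recovery parameters."""

    rate_k_per_s: float
    half_time_s: float
    plateau_pct: float
    post_bleach_pct: float
    mobile_fraction: float
    residual_sum_squares: float


def half_time(rate_k_per_s: float) -> float:
    """Recovery half-time ``ln 2 / k`` in seconds."""
    if rate_k_per_s <= 0:
        raise ValueError("rate constant must be > 0")
    return math.log(2.0) / rate_k_per_s


def normalize_trace(trace: FrapTrace) -> tuple[np.ndarray, np.ndarray]:
    """Reference-normalize a trace and scale the pre-bleach mean to 100%.

    Returns ``(times_s, intensity_pct)``.  Dividing by the reference region
    first removes any gain or illumination factor common to both regions, so
    the result is invariant to uniform intensity rescaling and to
    multiplicative drift.
    """
    ratio = trace.bleach_roi_intensity / trace.reference_intensity
    pre = ratio[: trace.n_prebleach_frames]
    pre_mean = float(pre.mean())
    if pre_mean <= 0:
        raise FrapError("pre-bleach mean is not positive; cannot normalize")
    return trace.times_s.copy(), 100.0 * ratio / pre_mean


def _recovery(t: np.ndarray, plateau: float, i0: float, k: float) -> np.ndarray:
    return plateau - (plateau - i0) * np.exp(-k * t)


def fit_recovery(
    intensity_pct: np.ndarray,
    times_s: np.ndarray,
    n_prebleach_frames: int,
    max_restarts: int = 5,
) -> FrapFit:
    """Least-squares fit of single-exponential recovery to a normalized trace.

    Only post-bleach frames are fitted, with time re-zeroed at the first
    post-bleach frame.  Initialization is deterministic from the data:
    I0 = first post-bleach value, P = mean of the last 10% of frames,
    k = ln 2 / (time to reach half the I0-to-P range).  On convergence
    failure the fit is restarted up to ``max_restarts`` times from perturbed
    (but deterministically generated) starting points.
    """
    intensity_pct = np.asarray(intensity_pct, float)
    times_s = np.asarray(times_s, float)
    y = intensity_pct[n_prebleach_frames:]
    t = times_s[n_prebleach_frames:]
    if len(y) < 5:
        raise FrapError("need >= 5 post-bleach points to fit recovery")
    pre_level = float(np.mean(intensity_pct[:n_prebleach_frames]))
    if float(y.min()) >= pre_level:
        raise FrapError("post-bleach minimum is not below the pre-bleach level")
    t = t - t[0]

    i0_init = float(y[0])
    n_tail = max(1, len(y) // 10)
    p_init = float(np.mean(y[-n_tail:]))
    if p_init <= i0_init:   # no visible recovery; still give the fitter a chance
        p_init = i0_init + max(1e-3, float(y.max()) - i0_init)
    half_level = 0.5 * (i0_init + p_init)
    above = np.nonzero(y >= half_level)[0]
    t_half_guess = float(t[above[0]]) if above.size and t[above[0]] > 0 else float(t[-1]) / 4
    k_init = math.log(2.0) / max(t_half_guess, float(t[1] - t[0]))

    p0 = [p_init, i0_init, k_init]
    bounds = ([0.0, 0.0, 1e-9], [np.inf, np.inf, np.inf])
    last_err: Exception | None = None
    for attempt in range(max_restarts + 1):
        scale = 1.0 + 0.5 * attempt
        start = [p0[0] * scale, p0[1] / scale, p0[2] * scale]
        try:
            popt, _ = curve_fit(
                _recovery, t, y, p0=start, bounds=bounds, maxfev=20000
            )
            break
        except RuntimeError as err:   # pragma: no cover - rare non-convergence
            last_err = err
    else:   # pragma: no cover
        raise FrapFitError(
            f"recovery fit failed after {max_restarts + 1} attempts: {last_err}"
        )

    plateau, i0, k = (float(v) for v in popt)
    if k <= 2e-9:   # at the lower bound: no kinetic information
        logger.warning("fitted rate constant at bound (k=%.3g /s)", k)
    rss = float(np.sum((y - _recovery(t, plateau, i0, k)) ** 2))
    mobile = (plateau - i0) / (100.0 - i0) if i0 < 100.0 else 1.0
    return FrapFit(
        rate_k_per_s=k,
        half_time_s=half_time(k),
        plateau_pct=plateau,
        post_bleach_pct=i0,
        mobile_fraction=float(min(1.0, max(0.0, mobile))),
        residual_sum_squares=rss,
    )


def fit_trace(trace: FrapTrace) -> FrapFit:
    """Normalize a raw trace and fit its recovery in one step."""
    times, pct = normalize_trace(trace)
    return fit_recovery(pct, times, trace.n_prebleach_frames)
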