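"""Colocalisation and set-overlap statistics.

Two light statistical utilities accompany the imaging pipeline: the Pearson
correlation of two fluorescence channels sampled along a drawn line (a
standard colocalisation readout for condensates), and an upper-tail
hypergeometric test for the overlap between two identifier sets (e.g. the
transcriptomes of two condensate types) with Benjamini-Hochberg control of
the false discovery rate across multiple comparisons.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp
from scipy.stats import hypergeom, pearsonr
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)


class StatsError(ValueError):
    """Raised for invalid statistical inputs."""


@dataclass
class LineProfile:
    """Two fluorescence channels sampled along a drawn line."""

    positions_um: np.ndarray
    intensity_a: np.ndarray
    intensity_b: np.ndarray

    def __post_init__(self) -> None:
        self.positions_um = np.asarray(self.positions_um, float)
        self.intensity_a = np.asarray(self.intensity_a, float)
        self.intensity_b = np.asarray(self.intensity_b, float)
        n = len(self.positions_um)
        if not (len(self.intensity_a) == len(self.intensity_b) == n):
            raise StatsError("positions and both intensity series must have equal length")
        if n < 3:
            raise StatsError("a line profile needs >= 3 samples")
        if np.any(np.diff(self.positions_um) <= 0):
            raise StatsError("positions must be strictly increasing")


@dataclass
class OverlapResult:
    """Hypergeometric overlap between two sets drawn from a universe.

    With a universe of ``N`` identifiers, a first set of size ``K`` and a
    second of size ``n`` sharing ``k`` members, ``p_value`` is the
    upper-tail probability P(X >= k) for X ~ Hypergeometric(N, K, n) and
    ``enrichment_factor`` is the observed overlap over its expectation
    ``n*K/N``.
    """

    universe_size: int
    set_a_size: int
    draw_size: int
    overlap: int
    p_value: float
    enrichment_factor: float
    adjusted_p: float | None = None
    log10_p_value: float = 0.0   # exact even when p_value underflows double precision


def pearson_line_profile(profile: LineProfile) -> float:
    """Sample Pearson correlation R of the two channels along the line."""
    if np.ptp(profile.intensity_a) == 0 or np.ptp(profile.intensity_b) == 0:
        raise StatsError("correlation undefined: a channel is constant along the line")
    r = pearsonr(profile.intensity_a, profile.intensity_b).statistic
    return float(r)


def hypergeom_overlap(N: int, K: int, n: int, k: int) -> OverlapResult:
    """Upper-tail hypergeometric enrichment test for a set overlap.

    The tail P(X >= k) is accumulated in log space (a logsumexp over the
    log-pmf from ``k`` to ``min(K, n)``) so that gene-scale universes do not
    underflow.
    """
    if not (0 <= K <= N and 0 <= n <= N):
        raise StatsError("set sizes must satisfy 0 <= K, n <= N")
    if not 0 <= k <= min(K, n):
        raise StatsError("overlap k must satisfy 0 <= k <= min(K, n)")
    if k == 0:
        p, log10_p = 1.0, 0.0
    else:
        support = np.arange(k, min(K, n) + 1)
        log_p = min(0.0, float(logsumexp(hypergeom.logpmf(support, N, K, n))))
        log10_p = log_p / np.log(10.0)
        # keep p_value in (0, 1] even when the tail underflows a double
        p = max(float(np.exp(log_p)), 5e-324)
    expected = n * K / N if N > 0 else 0.0
    factor = k / expected if expected > 0 else 0.0
    return OverlapResult(
        universe_size=N,
        set_a_size=K,
        draw_size=n,
        overlap=k,
        p_value=p,
        enrichment_factor=factor,
        log10_p_value=log10_p,
    )


def overlap_from_sets(
    set_a: set[str], set_b: set[str], universe: set[str] | None = None
) -> OverlapResult:
    """Overlap test between two identifier sets.

    The universe must contain both sets; when omitted it defaults to their
    union, which is conservative and makes the assumption explicit rather
    than silently inflating significance with an arbitrary background.
    """
    if universe is None:
        logger.warning("no universe supplied; defaulting to the union of both sets")
        universe = set_a | set_b
    if not (set_a <= universe and set_b <= universe):
        raise StatsError("both sets must be subsets of the universe")
    return hypergeom_overlap(
        len(universe), len(set_a), len(set_b), len(set_a & set_b)
    )


def bh_adjust(p_values: np.ndarray | list[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    Output is in the original ordering, elementwise >= the input, capped at
    1, and idempotent on already-adjusted inputs.
    """
    p = np.asarray(p_values, float)
    if p.size == 0:
        return p
    if np.any((p <= 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise StatsError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]
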