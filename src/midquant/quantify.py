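"""Channel integration, raw MIDs and average percent enrichment.

Integration always uses the *raw* (unsmoothed) intensities — smoothing is
only for locating the peak — and always within the cluster's shared
bounds, so the area ratio between channels is unbiased by per-channel
bound placement.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .chromatography import EIC, IsotopicCluster, PeakBounds
from .method import TargetIon

FLAG_OK = "ok"
FLAG_PEAK_NOT_FOUND = "peak_not_found"
FLAG_LOW_SIGNAL = "low_signal"
FLAG_CORRECTION_FAILED = "correction_failed"


@dataclass
class MIDRecord:
    """Integrated result for one target ion in one sample."""

    target: TargetIon
    sample_id: str
    areas: np.ndarray
    raw_mid: np.ndarray | None = None
    corrected_mid: np.ndarray | None = None
    ape_percent: list[float] | None = None  # one value per tracer
    flags: list[str] = field(default_factory=lambda: [FLAG_OK])

    @property
    def total_abundance(self) -> float:
        return float(np.sum(self.areas))

    @property
    def ok(self) -> bool:
        return self.flags == [FLAG_OK]


def integrate_channel(
    eic: EIC,
    bounds: PeakBounds,
    baseline: np.ndarray | str = "edges",
) -> float:
    """Baseline-subtracted sum of raw intensities between the peak edges.

    ``baseline="edges"`` (default) subtracts the channel's own straight
    line between its raw intensities at the two bound indices, clamped at
    zero; an explicit array uses that baseline instead; ``None`` subtracts
    nothing. Negative per-point contributions are clipped so areas stay
    non-negative.
    """
    lo, hi = bounds.left_index, bounds.right_index
    if not (0 <= lo <= hi < eic.intensity.size):
        raise ValueError("bounds outside EIC grid")
    y = eic.intensity[lo : hi + 1]
    if isinstance(baseline, str) and baseline == "edges":
        b = np.clip(np.linspace(y[0], y[-1], y.size), 0.0, None)
    elif baseline is None:
        b = np.zeros_like(y)
    else:
        b = np.asarray(baseline, dtype=float)[lo : hi + 1]
    return float(np.clip(y - b, 0.0, None).sum())


def integrate_cluster(cluster: IsotopicCluster) -> np.ndarray:
    """Integrate every channel of the cluster within its shared bounds."""
    if cluster.bounds is None:
        raise ValueError("cluster has no bounds; run peak matching first")
    return np.array(
        [integrate_channel(e, cluster.bounds) for e in cluster.channel_eics]
    )


def compute_mid(areas: np.ndarray) -> np.ndarray | None:
    """Relative area abundances; ``None`` when the total area is zero."""
    areas = np.asarray(areas, dtype=float)
    total = areas.sum()
    if total <= 0:
        return None
    return areas / total


def compute_ape(mid: np.ndarray, n_positions: int) -> float:
    """Average percent enrichment of a single-tracer MID over 0..n labels:
    ``100 * sum_i(i * mid_i) / n``."""
    if n_positions <= 0:
        raise ValueError("n_positions must be positive")
    mid = np.asarray(mid, dtype=float)
    labels = np.arange(mid.size)
    return float(100.0 * np.dot(labels, mid) / n_positions)


def compute_ape_dual(
    mid: np.ndarray,
    channels: list[tuple[int, int]],
    n_positions: tuple[int, int],
) -> tuple[float, float]:
    """Per-tracer APEs of a dual-tracer MID, by marginalizing over the
    flattened (i, j) channel list."""
    mid = np.asarray(mid, dtype=float)
    apes = []
    for axis in (0, 1):
        n = n_positions[axis]
        if n <= 0:
            raise ValueError("n_positions must be positive for both tracers")
        weighted = sum(m * ch[axis] for m, ch in zip(mid, channels))
        apes.append(float(100.0 * weighted / n))
    return tuple(apes)


def low_signal(areas: np.ndarray, noise_level: float, bounds: PeakBounds,
               multiplier: float = 10.0) -> bool:
    """Total area below ``multiplier * noise * width`` flags a weak record."""
    width = bounds.right_index - bounds.left_index + 1
    return float(np.sum(areas)) < multiplier * noise_level * width
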