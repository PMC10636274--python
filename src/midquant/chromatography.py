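"""Extracted ion chromatograms, composite peaks, and peak location/bounds.

The quantification strategy is built around one idea: all isotopologues of
a target ion are located and bounded *together*. The per-channel EICs are
summed into a composite trace, the peak is found on the Savitzky-Golay
smoothed composite, and the resulting integration bounds are stored once
per isotopic cluster and applied identically to every channel. Sharing
bounds keeps the area ratio of a weak isotopologue to a strong one exact
even when the weak channel's own peak shape is too poor to bound reliably.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import scipy.signal

from .errors import EmptyEICError, PeakNotFoundError
from .io_raw import RawRun, centroid_profile_scan
from .method import Method, MzTolerance, TargetIon, isotopologue_mz

logger = logging.getLogger(__name__)


@dataclass
class EIC:
    """Intensity versus retention time at a fixed m/z window."""

    rt: np.ndarray  # seconds, strictly increasing
    intensity: np.ndarray  # >= 0, same length
    target_mz: float
    tolerance: MzTolerance | None = None

    def __post_init__(self):
        self.rt = np.asarray(self.rt, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.rt.shape != self.intensity.shape or self.rt.size == 0:
            raise ValueError("EIC arrays must be non-empty and equal-length")


@dataclass
class PeakBounds:
    """Shared integration bounds on the cluster's RT grid."""

    apex_index: int
    left_index: int
    right_index: int

    def __post_init__(self):
        if not self.left_index <= self.apex_index <= self.right_index:
            raise ValueError("bounds must satisfy left <= apex <= right")


@dataclass
class IsotopicCluster:
    """All quantified isotopologue EICs of one target ion in one run.

    Bounds are deliberately a single attribute of the cluster, not of the
    channels: the same integration window applies to every isotopologue.
    """

    target: TargetIon
    channel_eics: list[EIC]
    composite: EIC
    smoothed_composite: EIC | None = None
    noise_level: float = 0.0
    baseline: np.ndarray | None = None
    bounds: PeakBounds | None = None

    def __post_init__(self):
        grids = [e.rt for e in self.channel_eics] + [self.composite.rt]
        first = grids[0]
        for g in grids[1:]:
            if g.shape != first.shape or not np.allclose(g, first):
                raise ValueError("all EICs in a cluster must share one RT grid")


# ------------------------------------------------------------ extraction ---

def extract_eic(
    run: RawRun,
    mz: float,
    tol: MzTolerance,
    ms_level: int = 1,
    precursor: float | None = None,
) -> EIC:
    """Sum centroided intensities within ``mz +/- tol`` across matching scans.

    Scans are selected by MS level; for MS2, the scan's precursor selection
    must lie within its isolation window of the requested precursor.
    Profile scans are centroided on the fly. Scans with no in-window signal
    contribute an explicit zero so the RT grid covers the full run.
    """
    half = tol.half_width(mz)
    rts, values = [], []
    for scan in run.scans:
        if scan.ms_level != ms_level:
            continue
        if ms_level == 2 and precursor is not None:
            window = scan.precursor_window if scan.precursor_window else 1.0
            if scan.precursor_mz is None or abs(scan.precursor_mz - precursor) > window:
                continue
        if not scan.centroided:
            scan = centroid_profile_scan(scan)
        lo = np.searchsorted(scan.mz_values, mz - half, side="left")
        hi = np.searchsorted(scan.mz_values, mz + half, side="right")
        rts.append(scan.rt)
        values.append(float(scan.intensities[lo:hi].sum()))
    if not rts:
        raise EmptyEICError(
            f"no scans at ms_level={ms_level}"
            + (f", precursor={precursor}" if precursor else "")
        )
    return EIC(rt=np.array(rts), intensity=np.array(values), target_mz=mz,
               tolerance=tol)


def extract_cluster(run: RawRun, target: TargetIon, method: Method) -> IsotopicCluster:
    """Extract all quantified isotopologue EICs of *target* plus their
    composite (pointwise sum) on the shared scan grid."""
    channel_eics = [
        extract_eic(
            run,
            isotopologue_mz(target, lc),
            method.mz_tolerance,
            ms_level=target.ms_level,
            precursor=target.precursor_mz,
        )
        for lc in target.quantified_isotopologues
    ]
    composite = EIC(
        rt=channel_eics[0].rt.copy(),
        intensity=np.sum([e.intensity for e in channel_eics], axis=0),
        target_mz=target.base_mz,
        tolerance=method.mz_tolerance,
    )
    return IsotopicCluster(target=target, channel_eics=channel_eics,
                           composite=composite)


# ------------------------------------------------------------- RT warping ---

def warp_rt(anchors: list[tuple[float, float]]):
    """Piecewise-linear RT correction from characteristic-ion anchors.

    *anchors* are (expected_rt, observed_rt) pairs of confidently matched
    characteristic ions. The returned callable maps an expected RT to the
    run's local time axis, interpolating linearly between anchors and
    extrapolating with a constant offset beyond the outermost ones. With no
    anchors the identity map is returned (with a warning).
    """
    anchors = sorted(anchors)
    if not anchors:
        logger.warning("no RT anchors matched; using identity warp")
        return lambda rt: rt
    expected = np.array([a[0] for a in anchors])
    offsets = np.array([a[1] - a[0] for a in anchors])

    def warp(rt: float) -> float:
        return float(rt + np.interp(rt, expected, offsets))

    return warp


# -------------------------------------------------------------- smoothing ---

def smooth(eic: EIC, window: int = 7, order: int = 3) -> EIC:
    """Savitzky-Golay smoothing; negative outputs clamped to zero.

    Ends are handled by fitting the edge polynomial on the truncated window
    (scipy's ``interp`` mode). Signals shorter than the window are returned
    unchanged with a warning — smoothing them would be pure extrapolation.
    """
    if window % 2 == 0 or window <= order:
        raise ValueError("window must be odd and greater than order")
    if eic.intensity.size < window:
        warnings.warn("EIC shorter than smoothing window; returned unsmoothed")
        return EIC(eic.rt.copy(), eic.intensity.copy(), eic.target_mz, eic.tolerance)
    smoothed = scipy.signal.savgol_filter(eic.intensity, window, order,
                                          mode="interp")
    return EIC(eic.rt.copy(), np.clip(smoothed, 0.0, None), eic.target_mz,
               eic.tolerance)


# ---------------------------------------------------- noise and baseline ---

def estimate_noise(eic: EIC) -> float:
    """Robust noise scale from successive differences of the raw trace.

    ``1.4826 * median(|x[i+1] - x[i]|) / sqrt(2)`` — the MAD-to-sigma
    factor for Gaussian noise, with sqrt(2) removing the variance doubling
    of differencing. Successive differences need no peak-free region and
    are nearly blind to the (smooth) peak itself.
    """
    if eic.intensity.size < 2:
        return 0.0
    diffs = np.abs(np.diff(eic.intensity))
    return float(1.4826 * np.median(diffs) / np.sqrt(2.0))


def estimate_baseline(
    eic: EIC,
    smoothed: EIC | None = None,
    edge_fraction: float = 0.1,
) -> np.ndarray:
    """Linear baseline anchored at the quietest smoothed point of each edge.

    The minimum smoothed intensity within the leading and trailing
    *edge_fraction* of the window is taken as the baseline level at that
    end; the baseline is the straight line between the two anchor points,
    clamped at zero.
    """
    y = (smoothed or eic).intensity
    rt = eic.rt
    n = y.size
    edge = max(1, int(np.ceil(n * edge_fraction)))
    left_idx = int(np.argmin(y[:edge]))
    right_idx = n - edge + int(np.argmin(y[n - edge:]))
    if right_idx == left_idx:
        return np.full(n, max(y[left_idx], 0.0))
    slope = (y[right_idx] - y[left_idx]) / (rt[right_idx] - rt[left_idx])
    baseline = y[left_idx] + slope * (rt - rt[left_idx])
    return np.clip(baseline, 0.0, None)


# ----------------------------------------------------------- peak finding ---

def _local_maxima(y: np.ndarray) -> np.ndarray:
    """Indices of local maxima, including plateau centers and array ends."""
    if y.size == 1:
        return np.array([0])
    peaks, _ = scipy.signal.find_peaks(y, plateau_size=1)
    maxima = list(peaks)
    if y[0] > y[1]:
        maxima.insert(0, 0)
    if y[-1] > y[-2]:
        maxima.append(y.size - 1)
    return np.array(sorted(maxima), dtype=int)


def match_peak(
    cluster: IsotopicCluster,
    expected_rt: float,
    rt_window: float,
    characteristic_apex_rts: list[float] | None = None,
    k: float = 3.0,
) -> int:
    """Locate the target's peak apex on the smoothed composite.

    Candidate apexes are local maxima within ``expected_rt +/- rt_window``
    rising above ``baseline + k * noise``. Each is scored

        S = exp(-drt^2 / (2 sigma^2)) * (apex - baseline) / max(apex - baseline)

    with ``sigma = rt_window / 2`` — a Gaussian retention-time kernel times
    the candidate's height relative to the tallest candidate. When
    characteristic sibling ions were matched, each candidate's score is
    further multiplied by the RT-proximity term of the nearest
    characteristic apex. Returns the index of the best candidate; ties go
    to the smaller RT deviation.
    """
    smoothed = cluster.smoothed_composite
    if smoothed is None:
        raise ValueError("cluster has no smoothed composite; smooth first")
    y = smoothed.intensity
    rt = smoothed.rt
    baseline = (
        cluster.baseline if cluster.baseline is not None else np.zeros_like(y)
    )
    threshold = baseline + k * cluster.noise_level
    in_window = np.abs(rt - expected_rt) <= rt_window
    candidates = [
        i for i in _local_maxima(y)
        if in_window[i] and y[i] >= threshold[i] and y[i] > baseline[i]
    ]
    if not candidates:
        raise PeakNotFoundError(
            f"no peak above threshold near RT {expected_rt:.1f}s "
            f"for {cluster.target.compound_name}/{cluster.target.ion_name}"
        )
    sigma = rt_window / 2.0
    heights = np.array([y[i] - baseline[i] for i in candidates])
    rel_height = heights / heights.max()
    scores = []
    for idx, i in enumerate(candidates):
        drt = rt[i] - expected_rt
        score = np.exp(-drt**2 / (2 * sigma**2)) * rel_height[idx]
        if characteristic_apex_rts:
            nearest = min(characteristic_apex_rts, key=lambda a: abs(rt[i] - a))
            score *= np.exp(-(rt[i] - nearest) ** 2 / (2 * sigma**2))
        scores.append(score)
    best = max(
        range(len(candidates)),
        key=lambda idx: (scores[idx], -abs(rt[candidates[idx]] - expected_rt)),
    )
    return int(candidates[best])


def find_bounds(
    cluster: IsotopicCluster,
    apex: int,
    k: float = 3.0,
    asymmetry_cap: float = 2.0,
    min_fraction: float = 0.05,
) -> PeakBounds:
    """Walk outward from the apex on the smoothed composite to the peak edges.

    Each direction stops when the smoothed intensity drops below
    ``baseline + k * noise``, when a local minimum below
    ``baseline + min_fraction * (apex height)`` is reached (shoulder-peak
    guard), or at the window edge. If the longer apex-to-edge distance then
    exceeds ``asymmetry_cap`` times the shorter, the longer side is clipped
    to exactly the cap (the near edge is trusted; signal beyond the capped
    far edge is treated as tailing artifact).
    """
    y = cluster.smoothed_composite.intensity
    baseline = (
        cluster.baseline if cluster.baseline is not None else np.zeros_like(y)
    )
    noise = cluster.noise_level
    n = y.size
    apex_height = y[apex] - baseline[apex]
    floor = baseline + min_fraction * apex_height

    def walk(direction: int) -> int:
        i = apex
        while True:
            nxt = i + direction
            if nxt < 0 or nxt >= n:
                return i
            if y[nxt] < baseline[nxt] + k * noise:
                return i
            # local minimum below the shoulder floor ends the peak
            after = nxt + direction
            if (
                y[nxt] <= floor[nxt]
                and 0 <= after < n
                and y[after] >= y[nxt]
            ):
                return nxt
            i = nxt

    left = walk(-1)
    right = walk(+1)
    left_w = apex - left
    right_w = right - apex
    if left_w > 0 and right_w > asymmetry_cap * left_w:
        right = apex + int(asymmetry_cap * left_w)
    elif right_w > 0 and left_w > asymmetry_cap * right_w:
        left = apex - int(asymmetry_cap * right_w)
    return PeakBounds(apex_index=apex, left_index=left, right_index=right)


def prepare_cluster(cluster: IsotopicCluster, method: Method) -> IsotopicCluster:
    """Fill in smoothed composite, noise level and baseline (in place)."""
    cluster.smoothed_composite = smooth(
        cluster.composite, method.smoothing_window, method.smoothing_order
    )
    cluster.noise_level = estimate_noise(cluster.composite)
    cluster.baseline = estimate_baseline(cluster.composite,
                                         cluster.smoothed_composite)
    return cluster
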