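"""Ground-truth-known synthetic runs.

Generates raw files (mzML/mzXML/netCDF) in which every chromatographic
peak, isotopologue ratio, baseline and noise realization is known exactly,
together with a sidecar truth table. The observable isotopologue fractions
are produced by pushing a chosen "true" label distribution through the
*same* correction-matrix forward model the corrector inverts, so a
noiseless generate-extract-integrate-correct round trip must return the
true distribution — this consistency is asserted in the test suite.

Emulated features of real data: Gaussian or exponentially-modified
Gaussian (EMG) elution profiles, constant-plus-linear baseline drift, and
multiplicative plus additive Gaussian noise (clamped at zero). Not
emulated: spray instability, detector saturation, isotopic fine structure
within a nominal channel, or co-eluting interferences beyond what the
method declares.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import scipy.stats

from .correction import CorrectionMatrix, build_correction_matrix, build_dual_matrix
from .io_raw import RawRun, Scan, write_cdf, write_mzml, write_mzxml
from .method import Method, TargetIon, isotopologue_mz


@dataclass
class TruthSpec:
    """True state of one target ion in a synthetic run."""

    target_name: str  # matches TargetIon.ion_name
    label_distribution: np.ndarray  # simplex over the quantified label states
    apex_rt: float  # seconds
    sigma: float  # Gaussian width, seconds
    apex_intensity: float  # counts
    tau: float = 0.0  # EMG tail constant, seconds (0 = pure Gaussian)
    baseline_const: float = 0.0
    baseline_slope: float = 0.0  # counts per second
    sigma_add: float = 0.0  # additive noise SD, counts
    sigma_mult: float = 0.0  # multiplicative noise SD, fractional

    def __post_init__(self):
        self.label_distribution = np.asarray(self.label_distribution, dtype=float)
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if abs(self.label_distribution.sum() - 1.0) > 1e-9:
            raise ValueError("label distribution must sum to 1")
        if np.any(self.label_distribution < 0):
            raise ValueError("label distribution must be non-negative")


def target_matrix(target: TargetIon, mode: str,
                  isotope_table=None) -> CorrectionMatrix:
    """Correction matrix over the target's quantified channels.

    Single tracer: channels are nominal shifts covering the quantified
    label counts. Dual tracer: the quantified (i, j) pairs themselves.
    """
    if target.is_dual_tracer:
        return build_dual_matrix(
            target.formula,
            target.tracers[0],
            target.tracers[1],
            mode,
            channels=[tuple(c) for c in target.quantified_isotopologues],
            isotope_table=isotope_table,
        )
    return build_correction_matrix(
        target.formula,
        target.tracers[0],
        mode,
        n_channels=max(target.quantified_isotopologues) + 1,
        isotope_table=isotope_table,
    )


def forward_mid(
    label_distribution: np.ndarray,
    target: TargetIon,
    mode: str,
    isotope_table=None,
) -> np.ndarray:
    """Observable channel fractions ``M @ x`` of a true label distribution."""
    m = target_matrix(target, mode, isotope_table)
    x = np.asarray(label_distribution, dtype=float)
    if x.size != m.n_states:
        raise ValueError(
            f"label distribution has {x.size} states, matrix expects {m.n_states}"
        )
    return m.matrix @ x


def _peak_shape(t: np.ndarray, apex_rt: float, sigma: float, tau: float
                ) -> np.ndarray:
    """Unit-apex elution profile (Gaussian, or EMG when tau > 0)."""
    if tau <= 0:
        return np.exp(-((t - apex_rt) ** 2) / (2 * sigma**2))
    k = tau / sigma
    # place the EMG apex at apex_rt and normalize it to 1
    dense = np.linspace(apex_rt - 6 * sigma, apex_rt + 6 * sigma + 6 * tau, 2001)
    profile = scipy.stats.exponnorm.pdf(dense, K=k, loc=apex_rt, scale=sigma)
    peak = profile.max()
    mode_rt = dense[int(np.argmax(profile))]
    shape = scipy.stats.exponnorm.pdf(
        t + (mode_rt - apex_rt), K=k, loc=apex_rt, scale=sigma
    )
    return shape / peak


def write_synthetic_run(
    truths: list[TruthSpec],
    method: Method,
    path,
    seed: int = 0,
    rt_start: float = 0.0,
    rt_end: float = 120.0,
    dt: float = 0.5,
    fmt: str = "mzml",
    truth_table_path=None,
) -> Path:
    """Materialize a synthetic run and its ground-truth table.

    Every channel trace is ``shape(t) * apex * observable_fraction +
    baseline + noise`` with noise ``I -> I * (1 + N(0, s_mult)) +
    N(0, s_add)`` clamped at zero; peaks sit at the method's isotopologue
    m/z values. Deterministic for a fixed seed. Targets closer than twice
    the m/z tolerance and overlapping in RT trigger a warning.

    Returns the path of the written raw file; the truth table (CSV with
    one row per target x channel) is written next to it unless an explicit
    path is given.
    """
    import logging

    logger = logging.getLogger(__name__)
    path = Path(path)
    rng = np.random.default_rng(seed)
    t = np.arange(rt_start, rt_end + dt / 2, dt)
    targets = {tg.ion_name: tg for tg in method.targets}
    table = method.isotope_table()

    # channel m/z and noiseless amplitude per (truth, channel)
    entries = []  # (truth, target, channel_label, mz, obs_fraction)
    for truth in truths:
        target = targets[truth.target_name]
        obs = forward_mid(truth.label_distribution, target,
                          method.correction_mode, table)
        if target.is_dual_tracer:
            tracked = [
                obs[i] for i, _ in enumerate(target.quantified_isotopologues)
            ]
        else:
            tracked = [obs[lc] for lc in target.quantified_isotopologues]
        for lc, frac in zip(target.quantified_isotopologues, tracked):
            entries.append((truth, target, lc,
                            isotopologue_mz(target, lc), float(frac)))

    # warn on unresolvable overlaps between different targets
    for a in range(len(entries)):
        for b in range(a + 1, len(entries)):
            ta, tb = entries[a][0], entries[b][0]
            if ta is tb:
                continue
            mza, mzb = entries[a][3], entries[b][3]
            tol = method.mz_tolerance.half_width((mza + mzb) / 2)
            if (abs(mza - mzb) < 2 * tol
                    and abs(ta.apex_rt - tb.apex_rt) < 2 * (ta.sigma + tb.sigma)):
                logger.warning(
                    "synthetic targets overlap in both m/z and RT: %s vs %s",
                    entries[a][1].ion_name, entries[b][1].ion_name,
                )

    scans = []
    shapes = {
        id(truth): _peak_shape(t, truth.apex_rt, truth.sigma, truth.tau)
        for truth in truths
    }
    for si, rt in enumerate(t):
        mzs, intensities = [], []
        for truth, target, lc, mz, frac in entries:
            clean = (
                shapes[id(truth)][si] * truth.apex_intensity * frac
                + truth.baseline_const
                + truth.baseline_slope * (rt - rt_start)
            )
            noisy = clean
            if truth.sigma_mult > 0:
                noisy *= 1.0 + rng.normal(0.0, truth.sigma_mult)
            if truth.sigma_add > 0:
                noisy += rng.normal(0.0, truth.sigma_add)
            mzs.append(mz)
            intensities.append(max(noisy, 0.0))
        order = np.argsort(mzs)
        scans.append(
            Scan(
                rt=float(rt),
                ms_level=1,
                mz_values=np.array(mzs)[order],
                intensities=np.array(intensities)[order],
                polarity="positive",
                centroided=True,
            )
        )
    run = RawRun(scans=scans, source_path=str(path))
    writer = {"mzml": write_mzml, "mzxml": write_mzxml, "cdf": write_cdf}[fmt]
    writer(run, path)

    if truth_table_path is None:
        truth_table_path = path.with_suffix(".truth.csv")
    with open(truth_table_path, "w", newline="") as fh:
        writer_ = csv.writer(fh)
        writer_.writerow(
            ["ion_name", "channel", "mz", "true_label_fraction",
             "observable_fraction", "apex_rt", "apex_intensity",
             "noiseless_total_counts"]
        )
        for truth, target, lc, mz, frac in entries:
            shape_sum = float(shapes[id(truth)].sum())
            if target.is_dual_tracer:
                idx = [tuple(c) for c in target.quantified_isotopologues].index(
                    tuple(lc))
                true_frac = float(truth.label_distribution[idx])
            else:
                x = truth.label_distribution
                true_frac = float(x[lc]) if lc < x.size else 0.0
            writer_.writerow([
                target.ion_name,
                lc if not isinstance(lc, (tuple, list)) else f"{lc[0]},{lc[1]}",
                f"{mz:.6f}",
                f"{true_frac:.9f}",
                f"{frac:.9f}",
                f"{truth.apex_rt:.3f}",
                f"{truth.apex_intensity:.3f}",
                f"{truth.apex_intensity * frac * shape_sum:.3f}",
            ])
    return path
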