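"""Natural isotope abundance correction of mass isotopomer distributions.

A measured MID is the convolution of the tracer-derived label distribution
with the natural isotopic background of the ion's formula. Writing the label
distribution as a simplex vector ``x`` over label states 0..n, the observable
channel fractions are ``M @ x`` where column ``j`` of the correction matrix
``M`` is the natural isotopologue distribution of the molecule carrying
``j`` labeled atoms. Correction inverts this map under a non-negativity
constraint.

Which atoms contribute to a column depends on the instrument mode:

``low_res_ms1``
    Unit mass resolution. Every element's heavy isotopes fall on the same
    nominal channels as the tracer shift, so the whole formula (minus the
    ``j`` labeled atoms) contributes.
``high_res_ms1``
    The mass defect of heavy isotopes of non-tracer elements (e.g. the
    +0.9970 Da of 15N vs the +1.0034 Da of 13C) is resolved away from the
    tracer channels, so only the tracer element's own atoms contribute.
``tandem``
    Product-ion MIDs are corrected with the product-ion formula only: atoms
    lost in the neutral fragment never appear in the measured m/z.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import scipy.optimize

from .errors import CorrectionError, IllConditionedError
from .isotopes import ISOTOPE_TABLE, TRACER_NOMINAL_SHIFTS
from .method import TracerSpec

CONDITION_LIMIT = 1e12

Formula = dict[str, int]
IsotopeTableT = dict[str, list[tuple[int, float, float]]]


def _element_distribution(
    element: str, count: int, table: IsotopeTableT
) -> np.ndarray:
    """Nominal-mass-shift distribution of ``count`` atoms of one element.

    The single-atom distribution is the isotope abundance vector placed at
    its nominal shifts; ``count`` atoms convolve it with itself ``count``
    times (binary exponentiation keeps this cheap for large counts).
    """
    if element not in table:
        raise CorrectionError(f"unknown element {element!r}")
    isotopes = table[element]
    lightest = isotopes[0][0]
    max_shift = isotopes[-1][0] - lightest
    single = np.zeros(max_shift + 1)
    for mass_number, _, abundance in isotopes:
        single[mass_number - lightest] = abundance
    result = np.array([1.0])
    base = single
    n = count
    while n > 0:
        if n & 1:
            result = np.convolve(result, base)
        n >>= 1
        if n:
            base = np.convolve(base, base)
    return result


def natural_distribution(
    formula: Formula,
    max_shift: int | None = None,
    isotope_table: IsotopeTableT | None = None,
    return_tail: bool = False,
):
    """Natural mass-isotopologue distribution of *formula*.

    Parameters
    ----------
    formula:
        Elemental composition, element symbol -> atom count.
    max_shift:
        Truncate the distribution at this nominal mass shift. ``None`` keeps
        the full support.
    isotope_table:
        Override the built-in abundance table.
    return_tail:
        Also return the probability mass beyond ``max_shift`` that was cut
        off by the truncation.

    Returns
    -------
    Fractions over nominal mass shifts ``0..max_shift`` (and the truncated
    tail mass if requested). An empty formula gives ``[1.0]``: the molecule
    has no atoms left to carry natural background.
    """
    table = isotope_table if isotope_table is not None else ISOTOPE_TABLE
    dist = np.array([1.0])
    for element, count in formula.items():
        if count < 0:
            raise CorrectionError(f"negative count for element {element!r}")
        if count == 0:
            continue
        dist = np.convolve(dist, _element_distribution(element, count, table))
    if max_shift is None:
        return (dist, 0.0) if return_tail else dist
    tail = float(dist[max_shift + 1 :].sum()) if dist.size > max_shift + 1 else 0.0
    out = np.zeros(max_shift + 1)
    n = min(dist.size, max_shift + 1)
    out[:n] = dist[:n]
    return (out, tail) if return_tail else out


@dataclass
class CorrectionMatrix:
    """Linear map from fractional label states to observable channels.

    ``matrix[r, c]`` is the probability that a molecule in label state ``c``
    is observed in channel ``r``. Columns sum to at most 1; mass falling
    outside the tracked channels is simply not observed.
    """

    matrix: np.ndarray
    mode: str
    formula: Formula
    tracers: tuple[TracerSpec, ...]
    channels: list = field(default_factory=list)  # labels of rows/columns

    @property
    def n_channels(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_states(self) -> int:
        return self.matrix.shape[1]


@dataclass
class CorrectedMID:
    """Result of constrained inversion of a correction matrix."""

    fractions: np.ndarray
    residual_norm: float


_MODES = ("low_res_ms1", "high_res_ms1")


def _column_formula(formula: Formula, tracer: TracerSpec, j: int, mode: str) -> Formula:
    """Atoms contributing natural background when ``j`` positions carry label."""
    element = tracer.element
    if mode == "high_res_ms1":
        return {element: formula.get(element, 0) - j}
    # low_res_ms1: full formula minus the j labeled atoms
    out = dict(formula)
    out[element] = out[element] - j
    return out


def build_correction_matrix(
    formula: Formula,
    tracer: TracerSpec,
    mode: str,
    n_channels: int | None = None,
    isotope_table: IsotopeTableT | None = None,
) -> CorrectionMatrix:
    """Single-tracer correction matrix.

    Column ``j`` is the natural distribution of the mode-dependent
    "correction formula" shifted down by ``j`` nominal tracer shifts.
    Channels (rows) are nominal shifts ``0..n_channels-1``; rows beyond the
    tracked channels are dropped, so columns may sum to < 1.
    """
    if mode not in _MODES:
        raise CorrectionError(f"unknown mode {mode!r}")
    element = tracer.element
    n = tracer.n_labeled_positions
    if formula.get(element, 0) < n:
        raise CorrectionError(
            f"formula has {formula.get(element, 0)} {element} atoms, "
            f"fewer than {n} labeled positions"
        )
    step = TRACER_NOMINAL_SHIFTS[(tracer.element, tracer.isotope_mass_number)]
    if n_channels is None:
        n_channels = n * step + 1
    matrix = np.zeros((n_channels, n + 1))
    for j in range(n + 1):
        offset = j * step
        room = n_channels - 1 - offset
        if room < 0:
            continue
        col = natural_distribution(
            _column_formula(formula, tracer, j, mode),
            max_shift=room,
            isotope_table=isotope_table,
        )
        matrix[offset : offset + col.size, j] = col
    return CorrectionMatrix(
        matrix=matrix,
        mode=mode,
        formula=dict(formula),
        tracers=(tracer,),
        channels=list(range(n_channels)),
    )


def build_dual_matrix(
    formula: Formula,
    tracer1: TracerSpec,
    tracer2: TracerSpec,
    mode: str,
    channels: Sequence[tuple[int, int]] | None = None,
    isotope_table: IsotopeTableT | None = None,
    allow_summed_channels: bool = False,
) -> CorrectionMatrix:
    """Dual-tracer correction matrix over flattened (i, j) label pairs.

    The pair layout is row-major with the first tracer outermost, matching
    the channel ordering used by the method module.

    In high-resolution mode the two tracer elements' contributions are
    independent and mass-resolved from each other, so the dual matrix is the
    Kronecker product of the two single-tracer matrices. At unit resolution
    the observable is only the combined nominal shift; distinct (i, j) pairs
    with equal combined shift are isobaric and rejected unless
    ``allow_summed_channels`` declares that the method sums them.
    """
    if tracer1.element == tracer2.element:
        raise CorrectionError("dual tracers must label distinct elements")
    n1, n2 = tracer1.n_labeled_positions, tracer2.n_labeled_positions
    if channels is None:
        channels = [(i, j) for i in range(n1 + 1) for j in range(n2 + 1)]
    channels = list(channels)

    if mode == "high_res_ms1":
        # a tracer with no labelable positions is no tracer at all: its
        # element joins the non-tracer background, which high resolution
        # resolves away, so its factor is the trivial identity
        def factor(tracer, n):
            if n == 0:
                return np.ones((1, 1))
            return build_correction_matrix(
                formula, tracer, mode, n_channels=n + 1,
                isotope_table=isotope_table,
            ).matrix

        full = np.kron(factor(tracer1, n1), factor(tracer2, n2))
        idx = [i * (n2 + 1) + j for (i, j) in channels]
        matrix = full[np.ix_(idx, idx)]
        return CorrectionMatrix(
            matrix=matrix,
            mode=mode,
            formula=dict(formula),
            tracers=(tracer1, tracer2),
            channels=channels,
        )

    if mode != "low_res_ms1":
        raise CorrectionError(f"unknown mode {mode!r}")

    step1 = TRACER_NOMINAL_SHIFTS[(tracer1.element, tracer1.isotope_mass_number)]
    step2 = TRACER_NOMINAL_SHIFTS[(tracer2.element, tracer2.isotope_mass_number)]
    shifts = [i * step1 + j * step2 for (i, j) in channels]
    if len(set(shifts)) != len(shifts) and not allow_summed_channels:
        raise MethodIsobarError(
            "isobaric label-state pairs at unit resolution; declare summed "
            "channels in the method to proceed"
        )
    matrix = np.zeros((len(channels), len(channels)))
    for c, (i, j) in enumerate(channels):
        corr_formula = dict(formula)
        corr_formula[tracer1.element] -= i
        corr_formula[tracer2.element] -= j
        base_shift = shifts[c]
        dist = natural_distribution(corr_formula, isotope_table=isotope_table)
        for r, row_shift in enumerate(shifts):
            k = row_shift - base_shift
            if 0 <= k < dist.size:
                matrix[r, c] += dist[k]
    return CorrectionMatrix(
        matrix=matrix,
        mode=mode,
        formula=dict(formula),
        tracers=(tracer1, tracer2),
        channels=channels,
    )


class MethodIsobarError(CorrectionError):
    """Distinct label-state pairs are unresolved at unit mass resolution."""


def build_tandem_matrix(
    precursor_formula: Formula,
    product_formula: Formula,
    tracer: TracerSpec,
    product_positions: int,
    mode: str = "high_res_ms1",
    n_channels: int | None = None,
    isotope_table: IsotopeTableT | None = None,
) -> CorrectionMatrix:
    """Correction matrix for a product-ion (MS/MS) MID.

    Only atoms retained in the product ion contribute to its measured m/z,
    so the matrix is the single-tracer matrix of the product formula with
    ``product_positions`` labelable positions.
    """
    for element, count in product_formula.items():
        if count > precursor_formula.get(element, 0):
            raise CorrectionError(
                f"product formula exceeds precursor for element {element!r}"
            )
    if product_positions > tracer.n_labeled_positions:
        raise CorrectionError(
            "product ion cannot retain more labeled positions than the precursor"
        )
    product_tracer = TracerSpec(
        element=tracer.element,
        isotope_mass_number=tracer.isotope_mass_number,
        n_labeled_positions=product_positions,
    )
    m = build_correction_matrix(
        product_formula,
        product_tracer,
        mode,
        n_channels=n_channels,
        isotope_table=isotope_table,
    )
    m.mode = "tandem_" + mode
    return m


def correct_mid(raw_mid: np.ndarray, m: CorrectionMatrix) -> CorrectedMID:
    """Invert the natural-abundance convolution of a measured MID.

    Solves ``min ||M x - raw_mid||_2`` subject to ``x >= 0`` and
    renormalizes ``x`` to the simplex. Non-negative least squares is used
    rather than direct inversion because negative label fractions are
    unphysical; when the matrix is square, well conditioned and the
    unconstrained solution is already non-negative the two coincide.
    """
    raw_mid = np.asarray(raw_mid, dtype=float)
    if raw_mid.shape[0] != m.matrix.shape[0]:
        raise CorrectionError(
            f"raw MID has {raw_mid.shape[0]} channels, matrix expects "
            f"{m.matrix.shape[0]}"
        )
    cond = np.linalg.cond(m.matrix)
    if not np.isfinite(cond) or cond > CONDITION_LIMIT:
        raise IllConditionedError(
            f"correction matrix condition number {cond:.3g} exceeds "
            f"{CONDITION_LIMIT:.0e}"
        )
    x, residual = scipy.optimize.nnls(m.matrix, raw_mid)
    total = x.sum()
    if total <= 0:
        raise CorrectionError("corrected MID is identically zero")
    return CorrectedMID(fractions=x / total, residual_norm=float(residual))
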