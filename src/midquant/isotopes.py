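"""Elemental isotope constants.

Natural abundances are IUPAC representative values; exact masses from the
standard atomic-mass tables. Both can be overridden per-method through the
``[isotopes]`` section of a method config (see :mod:`midquant.method`).
"""

from __future__ import annotations

# element -> list of (mass number, exact mass / Da, natural fractional abundance)
# Lightest isotope first; abundances sum to 1 per element.
ISOTOPE_TABLE: dict[str, list[tuple[int, float, float]]] = {
    "H": [(1, 1.0078250319, 0.999885), (2, 2.0141017779, 0.000115)],
    "C": [(12, 12.0, 0.9893), (13, 13.0033548378, 0.0107)],
    "N": [(14, 14.0030740052, 0.99636), (15, 15.0001088984, 0.00364)],
    "O": [
        (16, 15.9949146221, 0.99757),
        (17, 16.9991315, 0.00038),
        (18, 17.9991604, 0.00205),
    ],
    "S": [
        (32, 31.97207069, 0.9503),
        (33, 32.9714585, 0.0075),
        (34, 33.96786683, 0.0421),
        (36, 35.96708088, 0.0001),
    ],
    "P": [(31, 30.97376151, 1.0)],
    "F": [(19, 18.9984032, 1.0)],
    "I": [(127, 126.904473, 1.0)],
    "Na": [(23, 22.98976928, 1.0)],
    "K": [
        (39, 38.9637069, 0.932581),
        (40, 39.96399867, 0.000117),
        (41, 40.96182597, 0.067302),
    ],
    "Cl": [(35, 34.96885271, 0.7576), (37, 36.9659026, 0.2424)],
    "Br": [(79, 78.9183376, 0.5069), (81, 80.916291, 0.4931)],
    "Si": [
        (28, 27.9769265327, 0.92223),
        (29, 28.97649472, 0.04685),
        (30, 29.97377022, 0.03092),
    ],
    "Se": [
        (74, 73.9224764, 0.0089),
        (76, 75.9192136, 0.0937),
        (77, 76.9199140, 0.0763),
        (78, 77.9173091, 0.2377),
        (80, 79.9165213, 0.4961),
        (82, 81.9166994, 0.0873),
    ],
}

# Exact mass difference between the labeled isotope and the lightest isotope,
# for the tracer isotopes supported in labeling experiments.
TRACER_MASS_SHIFTS: dict[tuple[str, int], float] = {
    ("H", 2): 1.006277,
    ("C", 13): 1.003355,
    ("N", 15): 0.997035,
    ("O", 18): 2.004246,
    ("S", 34): 1.995796,
}

# Nominal (integer) mass shift of one labeled atom.
TRACER_NOMINAL_SHIFTS: dict[tuple[str, int], int] = {
    ("H", 2): 1,
    ("C", 13): 1,
    ("N", 15): 1,
    ("O", 18): 2,
    ("S", 34): 2,
}

SUPPORTED_TRACERS = frozenset(TRACER_MASS_SHIFTS)


def nominal_shifts(element: str) -> list[tuple[int, float]]:
    """(nominal mass shift, abundance) pairs of *element*'s isotopes,
    relative to the lightest isotope."""
    isotopes = ISOTOPE_TABLE[element]
    lightest = isotopes[0][0]
    return [(mass_number - lightest, ab) for mass_number, _, ab in isotopes]
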