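"""Independent oracles for isotope-distribution math.

These deliberately avoid polynomial convolution: the natural isotopologue
distribution is computed by direct enumeration of isotope-count
compositions per element with explicit multinomial coefficients, combined
across elements by nested summation over outcome dictionaries.
"""

from __future__ import annotations

import math
from itertools import product

from midquant.isotopes import ISOTOPE_TABLE


def _compositions(total: int, bins: int):
    """All tuples of `bins` non-negative ints summing to `total`."""
    if bins == 1:
        yield (total,)
        return
    for first in range(total + 1):
        for rest in _compositions(total - first, bins - 1):
            yield (first,) + rest


def element_distribution_enum(element: str, count: int, table=None) -> dict[int, float]:
    """Shift -> probability for `count` atoms of one element, by enumerating
    every isotope-count composition with its multinomial weight."""
    table = table or ISOTOPE_TABLE
    isotopes = table[element]
    lightest = isotopes[0][0]
    out: dict[int, float] = {}
    for combo in _compositions(count, len(isotopes)):
        weight = math.factorial(count)
        prob = 1.0
        shift = 0
        for k, (mass_number, _, abundance) in zip(combo, isotopes):
            weight //= math.factorial(k)
            prob *= abundance**k
            shift += k * (mass_number - lightest)
        out[shift] = out.get(shift, 0.0) + weight * prob
    return out


def natural_distribution_enum(formula: dict[str, int], table=None) -> dict[int, float]:
    """Shift -> probability for a whole formula, combining per-element
    enumerations by exhaustive cross products."""
    dists = [element_distribution_enum(e, c, table) for e, c in formula.items() if c]
    out = {0: 1.0}
    for dist in dists:
        new: dict[int, float] = {}
        for s1, p1 in out.items():
            for s2, p2 in dist.items():
                new[s1 + s2] = new.get(s1 + s2, 0.0) + p1 * p2
        out = new
    return out


def dual_matrix_enum(formula, element1, n1, element2, n2, table=None):
    """High-resolution dual-tracer matrix by enumeration.

    Entry ((o1, o2), (i, j)) is the probability that a molecule with i
    labels on element1 and j on element2 is observed at tracer shifts
    (o1, o2): the product of the two remaining-atom element distributions,
    since in high-resolution mode no other element contributes.
    """
    import numpy as np

    table = table or ISOTOPE_TABLE
    channels = [(i, j) for i in range(n1 + 1) for j in range(n2 + 1)]
    m = np.zeros((len(channels), len(channels)))
    for col, (i, j) in enumerate(channels):
        d1 = element_distribution_enum(element1, formula[element1] - i, table)
        d2 = element_distribution_enum(element2, formula[element2] - j, table)
        for row, (o1, o2) in enumerate(channels):
            m[row, col] = d1.get(o1 - i, 0.0) * d2.get(o2 - j, 0.0)
    return m
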