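"""Target-compound method definition and validation.

A *method* declares what to quantify: for each target ion its formula,
charge, expected retention time, tracer(s) and which isotopologues to
extract, plus the instrument/processing parameters shared by a batch
(m/z tolerance, resolution mode, smoothing, detection thresholds).

Methods are plain declarative JSON documents (schema below) so that they
are data, not code, and round-trip losslessly::

    {
      "schema_version": 1,
      "resolution_mode": "high_res",
      "mz_tolerance": {"ppm": 10},
      "smoothing": {"window": 7, "order": 3},
      "noise_multiplier_k": 3.0,
      "asymmetry_cap": 2.0,
      "correction_enabled": true,
      "targets": [
        {
          "compound": "glutamine", "ion": "Gln [M+H]+",
          "formula": "C5H11N2O3", "charge": 1, "base_mz": 147.07642,
          "expected_rt": 300.0, "rt_window": 30.0,
          "ms_level": 1, "is_characteristic": true,
          "tracers": [{"element": "C", "isotope": 13, "n_positions": 5}],
          "isotopologues": [0, 1, 2, 3, 4, 5]
        }
      ]
    }

Dual-tracer targets list two tracers and pairs ``[i, j]`` as
isotopologues; pairs enumerate row-major with the first tracer outermost.
An optional ``"isotopes"`` section overrides natural-abundance constants.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Union

from .errors import FormulaError, MethodValidationError
from .isotopes import ISOTOPE_TABLE, SUPPORTED_TRACERS, TRACER_MASS_SHIFTS

SCHEMA_VERSION = 1

DEFAULTS = {
    "mz_tolerance_ppm_highres": 10.0,
    "mz_tolerance_th_lowres": 0.3,
    "smoothing_window": 7,
    "smoothing_order": 3,
    "noise_multiplier_k": 3.0,
    "asymmetry_cap": 2.0,
    "rt_window": 30.0,
}

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")

LabelCount = Union[int, tuple[int, int]]


def parse_formula(formula_text: str) -> dict[str, int]:
    """Parse a Hill-notation-like formula string into element counts.

    "C5H10N2O3" -> {"C": 5, "H": 10, "N": 2, "O": 3}. Repeated element
    symbols accumulate. Unknown element symbols are rejected.
    """
    if not formula_text or not formula_text.strip():
        raise FormulaError("empty formula")
    composition: dict[str, int] = {}
    pos = 0
    text = formula_text.strip()
    while pos < len(text):
        m = _FORMULA_TOKEN.match(text, pos)
        if not m or not m.group(1):
            raise FormulaError(
                f"malformed formula {formula_text!r} at {text[pos:pos + 4]!r}"
            )
        element, count_text = m.groups()
        if element not in ISOTOPE_TABLE:
            raise FormulaError(f"unknown element {element!r} in {formula_text!r}")
        count = int(count_text) if count_text else 1
        if count == 0:
            raise FormulaError(f"zero count for {element!r} in {formula_text!r}")
        composition[element] = composition.get(element, 0) + count
        pos = m.end()
    return composition


def format_formula(composition: dict[str, int]) -> str:
    """Inverse of :func:`parse_formula` (Hill order: C, H, then alphabetical)."""
    elements = sorted(
        composition, key=lambda e: (e != "C", e != "H", e)
    )
    return "".join(
        f"{e}{composition[e] if composition[e] != 1 else ''}" for e in elements
    )


@dataclass(frozen=True)
class TracerSpec:
    """One isotopic tracer: which element, which heavy isotope, and how many
    atoms of that element can carry label in this ion."""

    element: str
    isotope_mass_number: int
    n_labeled_positions: int

    def __post_init__(self):
        pair = (self.element, self.isotope_mass_number)
        if pair not in SUPPORTED_TRACERS:
            raise MethodValidationError(
                [f"unsupported tracer isotope {self.isotope_mass_number}"
                 f"{self.element}; supported: 2H, 13C, 15N, 18O, 34S"]
            )
        # n_labeled_positions == 0 is allowed as a degenerate tracer so a
        # dual-label setup can reduce exactly to a single-label one
        if self.n_labeled_positions < 0:
            raise MethodValidationError(
                [f"tracer {self.element}: n_labeled_positions must be >= 0"]
            )

    @property
    def mass_shift(self) -> float:
        """Exact per-atom mass shift in Da."""
        return TRACER_MASS_SHIFTS[(self.element, self.isotope_mass_number)]


@dataclass
class MzTolerance:
    """m/z matching tolerance, either relative (ppm) or absolute (Th)."""

    value: float
    unit: str  # "ppm" or "Th"

    def half_width(self, mz: float) -> float:
        """Absolute half-window in Th at the given m/z."""
        if self.unit == "ppm":
            return mz * self.value * 1e-6
        return self.value


@dataclass
class TargetIon:
    compound_name: str
    ion_name: str
    formula: dict[str, int]
    charge: int
    base_mz: float
    tracers: tuple[TracerSpec, ...]
    expected_rt: float
    rt_window: float = DEFAULTS["rt_window"]
    ms_level: int = 1
    precursor_mz: float | None = None
    is_characteristic: bool = False
    quantified_isotopologues: list = field(default_factory=list)
    # MS/MS targets may quantify a product ion whose formula is a subset of
    # the precursor's; when set, natural-abundance correction uses it.
    product_formula: dict[str, int] | None = None
    product_positions: int | None = None

    @property
    def is_dual_tracer(self) -> bool:
        return len(self.tracers) == 2

    def validate(self) -> list[str]:
        """Collect every invariant violation (empty list = valid)."""
        problems = []
        name = f"target {self.compound_name}/{self.ion_name}"
        if self.base_mz <= 0:
            problems.append(f"{name}: base_mz must be > 0")
        if self.rt_window <= 0:
            problems.append(f"{name}: rt_window must be > 0")
        if self.charge == 0:
            problems.append(f"{name}: charge must be nonzero")
        if self.ms_level not in (1, 2):
            problems.append(f"{name}: ms_level must be 1 or 2")
        if self.ms_level == 2 and self.precursor_mz is None:
            problems.append(f"{name}: ms_level 2 requires precursor_mz")
        if len(self.tracers) not in (1, 2):
            problems.append(f"{name}: 1 or 2 tracers required")
        for tracer in self.tracers:
            available = self.formula.get(tracer.element, 0)
            if tracer.n_labeled_positions > available:
                problems.append(
                    f"{name}: tracer {tracer.element} has "
                    f"{tracer.n_labeled_positions} labeled positions but the "
                    f"formula contains only {available} {tracer.element} atoms"
                )
        if len(self.tracers) == 2 and self.tracers[0].element == self.tracers[1].element:
            problems.append(f"{name}: dual tracers must label distinct elements")
        if not self.quantified_isotopologues:
            problems.append(f"{name}: quantified_isotopologues is empty")
        else:
            seen = set()
            for lc in self.quantified_isotopologues:
                key = tuple(lc) if isinstance(lc, (tuple, list)) else lc
                if key in seen:
                    problems.append(f"{name}: duplicate isotopologue {lc}")
                seen.add(key)
                if not self._label_in_bounds(lc):
                    problems.append(f"{name}: isotopologue {lc} out of tracer bounds")
        return problems

    def _label_in_bounds(self, label_count: LabelCount) -> bool:
        if self.is_dual_tracer:
            if not isinstance(label_count, (tuple, list)) or len(label_count) != 2:
                return False
            i, j = label_count
            return (0 <= i <= self.tracers[0].n_labeled_positions
                    and 0 <= j <= self.tracers[1].n_labeled_positions)
        if isinstance(label_count, (tuple, list)):
            return False
        return 0 <= label_count <= self.tracers[0].n_labeled_positions


def isotopologue_mz(target: TargetIon, label_count: LabelCount) -> float:
    """m/z of the isotopologue of *target* carrying the given label count(s).

    base_mz plus the exact tracer mass shifts divided by |charge|.
    A label count of 0 returns base_mz exactly.
    """
    if not target._label_in_bounds(label_count):
        raise MethodValidationError(
            [f"label count {label_count} out of bounds for "
             f"{target.compound_name}/{target.ion_name}"]
        )
    counts = (
        tuple(label_count) if isinstance(label_count, (tuple, list))
        else (label_count,)
    )
    shift = sum(c * t.mass_shift for c, t in zip(counts, target.tracers))
    return target.base_mz + shift / abs(target.charge)


@dataclass
class Method:
    targets: list[TargetIon]
    mz_tolerance: MzTolerance
    resolution_mode: str = "high_res"  # "low_res" or "high_res"
    smoothing_window: int = DEFAULTS["smoothing_window"]
    smoothing_order: int = DEFAULTS["smoothing_order"]
    noise_multiplier_k: float = DEFAULTS["noise_multiplier_k"]
    asymmetry_cap: float = DEFAULTS["asymmetry_cap"]
    correction_enabled: bool = True
    isotope_overrides: dict = field(default_factory=dict)

    @property
    def correction_mode(self) -> str:
        return {"low_res": "low_res_ms1", "high_res": "high_res_ms1"}[
            self.resolution_mode
        ]

    def isotope_table(self):
        """Isotope table with any per-method abundance overrides applied."""
        if not self.isotope_overrides:
            return ISOTOPE_TABLE
        table = {k: list(v) for k, v in ISOTOPE_TABLE.items()}
        for element, rows in self.isotope_overrides.items():
            table[element] = [tuple(r) for r in rows]
        return table

    def compounds(self) -> dict[str, list[TargetIon]]:
        groups: dict[str, list[TargetIon]] = {}
        for t in self.targets:
            groups.setdefault(t.compound_name, []).append(t)
        return groups

    def validate(self) -> list[str]:
        problems = []
        if self.resolution_mode not in ("low_res", "high_res"):
            problems.append(f"resolution_mode {self.resolution_mode!r} invalid")
        if self.mz_tolerance.value <= 0:
            problems.append("mz_tolerance must be > 0")
        if self.mz_tolerance.unit not in ("ppm", "Th"):
            problems.append(f"mz_tolerance unit {self.mz_tolerance.unit!r} invalid")
        if self.smoothing_window % 2 == 0 or self.smoothing_window <= self.smoothing_order:
            problems.append(
                "smoothing window must be odd and greater than the polynomial order"
            )
        if self.asymmetry_cap < 1:
            problems.append("asymmetry_cap must be >= 1")
        if not self.targets:
            problems.append("method has no targets")
        for target in self.targets:
            problems.extend(target.validate())
        for compound, ions in self.compounds().items():
            if not any(t.is_characteristic for t in ions):
                problems.append(
                    f"compound {compound!r} has no characteristic ion"
                )
        return problems


def _target_to_dict(t: TargetIon) -> dict:
    d = {
        "compound": t.compound_name,
        "ion": t.ion_name,
        "formula": format_formula(t.formula),
        "charge": t.charge,
        "base_mz": t.base_mz,
        "expected_rt": t.expected_rt,
        "rt_window": t.rt_window,
        "ms_level": t.ms_level,
        "is_characteristic": t.is_characteristic,
        "tracers": [
            {"element": tr.element, "isotope": tr.isotope_mass_number,
             "n_positions": tr.n_labeled_positions}
            for tr in t.tracers
        ],
        "isotopologues": [
            list(lc) if isinstance(lc, (tuple, list)) else lc
            for lc in t.quantified_isotopologues
        ],
    }
    if t.precursor_mz is not None:
        d["precursor_mz"] = t.precursor_mz
    if t.product_formula is not None:
        d["product_formula"] = format_formula(t.product_formula)
        d["product_positions"] = t.product_positions
    return d


def _target_from_dict(d: dict) -> TargetIon:
    tracers = tuple(
        TracerSpec(tr["element"], tr["isotope"], tr["n_positions"])
        for tr in d["tracers"]
    )
    dual = len(tracers) == 2
    isotopologues = [
        tuple(lc) if isinstance(lc, list) else lc for lc in d["isotopologues"]
    ] if not dual else [tuple(lc) for lc in d["isotopologues"]]
    return TargetIon(
        compound_name=d["compound"],
        ion_name=d.get("ion", d["compound"]),
        formula=parse_formula(d["formula"]),
        charge=d["charge"],
        base_mz=d["base_mz"],
        tracers=tracers,
        expected_rt=d["expected_rt"],
        rt_window=d.get("rt_window", DEFAULTS["rt_window"]),
        ms_level=d.get("ms_level", 1),
        precursor_mz=d.get("precursor_mz"),
        is_characteristic=d.get("is_characteristic", False),
        quantified_isotopologues=isotopologues,
        product_formula=(
            parse_formula(d["product_formula"]) if "product_formula" in d else None
        ),
        product_positions=d.get("product_positions"),
    )


def load_method(path) -> Method:
    """Load, default-fill and validate a method config file.

    Raises :class:`MethodValidationError` listing *every* violation found,
    not just the first.
    """
    with open(path) as fh:
        try:
            doc = json.load(fh)
        except json.JSONDecodeError as exc:
            raise MethodValidationError([f"invalid JSON: {exc}"]) from exc
    if doc.get("schema_version", SCHEMA_VERSION) != SCHEMA_VERSION:
        raise MethodValidationError(
            [f"unsupported schema_version {doc.get('schema_version')}"]
        )
    resolution_mode = doc.get("resolution_mode", "high_res")
    tol_doc = doc.get("mz_tolerance")
    if tol_doc is None:
        if resolution_mode == "low_res":
            tol = MzTolerance(DEFAULTS["mz_tolerance_th_lowres"], "Th")
        else:
            tol = MzTolerance(DEFAULTS["mz_tolerance_ppm_highres"], "ppm")
    elif "ppm" in tol_doc:
        tol = MzTolerance(float(tol_doc["ppm"]), "ppm")
    elif "th" in tol_doc or "Th" in tol_doc:
        tol = MzTolerance(float(tol_doc.get("th", tol_doc.get("Th"))), "Th")
    else:
        raise MethodValidationError(["mz_tolerance must specify 'ppm' or 'th'"])
    smoothing = doc.get("smoothing", {})
    try:
        targets = [_target_from_dict(d) for d in doc.get("targets", [])]
    except (KeyError, TypeError) as exc:
        raise MethodValidationError([f"malformed target entry: {exc!r}"]) from exc
    method = Method(
        targets=targets,
        mz_tolerance=tol,
        resolution_mode=resolution_mode,
        smoothing_window=int(smoothing.get("window", DEFAULTS["smoothing_window"])),
        smoothing_order=int(smoothing.get("order", DEFAULTS["smoothing_order"])),
        noise_multiplier_k=float(
            doc.get("noise_multiplier_k", DEFAULTS["noise_multiplier_k"])
        ),
        asymmetry_cap=float(doc.get("asymmetry_cap", DEFAULTS["asymmetry_cap"])),
        correction_enabled=bool(doc.get("correction_enabled", True)),
        isotope_overrides=doc.get("isotopes", {}),
    )
    problems = method.validate()
    if problems:
        raise MethodValidationError(problems)
    return method


def save_method(method: Method, path) -> None:
    doc = {
        "schema_version": SCHEMA_VERSION,
        "resolution_mode": method.resolution_mode,
        "mz_tolerance": (
            {"ppm": method.mz_tolerance.value}
            if method.mz_tolerance.unit == "ppm"
            else {"th": method.mz_tolerance.value}
        ),
        "smoothing": {
            "window": method.smoothing_window,
            "order": method.smoothing_order,
        },
        "noise_multiplier_k": method.noise_multiplier_k,
        "asymmetry_cap": method.asymmetry_cap,
        "correction_enabled": method.correction_enabled,
        "targets": [_target_to_dict(t) for t in method.targets],
    }
    if method.isotope_overrides:
        doc["isotopes"] = method.isotope_overrides
    Path(path).write_text(json.dumps(doc, indent=2) + "\n")
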