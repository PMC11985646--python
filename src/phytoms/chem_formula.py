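"""Molecular formulas and mass arithmetic for small-molecule MS.

All m/z bookkeeping in the annotation pipeline flows through this module:
formula parsing (tolerant of the ``C_16_H_32_O_2_`` and Unicode-subscript
dialects used in printed metabolite tables), nominal and monoisotopic
masses, singly-charged proton adduct m/z, signed ppm errors, and
exhaustive candidate-formula generation within a ppm tolerance.

The element masses come from a versioned plain-text isotope table shipped
with the package (``data/isotopes.tsv``) so that library code and any
external check read the same constants.
"""

from __future__ import annotations

import re
from collections.abc import Iterator, Mapping
from dataclasses import dataclass, field
from importlib import resources

__all__ = [
    "MolecularFormula",
    "AdductSpec",
    "MassMeasurement",
    "FormulaError",
    "PROTON_MASS",
    "ADDUCTS",
    "parse_formula",
    "nominal_mass",
    "monoisotopic_mass",
    "adduct_mz",
    "ppm_error",
    "generate_formulas",
    "hill_order",
]

#: Mass of the proton in Da. Electron mass is absorbed into this convention,
#: matching standard TOF calibration practice for [M+H]+/[M-H]- ions.
PROTON_MASS = 1.007276466


class FormulaError(ValueError):
    """Malformed formula string, unknown element, or invalid count."""


def _load_isotope_table() -> tuple[dict[str, float], dict[str, int]]:
    exact: dict[str, float] = {}
    nominal: dict[str, int] = {}
    text = resources.files("phytoms.data").joinpath("isotopes.tsv").read_text()
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        element, mass_number, exact_mass = line.split("\t")
        exact[element] = float(exact_mass)
        nominal[element] = int(mass_number)
    return exact, nominal


EXACT_MASS, NOMINAL_MASS = _load_isotope_table()

_SUBSCRIPT_TRANS = str.maketrans("₀₁₂₃₄₅₆₇₈₉", "0123456789")
_TOKEN_RE = re.compile(r"([A-Z][a-z]?)_?(\d*)_?")


def _hill_key(element: str) -> tuple[int, str]:
    # Hill order: C first, H second, then alphabetical.
    return {"C": (0, ""), "H": (1, "")}.get(element, (2, element))


@dataclass(frozen=True)
class MolecularFormula:
    """Immutable element→count map with mass semantics.

    Counts are strictly positive; elements with count zero are absent, so
    two formulas are equal iff their maps are equal.
    """

    counts: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        cleaned = {}
        for element, count in self.counts.items():
            if element not in EXACT_MASS:
                raise FormulaError(f"unknown element: {element!r}")
            if not isinstance(count, int) or count < 0:
                raise FormulaError(f"invalid count for {element}: {count!r}")
            if count > 0:
                cleaned[element] = count
        object.__setattr__(self, "counts", cleaned)

    @classmethod
    def parse(cls, text: str) -> "MolecularFormula":
        return parse_formula(text)

    def __getitem__(self, element: str) -> int:
        return self.counts.get(element, 0)

    def __add__(self, other: "MolecularFormula") -> "MolecularFormula":
        merged = dict(self.counts)
        for element, count in other.counts.items():
            merged[element] = merged.get(element, 0) + count
        return MolecularFormula(merged)

    def __sub__(self, other: "MolecularFormula") -> "MolecularFormula":
        merged = dict(self.counts)
        for element, count in other.counts.items():
            left = merged.get(element, 0) - count
            if left < 0:
                raise FormulaError(
                    f"subtraction leaves negative {element} count"
                )
            merged[element] = left
        return MolecularFormula(merged)

    def contains(self, other: "MolecularFormula") -> bool:
        return all(self[el] >= n for el, n in other.counts.items())

    def __bool__(self) -> bool:
        return bool(self.counts)

    def __hash__(self) -> int:
        return hash(frozenset(self.counts.items()))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, MolecularFormula):
            return NotImplemented
        return dict(self.counts) == dict(other.counts)

    def __str__(self) -> str:
        return hill_order(self)

    def __repr__(self) -> str:
        return f"MolecularFormula({hill_order(self)!r})"

    @property
    def monoisotopic_mass(self) -> float:
        return monoisotopic_mass(self)

    @property
    def nominal_mass(self) -> int:
        return nominal_mass(self)


def hill_order(f: MolecularFormula) -> str:
    """Plain Hill-order string: C, H, then remaining elements alphabetically."""
    parts = []
    for element in sorted(f.counts, key=_hill_key):
        n = f.counts[element]
        parts.append(element if n == 1 else f"{element}{n}")
    return "".join(parts)


def parse_formula(text: str) -> MolecularFormula:
    """Parse a formula string into a :class:`MolecularFormula`.

    Accepts the plain Hill dialect (``"C16H32O2"``), the underscore dialect
    printed in tables (``"C_16_H_32_O_2_"``), and Unicode subscripts
    (``"C₁₆H₃₂O₂"``). Repeated element symbols accumulate.
    """
    if not isinstance(text, str) or not text.strip():
        raise FormulaError("empty formula string")
    normalized = text.strip().translate(_SUBSCRIPT_TRANS).replace(" ", "")
    counts: dict[str, int] = {}
    pos = 0
    while pos < len(normalized):
        match = _TOKEN_RE.match(normalized, pos)
        if match is None or match.end() == pos:
            raise FormulaError(
                f"malformed token at position {pos} in {text!r}"
            )
        element, digits = match.groups()
        if element not in EXACT_MASS:
            raise FormulaError(f"unknown element {element!r} in {text!r}")
        if digits == "":
            count = 1
        else:
            if digits != str(int(digits)):
                raise FormulaError(f"zero-prefixed count in {text!r}")
            count = int(digits)
            if count == 0:
                raise FormulaError(f"zero count for {element} in {text!r}")
        counts[element] = counts.get(element, 0) + count
        pos = match.end()
    return MolecularFormula(counts)


def nominal_mass(f: MolecularFormula) -> int:
    """Integer mass: sum of principal-isotope mass numbers (C=12, H=1, ...)."""
    return sum(f.counts[el] * NOMINAL_MASS[el] for el in sorted(f.counts))


def monoisotopic_mass(f: MolecularFormula) -> float:
    """Exact mass: sum of principal-isotope masses from the shipped table.

    Summation order is fixed (sorted element symbols) so the value is
    independent of how the counts map was built.
    """
    return sum(f.counts[el] * EXACT_MASS[el] for el in sorted(f.counts))


@dataclass(frozen=True)
class AdductSpec:
    """A singly charged ESI adduct hypothesis."""

    name: str
    polarity: str  # "negative" | "positive"
    mass_shift: float  # signed Da added to the neutral monoisotopic mass
    charge: int

    def __post_init__(self) -> None:
        if abs(self.charge) != 1:
            raise ValueError("only singly charged adducts are supported")


#: The two adducts used throughout: deprotonation and protonation.
ADDUCTS: dict[str, AdductSpec] = {
    "[M-H]-": AdductSpec("[M-H]-", "negative", -PROTON_MASS, -1),
    "[M+H]+": AdductSpec("[M+H]+", "positive", +PROTON_MASS, +1),
}

#: Adduct implied by an ionization mode.
MODE_ADDUCT = {"negative": ADDUCTS["[M-H]-"], "positive": ADDUCTS["[M+H]+"]}


def _resolve_adduct(a: AdductSpec | str) -> AdductSpec:
    if isinstance(a, AdductSpec):
        return a
    try:
        return ADDUCTS[a]
    except KeyError:
        raise ValueError(f"unsupported adduct: {a!r}") from None


@dataclass(frozen=True)
class MassMeasurement:
    """An observed m/z paired with its theoretical value and signed ppm error."""

    mz: float
    theoretical_mz: float

    @property
    def error_ppm(self) -> float:
        return ppm_error(self.mz, self.theoretical_mz)


def adduct_mz(f: MolecularFormula, a: AdductSpec | str) -> float:
    """Theoretical m/z of formula ``f`` under adduct ``a`` ([M±H]∓ only)."""
    return monoisotopic_mass(f) + _resolve_adduct(a).mass_shift


def ppm_error(observed: float, theoretical: float) -> float:
    """Signed relative error ×10⁶: (obs − theo) / theo × 1e6."""
    if theoretical <= 0:
        raise ValueError("theoretical m/z must be positive")
    return (observed - theoretical) / theoretical * 1e6


#: Default element bounds for formula generation; covers the CHNOS space of
#: flavonoid glycosides up to ~900 Da. Configurable per call.
DEFAULT_BOUNDS: dict[str, int] = {"C": 60, "H": 100, "N": 6, "O": 20, "S": 3}


def _enumerate(
    elements: list[str],
    idx: int,
    remaining_lo: float,
    remaining_hi: float,
    bounds: Mapping[str, int],
    partial: dict[str, int],
) -> Iterator[dict[str, int]]:
    if idx == len(elements):
        if remaining_lo <= 0.0 <= remaining_hi:
            yield dict(partial)
        return
    element = elements[idx]
    mass = EXACT_MASS[element]
    # Smallest achievable mass for the remaining elements is 0, so prune only
    # on overshoot of the upper edge.
    max_n = min(bounds[element], int(remaining_hi // mass))
    for n in range(max_n + 1):
        used = n * mass
        if used > remaining_hi:
            break
        if n:
            partial[element] = n
        else:
            partial.pop(element, None)
        yield from _enumerate(
            elements, idx + 1, remaining_lo - used, remaining_hi - used,
            bounds, partial,
        )
    partial.pop(element, None)


def generate_formulas(
    mz: float,
    a: AdductSpec | str,
    tol_ppm: float,
    bounds: Mapping[str, int] | None = None,
) -> list[MolecularFormula]:
    """All formulas within ``bounds`` whose adduct m/z lies within ``tol_ppm``.

    Exhaustive over the bounded CHNOS(+) lattice; the result is sorted by
    absolute ppm error ascending, ties broken by Hill-order string. A
    ``tol_ppm`` of 0 returns exactly the formulas with the exact target mass.
    """
    if mz <= 0:
        raise ValueError("mz must be positive")
    if tol_ppm < 0:
        raise ValueError("tol_ppm must be non-negative")
    adduct = _resolve_adduct(a)
    if bounds is None:
        bounds = DEFAULT_BOUNDS
    if not bounds:
        raise ValueError("element bounds must be non-empty")
    for element in bounds:
        if element not in EXACT_MASS:
            raise FormulaError(f"unknown element in bounds: {element!r}")
    neutral = mz - adduct.mass_shift
    # Enumerate over a slightly widened window, then filter with the exact
    # ppm criterion, so the result is complete w.r.t. ppm_error's definition
    # (whose denominator is the theoretical m/z, not the neutral mass).
    half_width = neutral * tol_ppm * 1e-6 * 1.01 + 1e-6
    elements = sorted(bounds, key=lambda el: -EXACT_MASS[el])
    hits = []
    for counts in _enumerate(
        elements, 0, neutral - half_width, neutral + half_width, bounds, {}
    ):
        f = MolecularFormula(counts)
        err = abs(ppm_error(mz, adduct_mz(f, adduct)))
        if err <= tol_ppm:
            hits.append((err, hill_order(f), f))
    hits.sort(key=lambda item: (item[0], item[1]))
    return [f for _, _, f in hits]
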