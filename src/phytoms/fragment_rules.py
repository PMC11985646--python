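"""Fragmentation chemistry for flavonoid glycosides and phenolics.

Three rule families drive MS2 interpretation:

* **Neutral losses** — glycosyl residues lost intact by O-glycosides
  (hexosyl 162, deoxyhexosyl 146, pentosyl 132, hexuronyl 176, the
  rutinose-type disaccharide 308), ester-linked acyl residues
  (coumaroyl 146), cross-ring sugar cleavages diagnostic of C-glycosides
  (−90, −120), and ubiquitous small losses (H2O, CO2, CO, CH3).
* **Linkage classification** — cross-ring losses imply a C-glycoside;
  a full glycosyl loss without cross-ring losses implies an O-glycoside.
* **Retro-Diels-Alder (RDA) fragments** — C-ring cleavages of the
  flavonoid skeleton whose products are labeled by the broken bonds and
  the retained ring (1,3A⁻, 1,3B⁻, 1,4B⁻, ...). Each aglycone record
  stores the neutral-form formula of the charge-retaining piece; the ion
  m/z and the complementary neutral are derived from it, so the pair
  always conserves the precursor mass.

Rules and the curated aglycone library ship as editable JSON files under
``phytoms/data``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from itertools import combinations_with_replacement

from .chem_formula import MolecularFormula, monoisotopic_mass, nominal_mass, parse_formula

__all__ = [
    "NeutralLossRule",
    "AglyconeRecord",
    "LossMatch",
    "RdaUndefined",
    "load_rules",
    "load_aglycones",
    "loss_candidates",
    "classify_linkage",
    "rda_fragments",
    "match_aglycone",
]


@dataclass(frozen=True)
class NeutralLossRule:
    """One named neutral loss with nominal and exact masses."""

    name: str
    formula: MolecularFormula
    category: str  # sugar | acyl | small | cross_ring

    @property
    def nominal_loss(self) -> int:
        return nominal_mass(self.formula)

    @property
    def exact_loss(self) -> float:
        return monoisotopic_mass(self.formula)


@dataclass(frozen=True)
class AglyconeRecord:
    """A flavonoid/chalcone aglycone with diagnostic and RDA fragment data.

    ``rda_pieces`` maps a cleavage label (e.g. ``"1,3A"``) to the
    neutral-form formula of the piece that retains the charge; ``None``
    for subclasses without a C-ring pyranone (chalcones, aurones).
    """

    name: str
    formula: MolecularFormula
    subclass: str
    diagnostic_fragments: dict[str, tuple[int, ...]] = field(default_factory=dict)
    rda_pieces: dict[str, MolecularFormula] | None = None

    def __post_init__(self) -> None:
        if self.rda_pieces is not None:
            for label, piece in self.rda_pieces.items():
                if not self.formula.contains(piece):
                    raise ValueError(
                        f"{self.name}: RDA piece {label} ({piece}) is not a "
                        f"sub-formula of {self.formula}"
                    )

    def deprotonated_nominal(self) -> int:
        return nominal_mass(self.formula) - 1

    def diagnostic_set(self, polarity: str) -> frozenset[int]:
        """Printed diagnostic fragments plus predicted RDA ions (one mode)."""
        printed = set(self.diagnostic_fragments.get(polarity, ()))
        if self.rda_pieces is not None:
            printed.update(mz for _, mz in rda_fragments(self, polarity))
        return frozenset(printed)


@dataclass(frozen=True)
class LossMatch:
    """A (chain of) neutral-loss rule(s) explaining parent → fragment."""

    rules: tuple[NeutralLossRule, ...]
    parent_mz: float
    fragment_mz: float
    delta: float  # signed residual: (parent - fragment) - loss
    matched_at: str  # "nominal" | "exact"

    @property
    def name(self) -> str:
        return "+".join(r.name for r in self.rules)

    @property
    def nominal_loss(self) -> int:
        return sum(r.nominal_loss for r in self.rules)

    @property
    def exact_loss(self) -> float:
        return sum(r.exact_loss for r in self.rules)

    @property
    def categories(self) -> frozenset[str]:
        return frozenset(r.category for r in self.rules)

    @property
    def is_chain(self) -> bool:
        return len(self.rules) > 1


class RdaUndefined(ValueError):
    """No RDA partition is defined for this aglycone's subclass."""


def _data_json(filename: str) -> dict:
    text = resources.files("phytoms.data").joinpath(filename).read_text()
    return json.loads(text)


def load_rules(path: str | None = None) -> list[NeutralLossRule]:
    """Load the neutral-loss rule set (shipped JSON by default).

    Each rule's declared nominal loss is checked against its residue
    formula, so an edited rules file cannot silently disagree with the
    mass table.
    """
    if path is None:
        raw = _data_json("neutral_losses.json")
    else:
        with open(path) as fh:
            raw = json.load(fh)
    rules = []
    for entry in raw["rules"]:
        rule = NeutralLossRule(
            name=entry["name"],
            formula=parse_formula(entry["formula"]),
            category=entry["category"],
        )
        declared = entry.get("nominal_loss")
        if declared is not None and declared != rule.nominal_loss:
            raise ValueError(
                f"rule {rule.name}: declared nominal loss {declared} != "
                f"{rule.nominal_loss} from formula {rule.formula}"
            )
        rules.append(rule)
    return rules


def load_aglycones(path: str | None = None) -> list[AglyconeRecord]:
    """Load the curated aglycone library (shipped JSON by default)."""
    if path is None:
        raw = _data_json("aglycones.json")
    else:
        with open(path) as fh:
            raw = json.load(fh)
    records = []
    for entry in raw["aglycones"]:
        pieces = entry.get("rda_pieces")
        records.append(
            AglyconeRecord(
                name=entry["name"],
                formula=parse_formula(entry["formula"]),
                subclass=entry["subclass"],
                diagnostic_fragments={
                    mode: tuple(mzs)
                    for mode, mzs in entry["diagnostic_fragments"].items()
                },
                rda_pieces=None
                if pieces is None
                else {lbl: parse_formula(f) for lbl, f in pieces.items()},
            )
        )
    return records


_DEFAULT_RULES: list[NeutralLossRule] | None = None
_DEFAULT_AGLYCONES: list[AglyconeRecord] | None = None


def default_rules() -> list[NeutralLossRule]:
    global _DEFAULT_RULES
    if _DEFAULT_RULES is None:
        _DEFAULT_RULES = load_rules()
    return _DEFAULT_RULES


def default_aglycones() -> list[AglyconeRecord]:
    global _DEFAULT_AGLYCONES
    if _DEFAULT_AGLYCONES is None:
        _DEFAULT_AGLYCONES = load_aglycones()
    return _DEFAULT_AGLYCONES


def loss_candidates(
    parent_mz: float,
    fragment_mz: float,
    tol: float = 0.5,
    rules: list[NeutralLossRule] | None = None,
    level: str = "nominal",
) -> list[LossMatch]:
    """Neutral-loss explanations of a parent → fragment mass difference.

    Tries every single rule and every chain of two sugar/acyl rules; a
    candidate matches when its summed loss is within ``tol`` Da of
    ``parent_mz − fragment_mz``. ``level`` selects nominal (integer, the
    default — printed fragment tables carry integer m/z) or exact-mass
    matching. Results are sorted by absolute residual, ties by name.
    """
    if fragment_mz > parent_mz:
        raise ValueError("fragment_mz must not exceed parent_mz")
    if fragment_mz < 0:
        raise ValueError("fragment_mz must be non-negative")
    if tol <= 0:
        raise ValueError("tol must be positive")
    if level not in ("nominal", "exact"):
        raise ValueError(f"unknown matching level: {level!r}")
    if rules is None:
        rules = default_rules()
    observed = parent_mz - fragment_mz
    chainable = [r for r in rules if r.category in ("sugar", "acyl")]
    candidates: list[tuple[NeutralLossRule, ...]] = [(r,) for r in rules]
    candidates += list(combinations_with_replacement(chainable, 2))
    matches = []
    for combo in candidates:
        if level == "nominal":
            loss = float(sum(r.nominal_loss for r in combo))
        else:
            loss = sum(r.exact_loss for r in combo)
        delta = observed - loss
        if abs(delta) <= tol:
            matches.append(
                LossMatch(
                    rules=combo,
                    parent_mz=parent_mz,
                    fragment_mz=fragment_mz,
                    delta=delta,
                    matched_at=level,
                )
            )
    matches.sort(key=lambda m: (abs(m.delta), m.name))
    return matches


def classify_linkage(matches: list[LossMatch]) -> str:
    """Classify glycosidic linkage from one feature's loss matches.

    Returns ``"C_glycoside"`` if any cross-ring loss (−90/−120) matched;
    ``"O_glycoside"`` if a full glycosyl loss matched with no cross-ring
    loss; ``"none"`` otherwise. Order-invariant in the match list.
    """
    has_cross = any("cross_ring" in m.categories for m in matches)
    if has_cross:
        return "C_glycoside"
    has_sugar = any(m.categories == {"sugar"} for m in matches)
    if has_sugar:
        return "O_glycoside"
    return "none"


def rda_fragments(
    a: AglyconeRecord, polarity: str = "negative"
) -> list[tuple[str, int]]:
    """Predicted retro-Diels-Alder ion m/z values for one aglycone.

    Each ion is the stored charge-retaining piece minus (negative mode)
    or plus (positive mode) one proton, at nominal mass; labels carry the
    mode's charge sign (``"1,3A-"``). Raises :class:`RdaUndefined` for
    subclasses without a defined partition (chalcones, aurones) so the
    absence of a prediction is explicit, never silent.
    """
    if polarity not in ("negative", "positive"):
        raise ValueError(f"unknown polarity: {polarity!r}")
    if a.rda_pieces is None:
        raise RdaUndefined(
            f"no RDA partition defined for {a.name} (subclass {a.subclass})"
        )
    sign = -1 if polarity == "negative" else +1
    suffix = "-" if polarity == "negative" else "+"
    return [
        (label + suffix, nominal_mass(piece) + sign)
        for label, piece in a.rda_pieces.items()
    ]


@dataclass(frozen=True)
class AglyconeMatch:
    """Scored aglycone candidate from diagnostic-fragment matching."""

    record: AglyconeRecord
    score: float  # fraction of the diagnostic set observed, in [0, 1]
    matched: tuple[int, ...]  # diagnostic m/z values that were observed


def match_aglycone(
    fragment_mzs: list[float],
    polarity: str = "negative",
    tol: float = 0.5,
    library: list[AglyconeRecord] | None = None,
) -> list[AglyconeMatch]:
    """Rank aglycones by the fraction of their diagnostic fragments observed.

    An aglycone with an empty diagnostic set for the given mode scores 0.
    Results are sorted by descending score, ties by name.
    """
    if library is None:
        library = default_aglycones()
    if not library:
        raise ValueError("aglycone library must be non-empty")
    results = []
    for record in library:
        diagnostics = record.diagnostic_set(polarity)
        matched = tuple(
            sorted(
                d
                for d in diagnostics
                if any(abs(mz - d) <= tol for mz in fragment_mzs)
            )
        )
        score = len(matched) / len(diagnostics) if diagnostics else 0.0
        results.append(AglyconeMatch(record=record, score=score, matched=matched))
    results.sort(key=lambda m: (-m.score, m.record.name))
    return results
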