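"""GC-MS lipoid composition summaries.

Peaks arrive already named (library matching happened upstream in the
acquisition software); this module classifies each peak as a saturated or
unsaturated fatty acid — by rule, via the ring-plus-double-bond
equivalent (RDBE) — or defers to a curated sterol/other category, then
aggregates area percentages per class.

A free fatty acid or its methyl/ethyl ester has exactly two oxygens and
an RDBE of 1 from the carbonyl alone; any additional unsaturation raises
the RDBE, so RDBE = 1 ⇔ saturated and RDBE ≥ 2 ⇔ unsaturated. Sterols
and the mixed bag of long-chain alcohols/tocopherols grouped as "other"
(labeled hydrocarbons in some reports) follow no comparable computable
rule and are curated flags on the input.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from io import StringIO

import pandas as pd

from .chem_formula import MolecularFormula, parse_formula

__all__ = [
    "GcPeak",
    "CompositionSummary",
    "rdbe",
    "classify_fatty_acid",
    "summarize",
    "read_gc_table",
    "load_reference_gc_table",
]


@dataclass(frozen=True)
class GcPeak:
    """One named GC peak with its relative area percentage."""

    rt: float  # minutes
    name: str
    formula: MolecularFormula
    area_pct: float
    curated_category: str | None = None  # "sterol" | "other" for non-FA peaks

    def __post_init__(self) -> None:
        if self.rt < 0:
            raise ValueError("retention time must be non-negative")
        if self.area_pct < 0:
            raise ValueError("area percentage must be non-negative")


@dataclass(frozen=True)
class CompositionSummary:
    """Per-class area-percent totals over a peak table."""

    saturated_fa_pct: float
    unsaturated_fa_pct: float
    sterol_pct: float
    other_pct: float

    @property
    def total_pct(self) -> float:
        return (
            self.saturated_fa_pct
            + self.unsaturated_fa_pct
            + self.sterol_pct
            + self.other_pct
        )

    def rounded(self, ndigits: int = 2) -> dict[str, float]:
        """Class sums rounded for comparison with printed tables."""
        return {
            "saturated_fa_pct": round(self.saturated_fa_pct, ndigits),
            "unsaturated_fa_pct": round(self.unsaturated_fa_pct, ndigits),
            "sterol_pct": round(self.sterol_pct, ndigits),
            "other_pct": round(self.other_pct, ndigits),
            "total_pct": round(self.total_pct, ndigits),
        }


def rdbe(f: MolecularFormula) -> float:
    """Ring-plus-double-bond equivalents: C − H/2 + N/2 + 1 (CHNOS)."""
    return f["C"] - f["H"] / 2 + f["N"] / 2 + 1


def classify_fatty_acid(p: GcPeak) -> str:
    """``"saturated"`` / ``"unsaturated"`` / ``"not_fa"`` for one peak.

    A peak is a fatty acid (free acid or methyl/ethyl ester) iff its name
    contains "acid" and its formula carries exactly two oxygens. The
    carbonyl contributes the baseline RDBE of 1; more means unsaturation.
    """
    is_fa = "acid" in p.name.lower() and p.formula["O"] == 2
    if not is_fa:
        return "not_fa"
    return "saturated" if rdbe(p.formula) == 1 else "unsaturated"


def summarize(peaks: list[GcPeak]) -> CompositionSummary:
    """Aggregate area percentages into the four composition classes.

    Non-fatty-acid peaks must carry a curated category; a missing flag is
    an error rather than a silent drop, so every peak lands in exactly
    one class and the class sums always add up to the full total.
    """
    groups: dict[str, list[float]] = {
        "saturated": [], "unsaturated": [], "sterol": [], "other": [],
    }
    for p in peaks:
        kind = classify_fatty_acid(p)
        if kind == "not_fa":
            if p.curated_category not in ("sterol", "other"):
                raise ValueError(
                    f"peak {p.name!r} is not a fatty acid and has no curated "
                    f"category (got {p.curated_category!r})"
                )
            groups[p.curated_category].append(p.area_pct)
        else:
            groups[kind].append(p.area_pct)
    # fsum over sorted addends: exact permutation invariance of the sums
    return CompositionSummary(
        saturated_fa_pct=math.fsum(sorted(groups["saturated"])),
        unsaturated_fa_pct=math.fsum(sorted(groups["unsaturated"])),
        sterol_pct=math.fsum(sorted(groups["sterol"])),
        other_pct=math.fsum(sorted(groups["other"])),
    )


def _peaks_from_frame(df: pd.DataFrame) -> list[GcPeak]:
    peaks = []
    for row in df.itertuples(index=False):
        category = getattr(row, "curated_category", None)
        if category is None or (isinstance(category, float) and math.isnan(category)):
            category = None
        elif isinstance(category, str):
            category = category.strip() or None
        peaks.append(
            GcPeak(
                rt=float(row.rt_min),
                name=str(row.name),
                formula=parse_formula(str(row.formula)),
                area_pct=float(row.area_pct),
                curated_category=category,
            )
        )
    return peaks


def read_gc_table(path_or_buffer) -> list[GcPeak]:
    """Read a GC peak table CSV (rt_min, name, formula, area_pct[, curated_category])."""
    return _peaks_from_frame(pd.read_csv(path_or_buffer))


def load_reference_gc_table() -> list[GcPeak]:
    """The shipped 19-peak lipoid reference table (aerial-part extract)."""
    text = resources.files("phytoms.data").joinpath("gc_peaks.csv").read_text()
    return read_gc_table(StringIO(text))
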