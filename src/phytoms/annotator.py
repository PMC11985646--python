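"""Rule-based annotation of LC-MS/MS features.

The identification procedure mirrors routine practice for plant-extract
profiling on a high-resolution QTOF:

1. a candidate molecular formula must match the precursor m/z within a
   ppm tolerance (default 20) under the mode's adduct ([M−H]⁻ or [M+H]⁺);
2. library compounds with that formula are retained;
3. each MS2 peak is explained, where possible, by a neutral-loss chain
   from the precursor (up to two glycosyl/acyl residues plus one small
   loss) or by a diagnostic/RDA fragment of the candidate's aglycone;
4. the glycosidic linkage is classified from the observed losses
   (cross-ring −90/−120 ⇒ C-glycoside; intact glycosyl ⇒ O-glycoside);
5. candidates are scored by a weighted sum of the explained-peak
   fraction and the aglycone diagnostic coverage.

Retention time is carried through but never scored: positional isomers
(hexose vs galactose conjugates and the like) are genuinely
indistinguishable to this rule set and are reported as ties.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from importlib import resources

import pandas as pd

from .chem_formula import (
    MODE_ADDUCT,
    MolecularFormula,
    adduct_mz,
    hill_order,
    parse_formula,
    ppm_error,
)
from .fragment_rules import (
    AglyconeRecord,
    NeutralLossRule,
    classify_linkage,
    default_aglycones,
    default_rules,
    loss_candidates,
)

__all__ = [
    "MS2Feature",
    "CompoundEntry",
    "AnnotationResult",
    "AnnotatorConfig",
    "annotate_feature",
    "annotate_table",
    "load_library",
    "read_features_csv",
    "read_features_mgf",
    "write_report",
]


@dataclass(frozen=True)
class MS2Feature:
    """One LC feature: precursor, mode, retention time, MS2 peak list."""

    id: str
    rt: float  # minutes
    precursor_mz: float
    polarity: str  # "negative" | "positive"
    peaks: tuple[tuple[float, float | None], ...] = ()  # (mz, intensity)

    def __post_init__(self) -> None:
        if self.precursor_mz <= 0:
            raise ValueError("precursor m/z must be positive")
        if self.rt < 0:
            raise ValueError("retention time must be non-negative")
        if self.polarity not in ("negative", "positive"):
            raise ValueError(f"unknown polarity: {self.polarity!r}")
        ordered = tuple(sorted(self.peaks, key=lambda p: p[0]))
        object.__setattr__(self, "peaks", ordered)

    @property
    def peak_mzs(self) -> tuple[float, ...]:
        return tuple(mz for mz, _ in self.peaks)


@dataclass(frozen=True)
class CompoundEntry:
    """A library compound: formula, class, optional aglycone + residues."""

    name: str
    formula: MolecularFormula
    compound_class: str
    aglycone: AglyconeRecord | None = None
    decorations: tuple[NeutralLossRule, ...] = ()
    linkage_hint: str | None = None  # "C" for C-glycosides, else None

    def __post_init__(self) -> None:
        if self.aglycone is not None:
            expected = self.aglycone.formula
            for rule in self.decorations:
                expected = expected + rule.formula
            if expected != self.formula:
                raise ValueError(
                    f"{self.name}: formula {self.formula} != aglycone "
                    f"{self.aglycone.name} + residues ({expected})"
                )


@dataclass(frozen=True)
class AnnotationResult:
    """One ranked putative identification for one feature."""

    feature_id: str
    name: str
    formula: str
    adduct: str
    theoretical_mz: float
    error_ppm: float
    explained_peaks: tuple[tuple[float, str], ...]
    linkage: str  # "O_glycoside" | "C_glycoside" | "none"
    score: float
    rank: int
    ms1_only: bool = False


@dataclass(frozen=True)
class AnnotatorConfig:
    """Tunable thresholds and score weights of the annotation procedure."""

    ppm_tol: float = 20.0  # precursor formula gate
    fragment_tol: float = 0.5  # Da, nominal fragment matching
    max_chain_depth: int = 3  # ≤2 sugar/acyl + 1 small loss
    weight_explained: float = 0.7
    weight_aglycone: float = 0.3


_DEFAULT_CONFIG = AnnotatorConfig()


def _loss_chains(
    rules: list[NeutralLossRule], max_depth: int
) -> list[tuple[NeutralLossRule, ...]]:
    """Candidate loss chains: singles, ≤2 sugar/acyl, each ± one small loss."""
    chainable = [r for r in rules if r.category in ("sugar", "acyl")]
    small = [r for r in rules if r.category == "small"]
    chains: list[tuple[NeutralLossRule, ...]] = [(r,) for r in rules]
    if max_depth >= 2:
        for i, r1 in enumerate(chainable):
            for r2 in chainable[i:]:
                chains.append((r1, r2))
        for r1 in chainable:
            for s in small:
                chains.append((r1, s))
    if max_depth >= 3:
        for i, r1 in enumerate(chainable):
            for r2 in chainable[i:]:
                for s in small:
                    chains.append((r1, r2, s))
    return chains


def _explain_peak(
    mz: float,
    precursor_mz: float,
    chains: list[tuple[NeutralLossRule, ...]],
    entry: CompoundEntry,
    polarity: str,
    tol: float,
) -> str | None:
    """Best explanation for one fragment peak, or None.

    Aglycone diagnostics take precedence over loss-chain arithmetic: a
    low-mass RDA ion like 151 is far more informative than a numerically
    coincident multi-residue chain from the precursor.
    """
    if entry.aglycone is not None:
        for d in sorted(entry.aglycone.diagnostic_set(polarity)):
            if abs(mz - d) <= tol:
                return f"aglycone {entry.aglycone.name} fragment {d}"
    observed_loss = precursor_mz - mz
    best: tuple[float, str] | None = None
    if observed_loss > 0:
        for chain in chains:
            loss = sum(r.nominal_loss for r in chain)
            delta = abs(observed_loss - loss)
            if delta <= tol and (best is None or delta < best[0]):
                label = "-[" + "+".join(r.name for r in chain) + f"] ({loss})"
                best = (delta, label)
    return best[1] if best is not None else None


def annotate_feature(
    f: MS2Feature,
    lib: list[CompoundEntry],
    cfg: AnnotatorConfig = _DEFAULT_CONFIG,
) -> list[AnnotationResult]:
    """Ranked putative identifications of one feature against a library.

    An empty peak list does not abort annotation: the precursor formula
    gate still runs and results are flagged ``ms1_only`` with score 0.
    Results are sorted by descending score, ties by absolute ppm error
    then name; tied candidates share a (competition-style) rank, so
    indistinguishable positional isomers are reported, not dropped.
    """
    if not lib:
        raise ValueError("compound library must be non-empty")
    adduct = MODE_ADDUCT[f.polarity]
    chains = _loss_chains(default_rules(), cfg.max_chain_depth)
    ms1_only = len(f.peaks) == 0

    linkage = "none"
    if not ms1_only:
        feature_matches = []
        for mz in f.peak_mzs:
            if mz < f.precursor_mz:
                feature_matches.extend(
                    loss_candidates(f.precursor_mz, mz, cfg.fragment_tol)
                )
        linkage = classify_linkage(feature_matches)

    scored = []
    for entry in lib:
        theoretical = adduct_mz(entry.formula, adduct)
        err = ppm_error(f.precursor_mz, theoretical)
        if abs(err) > cfg.ppm_tol:
            continue
        explained: list[tuple[float, str]] = []
        if not ms1_only:
            for mz in f.peak_mzs:
                label = _explain_peak(
                    mz, f.precursor_mz, chains, entry, f.polarity,
                    cfg.fragment_tol,
                )
                if label is not None:
                    explained.append((mz, label))
            explained_frac = len(explained) / len(f.peaks)
            if entry.aglycone is not None:
                diagnostics = entry.aglycone.diagnostic_set(f.polarity)
                if diagnostics:
                    hit = sum(
                        1
                        for d in diagnostics
                        if any(
                            abs(mz - d) <= cfg.fragment_tol
                            for mz in f.peak_mzs
                        )
                    )
                    agl_score = hit / len(diagnostics)
                else:
                    agl_score = 0.0
                score = (
                    cfg.weight_explained * explained_frac
                    + cfg.weight_aglycone * agl_score
                )
            else:
                # No aglycone reference: the explained fraction is the
                # only evidence, at full weight.
                score = explained_frac
        else:
            score = 0.0
        scored.append(
            AnnotationResult(
                feature_id=f.id,
                name=entry.name,
                formula=hill_order(entry.formula),
                adduct=adduct.name,
                theoretical_mz=theoretical,
                error_ppm=err,
                explained_peaks=tuple(explained),
                linkage=linkage,
                score=score,
                rank=0,
                ms1_only=ms1_only,
            )
        )

    scored.sort(key=lambda r: (-r.score, abs(r.error_ppm), r.name))
    ranked = []
    for pos, result in enumerate(scored):
        if pos > 0 and (
            result.score == ranked[-1].score
            and abs(result.error_ppm) == abs(ranked[-1].error_ppm)
        ):
            rank = ranked[-1].rank
        else:
            rank = pos + 1
        ranked.append(replace(result, rank=rank))
    return ranked


_REPORT_COLUMNS = [
    "feature_id",
    "rt_min",
    "polarity",
    "precursor_mz",
    "candidate",
    "formula",
    "adduct",
    "theoretical_mz",
    "error_ppm",
    "score",
    "rank",
    "linkage",
    "explained_ms2",
    "flags",
]


def annotate_table(
    features: list[MS2Feature],
    lib: list[CompoundEntry],
    cfg: AnnotatorConfig = _DEFAULT_CONFIG,
    top_k: int = 1,
) -> pd.DataFrame:
    """Annotate a feature table; one row per feature × top-k candidate.

    Unannotated features keep their row with empty candidate fields.
    Output is deterministic: identical input and config give an
    identical frame.
    """
    rows = []
    for f in features:
        results = annotate_feature(f, lib, cfg)
        kept = [r for r in results if r.rank <= top_k]
        if not kept:
            rows.append(
                {
                    "feature_id": f.id,
                    "rt_min": f.rt,
                    "polarity": f.polarity,
                    "precursor_mz": f.precursor_mz,
                    "candidate": "",
                    "formula": "",
                    "adduct": "",
                    "theoretical_mz": float("nan"),
                    "error_ppm": float("nan"),
                    "score": float("nan"),
                    "rank": pd.NA,
                    "linkage": "",
                    "explained_ms2": "",
                    "flags": "unannotated",
                }
            )
            continue
        for r in kept:
            rows.append(
                {
                    "feature_id": f.id,
                    "rt_min": f.rt,
                    "polarity": f.polarity,
                    "precursor_mz": f.precursor_mz,
                    "candidate": r.name,
                    "formula": r.formula,
                    "adduct": r.adduct,
                    "theoretical_mz": round(r.theoretical_mz, 5),
                    "error_ppm": round(r.error_ppm, 1),
                    "score": round(r.score, 4),
                    "rank": r.rank,
                    "linkage": r.linkage,
                    "explained_ms2": "; ".join(
                        f"{mz:g} {label}" for mz, label in r.explained_peaks
                    ),
                    "flags": "MS1-only" if r.ms1_only else "",
                }
            )
    return pd.DataFrame(rows, columns=_REPORT_COLUMNS)


def load_library(
    path: str | None = None,
    aglycones: list[AglyconeRecord] | None = None,
) -> list[CompoundEntry]:
    """Load a compound library JSON (shipped 82-compound library by default)."""
    if path is None:
        text = resources.files("phytoms.data").joinpath(
            "compound_library.json"
        ).read_text()
        raw = json.loads(text)
    else:
        with open(path) as fh:
            raw = json.load(fh)
    if aglycones is None:
        aglycones = default_aglycones()
    by_name = {a.name: a for a in aglycones}
    rules = {r.name: r for r in default_rules()}
    entries = []
    for item in raw["compounds"]:
        aglycone = None
        if item.get("aglycone"):
            aglycone = by_name[item["aglycone"]]
        entries.append(
            CompoundEntry(
                name=item["name"],
                formula=parse_formula(item["formula"]),
                compound_class=item["class"],
                aglycone=aglycone,
                decorations=tuple(
                    rules[name] for name in item.get("decorations", ())
                ),
                linkage_hint=item.get("linkage"),
            )
        )
    return entries


def _parse_peaks(text: str) -> tuple[tuple[float, float | None], ...]:
    text = (text or "").strip()
    if not text:
        return ()
    peaks = []
    for token in text.split():
        if ":" in token:
            mz, intensity = token.split(":", 1)
            peaks.append((float(mz), float(intensity)))
        else:
            peaks.append((float(token), None))
    return tuple(peaks)


def read_features_csv(path_or_buffer) -> list[MS2Feature]:
    """Read features from CSV.

    Required columns: ``id``, ``rt_min``, ``polarity``, ``precursor_mz``,
    ``ms2`` (space-separated fragment m/z, optionally ``mz:intensity``).
    Extra columns are ignored.
    """
    df = pd.read_csv(path_or_buffer, dtype={"ms2": str})
    features = []
    for row in df.itertuples(index=False):
        ms2 = row.ms2 if isinstance(row.ms2, str) else ""
        features.append(
            MS2Feature(
                id=str(row.id),
                rt=float(row.rt_min),
                precursor_mz=float(row.precursor_mz),
                polarity=str(row.polarity),
                peaks=_parse_peaks(ms2),
            )
        )
    return features


def read_features_mgf(path: str) -> list[MS2Feature]:
    """Read features from an MGF file (PEPMASS/CHARGE/RTINSECONDS fields)."""
    from pyteomics import mgf

    features = []
    with mgf.MGF(path) as reader:
        for i, spectrum in enumerate(reader):
            params = spectrum["params"]
            charges = params.get("charge", [1])
            polarity = "negative" if int(charges[0]) < 0 else "positive"
            rt_s = float(params.get("rtinseconds", 0.0))
            peaks = tuple(
                (float(mz), float(intensity))
                for mz, intensity in zip(
                    spectrum["m/z array"], spectrum["intensity array"]
                )
            )
            features.append(
                MS2Feature(
                    id=str(params.get("title", f"spectrum_{i + 1}")),
                    rt=rt_s / 60.0,
                    precursor_mz=float(params["pepmass"][0]),
                    polarity=polarity,
                    peaks=peaks,
                )
            )
    return features


def load_reference_features() -> list[MS2Feature]:
    """The shipped 82-feature LC-MS/MS reference table."""
    from io import StringIO

    text = resources.files("phytoms.data").joinpath("lcms_features.csv").read_text()
    return read_features_csv(StringIO(text))


def write_report(df: pd.DataFrame, tsv_path=None, json_path=None) -> None:
    """Write an annotation report as TSV and/or JSON records."""
    if tsv_path is not None:
        df.to_csv(tsv_path, sep="\t", index=False)
    if json_path is not None:
        with open(json_path, "w") as fh:
            json.dump(df.to_dict(orient="records"), fh, indent=1, default=str)
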