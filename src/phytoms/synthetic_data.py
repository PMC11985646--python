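"""Ground-truthed synthetic inputs for every pipeline stage.

The generators invert the analysis rules: MS2 spectra are built by
forward application of the neutral-loss and RDA fragment rules to
library compounds, GC peak tables draw named compounds from class
templates with Dirichlet-distributed area percentages, and plate
absorbances come from a known 4PL curve. Each generated record carries
exactly one truth entry, and all randomness flows from a single seed
through spawned NumPy generators (one child stream per record), so a
(config, seed) pair reproduces its output bit for bit.

The defaults emulate the acquisition design of the profiling study this
pipeline targets: negative-mode ESI glycoside spectra, a ~19-peak lipoid
table totalling 66.59 % identified area, and MTT viability plates with a
two-fold serial dilution from 100 down to 1.5625 mg/mL in triplicate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .annotator import CompoundEntry, MS2Feature
from .chem_formula import MODE_ADDUCT, adduct_mz, parse_formula
from .dose_response import PlateMeasurement, logistic4, serial_dilution
from .fragment_rules import default_rules
from .gcms_composition import GcPeak

__all__ = [
    "NoiseConfig",
    "gen_ms2",
    "gen_gc_table",
    "gen_plate",
    "DEFAULT_GC_TOTAL_PCT",
]

#: Total identified area % emulated by the GC generator.
DEFAULT_GC_TOTAL_PCT = 66.59

# Exact masses of the small losses appended to rule-free spectra.
_WATER = parse_formula("H2O").monoisotopic_mass
_CO2 = parse_formula("CO2").monoisotopic_mass


@dataclass(frozen=True)
class NoiseConfig:
    """All noise magnitudes and the master seed for the generators."""

    precursor_ppm_sigma: float = 0.0
    fragment_da_sigma: float = 0.0
    decoys_per_spectrum: int = 0
    plate_sigma_pct: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(
            self.precursor_ppm_sigma,
            self.fragment_da_sigma,
            self.plate_sigma_pct,
        ) < 0 or self.decoys_per_spectrum < 0:
            raise ValueError("noise magnitudes must be non-negative")


def _spawn(seed: int, n: int) -> list[np.random.Generator]:
    """One child generator per record from a single master seed."""
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def _theoretical_peaks(entry: CompoundEntry, polarity: str) -> list[float]:
    """Forward-predicted fragment m/z values for one library compound."""
    precursor = adduct_mz(entry.formula, MODE_ADDUCT[polarity])
    peaks: list[float] = []
    running = precursor
    for rule in entry.decorations:
        running -= rule.exact_loss
        peaks.append(running)
    if entry.aglycone is not None:
        peaks.extend(float(d) for d in entry.aglycone.diagnostic_set(polarity))
    if entry.aglycone is None and not entry.decorations:
        # Acids, sugars etc.: ubiquitous small losses stand in for their
        # (unmodelled) class-specific fragmentation.
        peaks.extend([precursor - _WATER, precursor - _CO2])
    return sorted(set(p for p in peaks if p > 0))


def gen_ms2(
    lib: list[CompoundEntry],
    n: int,
    noise: NoiseConfig,
    polarity: str = "negative",
) -> tuple[list[MS2Feature], list[dict]]:
    """Generate ``n`` MS2 features by forward application of the rules.

    Per feature: a library compound is drawn, its precursor m/z receives
    Gaussian ppm noise, its rule-derived fragments receive Gaussian Da
    jitter, and uniform decoy peaks are added on [50, precursor−5] —
    resampled whenever they land within 1 Da of any rule-derived mass,
    so decoys never collide with a real explanation by construction.
    Returns the features and a parallel truth list.
    """
    if not lib:
        raise ValueError("compound library must be non-empty")
    rngs = _spawn(noise.seed, n)
    features, truth = [], []
    rule_losses = [r.nominal_loss for r in default_rules()]
    for i, rng in enumerate(rngs):
        entry = lib[int(rng.integers(len(lib)))]
        true_mz = adduct_mz(entry.formula, MODE_ADDUCT[polarity])
        precursor = true_mz * (
            1.0 + rng.normal(0.0, noise.precursor_ppm_sigma) * 1e-6
        )
        clean = _theoretical_peaks(entry, polarity)
        forbidden = clean + [true_mz - loss for loss in rule_losses]
        peaks = [
            (mz + rng.normal(0.0, noise.fragment_da_sigma), 100.0)
            for mz in clean
        ]
        lo, hi = 50.0, max(51.0, true_mz - 5.0)
        for _ in range(noise.decoys_per_spectrum):
            for _attempt in range(100):
                decoy = float(rng.uniform(lo, hi))
                if all(abs(decoy - m) > 1.0 for m in forbidden):
                    break
            peaks.append((decoy, float(rng.uniform(5.0, 50.0))))
        features.append(
            MS2Feature(
                id=f"synth_{i + 1}",
                rt=float(rng.uniform(1.0, 20.0)),
                precursor_mz=float(precursor),
                polarity=polarity,
                peaks=tuple(peaks),
            )
        )
        truth.append(
            {
                "id": f"synth_{i + 1}",
                "name": entry.name,
                "formula": str(entry.formula),
                "polarity": polarity,
            }
        )
    return features, truth


#: (name, formula) templates per GC composition class.
GC_TEMPLATES: dict[str, list[tuple[str, str]]] = {
    "saturated": [
        ("Palmitic acid", "C16H32O2"),
        ("Palmitic acid, methyl ester", "C17H34O2"),
        ("Stearic acid", "C18H36O2"),
        ("Stearic acid, methyl ester", "C19H38O2"),
    ],
    "unsaturated": [
        ("Oleic acid", "C18H34O2"),
        ("Oleic acid, methyl ester", "C19H36O2"),
        ("Linoleic acid, methyl ester", "C19H34O2"),
        ("Linolenic acid", "C18H30O2"),
    ],
    "sterol": [
        ("Stigmasterol", "C29H48O"),
        ("Stigmastanol", "C29H52O"),
        ("Sitostenone", "C29H48O"),
        ("Betulin", "C30H50O2"),
    ],
    "other": [
        ("Tocopherol", "C29H50O2"),
        ("Heptatriacotanol", "C37H76O"),
    ],
}


def gen_gc_table(
    n: int,
    noise: NoiseConfig,
    total_pct: float = DEFAULT_GC_TOTAL_PCT,
    categories: tuple[str, ...] = ("saturated", "unsaturated", "sterol", "other"),
) -> tuple[list[GcPeak], list[dict]]:
    """Generate a GC peak table with Dirichlet areas summing to ``total_pct``."""
    if n < 1:
        raise ValueError("need at least one peak")
    rng = np.random.default_rng(np.random.SeedSequence(noise.seed).spawn(1)[0])
    areas = rng.dirichlet(np.ones(n)) * total_pct
    rts = np.sort(rng.uniform(25.0, 43.0, size=n))
    peaks, truth = [], []
    for i in range(n):
        category = categories[int(rng.integers(len(categories)))]
        name, formula = GC_TEMPLATES[category][
            int(rng.integers(len(GC_TEMPLATES[category])))
        ]
        curated = category if category in ("sterol", "other") else None
        peaks.append(
            GcPeak(
                rt=float(rts[i]),
                name=name,
                formula=parse_formula(formula),
                area_pct=float(areas[i]),
                curated_category=curated,
            )
        )
        truth.append({"index": i, "name": name, "category": category})
    return peaks, truth


def gen_plate(
    top: float = 100.0,
    bottom: float = 0.0,
    ic50: float = 1.66,
    hill: float = 1.0,
    dilution: list[float] | None = None,
    replicates: int = 3,
    noise: NoiseConfig = NoiseConfig(),
    control_abs: float = 1.0,
) -> list[PlateMeasurement]:
    """Simulate an MTT viability plate from a known 4PL curve.

    The default design is a two-fold serial dilution from 100 mg/mL over
    seven steps (ending at 1.5625) in triplicate, plus control wells.
    Absorbances are ``control_abs · v(c)/100`` plus Gaussian noise of
    ``plate_sigma_pct`` percent of the control absorbance, floored at 0.
    """
    if dilution is None:
        dilution = serial_dilution(100.0, 2.0, 7)
    rng = np.random.default_rng(np.random.SeedSequence(noise.seed).spawn(1)[0])
    sigma = noise.plate_sigma_pct / 100.0 * control_abs
    wells = []
    for rep in range(replicates):
        wells.append(
            PlateMeasurement(
                concentration=0.0,
                absorbance=max(0.0, control_abs + rng.normal(0.0, sigma)),
                replicate=rep,
                is_control=True,
            )
        )
    conc = np.asarray(dilution, dtype=float)
    expected = logistic4(conc, top, bottom, np.log10(ic50), hill)
    for rep in range(replicates):
        for c, v in zip(conc, expected):
            wells.append(
                PlateMeasurement(
                    concentration=float(c),
                    absorbance=max(
                        0.0, control_abs * v / 100.0 + rng.normal(0.0, sigma)
                    ),
                    replicate=rep,
                )
            )
    return wells
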