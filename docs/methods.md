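# Methods

This note documents the models and procedures implemented in `phytoms`,
the parameter choices that matter, what the synthetic-data generators do
and do not emulate, and the package's known limitations.

## Mass arithmetic

All masses derive from a versioned plain-text isotope table
(`phytoms/data/isotopes.tsv`: principal-isotope exact masses for
H, C, N, O, S, P, Na from the CODATA/IUPAC atomic-mass evaluation).
Nominal mass sums integer mass numbers (C=12, H=1, N=14, O=16, S=32) —
this, not a rounded average mass, is what "M.Wt" columns in GC tables
print. Monoisotopic mass sums the exact masses in a fixed element order
so the value is independent of how a formula was built.

Adducts are restricted to singly charged protonation states. The charge
carrier is the proton at 1.007276466 Da, i.e. `[M−H]⁻ = M − 1.007276`;
the electron mass is absorbed into this convention, matching standard
TOF calibration practice. Consequently the gap between a compound's
`[M+H]⁺` and `[M−H]⁻` ions is exactly 2 × 1.007276 Da.

Candidate-formula generation enumerates the bounded element lattice
recursively (heaviest element first, pruning on the remaining mass
window), then filters with the exact signed-ppm criterion so the result
is complete with respect to the ppm-error definition. Default bounds
C≤60, H≤100, N≤6, O≤20, S≤3 cover flavonoid glycosides to ~900 Da;
they are a per-call argument. Observed m/z values from printed tables
are never treated as ground truth for this arithmetic — several printed
precursor masses are internally inconsistent with their own printed
formulas and ppm errors (by 20–190 ppm), and the pipeline records both
observed and theoretical values instead of reconciling them.

## Fragmentation rules

Neutral losses are stored as residue formulas, from which nominal and
exact losses are derived (and cross-checked at load time). Matching is
nominal-integer by default with a 0.5 Da tolerance because printed MS²
columns carry integer fragment m/z; an exact-mass mode exists for
high-accuracy synthetic spectra. A loss of 146 Da is genuinely ambiguous
(deoxyhexosyl vs coumaroyl); both rules are always returned and the
annotator leaves the choice to scoring context rather than resolving it
silently.

Linkage classification implements the standard diagnostic: cross-ring
sugar cleavages (−90, −120 Da) occur only when the sugar is C-bonded to
the aglycone and cannot be lost intact, so any cross-ring match ⇒
C-glycoside; an intact glycosyl loss (162/146/132/176/308) without
cross-ring losses ⇒ O-glycoside.

Retro-Diels-Alder fragments are not derived from structure graphs.
Each aglycone record stores, per cleavage label, the neutral-form
formula of the charge-retaining piece (e.g. the 5,7-dihydroxy A-ring
¹,³A piece of most flavonoids is C₇H₄O₄, giving the ubiquitous m/z 151
anion); the ion is that formula ∓ one proton at nominal mass and the
complementary neutral is the aglycone minus the piece, so the
conservation law `ion + neutral = [M∓H]∓` holds identically and is
enforced by a library-wide test. Chalcones and aurones lack the C-ring
pyranone; asking for their RDA fragments raises an explicit
`RdaUndefined` rather than returning an empty list.

The shipped aglycone library covers the 15 aglycones underlying the
82-compound reference library (quercetin, kaempferol, isorhamnetin,
syringetin, rhamnetin, kaempferide, luteolin, apigenin, acacetin,
baicalein, naringenin, eriodictyol, hesperetin, maritimetin, okanin),
each with the integer diagnostic fragments reported for it in the
source feature tables. Both files are editable JSON with the schema
shown in the files themselves.

## Annotation

For a feature, candidates are the library entries whose formula matches
the precursor within the ppm gate (default 20 ppm — the conventional
QTOF identification limit) under the mode's adduct. Each MS² peak is
explained, if possible, first by an aglycone diagnostic/RDA fragment,
then by a neutral-loss chain from the precursor of depth ≤ 3 (at most
two glycosyl/acyl residues plus one small loss — the deepest pattern in
practice, e.g. coumaroyl + hexosyl, or disaccharide + H₂O). The score is

    0.7 · (explained-peak fraction) + 0.3 · (aglycone diagnostic coverage)

with configurable weights; entries without an aglycone reference are
scored on the explained fraction alone. These weights are a design
decision of this package — profiling papers do not state how many
fragments sufficed for an identification — and are exposed in
`AnnotatorConfig`.

Retention time is carried through but never scored: no RT model is
available, so positional and stereochemical isomers tie. Ties share a
competition-style rank and are all reported. Recovery statistics in the
tests therefore count a feature as recovered when the true compound is
in the rank-1 tie group; with three indistinguishable quercetin
O-hexosides in the library, demanding a unique first row would be
pretending to information the data does not contain.

An empty peak list does not abort annotation: the formula gate still
runs and results are flagged `MS1-only` with score 0.

On the shipped 82-feature reference table (transcribed verbatim,
including its defects), 48/82 features rank their reported compound in
the rank-1 tie group at the 20 ppm gate; this value is frozen as a
regression test. The misses are rows whose printed precursor m/z
contradicts the printed formula by far more than 20 ppm — no mass-based
gate can recover those, and widening the gate would trade them for
false positives.

## GC-MS composition

A peak is a fatty acid (free or methyl/ethyl ester) iff its name
contains "acid" and its formula has exactly two oxygens; saturation is
computed, not curated: RDBE = 1 means the ester/acid carbonyl only
(saturated), RDBE ≥ 2 means genuine unsaturation. Sterols and the
heterogeneous "other" group (long-chain alcohols, tocopherol, a cholate
ester — often labeled "hydrocarbons" in composition tables) follow no
computable rule that matches how such tables are actually grouped, so
they are curated flags validated by reproducing the reference class
totals (8.69 / 11.38 / 39.92 / 6.60 / 66.59 %). Class sums use `fsum`
over sorted addends, making `summarize` exactly permutation-invariant.

## Dose-response

Viability is `absorbance(test) / absorbance(control) × 100`. The 4PL
model is parameterized in log10 concentration with hill > 0 meaning
viability falls with dose; the curve equals (top+bottom)/2 at the IC50
by construction. Fits are bounded: log10(IC50) within the tested range
×[0.01, 100], hill in [0.01, 50]. `se_ic50` comes from the fit
covariance by the delta method (`ic50 · ln10 · se(log10 ic50)`) and is
labeled a standard error explicitly, since published "±" values often
leave SE vs SD unstated.

Untreated control wells enter the fit as zero-concentration points,
where the 4PL limit is exactly `top`. This matters: in the emulated
assay design (two-fold dilution from 100 down to 1.5625 mg/mL with an
IC50 near 1.66), the lowest tested dose sits at the IC50, so the data
alone never reach the upper plateau; with a free, unanchored top the
IC50 estimate is biased by ~25% at 5% noise, while control-anchored
fits recover the truth to ~1% in the mean over 500 seeded plates.
Controls defining 100% viability is precisely what the normalization
already assumes. Replicates are fitted as individual points, not
pre-averaged, so the SE reflects replicate scatter.

Published extract IC50 values cannot be reproduced without the raw
absorbances, which are not public; the package's acceptance surface for
this module is therefore parameter recovery on its own synthetic plates.

## Synthetic data

Generators invert the analysis rules. MS2 spectra: draw a library
compound, apply Gaussian ppm noise to the theoretical precursor,
emit the sequential decoration-loss peaks (exact masses) plus the
aglycone's diagnostic/RDA ions, jitter fragments with Gaussian Da
noise, and add uniform decoys on [50, precursor−5] Da that are
resampled until ≥1 Da away from every rule-derived mass — decoys are
plausible but never collide with a real explanation, by construction.
Compounds with neither aglycone nor decorations (acids, sugars) get
H₂O/CO₂ loss peaks as a stand-in for their unmodelled class-specific
fragmentation. GC tables: draw names/formulas from per-class templates
with Dirichlet-distributed areas scaled to a configured total (default
66.59%). Plates: absorbances from a known 4PL curve with Gaussian noise
as a percentage of the control absorbance, floored at zero.

All randomness flows from one seed through `numpy.random.SeedSequence`
spawning (one child stream per record), so output is reproducible bit
for bit and insensitive to record count changes upstream.

What the generators do **not** emulate — and hence what passing tests
cannot show about real data: chromatographic peak shapes and RT
structure, isotope envelopes, in-source fragmentation, intensity
response curves, co-eluting chimeric spectra, and real decoy structure
(real contaminant fragments can be rule-coincident; synthetic decoys
are constructed not to be). Recovery rates on synthetic spectra are
therefore upper bounds.

Problem sizes used in the routine test run — 200 noisy spectra for
annotation recovery, 500 plates for IC50 recovery, lattices up to
~10⁵ formulas for the enumeration cross-check — were chosen so the
whole suite completes in well under a minute while keeping Monte-Carlo
standard errors far below the asserted margins.

## Numerical choices and degenerate inputs

* Formula windows are enumerated slightly wide, then filtered with the
  exact ppm criterion; ties in the output ordering break by Hill string.
* Loss-candidate matches sort by absolute residual, then rule name.
* `fit_4pl` refuses < 5 distinct positive concentrations and constant
  responses with explicit errors; optimizer failure raises, never
  returns silently.
* Empty formulas have mass 0; empty peak tables summarize to all-zero
  compositions; empty feature lists produce an empty, fully typed
  report.

## Limitations

* Adducts beyond ±H (Na⁺, NH₄⁺), multiple charging, and isotope-pattern
  scoring are out of scope.
* The RDA table covers the shipped aglycone subclasses; novel
  substitution patterns require a new partition entry (validated
  automatically by the conservation test).
* No spectral-library cosine matching and no de novo elucidation: the
  annotator ranks hypotheses from a finite compound library.
* GC peaks must arrive named; deconvolution, retention indices and
  NIST/WILEY matching happen upstream.
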