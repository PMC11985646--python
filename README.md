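# phytoms

Rule-based annotation and profiling tools for untargeted metabolomics of
plant extracts — built around the chemistry of flavonoid glycosides and
phenolics as they fragment in ESI-MS/MS, with companion modules for GC-MS
lipoid composition summaries and MTT-assay IC50 estimation.

The package targets the common workflow of phytochemical profiling papers:
a crude extract (the motivating system is *Bidens pilosa* aerial parts) is
run on a high-resolution LC-MS/MS in negative and positive mode, on a GC-MS
for the saponifiable/lipoid fraction, and through a serial-dilution
viability assay. `phytoms` turns each of those outputs into reproducible,
testable computations:

* **`chem_formula`** — molecular formula parsing (tolerant of the
  `C_16_H_32_O_2_` and Unicode-subscript dialects used in printed tables),
  nominal and monoisotopic masses from a shipped isotope table, `[M−H]⁻` /
  `[M+H]⁺` adduct m/z (proton-mass convention, 1.007276 Da), signed ppm
  errors, and exhaustive candidate-formula generation within a ppm
  tolerance over a bounded CHNOS lattice.
* **`fragment_rules`** — the neutral-loss rule set (hexosyl 162,
  deoxyhexosyl 146, pentosyl 132, hexuronyl 176, rutinose-type
  disaccharide 308, coumaroyl 146, cross-ring −90/−120, H₂O/CO₂/CO/CH₃),
  O- vs C-glycoside linkage classification, and retro-Diels-Alder (RDA)
  fragment prediction (¹,³A⁻, ¹,³B⁻, ¹,⁴B⁻, …) for a curated library of 15
  flavonoid/chalcone aglycones, with mass conservation guaranteed by
  construction.
* **`annotator`** — the pipeline stage: formula gate at 20 ppm → library
  match → per-peak explanation by loss chains and aglycone diagnostics →
  linkage class → ranked, scored report (TSV/JSON; MGF and CSV input).
* **`gcms_composition`** — fatty-acid saturation classification via the
  ring-plus-double-bond equivalent (RDBE = C − H/2 + N/2 + 1) and
  per-class area-percent aggregation.
* **`dose_response`** — viability percentages and four-parameter logistic
  IC50 fitting with standard errors.
* **`synthetic_data`** — seeded generators that invert the rules, so every
  stage is testable with zero external data.

## Worked example

Annotate the classic quercetin-3-O-glucoside feature — precursor m/z
463.0918 in negative mode with fragments 301/283/255/151:

```python
from phytoms.annotator import MS2Feature, annotate_feature, load_library

lib = load_library()   # 82 reference compounds
feature = MS2Feature(
    id="peak_8", rt=6.18, precursor_mz=463.0918, polarity="negative",
    peaks=((301.0, None), (283.0, None), (255.0, None), (151.0, None)),
)
for r in annotate_feature(feature, lib):
    if r.rank == 1:
        print(r.name, r.formula, round(r.error_ppm, 1), r.linkage, round(r.score, 4))
```

prints

```
Hyperoside C21H20O12 7.8 O_glycoside 0.7857
Isoquercitrin C21H20O12 7.8 O_glycoside 0.7857
Quercetin-O-hexoside C21H20O12 7.8 O_glycoside 0.7857
```

All three rank-1 candidates are quercetin O-hexosides: hexose
stereochemistry (glucoside vs galactoside) is invisible to mass spectra,
so the annotator reports the tie instead of picking one arbitrarily —
distinguishing them needs retention-time standards. The per-peak
explanations of the top candidate read:

```
151.0 -> aglycone quercetin fragment 151     # the 1,3A- RDA ion
255.0 -> aglycone quercetin fragment 255
283.0 -> -[hexosyl+water] (180)
301.0 -> -[hexosyl] (162)                    # intact sugar loss => O-glycoside
```

The same machinery exists as a CLI:

```bash
phytoms annotate --input features.mgf --out report.tsv --ppm 20
phytoms gcsum    --input peaks.csv --out summary.json
phytoms ic50     --input plate.csv --out fit.json
phytoms simulate ms2 --seed 7 --out sim/
```

`phytoms gcsum` on the shipped 19-peak lipoid table prints

```json
{"saturated_fa_pct": 8.69, "unsaturated_fa_pct": 11.38, "sterol_pct": 39.92,
 "other_pct": 6.6, "total_pct": 66.59, "n_peaks": 19}
```

— saturated vs unsaturated decided per peak by the RDBE rule, sterols and
the mixed "other" group by curated flags.

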