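{
  "version": "1.0",
  "comment": "Neutral-loss rules for flavonoid glycoside / phenolic MS2 interpretation. nominal_loss is derived from the residue formula at load time and checked against the expected integer mass. Categories: sugar (full glycosyl residues, lost intact by O-glycosides), acyl (ester-linked acids), cross_ring (partial sugar losses diagnostic of C-glycosides), small (ubiquitous small-molecule losses).",
  "rules": [
    {"name": "hexosyl", "formula": "C6H10O5", "nominal_loss": 162, "category": "sugar"},
    {"name": "deoxyhexosyl", "formula": "C6H10O4", "nominal_loss": 146, "category": "sugar"},
    {"name": "pentosyl", "formula": "C5H8O4", "nominal_loss": 132, "category": "sugar"},
    {"name": "hexuronyl", "formula": "C6H8O6", "nominal_loss": 176, "category": "sugar"},
    {"name": "deoxyhexosyl-hexosyl", "formula": "C12H20O9", "nominal_loss": 308, "category": "sugar"},
    {"name": "coumaroyl", "formula": "C9H6O2", "nominal_loss": 146, "category": "acyl"},
    {"name": "cross-ring-120", "formula": "C4H8O4", "nominal_loss": 120, "category": "cross_ring"},
    {"name": "cross-ring-90", "formula": "C3H6O3", "nominal_loss": 90, "category": "cross_ring"},
    {"name": "water", "formula": "H2O", "nominal_loss": 18, "category": "small"},
    {"name": "CO2", "formula": "CO2", "nominal_loss": 44, "category": "small"},
    {"name": "CO", "formula": "CO", "nominal_loss": 28, "category": "small"},
    {"name": "methyl", "formula": "CH3", "nominal_loss": 15, "category": "small"}
  ]
}
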