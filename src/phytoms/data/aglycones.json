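{
  "version": "1.0",
  "comment": "Curated flavonoid/chalcone aglycone library. diagnostic_fragments are the integer fragment m/z values reported for each aglycone in the source feature tables, keyed by ionization mode. rda_pieces give the neutral-form molecular formula of the charge-retaining retro-Diels-Alder cleavage product for each cleavage label; the ion m/z is that formula's nominal mass minus (negative mode) or plus (positive mode) one proton, and the complementary neutral is the aglycone formula minus the piece, so mass conservation holds by construction. Aurones and chalcones lack a C-ring pyranone and carry no RDA partition.",
  "aglycones": [
    {
      "name": "quercetin",
      "formula": "C15H10O7",
      "subclass": "flavonol",
      "diagnostic_fragments": {"negative": [255, 193, 151, 135, 121], "positive": []},
      "rda_pieces": {"1,3A": "C7H4O4", "1,3B": "C8H6O3", "1,4B": "C9H8O4", "0,2A": "C7H4O3"}
    },
    {
      "name": "kaempferol",
      "formula": "C15H10O6",
      "subclass": "flavonol",
      "diagnostic_fragments": {"negative": [257, 135], "positive": []},
      "rda_pieces": {"1,3A": "C7H4O4", "1,3B": "C8H6O2", "0,3A": "C7H4O3"}
    },
    {
      "name": "isorhamnetin",
      "formula": "C16H12O7",
      "subclass": "flavonol",
      "diagnostic_fragments": {"negative": [300, 269, 151, 107], "positive": []},
      "rda_pieces": {"1,3A": "C7H4O4", "1,3B": "C9H8O3"}
    },
    {
      "name": "syringetin",
      "formula": "C17H14O8",
      "subclass": "flavonol",
      "diagnostic_fragments": {"negative": [], "positive": []},
      "rda_pieces": {"1,3A": "C7H4O4", "1,3B": "C10H10O4"}
    },
    {
      "name": "rhamnetin",
      "formula": "C16H12O7",
      "subclass": "flavonol",
      "diagnostic_fragments": {"negative": [], "positive": [299]},
      "rda_pieces": {"1,3A": "C8H6O4", "1,3B": "C8H6O3"}
    },
    {
      "name": "kaempferide",
      "formula": "C16H12O6",
      "subclass": "flavonol",
      "diagnostic_fragments": {"negative": [], "positive": []},
      "rda_pieces": {"1,3A": "C7H4O4", "1,3B": "C9H8O2"}
    },
    {
      "name": "luteolin",
      "formula": "C15H10O6",
      "subclass": "flavone",
      "diagnostic_fragments": {"negative": [257, 177, 151, 133, 107], "positive": []},
      "rda_pieces": {"1,3A": "C7H4O4", "1,3B": "C8H6O2"}
    },
    {
      "name": "apigenin",
      "formula": "C15H10O5",
      "subclass": "flavone",
      "diagnostic_fragments": {"negative": [159, 151, 133, 117], "positive": []},
      "rda_pieces": {"1,3A": "C7H4O4", "1,3B": "C8H6O"}
    },
    {
      "name": "acacetin",
      "formula": "C16H12O5",
      "subclass": "flavone",
      "diagnostic_fragments": {"negative": [268, 151, 131], "positive": []},
      "rda_pieces": {"1,3A": "C7H4O4", "1,3B": "C9H8O"}
    },
    {
      "name": "baicalein",
      "formula": "C15H10O5",
      "subclass": "flavone",
      "diagnostic_fragments": {"negative": [117], "positive": []},
      "rda_pieces": {"1,3A": "C7H4O5", "1,3B": "C8H6"}
    },
    {
      "name": "naringenin",
      "formula": "C15H12O5",
      "subclass": "flavanone",
      "diagnostic_fragments": {"negative": [225, 151, 136, 122, 119], "positive": []},
      "rda_pieces": {"1,3A": "C7H4O4", "1,3B": "C8H8O"}
    },
    {
      "name": "eriodictyol",
      "formula": "C15H12O6",
      "subclass": "flavanone",
      "diagnostic_fragments": {"negative": [213, 151, 135, 107], "positive": []},
      "rda_pieces": {"1,3A": "C7H4O4", "1,3B": "C8H8O2"}
    },
    {
      "name": "hesperetin",
      "formula": "C16H14O6",
      "subclass": "flavanone",
      "diagnostic_fragments": {"negative": [286, 151, 134], "positive": []},
      "rda_pieces": {"1,3A": "C7H4O4", "1,3B": "C9H10O2"}
    },
    {
      "name": "maritimetin",
      "formula": "C15H10O6",
      "subclass": "aurone",
      "diagnostic_fragments": {"negative": [], "positive": []},
      "rda_pieces": null
    },
    {
      "name": "okanin",
      "formula": "C15H12O6",
      "subclass": "chalcone",
      "diagnostic_fragments": {"negative": [271, 179, 163, 153], "positive": []},
      "rda_pieces": null
    }
  ]
}
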