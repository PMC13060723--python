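# Diabetes medication lexicon: 17 generic agents with common brand aliases.
# Matching is case-insensitive substring against the prescription free text.
- {generic: metformin, brands: [Diabex, Diaformin, Glucophage, Metex]}
- {generic: gliclazide, brands: [Diamicron, Glyade, Nidem]}
- {generic: glibenclamide, brands: [Daonil, Glimel]}
- {generic: glimepiride, brands: [Amaryl, Aylide, Dimirel]}
- {generic: glipizide, brands: [Melizide, Minidiab]}
- {generic: sitagliptin, brands: [Januvia]}
- {generic: linagliptin, brands: [Trajenta]}
- {generic: vildagliptin, brands: [Galvus]}
- {generic: saxagliptin, brands: [Onglyza]}
- {generic: empagliflozin, brands: [Jardiance]}
- {generic: dapagliflozin, brands: [Forxiga]}
- {generic: ertugliflozin, brands: [Steglatro]}
- {generic: exenatide, brands: [Byetta, Bydureon]}
- {generic: dulaglutide, brands: [Trulicity]}
- {generic: semaglutide, brands: [Ozempic, Rybelsus]}
- {generic: pioglitazone, brands: [Actos]}
- {generic: acarbose, brands: [Glucobay]}
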