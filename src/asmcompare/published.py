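"""Published monodontid reference-genome comparison tallies.

Per-category bp for pairwise whole-genome comparisons of beluga
(*Delphinapterus leucas*) and narwhal (*Monodon monoceros*) reference
assemblies, each evaluated against the most contiguous long-read assembly
of its species (Dl_5_ for beluga, Mm_3_ for narwhal).  These are inputs
for re-deriving the percentage tables and headline discrepancy totals;
``printed_pct`` records each cell as originally printed (the printing
precision varies cell to cell).
"""

from __future__ import annotations

#: per-category bp, keyed by the assembly evaluated in the comparison
COMPARISON_BP: dict[str, dict[str, int]] = {
    "Dl_Jones_": {
        "debris": 7_096_636,
        "translocation": 31_779_574,
        "inversion": 29_465_224,
        "relocation": 18_044_276,
        "unassessed": 109_570_873,
        "congruent": 2_166_825_960,
    },
    "Dl_zoo_": {
        "debris": 11_212_633,
        "translocation": 14_447_594,
        "inversion": 23_928_201,
        "relocation": 1_165_563,
        "unassessed": 116_520_692,
        "congruent": 2_189_291_240,
    },
    "Dl_3_": {
        "debris": 13_985_070,
        "translocation": 4_419_089,
        "inversion": 43_013_607,
        "relocation": 1_546_419,
        "unassessed": 274_690_520,
        "congruent": 2_068_226_002,
    },
    "Dl_4_": {
        "debris": 10_800_991,
        "translocation": 1_403_102,
        "inversion": 40_843_164,
        "relocation": 1_899_502,
        "unassessed": 191_862_255,
        "congruent": 2_122_477_807,
    },
    "Mm_Damas_": {
        "debris": 59_103_779,
        "translocation": 909_121,
        "inversion": 124_283_977,
        "relocation": 7_848_688,
        "unassessed": 115_575_344,
        "congruent": 2_034_233_699,
    },
}

#: percentages as printed in the published comparison tables
PRINTED_PCT: dict[str, dict[str, float]] = {
    "Dl_Jones_": {
        "debris": 0.3, "translocation": 1.35, "inversion": 1.25,
        "relocation": 0.8, "unassessed": 4.6, "congruent": 91.7,
    },
    "Dl_zoo_": {
        "debris": 0.5, "translocation": 0.6, "inversion": 1.0,
        "relocation": 0.1, "unassessed": 4.9, "congruent": 92.9,
    },
    "Dl_3_": {
        "debris": 0.6, "translocation": 0.1, "inversion": 1.8,
        "relocation": 0.1, "unassessed": 11.4, "congruent": 86.0,
    },
    "Dl_4_": {
        "debris": 0.4, "translocation": 0.1, "inversion": 1.7,
        "relocation": 0.1, "unassessed": 9.2, "congruent": 88.5,
    },
    "Mm_Damas_": {
        "debris": 2.5, "translocation": 0.05, "inversion": 5.3,
        "relocation": 0.35, "unassessed": 4.9, "congruent": 86.9,
    },
}


def printed_precision(value: float) -> int:
    """Decimal places a printed percentage carries (0.05 -> 2, 5.3 -> 1)."""
    text = repr(value)
    return len(text.split(".")[1]) if "." in text else 0
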