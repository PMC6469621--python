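"""Packaged reference data.

Published summary statistics of a 2013 winter survey of four diving sea-duck
species from the southern Baltic coast (per-species/tissue congener residue
summaries, dl-PCB TEQ summaries, wet-weight consumption levels, certified
reference material recoveries, and historical fat-tissue burdens), together
with the WHO-2005 toxic equivalency factors and the EU maximum levels for
PCBs in food of animal origin.

All residue summaries are arithmetic mean and sample standard deviation.
Units are stated per table; ``lw`` = lipid-weight basis, ``ww`` = wet-weight
basis.
"""

from __future__ import annotations

SPECIES = ("common_goldeneye", "tufted_duck", "common_pochard", "greater_scaup")
TISSUES = ("muscle", "liver", "fat")

#: Birds examined per species in the survey cohort.
SPECIES_N = {
    "common_goldeneye": 8,
    "tufted_duck": 9,
    "common_pochard": 9,
    "greater_scaup": 16,
}

#: Per-congener residue summary, ng/g lipid weight:
#: (species, tissue, congener) -> (mean, sd).
#: Congeners: the six indicator PCBs plus the mono-ortho dioxin-like PCB 118.
#:
#: One transcription repair: the greater scaup fat-tissue PCB 138 sd is
#: printed as 1148.42, which is impossible for n = 16 observations bounded
#: by the printed min 8.80 and max 490.95 (the sample sd of any such set is
#: at most ~249); the leading "1" is a typographical artefact and 148.42 is
#: used here.
RESIDUE_SUMMARY_LW: dict[tuple[str, str, int], tuple[float, float]] = {
    # common goldeneye, muscle
    ("common_goldeneye", "muscle", 28): (9.11, 2.53),
    ("common_goldeneye", "muscle", 52): (2.09, 2.48),
    ("common_goldeneye", "muscle", 101): (3.18, 3.23),
    ("common_goldeneye", "muscle", 153): (398.04, 153.03),
    ("common_goldeneye", "muscle", 138): (245.01, 195.13),
    ("common_goldeneye", "muscle", 180): (296.44, 265.38),
    ("common_goldeneye", "muscle", 118): (119.73, 99.07),
    # common goldeneye, liver
    ("common_goldeneye", "liver", 28): (2.65, 3.94),
    ("common_goldeneye", "liver", 52): (5.46, 3.84),
    ("common_goldeneye", "liver", 101): (2.17, 1.52),
    ("common_goldeneye", "liver", 153): (440.80, 413.71),
    ("common_goldeneye", "liver", 138): (243.37, 212.82),
    ("common_goldeneye", "liver", 180): (212.34, 163.98),
    ("common_goldeneye", "liver", 118): (108.25, 69.98),
    # common goldeneye, fat
    ("common_goldeneye", "fat", 28): (5.68, 1.47),
    ("common_goldeneye", "fat", 52): (4.18, 5.06),
    ("common_goldeneye", "fat", 101): (3.42, 1.24),
    ("common_goldeneye", "fat", 153): (265.36, 121.08),
    ("common_goldeneye", "fat", 138): (176.91, 60.95),
    ("common_goldeneye", "fat", 180): (190.63, 153.15),
    ("common_goldeneye", "fat", 118): (42.60, 7.49),
    # tufted duck, muscle
    ("tufted_duck", "muscle", 28): (5.59, 3.30),
    ("tufted_duck", "muscle", 52): (6.30, 3.09),
    ("tufted_duck", "muscle", 101): (1.86, 2.04),
    ("tufted_duck", "muscle", 153): (231.14, 189.59),
    ("tufted_duck", "muscle", 138): (192.41, 113.62),
    ("tufted_duck", "muscle", 180): (148.96, 82.57),
    ("tufted_duck", "muscle", 118): (65.25, 21.55),
    # tufted duck, liver
    ("tufted_duck", "liver", 28): (7.14, 8.26),
    ("tufted_duck", "liver", 52): (4.85, 4.58),
    ("tufted_duck", "liver", 101): (6.28, 6.11),
    ("tufted_duck", "liver", 153): (658.95, 391.59),
    ("tufted_duck", "liver", 138): (269.45, 172.64),
    ("tufted_duck", "liver", 180): (435.87, 295.38),
    ("tufted_duck", "liver", 118): (124.74, 84.88),
    # tufted duck, fat
    ("tufted_duck", "fat", 28): (2.2, 2.1),
    ("tufted_duck", "fat", 52): (0.6, 0.7),
    ("tufted_duck", "fat", 101): (1.4, 1.7),
    ("tufted_duck", "fat", 153): (72.3, 57.5),
    ("tufted_duck", "fat", 138): (52.1, 43.3),
    ("tufted_duck", "fat", 180): (63.2, 49.3),
    ("tufted_duck", "fat", 118): (33.20, 31.98),
    # common pochard, muscle
    ("common_pochard", "muscle", 28): (6.52, 4.59),
    ("common_pochard", "muscle", 52): (3.46, 3.20),
    ("common_pochard", "muscle", 101): (4.37, 3.64),
    ("common_pochard", "muscle", 153): (243.01, 66.22),
    ("common_pochard", "muscle", 138): (141.61, 45.75),
    ("common_pochard", "muscle", 180): (164.42, 47.29),
    ("common_pochard", "muscle", 118): (13.01, 15.00),
    # common pochard, liver
    ("common_pochard", "liver", 28): (10.59, 5.78),
    ("common_pochard", "liver", 52): (5.90, 7.46),
    ("common_pochard", "liver", 101): (7.25, 7.13),
    ("common_pochard", "liver", 153): (348.82, 208.04),
    ("common_pochard", "liver", 138): (174.55, 65.63),
    ("common_pochard", "liver", 180): (220.84, 68.32),
    ("common_pochard", "liver", 118): (12.45, 12.03),
    # common pochard, fat
    ("common_pochard", "fat", 28): (2.01, 0.85),
    ("common_pochard", "fat", 52): (0.47, 0.34),
    ("common_pochard", "fat", 101): (1.58, 0.42),
    ("common_pochard", "fat", 153): (124.10, 41.51),
    ("common_pochard", "fat", 138): (66.96, 21.21),
    ("common_pochard", "fat", 180): (70.93, 45.68),
    ("common_pochard", "fat", 118): (26.41, 3.48),
    # greater scaup, muscle
    ("greater_scaup", "muscle", 28): (2.34, 2.76),
    ("greater_scaup", "muscle", 52): (1.94, 2.38),
    ("greater_scaup", "muscle", 101): (2.44, 2.78),
    ("greater_scaup", "muscle", 153): (175.48, 153.87),
    ("greater_scaup", "muscle", 138): (97.52, 79.11),
    ("greater_scaup", "muscle", 180): (92.82, 81.21),
    ("greater_scaup", "muscle", 118): (35.60, 28.70),
    # greater scaup, liver
    ("greater_scaup", "liver", 28): (3.72, 3.37),
    ("greater_scaup", "liver", 52): (3.25, 2.70),
    ("greater_scaup", "liver", 101): (3.27, 3.34),
    ("greater_scaup", "liver", 153): (171.88, 178.08),
    ("greater_scaup", "liver", 138): (110.60, 91.74),
    ("greater_scaup", "liver", 180): (91.86, 114.57),
    ("greater_scaup", "liver", 118): (41.96, 47.84),
    # greater scaup, fat
    ("greater_scaup", "fat", 28): (5.05, 3.26),
    ("greater_scaup", "fat", 52): (5.43, 6.49),
    ("greater_scaup", "fat", 101): (2.78, 1.72),
    ("greater_scaup", "fat", 153): (213.39, 124.90),
    ("greater_scaup", "fat", 138): (194.89, 148.42),
    ("greater_scaup", "fat", 180): (174.29, 142.20),
    ("greater_scaup", "fat", 118): (61.18, 40.23),
}

#: Published per-(species, tissue) sum of the six indicator congeners,
#: ng/g lw (mean of per-bird sums as printed).
SUM_IPCB_LW: dict[tuple[str, str], float] = {
    ("common_goldeneye", "muscle"): 953.87,
    ("common_goldeneye", "liver"): 906.78,
    ("common_goldeneye", "fat"): 646.18,
    ("tufted_duck", "muscle"): 586.27,
    ("tufted_duck", "liver"): 1382.54,
    ("tufted_duck", "fat"): 191.80,
    ("common_pochard", "muscle"): 563.39,
    ("common_pochard", "liver"): 767.93,
    ("common_pochard", "fat"): 266.05,
    ("greater_scaup", "muscle"): 372.53,
    ("greater_scaup", "liver"): 384.57,
    ("greater_scaup", "fat"): 595.82,
}

#: Published wet-weight indicator-PCB sums, ng/g ww: (mean, sd).
SUM_IPCB_WW: dict[tuple[str, str], tuple[float, float]] = {
    ("common_goldeneye", "muscle"): (8.166, 6.401),
    ("common_goldeneye", "liver"): (14.53, 9.324),
    ("common_goldeneye", "fat"): (195.6, 57.32),
    ("tufted_duck", "muscle"): (7.424, 5.162),
    ("tufted_duck", "liver"): (18.51, 12.57),
    ("tufted_duck", "fat"): (181.8, 123.6),
    ("common_pochard", "muscle"): (8.926, 6.037),
    ("common_pochard", "liver"): (11.54, 6.497),
    ("common_pochard", "fat"): (101.7, 24.71),
    ("greater_scaup", "muscle"): (7.019, 5.162),
    ("greater_scaup", "liver"): (7.501, 6.055),
    ("greater_scaup", "fat"): (168.0, 116.7),
}

#: Published dl-PCB TEQ per (species, tissue), pg-TEQ/g lw: (mean, sd).
TEQ_SUMMARY_LW: dict[tuple[str, str], tuple[float, float]] = {
    ("common_goldeneye", "liver"): (0.23, 0.06),
    ("common_goldeneye", "muscle"): (0.18, 0.19),
    ("common_goldeneye", "fat"): (0.07, 0.06),
    ("common_pochard", "liver"): (0.29, 0.26),
    ("common_pochard", "muscle"): (0.31, 0.15),
    ("common_pochard", "fat"): (0.12, 0.10),
    ("tufted_duck", "liver"): (0.83, 1.27),
    ("tufted_duck", "muscle"): (0.71, 0.72),
    ("tufted_duck", "fat"): (0.11, 0.14),
    ("greater_scaup", "liver"): (0.19, 0.15),
    ("greater_scaup", "muscle"): (0.13, 0.17),
    ("greater_scaup", "fat"): (0.10, 0.08),
}

#: Published wet-weight consumption levels for the two game species,
#: (species, organ, percentile_label) -> level. Indicator-PCB sums in
#: ng/g ww; dl-PCB TEQ in pg-TEQ/g ww.
CONSUMPTION_SUM_IPCB_WW: dict[tuple[str, str, str], float] = {
    ("tufted_duck", "muscle", "P50"): 7.746,
    ("tufted_duck", "muscle", "P97.5"): 13.66,
    ("tufted_duck", "liver", "P50"): 16.89,
    ("tufted_duck", "liver", "P97.5"): 40.65,
    ("common_pochard", "muscle", "P50"): 8.441,
    ("common_pochard", "muscle", "P97.5"): 19.87,
    ("common_pochard", "liver", "P50"): 11.50,
    ("common_pochard", "liver", "P97.5"): 22.87,
}

CONSUMPTION_TEQ_WW: dict[tuple[str, str, str], float] = {
    ("tufted_duck", "muscle", "P50"): 0.004,
    ("tufted_duck", "muscle", "P97.5"): 0.011,
    ("tufted_duck", "liver", "P50"): 0.010,
    ("tufted_duck", "liver", "P97.5"): 0.016,
    ("common_pochard", "muscle", "P50"): 0.005,
    ("common_pochard", "muscle", "P97.5"): 0.011,
    ("common_pochard", "liver", "P50"): 0.009,
    ("common_pochard", "liver", "P97.5"): 0.013,
}

#: SRM 1946 (NIST Lake Superior fish tissue) validation rows with a
#: certified mass fraction: congener -> (certified ng/g ww, obtained ng/g ww,
#: published recovery %).  The PCB 52 row is omitted: its certified value is
#: ambiguous in the source text (8.1 vs 8.13 imply 83.5 vs 83.2%).  The
#: PCB 169 published recovery (83.2) does not reproduce from the published
#: certified/obtained pair (0.088/0.106 = 83.0%); the pair is kept as
#: published and flagged.
SRM1946_RECOVERY: dict[int, tuple[float, float, float]] = {
    77: (0.327, 0.271, 82.9),
    101: (34.6, 30.97, 89.5),
    118: (52.1, 45.82, 87.9),
    126: (0.38, 0.310, 81.6),
    138: (115.0, 101.7, 88.4),
    153: (170.0, 154.4, 90.8),
    156: (9.52, 7.635, 80.2),
    169: (0.106, 0.088, 83.2),
    180: (74.4, 61.75, 83.0),
}

#: Rows whose published recovery is internally inconsistent with the
#: certified/obtained pair at 0.1 percentage-point precision.
SRM1946_INCONSISTENT_ROWS = frozenset({169})

#: Historical fat-tissue indicator-PCB burdens, mg/kg lw, by winter season.
#: 1980s values from net-caught birds on the same coast; 2013 values are the
#: survey fat-tissue means.  The greater scaup 1980s baseline was not
#: published.
HISTORICAL_FAT_SUM_IPCB: dict[str, dict[str, float]] = {
    "tufted_duck": {"1981-1982": 52.0, "1982-1983": 4.6, "2013": 0.1918},
    "common_goldeneye": {"1981-1982": 26.0, "1982-1983": 9.0, "2013": 0.646},
    "greater_scaup": {"2013": 0.59582},
}

#: Interval convention for the decline rates: the early-1980s baseline
#: winters to the 2013 survey are treated as a 30-year span.
DECLINE_SPAN_YEARS = 30.0

#: Published average yearly decline rates (% of baseline per year) for
#: fat-tissue indicator-PCB burdens.
PUBLISHED_DECLINE_RATES = {
    "tufted_duck": 3.3,
    "common_goldeneye": 3.1,
    "greater_scaup": 2.9,
}

#: WHO-2005 consensus toxic equivalency factors for dioxin-like PCBs
#: (Van den Berg et al. re-evaluation), relative to 2,3,7,8-TCDD.
WHO2005_TEF: dict[int, float] = {
    # non-ortho
    77: 0.0001,
    81: 0.0003,
    126: 0.1,
    169: 0.03,
    # mono-ortho
    105: 0.00003,
    114: 0.00003,
    118: 0.00003,
    123: 0.00003,
    156: 0.00003,
    157: 0.00003,
    167: 0.00003,
    189: 0.00003,
}
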