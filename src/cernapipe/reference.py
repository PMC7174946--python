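"""Published group-level phenotype values for the five-arm ZDF-rat study.

Group means and SDs reported for the normal-control (NC), untreated
diabetic (DM), sitagliptin-phosphate (SP), Fuzhujiangtang-granule (FJG)
and combination (SP-FJG) arms. These printed summaries are the inputs to
the closed-form physiology metrics and the default operating point of the
synthetic phenotype generator.
"""

GROUPS = ("NC", "DM", "SP", "FJG", "SP-FJG")
TREATMENTS = ("SP", "FJG", "SP-FJG")

#: Glucose-tolerance curves, mmol/L at 0/30/60/120 min: (mean, sd) per time.
GLUCOSE_CURVES = {
    "OGTT": {
        "NC": [(3.72, 0.47), (6.24, 2.0), (4.46, 0.48), (3.42, 0.37)],
        "DM": [(11.24, 2.06), (23.48, 3.37), (27.04, 3.95), (22.64, 5.73)],
        "SP": [(8.4, 1.08), (20.08, 1.63), (21.56, 2.17), (17.68, 2.02)],
        "FJG": [(7.84, 1.39), (21.1, 2.83), (20.52, 2.15), (17.94, 4.29)],
        "SP-FJG": [(7.94, 1.43), (17.98, 2.17), (19.04, 3.1), (14.62, 1.67)],
    },
    "ITT": {
        "NC": [(3.02, 0.17), (1.88, 0.44), (1.66, 0.41), (2.04, 0.6)],
        "DM": [(16.7, 2.77), (12.34, 1.69), (8.64, 1.21), (10.46, 1.81)],
        "SP": [(7.8, 0.66), (4.68, 0.61), (4.36, 0.85), (5.3, 0.87)],
        "FJG": [(10.1, 1.34), (7.08, 0.83), (6.26, 1.8), (6.08, 0.63)],
        "SP-FJG": [(9.76, 2.25), (3.88, 0.42), (4.0, 0.71), (4.38, 0.64)],
    },
}

#: Published AUC summaries (mmol/L·h) for the same curves.
GLUCOSE_AUC = {
    "OGTT": {"NC": (9.11, 1.04), "DM": (46.15, 5.74), "SP": (37.15, 1.54),
             "FJG": (36.87, 2.77), "SP-FJG": (32.57, 3.15)},
    "ITT": {"NC": (3.96, 0.45), "DM": (22.06, 2.17), "SP": (10.21, 1.02),
            "FJG": (13.8, 1.56), "SP-FJG": (9.57, 1.08)},
}

#: Week-6 fasting blood glucose, mmol/L (mean, sd).
FBG_WEEK6 = {
    "NC": (3.7, 0.39), "DM": (12.65, 3.31), "SP": (7.31, 2.49),
    "FJG": (6.9, 0.77), "SP-FJG": (7.44, 1.12),
}

#: Fasting serum insulin, mIU/L (mean, sd).
FINS = {
    "NC": (13.00, 0.40), "DM": (21.48, 2.22), "SP": (23.84, 5.62),
    "FJG": (24.21, 3.26), "SP-FJG": (17.32, 1.55),
}

#: Serum markers (mean, sd) per group.
SERUM = {
    "TNFa": {"NC": (56.13, 3.82), "DM": (74.37, 3.79), "SP": (75.58, 5.30),
             "FJG": (78.89, 6.32), "SP-FJG": (69.01, 7.18)},
    "IL6": {"NC": (107.88, 10.53), "DM": (151.73, 5.62), "SP": (153.08, 9.63),
            "FJG": (159.44, 17.62), "SP-FJG": (133.02, 17.92)},
    "HDL": {"NC": (1.71, 0.17), "DM": (1.42, 0.24), "SP": (1.94, 0.20),
            "FJG": (1.44, 0.20), "SP-FJG": (1.59, 0.12)},
    "LDL": {"NC": (0.29, 0.08), "DM": (1.58, 0.19), "SP": (1.80, 0.26),
            "FJG": (1.40, 0.27), "SP-FJG": (1.44, 0.15)},
    "TC": {"NC": (1.99, 0.21), "DM": (2.92, 0.29), "SP": (3.20, 0.22),
           "FJG": (2.56, 0.37), "SP-FJG": (2.79, 0.13)},
    "TG": {"NC": (0.31, 0.11), "DM": (2.86, 0.11), "SP": (2.31, 0.47),
           "FJG": (2.46, 0.48), "SP-FJG": (2.39, 0.35)},
    "SOD": {"NC": (80.39, 4.25), "DM": (71.64, 2.73), "SP": (87.90, 3.59),
            "FJG": (100.07, 9.60), "SP-FJG": (89.11, 6.69)},
    "MDA": {"NC": (4.50, 0.58), "DM": (6.91, 0.69), "SP": (5.07, 0.95),
            "FJG": (4.72, 0.41), "SP-FJG": (4.82, 0.41)},
}

#: Published per-comparison differential-RNA counts (up/down per category).
#: Columns: mRNA_up, mRNA_down, ncRNA_up, ncRNA_down, circRNA_up,
#: circRNA_down, miRNA_up, miRNA_down, total.
DEG_TABLE = {
    "DM vs NC": (513, 572, 73, 45, 49, 29, 29, 29, 1339),
    "SP vs DM": (41, 21, 7, 2, 19, 30, 1, 13, 134),
    "SP vs NC": (435, 463, 80, 29, 24, 29, 39, 36, 1135),
    "FJG vs DM": (516, 259, 102, 23, 28, 41, 27, 30, 1026),
    "FJG vs NC": (1000, 784, 194, 58, 40, 46, 49, 60, 2231),
    "SP-FJG vs DM": (269, 142, 58, 19, 32, 52, 23, 26, 621),
    "SP-FJG vs NC": (732, 621, 164, 34, 43, 45, 50, 48, 1737),
}

#: Study-wide distinct differential RNA counts per category.
DEG_CATEGORY_TOTALS = {"mRNA": 1248, "ncRNA": 211, "circRNA": 202, "miRNA": 120}
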