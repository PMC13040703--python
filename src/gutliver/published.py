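"""Published phenotype summary statistics of the 2x2 MASH mouse study.

Group summaries (mean, sample SD, n) of plasma, liver and body parameters and
of hepatic mRNA fold changes, as printed for the Western-diet x MC4R-knockout
study design (WT-ND n=6, WT-WD n=6, KO-ND n=8, KO-WD n=8).  These serve as
worked-example inputs for the summary-based two-way ANOVA: the interaction
F-statistics reconstructed from them can be checked against the study's
printed ANOVA table.

Cells are ordered (WT-ND, WT-WD, KO-ND, KO-WD).
"""

from gutliver.groupstats import CellSummary

_N = (6, 6, 8, 8)


def _cells(spec):
    return tuple(CellSummary(mean=m, sd=s, n=n) for (m, s), n in zip(spec, _N))


#: Plasma, liver and body parameters: mean and SD per design cell.
PHENOTYPE_SUMMARIES = {
    "body_weight": _cells([(33.8, 1.8), (43.4, 1.1), (49.3, 2.0), (59.9, 4.1)]),
    "liver_weight": _cells([(1.41, 0.14), (2.71, 0.30), (3.29, 0.67), (7.32, 1.10)]),
    "ALT": _cells([(25.7, 7.1), (205.8, 91.2), (341.9, 170.1), (774.3, 104.3)]),
    "AST": _cells([(67.5, 11.9), (187.4, 91.4), (384.2, 187.1), (605.8, 90.9)]),
    "plasma_insulin": _cells([(1.89, 0.71), (3.33, 0.70), (8.77, 3.04), (26.29, 9.64)]),
    "plasma_TIMP1": _cells([(1.54, 0.20), (2.54, 0.58), (3.25, 0.80), (8.39, 1.47)]),
    "plasma_triglyceride": _cells([(65.2, 17.9), (50.6, 12.4), (32.7, 10.1), (83.0, 16.7)]),
    "plasma_total_cholesterol": _cells([(173.3, 23.1), (291.8, 36.0), (207.4, 45.2), (377.4, 25.7)]),
    "hepatic_hydroxyproline": _cells([(4.69, 0.76), (4.57, 0.68), (6.33, 0.95), (9.40, 1.36)]),
    "hepatic_triglyceride": _cells([(23.3, 11.7), (79.4, 21.0), (63.4, 13.6), (65.7, 9.2)]),
}

#: Hepatic mRNA expression (fold change vs WT-ND): mean and SD per cell.
MRNA_SUMMARIES = {
    "Col1a1": _cells([(1.00, 0.73), (7.16, 2.39), (3.06, 1.43), (12.38, 4.68)]),
    "aSMA": _cells([(1.00, 0.28), (1.50, 0.39), (1.80, 0.40), (2.11, 0.43)]),
    "F4_80": _cells([(1.00, 0.40), (2.20, 0.71), (1.88, 0.83), (3.71, 1.73)]),
    "TNFa": _cells([(1.00, 0.45), (2.67, 0.78), (1.84, 1.23), (3.61, 1.27)]),
    "MCP1": _cells([(1.00, 0.48), (4.10, 1.63), (3.46, 2.58), (9.04, 2.95)]),
    "TGFb1": _cells([(1.00, 0.20), (1.87, 0.28), (1.61, 0.37), (2.47, 0.36)]),
}

#: Decimal places the summaries were printed with (mean and SD alike);
#: needed to propagate rounding uncertainty through the reconstruction.
SUMMARY_DECIMALS = {
    "body_weight": 1,
    "liver_weight": 2,
    "ALT": 1,
    "AST": 1,
    "plasma_insulin": 2,
    "plasma_TIMP1": 2,
    "plasma_triglyceride": 1,
    "plasma_total_cholesterol": 1,
    "hepatic_hydroxyproline": 2,
    "hepatic_triglyceride": 1,
    "Col1a1": 2,
    "aSMA": 2,
    "F4_80": 2,
    "TNFa": 2,
    "MCP1": 2,
    "TGFb1": 2,
}

#: Printed interaction F-statistics (df 1, 24) for the parameters above.
PRINTED_INTERACTION_F = {
    "body_weight": 0.24,
    "liver_weight": 25.21,
    "ALT": 8.16,
    "AST": 1.23,
    "plasma_insulin": 14.77,
    "plasma_TIMP1": 32.79,
    "plasma_triglyceride": 34.44,
    "plasma_total_cholesterol": 3.89,
    "hepatic_hydroxyproline": 17.26,
    "hepatic_triglyceride": 25.06,
    "Col1a1": 2.06,
    "aSMA": 0.39,
    "F4_80": 0.57,
    "TNFa": 0.02,
    "MCP1": 2.07,
    "TGFb1": 0.00,
}
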