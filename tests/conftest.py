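"""Shared fixtures: the published screening-table counts and assay pairs.

The three per-week 2×2 screening tables (n = 28 pregnancies, 7 with the
outcome) and the paired urinary podocin ELISA concentrations (ng/mL) with
their printed percent-change column are the reference inputs the diagnostics
module must reproduce.
"""

import pytest

# week → (TP, FN, TN, FP)
WEEK_TABLES = {
    11: (1, 6, 21, 0),
    24: (6, 1, 21, 0),
    36: (6, 1, 19, 2),
}

# week → {statistic: (estimate, ci_low, ci_high)}; None = blank cell.
# Percent-scale statistics in %, likelihood ratios plain, all at 2 dp.
PRINTED_STATS = {
    11: {
        "sensitivity": (14.29, 0.36, 57.87),
        "specificity": (100.00, 83.89, 100.00),
        "PLR": (None, None, None),
        "NLR": (0.86, 0.63, 1.16),
        "prevalence": (25.00, 10.69, 44.87),
        "PPV": (100.00, None, None),
        "NPV": (77.78, 72.12, 82.57),
        "accuracy": (78.57, 59.05, 91.70),
    },
    24: {
        "sensitivity": (85.71, 42.13, 99.64),
        "specificity": (100.00, 83.89, 100.00),
        "PLR": (None, None, None),
        "NLR": (0.14, 0.02, 0.88),
        "prevalence": (25.00, 10.69, 44.87),
        "PPV": (100.00, None, None),
        "NPV": (95.45, 77.38, 99.23),
        "accuracy": (96.43, 81.65, 99.91),
    },
    36: {
        "sensitivity": (85.71, 42.13, 99.64),
        "specificity": (90.48, 69.62, 98.83),
        "PLR": (9.00, 2.33, 34.80),
        "NLR": (0.16, 0.03, 0.97),
        "prevalence": (25.00, 10.69, 44.87),
        "PPV": (75.00, 43.69, 92.06),
        "NPV": (95.00, 75.48, 99.15),
        "accuracy": (89.29, 71.77, 97.73),
    },
}

# (begin ng/mL, end ng/mL, printed integer % change); None = undetectable/missing.
ELISA_ROWS = [
    (1.166, 0.473, -59),
    (0.321, 0.878, 174),
    (2.128, 1.588, -25),
    (0.625, 0.693, 11),
    (0.49, 0.895, 83),
    (1.318, 0.997, -24),
    (None, 0.659, None),
    (1.301, 0.439, -66),
    (0.051, 1.402, 2649),
    (0.591, 0.659, 12),
    (None, 0.608, None),
    (0.895, 0.321, -64),
    (None, 0.017, None),
    (0.253, None, None),
    (None, 0.321, None),
    (0.287, 1.334, 365),
    (0.051, 0.321, 529),
    (None, 0.152, None),
    (None, None, None),
    (0.27, 0.101, -63),
    (0.338, 6.976, 1964),
    (0.321, None, None),
    (1.081, 0.22, -80),
    (0.659, 0.811, 23),
    (0.726, 0.405, -44),
    (0.186, 0.118, -37),
    (None, None, None),
    (1.284, None, None),
]

# The instrument-optimized MRM transitions monitored for MIAAEAEK:
# (precursor m/z, product m/z, expected ion, expected variant)
PRINTED_TRANSITIONS = [
    (862.45, 347.20, "y3", "native"),
    (862.45, 618.30, "y6", "native"),
    (862.45, 547.28, "y5", "native"),
    (878.43, 261.13, "b2", "ox"),
    (576.78, 637.30, "y3", "tpp"),
    (576.78, 308.20, "reporter", "tpp"),
]


@pytest.fixture
def week_tables():
    return WEEK_TABLES


@pytest.fixture
def printed_stats():
    return PRINTED_STATS


@pytest.fixture
def elisa_rows():
    return ELISA_ROWS
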