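"""Bundled reference case-study tables for demos and worked examples.

These are published summary results from a proteome-wide cis-MR screen of
plasma protein levels against heart failure (1557 proteins tested; the 16
genes passing a 5% FDR are tabulated, with odds ratios per unit protein,
Cochran's Q heterogeneity p-values, colocalization PP.H4 and druggability
annotations) plus the case/control counts of the top and bottom deciles of a
heart-failure polygenic risk score evaluated in an independent biobank. They
serve as fixture inputs for the reporting utilities — raw p-values in,
FDR/candidate calls out — not as outputs of this package's estimators.
"""

from __future__ import annotations

import pandas as pd

#: Total proteins tested in the screen (the BH family size).
M_PROTEINS = 1557

#: gene, n_snps, OR, CI low, CI high, raw MR p, Cochran's Q p (None for
#: single-variant instruments), printed FDR-adjusted p, coloc PP.H4,
#: druggability label, near-known-risk-locus flag
_MR_HITS_ROWS = [
    ("ITIH4",   2, 1.13, 1.07, 1.17, 2.51e-07, 0.66, 3.90e-04, 0.97, "Non-druggable", False),
    ("APOC3",   1, 1.19, 1.11, 1.28, 1.74e-06, None, 1.35e-03, 0.99, "Advanced Clinical Phase (Oligonucleotide)", False),
    ("MAPK3",   3, 0.95, 0.93, 0.97, 6.70e-06, 0.41, 3.48e-03, 0.52, "Advanced Clinical Phase (Small molecule)", False),
    ("TNFSF12", 2, 0.96, 0.94, 0.98, 1.78e-05, 0.05, 6.94e-03, 0.79, "Clinical Phase 1 (Antibody)", False),
    ("ABO",     2, 1.02, 1.01, 1.03, 2.89e-05, 0.11, 8.99e-03, 0.01, "Non-druggable", True),
    ("APOH",    2, 0.96, 0.94, 0.98, 5.24e-05, 0.83, 1.36e-02, 0.89, "Non-druggable", False),
    ("B3GNT8",  2, 0.97, 0.96, 0.99, 9.35e-05, 0.96, 2.08e-02, 0.48, "Non-druggable", False),
    ("NTN4",    2, 1.08, 1.04, 1.13, 1.10e-04, 0.68, 2.14e-02, 0.04, "Non-druggable", False),
    ("DLL1",    1, 0.87, 0.80, 0.93, 1.53e-04, None, 2.65e-02, 0.75, "Non-druggable", False),
    ("MST1",    3, 1.02, 1.01, 1.03, 1.99e-04, 0.11, 3.10e-02, 0.37, "Non-druggable", False),
    ("ENPEP",   4, 0.96, 0.94, 0.98, 3.12e-04, 0.18, 4.27e-02, 0.74, "Non-druggable", True),
    ("NAE1",    1, 0.82, 0.74, 0.91, 3.55e-04, None, 4.27e-02, 0.60, "Advanced Clinical Phase (Small molecule)", False),
    ("TNXB",    1, 1.03, 1.02, 1.05, 3.56e-04, None, 4.27e-02, 0.61, "Non-druggable", False),
    ("SIRPA",   1, 0.98, 0.97, 0.99, 3.94e-04, None, 4.39e-02, 0.56, "Non-druggable", False),
    ("EBI3",    1, 0.75, 0.64, 0.89, 4.44e-04, None, 4.61e-02, 0.01, "Non-druggable", False),
    ("IL27",    1, 0.75, 0.64, 0.89, 4.44e-04, None, 4.61e-02, 0.40, "Non-druggable", False),
]


def mr_hits_table() -> pd.DataFrame:
    """The 16-gene FDR-significant MR-proteomics reference table."""
    return pd.DataFrame(
        _MR_HITS_ROWS,
        columns=[
            "gene", "n_snps", "or_point", "or_low95", "or_high95",
            "pvalue", "q_pvalue", "fdr_printed", "pp_h4",
            "druggability", "near_known_locus",
        ],
    )


#: PRS top-decile vs bottom-decile contingency counts:
#: (cases_top, controls_top, cases_bottom, controls_bottom)
PRS_DECILE_COUNTS = (723, 6788, 416, 7096)
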