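"""Reference above-threshold records from the published KCNK cancer screen.

These are the printed per-study statistics (two-sided p-value, signed
linear fold change, integer gene-rank percentile) of every analysis that
cleared the standard gate (p < 0.05, |fold change| >= 2, percentile <= 10)
in the published Oncomine-based survey of the two-pore-domain potassium
channel (KCNK) gene family across cancers. They serve as worked examples:
small, real numbers against which the gate and the fold-change/median
aggregations can be checked end to end.

Study identifiers are anonymised positional labels (``ref01``...), since
the original per-study accessions are not part of this dataset.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .study_io import RECORD_COLUMNS

#: The 15 mammalian KCNK (K2P channel) family genes. KCNK8, KCNK11 and
#: KCNK14 were withdrawn as duplicated nomenclature and do not exist.
KCNK_GENES = [
    "KCNK1", "KCNK2", "KCNK3", "KCNK4", "KCNK5", "KCNK6", "KCNK7",
    "KCNK9", "KCNK10", "KCNK12", "KCNK13", "KCNK15", "KCNK16",
    "KCNK17", "KCNK18",
]

#: Default platform size for rebuilding ranks from printed percentiles:
#: the screened microarrays measured approximately 14,000 genes.
REFERENCE_N_GENES = 14000

# (gene, cancer_type, cancer_subtype, direction, p_value, fold_change, percentile)
_ROWS = [
    # TWIK family
    ("KCNK1", "Brain", "Glioblastoma", "under", 1.72e-24, -9.574, 2),
    ("KCNK1", "Brain", "Glioblastoma", "under", 1.80e-14, -20.541, 3),
    ("KCNK1", "Brain", "Glioblastoma", "under", 1.07e-08, -8.483, 3),
    ("KCNK1", "Brain", "Glioblastoma", "under", 1.03e-05, -13.309, 4),
    ("KCNK1", "Brain", "Glioblastoma", "over", 5.89e-04, 3.178, 6),
    ("KCNK1", "Breast", "Ductal", "over", 5.23e-04, 2.515, 5),
    ("KCNK1", "Breast", "Ductal", "over", 7.18e-04, 3.965, 5),
    ("KCNK1", "Breast", "Ductal", "over", 1.00e-03, 2.405, 5),
    ("KCNK1", "Breast", "Ductal", "over", 4.00e-03, 2.661, 9),
    ("KCNK1", "Breast", "Ductal", "over", 1.10e-02, 2.4, 9),
    ("KCNK1", "Breast", "Lobular", "over", 2.20e-02, 2.177, 4),
    ("KCNK1", "Cervical", "Squamous Cell", "over", 9.70e-13, 2.949, 1),
    ("KCNK1", "Leukaemia", "Acute Lymphocytic", "over", 4.00e-03, 2.173, 5),
    ("KCNK1", "Lung", "Adenocarcinoma", "over", 3.59e-07, 3.984, 2),
    ("KCNK1", "Lung", "Adenocarcinoma", "over", 5.38e-07, 2.141, 3),
    ("KCNK1", "Lung", "Adenocarcinoma", "over", 2.35e-05, 4.641, 1),
    ("KCNK1", "Lung", "Adenocarcinoma", "over", 6.21e-05, 2.137, 8),
    ("KCNK1", "Lung", "Squamous cell", "over", 5.98e-08, 2.138, 9),
    ("KCNK1", "Lung", "Squamous cell", "over", 2.61e-06, 7.79, 2),
    ("KCNK1", "Pancreas", "Adenocarcinoma", "over", 9.83e-10, 3.526, 5),
    ("KCNK1", "Pancreas", "Adenocarcinoma", "over", 2.61e-04, 6.584, 3),
    ("KCNK1", "Pancreas", "Adenocarcinoma", "over", 1.41e-04, 6.62, 5),
    ("KCNK1", "Pancreas", "Adenocarcinoma", "over", 1.21e-08, 4.613, 1),
    ("KCNK1", "Pancreas", "Adenocarcinoma", "over", 2.00e-03, 2.685, 9),
    ("KCNK6", "Breast", "Ductal", "over", 2.77e-19, 2.161, 9),
    ("KCNK6", "Breast", "Ductal", "over", 1.00e-03, 2.765, 1),
    ("KCNK6", "Colorectal", "Adenocarcinoma", "under", 1.77e-18, -2.071, 4),
    ("KCNK6", "Colorectal", "Adenocarcinoma", "under", 2.38e-15, -2.11, 7),
    ("KCNK6", "Colorectal", "Adenocarcinoma", "under", 9.37e-15, -2.136, 1),
    ("KCNK7", "Cervical", "Squamous cell", "under", 5.62e-10, -6.76, 1),
    ("KCNK7", "Cervical", "Squamous cell", "under", 1.86e-08, -3.055, 1),
    ("KCNK7", "Cervical", "Squamous cell", "under", 7.99e-04, -3.315, 5),
    ("KCNK7", "Gastrointestinal", "Adenocarcinoma", "under", 1.60e-02, -2.336, 10),
    # TREK family
    ("KCNK2", "Breast", "Invasive", "under", 5.70e-05, -2.23, 4),
    ("KCNK2", "Lung", "Squamous cell", "over", 2.98e-04, 2.111, 5),
    ("KCNK10", "Brain", "Glioblastoma", "under", 1.81e-17, -4.843, 5),
    ("KCNK10", "Brain", "Glioblastoma", "under", 1.56e-10, -2.974, 6),
    ("KCNK10", "Brain", "Glioblastoma", "over", 8.63e-04, 2.547, 7),
    ("KCNK10", "Breast", "Ductal", "under", 1.00e-03, -2.294, 2),
    ("KCNK10", "Breast", "Ductal", "under", 3.85e-04, -3.523, 2),
    ("KCNK10", "Colorectal", "Adenocarcinoma", "under", 1.74e-25, -7.227, 1),
    ("KCNK10", "Colorectal", "Adenocarcinoma", "under", 3.19e-22, -7.914, 2),
    ("KCNK10", "Colorectal", "Adenocarcinoma", "under", 2.85e-18, -6.275, 1),
    ("KCNK10", "Colorectal", "Adenocarcinoma", "under", 2.07e-14, -4.83, 2),
    ("KCNK10", "Colorectal", "Adenocarcinoma", "under", 1.11e-07, -6.275, 2),
    ("KCNK10", "Colorectal", "Adenocarcinoma", "under", 3.42e-07, -2.503, 3),
    # TASK family
    ("KCNK3", "Brain", "Glioblastoma", "under", 6.20e-08, -5.468, 10),
    ("KCNK3", "Brain", "Glioblastoma", "under", 2.61e-05, -4.471, 3),
    ("KCNK3", "Breast", "Invasive", "over", 4.41e-17, 2.782, 4),
    ("KCNK3", "Breast", "Invasive", "over", 1.50e-02, 2.958, 6),
    ("KCNK3", "Breast", "Invasive", "under", 1.00e-03, -2.375, 7),
    ("KCNK3", "Colorectal", "Adenoma", "under", 2.37e-04, -2.493, 10),
    ("KCNK3", "Colorectal", "Adenoma", "under", 2.00e-03, -4.175, 5),
    ("KCNK3", "Gastrointestinal", "Adenocarcinoma", "over", 2.85e-04, 3.567, 6),
    ("KCNK3", "Kidney", "Clear cell", "over", 1.53e-14, 8.407, 1),
    ("KCNK3", "Kidney", "Clear cell", "over", 2.57e-07, 6.014, 5),
    ("KCNK3", "Kidney", "Clear cell", "over", 4.01e-05, 4.541, 7),
    ("KCNK3", "Kidney", "Clear cell", "over", 1.89e-04, 6.344, 6),
    ("KCNK3", "Leukemia", "Acute lymphocytic", "over", 1.30e-02, 2.177, 9),
    ("KCNK3", "Lung", "Adenocarcinoma", "under", 6.55e-34, -4.136, 1),
    ("KCNK3", "Lung", "Adenocarcinoma", "under", 8.44e-20, -6.89, 1),
    ("KCNK3", "Lung", "Adenocarcinoma", "under", 8.67e-11, -7.375, 2),
    ("KCNK3", "Lung", "Adenocarcinoma", "under", 4.11e-10, -2.367, 1),
    ("KCNK3", "Lung", "Adenocarcinoma", "under", 2.54e-06, -7.399, 3),
    ("KCNK3", "Lung", "Adenocarcinoma", "under", 1.08e-04, -3.803, 4),
    ("KCNK3", "Lung", "Squamous cell", "under", 5.90e-20, -12.756, 2),
    ("KCNK3", "Lung", "Squamous cell", "under", 3.86e-06, -8.471, 3),
    ("KCNK3", "Lung", "Squamous cell", "under", 1.58e-05, -4.28, 3),
    ("KCNK3", "Lung", "Squamous cell", "under", 2.00e-03, -2.422, 7),
    ("KCNK3", "Pancreas", "Adenocarcinoma", "under", 7.34e-06, -6.459, 1),
    ("KCNK3", "Pancreas", "Adenocarcinoma", "under", 4.72e-05, -5.03, 1),
    ("KCNK3", "Pancreas", "Adenocarcinoma", "under", 1.19e-04, -2.191, 3),
    ("KCNK3", "Prostate", "Carcinoma", "under", 2.72e-08, -2.034, 3),
    ("KCNK3", "Prostate", "Carcinoma", "under", 1.02e-04, -2.638, 2),
    ("KCNK3", "Prostate", "Carcinoma", "under", 8.94e-04, -3.106, 4),
    ("KCNK9", "Breast", "Invasive", "over", 1.16e-12, 3.95, 9),
    ("KCNK15", "Breast", "Ductal", "over", 1.00e-03, 5.046, 6),
    ("KCNK15", "Breast", "Ductal", "over", 8.00e-03, 2.283, 9),
    ("KCNK15", "Breast", "Ductal", "over", 4.10e-02, 8.774, 8),
    ("KCNK15", "Gastrointestinal", "Adenocarcinoma", "under", 3.00e-03, -2.189, 5),
    # TALK family
    ("KCNK5", "Breast", "Ductal", "over", 2.14e-04, 2.977, 3),
    ("KCNK5", "Breast", "Ductal", "under", 7.70e-04, -3.629, 4),
    ("KCNK5", "Breast", "Ductal", "under", 2.00e-03, -2.498, 2),
    ("KCNK5", "Breast", "Ductal", "under", 1.00e-03, -3.856, 6),
    ("KCNK5", "Colorectal", "Adenocarcinoma", "under", 2.42e-12, -3.18, 3),
    ("KCNK5", "Colorectal", "Adenocarcinoma", "under", 1.95e-11, -2.498, 5),
    ("KCNK5", "Colorectal", "Adenocarcinoma", "under", 7.86e-08, -3.199, 2),
    ("KCNK17", "Breast", "Invasive", "over", 2.20e-02, 3.265, 8),
    # THIK family
    ("KCNK13", "Breast", "Invasive", "over", 3.35e-12, 3.193, 10),
    ("KCNK13", "Breast", "Invasive", "over", 4.99e-08, 2.05, 10),
]


def kcnk_reference_records() -> pd.DataFrame:
    """The published above-threshold KCNK records as a records table."""
    df = pd.DataFrame(
        _ROWS,
        columns=["gene", "cancer_type", "cancer_subtype", "direction",
                 "p_value", "fold_change", "percentile"],
    )
    df["study_id"] = [f"ref{i + 1:02d}" for i in range(len(df))]
    return df[RECORD_COLUMNS]


def as_gene_results(records: pd.DataFrame, n_genes: int = REFERENCE_N_GENES) -> pd.DataFrame:
    """Rebuild a per-study results frame from printed summary statistics.

    Printed rows carry only (p, fold change, percentile); rank and Q are
    reconstructed consistently with the integer percentile against an
    ``n_genes``-gene platform (rank = percentile * n_genes / 100 satisfies
    percentile = ceil(100 * rank / n_genes)). The t statistic is not
    recoverable and only its sign (from the fold change) is filled in.
    """
    rank = (records["percentile"].astype(int) * n_genes) // 100
    rank = rank.clip(lower=1)
    return pd.DataFrame(
        {
            "study_id": records["study_id"],
            "gene": records["gene"],
            "t": np.sign(records["fold_change"].astype(float)),
            "p": records["p_value"].astype(float),
            "fold_change": records["fold_change"].astype(float),
            "direction": records["direction"],
            "rank": rank.astype(int),
            "n_genes": n_genes,
            "percentile": records["percentile"].astype(int),
            "q": n_genes * records["p_value"].astype(float) / rank.astype(float),
            "cancer_type": records["cancer_type"],
            "cancer_subtype": records["cancer_subtype"],
        }
    )
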