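"""Packaged summary tables from the Scottish (2022) destructive-sampling trial.

The raw record-level field data are unpublished; what is public are the
cross-tabulated counts (treatment x infection outcome and developmental
stage x infection outcome), the population-structure margins, and the
block-level Bliss interaction table. These transcribed counts are enough to
reproduce every contingency and pooled-synergy statistic exactly, and the
helpers below expand them back into record-level tables for the analysis
pipeline.
"""

from __future__ import annotations

import pandas as pd

from .vocab import OUTCOMES, STAGES, TREATMENTS

#: Destructive-sampling counts, treatment x infection outcome
#: (columns ordered alive, nematode_killed, fungus_killed, indeterminate).
TREATMENT_OUTCOME_COUNTS = {
    "control": (113, 0, 2, 2),
    "fungi": (37, 0, 15, 1),
    "halfmix": (49, 51, 2, 6),
    "nematodes": (56, 62, 1, 2),
}

#: Destructive-sampling counts, developmental stage x infection outcome.
STAGE_OUTCOME_COUNTS = {
    "larva": (142, 79, 13, 10),
    "pupa": (87, 30, 6, 0),
    "adult": (26, 4, 1, 1),
}

#: Printed standardized residuals (Z scores) at 1 d.p., same cell order.
TREATMENT_OUTCOME_Z = {
    "control": (4.4, -5.8, -1.6, -0.7),
    "fungi": (0.5, -3.9, 7.6, -0.4),
    "halfmix": (-2.4, 3.7, -1.5, 1.8),
    "nematodes": (-2.4, 4.7, -2.1, -0.7),
}

STAGE_OUTCOME_Z = {
    "larva": (-1.1, 1.2, 0.2, 1.3),
    "pupa": (0.9, -0.8, -0.1, -1.8),
    "adult": (1.2, -1.7, -0.5, 0.1),
}

#: Relative emergence ratios vs control and Dunnett-adjusted p-values from
#: the negative-binomial emergence model (Scotland 2022), with the overall
#: likelihood-ratio test.
EMERGENCE_LRT = {"chi2": 12.274, "df": 3, "p": 0.007}
EMERGENCE_RATIOS = {
    "fungi": {"ratio": 0.468, "se": 0.149, "p": 0.046},
    "nematodes": {"ratio": 0.322, "se": 0.107, "p": 0.002},
    "halfmix": {"ratio": 0.393, "se": 0.130, "p": 0.013},
}

#: Block-level Bliss interaction table as printed (scope, observed combined
#: infection rate I_NF, Bliss expectation, deviation chi-square, p, synergy
#: score S, verdict).  Block18's chi-square and S are transcribed verbatim
#: even though they are not consistent with its printed rates.
BLISS_BLOCK_ROWS = [
    ("Total", 0.546296296, 0.37899579, 0.073851637, 0.785809, 0.167301, "Synergy"),
    ("Block5", 0.285714286, 0.5, 0.091836735, 0.761855, -0.21429, "Antagonist"),
    ("Block9", 0.764705882, 0.6125, 0.03782307, 0.845799, 0.152206, "Synergy"),
    ("Block10", 1.0, 0.5, 0.5, 0.4795, 0.5, "Synergy"),
    ("Block11", 0.8, 0.409090909, 0.373535354, 0.541084, 0.390909, "Synergy"),
    ("Block12", 0.0, 0.352941176, 0.352941176, 0.552453, -0.35294, "Antagonist"),
    ("Block13", 0.285714286, 0.428571429, 0.047619048, 0.827259, -0.14286, "Antagonist"),
    ("Block16", 0.647058824, 0.340697674, 0.275485161, 0.599676, 0.306361, "Synergy"),
    ("Block18", 0.296296296, 0.25, 0.49, 0.483927, 0.35, "Synergy"),
    ("Block19", 0.5, 0.25, 0.25, 0.617075, 0.25, "Synergy"),
    ("Block20", 0.9, 0.3125, 1.1045, 0.293281, 0.5875, "Synergy"),
]


def treatment_outcome_table() -> pd.DataFrame:
    """Treatment x outcome counts as a labelled DataFrame."""
    return pd.DataFrame.from_dict(
        TREATMENT_OUTCOME_COUNTS, orient="index", columns=list(OUTCOMES)
    ).reindex(list(TREATMENTS))


def stage_outcome_table() -> pd.DataFrame:
    """Developmental stage x outcome counts as a labelled DataFrame."""
    return pd.DataFrame.from_dict(
        STAGE_OUTCOME_COUNTS, orient="index", columns=list(OUTCOMES)
    ).reindex(list(STAGES))


def bliss_block_table() -> pd.DataFrame:
    """Block-level Bliss interaction results as printed."""
    return pd.DataFrame(
        BLISS_BLOCK_ROWS,
        columns=["scope", "i_nf", "i_bliss", "chi2_bliss", "p", "synergy", "verdict"],
    ).set_index("scope")


def records_from_counts(counts: pd.DataFrame, row_field: str, col_field: str) -> pd.DataFrame:
    """Expand a two-way count table into one row per individual.

    The expansion is synthetic in the ordering sense only — it contains
    exactly the individuals the counts tabulate, but any within-cell
    attributes (block, depth, ...) are absent.
    """
    rows = []
    for r, row in counts.iterrows():
        for c, k in row.items():
            rows.extend({row_field: r, col_field: c} for _ in range(int(k)))
    return pd.DataFrame(rows)


def destructive_records() -> pd.DataFrame:
    """Record-level expansion of the treatment x outcome table (399 weevils)."""
    return records_from_counts(treatment_outcome_table(), "treatment", "outcome")


def stage_records() -> pd.DataFrame:
    """Record-level expansion of the stage x outcome table (399 weevils)."""
    return records_from_counts(stage_outcome_table(), "stage", "outcome")
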