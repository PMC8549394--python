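"""Report tables in the study's layout, as CSV and markdown."""

from __future__ import annotations

from typing import Mapping

import pandas as pd

from .metrics import ClassificationMetrics, RegressionMetrics

REGRESSION_COLUMNS = ["Split (CV, %)", "MAE", "MAE per IL", "Range", "Covariance", "Decision"]
CLASSIFICATION_COLUMNS = [
    "Split (CV, %)", "Sensitivity", "Specificity", "BA", "Acc", "Acc (per IL)", "Decision",
]


def regression_table(results: Mapping[int, RegressionMetrics]) -> pd.DataFrame:
    """One row per CV-split percentage, columns as in the selectivity tables."""
    rows = [
        {
            "Split (CV, %)": split,
            "MAE": m.mae,
            "MAE per IL": m.mae_per_il,
            "Range": m.delta_range,
            "Covariance": m.delta_cov,
            "Decision": m.df,
        }
        for split, m in sorted(results.items())
    ]
    return pd.DataFrame(rows, columns=REGRESSION_COLUMNS)


def classification_table(results: Mapping[int, ClassificationMetrics]) -> pd.DataFrame:
    """One row per CV-split percentage, columns as in the reliability tables."""
    rows = [
        {
            "Split (CV, %)": split,
            "Sensitivity": m.sensitivity,
            "Specificity": m.specificity,
            "BA": m.ba,
            "Acc": m.acc,
            "Acc (per IL)": m.acc_per_il,
            "Decision": m.df,
        }
        for split, m in sorted(results.items())
    ]
    return pd.DataFrame(rows, columns=CLASSIFICATION_COLUMNS)


def to_markdown(df: pd.DataFrame, float_format: str = "{:.4g}") -> str:
    """Plain GitHub-style markdown table (no external dependencies)."""

    def fmt(v) -> str:
        if isinstance(v, float):
            return float_format.format(v)
        return str(v)

    header = "| " + " | ".join(df.columns) + " |"
    sep = "|" + "|".join(" --- " for _ in df.columns) + "|"
    body = ["| " + " | ".join(fmt(v) for v in row) + " |" for row in df.itertuples(index=False)]
    return "\n".join([header, sep, *body]) + "\n"


def write_report(df: pd.DataFrame, basename) -> None:
    """Write <basename>.csv and <basename>.md side by side."""
    df.to_csv(f"{basename}.csv", index=False)
    with open(f"{basename}.md", "w") as fh:
        fh.write(to_markdown(df))
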