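"""Publication-style performance tables from ensemble reports.

One row per ensemble; for each of sensitivity, specificity and AUC the
ensemble value is followed by the min, max and average over the individual
member classifiers. Values are rounded half-up at the configured precision
only here, at the presentation layer.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import pandas as pd

from .data_model import EnsembleReport
from .studies import round_half_up

__all__ = ["build_tables", "write_table"]

_METRICS = ("sensitivity", "specificity", "auc")


def build_tables(reports: Sequence[EnsembleReport], decimals: int = 2) -> pd.DataFrame:
    """Tabulate ensemble metrics next to member min/max/average."""
    columns = []
    for metric in _METRICS:
        columns += [f"{metric}_ensemble", f"{metric}_min", f"{metric}_max",
                    f"{metric}_average"]
    rows = {}
    for report in reports:
        row = {}
        for metric in _METRICS:
            row[f"{metric}_ensemble"] = round_half_up(getattr(report.ensemble, metric), decimals)
            for stat in ("min", "max", "average"):
                row[f"{metric}_{stat}"] = round_half_up(
                    report.member_summary[metric][stat], decimals)
        rows[report.spec.ensemble_id] = row
    frame = pd.DataFrame.from_dict(rows, orient="index")
    if frame.empty:
        return pd.DataFrame(columns=columns)
    return frame[columns]


def write_table(table: pd.DataFrame, path: str | Path, decimals: int = 2) -> None:
    table.to_csv(Path(path), sep="\t", index_label="ensemble",
                 float_format=f"%.{decimals}f")
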