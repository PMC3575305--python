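"""Bundled case-study classifier summaries.

Two published two-platform case studies ship with the package as plain TSV
tables of individual-classifier performance plus ensemble membership:

* ``kidney`` -- blood-based diagnosis of acute renal allograft rejection
  (11 AR / 21 NR samples); five genomic and five proteomic classifiers,
  five ensembles, metrics printed at 2 decimals.
* ``cancer`` -- tumour vs normal tissue across six cancer types (38 tumour /
  19 normal samples); twelve mRNA and twelve miRNA classifiers, six
  ensembles, metrics printed at 4 decimals.

Because sensitivities and specificities are count-valued (k correct out of
N_pos or N_neg), the exact fractions behind 2-decimal printed values can be
recovered, which matters when averaging member metrics: e.g. printed member
sensitivities 0.73 and 0.64 stand for 8/11 and 7/11, whose mean 15/22
prints as 0.68, not the 0.69 that naive averaging of the rounded values
would give.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from fractions import Fraction
from importlib import resources
from numbers import Real
from pathlib import Path

import pandas as pd

from ..ensemble import read_membership
from ..metrics import member_summary

__all__ = [
    "Study",
    "load_study",
    "round_half_up",
    "snap_to_count_fraction",
    "member_summary_table",
]

_METRICS = ("sensitivity", "specificity", "auc")


def round_half_up(value: Real, decimals: int) -> float:
    """Decimal round-half-up (the convention of printed clinical tables;
    avoids both float representation artefacts and banker's rounding)."""
    if isinstance(value, Fraction):
        d = Decimal(value.numerator) / Decimal(value.denominator)
    else:
        d = Decimal(repr(float(value)))
    q = Decimal(1).scaleb(-decimals)
    return float(d.quantize(q, rounding=ROUND_HALF_UP))


def snap_to_count_fraction(printed: float, denominator: int, decimals: int) -> Fraction:
    """Recover the exact count fraction k/denominator behind a printed value.

    Returns the unique k/denominator that rounds (half-up) to the printed
    value; if no such k exists the printed value itself is kept exactly.
    """
    k = round(printed * denominator)
    candidate = Fraction(k, denominator)
    if round_half_up(candidate, decimals) == round(printed, decimals):
        return candidate
    return Fraction(Decimal(repr(printed)))


@dataclass
class Study:
    """One bundled case study: classifier table plus ensemble membership."""

    name: str
    classifiers: pd.DataFrame  # index = classifier id
    memberships: dict[str, list[str]]
    n_pos: int
    n_neg: int
    decimals: int  # presentation precision of the printed tables

    def exact_metric(self, classifier: str, metric: str) -> Fraction:
        """Metric value as an exact fraction.

        Sensitivity and specificity are snapped to count fractions over
        N_pos and N_neg; AUC (and accuracy) keep their printed decimal value
        exactly.
        """
        printed = float(self.classifiers.loc[classifier, metric])
        if metric == "sensitivity":
            return snap_to_count_fraction(printed, self.n_pos, self.decimals)
        if metric == "specificity":
            return snap_to_count_fraction(printed, self.n_neg, self.decimals)
        return Fraction(Decimal(repr(printed)))


def _data_path(filename: str) -> Path:
    return Path(resources.files(__package__) / filename)


def load_study(name: str) -> Study:
    """Load a bundled study by name ('kidney' or 'cancer')."""
    meta = {
        "kidney": {"n_pos": 11, "n_neg": 21, "decimals": 2},
        "cancer": {"n_pos": 38, "n_neg": 19, "decimals": 4},
    }
    if name not in meta:
        raise ValueError(f"unknown study {name!r}; available: {sorted(meta)}")
    classifiers = pd.read_csv(_data_path(f"{name}_classifiers.tsv"), sep="\t",
                              index_col="classifier")
    memberships = read_membership(_data_path(f"{name}_ensembles.tsv"))
    return Study(name=name, classifiers=classifiers, memberships=memberships, **meta[name])


def member_summary_table(study: Study, rounded: bool = True) -> pd.DataFrame:
    """Min/max/average of each member metric for every ensemble of a study.

    Averages are computed on exact fractions and rounded half-up at the
    study's presentation precision only at the end (when ``rounded``).
    """
    rows = {}
    for ensemble_id, members in study.memberships.items():
        row = {}
        for metric in _METRICS:
            stats = member_summary([study.exact_metric(m, metric) for m in members])
            for stat_name, value in stats.items():
                key = f"{metric}_{stat_name}"
                row[key] = round_half_up(value, study.decimals) if rounded else value
        rows[ensemble_id] = row
    return pd.DataFrame.from_dict(rows, orient="index")
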