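"""Immunohistochemistry scoring, positivity rules and contingency tests.

Scoring bands for ER, PR, AR, PTEN, GCDFP15, GGT1 and EGFR: score 0 when
no tumor cell stains, score 1 for 1-10% positive cells, score 2 for
11-100%, irrespective of intensity. ERBB2 uses the Herceptest
0/+/++/+++ scale.

Positivity: ER/PR/AR are positive at score 2 only; GGT1, GCDFP15, EGFR
and PTEN are positive at score >= 1 (for GGT1 this is the 1%-stained-cell
threshold); ERBB2 is positive at Herceptest +++ by default.

A typed-in copy of the study's Cowden/apocrine characteristics table
(17 tumors: 15 Cowden plus the two non-Cowden apocrine carcinomas)
ships with the package and is loaded by :func:`load_table2`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats

from .io import DataError

__all__ = [
    "MARKER_PANEL",
    "IhcScoreTable",
    "ContingencyTable",
    "score_from_percent",
    "positivity",
    "marker_counts",
    "contingency_test",
    "load_table2",
    "table2_long",
]

MARKER_PANEL = ("AR", "ER", "PR", "ERBB2", "GCDFP15", "GGT1", "PTEN", "EGFR")
SCORE2_MARKERS = frozenset({"ER", "PR", "AR"})
SCORE1_MARKERS = frozenset({"GGT1", "GCDFP15", "EGFR", "PTEN"})
GROUPS = ("cowden", "apocrine_noncowden", "control")


@dataclass
class IhcScoreTable:
    """Long-format IHC scores: one row per (sample, marker).

    Columns: sample_id, group, marker, percent_positive_cells (may be NA),
    intensity (1-3 or NA), score (0|1|2 or 'nd'), herceptest (0/+/++/+++,
    ERBB2 only).
    """

    rows: pd.DataFrame

    def __post_init__(self) -> None:
        need = {"sample_id", "group", "marker", "score"}
        missing = need - set(self.rows.columns)
        if missing:
            raise DataError(f"IHC table missing columns: {sorted(missing)}")
        bad_marker = set(self.rows["marker"]) - set(MARKER_PANEL)
        if bad_marker:
            raise DataError(f"unknown markers: {sorted(bad_marker)}")
        bad_group = set(self.rows["group"]) - set(GROUPS)
        if bad_group:
            raise DataError(f"unknown groups: {sorted(bad_group)}")
        if "percent_positive_cells" in self.rows.columns:
            pct = pd.to_numeric(self.rows["percent_positive_cells"], errors="coerce")
            score = pd.to_numeric(self.rows["score"], errors="coerce")
            both = pct.notna() & score.notna()
            expected = pct[both].map(score_from_percent)
            if (expected != score[both]).any():
                bad = self.rows.loc[both][expected != score[both]].iloc[0]
                raise DataError(
                    f"score inconsistent with percent rule for sample "
                    f"{bad['sample_id']!r} marker {bad['marker']!r}"
                )


@dataclass
class ContingencyTable:
    row_labels: list[str]
    col_labels: list[str]
    counts: np.ndarray
    test_used: str
    statistic: float
    p_value: float

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        if (c < 0).any() or not np.allclose(c, np.round(c)):
            raise DataError("contingency counts must be non-negative integers")


def score_from_percent(percent_positive: float) -> int:
    """Map a percentage of stained tumor cells to the 0/1/2 score."""
    if not 0 <= percent_positive <= 100:
        raise DataError(f"percent must be in [0, 100], got {percent_positive}")
    if percent_positive == 0:
        return 0
    if percent_positive <= 10:
        return 1
    return 2


def positivity(
    marker: str,
    score: int | None = None,
    herceptest: str | None = None,
    erbb2_positive: tuple[str, ...] = ("+++",),
) -> bool:
    """Positive/negative call for one marker reading."""
    if marker not in MARKER_PANEL:
        raise DataError(f"unknown marker {marker!r}")
    if marker == "ERBB2":
        if herceptest is None:
            raise DataError("ERBB2 positivity needs a Herceptest value")
        return herceptest in erbb2_positive
    if score is None:
        raise DataError(f"{marker} positivity needs a score")
    if marker in SCORE2_MARKERS:
        return score == 2
    return score >= 1


def marker_counts(
    table: IhcScoreTable,
    marker: str,
    group: str,
    negative: bool = False,
) -> tuple[int, int]:
    """(n_positive, n_total) for one marker within one group.

    Rows scored 'nd' (not determined) are excluded from the denominator.
    With ``negative=True`` the numerator counts negative samples instead.
    """
    rows = table.rows
    sub = rows[(rows["marker"] == marker) & (rows["group"] == group)]
    if len(sub) == 0:
        raise DataError(f"no rows for marker {marker!r} in group {group!r}")
    sub = sub[sub["score"].astype(str).str.lower() != "nd"]
    n_total = len(sub)
    n_pos = 0
    for _, r in sub.iterrows():
        if marker == "ERBB2":
            pos = positivity(marker, herceptest=str(r["score"]))
        else:
            pos = positivity(marker, score=int(r["score"]))
        n_pos += int(pos)
    return (n_total - n_pos, n_total) if negative else (n_pos, n_total)


def contingency_test(counts) -> ContingencyTable:
    """Pearson chi-square test of independence; for 2x2 tables whose
    expected counts are not all above 5, the two-sided Fisher exact test
    (minimum-likelihood convention) is used instead."""
    c = np.asarray(counts, dtype=float)
    if c.ndim != 2 or min(c.shape) < 2:
        raise DataError(f"need an r x c table with r, c >= 2, got shape {c.shape}")
    if (c.sum(axis=0) == 0).any() or (c.sum(axis=1) == 0).any():
        raise DataError("contingency table has a zero margin")
    chi2, p, _, expected = stats.chi2_contingency(c, correction=False)
    test = "chi-square"
    statistic = float(chi2)
    if c.shape == (2, 2) and (expected <= 5).any():
        odds, p = stats.fisher_exact(c.astype(int), alternative="two-sided")
        test = "fisher"
        statistic = float(odds)
    elif (expected < 5).any():
        warnings.warn("sparse r x c table: chi-square approximation may be poor")
    rows = [f"r{i}" for i in range(c.shape[0])]
    cols = [f"c{j}" for j in range(c.shape[1])]
    return ContingencyTable(
        row_labels=rows,
        col_labels=cols,
        counts=c.astype(int),
        test_used=test,
        statistic=statistic,
        p_value=float(p),
    )


def load_table2() -> pd.DataFrame:
    """The shipped per-tumor characteristics table (wide format): 15 Cowden
    tumors plus the two non-Cowden apocrine carcinomas (cases 46 and 96)."""
    with resources.files("apocrine.data").joinpath("table2.tsv").open() as fh:
        t = pd.read_csv(fh, sep="\t", dtype=str, keep_default_na=False)
    return t.set_index("sample_id")


def table2_long(wide: pd.DataFrame | None = None) -> IhcScoreTable:
    """Convert the wide per-tumor table to the long IHC score format.

    Group is 'cowden' when the Cowden-disease column is yes, otherwise
    'apocrine_noncowden' (the table only contains those two groups).
    """
    if wide is None:
        wide = load_table2()
    markers = [m for m in MARKER_PANEL if m in wide.columns]
    rows = []
    for sample, r in wide.iterrows():
        group = "cowden" if r["cowden_disease"].strip().lower() == "yes" else "apocrine_noncowden"
        for m in markers:
            rows.append(
                {
                    "sample_id": sample,
                    "group": group,
                    "marker": m,
                    "percent_positive_cells": np.nan,
                    "intensity": np.nan,
                    "score": r[m],
                    "herceptest": r[m] if m == "ERBB2" else "",
                }
            )
    return IhcScoreTable(pd.DataFrame(rows))
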