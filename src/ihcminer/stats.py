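"""Contingency tables and chi-squared comparisons of receptor status by
metastatic site group.

2x2 tables get Pearson's chi-squared with Yates' continuity correction,
with the correction term clamped at |O - E| so a perfectly homogeneous
table yields a statistic of exactly 0; r x c tables get the plain Pearson
statistic. Upper-tail probabilities come from the regularized upper
incomplete gamma function Q(df/2, x/2).

Cases whose marker was not extracted ("not tested") are excluded from the
tables before testing. No multiple-testing correction is applied; raw
p-values are reported.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import numpy as np
from scipy.special import gammaincc

from .case_finder import DISTANT, REGIONAL
from .corpus_io import ExtractionRecord

__all__ = [
    "ContingencyTable",
    "Chi2Result",
    "build_contingency",
    "chi2_yates_2x2",
    "chi2_pearson",
    "chi2_sf",
    "compare_site_groups",
]

logger = logging.getLogger(__name__)

_STATUS_LEVELS = {
    "ER": ("positive", "negative"),
    "PR": ("positive", "negative"),
    "HER2": ("positive", "equivocal", "negative"),
}


@dataclass(frozen=True)
class ContingencyTable:
    row_labels: tuple[str, ...]
    col_labels: tuple[str, ...]
    counts: tuple[tuple[int, ...], ...]

    def __post_init__(self) -> None:
        arr = np.asarray(self.counts)
        if arr.ndim != 2 or arr.shape[0] < 2 or arr.shape[1] < 2:
            raise ValueError("contingency table must be at least 2x2")
        if arr.shape != (len(self.row_labels), len(self.col_labels)):
            raise ValueError("labels do not match table shape")
        if (arr < 0).any():
            raise ValueError("counts must be non-negative")

    def as_array(self) -> np.ndarray:
        return np.asarray(self.counts, dtype=float)


@dataclass(frozen=True)
class Chi2Result:
    statistic: float
    df: int
    p_value: float
    yates_applied: bool


def chi2_sf(x: float, df: int) -> float:
    """Upper-tail probability of the chi-squared distribution."""
    if x < 0:
        raise ValueError("chi-squared statistic must be non-negative")
    if df < 1:
        raise ValueError("df must be >= 1")
    return float(gammaincc(df / 2.0, x / 2.0))


def _expected(obs: np.ndarray) -> np.ndarray:
    rows = obs.sum(axis=1, keepdims=True)
    cols = obs.sum(axis=0, keepdims=True)
    total = obs.sum()
    if (rows == 0).any() or (cols == 0).any():
        bad = "row" if (rows == 0).any() else "column"
        raise ValueError(f"degenerate table: a {bad} margin is zero")
    return rows * cols / total


def chi2_yates_2x2(table: Union[ContingencyTable, Sequence[Sequence[int]]]) -> Chi2Result:
    """Yates-continuity-corrected chi-squared for a 2x2 table.

    statistic = sum((|O - E| - c)^2 / E) with c = min(0.5, |O - E|).
    """
    obs = table.as_array() if isinstance(table, ContingencyTable) else np.asarray(table, dtype=float)
    if obs.shape != (2, 2):
        raise ValueError(f"chi2_yates_2x2 requires a 2x2 table, got {obs.shape}")
    exp = _expected(obs)
    dev = np.abs(obs - exp)
    corrected = dev - np.minimum(0.5, dev)
    stat = float((corrected ** 2 / exp).sum())
    return Chi2Result(statistic=stat, df=1, p_value=chi2_sf(stat, 1),
                      yates_applied=True)


def chi2_pearson(table: Union[ContingencyTable, Sequence[Sequence[int]]]) -> Chi2Result:
    """Plain Pearson chi-squared for an r x c table; df = (r-1)(c-1)."""
    obs = table.as_array() if isinstance(table, ContingencyTable) else np.asarray(table, dtype=float)
    if obs.ndim != 2 or min(obs.shape) < 2:
        raise ValueError("chi2_pearson requires at least a 2x2 table")
    exp = _expected(obs)
    stat = float(((obs - exp) ** 2 / exp).sum())
    df = (obs.shape[0] - 1) * (obs.shape[1] - 1)
    return Chi2Result(statistic=stat, df=df, p_value=chi2_sf(stat, df),
                      yates_applied=False)


def build_contingency(
    records: Sequence[ExtractionRecord],
    marker: str,
    grouping: str = "site_class",
    *,
    sites: Sequence[str] = ("bone", "liver", "lung"),
) -> ContingencyTable:
    """Cross-tabulate a marker's status levels against site groups.

    ``grouping="site_class"`` yields columns (distant, regional);
    ``grouping="site"`` yields one column per entry of ``sites``.
    Records whose marker was not extracted are excluded.
    """
    marker = marker.upper()
    if marker not in _STATUS_LEVELS:
        raise ValueError(f"unknown marker {marker!r}")
    levels = _STATUS_LEVELS[marker]
    if grouping == "site_class":
        cols = (DISTANT, REGIONAL)
        col_of = lambda r: r.site_class
    elif grouping == "site":
        cols = tuple(sites)
        col_of = lambda r: (r.site_text or "").lower()
    else:
        raise ValueError(f"unknown grouping {grouping!r}")
    counts = [[0] * len(cols) for _ in levels]
    n = 0
    for rec in records:
        result = getattr(rec, marker.lower())
        if result is None or not result.found or result.status not in levels:
            continue
        col = col_of(rec)
        if col not in cols:
            continue
        counts[levels.index(result.status)][cols.index(col)] += 1
        n += 1
    if n == 0:
        raise ValueError(f"no records with a {marker} result in the selection")
    return ContingencyTable(row_labels=levels, col_labels=cols,
                            counts=tuple(tuple(r) for r in counts))


@dataclass(frozen=True)
class GroupComparison:
    marker: str
    grouping: str
    table: ContingencyTable
    result: Chi2Result


def compare_site_groups(
    records: Sequence[ExtractionRecord],
    *,
    min_group_size: int = 1,
    sites: Sequence[str] = ("bone", "liver", "lung"),
) -> list[GroupComparison]:
    """Chi-squared comparisons per marker: distant vs regional (Yates for
    2x2, Pearson otherwise) and across major distant sites (Pearson).

    Markers whose smallest group falls below ``min_group_size`` are
    skipped with a notice.
    """
    out: list[GroupComparison] = []
    for grouping in ("site_class", "site"):
        for marker in ("ER", "PR", "HER2"):
            try:
                table = build_contingency(records, marker, grouping, sites=sites)
            except ValueError as exc:
                logger.info("skipping %s by %s: %s", marker, grouping, exc)
                continue
            arr = table.as_array()
            if arr.sum(axis=0).min() < min_group_size:
                logger.info("skipping %s by %s: a group is below %d",
                            marker, grouping, min_group_size)
                continue
            try:
                if arr.shape == (2, 2) and grouping == "site_class":
                    result = chi2_yates_2x2(table)
                else:
                    result = chi2_pearson(table)
            except ValueError as exc:
                logger.info("skipping %s by %s: %s", marker, grouping, exc)
                continue
            out.append(GroupComparison(marker, grouping, table, result))
    if not out:
        raise ValueError("no marker/grouping combination could be tested")
    return out


def write_stats_csv(comparisons: Iterable[GroupComparison],
                    path: Union[str, Path]) -> int:
    path = Path(path)
    count = 0
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["marker", "grouping", "statistic", "df", "p_value",
                         "yates_correction"])
        for c in comparisons:
            writer.writerow([c.marker, c.grouping,
                             f"{c.result.statistic:.6g}", c.result.df,
                             f"{c.result.p_value:.6g}",
                             str(c.result.yates_applied).lower()])
            count += 1
    return count


def format_stats_report(comparisons: Iterable[GroupComparison]) -> str:
    """Human-readable tabulation of each comparison with its table."""
    lines = ["Chi-squared comparisons (raw p-values, no multiplicity correction)",
             ""]
    for c in comparisons:
        lines.append(f"{c.marker} by {c.grouping}")
        header = "\t".join([""] + list(c.table.col_labels))
        lines.append(header)
        for label, row in zip(c.table.row_labels, c.table.counts):
            lines.append("\t".join([label] + [str(v) for v in row]))
        corr = " (Yates)" if c.result.yates_applied else ""
        lines.append(
            f"chi2 = {c.result.statistic:.4f}, df = {c.result.df}, "
            f"p = {c.result.p_value:.4g}{corr}"
        )
        lines.append("")
    return "\n".join(lines)
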