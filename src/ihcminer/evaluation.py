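"""Scoring case-finding and extraction against gold annotations.

The source convention this mirrors uses nonstandard metric names:

* "specificity" of case detection = correctly labelled / labelled — this
  is conventionally precision / positive predictive value;
* "sensitivity" of result extraction = results detected / true cases;
* "specificity" of result extraction = correct extractions / detected.

Those names are kept for fidelity but every report co-emits the
conventional precision/recall/F1 so the vocabulary cannot silently
propagate.

Metric percentages are formatted by *truncation* to one decimal, the
convention the reference values follow (329/359 -> 91.6, 83/131 -> 63.3,
65/83 -> 78.3, 64/65 -> 98.4; half-up rounding would give 63.4 and 98.5).
Receptor-positivity percentages elsewhere use half-up rounding — see
:func:`format_percent`.
"""

from __future__ import annotations

import csv
import logging
import math
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

from .case_finder import DISTANT, REGIONAL, MetastasisCall
from .corpus_io import ExtractionRecord
from .ihc_extractor import ReceptorPanel, ReceptorResult, format_receptor, parse_receptor_cell

__all__ = [
    "GoldAnnotation",
    "ConfusionCounts",
    "Proportion",
    "EvaluationReport",
    "format_percent",
    "label_precision",
    "detection_sensitivity",
    "extraction_specificity",
    "score_run",
    "read_gold_csv",
    "write_gold_csv",
]

logger = logging.getLogger(__name__)

GOLD_HEADER = ["case_id", "true_metastatic", "true_site_class",
               "er", "pr", "her2", "confounder_type"]

CONFOUNDER_TYPES = ("none", "chest_wall_recurrence", "sp_breast_sentinel",
                    "treatment_note")


def format_percent(fraction: float, *, decimals: int = 1, mode: str = "truncate") -> str:
    """Format a fraction as a percent string.

    ``mode="truncate"`` floors to the given decimals (the detection /
    extraction metric convention); ``mode="half_up"`` rounds half-up (the
    receptor-positivity convention, 198/308 -> "64.3%").
    """
    value = fraction * 100.0
    if mode == "truncate":
        scale = 10 ** decimals
        value = math.floor(value * scale + 1e-9) / scale
        return f"{value:.{decimals}f}%"
    if mode == "half_up":
        q = Decimal(1).scaleb(-decimals)
        return f"{Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP)}%"
    raise ValueError(f"unknown mode {mode!r}")


@dataclass(frozen=True)
class Proportion:
    """A ratio reported both as a fraction and as a formatted percent."""

    numerator: int
    denominator: int
    percent: str

    @property
    def fraction(self) -> float:
        return self.numerator / self.denominator


def _proportion(numerator: int, denominator: int, what: str) -> Proportion:
    if denominator <= 0:
        raise ValueError(f"{what} is undefined for a zero denominator")
    if not 0 <= numerator <= denominator:
        raise ValueError(f"{what}: need 0 <= {numerator} <= {denominator}")
    return Proportion(numerator, denominator,
                      format_percent(numerator / denominator))


def label_precision(labeled: int, correct: int) -> Proportion:
    """Correctly labelled / labelled (the source's detection "specificity")."""
    return _proportion(correct, labeled, "label_precision")


def detection_sensitivity(total_with_result: int, detected: int) -> Proportion:
    """Results detected / true cases carrying a result."""
    return _proportion(detected, total_with_result, "detection_sensitivity")


def extraction_specificity(detected: int, correct: int) -> Proportion:
    """Correct extractions / detected."""
    return _proportion(correct, detected, "extraction_specificity")


@dataclass(frozen=True)
class GoldAnnotation:
    case_id: str
    true_metastatic: bool
    true_site_class: Optional[str] = None
    true_panel: Optional[ReceptorPanel] = None
    confounder_type: str = "none"

    def __post_init__(self) -> None:
        if self.true_metastatic != (self.true_site_class is not None):
            raise ValueError(
                f"{self.case_id}: true_site_class must be present iff true_metastatic"
            )
        if self.true_site_class not in (None, REGIONAL, DISTANT):
            raise ValueError(f"invalid true_site_class {self.true_site_class!r}")
        if self.confounder_type not in CONFOUNDER_TYPES:
            raise ValueError(f"invalid confounder_type {self.confounder_type!r}")


@dataclass
class ConfusionCounts:
    labeled: int = 0
    correct: int = 0
    total_with_result: int = 0
    detected: int = 0
    detected_correct: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.correct <= self.labeled if self.labeled else self.correct == 0):
            raise ValueError("need 0 <= correct <= labeled")
        if self.detected > self.total_with_result:
            raise ValueError("need detected <= total_with_result")


@dataclass
class EvaluationReport:
    by_class: dict
    standard: dict
    unassessable: list[str] = field(default_factory=list)


def _panel_mentions(panel: Optional[ReceptorPanel]) -> set[str]:
    if panel is None:
        return set()
    return {m for m in ("ER", "PR", "HER2") if panel.get(m).found}


def score_run(
    calls: Sequence[MetastasisCall],
    records: Sequence[ExtractionRecord],
    gold: Sequence[GoldAnnotation],
) -> EvaluationReport:
    """Aggregate detection and extraction scores per site class.

    Calls lacking a gold row are listed as unassessable and excluded from
    all counts. The result is invariant to input ordering.
    """
    gold_by_id = {g.case_id: g for g in gold}
    rec_by_id = {r.case_id: r for r in records}
    unassessable = sorted(
        c.case_id for c in calls if c.case_id not in gold_by_id
    )
    for cid in unassessable:
        logger.warning("case %s has no gold annotation; excluded", cid)

    by_class: dict[str, ConfusionCounts] = {}
    tp = fp = 0
    for cls in (REGIONAL, DISTANT):
        counts = ConfusionCounts()
        for call in calls:
            g = gold_by_id.get(call.case_id)
            if g is None or call.site_class != cls:
                continue
            counts.labeled += 1
            if g.true_metastatic and g.true_site_class == cls:
                counts.correct += 1
        # extraction scored on correctly labelled true cases of this class
        for call in calls:
            g = gold_by_id.get(call.case_id)
            if g is None or call.site_class != cls:
                continue
            if not (g.true_metastatic and g.true_site_class == cls):
                continue
            true_mentions = _panel_mentions(g.true_panel)
            if not true_mentions:
                continue
            counts.total_with_result += 1
            rec = rec_by_id.get(call.case_id)
            found = {
                m for m in ("ER", "PR", "HER2")
                if rec is not None and getattr(rec, m.lower()) is not None
                and getattr(rec, m.lower()).found
            }
            if found:
                counts.detected += 1
                ok = all(
                    getattr(rec, m.lower()) == g.true_panel.get(m)
                    for m in found & true_mentions
                ) and found <= true_mentions
                if ok:
                    counts.detected_correct += 1
        by_class[cls] = counts
        tp += counts.correct
        fp += counts.labeled - counts.correct

    n_true = sum(
        1 for g in gold if g.true_metastatic
    )
    fn = n_true - tp
    precision = tp / (tp + fp) if (tp + fp) else float("nan")
    recall = tp / (tp + fn) if (tp + fn) else float("nan")
    f1 = (2 * precision * recall / (precision + recall)
          if (tp + fp) and (tp + fn) and (precision + recall) > 0 else float("nan"))
    standard = {"precision": precision, "recall": recall, "f1": f1,
                "tp": tp, "fp": fp, "fn": fn}
    return EvaluationReport(by_class=by_class, standard=standard,
                            unassessable=unassessable)


# ---------------------------------------------------------------------------
# Gold CSV
# ---------------------------------------------------------------------------


def _panel_from_cells(er: str, pr: str, her2: str) -> Optional[ReceptorPanel]:
    cells = {"ER": er, "PR": pr, "HER2": her2}
    if all(c.strip() in ("", "None") for c in cells.values()):
        return None
    results = {}
    for marker, cell in cells.items():
        parsed = parse_receptor_cell(marker, cell)
        results[marker] = parsed if parsed is not None else ReceptorResult(marker)
    return ReceptorPanel(er=results["ER"], pr=results["PR"], her2=results["HER2"])


def read_gold_csv(path: Union[str, Path]) -> list[GoldAnnotation]:
    path = Path(path)
    out: list[GoldAnnotation] = []
    with path.open("r", newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        for row in reader:
            true_met = row["true_metastatic"].strip().lower() in ("1", "true", "yes")
            cls = row["true_site_class"].strip() or None
            out.append(GoldAnnotation(
                case_id=row["case_id"],
                true_metastatic=true_met,
                true_site_class=cls,
                true_panel=_panel_from_cells(row["er"], row["pr"], row["her2"]),
                confounder_type=row["confounder_type"].strip() or "none",
            ))
    return out


def write_gold_csv(gold: Iterable[GoldAnnotation], path: Union[str, Path]) -> int:
    path = Path(path)
    count = 0
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(GOLD_HEADER)
        for g in gold:
            panel = g.true_panel
            writer.writerow([
                g.case_id,
                "true" if g.true_metastatic else "false",
                g.true_site_class or "",
                format_receptor(panel.er) if panel else "None",
                format_receptor(panel.pr) if panel else "None",
                format_receptor(panel.her2) if panel else "None",
                g.confounder_type,
            ])
            count += 1
    return count
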