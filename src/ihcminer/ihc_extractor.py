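"""Two-step extraction of ER/PR/HER2 immunohistochemistry results.

Step one locates description paragraphs that carry immunohistochemical
findings (the diagnosis column is never scanned); step two parses each
marker with the 2013 CAP reporting patterns:

* ER/PR: ``ER (positive, 80%)``, ``ER: positive, 80%``, ``ER (negative)``
* HER2:  ``HER2 (positive, 3+)`` or
  ``Her-2: negative, score 1, weak staining in 10%``

ER/PR carry only positive/negative (an "equivocal" ER/PR token is treated
as unparseable); HER2 carries positive/equivocal/negative plus a score in
{0, 1+, 2+, 3+} and, in the colon dialect, an optional staining intensity
and percentage.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace
from typing import Optional

__all__ = [
    "ReceptorResult",
    "ReceptorPanel",
    "locate_ihc_paragraphs",
    "parse_er",
    "parse_pr",
    "parse_her2",
    "parse_marker",
    "extract_panel",
    "format_receptor",
    "parse_receptor_cell",
]

logger = logging.getLogger(__name__)

MARKERS = ("ER", "PR", "HER2")
STATUSES = ("positive", "negative", "equivocal", "not_found")
SCORES = ("0", "1+", "2+", "3+")

# score -> status consistency expected by the 2013 convention
_SCORE_STATUS = {"3+": "positive", "2+": "equivocal", "1+": "negative", "0": "negative"}


@dataclass(frozen=True)
class ReceptorResult:
    """A single marker's parsed result.

    ``raw_span`` is the matched text and is excluded from equality so that
    logically identical results compare equal across rendering dialects.
    """

    marker: str
    status: str = "not_found"
    percent: Optional[int] = None
    score: Optional[str] = None
    intensity: Optional[str] = None
    raw_span: str = field(default="", compare=False)

    def __post_init__(self) -> None:
        if self.marker not in MARKERS:
            raise ValueError(f"unknown marker {self.marker!r}")
        if self.status not in STATUSES:
            raise ValueError(f"unknown status {self.status!r}")
        if self.marker != "HER2":
            if self.status == "equivocal":
                raise ValueError("equivocal is only valid for HER2")
            if self.score is not None:
                raise ValueError("score is only valid for HER2")
            if self.intensity is not None:
                raise ValueError("intensity is only valid for HER2")
        if self.score is not None and self.score not in SCORES:
            raise ValueError(f"invalid HER2 score {self.score!r}")
        if self.percent is not None and not 0 <= self.percent <= 100:
            raise ValueError(f"percent out of range: {self.percent}")

    @property
    def found(self) -> bool:
        return self.status != "not_found"


@dataclass(frozen=True)
class ReceptorPanel:
    er: ReceptorResult
    pr: ReceptorResult
    her2: ReceptorResult

    def get(self, marker: str) -> ReceptorResult:
        return {"ER": self.er, "PR": self.pr, "HER2": self.her2}[marker]

    @classmethod
    def empty(cls) -> "ReceptorPanel":
        return cls(
            er=ReceptorResult("ER"),
            pr=ReceptorResult("PR"),
            her2=ReceptorResult("HER2"),
        )


# ---------------------------------------------------------------------------
# Step 1: locating immunohistochemistry-bearing paragraphs
# ---------------------------------------------------------------------------

_IHC_ANNOUNCE = re.compile(r"immunohistochem", re.IGNORECASE)
# a marker token followed by an opening parenthesis or a colon marks a
# result block in the row and comma dialects
_MARKER_CUE = re.compile(
    r"\b(?:ER|PR|Her-?2)\s*[(:]", re.IGNORECASE
)


def locate_ihc_paragraphs(report) -> list[str]:
    """Return description paragraphs carrying immunohistochemical results.

    Only the description column is scanned; the diagnosis column never
    influences extraction.
    """
    hits = []
    for para in report.description_paragraphs:
        if _IHC_ANNOUNCE.search(para) or _MARKER_CUE.search(para):
            hits.append(para)
    return hits


# ---------------------------------------------------------------------------
# Step 2: marker parsing
# ---------------------------------------------------------------------------

_PCT = r"(\d{1,3})(?:\s*-\s*\d{1,3})?\s*%"

def _erpr_patterns(marker: str) -> list[re.Pattern]:
    tok = rf"\b{marker}\b"
    return [
        # "ER (positive, 80%)" and "ER (negative)"
        re.compile(
            rf"{tok}\s*\(\s*(positive|negative)(?:\s*,\s*{_PCT})?\s*\)",
            re.IGNORECASE,
        ),
        # "ER: positive, 80%" / "ER: negative"
        re.compile(
            rf"{tok}\s*:\s*(positive|negative)(?:\s*,\s*{_PCT})?",
            re.IGNORECASE,
        ),
    ]


_ER_PATTERNS = _erpr_patterns("ER")
_PR_PATTERNS = _erpr_patterns("PR")

_HER2_TOK = r"\bHer-?2\b"
_HER2_STATUS = r"(positive|equivocal|negative)"
_HER2_SCORE = r"(?:score\s*([0-3])|([0-3])\s*\+|(0)\b)"
_HER2_PATTERNS = [
    # "HER2 (positive, 3+)"; score optional but expected
    re.compile(
        rf"{_HER2_TOK}\s*\(\s*{_HER2_STATUS}(?:\s*,\s*{_HER2_SCORE})?\s*\)",
        re.IGNORECASE,
    ),
    # "Her-2: negative, score 1, weak staining in 10%"
    re.compile(
        rf"{_HER2_TOK}\s*:\s*{_HER2_STATUS}(?:\s*,\s*{_HER2_SCORE})?"
        rf"(?:\s*,\s*(weak|moderate|strong)\s+staining\s+in\s+{_PCT})?",
        re.IGNORECASE,
    ),
]

_ERPR_TOKEN = {"ER": re.compile(r"\bER\b", re.IGNORECASE),
               "PR": re.compile(r"\bPR\b", re.IGNORECASE),
               "HER2": re.compile(_HER2_TOK, re.IGNORECASE)}


def _normalize_score(score_word: Optional[str], score_plus: Optional[str],
                     score_zero: Optional[str]) -> Optional[str]:
    # bare "score 2" -> "2+"; "score 0" and bare "0" stay "0"
    if score_word is not None:
        return "0" if score_word == "0" else f"{score_word}+"
    if score_plus is not None:
        return "0" if score_plus == "0" else f"{score_plus}+"
    if score_zero is not None:
        return "0"
    return None


def _parse_erpr(marker: str, patterns: list[re.Pattern], paragraph: str) -> ReceptorResult:
    best: Optional[re.Match] = None
    for pat in patterns:
        m = pat.search(paragraph)
        if m and (best is None or m.start() < best.start()):
            best = m
    if best is None:
        if _ERPR_TOKEN[marker].search(paragraph):
            logger.warning("%s token present but tail unparseable: %r",
                           marker, paragraph[:80])
        return ReceptorResult(marker)
    status = best.group(1).lower()
    percent = int(best.group(2)) if best.group(2) is not None else None
    if status == "negative":
        percent = None  # the convention reports a percentage only for positives
    return ReceptorResult(marker, status=status, percent=percent,
                          raw_span=best.group(0))


def parse_er(paragraph: str) -> ReceptorResult:
    """Parse the first ER mention in a paragraph."""
    return _parse_erpr("ER", _ER_PATTERNS, paragraph)


def parse_pr(paragraph: str) -> ReceptorResult:
    """Parse the first PR mention in a paragraph."""
    return _parse_erpr("PR", _PR_PATTERNS, paragraph)


def parse_her2(paragraph: str) -> ReceptorResult:
    """Parse the first HER2 mention (all four spellings, both dialects)."""
    best: Optional[re.Match] = None
    for pat in _HER2_PATTERNS:
        m = pat.search(paragraph)
        if m and (best is None or m.start() < best.start()):
            best = m
    if best is None:
        if _ERPR_TOKEN["HER2"].search(paragraph):
            logger.warning("HER2 token present but tail unparseable: %r",
                           paragraph[:80])
        return ReceptorResult("HER2")
    status = best.group(1).lower()
    score = _normalize_score(best.group(2), best.group(3), best.group(4))
    groups = best.groups()
    intensity = groups[4].lower() if len(groups) > 4 and groups[4] else None
    percent = int(groups[5]) if len(groups) > 5 and groups[5] else None
    if score is not None and _SCORE_STATUS[score] != status:
        logger.warning("HER2 status %r inconsistent with score %s in %r",
                       status, score, best.group(0))
    if score is None:
        logger.warning("HER2 result without score: %r", best.group(0))
    return ReceptorResult("HER2", status=status, score=score,
                          intensity=intensity, percent=percent,
                          raw_span=best.group(0))


def parse_marker(marker: str, paragraph: str) -> ReceptorResult:
    return {"ER": parse_er, "PR": parse_pr, "HER2": parse_her2}[marker](paragraph)


def extract_panel(report) -> ReceptorPanel:
    """Extract the full ER/PR/HER2 panel from a report.

    Located paragraphs are scanned in order; the first successful parse per
    marker wins. A later mention with a *different* status demotes the
    marker to not_found (conflict); a repeat with the same status is kept
    and logged.
    """
    results: dict[str, ReceptorResult] = {m: ReceptorResult(m) for m in MARKERS}
    conflicted: set[str] = set()
    for para in locate_ihc_paragraphs(report):
        for marker in MARKERS:
            hit = parse_marker(marker, para)
            if not hit.found:
                continue
            prev = results[marker]
            if not prev.found:
                results[marker] = hit
            elif prev.status != hit.status:
                logger.warning(
                    "%s: conflicting statuses %r vs %r in %s; demoting to not_found",
                    marker, prev.status, hit.status, getattr(report, "case_id", "?"),
                )
                conflicted.add(marker)
            else:
                logger.info("%s: repeat mention with same status ignored in %s",
                            marker, getattr(report, "case_id", "?"))
    for marker in conflicted:
        results[marker] = ReceptorResult(marker)
    return ReceptorPanel(er=results["ER"], pr=results["PR"], her2=results["HER2"])


# ---------------------------------------------------------------------------
# Canonical cell serialisation (used by the results CSV)
# ---------------------------------------------------------------------------


def format_receptor(result: ReceptorResult) -> str:
    """Canonical single-cell text for a parsed result."""
    if not result.found:
        return "None"
    parts = [result.status]
    if result.marker == "HER2":
        if result.score is not None:
            parts.append(result.score)
        if result.intensity is not None and result.percent is not None:
            parts.append(f"{result.intensity} staining in {result.percent}%")
    elif result.percent is not None:
        parts.append(f"{result.percent}%")
    return ", ".join(parts)


def parse_receptor_cell(marker: str, cell: str) -> Optional[ReceptorResult]:
    """Inverse of :func:`format_receptor`; ``"None"`` maps to None."""
    cell = cell.strip()
    if cell == "None" or not cell:
        return None
    if marker == "HER2":
        res = parse_her2(f"HER2: {cell}")
    else:
        res = parse_marker(marker, f"{marker}: {cell}")
    if not res.found:
        raise ValueError(f"cannot parse {marker} cell {cell!r}")
    return replace(res, raw_span=cell)
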