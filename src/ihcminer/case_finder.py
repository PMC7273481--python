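"""Four-step protocol labelling reports as regional/distant metastatic
breast cancer and parsing the metastatic site.

Step 1 — scan each diagnosis line for a metastatic-carcinoma phrase.
Step 2 — the SAME line must carry a breast-origin phrase.
Step 3 — if ANY diagnosis line shows a primary-breast-cancer phrase the
whole case is excluded (exclusion beats any positive evidence).
Step 4 — parse the metastatic site from the matched line: axillary soft
tissue / axillary lymph node classify as regional; any other leading organ
token classifies as distant, canonicalised through the organ vocabulary
(a non-axillary ``lymph node, <station>`` becomes "nonregional lymph
node"; an unknown organ is kept raw and logged).

The steps short-circuit in order; the evidence trail records which step
fired on which line.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Iterable, Optional

from .corpus_io import Report
from .lexicon import Lexicon, PhraseMatch, match_set

__all__ = ["MetastasisCall", "find_metastatic_line", "confirm_breast_origin",
           "excluded_by_primary", "parse_site", "find_cases"]

logger = logging.getLogger(__name__)

REGIONAL = "regional"
DISTANT = "distant"

# canonical regional site labels keyed by the default regional phrases
_REGIONAL_LABELS = {
    "soft tissue, axillary": "axillary soft tissue",
    "lymph node, axillary": "axillary lymph node",
}

_LN_RE = re.compile(r"^\s*lymph\s+nodes?\s*,\s*([^,]+)", re.IGNORECASE)
_AXILLARY_RE = re.compile(r"axillary", re.IGNORECASE)


@dataclass
class MetastasisCall:
    """The case finder's verdict for one report."""

    case_id: str
    is_metastatic_breast: bool = False
    excluded_as_primary: bool = False
    site_text: Optional[str] = None
    site_class: Optional[str] = None
    evidence: list[tuple[str, str, int]] = field(default_factory=list)
    error: Optional[str] = None

    @property
    def positive(self) -> bool:
        return self.is_metastatic_breast and not self.excluded_as_primary

    def __post_init__(self) -> None:
        if self.site_class is not None and self.site_class not in (REGIONAL, DISTANT):
            raise ValueError(f"invalid site_class {self.site_class!r}")


def find_metastatic_line(report: Report, lexicon: Lexicon) -> Optional[tuple[int, PhraseMatch]]:
    """Step 1: first diagnosis line matching a metastatic phrase, or None."""
    for idx, line in enumerate(report.diagnosis_lines):
        m = match_set(lexicon, "metastatic_phrases", line)
        if m:
            return idx, m
    return None


def confirm_breast_origin(matched_line: str, lexicon: Lexicon) -> bool:
    """Step 2: the same line must state breast origin."""
    return bool(match_set(lexicon, "breast_origin_phrases", matched_line))


def excluded_by_primary(report: Report, lexicon: Lexicon) -> bool:
    """Step 3: any diagnosis line showing a primary-breast phrase excludes
    the case; the description column is never consulted."""
    return any(
        match_set(lexicon, "primary_breast_phrases", line)
        for line in report.diagnosis_lines
    )


def parse_site(matched_line: str, lexicon: Lexicon) -> tuple[str, str]:
    """Step 4: (site_text, site_class) for a confirmed metastatic line."""
    if not matched_line.strip():
        raise ValueError("cannot parse site from an empty line")
    m = match_set(lexicon, "regional_site_phrases", matched_line)
    if m:
        label = _REGIONAL_LABELS.get(m.phrase.lower())
        if label is None:
            # user-configured regional phrase: use the matched text verbatim
            label = matched_line[m.span[0]:m.span[1]].lower()
        return label, REGIONAL
    ln = _LN_RE.match(matched_line)
    if ln and not _AXILLARY_RE.search(ln.group(1)):
        return "nonregional lymph node", DISTANT
    organ = matched_line.split(",", 1)[0].strip().lower()
    for key, canonical in lexicon.organ_vocabulary.items():
        if organ == key.lower():
            return canonical, DISTANT
    logger.warning("unknown organ %r; recording raw token as distant site", organ)
    return organ, DISTANT


def _call_one(report: Report, lexicon: Lexicon) -> MetastasisCall:
    call = MetastasisCall(case_id=report.case_id)
    hit = find_metastatic_line(report, lexicon)
    # if several lines match step 1, the first that also passes step 2
    # determines the site; the others are kept in evidence
    first_confirmed: Optional[tuple[int, PhraseMatch]] = None
    idx = 0
    while hit is not None:
        line_idx, m = hit
        call.evidence.append(("metastatic_phrase", m.phrase, line_idx))
        line = report.diagnosis_lines[line_idx]
        origin = match_set(lexicon, "breast_origin_phrases", line)
        if origin and first_confirmed is None:
            call.evidence.append(("breast_origin", origin.phrase, line_idx))
            first_confirmed = (line_idx, m)
        # continue scanning only to record remaining step-1 evidence
        nxt = None
        for j in range(line_idx + 1, len(report.diagnosis_lines)):
            mm = match_set(lexicon, "metastatic_phrases", report.diagnosis_lines[j])
            if mm:
                nxt = (j, mm)
                break
        hit = nxt
    if first_confirmed is None:
        return call
    call.is_metastatic_breast = True
    line_idx, _ = first_confirmed
    for j, line in enumerate(report.diagnosis_lines):
        pm = match_set(lexicon, "primary_breast_phrases", line)
        if pm:
            call.evidence.append(("primary_breast_exclusion", pm.phrase, j))
            call.excluded_as_primary = True
            return call
    site_text, site_class = parse_site(report.diagnosis_lines[line_idx], lexicon)
    call.site_text = site_text
    call.site_class = site_class
    call.evidence.append(("site", site_text, line_idx))
    return call


def find_cases(corpus: Iterable[Report], lexicon: Lexicon) -> list[MetastasisCall]:
    """Run the whole protocol over a corpus; one call per report.

    Per-report failures do not abort the run — the failing report yields a
    negative call carrying an error note.
    """
    calls: list[MetastasisCall] = []
    for report in corpus:
        try:
            calls.append(_call_one(report, lexicon))
        except Exception as exc:
            logger.error("case %s failed: %s", report.case_id, exc)
            calls.append(MetastasisCall(case_id=report.case_id, error=str(exc)))
    n_reg = sum(1 for c in calls if c.site_class == REGIONAL)
    n_dis = sum(1 for c in calls if c.site_class == DISTANT)
    logger.info("find_cases: %d reports, %d regional, %d distant",
                len(calls), n_reg, n_dis)
    return calls
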