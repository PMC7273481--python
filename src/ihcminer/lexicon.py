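"""Configurable phrase sets driving the case finder.

Five vocabularies: phrases flagging a metastatic carcinoma line, phrases
confirming breast origin, phrases that exclude a case as primary breast
cancer, regional-site phrases (axillary), and an organ vocabulary mapping
distant organ tokens to canonical site labels.

Phrases are treated as case-insensitive regular-expression fragments in
which runs of whitespace match any whitespace. User config (YAML or JSON)
is merged on top of the shipped defaults: list keys extend, the organ map
updates.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

import yaml

__all__ = [
    "Lexicon",
    "LexiconError",
    "PhraseMatch",
    "load_lexicon",
    "match_any",
    "DEFAULT_CONFIG",
]


class LexiconError(ValueError):
    """Invalid lexicon configuration."""


DEFAULT_CONFIG: dict = {
    "metastatic_phrases": [
        "carcinoma, metastatic",
        "carcinoma, involved",
    ],
    "breast_origin_phrases": [
        "breast origin",
        "breast primary",
    ],
    # the concrete primary-breast list is a local convention and must stay
    # overridable in config
    "primary_breast_phrases": [
        "mastectomy",
        "breast, (left|right|bilateral)",
        "invasive ductal carcinoma",
        "invasive lobular carcinoma",
        "ductal carcinoma in situ",
    ],
    "regional_site_phrases": [
        "soft tissue, axillary",
        "lymph node, axillary",
    ],
    # distant organ token -> canonical site label
    "organ_vocabulary": {
        "bone": "bone",
        "brain": "brain",
        "liver": "liver",
        "lung": "lung",
        "stomach": "GI tract",
        "colon": "GI tract",
        "rectum": "GI tract",
        "duodenum": "GI tract",
        "small intestine": "GI tract",
        "esophagus": "GI tract",
        "uterus": "uterus",
        "pleura": "pleura",
        "pelvic cavity": "pelvic cavity",
        "ovary": "ovary",
        "mediastinum": "mediastinum",
        "urinary bladder": "urinary bladder",
    },
}


def _compile(phrase: str) -> re.Pattern:
    """Compile a phrase: whitespace-tolerant, case-insensitive regex."""
    pattern = re.sub(r"\s+", r"\\s+", phrase.strip())
    try:
        return re.compile(pattern, re.IGNORECASE)
    except re.error as exc:
        raise LexiconError(f"phrase does not compile: {phrase!r} ({exc})") from exc


@dataclass(frozen=True)
class PhraseMatch:
    matched: bool
    phrase: Optional[str] = None
    span: Optional[tuple[int, int]] = None

    def __bool__(self) -> bool:
        return self.matched


@dataclass(frozen=True)
class Lexicon:
    metastatic_phrases: tuple[str, ...]
    breast_origin_phrases: tuple[str, ...]
    primary_breast_phrases: tuple[str, ...]
    regional_site_phrases: tuple[str, ...]
    organ_vocabulary: Mapping[str, str]
    _compiled: dict = field(default_factory=dict, compare=False, repr=False)

    def __post_init__(self) -> None:
        for name in ("metastatic_phrases", "breast_origin_phrases",
                     "primary_breast_phrases", "regional_site_phrases"):
            phrases = getattr(self, name)
            if not phrases:
                raise LexiconError(f"{name} must be non-empty")
        if not self.organ_vocabulary:
            raise LexiconError("organ_vocabulary must be non-empty")
        # a site cannot be both regional and distant
        for organ in self.organ_vocabulary:
            for phrase in self.regional_site_phrases:
                lo, lp = organ.lower(), phrase.lower()
                if lo in lp or lp in lo:
                    raise LexiconError(
                        f"organ {organ!r} collides with regional phrase {phrase!r}"
                    )
        compiled = {
            name: tuple(_compile(p) for p in getattr(self, name))
            for name in ("metastatic_phrases", "breast_origin_phrases",
                         "primary_breast_phrases", "regional_site_phrases")
        }
        object.__setattr__(self, "_compiled", compiled)

    def compiled(self, name: str) -> tuple[re.Pattern, ...]:
        return self._compiled[name]


def load_lexicon(config_path: Union[str, Path, None] = None) -> Lexicon:
    """Load the shipped defaults, merged with an optional YAML/JSON config."""
    cfg = {k: (list(v) if isinstance(v, list) else dict(v))
           for k, v in DEFAULT_CONFIG.items()}
    if config_path is not None:
        path = Path(config_path)
        text = path.read_text(encoding="utf-8")
        if path.suffix == ".json":
            user = json.loads(text)
        else:
            user = yaml.safe_load(text)
        if user is None:
            user = {}
        if not isinstance(user, dict):
            raise LexiconError(f"config root must be a mapping, got {type(user)}")
        for key, value in user.items():
            if key == "organ_vocabulary":
                if not isinstance(value, dict):
                    raise LexiconError("organ_vocabulary must be a mapping")
                cfg["organ_vocabulary"].update(
                    {str(k).lower(): str(v) for k, v in value.items()}
                )
            elif key in cfg:
                if not isinstance(value, list):
                    raise LexiconError(f"{key} must be a list")
                for phrase in value:
                    if phrase not in cfg[key]:
                        cfg[key].append(str(phrase))
            else:
                raise LexiconError(f"unknown lexicon key {key!r}")
    return Lexicon(
        metastatic_phrases=tuple(cfg["metastatic_phrases"]),
        breast_origin_phrases=tuple(cfg["breast_origin_phrases"]),
        primary_breast_phrases=tuple(cfg["primary_breast_phrases"]),
        regional_site_phrases=tuple(cfg["regional_site_phrases"]),
        organ_vocabulary=dict(cfg["organ_vocabulary"]),
    )


def match_any(
    phrases: Sequence[str], line: str, *, compiled: Optional[Sequence[re.Pattern]] = None
) -> PhraseMatch:
    """First match by leftmost position; ties broken by list order."""
    if compiled is None:
        compiled = [_compile(p) for p in phrases]
    best: Optional[tuple[int, int, int]] = None  # (start, list_idx, end)
    for idx, pat in enumerate(compiled):
        m = pat.search(line)
        if m is None:
            continue
        key = (m.start(), idx, m.end())
        if best is None or key[:2] < best[:2]:
            best = key
    if best is None:
        return PhraseMatch(False)
    start, idx, end = best
    return PhraseMatch(True, phrase=phrases[idx], span=(start, end))


def match_set(lexicon: Lexicon, set_name: str, line: str) -> PhraseMatch:
    """match_any against a named lexicon phrase set, using cached patterns."""
    return match_any(
        getattr(lexicon, set_name), line, compiled=lexicon.compiled(set_name)
    )
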