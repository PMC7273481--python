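"""Synthetic pathology-report corpora with ground truth.

Generates clean regional/distant metastatic reports whose IHC panels are
rendered in one of three supported dialects (an announcing sentence, a
multi-row block, a comma-separated block) or a deliberately unsupported
narrative dialect that models extraction misses; benign filler reports;
and the three known false-positive confounder report types (chest-wall
recurrence, "s/p breast cancer" sentinel-node notes, treatment notes).

All sampling is driven by one seeded ``random.Random`` so a fixed seed
reproduces the corpus byte-for-byte.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

from .corpus_io import Report, serialize_export
from .evaluation import GoldAnnotation, write_gold_csv
from .ihc_extractor import ReceptorPanel, ReceptorResult, format_receptor

__all__ = ["SynthSpec", "GroundTruth", "gen_corpus", "gen_confounder",
           "truths_to_gold", "write_corpus"]

DIALECTS = ("sentence", "multirow", "comma_block", "unsupported")
CONFOUNDERS = ("chest_wall_recurrence", "sp_breast_sentinel", "treatment_note")

# distant site templates: (diagnosis-line organ text, canonical truth site),
# weighted roughly like the observed site distribution
_DISTANT_SITES = [
    (("Lymph node, supraclavicular", "nonregional lymph node"), 8),
    (("Lymph node, cervical", "nonregional lymph node"), 7),
    (("Lymph node, inguinal", "nonregional lymph node"), 7),
    (("Bone", "bone"), 20),
    (("Brain", "brain"), 12),
    (("Liver", "liver"), 8),
    (("Stomach", "GI tract"), 4),
    (("Colon", "GI tract"), 4),
    (("Lung", "lung"), 7),
    (("Uterus", "uterus"), 1),
    (("Pleura", "pleura"), 1),
    (("Pelvic cavity", "pelvic cavity"), 1),
    (("Ovary", "ovary"), 1),
    (("Mediastinum", "mediastinum"), 1),
    (("Urinary bladder", "urinary bladder"), 1),
]

_REGIONAL_SITES = [
    ("Lymph node, axillary", "axillary lymph node"),
    ("Soft tissue, axillary", "axillary soft tissue"),
]

_PROCEDURES = ["excision", "biopsy", "core biopsy", "dissection"]
_MET_PHRASES = ["carcinoma, metastatic", "carcinoma, involved"]
_ORIGIN_PHRASES = ["breast origin", "breast primary"]

_BENIGN_TEMPLATES = [
    ("Stomach, biopsy --- chronic gastritis",
     "The gastric mucosa shows infiltration of lymphocytes and plasma cells."),
    ("Appendix, appendectomy --- acute suppurative appendicitis",
     "The appendiceal wall is infiltrated by neutrophils with serosal exudate."),
    ("Skin, back, excision --- intradermal nevus",
     "Nests of bland nevus cells are present within the dermis."),
    ("Gallbladder, cholecystectomy --- chronic cholecystitis",
     "The gallbladder wall is thickened with chronic inflammation."),
    ("Colon, polypectomy --- tubular adenoma",
     "The polyp shows tubular glands with low-grade dysplasia."),
    ("Thyroid, right lobe, lobectomy --- nodular hyperplasia",
     "Sections show colloid-filled follicles of varying size."),
]


@dataclass(frozen=True)
class SynthSpec:
    n_regional: int = 10
    n_distant: int = 5
    n_benign: int = 5
    dialect_mix: dict = field(default_factory=lambda: {
        "sentence": 0.4, "multirow": 0.3, "comma_block": 0.3, "unsupported": 0.0,
    })
    confounder_counts: dict = field(default_factory=dict)
    panel_distribution: dict = field(default_factory=lambda: {
        "ER": {"positive": 0.6, "negative": 0.3, "not_tested": 0.1},
        "PR": {"positive": 0.4, "negative": 0.4, "not_tested": 0.2},
        "HER2": {"positive": 0.3, "equivocal": 0.2, "negative": 0.4,
                 "not_tested": 0.1},
    })
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_regional, self.n_distant, self.n_benign) < 0:
            raise ValueError("counts must be non-negative")
        if any(v < 0 for v in self.confounder_counts.values()):
            raise ValueError("confounder counts must be non-negative")
        if set(self.confounder_counts) - set(CONFOUNDERS):
            raise ValueError(f"unknown confounder in {self.confounder_counts}")
        if set(self.dialect_mix) - set(DIALECTS):
            raise ValueError(f"unknown dialect in {self.dialect_mix}")
        total = sum(self.dialect_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"dialect_mix must sum to 1, got {total}")


@dataclass(frozen=True)
class GroundTruth:
    case_id: str
    true_metastatic: bool
    true_site_class: Optional[str] = None
    true_site: Optional[str] = None
    true_panel: Optional[ReceptorPanel] = None
    dialect: Optional[str] = None
    confounder_type: str = "none"


def _sample_panel(rng: random.Random, dist: dict, with_intensity: bool) -> ReceptorPanel:
    results = {}
    for marker in ("ER", "PR", "HER2"):
        probs = dist[marker]
        outcomes = list(probs)
        status = rng.choices(outcomes, weights=[probs[o] for o in outcomes])[0]
        if status == "not_tested":
            results[marker] = ReceptorResult(marker)
            continue
        if marker == "HER2":
            score = {"positive": "3+", "equivocal": "2+",
                     "negative": rng.choice(["0", "1+"])}[status]
            intensity = percent = None
            if with_intensity and rng.random() < 0.3:
                intensity = rng.choice(["weak", "moderate", "strong"])
                percent = rng.randrange(5, 100, 5)
            results[marker] = ReceptorResult(marker, status=status, score=score,
                                             intensity=intensity, percent=percent)
        else:
            percent = rng.randrange(5, 100, 5) if status == "positive" else None
            results[marker] = ReceptorResult(marker, status=status, percent=percent)
    return ReceptorPanel(er=results["ER"], pr=results["PR"], her2=results["HER2"])


def _render_result_paren(r: ReceptorResult) -> str:
    inner = r.status
    if r.marker == "HER2" and r.score is not None:
        inner += f", {r.score}"
    elif r.percent is not None:
        inner += f", {r.percent}%"
    return f"{r.marker} ({inner})"


def _render_result_colon(r: ReceptorResult) -> str:
    out = f"{r.marker}: {r.status}"
    if r.marker == "HER2":
        if r.score is not None:
            out += f", {r.score}"
        if r.intensity is not None and r.percent is not None:
            out += f", {r.intensity} staining in {r.percent}%"
    elif r.percent is not None:
        out += f", {r.percent}%"
    return out


_SPELLED = {"ER": "estrogen receptor", "PR": "progesterone receptor",
            "HER2": "Her-2 protein"}


def _render_ihc(panel: ReceptorPanel, dialect: str, rng: random.Random) -> Optional[str]:
    tested = [panel.get(m) for m in ("ER", "PR", "HER2") if panel.get(m).found]
    if not tested:
        return None
    if dialect == "sentence":
        parts = ", ".join(_render_result_paren(r) for r in tested)
        return f"Immunohistochemical study shows: {parts}."
    if dialect == "multirow":
        return "\n".join(_render_result_paren(r) for r in tested)
    if dialect == "comma_block":
        return "Immunohistochemical studies: " + ", ".join(
            _render_result_colon(r) for r in tested) + "."
    if dialect == "unsupported":
        # narrative phrasing with spelled-out marker names; deliberately
        # outside the supported patterns so extraction misses it
        bits = []
        for r in tested:
            name = _SPELLED[r.marker]
            if r.status == "positive" and r.percent is not None:
                bits.append(f"immunoreactive for {name} in {r.percent}% of tumor nuclei")
            elif r.status == "equivocal":
                bits.append(f"equivocally stained for {name}")
            else:
                bits.append(f"{r.status} for {name}")
        return "The tumor cells are " + "; ".join(bits) + "."
    raise ValueError(f"unknown dialect {dialect!r}")


def _metastatic_report(case_id: str, rng: random.Random, spec: SynthSpec,
                       site_line: str, true_site: str, site_class: str) -> tuple[Report, GroundTruth]:
    procedure = rng.choice(_PROCEDURES)
    met = rng.choice(_MET_PHRASES)
    origin = rng.choice(_ORIGIN_PHRASES)
    diagnosis = [f"{site_line}, {procedure} --- {met}, {origin}"]
    dialects = list(spec.dialect_mix)
    dialect = rng.choices(dialects, weights=[spec.dialect_mix[d] for d in dialects])[0]
    panel = _sample_panel(rng, spec.panel_distribution,
                          with_intensity=(dialect == "comma_block"))
    paragraphs = ["Sections show metastatic carcinoma consistent with breast origin."]
    ihc = _render_ihc(panel, dialect, rng)
    if ihc is not None:
        paragraphs.append(ihc)
    report = Report(case_id=case_id, diagnosis_lines=diagnosis,
                    description_paragraphs=paragraphs)
    truth = GroundTruth(case_id=case_id, true_metastatic=True,
                        true_site_class=site_class, true_site=true_site,
                        true_panel=panel, dialect=dialect)
    return report, truth


def gen_confounder(ctype: str, rng: random.Random, case_id: str = "C0000") -> Report:
    """A report that the finding protocol is known to falsely flag."""
    if ctype == "chest_wall_recurrence":
        met = rng.choice(_MET_PHRASES)
        return Report(
            case_id=case_id,
            diagnosis_lines=[
                f"Soft tissue, chest wall, wide excision --- {met}, "
                "recurrent disease, breast origin"
            ],
            description_paragraphs=[
                "Sections of the chest wall show recurrent carcinoma involving "
                "dermis and skeletal muscle."
            ],
        )
    if ctype == "sp_breast_sentinel":
        return Report(
            case_id=case_id,
            diagnosis_lines=[
                "Lymph node, sentinel, biopsy --- negative for carcinoma, "
                "metastatic, s/p breast cancer, breast origin"
            ],
            description_paragraphs=[
                "Three sentinel lymph nodes are examined and show no tumor."
            ],
        )
    if ctype == "treatment_note":
        return Report(
            case_id=case_id,
            diagnosis_lines=[
                "Uterus, endometrium, curettage --- endometrial hyperplasia; "
                "under tamoxifen treatment for carcinoma, metastatic, breast origin"
            ],
            description_paragraphs=[
                "Endometrial fragments show glandular hyperplasia without atypia."
            ],
        )
    raise ValueError(f"unknown confounder type {ctype!r}")


def gen_corpus(spec: SynthSpec) -> tuple[list[Report], list[GroundTruth]]:
    """Generate a corpus plus its aligned ground-truth table."""
    rng = random.Random(spec.seed)
    reports: list[Report] = []
    truths: list[GroundTruth] = []
    counter = 0

    def next_id() -> str:
        nonlocal counter
        counter += 1
        return f"S{counter:04d}"

    for _ in range(spec.n_regional):
        site_line, true_site = rng.choice(_REGIONAL_SITES)
        r, t = _metastatic_report(next_id(), rng, spec, site_line, true_site,
                                  "regional")
        reports.append(r)
        truths.append(t)
    site_choices = [s for s, _ in _DISTANT_SITES]
    site_weights = [w for _, w in _DISTANT_SITES]
    for _ in range(spec.n_distant):
        site_line, true_site = rng.choices(site_choices, weights=site_weights)[0]
        r, t = _metastatic_report(next_id(), rng, spec, site_line, true_site,
                                  "distant")
        reports.append(r)
        truths.append(t)
    for _ in range(spec.n_benign):
        diag, desc = rng.choice(_BENIGN_TEMPLATES)
        cid = next_id()
        reports.append(Report(case_id=cid, diagnosis_lines=[diag],
                              description_paragraphs=[desc]))
        truths.append(GroundTruth(case_id=cid, true_metastatic=False))
    for ctype in CONFOUNDERS:
        for _ in range(spec.confounder_counts.get(ctype, 0)):
            cid = next_id()
            reports.append(gen_confounder(ctype, rng, case_id=cid))
            truths.append(GroundTruth(case_id=cid, true_metastatic=False,
                                      confounder_type=ctype))

    order = list(range(len(reports)))
    rng.shuffle(order)
    reports = [reports[i] for i in order]
    truths = [truths[i] for i in order]
    return reports, truths


def truths_to_gold(truths: list[GroundTruth]) -> list[GoldAnnotation]:
    out = []
    for t in truths:
        panel = t.true_panel
        if panel is not None and not any(
            panel.get(m).found for m in ("ER", "PR", "HER2")
        ):
            panel = None  # an all-untested panel carries no information
        out.append(GoldAnnotation(
            case_id=t.case_id,
            true_metastatic=t.true_metastatic,
            true_site_class=t.true_site_class,
            true_panel=panel,
            confounder_type=t.confounder_type,
        ))
    return out


def write_corpus(reports: list[Report], truths: list[GroundTruth],
                 out_dir: Union[str, Path]) -> tuple[Path, Path]:
    """Write the export-dialect corpus and the gold CSV; returns both paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    corpus_path = out_dir / "corpus.txt"
    corpus_path.write_text(serialize_export(reports), encoding="utf-8")
    gold_path = out_dir / "gold.csv"
    write_gold_csv(truths_to_gold(truths), gold_path)
    return corpus_path, gold_path
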