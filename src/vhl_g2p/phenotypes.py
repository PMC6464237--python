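"""Controlled phenotype vocabulary for VHL disease manifestations.

Case reports describing novel VHL mutations use heterogeneous labels for the
same clinical manifestation ("ccRCC", "renal carcinoma", "renal cysts", ...).
Renal manifestations in particular are collapsed into a single ``renal_disease``
term because the cancer sub-type is often not precisely reported.  Every raw
label maps to exactly one controlled term; labels outside the vocabulary map
to ``other`` and are logged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

logger = logging.getLogger(__name__)

#: Closed controlled vocabulary, with ``other`` as the sink term.
VOCABULARY: tuple[str, ...] = (
    "renal_disease",
    "pheochromocytoma",
    "hemangioblastoma_cerebellar",
    "hemangioblastoma_retinal",
    "paraganglioma",
    "pnet",
    "pancreatic_cyst",
    "polycythemia",
    "elst",
    "colorectal_cancer",
    "glial_tumor",
    "cystadenoma",
    "si_net",
    "other",
)

# Synonym map: lower-cased raw label -> controlled term.  Users may extend it
# at run time (see `register_synonym`) or ship their own copy as config.
SYNONYMS: dict[str, str] = {
    # renal manifestations are collectively presented as renal disease
    "renal_disease": "renal_disease",
    "renal disease": "renal_disease",
    "ccrcc": "renal_disease",
    "rcc": "renal_disease",
    "renal cell carcinoma": "renal_disease",
    "clear cell renal cell carcinoma": "renal_disease",
    "renal carcinoma": "renal_disease",
    "renal cancer": "renal_disease",
    "renal cyst": "renal_disease",
    "renal cysts": "renal_disease",
    "kidney cyst": "renal_disease",
    # pheochromocytoma / paraganglioma
    "pheochromocytoma": "pheochromocytoma",
    "phaeochromocytoma": "pheochromocytoma",
    "pheo": "pheochromocytoma",
    "paraganglioma": "paraganglioma",
    # hemangioblastoma subtypes
    "hemangioblastoma_cerebellar": "hemangioblastoma_cerebellar",
    "cerebellar hemangioblastoma": "hemangioblastoma_cerebellar",
    "cns hemangioblastoma": "hemangioblastoma_cerebellar",
    "hemangioblastoma_retinal": "hemangioblastoma_retinal",
    "retinal hemangioblastoma": "hemangioblastoma_retinal",
    "retinal angioma": "hemangioblastoma_retinal",
    # pancreatic lesions
    "pnet": "pnet",
    "pancreatic neuroendocrine tumor": "pnet",
    "pancreatic_cyst": "pancreatic_cyst",
    "pancreatic cyst": "pancreatic_cyst",
    "pancreatic cysts": "pancreatic_cyst",
    # the rest
    "polycythemia": "polycythemia",
    "erythrocytosis": "polycythemia",
    "chuvash polycythemia": "polycythemia",
    "elst": "elst",
    "endolymphatic sac tumor": "elst",
    "colorectal_cancer": "colorectal_cancer",
    "colorectal cancer": "colorectal_cancer",
    "glial_tumor": "glial_tumor",
    "glial tumor": "glial_tumor",
    "glioma": "glial_tumor",
    "cystadenoma": "cystadenoma",
    "epididymal cystadenoma": "cystadenoma",
    "ovarian cystadenoma": "cystadenoma",
    "si_net": "si_net",
    "small intestine neuroendocrine tumor": "si_net",
    "si-net": "si_net",
    "other": "other",
}


@dataclass(frozen=True)
class PhenotypeTerm:
    """A normalized phenotype label plus the raw text it came from."""

    term: str
    raw_label: str

    def __post_init__(self) -> None:
        if self.term not in VOCABULARY:
            raise ValueError(f"term {self.term!r} not in controlled vocabulary")


def register_synonym(raw_label: str, term: str) -> None:
    """Add a raw-label -> term mapping to the active synonym table."""
    if term not in VOCABULARY:
        raise ValueError(f"term {term!r} not in controlled vocabulary")
    SYNONYMS[raw_label.strip().lower()] = term


def normalize_phenotype(raw_label: str) -> PhenotypeTerm:
    """Map a free-text phenotype label to its controlled-vocabulary term.

    Matching is case-insensitive and whitespace/underscore tolerant.  Unknown
    labels map to ``other`` with a log entry, never an error.
    """
    if not raw_label or not raw_label.strip():
        raise ValueError("raw phenotype label must be non-empty")
    key = raw_label.strip().lower()
    term = SYNONYMS.get(key) or SYNONYMS.get(key.replace("_", " "))
    if term is None:
        logger.warning("unknown phenotype label %r mapped to 'other'", raw_label)
        term = "other"
    return PhenotypeTerm(term=term, raw_label=raw_label)


def normalize_set(raw_labels) -> frozenset[str]:
    """Normalize a collection of raw labels to a set of controlled terms."""
    return frozenset(normalize_phenotype(x).term for x in raw_labels if str(x).strip())
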