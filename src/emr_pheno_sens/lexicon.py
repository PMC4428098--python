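"""Lipid-lowering medication lexicon and note search.

Clinical notes are scanned for dated evidence of lipid-lowering drugs using a
term lexicon covering six classes (fibrates, niacin, resins,
cholesterol-absorption inhibitors, statins, and combination products), each
generic and brand name plus the bare class words. Matching is deliberately
simple — case-insensitive exact substring on word boundaries, trademark
glyphs stripped — with no negation handling and no fuzzy matching by
default, so "denies taking statins" counts as a mention (a documented
false-positive source) and a misspelled drug name does not match at all.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from datetime import date
from importlib import resources
from pathlib import Path

import pandas as pd

from .types import MedicationMention, NoteDocument

DRUG_CLASSES = frozenset(
    {"fibrate", "niacin", "resin", "cholesterol-absorption-inhibitor", "statin", "combination"}
)

_TRADEMARK_RE = re.compile("[®™]")  # ® ™

_CLASS_TERMS = frozenset(
    {
        "fibrate",
        "fibrates",
        "resin",
        "resins",
        "statin",
        "statins",
        "niacin",
        "cholesterol absorption inhibitor",
        "hmg coa reductase inhibitor",
        "hmg coa reductase inhibitors",
    }
)


def _normalize(text: str) -> str:
    return _TRADEMARK_RE.sub("", text).casefold()


@dataclass(frozen=True)
class LexiconEntry:
    term: str
    generic_name: str
    drug_class: str


class DrugLexicon:
    """A validated set of searchable terms mapped to generic name and class."""

    def __init__(self, entries: list[LexiconEntry]):
        if not entries:
            raise ValueError("lexicon must contain at least one entry")
        seen: dict[str, LexiconEntry] = {}
        for e in entries:
            key = _normalize(e.term)
            if not key:
                raise ValueError("lexicon term is empty after normalization")
            if key in seen:
                raise ValueError(f"duplicate lexicon term after case-folding: {e.term!r}")
            if e.drug_class not in DRUG_CLASSES:
                raise ValueError(f"unknown drug class {e.drug_class!r} for term {e.term!r}")
            seen[key] = e
        self.entries = list(entries)
        # one word-boundary pattern per normalized term; terms may span spaces
        self._patterns = [
            (re.compile(r"(?<!\w)" + re.escape(_normalize(e.term)) + r"(?!\w)"), e)
            for e in entries
        ]

    def __len__(self) -> int:
        return len(self.entries)

    def terms(self) -> list[str]:
        return [e.term for e in self.entries]

    def drug_terms(self) -> list[str]:
        """Specific drug names (generic + brand), excluding bare class words."""
        return [e.term for e in self.entries if _normalize(e.term) not in _CLASS_TERMS]

    def match(self, text: str) -> list[LexiconEntry]:
        """All entries whose term occurs in the text, at most once per term."""
        hay = _normalize(text)
        return [e for pat, e in self._patterns if pat.search(hay)]


def default_lexicon_path() -> Path:
    return Path(str(resources.files("emr_pheno_sens").joinpath("data", "lipid_lexicon.tsv")))


def load_lexicon(path: str | Path | None = None) -> DrugLexicon:
    path = default_lexicon_path() if path is None else Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    if missing := {"term", "generic", "drug_class"} - set(df.columns):
        raise ValueError(f"lexicon file missing columns: {sorted(missing)}")
    return DrugLexicon(
        [LexiconEntry(r.term, r.generic, r.drug_class) for r in df.itertuples(index=False)]
    )


def scan_notes(
    notes: list[NoteDocument] | pd.DataFrame, lexicon: DrugLexicon
) -> list[MedicationMention]:
    """Search dated notes for lexicon terms.

    Emits one mention per (note, matched term) pair with
    ``mention_date = note_date``. Output order is canonical
    (subject, date, term) regardless of input note order.
    """
    if isinstance(notes, pd.DataFrame):
        notes = [
            NoteDocument(str(r.subject_id), _as_date(r.note_date), str(r.text))
            for r in notes.itertuples(index=False)
        ]
    mentions = [
        MedicationMention(n.subject_id, n.note_date, e.term, e.generic_name, e.drug_class)
        for n in notes
        for e in lexicon.match(n.text)
    ]
    mentions.sort(key=lambda m: (m.subject_id, m.mention_date, m.matched_term))
    return mentions


def first_medication_date(
    mentions: list[MedicationMention], subject_id: str
) -> date | None:
    """Earliest mention date for the subject; None means no drug evidence."""
    dates = [m.mention_date for m in mentions if m.subject_id == subject_id]
    return min(dates) if dates else None


def mentions_frame(mentions: list[MedicationMention]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "subject_id": [m.subject_id for m in mentions],
            "mention_date": [m.mention_date.isoformat() for m in mentions],
            "matched_term": [m.matched_term for m in mentions],
            "generic": [m.generic_name for m in mentions],
            "drug_class": [m.drug_class for m in mentions],
        }
    )


def _as_date(value) -> date:
    if isinstance(value, date):
        return value
    return pd.Timestamp(value).date()
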