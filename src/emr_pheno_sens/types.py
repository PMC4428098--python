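"""Domain records shared across the pipeline stages."""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date

import numpy as np


@dataclass(frozen=True)
class LabMeasurement:
    """One dated HDL-C measurement, in mg/dl."""

    subject_id: str
    lab_date: date
    value: float
    analyte: str = "HDL-C"
    units: str = "mg/dl"

    def __post_init__(self) -> None:
        if not (np.isfinite(self.value) and self.value > 0):
            raise ValueError(f"lab value must be positive and finite, got {self.value}")


@dataclass(frozen=True)
class NoteDocument:
    """A dated free-text clinical note snippet."""

    subject_id: str
    note_date: date
    text: str

    def __post_init__(self) -> None:
        if not self.text:
            raise ValueError("note text must be non-empty")


@dataclass(frozen=True)
class MedicationMention:
    """A dated lexicon hit in one note."""

    subject_id: str
    mention_date: date
    matched_term: str
    generic_name: str
    drug_class: str


@dataclass(frozen=True)
class SnpWeight:
    """One scored variant: effect allele plus its per-allele trait weight."""

    snp_id: str
    gene: str
    effect_allele: str
    beta: float

    def __post_init__(self) -> None:
        if self.effect_allele not in {"A", "C", "G", "T"}:
            raise ValueError(f"{self.snp_id}: effect allele must be a single base")
        if not np.isfinite(self.beta):
            raise ValueError(f"{self.snp_id}: beta must be finite")


@dataclass
class SubjectRecord:
    """One simulated subject: demographics, labs, notes, genotypes, and the
    generative truth used by recovery tests (genetic value, medication start)."""

    subject_id: str
    sex: str  # "male" | "female"
    birth_date: date
    labs: list[LabMeasurement] = field(default_factory=list)
    notes: list[NoteDocument] = field(default_factory=list)
    genotypes: np.ndarray | None = None  # effect-allele counts, NaN = missing
    med_start: date | None = None
    genetic_value: float = 0.0
    subject_intercept: float = 0.0


@dataclass(frozen=True)
class AssociationResult:
    """Sex-adjusted OLS coefficient of one HDL-C definition on one GRS."""

    phenotype_definition: str  # all | first | last | premed | postmed
    grs_mode: str  # unweighted | weighted
    n: int
    beta: float
    se: float
    ci95_low: float
    ci95_high: float
    p_value: float
    t_value: float

    def __post_init__(self) -> None:
        if not (self.ci95_low <= self.beta <= self.ci95_high):
            raise ValueError("CI must bracket the point estimate")
        if self.n < 3:
            raise ValueError("association result requires n >= 3")
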