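"""Synthetic longitudinal-EMR cohort generator.

Emulates the data structure a biorepository linked to de-identified medical
records provides for a quantitative lipid trait: per-subject demographics,
a variable number of dated HDL-C labs, free-text notes that may mention a
lipid-lowering drug from the packaged lexicon, and genotypes at the seven
scored SNPs. The generative model for a lab value is

    y_ij = beta0 + sex_effect * 1[female_i]
           + sum_k effect_k * g_ik
           + delta * 1[lab_date_ij >= med_start_i]
           + b_i + eps_ij

with g_ik ~ Binomial(2, f_k) per SNP, subject intercept
b_i ~ N(0, subject_noise_sd^2) and within-subject noise
eps_ij ~ N(0, obs_noise_sd^2). The medication effect is a step at the
first prescription date, the simplest model consistent with a pre/post
dichotomy. Everything is driven by one numpy Generator, so a (config, seed)
pair reproduces the cohort byte for byte.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from datetime import date, timedelta
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from ._dates import add_years, eighteenth_birthday, uniform_date
from .lexicon import DrugLexicon, load_lexicon
from .types import LabMeasurement, NoteDocument, SnpWeight, SubjectRecord
from .weights import load_weights

# Approximate chromosome/position anchors for the seven scored loci,
# used only to emit a well-formed sorted VCF.
_SNP_LOCI = {
    "rs10096633": ("8", 19830921),
    "rs6601299": ("8", 9180000),
    "rs189069311": ("11", 116650000),
    "rs1077834": ("15", 58723675),
    "rs247617": ("16", 56990716),
    "rs255054": ("16", 67970000),
    "rs4810479": ("20", 44540000),
}
_BASES = ("A", "C", "G", "T")

_NOTE_TEMPLATES = (
    "Assessment and plan: continue {drug} as prescribed.",
    "Patient started on {drug} for dyslipidemia.",
    "Medication list reviewed; {drug} dose unchanged.",
    "Lipid panel discussed, {drug} refilled for 90 days.",
)
_NEUTRAL_NOTE = "Follow-up visit. No medication changes today."


@dataclass
class SimulationConfig:
    """Parameters of the generative model; defaults target a mid-sized
    outpatient cohort with HDL-C around 50 mg/dl and a modal risk-allele
    total of 8 out of 14."""

    n_subjects: int = 500
    seed: int = 0
    snp_table: list[SnpWeight] = field(default_factory=load_weights)
    effect_allele_freqs: list[float] = field(default_factory=lambda: [0.57] * 7)
    per_allele_effects: list[float] = field(default_factory=lambda: [-2.0] * 7)
    intercept_beta0: float = 62.0
    sex_effect: float = 8.0  # female minus male, mg/dl
    prob_female: float = 0.5
    medication_effect_delta: float = -3.0
    prob_ever_medicated: float = 0.4
    labs_per_subject_dist: dict = field(default_factory=lambda: {"name": "poisson", "lam": 3.0})
    obs_noise_sd: float = 6.0
    subject_noise_sd: float = 12.0
    prob_minor_age: float = 0.05
    missing_genotype_rate: float = 0.0
    misspelling_rate: float = 0.0
    date_range: tuple[date, date] = (date(1995, 1, 1), date(2011, 12, 31))

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        k = len(self.snp_table)
        if not (len(self.effect_allele_freqs) == len(self.per_allele_effects) == k):
            raise ValueError(
                "snp_table, effect_allele_freqs and per_allele_effects must have equal length"
            )
        for name, probs, open_interval in (
            ("effect_allele_freqs", self.effect_allele_freqs, True),
            (
                "prob_ever_medicated / prob_minor_age / misspelling_rate / "
                "missing_genotype_rate / prob_female",
                [
                    self.prob_ever_medicated,
                    self.prob_minor_age,
                    self.misspelling_rate,
                    self.missing_genotype_rate,
                    self.prob_female,
                ],
                False,
            ),
        ):
            for p in probs:
                ok = 0.0 < p < 1.0 if open_interval else 0.0 <= p <= 1.0
                if not ok:
                    raise ValueError(f"{name}: probability {p} out of range")
        for name, sd in (
            ("obs_noise_sd", self.obs_noise_sd),
            ("subject_noise_sd", self.subject_noise_sd),
        ):
            if sd < 0:
                raise ValueError(f"{name} must be >= 0")
        start, end = self.date_range
        if start > end:
            raise ValueError("date_range start must not exceed end")
        if "name" not in self.labs_per_subject_dist:
            raise ValueError("labs_per_subject_dist needs a 'name' key")

    @classmethod
    def table2_preset(cls, **overrides) -> "SimulationConfig":
        """Per-allele effects equal to the packaged published betas."""
        weights = load_weights()
        return cls(per_allele_effects=[w.beta for w in weights], **overrides)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "SimulationConfig":
        kwargs = dict(raw)
        if "date_range" in kwargs:
            lo, hi = kwargs["date_range"]
            kwargs["date_range"] = (_coerce_date(lo), _coerce_date(hi))
        if "snp_table" in kwargs:
            kwargs["snp_table"] = [
                SnpWeight(d["snp_id"], d.get("gene", ""), d["effect_allele"], float(d["beta"]))
                for d in kwargs["snp_table"]
            ]
        try:
            return cls(**kwargs)
        except TypeError as exc:
            raise ValueError(f"unknown simulation config field: {exc}") from exc


def _coerce_date(value) -> date:
    if isinstance(value, date):
        return value
    return date.fromisoformat(str(value))


def _draw_lab_count(rng: np.random.Generator, spec: dict) -> int:
    name = spec["name"]
    if name == "poisson":
        return int(rng.poisson(spec["lam"]))
    if name == "fixed":
        return int(spec["n"])
    if name == "uniform_int":
        return int(rng.integers(spec["low"], spec["high"] + 1))
    raise ValueError(f"unknown lab-count distribution {name!r}")


def _misspell(term: str, rng: np.random.Generator) -> str:
    """Single-character deletion — the simplest corruption that defeats
    exact matching."""
    if len(term) < 2:
        return term
    i = int(rng.integers(0, len(term)))
    return term[:i] + term[i + 1 :]


def simulate_cohort(
    config: SimulationConfig, lexicon: DrugLexicon | None = None
) -> list[SubjectRecord]:
    """Generate a fully seeded cohort of :class:`SubjectRecord`.

    Subjects are 25–70 years old at the start of the record window, so both
    minor-age and adult labs are possible; minor-age labs (probability
    ``prob_minor_age`` each) are dated between age 12 and the day before
    the 18th birthday and exist to exercise the adult filter downstream.
    """
    config.validate()
    lexicon = lexicon if lexicon is not None else load_lexicon()
    drug_terms = lexicon.drug_terms()
    rng = np.random.default_rng(config.seed)
    start, end = config.date_range
    freqs = np.asarray(config.effect_allele_freqs, dtype=float)
    effects = np.asarray(config.per_allele_effects, dtype=float)
    width = len(str(max(config.n_subjects - 1, 1)))

    cohort: list[SubjectRecord] = []
    for i in range(config.n_subjects):
        sid = f"S{i:0{width}d}"
        female = rng.random() < config.prob_female
        age_days = int(rng.integers(25 * 365, 70 * 365 + 1))
        birth = start - timedelta(days=age_days)
        g_true = rng.binomial(2, freqs).astype(float)
        genetic_value = float(effects @ g_true)
        g_obs = g_true.copy()
        if config.missing_genotype_rate > 0:
            g_obs[rng.random(len(g_obs)) < config.missing_genotype_rate] = np.nan
        b_i = rng.normal(0.0, config.subject_noise_sd) if config.subject_noise_sd else 0.0
        med_start = (
            uniform_date(rng, start, end)
            if rng.random() < config.prob_ever_medicated
            else None
        )
        base = (
            config.intercept_beta0
            + (config.sex_effect if female else 0.0)
            + genetic_value
            + b_i
        )

        labs: list[LabMeasurement] = []
        adult_from = max(start, eighteenth_birthday(birth))
        for _ in range(_draw_lab_count(rng, config.labs_per_subject_dist)):
            if rng.random() < config.prob_minor_age:
                lab_date = uniform_date(
                    rng, add_years(birth, 12), eighteenth_birthday(birth) - timedelta(days=1)
                )
            else:
                lab_date = uniform_date(rng, adult_from, end)
            value = base
            if med_start is not None and lab_date >= med_start:
                value += config.medication_effect_delta
            if config.obs_noise_sd:
                value += rng.normal(0.0, config.obs_noise_sd)
            value = max(value, 1.0)  # lab values are physically positive
            labs.append(LabMeasurement(sid, lab_date, float(value)))
        labs.sort(key=lambda l: (l.lab_date, l.value))

        notes: list[NoteDocument] = []
        if med_start is not None:
            term = drug_terms[int(rng.integers(0, len(drug_terms)))]
            n_notes = 1 + int(rng.poisson(1.0))
            note_dates = [med_start] + [
                uniform_date(rng, med_start, end) for _ in range(n_notes - 1)
            ]
            for nd in sorted(note_dates):
                written = (
                    _misspell(term, rng)
                    if rng.random() < config.misspelling_rate
                    else term
                )
                template = _NOTE_TEMPLATES[int(rng.integers(0, len(_NOTE_TEMPLATES)))]
                notes.append(NoteDocument(sid, nd, template.format(drug=written)))
        elif rng.random() < 0.5:
            notes.append(NoteDocument(sid, uniform_date(rng, start, end), _NEUTRAL_NOTE))

        cohort.append(
            SubjectRecord(
                subject_id=sid,
                sex="female" if female else "male",
                birth_date=birth,
                labs=labs,
                notes=notes,
                genotypes=g_obs,
                med_start=med_start,
                genetic_value=genetic_value,
                subject_intercept=float(b_i),
            )
        )
    return cohort


def simulate_trait_replicate(
    n: int,
    rng: np.random.Generator,
    *,
    effect_allele_freqs: np.ndarray | list[float] = (0.57,) * 7,
    per_allele_effects: np.ndarray | list[float] = (-2.0,) * 7,
    intercept: float = 62.0,
    sex_effect: float = 8.0,
    subject_noise_sd: float = 12.0,
    obs_noise_sd: float = 6.0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized one-lab-per-subject draw from the same generative model.

    Returns ``(genotype_counts, female_indicator, trait)``. This is the
    calibration harness behind the type-I-error and parameter-recovery
    studies, where thousands of replicates are needed and the longitudinal
    and free-text layers of the full simulator are irrelevant to the
    regression being calibrated.
    """
    freqs = np.asarray(effect_allele_freqs, dtype=float)
    effects = np.asarray(per_allele_effects, dtype=float)
    g = rng.binomial(2, freqs, size=(n, len(freqs))).astype(float)
    female = rng.binomial(1, 0.5, size=n).astype(float)
    y = (
        intercept
        + sex_effect * female
        + g @ effects
        + rng.normal(0.0, subject_noise_sd, size=n)
        + rng.normal(0.0, obs_noise_sd, size=n)
    )
    return g, female, y


# ---------------------------------------------------------------------------
# writers


def cohort_frames(cohort: list[SubjectRecord]) -> dict[str, pd.DataFrame]:
    """Tabular views: demographics, labs, notes, truth."""
    demo = pd.DataFrame(
        {
            "subject_id": [s.subject_id for s in cohort],
            "sex": [s.sex for s in cohort],
            "birth_date": [s.birth_date.isoformat() for s in cohort],
        }
    )
    labs = pd.DataFrame(
        [
            (l.subject_id, l.lab_date.isoformat(), l.analyte, l.value, l.units)
            for s in cohort
            for l in s.labs
        ],
        columns=["subject_id", "date", "analyte", "value", "units"],
    )
    notes = pd.DataFrame(
        [(n.subject_id, n.note_date.isoformat(), n.text) for s in cohort for n in s.notes],
        columns=["subject_id", "note_date", "text"],
    )
    truth = pd.DataFrame(
        {
            "subject_id": [s.subject_id for s in cohort],
            "genetic_value": [s.genetic_value for s in cohort],
            "subject_intercept": [s.subject_intercept for s in cohort],
            "med_start_date": [
                s.med_start.isoformat() if s.med_start else "" for s in cohort
            ],
        }
    )
    return {"demographics": demo, "labs": labs, "notes": notes, "truth": truth}


def write_vcf(cohort: list[SubjectRecord], weights: list[SnpWeight], path: str | Path,
              seed: int = 0) -> None:
    """Emit a minimal sorted VCF v4.2 with GT-only genotypes.

    Whether the effect allele sits in REF or ALT is randomized per SNP
    (seeded) so that downstream orientation handling is actually exercised;
    the non-effect allele is a different base drawn at random.
    """
    rng = np.random.default_rng(seed)
    records = []
    for k, w in enumerate(weights):
        chrom, pos = _SNP_LOCI.get(w.snp_id, ("1", 1_000_000 + 10_000 * k))
        other = _BASES[int(rng.integers(0, 4))]
        while other == w.effect_allele:
            other = _BASES[int(rng.integers(0, 4))]
        effect_is_ref = bool(rng.random() < 0.5)
        ref, alt = (w.effect_allele, other) if effect_is_ref else (other, w.effect_allele)
        gts = []
        for s in cohort:
            c = s.genotypes[k]
            if np.isnan(c):
                gts.append("./.")
            else:
                n_alt = int(2 - c) if effect_is_ref else int(c)
                gts.append({0: "0/0", 1: "0/1", 2: "1/1"}[n_alt])
        records.append((chrom, pos, w.snp_id, ref, alt, gts))
    records.sort(key=lambda r: (int(r[0]), r[1]))

    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=emr-pheno-sens synthetic cohort\n")
        for chrom in sorted({r[0] for r in records}, key=int):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(s.subject_id for s in cohort)
            + "\n"
        )
        for chrom, pos, rsid, ref, alt, gts in records:
            fh.write(
                f"{chrom}\t{pos}\t{rsid}\t{ref}\t{alt}\t.\t.\t.\tGT\t" + "\t".join(gts) + "\n"
            )


def write_cohort(
    cohort: list[SubjectRecord],
    out_dir: str | Path,
    weights: list[SnpWeight] | None = None,
    vcf_seed: int = 0,
) -> dict[str, Path]:
    """Write demographics CSV, labs CSV, notes JSONL, genotypes VCF, truth TSV."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    weights = weights if weights is not None else load_weights()
    frames = cohort_frames(cohort)
    paths = {
        "demographics": out / "demographics.csv",
        "labs": out / "labs.csv",
        "notes": out / "notes.jsonl",
        "genotypes": out / "genotypes.vcf",
        "truth": out / "truth.tsv",
    }
    frames["demographics"].to_csv(paths["demographics"], index=False)
    frames["labs"].to_csv(paths["labs"], index=False)
    with open(paths["notes"], "w") as fh:
        for row in frames["notes"].itertuples(index=False):
            fh.write(
                json.dumps(
                    {"subject_id": row.subject_id, "note_date": row.note_date, "text": row.text}
                )
                + "\n"
            )
    write_vcf(cohort, weights, paths["genotypes"], seed=vcf_seed)
    frames["truth"].to_csv(paths["truth"], sep="\t", index=False)
    return paths
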