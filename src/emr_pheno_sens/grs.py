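"""Genetic risk scores from effect-allele counts.

The score for a subject is the weighted sum of effect-allele counts across
the scored SNPs divided by the number of non-missing SNPs — the average
per-SNP contribution, matching PLINK ``--score`` average-mode conventions.
Unweighted scoring sets every weight to one; weighted scoring uses the
published per-allele effects. Missing genotypes drop out of both numerator
and denominator — no imputation to mean dosage.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .types import SnpWeight

GRS_MODES = ("unweighted", "weighted")


@dataclass
class GenotypeMatrix:
    """Subjects x SNPs effect-allele counts; NaN marks a missing call."""

    subject_ids: list[str]
    snp_ids: list[str]
    counts: np.ndarray  # float array, values in {0,1,2,NaN}

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape != (len(self.subject_ids), len(self.snp_ids)):
            raise ValueError("counts shape does not match subject/snp labels")
        valid = np.isnan(self.counts) | np.isin(self.counts, (0.0, 1.0, 2.0))
        if not valid.all():
            raise ValueError("effect-allele counts must be in {0, 1, 2} or missing")


def orient_effect_alleles(vcf_path: str | Path, weights: list[SnpWeight]) -> GenotypeMatrix:
    """Read a VCF and express each genotype as an effect-allele count.

    VCF stores REF/ALT dosage; the score is defined on the effect allele,
    which may sit on either side, so dosage is flipped (d -> 2 - d) where
    the effect allele is REF. Each scored SNP must appear exactly once and
    be biallelic with the effect allele equal to REF or ALT.
    """
    vcf = VCF(str(vcf_path))
    samples = list(vcf.samples)
    by_id: dict[str, np.ndarray] = {}
    wanted = {w.snp_id: w for w in weights}
    for variant in vcf:
        w = wanted.get(variant.ID)
        if w is None:
            continue
        if variant.ID in by_id:
            raise ValueError(f"{w.snp_id}: duplicated in VCF")
        if len(variant.ALT) != 1:
            raise ValueError(f"{w.snp_id}: multiallelic records are not supported")
        ref, alt = variant.REF, variant.ALT[0]
        if w.effect_allele == alt:
            flip = False
        elif w.effect_allele == ref:
            flip = True
        else:
            raise ValueError(
                f"{w.snp_id}: effect allele {w.effect_allele} matches neither "
                f"REF={ref} nor ALT={alt}"
            )
        col = np.full(len(samples), np.nan)
        for i, gt in enumerate(variant.genotypes):
            alleles = gt[:-1]  # last element is the phasing flag
            if any(a < 0 for a in alleles):
                continue
            d = float(sum(alleles))
            col[i] = 2.0 - d if flip else d
        by_id[variant.ID] = col
    if missing := [w.snp_id for w in weights if w.snp_id not in by_id]:
        raise ValueError(f"SNPs absent from VCF: {missing}")
    counts = np.column_stack([by_id[w.snp_id] for w in weights])
    return GenotypeMatrix(samples, [w.snp_id for w in weights], counts)


def compute_grs(
    genotypes: GenotypeMatrix, weights: list[SnpWeight], mode: str
) -> pd.DataFrame:
    """Per-subject GRS: sum of weighted counts over non-missing SNPs,
    divided by the number of non-missing SNPs.

    Returns a frame with columns ``subject_id, score, n_nonmissing,
    risk_allele_total``; the score is NaN when every genotype is missing,
    and ``risk_allele_total`` (the raw allele count) is reported only for
    complete genotypes so the risk-allele histogram stays well defined.
    """
    if mode not in GRS_MODES:
        raise ValueError(f"mode must be one of {GRS_MODES}")
    if [w.snp_id for w in weights] != genotypes.snp_ids:
        raise ValueError("weight order does not match genotype matrix columns")
    w = np.ones(len(weights)) if mode == "unweighted" else np.array([w.beta for w in weights])
    c = genotypes.counts
    observed = ~np.isnan(c)
    n_nonmissing = observed.sum(axis=1)
    num = np.nansum(c * w, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        score = np.where(n_nonmissing > 0, num / np.maximum(n_nonmissing, 1), np.nan)
    complete = n_nonmissing == c.shape[1]
    total = np.where(complete, np.nansum(c, axis=1), np.nan)
    return pd.DataFrame(
        {
            "subject_id": genotypes.subject_ids,
            "score": score,
            "n_nonmissing": n_nonmissing.astype(int),
            "risk_allele_total": total,
        }
    )


def grs_table(genotypes: GenotypeMatrix, weights: list[SnpWeight]) -> pd.DataFrame:
    """Both scoring modes side by side, ready for the association stage."""
    unw = compute_grs(genotypes, weights, "unweighted")
    wtd = compute_grs(genotypes, weights, "weighted")
    return pd.DataFrame(
        {
            "subject_id": unw["subject_id"],
            "grs_unweighted": unw["score"],
            "grs_weighted": wtd["score"],
            "n_nonmissing": unw["n_nonmissing"],
            "risk_allele_total": unw["risk_allele_total"],
        }
    )
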