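# Methods

## Problem setting

Clinical repositories provide repeated, irregularly timed lab
measurements collected for care, not research. An analyst must choose a
rule for collapsing a subject's HDL-C history to one value — the median of
everything, the first or last measurement, or medication-aware strata —
and any such rule could in principle distort a genetic association
estimate. This package operationalizes that question: it extracts the same
trait five ways, computes a 7-SNP genetic risk score (GRS), and compares
the sex-adjusted regression coefficients across definitions.

## Generative model of the synthetic cohort

Each subject has sex (female with probability 0.5), a birth date placing
them 25–70 years old at the start of the record window, genotypes
`g_ik ~ Binomial(2, f_k)` independently across the seven scored SNPs, a
latent intercept `b_i ~ N(0, σ_b²)`, and, with probability
`prob_ever_medicated`, a medication start date uniform over the record
window. Lab values follow

```
y_ij = β₀ + s·1[female_i] + Σ_k γ_k g_ik + δ·1[t_ij ≥ med_start_i] + b_i + ε_ij
ε_ij ~ N(0, σ_e²)
```

with lab dates uniform over the window. The medication effect is a step
function at the start date — the simplest model consistent with a
pre/post dichotomy. Medicated subjects receive notes mentioning one
uniformly chosen drug name from the packaged lexicon, the first dated
exactly at `med_start`, so note evidence and the generative truth agree by
construction. With probability `misspelling_rate` (default 0) a note
carries the term with one character deleted — the minimal corruption that
defeats exact matching. A configurable fraction of labs (default 5%) is
dated before the subject's 18th birthday to exercise the adult filter, and
genotypes can be masked missing at a configurable rate (default 0) to
exercise the non-missing-SNP denominator.

### Default parameters and why

| parameter | default | rationale |
|---|---|---|
| effect allele frequency `f_k` | 0.57 (all SNPs) | gives a mean risk-allele total of 2·7·0.57 ≈ 8 of 14, the modal count reported for the motivating cohort |
| per-allele effect `γ_k` | −2 mg/dl (all SNPs) | equal effects make the implied slope on the per-SNP-average GRS exactly 7γ = −14, an analytically checkable target; the published per-SNP betas are available as a named preset (`SimulationConfig.table2_preset`), but their scale is left uninterpreted |
| intercept `β₀` | 62 mg/dl | with the genetic mean (−16) and half the sex effect (+4), cohort mean HDL-C ≈ 50 mg/dl, the clinically typical median |
| sex effect `s` | +8 mg/dl (female) | typical female–male HDL-C difference |
| medication step `δ` | −3 mg/dl | reproduces the observed pattern of post-medication medians a few mg/dl below pre-medication ones (in real data largely confounding by indication; here modeled causally for simplicity) |
| `prob_ever_medicated` | 0.4 | roughly the fraction of subjects with a post-medication stratum in the motivating cohort |
| labs per subject | Poisson(3) | median of three visits/records-years, with a realistic zero-lab mass |
| within-subject σ_e / between-subject σ_b | 6 / 12 mg/dl | total SD ≈ 14–15 mg/dl consistent with an IQR in the low 20s |
| record window | 1995-01-01 – 2011-12-31 | plausible accrual window for a repository frozen in 2011 |

Values are floored at 1 mg/dl (labs are physically positive); with the
default intercept the floor is never reached, so the noise-free limit
remains exact.

### What the generator does not emulate

Real clinical text (notes are templated sentences), ICD-9 codes and
visit structure, assay changes and unit variants, informative observation
(sicker patients measured more often), and medication adherence or
discontinuation. Passing tests therefore demonstrate the correctness and
calibration of the extraction and analysis machinery under a
well-specified model — not robustness to real clinical-text noise, which
the exact-matching lexicon is known (and documented) not to provide.

## Phenotype algorithms

Adult filter: a lab counts if `lab_date ≥ birth_date + 18 years`, computed
by calendar arithmetic (a Feb-29 birthday anniversaries to Mar 1).
Even-count medians are the mean of the two middle order statistics.
Same-date ties break to the minimum value for *First* and maximum for
*Last* — deterministic, order-independent, and agnostic about intraday
ordering that EMRs do not reliably record. A lab dated the same day as the
first medication mention is classified post-medication, since it cannot be
confirmed medication-naive. Subjects with no drug evidence contribute
their whole history to the pre-medication stratum; a medicated subject can
contribute to both strata, so the per-definition `n` values overlap and
need not sum to the cohort size.

## Medication evidence

Matching is case-insensitive exact substring on word boundaries after
stripping trademark glyphs (®, ™), one mention per (note, term) pair. Word
boundaries mean `Lipitor 10mg` matches but `Lipitor10mg` does not, and the
bare class word `statin` does not fire inside `simvastatin`. There is no
negation handling — "denies taking statins" counts — and no fuzzy
matching; both are deliberate, documented false-positive/-negative
sources of the term-search approach. Combination products (Advicor,
Caduet, Vytorin) count as lipid-lowering evidence under class
`combination`; niacin is carried as a class term without an enumerated
drug list.

## Risk score

`score_i = Σ_{k non-missing} w_k c_ik / m_i` with the non-missing count
`m_i` as denominator — no imputation to mean dosage. Effect alleles are
oriented against the VCF explicitly: dosage is flipped (`d → 2 − d`) where
the effect allele is REF, and a SNP that is absent, duplicated,
multiallelic, or inconsistent with both REF and ALT is a hard error naming
the SNP. The raw risk-allele total is reported only for complete
genotypes so the risk-allele histogram is well defined.

## Regression and comparison

Ordinary least squares of the phenotype on `[1, GRS, female]` via
statsmodels, complete cases per definition (so `n` varies), t-based CIs
and two-sided p-values on n − 3 degrees of freedom — indistinguishable
from normal intervals at realistic n, correct for small fixtures. The GRS
coefficient is invariant to the sex coding. Designs with zero residual are
reported with SE = 0, p = 0, and a degenerate CI at the point estimate
(the estimate snapped to 12 decimals, removing pure round-off). Pairwise
heterogeneity `z = (β₁−β₂)/√(se₁²+se₂²)` is descriptive only: the
definitions share subjects, so no formal test or multiplicity correction
is attached. The "effect sizes agree" claim is assessed as mutual overlap
of the five 95% CIs.

## Calibration studies and problem sizes

Type-I error (per-allele effects all zero, n = 1,000, 2,000 replicates)
and parameter recovery/coverage (γ = −2, n = 5,000, 200 replicates) run
through `simulate_trait_replicate`, a vectorized one-lab-per-subject draw
from the same generative model, then through the real `compute_grs`-style
scoring and `fit_association` path. The full longitudinal/free-text
simulator adds nothing to what these studies measure, and the vectorized
harness keeps thousands of replicates cheap. The acceptance script runs
the complete pipeline at n = 5,000 — comfortably resolving the −14 mg/dl
implied slope — and 500/200 calibration replicates.

## Numerical and reproducibility choices

One global seed fans out through `numpy.random.SeedSequence` to per-stage
child seeds; identical configurations rerun to byte-identical artifacts
(the manifest stores relative paths and content hashes, and timing goes
to the log, not the manifest). All dates are ISO-8601; missing values
serialize as empty fields; scores and betas are written at full precision
and rounded only for display. The synthetic VCF is v4.2, sorted, GT-only,
with effect-allele placement in REF or ALT randomized per SNP (seeded) so
orientation handling is always exercised.

## Known limitations

The weighted score's published per-allele weights are used as abstract
numbers; their units are not interpreted. The heterogeneity screen
ignores the correlation induced by shared subjects. The lexicon is
English-only and exact; misspelling simulation exists precisely to
demonstrate the resulting sensitivity loss, not to work around it. The
medication step model ignores confounding by indication, adherence, and
dose.
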