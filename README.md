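# emr-pheno-sens

Does the decision logic of an electronic-medical-record (EMR) phenotyping
algorithm change the effect sizes a genetic association study reports?
This package implements that sensitivity analysis end to end for a
quantitative lipid trait, high-density lipoprotein cholesterol (HDL-C,
mg/dl), and ships a synthetic longitudinal-EMR generator so the whole
pipeline is runnable and testable without access to any clinical
repository.

It is aimed at quantitative geneticists and biomedical informaticians who
derive analysis-ready traits from repeated clinical measurements and want
to know how much the derivation rules matter downstream.

## What it computes

**Five phenotype definitions.** From each subject's adult (age ≥ 18 at
draw) HDL-C labs: the median of all values (*All*), the earliest and
latest values (*First*/*Last*), and medians of the labs strictly before
(*pre-medication*) and on/after (*post-medication*) the first dated
evidence of a lipid-lowering drug. Drug evidence comes from scanning
clinical notes against a packaged lexicon of fibrates, niacin, resins,
cholesterol-absorption inhibitors, statins, and combination products
(generic, brand, and class terms; exact case-insensitive word-boundary
matching).

**Genetic risk score.** For seven HDL-C-associated SNPs, each subject's
score is

```
GRS_i = Σ_k w_k · c_ik / m_i
```

where `c_ik ∈ {0,1,2}` counts effect alleles, `m_i` is the number of
non-missing SNPs, and `w_k = 1` (unweighted) or the published per-allele
effect (weighted) — the average score per SNP, as in PLINK `--score`
average mode. Effect-allele orientation against VCF REF/ALT is handled
explicitly.

**Association and comparison.** Each definition is regressed on the GRS
with a female indicator as covariate (ordinary least squares, complete
cases, t-based intervals):

```
HDL-C_i = α + β·GRS_i + γ·female_i + ε_i
```

and the five `(β, 95% CI)` pairs are compared forest-plot style, with
descriptive pairwise z statistics for β differences.

## Worked example

```python
from emr_pheno_sens import PipelineConfig, run_pipeline
import pandas as pd

cfg = PipelineConfig(out_dir="demo", seed=42, simulate={"n_subjects": 500})
run_pipeline(cfg)
print(pd.read_csv("demo/associations.tsv", sep="\t").head(5).to_string(index=False))
```

prints (abridged to the unweighted rows)

```
definition   grs_mode   n       beta       se   ci95_low  ci95_high      p_value
       all unweighted 471 -14.504455 2.274047 -18.973062 -10.035847 4.306342e-10
     first unweighted 471 -13.331888 2.357011 -17.963522  -8.700254 2.696675e-08
      last unweighted 471 -14.816188 2.403476 -19.539128 -10.093248 1.528204e-09
    premed unweighted 410 -13.362920 2.394511 -18.070073  -8.655768 4.381163e-08
   postmed unweighted 126 -17.006342 5.025914 -26.954831  -7.057853 9.597895e-04
```

The generator's default per-allele effect is −2 mg/dl at each of the 7
SNPs, so the implied slope on the per-SNP-average GRS is 7 × (−2) = −14
mg/dl: all five definitions recover it, their confidence intervals
mutually overlap, and `n` varies by definition because complete-case sets
differ — the qualitative robustness finding the analysis is designed to
probe. The same stages are available as a CLI
(`emr-pheno-sens {simulate,scan,extract,grs,associate,compare,run}`).

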