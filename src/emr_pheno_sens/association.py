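"""Sex-adjusted association tests and the cross-definition comparison.

Each HDL-C definition is regressed on the genetic risk score with a female
indicator as the only covariate, by ordinary least squares on complete
cases. Confidence intervals and p-values use the t distribution with
n - 3 degrees of freedom; at cohort sizes in the thousands this is
indistinguishable from the normal approximation but remains correct for
small fixtures. The comparison report lines the five definitions up
forest-plot style and adds descriptive pairwise z statistics for the
difference of betas; because the definitions share subjects these z values
are approximate screens, not formal tests.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .phenotypes import DEFINITIONS
from .types import AssociationResult

_DEF_ORDER = {d: i for i, d in enumerate(DEFINITIONS)}


def fit_association(
    phenotype: np.ndarray | pd.Series,
    grs: np.ndarray | pd.Series,
    female: np.ndarray | pd.Series,
    *,
    definition: str = "all",
    grs_mode: str = "unweighted",
) -> AssociationResult:
    """OLS of phenotype on [1, GRS, female]; returns the GRS coefficient.

    Rows with a missing phenotype or score are dropped (complete-case).
    Raises on fewer than 3 complete cases or a constant GRS.
    """
    y = np.asarray(phenotype, dtype=float)
    g = np.asarray(grs, dtype=float)
    f = np.asarray(female, dtype=float)
    keep = np.isfinite(y) & np.isfinite(g) & np.isfinite(f)
    y, g, f = y[keep], g[keep], f[keep]
    n = len(y)
    if n < 3:
        raise ValueError(f"insufficient data: {n} complete cases (need >= 3)")
    if np.ptp(g) == 0:
        raise ValueError("GRS is constant; design matrix is singular")
    X = pd.DataFrame({"const": 1.0, "grs": g, "female": f})
    res = sm.OLS(y, X).fit()
    beta = float(res.params["grs"])
    se = float(res.bse["grs"])
    # zero-residual (perfect-fit) designs: the residual norm is pure
    # round-off, so report the degenerate but well-defined exact result
    perfect = np.sqrt(res.ssr) <= 1e-12 * max(np.linalg.norm(y), 1.0)
    if perfect or se == 0 or not np.isfinite(se):
        beta = float(np.round(beta, 12)) if perfect else beta
        return AssociationResult(definition, grs_mode, n, beta, 0.0, beta, beta, 0.0,
                                 float("inf"))
    ci_low, ci_high = (float(v) for v in res.conf_int().loc["grs"])
    return AssociationResult(
        definition,
        grs_mode,
        n,
        beta,
        se,
        ci_low,
        ci_high,
        float(res.pvalues["grs"]),
        float(res.tvalues["grs"]),
    )


def fit_all_definitions(
    phenotypes: pd.DataFrame,
    grs: pd.DataFrame,
    demographics: pd.DataFrame,
    modes: tuple[str, ...] = ("unweighted", "weighted"),
    min_n: int = 30,
) -> tuple[list[AssociationResult], list[str]]:
    """Fit every definition x GRS mode on the merged cohort tables.

    Returns the results plus flags for definitions whose complete-case n
    fell below ``min_n`` (flagged, not dropped) or that could not be fit.
    """
    demo = demographics.assign(subject_id=demographics["subject_id"].astype(str))
    female = (demo["sex"].str.lower() == "female").astype(float)
    merged = (
        demo[["subject_id"]]
        .assign(female=female)
        .merge(phenotypes.assign(subject_id=phenotypes["subject_id"].astype(str)),
               on="subject_id", how="left")
        .merge(grs.assign(subject_id=grs["subject_id"].astype(str)),
               on="subject_id", how="left")
    )
    results: list[AssociationResult] = []
    flags: list[str] = []
    for definition in DEFINITIONS:
        col = f"{definition}_hdl"
        for mode in modes:
            score_col = f"grs_{mode}"
            try:
                res = fit_association(
                    merged[col], merged[score_col], merged["female"],
                    definition=definition, grs_mode=mode,
                )
            except ValueError as exc:
                flags.append(f"{definition}/{mode}: not fit ({exc})")
                continue
            if res.n < min_n:
                flags.append(f"{definition}/{mode}: n={res.n} below minimum {min_n}")
            results.append(res)
    return results, flags


@dataclass
class ComparisonReport:
    """Forest-plot-ready table plus approximate pairwise heterogeneity."""

    table: pd.DataFrame  # definition, grs_mode, n, beta, se, ci95_low, ci95_high, p_value
    pairwise_z: pd.DataFrame  # definition_1, definition_2, grs_mode, z
    all_ci_overlap: bool


def compare_definitions(results: list[AssociationResult]) -> ComparisonReport:
    """Cross-definition effect-size comparison.

    Pairwise z = (b1 - b2) / sqrt(se1^2 + se2^2) within each GRS mode is a
    descriptive heterogeneity screen only — the definitions share subjects,
    so these are approximate. ``all_ci_overlap`` records whether every pair
    of 95% CIs (within mode) intersects.
    """
    if len(results) < 2:
        raise ValueError("comparison requires at least two association results")
    table = pd.DataFrame(
        {
            "definition": [r.phenotype_definition for r in results],
            "grs_mode": [r.grs_mode for r in results],
            "n": [r.n for r in results],
            "beta": [r.beta for r in results],
            "se": [r.se for r in results],
            "ci95_low": [r.ci95_low for r in results],
            "ci95_high": [r.ci95_high for r in results],
            "p_value": [r.p_value for r in results],
        }
    ).sort_values(
        ["grs_mode", "definition"],
        key=lambda s: s.map(_DEF_ORDER) if s.name == "definition" else s,
        kind="stable",
    ).reset_index(drop=True)

    rows = []
    overlap = True
    for mode in table["grs_mode"].unique():
        sub = [r for r in results if r.grs_mode == mode]
        for r1, r2 in combinations(sub, 2):
            denom = np.hypot(r1.se, r2.se)
            z = (r1.beta - r2.beta) / denom if denom > 0 else np.inf
            rows.append(
                {
                    "definition_1": r1.phenotype_definition,
                    "definition_2": r2.phenotype_definition,
                    "grs_mode": mode,
                    "z": z,
                }
            )
            if r1.ci95_low > r2.ci95_high or r2.ci95_low > r1.ci95_high:
                overlap = False
    return ComparisonReport(table, pd.DataFrame(rows), overlap)


def risk_allele_histogram(grs: pd.DataFrame, n_snps: int = 7) -> pd.Series:
    """Counts of total risk alleles over 0..2*n_snps.

    Subjects with any missing genotype carry no total and are excluded;
    the counts therefore sum to the number of complete-genotype subjects.
    """
    totals = pd.to_numeric(grs["risk_allele_total"], errors="coerce").dropna().astype(int)
    support = range(0, 2 * n_snps + 1)
    return totals.value_counts().reindex(support, fill_value=0).sort_index()


def forest_plot(report: ComparisonReport, path: str | Path, grs_mode: str = "unweighted"):
    """Per-definition beta with 95% CI, one row per definition."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    sub = report.table[report.table["grs_mode"] == grs_mode]
    fig, ax = plt.subplots(figsize=(6, 3))
    ypos = np.arange(len(sub))[::-1]
    ax.errorbar(
        sub["beta"],
        ypos,
        xerr=[sub["beta"] - sub["ci95_low"], sub["ci95_high"] - sub["beta"]],
        fmt="D",
        color="black",
        capsize=3,
    )
    ax.set_yticks(ypos, sub["definition"])
    ax.set_xlabel(f"beta per {grs_mode} GRS unit (mg/dl)")
    ax.axvline(0, color="grey", lw=0.5)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def histogram_plot(counts: pd.Series, path: str | Path):
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 3))
    ax.bar(counts.index, counts.values, color="steelblue")
    ax.set_xlabel("total risk alleles")
    ax.set_ylabel("subjects")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
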