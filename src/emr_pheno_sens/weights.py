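"""The 7-SNP HDL-C risk-score weight table.

The packaged default lists the seven index SNPs from HDL-C loci replicated
in African Americans, each with its effect allele and the published
per-allele effect used by the weighted score. The weights are treated as
abstract per-allele numbers; no unit interpretation is asserted.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import pandas as pd

from .types import SnpWeight

_DEFAULT_RESOURCE = "hdl_grs_weights.tsv"


def default_weights_path() -> Path:
    return Path(str(resources.files("emr_pheno_sens").joinpath("data", _DEFAULT_RESOURCE)))


def load_weights(path: str | Path | None = None) -> list[SnpWeight]:
    """Read a weight table TSV (snp_id, gene, effect_allele, beta)."""
    path = default_weights_path() if path is None else Path(path)
    df = pd.read_csv(path, sep="\t", dtype={"snp_id": str, "gene": str, "effect_allele": str})
    required = {"snp_id", "gene", "effect_allele", "beta"}
    if missing := required - set(df.columns):
        raise ValueError(f"weight table missing columns: {sorted(missing)}")
    if df["snp_id"].duplicated().any():
        raise ValueError("weight table contains duplicated snp_ids")
    return [
        SnpWeight(row.snp_id, row.gene, row.effect_allele, float(row.beta))
        for row in df.itertuples(index=False)
    ]


def weights_frame(weights: list[SnpWeight]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "snp_id": [w.snp_id for w in weights],
            "gene": [w.gene for w in weights],
            "effect_allele": [w.effect_allele for w in weights],
            "beta": [w.beta for w in weights],
        }
    )
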