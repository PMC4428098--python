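"""End-to-end pipeline driver: simulate -> scan -> extract -> grs ->
associate -> compare, with a hashed artifact manifest.

A single global seed fans out through :class:`numpy.random.SeedSequence`
into per-stage child seeds, so individual stages are reproducible in
isolation and the whole run is byte-identical for a fixed configuration.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import association, grs as grs_mod, lexicon as lexicon_mod, phenotypes, synthetic
from .weights import load_weights

log = logging.getLogger("emr_pheno_sens")

STAGES = ("simulate", "scan", "extract", "grs", "associate", "compare")


class StageError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    out_dir: Path
    seed: int = 0
    simulate: dict = field(default_factory=dict)  # SimulationConfig overrides
    run_simulate: bool = True
    demographics: Path | None = None  # required when run_simulate is False
    labs: Path | None = None
    notes: Path | None = None
    vcf: Path | None = None
    lexicon_path: Path | None = None  # None -> packaged default
    weights_path: Path | None = None
    min_n_per_definition: int = 30
    make_plots: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path, seed: int | None = None) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("out_dir", "demographics", "labs", "notes", "vcf",
                    "lexicon_path", "weights_path"):
            if raw.get(key) is not None:
                raw[key] = Path(raw[key])
        cfg = cls(**raw)
        if seed is not None:
            cfg.seed = seed
        return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _count_rows(path: Path) -> int:
    with open(path) as fh:
        return max(sum(1 for _ in fh) - (0 if path.suffix == ".jsonl" else 1), 0)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the pipeline and return the artifact manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    child = np.random.SeedSequence(config.seed).spawn(2)
    sim_seed = int(child[0].generate_state(1)[0] % (2**31))
    vcf_seed = int(child[1].generate_state(1)[0] % (2**31))

    weights = load_weights(config.weights_path)
    lex = lexicon_mod.load_lexicon(config.lexicon_path)
    stage_log: list[dict] = []
    artifacts: dict[str, Path] = {}

    def _record(stage: str, t0: float, **counts) -> None:
        stage_log.append({"stage": stage, "duration_s": round(time.time() - t0, 3), **counts})
        log.info("stage %s done: %s", stage, counts)

    # -- simulate ----------------------------------------------------------
    if config.run_simulate:
        t0 = time.time()
        try:
            sim_cfg = synthetic.SimulationConfig.from_dict(
                {**config.simulate, "seed": sim_seed}
            )
            cohort = synthetic.simulate_cohort(sim_cfg, lexicon=lex)
            paths = synthetic.write_cohort(cohort, out, weights=weights, vcf_seed=vcf_seed)
        except ValueError as exc:
            raise StageError("simulate", str(exc)) from exc
        artifacts.update(paths)
        _record("simulate", t0, n_subjects=len(cohort))
        demo_path, labs_path = paths["demographics"], paths["labs"]
        notes_path, vcf_path = paths["notes"], paths["genotypes"]
    else:
        demo_path, labs_path = config.demographics, config.labs
        notes_path, vcf_path = config.notes, config.vcf
        for stage_name, p in (
            ("scan", notes_path), ("extract", labs_path),
            ("extract", demo_path), ("grs", vcf_path),
        ):
            if p is None or not Path(p).exists():
                raise StageError(stage_name, f"required input file missing: {p}")

    # -- scan notes --------------------------------------------------------
    t0 = time.time()
    notes_df = read_notes(notes_path)
    mentions = lexicon_mod.scan_notes(notes_df, lex)
    mentions_df = lexicon_mod.mentions_frame(mentions)
    artifacts["mentions"] = out / "mentions.csv"
    mentions_df.to_csv(artifacts["mentions"], index=False)
    _record("scan", t0, n_notes=len(notes_df), n_mentions=len(mentions))

    # -- extract phenotypes ------------------------------------------------
    t0 = time.time()
    demo = pd.read_csv(demo_path, dtype={"subject_id": str})
    labs = pd.read_csv(labs_path, dtype={"subject_id": str})
    try:
        phenos = phenotypes.build_phenotype_table(demo, labs, mentions_df)
    except ValueError as exc:
        raise StageError("extract", str(exc)) from exc
    artifacts["phenotypes"] = out / "phenotypes.tsv"
    phenos.to_csv(artifacts["phenotypes"], sep="\t", index=False)
    _record("extract", t0, n_subjects=len(phenos),
            n_with_labs=int(phenos["all_hdl"].notna().sum()))

    # -- genetic risk score ------------------------------------------------
    t0 = time.time()
    try:
        gm = grs_mod.orient_effect_alleles(vcf_path, weights)
        grs_df = grs_mod.grs_table(gm, weights)
    except ValueError as exc:
        raise StageError("grs", str(exc)) from exc
    artifacts["grs"] = out / "grs.tsv"
    grs_df.to_csv(artifacts["grs"], sep="\t", index=False)
    _record("grs", t0, n_subjects=len(grs_df))

    # -- associate ---------------------------------------------------------
    t0 = time.time()
    try:
        results, flags = association.fit_all_definitions(
            phenos, grs_df, demo, min_n=config.min_n_per_definition
        )
        report = association.compare_definitions(results)
    except ValueError as exc:
        raise StageError("associate", str(exc)) from exc
    for flag in flags:
        log.warning("associate: %s", flag)
    artifacts["associations"] = out / "associations.tsv"
    report.table.to_csv(artifacts["associations"], sep="\t", index=False)
    _record("associate", t0, n_results=len(results), n_flags=len(flags))

    # -- compare -----------------------------------------------------------
    t0 = time.time()
    artifacts["comparison"] = out / "comparison.tsv"
    report.pairwise_z.to_csv(artifacts["comparison"], sep="\t", index=False)
    hist = association.risk_allele_histogram(grs_df)
    artifacts["risk_allele_histogram"] = out / "risk_allele_histogram.tsv"
    hist.rename_axis("risk_allele_total").rename("n_subjects").to_csv(
        artifacts["risk_allele_histogram"], sep="\t"
    )
    if config.make_plots:
        association.forest_plot(report, out / "forest.svg")
        association.histogram_plot(hist, out / "risk_alleles.svg")
        artifacts["forest_plot"] = out / "forest.svg"
        artifacts["histogram_plot"] = out / "risk_alleles.svg"
    _record("compare", t0, all_ci_overlap=bool(report.all_ci_overlap))

    manifest = {
        "seed": config.seed,
        "all_ci_overlap": bool(report.all_ci_overlap),
        "files": {
            name: {"path": p.name, "sha256": _sha256(p), "n_rows": _count_rows(p)}
            for name, p in sorted(artifacts.items())
            if p.suffix in {".csv", ".tsv", ".vcf", ".jsonl"}
        },
        "stages": [{k: v for k, v in s.items() if k != "duration_s"} for s in stage_log],
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def read_notes(path: str | Path) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.strip():
                rows.append(json.loads(line))
    return pd.DataFrame(rows, columns=["subject_id", "note_date", "text"])
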