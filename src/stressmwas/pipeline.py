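"""End-to-end pipeline driver.

Orchestrates the analysis in its natural order on a simulated cohort:
simulate -> correct (technical, biological) -> association engines ->
inflation/Miami exports -> profile scores across the two Sets -> kinship
GLMM of phenotype pairs.  Every stage writes TSV outputs into the run
directory and a manifest records seeds and SHA-256 checksums so a re-run
with the same configuration is verifiably identical.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as sio
from .mwas1 import run_mwas1
from .mwas2 import MomentConfig, run_mwas2
from .postassoc import bonferroni_threshold, genomic_inflation_lambda, miami_export
from .preprocess import correct_biological, correct_technical
from .scoring import threshold_sweep
from .synth import CELL_COUNTS, CohortDesign, simulate_cohort


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: sio.RunConfig, design: CohortDesign | None = None) -> dict:
    """Run the full pipeline; returns the manifest dictionary."""
    config.validate()
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "stages": {}, "checksums": {}}

    design = design or CohortDesign(n_individuals=config.n_individuals,
                                    n_cpgs=config.n_cpgs, seed=config.seed)
    cohort = simulate_cohort(design)
    paths = sio.write_cohort(cohort, out / "cohort")
    manifest["stages"]["simulate"] = paths

    missing = [p for p in config.phenotype_names if p not in cohort.samples]
    if missing:
        raise ValueError(f"phenotype columns missing from sample table: {missing}")

    matrix = cohort.methylome
    if config.correct:
        batch = cohort.samples[["plate", "draw_date", "position", "set_id"]].copy()
        matrix = correct_technical(matrix, batch)
        matrix, vc = correct_biological(
            matrix, cohort.rel.matrices, cohort.samples["sex"],
            cohort.samples["age"],
            cohort.samples[["CD8T", "CD4T", "NK", "Bcell", "Mono", "Gran"]])
        vc.to_csv(out / "variance_components.tsv", sep="\t", index=False)
        manifest["stages"]["correct"] = {"provenance": matrix.provenance}

    covs = pd.DataFrame({
        "set_id": cohort.samples["set_id"].astype(float),
        "smoking_ever": cohort.samples["smoking_ever"].astype(float),
        "pack_years": cohort.samples["pack_years"].astype(float),
    })
    cells = cohort.samples[list(CELL_COUNTS)]
    threshold = bonferroni_threshold(config.alpha, len(matrix.cpg_ids))
    manifest["threshold"] = threshold

    tables = {}
    for name in config.phenotype_names:
        y = cohort.samples[name]
        if "mwas1" in config.engines:
            t1 = run_mwas1(matrix, y, covs, n_pcs=config.n_pcs)
            sio.write_assoc(t1, out / f"assoc_{name}_mwas1.tsv")
            tables[(name, "mwas1")] = t1
        if "mwas2" in config.engines:
            mc = MomentConfig(n_groups=config.moment_groups,
                              window_bp=config.moment_window_bp)
            t2 = run_mwas2(matrix, y, covs, cells, mc, n_pcs=config.n_pcs)
            sio.write_assoc(t2, out / f"assoc_{name}_mwas2.tsv")
            tables[(name, "mwas2")] = t2
        if (name, "mwas1") in tables and (name, "mwas2") in tables:
            miami = miami_export(tables[(name, "mwas1")],
                                 tables[(name, "mwas2")], threshold)
            miami.to_csv(out / f"miami_{name}.tsv", sep="\t", index=False)

    lambdas = {f"{n}_{e}": genomic_inflation_lambda(t["p"].dropna()).lam
               for (n, e), t in tables.items()}
    manifest["lambda"] = lambdas
    pd.Series(lambdas, name="lambda").rename_axis("analysis").to_csv(
        out / "lambda.tsv", sep="\t")

    # profile scores: discovery in Set 1, evaluation in Set 2
    set1 = cohort.samples["set_id"] == 1
    set2 = ~set1
    engine = "mwas2" if "mwas2" in config.engines else "mwas1"
    frame = matrix.frame()
    score_rows = []
    for name in config.phenotype_names:
        disc = tables.get((name, engine))
        if disc is None or set2.sum() < 30:
            continue
        target = frame.loc[:, set2.to_numpy()]
        y2 = cohort.samples.loc[set2.to_numpy(), name]
        y2.index = target.columns
        sweep = threshold_sweep(disc, target, y2,
                                thresholds=config.score_thresholds,
                                n_phenotypes=len(config.phenotype_names))
        sweep.insert(0, "phenotype", name)
        score_rows.append(sweep)
    if score_rows:
        scores = pd.concat(score_rows, ignore_index=True)
        scores.to_csv(out / "profile_scores.tsv", sep="\t", index=False)
        manifest["stages"]["scores"] = str(out / "profile_scores.tsv")

    for f in sorted(out.rglob("*.tsv")) + sorted(out.rglob("*.bed")):
        manifest["checksums"][str(f.relative_to(out))] = _sha256(f)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
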