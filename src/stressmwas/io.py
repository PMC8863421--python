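"""Readers and writers for the package's tab-separated interchange formats.

Everything is plain TSV for inspectability (gzip transparently supported via
the filename); genomic coordinates are 0-based half-open internally and BED
convention on disk.  Round-tripping any table through write then read
returns the canonical form.  Schema violations raise with the offending
identifier or line.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .synth import MValueMatrix


def _check_unique(values, what: str) -> None:
    s = pd.Series(values)
    dup = s[s.duplicated()]
    if not dup.empty:
        first = dup.iloc[0]
        line = int(dup.index[0]) + 2       # +1 header, +1 one-based
        raise ValueError(f"duplicate {what} {first!r} (line {line})")


def write_mvalues(matrix: MValueMatrix, path) -> None:
    matrix.frame().to_csv(path, sep="\t")


def read_mvalues(path, positions: pd.DataFrame | None = None) -> MValueMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    _check_unique(df.index, "cpg_id")
    if positions is None:
        positions = pd.DataFrame({"chrom": "chrUn", "start": 0, "end": 1,
                                  "cpg_id": df.index})
    return MValueMatrix(values=df.to_numpy(dtype=float),
                        cpg_ids=list(df.index),
                        positions=positions.reset_index(drop=True),
                        sample_ids=list(df.columns))


def write_sample_table(samples: pd.DataFrame, path) -> None:
    samples.to_csv(path, sep="\t", index=False)


def read_sample_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if "sample_id" in df.columns:
        _check_unique(df["sample_id"], "sample_id")
    return df


def write_bed_positions(positions: pd.DataFrame, path) -> None:
    positions[["chrom", "start", "end", "cpg_id"]].to_csv(
        path, sep="\t", index=False, header=False)


def read_bed_positions(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["chrom", "start", "end", "cpg_id"])
    _check_unique(df["cpg_id"], "cpg_id")
    bad = df[(df["end"] <= df["start"]) | (df["start"] < 0)]
    if not bad.empty:
        raise ValueError(f"invalid BED interval at line {int(bad.index[0]) + 1}")
    return df


def write_relmatrix(matrix: np.ndarray, sample_ids: list[str], path) -> None:
    pd.DataFrame(matrix, index=sample_ids, columns=sample_ids).to_csv(path, sep="\t")


def read_relmatrix(path) -> tuple[np.ndarray, list[str]]:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if list(df.index) != list(df.columns):
        raise ValueError("relationship matrix rows and columns disagree")
    return df.to_numpy(dtype=float), list(df.index)


def write_gmt(gene_sets: dict[str, list[str]], path,
              descriptions: dict[str, str] | None = None) -> None:
    with open(path, "w") as fh:
        for name, genes in gene_sets.items():
            desc = (descriptions or {}).get(name, "na")
            fh.write("\t".join([name, desc, *genes]) + "\n")


def read_gmt(path) -> dict[str, list[str]]:
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"GMT line {i}: need name, description and at least one gene")
            name = fields[0]
            if name in sets:
                raise ValueError(f"GMT line {i}: duplicate set name {name!r}")
            sets[name] = [g for g in fields[2:] if g]
    return sets


ASSOC_COLUMNS = ["cpg_id", "chrom", "pos", "effect", "se", "stat", "p", "n", "engine"]


def write_assoc(table: pd.DataFrame, path) -> None:
    missing = [c for c in ASSOC_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"association table missing columns: {missing}")
    table[ASSOC_COLUMNS].to_csv(path, sep="\t", index=False)


def read_assoc(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in ASSOC_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"association table missing columns: {missing}")
    _check_unique(df["cpg_id"], "cpg_id")
    return df


def read_fam(path) -> pd.DataFrame:
    """FAM-like pedigree: family, individual, father, mother, sex, phenotype."""
    df = pd.read_csv(path, sep=r"\s+", header=None,
                     names=["family_id", "sample_id", "father", "mother",
                            "sex", "phenotype"])
    _check_unique(df["sample_id"], "sample_id")
    return df


def read_weights(path) -> pd.Series:
    """External score weights: two columns, cpg_id and effect."""
    df = pd.read_csv(path, sep="\t")
    if not {"cpg_id", "effect"}.issubset(df.columns):
        raise ValueError("weights file needs cpg_id and effect columns")
    _check_unique(df["cpg_id"], "cpg_id")
    return df.set_index("cpg_id")["effect"]


def write_annotation(annotation: pd.DataFrame, path) -> None:
    annotation[["cpg_id", "chrom", "pos", "gene"]].to_csv(path, sep="\t", index=False)


def read_annotation(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    need = {"cpg_id", "gene"}
    if not need.issubset(df.columns):
        raise ValueError("annotation needs cpg_id and gene columns")
    return df


@dataclass
class RunConfig:
    """Validated configuration for the end-to-end pipeline."""

    seed: int = 0
    outdir: str = "results"
    n_individuals: int = 500
    n_cpgs: int = 2000
    phenotype_names: list[str] = field(default_factory=lambda: ["preterm", "mdd"])
    engines: list[str] = field(default_factory=lambda: ["mwas1", "mwas2"])
    alpha: float = 0.05
    n_pcs: int = 10
    score_thresholds: list[float] = field(
        default_factory=lambda: [1e-7, 1e-6, 1e-5, 1e-4, 1e-3, 1e-2, 1e-1])
    moment_groups: int = 2
    moment_window_bp: int = 50_000
    correct: bool = True
    extra: dict = field(default_factory=dict)

    def validate(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        for t in self.score_thresholds:
            if not 0 < t <= 1:
                raise ValueError(f"score threshold {t} outside (0, 1]")
        bad = [e for e in self.engines if e not in ("mwas1", "mwas2")]
        if bad:
            raise ValueError(f"unknown engines: {bad}")


def load_config(path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = {f for f in RunConfig.__dataclass_fields__}
    kwargs = {k: v for k, v in raw.items() if k in known}
    kwargs["extra"] = {k: v for k, v in raw.items() if k not in known}
    cfg = RunConfig(**kwargs)
    cfg.validate()
    return cfg


def write_cohort(cohort, outdir) -> dict[str, str]:
    """Write every artefact of a simulated cohort to a directory of TSVs."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    write_mvalues(cohort.methylome, out / "mvalues.tsv")
    paths["mvalues"] = str(out / "mvalues.tsv")
    write_sample_table(cohort.samples, out / "samples.tsv")
    paths["samples"] = str(out / "samples.tsv")
    write_bed_positions(cohort.methylome.positions, out / "cpg_positions.bed")
    paths["positions"] = str(out / "cpg_positions.bed")
    ids = cohort.rel.sample_ids
    for label, m in cohort.rel.matrices.items():
        p = out / f"rel_{label}.tsv"
        write_relmatrix(m, ids, p)
        paths[f"rel_{label}"] = str(p)
    truth_rows = []
    for name, cpgs in cohort.truth.causal.items():
        for c, s in zip(cpgs, cohort.truth.slopes[name]):
            truth_rows.append({"phenotype": name, "cpg_id": c, "slope": s})
    pd.DataFrame(truth_rows, columns=["phenotype", "cpg_id", "slope"]).to_csv(
        out / "truth.tsv", sep="\t", index=False)
    paths["truth"] = str(out / "truth.tsv")
    return paths
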