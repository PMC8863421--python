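"""Family-structured synthetic methylome cohorts with known ground truth.

Emulates the covariance anatomy of a family-based methylation cohort:
nuclear-family pedigrees inducing the five relationship structures used by
the correction model (G: common genetic, K: kinship, F: nuclear family,
C: couple, S: sibling), plate and blood-draw-date batch effects, estimated
blood-cell compositions with an optional seasonal shift tied to birth date,
smoking covariates, and planted CpG effects feeding binary phenotypes through
a liability-threshold model at configured prevalences.

All randomness flows from one integer seed; each stage draws from its own
deterministic substream so regenerating any stage is reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

COMPONENTS = ("G", "K", "F", "C", "S")
CELL_PROPORTIONS = ("CD8T", "CD4T", "NK", "Bcell", "Mono", "Gran")
CELL_COUNTS = ("basophil", "eosinophil", "lymphocyte", "monocyte", "neutrophil")

_STAGE_PEDIGREE = 0
_STAGE_METHYLOME = 1
_STAGE_PHENOTYPES = 2


class InvalidDesignError(ValueError):
    """Raised when a cohort design violates its invariants."""


@dataclass
class PhenotypeSpec:
    """One simulated phenotype: binary (liability threshold) or continuous."""

    kind: str = "binary"                  # "binary" | "continuous"
    prevalence: float | None = 0.035
    n_causal: int = 0
    effect_size: float = 0.3              # liability slope per causal CpG (M-value scale)
    familial: float = 0.2                 # kinship-correlated share of liability variance

    def __post_init__(self):
        if self.kind not in ("binary", "continuous"):
            raise InvalidDesignError(f"unknown phenotype kind {self.kind!r}")
        if self.kind == "binary":
            if self.prevalence is None or not (0.0 < self.prevalence < 1.0):
                raise InvalidDesignError("prevalence must lie in (0, 1)")


def _default_phenotypes() -> dict[str, PhenotypeSpec]:
    # prevalences follow the cohort demographics: preterm 3.5%, MDD 13%
    return {
        "preterm": PhenotypeSpec(kind="binary", prevalence=0.035),
        "mdd": PhenotypeSpec(kind="binary", prevalence=0.13),
    }


def _default_fractions() -> dict[str, float]:
    # shares of per-CpG M-value variance; placeholders for unreported cohort
    # estimates (G collapsed into K by default, see CohortDesign.separate_g)
    return {
        "G": 0.0, "K": 0.20, "F": 0.10, "C": 0.05, "S": 0.05,
        "plate": 0.10, "date": 0.05, "residual": 0.45,
    }


@dataclass
class CohortDesign:
    """Parameters of a simulated family cohort.

    ``variance_fractions`` are the generative shares of each covariance
    component in every CpG's M-value; they must sum to at most 1 (a shortfall
    is left as extra residual headroom, i.e. total variance < 1).
    """

    n_individuals: int = 500
    n_cpgs: int = 2000
    family_distribution: dict[str, float] = field(
        default_factory=lambda: {"couples": 0.2, "trios": 0.3, "sibships": 0.5})
    variance_fractions: dict[str, float] = field(default_factory=_default_fractions)
    phenotypes: dict[str, PhenotypeSpec] = field(default_factory=_default_phenotypes)
    separate_g: bool = False              # if True, G gets its own iid-genetic draw
    plate_size: int = 96
    n_draw_dates: int = 60
    seasonal_cell_shift: float = 0.0      # SD of lymphocyte/neutrophil shift per unit birth-date score
    cell_meth_fraction: float = 0.0       # variance share of cell composition in affected CpGs
    cell_affected_prop: float = 0.3       # proportion of CpGs loaded on cell composition
    ar1_rho: float = 0.0                  # optional co-methylation between adjacent CpGs
    seed: int = 0

    def __post_init__(self):
        if self.n_individuals < 2:
            raise InvalidDesignError("need at least two individuals")
        if self.n_cpgs < 1:
            raise InvalidDesignError("need at least one CpG")
        total = sum(self.variance_fractions.values())
        if total > 1.0 + 1e-9:
            raise InvalidDesignError(
                f"variance fractions sum to {total:.3f} > 1")
        if any(v < 0 for v in self.variance_fractions.values()):
            raise InvalidDesignError("variance fractions must be non-negative")
        for name, spec in self.phenotypes.items():
            if spec.n_causal > self.n_cpgs:
                raise InvalidDesignError(
                    f"phenotype {name!r}: n_causal exceeds n_cpgs")

    def rng(self, stage: int) -> np.random.Generator:
        """Stage-keyed substream of the global seed."""
        return np.random.default_rng(
            np.random.SeedSequence(entropy=self.seed, spawn_key=(stage,)))


@dataclass
class RelationshipMatrixSet:
    """The five sample-by-sample covariance structures plus batch groupings."""

    matrices: dict[str, np.ndarray]
    samples: pd.DataFrame                 # sample_id, family_id, role, sex, age, batches...

    @property
    def sample_ids(self) -> list[str]:
        return list(self.samples["sample_id"])

    def validate(self) -> None:
        n = len(self.samples)
        for label, m in self.matrices.items():
            if m.shape != (n, n):
                raise ValueError(f"matrix {label} has shape {m.shape}, expected {(n, n)}")
            if not np.allclose(m, m.T):
                raise ValueError(f"matrix {label} is not symmetric")
            if not np.allclose(np.diag(m), 1.0):
                raise ValueError(f"matrix {label} diagonal is not 1")
            w = np.linalg.eigvalsh(m)
            if w.min() < -1e-8:
                raise ValueError(f"matrix {label} is not positive semidefinite")


@dataclass
class MValueMatrix:
    """CpG-by-sample M-value matrix with coordinates and sample metadata."""

    values: np.ndarray                    # (n_cpgs, n_samples)
    cpg_ids: list[str]
    positions: pd.DataFrame               # chrom, start, end, cpg_id (BED, 0-based)
    sample_ids: list[str]
    provenance: str = "raw"               # raw | technical | biological
    sample_meta: pd.DataFrame | None = None

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=pd.Index(self.cpg_ids, name="cpg_id"),
                            columns=self.sample_ids)

    def copy_with(self, values: np.ndarray, provenance: str) -> "MValueMatrix":
        return MValueMatrix(values=values, cpg_ids=list(self.cpg_ids),
                            positions=self.positions.copy(),
                            sample_ids=list(self.sample_ids),
                            provenance=provenance,
                            sample_meta=None if self.sample_meta is None
                            else self.sample_meta.copy())


@dataclass
class SimTruth:
    """Planted ground truth for recovery tests."""

    causal: dict[str, list[str]]          # phenotype -> causal CpG ids
    slopes: dict[str, np.ndarray]         # phenotype -> liability slopes
    cell_shift: float                     # seasonal lymphocyte/neutrophil shift used
    cell_loaded_cpgs: list[str]           # CpGs carrying cell-composition variance


def simulate_pedigree(design: CohortDesign) -> RelationshipMatrixSet:
    """Generate nuclear families and the implied G/K/F/C/S matrices.

    Families are independent: two unrelated founders plus 0-3 offspring
    ("couples" have none, "trios" one, "sibships" two or three).  Expected
    relatedness fills K (parent-offspring and full sibs 0.5); F, C and S are
    block indicators for whole family, couple and sibship; G equals K unless
    ``separate_g`` requests an independent genetic component.
    """
    rng = design.rng(_STAGE_PEDIGREE)
    kinds = list(design.family_distribution)
    probs = np.array([design.family_distribution[k] for k in kinds], dtype=float)
    probs = probs / probs.sum()

    rows = []
    fam = 0
    while len(rows) < design.n_individuals:
        kind = kinds[rng.choice(len(kinds), p=probs)]
        n_kids = {"couples": 0, "trios": 1}.get(kind, int(rng.integers(2, 4)))
        remaining = design.n_individuals - len(rows)
        size = 2 + n_kids
        if size > remaining:
            if remaining == 1:
                # a singleton to hit the target exactly
                rows.append((fam, "singleton"))
                fam += 1
                break
            n_kids = max(0, remaining - 2)
            size = 2 + n_kids
        rows.append((fam, "mother"))
        rows.append((fam, "father"))
        rows.extend((fam, f"child{j}") for j in range(n_kids))
        fam += 1
    rows = rows[:design.n_individuals]
    n = len(rows)

    fam_ids = np.array([r[0] for r in rows])
    roles = [r[1] for r in rows]
    is_child = np.array([r.startswith("child") for r in roles])
    is_parent = np.array([r in ("mother", "father") for r in roles])

    K = np.eye(n)
    F = np.eye(n)
    C = np.eye(n)
    S = np.eye(n)
    for f in np.unique(fam_ids):
        idx = np.where(fam_ids == f)[0]
        for a_pos, i in enumerate(idx):
            for j in idx[a_pos + 1:]:
                F[i, j] = F[j, i] = 1.0
                pi, pj = is_parent[i], is_parent[j]
                ci, cj = is_child[i], is_child[j]
                if pi and pj:
                    C[i, j] = C[j, i] = 1.0           # the couple
                elif ci and cj:
                    S[i, j] = S[j, i] = 1.0           # full sibs
                    K[i, j] = K[j, i] = 0.5
                if (pi and cj) or (ci and pj):
                    K[i, j] = K[j, i] = 0.5           # parent-offspring

    G = np.eye(n) if design.separate_g else K.copy()

    n_plates = max(1, int(np.ceil(n / design.plate_size)))
    plate = rng.permutation(np.arange(n) % n_plates)
    position = rng.integers(1, design.plate_size + 1, size=n)
    draw_date = rng.integers(0, design.n_draw_dates, size=n)
    # whole families assigned to a Set so the two Sets share no relatives
    fam_set = {f: 1 + int(rng.random() < 0.5) for f in np.unique(fam_ids)}
    set_id = np.array([fam_set[f] for f in fam_ids])

    samples = pd.DataFrame({
        "sample_id": [f"S{i:05d}" for i in range(n)],
        "family_id": [f"F{f:04d}" for f in fam_ids],
        "role": roles,
        "sex": rng.choice(["F", "M"], size=n, p=[0.59, 0.41]),
        "age": np.round(rng.normal(49.8, 13.7, size=n).clip(18, 99), 1),
        "plate": [f"P{p:02d}" for p in plate],
        "position": position,
        "set_id": set_id,
        "draw_date": [f"D{d:03d}" for d in draw_date],
        "birth_doy": rng.integers(1, 366, size=n).astype(float),
        "smoking_ever": rng.integers(0, 2, size=n),
    })
    samples["birth_month"] = np.minimum(12, samples["birth_doy"] // 30.5 + 1).astype(int)
    samples["pack_years"] = np.where(
        samples["smoking_ever"] == 1, rng.gamma(2.0, 6.0, size=n), 0.0).round(1)

    rel = RelationshipMatrixSet(
        matrices={"G": G, "K": K, "F": F, "C": C, "S": S}, samples=samples)
    return rel


def _seasonal_score(doy: np.ndarray) -> np.ndarray:
    return -np.cos(2.0 * np.pi * (doy + 10.0) / 365.0)


def _draw_cells(design: CohortDesign, samples: pd.DataFrame,
                rng: np.random.Generator) -> pd.DataFrame:
    """Blood-cell compositions and counts, optionally shifted by birth season.

    The seasonal shift moves lymphocyte-lineage proportions up and
    granulocyte/neutrophil measures down (or vice versa) in proportion to the
    birth-date score, mirroring the seasonally structured cell-count
    differences the pipeline must be able to detect and adjust away.
    """
    n = len(samples)
    base = np.array([0.08, 0.17, 0.06, 0.06, 0.08, 0.55])  # CD8T..Gran means
    props = rng.dirichlet(base * 120.0, size=n)
    season = _seasonal_score(samples["birth_doy"].to_numpy())
    shift = design.seasonal_cell_shift * season
    lymph_cols = [0, 1, 2, 3]
    props[:, lymph_cols] *= np.exp(shift[:, None] * 0.5)
    props[:, 5] *= np.exp(-shift * 0.5)
    props = props / props.sum(axis=1, keepdims=True)
    # deconvolution-style estimates carry measurement error, so the six
    # proportions do not sum exactly to one (keeps designs full rank too)
    props = np.clip(props + rng.normal(0.0, 0.005, size=props.shape), 1e-4, None)
    cells = pd.DataFrame(props, columns=list(CELL_PROPORTIONS))

    lympho = props[:, lymph_cols].sum(axis=1)
    counts = pd.DataFrame({
        "basophil": rng.normal(0.03, 0.01, n).clip(0),
        "eosinophil": rng.normal(0.15, 0.05, n).clip(0),
        "lymphocyte": (2.0 * lympho + rng.normal(0, 0.05, n)).clip(0),
        "monocyte": (0.5 * props[:, 4] * 6 + rng.normal(0, 0.03, n)).clip(0),
        "neutrophil": (4.0 * props[:, 5] + rng.normal(0, 0.1, n)).clip(0),
    })
    return pd.concat([cells, counts], axis=1)


def simulate_methylome(design: CohortDesign,
                       rel: RelationshipMatrixSet) -> tuple[MValueMatrix, SimTruth]:
    """Draw the CpG-by-sample M-value matrix with the configured covariance.

    Each CpG is a sum of component draws (Cholesky factors of the G/K/F/C/S
    matrices scaled by their variance fractions), plate and draw-date random
    intercepts, an optional cell-composition term on a subset of CpGs, and
    iid residual noise.  Causal CpGs for each phenotype are chosen here and
    recorded in the returned SimTruth (they acquire their effect only when
    phenotypes are generated from the matrix).
    """
    rng = design.rng(_STAGE_METHYLOME)
    n = len(rel.samples)
    p = design.n_cpgs
    vf = design.variance_fractions

    chol = {}
    for label in COMPONENTS:
        if vf.get(label, 0.0) > 0:
            m = rel.matrices[label]
            w, Q = np.linalg.eigh(m)
            chol[label] = Q * np.sqrt(np.maximum(w, 0.0))

    M = np.zeros((p, n))
    for label, L in chol.items():
        draws = rng.standard_normal((p, n))
        M += np.sqrt(vf[label]) * draws @ L.T

    for batch_col, frac_key in (("plate", "plate"), ("draw_date", "date")):
        frac = vf.get(frac_key, 0.0)
        if frac > 0:
            codes, levels = pd.factorize(rel.samples[batch_col])
            intercepts = rng.standard_normal((p, len(levels)))
            M += np.sqrt(frac) * intercepts[:, codes]

    cells = _draw_cells(design, rel.samples, rng)
    cell_loaded: list[str] = []
    if design.cell_meth_fraction > 0:
        n_loaded = int(round(design.cell_affected_prop * p))
        loaded = rng.choice(p, size=n_loaded, replace=False)
        lympho = cells[list(CELL_PROPORTIONS[:4])].sum(axis=1).to_numpy()
        factor = (lympho - lympho.mean()) / lympho.std()
        loadings = rng.choice([-1.0, 1.0], size=n_loaded)
        M[loaded] += np.sqrt(design.cell_meth_fraction) * loadings[:, None] * factor[None, :]
        cell_loaded = [f"cg{i:06d}" for i in sorted(loaded)]

    resid_frac = vf.get("residual", 0.0)
    if resid_frac > 0:
        noise = rng.standard_normal((p, n))
        if design.ar1_rho:
            rho = design.ar1_rho
            for j in range(1, p):
                noise[j] = rho * noise[j - 1] + np.sqrt(1 - rho ** 2) * noise[j]
        M += np.sqrt(resid_frac) * noise

    # per-CpG baseline level (removed by any correction; keeps raw values M-like)
    M += rng.normal(0.0, 2.0, size=(p, 1))

    cpg_ids = [f"cg{i:06d}" for i in range(p)]
    chrom = np.sort(rng.integers(1, 23, size=p))
    pos = np.zeros(p, dtype=int)
    for c in np.unique(chrom):
        idx = np.where(chrom == c)[0]
        pos[idx] = np.sort(rng.integers(1, 200_000_000, size=idx.size))
    positions = pd.DataFrame({
        "chrom": [f"chr{c}" for c in chrom], "start": pos, "end": pos + 1,
        "cpg_id": cpg_ids,
    })

    causal: dict[str, list[str]] = {}
    slopes: dict[str, np.ndarray] = {}
    for name, spec in design.phenotypes.items():
        if spec.n_causal > 0:
            chosen = rng.choice(p, size=spec.n_causal, replace=False)
            causal[name] = [cpg_ids[i] for i in chosen]
            signs = rng.choice([-1.0, 1.0], size=spec.n_causal)
            slopes[name] = spec.effect_size * signs
        else:
            causal[name] = []
            slopes[name] = np.zeros(0)

    meta = pd.concat([rel.samples.reset_index(drop=True), cells], axis=1)
    mvals = MValueMatrix(values=M, cpg_ids=cpg_ids, positions=positions,
                         sample_ids=list(rel.samples["sample_id"]),
                         provenance="raw", sample_meta=meta)
    truth = SimTruth(causal=causal, slopes=slopes,
                     cell_shift=design.seasonal_cell_shift,
                     cell_loaded_cpgs=cell_loaded)
    return mvals, truth


def simulate_phenotypes(design: CohortDesign, methylome: MValueMatrix,
                        truth: SimTruth,
                        rel: RelationshipMatrixSet | None = None) -> pd.DataFrame:
    """Draw phenotypes from the simulated methylome via liability thresholds.

    Binary traits: liability = sum(slope * M over causal CpGs) + a
    kinship-correlated familial term + iid residual, standardised, and
    thresholded at the normal quantile matching the configured prevalence.
    Continuous traits use the same liability, standardised, without the
    threshold.  Demographics and cell columns from the methylome's sample
    metadata are carried into the returned table.
    """
    rng = design.rng(_STAGE_PHENOTYPES)
    meta = methylome.sample_meta
    if meta is None:
        raise ValueError("methylome carries no sample metadata")
    n = len(methylome.sample_ids)
    out = meta.copy().reset_index(drop=True)
    out["birth_date_score"] = _seasonal_score(out["birth_doy"].to_numpy())

    Lk = None
    needs_familial = any(s.familial > 0 for s in design.phenotypes.values())
    if rel is not None and needs_familial:
        w, Q = np.linalg.eigh(rel.matrices["K"])
        Lk = Q * np.sqrt(np.maximum(w, 0.0))

    idx = {c: i for i, c in enumerate(methylome.cpg_ids)}
    for name, spec in design.phenotypes.items():
        if spec.prevalence is not None and not (0.0 < spec.prevalence < 1.0):
            raise InvalidDesignError("prevalence outside (0, 1)")
        cpgs = truth.causal.get(name, [])
        slopes = truth.slopes.get(name, np.zeros(0))
        missing = [c for c in cpgs if c not in idx]
        if missing:
            raise ValueError(f"causal CpGs absent from matrix: {missing[:3]}")
        liab = np.zeros(n)
        if cpgs:
            sub = methylome.values[[idx[c] for c in cpgs]]
            liab = liab + slopes @ sub
        fam_var = spec.familial
        if fam_var > 0 and Lk is not None:
            liab = liab + np.sqrt(fam_var) * (Lk @ rng.standard_normal(n))
        resid_var = max(1.0 - fam_var, 0.05)
        liab = liab + np.sqrt(resid_var) * rng.standard_normal(n)
        liab = (liab - liab.mean()) / liab.std()
        if spec.kind == "binary":
            from scipy.stats import norm
            thr = norm.isf(spec.prevalence)
            out[name] = (liab > thr).astype(int)
        else:
            out[name] = liab
    return out


@dataclass
class SimulatedCohort:
    design: CohortDesign
    rel: RelationshipMatrixSet
    methylome: MValueMatrix
    truth: SimTruth
    samples: pd.DataFrame


def simulate_cohort(design: CohortDesign) -> SimulatedCohort:
    """Run all three stages: pedigree -> methylome -> phenotypes."""
    rel = simulate_pedigree(design)
    methylome, truth = simulate_methylome(design, rel)
    samples = simulate_phenotypes(design, methylome, truth, rel=rel)
    methylome.sample_meta = samples
    return SimulatedCohort(design=design, rel=rel, methylome=methylome,
                           truth=truth, samples=samples)
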