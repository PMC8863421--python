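"""Post-association diagnostics and gene-level summaries.

Covers the genomic inflation factor (median observed association chi-square
over the null median), Bonferroni family-wise thresholds, QQ-plot points
with a beta-distribution 95% band, Miami-plot data export (signed -log10
columns for the two engines), location-based gene annotation of significant
CpGs, and gene-set over-representation corrected for the number of array
probes per gene via Wallenius' noncentral hypergeometric distribution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

CHI2_MEDIAN_1DF = float(stats.chi2.ppf(0.5, 1))   # ~0.45494


@dataclass
class InflationEstimate:
    lam: float
    n_probes: int


@dataclass
class SignificanceConfig:
    alpha: float = 0.05
    n_tests: int = 1

    @property
    def threshold(self) -> float:
        return bonferroni_threshold(self.alpha, self.n_tests)


def bonferroni_threshold(alpha: float, n_tests: int) -> float:
    """Family-wise significance threshold alpha / n_tests."""
    if n_tests < 1:
        raise ValueError("n_tests must be at least 1")
    return alpha / n_tests


def genomic_inflation_lambda(p_values) -> InflationEstimate:
    """lambda = median(qchisq1(1 - p)) / median of the chi-square(1) null."""
    p = np.asarray(p_values, dtype=float)
    p = p[~np.isnan(p)]
    if p.size == 0:
        raise ValueError("no valid P-values")
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("P-values must lie in (0, 1]")
    chi = stats.chi2.isf(p, 1)
    return InflationEstimate(lam=float(np.median(chi) / CHI2_MEDIAN_1DF),
                             n_probes=int(p.size))


def qq_points(p_values, band: float = 0.95) -> pd.DataFrame:
    """Observed vs expected -log10 P with a pointwise beta confidence band.

    The expected P at ascending rank i of n is i/(n+1) (the mean of the i-th
    uniform order statistic); the band is the matching beta(i, n-i+1)
    quantile interval.
    """
    p = np.sort(np.asarray(p_values, dtype=float))
    p = p[~np.isnan(p)]
    if p.size == 0:
        raise ValueError("no valid P-values")
    n = p.size
    i = np.arange(1, n + 1)
    expected = i / (n + 1.0)
    a = (1.0 - band) / 2.0
    lower = stats.beta.ppf(a, i, n - i + 1)
    upper = stats.beta.ppf(1 - a, i, n - i + 1)
    return pd.DataFrame({
        "expected_nlog10": -np.log10(expected),
        "observed_nlog10": -np.log10(np.clip(p, np.nextafter(0, 1), 1.0)),
        "band_lower_nlog10": -np.log10(upper),
        "band_upper_nlog10": -np.log10(lower),
    })


def miami_export(table_mwas1: pd.DataFrame, table_mwas2: pd.DataFrame,
                 threshold: float) -> pd.DataFrame:
    """Plot-ready Miami table: signed -log10 P, genome order, threshold line.

    MWAS 1 appears as log10 P (negative values, plotted downward) and MWAS 2
    as -log10 P.  A probe missing from one engine keeps a null cell in that
    engine's column rather than dropping the row.
    """
    cols = ["cpg_id", "chrom", "pos", "p"]
    t1 = table_mwas1[cols].rename(columns={"p": "p_mwas1"})
    t2 = table_mwas2[cols].rename(columns={"p": "p_mwas2"})
    merged = t1.merge(t2, on="cpg_id", how="outer", suffixes=("", "_2"))
    for c in ("chrom", "pos"):
        alt = f"{c}_2"
        if alt in merged:
            merged[c] = merged[c].fillna(merged[alt])
            merged = merged.drop(columns=[alt])
    chrom_num = (merged["chrom"].astype(str).str.replace("chr", "", regex=False)
                 .replace({"X": "23", "Y": "24"}).astype(float))
    merged = (merged.assign(_c=chrom_num)
              .sort_values(["_c", "pos"]).drop(columns="_c")
              .reset_index(drop=True))
    merged["signed_log10_mwas1"] = np.log10(merged["p_mwas1"])
    merged["signed_log10_mwas2"] = -np.log10(merged["p_mwas2"])
    merged["significance_line"] = -np.log10(threshold)
    return merged


def annotate_significant(table: pd.DataFrame, annotation: pd.DataFrame,
                         threshold: float) -> dict:
    """Unique genes mapped from sub-threshold CpGs, unannotated ones counted.

    ``annotation`` maps cpg_id -> gene (empty/NaN = no gene at that location).
    """
    sig = table.loc[table["p"] < threshold, "cpg_id"]
    ann = annotation.set_index("cpg_id")["gene"]
    genes: set[str] = set()
    unannotated = 0
    for c in sig:
        g = ann.get(c)
        if g is None or (isinstance(g, float) and np.isnan(g)) or g == "":
            unannotated += 1
        elif isinstance(g, pd.Series):    # a CpG mapping to several genes
            genes.update(x for x in g if isinstance(x, str) and x)
        else:
            genes.add(g)
    return {"genes": sorted(genes), "n_significant": int(sig.size),
            "n_unannotated": unannotated}


def gene_overlap(genes_a, genes_b) -> list[str]:
    return sorted(set(genes_a) & set(genes_b))


def _wallenius_sf(x: int, total: int, in_set: int, drawn: int, odds: float) -> float:
    """P(X >= x) for Wallenius' noncentral hypergeometric; odds=1 is the
    central hypergeometric tail (computed exactly in that case)."""
    if in_set == 0 or drawn == 0:
        return 1.0
    if x <= 0:
        return 1.0
    if abs(odds - 1.0) < 1e-12:
        return float(stats.hypergeom.sf(x - 1, total, in_set, drawn))
    dist = stats.nchypergeom_wallenius(total, in_set, drawn, odds)
    return float(dist.sf(x - 1))


def geneset_enrichment(sig_cpgs, all_cpgs, annotation: pd.DataFrame,
                       gene_sets: dict[str, list[str]],
                       *, correct_bias: bool = True) -> pd.DataFrame:
    """Gene-set over-representation with probe-number bias correction.

    Genes carrying more array probes are more likely to contain a
    significant CpG by chance; the test therefore draws genes with weights
    proportional to their probe counts, i.e. the null is Wallenius'
    noncentral hypergeometric with odds equal to the ratio of mean probe
    counts inside vs outside each set.  With equal probe counts this reduces
    exactly to the ordinary hypergeometric test.  Unadjusted and BH-adjusted
    P-values are both reported; a set with no annotated genes gets missing P.
    """
    from statsmodels.stats.multitest import multipletests

    ann = annotation.dropna(subset=["gene"])
    ann = ann[ann["gene"] != ""]
    universe_counts = ann.groupby("gene")["cpg_id"].nunique()
    universe = set(universe_counts.index)
    sig_set = set(sig_cpgs)
    sig_genes = set(ann.loc[ann["cpg_id"].isin(sig_set), "gene"])
    n_universe = len(universe)
    k = len(sig_genes)

    rows = []
    for name, members in gene_sets.items():
        in_set = sorted(universe & set(members))
        m = len(in_set)
        if m == 0:
            rows.append({"gene_set": name, "n_genes": 0, "n_sig": 0,
                         "odds": np.nan, "p": np.nan})
            continue
        x = len(sig_genes & set(in_set))
        if correct_bias:
            w_in = universe_counts.loc[in_set].mean()
            out_genes = universe - set(in_set)
            w_out = universe_counts.loc[sorted(out_genes)].mean() if out_genes else w_in
            odds = float(w_in / w_out) if w_out > 0 else 1.0
        else:
            odds = 1.0
        p = _wallenius_sf(x, n_universe, m, k, odds) if k > 0 else 1.0
        rows.append({"gene_set": name, "n_genes": m, "n_sig": x,
                     "odds": odds, "p": p})
    out = pd.DataFrame(rows)
    valid = out["p"].notna()
    out["p_fdr"] = np.nan
    if valid.any():
        out.loc[valid, "p_fdr"] = multipletests(out.loc[valid, "p"],
                                                method="fdr_bh")[1]
    return out
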