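"""Early-life environment phenotype constructors and the resilience score.

Eight early-life exposures are derived from raw birth records: preterm birth
(<37 weeks), low birth weight (below a sex- and gestation-adjusted centile
threshold supplied as a table), birth month (April-October inclusive), a
continuous seasonal birth-date score, having a young parent (<21 years),
having a lone parent (parents in different regions at birth), urban birth
region, and population density.  Psychological resilience (BRS) is the first
unrotated principal component of six 5-point Likert items after iterative
tree-ensemble imputation of sparse missingness.

Conventions: exposure present = 1; all thresholds are strict, so equality
means unexposed; missing inputs yield missing outputs, never 0.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

URBAN_REGIONS = frozenset({"Edinburgh", "Glasgow", "Aberdeen", "Dundee"})
LEAP_DAY_INDEX = 59.5


def preterm_flag(gestation_weeks: pd.Series) -> pd.Series:
    """1 iff recorded gestation is under 37 weeks; missing stays missing."""
    g = pd.to_numeric(gestation_weeks, errors="coerce")
    out = (g < 37).astype(float)
    out[g.isna()] = np.nan
    return out


def low_birth_weight_flag(records: pd.DataFrame,
                          centile_table: pd.DataFrame) -> pd.Series:
    """1 iff birth weight is strictly below the (sex, gestation-week) threshold.

    ``centile_table`` needs columns sex, gestation_weeks, threshold_g.  A
    record whose (sex, week) cell is absent from the table becomes missing
    and is counted in a logged warning.
    """
    req = {"sex", "gestation_weeks", "threshold_g"}
    if not req.issubset(centile_table.columns):
        raise ValueError(f"centile table must have columns {sorted(req)}")
    tab = centile_table.set_index(["sex", "gestation_weeks"])["threshold_g"]
    out = np.full(len(records), np.nan)
    n_absent = 0
    weights = pd.to_numeric(records["birth_weight_g"], errors="coerce")
    gest = pd.to_numeric(records["gestation_weeks"], errors="coerce")
    for i, (sex, gw, w) in enumerate(zip(records["sex"], gest, weights)):
        if pd.isna(w) or pd.isna(gw):
            continue
        key = (sex, int(gw))
        if key not in tab.index:
            n_absent += 1
            continue
        out[i] = float(w < tab.loc[key])
    if n_absent:
        logger.warning("low_birth_weight_flag: %d records had no centile cell "
                       "and were set missing", n_absent)
    return pd.Series(out, index=records.index)


def birth_month_flag(birth_month: pd.Series) -> pd.Series:
    """1 iff born April through October inclusive."""
    m = pd.to_numeric(birth_month, errors="coerce")
    out = m.between(4, 10).astype(float)
    out[m.isna()] = np.nan
    return out


def birth_date_score(date):
    """Seasonal birth-date score y = -cos(2*pi*(date+10)/365).

    ``date`` is the day of birth within the year (1 Jan = 1); 29 February is
    encoded as 59.5.  The score runs from -1 at the winter solstice (21 Dec,
    day 355) to +1 at the summer solstice (21 Jun, day 172).
    """
    d = np.asarray(date, dtype=float)
    valid = np.isnan(d) | ((d >= 1.0) & (d <= 365.0))
    if not np.all(valid):
        bad = np.atleast_1d(d)[~np.atleast_1d(valid)][:3]
        raise ValueError(f"date outside [1, 365]: {bad}")
    y = -np.cos(2.0 * np.pi * (d + 10.0) / 365.0)
    if np.isscalar(date) or np.ndim(date) == 0:
        return float(y)
    return pd.Series(y, index=date.index) if isinstance(date, pd.Series) else y


def young_parent_flag(records: pd.DataFrame) -> pd.Series:
    """1 iff the youngest relevant parent was under 21 at the birth.

    Uses both parental ages when available; for individuals flagged as
    living with a lone parent (``lives_with`` is "mother" or "father"), only
    the co-resident parent's age counts.  Missing when no relevant age is
    recorded.
    """
    mother = pd.to_numeric(records.get("mother_age"), errors="coerce")
    father = pd.to_numeric(records.get("father_age"), errors="coerce")
    lives = records.get("lives_with")
    out = np.full(len(records), np.nan)
    for i in range(len(records)):
        ages = []
        lw = None if lives is None else lives.iloc[i]
        if lw == "mother":
            ages = [mother.iloc[i]]
        elif lw == "father":
            ages = [father.iloc[i]]
        else:
            ages = [mother.iloc[i], father.iloc[i]]
        ages = [a for a in ages if pd.notna(a)]
        if ages:
            out[i] = float(min(ages) < 21)
    return pd.Series(out, index=records.index)


def lone_parent_flag(records: pd.DataFrame) -> pd.Series:
    """1 iff exactly one parent shared the individual's region at birth.

    Missing when the individual lived with neither parent or when the region
    information needed for the comparison is absent.
    """
    child = records["birth_region"]
    mother = records.get("mother_region")
    father = records.get("father_region")
    out = np.full(len(records), np.nan)
    for i in range(len(records)):
        c = child.iloc[i]
        m = None if mother is None else mother.iloc[i]
        f = None if father is None else father.iloc[i]
        if pd.isna(c) or pd.isna(m) or pd.isna(f):
            continue
        with_m = m == c
        with_f = f == c
        if not with_m and not with_f:
            continue                       # lived with neither parent: excluded
        out[i] = float(with_m != with_f)
    return pd.Series(out, index=records.index)


def urban_flag(birth_region: pd.Series,
               urban_regions: frozenset[str] = URBAN_REGIONS) -> pd.Series:
    """1 iff the birth region is one of the four large cities."""
    out = np.full(len(birth_region), np.nan)
    for i, r in enumerate(birth_region):
        if pd.isna(r):
            continue
        out[i] = float(r in urban_regions)
    return pd.Series(out, index=birth_region.index)


def population_density(records: pd.DataFrame,
                       density_table: pd.DataFrame) -> pd.Series:
    """Individuals per square kilometre for (birth region, birth year)."""
    req = {"region", "year", "density"}
    if not req.issubset(density_table.columns):
        raise ValueError(f"density table must have columns {sorted(req)}")
    tab = density_table.set_index(["region", "year"])["density"]
    out = np.full(len(records), np.nan)
    for i, (r, y) in enumerate(zip(records["birth_region"], records["birth_year"])):
        if pd.isna(r) or pd.isna(y):
            continue
        key = (r, int(y))
        if key in tab.index:
            out[i] = float(tab.loc[key])
    return pd.Series(out, index=records.index)


def brs_score(likert: pd.DataFrame, *, min_responses: int = 5,
              reverse_items: list[str] | None = None,
              n_estimators: int = 500, standardize_output: bool = False,
              seed: int = 0) -> pd.Series:
    """Brief-resilience-scale score: first unrotated PC of six Likert items.

    Individuals answering fewer than ``min_responses`` of the six items are
    dropped; remaining missing cells are imputed by iterative chained
    imputation with a random-forest regressor (``n_estimators`` trees,
    mirroring a 500-tree forest imputer).  The first principal component is
    oriented so that higher scores mean higher mean item response.  Raw PC
    scores are returned by default; pass ``standardize_output=True`` for
    unit-variance scores.
    """
    items = likert.copy()
    if reverse_items:
        for col in reverse_items:
            items[col] = 6 - items[col]
    n_items = items.shape[1]
    answered = items.notna().sum(axis=1)
    kept = items.loc[answered >= min_responses]
    if kept.empty:
        raise ValueError("no individuals with enough responses")
    X = kept.to_numpy(dtype=float)
    if np.any(np.isnan(X)):
        from sklearn.ensemble import RandomForestRegressor
        from sklearn.experimental import enable_iterative_imputer  # noqa: F401
        from sklearn.impute import IterativeImputer
        imputer = IterativeImputer(
            estimator=RandomForestRegressor(n_estimators=n_estimators,
                                            random_state=seed),
            random_state=seed, max_iter=10, sample_posterior=False)
        X = imputer.fit_transform(X)
    centered = X - X.mean(axis=0)
    if np.allclose(centered.std(axis=0), 0.0):
        raise ValueError("zero item variance: cannot extract a component")
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    pc1 = centered @ vt[0]
    row_mean = X.mean(axis=1)
    if np.corrcoef(pc1, row_mean)[0, 1] < 0:
        pc1 = -pc1
    if standardize_output:
        pc1 = (pc1 - pc1.mean()) / pc1.std()
    return pd.Series(pc1, index=kept.index, name="brs")


def standardize(values: pd.Series) -> pd.Series:
    """Centre and scale to mean 0, SD 1 (population SD) over non-missing entries."""
    v = pd.to_numeric(values, errors="coerce")
    obs = v.dropna()
    if len(obs) < 2:
        raise ValueError("need at least two non-missing values")
    sd = float(obs.std(ddof=0))
    if sd == 0:
        raise ValueError("zero variance: cannot standardize a constant")
    return (v - float(obs.mean())) / sd


def build_phenotype_table(records: pd.DataFrame, *, centile_table=None,
                          density_table=None) -> pd.DataFrame:
    """Convenience wrapper: construct every available early-life phenotype."""
    out = pd.DataFrame(index=records.index)
    if "gestation_weeks" in records:
        out["preterm"] = preterm_flag(records["gestation_weeks"])
    if centile_table is not None and "birth_weight_g" in records:
        out["low_birth_weight"] = low_birth_weight_flag(records, centile_table)
    if "birth_month" in records:
        out["birth_month"] = birth_month_flag(records["birth_month"])
    if "birth_doy" in records:
        out["birth_date_score"] = birth_date_score(records["birth_doy"])
    if "mother_age" in records or "father_age" in records:
        out["young_parent"] = young_parent_flag(records)
    if "birth_region" in records:
        if "mother_region" in records and "father_region" in records:
            out["lone_parent"] = lone_parent_flag(records)
        out["urban"] = urban_flag(records["birth_region"])
        if density_table is not None and "birth_year" in records:
            out["population_density"] = population_density(records, density_table)
    return out
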