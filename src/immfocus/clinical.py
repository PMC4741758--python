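"""Association of expression-stratified patient groups with clinical covariates.

Patients in the bottom and top expression tertiles of a gene are compared
on pathological stage (I+II vs III+IV, 2x2 chi-square with Yates
continuity correction), age (two-sample pooled-variance t-test) and gender
(2x2 Yates chi-square).  Stage p-values can be Bonferroni-adjusted; a
``legacy_rounding`` mode rounds the raw p to 4 decimal places before
multiplying, matching the convention of published per-gene stage tables,
and is off by default for new analyses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .survival import stratify_by_tertiles

EARLY_STAGES = ("I", "II")
LATE_STAGES = ("III", "IV")


def adjust_p(p_raw: float, n_tests: int, legacy_rounding: bool = False) -> float:
    """Bonferroni adjustment, optionally rounding the raw p to 4 decimals first."""
    p = round(p_raw, 4) if legacy_rounding else p_raw
    return min(p * n_tests, 1.0)


@dataclass
class StageAssociation:
    chi_square: float
    p_raw: float
    p_adjusted: float
    counts: np.ndarray    # rows: low/high tertile; cols: stage I+II / III+IV
    flagged: bool = False


def yates_chi2_2x2(counts) -> tuple[float, float]:
    """Pearson chi-square on a 2x2 table with Yates continuity correction.

    Returns (nan, nan) when a margin is empty (test undefined).
    """
    table = np.asarray(counts, dtype=float)
    if table.shape != (2, 2):
        raise ValueError("expected a 2x2 table")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        return float("nan"), float("nan")
    chi2, p, _, _ = sps.chi2_contingency(table, correction=True)
    return float(chi2), float(p)


def stage_association_from_counts(counts, n_tests: int = 1,
                                  legacy_rounding: bool = False
                                  ) -> StageAssociation:
    """Stage test directly from a (low, high) x (I+II, III+IV) count table."""
    table = np.asarray(counts, dtype=float)
    chi2, p = yates_chi2_2x2(table)
    if np.isnan(p):
        return StageAssociation(chi2, p, float("nan"), table, flagged=True)
    return StageAssociation(chi2, p, adjust_p(p, n_tests, legacy_rounding), table)


def stage_association(values: pd.Series, clin: pd.DataFrame,
                      n_tests: int = 1, legacy_rounding: bool = False
                      ) -> StageAssociation:
    """Stage I+II vs III+IV distribution across expression tertiles.

    Samples with unknown stage are dropped per-test (never imputed).
    """
    low, high = stratify_by_tertiles(values)
    counts = np.zeros((2, 2))
    for i, ids in enumerate((low, high)):
        stages = clin.loc[ids, "stage"]
        counts[i, 0] = stages.isin(EARLY_STAGES).sum()
        counts[i, 1] = stages.isin(LATE_STAGES).sum()
    return stage_association_from_counts(counts, n_tests, legacy_rounding)


@dataclass
class CovariateAssociation:
    statistic: float
    p: float
    flagged: bool = False


def age_association(values: pd.Series, clin: pd.DataFrame) -> CovariateAssociation:
    """Two-sided pooled-variance t-test on ages of the low vs high tertile."""
    low, high = stratify_by_tertiles(values)
    a = clin.loc[low, "age"].dropna().to_numpy(dtype=float)
    b = clin.loc[high, "age"].dropna().to_numpy(dtype=float)
    if a.size < 2 or b.size < 2:
        return CovariateAssociation(float("nan"), float("nan"), flagged=True)
    if np.var(a, ddof=1) == 0 and np.var(b, ddof=1) == 0:
        if a.mean() == b.mean():
            return CovariateAssociation(0.0, 1.0)
        return CovariateAssociation(float("nan"), float("nan"), flagged=True)
    t, p = sps.ttest_ind(a, b, equal_var=True)
    return CovariateAssociation(float(t), float(p))


def gender_association(values: pd.Series, clin: pd.DataFrame) -> CovariateAssociation:
    """Yates 2x2 chi-square on the gender split of the low vs high tertile."""
    low, high = stratify_by_tertiles(values)
    counts = np.zeros((2, 2))
    for i, ids in enumerate((low, high)):
        genders = clin.loc[ids, "gender"]
        counts[i, 0] = (genders == "male").sum()
        counts[i, 1] = (genders == "female").sum()
    chi2, p = yates_chi2_2x2(counts)
    return CovariateAssociation(chi2, p, flagged=bool(np.isnan(p)))


def associate_genes(raw: pd.DataFrame, norm: pd.DataFrame, clin: pd.DataFrame,
                    genes, use: str = "normalized", n_tests: int | str = "auto",
                    legacy_rounding: bool = False) -> pd.DataFrame:
    """Stage/age/gender association report for a list of genes.

    Stratification uses the normalized matrix by default (``use="raw"``
    switches).  Returns one row per gene mirroring a per-gene stage table:
    the four contingency counts, the chi-square, and raw/adjusted p-values,
    plus age and gender test p-values.
    """
    genes = list(genes)
    matrix = norm if use == "normalized" else raw
    if n_tests == "auto":
        n_tests = len(genes)
    rows = []
    for g in genes:
        values = matrix.loc[g]
        st = stage_association(values, clin, n_tests=n_tests,
                               legacy_rounding=legacy_rounding)
        age = age_association(values, clin)
        gender = gender_association(values, clin)
        rows.append({
            "gene": g,
            "low_stage12": int(st.counts[0, 0]), "low_stage34": int(st.counts[0, 1]),
            "high_stage12": int(st.counts[1, 0]), "high_stage34": int(st.counts[1, 1]),
            "stage_chi2": st.chi_square, "stage_p": st.p_raw,
            "stage_p_adjusted": st.p_adjusted,
            "age_t": age.statistic, "age_p": age.p,
            "gender_chi2": gender.statistic, "gender_p": gender.p,
        })
    return pd.DataFrame(rows).set_index("gene")
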