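"""Coefficient-of-variation ratio (CVR) analysis and gene-group selection.

For each gene the CV (sample standard deviation over mean, across samples)
is computed on the raw and on the normalized matrix; their ratio
CVR = CV_norm / CV_raw quantifies how much the normalization reduced
(CVR < 1) or inflated (CVR > 1) the gene's apparent variability.  Three
equally sized gene groups are then drawn: the lowest-CVR genes (most
responsive to normalization), the highest-CVR genes, and a seeded random
sample taken regardless of CVR.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

DEFAULT_GROUP_SIZE = 500


def coefficient_of_variation(values) -> float:
    """Sample CV: standard deviation (n-1 denominator) divided by the mean.

    Undefined (NaN) when the mean is not strictly positive; requires at
    least two values.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("CV requires at least 2 values")
    m = v.mean()
    if m <= 0:
        return float("nan")
    return float(v.std(ddof=1) / m)


def compute_cvr_table(raw: pd.DataFrame, normalized: pd.DataFrame) -> pd.DataFrame:
    """Per-gene CV before/after normalization and their ratio.

    Returns a frame with columns ``cv_raw``, ``cv_norm``, ``cvr`` and
    ``excluded``; genes with nonpositive mean or zero raw variance are
    flagged excluded and carry no CVR.
    """
    if not raw.index.equals(normalized.index) or not raw.columns.equals(normalized.columns):
        raise ValueError("raw and normalized matrices must share genes and samples")
    if raw.shape[1] < 2:
        raise ValueError("need at least 2 samples to compute CV")
    R = raw.to_numpy(dtype=float)
    N = normalized.to_numpy(dtype=float)
    mr, mn = R.mean(axis=1), N.mean(axis=1)
    sr = R.std(axis=1, ddof=1)
    sn = N.std(axis=1, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        cv_raw = np.where(mr > 0, sr / mr, np.nan)
        cv_norm = np.where(mn > 0, sn / mn, np.nan)
        cvr = np.where((cv_raw > 0) & np.isfinite(cv_norm), cv_norm / cv_raw, np.nan)
    excluded = ~np.isfinite(cvr)
    return pd.DataFrame(
        {"cv_raw": cv_raw, "cv_norm": cv_norm, "cvr": cvr, "excluded": excluded},
        index=raw.index)


@dataclass
class GeneGroups:
    """The three CVR-defined gene groups used to evaluate normalization."""

    cvr_low: list[str]
    cvr_high: list[str]
    cvr_random: list[str]
    seed: int
    group_size: int = DEFAULT_GROUP_SIZE

    def as_dict(self) -> dict[str, list[str]]:
        return {"cvr_low": self.cvr_low, "cvr_high": self.cvr_high,
                "cvr_random": self.cvr_random}

    def union(self) -> list[str]:
        out: dict[str, None] = {}
        for genes in self.as_dict().values():
            for g in genes:
                out[g] = None
        return list(out)


def select_cvr_groups(table: pd.DataFrame, group_size: int = DEFAULT_GROUP_SIZE,
                      seed: int = 0) -> GeneGroups:
    """Pick the lowest-, highest-, and randomly-CVR'd gene groups.

    Ranking is by (cvr, gene id) for reproducible tie-breaks; the random
    group is a seeded uniform sample without replacement from all rankable
    genes, regardless of CVR, and may overlap the other two.
    """
    rankable = table.loc[~table["excluded"]]
    if len(rankable) < group_size:
        raise ValueError(
            f"only {len(rankable)} rankable genes; need {group_size}")
    order = (rankable.assign(_gene=rankable.index.astype(str))
             .sort_values(["cvr", "_gene"], kind="mergesort"))
    ranked = order.index.to_list()
    low = ranked[:group_size]
    high = ranked[-group_size:]
    rng = np.random.default_rng(seed)
    random = list(rng.choice(rankable.index.to_numpy(), size=group_size,
                             replace=False))
    return GeneGroups(cvr_low=low, cvr_high=high, cvr_random=random,
                      seed=seed, group_size=group_size)


def compare_group_cvr(groups: GeneGroups, table: pd.DataFrame) -> dict:
    """Mean +/- sd of CVR per group and pairwise two-sample t-test p-values.

    Degenerate comparisons (zero variance in both groups) are reported with
    a NaN p-value and flagged.
    """
    summary = {}
    values = {}
    for name, genes in groups.as_dict().items():
        missing = [g for g in genes if g not in table.index]
        if missing:
            raise KeyError(f"group {name} contains genes absent from the "
                           f"CVR table: {missing[:5]}")
        v = table.loc[genes, "cvr"].to_numpy(dtype=float)
        values[name] = v
        summary[name] = {"mean": float(np.mean(v)), "sd": float(np.std(v, ddof=1)),
                         "n": int(v.size)}
    pairwise = {}
    for a, b in combinations(values, 2):
        va, vb = values[a], values[b]
        degenerate = va.std(ddof=1) == 0 and vb.std(ddof=1) == 0
        if degenerate and np.mean(va) == np.mean(vb):
            t, p = 0.0, 1.0
        elif degenerate:
            t, p = float("nan"), float("nan")
        else:
            t, p = sps.ttest_ind(va, vb)
        pairwise[(a, b)] = {"t": float(t), "p": float(p),
                            "degenerate": bool(degenerate)}
    return {"groups": summary, "pairwise": pairwise}
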