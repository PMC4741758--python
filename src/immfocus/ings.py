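"""Derivation of the immune-normalizing gene set (INGS).

The INGS is derived empirically from the cohort itself, anchored on a
pan-leukocyte marker gene (PTPRC/CD45 by default):

1. every gene is correlated (Pearson, across samples) with the anchor;
2. a provisional set keeps genes with r^2 strictly above a threshold
   (default 0.5), by default additionally requiring r > 0 so that the set
   tracks — rather than anti-tracks — immune content;
3. each provisional gene is normalized by its leave-one-out factor built
   from the provisional set, its CV ratio (CV after / CV before) is
   computed, and genes with CVR above a threshold (default 0.8) are
   dropped in a single pass, yielding the final INGS.

The mean expression of the final INGS genes in a sample is the per-sample
immune normalization factor, a proxy for the immune-cell fraction of the
biopsy.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cvr import coefficient_of_variation

DEFAULT_ANCHOR = "PTPRC"
DEFAULT_R2_THRESHOLD = 0.5
DEFAULT_CVR_THRESHOLD = 0.8


@dataclass
class INGS:
    """An immune-normalizing gene set with its derivation provenance."""

    genes: list[str]
    anchor: str = DEFAULT_ANCHOR
    r2_threshold: float = DEFAULT_R2_THRESHOLD
    cvr_threshold: float = DEFAULT_CVR_THRESHOLD
    per_gene_stats: dict[str, dict[str, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.genes = sorted(self.genes)

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, gene: str) -> bool:
        return gene in set(self.genes)

    def to_json(self, path: str | os.PathLike) -> None:
        payload = {
            "anchor": self.anchor,
            "r2_threshold": self.r2_threshold,
            "cvr_threshold": self.cvr_threshold,
            "genes": self.genes,
            "per_gene_stats": self.per_gene_stats,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path: str | os.PathLike) -> "INGS":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(**payload)


def correlate_with_anchor(expr: pd.DataFrame, anchor: str = DEFAULT_ANCHOR
                          ) -> pd.DataFrame:
    """Pearson correlation of every gene with the anchor gene.

    Returns a frame indexed by gene with columns ``r`` and ``r2``.
    Zero-variance genes have undefined correlation and are excluded.
    """
    if anchor not in expr.index:
        raise KeyError(f"anchor gene {anchor!r} not present in expression matrix")
    if expr.shape[1] < 3:
        raise ValueError("need at least 3 samples to correlate with the anchor")
    X = expr.to_numpy(dtype=float)
    a = expr.loc[anchor].to_numpy(dtype=float)
    a_c = a - a.mean()
    a_ss = float(a_c @ a_c)
    if a_ss == 0.0:
        raise ValueError(f"anchor gene {anchor!r} has zero variance")
    Xc = X - X.mean(axis=1, keepdims=True)
    ss = np.einsum("ij,ij->i", Xc, Xc)
    defined = ss > 0
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (Xc @ a_c) / np.sqrt(ss * a_ss)
    r = np.clip(r, -1.0, 1.0)
    out = pd.DataFrame({"r": r, "r2": r * r}, index=expr.index)
    return out.loc[defined]


def build_provisional_ings(correlations: pd.DataFrame,
                           r2_threshold: float = DEFAULT_R2_THRESHOLD,
                           require_positive: bool = True) -> list[str]:
    """Genes whose squared anchor correlation is strictly above threshold.

    With ``require_positive`` (default), only positively correlated genes
    qualify — a factor averaging anti-correlated genes would not track
    immune content.  The anchor itself always qualifies (r = 1).
    """
    if correlations.empty:
        raise ValueError("empty correlation table")
    keep = correlations["r2"] > r2_threshold
    if require_positive:
        keep &= correlations["r"] > 0
    genes = sorted(correlations.index[keep])
    if len(genes) < 2:
        raise ValueError(
            f"provisional INGS has {len(genes)} gene(s); need at least 2 "
            "for a leave-one-out normalization factor")
    return genes


def _loo_cvr(expr: pd.DataFrame, members: list[str]) -> pd.Series:
    """CVR of each member gene under leave-one-out normalization.

    For member i the factor is the per-sample mean of the other members;
    CVR_i = CV(x_i / f_loo_i) / CV(x_i).
    """
    X = expr.loc[members].to_numpy(dtype=float)
    k = len(members)
    total = X.sum(axis=0)
    cvr = np.empty(k)
    for i in range(k):
        loo = (total - X[i]) / (k - 1)
        if (loo <= 0).any():
            cvr[i] = np.inf
            continue
        raw_cv = coefficient_of_variation(X[i])
        norm_cv = coefficient_of_variation(X[i] / loo)
        cvr[i] = norm_cv / raw_cv if raw_cv > 0 else np.inf
    return pd.Series(cvr, index=members)


def refine_ings(expr: pd.DataFrame, provisional: list[str],
                cvr_threshold: float = DEFAULT_CVR_THRESHOLD,
                anchor: str = DEFAULT_ANCHOR,
                correlations: pd.DataFrame | None = None,
                r2_threshold: float = DEFAULT_R2_THRESHOLD,
                iterate: bool = False) -> INGS:
    """Drop provisional genes whose CV ratio exceeds the threshold.

    A single pass by default: leave-one-out factors are built from the
    provisional set, each gene's CVR is computed, and genes with
    CVR > ``cvr_threshold`` are omitted.  ``iterate=True`` repeats the
    pass on the surviving set until a fixpoint (off by default).
    """
    if len(provisional) < 2:
        raise ValueError("provisional INGS must have at least 2 genes")
    missing = [g for g in provisional if g not in expr.index]
    if missing:
        raise KeyError(f"provisional genes absent from matrix: {missing[:5]}")

    members = sorted(provisional)
    while True:
        cvr = _loo_cvr(expr, members)
        survivors = sorted(cvr.index[cvr <= cvr_threshold])
        if not survivors:
            raise ValueError("CVR refinement removed every provisional gene")
        if not iterate or survivors == members:
            members = survivors
            break
        members = survivors

    stats: dict[str, dict[str, float]] = {}
    for g in members:
        entry = {"cvr": float(cvr[g])}
        if correlations is not None and g in correlations.index:
            entry["r"] = float(correlations.loc[g, "r"])
            entry["r2"] = float(correlations.loc[g, "r2"])
        stats[g] = entry
    return INGS(genes=members, anchor=anchor, r2_threshold=r2_threshold,
                cvr_threshold=cvr_threshold, per_gene_stats=stats)


def derive_ings(expr: pd.DataFrame, anchor: str = DEFAULT_ANCHOR,
                r2_threshold: float = DEFAULT_R2_THRESHOLD,
                cvr_threshold: float = DEFAULT_CVR_THRESHOLD,
                require_positive: bool = True,
                iterate: bool = False) -> INGS:
    """Full derivation: anchor correlation -> provisional set -> refinement."""
    correlations = correlate_with_anchor(expr, anchor)
    provisional = build_provisional_ings(correlations, r2_threshold,
                                         require_positive)
    return refine_ings(expr, provisional, cvr_threshold, anchor=anchor,
                       correlations=correlations, r2_threshold=r2_threshold,
                       iterate=iterate)
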