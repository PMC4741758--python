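"""Per-sample immune normalization factors and matrix normalization.

The biopsy-specific factor f for sample s is the arithmetic mean of the
INGS gene abundances in s — a proxy for the immune-cell fraction captured
by that biopsy.  Every non-member gene is divided by f; each INGS member i
is instead divided by its leave-one-out factor (the mean over the other
members), avoiding self-normalization.
"""

from __future__ import annotations

import datetime
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ings import INGS


@dataclass
class NormalizationFactors:
    """Per-sample factors: shared ``f`` plus a leave-one-out row per member.

    The exact identity k*f(s) = (k-1)*loo(i,s) + expr(i,s) holds for every
    member i, where k is the INGS size.
    """

    f: pd.Series                 # index: sample ids
    loo: pd.DataFrame            # index: INGS genes, columns: sample ids

    @property
    def sample_ids(self) -> list[str]:
        return list(self.f.index)


def compute_factors(expr: pd.DataFrame, ings: INGS,
                    mean: str = "arithmetic") -> NormalizationFactors:
    """Compute f and the leave-one-out factors from the final INGS.

    ``mean="geometric"`` is available for robustness experiments; the
    default (and the factor definition used everywhere else) is the
    arithmetic mean.
    """
    missing = [g for g in ings.genes if g not in expr.index]
    if missing:
        raise KeyError(f"INGS genes absent from matrix: {missing[:5]}")
    X = expr.loc[ings.genes].to_numpy(dtype=float)
    k = len(ings.genes)
    if mean == "arithmetic":
        f = X.mean(axis=0)
        loo = (X.sum(axis=0, keepdims=True) - X) / (k - 1)
    elif mean == "geometric":
        if (X <= 0).any():
            raise ValueError("geometric mean requires strictly positive values")
        L = np.log(X)
        f = np.exp(L.mean(axis=0))
        loo = np.exp((L.sum(axis=0, keepdims=True) - L) / (k - 1))
    else:
        raise ValueError(f"unknown mean {mean!r}")
    if (f <= 0).any():
        bad = expr.columns[np.asarray(f) <= 0][0]
        raise ValueError(
            f"normalization factor is zero for sample {bad!r} "
            "(all INGS genes zero)")
    if (loo <= 0).any():
        g, s = np.argwhere(loo <= 0)[0]
        raise ValueError(
            f"leave-one-out factor is zero for gene {ings.genes[g]!r}, "
            f"sample {expr.columns[s]!r}")
    return NormalizationFactors(
        f=pd.Series(f, index=expr.columns, name="f_ings"),
        loo=pd.DataFrame(loo, index=ings.genes, columns=expr.columns))


def normalize(expr: pd.DataFrame, ings: INGS,
              mean: str = "arithmetic") -> pd.DataFrame:
    """Divide every gene by its per-sample immune normalization factor.

    Non-member genes are divided by f; INGS members by their leave-one-out
    factor.  Zero raw values stay zero — the operation is a pure ratio, no
    pseudocounts are added.
    """
    factors = compute_factors(expr, ings, mean=mean)
    out = expr.div(factors.f, axis=1)
    out.loc[ings.genes] = expr.loc[ings.genes] / factors.loo
    out.attrs = dict(expr.attrs)
    out.attrs["normalization"] = {
        "anchor": ings.anchor,
        "r2_threshold": ings.r2_threshold,
        "cvr_threshold": ings.cvr_threshold,
        "n_ings_genes": len(ings),
        "mean": mean,
        "timestamp": datetime.datetime.now().isoformat(timespec="seconds"),
    }
    return out
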