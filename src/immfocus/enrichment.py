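"""Annotation enrichment of gene groups.

Tests whether gene groups (e.g. the CVR-defined groups) differ in their
fraction of members carrying a user-supplied annotation such as
"immune-related".  Annotation lists are plain-text files, one gene symbol
per line, with ``#`` comments; matching is by canonical (uppercased)
symbol only — no identifier-mapping service is involved.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

logger = logging.getLogger(__name__)


def canonical_symbol(symbol: str) -> str:
    return str(symbol).strip().upper()


@dataclass
class AnnotationSet:
    """A named set of annotated gene symbols."""

    name: str
    genes: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        self.genes = {canonical_symbol(g) for g in self.genes if str(g).strip()}
        if not self.genes:
            raise ValueError(f"annotation set {self.name!r} is empty")

    def __contains__(self, gene: str) -> bool:
        return canonical_symbol(gene) in self.genes

    def __len__(self) -> int:
        return len(self.genes)

    @classmethod
    def from_file(cls, path: str | os.PathLike, name: str | None = None
                  ) -> "AnnotationSet":
        genes = set()
        with open(path) as fh:
            for line in fh:
                line = line.split("#", 1)[0].strip()
                if line:
                    genes.add(line)
        return cls(name=name or os.path.splitext(os.path.basename(path))[0],
                   genes=genes)


def annotate_group(group, annotation: AnnotationSet) -> tuple[int, int]:
    """(number of group members in the annotation, group size)."""
    members = [canonical_symbol(g) for g in group]
    annotated = sum(1 for g in members if g in annotation.genes)
    return annotated, len(members)


def enrichment_test(groups: list[tuple[int, int]]) -> tuple[float, float]:
    """Pearson chi-square on a k x 2 annotated/not-annotated table.

    ``groups`` is a list of (annotated, total) pairs.  No continuity
    correction.  Returns (nan, nan) with a warning when an expected count
    is zero (test undefined).
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    table = np.array([[a, t - a] for a, t in groups], dtype=float)
    if (table < 0).any():
        raise ValueError("annotated count exceeds group total")
    if (table.sum(axis=1) <= 0).any():
        raise ValueError("every group must be nonempty")
    expected = sps.contingency.expected_freq(table)
    if (expected == 0).any():
        logger.warning("enrichment test undefined: zero expected count")
        return float("nan"), float("nan")
    chi2, p, _, _ = sps.chi2_contingency(table, correction=False)
    return float(chi2), float(p)
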