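"""Validation of H against the injury index, and tolerance grouping.

A sound composite tolerance value must anticorrelate with the directly
observed heat injury index: genotypes scoring high H should show little
visual damage.  The check is a Pearson correlation with its two-sided
t-test; a non-negative correlation sets ``direction_ok = False`` and is
surfaced as a prominent warning, not a pipeline failure.

Genotypes are then partitioned into tolerance groups by agglomerative
clustering of the one-dimensional H values (squared Euclidean distance,
average linkage), cutting the dendrogram at ``n_groups`` clusters and
labelling groups I, II, ... in order of decreasing group-mean H, so Group
I is always the strongly resistant set.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
import scipy.stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist

from .errors import DomainError


@dataclass(frozen=True)
class ValidationResult:
    pearson_r: float
    p_value: float
    n: int
    direction_ok: bool  # True iff r < 0 (H anticorrelates with injury)


def correlate_with_injury(h: pd.Series, hii: pd.Series) -> ValidationResult:
    """Pearson correlation of H with HII over the shared genotypes."""
    shared = h.index.intersection(hii.index)
    if len(shared) < 3:
        raise DomainError(f"need at least 3 shared genotypes, got {len(shared)}")
    x = h.loc[shared].to_numpy(dtype=float)
    y = hii.loc[shared].to_numpy(dtype=float)
    if x.std() == 0 or y.std() == 0:
        raise DomainError("zero variance in H or HII; correlation undefined")
    r, p = scipy.stats.pearsonr(x, y)
    return ValidationResult(
        pearson_r=float(r), p_value=float(p), n=len(shared), direction_ok=bool(r < 0)
    )


def roman(n: int) -> str:
    """Roman numeral for small positive group numbers."""
    numerals = (
        (10, "X"), (9, "IX"), (5, "V"), (4, "IV"), (1, "I"),
    )
    if n < 1:
        raise ValueError("group numbers start at 1")
    out = []
    for value, sym in numerals:
        while n >= value:
            out.append(sym)
            n -= value
    return "".join(out)


@dataclass(frozen=True)
class GroupAssignment:
    """Tolerance groups, numbered 1..k by descending group-mean H."""

    groups: pd.Series            # genotype -> group number (1 = most tolerant)
    linkage_matrix: Optional[np.ndarray]  # merge record; None for trivial cuts

    def labels(self) -> pd.Series:
        """Roman-numeral rendering ("I" = strongly resistant)."""
        return self.groups.map(lambda g: roman(int(g))).rename("group")


def cluster_tolerance(h: pd.Series, n_groups: int) -> GroupAssignment:
    """Cut an average-linkage dendrogram of 1-D H values into n_groups.

    Distances are squared Euclidean on the scalar H.  Group numbers are
    reassigned by descending mean H, so group 1 collects the most tolerant
    genotypes.
    """
    n = len(h)
    if n_groups < 1:
        raise DomainError("n_groups must be positive")
    if n_groups > n:
        raise DomainError(f"cannot form {n_groups} groups from {n} genotypes")
    if n_groups == n:
        raw = np.arange(1, n + 1)
        lk = None
    else:
        d = pdist(h.to_numpy(dtype=float)[:, None], metric="sqeuclidean")
        lk = linkage(d, method="average")
        raw = fcluster(lk, t=n_groups, criterion="maxclust")
    raw = pd.Series(raw, index=h.index)
    order = h.groupby(raw).mean().sort_values(ascending=False).index
    remap = {old: new for new, old in enumerate(order, start=1)}
    return GroupAssignment(groups=raw.map(remap).rename("group"), linkage_matrix=lk)
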