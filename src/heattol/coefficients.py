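"""Heat-resistance coefficients: stress/control ratios per genotype × index.

The coefficient h of an index is the ratio of its replicate mean under
heat stress to its replicate mean under control, h = HS / CK.  It is a
dimensionless number stored on the ratio scale (1.0 = unchanged by
stress); reports may render it as a percentage.  Because each index is
z-scored before the PCA, the ratio-vs-percent choice cannot change any
downstream score.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import DomainError, MissingIndexError
from .io import AggregatedPheno


@dataclass(frozen=True)
class CoefficientMatrix:
    """Genotype × index matrix of heat-resistance coefficients h."""

    h: pd.DataFrame  # rows: genotypes, columns: indices

    def __post_init__(self):
        df = self.h
        if df.index.has_duplicates or df.columns.has_duplicates:
            raise DomainError("coefficient matrix labels must be unique")
        arr = df.to_numpy(dtype=float)
        if not np.all(np.isfinite(arr)) or np.any(arr < 0):
            raise DomainError("coefficients must be finite and non-negative")
        object.__setattr__(self, "h", df.astype(float))

    @property
    def genotypes(self) -> list[str]:
        return list(self.h.index)

    @property
    def indices(self) -> list[str]:
        return list(self.h.columns)

    def to_csv(self, path) -> None:
        self.h.to_csv(path, index_label="genotype", float_format="%.6f")

    @classmethod
    def from_csv(cls, path) -> "CoefficientMatrix":
        return cls(pd.read_csv(path, index_col="genotype"))


def compute_coefficients(
    agg: AggregatedPheno, index_list: Optional[Sequence[str]] = None
) -> CoefficientMatrix:
    """Form the complete h matrix from aggregated CK/HS means.

    ``index_list`` restricts and orders the columns; every listed index must
    be present for every genotype, and every CK mean must be strictly
    positive (a ratio against zero control is undefined).
    """
    means = agg.means
    available = list(means.index.get_level_values("index").unique())
    if index_list is None:
        index_list = available
    else:
        absent = [ix for ix in index_list if ix not in available]
        if absent:
            raise MissingIndexError(f"indices {absent} not present in the data")

    ck, hs = means["CK"], means["HS"]
    nonpos = ck[(ck <= 0) & ck.index.get_level_values("index").isin(index_list)]
    if len(nonpos):
        genotype, index = nonpos.index[0]
        raise DomainError(
            f"genotype {genotype!r}, index {index!r}: CK mean {nonpos.iloc[0]} <= 0, "
            "heat-resistance ratio undefined"
        )
    ratio = (hs / ck).unstack("index")
    genotype_order = list(means.index.get_level_values("genotype").unique())
    return CoefficientMatrix(ratio.reindex(index=genotype_order, columns=list(index_list)))
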