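"""Heat injury index (HII) from graded seedling damage counts.

Seedlings are scored into five visual damage classes after long-term heat
stress: class 0 (no symptoms) through class 4 (more than half of the
cotyledon/true-leaf area dehydrated and yellowing).  The injury index
summarises the per-genotype class counts N0..N4 as

    HII = Σ(i · Ni) / (4 · N) × 100,

a percentage between 0 (whole population undamaged) and 100 (every
seedling maximally damaged).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DomainError, FormatError

N_GRADES = 5
GRADE_COLUMNS = tuple(f"class{i}" for i in range(N_GRADES))


@dataclass(frozen=True)
class InjuryGradeTable:
    """Per-genotype counts of seedlings in damage classes 0–4."""

    counts: pd.DataFrame  # index: genotype; columns: class0..class4

    def __post_init__(self):
        df = self.counts
        missing = [c for c in GRADE_COLUMNS if c not in df.columns]
        if missing:
            raise FormatError(f"injury table is missing columns {missing}")
        df = df.loc[:, list(GRADE_COLUMNS)]
        arr = df.to_numpy()
        if not np.all(np.isfinite(arr)) or np.any(arr < 0) or np.any(arr != np.round(arr)):
            raise FormatError("injury counts must be non-negative integers")
        if df.index.has_duplicates:
            raise FormatError("duplicate genotype in injury table")
        object.__setattr__(self, "counts", df.astype(int))

    @property
    def totals(self) -> pd.Series:
        return self.counts.sum(axis=1)


def read_injury_table(path) -> InjuryGradeTable:
    """Read an injury CSV with header ``genotype,class0,...,class4``."""
    df = pd.read_csv(path, dtype={"genotype": str})
    if "genotype" not in df.columns:
        raise FormatError("injury table is missing the 'genotype' column")
    return InjuryGradeTable(df.set_index("genotype"))


def compute_hii(grades: InjuryGradeTable) -> pd.Series:
    """Heat injury index per genotype, on the 0–100 percentage scale.

    HII = Σ(i·Ni) / (4N) × 100; equals 0 iff all seedlings are class 0 and
    100 iff all are class 4.  A genotype with zero seedlings is an error.
    """
    n = grades.totals
    if (n == 0).any():
        bad = n.index[n == 0][0]
        raise DomainError(f"genotype {bad!r}: no seedlings graded (N = 0)")
    weighted = grades.counts.to_numpy() @ np.arange(N_GRADES)
    hii = pd.Series(weighted / ((N_GRADES - 1) * n.to_numpy()) * 100.0,
                    index=grades.counts.index, name="HII")
    return hii
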