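"""Composite tolerance scoring: correlation-matrix PCA, membership values,
variance-contribution weights and the tolerance value H.

The scoring machinery turns the genotype × index coefficient matrix into a
single number per genotype:

1. each index column is z-scored (mean 0, sd 1 with the n−1 denominator),
   so indices with wildly different units contribute comparably;
2. the principal components of the column correlation matrix are
   extracted; component i's variance proportion is
   Pi = eigenvalue_i / Σ eigenvalues, and enough components are retained
   to reach a cumulative proportion threshold (default 0.80);
3. each genotype's scores on the retained components (the "comprehensive
   indices" CI) are min–max normalised across genotypes into membership
   values Ui = (Xi − Xmin)/(Xmax − Xmin) ∈ [0, 1];
4. retained proportions are normalised into weights Wi = Pi / Σ retained
   Pi, and the tolerance value is the weighted sum H = Σ Ui·Wi ∈ [0, 1].

Because the membership function is not sign-invariant, each retained
component is deterministically oriented: its loading on a configured
anchor index (default chlorophyll-a retention, a benefit trait) is made
non-negative, falling back to making the largest-magnitude loading
positive when the anchor loading is numerically zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .coefficients import CoefficientMatrix
from .errors import (
    DegenerateComponentError,
    DegenerateIndexError,
    DomainError,
)
from .io import AnalysisConfig

_ZERO_LOADING_TOL = 1e-10


def standardize_matrix(cm: CoefficientMatrix) -> pd.DataFrame:
    """Z-score every column of the coefficient matrix (sd with ddof=1).

    Requires at least 3 genotypes and nonzero variance in every column;
    a constant index carries no information and breaks the correlation
    matrix, so it is rejected by name.
    """
    df = cm.h
    if len(df) < 3:
        raise DomainError(f"need at least 3 genotypes to standardize, got {len(df)}")
    sd = df.std(ddof=1)
    # relative floor: a column constant up to rounding is as degenerate as an
    # exactly constant one
    degenerate = sd[sd <= (df.abs().mean() + 1.0) * 1e-12]
    if len(degenerate):
        raise DegenerateIndexError(
            f"index {degenerate.index[0]!r} is constant across genotypes"
        )
    return (df - df.mean()) / sd


@dataclass(frozen=True)
class PCAResult:
    """Eigenstructure of the coefficient correlation matrix.

    ``eigenvalues``/``proportions`` cover ALL components (they sum to the
    number of indices and to 1 respectively); ``loadings`` holds the
    orthonormal, sign-oriented eigenvectors as columns PC1..PCp and
    ``scores`` the genotype scores (comprehensive indices) on the retained
    components only.
    """

    eigenvalues: np.ndarray
    proportions: np.ndarray
    loadings: pd.DataFrame  # rows: indices, columns: PC1..PCp
    scores: pd.DataFrame    # rows: genotypes, columns: PC1..PCm (retained)
    n_retained: int
    cumulative_retained: float

    @property
    def retained_proportions(self) -> np.ndarray:
        return self.proportions[: self.n_retained]


def _orient(vec: np.ndarray, anchor_pos: int | None) -> np.ndarray:
    if anchor_pos is not None and abs(vec[anchor_pos]) > _ZERO_LOADING_TOL:
        return -vec if vec[anchor_pos] < 0 else vec
    j = int(np.argmax(np.abs(vec)))
    return -vec if vec[j] < 0 else vec


def principal_components(z: pd.DataFrame, config: AnalysisConfig | None = None) -> PCAResult:
    """Eigendecomposition of the column correlation matrix of ``z``.

    Components are sorted by descending eigenvalue and sign-oriented (see
    module docstring).  Retention is ``config.n_components_override`` when
    set — an error if it exceeds the matrix rank — otherwise the smallest
    m whose cumulative variance proportion reaches
    ``config.variance_threshold``.
    """
    config = config or AnalysisConfig()
    n, p = z.shape
    if n < 2:
        raise DomainError("PCA needs more than one genotype")
    zz = z.to_numpy(dtype=float)
    corr = zz.T @ zz / (n - 1)
    evals, evecs = np.linalg.eigh(corr)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order]
    proportions = evals / evals.sum()

    rank = int(np.sum(evals > evals[0] * 1e-10))
    if config.n_components_override is not None:
        m = config.n_components_override
        if m > rank:
            raise DomainError(
                f"requested {m} components but the correlation matrix has rank {rank}"
            )
    else:
        m = int(np.searchsorted(np.cumsum(proportions), config.variance_threshold - 1e-12) + 1)
        m = min(m, p)

    anchor_pos = (
        z.columns.get_loc(config.anchor_index) if config.anchor_index in z.columns else None
    )
    oriented = np.column_stack([_orient(evecs[:, k], anchor_pos) for k in range(p)])
    pc_labels = [f"PC{k + 1}" for k in range(p)]
    loadings = pd.DataFrame(oriented, index=z.columns, columns=pc_labels)
    scores = pd.DataFrame(
        zz @ oriented[:, :m], index=z.index, columns=pc_labels[:m]
    )
    return PCAResult(
        eigenvalues=evals,
        proportions=proportions,
        loadings=loadings,
        scores=scores,
        n_retained=m,
        cumulative_retained=float(np.cumsum(proportions)[m - 1]),
    )


def membership_values(scores: pd.DataFrame) -> pd.DataFrame:
    """Min–max normalise each component's scores across genotypes.

    Ui = (Xi − Xmin)/(Xmax − Xmin); per component the minimum maps to 0 and
    the maximum to 1.  Exact ties share the endpoint values.  A component
    with Xmax == Xmin is degenerate and rejected.
    """
    lo, hi = scores.min(), scores.max()
    flat = hi[hi == lo]
    if len(flat):
        raise DegenerateComponentError(
            f"component {flat.index[0]!r} has identical scores for all genotypes"
        )
    return (scores - lo) / (hi - lo)


def component_weights(pca: PCAResult) -> pd.Series:
    """Wi = Pi / Σ(retained Pi); non-negative and summing to 1."""
    if pca.n_retained < 1:
        raise DomainError("no retained components")
    p = pca.retained_proportions
    return pd.Series(p / p.sum(), index=list(pca.scores.columns), name="W")


@dataclass(frozen=True)
class ToleranceScores:
    """Per-genotype memberships, component weights and composite value H."""

    memberships: pd.DataFrame  # rows: genotypes, columns: retained components
    weights: pd.Series
    h: pd.Series  # composite tolerance value per genotype, in [0, 1]


def tolerance_values(memberships: pd.DataFrame, weights: pd.Series) -> ToleranceScores:
    """H = Σ Ui·Wi per genotype.

    H lies in [0, 1]; a genotype attaining the per-component maximum on
    every retained component scores exactly 1.
    """
    if list(memberships.columns) != list(weights.index):
        raise DomainError("membership columns and weight labels do not agree")
    h = memberships.to_numpy() @ weights.to_numpy()
    return ToleranceScores(
        memberships=memberships,
        weights=weights,
        h=pd.Series(h, index=memberships.index, name="H"),
    )


def score_matrix(
    cm: CoefficientMatrix, config: AnalysisConfig | None = None
) -> tuple[PCAResult, ToleranceScores]:
    """Convenience: coefficient matrix → (PCA result, tolerance scores)."""
    config = config or AnalysisConfig()
    z = standardize_matrix(cm)
    pca = principal_components(z, config)
    u = membership_values(pca.scores)
    w = component_weights(pca)
    return pca, tolerance_values(u, w)
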