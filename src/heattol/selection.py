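"""Stepwise selection of a minimal predictive index equation for H.

The composite tolerance value H is regressed on the heat-resistance
coefficients of the candidate indices by classical forward-entry /
backward-removal stepwise ordinary least squares: at each step the
candidate with the smallest partial-F p-value enters if it clears
``alpha_enter``; any included predictor whose partial-F p-value has risen
to ``alpha_remove`` is then dropped; iterate to a fixed point.  The final
equation (e.g. H = b1·Chl a + b2·CAT + intercept) lets new genotypes be
scored from a couple of bench measurements instead of the full panel.

Coefficients are reported on the raw h-ratio scale (with intercept) and,
alongside, as beta-standardised coefficients (per-sd, no intercept).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm

from .coefficients import CoefficientMatrix
from .errors import DomainError, MissingIndexError
from .io import AnalysisConfig

_COLLINEARITY_TOL = 1e-8
# refuse entry steps that would leave fewer than this many residual df
_MIN_RESID_DF = 2


@dataclass
class RegressionModel:
    """Stepwise-selected OLS model of H on index coefficients."""

    selected_indices: list[str]
    coefficients: pd.Series       # raw scale, per selected index
    intercept: float
    r_squared: float
    f_statistic: float
    p_value: float
    n_obs: int
    standardized_coefficients: pd.Series
    alpha_enter: float
    alpha_remove: float
    empty_model: bool = False     # warning flag: nothing met the entry criterion
    skipped_collinear: list[str] = field(default_factory=list)

    def to_json(self, path) -> None:
        payload = {
            "selected_indices": self.selected_indices,
            "coefficients": {k: float(v) for k, v in self.coefficients.items()},
            "intercept": float(self.intercept),
            "r_squared": float(self.r_squared),
            "f_statistic": float(self.f_statistic),
            "p_value": float(self.p_value),
            "n_obs": int(self.n_obs),
            "standardized_coefficients": {
                k: float(v) for k, v in self.standardized_coefficients.items()
            },
            "alpha_enter": self.alpha_enter,
            "alpha_remove": self.alpha_remove,
            "empty_model": self.empty_model,
            "skipped_collinear": self.skipped_collinear,
        }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")

    @classmethod
    def from_json(cls, path) -> "RegressionModel":
        raw = json.loads(Path(path).read_text())
        return cls(
            selected_indices=list(raw["selected_indices"]),
            coefficients=pd.Series(raw["coefficients"], dtype=float),
            intercept=float(raw["intercept"]),
            r_squared=float(raw["r_squared"]),
            f_statistic=float(raw["f_statistic"]),
            p_value=float(raw["p_value"]),
            n_obs=int(raw["n_obs"]),
            standardized_coefficients=pd.Series(
                raw["standardized_coefficients"], dtype=float
            ),
            alpha_enter=float(raw["alpha_enter"]),
            alpha_remove=float(raw["alpha_remove"]),
            empty_model=bool(raw["empty_model"]),
            skipped_collinear=list(raw.get("skipped_collinear", [])),
        )

    def equation(self) -> str:
        terms = [f"{b:+.3f}*{ix}" for ix, b in self.coefficients.items()]
        return "H = " + " ".join(terms) + f" {self.intercept:+.3f}"


def _ols(y: np.ndarray, X: np.ndarray):
    return sm.OLS(y, sm.add_constant(X, has_constant="add")).fit()


def _partial_pvalue(y: np.ndarray, X_in: np.ndarray | None, x_new: np.ndarray) -> float:
    """Two-sided p-value of the added predictor (equivalent to its partial F)."""
    X = x_new[:, None] if X_in is None else np.column_stack([X_in, x_new])
    res = _ols(y, X)
    return float(res.pvalues[-1])


def _tolerance(X_in: np.ndarray | None, x_new: np.ndarray) -> float:
    """1 − R² of the candidate regressed on the included set (1 if none)."""
    if x_new.std() == 0:
        return 0.0
    if X_in is None:
        return 1.0
    res = _ols(x_new, X_in)
    return float(max(0.0, 1.0 - res.rsquared))


def stepwise_select(
    h: pd.Series, cm: CoefficientMatrix, config: AnalysisConfig | None = None
) -> RegressionModel:
    """Forward-entry / backward-removal stepwise OLS of H on the h columns.

    Candidates are scanned in lexicographic label order, which also breaks
    exact p-value ties deterministically.  Collinear candidates
    (tolerance < 1e-8 against the included set) are skipped and recorded.
    If nothing meets the entry criterion an intercept-only model is
    returned with ``empty_model`` set — a warning, not an error.
    """
    config = config or AnalysisConfig()
    X = cm.h
    y = h.reindex(X.index)
    if y.isna().any():
        raise DomainError("H is missing for some genotypes in the coefficient matrix")
    n = len(y)
    if n < 4:
        raise DomainError(f"stepwise selection needs at least 4 observations, got {n}")
    yv = y.to_numpy(dtype=float)

    included: list[str] = []
    skipped: set[str] = set()
    seen: set[frozenset] = set()
    while True:
        changed = False
        # --- forward entry ---
        if n - (len(included) + 1) - 1 >= _MIN_RESID_DF:
            X_in = X[included].to_numpy() if included else None
            best_label, best_p = None, np.inf
            for label in sorted(set(X.columns) - set(included)):
                xv = X[label].to_numpy(dtype=float)
                if _tolerance(X_in, xv) < _COLLINEARITY_TOL:
                    skipped.add(label)
                    continue
                p = _partial_pvalue(yv, X_in, xv)
                if p < best_p:  # strict: first (lexicographic) wins ties
                    best_label, best_p = label, p
            if best_label is not None and best_p <= config.alpha_enter:
                included.append(best_label)
                changed = True
        # --- backward removal ---
        while len(included) >= 1:
            res = _ols(yv, X[included].to_numpy())
            pvals = pd.Series(res.pvalues[1:], index=included)
            worst = pvals.sort_index().idxmax()  # lexicographic tie-break
            if pvals[worst] >= config.alpha_remove:
                included.remove(worst)
                changed = True
            else:
                break
        state = frozenset(included)
        if not changed or state in seen:
            break
        seen.add(state)

    if not included:
        return RegressionModel(
            selected_indices=[],
            coefficients=pd.Series(dtype=float),
            intercept=float(yv.mean()),
            r_squared=0.0,
            f_statistic=0.0,
            p_value=1.0,
            n_obs=n,
            standardized_coefficients=pd.Series(dtype=float),
            alpha_enter=config.alpha_enter,
            alpha_remove=config.alpha_remove,
            empty_model=True,
            skipped_collinear=sorted(skipped),
        )

    res = _ols(yv, X[included].to_numpy())
    k = len(included)
    r2 = float(res.rsquared)
    if 1.0 - r2 > 0:
        f_stat = (r2 / k) / ((1.0 - r2) / (n - k - 1))
        p_val = float(scipy.stats.f.sf(f_stat, k, n - k - 1))
    else:  # exact fit: unbounded F
        f_stat, p_val = np.inf, 0.0
    coefs = pd.Series(res.params[1:], index=included)
    sd_x = X[included].std(ddof=1)
    sd_y = y.std(ddof=1)
    return RegressionModel(
        selected_indices=included,
        coefficients=coefs,
        intercept=float(res.params[0]),
        r_squared=r2,
        f_statistic=float(f_stat),
        p_value=p_val,
        n_obs=n,
        standardized_coefficients=coefs * sd_x / sd_y,
        alpha_enter=config.alpha_enter,
        alpha_remove=config.alpha_remove,
        skipped_collinear=sorted(skipped),
    )


def predict_h(
    model: RegressionModel,
    new_coefficients: pd.DataFrame | Mapping[str, float],
) -> pd.DataFrame:
    """Apply a fitted equation to new genotypes' h coefficients.

    ``new_coefficients`` is a genotype × index frame (or a single mapping
    index → h).  Every selected index must be supplied.  Predictions are
    returned unclipped with an ``in_unit_interval`` flag, since values from
    extreme genotypes can legitimately fall outside [0, 1].
    """
    if isinstance(new_coefficients, Mapping):
        new_coefficients = pd.DataFrame([new_coefficients], index=["sample"])
    missing = [ix for ix in model.selected_indices if ix not in new_coefficients.columns]
    if missing:
        raise MissingIndexError(f"coefficients for selected index {missing[0]!r} missing")
    if model.selected_indices:
        xs = new_coefficients[model.selected_indices].to_numpy(dtype=float)
        pred = xs @ model.coefficients.to_numpy() + model.intercept
    else:
        pred = np.full(len(new_coefficients), model.intercept)
    return pd.DataFrame(
        {
            "H_pred": pred,
            "in_unit_interval": (pred >= 0) & (pred <= 1),
        },
        index=new_coefficients.index,
    )
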