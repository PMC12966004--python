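"""End-to-end orchestration: raw tables in, scored report out.

``run_pipeline`` composes the stages — replicate aggregation, resistance
coefficients, standardisation, PCA, membership values, weights, H,
injury validation, stepwise index selection, tolerance grouping — and
returns a :class:`RunReport`.  With an output directory it also writes a
machine-readable report (JSON + CSVs) whose config echo makes the run
reproducible bit-for-bit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

from . import __version__
from .coefficients import CoefficientMatrix, compute_coefficients
from .errors import HeattolError, StageError
from .injury import InjuryGradeTable, compute_hii, read_injury_table
from .io import AnalysisConfig, PhenoTable, aggregate_replicates, read_pheno_table
from .scoring import PCAResult, ToleranceScores, score_matrix
from .selection import RegressionModel, stepwise_select
from .validation import GroupAssignment, ValidationResult, cluster_tolerance, correlate_with_injury

REPORT_SCHEMA_VERSION = 1


@dataclass
class RunReport:
    """Self-contained record of one pipeline run."""

    config: AnalysisConfig
    coefficients: CoefficientMatrix
    pca: PCAResult
    scores: ToleranceScores
    model: RegressionModel
    groups: GroupAssignment
    validation: Optional[ValidationResult]  # None when no injury table given
    hii: Optional[pd.Series]
    version: str = __version__

    def genotype_table(self) -> pd.DataFrame:
        """Per-genotype report: h columns, CI, Ui, H, HII, group, H rank."""
        out = self.coefficients.h.copy()
        out = out.join(self.pca.scores.add_prefix("CI_"))
        out = out.join(self.scores.memberships.add_prefix("U_"))
        out["H"] = self.scores.h
        if self.hii is not None:
            out["HII"] = self.hii.reindex(out.index)
        out["group"] = self.groups.labels()
        out["H_rank"] = self.scores.h.rank(ascending=False, method="min").astype(int)
        return out

    def to_json_dict(self) -> dict:
        d = {
            "schema_version": REPORT_SCHEMA_VERSION,
            "software_version": self.version,
            "config": self.config.to_dict(),
            "pca": {
                "eigenvalues": [float(v) for v in self.pca.eigenvalues],
                "proportions": [float(v) for v in self.pca.proportions],
                "n_retained": self.pca.n_retained,
                "cumulative_retained": float(self.pca.cumulative_retained),
            },
            "weights": {k: float(v) for k, v in self.scores.weights.items()},
            "H": {k: float(v) for k, v in self.scores.h.items()},
            "groups": {k: int(v) for k, v in self.groups.groups.items()},
            "model": {
                "selected_indices": self.model.selected_indices,
                "coefficients": {k: float(v) for k, v in self.model.coefficients.items()},
                "intercept": float(self.model.intercept),
                "r_squared": float(self.model.r_squared),
                "f_statistic": float(self.model.f_statistic),
                "p_value": float(self.model.p_value),
                "empty_model": self.model.empty_model,
            },
        }
        if self.validation is None:
            d["validation"] = {"status": "skipped", "reason": "no injury table supplied"}
        else:
            d["validation"] = {
                "status": "ok" if self.validation.direction_ok else "warning",
                "pearson_r": self.validation.pearson_r,
                "p_value": self.validation.p_value,
                "n": self.validation.n,
                "direction_ok": self.validation.direction_ok,
            }
        return d

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(
            json.dumps(self.to_json_dict(), indent=2, sort_keys=True) + "\n"
        )
        self.config.to_json(out / "config.json")
        self.genotype_table().to_csv(
            out / "genotype_report.csv", index_label="genotype", float_format="%.10g"
        )
        self.coefficients.to_csv(out / "coefficients.csv")
        pca_tbl = pd.DataFrame(
            {"eigenvalue": self.pca.eigenvalues, "proportion": self.pca.proportions},
            index=self.pca.loadings.columns,
        )
        pca_tbl["cumulative"] = np.cumsum(self.pca.proportions)
        pca_tbl.join(self.pca.loadings.T).to_csv(
            out / "pca.csv", index_label="component", float_format="%.10g"
        )
        self.model.to_json(out / "model.json")


def _stage(name: str, fn, *args, **kw):
    try:
        return fn(*args, **kw)
    except StageError:
        raise
    except HeattolError as e:
        raise StageError(name, str(e)) from e


def run_pipeline(
    pheno: Union[PhenoTable, str, Path],
    injury: Union[InjuryGradeTable, str, Path, None] = None,
    config: AnalysisConfig | None = None,
    out_dir=None,
) -> RunReport:
    """Run every stage on a phenotype table (path or object).

    The injury table is optional; without it the H-vs-HII validation is
    marked "skipped" in the report.  Any stage failure raises
    :class:`StageError` naming the stage.
    """
    config = config or AnalysisConfig()
    if not isinstance(pheno, PhenoTable):
        pheno = _stage("read_pheno", read_pheno_table, pheno)
    if injury is not None and not isinstance(injury, InjuryGradeTable):
        injury = _stage("read_injury", read_injury_table, injury)

    agg = _stage("aggregate", aggregate_replicates, pheno)
    cm = _stage("coefficients", compute_coefficients, agg, config.index_list)
    pca, scores = _stage("scoring", score_matrix, cm, config)
    model = _stage("stepwise", stepwise_select, scores.h, cm, config)
    groups = _stage("clustering", cluster_tolerance, scores.h, config.n_groups)

    hii = validation = None
    if injury is not None:
        hii = _stage("injury_index", compute_hii, injury)
        validation = _stage("validation", correlate_with_injury, scores.h, hii)

    report = RunReport(
        config=config,
        coefficients=cm,
        pca=pca,
        scores=scores,
        model=model,
        groups=groups,
        validation=validation,
        hii=hii,
    )
    if out_dir is not None:
        report.write(out_dir)
    return report


def score_coefficient_table(
    cm: Union[CoefficientMatrix, str, Path],
    config: AnalysisConfig | None = None,
) -> tuple[PCAResult, ToleranceScores]:
    """Score a pre-computed coefficient CSV/matrix (skips the raw stages)."""
    if not isinstance(cm, CoefficientMatrix):
        cm = CoefficientMatrix.from_csv(cm)
    return score_matrix(cm, config or AnalysisConfig())
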