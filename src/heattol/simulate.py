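"""Synthetic heat-stress trials with a known latent tolerance factor.

The generator emulates the structure of a paired-chamber seedling trial:
a panel of genotypes differing in a single latent tolerance θ ∈ [0, 1],
a handful of physiological/morphological indices measured with replicate
noise under control (CK) and heat-stress (HS) conditions, and 5-grade
visual injury counts.  Each index responds linearly to tolerance on the
ratio scale, E[h_j(θ)] = a_j + b_j·θ: benefit traits (chlorophyll-a
retention, antioxidant-enzyme induction, germination) have b_j > 0,
hazard traits (hypocotyl elongation, sugar accumulation) b_j < 0.

Replicate values are Normal around the condition mean with a fixed
coefficient of variation, truncated at zero; per-seedling injury grades
are Binomial(4, 1 − θ + noise), so the expected injury index is
(1 − θ)·100.  Identical seeds yield byte-identical trials, and each
index draws from its own child stream (seeded by hashing the trial seed
with the index label) so adding an index never perturbs the draws of the
existing columns.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.stats

from .errors import ConfigError, DomainError
from .injury import GRADE_COLUMNS, InjuryGradeTable, N_GRADES
from .io import PHENO_COLUMNS, PhenoTable
from .scoring import ToleranceScores

# sub-stream tags so theta / index / injury draws never collide
_THETA_STREAM = 0
_INDEX_STREAM = 1
_INJURY_STREAM = 2


@dataclass(frozen=True)
class IndexSpec:
    """One simulated index: CK mean and linear tolerance response.

    ``control_mean`` is the CK-condition mean in the index's native units;
    the expected stress/control ratio is a + b·θ, which must stay positive
    over θ ∈ [0, 1].  ``sign`` records whether the trait benefits from
    tolerance (b > 0) or marks susceptibility (b < 0).
    """

    label: str
    control_mean: float
    response_intercept: float  # a: expected h at theta = 0
    response_slope: float      # b: change in expected h per unit theta
    sign: str                  # "benefit" | "hazard"

    def __post_init__(self):
        if self.control_mean <= 0:
            raise ConfigError(f"index {self.label!r}: control_mean must be > 0")
        if self.sign not in ("benefit", "hazard"):
            raise ConfigError(f"index {self.label!r}: sign must be 'benefit' or 'hazard'")
        a, b = self.response_intercept, self.response_slope
        # linear in theta, so positivity on [0, 1] reduces to the endpoints
        if a <= 0 or a + b <= 0:
            raise ConfigError(
                f"index {self.label!r}: expected ratio a + b*theta must stay positive "
                f"on [0, 1] (a = {a}, a + b = {a + b})"
            )

    def expected_ratio(self, theta):
        return self.response_intercept + self.response_slope * np.asarray(theta)


def default_index_specs() -> list[IndexSpec]:
    """Six indices: four benefit, two hazard, with field-plausible CK means."""
    return [
        IndexSpec("Chl a", 1.8, 0.30, 0.70, "benefit"),     # mg/g FW retention
        IndexSpec("CAT", 25.0, 1.00, 1.50, "benefit"),      # U/g induction
        IndexSpec("SOD", 180.0, 1.05, 0.85, "benefit"),     # U/g induction
        IndexSpec("GR", 0.92, 0.35, 0.60, "benefit"),       # germination rate ratio
        IndexSpec("HL", 4.5, 2.20, -1.00, "hazard"),        # hypocotyl elongation
        IndexSpec("Sol sugar", 12.0, 2.80, -1.40, "hazard"),  # sugar accumulation
    ]


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions of the synthetic trial (defaults mirror a
    10-genotype, 3-replicate, 30-seedling chamber experiment)."""

    n_genotypes: int = 10
    n_replicates: int = 3
    index_specs: Sequence[IndexSpec] = field(default_factory=default_index_specs)
    replicate_cv: float = 0.05
    n_seedlings: int = 30
    grade_noise_sd: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if self.n_genotypes < 1 or self.n_replicates < 1 or self.n_seedlings < 1:
            raise ConfigError("counts must be positive integers")
        if self.replicate_cv < 0 or self.grade_noise_sd < 0:
            raise ConfigError("noise levels must be non-negative")
        if self.seed < 0:
            raise ConfigError("seed must be non-negative")
        labels = [s.label for s in self.index_specs]
        if len(set(labels)) != len(labels):
            raise ConfigError("index labels must be unique")

    def with_seed(self, seed: int) -> "SimulationConfig":
        return replace(self, seed=seed)


@dataclass(frozen=True)
class GroundTruth:
    """Latent tolerance per genotype and the noise-free expected ratios."""

    theta: pd.Series           # genotype -> latent tolerance in [0, 1]
    expected_h: pd.DataFrame   # genotype x index, a_j + b_j * theta


def _index_rng(seed: int, label: str) -> np.random.Generator:
    return np.random.default_rng([seed, _INDEX_STREAM, zlib.crc32(label.encode())])


def _truncated_normal(rng, mean: np.ndarray, cv: float) -> np.ndarray:
    if cv == 0:
        return mean.copy()
    draw = rng.normal(mean, cv * mean)
    return np.clip(draw, 0.0, None)


def generate_trial(
    config: SimulationConfig | None = None,
) -> tuple[PhenoTable, InjuryGradeTable, GroundTruth]:
    """Simulate one complete trial: phenotypes, injury counts, ground truth."""
    config = config or SimulationConfig()
    genotypes = [f"G{i + 1:02d}" for i in range(config.n_genotypes)]

    theta = np.random.default_rng([config.seed, _THETA_STREAM]).uniform(
        0.0, 1.0, config.n_genotypes
    )
    theta_s = pd.Series(theta, index=pd.Index(genotypes, name="genotype"), name="theta")

    rows = []
    for spec in config.index_specs:
        rng = _index_rng(config.seed, spec.label)
        ratio = spec.expected_ratio(theta)
        for cond, cond_mean in (("CK", np.full_like(theta, spec.control_mean)),
                                ("HS", spec.control_mean * ratio)):
            for rep in range(1, config.n_replicates + 1):
                vals = _truncated_normal(rng, cond_mean, config.replicate_cv)
                for g, v in zip(genotypes, vals):
                    rows.append((g, spec.label, cond, rep, float(v)))
    pheno = PhenoTable(pd.DataFrame(rows, columns=list(PHENO_COLUMNS)))

    inj_rng = np.random.default_rng([config.seed, _INJURY_STREAM])
    counts = np.zeros((config.n_genotypes, N_GRADES), dtype=int)
    for gi in range(config.n_genotypes):
        p_damage = 1.0 - theta[gi]
        if config.grade_noise_sd > 0:
            p_damage += inj_rng.normal(0.0, config.grade_noise_sd)
        p_damage = float(np.clip(p_damage, 0.0, 1.0))
        grades = inj_rng.binomial(N_GRADES - 1, p_damage, size=config.n_seedlings)
        counts[gi] = np.bincount(grades, minlength=N_GRADES)
    injury = InjuryGradeTable(
        pd.DataFrame(counts, index=pd.Index(genotypes, name="genotype"),
                     columns=list(GRADE_COLUMNS))
    )

    expected_h = pd.DataFrame(
        {spec.label: spec.expected_ratio(theta) for spec in config.index_specs},
        index=theta_s.index,
    )
    return pheno, injury, GroundTruth(theta=theta_s, expected_h=expected_h)


def recovery_statistic(truth: GroundTruth, scores: ToleranceScores) -> float:
    """Spearman rank correlation between latent θ and recovered H."""
    shared = truth.theta.index.intersection(scores.h.index)
    if len(shared) < 3:
        raise DomainError(f"need at least 3 shared genotypes, got {len(shared)}")
    if set(shared) != set(truth.theta.index) or set(shared) != set(scores.h.index):
        raise DomainError("ground truth and scores cover different genotype sets")
    rx = scipy.stats.rankdata(truth.theta.loc[shared].to_numpy())
    ry = scipy.stats.rankdata(scores.h.loc[shared].to_numpy())
    # exactly monotone (or anti-monotone) maps have rho = +/-1 by definition
    if np.array_equal(rx, ry):
        return 1.0
    if np.array_equal(rx, len(rx) + 1 - ry):
        return -1.0
    return float(np.corrcoef(rx, ry)[0, 1])
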