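"""Fixed-effect inverse-variance meta-analysis of cohort summary statistics.

Published cohort tables often print only the effect and its two-sided P
value; the standard error is then back-derived as
``se = |beta| / PhiInv(1 - p/2)`` under the normal approximation.  Cohorts
are combined with weights ``1/se^2`` and heterogeneity is assessed with
Cochran's Q.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats


@dataclass
class CohortSummary:
    label: str
    beta: float
    p: float | None = None
    se: float | None = None
    n: int | None = None

    def __post_init__(self) -> None:
        if self.se is None and self.p is None:
            raise ValueError(f"{self.label}: need p or se")
        if self.se is not None and self.se <= 0:
            raise ValueError(f"{self.label}: se must be positive")
        if self.p is not None and not (0.0 < self.p < 1.0):
            raise ValueError(f"{self.label}: p must lie in (0, 1)")

    def resolved_se(self) -> float:
        if self.se is not None:
            return self.se
        return se_from_p(self.beta, self.p)


@dataclass
class MetaResult:
    beta: float
    se: float
    p: float
    z: float
    n_cohorts: int


@dataclass
class HeterogeneityResult:
    q: float
    df: int
    p: float


def se_from_p(beta: float, p: float) -> float:
    """Standard error back-derived from an effect and its two-sided P."""
    if beta == 0:
        raise ValueError("se undefined for beta = 0")
    if not (0.0 < p < 1.0):
        raise ValueError("p must lie in (0, 1)")
    if p > 0.999:
        warnings.warn("p close to 1: back-derived se is numerically unstable")
    z = stats.norm.ppf(1.0 - p / 2.0)
    return abs(beta) / z


def fixed_effect_meta(cohorts: list[CohortSummary]) -> MetaResult:
    """Inverse-variance fixed-effect combination of cohort effects."""
    if not cohorts:
        raise ValueError("no cohorts supplied")
    betas = np.array([c.beta for c in cohorts], dtype=float)
    ses = np.array([c.resolved_se() for c in cohorts], dtype=float)
    w = 1.0 / ses**2
    beta = float((w * betas).sum() / w.sum())
    se = float(w.sum() ** -0.5)
    z = beta / se
    p = float(2.0 * stats.norm.sf(abs(z)))
    return MetaResult(beta=beta, se=se, p=p, z=float(z), n_cohorts=len(cohorts))


def heterogeneity_test(
    cohorts: list[CohortSummary], combined_beta: float | None = None
) -> HeterogeneityResult:
    """Cochran's Q test of effect heterogeneity across cohorts."""
    if len(cohorts) < 2:
        raise ValueError("heterogeneity test needs at least 2 cohorts")
    betas = np.array([c.beta for c in cohorts], dtype=float)
    ses = np.array([c.resolved_se() for c in cohorts], dtype=float)
    w = 1.0 / ses**2
    if combined_beta is None:
        combined_beta = float((w * betas).sum() / w.sum())
    q = float((w * (betas - combined_beta) ** 2).sum())
    df = len(cohorts) - 1
    p = float(stats.chi2.sf(q, df))
    return HeterogeneityResult(q=q, df=df, p=p)
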