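"""Dosage-based association, fine-mapping and genomic control.

Quantitative traits are pre-processed as in large lipid GWAS practice:
multiple measurements per individual are averaged, residualized on
covariates, then mapped onto a standard normal by rank-based inverse-normal
transformation.  Effects estimated on the transformed scale (SD units) are
rescaled to trait units by multiplying with the trait SD; for log-scale
traits the effect is reported as percent change.  Relatedness and
stratification are corrected by genomic control: chi-square statistics are
divided by the median-based inflation factor when it exceeds one.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm

logger = logging.getLogger(__name__)

#: median of the chi-square distribution with 1 df
CHI2_MEDIAN_1DF = float(stats.chi2.ppf(0.5, 1))

#: default imputation-information threshold below which variants are excluded
INFO_MIN = 0.8


class DegenerateVariantError(ValueError):
    """Zero dosage variance: no association can be estimated."""


@dataclass
class AssociationResult:
    variant: str
    beta_sd: float
    beta_units: float
    se: float
    chi2: float
    p: float
    log10_p: float
    adjusted_for: list[str] = field(default_factory=list)
    n: int = 0
    flagged: str | None = None

    def to_dict(self) -> dict:
        d = self.__dict__.copy()
        d["adjusted_for"] = ",".join(self.adjusted_for)
        return d


@dataclass
class GenomicControlResult:
    lambda_g: float
    n_variants_used: int


def _chi2_p(chi2: float) -> tuple[float, float]:
    """Two-sided P and log10 P from a 1-df chi-square, underflow-guarded."""
    log_p = stats.chi2.logsf(chi2, 1)
    log10_p = log_p / np.log(10.0)
    p = float(np.exp(log_p))
    if p == 0.0:
        p = np.nextafter(0.0, 1.0)
    return p, float(log10_p)


def inverse_normal_transform(values) -> np.ndarray:
    """Rank-based inverse-normal transform (quantile normalization to N(0,1)).

    Each non-missing value maps to the standard-normal quantile of
    ``rank / (n + 1)`` with ties sharing the average rank; missing values
    stay missing.  The output is invariant to monotone transforms of the
    input.
    """
    x = np.asarray(values, dtype=float)
    out = np.full(x.shape, np.nan)
    mask = ~np.isnan(x)
    n = int(mask.sum())
    if n < 2:
        raise ValueError("need at least 2 non-missing values")
    ranks = stats.rankdata(x[mask], method="average")
    out[mask] = stats.norm.ppf(ranks / (n + 1))
    return out


def adjust_phenotype(
    table: pd.DataFrame,
    covariates: list[str] | None = None,
    trait: str = "trait",
    individual: str = "individual",
    categorical: tuple[str, ...] = ("site", "sex", "med"),
    quadratic: tuple[str, ...] = ("age",),
) -> pd.Series:
    """Average repeated measurements, residualize on covariates, and
    inverse-normal transform.

    Numeric covariates listed in ``quadratic`` enter with first- and
    second-order terms; covariates in ``categorical`` are dummy-encoded.
    Covariates with a single level are dropped with a warning.  Returns the
    adjusted normalized trait indexed by individual.
    """
    covariates = list(covariates or [])
    first = table.groupby(individual, sort=False).first()
    agg = {trait: table.groupby(individual, sort=False)[trait].mean()}
    for c in covariates:
        agg[c] = first[c]
    df = pd.DataFrame(agg)

    design = [pd.Series(1.0, index=df.index, name="const")]
    for c in covariates:
        col = df[c]
        if col.nunique() < 2:
            warnings.warn(f"covariate {c!r} has a single level; dropped")
            continue
        if c in categorical or not pd.api.types.is_numeric_dtype(col):
            dummies = pd.get_dummies(col, prefix=c, drop_first=True, dtype=float)
            design.extend(dummies[c2] for c2 in dummies)
        else:
            centred = col.astype(float) - col.astype(float).mean()
            design.append(centred.rename(c))
            if c in quadratic:
                design.append((centred**2).rename(f"{c}^2"))
    X = np.column_stack([np.asarray(s, dtype=float) for s in design])
    y = df[trait].to_numpy(dtype=float)
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return pd.Series(
        inverse_normal_transform(resid), index=df.index, name="adjusted_trait"
    )


def _ols_fit(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Least squares with coefficient SEs; returns (beta, se, dof)."""
    n, k = X.shape
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    dof = n - k
    sigma2 = float(resid @ resid) / dof if dof > 0 else np.nan
    xtx_inv = np.linalg.pinv(X.T @ X)
    se = np.sqrt(np.clip(np.diag(xtx_inv) * sigma2, 0.0, None))
    return beta, se, dof


def linear_assoc(
    dosages: pd.Series | np.ndarray,
    trait: pd.Series | np.ndarray,
    trait_sd: float = 1.0,
    condition_on: pd.DataFrame | None = None,
    variant: str = "variant",
) -> AssociationResult:
    """Single-variant linear association of an adjusted (SD-scale) trait on
    allele dosage, optionally conditioning on other variants' dosages.

    ``beta_units = beta_sd * trait_sd``; the test statistic is
    ``chi2 = (beta / se)^2`` referred to a 1-df chi-square.
    """
    d = np.asarray(dosages, dtype=float)
    y = np.asarray(trait, dtype=float)
    if d.shape[0] != y.shape[0]:
        raise ValueError("dosage and trait must be indexed by the same individuals")
    if np.var(d) == 0:
        raise DegenerateVariantError(f"{variant}: dosage has zero variance")
    cols = [np.ones_like(d), d]
    adjusted_for: list[str] = []
    if condition_on is not None:
        for c in condition_on.columns:
            cols.append(np.asarray(condition_on[c], dtype=float))
            adjusted_for.append(str(c))
    X = np.column_stack(cols)
    beta, se, _ = _ols_fit(X, y)
    b, s = float(beta[1]), float(se[1])
    chi2 = (b / s) ** 2 if s > 0 else np.inf
    p, log10_p = _chi2_p(chi2)
    return AssociationResult(
        variant=variant,
        beta_sd=b,
        beta_units=b * trait_sd,
        se=s,
        chi2=float(chi2),
        p=p,
        log10_p=log10_p,
        adjusted_for=adjusted_for,
        n=len(y),
    )


def logistic_assoc(
    dosages: pd.Series | np.ndarray,
    status: pd.Series | np.ndarray,
    covariates: pd.DataFrame | None = None,
    condition_on: pd.DataFrame | None = None,
    variant: str = "variant",
) -> AssociationResult:
    """Logistic association of binary status on allele dosage.

    Maximum-likelihood fit with nuisance covariates and conditioning
    dosages; the reported test is the likelihood-ratio chi-square against
    the model without the variant, and ``beta_units`` is the odds ratio.
    Complete separation yields a flagged result with no estimate.
    """
    d = np.asarray(dosages, dtype=float)
    y = np.asarray(status, dtype=float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("status must be binary 0/1")
    if len(np.unique(y)) < 2:
        raise ValueError("both case and control classes must be present")
    if np.var(d) == 0:
        raise DegenerateVariantError(f"{variant}: dosage has zero variance")

    nuisance = [np.ones_like(d)]
    adjusted_for: list[str] = []
    if covariates is not None:
        nuisance.extend(
            np.asarray(covariates[c], dtype=float) for c in covariates.columns
        )
    if condition_on is not None:
        for c in condition_on.columns:
            nuisance.append(np.asarray(condition_on[c], dtype=float))
            adjusted_for.append(str(c))
    X0 = np.column_stack(nuisance)
    X1 = np.column_stack([X0, d])
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit0 = sm.Logit(y, X0).fit(disp=False, maxiter=200)
            fit1 = sm.Logit(y, X1).fit(disp=False, maxiter=200)
        if not np.isfinite(fit1.bse[-1]) or fit1.bse[-1] > 1e3:
            raise np.linalg.LinAlgError("unstable fit")
    except Exception as exc:  # perfect separation, singular hessian, ...
        return AssociationResult(
            variant=variant,
            beta_sd=np.nan,
            beta_units=np.nan,
            se=np.nan,
            chi2=np.nan,
            p=np.nan,
            log10_p=np.nan,
            adjusted_for=adjusted_for,
            n=len(y),
            flagged=f"no estimate: {exc}",
        )
    b = float(fit1.params[-1])
    se = float(fit1.bse[-1])
    lr_chi2 = float(2.0 * (fit1.llf - fit0.llf))
    p, log10_p = _chi2_p(lr_chi2)
    return AssociationResult(
        variant=variant,
        beta_sd=b,
        beta_units=float(np.exp(b)),  # odds ratio
        se=se,
        chi2=lr_chi2,
        p=p,
        log10_p=log10_p,
        adjusted_for=adjusted_for,
        n=len(y),
    )


def stepwise_select(
    dosages: pd.DataFrame,
    trait: pd.Series | np.ndarray,
    threshold: float = 5e-8,
    positions: dict[str, int] | None = None,
) -> list[AssociationResult]:
    """Stepwise forward selection of independent signals in a region.

    Iteratively adds the variant with the smallest conditional P (largest
    conditional chi-square) while that P is below ``threshold``, conditioning
    on all previously selected variants.  Ties are broken by genomic
    position then id.  Returns the selected variants with their conditional
    results (each adjusted for the other selected variants).
    """
    if dosages.shape[1] < 1:
        raise ValueError("need at least one variant")
    y = np.asarray(trait, dtype=float)
    X = dosages.to_numpy(dtype=float)
    names = list(dosages.columns)
    n = len(y)
    pos = positions or {}
    order = {
        name: (pos.get(name, i), name) for i, name in enumerate(names)
    }

    selected: list[int] = []
    while True:
        k = len(selected)
        Z = np.column_stack([np.ones(n)] + [X[:, j] for j in selected])
        Q, _ = np.linalg.qr(Z)
        y_res = y - Q @ (Q.T @ y)
        X_res = X - Q @ (Q.T @ X)
        ss = (X_res**2).sum(axis=0)
        usable = ss > 1e-10 * n
        usable[selected] = False
        if not usable.any():
            break
        xy = X_res.T @ y_res
        with np.errstate(divide="ignore", invalid="ignore"):
            beta = np.where(usable, xy / ss, 0.0)
        rss = float(y_res @ y_res) - beta**2 * ss
        dof = n - k - 2
        sigma2 = rss / dof
        with np.errstate(divide="ignore", invalid="ignore"):
            chi2 = np.where(usable & (sigma2 > 0), beta**2 * ss / sigma2, 0.0)
        best_chi2 = chi2[usable].max()
        candidates = [
            j for j in np.flatnonzero(usable) if chi2[j] >= best_chi2 - 1e-9
        ]
        j_best = min(candidates, key=lambda j: order[names[j]])
        p_best, _ = _chi2_p(best_chi2)
        if p_best >= threshold:
            break
        selected.append(j_best)

    results = []
    for j in selected:
        others = [names[i] for i in selected if i != j]
        res = linear_assoc(
            dosages.iloc[:, j],
            y,
            condition_on=dosages[others] if others else None,
            variant=names[j],
        )
        results.append(res)
    return results


def genomic_control(
    chi2_values, trait: str = ""
) -> tuple[GenomicControlResult, np.ndarray]:
    """Estimate the inflation factor and correct chi-square statistics.

    ``lambda_g = median(chi2) / 0.4549`` (the 1-df chi-square median);
    statistics are divided by ``max(lambda_g, 1)`` — deflation is never
    applied.  Returns the estimate and the corrected chi-square values.
    """
    chi2 = np.asarray(chi2_values, dtype=float)
    if chi2.size == 0:
        raise ValueError("no chi-square values supplied")
    if chi2.size < 100:
        warnings.warn(
            f"lambda estimated from only {chi2.size} variants; unstable"
        )
    lam = float(np.median(chi2) / CHI2_MEDIAN_1DF)
    corrected = chi2 / max(lam, 1.0)
    return GenomicControlResult(lambda_g=lam, n_variants_used=chi2.size), corrected


def corrected_p(corrected_chi2) -> np.ndarray:
    return stats.chi2.sf(np.asarray(corrected_chi2, dtype=float), 1)


def imputation_info(dosages, allele_freq: float, phased: bool | None = None) -> float:
    """Imputation information: Var(expected allele count) / Var(true count).

    With per-haplotype dosages (an (n, 2) array) the haploid variance is
    referred to ``p (1 - p)``; a 1-D diploid dosage vector is referred to
    ``2 p (1 - p)``.  Values are clamped to [0, 1] after computation.
    """
    p = float(allele_freq)
    if p <= 0.0 or p >= 1.0:
        raise ValueError(f"info undefined at allele frequency {p}")
    d = np.asarray(dosages, dtype=float)
    if d.ndim == 2 and d.shape[1] == 2:
        var = float(np.var(d.ravel()))
        denom = p * (1.0 - p)
    else:
        var = float(np.var(d))
        denom = 2.0 * p * (1.0 - p)
    info = var / denom
    if info > 1.0:
        logger.info("info %.4f > 1 before clamping", info)
    return float(np.clip(info, 0.0, 1.0))


def percent_change_effect(beta_log: float) -> float:
    """Effect of a natural-log-scale fit expressed as percent change."""
    return float(100.0 * (np.exp(beta_log) - 1.0))
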