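"""Case/control association statistics.

Logistic regression is fit by plain IRLS first and falls back to
Firth's bias-reduced fit (penalized log-likelihood l(b) + 0.5*log det
I(b)) when the ML fit diverges or fails to converge — the behaviour of
"Firth fallback" association software.  P-values are Wald throughout.
A crude allelic odds ratio, MAF/imputation-quality variant filtering,
the genomic-inflation factor and inverse-variance fixed-effects
meta-analysis round out the layer.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "AssocResult",
    "MetaResult",
    "VariantFilterRule",
    "allelic_or",
    "logistic_firth",
    "firth_fit",
    "penalized_loglik",
    "variant_filter",
    "genomic_inflation",
    "meta_fixed",
]

_CHI2_1_MEDIAN = float(stats.chi2.ppf(0.5, 1))


@dataclass(frozen=True)
class AssocResult:
    beta: float
    se: float
    or_: float
    p_value: float
    method: str  # "ML" | "FIRTH" | "WALD-2x2"
    converged: bool


@dataclass(frozen=True)
class MetaResult:
    beta: float
    se: float
    or_: float
    z: float
    p_value: float
    weights: tuple[float, ...]


@dataclass(frozen=True)
class VariantFilterRule:
    """Retain variants with maf >= min_maf and info >= min_info."""

    min_maf: float = 0.005
    min_info: float = 0.3

    def __post_init__(self) -> None:
        for v in (self.min_maf, self.min_info):
            if not 0 <= v <= 1:
                raise ValueError(f"thresholds must be in [0, 1], got {v}")


def _wald(beta: float, se: float) -> float:
    if se == 0:
        return math.nan
    return float(2 * stats.norm.sf(abs(beta) / se))


def allelic_or(
    case_alt: int, case_ref: int, ctrl_alt: int, ctrl_ref: int
) -> AssocResult:
    """Crude allelic odds ratio from a 2x2 allele-count table.

    Haldane-Anscombe: 0.5 is added to every cell when any cell is zero.
    """
    cells = (case_alt, case_ref, ctrl_alt, ctrl_ref)
    if any(c < 0 or c != int(c) for c in cells):
        raise ValueError("allele counts must be nonnegative integers")
    if case_alt + case_ref == 0 or ctrl_alt + ctrl_ref == 0:
        raise ValueError("empty case or control margin")
    if case_alt + ctrl_alt == 0 or case_ref + ctrl_ref == 0:
        raise ValueError("an allele is absent from the whole table")
    a, b, c, d = (float(x) for x in cells)
    if min(cells) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    or_ = (a * d) / (b * c)
    beta = math.log(or_)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return AssocResult(
        beta=beta, se=se, or_=or_, p_value=_wald(beta, se), method="WALD-2x2",
        converged=True,
    )


# --------------------------------------------------------------------------
# logistic regression with Firth fallback


def _design(dosages, covariates) -> np.ndarray:
    g = np.asarray(dosages, dtype=float).reshape(-1, 1)
    cols = [np.ones_like(g), g]
    if covariates is not None:
        cov = np.asarray(covariates, dtype=float)
        if cov.ndim == 1:
            cov = cov.reshape(-1, 1)
        cols.append(cov)
    return np.hstack(cols)


def penalized_loglik(beta: np.ndarray, x: np.ndarray, y: np.ndarray) -> float:
    """Firth-penalized log-likelihood l(b) + 0.5*log det X'WX."""
    eta = x @ beta
    ll = float(np.sum(y * eta - np.logaddexp(0.0, eta)))
    p = 1.0 / (1.0 + np.exp(-eta))
    w = p * (1 - p)
    info = x.T @ (x * w[:, None])
    sign, logdet = np.linalg.slogdet(info)
    if sign <= 0:
        return -math.inf
    return ll + 0.5 * logdet


def _ml_fit(
    x: np.ndarray, y: np.ndarray, max_iter: int, beta_limit: float, tol: float
) -> tuple[np.ndarray, np.ndarray, bool]:
    """IRLS; returns (beta, covariance, converged). Divergence (any
    |beta| > beta_limit) counts as non-convergence."""
    beta = np.zeros(x.shape[1])
    converged = False
    info = np.eye(x.shape[1])
    for _ in range(max_iter):
        eta = np.clip(x @ beta, -30, 30)
        p = 1.0 / (1.0 + np.exp(-eta))
        w = np.maximum(p * (1 - p), 1e-12)
        info = x.T @ (x * w[:, None])
        score = x.T @ (y - p)
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError:
            break
        beta = beta + step
        if np.any(np.abs(beta) > beta_limit):
            return beta, np.full_like(info, np.nan), False
        if np.max(np.abs(step)) < tol:
            converged = True
            break
    cov = np.linalg.pinv(info)
    return beta, cov, converged


def firth_fit(
    x: np.ndarray, y: np.ndarray, max_iter: int = 100, tol: float = 1e-10
) -> tuple[np.ndarray, np.ndarray]:
    """Maximize the Firth-penalized likelihood by Newton steps on the
    modified score, with step-halving.  Returns (beta, covariance)."""
    beta = np.zeros(x.shape[1])
    ll_old = penalized_loglik(beta, x, y)
    info = np.eye(x.shape[1])
    for _ in range(max_iter):
        eta = x @ beta
        p = 1.0 / (1.0 + np.exp(-eta))
        w = np.maximum(p * (1 - p), 1e-12)
        xw = x * np.sqrt(w)[:, None]
        info = xw.T @ xw
        info_inv = np.linalg.inv(info)
        h = np.einsum("ij,jk,ik->i", xw, info_inv, xw)
        score = x.T @ (y - p + h * (0.5 - p))
        step = info_inv @ score
        # step-halving on the penalized objective
        for _ in range(25):
            candidate = beta + step
            ll_new = penalized_loglik(candidate, x, y)
            if ll_new >= ll_old - 1e-12:
                break
            step = step / 2
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            break
        ll_old = penalized_loglik(beta, x, y)
    eta = x @ beta
    p = 1.0 / (1.0 + np.exp(-eta))
    w = np.maximum(p * (1 - p), 1e-12)
    cov = np.linalg.inv(x.T @ (x * w[:, None]))
    return beta, cov


def logistic_firth(
    genotype_dosages,
    phenotype,
    covariates=None,
    max_iter: int = 25,
    beta_limit: float = 15.0,
    force_firth: bool = False,
) -> AssocResult:
    """Per-variant logistic regression with Firth fallback.

    The genotype coefficient is reported.  The fallback fires on IRLS
    non-convergence within ``max_iter`` iterations or any coefficient
    exceeding ``beta_limit`` (the practical signature of separation).
    """
    y = np.asarray(phenotype, dtype=float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("phenotype must be binary 0/1")
    if len(np.unique(y)) < 2:
        raise ValueError("phenotype is constant")
    x = _design(genotype_dosages, covariates)
    if x.shape[0] != y.shape[0]:
        raise ValueError("design/phenotype length mismatch")
    rank = np.linalg.matrix_rank(x)
    if rank < x.shape[1]:
        raise ValueError(
            f"design matrix is rank deficient (rank {rank} < {x.shape[1]} columns)"
        )
    method = "ML"
    converged = True
    if force_firth:
        beta_vec, cov = firth_fit(x, y)
        method = "FIRTH"
    else:
        beta_vec, cov, ml_ok = _ml_fit(x, y, max_iter, beta_limit, tol=1e-8)
        if not ml_ok or np.any(np.abs(beta_vec) > beta_limit):
            beta_vec, cov = firth_fit(x, y)
            method = "FIRTH"
            converged = True
        else:
            converged = ml_ok
    beta = float(beta_vec[1])
    se = float(math.sqrt(max(cov[1, 1], 0.0)))
    return AssocResult(
        beta=beta,
        se=se,
        or_=math.exp(beta),
        p_value=_wald(beta, se),
        method=method,
        converged=converged,
    )


# --------------------------------------------------------------------------


def variant_filter(variant_stats, rule: VariantFilterRule = VariantFilterRule()):
    """Split variants into (retained, exclusion_log).

    Each variant must expose ``maf`` and ``info`` (attribute or mapping
    key).  Boundary values are retained: exclusion is strict ``<``.
    The log is a list of (variant, reason) with reason "MAF", "INFO" or
    "MAF,INFO".
    """
    def get(v, name):
        if isinstance(v, dict):
            return v[name]
        return getattr(v, name)

    retained = []
    log = []
    for v in variant_stats:
        reasons = []
        if get(v, "maf") < rule.min_maf:
            reasons.append("MAF")
        if get(v, "info") < rule.min_info:
            reasons.append("INFO")
        if reasons:
            log.append((v, ",".join(reasons)))
        else:
            retained.append(v)
    return retained, log


def genomic_inflation(p_values) -> float:
    """lambda = median observed chi-square(1 df) / chi-square(1) median."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("no p-values")
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    chi = stats.chi2.isf(p, 1)
    return float(np.median(chi) / _CHI2_1_MEDIAN)


def meta_fixed(studies) -> MetaResult:
    """Inverse-variance fixed-effects pooling of (beta, se) pairs."""
    studies = list(studies)
    if not studies:
        raise ValueError("no studies")
    betas = np.array([b for b, _ in studies], dtype=float)
    ses = np.array([s for _, s in studies], dtype=float)
    if np.any(ses <= 0):
        raise ValueError("all standard errors must be positive")
    w = 1.0 / ses**2
    beta = float(np.sum(w * betas) / np.sum(w))
    se = float(1.0 / math.sqrt(np.sum(w)))
    z = beta / se
    return MetaResult(
        beta=beta,
        se=se,
        or_=math.exp(beta),
        z=z,
        p_value=float(2 * stats.norm.sf(abs(z))),
        weights=tuple(float(x) for x in w),
    )
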