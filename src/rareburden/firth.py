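"""Firth penalized-likelihood logistic regression and the burden test.

Firth's correction maximizes the logistic log-likelihood plus a Jeffreys
prior penalty, 1/2 log det I(beta), where I is the Fisher information. The
penalty removes the first-order small-sample bias of the MLE and, crucially
for rare-variant burdens, yields finite estimates under complete or
quasi-complete separation (e.g. when every carrier of a rare allele is a
case). Estimation uses the modified-score Newton iteration

    U*(b)_j = sum_i (y_i - p_i + h_i (1/2 - p_i)) x_ij

with h_i the leverages of the weighted hat matrix, and step-halving whenever
a full step would decrease the penalized log-likelihood.

The burden test regresses case status on an individual's qualifying-allele
count with the covariate structure used in targeted case-control sequencing:
a baseline synonymous count, ten ancestry principal components, sex, and
(for the targeted-sequencing design only) sequencing-wave indicators.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, stats
from scipy.special import expit

logger = logging.getLogger(__name__)

_PC_COLUMNS = tuple(f"PC{i}" for i in range(1, 11))


class RankDeficientError(np.linalg.LinAlgError):
    """Design matrix is rank-deficient; carries the offending columns."""

    def __init__(self, columns):
        self.columns = list(columns)
        super().__init__(f"design matrix is rank deficient; collinear "
                         f"columns: {self.columns}")


class DegenerateBurdenError(ValueError):
    """Burden column has no variation: the test cannot be run."""


@dataclass
class FirthFit:
    """Result of a Firth penalized-likelihood logistic fit."""

    beta: np.ndarray
    se: np.ndarray
    loglik: float                 # penalized log-likelihood at the optimum
    iterations: int
    converged: bool
    columns: list = field(default_factory=list)
    cov: np.ndarray | None = None

    def coef(self, name: str) -> tuple[float, float]:
        i = self.columns.index(name)
        return float(self.beta[i]), float(self.se[i])


@dataclass
class AssociationResult:
    """One burden association: effect on the log-odds scale plus metadata."""

    log_or: float
    se: float
    or_point: float
    ci95_low: float
    ci95_high: float
    p_two_sided: float
    n_cases: int
    n_controls: int
    analysis_class: str = ""
    regime: str = ""
    gene_subset: str = ""

    def to_dict(self) -> dict:
        return {
            "gene_subset": self.gene_subset,
            "analysis_class": self.analysis_class,
            "regime": self.regime,
            "n_cases": self.n_cases,
            "n_controls": self.n_controls,
            "log_or": self.log_or,
            "se": self.se,
            "or": self.or_point,
            "ci95_low": self.ci95_low,
            "ci95_high": self.ci95_high,
            "p": self.p_two_sided,
        }


def _check_rank(X: np.ndarray, columns) -> None:
    # pivoted QR exposes which columns complete the rank loss
    _, r, piv = linalg.qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps if diag.size else 0.0
    rank = int((diag > tol).sum())
    if rank < X.shape[1]:
        bad = [columns[j] for j in piv[rank:]]
        raise RankDeficientError(bad)


def penalized_loglik(X: np.ndarray, y: np.ndarray, beta: np.ndarray) -> float:
    """Logistic log-likelihood plus the Jeffreys-prior penalty at ``beta``."""
    eta = X @ beta
    ll = float(y @ eta - np.logaddexp(0.0, eta).sum())
    p = expit(eta)
    w = p * (1.0 - p)
    info = (X * w[:, None]).T @ X
    sign, logdet = np.linalg.slogdet(info)
    if sign <= 0:
        return -np.inf
    return ll + 0.5 * logdet


def firth_fit(X, y, tol: float = 1e-8, max_iter: int = 100,
              columns=None) -> FirthFit:
    """Fit a Firth penalized-likelihood logistic regression.

    Parameters
    ----------
    X : (n, p) array
        Design matrix including the intercept column.
    y : (n,) array of 0/1
        Binary outcome.
    tol
        Convergence: max absolute coefficient update below ``tol``.
    max_iter
        Iteration cap; non-convergence is flagged on the result, never
        silent.
    columns
        Optional column names, used in error messages and ``coef``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or y.shape[0] != X.shape[0]:
        raise ValueError("X must be (n, p) and y length n")
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValueError("labels must be binary 0/1")
    n, p = X.shape
    columns = list(columns) if columns is not None else [f"x{j}" for j in range(p)]
    _check_rank(X, columns)

    beta = np.zeros(p)
    pll = penalized_loglik(X, y, beta)
    it = 0
    converged = False
    for it in range(1, max_iter + 1):
        eta = X @ beta
        prob = expit(eta)
        w = prob * (1.0 - prob)
        Xw = X * np.sqrt(w)[:, None]
        info = Xw.T @ Xw
        cho = linalg.cho_factor(info)
        # leverages of the weighted hat matrix
        h = np.einsum("ij,ij->i", Xw, linalg.cho_solve(cho, Xw.T).T)
        score = X.T @ (y - prob + h * (0.5 - prob))
        delta = linalg.cho_solve(cho, score)
        # step-halving keeps the penalized likelihood non-decreasing
        step = 1.0
        for _ in range(25):
            cand = beta + step * delta
            cand_pll = penalized_loglik(X, y, cand)
            if cand_pll >= pll - 1e-12:
                break
            step *= 0.5
        beta = beta + step * delta
        pll = penalized_loglik(X, y, beta)
        if np.max(np.abs(step * delta)) < tol:
            converged = True
            break
    if not converged:
        logger.warning("Firth fit did not converge in %d iterations", max_iter)

    prob = expit(X @ beta)
    w = prob * (1.0 - prob)
    info = (X * w[:, None]).T @ X
    cov = linalg.inv(info)
    se = np.sqrt(np.diag(cov))
    return FirthFit(beta=beta, se=se, loglik=pll, iterations=it,
                    converged=converged, columns=columns, cov=cov)


def wald_ci(beta: float, se: float, level: float = 0.95
            ) -> tuple[float, float]:
    """Wald confidence interval for the odds ratio exp(beta)."""
    if not (0 < level < 1):
        raise ValueError(f"level must be in (0, 1), got {level}")
    if se < 0:
        raise ValueError("se must be non-negative")
    z = stats.norm.ppf(0.5 + level / 2.0)
    return float(np.exp(beta - z * se)), float(np.exp(beta + z * se))


def wald_pvalue(beta: float, se: float) -> float:
    """Two-sided Wald p-value, 2 * Phi(-|beta / se|)."""
    if se <= 0:
        raise ValueError("se must be positive")
    return float(2.0 * stats.norm.sf(abs(beta) / se))


def _constrained_penalized_loglik(X: np.ndarray, y: np.ndarray,
                                  beta_start: np.ndarray, j: int) -> float:
    """Max penalized log-likelihood with coefficient ``j`` fixed at zero.

    The penalty stays that of the *full* design's Fisher information, so the
    penalized likelihood-ratio statistic compares like with like (dropping
    the column instead would shift the log-det penalty by the dimension
    change).
    """
    from scipy.optimize import minimize

    p = X.shape[1]
    free = [k for k in range(p) if k != j]

    def neg(bfree: np.ndarray) -> float:
        beta = np.zeros(p)
        beta[free] = bfree
        return -penalized_loglik(X, y, beta)

    start = beta_start[free]
    res = minimize(neg, start, method="BFGS",
                   options={"gtol": 1e-8, "maxiter": 500})
    return float(-res.fun)


def build_design(burden: pd.DataFrame, include_wave: bool = False,
                 include_cohort: bool = False,
                 extra_covariates: tuple = ()) -> tuple[np.ndarray, np.ndarray, list]:
    """Assemble (X, y, column names) for the burden regression.

    Covariates: burden count, baseline synonymous count, PC1..PC10 (those
    present), sex; wave indicator contrasts against the first wave when
    ``include_wave`` (the targeted-sequencing design only); cohort
    indicators when ``include_cohort`` (pooled meta-analysis). Covariates
    that are constant in the data are dropped with a logged warning; a
    constant burden column is an error.
    """
    required = ["n_test_variants", "baseline_synonymous_count", "is_case"]
    missing = [c for c in required if c not in burden.columns]
    if missing:
        raise ValueError(f"burden table is missing columns: {missing}")
    y = burden["is_case"].to_numpy(dtype=float)

    cols: list[str] = ["intercept"]
    data = [np.ones(len(burden))]

    if burden["n_test_variants"].nunique() < 2:
        raise DegenerateBurdenError(
            "n_test_variants is constant (no qualifying carriers vary); "
            "burden test skipped")
    covs = ["n_test_variants", "baseline_synonymous_count"]
    covs += [c for c in _PC_COLUMNS if c in burden.columns]
    if "sex" in burden.columns:
        covs.append("sex")
    covs += [c for c in extra_covariates if c in burden.columns]
    for c in covs:
        v = burden[c].to_numpy(dtype=float)
        if np.ptp(v) == 0:
            logger.warning("dropping constant covariate %r", c)
            continue
        cols.append(c)
        data.append(v)

    for flag, col in ((include_wave, "wave"), (include_cohort, "cohort")):
        if not flag:
            continue
        if col not in burden.columns:
            raise ValueError(f"covariate column {col!r} requested but absent")
        levels = sorted(pd.unique(burden[col]))
        if len(levels) < 2:
            logger.warning("covariate %r is constant within dataset; dropped",
                           col)
            continue
        for lev in levels[1:]:  # contrasts against the first level
            cols.append(f"{col}={lev}")
            data.append((burden[col] == lev).to_numpy(dtype=float))

    return np.column_stack(data), y, cols


def burden_test(burden: pd.DataFrame, include_wave: bool = False,
                include_cohort: bool = False,
                p_method: str = "wald",
                analysis_class: str = "", regime: str = "",
                gene_subset: str = "") -> AssociationResult:
    """Firth burden association test on a per-individual burden table.

    ``p_method`` selects Wald (default, matching how printed odds ratios,
    intervals and p-values cohere in published summary tables) or the
    penalized likelihood-ratio test (``"plr"``).
    """
    if p_method not in ("wald", "plr"):
        raise ValueError(f"unknown p_method {p_method!r}")
    X, y, cols = build_design(burden, include_wave, include_cohort)
    fit = firth_fit(X, y, columns=cols)
    beta, se = fit.coef("n_test_variants")
    if p_method == "wald":
        p = wald_pvalue(beta, se)
    else:
        j = cols.index("n_test_variants")
        pll0 = _constrained_penalized_loglik(X, y, fit.beta, j)
        lr = 2.0 * (fit.loglik - pll0)
        p = float(stats.chi2.sf(max(lr, 0.0), df=1))
    lo, hi = wald_ci(beta, se)
    return AssociationResult(
        log_or=beta, se=se, or_point=float(np.exp(beta)),
        ci95_low=lo, ci95_high=hi, p_two_sided=p,
        n_cases=int(burden["is_case"].sum()),
        n_controls=int((1 - burden["is_case"]).sum()),
        analysis_class=analysis_class, regime=regime, gene_subset=gene_subset)
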