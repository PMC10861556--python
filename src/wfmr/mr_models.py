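"""Association models of the within-family MR framework.

The framework regresses a child's binary disease status on polygenic scores
for maternal effects on birth weight, fit three ways on identical rows:

* PARENT_ONLY: ``disease ~ PGS_parent + covariates`` — the naive MR model,
  biased toward the fetal effect because the parent and child scores are
  correlated 0.5 through transmission;
* CHILD_ONLY:  ``disease ~ PGS_child + covariates``;
* JOINT:       ``disease ~ PGS_parent + PGS_child + covariates`` — the
  conditioned model whose parent term isolates the intrauterine path.

Under a purely fetal (pleiotropic) effect the PARENT_ONLY parent slope tends
to rho * beta_child (~half the child effect) while the JOINT parent slope
tends to zero; under a true maternal effect the parent slope is invariant to
adding the child's score.  The attenuation report quantifies this contrast.

Logistic fits use iteratively reweighted least squares (Newton-Raphson on
the binomial log-likelihood) with Wald standard errors from the inverse
observed information, a score-norm convergence tolerance of 1e-8, explicit
detection of rank deficiency (naming the collinear columns) and of
complete/quasi-complete separation (raising rather than silently penalising;
an optional Firth-penalised fallback is available for small strata).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import linalg, special, stats
from sklearn.base import BaseEstimator

from ._random import stage_rng
from .errors import ConvergenceError, SeparationError, ValidationError

__all__ = [
    "LogisticFit",
    "AssocResult",
    "AttenuationReport",
    "fit_logistic",
    "LogisticRegressionIRLS",
    "MRTriplet",
    "mr_triplet",
    "select_independent_pairs",
    "add_covariate_score",
]

_MAX_ABS_COEF = 40.0  # |beta| beyond this on standardized inputs => separation


@dataclass
class LogisticFit:
    """MLE output: coefficient vector with Wald inference."""

    params: pd.Series
    se: pd.Series
    pvalues: pd.Series
    cov: pd.DataFrame
    loglik: float
    n: int
    n_cases: int
    n_iter: int

    def zvalues(self) -> pd.Series:
        return self.params / self.se

    def conf_int(self, level: float = 0.95) -> pd.DataFrame:
        z = stats.norm.ppf(0.5 + level / 2.0)
        return pd.DataFrame({"low": self.params - z * self.se, "high": self.params + z * self.se})


@dataclass
class AssocResult:
    """One PGS term from one model, on the logOR-per-SD scale."""

    term: str  # PARENT_PGS | CHILD_PGS | covariate name
    logOR: float
    se: float
    p: float
    or_ci95: tuple[float, float]
    model: str  # PARENT_ONLY | CHILD_ONLY | JOINT | CONDITIONAL
    n: int
    n_cases: int

    @classmethod
    def from_fit(cls, fit: LogisticFit, column: str, term: str, model: str) -> "AssocResult":
        ci = fit.conf_int().loc[column]
        return cls(
            term=term,
            logOR=float(fit.params[column]),
            se=float(fit.se[column]),
            p=float(fit.pvalues[column]),
            or_ci95=(float(np.exp(ci["low"])), float(np.exp(ci["high"]))),
            model=model,
            n=fit.n,
            n_cases=fit.n_cases,
        )

    def to_dict(self) -> dict:
        d = self.__dict__.copy()
        d["or_ci95_low"], d["or_ci95_high"] = d.pop("or_ci95")
        return d


@dataclass
class AttenuationReport:
    """How the parent estimate changes when conditioning on the child's PGS."""

    parent_logOR_unadjusted: float
    parent_logOR_joint: float
    child_logOR_joint: float
    attenuation_ratio: float | None
    ratio_ci95: tuple[float, float] | None = None
    n_boot: int = 0


# ---------------------------------------------------------------------------
# core fitter
# ---------------------------------------------------------------------------

def _check_rank(X: np.ndarray, names: Sequence[str]) -> None:
    _, r, piv = linalg.qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps if diag.size else 0.0
    rank = int((diag > tol).sum())
    if rank < X.shape[1]:
        collinear = [names[j] for j in piv[rank:]]
        raise ValidationError(f"design matrix is rank deficient; collinear columns: {collinear}")


def _irls(y: np.ndarray, X: np.ndarray, tol: float, max_iter: int, firth: bool) -> tuple[np.ndarray, np.ndarray, float, int]:
    """Newton/IRLS on the binomial log-likelihood; returns (beta, cov, ll, iters)."""
    n, p = X.shape
    beta = np.zeros(p)
    ll_old = -np.inf
    for it in range(1, max_iter + 1):
        eta = X @ beta
        mu = special.expit(eta)
        w = mu * (1.0 - mu)
        xw = X * w[:, None]
        hess = X.T @ xw
        if firth:
            # hat diagonals of W^1/2 X (X'WX)^-1 X' W^1/2
            try:
                hinv_xt = np.linalg.solve(hess, X.T)
            except np.linalg.LinAlgError as exc:
                raise ConvergenceError("information matrix singular during Firth fit") from exc
            h = np.einsum("ij,ji->i", X, hinv_xt) * w
            score = X.T @ (y - mu + h * (0.5 - mu))
            sign, logdet = np.linalg.slogdet(hess)
            ll = float(np.sum(y * eta - np.logaddexp(0.0, eta)) + 0.5 * logdet)
        else:
            score = X.T @ (y - mu)
            ll = float(np.sum(y * eta - np.logaddexp(0.0, eta)))
        if np.linalg.norm(score) <= tol:
            try:
                cov = np.linalg.inv(hess)
            except np.linalg.LinAlgError as exc:
                raise SeparationError("information matrix singular at optimum (separation)") from exc
            return beta, cov, ll, it
        try:
            step = np.linalg.solve(hess, score)
        except np.linalg.LinAlgError as exc:
            raise SeparationError("information matrix singular (fitted probabilities at 0/1)") from exc
        # step-halving keeps the likelihood monotone
        scale = 1.0
        while scale > 1e-10:
            cand = beta + scale * step
            eta_c = X @ cand
            ll_c = float(np.sum(y * eta_c - np.logaddexp(0.0, eta_c)))
            if firth:
                mu_c = special.expit(eta_c)
                w_c = mu_c * (1.0 - mu_c)
                sign, logdet = np.linalg.slogdet(X.T @ (X * w_c[:, None]))
                ll_c += 0.5 * logdet if sign > 0 else -np.inf
            # accept unless the likelihood genuinely decreases (allow rounding noise)
            if ll_c >= ll - 1e-9 * (abs(ll) + 1.0) or scale <= 1e-10:
                break
            scale /= 2.0
        beta = beta + scale * step
        if np.max(np.abs(beta)) > _MAX_ABS_COEF and not firth:
            raise SeparationError(
                "diverging coefficients: complete or quasi-complete separation "
                "(consider firth=True for small strata)"
            )
        ll_old = ll
    raise ConvergenceError(f"IRLS did not converge in {max_iter} iterations (last log-lik {ll_old:.6g})")


def fit_logistic(
    y: Sequence[float] | np.ndarray | pd.Series,
    X: pd.DataFrame | np.ndarray,
    add_intercept: bool = True,
    tol: float = 1e-8,
    max_iter: int = 100,
    firth: bool = False,
) -> LogisticFit:
    """Maximum-likelihood logistic regression via IRLS.

    Parameters
    ----------
    y : binary outcome vector (both classes must be present).
    X : design matrix; a named DataFrame gives named coefficients.
    add_intercept : prepend an ``intercept`` column unless one exists.
    firth : use Firth's bias-reduced penalised likelihood (finite estimates
        under separation).

    Raises
    ------
    ValidationError  : degenerate outcome or rank-deficient design.
    SeparationError  : diverging MLE (complete/quasi-complete separation).
    ConvergenceError : iteration limit without convergence or separation.
    """
    y = np.asarray(y, dtype=float)
    if np.isnan(y).any() or not np.isin(y, (0.0, 1.0)).all():
        raise ValidationError("outcome must be binary 0/1 without missing values")
    n_cases = int(y.sum())
    if n_cases == 0 or n_cases == len(y):
        raise ValidationError("outcome has a single class; logistic model undefined")
    if isinstance(X, pd.DataFrame):
        names = list(X.columns)
        Xm = X.to_numpy(dtype=float)
    else:
        Xm = np.asarray(X, dtype=float)
        if Xm.ndim == 1:
            Xm = Xm[:, None]
        names = [f"x{i}" for i in range(Xm.shape[1])]
    if len(Xm) != len(y):
        raise ValidationError("outcome and design have different lengths")
    if add_intercept and "intercept" not in names:
        Xm = np.column_stack([np.ones(len(y)), Xm])
        names = ["intercept"] + names
    if np.isnan(Xm).any():
        raise ValidationError("design matrix contains missing values")
    _check_rank(Xm, names)
    beta, cov, ll, it = _irls(y, Xm, tol, max_iter, firth)
    se = np.sqrt(np.diag(cov))
    z = beta / se
    pvals = 2.0 * stats.norm.sf(np.abs(z))
    idx = pd.Index(names)
    return LogisticFit(
        params=pd.Series(beta, index=idx),
        se=pd.Series(se, index=idx),
        pvalues=pd.Series(pvals, index=idx),
        cov=pd.DataFrame(cov, index=idx, columns=idx),
        loglik=ll,
        n=len(y),
        n_cases=n_cases,
        n_iter=it,
    )


class LogisticRegressionIRLS(BaseEstimator):
    """sklearn-style wrapper around :func:`fit_logistic`.

    Fitted attributes: ``coef_`` (1, p), ``intercept_``, ``se_``,
    ``pvalues_``, ``n_iter_``.
    """

    def __init__(self, add_intercept: bool = True, tol: float = 1e-8, max_iter: int = 100, firth: bool = False):
        self.add_intercept = add_intercept
        self.tol = tol
        self.max_iter = max_iter
        self.firth = firth

    def fit(self, X, y):
        res = fit_logistic(y, X, self.add_intercept, self.tol, self.max_iter, self.firth)
        self.result_ = res
        params = res.params
        if self.add_intercept:
            self.intercept_ = float(params.iloc[0])
            self.coef_ = params.iloc[1:].to_numpy()[None, :]
            self.se_ = res.se.iloc[1:].to_numpy()
            self.pvalues_ = res.pvalues.iloc[1:].to_numpy()
        else:
            self.intercept_ = 0.0
            self.coef_ = params.to_numpy()[None, :]
            self.se_ = res.se.to_numpy()
            self.pvalues_ = res.pvalues.to_numpy()
        self.n_iter_ = res.n_iter
        return self

    def decision_function(self, X):
        Xm = X.to_numpy(dtype=float) if isinstance(X, pd.DataFrame) else np.asarray(X, dtype=float)
        return self.intercept_ + Xm @ self.coef_[0]

    def predict_proba(self, X):
        p1 = special.expit(self.decision_function(X))
        return np.column_stack([1.0 - p1, p1])

    def predict(self, X):
        return (self.decision_function(X) > 0).astype(int)


# ---------------------------------------------------------------------------
# MR triplet
# ---------------------------------------------------------------------------

class MRTriplet(BaseEstimator):
    """Fit PARENT_ONLY, CHILD_ONLY and JOINT models on identical pair rows.

    ``fit(df)`` expects one row per parent-child pair with the outcome,
    the two standardized PGS columns, and any covariate columns; the same
    covariates enter all three models.  Fitted attributes:

    * ``results_`` — {model: [AssocResult, ...]} for the PGS terms;
    * ``attenuation_`` — :class:`AttenuationReport` (bootstrap CI when
      ``n_boot`` > 0, pair-resampling);
    * ``fits_`` — the raw :class:`LogisticFit` objects.
    """

    def __init__(
        self,
        parent_col: str = "pgs_parent",
        child_col: str = "pgs_child",
        outcome_col: str = "outcome",
        covariates: Sequence[str] = (),
        firth: bool = False,
        n_boot: int = 0,
        seed: int = 0,
    ):
        self.parent_col = parent_col
        self.child_col = child_col
        self.outcome_col = outcome_col
        self.covariates = covariates
        self.firth = firth
        self.n_boot = n_boot
        self.seed = seed

    def _designs(self, df: pd.DataFrame) -> dict[str, pd.DataFrame]:
        cov = list(self.covariates)
        return {
            "PARENT_ONLY": df[[self.parent_col] + cov],
            "CHILD_ONLY": df[[self.child_col] + cov],
            "JOINT": df[[self.parent_col, self.child_col] + cov],
        }

    def _fit_all(self, df: pd.DataFrame) -> dict[str, LogisticFit]:
        y = df[self.outcome_col]
        return {m: fit_logistic(y, X, firth=self.firth) for m, X in self._designs(df).items()}

    def fit(self, df: pd.DataFrame, y=None):
        needed = [self.outcome_col, self.parent_col, self.child_col, *self.covariates]
        missing = [c for c in needed if c not in df.columns]
        if missing:
            raise ValidationError(f"pair table is missing columns: {missing}")
        df = df[needed].dropna()
        fits = self._fit_all(df)
        self.fits_ = fits
        self.results_ = {
            "PARENT_ONLY": [AssocResult.from_fit(fits["PARENT_ONLY"], self.parent_col, "PARENT_PGS", "PARENT_ONLY")],
            "CHILD_ONLY": [AssocResult.from_fit(fits["CHILD_ONLY"], self.child_col, "CHILD_PGS", "CHILD_ONLY")],
            "JOINT": [
                AssocResult.from_fit(fits["JOINT"], self.parent_col, "PARENT_PGS", "JOINT"),
                AssocResult.from_fit(fits["JOINT"], self.child_col, "CHILD_PGS", "JOINT"),
            ],
        }
        unadj = float(fits["PARENT_ONLY"].params[self.parent_col])
        joint_p = float(fits["JOINT"].params[self.parent_col])
        joint_c = float(fits["JOINT"].params[self.child_col])
        ratio = joint_p / unadj if unadj != 0.0 else None
        ci = None
        if self.n_boot > 0 and ratio is not None:
            rng = stage_rng(self.seed, "attenuation_boot")
            ratios = []
            idx = np.arange(len(df))
            for _ in range(self.n_boot):
                take = rng.choice(idx, size=len(idx), replace=True)
                sub = df.iloc[take]
                try:
                    f = {m: fit_logistic(sub[self.outcome_col], X.iloc[take], firth=self.firth)
                         for m, X in (("PARENT_ONLY", self._designs(df)["PARENT_ONLY"]),
                                      ("JOINT", self._designs(df)["JOINT"]))}
                except (SeparationError, ValidationError):
                    continue
                u = float(f["PARENT_ONLY"].params[self.parent_col])
                if u != 0.0:
                    ratios.append(float(f["JOINT"].params[self.parent_col]) / u)
            if ratios:
                lo, hi = np.percentile(ratios, [2.5, 97.5])
                ci = (float(lo), float(hi))
        self.attenuation_ = AttenuationReport(
            parent_logOR_unadjusted=unadj,
            parent_logOR_joint=joint_p,
            child_logOR_joint=joint_c,
            attenuation_ratio=ratio,
            ratio_ci95=ci,
            n_boot=self.n_boot if ci is not None else 0,
        )
        return self


def mr_triplet(
    pairs: pd.DataFrame,
    parent_col: str = "pgs_parent",
    child_col: str = "pgs_child",
    outcome_col: str = "outcome",
    covariates: Sequence[str] = (),
    firth: bool = False,
    n_boot: int = 0,
    seed: int = 0,
) -> tuple[dict[str, list[AssocResult]], AttenuationReport]:
    """Functional wrapper over :class:`MRTriplet`; returns (results, attenuation)."""
    est = MRTriplet(parent_col, child_col, outcome_col, covariates, firth, n_boot, seed).fit(pairs)
    return est.results_, est.attenuation_


# ---------------------------------------------------------------------------
# pair filtering and covariates
# ---------------------------------------------------------------------------

def select_independent_pairs(pairs: pd.DataFrame, mode: str = "one_child_per_mother") -> pd.DataFrame:
    """Reduce parent-child pairs to (approximately) independent ones.

    ``one_child_per_mother`` keeps the oldest child per parent (ties broken
    by child_id, so the result is deterministic).  ``max_4th_degree`` keeps
    one pair per family — the oldest parent in the family and her oldest
    child — which, in simulated cohorts where relatedness exists only inside
    families, guarantees no two retained individuals are closer than 4th
    degree.
    """
    required = {"parent_id", "child_id", "child_age"}
    if not required <= set(pairs.columns):
        raise ValidationError(f"pair table needs columns {sorted(required)}")
    ordered = pairs.sort_values(["child_age", "child_id"], ascending=[False, True], kind="mergesort")
    if mode == "one_child_per_mother":
        return ordered.drop_duplicates("parent_id", keep="first").sort_index()
    if mode == "max_4th_degree":
        if "family_id" not in pairs.columns:
            raise ValidationError("max_4th_degree filtering needs a family_id column")
        ordered = pairs.sort_values(
            ["parent_age", "child_age", "child_id"], ascending=[False, False, True], kind="mergesort"
        )
        return ordered.drop_duplicates("family_id", keep="first").sort_index()
    raise ValidationError(f"unknown filter mode: {mode!r}")


def add_covariate_score(design: pd.DataFrame, extra_pgs: pd.Series, name: str | None = None) -> pd.DataFrame:
    """Append a standardized extra score (e.g. gestational-length PGS) as covariate."""
    name = name or str(extra_pgs.name)
    if name in design.columns:
        raise ValidationError(f"covariate column already present: {name}")
    out = design.copy()
    out[name] = extra_pgs.reindex(design.index)
    if out[name].isna().any():
        raise ValidationError(f"extra score {name} does not cover all rows")
    return out
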