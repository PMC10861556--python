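"""Discordant-sibling analysis: within-family PGS effects.

Full siblings share their mother's genotype-mediated intrauterine
environment, so in a matched comparison of same-sex siblings discordant for
disease, any association between a birth-weight PGS and disease must come
from the siblings' *own* genomes — maternal effects cancel.  This is the
design's key identification property and complements the joint mother+child
model.

Estimation uses the exact 1:1 matched conditional likelihood

    L(beta) = prod_pairs exp(beta x_case) / (exp(beta x_case) + exp(beta x_control)),

equivalently an intercept-free logistic regression on the within-pair score
differences d = x_case - x_control with an all-ones response.  Ties (d = 0)
contribute a constant 1/2 and are retained.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from sklearn.base import BaseEstimator

from ._random import stage_rng
from .errors import SeparationError, ValidationError
from .family_sim import FamilyCohort
from .io import PhenotypeTable
from .mr_models import AssocResult

__all__ = ["SibPairSet", "select_discordant_pairs", "conditional_logit", "PairedConditionalLogit"]

_MAX_ABS_COEF = 40.0


@dataclass
class SibPairSet:
    """Same-sex disease-discordant full-sibling pairs with their PGS values.

    ``table`` columns: pair_id, family_id, case_individual,
    control_individual, sex, pgs_case, pgs_control.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"pair_id", "family_id", "case_individual", "control_individual", "sex", "pgs_case", "pgs_control"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValidationError(f"sibling pair table missing columns: {sorted(missing)}")

    @property
    def n_pairs(self) -> int:
        return len(self.table)

    def differences(self) -> np.ndarray:
        return (self.table["pgs_case"] - self.table["pgs_control"]).to_numpy(dtype=float)


def select_discordant_pairs(
    cohort: FamilyCohort,
    phenotypes: PhenotypeTable,
    scores: pd.DataFrame,
    score: str,
    endpoint: str = "disease",
    seed: int = 0,
) -> SibPairSet:
    """Select one same-sex disease-discordant full-sibling duo per family.

    Families offering several eligible duos contribute one, chosen uniformly
    at random under ``seed`` (keeping pairs independent across families).
    Families with no eligible duo are dropped; zero pairs overall raises.
    """
    if score not in scores.columns:
        raise ValidationError(f"score {score!r} not found in score matrix")
    duos = cohort.sibling_duos()
    if duos.empty:
        raise ValidationError("cohort contains no sibling duos")
    info = cohort.individuals.set_index("individual_id")
    pheno = phenotypes.table[endpoint]

    duos = duos.assign(
        sex1=info.loc[duos["sib1"], "sex"].to_numpy(),
        sex2=info.loc[duos["sib2"], "sex"].to_numpy(),
        y1=pheno.reindex(duos["sib1"]).to_numpy(),
        y2=pheno.reindex(duos["sib2"]).to_numpy(),
    )
    eligible = duos[(duos["sex1"] == duos["sex2"]) & (duos["y1"] + duos["y2"] == 1.0)]
    if eligible.empty:
        raise ValidationError(f"no same-sex discordant sibling pairs for endpoint {endpoint!r}")

    rng = stage_rng(seed, "sibling_pairs")
    # one duo per family, uniformly among that family's eligible duos
    eligible = eligible.sort_values("family_id", kind="mergesort").reset_index(drop=True)
    sizes = eligible.groupby("family_id", sort=False).size().to_numpy()
    starts = np.concatenate([[0], np.cumsum(sizes)[:-1]])
    picked = eligible.iloc[starts + rng.integers(0, sizes)]
    case = np.where(picked["y1"] == 1.0, picked["sib1"], picked["sib2"])
    control = np.where(picked["y1"] == 1.0, picked["sib2"], picked["sib1"])
    table = pd.DataFrame(
        {
            "pair_id": [f"P{i:06d}" for i in range(len(picked))],
            "family_id": picked["family_id"].to_numpy(),
            "case_individual": case,
            "control_individual": control,
            "sex": picked["sex1"].to_numpy(),
            "pgs_case": scores.loc[case, score].to_numpy(),
            "pgs_control": scores.loc[control, score].to_numpy(),
        }
    )
    return SibPairSet(table)


def _conditional_fit(d: np.ndarray, tol: float = 1e-10, max_iter: int = 100) -> tuple[float, float, int]:
    """1-D Newton on the paired conditional log-likelihood sum log expit(beta d)."""
    if np.all(d == 0):
        raise ValidationError("all within-pair PGS differences are zero; beta unidentifiable")
    nz = d[d != 0]
    if np.all(nz > 0) or np.all(nz < 0):
        raise SeparationError("all discordant pairs favour one direction; conditional MLE diverges")
    beta = 0.0
    for it in range(1, max_iter + 1):
        mu = special.expit(beta * d)
        score = float(np.sum(d * (1.0 - mu)))
        info = float(np.sum(d**2 * mu * (1.0 - mu)))
        if abs(score) <= tol:
            return beta, info, it
        beta += score / info
        if abs(beta) > _MAX_ABS_COEF:
            raise SeparationError("diverging conditional-logit coefficient (separation)")
    raise SeparationError("conditional-logit Newton iteration did not converge")


def conditional_logit(pairs: SibPairSet | np.ndarray) -> AssocResult:
    """Conditional logistic regression on 1:1 matched sibling pairs.

    Returns the within-family logOR per SD of the PGS with Wald SE and
    two-sided p-value.  Accepts a :class:`SibPairSet` or a raw vector of
    within-pair differences.
    """
    d = pairs.differences() if isinstance(pairs, SibPairSet) else np.asarray(pairs, dtype=float)
    if d.size == 0:
        raise ValidationError("no pairs supplied")
    beta, info, _ = _conditional_fit(d)
    se = float(1.0 / np.sqrt(info))
    z = beta / se
    p = float(2.0 * stats.norm.sf(abs(z)))
    ci = (float(np.exp(beta - 1.959963984540054 * se)), float(np.exp(beta + 1.959963984540054 * se)))
    return AssocResult(
        term="CHILD_PGS",
        logOR=float(beta),
        se=se,
        p=p,
        or_ci95=ci,
        model="CONDITIONAL",
        n=2 * len(d),
        n_cases=len(d),
    )


class PairedConditionalLogit(BaseEstimator):
    """sklearn-style estimator for the 1:1 matched conditional likelihood.

    ``fit(X)`` accepts a :class:`SibPairSet`, a vector of within-pair
    differences, or an (n, 2) array of (case, control) scores.  Fitted
    attributes: ``coef_``, ``se_``, ``pvalue_``, ``result_``.
    """

    def fit(self, X, y=None):
        if isinstance(X, SibPairSet):
            d = X.differences()
        else:
            arr = np.asarray(X, dtype=float)
            d = arr[:, 0] - arr[:, 1] if arr.ndim == 2 else arr
        res = conditional_logit(d)
        self.result_ = res
        self.coef_ = np.array([res.logOR])
        self.se_ = np.array([res.se])
        self.pvalue_ = res.p
        return self
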