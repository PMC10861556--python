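"""Polygenic score construction and standardization.

Unweighted scores count birth-weight-increasing effect alleles over a panel
subset (the convention for maternal instruments when per-SNP intrauterine
effect sizes are unknown); weighted scores use the per-allele maternal or
fetal weights.  All scores are reported as z-scores (SD units) relative to a
reference group, whole cohort by default.

The standard score catalog derived from a panel's effect classes:

========  ==========================================================
name      variant classes
========  ==========================================================
M-SPECIFIC   M_ONLY (strictly maternal effects; the primary instrument)
F-SPECIFIC   F_ONLY
M-ALL        M_ONLY + SHARED_CONC + SHARED_OPP
MF-ALL       M-ALL + F_ONLY + UNCLASSIFIED (the full panel)
weighted-maternal / weighted-fetal: all variants, weight columns
========  ==========================================================
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .errors import ValidationError
from .io import DosageMatrix, SNPPanel

__all__ = [
    "ScoreDefinition",
    "PGSMatrix",
    "PolygenicScorer",
    "unweighted_score",
    "weighted_score",
    "standardize",
    "score_catalog",
    "compute_scores",
]

_CATALOG_CLASSES = {
    "M-SPECIFIC": ("M_ONLY",),
    "F-SPECIFIC": ("F_ONLY",),
    "M-ALL": ("M_ONLY", "SHARED_CONC", "SHARED_OPP"),
    "MF-ALL": ("M_ONLY", "SHARED_CONC", "SHARED_OPP", "F_ONLY", "UNCLASSIFIED"),
}
# orientation check: which weight column defines "birth-weight increasing"
# for each class when building unweighted (allele-counting) scores
_ORIENTING_COLUMN = {
    "M_ONLY": "w_maternal",
    "SHARED_CONC": "w_maternal",
    "SHARED_OPP": "w_maternal",
    "F_ONLY": "w_fetal",
    "UNCLASSIFIED": None,
}


@dataclass(frozen=True)
class ScoreDefinition:
    """A named score: a panel subset and an optional weight column."""

    name: str
    classes: tuple[str, ...]
    weight_column: str | None = None  # None => unweighted allele count
    n_variants: int = 0
    empty: bool = False


@dataclass
class PGSMatrix:
    """Score values (individuals x scores) plus per-score variant counts."""

    values: pd.DataFrame
    n_variants_used: dict[str, int] = field(default_factory=dict)


def score_catalog(panel: SNPPanel) -> list[ScoreDefinition]:
    """Standard score definitions implied by a panel's effect classes.

    Sizes are reported from the panel as given; empty subsets are flagged
    rather than raising, so callers can skip them.
    """
    counts = panel.class_counts()
    defs = []
    for name, classes in _CATALOG_CLASSES.items():
        n = sum(counts[c] for c in classes)
        defs.append(ScoreDefinition(name, classes, None, n, empty=n == 0))
    all_classes = tuple(c for c in counts)
    for name, col in (("weighted-maternal", "w_maternal"), ("weighted-fetal", "w_fetal")):
        nz = int((panel.table[col] != 0).sum())
        defs.append(ScoreDefinition(name, all_classes, col, nz, empty=nz == 0))
    return defs


def _subset_matrix(dosages: DosageMatrix, panel_subset: SNPPanel) -> pd.DataFrame:
    missing = [v for v in panel_subset.variant_ids if v not in dosages.matrix.columns]
    if missing:
        raise ValidationError(f"subset variants absent from dosages: {missing}")
    return dosages.matrix.loc[:, panel_subset.variant_ids]


def unweighted_score(dosages: DosageMatrix, panel_subset: SNPPanel) -> pd.Series:
    """Raw allele-count score: sum of effect-allele dosages over the subset.

    Effect alleles must be pre-oriented to increase birth weight; a negative
    defining weight in the subset indicates mis-orientation and raises.
    """
    if panel_subset.n_variants == 0:
        raise ValidationError("cannot score an empty panel subset")
    for cls, grp in panel_subset.table.groupby("effect_class"):
        col = _ORIENTING_COLUMN[str(cls)]
        if col is not None and (grp[col] < 0).any():
            bad = grp.loc[grp[col] < 0, "variant_id"]
            raise ValidationError(
                f"effect alleles must be birth-weight increasing for unweighted scoring; negative {col} for: {list(bad)}"
            )
    mat = _subset_matrix(dosages, panel_subset)
    return mat.sum(axis=1).rename("raw_score")


def weighted_score(
    dosages: DosageMatrix, panel: SNPPanel, which: Literal["maternal", "fetal"]
) -> pd.Series:
    """Raw weighted score: sum of w * dosage with the chosen weight column."""
    col = {"maternal": "w_maternal", "fetal": "w_fetal"}[which]
    w = panel.table.set_index("variant_id")[col]
    if (w == 0).all():
        raise ValidationError(f"all {col} weights are zero; weighted score undefined")
    mat = _subset_matrix(dosages, panel)
    return pd.Series(mat.to_numpy() @ w.loc[mat.columns].to_numpy(), index=mat.index, name="raw_score")


def standardize(
    raw: pd.Series | pd.DataFrame,
    reference: Literal["whole_cohort", "within_role"] = "whole_cohort",
    roles: pd.Series | None = None,
) -> pd.Series | pd.DataFrame:
    """Convert raw scores to z-scores.

    ``whole_cohort`` pools all individuals for the reference mean/SD;
    ``within_role`` standardizes separately per role (requires ``roles``
    aligned to the score index).  SDs use the n-1 (sample) convention.
    """
    if isinstance(raw, pd.Series):
        return standardize(raw.to_frame(), reference, roles).iloc[:, 0]
    out = {}
    for name, col in raw.items():
        if reference == "within_role":
            if roles is None:
                raise ValidationError("within_role standardization requires a roles series")
            z = col.groupby(roles.loc[col.index]).transform(lambda g: (g - g.mean()) / g.std(ddof=1))
            if z.isna().any() and not col.isna().any():
                raise ValidationError(f"zero-variance score within a role: {name}")
        else:
            sd = col.std(ddof=1)
            if not sd > 0:
                raise ValidationError(f"zero-variance score: {name}")
            z = (col - col.mean()) / sd
        out[name] = z
    return pd.DataFrame(out, index=raw.index)


class PolygenicScorer(BaseEstimator, TransformerMixin):
    """Compute and standardize a set of polygenic scores from dosages.

    scikit-learn style transformer: ``fit`` learns the reference means/SDs
    (and which catalog scores are computable from the panel), ``transform``
    maps a dosage matrix to z-scores with the fitted reference, so new
    individuals can be scored on the fitting cohort's scale.

    Parameters
    ----------
    panel : SNPPanel
    scores : "all" or sequence of catalog names
        Empty catalog entries are skipped under "all" but raise if requested
        explicitly.
    standardize : "whole_cohort" | "within_role" | None
        None returns raw scores from ``transform``.
    """

    def __init__(
        self,
        panel: SNPPanel | None = None,
        scores: str | Sequence[str] = "all",
        standardize: str | None = "whole_cohort",
    ):
        self.panel = panel
        self.scores = scores
        self.standardize = standardize

    def _raw(self, dosages: DosageMatrix) -> tuple[pd.DataFrame, dict[str, int]]:
        panel = self.panel.restrict(dosages.variant_ids)
        catalog = {d.name: d for d in score_catalog(panel)}
        if self.scores == "all":
            wanted = [d for d in catalog.values() if not d.empty]
        else:
            unknown = [s for s in self.scores if s not in catalog]
            if unknown:
                raise ValidationError(f"unknown score names: {unknown}")
            wanted = [catalog[s] for s in self.scores]
            empties = [d.name for d in wanted if d.empty]
            if empties:
                raise ValidationError(f"requested scores have no usable variants: {empties}")
        cols, used = {}, {}
        for d in wanted:
            if d.weight_column is None:
                cols[d.name] = unweighted_score(dosages, panel.subset(d.classes))
            else:
                which = "maternal" if d.weight_column == "w_maternal" else "fetal"
                cols[d.name] = weighted_score(dosages, panel, which)
            used[d.name] = d.n_variants
        return pd.DataFrame(cols), used

    def fit(self, X: DosageMatrix, y=None, roles: pd.Series | None = None):
        if self.panel is None:
            raise ValidationError("PolygenicScorer requires a panel")
        raw, used = self._raw(X)
        self.n_variants_used_ = used
        self.score_names_ = list(raw.columns)
        self._fit_roles = roles
        if self.standardize == "within_role":
            if roles is None:
                raise ValidationError("within_role standardization requires roles at fit time")
            grouped = raw.groupby(roles.loc[raw.index].to_numpy())
            self.means_ = grouped.mean()
            self.sds_ = grouped.std(ddof=1)
        else:
            self.means_ = raw.mean()
            self.sds_ = raw.std(ddof=1)
        if self.standardize is not None and np.any(~(np.asarray(self.sds_) > 0)):
            bad = [c for c in raw.columns if not np.all(np.asarray(self.sds_)[..., raw.columns.get_loc(c)] > 0)]
            raise ValidationError(f"zero-variance score(s): {bad}")
        return self

    def transform(self, X: DosageMatrix, roles: pd.Series | None = None) -> pd.DataFrame:
        raw, _ = self._raw(X)
        raw = raw[self.score_names_]
        if self.standardize is None:
            return raw
        if self.standardize == "within_role":
            roles = roles if roles is not None else self._fit_roles
            r = roles.loc[raw.index].to_numpy()
            mu = self.means_.loc[r].to_numpy()
            sd = self.sds_.loc[r].to_numpy()
            return pd.DataFrame((raw.to_numpy() - mu) / sd, index=raw.index, columns=raw.columns)
        return (raw - self.means_) / self.sds_

    def fit_transform(self, X: DosageMatrix, y=None, **fit_params) -> pd.DataFrame:
        return self.fit(X, y, **fit_params).transform(X, fit_params.get("roles"))


def compute_scores(
    dosages: DosageMatrix,
    panel: SNPPanel,
    scores: str | Sequence[str] = "all",
    standardize: str | None = "whole_cohort",
    roles: pd.Series | None = None,
) -> PGSMatrix:
    """One-shot convenience wrapper over :class:`PolygenicScorer`."""
    scorer = PolygenicScorer(panel=panel, scores=scores, standardize=standardize)
    values = scorer.fit_transform(dosages, roles=roles)
    return PGSMatrix(values=values, n_variants_used=scorer.n_variants_used_)
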