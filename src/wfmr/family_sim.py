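"""Synthetic family cohorts with the statistical structure the MR design assumes.

The generator emulates, stage by stage, the data-generating process the
within-family analysis relies on:

1.  **Parental genotypes** at independent biallelic loci, drawn per locus as
    Binomial(2, eaf), i.e. Hardy-Weinberg equilibrium under random mating
    (an optional assortative-mating knob induces a parental-score
    correlation via a Gaussian-copula matching of spouses).
2.  **Mendelian transmission**: each child receives one allele from each
    parent; a heterozygous parent transmits the effect allele with
    probability 1/2, independently across loci.  This yields the
    parent-offspring polygenic-score correlation of 0.5 that the joint
    mother+child model must condition on.
3.  **Birth weight** as maternal-genome effect + fetal-genome effect +
    Gaussian noise: the maternal component is a weighted sum over the
    *mother's* genotypes, the fetal component over the *child's* own
    genotypes, with configurable variance fractions, rescaled to gram units.
4.  **Binary disease** from the logistic risk function
    ``risk = expit(alpha + beta_child * PGS_child + beta_mother * PGS_mother)``
    with the intercept ``alpha`` calibrated deterministically so that the
    expected risk equals the target prevalence.

Loci are simulated without linkage disequilibrium, X-chromosome dosage or
imprinting; "principal component" covariates are pure noise (no population
structure).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from ._random import stage_rng
from .errors import ValidationError
from .io import EFFECT_CLASSES, DosageMatrix, PhenotypeTable, SNPPanel

__all__ = [
    "DiseaseScenario",
    "PGSPairSample",
    "FamilyCohort",
    "simulate_panel",
    "simulate_families",
    "assign_birthweight",
    "assign_disease",
    "sample_pgs_pairs",
    "calibrate_intercept",
    "simulate_covariates",
    "DEFAULT_CLASS_MIX",
]

#: Default variant-class proportions, matching the lead-SNP birth-weight
#: panel used by the study design this package emulates (32 maternal-only,
#: 68 fetal-only, 27 shared-concordant, 15 shared-opposing, 71 unclassified).
DEFAULT_CLASS_MIX: dict[str, float] = {
    "M_ONLY": 32 / 213,
    "F_ONLY": 68 / 213,
    "SHARED_CONC": 27 / 213,
    "SHARED_OPP": 15 / 213,
    "UNCLASSIFIED": 71 / 213,
}

#: Child age distribution (years): mean 46.3, SD 14.2, truncated at 18.
CHILD_AGE_MEAN, CHILD_AGE_SD, CHILD_AGE_MIN = 46.3, 14.2, 18.0
_PARENT_AGE_GAP_MEAN, _PARENT_AGE_GAP_SD, _PARENT_AGE_GAP_MIN = 25.0, 4.0, 15.0


@dataclass(frozen=True)
class DiseaseScenario:
    """Causal scenario for the binary endpoint.

    ``beta_maternal`` and ``beta_child`` are log odds ratios per SD of the
    mother's and the child's standardized PGS.  Under
    ``mediation="via_birthweight"`` the maternal path runs through the
    generated birth weight instead (beta_maternal is then per SD of birth
    weight), emulating a true intrauterine (DOHaD) mechanism rather than a
    direct PGS effect.
    """

    beta_maternal: float
    beta_child: float
    prevalence: float
    mediation: str = "direct_pgs"

    def __post_init__(self) -> None:
        if not 0.0 < self.prevalence < 1.0:
            raise ValidationError(f"prevalence must lie in (0, 1), got {self.prevalence}")
        if self.mediation not in ("direct_pgs", "via_birthweight"):
            raise ValidationError(f"unknown mediation mode: {self.mediation!r}")


@dataclass
class PGSPairSample:
    """Bivariate-normal mother/child PGS draws (means 0, variances 1)."""

    mother: np.ndarray
    child: np.ndarray
    rho: float

    @property
    def n(self) -> int:
        return len(self.mother)


@dataclass
class FamilyCohort:
    """Simulated individuals (mother, father, children) plus their dosages.

    ``individuals`` columns: family_id, individual_id, role, sex, age,
    mother_id, father_id (parent links set for children only).
    """

    individuals: pd.DataFrame
    dosages: DosageMatrix

    def __post_init__(self) -> None:
        kids = self.individuals[self.individuals["role"] == "CHILD"]
        if kids["mother_id"].isna().any() or kids["father_id"].isna().any():
            raise ValidationError("every CHILD must link to one MOTHER and one FATHER")

    def of_role(self, role: str) -> pd.DataFrame:
        return self.individuals[self.individuals["role"] == role]

    def parent_child_pairs(self, parent_role: str = "MOTHER") -> pd.DataFrame:
        """One row per (parent, child) pair: parent_id, child_id, ages, family."""
        link = "mother_id" if parent_role == "MOTHER" else "father_id"
        kids = self.of_role("CHILD")
        parents = self.individuals.set_index("individual_id")
        out = pd.DataFrame(
            {
                "family_id": kids["family_id"].to_numpy(),
                "parent_id": kids[link].to_numpy(),
                "child_id": kids["individual_id"].to_numpy(),
                "child_age": kids["age"].to_numpy(),
                "child_sex": kids["sex"].to_numpy(),
            }
        )
        out["parent_age"] = parents.loc[out["parent_id"], "age"].to_numpy()
        return out

    def sibling_duos(self) -> pd.DataFrame:
        """All unordered full-sibling duos within each family."""
        kids = self.of_role("CHILD")
        rows = []
        for fam, grp in kids.groupby("family_id", sort=True):
            ids = grp["individual_id"].to_numpy()
            for i in range(len(ids)):
                for j in range(i + 1, len(ids)):
                    rows.append((fam, ids[i], ids[j]))
        return pd.DataFrame(rows, columns=["family_id", "sib1", "sib2"])


# ---------------------------------------------------------------------------
# panel simulation
# ---------------------------------------------------------------------------

def _allocate_counts(n: int, mix: Mapping[str, float]) -> dict[str, int]:
    """Largest-remainder apportionment of n variants to classes."""
    props = np.array([mix.get(c, 0.0) for c in EFFECT_CLASSES], dtype=float)
    if (props < 0).any() or not np.isclose(props.sum(), 1.0):
        raise ValidationError("class_mix proportions must be nonnegative and sum to 1")
    raw = props * n
    counts = np.floor(raw).astype(int)
    for idx in np.argsort(-(raw - counts))[: n - counts.sum()]:
        counts[idx] += 1
    return dict(zip(EFFECT_CLASSES, (int(c) for c in counts)))


def simulate_panel(
    n_snps: int,
    maf_low: float = 0.05,
    maf_high: float = 0.45,
    class_mix: Mapping[str, float] | None = None,
    effect_scale: float = 1.0,
    seed: int = 0,
) -> SNPPanel:
    """Draw a synthetic SNP panel.

    Allele frequencies are uniform on [maf_low, maf_high].  Per-allele
    weights are half-normal draws, oriented so the effect allele increases
    birth weight through its *defining* genome (for shared-opposing variants
    the maternal weight is positive and the fetal weight negative), then
    rescaled so the total additive variance ``sum 2 p (1-p) w^2`` of each
    nonzero weight column equals ``effect_scale``.  Unclassified variants
    carry both maternal and fetal weights.
    """
    if n_snps <= 0:
        raise ValidationError("n_snps must be positive")
    if not 0.0 < maf_low <= maf_high < 0.5:
        raise ValidationError("require 0 < maf_low <= maf_high < 0.5")
    if effect_scale < 0:
        raise ValidationError("effect_scale must be nonnegative")
    mix = dict(class_mix) if class_mix is not None else dict(DEFAULT_CLASS_MIX)
    total = sum(mix.values())
    if total <= 0:
        raise ValidationError("class_mix proportions must have a positive sum")
    mix = {k: v / total for k, v in mix.items()}
    counts = _allocate_counts(n_snps, mix)

    rng = stage_rng(seed, "panel")
    classes = np.concatenate([[c] * counts[c] for c in EFFECT_CLASSES])
    rng.shuffle(classes)
    eaf = rng.uniform(maf_low, maf_high, n_snps)
    w_m = np.abs(rng.normal(size=n_snps))
    w_f = np.abs(rng.normal(size=n_snps))
    w_m[np.isin(classes, ["F_ONLY"])] = 0.0
    w_f[np.isin(classes, ["M_ONLY"])] = 0.0
    w_f[classes == "SHARED_OPP"] *= -1.0

    het = 2.0 * eaf * (1.0 - eaf)
    for w in (w_m, w_f):
        var = float(np.sum(het * w**2))
        if var > 0:
            w *= np.sqrt(effect_scale / var) if effect_scale > 0 else 0.0
    alleles = rng.choice(list("ACGT"), size=n_snps)
    table = pd.DataFrame(
        {
            "variant_id": [f"rs{seed % 1000}{i:05d}" for i in range(n_snps)],
            "effect_allele": alleles,
            "eaf": eaf,
            "effect_class": classes,
            "w_maternal": w_m,
            "w_fetal": w_f,
        }
    )
    return SNPPanel(table)


# ---------------------------------------------------------------------------
# family simulation
# ---------------------------------------------------------------------------

def _match_spouses(score_m: np.ndarray, score_f: np.ndarray, rho: float, rng: np.random.Generator) -> np.ndarray:
    """Permutation of fathers inducing ~rho rank correlation with mothers.

    Gaussian-copula matching: draw target normals correlated with the
    mothers' score ranks, then align father score ranks to the targets.
    """
    n = len(score_m)
    z_m = stats.norm.ppf((stats.rankdata(score_m) - 0.5) / n)
    target = rho * z_m + np.sqrt(1 - rho**2) * rng.normal(size=n)
    order_f = np.argsort(score_f)
    perm = np.empty(n, dtype=int)
    perm[np.argsort(target)] = order_f
    return perm


def simulate_families(
    panel: SNPPanel,
    n_families: int,
    seed: int = 0,
    n_children: int = 1,
    parent_pgs_corr: float = 0.0,
) -> FamilyCohort:
    """Simulate mother/father/child families with Mendelian transmission.

    Parents are drawn per locus as Binomial(2, eaf) (HWE).  Each child
    receives, independently per locus, one allele from each parent; the
    transmitted allele is the effect allele with probability dosage/2.
    ``n_children=2`` adds a full sibling for the discordant-pair analyses.
    ``parent_pgs_corr`` > 0 matches spouses on their birth-weight genetic
    value to emulate assortative mating (default: random mating).
    """
    if n_families <= 0:
        raise ValidationError("n_families must be positive")
    if n_children < 1:
        raise ValidationError("n_children must be >= 1")
    if not -1.0 < parent_pgs_corr < 1.0:
        raise ValidationError("parent_pgs_corr must lie in (-1, 1)")

    rng = stage_rng(seed, "families")
    p = panel.table["eaf"].to_numpy()
    n_snps = len(p)
    mother = rng.binomial(2, p, size=(n_families, n_snps)).astype(float)
    father = rng.binomial(2, p, size=(n_families, n_snps)).astype(float)
    if parent_pgs_corr != 0.0:
        w = panel.table["w_maternal"].to_numpy() + panel.table["w_fetal"].to_numpy()
        if not np.any(w):
            w = np.ones(n_snps)
        father = father[_match_spouses(mother @ w, father @ w, parent_pgs_corr, rng)]

    children = []
    for _ in range(n_children):
        mat_transmit = rng.binomial(1, mother / 2.0)
        pat_transmit = rng.binomial(1, father / 2.0)
        children.append((mat_transmit + pat_transmit).astype(float))

    fam_ids = np.array([f"F{i:06d}" for i in range(n_families)])
    a_lo = (CHILD_AGE_MIN - CHILD_AGE_MEAN) / CHILD_AGE_SD
    child_ages = [
        stats.truncnorm.rvs(a_lo, np.inf, loc=CHILD_AGE_MEAN, scale=CHILD_AGE_SD, size=n_families, random_state=rng)
        for _ in range(n_children)
    ]
    oldest = np.max(np.column_stack(child_ages), axis=1)
    gap_lo = (_PARENT_AGE_GAP_MIN - _PARENT_AGE_GAP_MEAN) / _PARENT_AGE_GAP_SD
    mother_age = oldest + stats.truncnorm.rvs(
        gap_lo, np.inf, loc=_PARENT_AGE_GAP_MEAN, scale=_PARENT_AGE_GAP_SD, size=n_families, random_state=rng
    )
    father_age = oldest + stats.truncnorm.rvs(
        gap_lo, np.inf, loc=_PARENT_AGE_GAP_MEAN + 1.2, scale=_PARENT_AGE_GAP_SD, size=n_families, random_state=rng
    )

    frames = [
        pd.DataFrame(
            {
                "family_id": fam_ids,
                "individual_id": [f + "_M" for f in fam_ids],
                "role": "MOTHER",
                "sex": "F",
                "age": mother_age,
                "mother_id": pd.NA,
                "father_id": pd.NA,
            }
        ),
        pd.DataFrame(
            {
                "family_id": fam_ids,
                "individual_id": [f + "_P" for f in fam_ids],
                "role": "FATHER",
                "sex": "M",
                "age": father_age,
                "mother_id": pd.NA,
                "father_id": pd.NA,
            }
        ),
    ]
    dosage_blocks = {**{f + "_M": g for f, g in zip(fam_ids, mother)}, **{f + "_P": g for f, g in zip(fam_ids, father)}}
    for k, child in enumerate(children, start=1):
        ids = [f + f"_C{k}" for f in fam_ids]
        frames.append(
            pd.DataFrame(
                {
                    "family_id": fam_ids,
                    "individual_id": ids,
                    "role": "CHILD",
                    "sex": np.where(rng.random(n_families) < 0.5, "F", "M"),
                    "age": child_ages[k - 1],
                    "mother_id": [f + "_M" for f in fam_ids],
                    "father_id": [f + "_P" for f in fam_ids],
                }
            )
        )
        dosage_blocks.update({i: g for i, g in zip(ids, child)})

    individuals = pd.concat(frames, ignore_index=True)
    matrix = pd.DataFrame.from_dict(dosage_blocks, orient="index", columns=panel.variant_ids)
    matrix.index.name = "individual_id"
    matrix = matrix.loc[individuals["individual_id"]]
    return FamilyCohort(individuals, DosageMatrix(matrix))


# ---------------------------------------------------------------------------
# phenotypes
# ---------------------------------------------------------------------------

def _standardized_component(values: np.ndarray, label: str) -> np.ndarray:
    sd = values.std()
    if sd == 0:
        raise ValidationError(f"{label} genetic component has zero variance; cannot target a nonzero h2")
    return (values - values.mean()) / sd


def assign_birthweight(
    cohort: FamilyCohort,
    panel: SNPPanel,
    h2_maternal: float = 0.02,
    h2_fetal: float = 0.05,
    mean_g: float = 3500.0,
    sd_g: float = 500.0,
    seed: int = 0,
) -> PhenotypeTable:
    """Assign children a birth weight partitioned into maternal and fetal parts.

    birth_weight = mean_g + sd_g * (sqrt(h2_m) * z(G_mother) +
    sqrt(h2_f) * z(G_child) + sqrt(1 - h2_m - h2_f) * eps), where G_mother is
    the mother's w_maternal-weighted dosage sum, G_child the child's
    w_fetal-weighted sum, and eps standard normal.  The defaults correspond
    to a lead-SNP panel explaining a few percent of birth-weight variance.
    Only children receive a value; parents get NaN.
    """
    if h2_maternal < 0 or h2_fetal < 0:
        raise ValidationError("variance fractions must be nonnegative")
    if h2_maternal + h2_fetal >= 1:
        raise ValidationError("h2_maternal + h2_fetal must be < 1")
    rng = stage_rng(seed, "birthweight")
    kids = cohort.of_role("CHILD")
    mat = cohort.dosages.matrix
    w_m = panel.table.set_index("variant_id").loc[mat.columns, "w_maternal"].to_numpy()
    w_f = panel.table.set_index("variant_id").loc[mat.columns, "w_fetal"].to_numpy()

    g_mother = mat.loc[kids["mother_id"]].to_numpy() @ w_m
    g_child = mat.loc[kids["individual_id"]].to_numpy() @ w_f
    n = len(kids)
    bw_z = np.sqrt(1.0 - h2_maternal - h2_fetal) * rng.normal(size=n)
    if h2_maternal > 0:
        bw_z += np.sqrt(h2_maternal) * _standardized_component(g_mother, "maternal")
    if h2_fetal > 0:
        bw_z += np.sqrt(h2_fetal) * _standardized_component(g_child, "fetal")

    table = cohort.individuals.set_index("individual_id")[["family_id", "role", "sex", "age"]].copy()
    table["birth_weight"] = np.nan
    table.loc[kids["individual_id"], "birth_weight"] = mean_g + sd_g * bw_z
    return PhenotypeTable(table)


def calibrate_intercept(
    prevalence: float,
    beta_mother: float = 0.0,
    beta_child: float = 0.0,
    rho: float = 0.5,
    n_nodes: int = 128,
) -> float:
    """Intercept alpha with E[expit(alpha + eta)] = prevalence.

    The linear predictor eta = beta_mother*PGS_m + beta_child*PGS_c is
    normal with variance b_m^2 + b_c^2 + 2 rho b_m b_c when the PGS pair is
    standard bivariate normal with correlation rho; the expectation over eta
    is computed by Gauss-Hermite quadrature and inverted by Brent
    root-finding.  Deterministic (no sampling), so calibration does not
    consume random numbers.
    """
    if not 0.0 < prevalence < 1.0:
        raise ValidationError(f"prevalence must lie in (0, 1), got {prevalence}")
    eta_sd = float(np.sqrt(beta_mother**2 + beta_child**2 + 2.0 * rho * beta_mother * beta_child))
    if eta_sd == 0.0:
        return float(special.logit(prevalence))
    nodes, weights = np.polynomial.hermite.hermgauss(n_nodes)
    z = np.sqrt(2.0) * nodes
    wts = weights / np.sqrt(np.pi)

    def mean_risk(alpha: float) -> float:
        return float(np.sum(wts * special.expit(alpha + eta_sd * z)) - prevalence)

    return float(optimize.brentq(mean_risk, -40.0, 40.0, xtol=1e-12))


def _calibrate_on_sample(eta: np.ndarray, prevalence: float) -> float:
    """Empirical-intercept variant: mean over realized linear predictors."""

    def mean_risk(alpha: float) -> float:
        return float(np.mean(special.expit(alpha + eta)) - prevalence)

    return float(optimize.brentq(mean_risk, -40.0, 40.0, xtol=1e-12))


def assign_disease(
    cohort: FamilyCohort,
    phenotypes: PhenotypeTable,
    scenario: DiseaseScenario,
    scores: pd.DataFrame,
    score: str,
    seed: int = 0,
    endpoint: str = "disease",
) -> PhenotypeTable:
    """Draw children's binary disease status from the logistic risk function.

    ``scores`` holds standardized PGS values (individuals x score columns);
    the maternal term uses the mother's value of ``score``, the child term
    the child's own value.  Under ``mediation="via_birthweight"`` the
    maternal path instead uses the child's standardized birth weight, so a
    maternal-genome effect reaches disease only through intrauterine growth.
    Case status is Bernoulli(risk) per child; parents get NaN.
    """
    rng = stage_rng(seed, "disease")
    kids = cohort.of_role("CHILD")
    if score not in scores.columns:
        raise ValidationError(f"score {score!r} not found in score matrix")
    pgs_child = scores.loc[kids["individual_id"], score].to_numpy()

    if scenario.mediation == "via_birthweight":
        bw = phenotypes.table.loc[kids["individual_id"], "birth_weight"].to_numpy()
        if np.isnan(bw).any():
            raise ValidationError("birth weight must be assigned before via_birthweight disease")
        maternal_term = (bw - bw.mean()) / bw.std()
        eta = scenario.beta_maternal * maternal_term + scenario.beta_child * pgs_child
        alpha = _calibrate_on_sample(eta, scenario.prevalence)
    else:
        pgs_mother = scores.loc[kids["mother_id"], score].to_numpy()
        eta = scenario.beta_maternal * pgs_mother + scenario.beta_child * pgs_child
        alpha = calibrate_intercept(scenario.prevalence, scenario.beta_maternal, scenario.beta_child)

    risk = special.expit(alpha + eta)
    status = (rng.random(len(kids)) < risk).astype(float)
    out = phenotypes.table.copy()
    out[endpoint] = np.nan
    out.loc[kids["individual_id"], endpoint] = status
    return PhenotypeTable(out, phenotypes.endpoints + (endpoint,))


def sample_pgs_pairs(n: int, rho: float = 0.5, seed: int = 0, rng: np.random.Generator | None = None) -> PGSPairSample:
    """Bivariate-normal mother/child PGS pairs (means 0, variances 1)."""
    if n <= 0:
        raise ValidationError("n must be positive")
    if not -1.0 < rho < 1.0:
        raise ValidationError("rho must lie in (-1, 1)")
    if rng is None:
        rng = stage_rng(seed, "pgs_pairs")
    z = rng.standard_normal((n, 2))
    mother = z[:, 0]
    child = rho * z[:, 0] + np.sqrt(1.0 - rho**2) * z[:, 1]
    return PGSPairSample(mother=mother, child=child, rho=rho)


def simulate_covariates(
    individual_ids: Sequence[str],
    seed: int = 0,
    n_pcs: int = 10,
    n_batches: int = 8,
) -> pd.DataFrame:
    """Structural stand-in covariates: noise PCs and a random batch factor.

    The PC columns are i.i.d. standard normal (no population structure is
    generated) and the genotyping batch is uniform over ``n_batches`` levels,
    returned as 0/1 indicator columns (first level as reference).
    """
    rng = stage_rng(seed, "covariates")
    n = len(individual_ids)
    cols = {f"PC{i + 1}": rng.standard_normal(n) for i in range(n_pcs)}
    batch = rng.integers(0, n_batches, size=n)
    for b in range(1, n_batches):
        cols[f"batch_{b}"] = (batch == b).astype(float)
    return pd.DataFrame(cols, index=pd.Index(individual_ids, name="individual_id"))
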