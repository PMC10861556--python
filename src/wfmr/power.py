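"""Simulation-based power analysis for the joint mother+child model.

Each replicate executes the four-step recipe the framework's power analysis
prescribes:

1. draw N mother/child PGS pairs from a bivariate normal distribution
   (means 0, variances 1, correlation rho = 0.5, the parent-offspring value);
2. form per-child risk through the logistic function
   ``risk = expit(alpha + beta_child * PGS_child + beta_mother * PGS_mother)``
   with the intercept alpha calibrated so that the expected risk equals the
   observed disease prevalence (cases / pairs);
3. draw Bernoulli case-control status from the risk values;
4. regress status jointly on both PGSs and record the Wald p-values.

Power for a coefficient is the fraction of replicates with p below the test
level (default alpha = 0.05, no multiplicity correction).  Replicates use
independently spawned seeds, so estimates are invariant to the parallel
schedule.  ``min_detectable_or`` sweeps an OR grid (default step 0.01)
upward and reports the smallest OR whose estimated power reaches the target,
with the Monte-Carlo SE of the bracketing grid points.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import special, stats

from ._random import spawn_rngs, stage_rng
from .errors import ValidationError
from .family_sim import calibrate_intercept, sample_pgs_pairs
from .mr_models import fit_logistic

__all__ = [
    "PowerEstimate",
    "MinDetectableOR",
    "simulate_once",
    "estimate_power",
    "power_grid",
    "min_detectable_or",
    "analytic_power",
]


@dataclass
class PowerEstimate:
    """One PowerGrid row: estimated power with Monte-Carlo error."""

    beta_mother: float
    beta_child: float
    prevalence: float
    n_pairs: int
    reps: int
    alpha: float
    power_mother: float
    power_child: float

    @property
    def mc_se_mother(self) -> float:
        return float(np.sqrt(self.power_mother * (1.0 - self.power_mother) / self.reps))

    @property
    def mc_se_child(self) -> float:
        return float(np.sqrt(self.power_child * (1.0 - self.power_child) / self.reps))

    def to_dict(self) -> dict:
        d = self.__dict__.copy()
        d["mc_se_mother"] = self.mc_se_mother
        d["mc_se_child"] = self.mc_se_child
        return d


@dataclass
class MinDetectableOR:
    """Smallest grid OR reaching the target power, with the evaluated grid."""

    or_value: float
    beta: float
    target_power: float
    grid: pd.DataFrame = field(repr=False)

    def bracketing(self) -> pd.DataFrame:
        """The grid rows just below and at the detected boundary."""
        at = self.grid[self.grid["or_mother"] >= self.or_value].head(1)
        below = self.grid[self.grid["or_mother"] < self.or_value].tail(1)
        return pd.concat([below, at])


def _one_rep(
    rng: np.random.Generator,
    n_pairs: int,
    beta_mother: float,
    beta_child: float,
    alpha_intercept: float,
    rho: float,
    on_degenerate: str,
) -> tuple[float, float]:
    for _ in range(100):
        pair = sample_pgs_pairs(n_pairs, rho=rho, rng=rng)
        risk = special.expit(alpha_intercept + beta_mother * pair.mother + beta_child * pair.child)
        y = (rng.random(n_pairs) < risk).astype(float)
        n_cases = y.sum()
        if 0 < n_cases < n_pairs:
            X = np.column_stack([pair.mother, pair.child])
            fit = fit_logistic(y, X, add_intercept=True)
            return float(fit.pvalues.iloc[1]), float(fit.pvalues.iloc[2])
        if on_degenerate == "error":
            raise ValidationError("sampled outcome is degenerate (all cases or all controls)")
    raise ValidationError("degenerate outcome persisted across 100 resampling attempts")


def simulate_once(
    n_pairs: int,
    beta_mother: float,
    beta_child: float,
    prevalence: float,
    seed: int = 0,
    rho: float = 0.5,
    on_degenerate: str = "error",
    rng: np.random.Generator | None = None,
) -> tuple[float, float]:
    """One power-simulation replicate; returns (p_mother, p_child)."""
    if n_pairs < 100:
        raise ValidationError("n_pairs must be >= 100")
    if on_degenerate not in ("error", "resample"):
        raise ValidationError("on_degenerate must be 'error' or 'resample'")
    alpha_intercept = calibrate_intercept(prevalence, beta_mother, beta_child, rho)
    if rng is None:
        rng = stage_rng(seed, "power_rep")
    return _one_rep(rng, n_pairs, beta_mother, beta_child, alpha_intercept, rho, on_degenerate)


def estimate_power(
    n_pairs: int,
    beta_mother: float,
    beta_child: float,
    prevalence: float,
    reps: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
    rho: float = 0.5,
    on_degenerate: str = "error",
    threads: int = 1,
) -> PowerEstimate:
    """Monte-Carlo power for both PGS terms of the joint model.

    Per-replicate seeds are spawned from ``seed``; with ``threads`` > 1 the
    replicates run in parallel (joblib) with identical results.
    """
    if reps < 100:
        raise ValidationError("reps must be >= 100")
    if not 0.0 < alpha < 1.0:
        raise ValidationError("alpha must lie in (0, 1)")
    alpha_intercept = calibrate_intercept(prevalence, beta_mother, beta_child, rho)
    rngs = spawn_rngs(seed, "power_reps", reps)

    def run(r: np.random.Generator) -> tuple[float, float]:
        return _one_rep(r, n_pairs, beta_mother, beta_child, alpha_intercept, rho, on_degenerate)

    if threads > 1:
        from joblib import Parallel, delayed

        pvals = Parallel(n_jobs=threads, prefer="threads")(delayed(run)(r) for r in rngs)
    else:
        pvals = [run(r) for r in rngs]
    pm, pc = np.asarray(pvals).T
    return PowerEstimate(
        beta_mother=beta_mother,
        beta_child=beta_child,
        prevalence=prevalence,
        n_pairs=n_pairs,
        reps=reps,
        alpha=alpha,
        power_mother=float(np.mean(pm < alpha)),
        power_child=float(np.mean(pc < alpha)),
    )


def power_grid(
    n_pairs: int,
    beta_mothers: Sequence[float],
    beta_children: Sequence[float],
    prevalences: Sequence[float],
    reps: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
    rho: float = 0.5,
    threads: int = 1,
) -> pd.DataFrame:
    """Power over the cartesian grid of effect and prevalence settings."""
    rows = []
    for k, (bm, bc, prev) in enumerate(
        (bm, bc, prev) for prev in prevalences for bm in beta_mothers for bc in beta_children
    ):
        est = estimate_power(n_pairs, bm, bc, prev, reps, alpha, seed=seed + k, rho=rho, threads=threads)
        rows.append(est.to_dict())
    return pd.DataFrame(rows)


def min_detectable_or(
    n_pairs: int,
    prevalence: float,
    beta_child: float = 0.0,
    target_power: float = 0.8,
    grid_step: float = 0.01,
    reps: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
    rho: float = 0.5,
    or_max: float = 2.0,
    threads: int = 1,
) -> MinDetectableOR:
    """Smallest maternal OR on the grid {1 + k * grid_step} with power >= target.

    Scans the grid upward, evaluating Monte-Carlo power for the maternal
    term of the joint model at each point with an independently derived
    seed, and stops at the first crossing.  Raises with diagnostics if the
    target is not reached by ``or_max``.
    """
    if grid_step <= 0:
        raise ValidationError("grid_step must be positive")
    if not 0.0 < target_power < 1.0:
        raise ValidationError("target_power must lie in (0, 1)")
    rows = []
    k = 1
    while True:
        or_mother = 1.0 + k * grid_step
        if or_mother > or_max + 1e-12:
            grid = pd.DataFrame(rows)
            raise ValidationError(
                f"target power {target_power} not reached by OR {or_max}; max observed "
                f"power {grid['power_mother'].max() if len(grid) else float('nan'):.3f}"
            )
        est = estimate_power(
            n_pairs, float(np.log(or_mother)), beta_child, prevalence, reps, alpha,
            seed=seed + k, rho=rho, threads=threads,
        )
        row = est.to_dict()
        row["or_mother"] = or_mother
        rows.append(row)
        if est.power_mother >= target_power:
            return MinDetectableOR(
                or_value=round(or_mother, 10),
                beta=float(np.log(or_mother)),
                target_power=target_power,
                grid=pd.DataFrame(rows),
            )
        k += 1


def analytic_power(
    n_pairs: int,
    beta_mother: float,
    beta_child: float,
    prevalence: float,
    alpha: float = 0.05,
    rho: float = 0.5,
    term: str = "mother",
    n_nodes: int = 40,
) -> float:
    """Wald power approximation from the expected Fisher information.

    Integrates the per-observation information of the joint model over the
    bivariate-normal PGS distribution with 2-D Gauss-Hermite quadrature,
    inverts it for the asymptotic SE of the requested term, and applies the
    two-sided normal power formula.  Used as an independent benchmark for
    the simulation-based estimates.
    """
    alpha_icpt = calibrate_intercept(prevalence, beta_mother, beta_child, rho)
    nodes, weights = np.polynomial.hermite.hermgauss(n_nodes)
    z = np.sqrt(2.0) * nodes
    w = weights / np.sqrt(np.pi)
    zm, zc = np.meshgrid(z, z, indexing="ij")
    wm, wc = np.meshgrid(w, w, indexing="ij")
    pgs_m = zm
    pgs_c = rho * zm + np.sqrt(1.0 - rho**2) * zc
    mu = special.expit(alpha_icpt + beta_mother * pgs_m + beta_child * pgs_c)
    v = mu * (1.0 - mu) * wm * wc
    feats = [np.ones_like(pgs_m), pgs_m, pgs_c]
    info = np.array([[float(np.sum(v * a * b)) for b in feats] for a in feats])
    cov = np.linalg.inv(info) / n_pairs
    idx = 1 if term == "mother" else 2
    se = float(np.sqrt(cov[idx, idx]))
    beta = beta_mother if term == "mother" else beta_child
    z_crit = stats.norm.ppf(1.0 - alpha / 2.0)
    return float(stats.norm.sf(z_crit - abs(beta) / se) + stats.norm.cdf(-z_crit - abs(beta) / se))
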