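"""Two-source linked-sample simulator and experiment runner.

Generates a target population with correlated, possibly discordant binary
outcomes (Y1, Y2) — the gold-standard and record-based measurements of the
same condition — draws an overlapping probability survey and a nonprobability
EHR sample under logistic inclusion models, and runs replicated experiments
comparing four prevalence estimators: survey-only, post-stratified EHR,
Mosteller pooling, and subject-level multiple imputation.

The joint outcome distribution is parameterised through its conditionals:
with eta10 = g0 + g1 x1 + g2 x2 and eta01 = b0 + b1 x1 + b2 x2,

    (p11 : p10 : p01 : p00) = (e^(phi + eta10 + eta01) : e^eta10 : e^eta01 : 1)

which guarantees logit P(Y1=1 | Y2=y) = eta10 + phi*y and
logit P(Y2=1 | Y1=y) = eta01 + phi*y exactly.  Intercepts are calibrated so
the marginal prevalences hit the configured targets; the gap between
target_p1 and target_p2 is the misclassification bias of the record source.

Selection into both samples depends on a covariate (x1) that also drives the
outcomes, so the missingness is missing-at-random but not completely at
random; post-stratification on the design cells corrects the EHR selection
bias but not its misclassification bias.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from numpy.polynomial.hermite import hermgauss
from scipy import optimize

from . import mosteller
from .core import SubjectTable, cut_labels, expit, post_stratify, \
    weighted_prevalence_se_logit
from .imputation import ImputationConfig, run_imputation

__all__ = [
    "GenerativeParams",
    "ExperimentResult",
    "joint_probs",
    "calibrate_intercepts",
    "draw_population",
    "sample_sources",
    "attach_poststrat_weights",
    "run_experiment",
    "make_fixture",
    "ESTIMATORS",
]

logger = logging.getLogger(__name__)

ESTIMATORS = ("survey", "ehr", "mosteller", "imputation")


@dataclass(frozen=True)
class GenerativeParams:
    """Generative configuration of one simulation scenario.

    Defaults reproduce the study conditions: inclusion coefficients
    (1, 1, 1, 0.187) for both sources, population of ten million, survey of
    500 with all of it linked, EHR of 100,000.  The outcome-model slopes and
    the log odds ratio ``phi`` between the two outcomes shape the
    misclassification structure; the intercepts (first elements of ``gamma``
    and ``beta``) are normally left as NaN and calibrated so the marginal
    prevalences equal ``target_p1``/``target_p2``.
    """

    N: int = 10_000_000
    phi: float = 1.5
    gamma: tuple[float, float, float] = (float("nan"), 0.3, 0.3)
    beta: tuple[float, float, float] = (float("nan"), 0.3, 0.3)
    target_p1: float = 0.30
    target_p2: float = 0.35
    a: tuple[float, float, float, float] = (1.0, 1.0, 1.0, 0.187)
    b: tuple[float, float, float, float] = (1.0, 1.0, 1.0, 0.187)
    n1: int = 500
    n2: int = 100_000
    overlap: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.target_p1 < 1.0 or not 0.0 < self.target_p2 < 1.0:
            raise ValueError("target prevalences must be in (0, 1)")
        if not 0.0 < self.overlap <= 1.0:
            raise ValueError("overlap must be in (0, 1]")
        if self.n1 < 2 or self.n2 < 2:
            raise ValueError("sample sizes must be >= 2")
        if self.n1 > self.N or self.n2 > self.N:
            raise ValueError("sample sizes cannot exceed the population size")

    def calibrated(self) -> "GenerativeParams":
        """Return a copy with intercepts solved for the target prevalences."""
        g0, b0 = calibrate_intercepts(self)
        return replace(self, gamma=(g0,) + self.gamma[1:],
                       beta=(b0,) + self.beta[1:])


@dataclass(frozen=True)
class ExperimentResult:
    """Per-replicate estimates and their summary (mean and root-MSE)."""

    replicates: pd.DataFrame = field(compare=False)
    summary: pd.DataFrame = field(compare=False)
    params: GenerativeParams = field(compare=False, default=None)
    failures: dict = field(default_factory=dict, compare=False)


# ---------------------------------------------------------------------------
# joint outcome distribution
# ---------------------------------------------------------------------------

def joint_probs(eta10, eta01, phi):
    """Joint probabilities (p00, p01, p10, p11) of the correlated outcome pair.

    Overflow-safe: the four log-weights (0, eta01, eta10, phi+eta10+eta01)
    are shifted by their maximum before exponentiation.  Subscripts are
    (y1, y2), so p10 is P(Y1=1, Y2=0).
    """
    eta10 = np.asarray(eta10, dtype=float)
    eta01 = np.asarray(eta01, dtype=float)
    logw = np.stack(np.broadcast_arrays(
        np.zeros_like(eta10 + eta01), eta01, eta10, phi + eta10 + eta01))
    logw -= logw.max(axis=0)
    w = np.exp(logw)
    w /= w.sum(axis=0)
    p00, p01, p10, p11 = w
    if p00.ndim == 0:
        return float(p00), float(p01), float(p10), float(p11)
    return p00, p01, p10, p11


def calibrate_intercepts(params: GenerativeParams,
                         box: tuple[float, float] = (-80.0, 40.0)
                         ) -> tuple[float, float]:
    """Solve the intercepts so the marginal prevalences hit their targets.

    Expectations over the covariates use an exact sum over x1 ~ Bernoulli(0.5)
    and 60-node Gauss-Hermite quadrature over x2 ~ N(0, 1).  Each marginal is
    strictly increasing in its own intercept, so the 2-d root is found by
    nested bisection: the inner solve pins g0 to hit target_p1 for any b0,
    the outer solve moves b0 to hit target_p2.  This stays robust for any log
    odds ratio phi, including strongly coupled outcomes.
    """
    nodes, wts = hermgauss(60)
    x2 = np.sqrt(2.0) * nodes
    qw = wts / np.sqrt(np.pi)
    # grids: (2 x1-values) x (60 x2-nodes)
    X1 = np.array([0.0, 1.0])[:, None]
    X2 = x2[None, :]
    W = 0.5 * qw[None, :]

    g1, g2 = params.gamma[1], params.gamma[2]
    b1, b2 = params.beta[1], params.beta[2]

    def marginals(g0, b0):
        eta10 = g0 + g1 * X1 + g2 * X2
        eta01 = b0 + b1 * X1 + b2 * X2
        p00, p01, p10, p11 = joint_probs(eta10, eta01, params.phi)
        return float(np.sum(W * (p11 + p10))), float(np.sum(W * (p11 + p01)))

    lo, hi = box

    def g0_for(b0):
        f = lambda g0: marginals(g0, b0)[0] - params.target_p1
        if f(lo) > 0 or f(hi) < 0:
            raise ValueError(
                f"target_p1={params.target_p1} unattainable; attainable range "
                f"({marginals(lo, b0)[0]:.3g}, {marginals(hi, b0)[0]:.3g})"
            )
        return optimize.brentq(f, lo, hi, xtol=1e-13)

    def outer(b0):
        return marginals(g0_for(b0), b0)[1] - params.target_p2

    f_lo, f_hi = outer(lo), outer(hi)
    if f_lo > 0 or f_hi < 0:
        raise ValueError(
            f"target_p2={params.target_p2} unattainable with the given slopes; "
            f"attainable range ({f_lo + params.target_p2:.3g}, "
            f"{f_hi + params.target_p2:.3g})"
        )
    b0 = optimize.brentq(outer, lo, hi, xtol=1e-13)
    g0 = g0_for(b0)
    p1, p2 = marginals(g0, b0)
    if max(abs(p1 - params.target_p1), abs(p2 - params.target_p2)) > 1e-8:
        raise ValueError("intercept calibration did not converge")
    return float(g0), float(b0)


# ---------------------------------------------------------------------------
# population and samples
# ---------------------------------------------------------------------------

def draw_population(params: GenerativeParams,
                    rng: np.random.Generator) -> pd.DataFrame:
    """Draw the target population: covariates, design factors, both outcomes.

    Returns a plain DataFrame with columns id, x1, x2, u1, u2, y1, y2 (both
    outcomes fully observed — deletion happens at the sampling stage).
    """
    if params.N < 1000:
        raise ValueError("population size must be >= 1000 for stable "
                         "downstream quartiles")
    if np.isnan(params.gamma[0]) or np.isnan(params.beta[0]):
        raise ValueError("intercepts not calibrated; call params.calibrated()")
    N = params.N
    x1 = (rng.random(N) < 0.5).astype(np.int8)
    x2 = rng.standard_normal(N)
    u1 = (rng.random(N) < 0.5).astype(np.int8)
    u2 = rng.standard_normal(N)
    g0, g1, g2 = params.gamma
    b0, b1, b2 = params.beta
    eta10 = g0 + g1 * x1 + g2 * x2
    eta01 = b0 + b1 * x1 + b2 * x2
    p00, p01, p10, p11 = joint_probs(eta10, eta01, params.phi)
    u = rng.random(N)
    # categories in cumulative order 00, 01, 10, 11
    c1 = p00
    c2 = c1 + p01
    c3 = c2 + p10
    y1 = (u >= c2).astype(np.int8)
    y2 = ((u >= c1) & (u < c2) | (u >= c3)).astype(np.int8)
    return pd.DataFrame({
        "id": np.arange(N, dtype=np.int64),
        "x1": x1, "x2": x2, "u1": u1, "u2": u2,
        "y1": y1, "y2": y2,
    })


def _sequential_poisson(size_measure: np.ndarray, n: int,
                        rng: np.random.Generator
                        ) -> tuple[np.ndarray, np.ndarray]:
    """Fixed-size unequal-probability sample; returns (indices, pi).

    Inclusion probabilities are the size measures scaled to sum to n, with
    values above 1 capped and the remainder rescaled.  Selection takes the n
    smallest of xi_i = U_i / pi_i (sequential Poisson sampling).
    """
    N = size_measure.size
    if n > N:
        raise ValueError(f"cannot sample {n} from {N}")
    pi = size_measure.astype(float).copy()
    for _ in range(100):
        scale = (n - (pi >= 1.0).sum()) / pi[pi < 1.0].sum()
        new = np.where(pi >= 1.0, 1.0, np.minimum(pi * scale, 1.0))
        if np.allclose(new.sum(), n, atol=1e-9):
            pi = new
            break
        pi = new
    xi = rng.random(N) / pi
    idx = np.argpartition(xi, n - 1)[:n]
    return idx, pi


def sample_sources(pop: pd.DataFrame, params: GenerativeParams,
                   rng: np.random.Generator) -> SubjectTable:
    """Draw the survey and EHR samples and delete what each source cannot see.

    Inclusion probabilities are proportional to expit of the linear predictors
    a'(1, u1, u2, x1) and b'(1, u1, u2, x1), scaled to the expected sample
    sizes; additional EHR members are then drawn uniformly among survey
    participants until the linked fraction reaches ``overlap``.  Survey
    weights are w1 = 1/pi1.  Afterwards y1 and pi1 survive only inside the
    survey, y2 only inside the EHR, and pi2 nowhere (inclusion to a record
    system is unknown in practice).
    """
    N = len(pop)
    u1 = pop["u1"].to_numpy(float)
    u2 = pop["u2"].to_numpy(float)
    x1 = pop["x1"].to_numpy(float)
    a0, a1, a2, a3 = params.a
    b0, b1, b2, b3 = params.b
    s1 = expit(a0 + a1 * u1 + a2 * u2 + a3 * x1)
    s2 = expit(b0 + b1 * u1 + b2 * u2 + b3 * x1)
    survey_idx, pi1 = _sequential_poisson(s1, params.n1, rng)
    ehr_idx, _ = _sequential_poisson(s2, params.n2, rng)

    in_survey = np.zeros(N, dtype=bool)
    in_survey[survey_idx] = True
    in_ehr = np.zeros(N, dtype=bool)
    in_ehr[ehr_idx] = True

    n12_target = int(round(params.overlap * params.n1))
    current = int((in_survey & in_ehr).sum())
    if current < n12_target:
        candidates = np.flatnonzero(in_survey & ~in_ehr)
        extra = rng.choice(candidates, size=n12_target - current, replace=False)
        in_ehr[extra] = True

    keep = in_survey | in_ehr
    sub = pop.loc[keep].copy()
    surv = in_survey[keep]
    ehr = in_ehr[keep]
    table = pd.DataFrame({
        "id": sub["id"].to_numpy(),
        "x1": sub["x1"].to_numpy(float),
        "x2": sub["x2"].to_numpy(float),
        "u1": sub["u1"].to_numpy(float),
        "u2": sub["u2"].to_numpy(float),
        "y1": np.where(surv, sub["y1"].to_numpy(float), np.nan),
        "y2": np.where(ehr, sub["y2"].to_numpy(float), np.nan),
        "pi1": np.where(surv, pi1[keep], np.nan),
        "pi2": np.nan,
        "in_survey": surv.astype(int),
        "in_ehr": ehr.astype(int),
        "linked": (surv & ehr).astype(int),
        "w1": np.where(surv, 1.0 / pi1[keep], np.nan),
        "w2": np.nan,
    })
    return SubjectTable(table)


def _population_cells(pop: pd.DataFrame) -> tuple[pd.Series, np.ndarray, dict]:
    """Joint u1 x quartile(u2) x x1 cells of the population and their shares."""
    cuts = np.quantile(pop["u2"].to_numpy(float), [0.25, 0.5, 0.75])
    q = cut_labels(pop["u2"].to_numpy(float), cuts)
    labels = (pop["u1"].to_numpy(int) * 8 + (q - 1) * 2
              + pop["x1"].to_numpy(int))
    counts = np.bincount(labels, minlength=16)
    shares = {c: counts[c] / len(pop) for c in range(16) if counts[c] > 0}
    return labels, cuts, shares


def attach_poststrat_weights(t: SubjectTable, pop: pd.DataFrame) -> SubjectTable:
    """Compute post-stratified EHR weights w2 against the population cells.

    Cells are the joint distribution of u1, population-quartile of u2, and x1
    — the factors that drive selection — so the weighted EHR reproduces the
    population joint distribution of those factors exactly.
    """
    _, cuts, shares = _population_cells(pop)
    df = t.df.copy()
    ehr = t.in_ehr
    q = cut_labels(df.loc[ehr, "u2"].to_numpy(float), cuts)
    cells = (df.loc[ehr, "u1"].to_numpy(int) * 8 + (q - 1) * 2
             + df.loc[ehr, "x1"].to_numpy(int))
    df.loc[ehr, "w2"] = post_stratify(cells, shares)
    return SubjectTable(df)


def make_fixture(seed: int = 20200406, N: int = 20_000, n1: int = 200,
                 n2: int = 2000, overlap: float = 0.5,
                 target_p1: float = 0.30, target_p2: float = 0.35
                 ) -> SubjectTable:
    """A small, fully prepared subject table for tests and documentation."""
    params = GenerativeParams(N=N, n1=n1, n2=n2, overlap=overlap,
                              target_p1=target_p1, target_p2=target_p2,
                              seed=seed).calibrated()
    rng = np.random.default_rng(seed)
    pop = draw_population(params, rng)
    return attach_poststrat_weights(sample_sources(pop, params, rng), pop)


# ---------------------------------------------------------------------------
# experiment runner
# ---------------------------------------------------------------------------

def _estimate_once(table: SubjectTable, estimators, imputation_cfg, rep_seed):
    row: dict[str, float] = {}
    df = table.df
    surv, ehr = table.in_survey, table.in_ehr
    if "survey" in estimators:
        p, se = weighted_prevalence_se_logit(df.loc[surv, "y1"].to_numpy(float),
                                             df.loc[surv, "w1"].to_numpy(float))
        row["est_survey"], row["se_survey"] = p, se
    if "ehr" in estimators:
        p, se = weighted_prevalence_se_logit(df.loc[ehr, "y2"].to_numpy(float),
                                             df.loc[ehr, "w2"].to_numpy(float))
        row["est_ehr"], row["se_ehr"] = p, se
    if "mosteller" in estimators:
        pooled = mosteller.pool_from_subject_table(table)
        row["est_mosteller"] = pooled.p_hat
        row["se_mosteller"] = pooled.post_sd
    if "imputation" in estimators:
        cfg = replace(imputation_cfg, seed=rep_seed)
        res = run_imputation(table, cfg)
        row["est_imputation"] = res.P_R
        row["se_imputation"] = res.se_phi
    return row


def run_experiment(params: GenerativeParams, replicates: int,
                   imputation_cfg: ImputationConfig | None = None,
                   estimators=ESTIMATORS,
                   fresh_population: bool = True) -> ExperimentResult:
    """Replicate the full generate-sample-estimate pipeline.

    Each replicate r uses seed ``params.seed + r``; by default a fresh
    population is generated per replicate (the alternative holds one
    population fixed and redraws only the samples).  Estimator failures in a
    replicate are recorded as NaN and counted, never silently dropped.
    The summary reports, per estimator, the mean estimate and
    sqrt(mean((estimate - target_p1)^2)) over successful replicates.
    """
    if replicates < 2:
        raise ValueError("need at least 2 replicates")
    unknown = set(estimators) - set(ESTIMATORS)
    if unknown:
        raise ValueError(f"unknown estimators: {sorted(unknown)}")
    if "imputation" in estimators and imputation_cfg is None:
        imputation_cfg = ImputationConfig(M=30, B=10)
    params = params if not np.isnan(params.gamma[0]) else params.calibrated()

    fixed_pop = None
    if not fresh_population:
        fixed_pop = draw_population(params, np.random.default_rng(params.seed))

    rows = []
    failures: dict[str, int] = {e: 0 for e in estimators}
    for r in range(replicates):
        rep_seed = params.seed + r
        rng = np.random.default_rng(rep_seed)
        pop = fixed_pop if fixed_pop is not None else draw_population(params, rng)
        table = attach_poststrat_weights(sample_sources(pop, params, rng), pop)
        row = {"replicate": r, "seed": rep_seed}
        for est in estimators:
            try:
                row.update(_estimate_once(table, (est,), imputation_cfg,
                                          rep_seed))
            except (ValueError, RuntimeError) as exc:
                failures[est] += 1
                row[f"est_{est}"] = np.nan
                logger.warning("replicate %d: estimator %s failed: %s",
                               r, est, exc)
        rows.append(row)
        logger.info("replicate %d/%d done (seed %d)", r + 1, replicates,
                    rep_seed)

    rep_df = pd.DataFrame(rows)
    summary_rows = []
    for est in estimators:
        vals = rep_df[f"est_{est}"].dropna().to_numpy(float)
        summary_rows.append({
            "estimator": est,
            "mean_estimate": float(vals.mean()) if vals.size else np.nan,
            "sqrt_mse": float(np.sqrt(np.mean((vals - params.target_p1) ** 2)))
            if vals.size else np.nan,
            "replicates": int(vals.size),
            "failures": failures[est],
        })
    return ExperimentResult(replicates=rep_df,
                            summary=pd.DataFrame(summary_rows),
                            params=params, failures=failures)
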