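"""Subject-level multiple-imputation prevalence estimator for two linked samples.

The gold-standard outcome Y1 is observed only in the small survey sample S1
and the error-prone outcome Y2 only in the large record sample S2; the linked
subset S_c (subjects identified in both) observes the pair and identifies a
misclassification model between the two outcomes.  Two stratified logistic
models are fit with weakly informative Cauchy priors:

    M1:  logit P(Y2 = 1 | Y1, z) = b0_l + b1_l' z + b2_l Y1
    M2:  logit P(Y1 = 1 | Y2, z) = g0_l + g1_l' z + g2_l Y2

each within four strata l defined by quartiles of the inclusion probabilities
(to the EHR for M1, to the survey for M2); the stratification carries the
design information into otherwise unweighted fits.  Missing Y2 values (survey-
only subjects) and missing Y1 values (EHR-only subjects) are imputed in
alternation, iterated B times per imputation with the latest imputations
treated as observed, and the whole procedure is repeated for M independent
imputations.  The per-imputation weighted prevalences over S2 are combined by
Rubin's rules with Barnard-Rubin degrees of freedom on the logit scale.

Observed outcomes are never overwritten: imputation fills only values that
are structurally missing.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .core import SubjectTable, cut_labels, expit, logit, weighted_prevalence_se_logit

__all__ = [
    "ImputationConfig",
    "ImputationResult",
    "BayesLogisticFit",
    "bayes_logistic_fit",
    "fit_inclusion_survey",
    "fit_inclusion_ehr",
    "assign_strata",
    "run_imputation",
    "rubin_combine",
    "cv_auc_misclassification",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ImputationConfig:
    """Configuration of the imputation estimator.

    ``covariates_z`` are the misclassification-model predictors;
    ``design_factors_u``/``design_factors_v`` drive the survey- and
    EHR-inclusion models.  ``M`` imputations, each iterated ``B`` times;
    ``prior_scale`` is the scale of the zero-location Cauchy priors on all
    coefficients of M1/M2.
    """

    covariates_z: tuple[str, ...] = ("x1", "x2")
    design_factors_u: tuple[str, ...] = ("u1", "u2", "x1")
    design_factors_v: tuple[str, ...] = ("u1", "u2", "x1")
    M: int = 30
    B: int = 10
    prior_scale: float = 2.5
    seed: int = 0
    ci_level: float = 0.95

    def __post_init__(self) -> None:
        if self.M < 2:
            raise ValueError("M must be >= 2")
        if self.B < 1:
            raise ValueError("B must be >= 1")
        if self.prior_scale <= 0:
            raise ValueError("prior_scale must be positive")
        if not 0.0 < self.ci_level < 1.0:
            raise ValueError("ci_level must be in (0, 1)")


@dataclass(frozen=True)
class ImputationResult:
    """Combined inference over M imputations."""

    p_m: tuple[float, ...]        # per-imputation weighted prevalences
    s_m: tuple[float, ...]        # per-imputation naive logit-scale SEs
    P_R: float                    # mean of p_m (probability scale)
    phi_R: float                  # mean of logit(p_m) (combination centre)
    se_phi: float                 # Rubin total SE on the logit scale
    df: float                     # Barnard-Rubin degrees of freedom
    ci_prob: tuple[float, float]
    W: float                      # mean within-imputation variance
    B_between: float              # between-imputation variance
    strata_coefficients: dict = field(default_factory=dict, compare=False)

    def to_dict(self) -> dict:
        return {
            "p_m": list(self.p_m), "s_m": list(self.s_m),
            "P_R": self.P_R, "phi_R": self.phi_R,
            "se_phi": self.se_phi, "df": self.df,
            "ci_prob": list(self.ci_prob),
            "W": self.W, "B_between": self.B_between,
        }


# ---------------------------------------------------------------------------
# Cauchy-prior Bayesian logistic regression
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BayesLogisticFit:
    """Posterior mode, covariance, and one normal-approximation draw.

    Coefficients are on the original predictor scale; index 0 is the
    intercept.  ``draw`` is None when no generator was supplied.
    """

    mode: np.ndarray
    cov: np.ndarray
    draw: np.ndarray | None

    def predict(self, X: np.ndarray, coef: np.ndarray | None = None) -> np.ndarray:
        b = self.mode if coef is None else coef
        return expit(b[0] + np.asarray(X, float) @ b[1:])


def _standardize(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Center all columns; rescale continuous columns to SD 0.5.

    Binary columns (at most two distinct values) are only shifted to mean 0,
    so the common Cauchy prior scale refers to a change of roughly one unit
    (binary flip) or two standard deviations (continuous predictor).
    """
    X = np.asarray(X, dtype=float)
    means = X.mean(axis=0)
    scales = np.ones(X.shape[1])
    for j in range(X.shape[1]):
        col = X[:, j]
        if len(np.unique(col)) > 2:
            sd = col.std()
            if sd > 0:
                scales[j] = 2.0 * sd
    return (X - means) / scales, means, scales


def _penalized_logistic_mode(Xd: np.ndarray, y: np.ndarray, scale: float,
                             max_iter: int = 100, tol: float = 1e-6
                             ) -> tuple[np.ndarray, np.ndarray]:
    """Damped-Newton mode of logistic likelihood x independent Cauchy priors.

    ``Xd`` includes the intercept column.  Returns (mode, negative Hessian of
    the log posterior at the mode).  The Cauchy log-prior is smooth and its
    curvature at the origin (2/scale^2) keeps the system nonsingular even
    under complete separation or collinear predictors.
    """
    n, p = Xd.shape
    b = np.zeros(p)
    s2 = scale * scale

    def objective(beta):
        eta = Xd @ beta
        # log-lik via numerically stable log(1 + e^eta)
        ll = float(y @ eta - np.logaddexp(0.0, eta).sum())
        return ll - np.log1p(beta * beta / s2).sum()

    obj = objective(b)
    grad = np.full(p, np.inf)
    for _ in range(max_iter):
        eta = Xd @ b
        mu = expit(eta)
        grad = Xd.T @ (y - mu) - 2.0 * b / (s2 + b * b)
        if np.max(np.abs(grad)) < tol:
            break
        w = mu * (1.0 - mu)
        neg_hess = (Xd * w[:, None]).T @ Xd
        neg_hess[np.diag_indices(p)] += 2.0 * (s2 - b * b) / (s2 + b * b) ** 2
        try:
            step = np.linalg.solve(neg_hess, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.solve(neg_hess + 1e-6 * np.eye(p), grad)
        alpha, accepted = 1.0, False
        for _ in range(15):
            cand_obj = objective(b + alpha * step)
            if cand_obj > obj + 1e-12:
                b, obj, accepted = b + alpha * step, cand_obj, True
                break
            alpha *= 0.5
        if not accepted:
            break   # stalled at numerical precision of the objective
    if np.max(np.abs(grad)) > 1e-3:
        raise RuntimeError("penalized logistic fit did not converge")
    # recompute curvature at the mode
    mu = expit(Xd @ b)
    w = mu * (1.0 - mu)
    neg_hess = (Xd * w[:, None]).T @ Xd
    neg_hess[np.diag_indices(p)] += 2.0 * (s2 - b * b) / (s2 + b * b) ** 2
    return b, neg_hess


def bayes_logistic_fit(X, y, prior_scale: float = 2.5,
                       rng: np.random.Generator | None = None) -> BayesLogisticFit:
    """Fit a logistic regression with independent Cauchy(0, scale) priors.

    Predictors are standardized internally (binary shifted to mean 0,
    continuous rescaled to SD 0.5), the posterior mode is found by damped
    Newton iteration, and — when ``rng`` is supplied — one coefficient vector
    is drawn from the normal approximation at the mode (mean = mode,
    covariance = inverse observed information).  All returned coefficients
    are mapped back to the original predictor scale, intercept first.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float)
    if X.shape[0] != y.shape[0]:
        raise ValueError("X and y have different numbers of rows")
    if X.shape[0] < X.shape[1]:
        raise ValueError("need at least as many rows as predictors")
    Xs, means, scales = _standardize(X)
    Xd = np.column_stack([np.ones(len(y)), Xs])
    mode_s, neg_hess = _penalized_logistic_mode(Xd, y, prior_scale)

    # map standardized-scale coefficients back: beta_j = b_j / s_j,
    # beta_0 = b_0 - sum_j b_j m_j / s_j  (a linear map A)
    p = Xd.shape[1]
    A = np.eye(p)
    A[0, 1:] = -means / scales
    A[1:, 1:] = np.diag(1.0 / scales)
    mode = A @ mode_s

    try:
        L = np.linalg.cholesky(neg_hess)
    except np.linalg.LinAlgError:
        L = np.linalg.cholesky(neg_hess + 1e-8 * np.eye(p))
    Linv = np.linalg.solve(L, np.eye(p))
    cov_s = Linv.T @ Linv
    cov = A @ cov_s @ A.T

    draw = None
    if rng is not None:
        z = rng.standard_normal(p)
        draw_s = mode_s + np.linalg.solve(L.T, z)
        draw = A @ draw_s
    return BayesLogisticFit(mode=mode, cov=cov, draw=draw)


# ---------------------------------------------------------------------------
# inclusion-probability models
# ---------------------------------------------------------------------------

def _weighted_logistic(X: pd.DataFrame, y: np.ndarray, w: np.ndarray):
    exog = sm.add_constant(X.to_numpy(float), has_constant="add")
    model = sm.GLM(y, exog, family=sm.families.Binomial(), var_weights=w)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return model.fit()


def fit_inclusion_survey(t: SubjectTable, cfg: ImputationConfig
                         ) -> tuple[np.ndarray, np.ndarray]:
    """Model the survey-inclusion probability pi1 for every subject.

    A weighted logistic regression of the survey-membership indicator on the
    survey design factors is fit over the EHR subjects (weights ``w2``, which
    make the EHR representative of the population).  Fitted values are then
    rescaled so that, on average over subjects whose design pi1 is known, the
    predictions match the known values; known pi1 always take precedence over
    predictions.  Returns (coefficients, pi1 for all subjects).
    """
    df = t.df
    known = df["pi1"].notna().to_numpy()
    if not known.any():
        raise ValueError(
            "no known pi1 anywhere: survey-inclusion model is unidentified for scaling"
        )
    ehr = t.in_ehr
    if df.loc[ehr, "w2"].isna().any():
        raise ValueError("EHR subjects must carry post-stratified weights w2")
    u_cols = list(cfg.design_factors_u)
    y = df.loc[ehr, "in_survey"].to_numpy(float)
    w = df.loc[ehr, "w2"].to_numpy(float)
    X_all = df[u_cols]
    if y.min() == y.max():
        warnings.warn(
            "survey membership has no variation among EHR subjects; "
            "using a constant inclusion model", stacklevel=2)
        rate = min(max(float(np.average(y, weights=w)), 1e-10), 1 - 1e-10)
        coef = np.array([logit(rate)] + [0.0] * len(u_cols))
        pred = np.full(len(df), rate)
    else:
        res = _weighted_logistic(X_all.loc[ehr], y, w)
        coef = np.asarray(res.params)
        exog_all = sm.add_constant(X_all.to_numpy(float), has_constant="add")
        pred = np.asarray(res.predict(exog_all))
    # anchor the prediction scale to the known design probabilities
    scale = df.loc[known, "pi1"].mean() / max(pred[known].mean(), 1e-300)
    pi1 = np.clip(pred * scale, 1e-12, 1 - 1e-12)
    pi1[known] = df.loc[known, "pi1"].to_numpy(float)
    return coef, pi1


def fit_inclusion_ehr(t: SubjectTable, cfg: ImputationConfig
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Model the EHR-inclusion probability pi2 for every subject.

    A weighted logistic regression of the EHR-membership indicator (known
    through linkage) on the design factors ``v`` is fit over the survey
    subjects with their survey weights ``w1``.  Only the ordering of the
    predictions matters downstream (quartile stratification), so no rescaling
    is applied.  Returns (coefficients, pi2 for all subjects).
    """
    df = t.df
    surv = t.in_survey
    v_cols = list(cfg.design_factors_v)
    y = df.loc[surv, "in_ehr"].to_numpy(float)
    if y.min() == y.max():
        raise ValueError(
            "EHR membership has no variation among survey subjects "
            f"(all {'linked' if y.min() == 1 else 'unlinked'}): pi2 model cannot be fit"
        )
    w = df.loc[surv, "w1"].to_numpy(float)
    res = _weighted_logistic(df.loc[surv, v_cols], y, w)
    exog_all = sm.add_constant(df[v_cols].to_numpy(float), has_constant="add")
    return np.asarray(res.params), np.asarray(res.predict(exog_all))


def assign_strata(pi) -> np.ndarray:
    """Quartile strata 1..4 of inclusion probabilities (right-closed bins).

    Ties at the cut points fall to the lower stratum; if all values are equal
    the stratification collapses to a single stratum with a warning.
    """
    pi = np.asarray(pi, dtype=float)
    if pi.size < 8:
        raise ValueError(f"need at least 8 subjects to stratify; got {pi.size}")
    if np.isnan(pi).any():
        raise ValueError("pi contains missing values; predict them first")
    cuts = np.quantile(pi, [0.25, 0.5, 0.75])
    labels = cut_labels(pi, cuts)
    if len(np.unique(labels)) == 1:
        warnings.warn("degenerate stratification: all inclusion probabilities "
                      "coincide; collapsing to a single stratum", stacklevel=2)
    return labels


# ---------------------------------------------------------------------------
# Rubin's rules with Barnard-Rubin degrees of freedom
# ---------------------------------------------------------------------------

def rubin_combine(phi_m, s_m, nu_com: float, level: float = 0.95
                  ) -> tuple[float, float, tuple[float, float]]:
    """Combine M logit-scale estimates by Rubin's rules.

    Total variance T = W + (1 + 1/M) B with W the mean of the squared naive
    SEs and B the between-imputation sample variance.  The reference t
    distribution uses the Barnard-Rubin degrees of freedom, which shrink the
    complete-data df ``nu_com`` by the fraction of missing information
    lambda = (1 + 1/M) B / T.  Returns (se, df, ci_logit).
    """
    phi_m = np.asarray(phi_m, dtype=float)
    s_m = np.asarray(s_m, dtype=float)
    if phi_m.shape != s_m.shape or phi_m.size < 2:
        raise ValueError("phi_m and s_m must have equal length M >= 2")
    if nu_com <= 0:
        raise ValueError("nu_com must be positive")
    M = phi_m.size
    W = float(np.mean(s_m**2))
    B = float(np.var(phi_m, ddof=1))
    T = W + (1.0 + 1.0 / M) * B
    if T <= 0.0:
        raise ValueError("no variance information: all s_m and the "
                         "between-imputation variance are zero")
    lam = (1.0 + 1.0 / M) * B / T
    nu_obs = ((nu_com + 1.0) / (nu_com + 3.0)) * nu_com * (1.0 - lam)
    if lam <= 0.0:
        df = nu_obs
    else:
        nu_M = (M - 1.0) / lam**2
        df = 1.0 / (1.0 / nu_M + 1.0 / nu_obs)
    se = float(np.sqrt(T))
    centre = float(np.mean(phi_m))
    tq = float(stats.t.ppf(0.5 + level / 2.0, df))
    return se, float(df), (centre - tq * se, centre + tq * se)


# ---------------------------------------------------------------------------
# the iterative imputation procedure
# ---------------------------------------------------------------------------

def _fit_and_impute(Z, cond, y_target, train, to_impute, prior_scale, rng,
                    label: str, first_pass: bool):
    """Fit one stratum model and impute its missing outcomes in place."""
    Xtr = np.column_stack([Z[train], cond[train]])
    ytr = y_target[train]
    if first_pass:
        if train.sum() < 10:
            raise ValueError(f"{label}: only {int(train.sum())} training rows "
                             "in the first pass (need >= 10); reduce strata")
        if ytr.min() == ytr.max():
            raise ValueError(f"{label}: single-class outcome in the first pass")
    fit = bayes_logistic_fit(Xtr, ytr, prior_scale, rng)
    if to_impute.any():
        Ximp = np.column_stack([Z[to_impute], cond[to_impute]])
        p = fit.predict(Ximp, fit.draw)
        y_target[to_impute] = rng.binomial(1, p).astype(float)
    return fit


def run_imputation(t: SubjectTable, cfg: ImputationConfig) -> ImputationResult:
    """Run the full iterative multiple-imputation estimator on a subject table.

    For each of M imputations (independent substreams of ``cfg.seed``): impute
    missing Y2 within quartile strata of the EHR-inclusion probability (model
    M1, fit on the linked subset in the first pass), then missing Y1 within
    quartile strata of the survey-inclusion probability (model M2, fit on
    subjects with observed Y1 in the first pass); iterate B times, each later
    pass fitting on all subjects and treating the latest imputations as
    observed.  The per-imputation estimate is the w2-weighted prevalence of
    (observed-or-imputed) Y1 over the EHR sample; combination is by Rubin's
    rules with Barnard-Rubin degrees of freedom on the logit scale.
    """
    df = t.df
    if not t.linked.any():
        raise ValueError("linked subset S_c is empty: misclassification models "
                         "are unidentified")
    s1, s2, sc = t.in_survey, t.in_ehr, t.linked
    if df.loc[s2, "w2"].isna().any():
        raise ValueError("EHR subjects must carry post-stratified weights w2")

    Z = df[list(cfg.covariates_z)].to_numpy(float)
    y1_obs = df["y1"].to_numpy(float)
    y2_obs = df["y2"].to_numpy(float)
    missing_y1 = ~s1
    missing_y2 = ~s2
    w2 = df["w2"].to_numpy(float)

    strata1 = strata2 = None
    if missing_y1.any():
        _, pi1 = fit_inclusion_survey(t, cfg)
        strata1 = assign_strata(pi1)
    if missing_y2.any():
        _, pi2 = fit_inclusion_ehr(t, cfg)
        strata2 = assign_strata(pi2)

    p_list: list[float] = []
    s_list: list[float] = []
    coef_summary: dict = {}
    for m in range(cfg.M):
        rng = np.random.default_rng(
            np.random.SeedSequence(entropy=cfg.seed, spawn_key=(m,)))
        y1_cur = y1_obs.copy()
        y2_cur = y2_obs.copy()
        traj: list[float] = []
        for b_pass in range(cfg.B):
            first = b_pass == 0
            if missing_y2.any():
                for lev in np.unique(strata2):
                    in_l = strata2 == lev
                    train = in_l & (sc if first else np.ones(len(df), bool))
                    fit = _fit_and_impute(
                        Z, y1_cur, y2_cur, train, in_l & missing_y2,
                        cfg.prior_scale, rng,
                        f"M1 stratum {lev} (pass {b_pass + 1})", first)
                    if m == 0 and b_pass == cfg.B - 1:
                        coef_summary[f"M1/stratum{lev}"] = fit.mode.tolist()
            if missing_y1.any():
                for lev in np.unique(strata1):
                    in_l = strata1 == lev
                    train = in_l & (s1 if first else np.ones(len(df), bool))
                    fit = _fit_and_impute(
                        Z, y2_cur, y1_cur, train, in_l & missing_y1,
                        cfg.prior_scale, rng,
                        f"M2 stratum {lev} (pass {b_pass + 1})", first)
                    if m == 0 and b_pass == cfg.B - 1:
                        coef_summary[f"M2/stratum{lev}"] = fit.mode.tolist()
            traj.append(float(np.average(y1_cur[s2], weights=w2[s2])))
        # observed values must survive every pass untouched
        assert np.array_equal(y1_cur[s1], y1_obs[s1])
        assert np.array_equal(y2_cur[s2], y2_obs[s2])
        if (missing_y1.any() or missing_y2.any()) and len(traj) >= 3:
            tail = traj[-3:]
            if max(tail) - min(tail) >= 0.002:
                warnings.warn(
                    f"imputation {m}: prevalence trajectory still moving by "
                    f"{max(tail) - min(tail):.4f} over the last 3 of {cfg.B} "
                    "iterations; consider increasing B", stacklevel=2)
        p_hat, s_hat = weighted_prevalence_se_logit(y1_cur[s2], w2[s2])
        logger.info("imputation %d/%d: p=%.5f se_logit=%.5f", m + 1, cfg.M,
                    p_hat, s_hat)
        p_list.append(p_hat)
        s_list.append(s_hat)

    phi_m = logit(np.asarray(p_list))
    kish_n = float(w2[s2].sum() ** 2 / np.sum(w2[s2] ** 2))
    se, dof, ci_logit = rubin_combine(phi_m, np.asarray(s_list),
                                      nu_com=kish_n - 1.0, level=cfg.ci_level)
    return ImputationResult(
        p_m=tuple(p_list), s_m=tuple(s_list),
        P_R=float(np.mean(p_list)), phi_R=float(np.mean(phi_m)),
        se_phi=se, df=dof,
        ci_prob=(expit(ci_logit[0]), expit(ci_logit[1])),
        W=float(np.mean(np.asarray(s_list) ** 2)),
        B_between=float(np.var(phi_m, ddof=1)),
        strata_coefficients=coef_summary,
    )


# ---------------------------------------------------------------------------
# model-fit diagnostic
# ---------------------------------------------------------------------------

def _rank_auc(y: np.ndarray, score: np.ndarray) -> float:
    r = stats.rankdata(score)
    n1 = int(y.sum())
    n0 = y.size - n1
    if n1 == 0 or n0 == 0:
        return float("nan")
    return float((r[y == 1].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0))


def cv_auc_misclassification(t: SubjectTable, cfg: ImputationConfig,
                             folds: int = 5) -> dict[int, float]:
    """Cross-validated AUC of model M2 on the linked subset, per stratum.

    A purely diagnostic check of how well the misclassification model predicts
    the gold-standard outcome from the covariates and the record outcome; a
    value near 0.5 warns that the imputation estimator has little to work
    with.  Fold assignment is stratified by the outcome; strata where the fit
    or split fails persistently report NaN.
    """
    df = t.df
    sc = t.linked
    if int(sc.sum()) < 5 * folds:
        raise ValueError(f"need at least {5 * folds} linked subjects for "
                         f"{folds}-fold CV; got {int(sc.sum())}")
    pi1 = df["pi1"].to_numpy(float)
    sub = df[sc]
    if np.isnan(pi1[sc.nonzero()[0]]).any():
        strata = np.ones(len(sub), dtype=int)
    else:
        strata = assign_strata(pi1[sc]) if sc.sum() >= 8 else np.ones(len(sub), int)
    Z = sub[list(cfg.covariates_z)].to_numpy(float)
    y2 = sub["y2"].to_numpy(float)
    y1 = sub["y1"].to_numpy(float)
    X = np.column_stack([Z, y2])
    rng = np.random.default_rng(np.random.SeedSequence(entropy=cfg.seed,
                                                       spawn_key=(999,)))
    out: dict[int, float] = {}
    for lev in np.unique(strata):
        idx = np.flatnonzero(strata == lev)
        auc = float("nan")
        for _ in range(3):   # retry with a fresh stratified shuffle
            fold_of = np.empty(idx.size, dtype=int)
            ok = True
            for cls in (0.0, 1.0):
                cls_idx = np.flatnonzero(y1[idx] == cls)
                if cls_idx.size < folds:
                    ok = False
                    break
                rng.shuffle(cls_idx)
                fold_of[cls_idx] = np.arange(cls_idx.size) % folds
            if not ok:
                break
            scores = np.full(idx.size, np.nan)
            try:
                for f in range(folds):
                    tr = idx[fold_of != f]
                    te = idx[fold_of == f]
                    fit = bayes_logistic_fit(X[tr], y1[tr], cfg.prior_scale)
                    scores[fold_of == f] = fit.predict(X[te])
                auc = _rank_auc(y1[idx], scores)
                break
            except (ValueError, RuntimeError):
                continue
        out[int(lev)] = auc
    return out
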