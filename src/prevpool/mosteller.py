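"""Logit-scale Mosteller pooling of a gold-standard and a possibly biased estimate.

The pooled estimator is a precision-weighted average of the two logit-scale
prevalence estimates, ``phi = (k1 y1 + k2 y2) / (k1 + k2)``, where the weight
of the error-prone source is discounted by the squared estimated bias:

    k1 = 1 / sigma1^2,      k2 = 1 / (tau^2 + sigma2^2),
    tau^2 = (y1 - y2)^2.

These weights minimise the mean squared error in the family of weighted
averages; equivalently, the estimate is the posterior mean of the true logit
prevalence under a flat prior and a zero-mean normal prior with variance
``tau^2`` on the bias of the second source.  The posterior SD

    sigma1 * sqrt((sigma2^2 + tau^2) / (sigma1^2 + sigma2^2 + tau^2))

is never larger than ``sigma1``: pooling cannot lose against the gold
standard alone.  Credibility intervals are built on the logit scale and
back-transformed to the probability scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from scipy import stats

from .core import (
    SourceSummary,
    SubjectTable,
    expit,
    logit,
    se_logit_from_ci,
    weighted_prevalence_se_logit,
)

__all__ = ["PooledEstimate", "pool", "credibility_interval", "pool_from_subject_table"]


@dataclass(frozen=True)
class PooledEstimate:
    """All quantities of one Mosteller pooling: inputs, weights and interval."""

    y1: float                       # logit of the survey estimate
    y2: float                       # logit of the EHR estimate
    sigma1: float                   # logit-scale SE of y1
    sigma2: float                   # logit-scale SE of y2
    tau2: float                     # squared estimated bias (y1 - y2)^2
    k1: float
    k2: float
    phi_hat: float                  # pooled logit prevalence
    post_sd: float                  # posterior SD of the logit prevalence
    ci_logit: tuple[float, float]
    p_hat: float
    ci_prob: tuple[float, float]
    rel_weights: tuple[float, float]  # (survey, EHR), sum to 1
    level: float = field(default=0.95)

    def to_dict(self) -> dict:
        return {
            "y1": self.y1, "y2": self.y2,
            "sigma1": self.sigma1, "sigma2": self.sigma2,
            "tau2": self.tau2, "k1": self.k1, "k2": self.k2,
            "phi_hat": self.phi_hat, "post_sd": self.post_sd,
            "ci_logit": list(self.ci_logit),
            "p_hat": self.p_hat, "ci_prob": list(self.ci_prob),
            "rel_weights": list(self.rel_weights), "level": self.level,
        }


def _pool_logits(y1: float, y2: float, sigma1: float, sigma2: float,
                 level: float = 0.95) -> PooledEstimate:
    for name, v in (("y1", y1), ("y2", y2)):
        if not math.isfinite(v):
            raise ValueError(f"non-finite logit {name}={v}")
    if sigma1 <= 0 or sigma2 <= 0:
        raise ValueError("standard errors must be positive")
    if not 0.0 < level < 1.0:
        raise ValueError(f"level must be in (0, 1); got {level}")
    tau2 = (y1 - y2) ** 2
    k1 = 1.0 / sigma1**2
    k2 = 1.0 / (tau2 + sigma2**2)
    phi_hat = (k1 * y1 + k2 * y2) / (k1 + k2)
    post_sd = sigma1 * math.sqrt(
        (sigma2**2 + tau2) / (sigma1**2 + sigma2**2 + tau2)
    )
    z = float(stats.norm.ppf(0.5 + level / 2.0))
    ci_logit = (phi_hat - z * post_sd, phi_hat + z * post_sd)
    return PooledEstimate(
        y1=y1, y2=y2, sigma1=sigma1, sigma2=sigma2, tau2=tau2,
        k1=k1, k2=k2, phi_hat=phi_hat, post_sd=post_sd,
        ci_logit=ci_logit, p_hat=expit(phi_hat),
        ci_prob=(expit(ci_logit[0]), expit(ci_logit[1])),
        rel_weights=(k1 / (k1 + k2), k2 / (k1 + k2)),
        level=level,
    )


def pool(survey: SourceSummary, ehr: SourceSummary, *,
         se1: float | None = None, se2: float | None = None,
         level: float = 0.95) -> PooledEstimate:
    """Pool two source summaries on the logit scale.

    Logit-scale standard errors are recovered from the printed confidence
    intervals unless explicit design-based SEs are supplied via ``se1``/``se2``
    (explicit values take precedence).
    """
    sigma1 = se1 if se1 is not None else se_logit_from_ci(survey)
    sigma2 = se2 if se2 is not None else se_logit_from_ci(ehr)
    return _pool_logits(logit(survey.p_hat), logit(ehr.p_hat), sigma1, sigma2,
                        level=level)


def credibility_interval(e: PooledEstimate, level: float = 0.95) -> tuple[float, float]:
    """Probability-scale highest-density credibility interval at ``level``.

    The posterior of the logit prevalence is normal, so the highest-density
    interval is symmetric on the logit scale: ``expit(phi_hat +/- z post_sd)``.
    """
    if not 0.0 < level < 1.0:
        raise ValueError(f"level must be in (0, 1); got {level}")
    z = float(stats.norm.ppf(0.5 + level / 2.0))
    return (expit(e.phi_hat - z * e.post_sd), expit(e.phi_hat + z * e.post_sd))


def pool_from_subject_table(t: SubjectTable, level: float = 0.95) -> PooledEstimate:
    """Pool the two design-weighted prevalences computed from subject-level data.

    The survey estimate uses rows with ``in_survey`` and weights ``w1``; the
    EHR estimate uses rows with ``in_ehr`` and post-stratified weights ``w2``.
    SEs are the weighted-ratio linearization mapped to the logit scale.
    """
    df = t.df
    surv = df[t.in_survey]
    ehr = df[t.in_ehr]
    if len(surv) < 2 or len(ehr) < 2:
        raise ValueError(
            f"need >= 2 subjects per source; got {len(surv)} survey, {len(ehr)} EHR"
        )
    if ehr["w2"].isna().any():
        raise ValueError("EHR subjects must carry post-stratified weights w2")
    p1, sigma1 = weighted_prevalence_se_logit(
        surv["y1"].to_numpy(float), surv["w1"].to_numpy(float))
    p2, sigma2 = weighted_prevalence_se_logit(
        ehr["y2"].to_numpy(float), ehr["w2"].to_numpy(float))
    return _pool_logits(logit(p1), logit(p2), sigma1, sigma2, level=level)
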