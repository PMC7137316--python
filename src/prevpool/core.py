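"""Shared domain types and survey-statistics primitives.

This module holds the pieces every estimator needs: logit-scale
transformations, design-weighted prevalence, exact cell post-stratification
of a nonprobability sample, and the two tabular containers used throughout —
:class:`SourceSummary` (one source's published prevalence estimate with its
95% CI) and :class:`SubjectTable` (per-subject records for the union of the
survey and EHR samples).
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import special, stats

__all__ = [
    "SourceSummary",
    "SubjectTable",
    "SUBJECT_COLUMNS",
    "logit",
    "expit",
    "se_logit_from_ci",
    "weighted_prevalence",
    "weighted_prevalence_se_logit",
    "post_stratify",
    "discretize",
]

#: canonical column order of the SubjectTable CSV schema
SUBJECT_COLUMNS = (
    "id", "x1", "x2", "u1", "u2", "y1", "y2",
    "pi1", "pi2", "in_survey", "in_ehr", "linked", "w1", "w2",
)


# ---------------------------------------------------------------------------
# logit-scale utilities
# ---------------------------------------------------------------------------

def logit(p):
    """Log-odds of a proportion, ``ln(p / (1 - p))``.

    Raises ``ValueError`` for arguments outside the open interval (0, 1);
    a prevalence of exactly 0 or 1 has no finite log-odds and silent
    continuity corrections would distort the pooled estimator downstream.
    """
    arr = np.asarray(p, dtype=float)
    if np.any(arr <= 0.0) or np.any(arr >= 1.0):
        bad = arr[(arr <= 0.0) | (arr >= 1.0)].ravel()[:5].tolist()
        raise ValueError(f"logit requires values in (0, 1); got {bad}")
    out = special.logit(arr)
    return float(out) if np.isscalar(p) or arr.ndim == 0 else out


def expit(x):
    """Inverse logit, ``1 / (1 + exp(-x))``."""
    out = special.expit(np.asarray(x, dtype=float))
    return float(out) if np.isscalar(x) or out.ndim == 0 else out


def _z(level: float) -> float:
    if not 0.0 < level < 1.0:
        raise ValueError(f"confidence level must be in (0, 1); got {level}")
    return float(stats.norm.ppf(0.5 + level / 2.0))


# ---------------------------------------------------------------------------
# SourceSummary
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SourceSummary:
    """A single source's prevalence estimate with its 95% confidence interval.

    This is the aggregate-mode input: what a published table prints for one
    source — a point estimate ``p_hat`` and interval ``(ci_lower, ci_upper)``
    on the probability scale, plus an optional informational sample size.
    """

    label: str
    p_hat: float
    ci_lower: float
    ci_upper: float
    n: int | None = None

    def __post_init__(self) -> None:
        if not (0.0 < self.ci_lower <= self.p_hat <= self.ci_upper < 1.0):
            raise ValueError(
                f"{self.label!r}: require 0 < ci_lower <= p_hat <= ci_upper < 1; "
                f"got ({self.ci_lower}, {self.p_hat}, {self.ci_upper})"
            )
        if self.n is not None and self.n <= 0:
            raise ValueError(f"{self.label!r}: n must be positive")

    @staticmethod
    def read_csv(path_or_buf) -> list["SourceSummary"]:
        """Read summaries from a CSV with header ``label,p_hat,ci_lower,ci_upper,n``."""
        df = pd.read_csv(path_or_buf, comment="#")
        expected = ["label", "p_hat", "ci_lower", "ci_upper", "n"]
        if list(df.columns) != expected:
            raise ValueError(f"expected columns {expected}, got {list(df.columns)}")
        out = []
        for _, row in df.iterrows():
            n = None if pd.isna(row["n"]) else int(row["n"])
            out.append(SourceSummary(str(row["label"]), float(row["p_hat"]),
                                     float(row["ci_lower"]), float(row["ci_upper"]), n))
        return out

    @staticmethod
    def to_csv(summaries: Sequence["SourceSummary"]) -> str:
        buf = io.StringIO()
        buf.write("label,p_hat,ci_lower,ci_upper,n\n")
        for s in summaries:
            n = "" if s.n is None else str(s.n)
            buf.write(f"{s.label},{s.p_hat},{s.ci_lower},{s.ci_upper},{n}\n")
        return buf.getvalue()


def se_logit_from_ci(s: SourceSummary, level: float = 0.95) -> float:
    """Recover the logit-scale standard error from a printed probability-scale CI.

    Interprets the interval as symmetric on the logit scale — the convention
    under which the pooled estimator's own credibility interval is built —
    so SE = (logit(upper) - logit(lower)) / (2 z).
    """
    if s.ci_lower == s.ci_upper:
        raise ValueError(
            f"{s.label!r}: degenerate CI (lower == upper); supply the standard error directly"
        )
    return (logit(s.ci_upper) - logit(s.ci_lower)) / (2.0 * _z(level))


# ---------------------------------------------------------------------------
# weighted prevalence
# ---------------------------------------------------------------------------

def weighted_prevalence(y, w) -> float:
    """Design-weighted prevalence ``sum(w*y) / sum(w)`` of a binary outcome."""
    y = np.asarray(y, dtype=float)
    w = np.asarray(w, dtype=float)
    if y.shape != w.shape:
        raise ValueError(f"length mismatch: y has {y.shape}, w has {w.shape}")
    if y.size == 0:
        raise ValueError("empty vectors")
    if np.any((y != 0.0) & (y != 1.0)):
        raise ValueError("y must be binary (0/1)")
    if np.any(w < 0.0):
        raise ValueError("weights must be nonnegative")
    total = w.sum()
    if total <= 0.0:
        raise ValueError("sum of weights must be positive")
    return float((w * y).sum() / total)


def weighted_prevalence_se_logit(y, w) -> tuple[float, float]:
    """Weighted prevalence and its naive logit-scale standard error.

    The probability-scale variance of the weighted ratio estimator is the
    standard linearization ``sum(w_i^2 (y_i - p)^2) / (sum w)^2``; the delta
    method maps it to the logit scale by dividing the SE by ``p (1 - p)``.
    Raises if the prevalence is exactly 0 or 1 (no finite logit).
    """
    y = np.asarray(y, dtype=float)
    w = np.asarray(w, dtype=float)
    p = weighted_prevalence(y, w)
    if p <= 0.0 or p >= 1.0:
        raise ValueError(
            f"weighted prevalence is {p}: logit-scale SE undefined "
            "(all-0 or all-1 outcomes)"
        )
    se_p = float(np.sqrt(np.sum(w**2 * (y - p) ** 2)) / w.sum())
    return p, se_p / (p * (1.0 - p))


# ---------------------------------------------------------------------------
# post-stratification
# ---------------------------------------------------------------------------

def post_stratify(sample_cells, population_cell_shares: Mapping) -> np.ndarray:
    """Exact cell post-stratification weights for a nonprobability sample.

    Each subject in cell ``c`` receives weight ``pop_share(c) / sample_share(c)``,
    so weighted cell shares reproduce the population joint distribution exactly
    and the mean weight is 1. No raking or cell collapsing: a population cell
    with nonzero share that is empty in the sample is an error, because its
    subjects are unrepresentable by reweighting.
    """
    cells = pd.Series(sample_cells)
    if cells.empty:
        raise ValueError("empty sample")
    shares = {k: float(v) for k, v in population_cell_shares.items()}
    total = sum(shares.values())
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"population shares must sum to 1; got {total}")
    counts = cells.value_counts()
    unknown = set(counts.index) - set(shares)
    if unknown:
        raise ValueError(f"sample cells missing from population shares: {sorted(map(str, unknown))}")
    empty = [c for c, s in shares.items() if s > 0.0 and c not in counts.index]
    if empty:
        raise ValueError(
            f"population cells with nonzero share are empty in the sample: {sorted(map(str, empty))}"
        )
    n = len(cells)
    weight_by_cell = {c: shares[c] / (counts[c] / n) for c in counts.index}
    return cells.map(weight_by_cell).to_numpy(dtype=float)


def discretize(values, k: int) -> np.ndarray:
    """Empirical quantile bins (1..k), right-closed, minimum in bin 1.

    Used to coarsen continuous design factors before cell post-stratification
    and to stratify subjects by inclusion-probability quartiles (k=4).
    """
    values = np.asarray(values, dtype=float)
    if k < 2:
        raise ValueError("k must be >= 2")
    if values.size < k:
        raise ValueError(f"need at least k={k} values; got {values.size}")
    if len(np.unique(values)) < k:
        raise ValueError(
            f"only {len(np.unique(values))} distinct values; reduce k below {k}"
        )
    cuts = np.quantile(values, np.linspace(0, 1, k + 1)[1:-1])
    return cut_labels(values, cuts)


def cut_labels(values, cuts) -> np.ndarray:
    """Assign 1-based bin labels for right-closed cut points (helper for discretize)."""
    values = np.asarray(values, dtype=float)
    cuts = np.asarray(cuts, dtype=float)
    return (np.searchsorted(cuts, values, side="left") + 1).astype(np.int64)


# ---------------------------------------------------------------------------
# SubjectTable
# ---------------------------------------------------------------------------

class SubjectTable:
    """Rectangular per-subject records for the union of survey and EHR samples.

    Wraps a :class:`pandas.DataFrame` with the fixed column schema
    ``id,x1,x2,u1,u2,y1,y2,pi1,pi2,in_survey,in_ehr,linked,w1,w2``:

    - ``x1`` (binary) and ``x2`` (real) — outcome-model covariates,
    - ``u1`` (binary) and ``u2`` (real) — survey design factors,
    - ``y1`` — gold-standard outcome, observed only for survey members,
    - ``y2`` — record-based (EHR) outcome, observed only for EHR members,
    - ``pi1``/``pi2`` — inclusion probabilities where known,
    - ``in_survey``/``in_ehr``/``linked`` — membership flags,
    - ``w1``/``w2`` — survey design weights and EHR post-stratified weights.

    Missingness is encoded as NaN; flags as 0/1.
    """

    def __init__(self, df: pd.DataFrame, validate: bool = True):
        missing = [c for c in SUBJECT_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"SubjectTable missing columns: {missing}")
        self.df = df.loc[:, list(SUBJECT_COLUMNS)].reset_index(drop=True)
        for flag in ("in_survey", "in_ehr", "linked"):
            self.df[flag] = self.df[flag].astype(int)
        if validate:
            self.validate()

    def __len__(self) -> int:
        return len(self.df)

    # -- masks ------------------------------------------------------------
    @property
    def in_survey(self) -> np.ndarray:
        return self.df["in_survey"].to_numpy(dtype=bool)

    @property
    def in_ehr(self) -> np.ndarray:
        return self.df["in_ehr"].to_numpy(dtype=bool)

    @property
    def linked(self) -> np.ndarray:
        return self.df["linked"].to_numpy(dtype=bool)

    def validate(self) -> None:
        df = self.df
        surv, ehr, link = self.in_survey, self.in_ehr, self.linked
        if np.any(link & ~(surv & ehr)):
            bad = df.loc[link & ~(surv & ehr), "id"].tolist()[:5]
            raise ValueError(f"linked subjects must be in both sources; offenders: {bad}")
        if df.loc[surv, "y1"].isna().any() or df.loc[surv, "w1"].isna().any():
            raise ValueError("survey subjects must have y1 and w1")
        if df.loc[~surv, "y1"].notna().any():
            raise ValueError("y1 must be missing outside the survey")
        if df.loc[ehr, "y2"].isna().any():
            raise ValueError("EHR subjects must have y2")
        if df.loc[~ehr, "y2"].notna().any():
            raise ValueError("y2 must be missing outside the EHR")
        for col in ("w1", "w2"):
            vals = df[col].dropna()
            if (vals < 0).any():
                raise ValueError(f"{col} must be nonnegative")
        for col in ("pi1", "pi2"):
            vals = df[col].dropna()
            if ((vals <= 0) | (vals >= 1)).any():
                raise ValueError(f"{col} must lie in (0, 1)")
        for col in ("y1", "y2"):
            vals = df[col].dropna()
            if (~vals.isin([0, 1])).any():
                raise ValueError(f"{col} must be binary")

    # -- IO ---------------------------------------------------------------
    def to_csv(self, path) -> None:
        out = self.df.copy()
        for flag in ("in_survey", "in_ehr", "linked"):
            out[flag] = out[flag].astype(int)
        for col in ("y1", "y2"):
            out[col] = out[col].map(lambda v: "" if pd.isna(v) else str(int(v)))
        out.to_csv(path, index=False, float_format="%.17g")

    @staticmethod
    def read_csv(path) -> "SubjectTable":
        df = pd.read_csv(path, comment="#")
        if list(df.columns) != list(SUBJECT_COLUMNS):
            raise ValueError(
                f"expected columns {list(SUBJECT_COLUMNS)}, got {list(df.columns)}"
            )
        return SubjectTable(df)
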