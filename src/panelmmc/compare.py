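"""Statistical comparison of classifiers and markers.

Three tools: McNemar's test for correlated proportions (paired per-case
diagnoses of two classifiers), the Hanley-McNeil z-ratio for the difference
of two correlated AUCs measured on the same subjects, and Pearson
correlation of each marker with an anchor marker (CA 19-9-like) among
cases.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import Cohort

__all__ = [
    "MCNEMAR_CHI2_CUTOFF",
    "HM_Z_CUTOFF",
    "PairedClassification",
    "AucComparison",
    "mcnemar_chi2",
    "paired_calls",
    "hanley_mcneil_se",
    "hanley_mcneil_z",
    "pearson_to_anchor",
]

#: 95th percentile of the chi-square distribution with 1 df
MCNEMAR_CHI2_CUTOFF = 3.841
#: z-ratio magnitude treated as significant for AUC differences
HM_Z_CUTOFF = 2.0


@dataclass
class PairedClassification:
    """Discordant-pair counts for two classifiers on the same cases."""

    b: int  # A positive, B negative
    c: int  # A negative, B positive
    n: int  # cases compared

    def __post_init__(self) -> None:
        if self.b < 0 or self.c < 0 or self.b + self.c > self.n:
            raise ValueError("invalid discordant counts")


def paired_calls(calls_a, calls_b) -> PairedClassification:
    """Tabulate discordant calls of two classifiers on the same samples."""
    a = np.asarray(calls_a, dtype=bool)
    b = np.asarray(calls_b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError("call vectors must cover the same samples")
    return PairedClassification(
        b=int((a & ~b).sum()), c=int((~a & b).sum()), n=a.size
    )


def mcnemar_chi2(b: int, c: int) -> tuple[float, bool]:
    """McNemar chi-square for correlated proportions, without continuity
    correction: chi2 = (b - c)^2 / (b + c); significant iff chi2 > 3.841
    (the 5% point of chi-square with 1 df).

    The degenerate b + c = 0 case (no discordant pairs) is defined as
    chi2 = 0, not significant.
    """
    if b < 0 or c < 0:
        raise ValueError("counts must be non-negative")
    if b + c == 0:
        return 0.0, False
    chi2 = (b - c) ** 2 / (b + c)
    return float(chi2), bool(chi2 > MCNEMAR_CHI2_CUTOFF)


@dataclass
class AucComparison:
    """Correlated-AUC comparison between two score sets."""

    auc_a: float
    auc_b: float
    se_a: float
    se_b: float
    r: float
    z: float

    @property
    def significant(self) -> bool:
        return abs(self.z) >= HM_Z_CUTOFF


def hanley_mcneil_se(auc: float, n_case: int, n_ctrl: int) -> float:
    """Standard error of an AUC per Hanley & McNeil (1982).

    SE^2 = [A(1-A) + (n_case-1)(Q1 - A^2) + (n_ctrl-1)(Q2 - A^2)]
           / (n_case * n_ctrl),
    with Q1 = A/(2-A) and Q2 = 2A^2/(1+A).
    """
    a = float(auc)
    q1 = a / (2.0 - a)
    q2 = 2.0 * a * a / (1.0 + a)
    var = (
        a * (1.0 - a)
        + (n_case - 1) * (q1 - a * a)
        + (n_ctrl - 1) * (q2 - a * a)
    ) / (n_case * n_ctrl)
    return float(np.sqrt(max(var, 0.0)))


def _rank_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    r = stats.rankdata(scores)
    n1 = int(labels.sum())
    n0 = labels.size - n1
    return float((r[labels].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0))


def hanley_mcneil_z(scores_a, scores_b, labels) -> AucComparison:
    """Z-ratio for the difference of two correlated AUCs.

    Both score sets must cover the same subjects.  The score-set
    correlation r entering the covariance term is estimated as the mean of
    the Pearson correlations of the two scores within cases and within
    controls (the Hanley-McNeil intermediate quantity; their table maps it
    through the average AUC almost linearly, so the average correlation is
    used directly — the convention is deliberately explicit here and the
    component correlations are recoverable from the inputs).

    z = (A_a - A_b) / sqrt(se_a^2 + se_b^2 - 2 r se_a se_b); |z| >= 2 is
    treated as significant.
    """
    sa = np.asarray(scores_a, dtype=float)
    sb = np.asarray(scores_b, dtype=float)
    y = np.asarray(labels, dtype=bool)
    if sa.shape != sb.shape or sa.shape != y.shape:
        raise ValueError("score sets must cover the same subjects")
    if y.all() or not y.any():
        raise ValueError("both classes must be present")
    auc_a = _rank_auc(sa, y)
    auc_b = _rank_auc(sb, y)
    se_a = hanley_mcneil_se(auc_a, int(y.sum()), int((~y).sum()))
    se_b = hanley_mcneil_se(auc_b, int(y.sum()), int((~y).sum()))

    def _safe_corr(u, v):
        if np.std(u) == 0 or np.std(v) == 0:
            return 1.0 if np.allclose(u, v) else 0.0
        return float(stats.pearsonr(u, v)[0])

    r = 0.5 * (_safe_corr(sa[y], sb[y]) + _safe_corr(sa[~y], sb[~y]))
    denom_sq = se_a**2 + se_b**2 - 2.0 * r * se_a * se_b
    if denom_sq <= 0:
        z = 0.0 if np.isclose(auc_a, auc_b) else np.inf * np.sign(auc_a - auc_b)
    else:
        z = (auc_a - auc_b) / np.sqrt(denom_sq)
    return AucComparison(auc_a, auc_b, se_a, se_b, r, float(z))


def pearson_to_anchor(
    cohort: Cohort,
    anchor: str,
    markers: list[str] | None = None,
    log_scale: bool = False,
) -> pd.DataFrame:
    """Pearson correlation of each marker with the anchor, in cases only.

    Returns a frame with r, r^2 and the two-sided p-value from the
    t-transform with n-2 df.  Raw concentrations by default; ``log_scale``
    correlates log concentrations instead.
    """
    if anchor not in cohort.marker_registry:
        raise KeyError(f"anchor {anchor!r} not in marker registry")
    markers = markers if markers is not None else [
        m for m in cohort.marker_registry if m != anchor
    ]
    a = cohort.values(anchor, status="case")
    if a.size < 3:
        raise ValueError("need at least 3 cases for correlation")
    if log_scale:
        a = np.log(a)
    rows = []
    for m in markers:
        v = cohort.values(m, status="case")
        if log_scale:
            v = np.log(v)
        r, p = stats.pearsonr(a, v)
        rows.append({"marker": m, "r": float(r), "r2": float(r * r),
                     "p": float(p)})
    return pd.DataFrame(rows)
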