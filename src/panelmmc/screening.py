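"""Per-marker case/control screening.

Mann-Whitney U test per marker, Benjamini-Hochberg step-up control of the
false discovery rate across the panel, rank-formula AUC, and the
concentration cut-point giving a target specificity (the minimum value
calling a case for up-markers, maximum for down-markers), with sensitivity
at that cut-point.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import Cohort

__all__ = [
    "MarkerResult",
    "ScreenResults",
    "mann_whitney",
    "bh_fdr",
    "marker_auc",
    "cutpoint_at_specificity",
    "screen_markers",
]


def _u_statistic(case_values: np.ndarray, control_values: np.ndarray) -> float:
    """Mann-Whitney U counting case-over-control wins, ties as 1/2."""
    x = np.asarray(case_values, dtype=float)
    y = np.asarray(control_values, dtype=float)
    ranks = stats.rankdata(np.concatenate([x, y]))
    r1 = ranks[: x.size].sum()
    return float(r1 - x.size * (x.size + 1) / 2.0)


def mann_whitney(case_values, control_values) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test.

    Returns (U, p).  U counts case-over-control wins with ties as 1/2.  The
    p-value is exact (full enumeration of group labelings, tie-aware) when
    n1*n2 <= 64, otherwise a tie-corrected normal approximation with
    continuity correction.
    """
    x = np.asarray(case_values, dtype=float)
    y = np.asarray(control_values, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    u = _u_statistic(x, y)
    n1, n2 = x.size, y.size
    if n1 * n2 <= 64:
        pooled = np.concatenate([x, y])
        mu = n1 * n2 / 2.0
        dev = abs(u - mu)
        total = 0
        hits = 0
        idx = np.arange(pooled.size)
        for comb in itertools.combinations(idx, n1):
            mask = np.zeros(pooled.size, dtype=bool)
            mask[list(comb)] = True
            u_perm = _u_statistic(pooled[mask], pooled[~mask])
            total += 1
            if abs(u_perm - mu) >= dev - 1e-12:
                hits += 1
        p = hits / total
    else:
        p = float(
            stats.mannwhitneyu(
                x, y, alternative="two-sided", method="asymptotic",
                use_continuity=True,
            ).pvalue
        )
    return u, min(1.0, p)


def bh_fdr(p_values, q: float = 0.05, m: int | None = None) -> np.ndarray:
    """Benjamini-Hochberg step-up significance flags.

    Compares the ranked p-values to i*q/m (i = rank, m = total number of
    comparisons, which may exceed ``len(p_values)`` when only a subset of a
    larger family is supplied) and flags every p-value with rank at or below
    the largest i satisfying p_(i) <= i*q/m.
    """
    p = np.asarray(p_values, dtype=float)
    if not 0 < q < 1:
        raise ValueError("q must be in (0, 1)")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if m is None:
        m = p.size
    if m < p.size:
        raise ValueError("m must be >= number of p-values")
    order = np.argsort(p, kind="stable")
    ranks = np.arange(1, p.size + 1)
    ok = p[order] <= ranks * q / m
    flags = np.zeros(p.size, dtype=bool)
    if ok.any():
        k = int(np.nonzero(ok)[0].max())
        flags[order[: k + 1]] = True
    return flags


def marker_auc(case_values, control_values) -> float:
    """Area under the empirical ROC curve via the rank (win-fraction) formula."""
    x = np.asarray(case_values, dtype=float)
    y = np.asarray(control_values, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    return _u_statistic(x, y) / (x.size * y.size)


def cutpoint_at_specificity(
    case_values,
    control_values,
    sp_target: float = 95.0,
    direction: str = "up",
) -> tuple[float, float, float]:
    """Concentration cut-point achieving at least the target specificity.

    For an up-marker the rule is "case if value >= cut-point" and the
    cut-point is the smallest observed value leaving at most
    (1 - sp_target/100) of controls at or above it; the tie-break maximizes
    sensitivity.  Down-markers use the mirrored rule (case if value <=
    cut-point).  Returns (cut_point, sn_percent, achieved_sp_percent).
    """
    x = np.asarray(case_values, dtype=float)
    y = np.asarray(control_values, dtype=float)
    if y.size == 0:
        raise ValueError("controls must be non-empty")
    if not 0 < sp_target < 100:
        raise ValueError("sp_target must be in (0, 100)")
    if direction not in ("up", "down"):
        raise ValueError("direction must be 'up' or 'down'")
    sign = 1.0 if direction == "up" else -1.0
    xs, ys = sign * x, sign * y
    allowed = math.floor(y.size * (1.0 - sp_target / 100.0))
    candidates = np.unique(np.concatenate([xs, ys]))
    qualifying = [v for v in candidates if (ys >= v).sum() <= allowed]
    if not qualifying:
        max_sp = 100.0 * (1.0 - 1.0 / y.size)
        raise ValueError(
            f"specificity {sp_target}% unattainable with {y.size} controls; "
            f"minimum resolvable specificity above chance is {max_sp:.4g}%"
        )
    v = min(qualifying)  # smallest qualifying value maximizes sensitivity
    sn = 100.0 * float((xs >= v).mean()) if x.size else float("nan")
    achieved_sp = 100.0 * float((ys < v).mean())
    return float(sign * v), sn, achieved_sp


@dataclass
class MarkerResult:
    """Univariate summary for one biomarker."""

    marker: str
    u_statistic: float
    p_value: float
    bh_significant: bool
    case_low: float
    case_high: float
    case_mean: float
    control_low: float
    control_high: float
    control_mean: float
    auc: float
    direction: str
    cut_point: float
    sn_at_sp: float
    achieved_sp: float


class ScreenResults:
    """Results of a full univariate screen; Table-5-shaped report."""

    def __init__(
        self, results: list[MarkerResult], q: float, m: int, sp_target: float
    ):
        self.results = results
        self.q = q
        self.m = m
        self.sp_target = sp_target

    @property
    def significant(self) -> list[MarkerResult]:
        return [r for r in self.results if r.bh_significant]

    @property
    def realized_p_threshold(self) -> float:
        """Largest p-value flagged by the step-up rule (0 if none)."""
        flagged = [r.p_value for r in self.significant]
        return max(flagged) if flagged else 0.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(r) for r in self.results])

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def summary(self) -> str:
        lines = [
            f"Univariate marker screen ({len(self.results)} markers, "
            f"BH q={self.q}, m={self.m}, SP target {self.sp_target}%)",
            f"Significant markers: {len(self.significant)} "
            f"(realized p threshold {self.realized_p_threshold:.4g})",
            f"{'marker':<14}{'p':>10}{'AUC':>8}{'dir':>6}"
            f"{'cut-point':>12}{'SN%':>8}{'SP%':>8}",
        ]
        for r in sorted(self.results, key=lambda r: r.p_value):
            if not r.bh_significant:
                continue
            lines.append(
                f"{r.marker:<14}{r.p_value:>10.3g}{r.auc:>8.3f}"
                f"{r.direction:>6}{r.cut_point:>12.4g}{r.sn_at_sp:>8.1f}"
                f"{r.achieved_sp:>8.1f}"
            )
        return "\n".join(lines)


def screen_markers(
    cohort: Cohort,
    markers: list[str] | None = None,
    q: float = 0.05,
    m: int | None = None,
    sp_target: float = 95.0,
) -> ScreenResults:
    """Run the univariate screen over a marker list (default: full registry)."""
    cohort.require_unblinded("univariate screening")
    markers = markers if markers is not None else list(cohort.marker_registry)
    m_total = m if m is not None else len(markers)
    rows = []
    pvals = []
    for name in markers:
        x, y = cohort.case_control_values(name)
        u, p = mann_whitney(x, y)
        auc = u / (x.size * y.size)
        direction = "up" if np.median(x) >= np.median(y) else "down"
        cut, sn, asp = cutpoint_at_specificity(x, y, sp_target, direction)
        rows.append(
            MarkerResult(
                marker=name,
                u_statistic=u,
                p_value=p,
                bh_significant=False,
                case_low=float(x.min()),
                case_high=float(x.max()),
                case_mean=float(x.mean()),
                control_low=float(y.min()),
                control_high=float(y.max()),
                control_mean=float(y.mean()),
                auc=auc,
                direction=direction,
                cut_point=cut,
                sn_at_sp=sn,
                achieved_sp=asp,
            )
        )
        pvals.append(p)
    flags = bh_fdr(pvals, q=q, m=m_total)
    for r, f in zip(rows, flags):
        r.bh_significant = bool(f)
    return ScreenResults(rows, q=q, m=m_total, sp_target=sp_target)
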