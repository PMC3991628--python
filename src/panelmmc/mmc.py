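"""Metropolis/Monte-Carlo optimization of multimarker scoring functions.

The scoring function (SF) for a biomarker panel is a linear combination of
logarithms of the panel's concentrations,

    SF(c) = sum_i  w_i * ln(c_i),

and a sample is called a case when its score reaches a threshold calibrated
to a predetermined specificity (default 95%) on control scores.  The
coefficients w_i are assigned by a Metropolis algorithm: starting from unit
weights, one coefficient at a time is perturbed by a Gaussian step, the
cross-validated sensitivity at the target specificity is recomputed, and
the move is accepted when the objective improves or, with Boltzmann
probability exp(delta/T), when it worsens; the temperature decays
geometrically.  The best-seen state is retained, so the incumbent objective
is monotone over iterations.

Panel discovery enumerates all combinations of 2, 3 or 4 markers, fits each
panel's SF, and ranks panels by cross-validated sensitivity.  To make the
ranking fair, every panel is scored against the same Monte-Carlo
train/test splits (common random numbers).

A statsmodels-flavoured front door is provided: ``PanelModel(cohort,
markers).fit(config)`` returns :class:`PanelResults` carrying the fitted
scoring function, its cross-validated performance and a ``summary()``.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .cohort import Cohort, Subject

__all__ = [
    "ScoringFunction",
    "MetropolisConfig",
    "PanelPerformance",
    "PanelModel",
    "PanelResults",
    "PanelSearchResults",
    "score",
    "calibrate_threshold",
    "fit_scoring_function",
    "cross_validate",
    "search_panels",
]


@dataclass
class ScoringFunction:
    """A fitted log-linear classifier over a marker panel."""

    markers: tuple[str, ...]
    coefficients: np.ndarray
    threshold: float
    sp_target: float = 95.0

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if self.coefficients.size != len(self.markers):
            raise ValueError("one coefficient per marker required")

    def score_vector(self, log_conc: np.ndarray) -> float | np.ndarray:
        return log_conc @ self.coefficients

    def score_subject(self, subject: Subject) -> float:
        missing = [m for m in self.markers if m not in subject.concentrations]
        if missing:
            raise KeyError(
                f"subject {subject.subject_id} lacks markers: {missing}"
            )
        logc = np.log([subject.concentrations[m] for m in self.markers])
        return float(logc @ self.coefficients)

    def score_cohort(self, cohort: Cohort, subjects=None) -> np.ndarray:
        X = cohort.marker_matrix(self.markers, log=True, subjects=subjects)
        return X @ self.coefficients

    def classify(self, scores: np.ndarray | float) -> np.ndarray | bool:
        """Diagnose: case iff score >= threshold."""
        return np.asarray(scores) >= self.threshold

    def to_dict(self) -> dict:
        return {
            "markers": list(self.markers),
            "coefficients": self.coefficients.tolist(),
            "threshold": self.threshold,
            "sp_target": self.sp_target,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ScoringFunction":
        return cls(
            markers=tuple(d["markers"]),
            coefficients=np.asarray(d["coefficients"], dtype=float),
            threshold=float(d["threshold"]),
            sp_target=float(d.get("sp_target", 95.0)),
        )


def score(sf: ScoringFunction, subject: Subject) -> float:
    """Score one subject: sum of w_i * ln(c_i) over the panel."""
    return sf.score_subject(subject)


def calibrate_threshold(scores_controls, sp_target: float = 95.0) -> float:
    """Smallest threshold t with #(control scores >= t)/n <= 1 - SP/100.

    Ties among control scores push the threshold upward (specificity-
    protective); if no observed score qualifies the threshold is set just
    above the largest control score, giving 100% specificity.
    """
    s = np.asarray(scores_controls, dtype=float)
    if s.size == 0:
        raise ValueError("controls must be non-empty")
    if not 0 < sp_target < 100:
        raise ValueError("sp_target must be in (0, 100)")
    allowed = math.floor(s.size * (1.0 - sp_target / 100.0))
    for v in np.unique(s):  # ascending
        if (s >= v).sum() <= allowed:
            return float(v)
    return float(np.nextafter(s.max(), np.inf))


@dataclass
class MetropolisConfig:
    """Optimizer settings.  Seeds are mandatory for reproducibility.

    ``n_splits_objective`` Monte-Carlo splits (fixed per fit, shared across
    panels during a search) drive the Metropolis objective;
    ``n_cv`` is the number of cross-validation replicates used to evaluate
    selected panels.
    """

    n_iterations: int = 2000
    proposal_sd: float = 0.25
    temperature_init: float = 1.0
    temperature_decay: float = 0.995
    n_cv: int = 500
    cv_test_fraction: float = 1.0 / 3.0
    n_splits_objective: int = 16
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")
        if not 0 < self.cv_test_fraction < 1:
            raise ValueError("cv_test_fraction must be in (0, 1)")


@dataclass
class PanelPerformance:
    """Performance record for one panel at the target specificity."""

    panel: tuple[str, ...]
    sn: float
    achieved_sp: float
    auc: float
    cv_sn_distribution: np.ndarray
    cv_sp_distribution: np.ndarray
    best_sf: ScoringFunction
    objective: float = float("nan")


# ---------------------------------------------------------------------------
# internal vectorised machinery
# ---------------------------------------------------------------------------


class _SplitSet:
    """Pre-drawn stratified Monte-Carlo train/test splits as index arrays.

    Rectangular index matrices allow one fancy-indexing gather per
    objective evaluation.  Threshold selection inside the hot loop assumes
    continuous (tie-free) scores; the canonical ``calibrate_threshold``
    handles ties exactly and is used for the final returned threshold.
    """

    def __init__(
        self,
        case_idx: np.ndarray,
        ctrl_idx: np.ndarray,
        n_splits: int,
        test_fraction: float,
        sp_target: float,
        rng: np.random.Generator,
    ):
        n_case, n_ctrl = case_idx.size, ctrl_idx.size
        if n_case < 2 or n_ctrl < 2:
            raise ValueError("need at least 2 cases and 2 controls")
        n_case_test = min(n_case - 1, max(1, round(n_case * test_fraction)))
        n_ctrl_test = min(n_ctrl - 1, max(1, round(n_ctrl * test_fraction)))
        tc, ttc, tk, ttk = [], [], [], []
        for _ in range(n_splits):
            pc = rng.permutation(n_case)
            pk = rng.permutation(n_ctrl)
            ttc.append(case_idx[pc[:n_case_test]])
            tc.append(case_idx[pc[n_case_test:]])
            ttk.append(ctrl_idx[pk[:n_ctrl_test]])
            tk.append(ctrl_idx[pk[n_ctrl_test:]])
        self.train_case = np.array(tc)
        self.test_case = np.array(ttc)
        self.train_ctrl = np.array(tk)
        self.test_ctrl = np.array(ttk)
        self.sp_target = sp_target
        self.allowed = math.floor(
            self.train_ctrl.shape[1] * (1.0 - sp_target / 100.0)
        )

    def thresholds(self, s: np.ndarray) -> np.ndarray:
        """Per-split thresholds calibrated on the training controls."""
        stc = s[self.train_ctrl]  # (n_splits, n_train_ctrl)
        if self.allowed == 0:
            return np.nextafter(stc.max(axis=1), np.inf)
        # allowed-th largest training-control score: count(>= t) == allowed
        # for tie-free scores, matching calibrate_threshold exactly
        return -np.partition(-stc, self.allowed - 1, axis=1)[:, self.allowed - 1]

    def mean_test_sn(self, s: np.ndarray) -> float:
        t = self.thresholds(s)
        return float((s[self.test_case] >= t[:, None]).mean())

    def test_sn_sp(self, s: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        t = self.thresholds(s)
        sn = (s[self.test_case] >= t[:, None]).mean(axis=1)
        sp = (s[self.test_ctrl] < t[:, None]).mean(axis=1)
        return 100.0 * sn, 100.0 * sp


def _panel_data(
    cohort: Cohort, panel: Sequence[str]
) -> tuple[np.ndarray, np.ndarray]:
    cohort.require_unblinded("scoring-function fitting")
    subjects = cohort.primary_subjects()
    X = cohort.marker_matrix(panel, log=True, subjects=subjects)
    y = np.array([s.is_case for s in subjects])
    return X, y


def _metropolis(
    X: np.ndarray,
    splits: _SplitSet,
    cfg: MetropolisConfig,
    rng: np.random.Generator,
    w0: np.ndarray | None = None,
) -> tuple[np.ndarray, float, np.ndarray]:
    """Core sampler.  Returns (best weights, best objective, trace)."""
    k = X.shape[1]
    w = np.ones(k) if w0 is None else np.asarray(w0, dtype=float).copy()
    s = X @ w
    obj = splits.mean_test_sn(s)
    best_w, best_obj = w.copy(), obj
    n = cfg.n_iterations
    which = rng.integers(0, k, size=n)
    steps = rng.normal(0.0, cfg.proposal_sd, size=n)
    us = rng.random(n)
    temps = cfg.temperature_init * cfg.temperature_decay ** np.arange(n)
    trace = np.empty(n)
    for i in range(n):
        j = which[i]
        s_new = s + steps[i] * X[:, j]
        obj_new = splits.mean_test_sn(s_new)
        delta = obj_new - obj
        if delta >= 0 or us[i] < math.exp(delta / max(temps[i], 1e-12)):
            s = s_new
            w[j] += steps[i]
            obj = obj_new
            if obj > best_obj:
                best_obj = obj
                best_w = w.copy()
        trace[i] = best_obj
    return best_w, best_obj, trace


def fit_scoring_function(
    cohort: Cohort,
    panel: Sequence[str],
    cfg: MetropolisConfig,
    _splits: _SplitSet | None = None,
    _rng: np.random.Generator | None = None,
) -> ScoringFunction:
    """Fit panel coefficients by Metropolis/Monte-Carlo optimization.

    The objective is the mean test-set sensitivity over Monte-Carlo
    stratified splits with the threshold recalibrated on each split's
    training controls (so specificity is enforced without leakage).  The
    returned threshold is calibrated on the full training controls.
    Deterministic given ``cfg.seed``.
    """
    X, y = _panel_data(cohort, panel)
    rng = _rng if _rng is not None else np.random.default_rng(cfg.seed)
    splits = _splits
    if splits is None:
        splits = _SplitSet(
            np.flatnonzero(y),
            np.flatnonzero(~y),
            cfg.n_splits_objective,
            cfg.cv_test_fraction,
            sp_target=95.0,
            rng=rng,
        )
    best_w, best_obj, _ = _metropolis(X, splits, cfg, rng)
    scores = X @ best_w
    threshold = calibrate_threshold(scores[~y], splits.sp_target)
    return ScoringFunction(
        markers=tuple(panel),
        coefficients=best_w,
        threshold=threshold,
        sp_target=splits.sp_target,
    )


def cross_validate(
    cohort: Cohort,
    panel: Sequence[str],
    cfg: MetropolisConfig,
    sp_target: float = 95.0,
    refit: bool = True,
    weights: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Repeated random stratified-subsampling cross-validation.

    Each of ``cfg.n_cv`` replicates holds out ``cv_test_fraction`` of cases
    and controls, fits the scoring function on the remainder (weights by
    Metropolis unless ``refit=False``, threshold always calibrated on the
    training controls), and records test sensitivity and specificity.
    Returns (sn_percent, sp_percent) vectors of length ``n_cv``.
    """
    X, y = _panel_data(cohort, panel)
    rng = np.random.default_rng(cfg.seed)
    case_idx, ctrl_idx = np.flatnonzero(y), np.flatnonzero(~y)
    eval_splits = _SplitSet(
        case_idx, ctrl_idx, cfg.n_cv, cfg.cv_test_fraction, sp_target, rng
    )
    if not refit:
        w = np.asarray(weights, dtype=float)
        return eval_splits.test_sn_sp(X @ w)
    sn = np.empty(cfg.n_cv)
    sp = np.empty(cfg.n_cv)
    for r in range(cfg.n_cv):
        tr_case = eval_splits.train_case[r]
        tr_ctrl = eval_splits.train_ctrl[r]
        tr = np.concatenate([tr_case, tr_ctrl])
        Xtr = X[tr]
        ytr = np.zeros(tr.size, dtype=bool)
        ytr[: tr_case.size] = True
        inner = _SplitSet(
            np.flatnonzero(ytr),
            np.flatnonzero(~ytr),
            cfg.n_splits_objective,
            cfg.cv_test_fraction,
            sp_target,
            rng,
        )
        w, _, _ = _metropolis(Xtr, inner, cfg, rng)
        t = calibrate_threshold(Xtr[~ytr] @ w, sp_target)
        sn[r] = 100.0 * float((X[eval_splits.test_case[r]] @ w >= t).mean())
        sp[r] = 100.0 * float((X[eval_splits.test_ctrl[r]] @ w < t).mean())
    return sn, sp


def _rank_auc(scores: np.ndarray, y: np.ndarray) -> float:
    from scipy.stats import rankdata

    r = rankdata(scores)
    n1 = int(y.sum())
    n0 = y.size - n1
    u = r[y].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


class PanelSearchResults:
    """Ranked exhaustive-search results over panel sizes."""

    def __init__(self, performances: list[PanelPerformance], sp_target: float):
        self.performances = sorted(
            performances, key=lambda p: p.objective, reverse=True
        )
        self.sp_target = sp_target

    def best(self, size: int | None = None) -> PanelPerformance:
        for p in self.performances:
            if size is None or len(p.panel) == size:
                return p
        raise KeyError(f"no panel of size {size}")

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            [
                {
                    "panel": "/".join(p.panel),
                    "size": len(p.panel),
                    "objective_cv_sn": 100.0 * p.objective,
                    "sn": p.sn,
                    "achieved_sp": p.achieved_sp,
                    "auc": p.auc,
                }
                for p in self.performances
            ]
        )

    def summary(self, top: int = 10) -> str:
        lines = [
            f"Exhaustive panel search (SP target {self.sp_target}%): "
            f"{len(self.performances)} panels evaluated",
            f"{'panel':<40}{'CV SN%':>8}{'SN%':>8}{'SP%':>8}{'AUC':>8}",
        ]
        for p in self.performances[:top]:
            lines.append(
                f"{'/'.join(p.panel):<40}{100 * p.objective:>8.1f}"
                f"{p.sn:>8.1f}{p.achieved_sp:>8.1f}{p.auc:>8.3f}"
            )
        return "\n".join(lines)


def search_panels(
    cohort: Cohort,
    sizes: Sequence[int] = (2, 3, 4),
    cfg: MetropolisConfig | None = None,
    markers: Sequence[str] | None = None,
    sp_target: float = 95.0,
    evaluate_best: bool = True,
) -> PanelSearchResults:
    """Exhaustively enumerate and fit all panels of the requested sizes.

    Every C(n, k) combination is fitted by Metropolis optimization against
    a split set shared across panels (common random numbers), and panels
    are ranked by cross-validated sensitivity at the target specificity.
    When ``evaluate_best`` is set, the top panel of each size additionally
    receives a full ``cfg.n_cv``-replicate cross-validation and full-data
    AUC/SN/SP.
    """
    cfg = cfg or MetropolisConfig()
    marker_pool = list(markers) if markers is not None else list(cohort.marker_registry)
    if max(sizes) > len(marker_pool):
        raise ValueError("panel size exceeds marker registry")
    X_all, y = _panel_data(cohort, marker_pool)
    rng = np.random.default_rng(cfg.seed)
    splits = _SplitSet(
        np.flatnonzero(y),
        np.flatnonzero(~y),
        cfg.n_splits_objective,
        cfg.cv_test_fraction,
        sp_target,
        rng,
    )
    perfs: list[PanelPerformance] = []
    for k in sizes:
        for combo in itertools.combinations(range(len(marker_pool)), k):
            panel = tuple(marker_pool[i] for i in combo)
            Xp = X_all[:, combo]
            panel_rng = np.random.default_rng(
                np.random.SeedSequence([cfg.seed, k, *combo])
            )
            best_w, best_obj, _ = _metropolis(Xp, splits, cfg, panel_rng)
            scores = Xp @ best_w
            threshold = calibrate_threshold(scores[~y], sp_target)
            sf = ScoringFunction(panel, best_w, threshold, sp_target)
            calls = scores >= threshold
            perfs.append(
                PanelPerformance(
                    panel=panel,
                    sn=100.0 * float(calls[y].mean()),
                    achieved_sp=100.0 * float((~calls[~y]).mean()),
                    auc=_rank_auc(scores, y),
                    cv_sn_distribution=np.array([]),
                    cv_sp_distribution=np.array([]),
                    best_sf=sf,
                    objective=best_obj,
                )
            )
    results = PanelSearchResults(perfs, sp_target)
    if evaluate_best:
        for k in sizes:
            best = results.best(k)
            sn, sp = cross_validate(
                cohort,
                best.panel,
                cfg,
                sp_target=sp_target,
                refit=False,
                weights=best.best_sf.coefficients,
            )
            best.cv_sn_distribution = sn
            best.cv_sp_distribution = sp
    return results


# ---------------------------------------------------------------------------
# Model / Results front door
# ---------------------------------------------------------------------------


class PanelModel:
    """Scoring-function model for one biomarker panel on one cohort.

    Parameters
    ----------
    cohort : Cohort
        Unblinded training cohort (duplicate rows are excluded from
        fitting).
    markers : sequence of str
        The panel; order fixes the coefficient order.
    sp_target : float
        Specificity (%) at which the threshold is calibrated and
        sensitivity is optimized.
    """

    def __init__(self, cohort: Cohort, markers: Sequence[str],
                 sp_target: float = 95.0):
        cohort.require_unblinded("PanelModel")
        self.cohort = cohort
        self.markers = tuple(markers)
        self.sp_target = sp_target

    @classmethod
    def from_dataframe(
        cls, frame, markers: Sequence[str], sp_target: float = 95.0, **kwargs
    ) -> "PanelModel":
        """Build from a cohort dataframe (same columns as the cohort CSV)."""
        import io

        from .cohort import read_cohort

        buf = io.StringIO()
        frame.to_csv(buf, index=False)
        buf.seek(0)
        return cls(read_cohort(buf), markers, sp_target)

    def fit(self, config: MetropolisConfig | None = None) -> "PanelResults":
        cfg = config or MetropolisConfig()
        X, y = _panel_data(self.cohort, self.markers)
        rng = np.random.default_rng(cfg.seed)
        splits = _SplitSet(
            np.flatnonzero(y),
            np.flatnonzero(~y),
            cfg.n_splits_objective,
            cfg.cv_test_fraction,
            self.sp_target,
            rng,
        )
        best_w, best_obj, trace = _metropolis(X, splits, cfg, rng)
        scores = X @ best_w
        threshold = calibrate_threshold(scores[~y], self.sp_target)
        sf = ScoringFunction(self.markers, best_w, threshold, self.sp_target)
        cv_sn, cv_sp = cross_validate(
            self.cohort, self.markers, cfg, sp_target=self.sp_target,
            refit=False, weights=best_w,
        )
        calls = scores >= threshold
        perf = PanelPerformance(
            panel=self.markers,
            sn=100.0 * float(calls[y].mean()),
            achieved_sp=100.0 * float((~calls[~y]).mean()),
            auc=_rank_auc(scores, y),
            cv_sn_distribution=cv_sn,
            cv_sp_distribution=cv_sp,
            best_sf=sf,
            objective=best_obj,
        )
        return PanelResults(self, sf, perf, trace, cfg)


class PanelResults:
    """Fitted scoring function plus performance diagnostics."""

    def __init__(self, model, scoring_function, performance, trace, config):
        self.model = model
        self.scoring_function = scoring_function
        self.performance = performance
        self.objective_trace = trace
        self.config = config

    @property
    def coefficients(self) -> dict[str, float]:
        return dict(
            zip(self.scoring_function.markers,
                self.scoring_function.coefficients)
        )

    def predict(self, cohort: Cohort, subjects=None) -> np.ndarray:
        """Case calls for (possibly blinded) samples."""
        return self.scoring_function.classify(
            self.scoring_function.score_cohort(cohort, subjects)
        )

    def summary(self) -> str:
        p = self.performance
        sf = self.scoring_function
        lines = [
            "Scoring-function fit (Metropolis/Monte-Carlo)",
            f"Panel: {'/'.join(sf.markers)}",
            f"SP target: {sf.sp_target:.1f}%   threshold: {sf.threshold:.4f}",
            "Coefficients:",
        ]
        for m, w in zip(sf.markers, sf.coefficients):
            lines.append(f"  {m:<14} {w:+.4f}")
        lines += [
            f"Training SN at threshold: {p.sn:.1f}% "
            f"(achieved SP {p.achieved_sp:.1f}%)",
            f"Full-data AUC: {p.auc:.3f}",
        ]
        if p.cv_sn_distribution.size:
            lines.append(
                f"Cross-validated SN: mean {p.cv_sn_distribution.mean():.1f}% "
                f"(sd {p.cv_sn_distribution.std():.1f}%, "
                f"{p.cv_sn_distribution.size} replicates)"
            )
        return "\n".join(lines)

    def plot_roc(self, ax=None):
        """Empirical ROC of the fitted score on the training cohort."""
        import matplotlib.pyplot as plt

        X, y = _panel_data(self.model.cohort, self.scoring_function.markers)
        s = X @ self.scoring_function.coefficients
        order = np.argsort(-s)
        tps = np.concatenate([[0], np.cumsum(y[order])]) / max(1, y.sum())
        fps = np.concatenate([[0], np.cumsum(~y[order])]) / max(1, (~y).sum())
        if ax is None:
            _, ax = plt.subplots()
        ax.plot(fps, tps, label="/".join(self.scoring_function.markers))
        ax.plot([0, 1], [0, 1], "--", color="grey", lw=0.8)
        ax.set_xlabel("1 - specificity")
        ax.set_ylabel("sensitivity")
        ax.legend()
        return ax

    def save_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.scoring_function.to_dict(), fh, indent=2)
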