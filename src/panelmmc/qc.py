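"""Duplicate-sample reproducibility QC.

Blinded duplicate pairs embedded in the cohort measure assay
reproducibility: per marker, the coefficient of variation (CV) of each
pair, summarised as a range and mean, and — when a fitted scoring function
is supplied — whether both members of each pair receive the same
case/control diagnosis.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import Cohort
from .mmc import ScoringFunction

__all__ = ["pair_cv", "DuplicateReport", "duplicate_report"]


def pair_cv(x1: float, x2: float) -> float:
    """CV (%) of a duplicate pair: 100 * s / m with m the pair mean and
    s = |x1 - x2| / sqrt(2) the sample SD of two observations."""
    if x1 <= 0 or x2 <= 0:
        raise ValueError("concentrations must be positive")
    m = (x1 + x2) / 2.0
    s = abs(x1 - x2) / math.sqrt(2.0)
    return 100.0 * s / m


@dataclass
class DuplicateReport:
    """Per-marker CV summary and per-pair diagnosis consistency."""

    marker_cv: pd.DataFrame  # marker, cv_min, cv_max, cv_mean
    pair_consistency: pd.DataFrame | None  # pair, call_original, call_duplicate, consistent
    n_pairs: int

    @property
    def all_consistent(self) -> bool:
        if self.pair_consistency is None or self.pair_consistency.empty:
            return True
        return bool(self.pair_consistency["consistent"].all())

    def to_csv(self, path) -> None:
        self.marker_cv.to_csv(path, index=False)

    def summary(self) -> str:
        lines = [f"Duplicate-sample QC: {self.n_pairs} pairs"]
        if not self.marker_cv.empty:
            lines.append(
                f"Per-marker mean CV: {self.marker_cv['cv_mean'].min():.1f}% "
                f"to {self.marker_cv['cv_mean'].max():.1f}%"
            )
            lines.append(
                f"Per-pair CV range: {self.marker_cv['cv_min'].min():.1f}% "
                f"to {self.marker_cv['cv_max'].max():.1f}%"
            )
        if self.pair_consistency is not None:
            n_bad = int((~self.pair_consistency["consistent"]).sum())
            lines.append(
                "Diagnoses consistent within every pair"
                if n_bad == 0
                else f"{n_bad} pair(s) with inconsistent diagnoses"
            )
        return "\n".join(lines)


def duplicate_report(
    cohort: Cohort, sf: ScoringFunction | None = None
) -> DuplicateReport:
    """CV range/mean per marker over duplicate pairs; optional diagnosis
    consistency under a scoring function."""
    pairs = [(cohort[s.duplicate_of], s) for s in cohort.duplicates()]
    if not pairs:
        warnings.warn("cohort contains no duplicate pairs", stacklevel=2)
        return DuplicateReport(
            marker_cv=pd.DataFrame(columns=["marker", "cv_min", "cv_max", "cv_mean"]),
            pair_consistency=None,
            n_pairs=0,
        )
    rows = []
    for m in cohort.marker_registry:
        cvs = np.array(
            [pair_cv(src.concentrations[m], dup.concentrations[m])
             for src, dup in pairs]
        )
        rows.append(
            {"marker": m, "cv_min": cvs.min(), "cv_max": cvs.max(),
             "cv_mean": cvs.mean()}
        )
    consistency = None
    if sf is not None:
        crows = []
        for src, dup in pairs:
            call_src = bool(sf.classify(sf.score_subject(src)))
            call_dup = bool(sf.classify(sf.score_subject(dup)))
            crows.append(
                {
                    "pair": src.subject_id,
                    "call_original": call_src,
                    "call_duplicate": call_dup,
                    "consistent": call_src == call_dup,
                }
            )
        consistency = pd.DataFrame(crows)
    return DuplicateReport(pd.DataFrame(rows), consistency, len(pairs))
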