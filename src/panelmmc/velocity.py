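"""Biomarker velocity: level trends versus time to diagnosis.

For each marker, case concentrations (raw or log) are regressed on days
to diagnosis by ordinary least squares; a slope significantly different
from zero indicates a prediagnostic trend.  Because the regressor is time
*until* diagnosis, markers that rise as diagnosis approaches have negative
slopes.  The screen is run on the complete case set and on the stratum of
samples drawn more than 12 months before diagnosis, where selectively
significant slopes point at early (potentially resectable-stage) signal.

No multiplicity correction is applied in this screen; each marker is
flagged at p <= 0.05 on its own, and reports state this.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import MTD_12_35, MTD_COMPLETE, Cohort, MtdStratum

__all__ = [
    "VelocityFit",
    "VelocityModel",
    "VelocityResults",
    "fit_velocity",
    "velocity_screen",
    "MTD_GT_12",
]

#: samples collected more than 12 months before diagnosis
MTD_GT_12 = MtdStratum("MTD >12", 365, float("inf"))

DEFAULT_VELOCITY_STRATA = (MTD_COMPLETE, MTD_GT_12)


@dataclass
class VelocityFit:
    """OLS fit of one marker's level against days to diagnosis."""

    marker: str
    stratum: str
    slope: float  # pg/ml per day (log-units per day under log_scale)
    intercept: float
    slope_p: float
    n: int
    log_scale: bool

    @property
    def significant(self) -> bool:
        return self.slope_p <= 0.05


def fit_velocity(
    cohort: Cohort,
    marker: str,
    stratum: MtdStratum = MTD_COMPLETE,
    log_scale: bool = False,
) -> VelocityFit:
    """Regress a marker's case levels on days to diagnosis within a stratum.

    Uses ordinary least squares; the slope p-value is two-sided from the t
    statistic with n-2 df.  A constant response yields slope 0, p = 1; a
    degenerate predictor (all draws at the same time) is an error.
    """
    cases = [
        s for s in cohort.cases() if stratum.contains(s.days_to_dx)
    ]
    if len(cases) < 3:
        raise ValueError(
            f"need >= 3 cases in stratum {stratum.label!r}, have {len(cases)}"
        )
    t = np.array([s.days_to_dx for s in cases], dtype=float)
    y = np.array([s.concentrations[marker] for s in cases], dtype=float)
    if log_scale:
        y = np.log(y)
    if np.ptp(t) == 0:
        raise ValueError("degenerate predictor: all samples drawn at the same time")
    if np.ptp(y) == 0:
        return VelocityFit(marker, stratum.label, 0.0, float(y[0]), 1.0,
                           len(cases), log_scale)
    res = stats.linregress(t, y)
    return VelocityFit(
        marker=marker,
        stratum=stratum.label,
        slope=float(res.slope),
        intercept=float(res.intercept),
        slope_p=float(res.pvalue),
        n=len(cases),
        log_scale=log_scale,
    )


class VelocityResults:
    """Screen results over markers x strata with a report frame."""

    def __init__(self, fits: list[VelocityFit]):
        self.fits = fits

    def to_frame(self) -> pd.DataFrame:
        f = pd.DataFrame([vars(x) for x in self.fits])
        f["significant"] = f["slope_p"] <= 0.05
        return f

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def significant(self, stratum: str | None = None) -> list[VelocityFit]:
        return [
            f
            for f in self.fits
            if f.significant and (stratum is None or f.stratum == stratum)
        ]

    def late_only_markers(self) -> list[str]:
        """Markers significant only in the >12-month stratum.

        These trend early in the prediagnostic window but the signal is
        diluted when near-diagnosis samples are pooled in.
        """
        sig_far = {f.marker for f in self.significant(MTD_GT_12.label)}
        sig_all = {f.marker for f in self.significant(MTD_COMPLETE.label)}
        return sorted(sig_far - sig_all)

    def summary(self) -> str:
        lines = [
            "Biomarker velocity screen (OLS on days to diagnosis; "
            "per-marker p <= 0.05, no multiplicity correction)",
        ]
        for f in sorted(self.significant(), key=lambda f: f.slope_p):
            lines.append(
                f"  {f.marker:<14} [{f.stratum:<9}] slope {f.slope:+.4g}/day "
                f"p={f.slope_p:.3g} n={f.n}"
            )
        late = self.late_only_markers()
        if late:
            lines.append(f"Significant only >12 months before diagnosis: "
                         f"{', '.join(late)}")
        return "\n".join(lines)


def velocity_screen(
    cohort: Cohort,
    markers: Sequence[str] | None = None,
    strata: Sequence[MtdStratum] = DEFAULT_VELOCITY_STRATA,
    log_scale: bool = False,
) -> VelocityResults:
    """Fit all markers in all requested strata and flag non-zero slopes."""
    markers = markers if markers is not None else list(cohort.marker_registry)
    fits = [
        fit_velocity(cohort, m, stratum, log_scale)
        for stratum in strata
        for m in markers
    ]
    return VelocityResults(fits)


class VelocityModel:
    """statsmodels-style wrapper: per-marker trend model on one cohort."""

    def __init__(self, cohort: Cohort, markers: Sequence[str] | None = None,
                 log_scale: bool = False):
        self.cohort = cohort
        self.markers = list(markers) if markers is not None else None
        self.log_scale = log_scale

    def fit(self, strata: Sequence[MtdStratum] = DEFAULT_VELOCITY_STRATA
            ) -> VelocityResults:
        return velocity_screen(self.cohort, self.markers, strata,
                               self.log_scale)
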