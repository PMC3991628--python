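"""Test-local helpers for constructing cohorts from raw matrices."""

from __future__ import annotations

from datetime import date

import numpy as np

from panelmmc.cohort import Cohort, Subject


def make_cohort(markers, case_rows, control_rows, days=None):
    """Hand-build a tiny cohort from per-subject concentration rows."""
    subjects = []
    for i, row in enumerate(case_rows):
        subjects.append(
            Subject(
                subject_id=f"C{i}",
                status="case",
                age_years=60,
                sex="female",
                race="white",
                draw_date=date(1999, 1, 10),
                days_to_dx=int(days[i]) if days is not None else 100 * i + 40,
                concentrations=dict(zip(markers, map(float, row))),
            )
        )
    for i, row in enumerate(control_rows):
        subjects.append(
            Subject(
                subject_id=f"K{i}",
                status="control",
                age_years=60,
                sex="female",
                race="white",
                draw_date=date(1999, 1, 10),
                concentrations=dict(zip(markers, map(float, row))),
            )
        )
    return Cohort(subjects, list(markers))


def cohort_from_log_matrix(markers, log_cases, log_controls, days=None):
    """Build a cohort whose log-concentrations equal the given matrices."""
    log_cases = np.atleast_2d(log_cases)
    log_controls = np.atleast_2d(log_controls)
    subjects = []
    for i, row in enumerate(np.exp(log_cases)):
        subjects.append(
            Subject(
                subject_id=f"C{i}",
                status="case",
                age_years=60,
                sex="male",
                race="white",
                draw_date=date(1998, 5, 1),
                days_to_dx=int(days[i]) if days is not None else 40 + 7 * i,
                concentrations=dict(zip(markers, map(float, row))),
            )
        )
    for i, row in enumerate(np.exp(log_controls)):
        subjects.append(
            Subject(
                subject_id=f"K{i}",
                status="control",
                age_years=60,
                sex="male",
                race="white",
                draw_date=date(1998, 5, 1),
                concentrations=dict(zip(markers, map(float, row))),
            )
        )
    return Cohort(subjects, list(markers))
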