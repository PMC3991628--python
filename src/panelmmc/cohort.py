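"""Core cohort data structures and plumbing.

A :class:`Cohort` is an ordered collection of serum samples
(:class:`Subject`) from a nested case-control study: each incident case is
matched to a fixed number of controls on age (+/- 5 years), race, sex and
calendar date of blood draw (2-month blocks).  Every sample carries a map of
biomarker concentrations in pg/ml.  Cases additionally carry the number of
days elapsed between blood draw and diagnosis, which downstream modules use
both for "months to diagnosis" (MTD) stratification and for biomarker
velocity regressions.

The module also implements the three structural operations the blinded
training/validation protocol relies on: splitting a cohort into halves by
match group, blinding (stripping case/control status and time-to-diagnosis
into a :class:`KeyTable`), and exact unblinding.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field, replace
from datetime import date
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Subject",
    "Cohort",
    "KeyTable",
    "MtdStratum",
    "MTD_1_12",
    "MTD_12_35",
    "MTD_COMPLETE",
    "CohortValidationError",
    "BlindedCohortError",
    "read_cohort",
    "write_cohort",
    "split_halves",
    "blind",
    "unblind",
    "months_to_diagnosis",
    "draw_date_block",
    "apply_concentration_floor",
]

#: average Gregorian month length in days, used to convert days to MTD
DAYS_PER_MONTH = 30.44

CASE = "case"
CONTROL = "control"
BLINDED = "blinded"

_STATUSES = (CASE, CONTROL, BLINDED)
_SURVIVAL_CATEGORIES = ("<6mo", "6-24mo", ">24mo", "NA")


class CohortValidationError(ValueError):
    """Raised when cohort data violate structural invariants.

    Carries ``rows``: the offending 1-based data-row numbers (when known).
    """

    def __init__(self, message: str, rows: Sequence[int] | None = None):
        self.rows = list(rows or [])
        if self.rows:
            message = f"{message} (rows: {self.rows})"
        super().__init__(message)


class BlindedCohortError(RuntimeError):
    """Raised when an operation requiring true labels meets a blinded cohort."""


@dataclass
class MtdStratum:
    """A half-open interval of days-to-diagnosis defining an MTD stratum."""

    label: str
    day_lo: float  # inclusive
    day_hi: float  # exclusive

    def contains(self, days: float | None) -> bool:
        if days is None:
            return False
        return self.day_lo <= days < self.day_hi


# Samples collected <12 months prior to diagnosis.
MTD_1_12 = MtdStratum("MTD 1-12", 0, 365)
# Samples collected 12-35 months prior to diagnosis.
MTD_12_35 = MtdStratum("MTD 12-35", 365, 1065)
MTD_COMPLETE = MtdStratum("complete", 0, math.inf)

DEFAULT_STRATA = (MTD_COMPLETE, MTD_1_12, MTD_12_35)


def months_to_diagnosis(days: float) -> int:
    """Convert days-to-diagnosis to whole months (floor of days/30.44)."""
    return int(math.floor(days / DAYS_PER_MONTH))


def draw_date_block(d: date) -> tuple[int, int]:
    """2-month calendar block of a draw date, anchored at January 1."""
    return (d.year, (d.month - 1) // 2)


@dataclass
class Subject:
    """One serum sample with matching covariates and marker concentrations."""

    subject_id: str
    status: str
    age_years: int
    sex: str
    race: str
    draw_date: date
    days_to_dx: int | None = None
    survival_cat: str = "NA"
    duplicate_of: str | None = None
    concentrations: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.status not in _STATUSES:
            raise CohortValidationError(
                f"unknown status {self.status!r} for subject {self.subject_id}"
            )
        if self.sex not in ("female", "male"):
            raise CohortValidationError(
                f"unknown sex {self.sex!r} for subject {self.subject_id}"
            )

    @property
    def is_case(self) -> bool:
        return self.status == CASE

    @property
    def is_blinded(self) -> bool:
        return self.status == BLINDED

    def mtd(self) -> int | None:
        """Months to diagnosis, or None for controls/blinded samples."""
        if self.days_to_dx is None:
            return None
        return months_to_diagnosis(self.days_to_dx)


@dataclass
class KeyTable:
    """The unblinding key: true status and time-to-diagnosis per subject.

    Only the adjudication step may consult it; handing it to a training
    routine before submission of blinded diagnoses is a protocol violation.
    """

    status: dict[str, str]
    days_to_dx: dict[str, int | None]
    survival_cat: dict[str, str]

    @property
    def n_cases(self) -> int:
        return sum(1 for s in self.status.values() if s == CASE)

    @property
    def n_controls(self) -> int:
        return sum(1 for s in self.status.values() if s == CONTROL)

    def write_csv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["subject_id", "status", "days_to_dx", "survival_cat"])
            for sid, st in self.status.items():
                d = self.days_to_dx.get(sid)
                w.writerow([sid, st, "" if d is None else d,
                            self.survival_cat.get(sid, "NA")])

    @classmethod
    def read_csv(cls, path) -> "KeyTable":
        status, days, surv = {}, {}, {}
        with open(path, newline="") as fh:
            for row in csv.DictReader(fh):
                sid = row["subject_id"]
                status[sid] = row["status"]
                days[sid] = int(row["days_to_dx"]) if row.get("days_to_dx") else None
                surv[sid] = row.get("survival_cat") or "NA"
        return cls(status, days, surv)


@dataclass
class Cohort:
    """Ordered collection of subjects plus marker registry and match groups.

    ``match_groups`` maps each case's subject_id to the ids of its matched
    controls.  Unmatched (retrospective case/control) cohorts carry an empty
    mapping; operations that need the matching structure (half-splitting)
    refuse to run on them.
    """

    subjects: list[Subject]
    marker_registry: list[str]
    match_groups: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self._index = {s.subject_id: s for s in self.subjects}
        if len(self._index) != len(self.subjects):
            raise CohortValidationError("duplicate subject_id in cohort")

    # -- basic access -------------------------------------------------------

    def __len__(self) -> int:
        return len(self.subjects)

    def __getitem__(self, subject_id: str) -> Subject:
        return self._index[subject_id]

    def __contains__(self, subject_id: str) -> bool:
        return self._index.__contains__(subject_id)

    @property
    def is_blinded(self) -> bool:
        return any(s.is_blinded for s in self.subjects)

    def primary_subjects(self) -> list[Subject]:
        """Subjects excluding embedded duplicate rows."""
        return [s for s in self.subjects if s.duplicate_of is None]

    def cases(self) -> list[Subject]:
        self.require_unblinded("cases()")
        return [s for s in self.primary_subjects() if s.status == CASE]

    def controls(self) -> list[Subject]:
        self.require_unblinded("controls()")
        return [s for s in self.primary_subjects() if s.status == CONTROL]

    def duplicates(self) -> list[Subject]:
        return [s for s in self.subjects if s.duplicate_of is not None]

    def require_unblinded(self, what: str = "this operation") -> None:
        if self.is_blinded:
            raise BlindedCohortError(
                f"{what} requires true case/control labels but the cohort is blinded"
            )

    # -- numeric views ------------------------------------------------------

    def marker_matrix(
        self,
        markers: Sequence[str] | None = None,
        log: bool = False,
        subjects: Sequence[Subject] | None = None,
    ) -> np.ndarray:
        """Concentration matrix (n_subjects x n_markers), optionally log-scale."""
        markers = list(markers) if markers is not None else self.marker_registry
        missing = [m for m in markers if m not in self.marker_registry]
        if missing:
            raise KeyError(f"markers not in registry: {missing}")
        if subjects is None:
            subjects = self.primary_subjects()
        X = np.array(
            [[s.concentrations[m] for m in markers] for s in subjects], dtype=float
        )
        return np.log(X) if log else X

    def values(self, marker: str, status: str | None = None) -> np.ndarray:
        """Concentration vector for one marker over primary subjects."""
        if status is not None and status in (CASE, CONTROL):
            self.require_unblinded(f"values(status={status!r})")
        subs = [
            s
            for s in self.primary_subjects()
            if status is None or s.status == status
        ]
        return np.array([s.concentrations[marker] for s in subs], dtype=float)

    def case_control_values(self, marker: str) -> tuple[np.ndarray, np.ndarray]:
        return self.values(marker, CASE), self.values(marker, CONTROL)

    # -- dataframe / CSV ----------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for s in self.subjects:
            row = {
                "subject_id": s.subject_id,
                "status": s.status,
                "age": s.age_years,
                "sex": s.sex,
                "race": s.race,
                "draw_date": s.draw_date.isoformat(),
                "days_to_dx": s.days_to_dx,
                "survival_cat": s.survival_cat,
                "duplicate_of": s.duplicate_of,
            }
            row.update({m: s.concentrations.get(m) for m in self.marker_registry})
            rows.append(row)
        return pd.DataFrame(rows)

    def validate(self) -> None:
        """Enforce all structural invariants; raise CohortValidationError."""
        bad_rows: list[int] = []
        msgs: list[str] = []
        for i, s in enumerate(self.subjects, start=1):
            if s.status == CASE and s.days_to_dx is None:
                bad_rows.append(i)
                msgs.append(f"case {s.subject_id} lacks days_to_dx")
            if s.status == CONTROL and s.days_to_dx is not None:
                bad_rows.append(i)
                msgs.append(f"control {s.subject_id} has days_to_dx")
            extra = set(s.concentrations) - set(self.marker_registry)
            if extra:
                bad_rows.append(i)
                msgs.append(f"{s.subject_id}: markers outside registry {sorted(extra)}")
            if s.duplicate_of is not None:
                if s.duplicate_of not in self._index:
                    bad_rows.append(i)
                    msgs.append(
                        f"{s.subject_id}: duplicate_of {s.duplicate_of} not in cohort"
                    )
                else:
                    src = self._index[s.duplicate_of]
                    same = (
                        s.age_years == src.age_years
                        and s.sex == src.sex
                        and s.race == src.race
                        and s.draw_date == src.draw_date
                    )
                    if not same:
                        bad_rows.append(i)
                        msgs.append(
                            f"{s.subject_id}: covariates differ from source "
                            f"{s.duplicate_of}"
                        )
        seen: set[str] = set()
        for case_id, ctrl_ids in self.match_groups.items():
            members = [case_id, *ctrl_ids]
            for sid in members:
                if sid not in self._index:
                    msgs.append(f"match group {case_id}: unknown member {sid}")
                elif sid in seen:
                    msgs.append(f"subject {sid} appears in two match groups")
                seen.add(sid)
        if msgs:
            raise CohortValidationError("; ".join(msgs), rows=sorted(set(bad_rows)))

    def validate_matching(self, age_tolerance: int = 5) -> None:
        """Check covariate agreement inside every match group."""
        msgs = []
        for case_id, ctrl_ids in self.match_groups.items():
            case = self._index[case_id]
            for cid in ctrl_ids:
                ctrl = self._index[cid]
                if abs(ctrl.age_years - case.age_years) > age_tolerance:
                    msgs.append(f"{cid}: age outside +/-{age_tolerance}y of {case_id}")
                if ctrl.sex != case.sex:
                    msgs.append(f"{cid}: sex mismatch with {case_id}")
                if ctrl.race != case.race:
                    msgs.append(f"{cid}: race mismatch with {case_id}")
                if draw_date_block(ctrl.draw_date) != draw_date_block(case.draw_date):
                    msgs.append(f"{cid}: draw-date block mismatch with {case_id}")
        if msgs:
            raise CohortValidationError("; ".join(msgs))

    def subset(self, subject_ids: Iterable[str]) -> "Cohort":
        ids = set(subject_ids)
        subs = [s for s in self.subjects if s.subject_id in ids]
        groups = {
            c: list(g) for c, g in self.match_groups.items() if c in ids
        }
        return Cohort(subs, list(self.marker_registry), groups)


# -- CSV round trip ---------------------------------------------------------

_META_COLUMNS = (
    "subject_id",
    "status",
    "age",
    "sex",
    "race",
    "draw_date",
    "days_to_dx",
    "survival_cat",
    "duplicate_of",
)


def write_cohort(cohort: Cohort, path) -> None:
    """Write a cohort to CSV (one row per sample, markers as pg/ml columns)."""
    frame = cohort.to_frame()
    # %.17g guarantees binary round-trip of the concentrations
    frame.to_csv(path, index=False, float_format="%.17g")


def write_match_groups(cohort: Cohort, path) -> None:
    """Persist the case -> controls mapping as a two-column CSV."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["case_id", "control_id"])
        for case_id, ctrl_ids in cohort.match_groups.items():
            for cid in ctrl_ids:
                w.writerow([case_id, cid])


def read_match_groups(path) -> dict[str, list[str]]:
    groups: dict[str, list[str]] = {}
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            groups.setdefault(row["case_id"], []).append(row["control_id"])
    return groups


def read_cohort(
    path,
    schema: Mapping[str, str] | None = None,
    match_groups: dict[str, list[str]] | None = None,
    floor: bool = True,
) -> Cohort:
    """Read a cohort CSV.

    Parameters
    ----------
    path : path-like
        CSV with the published schema (subject_id, status, age, sex, race,
        draw_date, days_to_dx, survival_cat, duplicate_of, then one column
        per marker).
    schema : mapping, optional
        Renames file columns to the canonical names, e.g.
        ``{"patient": "subject_id"}`` maps file column ``patient``.
    match_groups : dict, optional
        Pre-read case -> controls mapping (see :func:`read_match_groups`).
    floor : bool
        Apply the limit-of-detection floor so every concentration is
        strictly positive (required by the log-scale scoring function).
    """
    frame = pd.read_csv(
        path,
        dtype={"subject_id": str, "duplicate_of": str},
        float_precision="round_trip",
    )
    if schema:
        frame = frame.rename(columns=dict(schema))
    missing = [c for c in _META_COLUMNS if c not in frame.columns]
    if missing:
        raise CohortValidationError(f"missing required columns: {missing}")
    markers = [c for c in frame.columns if c not in _META_COLUMNS]
    if not markers:
        raise CohortValidationError("no marker columns found")

    subjects = []
    for i, row in enumerate(frame.itertuples(index=False, name=None), start=1):
        r = dict(zip(frame.columns, row))
        days = r["days_to_dx"]
        days = None if pd.isna(days) else int(days)
        dup = r["duplicate_of"]
        dup = None if (dup is None or (isinstance(dup, float) and math.isnan(dup))) else str(dup)
        conc = {}
        for m in markers:
            v = r[m]
            if pd.isna(v):
                raise CohortValidationError(
                    f"non-numeric concentration for marker {m}", rows=[i]
                )
            conc[m] = float(v)
        surv = r["survival_cat"]
        surv = "NA" if pd.isna(surv) else str(surv)
        subjects.append(
            Subject(
                subject_id=str(r["subject_id"]),
                status=str(r["status"]),
                age_years=int(r["age"]),
                sex=str(r["sex"]),
                race=str(r["race"]),
                draw_date=date.fromisoformat(str(r["draw_date"])),
                days_to_dx=days,
                survival_cat=surv,
                duplicate_of=dup,
                concentrations=conc,
            )
        )
    cohort = Cohort(subjects, markers, match_groups or {})
    cohort.validate()
    if floor:
        apply_concentration_floor(cohort)
    return cohort


def apply_concentration_floor(
    cohort: Cohort, lod: Mapping[str, float] | None = None
) -> dict[str, float]:
    """Replace concentrations <= 0 (or below a per-marker LOD) by LOD/2.

    The scoring function takes logarithms of concentrations, so zeros and
    negative read-outs must be floored.  Default LOD per marker is the
    smallest strictly positive observed value.  Returns the LOD map used.
    """
    lods: dict[str, float] = dict(lod or {})
    for m in cohort.marker_registry:
        if m not in lods:
            vals = np.array(
                [s.concentrations[m] for s in cohort.subjects], dtype=float
            )
            pos = vals[vals > 0]
            if pos.size == 0:
                raise CohortValidationError(
                    f"marker {m}: no positive concentration to derive an LOD"
                )
            lods[m] = float(pos.min())
    for s in cohort.subjects:
        for m in cohort.marker_registry:
            v = s.concentrations[m]
            if v <= 0 or v < lods[m]:
                s.concentrations[m] = lods[m] / 2.0
    return lods


# -- protocol structure operations -----------------------------------------


def split_halves(
    cohort: Cohort, seed: int, fraction: float = 0.5
) -> tuple[Cohort, Cohort]:
    """Partition a matched cohort into two halves by match group.

    Cases travel with their matched controls (and any embedded duplicate of
    a group member travels with its source), so neither half ever contains a
    control without its case.  ``fraction`` is the share of match groups in
    the first half; deterministic given ``seed``.
    """
    if not cohort.subjects:
        raise CohortValidationError("cannot split an empty cohort")
    if not cohort.match_groups:
        raise CohortValidationError("cohort has no match groups to split by")
    rng = np.random.default_rng(seed)
    case_ids = list(cohort.match_groups)
    order = rng.permutation(len(case_ids))
    n_a = int(round(len(case_ids) * fraction))
    ids_a: set[str] = set()
    ids_b: set[str] = set()
    for pos, gi in enumerate(order):
        case_id = case_ids[gi]
        target = ids_a if pos < n_a else ids_b
        target.add(case_id)
        target.update(cohort.match_groups[case_id])
    # duplicates travel with their source sample
    for s in cohort.duplicates():
        if s.duplicate_of in ids_a:
            ids_a.add(s.subject_id)
        elif s.duplicate_of in ids_b:
            ids_b.add(s.subject_id)
    return cohort.subset(ids_a), cohort.subset(ids_b)


def blind(cohort: Cohort) -> tuple[Cohort, KeyTable]:
    """Strip labels for blinded analysis; return the cohort and the key."""
    cohort.require_unblinded("blind()")
    key = KeyTable(
        status={s.subject_id: s.status for s in cohort.subjects},
        days_to_dx={s.subject_id: s.days_to_dx for s in cohort.subjects},
        survival_cat={s.subject_id: s.survival_cat for s in cohort.subjects},
    )
    blinded_subjects = [
        replace(
            s,
            status=BLINDED,
            days_to_dx=None,
            survival_cat="NA",
            concentrations=dict(s.concentrations),
        )
        for s in cohort.subjects
    ]
    blinded = Cohort(
        blinded_subjects, list(cohort.marker_registry), dict(cohort.match_groups)
    )
    return blinded, key


def unblind(cohort: Cohort, key: KeyTable) -> Cohort:
    """Restore true labels from the key (exact inverse of :func:`blind`)."""
    missing = [s.subject_id for s in cohort.subjects if s.subject_id not in key.status]
    if missing:
        raise CohortValidationError(f"key lacks subjects: {missing}")
    restored = [
        replace(
            s,
            status=key.status[s.subject_id],
            days_to_dx=key.days_to_dx.get(s.subject_id),
            survival_cat=key.survival_cat.get(s.subject_id, "NA"),
            concentrations=dict(s.concentrations),
        )
        for s in cohort.subjects
    ]
    return Cohort(restored, list(cohort.marker_registry), dict(cohort.match_groups))
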