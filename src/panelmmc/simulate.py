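"""Synthetic nested case-control cohort generator.

Emulates the structure of a prospective-trial serum collection: incident
cases with 4:1 matched controls (age +/- 5 y, race, sex, blood-draw date in
2-month calendar blocks), 67 log-normally distributed biomarkers, case
effect shifts for a small subset of markers (seven elevated, a
prolactin-like marker depressed), negative level-versus-time-to-diagnosis
slopes for selected markers, two markers correlated with a CA 19-9-like
anchor through a shared latent factor, and embedded duplicate samples with
assay-level multiplicative noise.

Marker model.  For subject *i* and marker *j*,

    log c_ij = mu_j + case_i * (delta_j + beta_j * (t_i - t_bar))
               + sigma_j * (rho_j * z_i + sqrt(1 - rho_j^2) * eps_ij)

with mu_j the control log-mean, delta_j the case log-shift, beta_j the
velocity slope (log-units per day of time-to-diagnosis t_i, centred at the
middle of the sampling window), rho_j the correlation to the anchor's
latent factor z_i, and eps_ij iid standard normal.  All ground-truth
parameters are recorded so downstream parameter-recovery tests can compare
estimates against them.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from datetime import date
from typing import Sequence

import numpy as np
import yaml

from .cohort import CASE, CONTROL, Cohort, Subject

__all__ = [
    "MarkerSpec",
    "GeneratorConfig",
    "GroundTruth",
    "generate_cohort",
    "inject_duplicates",
    "default_marker_specs",
    "null_marker_specs",
    "planted_pair_specs",
    "retrospective_config",
    "ANCHOR_MARKER",
]

ANCHOR_MARKER = "CA 19-9"

#: middle of the default [30, 1065) days-to-diagnosis sampling window;
#: velocity terms are centred here so they do not shift the case mean.
_DAYS_CENTER = 547.5


@dataclass
class MarkerSpec:
    """Generative parameters for one biomarker (log-normal model)."""

    name: str
    log_mean_control: float
    log_sd: float
    case_log_shift: float = 0.0
    velocity_slope: float = 0.0  # log-units per day of time-to-diagnosis
    corr_with_anchor: float = 0.0

    def __post_init__(self) -> None:
        if self.log_sd <= 0:
            raise ValueError(f"{self.name}: log_sd must be > 0")
        if not -1.0 <= self.corr_with_anchor <= 1.0:
            raise ValueError(
                f"{self.name}: corr_with_anchor {self.corr_with_anchor} "
                "outside [-1, 1] makes the correlation structure "
                "non-positive-definite"
            )


@dataclass
class GeneratorConfig:
    """Study conditions for one simulated cohort."""

    n_cases: int = 135
    control_ratio: int = 4
    marker_specs: list[MarkerSpec] = field(default_factory=lambda: default_marker_specs())
    n_duplicates_case: int = 7
    n_duplicates_control: int = 10
    assay_cv_range: tuple[float, float] = (1.0, 7.8)
    seed: int = 0
    days_to_dx_range: tuple[int, int] = (30, 1065)
    matched: bool = True
    n_controls: int | None = None  # only for unmatched designs

    def __post_init__(self) -> None:
        if self.n_cases < 1:
            raise ValueError("n_cases must be >= 1")
        if self.control_ratio < 1:
            raise ValueError("control_ratio must be >= 1")
        lo, hi = self.assay_cv_range
        if not (0 <= lo <= hi <= 100):
            raise ValueError("assay_cv_range must lie within [0, 100]")

    @property
    def marker_names(self) -> list[str]:
        return [m.name for m in self.marker_specs]

    # -- YAML round trip ---------------------------------------------------

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "GeneratorConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        specs = [MarkerSpec(**m) for m in d.pop("marker_specs", [])]
        for key in ("assay_cv_range", "days_to_dx_range"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        return cls(marker_specs=specs, **d)


@dataclass
class GroundTruth:
    """True generative parameters and latent means, for recovery tests."""

    shifts: dict[str, float]
    slopes: dict[str, float]
    corrs: dict[str, float]
    latent_log_means: "np.ndarray"  # (n_subjects, n_markers), pre-noise
    subject_ids: list[str]
    marker_names: list[str]

    def to_json(self, path) -> None:
        """Persist the scalar parameters (not the latent matrix) as JSON."""
        with open(path, "w") as fh:
            json.dump(
                {"shifts": self.shifts, "slopes": self.slopes, "corrs": self.corrs},
                fh,
                indent=2,
            )


# ---------------------------------------------------------------------------
# Marker presets
# ---------------------------------------------------------------------------

# The eight markers with case/control differences in the prediagnostic
# setting.  Control log-means/log-SDs approximate published serum levels
# (pg/ml); shifts are expressed as standardized effect d times log_sd, with
# d = sqrt(2) * Phi^-1(AUC) matching modest prediagnostic AUCs in the
# 0.52-0.66 range.  Seven markers rise in cases; prolactin falls.
_SIGNIFICANT = {
    # name: (log_mean_control, log_sd, d, velocity, corr_with_anchor)
    "CA 19-9":  (3.219, 1.77, 0.567, -0.0016, 0.0),   # anchor
    "CEA":      (9.038, 1.62, 0.089, -0.0016, 0.833),
    "CA 125":   (3.339, 1.31, 0.264, -0.0016, 0.732),
    "NSE":      (8.355, 0.86, 0.275, 0.0, 0.0),
    "IL-8":     (2.011, 0.62, 0.344, -0.0016, 0.0),
    "bHCG":     (-0.832, 0.42, 0.282, 0.0, 0.0),
    "CEACAM-1": (7.073, 0.47, 0.124, 0.0, 0.0),
    "PRL":      (10.756, 0.93, -0.250, -0.0016, 0.0),
}

# Remaining panel members (59 markers, null in the prediagnostic setting
# except AGRP which carries a velocity trend).
_NULL_MARKERS = [
    "ALCAM", "AFP", "CA 72-4", "CEACAM-6", "CYFRA 21-1", "HE4",
    "Apo CIII", "Apo E", "Complement C4", "CRP", "TTR",
    "FSH", "GH",
    "EGFR", "ErbB2", "FGF2", "HGF", "IGFBP-3", "VEGFR1", "VEGFR2", "VEGFR3",
    "TGFa",
    "Fas", "FasL", "Clusterin",
    "MIF", "MPO", "IL-1R1", "IL-4R", "IL-6R", "TNFRI", "TNFRII", "YKL40",
    "MIC-1", "MIP-4", "HIF-1a",
    "MMP-3", "MMP-9", "TIMP-1", "TIMP-2", "TIMP-3", "TIMP-4", "tPAI1", "NGAL",
    "ICAM-1", "VCAM-1", "NCAM", "Periostin",
    "Cathepsin D", "Insulin", "PTH",
    "AGRP", "BDNF", "CNTF",
    "OC", "OPG", "OSN", "OPN", "TRAP5",
]


def default_marker_specs() -> list[MarkerSpec]:
    """The 67-marker prediagnostic preset (8 shifted, 6 with velocity)."""
    specs = []
    for name, (mu, sd, d, vel, rho) in _SIGNIFICANT.items():
        specs.append(
            MarkerSpec(
                name=name,
                log_mean_control=mu,
                log_sd=sd,
                case_log_shift=d * sd,
                velocity_slope=vel * sd,
                corr_with_anchor=rho,
            )
        )
    for i, name in enumerate(_NULL_MARKERS):
        # spread baseline levels over a few orders of magnitude
        mu = 2.0 + (i % 8)
        vel = -0.0016 * 0.8 if name == "AGRP" else 0.0
        specs.append(
            MarkerSpec(
                name=name,
                log_mean_control=mu,
                log_sd=0.8 if name == "AGRP" else 0.7,
                velocity_slope=vel,
            )
        )
    assert len(specs) == 67
    return specs


def null_marker_specs(n_markers: int = 67) -> list[MarkerSpec]:
    """All-null preset for type-I calibration experiments."""
    return [
        MarkerSpec(name=f"MK{i + 1:02d}", log_mean_control=2.0 + (i % 8), log_sd=0.7)
        for i in range(n_markers)
    ]


def planted_pair_specs(
    n_markers: int = 67, shifts: tuple[float, float] = (1.2, 1.0)
) -> list[MarkerSpec]:
    """Two informative markers among nulls, for panel-recovery experiments."""
    specs = null_marker_specs(n_markers)
    specs[0] = dataclasses.replace(specs[0], case_log_shift=shifts[0] * specs[0].log_sd)
    specs[1] = dataclasses.replace(specs[1], case_log_shift=shifts[1] * specs[1].log_sd)
    return specs


def retrospective_config(seed: int = 0) -> GeneratorConfig:
    """Diagnosis-time case/control set for initial training (Step 1).

    343 cases / 227 controls, unmatched, with the much larger effect sizes
    seen at diagnosis (including bone-metabolic markers that later prove
    uninformative prediagnostically).
    """
    boost = {
        "CA 19-9": 1.8,
        "CEA": 0.5,
        "CA 125": 0.5,
        "NSE": 0.4,
        "IL-8": 0.6,
        "bHCG": 0.3,
        "CEACAM-1": 0.3,
        "PRL": -0.35,
        "OPG": 1.2,
        "OPN": 1.0,
        "TIMP-1": 0.5,
        "ICAM-1": 0.5,
    }
    specs = []
    for s in default_marker_specs():
        d = boost.get(s.name)
        if d is not None:
            s = dataclasses.replace(
                s, case_log_shift=d * s.log_sd, velocity_slope=0.0
            )
        else:
            s = dataclasses.replace(s, case_log_shift=0.0, velocity_slope=0.0)
        specs.append(s)
    return GeneratorConfig(
        n_cases=343,
        n_controls=227,
        matched=False,
        marker_specs=specs,
        n_duplicates_case=0,
        n_duplicates_control=0,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------

_RACES = ["white", "black", "hispanic", "asian", "pacific"]
_RACE_P = [0.89, 0.05, 0.02, 0.03, 0.01]
_SURVIVAL = ["<6mo", "6-24mo", ">24mo"]
_SURVIVAL_P = [0.48, 0.37, 0.15]


def _random_draw_date(rng: np.random.Generator) -> date:
    return date(
        int(rng.integers(1994, 2002)),
        int(rng.integers(1, 13)),
        int(rng.integers(1, 29)),
    )


def _date_in_same_block(d: date, rng: np.random.Generator) -> date:
    block_start = 2 * ((d.month - 1) // 2) + 1
    return date(d.year, int(block_start + rng.integers(0, 2)), int(rng.integers(1, 29)))


def generate_cohort(config: GeneratorConfig) -> tuple[Cohort, GroundTruth]:
    """Draw one synthetic cohort; deterministic given ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    specs = config.marker_specs
    names = [s.name for s in specs]
    if len(set(names)) != len(names):
        raise ValueError("duplicate marker names in marker_specs")

    n_cases = config.n_cases
    if config.matched:
        n_controls = n_cases * config.control_ratio
    else:
        if config.n_controls is None:
            raise ValueError("unmatched design requires n_controls")
        n_controls = config.n_controls

    # covariates: cases first, then controls
    subjects_meta = []
    match_groups: dict[str, list[str]] = {}
    lo_d, hi_d = config.days_to_dx_range
    for i in range(n_cases):
        cid = f"C{i + 1:04d}"
        age = int(rng.integers(55, 75))
        sex = "male" if rng.random() < 0.58 else "female"
        race = _RACES[int(rng.choice(len(_RACES), p=_RACE_P))]
        dd = _random_draw_date(rng)
        days = int(rng.integers(lo_d, hi_d))
        surv = _SURVIVAL[int(rng.choice(len(_SURVIVAL), p=_SURVIVAL_P))]
        subjects_meta.append((cid, CASE, age, sex, race, dd, days, surv))
        if config.matched:
            ctrl_ids = []
            for j in range(config.control_ratio):
                kid = f"K{i + 1:04d}-{j + 1}"
                k_age = int(np.clip(age + rng.integers(-5, 6), 55, 74))
                subjects_meta.append(
                    (kid, CONTROL, k_age, sex, race, _date_in_same_block(dd, rng),
                     None, "NA")
                )
                ctrl_ids.append(kid)
            match_groups[cid] = ctrl_ids
    if not config.matched:
        for j in range(n_controls):
            kid = f"K{j + 1:04d}"
            age = int(rng.integers(55, 75))
            sex = "male" if rng.random() < 0.58 else "female"
            race = _RACES[int(rng.choice(len(_RACES), p=_RACE_P))]
            subjects_meta.append(
                (kid, CONTROL, age, sex, race, _random_draw_date(rng), None, "NA")
            )

    n = len(subjects_meta)
    is_case = np.array([m[1] == CASE for m in subjects_meta])
    days_vec = np.array(
        [m[6] if m[6] is not None else 0 for m in subjects_meta], dtype=float
    )
    center = 0.5 * (lo_d + hi_d)

    # latent anchor factor shared across correlated markers
    z = rng.standard_normal(n)
    latent = np.empty((n, len(specs)))
    logc = np.empty((n, len(specs)))
    for j, s in enumerate(specs):
        mean = np.full(n, s.log_mean_control)
        mean += np.where(
            is_case,
            s.case_log_shift + s.velocity_slope * (days_vec - center),
            0.0,
        )
        latent[:, j] = mean
        rho = 1.0 if s.name == ANCHOR_MARKER else s.corr_with_anchor
        eps = rng.standard_normal(n)
        noise = rho * z + math.sqrt(max(0.0, 1.0 - rho**2)) * eps
        logc[:, j] = mean + s.log_sd * noise

    subjects = []
    for i, (sid, status, age, sex, race, dd, days, surv) in enumerate(subjects_meta):
        subjects.append(
            Subject(
                subject_id=sid,
                status=status,
                age_years=age,
                sex=sex,
                race=race,
                draw_date=dd,
                days_to_dx=days,
                survival_cat=surv,
                concentrations={
                    name: float(np.exp(logc[i, j])) for j, name in enumerate(names)
                },
            )
        )
    cohort = Cohort(subjects, names, match_groups)
    truth = GroundTruth(
        shifts={s.name: s.case_log_shift for s in specs},
        slopes={s.name: s.velocity_slope for s in specs},
        corrs={
            s.name: (1.0 if s.name == ANCHOR_MARKER else s.corr_with_anchor)
            for s in specs
        },
        latent_log_means=latent,
        subject_ids=[m[0] for m in subjects_meta],
        marker_names=names,
    )
    if config.n_duplicates_case or config.n_duplicates_control:
        cohort = inject_duplicates(cohort, config, rng=rng)
    return cohort, truth


def inject_duplicates(
    cohort: Cohort,
    config: GeneratorConfig,
    rng: np.random.Generator | None = None,
) -> Cohort:
    """Embed duplicate samples with assay-level multiplicative noise.

    Each duplicate is its source sample re-measured: concentrations are
    multiplied by exp(N(0, s_j)) with s_j calibrated so the expected
    pair CV of marker j equals a target drawn uniformly from
    ``assay_cv_range`` (pair CV ~ 100*|delta|/sqrt(2) for small noise, so
    E[CV] = 100*s/sqrt(pi) and s_j = sqrt(pi)*target/100).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    cases = [s for s in cohort.primary_subjects() if s.status == CASE]
    controls = [s for s in cohort.primary_subjects() if s.status == CONTROL]
    if len(cases) < config.n_duplicates_case:
        raise ValueError(
            f"need {config.n_duplicates_case} cases, have {len(cases)}"
        )
    if len(controls) < config.n_duplicates_control:
        raise ValueError(
            f"need {config.n_duplicates_control} controls, have {len(controls)}"
        )
    lo, hi = config.assay_cv_range
    target_cv = {
        m: float(rng.uniform(lo, hi)) for m in cohort.marker_registry
    }
    sources = [
        *(cases[i] for i in rng.choice(len(cases), config.n_duplicates_case,
                                       replace=False)),
        *(controls[i] for i in rng.choice(len(controls),
                                          config.n_duplicates_control,
                                          replace=False)),
    ]
    new_subjects = list(cohort.subjects)
    for src in sources:
        conc = {}
        for m, v in src.concentrations.items():
            s_j = math.sqrt(math.pi) * target_cv[m] / 100.0
            conc[m] = float(v * np.exp(rng.normal(0.0, s_j))) if s_j > 0 else v
        new_subjects.append(
            Subject(
                subject_id=src.subject_id + "-dup",
                status=src.status,
                age_years=src.age_years,
                sex=src.sex,
                race=src.race,
                draw_date=src.draw_date,
                days_to_dx=src.days_to_dx,
                survival_cat=src.survival_cat,
                duplicate_of=src.subject_id,
                concentrations=conc,
            )
        )
    return Cohort(new_subjects, list(cohort.marker_registry),
                  dict(cohort.match_groups))
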