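"""The five-step blinded training/validation protocol.

Step 1  trains candidate panels on an external retrospective case/control
set.  Step 2 applies the resulting scoring functions to the first, blinded
half of the prospective cohort and adjudicates the submitted diagnoses
against the key.  Step 3 unblinds that half and retrains over the full
marker registry.  Step 4 validates the retrained classifier on the second,
still-blinded half.  Step 5 unblinds everything and trains on the entire
prospective set.

The blinding firewall is structural: a blinded cohort carries no
case/control status and refuses any label-dependent operation; only
:func:`adjudicate`, which takes the key explicitly, can evaluate blinded
submissions.  Performance is reported per months-to-diagnosis (MTD)
stratum: complete / MTD 1-12 / MTD 12-35.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cohort import (
    CASE,
    CONTROL,
    DEFAULT_STRATA,
    Cohort,
    KeyTable,
    MtdStratum,
    blind,
    split_halves,
    unblind,
)
from .compare import hanley_mcneil_z, mcnemar_chi2, paired_calls
from .mmc import MetropolisConfig, ScoringFunction, search_panels

logger = logging.getLogger("panelmmc.workflow")

__all__ = [
    "ProtocolConfig",
    "StepResult",
    "StratumPerformance",
    "adjudicate",
    "run_protocol",
]


@dataclass
class ProtocolConfig:
    """Settings for a full protocol run."""

    panel_sizes: tuple[int, ...] = (2, 3)
    sp_target: float = 95.0
    anchor_marker: str = "CA 19-9"
    split_fraction: float = 0.5
    split_seed: int = 17
    metropolis: MetropolisConfig = field(default_factory=MetropolisConfig)
    strata: tuple[MtdStratum, ...] = DEFAULT_STRATA


@dataclass
class StratumPerformance:
    """SN/SP/AUC for one classifier in one MTD stratum."""

    classifier: str
    stratum: str
    sn: float
    sp: float
    auc: float | None
    n_cases: int
    n_controls: int


@dataclass
class StepResult:
    """Outcome of one protocol step."""

    step: int
    description: str
    trained_sfs: list[ScoringFunction] = field(default_factory=list)
    submitted_diagnoses: dict[str, dict[str, bool]] = field(default_factory=dict)
    performance: list[StratumPerformance] = field(default_factory=list)

    def report_frame(self) -> pd.DataFrame:
        """Table-shaped report: one row per classifier x stratum."""
        return pd.DataFrame(
            [
                {
                    "step": self.step,
                    "classifier": p.classifier,
                    "stratum": p.stratum,
                    "sn": p.sn,
                    "sp": p.sp,
                    "auc": p.auc,
                    "n_cases": p.n_cases,
                    "n_controls": p.n_controls,
                }
                for p in self.performance
            ]
        )

    def summary(self) -> str:
        lines = [f"Step {self.step}: {self.description}"]
        for p in self.performance:
            auc = f"{p.auc:.3f}" if p.auc is not None else "  -  "
            lines.append(
                f"  {p.classifier:<32} [{p.stratum:<9}] "
                f"SN {p.sn:5.1f}%  SP {p.sp:5.1f}%  AUC {auc}"
            )
        return "\n".join(lines)


def adjudicate(
    submission: Mapping[str, bool],
    key: KeyTable,
    strata: Sequence[MtdStratum] = DEFAULT_STRATA,
    scores: Mapping[str, float] | None = None,
    classifier: str = "classifier",
) -> list[StratumPerformance]:
    """Compare blinded diagnoses against the key, per MTD stratum.

    ``submission`` maps subject_id -> case call.  Sensitivity is computed
    on true cases within each stratum, specificity on all true controls,
    AUC from submitted scores when provided (cases in stratum vs all
    controls), otherwise omitted.  Duplicate QC rows (ids not in the key)
    raise.
    """
    unknown = [sid for sid in submission if sid not in key.status]
    if unknown:
        raise KeyError(f"submitted ids not in key: {unknown[:5]}")
    ctrl_ids = [sid for sid in submission if key.status[sid] == CONTROL]
    case_ids = [sid for sid in submission if key.status[sid] == CASE]
    out = []
    for stratum in strata:
        sc_ids = [
            sid for sid in case_ids if stratum.contains(key.days_to_dx.get(sid))
        ]
        sn = (
            100.0 * np.mean([submission[sid] for sid in sc_ids])
            if sc_ids
            else float("nan")
        )
        sp = (
            100.0 * np.mean([not submission[sid] for sid in ctrl_ids])
            if ctrl_ids
            else float("nan")
        )
        auc = None
        if scores is not None and sc_ids and ctrl_ids:
            from scipy.stats import rankdata

            s = np.array([scores[sid] for sid in sc_ids + ctrl_ids])
            r = rankdata(s)
            n1, n0 = len(sc_ids), len(ctrl_ids)
            auc = float(
                (r[:n1].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0)
            )
        out.append(
            StratumPerformance(
                classifier=classifier,
                stratum=stratum.label,
                sn=float(sn),
                sp=float(sp),
                auc=auc,
                n_cases=len(sc_ids),
                n_controls=len(ctrl_ids),
            )
        )
    return out


def _submit(
    sf: ScoringFunction, blinded: Cohort
) -> tuple[dict[str, bool], dict[str, float]]:
    """Score a blinded cohort and produce the diagnosis submission."""
    subs = blinded.primary_subjects()
    s = sf.score_cohort(blinded, subjects=subs)
    calls = sf.classify(s)
    ids = [x.subject_id for x in subs]
    return dict(zip(ids, map(bool, calls))), dict(zip(ids, map(float, s)))


def _anchor_sf(
    cohort: Cohort, anchor: str, sp_target: float
) -> ScoringFunction:
    """Single-marker reference classifier (unit weight, calibrated cut)."""
    from .mmc import calibrate_threshold

    scores = np.log(cohort.values(anchor, status=CONTROL))
    return ScoringFunction(
        markers=(anchor,),
        coefficients=np.array([1.0]),
        threshold=calibrate_threshold(scores, sp_target),
        sp_target=sp_target,
    )


def _train_step(
    cohort: Cohort, cfg: ProtocolConfig, step: int, description: str,
    seed_offset: int,
) -> StepResult:
    """Shared logic of the unblinded training steps (1, 3, 5)."""
    mcfg = MetropolisConfig(
        **{**vars(cfg.metropolis), "seed": cfg.metropolis.seed + seed_offset}
    )
    res = search_panels(
        cohort, sizes=cfg.panel_sizes, cfg=mcfg, sp_target=cfg.sp_target
    )
    sfs = [res.best(k).best_sf for k in cfg.panel_sizes]
    anchor_sf = _anchor_sf(cohort, cfg.anchor_marker, cfg.sp_target)
    step_res = StepResult(step=step, description=description,
                          trained_sfs=[anchor_sf, *sfs])
    # self-evaluation on the training set, per stratum
    _, key = blind(cohort)  # key of the training cohort itself
    for sf in step_res.trained_sfs:
        name = "/".join(sf.markers)
        subs = cohort.primary_subjects()
        scores = sf.score_cohort(cohort, subjects=subs)
        calls = dict(
            zip((s.subject_id for s in subs), map(bool, sf.classify(scores)))
        )
        sc = dict(zip((s.subject_id for s in subs), map(float, scores)))
        step_res.performance.extend(
            adjudicate(calls, key, cfg.strata, scores=sc, classifier=name)
        )
    return step_res


def _validate_step(
    blinded: Cohort,
    key: KeyTable,
    sfs: Sequence[ScoringFunction],
    cfg: ProtocolConfig,
    step: int,
    description: str,
) -> StepResult:
    """Shared logic of the blinded validation steps (2, 4)."""
    step_res = StepResult(step=step, description=description,
                          trained_sfs=list(sfs))
    # submissions are assembled before the key is consulted
    submissions = {}
    for sf in sfs:
        name = "/".join(sf.markers)
        calls, scores = _submit(sf, blinded)
        submissions[name] = (calls, scores)
        step_res.submitted_diagnoses[name] = calls
    for name, (calls, scores) in submissions.items():
        step_res.performance.extend(
            adjudicate(calls, key, cfg.strata, scores=scores, classifier=name)
        )
    return step_res


def run_protocol(
    train_cohort: Cohort,
    prospective_cohort: Cohort,
    cfg: ProtocolConfig | None = None,
) -> list[StepResult]:
    """Run the five-step blinded protocol end to end.

    ``train_cohort`` is the external retrospective case/control set used
    in Step 1; ``prospective_cohort`` is the matched nested case-control
    set that is split into halves, blinded, validated on, and finally
    fully unblinded for Step 5 training.
    """
    cfg = cfg or ProtocolConfig()
    cfg_hash = hashlib.sha256(
        json.dumps(
            {
                "sizes": cfg.panel_sizes,
                "sp": cfg.sp_target,
                "seed": cfg.metropolis.seed,
                "split_seed": cfg.split_seed,
            },
            sort_keys=True,
        ).encode()
    ).hexdigest()[:12]
    logger.info(
        "protocol start: config %s, train n=%d, prospective n=%d",
        cfg_hash, len(train_cohort), len(prospective_cohort),
    )

    half_a, half_b = split_halves(
        prospective_cohort, seed=cfg.split_seed, fraction=cfg.split_fraction
    )
    blinded_a, key_a = blind(half_a)
    blinded_b, key_b = blind(half_b)

    results = []

    step1 = _train_step(
        train_cohort, cfg, 1,
        "initial training on the retrospective case/control set",
        seed_offset=101,
    )
    results.append(step1)
    logger.info("step 1 done: %d panels trained", len(step1.trained_sfs))

    step2 = _validate_step(
        blinded_a, key_a, step1.trained_sfs, cfg, 2,
        "validation of the initial classifiers on the blinded first half",
    )
    results.append(step2)

    # Step 3: unblind half A only after its diagnoses were submitted
    unblinded_a = unblind(blinded_a, key_a)
    step3 = _train_step(
        unblinded_a, cfg, 3,
        "training on the unblinded first half (full marker registry)",
        seed_offset=103,
    )
    results.append(step3)

    step4 = _validate_step(
        blinded_b, key_b, step3.trained_sfs, cfg, 4,
        "validation of the retrained classifiers on the blinded second half",
    )
    results.append(step4)

    unblinded_b = unblind(blinded_b, key_b)
    full = Cohort(
        unblinded_a.subjects + unblinded_b.subjects,
        list(prospective_cohort.marker_registry),
        dict(prospective_cohort.match_groups),
    )
    step5 = _train_step(
        full, cfg, 5, "training on the entire unblinded prospective set",
        seed_offset=105,
    )
    # head-to-head statistics of the best panels vs the anchor alone
    step5.performance.extend(
        _head_to_head(full, step5.trained_sfs, cfg)
    )
    results.append(step5)
    logger.info("protocol complete: %d steps", len(results))
    return results


def _head_to_head(
    cohort: Cohort, sfs: Sequence[ScoringFunction], cfg: ProtocolConfig
) -> list[StratumPerformance]:
    """No extra rows; head-to-head stats are logged.  Kept separate so the
    report frame stays schema-stable."""
    anchor_sf = sfs[0]
    subs = cohort.primary_subjects()
    y = np.array([s.is_case for s in subs])
    s_anchor = anchor_sf.score_cohort(cohort, subjects=subs)
    calls_anchor = anchor_sf.classify(s_anchor)
    for sf in sfs[1:]:
        s_panel = sf.score_cohort(cohort, subjects=subs)
        calls_panel = sf.classify(s_panel)
        pc = paired_calls(calls_panel[y], calls_anchor[y])
        chi2, sig = mcnemar_chi2(pc.b, pc.c)
        cmp = hanley_mcneil_z(s_panel, s_anchor, y)
        logger.info(
            "%s vs %s: McNemar chi2=%.3f (sig=%s); HM z=%.2f (sig=%s)",
            "/".join(sf.markers), "/".join(anchor_sf.markers),
            chi2, sig, cmp.z, cmp.significant,
        )
    return []
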