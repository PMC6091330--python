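"""Synthetic myeloma cohorts with known ground truth.

Generates cohorts shaped like the packaged baseline table: an IMPeTUs
descriptor per patient (drawn from the observed token vocabulary), a
laboratory panel, the three stage labels — derived by running the actual
staging engines on the sampled labs/descriptor, so labels are internally
consistent by construction — and right-censored survival times from a
proportional-hazards model whose log-hazard is

    log h(t | patient) = log h0(t) + log HR_stage + [BM >= 4] log HR_bm
                         + [EMD+] log HR_em

with an exponential or Weibull baseline h0.  The default stage hazard
ratios (1, 4.818, 11.539 for DS Plus I/II/III) and flag effects (3.487 for
marrow Deauville >= 4, 1.463 for PET-positive extramedullary disease) are
presets on the scale reported for this disease setting, so demonstration
cohorts behave like a plausible clinic population; they are inputs, not
estimates.  Censoring is administrative: patients accrue uniformly over a
follow-up window and are censored at data cut-off.

Distribution defaults mimic the baseline cohort: marrow Deauville scores
concentrated at 2-3 with ~30% at >= 4, two-thirds of patients carrying
extramedullary disease tokens, a bimodal creatinine mix putting ~1/3 of
patients above 2 mg/dL, and a log-normal beta-2-microglobulin centred near
4 mg/L.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

from .impetus import (
    EmSite,
    ImpetusDescriptor,
    serialize_descriptor,
    em_positive,
)
from .staging import (
    LabPanel,
    Stage,
    StagingRules,
    DEFAULT_RULES,
    XrayBoneCategory,
    stage_dss,
    stage_dsplus,
    stage_riss,
)
from .cohort import Cohort, PatientRecord

__all__ = [
    "LabModel",
    "DescriptorModel",
    "SurvivalModel",
    "CohortConfig",
    "generate_descriptor",
    "generate_labs",
    "generate_cohort",
    "SyntheticCohort",
]


@dataclass(frozen=True)
class LabModel:
    """Sampling distributions for the laboratory panel (units as in LabPanel)."""

    hemoglobin_mean: float = 10.0
    hemoglobin_sd: float = 2.0
    calcium_mean: float = 9.8
    calcium_sd: float = 1.3
    albumin_mean: float = 3.7
    albumin_sd: float = 0.6
    beta2m_log_mean: float = 1.4  # log mg/L; exp(1.4) ~ 4.1
    beta2m_log_sd: float = 0.65
    # creatinine: mixture of a normal-renal and an impaired-renal component
    creatinine_high_prob: float = 0.33
    creatinine_normal_log_mean: float = -0.1
    creatinine_normal_log_sd: float = 0.25
    creatinine_high_log_mean: float = 1.1
    creatinine_high_log_sd: float = 0.35
    igg_log_mean: float = 1.4  # g/dL among IgG patients
    igg_log_sd: float = 0.5
    iga_log_mean: float = 1.0
    iga_log_sd: float = 0.5
    bence_jones_log_mean: float = 1.0  # g/24 h among light-chain patients
    bence_jones_log_sd: float = 0.7
    ldh_elevated_prob: float = 0.30
    high_risk_cytogenetics_prob: float = 0.25
    xray_probs: tuple = (0.10, 0.20, 0.70)  # normal/solitary, intermediate, advanced


@dataclass(frozen=True)
class DescriptorModel:
    """Categorical distributions over the IMPeTUs token vocabulary."""

    bm_score_probs: dict = field(
        default_factory=lambda: {1: 0.02, 2: 0.34, 3: 0.32, 4: 0.25, 5: 0.07}
    )
    bm_appendicular_prob: float = 0.25
    focal_grade_probs: dict = field(
        default_factory=lambda: {1: 0.06, 2: 0.21, 3: 0.18, 4: 0.55}
    )
    focal_absent_prob: float = 0.06  # no F token at all
    focal_site_probs: dict = field(
        default_factory=lambda: {"skull": 0.2, "spine": 0.85, "extraspine": 0.75}
    )
    focal_score_probs: dict = field(
        default_factory=lambda: {2: 0.04, 3: 0.14, 4: 0.47, 5: 0.35}
    )
    lytic_grade_probs: dict = field(
        default_factory=lambda: {1: 0.19, 2: 0.31, 3: 0.16, 4: 0.34}
    )
    fracture_prob: float = 0.05
    paramedullary_prob: float = 0.55
    em_prob: float = 0.65
    em_nodal_prob: float = 0.35  # each site drawn independently; at least one kept
    em_extranodal_prob: float = 0.80
    em_score_probs: dict = field(
        default_factory=lambda: {2: 0.06, 3: 0.27, 4: 0.40, 5: 0.27}
    )


@dataclass(frozen=True)
class SurvivalModel:
    """Proportional-hazards survival with administrative censoring."""

    baseline: str = "exponential"  # or "weibull"
    baseline_rate: float = 0.006  # events/month for the reference patient
    weibull_shape: float = 1.0
    stage_hr: dict = field(
        default_factory=lambda: {Stage.I: 1.0, Stage.II: 4.818, Stage.III: 11.539}
    )
    bm_high_hr: float = 3.487  # marrow Deauville >= 4
    em_hr: float = 1.463  # PET-positive extramedullary disease
    followup_window_months: float = 72.0  # uniform accrual before data cut-off
    censoring: bool = True


@dataclass(frozen=True)
class CohortConfig:
    n_patients: int = 100
    seed: int = 0
    labs: LabModel = field(default_factory=LabModel)
    descriptors: DescriptorModel = field(default_factory=DescriptorModel)
    survival: SurvivalModel = field(default_factory=SurvivalModel)
    rules: StagingRules = DEFAULT_RULES

    def __post_init__(self) -> None:
        if self.n_patients < 0:
            raise ValueError("n_patients must be nonnegative")
        for name, probs in (
            ("bm_score_probs", self.descriptors.bm_score_probs),
            ("focal_grade_probs", self.descriptors.focal_grade_probs),
            ("focal_score_probs", self.descriptors.focal_score_probs),
            ("lytic_grade_probs", self.descriptors.lytic_grade_probs),
            ("em_score_probs", self.descriptors.em_score_probs),
        ):
            total = sum(probs.values())
            if not np.isclose(total, 1.0):
                raise ValueError(f"{name} must sum to 1, got {total}")
            if any(p < 0 for p in probs.values()):
                raise ValueError(f"{name} has negative probability")
        if self.survival.baseline not in ("exponential", "weibull"):
            raise ValueError(f"unknown baseline {self.survival.baseline!r}")
        if self.survival.baseline_rate <= 0:
            raise ValueError("baseline_rate must be positive")


def _draw(rng: np.random.Generator, probs: dict):
    keys = list(probs)
    return keys[rng.choice(len(keys), p=np.array([probs[k] for k in keys]))]


def generate_descriptor(
    config: CohortConfig,
    rng: Optional[np.random.Generator] = None,
    stage_target: Optional[Stage] = None,
    max_attempts: int = 10_000,
) -> ImpetusDescriptor:
    """Sample one descriptor; optionally rejection-sample to a DS Plus stage.

    Stage-conditional generation re-draws until the DS Plus engine (with a
    creatinine of 1.0 mg/dL, which does not affect the main stage) returns
    ``stage_target``; unreachable targets error after ``max_attempts``.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    dm = config.descriptors
    for _ in range(max_attempts):
        bm = _draw(rng, dm.bm_score_probs)
        kwargs: dict = {
            "bm_score": bm,
            "bm_appendicular": bool(rng.random() < dm.bm_appendicular_prob),
            "fracture": bool(rng.random() < dm.fracture_prob),
            "paramedullary": bool(rng.random() < dm.paramedullary_prob),
        }
        if rng.random() >= dm.focal_absent_prob:
            grade = _draw(rng, dm.focal_grade_probs)
            kwargs["focal_grade"] = grade
            if grade > 1:
                sites = frozenset(
                    s for s, p in dm.focal_site_probs.items() if rng.random() < p
                )
                kwargs["focal_sites"] = sites
                kwargs["focal_score"] = _draw(rng, dm.focal_score_probs)
                kwargs["lytic_grade"] = _draw(rng, dm.lytic_grade_probs)
            else:
                kwargs["lytic_grade"] = 1
        if rng.random() < dm.em_prob:
            sites = []
            if rng.random() < dm.em_nodal_prob:
                sites.append(EmSite("nodal", _draw(rng, dm.em_score_probs)))
            if rng.random() < dm.em_extranodal_prob or not sites:
                sites.append(EmSite("extranodal", _draw(rng, dm.em_score_probs)))
            kwargs["em_present"] = True
            kwargs["em_sites"] = tuple(sites)
        d = ImpetusDescriptor(**kwargs)
        d = replace(d, raw=serialize_descriptor(d))
        if stage_target is None:
            return d
        assigned = stage_dsplus(d, LabPanel(creatinine=1.0), config.rules)
        if assigned.stage == stage_target:
            return d
    raise ValueError(
        f"could not reach DS Plus stage {stage_target} in {max_attempts} draws "
        "under the configured descriptor distribution"
    )


_MYELOMA_TYPES = (
    ("IgG κ", 0.33),
    ("IgG λ", 0.30),
    ("IgA κ", 0.04),
    ("IgA λ", 0.04),
    ("Light chain κ", 0.18),
    ("Light chain λ", 0.05),
    ("IgD λ", 0.03),
    ("Nonsecretory", 0.03),
)


def generate_labs(
    config: CohortConfig, myeloma_type: str, rng: np.random.Generator
) -> LabPanel:
    """Sample a laboratory panel consistent with the myeloma isotype."""
    lm = config.labs
    igg = iga = bj = None
    if myeloma_type.startswith("IgG") or myeloma_type.startswith("IgD"):
        igg = float(rng.lognormal(lm.igg_log_mean, lm.igg_log_sd))
    elif myeloma_type.startswith("IgA"):
        iga = float(rng.lognormal(lm.iga_log_mean, lm.iga_log_sd))
    elif myeloma_type.startswith("Light chain"):
        bj = float(rng.lognormal(lm.bence_jones_log_mean, lm.bence_jones_log_sd))
    if rng.random() < lm.creatinine_high_prob:
        creat = rng.lognormal(lm.creatinine_high_log_mean, lm.creatinine_high_log_sd)
    else:
        creat = rng.lognormal(
            lm.creatinine_normal_log_mean, lm.creatinine_normal_log_sd
        )
    xray = list(XrayBoneCategory)[
        rng.choice(3, p=np.asarray(lm.xray_probs) / np.sum(lm.xray_probs))
    ]
    return LabPanel(
        hemoglobin=float(max(rng.normal(lm.hemoglobin_mean, lm.hemoglobin_sd), 3.0)),
        serum_calcium=float(max(rng.normal(lm.calcium_mean, lm.calcium_sd), 5.0)),
        igg=igg,
        iga=iga,
        bence_jones=bj,
        creatinine=float(creat),
        albumin=float(max(rng.normal(lm.albumin_mean, lm.albumin_sd), 1.0)),
        beta2m=float(rng.lognormal(lm.beta2m_log_mean, lm.beta2m_log_sd)),
        ldh_elevated=bool(rng.random() < lm.ldh_elevated_prob),
        high_risk_cytogenetics=bool(rng.random() < lm.high_risk_cytogenetics_prob),
        xray_bone_category=xray,
    )


@dataclass(frozen=True)
class SyntheticCohort:
    """Generated cohort plus the latent truth behind each patient."""

    cohort: Cohort
    truth: pd.DataFrame  # per patient: hazard multiplier, uncensored time, ...

    def __len__(self) -> int:
        return len(self.cohort)


def _sample_survival(
    sm: SurvivalModel,
    hr: float,
    rng: np.random.Generator,
) -> tuple[float, float, bool]:
    """Return (observed time, latent event time, event flag)."""
    rate = sm.baseline_rate * hr
    u = rng.random()
    if sm.baseline == "exponential":
        t_event = -np.log(u) / rate
    else:  # Weibull with h(t) = rate * shape * t^(shape-1)
        t_event = (-np.log(u) / rate) ** (1.0 / sm.weibull_shape)
    if not sm.censoring:
        return float(t_event), float(t_event), True
    t_censor = rng.uniform(0.0, sm.followup_window_months)
    if t_event <= t_censor:
        return float(t_event), float(t_event), True
    return float(t_censor), float(t_event), False


def generate_cohort(config: CohortConfig) -> SyntheticCohort:
    """Generate a fully reproducible synthetic cohort.

    Labs and descriptors are sampled first, the three stage labels are then
    *derived* by the staging engines, and survival is drawn from the
    proportional-hazards model given the derived DS Plus stage and PET
    flags.  The same config (including seed) yields byte-identical output.
    """
    rng = np.random.default_rng(config.seed)
    sm = config.survival
    records = []
    truth_rows = []
    type_names = [t for t, _ in _MYELOMA_TYPES]
    type_probs = np.array([p for _, p in _MYELOMA_TYPES])
    type_probs = type_probs / type_probs.sum()
    for i in range(config.n_patients):
        sex = "M" if rng.random() < 0.6 else "F"
        age = float(np.round(np.clip(rng.normal(60.0, 10.0), 30, 85)))
        mtype = type_names[rng.choice(len(type_names), p=type_probs)]
        labs = generate_labs(config, mtype, rng)
        descriptor = generate_descriptor(config, rng)
        dss = stage_dss(labs, config.rules)
        riss = stage_riss(labs, config.rules)
        dsplus = stage_dsplus(descriptor, labs, config.rules)

        bm_high = descriptor.bm_score >= 4
        em_pos = em_positive(descriptor, min_score=config.rules.em_positive_min_score)
        hr = float(
            sm.stage_hr[dsplus.stage]
            * (sm.bm_high_hr if bm_high else 1.0)
            * (sm.em_hr if em_pos else 1.0)
        )
        t_obs, t_event, event = _sample_survival(sm, hr, rng)

        pid = str(i + 1)
        records.append(
            PatientRecord(
                patient_id=pid,
                sex=sex,
                age=age,
                myeloma_type=mtype,
                impetus=descriptor.raw,
                stage_dss=(dss.stage, dss.subgroup),
                stage_dsplus=(dsplus.stage, dsplus.subgroup),
                stage_riss=(riss.stage, riss.subgroup),
                treatment="None",
                os_months=round(t_obs, 3),
                os_event=event,
                labs={
                    "hemoglobin": round(labs.hemoglobin, 2),
                    "serum_calcium": round(labs.serum_calcium, 2),
                    **({"igg": round(labs.igg, 2)} if labs.igg is not None else {}),
                    **({"iga": round(labs.iga, 2)} if labs.iga is not None else {}),
                    **(
                        {"bence_jones": round(labs.bence_jones, 2)}
                        if labs.bence_jones is not None
                        else {}
                    ),
                    "creatinine": round(labs.creatinine, 2),
                    "albumin": round(labs.albumin, 2),
                    "beta2m": round(labs.beta2m, 2),
                    "ldh_elevated": labs.ldh_elevated,
                    "high_risk_cytogenetics": labs.high_risk_cytogenetics,
                    "xray_bone_category": labs.xray_bone_category.value,
                },
            )
        )
        truth_rows.append(
            {
                "patient_id": pid,
                "hazard_ratio": hr,
                "event_time_uncensored": t_event,
                "bm_high": bm_high,
                "em_positive": em_pos,
                "dsplus_stage": str(dsplus.stage),
            }
        )
    truth = pd.DataFrame(
        truth_rows,
        columns=[
            "patient_id",
            "hazard_ratio",
            "event_time_uncensored",
            "bm_high",
            "em_positive",
            "dsplus_stage",
        ],
    )
    return SyntheticCohort(cohort=Cohort(tuple(records)), truth=truth)
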