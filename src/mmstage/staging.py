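"""Stage-assignment engines for the three myeloma staging systems.

Implements, as deterministic rule engines over a laboratory panel and a
parsed IMPeTUs descriptor:

DSS (Durie–Salmon)
    Stage I requires *all* of: hemoglobin > 10 g/dL, calcium <= 10.5 mg/dL,
    normal bone survey or a solitary plasmacytoma, and low M-component
    production (IgG < 5 g/dL, IgA < 3 g/dL, Bence Jones < 4 g/24 h).
    Stage III requires *any* of: hemoglobin < 8.5 g/dL, calcium > 12 mg/dL,
    advanced lytic bone lesions, or high M-component production (IgG > 7,
    IgA > 5, Bence Jones > 12).  Stage II is the complement.  Subgroup A/B
    splits on serum creatinine (< 2.0 vs >= 2.0 mg/dL).

RISS (Revised International Staging System)
    Stage I: albumin >= 3.5 g/dL, beta-2-microglobulin < 3.5 mg/L, normal
    LDH, no high-risk cytogenetics (t(4;14), t(14;16), del17p).
    Stage III: beta-2-microglobulin > 5.5 mg/L and (elevated LDH or
    high-risk cytogenetics).  Stage II is the complement.  RISS has no
    renal subgroup.

DS Plus (Durie–Salmon Plus, imaging based)
    Stage is the worse of a focal-lesion-burden component (count grade
    1-2 -> I, 3 -> II, 4 -> III, demoted one level when the focal Deauville
    score is below the bone-positivity cutoff) and a diffuse marrow
    component (BM Deauville <= 2 -> I, 3 -> II, >= 4 -> III).  Subgroup B
    when creatinine > 2.0 mg/dL and/or PET-positive extramedullary disease.

All thresholds and the DS Plus grade-to-stage tables are configuration
(:class:`StagingRules`, YAML-serializable), shipped with the defaults above.
Every engine records the clauses it fired as a human-readable rule trace on
the returned :class:`StageAssignment`.

Note on the DSS calcium trigger: the stage-III threshold is implemented as
calcium *greater than* 12 mg/dL (hypercalcemia), the direction of the
original Durie–Salmon criterion; the threshold and direction are exposed in
the rules config.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Optional, Sequence

import yaml

from .impetus import ImpetusDescriptor, em_positive, bone_positive

__all__ = [
    "Stage",
    "Subgroup",
    "System",
    "StageAssignment",
    "LabPanel",
    "XrayBoneCategory",
    "StagingRules",
    "StagingError",
    "stage_dss",
    "stage_riss",
    "stage_dsplus",
    "agreement_report",
    "AgreementReport",
]


class Stage(enum.IntEnum):
    """Main numerical stage; ordering I < II < III is meaningful."""

    I = 1
    II = 2
    III = 3

    def __str__(self) -> str:  # roman numeral, as printed in cohort files
        return self.name


class Subgroup(str, enum.Enum):
    A = "A"
    B = "B"
    NONE = ""

    def __str__(self) -> str:
        return self.value


class System(str, enum.Enum):
    DSS = "DSS"
    RISS = "RISS"
    DSPLUS = "DSPLUS"


class XrayBoneCategory(str, enum.Enum):
    """Skeletal-survey reading feeding the DSS bone clauses."""

    NORMAL_OR_SOLITARY = "normal_or_solitary"
    INTERMEDIATE = "intermediate"
    ADVANCED_LYTIC = "advanced_lytic"


class StagingError(ValueError):
    """A required staging input is missing or inconsistent."""


@dataclass(frozen=True)
class StageAssignment:
    """(system, stage, subgroup) label with the rule trace that produced it."""

    system: System
    stage: Stage
    subgroup: Subgroup
    trace: tuple = field(default=(), compare=False)

    def __post_init__(self) -> None:
        if (self.subgroup is Subgroup.NONE) != (self.system is System.RISS):
            raise ValueError("subgroup is NONE exactly for RISS assignments")

    @property
    def label(self) -> str:
        """Printed form, e.g. ``'IIIB'`` or ``'II'`` (RISS)."""
        return f"{self.stage}{self.subgroup}"


@dataclass(frozen=True)
class LabPanel:
    """Laboratory and cytogenetic inputs to the DSS and RISS engines.

    Concentrations use the conventional clinical units noted per field.
    M-component fields are set only for the relevant myeloma isotype;
    clauses referencing an absent isotype simply do not trigger.
    """

    hemoglobin: Optional[float] = None  # g/dL
    serum_calcium: Optional[float] = None  # mg/dL
    igg: Optional[float] = None  # g/dL
    iga: Optional[float] = None  # g/dL
    bence_jones: Optional[float] = None  # g/24 h
    creatinine: Optional[float] = None  # mg/dL
    albumin: Optional[float] = None  # g/dL
    beta2m: Optional[float] = None  # mg/L
    ldh: Optional[float] = None  # U/L, informational
    ldh_elevated: Optional[bool] = None  # vs local upper limit
    high_risk_cytogenetics: Optional[bool] = None  # t(4;14), t(14;16), del17p
    xray_bone_category: Optional[XrayBoneCategory] = None

    def __post_init__(self) -> None:
        for name in (
            "hemoglobin",
            "serum_calcium",
            "igg",
            "iga",
            "bence_jones",
            "creatinine",
            "albumin",
            "beta2m",
            "ldh",
        ):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"{name} must be nonnegative, got {v}")
        if self.xray_bone_category is not None and not isinstance(
            self.xray_bone_category, XrayBoneCategory
        ):
            object.__setattr__(
                self,
                "xray_bone_category",
                XrayBoneCategory(self.xray_bone_category),
            )

    def require(self, *names: str) -> None:
        missing = [n for n in names if getattr(self, n) is None]
        if missing:
            raise StagingError(f"missing required lab field(s): {', '.join(missing)}")


@dataclass(frozen=True)
class StagingRules:
    """All staging thresholds and DS Plus mapping tables, as configuration."""

    # DSS stage I (all must hold) / stage III (any triggers)
    dss_stage1_hb_gt: float = 10.0
    dss_stage1_ca_le: float = 10.5
    dss_stage1_igg_lt: float = 5.0
    dss_stage1_iga_lt: float = 3.0
    dss_stage1_bj_lt: float = 4.0
    dss_stage3_hb_lt: float = 8.5
    dss_stage3_ca_gt: float = 12.0  # hypercalcemia trigger, see module docstring
    dss_stage3_igg_gt: float = 7.0
    dss_stage3_iga_gt: float = 5.0
    dss_stage3_bj_gt: float = 12.0
    dss_subgroup_b_creatinine_ge: float = 2.0
    # RISS
    riss_stage1_albumin_ge: float = 3.5
    riss_stage1_beta2m_lt: float = 3.5
    riss_stage3_beta2m_gt: float = 5.5
    # DS Plus
    dsplus_focal_grade_stage: dict = field(
        default_factory=lambda: {1: Stage.I, 2: Stage.I, 3: Stage.II, 4: Stage.III}
    )
    dsplus_diffuse_score_stage: dict = field(
        default_factory=lambda: {
            1: Stage.I,
            2: Stage.I,
            3: Stage.II,
            4: Stage.III,
            5: Stage.III,
        }
    )
    dsplus_demote_if_not_bone_positive: bool = True
    dsplus_subgroup_b_creatinine_gt: float = 2.0
    # shared PET positivity cutoffs
    bone_positive_min_score: int = 4
    em_positive_min_score: int = 4

    @classmethod
    def from_yaml(cls, path) -> "StagingRules":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        for key in ("dsplus_focal_grade_stage", "dsplus_diffuse_score_stage"):
            if key in data:
                data[key] = {int(k): Stage[v] for k, v in data[key].items()}
        return cls(**data)

    def to_yaml(self, path) -> None:
        data = {}
        for name in self.__dataclass_fields__:
            v = getattr(self, name)
            if isinstance(v, dict):
                v = {k: s.name for k, s in v.items()}
            data[name] = v
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)


DEFAULT_RULES = StagingRules()


def stage_dss(labs: LabPanel, rules: StagingRules = DEFAULT_RULES) -> StageAssignment:
    """Assign the Durie–Salmon stage and renal subgroup from a lab panel."""
    labs.require("hemoglobin", "serum_calcium", "creatinine", "xray_bone_category")
    trace: list[str] = []

    def low_m_component() -> bool:
        checks = []
        if labs.igg is not None:
            checks.append(labs.igg < rules.dss_stage1_igg_lt)
        if labs.iga is not None:
            checks.append(labs.iga < rules.dss_stage1_iga_lt)
        if labs.bence_jones is not None:
            checks.append(labs.bence_jones < rules.dss_stage1_bj_lt)
        return all(checks)  # absent isotypes do not block stage I

    stage1 = (
        labs.hemoglobin > rules.dss_stage1_hb_gt
        and labs.serum_calcium <= rules.dss_stage1_ca_le
        and labs.xray_bone_category is XrayBoneCategory.NORMAL_OR_SOLITARY
        and low_m_component()
    )
    triggers = []
    if labs.hemoglobin < rules.dss_stage3_hb_lt:
        triggers.append(f"hemoglobin {labs.hemoglobin} < {rules.dss_stage3_hb_lt}")
    if labs.serum_calcium > rules.dss_stage3_ca_gt:
        triggers.append(f"calcium {labs.serum_calcium} > {rules.dss_stage3_ca_gt}")
    if labs.xray_bone_category is XrayBoneCategory.ADVANCED_LYTIC:
        triggers.append("advanced lytic bone lesions")
    if labs.igg is not None and labs.igg > rules.dss_stage3_igg_gt:
        triggers.append(f"IgG {labs.igg} > {rules.dss_stage3_igg_gt}")
    if labs.iga is not None and labs.iga > rules.dss_stage3_iga_gt:
        triggers.append(f"IgA {labs.iga} > {rules.dss_stage3_iga_gt}")
    if labs.bence_jones is not None and labs.bence_jones > rules.dss_stage3_bj_gt:
        triggers.append(f"Bence Jones {labs.bence_jones} > {rules.dss_stage3_bj_gt}")

    if triggers:
        stage = Stage.III
        trace.append("DSS III: " + "; ".join(triggers))
    elif stage1:
        stage = Stage.I
        trace.append("DSS I: all stage-I clauses hold")
    else:
        stage = Stage.II
        trace.append("DSS II: neither stage I nor stage III")
    if labs.creatinine < rules.dss_subgroup_b_creatinine_ge:
        sub = Subgroup.A
        trace.append(
            f"subgroup A: creatinine {labs.creatinine} < "
            f"{rules.dss_subgroup_b_creatinine_ge}"
        )
    else:
        sub = Subgroup.B
        trace.append(
            f"subgroup B: creatinine {labs.creatinine} >= "
            f"{rules.dss_subgroup_b_creatinine_ge}"
        )
    return StageAssignment(System.DSS, stage, sub, tuple(trace))


def stage_riss(labs: LabPanel, rules: StagingRules = DEFAULT_RULES) -> StageAssignment:
    """Assign the Revised ISS stage from albumin, beta-2-M, LDH and cytogenetics."""
    labs.require("albumin", "beta2m", "ldh_elevated", "high_risk_cytogenetics")
    trace: list[str] = []
    if labs.beta2m > rules.riss_stage3_beta2m_gt and (
        labs.ldh_elevated or labs.high_risk_cytogenetics
    ):
        stage = Stage.III
        trace.append(
            f"RISS III: beta2m {labs.beta2m} > {rules.riss_stage3_beta2m_gt} and "
            + ("elevated LDH" if labs.ldh_elevated else "high-risk cytogenetics")
        )
    elif (
        labs.albumin >= rules.riss_stage1_albumin_ge
        and labs.beta2m < rules.riss_stage1_beta2m_lt
        and not labs.ldh_elevated
        and not labs.high_risk_cytogenetics
    ):
        stage = Stage.I
        trace.append("RISS I: ISS I, normal LDH, standard-risk cytogenetics")
    else:
        stage = Stage.II
        trace.append("RISS II: neither stage I nor stage III")
    return StageAssignment(System.RISS, stage, Subgroup.NONE, tuple(trace))


def stage_dsplus(
    d: ImpetusDescriptor,
    labs: LabPanel,
    rules: StagingRules = DEFAULT_RULES,
) -> StageAssignment:
    """Assign the Durie–Salmon Plus stage from PET findings and creatinine.

    The stage is ``max(focal component, diffuse component)``; the grade/score
    to stage tables and the demotion rule live in ``rules``.
    """
    labs.require("creatinine")
    if d.focal_grade is None and d.bm_score is None:  # pragma: no cover - grammar
        raise StagingError("descriptor carries neither focal nor marrow information")
    trace: list[str] = []

    components: list[Stage] = []
    if d.focal_grade is not None:
        focal = rules.dsplus_focal_grade_stage[d.focal_grade]
        note = f"focal grade {d.focal_grade} -> {focal}"
        if (
            rules.dsplus_demote_if_not_bone_positive
            and focal > Stage.I
            and not bone_positive(d, min_score=rules.bone_positive_min_score)
        ):
            focal = Stage(focal - 1)
            note += f", demoted to {focal} (focal score not PET-positive)"
        components.append(focal)
        trace.append(note)
    diffuse = rules.dsplus_diffuse_score_stage[d.bm_score]
    components.append(diffuse)
    trace.append(f"diffuse BM score {d.bm_score} -> {diffuse}")

    stage = max(components)
    trace.append(f"DS Plus stage = max(components) = {stage}")

    em = em_positive(d, min_score=rules.em_positive_min_score)
    if labs.creatinine > rules.dsplus_subgroup_b_creatinine_gt or em:
        sub = Subgroup.B
        reasons = []
        if labs.creatinine > rules.dsplus_subgroup_b_creatinine_gt:
            reasons.append(
                f"creatinine {labs.creatinine} > {rules.dsplus_subgroup_b_creatinine_gt}"
            )
        if em:
            reasons.append("PET-positive extramedullary disease")
        trace.append("subgroup B: " + " and ".join(reasons))
    else:
        sub = Subgroup.A
        trace.append("subgroup A: creatinine normal and no PET-positive EMD")
    return StageAssignment(System.DSPLUS, stage, sub, tuple(trace))


@dataclass(frozen=True)
class AgreementReport:
    """Per-patient comparison of engine-derived vs reference stage labels."""

    rows: tuple  # (index, derived StageAssignment, reference StageAssignment, match)
    n: int
    n_match: int

    @property
    def agreement(self) -> float:
        return self.n_match / self.n if self.n else float("nan")

    @property
    def mismatches(self) -> tuple:
        return tuple(r for r in self.rows if not r[3])

    def to_text(self) -> str:
        lines = [f"agreement {self.n_match}/{self.n} = {self.agreement:.4f}"]
        for idx, derived, ref, match in self.rows:
            if not match:
                lines.append(f"  #{idx}: derived {derived.label} != reference {ref.label}")
                for step in derived.trace:
                    lines.append(f"      {step}")
        return "\n".join(lines)


def agreement_report(
    derived: Sequence[StageAssignment],
    reference: Sequence[StageAssignment],
    ids: Optional[Sequence] = None,
    compare_subgroup: bool = False,
) -> AgreementReport:
    """Tabulate where engine output matches reference labels.

    By default only the main numerical stage is compared (subgroups are
    combined within the main grouping for statistics); set
    ``compare_subgroup`` to require the A/B letter to match too.
    Inputs are never mutated.
    """
    if len(derived) != len(reference):
        raise ValueError(
            f"length mismatch: {len(derived)} derived vs {len(reference)} reference"
        )
    if ids is None:
        ids = list(range(1, len(derived) + 1))
    rows = []
    n_match = 0
    for idx, dvd, ref in zip(ids, derived, reference):
        match = dvd.stage == ref.stage and (
            not compare_subgroup or dvd.subgroup == ref.subgroup
        )
        n_match += match
        rows.append((idx, dvd, ref, match))
    return AgreementReport(tuple(rows), len(rows), n_match)
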