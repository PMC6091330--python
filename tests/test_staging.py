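"""Staging engines: clause logic, complements, monotonicity, fixture behaviour."""

import itertools

import pytest

from mmstage.cohort import parse_stage_label
from mmstage.impetus import parse_descriptor
from mmstage.staging import (
    DEFAULT_RULES,
    LabPanel,
    Stage,
    StagingError,
    StagingRules,
    Subgroup,
    XrayBoneCategory,
    agreement_report,
    stage_dsplus,
    stage_dss,
    stage_riss,
)


def labs_stage1_dss(**overrides):
    base = dict(
        hemoglobin=11.0,
        serum_calcium=10.0,
        igg=4.0,
        creatinine=1.0,
        xray_bone_category=XrayBoneCategory.NORMAL_OR_SOLITARY,
    )
    base.update(overrides)
    return LabPanel(**base)


class TestDss:
    def test_all_stage1_clauses(self):
        a = stage_dss(labs_stage1_dss())
        assert (a.stage, a.subgroup) == (Stage.I, Subgroup.A)

    def test_any_stage3_trigger_and_renal_subgroup(self):
        a = stage_dss(labs_stage1_dss(hemoglobin=8.0, creatinine=2.5))
        assert (a.stage, a.subgroup) == (Stage.III, Subgroup.B)

    def test_neither_gives_stage2(self):
        a = stage_dss(
            labs_stage1_dss(
                hemoglobin=9.5, igg=6.0, xray_bone_category=XrayBoneCategory.INTERMEDIATE
            )
        )
        assert (a.stage, a.subgroup) == (Stage.II, Subgroup.A)

    def test_hypercalcemia_triggers_stage3(self):
        # calcium > 12 mg/dL is the stage-III direction; 11 mg/dL must not fire
        assert stage_dss(labs_stage1_dss(serum_calcium=12.5)).stage == Stage.III
        assert stage_dss(labs_stage1_dss(serum_calcium=11.0)).stage == Stage.II

    def test_absent_isotype_clauses_do_not_trigger(self):
        # nonsecretory patient: no M-component fields at all
        a = stage_dss(labs_stage1_dss(igg=None))
        assert a.stage == Stage.I
        assert stage_dss(labs_stage1_dss(igg=None, bence_jones=13.0)).stage == Stage.III

    def test_missing_field_raises(self):
        with pytest.raises(StagingError, match="hemoglobin"):
            stage_dss(LabPanel(serum_calcium=10.0, creatinine=1.0))

    def test_stage2_is_exact_complement_by_enumeration(self):
        """Brute-force grid: stage II fires exactly when neither I nor III does."""
        grid = itertools.product(
            [7.5, 9.0, 10.5, 11.5],  # hemoglobin
            [9.0, 10.5, 11.0, 12.5],  # calcium
            [4.0, 6.0, 8.0],  # IgG
            list(XrayBoneCategory),
        )
        for hb, ca, igg, xray in grid:
            labs = LabPanel(
                hemoglobin=hb,
                serum_calcium=ca,
                igg=igg,
                creatinine=1.5,
                xray_bone_category=xray,
            )
            r = DEFAULT_RULES
            is_one = (
                hb > r.dss_stage1_hb_gt
                and ca <= r.dss_stage1_ca_le
                and xray is XrayBoneCategory.NORMAL_OR_SOLITARY
                and igg < r.dss_stage1_igg_lt
            )
            is_three = (
                hb < r.dss_stage3_hb_lt
                or ca > r.dss_stage3_ca_gt
                or xray is XrayBoneCategory.ADVANCED_LYTIC
                or igg > r.dss_stage3_igg_gt
            )
            expected = Stage.III if is_three else Stage.I if is_one else Stage.II
            assert stage_dss(labs).stage == expected, (hb, ca, igg, xray)

    def test_stage3_triggers_monotone(self):
        """Worsening any single stage-III input never lowers the DSS stage."""
        base = labs_stage1_dss(hemoglobin=9.5)
        assert stage_dss(base).stage == Stage.II
        for worse in (
            labs_stage1_dss(hemoglobin=8.0),
            labs_stage1_dss(hemoglobin=9.5, serum_calcium=13.0),
            labs_stage1_dss(
                hemoglobin=9.5, xray_bone_category=XrayBoneCategory.ADVANCED_LYTIC
            ),
            labs_stage1_dss(hemoglobin=9.5, igg=8.0),
        ):
            assert stage_dss(worse).stage >= stage_dss(base).stage


def labs_riss(**overrides):
    base = dict(albumin=4.0, beta2m=2.0, ldh_elevated=False, high_risk_cytogenetics=False)
    base.update(overrides)
    return LabPanel(**base)


class TestRiss:
    def test_worked_stage3_example(self):
        # beta-2-M of 6.08 mg/L with elevated LDH classifies as RISS III
        a = stage_riss(labs_riss(albumin=3.0, beta2m=6.08, ldh_elevated=True))
        assert a.stage == Stage.III
        assert a.subgroup is Subgroup.NONE

    def test_stage1_requires_all_clauses(self):
        assert stage_riss(labs_riss()).stage == Stage.I
        assert stage_riss(labs_riss(albumin=3.0)).stage == Stage.II
        assert stage_riss(labs_riss(ldh_elevated=True)).stage == Stage.II
        assert stage_riss(labs_riss(high_risk_cytogenetics=True)).stage == Stage.II

    def test_stage3_needs_ldh_or_cytogenetics_disjunct(self):
        assert stage_riss(labs_riss(beta2m=6.0)).stage == Stage.II
        assert stage_riss(labs_riss(beta2m=6.0, high_risk_cytogenetics=True)).stage == Stage.III

    def test_missing_field_raises(self):
        with pytest.raises(StagingError, match="beta2m"):
            stage_riss(LabPanel(albumin=4.0, ldh_elevated=False, high_risk_cytogenetics=False))

    @pytest.mark.parametrize(
        "worse",
        [
            dict(beta2m=6.0),
            dict(albumin=3.0),
            dict(ldh_elevated=True),
            dict(high_risk_cytogenetics=True),
        ],
    )
    def test_worsening_never_lowers_stage(self, worse):
        for base_kwargs in (dict(), dict(beta2m=6.0), dict(beta2m=6.0, ldh_elevated=True)):
            base = stage_riss(labs_riss(**base_kwargs)).stage
            merged = {**base_kwargs, **worse}
            assert stage_riss(labs_riss(**merged)).stage >= base


class TestDsPlus:
    def test_maximal_burden(self):
        d = parse_descriptor("BM(5), F4.SP.ExtraSP(5), L4, EM.EN(5)")
        a = stage_dsplus(d, LabPanel(creatinine=1.0))
        assert (a.stage, a.subgroup) == (Stage.III, Subgroup.B)

    def test_minimal_burden(self):
        d = parse_descriptor("BM(2), F1, L1")
        a = stage_dsplus(d, LabPanel(creatinine=1.0))
        assert (a.stage, a.subgroup) == (Stage.I, Subgroup.A)

    def test_demotion_when_not_pet_positive(self):
        hot = parse_descriptor("BM(2), F4.SP(4), L2")
        cold = parse_descriptor("BM(2), F4.SP(3), L2")
        assert stage_dsplus(hot, LabPanel(creatinine=1.0)).stage == Stage.III
        assert stage_dsplus(cold, LabPanel(creatinine=1.0)).stage == Stage.II

    def test_diffuse_component_alone(self):
        a = stage_dsplus(parse_descriptor("BM(4)A, EM.EN(4)"), LabPanel(creatinine=1.0))
        assert (a.stage, a.subgroup) == (Stage.III, Subgroup.B)

    def test_subgroup_b_from_creatinine_alone(self):
        a = stage_dsplus(parse_descriptor("BM(2), F1"), LabPanel(creatinine=2.5))
        assert a.subgroup is Subgroup.B

    def test_missing_creatinine_raises(self):
        with pytest.raises(StagingError, match="creatinine"):
            stage_dsplus(parse_descriptor("BM(2)"), LabPanel())

    def test_rule_trace_emitted(self):
        a = stage_dsplus(parse_descriptor("BM(3), F3.SP(4), L2"), LabPanel(creatinine=1.0))
        assert any("focal grade" in line for line in a.trace)
        assert any("diffuse BM" in line for line in a.trace)

    def test_rule_table_is_configuration(self):
        rules = StagingRules(
            dsplus_focal_grade_stage={1: Stage.I, 2: Stage.II, 3: Stage.II, 4: Stage.III}
        )
        d = parse_descriptor("BM(2), F2.SP(4), L2")
        assert stage_dsplus(d, LabPanel(creatinine=1.0), rules).stage == Stage.II
        assert stage_dsplus(d, LabPanel(creatinine=1.0)).stage == Stage.I


class TestAgreementReport:
    def _assignments(self, labels, system="dsplus"):
        out = []
        for lab in labels:
            stage, sub = parse_stage_label(lab)
            from mmstage.staging import StageAssignment, System

            out.append(StageAssignment(System.DSPLUS, stage, sub))
        return out

    def test_identical_inputs(self):
        a = self._assignments(["IA", "IIB", "IIIB"])
        rep = agreement_report(a, a)
        assert rep.agreement == 1.0 and not rep.mismatches

    def test_single_mismatch_arithmetic(self):
        a = self._assignments(["IA"] * 32 + ["IIIB"])
        b = self._assignments(["IA"] * 33)
        rep = agreement_report(a, b)
        assert rep.n_match == 32 and rep.agreement == pytest.approx(32 / 33)

    def test_length_mismatch_rejected(self):
        a = self._assignments(["IA"])
        with pytest.raises(ValueError, match="length"):
            agreement_report(a, a * 2)

    def test_fixture_mismatches_include_identical_descriptor_pair(self, cohort):
        """Patients 7 and 20 share focal grade and score but print different
        DS Plus stages, so a descriptor-only engine must miss at least one."""
        derived = []
        printed = []
        for rec in cohort:
            d = parse_descriptor(rec.impetus)
            derived.append(stage_dsplus(d, LabPanel(creatinine=1.0)))
            from mmstage.staging import StageAssignment, System

            stage, sub = rec.stage_dsplus
            printed.append(
                StageAssignment(System.DSPLUS, stage, sub if sub else Subgroup.A)
            )
        rep = agreement_report(derived, printed, ids=[r.patient_id for r in cohort])
        mismatch_ids = {row[0] for row in rep.mismatches}
        assert mismatch_ids & {"7", "20"}
        assert 0 < rep.agreement < 1
        assert "agreement" in rep.to_text()
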