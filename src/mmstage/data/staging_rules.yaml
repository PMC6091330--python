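# Default staging thresholds and DS Plus mapping tables.
# Edit a copy and pass it via --config / StagingRules.from_yaml to override.
#
# DSS stage I requires ALL stage-1 clauses; stage III fires on ANY stage-3
# clause.  The stage-III calcium trigger is implemented as calcium > 12 mg/dL
# (hypercalcemia), the direction of the original Durie-Salmon criterion.
dss_stage1_hb_gt: 10.0        # g/dL
dss_stage1_ca_le: 10.5        # mg/dL
dss_stage1_igg_lt: 5.0        # g/dL
dss_stage1_iga_lt: 3.0        # g/dL
dss_stage1_bj_lt: 4.0         # g/24 h
dss_stage3_hb_lt: 8.5         # g/dL
dss_stage3_ca_gt: 12.0        # mg/dL
dss_stage3_igg_gt: 7.0        # g/dL
dss_stage3_iga_gt: 5.0        # g/dL
dss_stage3_bj_gt: 12.0        # g/24 h
dss_subgroup_b_creatinine_ge: 2.0   # mg/dL
riss_stage1_albumin_ge: 3.5   # g/dL
riss_stage1_beta2m_lt: 3.5    # mg/L
riss_stage3_beta2m_gt: 5.5    # mg/L
dsplus_focal_grade_stage: {1: I, 2: I, 3: II, 4: III}
dsplus_diffuse_score_stage: {1: I, 2: I, 3: II, 4: III, 5: III}
dsplus_demote_if_not_bone_positive: true
dsplus_subgroup_b_creatinine_gt: 2.0  # mg/dL
bone_positive_min_score: 4    # Deauville cutoff for focal bone lesions
em_positive_min_score: 4      # Deauville cutoff for extramedullary lesions
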