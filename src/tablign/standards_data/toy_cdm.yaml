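# Toy clinical common-data-model used throughout the test suite.
# Synthetic: a small stand-in for large cancer-research CDMs, with the same
# shape (enumerated permissible values, curated descriptions, units).
name: toy_cdm
attributes:
  - name: gender
    description: Self-reported gender of the participant.
    values: [female, male, unknown]
  - name: race
    description: Self-reported race of the participant.
    values: [white, black or african american, asian, american indian or alaska native, other, not reported]
  - name: ethnicity
    description: Self-reported ethnicity of the participant.
    values: [hispanic or latino, not hispanic or latino, not reported]
  - name: bmi
    description: Body mass index at enrollment.
    metadata:
      unit: kg/m2
      type: numeric
  - name: tumor_focality
    description: Whether the tumor is unifocal or multifocal.
    values: [unifocal, multifocal, unknown]
  - name: age_at_diagnosis
    description: Participant age at the time of diagnosis.
    metadata:
      unit: days
      type: numeric
  - name: age_at_index
    description: Participant age at the index date of the study.
    metadata:
      unit: days
      type: numeric
  - name: vital_status
    description: Survival state of the participant at last follow-up.
    values: [alive, dead, unknown]
  - name: tumor_grade
    description: Histologic grade of the tumor.
    values: [g1, g2, g3, g4, gx]
  - name: primary_site
    description: Anatomical site of the primary tumor.
    values: [kidney, lung, breast, colon, uterus, other]
  - name: cnv_status
    description: Copy-number-variation class of the tumor sample.
    values: [CNV_L, CNV_H, CNV_N]
  - name: days_to_death
    description: Days from the index date to death, when applicable.
    metadata:
      unit: days
      type: numeric
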