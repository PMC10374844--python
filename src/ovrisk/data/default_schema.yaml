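# Default clinical schema for BRCA-mutated RRSO cohorts: 20 features with
# the marginal summaries (median/quartiles, Yes counts, NA counts) of the
# 184-patient reference cohort. Continuous marginals are (q1, median, q3)
# with a lower plausibility bound; binary marginals are Yes/observed-total
# counts; count marginals are category probabilities on {0..4} chosen to
# reproduce the printed median and quartiles.
features:
  - name: age
    display_name: Age
    kind: continuous
    unit: years
    quartiles: [45, 50, 56]
    lower_bound: 18
    na_count: 4
  - name: bmi
    display_name: BMI
    kind: continuous
    unit: kg/m2
    quartiles: [22.0, 24.2, 27.2]
    lower_bound: 14
    na_count: 17
  - name: menarche_age
    display_name: Age of menarche
    kind: continuous
    unit: years
    quartiles: [12, 12, 13]
    lower_bound: 8
    na_count: 0
  - name: brca1
    display_name: BRCA 1
    kind: binary
    unit: ""
    yes_count: 104
    observed: 184
    na_count: 0
  - name: brca2
    display_name: BRCA 2
    kind: binary
    unit: ""
    yes_count: 80
    observed: 184
    na_count: 0
  - name: ca125
    display_name: CA-125
    kind: continuous
    unit: UI/ml
    quartiles: [7.0, 10.5, 15.6]
    lower_bound: 0
    na_count: 0
  - name: meno_at_rrso
    display_name: MatoRRSO
    kind: binary
    unit: ""
    yes_count: 104
    observed: 166
    na_count: 18
  - name: pregnancy_nftd
    display_name: Pregnancy nftd
    kind: count
    unit: ""
    probs: [0.18, 0.22, 0.42, 0.12, 0.06]
    na_count: 14
  - name: estroprogestin
    display_name: Estroprogestin use
    kind: binary
    unit: ""
    yes_count: 59
    observed: 184
    na_count: 0
  - name: endometriosis
    display_name: History of endometriosis
    kind: binary
    unit: ""
    yes_count: 3
    observed: 184
    na_count: 0
  - name: paps
    display_name: PAPS
    kind: binary
    unit: ""
    yes_count: 71
    observed: 184
    na_count: 0
  - name: previous_bc
    display_name: Previous BC
    kind: binary
    unit: ""
    yes_count: 106
    observed: 184
    na_count: 0
  - name: bc_fdr
    display_name: BC FDR
    kind: binary
    unit: ""
    yes_count: 56
    observed: 172
    na_count: 12
  - name: bc_nfdr
    display_name: BC Nfdr
    kind: count
    unit: ""
    probs: [0.60, 0.30, 0.08, 0.02]
    na_count: 12
  - name: bc_sdr
    display_name: BC SDR
    kind: binary
    unit: ""
    yes_count: 78
    observed: 172
    na_count: 12
  - name: bc_nsdr
    display_name: BC Nsdr
    kind: count
    unit: ""
    probs: [0.60, 0.30, 0.08, 0.02]
    na_count: 12
  - name: oc_fdr
    display_name: OC FDR
    kind: binary
    unit: ""
    yes_count: 31
    observed: 172
    na_count: 12
  - name: oc_nfdr
    display_name: OC Nfdr
    kind: count
    unit: ""
    probs: [0.60, 0.30, 0.08, 0.02]
    na_count: 12
  - name: oc_sdr
    display_name: OC SDR
    kind: binary
    unit: ""
    yes_count: 35
    observed: 172
    na_count: 12
  - name: oc_nsdr
    display_name: OC Nsdr
    kind: count
    unit: ""
    probs: [0.60, 0.30, 0.08, 0.02]
    na_count: 12
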