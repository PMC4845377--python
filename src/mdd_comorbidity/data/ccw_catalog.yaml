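# Chronic-condition catalog: 24 CCW-style categories (the CCW set after
# removing dementia/Alzheimer's disease and depression).
#
# The ICD-9-CM prefix lists below are a representative mapping, not the
# versioned CCW reference lists (which are distributed separately by CMS);
# the catalog is a first-class input, so the official lists can be
# substituted by pointing the pipeline at an edited copy of this file.
# Prefix semantics: a diagnosis code matches a condition when the
# normalized code string starts with any listed prefix.
conditions:
  - id: hypothyroidism
    name: Acquired hypothyroidism
    icd9_prefixes: ["244"]
    sex_restriction: none
  - id: acute_mi
    name: Acute myocardial infarction
    icd9_prefixes: ["410"]
    sex_restriction: none
  - id: anemia
    name: Anemia
    icd9_prefixes: ["280", "281", "285"]
    sex_restriction: none
  - id: asthma
    name: Asthma
    icd9_prefixes: ["493"]
    sex_restriction: none
  - id: atrial_fibrillation
    name: Atrial fibrillation
    icd9_prefixes: ["427.3"]
    sex_restriction: none
  - id: bph
    name: Benign prostatic hyperplasia
    icd9_prefixes: ["600"]
    sex_restriction: male_only
  - id: breast_cancer
    name: Breast cancer
    icd9_prefixes: ["174", "233.0"]
    sex_restriction: none
  - id: cataract
    name: Cataract
    icd9_prefixes: ["366"]
    sex_restriction: none
  - id: chronic_kidney_disease
    name: Chronic kidney disease
    icd9_prefixes: ["585"]
    sex_restriction: none
  - id: copd
    name: Chronic obstructive pulmonary disease
    icd9_prefixes: ["491", "492", "496"]
    sex_restriction: none
  - id: colorectal_cancer
    name: Colorectal cancer
    icd9_prefixes: ["153", "154.0", "154.1"]
    sex_restriction: none
  - id: diabetes
    name: Diabetes mellitus
    icd9_prefixes: ["250"]
    sex_restriction: none
  - id: endometrial_cancer
    name: Endometrial cancer
    icd9_prefixes: ["182"]
    sex_restriction: female_only
  - id: glaucoma
    name: Glaucoma
    icd9_prefixes: ["365"]
    sex_restriction: none
  - id: heart_failure
    name: Heart failure
    icd9_prefixes: ["428"]
    sex_restriction: none
  - id: hip_fracture
    name: Hip/pelvic fracture
    icd9_prefixes: ["820", "808"]
    sex_restriction: none
  - id: hyperlipidemia
    name: Hyperlipidemia
    icd9_prefixes: ["272.0", "272.1", "272.2", "272.3", "272.4"]
    sex_restriction: none
  - id: hypertension
    name: Hypertension
    icd9_prefixes: ["401", "402", "403", "404", "405"]
    sex_restriction: none
  - id: ischemic_heart_disease
    name: Ischemic heart disease
    icd9_prefixes: ["411", "412", "413", "414"]
    sex_restriction: none
  - id: lung_cancer
    name: Lung cancer
    icd9_prefixes: ["162"]
    sex_restriction: none
  - id: osteoporosis
    name: Osteoporosis
    icd9_prefixes: ["733.0"]
    sex_restriction: none
  - id: prostate_cancer
    name: Prostate cancer
    icd9_prefixes: ["185"]
    sex_restriction: male_only
  - id: ra_oa
    name: Rheumatoid arthritis / osteoarthritis
    icd9_prefixes: ["714", "715"]
    sex_restriction: none
  - id: stroke_tia
    name: Stroke / transient ischemic attack
    icd9_prefixes: ["430", "431", "433", "434", "435", "436"]
    sex_restriction: none
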