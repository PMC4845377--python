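# Code sets driving the rule-based MDD case-finding algorithm.
# The algorithm is data-driven: every list here can be overridden from a
# user-supplied copy of this file.
mdd_icd9_prefixes: ["296.2", "296.3"]
antidepressant_ndfrt_classes: ["C8870", "C8872", "C8874", "C8876"]
phq9_threshold: 15
exclusion_icd9_prefixes:
  bipolar: ["296.1", "296.4", "296.5", "296.6", "296.7", "296.8", "296.9"]
  dementia_delirium: ["290"]
  psychotic: ["295", "298"]
obesity_icd9_codes:
  ["278.0", "564.2", "V45.3", "V45.86", "649.1", "649.2", "V85.3", "V85.4", "V77.8"]
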