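{
  "n_fetuses": 610,
  "n_trios": 596,
  "n_dyads": 14,
  "n_parent_samples": 1202,
  "n_candidate_variants": 321,
  "n_potential_diagnoses": 255,
  "n_clinically_relevant_vus": 24,
  "class_sizes": {
    "abdominal": 45,
    "brain": 69,
    "cardiac": 81,
    "thoracic": 23,
    "facial_cleft": 32,
    "hydrops": 33,
    "increased_NT": 93,
    "renal": 16,
    "skeletal": 65,
    "spinal": 10,
    "multisystem": 143
  },
  "outcomes": {
    "known": 474,
    "termination": 142,
    "miscarriage": 14,
    "stillbirth": 22,
    "neonatal_death": 14,
    "livebirth": 282,
    "diagnostic_not_survived": 27,
    "diagnostic_liveborn": 20
  },
  "pre_exclusion": {
    "reviewed_eligible": 564,
    "excluded_total": 134,
    "qf_pcr": 97,
    "microarray": 37
  }
}
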