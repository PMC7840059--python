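# Template point table: transcribe the published POSPOM point values here
# (Le Manach et al. 2016, supplementary score table) and map each original
# index-surgery category to the OPS prefixes used at your institution.
#
# Every `points: null` must be replaced by the published integer value and
# every `icd_prefixes`/`ops_prefixes` list filled before the file will load;
# `gpospom score --table <this file>` validates the result and lists every
# violation.  Age-band boundaries below follow the published strata; adjust
# if your transcription source differs.
version: "FILL-IN: provenance of the transcription (source, date, transcriber)"
age_bands:
  - {lower_age: 18, upper_age: 45, points: null}
  - {lower_age: 46, upper_age: 55, points: null}
  - {lower_age: 56, upper_age: 65, points: null}
  - {lower_age: 66, upper_age: 75, points: null}
  - {lower_age: 76, upper_age: 85, points: null}
  - {lower_age: 86, upper_age: null, points: null}
comorbidities:
  - {name: cardiac arrhythmia,                  icd_prefixes: [], points: null}
  - {name: congestive heart failure,            icd_prefixes: [], points: null}
  - {name: coronary artery disease,             icd_prefixes: [], points: null}
  - {name: valvular heart disease,              icd_prefixes: [], points: null}
  - {name: peripheral vascular disease,         icd_prefixes: [], points: null}
  - {name: cerebrovascular disease,             icd_prefixes: [], points: null}
  - {name: neurological disease,                icd_prefixes: [], points: null}
  - {name: chronic pulmonary disease,           icd_prefixes: [], points: null}
  - {name: chronic kidney disease,              icd_prefixes: [], points: null}
  - {name: chronic liver disease,               icd_prefixes: [], points: null}
  - {name: diabetes mellitus,                   icd_prefixes: [], points: null}
  - {name: cancer,                              icd_prefixes: [], points: null}
  - {name: metastatic cancer,                   icd_prefixes: [], points: null}
  - {name: haematological malignancy,           icd_prefixes: [], points: null}
  - {name: alcohol or substance use disorder,   icd_prefixes: [], points: null}
surgeries:
  - {name: skin and soft tissue,                ops_prefixes: [], points: null}
  - {name: ear nose throat and maxillofacial,   ops_prefixes: [], points: null}
  - {name: ophthalmic,                          ops_prefixes: [], points: null}
  - {name: endocrine,                           ops_prefixes: [], points: null}
  - {name: gynaecological and breast,           ops_prefixes: [], points: null}
  - {name: urological,                          ops_prefixes: [], points: null}
  - {name: orthopaedic and trauma,              ops_prefixes: [], points: null}
  - {name: spine,                               ops_prefixes: [], points: null}
  - {name: abdominal wall and hernia,           ops_prefixes: [], points: null}
  - {name: upper gastrointestinal,              ops_prefixes: [], points: null}
  - {name: lower gastrointestinal,              ops_prefixes: [], points: null}
  - {name: hepatobiliary and pancreatic,        ops_prefixes: [], points: null}
  - {name: major vascular,                      ops_prefixes: [], points: null}
  - {name: thoracic,                            ops_prefixes: [], points: null}
  - {name: cardiac,                             ops_prefixes: [], points: null}
  - {name: neurosurgical,                       ops_prefixes: [], points: null}
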