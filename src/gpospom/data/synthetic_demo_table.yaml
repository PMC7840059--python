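# SYNTHETIC demo point table.
#
# The point values below are NOT the published POSPOM values: they are a
# synthetic stand-in with the published table's *shape* (age bands, 15
# ICD-10-prefix comorbidity groups, OPS-prefix index-surgery categories,
# maximum attainable score 49) so that the pipeline, the simulator and the
# documentation examples run out of the box.  For real analyses transcribe
# the published values into point_table_template.yaml.
version: "synthetic-demo-0.1 (NOT the published score)"
age_bands:
  - {lower_age: 18, upper_age: 45, points: 0}
  - {lower_age: 46, upper_age: 55, points: 2}
  - {lower_age: 56, upper_age: 65, points: 4}
  - {lower_age: 66, upper_age: 75, points: 6}
  - {lower_age: 76, upper_age: 85, points: 8}
  - {lower_age: 86, upper_age: null, points: 10}
comorbidities:
  - {name: congestive heart failure,       icd_prefixes: [I50],                          points: 2}
  - {name: ischaemic heart disease,        icd_prefixes: [I20, I21, I22, I24, I25],      points: 2}
  - {name: cardiac arrhythmia,             icd_prefixes: [I44, I45, I47, I48, I49],      points: 1}
  - {name: valvular heart disease,         icd_prefixes: [I05, I06, I07, I08, I34, I35, I36, I37], points: 2}
  - {name: peripheral vascular disease,    icd_prefixes: [I70, I71, I73],                points: 1}
  - {name: cerebrovascular disease,        icd_prefixes: [I60, I61, I62, I63, I64, I65, I66, I67, I69], points: 2}
  - {name: dementia,                       icd_prefixes: [F00, F01, F02, F03, G30],      points: 1}
  - {name: chronic pulmonary disease,      icd_prefixes: [J40, J41, J42, J43, J44, J45, J46, J47], points: 1}
  - {name: chronic kidney disease,         icd_prefixes: [N18, N19],                     points: 3}
  - {name: chronic liver disease,          icd_prefixes: [K70, K72, K74],                points: 3}
  - {name: diabetes mellitus,              icd_prefixes: [E10, E11, E13, E14],           points: 1}
  - {name: malignancy,                     icd_prefixes: [C1, C2, C3, C4, C5, C6, C90, C91, C92], points: 3}
  - {name: metastatic solid tumour,        icd_prefixes: [C77, C78, C79, C80],           points: 2}
  - {name: hemiplegia or paraplegia,       icd_prefixes: [G81, G82],                     points: 1}
  - {name: alcohol-related disorder,       icd_prefixes: [F10],                          points: 1}
surgeries:
  - {name: skin and soft tissue surgery,   ops_prefixes: [5-89, 5-90],                   points: 0}
  - {name: ent and maxillofacial surgery,  ops_prefixes: [5-21, 5-22, 5-24],             points: 1}
  - {name: gynaecological surgery,         ops_prefixes: [5-65, 5-66, 5-68],             points: 2}
  - {name: orthopaedic limb surgery,       ops_prefixes: [5-78, 5-79, 5-82],             points: 3}
  - {name: abdominal wall and hernia,      ops_prefixes: [5-53],                         points: 3}
  - {name: urological surgery,             ops_prefixes: [5-55, 5-56, 5-57, 5-60],       points: 4}
  - {name: gastrointestinal resection,     ops_prefixes: [5-43, 5-45, 5-46],             points: 7}
  - {name: major vascular surgery,         ops_prefixes: [5-38, 5-39],                   points: 8}
  - {name: hepatobiliary and pancreatic,   ops_prefixes: [5-50, 5-51, 5-52],             points: 9}
  - {name: thoracic surgery,               ops_prefixes: [5-32, 5-33, 5-34],             points: 10}
  - {name: cranial neurosurgery,           ops_prefixes: [5-01, 5-02],                   points: 11}
  - {name: open cardiac surgery,           ops_prefixes: [5-35, 5-36],                   points: 13}
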