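# Clinical scenario library (schema v1): 33 combinations of chemotherapy
# protocol, risk group and G-CSF schedule.
#
# Dose units: doses above 300 (Filgrastim 480, Pegfilgrastim 6000) are the
# standard absolute amounts and are stored with dose_unit `ug`; true
# per-kilogram doses use `ug_per_kg`.
# `validation: true` marks the three scenarios excluded from every fitting
# step and reserved for model validation.
schema_version: 1
metadata:
  known_inconsistencies:
    - "ESHAP Pegfilgrastim scenario 32: injection day reported as both day 5
       and day 6 in different sources; day 6 is used."
    - "Doses above 300 ug sometimes mislabelled per-kg are stored as
       absolute amounts."
scenarios:
  - {id: 1,  gcsf: {derivative: fil, dose: 5,    dose_unit: ug_per_kg, days: [2,3,4,5,6,7,8,9,10,11,12,13]}, disease: "Breast cancer", protocol: TA}
  - {id: 2,  gcsf: {derivative: fil, dose: 5,    dose_unit: ug_per_kg, days: [2,3,4,5,6]},                   disease: NSCLC, protocol: CP}
  - {id: 3,  gcsf: {derivative: fil, dose: 480,  dose_unit: ug, days: [6,7,8,9,10,11,12,13]},                disease: NHL, protocol: high-CHOEP, cycle_days: 14}
  - {id: 4,  gcsf: {derivative: peg, dose: 30,   dose_unit: ug_per_kg, days: [2]},                           disease: "Breast cancer", protocol: TA}
  - {id: 5,  gcsf: {derivative: peg, dose: 60,   dose_unit: ug_per_kg, days: [2]},                           disease: "Breast cancer", protocol: TA}
  - {id: 6,  gcsf: {derivative: peg, dose: 100,  dose_unit: ug_per_kg, days: [2]},                           disease: "Breast cancer", protocol: TA}
  - {id: 7,  gcsf: {derivative: peg, dose: 6000, dose_unit: ug, days: [2]},                                  disease: "Breast cancer", protocol: TA}
  - {id: 8,  gcsf: {derivative: peg, dose: 6000, dose_unit: ug, days: [2]},                                  disease: "Breast cancer", protocol: TA}
  - {id: 9,  gcsf: {derivative: peg, dose: 30,   dose_unit: ug_per_kg, days: [2]},                           disease: NSCLC, protocol: CP}
  - {id: 10, gcsf: {derivative: peg, dose: 100,  dose_unit: ug_per_kg, days: [2]},                           disease: NSCLC, protocol: CP}
  - {id: 11, gcsf: {derivative: peg, dose: 300,  dose_unit: ug_per_kg, days: [2]},                           disease: NSCLC, protocol: CP}
  - {id: 12, gcsf: {derivative: peg, dose: 6000, dose_unit: ug, days: [2]},                                  disease: NHL, protocol: CHOP, cycle_days: 14, risk_group: elderly, validation: true}
  - {id: 13, gcsf: {derivative: peg, dose: 6000, dose_unit: ug, days: [2]},                                  disease: DLBCL, protocol: CHOP, cycle_days: 14, risk_group: elderly, notes: "R-CHOP; rituximab treated as plain CHOP"}
  - {id: 14, gcsf: null,                                                                                     disease: NHL, protocol: CHOP, cycle_days: 21, risk_group: young}
  - {id: 15, gcsf: null,                                                                                     disease: NHL, protocol: CHOP, cycle_days: 21, risk_group: elderly}
  - {id: 16, gcsf: null,                                                                                     disease: NHL, protocol: CHOEP, cycle_days: 21, risk_group: young}
  - {id: 17, gcsf: null,                                                                                     disease: NHL, protocol: CHOEP, cycle_days: 21, risk_group: elderly}
  - {id: 18, gcsf: null,                                                                                     disease: HD, protocol: BEACOPP, cycle_days: 21}
  - {id: 19, gcsf: null,                                                                                     disease: "Breast cancer", protocol: EC-T}
  - {id: 20, gcsf: {derivative: fil, dose: 480,  dose_unit: ug, days: [4,5,6,7,8,9,10,11,12,13]},            disease: NHL, protocol: CHOP, cycle_days: 14, risk_group: young}
  - {id: 21, gcsf: {derivative: fil, dose: 480,  dose_unit: ug, days: [4,5,6,7,8,9,10,11,12,13]},            disease: NHL, protocol: CHOP, cycle_days: 14, risk_group: elderly}
  - {id: 22, gcsf: {derivative: fil, dose: 480,  dose_unit: ug, days: [6,7,8,9,10,11,12]},                   disease: NHL, protocol: CHOP, cycle_days: 14, risk_group: elderly, validation: true}
  - {id: 23, gcsf: {derivative: fil, dose: 480,  dose_unit: ug, days: [4,5,6,7,8,9,10,11,12,13]},            disease: NHL, protocol: CHOEP, cycle_days: 14, risk_group: young}
  - {id: 24, gcsf: {derivative: fil, dose: 480,  dose_unit: ug, days: [4,5,6,7,8,9,10,11,12,13]},            disease: NHL, protocol: CHOEP, cycle_days: 14, risk_group: elderly}
  - {id: 25, gcsf: {derivative: fil, dose: 480,  dose_unit: ug, days: [6,7,8,9,10,11,12,13]},                disease: NHL, protocol: high-CHOEP, cycle_days: 21}
  - {id: 26, gcsf: {derivative: fil, dose: 480,  dose_unit: ug, days: [8,9,10,11,12,13]},                    disease: HD, protocol: BEACOPP, cycle_days: 14}
  - {id: 27, gcsf: {derivative: fil, dose: 480,  dose_unit: ug, days: [8,9,10,11,12,13,14,15]},              disease: HD, protocol: BEACOPP-escalated, cycle_days: 21}
  - {id: 28, gcsf: {derivative: fil, dose: 480,  dose_unit: ug, days: [3,4,5,6,7,8,9,10]},                   disease: "Breast cancer", protocol: ETC}
  - {id: 29, gcsf: {derivative: fil, dose: 5,    dose_unit: ug_per_kg, days: [5,6,7,8,9,10,11,12,13,14,15,16]}, disease: "relapsed/persistent HD or NHL", protocol: ESHAP}
  - {id: 30, gcsf: {derivative: peg, dose: 6000, dose_unit: ug, days: [2]},                                  disease: NHL, protocol: CHOP, cycle_days: 14, risk_group: elderly}
  - {id: 31, gcsf: {derivative: peg, dose: 6000, dose_unit: ug, days: [4]},                                  disease: NHL, protocol: CHOP, cycle_days: 14, risk_group: elderly}
  - {id: 32, gcsf: {derivative: peg, dose: 100,  dose_unit: ug_per_kg, days: [6]},                           disease: "relapsed/persistent HD or NHL", protocol: ESHAP, validation: true}
  - {id: 33, gcsf: {derivative: peg, dose: 6000, dose_unit: ug, days: [2]},                                  disease: DLBCL, protocol: CHOP, cycle_days: 14, risk_group: young, notes: "R-CHOP; rituximab treated as plain CHOP"}
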