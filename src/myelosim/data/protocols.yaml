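# Chemotherapy protocol library (schema v1).
#
# Days are 1-based within a cycle.  Inseparable drug combinations are driven
# by a single pulse train at the combination's anchor day and map to one
# toxicity label.  Labels may be a single string or a per-risk-group map.
# `cycles` restricts an agent to specific cycle numbers (sequential
# protocols); omitted means every cycle.  Entries whose within-cycle days are
# not fixed by the dose summary follow the standard published protocol and
# are marked `external_knowledge: true`.
schema_version: 1
protocols:
  CHOP:
    default_cycle_days: 21
    default_n_cycles: 6
    risk_groups: [young, elderly]
    agents:
      - drug: cyclophosphamide+doxorubicin+vincristine
        doses: "cyclophosphamide 750 mg/m2, doxorubicin 50 mg/m2, vincristine 2 mg"
        toxicity_label: {young: CHOPy, elderly: CHOPo}
        days: [1]
        infusion_h: 1.0
      - drug: prednisone
        doses: "100 mg"
        days: [1, 2, 3, 4, 5]
        cytotoxic: false
        external_knowledge: true
  CHOEP:
    default_cycle_days: 21
    default_n_cycles: 6
    risk_groups: [young, elderly]
    agents:
      - drug: cyclophosphamide+doxorubicin+vincristine
        doses: "cyclophosphamide 750 mg/m2, doxorubicin 50 mg/m2, vincristine 2 mg"
        toxicity_label: {young: CHOPy, elderly: CHOPo}
        days: [1]
        infusion_h: 1.0
      - drug: etoposide
        doses: "100 mg/m2/d"
        toxicity_label: {young: ETy, elderly: ETo}
        days: [1, 2, 3]
        infusion_h: 1.0
      - drug: prednisone
        doses: "100 mg"
        days: [1, 2, 3, 4, 5]
        cytotoxic: false
        external_knowledge: true
  high-CHOEP:
    default_cycle_days: 21
    default_n_cycles: 6
    agents:
      - drug: cyclophosphamide+doxorubicin+vincristine
        doses: "cyclophosphamide 1400 mg/m2, doxorubicin 32.5 mg/m2/d d1-2, vincristine 2 mg"
        toxicity_label: CDh
        days: [1]
        infusion_h: 1.0
      - drug: etoposide
        doses: "175 mg/m2/d"
        toxicity_label: ETh
        days: [1, 2, 3]
        infusion_h: 1.0
      - drug: prednisone
        doses: "100 mg"
        days: [1, 2, 3, 4, 5]
        cytotoxic: false
        external_knowledge: true
  BEACOPP:
    default_cycle_days: 21
    default_n_cycles: 8
    agents:
      - drug: cyclophosphamide+doxorubicin+vincristine
        doses: "cyclophosphamide 650 mg/m2, doxorubicin 25 mg/m2, vincristine 2 mg"
        toxicity_label: CD
        days: [1]
        infusion_h: 1.0
      - drug: etoposide
        doses: "100 mg/m2/d"
        toxicity_label: ETy
        days: [1, 2, 3]
        infusion_h: 1.0
      - drug: bleomycin
        doses: "10 mg/m2"
        toxicity_label: VB
        days: [8]
        infusion_h: 1.0
        external_knowledge: true
      - drug: procarbazine
        doses: "100 mg/m2/d"
        toxicity_label: PROC
        days: [1, 2, 3, 4, 5, 6, 7]
        infusion_h: 1.0
      - drug: prednisone
        doses: "100 mg"
        days: [1, 2, 3, 4, 5, 6, 7, 8, 9, 10, 11, 12, 13, 14]
        cytotoxic: false
        external_knowledge: true
  BEACOPP-escalated:
    default_cycle_days: 21
    default_n_cycles: 8
    agents:
      - drug: cyclophosphamide+doxorubicin+vincristine
        doses: "cyclophosphamide 1250 mg/m2, doxorubicin 35 mg/m2, vincristine 2 mg"
        toxicity_label: CDesk
        days: [1]
        infusion_h: 1.0
      - drug: etoposide
        doses: "200 mg/m2/d"
        toxicity_label: ETesk
        days: [1, 2, 3]
        infusion_h: 1.0
      - drug: bleomycin
        doses: "10 mg/m2"
        toxicity_label: VB
        days: [8]
        infusion_h: 1.0
        external_knowledge: true
      - drug: procarbazine
        doses: "100 mg/m2/d"
        toxicity_label: PROC
        days: [1, 2, 3, 4, 5, 6, 7]
        infusion_h: 1.0
      - drug: prednisone
        doses: "100 mg"
        days: [1, 2, 3, 4, 5, 6, 7, 8, 9, 10, 11, 12, 13, 14]
        cytotoxic: false
        external_knowledge: true
  TA:
    default_cycle_days: 21
    default_n_cycles: 4
    agents:
      - drug: doxorubicin+docetaxel
        doses: "doxorubicin 60 mg/m2, docetaxel 75 mg/m2"
        toxicity_label: TA
        days: [1]
        infusion_h: 1.0
  CP:
    default_cycle_days: 21
    default_n_cycles: 4
    agents:
      - drug: carboplatin+paclitaxel
        doses: "carboplatin AUC-dosed, paclitaxel 225 mg/m2"
        toxicity_label: CP
        days: [1]
        infusion_h: 3.0
  ETC:
    # dose-dense sequential blocks: 3x epirubicin, 3x paclitaxel,
    # 3x cyclophosphamide, every 14 days
    default_cycle_days: 14
    default_n_cycles: 9
    agents:
      - drug: epirubicin
        doses: "150 mg/m2"
        toxicity_label: E150
        days: [1]
        infusion_h: 3.0
        cycles: [1, 2, 3]
      - drug: paclitaxel
        doses: "225 mg/m2"
        toxicity_label: P225
        days: [1]
        infusion_h: 3.0
        cycles: [4, 5, 6]
      - drug: cyclophosphamide
        doses: "2500 mg/m2"
        toxicity_label: C2500
        days: [1]
        infusion_h: 24.0
        cycles: [7, 8, 9]
  EC-T:
    # 4x epirubicin+cyclophosphamide followed by 4x paclitaxel, every 21 days
    default_cycle_days: 21
    default_n_cycles: 8
    agents:
      - drug: epirubicin
        doses: "90 mg/m2"
        toxicity_label: E90
        days: [1]
        infusion_h: 3.0
        cycles: [1, 2, 3, 4]
      - drug: cyclophosphamide
        doses: "600 mg/m2"
        toxicity_label: C600
        days: [1]
        infusion_h: 24.0
        cycles: [1, 2, 3, 4]
      - drug: paclitaxel
        doses: "175 mg/m2"
        toxicity_label: P175
        days: [1]
        infusion_h: 3.0
        cycles: [5, 6, 7, 8]
  ESHAP:
    default_cycle_days: 28
    default_n_cycles: 4
    agents:
      - drug: etoposide
        doses: "40 mg/m2/d"
        toxicity_label: ET40
        days: [1, 2, 3, 4]
        infusion_h: 1.0
        external_knowledge: true
      - drug: cisplatin
        doses: "25 mg/m2/d"
        toxicity_label: Cisp
        days: [1, 2, 3, 4]
        infusion_h: 24.0
        external_knowledge: true
      - drug: cytarabine
        doses: "2000 mg/m2"
        toxicity_label: Cyta
        days: [5]
        infusion_h: 2.0
        external_knowledge: true
      - drug: methylprednisolone
        doses: "500 mg"
        days: [1, 2, 3, 4, 5]
        cytotoxic: false
        external_knowledge: true
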