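# SARA obstetric-care tracer items: 15 health-centre items + 7 hospital
# additions across three readiness domains. Labels are representative
# tracer descriptions; the counts and domain structure are the contract.
framework: SARA
domains: [staff_and_training, equipment, medicines_and_commodities]
items:
  - {id: sara_st_01, label: Staff trained in basic emergency obstetric and newborn care, domain: staff_and_training, tier: both}
  - {id: sara_st_02, label: Guidelines for management of labour and delivery, domain: staff_and_training, tier: both}
  - {id: sara_st_03, label: Delivery care provider on site or on call 24/7, domain: staff_and_training, tier: both}
  - {id: sara_st_04, label: Checklist or job aid for childbirth care, domain: staff_and_training, tier: both}
  - {id: sara_st_05, label: Staff trained in comprehensive emergency obstetric care, domain: staff_and_training, tier: hospital_only}
  - {id: sara_eq_01, label: Emergency transport for obstetric referral, domain: equipment, tier: both}
  - {id: sara_eq_02, label: Sterilisation equipment, domain: equipment, tier: both}
  - {id: sara_eq_03, label: Examination light, domain: equipment, tier: both}
  - {id: sara_eq_04, label: Delivery pack, domain: equipment, tier: both}
  - {id: sara_eq_05, label: Suction apparatus, domain: equipment, tier: both}
  - {id: sara_eq_06, label: Manual vacuum extractor, domain: equipment, tier: both}
  - {id: sara_eq_07, label: Anaesthesia equipment, domain: equipment, tier: hospital_only}
  - {id: sara_eq_08, label: Neonatal incubator, domain: equipment, tier: hospital_only}
  - {id: sara_mc_01, label: Injectable oxytocin, domain: medicines_and_commodities, tier: both}
  - {id: sara_mc_02, label: Injectable magnesium sulphate, domain: medicines_and_commodities, tier: both}
  - {id: sara_mc_03, label: Injectable antibiotic, domain: medicines_and_commodities, tier: both}
  - {id: sara_mc_04, label: Skin disinfectant, domain: medicines_and_commodities, tier: both}
  - {id: sara_mc_05, label: Intravenous solution with infusion set, domain: medicines_and_commodities, tier: both}
  - {id: sara_mc_06, label: Blood supply for transfusion, domain: medicines_and_commodities, tier: hospital_only}
  - {id: sara_mc_07, label: Blood typing and cross-match capacity, domain: medicines_and_commodities, tier: hospital_only}
  - {id: sara_mc_08, label: General anaesthetic agent (ketamine), domain: medicines_and_commodities, tier: hospital_only}
  - {id: sara_mc_09, label: Caesarean surgical supplies, domain: medicines_and_commodities, tier: hospital_only}
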