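# WHO quality-of-maternal-and-newborn-care standards items: 44
# health-centre items + 8 hospital additions across four readiness
# domains. Each item also maps to one of the five WHO standards
# (three provision-of-care, two cross-cutting). Three staffing/systems
# items are asked of government facilities only.
framework: WHO_standards
domains: [equipment_supplies_amenities, medicines_and_health_commodities,
          staffing_and_systems, signal_functions]
items:
  - {id: who_eq_01, label: Newborn resuscitation table with heat source, domain: equipment_supplies_amenities, tier: both, standard: physical_resources}
  - {id: who_eq_02, label: Functional newborn weighing scale, domain: equipment_supplies_amenities, tier: both, standard: physical_resources}
  - {id: who_eq_03, label: Blood pressure apparatus, domain: equipment_supplies_amenities, tier: both, standard: physical_resources}
  - {id: who_eq_04, label: Fetal stethoscope or doppler, domain: equipment_supplies_amenities, tier: both, standard: physical_resources}
  - {id: who_eq_05, label: Oxygen supply with flow meter, domain: equipment_supplies_amenities, tier: both, standard: physical_resources}
  - {id: who_eq_06, label: Handwashing station in delivery area, domain: equipment_supplies_amenities, tier: both, standard: physical_resources}
  - {id: who_eq_07, label: Sterile gloves, domain: equipment_supplies_amenities, tier: both, standard: physical_resources}
  - {id: who_eq_08, label: Sharps container, domain: equipment_supplies_amenities, tier: both, standard: physical_resources}
  - {id: who_eq_09, label: Privacy screen in delivery area, domain: equipment_supplies_amenities, tier: both, standard: physical_resources}
  - {id: who_eq_10, label: Functional toilet for clients, domain: equipment_supplies_amenities, tier: both, standard: physical_resources}
  - {id: who_eq_11, label: Self-inflating bag and neonatal masks, domain: equipment_supplies_amenities, tier: both, standard: physical_resources}
  - {id: who_eq_12, label: Thermometer, domain: equipment_supplies_amenities, tier: both, standard: physical_resources}
  - {id: who_eq_13, label: Functional operating theatre, domain: equipment_supplies_amenities, tier: hospital_only, standard: physical_resources}
  - {id: who_eq_14, label: Neonatal incubator or radiant warmer, domain: equipment_supplies_amenities, tier: hospital_only, standard: physical_resources}
  - {id: who_mc_01, label: Injectable oxytocin, domain: medicines_and_health_commodities, tier: both, standard: physical_resources}
  - {id: who_mc_02, label: Injectable magnesium sulphate, domain: medicines_and_health_commodities, tier: both, standard: physical_resources}
  - {id: who_mc_03, label: Misoprostol, domain: medicines_and_health_commodities, tier: both, standard: physical_resources}
  - {id: who_mc_04, label: Injectable ampicillin, domain: medicines_and_health_commodities, tier: both, standard: physical_resources}
  - {id: who_mc_05, label: Injectable gentamicin, domain: medicines_and_health_commodities, tier: both, standard: physical_resources}
  - {id: who_mc_06, label: Dexamethasone or betamethasone, domain: medicines_and_health_commodities, tier: both, standard: physical_resources}
  - {id: who_mc_07, label: Chlorhexidine gel for cord care, domain: medicines_and_health_commodities, tier: both, standard: physical_resources}
  - {id: who_mc_08, label: BCG vaccine, domain: medicines_and_health_commodities, tier: both, standard: physical_resources}
  - {id: who_mc_09, label: Oral polio vaccine, domain: medicines_and_health_commodities, tier: both, standard: physical_resources}
  - {id: who_mc_10, label: Vitamin K, domain: medicines_and_health_commodities, tier: both, standard: physical_resources}
  - {id: who_mc_11, label: Antibiotic eye ointment for the newborn, domain: medicines_and_health_commodities, tier: both, standard: physical_resources}
  - {id: who_mc_12, label: Benzathine benzylpenicillin, domain: medicines_and_health_commodities, tier: both, standard: physical_resources}
  - {id: who_mc_13, label: Blood products available, domain: medicines_and_health_commodities, tier: hospital_only, standard: physical_resources}
  - {id: who_mc_14, label: General anaesthetic agents, domain: medicines_and_health_commodities, tier: hospital_only, standard: physical_resources}
  - {id: who_ss_01, label: Skilled birth attendant on site or on call 24/7, domain: staffing_and_systems, tier: both, standard: human_resources}
  - {id: who_ss_02, label: In-service training on childbirth care in last year, domain: staffing_and_systems, tier: both, standard: human_resources}
  - {id: who_ss_03, label: Maternal death review process in place, domain: staffing_and_systems, tier: both, standard: information_systems, conditional: government_only}
  - {id: who_ss_04, label: Partograph used to monitor every labour, domain: staffing_and_systems, tier: both, standard: information_systems}
  - {id: who_ss_05, label: Birth register complete and up to date, domain: staffing_and_systems, tier: both, standard: information_systems}
  - {id: who_ss_06, label: Quality improvement committee meeting regularly, domain: staffing_and_systems, tier: both, standard: information_systems, conditional: government_only}
  - {id: who_ss_07, label: Functional referral communication system, domain: staffing_and_systems, tier: both, standard: referral_systems}
  - {id: who_ss_08, label: Emergency transport available 24/7, domain: staffing_and_systems, tier: both, standard: referral_systems}
  - {id: who_ss_09, label: Written referral protocol displayed, domain: staffing_and_systems, tier: both, standard: referral_systems}
  - {id: who_ss_10, label: Routine reporting of perinatal indicators, domain: staffing_and_systems, tier: both, standard: information_systems, conditional: government_only}
  - {id: who_ss_11, label: Obstetrician or surgeon on call 24/7, domain: staffing_and_systems, tier: hospital_only, standard: human_resources}
  - {id: who_sf_01, label: Parenteral antibiotics administered in last 3 months, domain: signal_functions, tier: both, standard: provision_evidence_based}
  - {id: who_sf_02, label: Parenteral uterotonic administered in last 3 months, domain: signal_functions, tier: both, standard: provision_evidence_based}
  - {id: who_sf_03, label: Parenteral anticonvulsant administered in last 3 months, domain: signal_functions, tier: both, standard: provision_evidence_based}
  - {id: who_sf_04, label: Manual removal of placenta performed in last 3 months, domain: signal_functions, tier: both, standard: provision_evidence_based}
  - {id: who_sf_05, label: Removal of retained products performed in last 3 months, domain: signal_functions, tier: both, standard: provision_evidence_based}
  - {id: who_sf_06, label: Assisted vaginal delivery performed in last 3 months, domain: signal_functions, tier: both, standard: provision_evidence_based}
  - {id: who_sf_07, label: Neonatal resuscitation performed in last 3 months, domain: signal_functions, tier: both, standard: provision_evidence_based}
  - {id: who_sf_08, label: Active management of third stage of labour practised, domain: signal_functions, tier: both, standard: provision_evidence_based}
  - {id: who_sf_09, label: Immediate newborn care (drying and warmth) practised, domain: signal_functions, tier: both, standard: provision_evidence_based}
  - {id: who_sf_10, label: Pre-eclampsia screening during labour, domain: signal_functions, tier: both, standard: provision_evidence_based}
  - {id: who_sf_11, label: Caesarean section performed in last 3 months, domain: signal_functions, tier: hospital_only, standard: provision_evidence_based}
  - {id: who_sf_12, label: Blood transfusion performed in last 3 months, domain: signal_functions, tier: hospital_only, standard: provision_evidence_based}
  - {id: who_sf_13, label: Care for the sick newborn (oxygen or CPAP), domain: signal_functions, tier: hospital_only, standard: provision_evidence_based}
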