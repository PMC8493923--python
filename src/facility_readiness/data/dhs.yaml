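# DHS analytical-study obstetric and newborn readiness indicators:
# 30 health-centre items + 3 hospital additions across five readiness
# domains plus a 'guidelines, staff training and supervision' domain
# that is excluded from domain-weighted aggregation (it still counts in
# simple addition and PCA). Two general-requirements items are asked of
# government facilities only.
framework: DHS
domains: [emoc_signal_functions, newborn_signal_functions, general_requirements,
          equipment, medicines_and_commodities, guidelines_training_supervision]
excluded_from_weighting: [guidelines_training_supervision]
items:
  - {id: dhs_sf_01, label: Parenteral antibiotics administered in last 3 months, domain: emoc_signal_functions, tier: both}
  - {id: dhs_sf_02, label: Parenteral uterotonic administered in last 3 months, domain: emoc_signal_functions, tier: both}
  - {id: dhs_sf_03, label: Parenteral anticonvulsant administered in last 3 months, domain: emoc_signal_functions, tier: both}
  - {id: dhs_sf_04, label: Manual removal of placenta performed in last 3 months, domain: emoc_signal_functions, tier: both}
  - {id: dhs_sf_05, label: Removal of retained products performed in last 3 months, domain: emoc_signal_functions, tier: both}
  - {id: dhs_sf_06, label: Assisted vaginal delivery performed in last 3 months, domain: emoc_signal_functions, tier: both}
  - {id: dhs_sf_07, label: Neonatal resuscitation performed in last 3 months, domain: emoc_signal_functions, tier: both}
  - {id: dhs_sf_08, label: Caesarean section performed in last 3 months, domain: emoc_signal_functions, tier: hospital_only}
  - {id: dhs_sf_09, label: Blood transfusion performed in last 3 months, domain: emoc_signal_functions, tier: hospital_only}
  - {id: dhs_nb_01, label: Immediate skin-to-skin contact practised, domain: newborn_signal_functions, tier: both}
  - {id: dhs_nb_02, label: Early initiation of breastfeeding practised, domain: newborn_signal_functions, tier: both}
  - {id: dhs_nb_03, label: Injectable gentamicin for newborn sepsis, domain: newborn_signal_functions, tier: both}
  - {id: dhs_nb_04, label: Kangaroo mother care practised, domain: newborn_signal_functions, tier: both}
  - {id: dhs_nb_05, label: Antenatal corticosteroids administered for preterm labour, domain: newborn_signal_functions, tier: both}
  - {id: dhs_gr_01, label: 24-hour duty schedule for delivery staff, domain: general_requirements, tier: both}
  - {id: dhs_gr_02, label: Improved water source on site, domain: general_requirements, tier: both}
  - {id: dhs_gr_03, label: Electricity available during service hours, domain: general_requirements, tier: both}
  - {id: dhs_gr_04, label: Routine reporting to national health information system, domain: general_requirements, tier: both, conditional: government_only}
  - {id: dhs_gr_05, label: External supervisory visit in last 6 months, domain: general_requirements, tier: both, conditional: government_only}
  - {id: dhs_eq_01, label: Delivery bed, domain: equipment, tier: both}
  - {id: dhs_eq_02, label: Examination light, domain: equipment, tier: both}
  - {id: dhs_eq_03, label: Neonatal bag and mask, domain: equipment, tier: both}
  - {id: dhs_eq_04, label: Blood pressure apparatus, domain: equipment, tier: both}
  - {id: dhs_eq_05, label: Delivery pack, domain: equipment, tier: both}
  - {id: dhs_eq_06, label: Suction apparatus, domain: equipment, tier: both}
  - {id: dhs_eq_07, label: Vacuum aspirator or dilation-and-curettage kit, domain: equipment, tier: hospital_only}
  - {id: dhs_mc_01, label: Oxytocin in delivery room, domain: medicines_and_commodities, tier: both}
  - {id: dhs_mc_02, label: Magnesium sulphate in delivery room, domain: medicines_and_commodities, tier: both}
  - {id: dhs_mc_03, label: Antibiotic eye ointment for the newborn, domain: medicines_and_commodities, tier: both}
  - {id: dhs_mc_04, label: Vitamin K in delivery room, domain: medicines_and_commodities, tier: both}
  - {id: dhs_mc_05, label: Chlorhexidine for cord care, domain: medicines_and_commodities, tier: both}
  - {id: dhs_gt_01, label: Guidelines for integrated management of pregnancy and childbirth, domain: guidelines_training_supervision, tier: both}
  - {id: dhs_gt_02, label: Staff trained in neonatal resuscitation in last 2 years, domain: guidelines_training_supervision, tier: both}
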