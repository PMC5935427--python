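# Versioned classification rules: ICD-10 chapter ranges, chapter-coarse GBD
# broad-cause grouping, and single-year age bins for the children scope.
# Codes R95-R99 are split out of the symptoms chapter as 'Death'.
version: 1
icd_chapter_ranges:
- start: A00
  end: B99
  label: Infectious diseases and parasitic diseases
- start: C00
  end: D48
  label: Tumor
- start: D50
  end: D89
  label: Blood diseases
- start: E00
  end: E90
  label: Endocrine, nutritional and metabolic disease
- start: F00
  end: F99
  label: Mental and behavior disorders
- start: G00
  end: G99
  label: Nervous system diseases
- start: H00
  end: H59
  label: Eye diseases
- start: H60
  end: H95
  label: Ear diseases
- start: I00
  end: I99
  label: Circulatory system diseases
- start: J00
  end: J99
  label: Respiratory system diseases
- start: K00
  end: K93
  label: Digestive system diseases
- start: L00
  end: L99
  label: Skin and subcutaneous tissue disease
- start: M00
  end: M99
  label: Muscular and connective tissue diseases
- start: N00
  end: N99
  label: Urogenital system diseases
- start: O00
  end: O99
  label: Pregnancy, childbirth and puerperium diseases
- start: P00
  end: P96
  label: Perinatal diseases
- start: Q00
  end: Q99
  label: Congenital anomalies and chromosomal abnormalities
- start: R00
  end: R94
  label: Symptoms, signs, clinical and laboratory abnormalities
- start: R95
  end: R99
  label: Death
- start: S00
  end: T98
  label: Injury, poisoning and external causes
- start: V01
  end: Y98
  label: Injury, poisoning and external causes
- start: Z00
  end: Z99
  label: Factors influencing health status
gbd_group_map:
  Infectious diseases and parasitic diseases: group_I_communicable_maternal_perinatal_nutritional
  Tumor: group_II_noncommunicable
  Blood diseases: group_II_noncommunicable
  Endocrine, nutritional and metabolic disease: group_II_noncommunicable
  Mental and behavior disorders: group_II_noncommunicable
  Nervous system diseases: group_II_noncommunicable
  Eye diseases: group_II_noncommunicable
  Ear diseases: group_II_noncommunicable
  Circulatory system diseases: group_II_noncommunicable
  Respiratory system diseases: group_II_noncommunicable
  Digestive system diseases: group_II_noncommunicable
  Skin and subcutaneous tissue disease: group_II_noncommunicable
  Muscular and connective tissue diseases: group_II_noncommunicable
  Urogenital system diseases: group_II_noncommunicable
  Pregnancy, childbirth and puerperium diseases: group_I_communicable_maternal_perinatal_nutritional
  Perinatal diseases: group_I_communicable_maternal_perinatal_nutritional
  Congenital anomalies and chromosomal abnormalities: group_II_noncommunicable
  Symptoms, signs, clinical and laboratory abnormalities: group_II_noncommunicable
  Death: group_II_noncommunicable
  Injury, poisoning and external causes: group_III_injury
  Factors influencing health status: group_II_noncommunicable
age_bins:
- lower: 0
  upper: 1
  label: 0-1
- lower: 1
  upper: 2
  label: 1-2
- lower: 2
  upper: 3
  label: 2-3
- lower: 3
  upper: 4
  label: 3-4
- lower: 4
  upper: 5
  label: 4-5
- lower: 5
  upper: 6
  label: 5-6
- lower: 6
  upper: 7
  label: 6-7
- lower: 7
  upper: 8
  label: 7-8
- lower: 8
  upper: 9
  label: 8-9
- lower: 9
  upper: 10
  label: 9-10
- lower: 10
  upper: 11
  label: 10-11
- lower: 11
  upper: 12
  label: 11-12
- lower: 12
  upper: 13
  label: 12-13
- lower: 13
  upper: 14
  label: 13-14
children_age_max: 14
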