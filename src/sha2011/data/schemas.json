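{
  "encounters.csv": {
    "format": "CSV, UTF-8, header row, one service contact per row",
    "columns": {
      "institution_id": "string id joining to institutions.csv",
      "age_years": "integer 0-120",
      "sex": "optional category (F/M)",
      "icd10_code": "ICD-10 code (letter + 2 digits, optional decimal part); may be blank",
      "service_type": [
        "outpatient_curative",
        "outpatient_preventive",
        "inpatient",
        "public_health"
      ],
      "bed_days": "non-negative integer; >0 only for inpatient",
      "total_cost": "non-negative money, CNY",
      "social_insurance": "non-negative money, CNY; payer components sum to total_cost",
      "commercial_insurance": "non-negative money, CNY; payer components sum to total_cost",
      "donation": "non-negative money, CNY; payer components sum to total_cost",
      "government_program": "non-negative money, CNY; payer components sum to total_cost",
      "out_of_pocket": "non-negative money, CNY; payer components sum to total_cost"
    }
  },
  "institutions.csv": {
    "format": "CSV, UTF-8, header row, one institution per row",
    "columns": {
      "institution_id": "string id",
      "provider_type": [
        "provincial_hospital",
        "general_hospital",
        "specialized_hospital",
        "tcm_hospital",
        "maternal_child_center",
        "outpatient_service_institution",
        "township_hospital",
        "community_health_center",
        "village_or_individual_clinic",
        "public_health_institution"
      ],
      "outpatient_income": "non-negative money, CNY",
      "preventive_outpatient_income": "non-negative money, CNY",
      "inpatient_income": "non-negative money, CNY",
      "basic_subsidy": "non-negative money, CNY",
      "outpatient_project_subsidy": "non-negative money, CNY",
      "inpatient_project_subsidy": "non-negative money, CNY",
      "superior_institution_subsidy": "non-negative money, CNY",
      "science_education_income": "non-negative money, CNY",
      "other_income": "non-negative money, CNY",
      "assistant_service_cost": "non-negative money, CNY",
      "medicine_cost": "non-negative money, CNY",
      "management_cost": "non-negative money, CNY",
      "capital_expenditure": "non-negative money, CNY",
      "prevention_projects": "JSON list of [project_id, income, expense] triples"
    }
  },
  "provincial.yaml": {
    "format": "YAML mapping",
    "keys": {
      "year": "integer",
      "exchange_rate_cny_per_usd": "positive real; defaults to 6.20 if absent",
      "strata": {
        "<provider_type>": {
          "outpatient_income": "non-negative number",
          "inpatient_income": "non-negative number",
          "outpatient_visits": "non-negative number",
          "inpatient_bed_days": "non-negative number",
          "basic_subsidy": "non-negative number",
          "outpatient_project_subsidy": "non-negative number",
          "inpatient_project_subsidy": "non-negative number"
        }
      }
    }
  }
}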