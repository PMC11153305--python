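{
  "_comment": "Default glucose-lowering drug table for medication effect scoring. max_daily_dose is the maximum recommended monotherapy dose; adjustment_factor is the expected maximal HbA1c reduction (percentage points) at that dose. Values are conventional figures from the clinical literature on medication effect scoring and Dutch type 2 diabetes prescribing, not trial-specific constants: override with your own table for formal analyses.",
  "drugs": [
    {"name": "metformin", "drug_class": "biguanide", "max_daily_dose": 3000, "dose_unit": "mg/day", "adjustment_factor": 1.5},
    {"name": "gliclazide", "drug_class": "sulfonylurea", "max_daily_dose": 240, "dose_unit": "mg/day", "adjustment_factor": 1.5},
    {"name": "glimepiride", "drug_class": "sulfonylurea", "max_daily_dose": 6, "dose_unit": "mg/day", "adjustment_factor": 1.5},
    {"name": "sitagliptin", "drug_class": "DPP4 inhibitor", "max_daily_dose": 100, "dose_unit": "mg/day", "adjustment_factor": 0.75},
    {"name": "liraglutide", "drug_class": "GLP-1 agonist", "max_daily_dose": 1.8, "dose_unit": "mg/day", "adjustment_factor": 1.0},
    {"name": "insulin", "drug_class": "insulin", "max_daily_dose": 100, "dose_unit": "IU/day", "adjustment_factor": 2.5}
  ]
}
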