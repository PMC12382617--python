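{
 "description": "Fitted dose-response coefficients for seven antibiotics and their degradation products under 1 MeV e-beam irradiation. Rates are per kGy; C0 on the relative scale where the unirradiated parent is 100. Product analytes are labeled by accurate mass [M+H]+.",
 "analytes": [
  {"analyte": "tetracycline", "role": "antibiotic", "C0": 100, "alpha": 1.28, "mz": 445.1592, "rt_min": 6.68},
  {"analyte": "doxycycline", "role": "antibiotic", "C0": 100, "alpha": 0.56, "mz": 445.1594, "rt_min": 7.70},
  {"analyte": "ampicillin", "role": "antibiotic", "C0": 100, "alpha": 2.38, "mz": 350.1163, "rt_min": 6.00},
  {"analyte": "amoxicillin", "role": "antibiotic", "C0": 100, "alpha": 2.18, "mz": 366.1110, "rt_min": 4.45},
  {"analyte": "benzylpenicillin", "role": "antibiotic", "C0": 100, "alpha": 2.51, "mz": 335.1056, "rt_min": 9.62},
  {"analyte": "streptomycin", "role": "antibiotic", "C0": 100, "alpha": 1.02, "mz": 582.2725, "rt_min": 0.86},
  {"analyte": "chloramphenicol", "role": "antibiotic", "C0": 100, "alpha": 1.49, "mz": 321.0050, "rt_min": 8.73},
  {"analyte": "461.1549", "role": "product", "parent": "tetracycline", "beta": 0.65, "D0": 0.98, "k": 0.14, "mz": 461.1549, "rt_min": 6.51},
  {"analyte": "400.1024", "role": "product", "parent": "tetracycline", "beta": 1.44, "D0": 0.09, "k": 0.10, "mz": 400.1024, "rt_min": 9.33},
  {"analyte": "384.1074", "role": "product", "parent": "tetracycline", "beta": 1.20, "D0": 0.09, "k": 0.07, "mz": 384.1074, "rt_min": 9.68},
  {"analyte": "416.1334", "role": "product", "parent": "tetracycline", "beta": 0.98, "D0": 0.53, "k": 0.09, "mz": 416.1334, "rt_min": 7.74},
  {"analyte": "437.1205", "role": "product", "parent": "tetracycline", "beta": 0.10, "D0": 1.04, "k": 0.015, "mz": 437.1205, "rt_min": 7.92},
  {"analyte": "366.1111", "role": "product", "parent": "ampicillin", "beta": 3.38, "D0": 2.33, "k": 0.12, "mz": 366.1111, "rt_min": 5.12},
  {"analyte": "368.1274", "role": "product", "parent": "ampicillin", "beta": 32.12, "D0": 0.07, "k": 0.28, "mz": 368.1274, "rt_min": 5.60},
  {"analyte": "365.0801", "role": "product", "parent": "amoxicillin", "beta": 3.29, "D0": 6.01, "k": 0.72, "mz": 365.0801, "rt_min": 2.81},
  {"analyte": "382.1066", "role": "product", "parent": "amoxicillin", "beta": 3.34, "D0": 3.08, "k": 0.76, "mz": 382.1066, "rt_min": 1.97},
  {"analyte": "351.1007", "role": "product", "parent": "benzylpenicillin", "beta": 4.97, "D0": 3.86, "k": 0.54, "mz": 351.1007, "rt_min": 8.16},
  {"analyte": "353.1168", "role": "product", "parent": "benzylpenicillin", "beta": 22.77, "D0": 0.0022, "k": 1.60, "mz": 353.1168, "rt_min": 7.83},
  {"analyte": "302.1233", "role": "product", "parent": "streptomycin", "beta": 1.12, "D0": 2.39, "k": 0.96, "mz": 302.1233, "rt_min": 1.31},
  {"analyte": "290.1232", "role": "product", "parent": "streptomycin", "beta": 3.28, "D0": 0.05, "k": 0.74, "mz": 290.1232, "rt_min": 1.82},
  {"analyte": "288.1077", "role": "product", "parent": "streptomycin", "beta": 0.68, "D0": 0.05, "k": 0.38, "mz": 288.1077, "rt_min": 3.07}
 ]
}
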