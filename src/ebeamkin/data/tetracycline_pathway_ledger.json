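{
 "description": "Catalogue of e-beam degradation products, DFT-derived C-H bond-dissociation energies for tetracycline, and transformation pathways with ionization-event counts. Energies are bundled data from quantum-chemical calculations (PBE/L1), never recomputed here.",
 "species": [
  {"name": "DP-TC-460", "formula": "C22H25N2O9", "mz": 461.1549, "rt_min": [6.51, 7.31], "table_dose_kGy": 1, "text_dose_kGy": 1, "parent": "tetracycline"},
  {"name": "DP-TC-399", "formula": "C20H18NO8", "mz": 400.1024, "rt_min": [9.33], "table_dose_kGy": 1, "text_dose_kGy": 1, "parent": "tetracycline"},
  {"name": "DP-TC-383", "formula": "C20H18NO7", "mz": 384.1074, "rt_min": [9.68], "table_dose_kGy": 1, "text_dose_kGy": 1, "parent": "tetracycline"},
  {"name": "DP-TC-415", "formula": "C21H22NO8", "mz": 416.1334, "rt_min": [7.74], "table_dose_kGy": 1, "text_dose_kGy": 3, "parent": "tetracycline"},
  {"name": "DP-TC-436", "formula": "C19H21N2O10", "mz": 437.1205, "rt_min": [7.92], "table_dose_kGy": 3, "text_dose_kGy": 3, "parent": "tetracycline"},
  {"name": "DP-AMO-364", "formula": "C16H17N2SO6", "mz": 365.0801, "rt_min": [2.81], "table_dose_kGy": 0.1, "text_dose_kGy": 0.1, "parent": "amoxicillin"},
  {"name": "DP-AMO-381", "formula": "C16H20N3SO6", "mz": 382.1066, "rt_min": [1.97], "table_dose_kGy": 0.1, "text_dose_kGy": 0.1, "parent": "amoxicillin"},
  {"name": "DP-AMP-365", "formula": "C16H20N3SO5", "mz": 366.1111, "rt_min": [5.12], "table_dose_kGy": 0.1, "text_dose_kGy": 0.1, "parent": "ampicillin"},
  {"name": "DP-AMP-367", "formula": "C16H22N3SO5", "mz": 368.1274, "rt_min": [5.60], "table_dose_kGy": 0.1, "text_dose_kGy": 0.1, "parent": "ampicillin"},
  {"name": "DP-PENG-350", "formula": "C16H19N2SO5", "mz": 351.1007, "rt_min": [8.16, 8.40, 8.83], "table_dose_kGy": 0.1, "text_dose_kGy": 0.1, "parent": "benzylpenicillin"},
  {"name": "DP-PENG-352", "formula": "C16H21N2SO5", "mz": 353.1168, "rt_min": [7.83], "table_dose_kGy": 0.1, "text_dose_kGy": 0.1, "parent": "benzylpenicillin"},
  {"name": "DP-PENG-308", "formula": "C15H21N2SO3", "mz": 309.1276, "rt_min": [7.83], "table_dose_kGy": 0.1, "text_dose_kGy": 0.1, "parent": "benzylpenicillin"},
  {"name": "DP-STR-301", "formula": "C13H20O7N", "mz": 302.1233, "rt_min": [1.31], "table_dose_kGy": 0.1, "text_dose_kGy": 0.1, "parent": "streptomycin"},
  {"name": "DP-STR-289", "formula": "C12H20O7N", "mz": 290.1232, "rt_min": [1.82], "table_dose_kGy": 0.1, "text_dose_kGy": 0.1, "parent": "streptomycin"},
  {"name": "DP-STR-287", "formula": "C12H18O7N", "mz": 288.1077, "rt_min": [3.07], "table_dose_kGy": 0.1, "text_dose_kGy": 0.1, "parent": "streptomycin"}
 ],
 "bde_table": {
  "description": "C-H bond-dissociation energies of tetracycline per carbon position: total energy change dE and Gibbs energy change dG, kcal/mol, for TC -> Radical(Cn). + H.",
  "positions": {
   "C4":  {"dE": 113.5, "dG": 105.4},
   "C5":  {"dE": 115.2, "dG": 105.8},
   "C6":  {"dE": 115.5, "dG": 106.6},
   "C9":  {"dE": 77.5,  "dG": 69.4},
   "C14": {"dE": 94.7,  "dG": 85.2},
   "C15": {"dE": 99.7,  "dG": 90.9},
   "C19": {"dE": 74.8,  "dG": 66.8}
  }
 },
 "narrative_energies_kcal_mol": {
  "c19_vs_c5_dG_gap": 39.0,
  "c19_vs_c5_dE_gap": 40.4,
  "dp_tc_460_c19_isomer_penalty_vs_c5": 6.3,
  "dp_tc_399_deaminomethylation": 38.4,
  "dp_tc_399_h_dissociation": 37.8,
  "dp_tc_383_total_energy_gain": 72.8,
  "dp_tc_415_energy_decrease": 22.2,
  "dp_tc_436_energy_decrease": 68.3
 },
 "pathways": [
  {
   "product": "DP-TC-460",
   "parent": "tetracycline",
   "uncertain": false,
   "total_energy_change_kcal_mol": null,
   "steps": [
    {"reaction": "H-elimination", "site": "C19", "delta_e_kcal_mol": 74.8, "direct_ionizations": 1, "indirect_ionizations": 0, "note": "direct ionization breaks the C19-H bond (lowest BDE position)"},
    {"reaction": "hydroxylation", "site": "C19", "delta_e_kcal_mol": null, "direct_ionizations": 0, "indirect_ionizations": 1, "note": "OH radical from water radiolysis adds to the primary radical"}
   ]
  },
  {
   "product": "DP-TC-399",
   "parent": "tetracycline",
   "uncertain": false,
   "total_energy_change_kcal_mol": null,
   "steps": [
    {"reaction": "deaminomethylation", "site": "C19", "delta_e_kcal_mol": 38.4, "direct_ionizations": 1, "indirect_ionizations": 0, "note": "loss of the dimethylamine group from C19"},
    {"reaction": "H-elimination", "site": null, "delta_e_kcal_mol": 37.8, "direct_ionizations": 1, "indirect_ionizations": 0, "note": "dissociation of a hydrogen radical"}
   ]
  },
  {
   "product": "DP-TC-383",
   "parent": "tetracycline",
   "uncertain": true,
   "total_energy_change_kcal_mol": -72.8,
   "steps": [
    {"reaction": "dehydroxylation", "site": "C18", "delta_e_kcal_mol": null, "direct_ionizations": 1, "indirect_ionizations": 0, "note": "formed from DP-TC-399: hydroxyl elimination, presumably at C18"},
    {"reaction": "H-addition", "site": "C18", "delta_e_kcal_mol": null, "direct_ionizations": 0, "indirect_ionizations": 1, "note": "hydrogen radical addition"},
    {"reaction": "deaminomethylation", "site": "C19", "delta_e_kcal_mol": null, "direct_ionizations": 1, "indirect_ionizations": 0, "note": "dimethylamino group eliminated from C19"},
    {"reaction": "H-elimination", "site": "C14", "delta_e_kcal_mol": null, "direct_ionizations": 1, "indirect_ionizations": 0, "note": "hydrogen radical eliminated from C14; step order/attribution uncertain"}
   ]
  },
  {
   "product": "DP-TC-415",
   "parent": "tetracycline",
   "uncertain": true,
   "total_energy_change_kcal_mol": -22.2,
   "steps": [
    {"reaction": "demethylation", "site": "N(CH3)2", "delta_e_kcal_mol": null, "direct_ionizations": 1, "indirect_ionizations": 0, "note": "one methyl radical eliminated from the dimethylamino nitrogen"},
    {"reaction": "deamination", "site": "C22", "delta_e_kcal_mol": null, "direct_ionizations": 1, "indirect_ionizations": 0, "note": "amino group eliminated from C22"},
    {"reaction": "H-elimination", "site": null, "delta_e_kcal_mol": null, "direct_ionizations": 1, "indirect_ionizations": 0, "note": "third direct event implied by the stated count; attribution uncertain"},
    {"reaction": "H-addition", "site": null, "delta_e_kcal_mol": null, "direct_ionizations": 0, "indirect_ionizations": 1, "note": "indirect ionization by hydrogen radical"}
   ]
  },
  {
   "product": "DP-TC-436",
   "parent": "tetracycline",
   "uncertain": false,
   "total_energy_change_kcal_mol": -68.3,
   "steps": [
    {"reaction": "hydroxylation", "site": "C8", "delta_e_kcal_mol": null, "direct_ionizations": 0, "indirect_ionizations": 1, "note": "OH radical addition"},
    {"reaction": "hydroxylation", "site": "C9", "delta_e_kcal_mol": null, "direct_ionizations": 0, "indirect_ionizations": 1, "note": "OH radical addition"},
    {"reaction": "deaminomethylation", "site": "C19", "delta_e_kcal_mol": null, "direct_ionizations": 1, "indirect_ionizations": 0, "note": "dimethylamino group eliminated"},
    {"reaction": "amination", "site": "C19", "delta_e_kcal_mol": null, "direct_ionizations": 0, "indirect_ionizations": 1, "note": "amino radical addition"},
    {"reaction": "methyl-elimination", "site": "C10", "delta_e_kcal_mol": null, "direct_ionizations": 1, "indirect_ionizations": 0, "note": "methyl radical eliminated"}
   ]
  }
 ]
}
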