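{
  "acetate_exchange_id": "EX_ac",
  "biomass_id": "biomass",
  "crowding_budget": 1.0,
  "metabolites": [
    {
      "carbon_atoms": 3,
      "id": "pyr",
      "is_external": false,
      "molar_mass": null,
      "name": "pyruvate"
    },
    {
      "carbon_atoms": 0,
      "id": "atp",
      "is_external": false,
      "molar_mass": null,
      "name": "ATP"
    },
    {
      "carbon_atoms": 2,
      "id": "ac",
      "is_external": false,
      "molar_mass": null,
      "name": "acetate (intracellular)"
    },
    {
      "carbon_atoms": 1,
      "id": "co2",
      "is_external": false,
      "molar_mass": null,
      "name": "CO2 (intracellular)"
    },
    {
      "carbon_atoms": 2,
      "id": "ac_e",
      "is_external": true,
      "molar_mass": 60.05,
      "name": "acetate (medium)"
    },
    {
      "carbon_atoms": 1,
      "id": "co2_e",
      "is_external": true,
      "molar_mass": 44.01,
      "name": "CO2 (offgas)"
    },
    {
      "carbon_atoms": 6,
      "id": "glu_e",
      "is_external": true,
      "molar_mass": 180.16,
      "name": "glucose (medium)"
    },
    {
      "carbon_atoms": 6,
      "id": "glu_c",
      "is_external": false,
      "molar_mass": null,
      "name": "glucose (cytoplasm)"
    },
    {
      "carbon_atoms": 12,
      "id": "mal_e",
      "is_external": true,
      "molar_mass": 342.3,
      "name": "maltose (medium)"
    },
    {
      "carbon_atoms": 12,
      "id": "mal_c",
      "is_external": false,
      "molar_mass": null,
      "name": "maltose (cytoplasm)"
    },
    {
      "carbon_atoms": 6,
      "id": "gal_e",
      "is_external": true,
      "molar_mass": 180.16,
      "name": "galactose (medium)"
    },
    {
      "carbon_atoms": 6,
      "id": "gal_c",
      "is_external": false,
      "molar_mass": null,
      "name": "galactose (cytoplasm)"
    },
    {
      "carbon_atoms": 3,
      "id": "lac_e",
      "is_external": true,
      "molar_mass": 90.08,
      "name": "lactate (medium)"
    },
    {
      "carbon_atoms": 3,
      "id": "lac_c",
      "is_external": false,
      "molar_mass": null,
      "name": "lactate (cytoplasm)"
    },
    {
      "carbon_atoms": 3,
      "id": "gly_e",
      "is_external": true,
      "molar_mass": 92.09,
      "name": "glycerol (medium)"
    },
    {
      "carbon_atoms": 3,
      "id": "gly_c",
      "is_external": false,
      "molar_mass": null,
      "name": "glycerol (cytoplasm)"
    }
  ],
  "name": "ccr-reduced-fixture",
  "reactions": [
    {
      "crowding_coefficient": 0.0,
      "id": "EX_glu",
      "kind": "exchange",
      "lower_bound": 0.0,
      "stoichiometry": {
        "glu_c": 1.0,
        "glu_e": -1.0
      },
      "upper_bound": 12.0
    },
    {
      "crowding_coefficient": 0.02,
      "id": "cat_glu",
      "kind": "internal",
      "lower_bound": 0.0,
      "stoichiometry": {
        "atp": 2.0,
        "glu_c": -1.0,
        "pyr": 2.0
      },
      "upper_bound": "inf"
    },
    {
      "crowding_coefficient": 0.0,
      "id": "EX_mal",
      "kind": "exchange",
      "lower_bound": 0.0,
      "stoichiometry": {
        "mal_c": 1.0,
        "mal_e": -1.0
      },
      "upper_bound": 5.0
    },
    {
      "crowding_coefficient": 0.03,
      "id": "cat_mal",
      "kind": "internal",
      "lower_bound": 0.0,
      "stoichiometry": {
        "atp": 3.0,
        "mal_c": -1.0,
        "pyr": 4.0
      },
      "upper_bound": "inf"
    },
    {
      "crowding_coefficient": 0.0,
      "id": "EX_gal",
      "kind": "exchange",
      "lower_bound": 0.0,
      "stoichiometry": {
        "gal_c": 1.0,
        "gal_e": -1.0
      },
      "upper_bound": 10.0
    },
    {
      "crowding_coefficient": 0.12,
      "id": "cat_gal",
      "kind": "internal",
      "lower_bound": 0.0,
      "stoichiometry": {
        "atp": 2.0,
        "gal_c": -1.0,
        "pyr": 2.0
      },
      "upper_bound": "inf"
    },
    {
      "crowding_coefficient": 0.0,
      "id": "EX_lac",
      "kind": "exchange",
      "lower_bound": 0.0,
      "stoichiometry": {
        "lac_c": 1.0,
        "lac_e": -1.0
      },
      "upper_bound": 20.0
    },
    {
      "crowding_coefficient": 0.1,
      "id": "cat_lac",
      "kind": "internal",
      "lower_bound": 0.0,
      "stoichiometry": {
        "atp": 0.5,
        "lac_c": -1.0,
        "pyr": 1.0
      },
      "upper_bound": "inf"
    },
    {
      "crowding_coefficient": 0.0,
      "id": "EX_gly",
      "kind": "exchange",
      "lower_bound": 0.0,
      "stoichiometry": {
        "gly_c": 1.0,
        "gly_e": -1.0
      },
      "upper_bound": 20.0
    },
    {
      "crowding_coefficient": 0.15,
      "id": "cat_gly",
      "kind": "internal",
      "lower_bound": 0.0,
      "stoichiometry": {
        "atp": 0.5,
        "gly_c": -1.0,
        "pyr": 1.0
      },
      "upper_bound": "inf"
    },
    {
      "crowding_coefficient": 1.2,
      "id": "oxphos",
      "kind": "internal",
      "lower_bound": 0.0,
      "stoichiometry": {
        "atp": 15.0,
        "co2": 3.0,
        "pyr": -1.0
      },
      "upper_bound": "inf"
    },
    {
      "crowding_coefficient": 0.03,
      "id": "ferm",
      "kind": "internal",
      "lower_bound": 0.0,
      "stoichiometry": {
        "ac": 1.0,
        "atp": 2.0,
        "co2": 1.0,
        "pyr": -1.0
      },
      "upper_bound": "inf"
    },
    {
      "crowding_coefficient": 0.7,
      "id": "ac_ox",
      "kind": "internal",
      "lower_bound": 0.0,
      "stoichiometry": {
        "ac": -1.0,
        "atp": 6.0,
        "co2": 2.0
      },
      "upper_bound": "inf"
    },
    {
      "crowding_coefficient": 0.15,
      "id": "ac_ana",
      "kind": "internal",
      "lower_bound": 0.0,
      "stoichiometry": {
        "ac": -2.0,
        "atp": -2.0,
        "co2": 1.0,
        "pyr": 1.0
      },
      "upper_bound": "inf"
    },
    {
      "crowding_coefficient": 0.25,
      "id": "biomass",
      "kind": "biomass",
      "lower_bound": 0.0,
      "stoichiometry": {
        "atp": -40.0,
        "pyr": -13.0
      },
      "upper_bound": "inf"
    },
    {
      "crowding_coefficient": 0.0,
      "id": "EX_ac",
      "kind": "exchange",
      "lower_bound": -1000.0,
      "stoichiometry": {
        "ac": -1.0,
        "ac_e": 1.0
      },
      "upper_bound": 1000.0
    },
    {
      "crowding_coefficient": 0.0,
      "id": "EX_co2",
      "kind": "exchange",
      "lower_bound": 0.0,
      "stoichiometry": {
        "co2": -1.0,
        "co2_e": 1.0
      },
      "upper_bound": "inf"
    }
  ],
  "schema_version": 1,
  "substrate_exchange_ids": {
    "galactose": "EX_gal",
    "glucose": "EX_glu",
    "glycerol": "EX_gly",
    "lactate": "EX_lac",
    "maltose": "EX_mal"
  }
}
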