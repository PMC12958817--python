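{
  "trait": "CL_IS",
  "lead_snp": "snp_2_24600000",
  "effect": {
    "marker_id": "snp_2_24600000",
    "beta_log": -0.7579502690587414,
    "se_log": 0.21208727500761085,
    "beta_psd": -0.7637153149597232,
    "se_psd": 0.21370043213063877,
    "p_value": 0.00035188357027911163,
    "maf": 0.10333333333333333
  },
  "percent_change": -53.13739995467345,
  "ld": [
    {
      "marker_a": "snp_2_24600000",
      "marker_b": "snp_2_24061164",
      "r2": 0.6350317654617983
    }
  ],
  "group_effects": {
    "per_group": {
      "0": {
        "marker_id": "snp_2_24600000",
        "beta_log": -1.7429914417004448,
        "se_log": 0.3911387305114821,
        "beta_psd": -1.7562488097318596,
        "se_psd": 0.3941137709951418,
        "p_value": 8.342617116718115e-06,
        "maf": 0.10333333333333333
      },
      "1": {
        "marker_id": "snp_2_24600000",
        "beta_log": -0.45869231662484117,
        "se_log": 0.39307729831803384,
        "beta_psd": -0.4621811764718781,
        "se_psd": 0.3960670837432063,
        "p_value": 0.24324005238778568,
        "maf": 0.10333333333333333
      },
      "2": {
        "marker_id": "snp_2_24600000",
        "beta_log": -0.9707207856667088,
        "se_log": 0.7410517379560103,
        "beta_psd": -0.9781041854949791,
        "se_psd": 0.7466882519315567,
        "p_value": 0.19022185357969323,
        "maf": 0.10333333333333333
      },
      "3": {
        "marker_id": "snp_2_24600000",
        "beta_log": -0.0812442496319128,
        "se_log": 0.5100211336528312,
        "beta_psd": -0.08186220155757207,
        "se_psd": 0.5139004056394099,
        "p_value": 0.8734357908060786,
        "maf": 0.10333333333333333
      },
      "4": {
        "marker_id": "snp_2_24600000",
        "beta_log": 0.025792667420029215,
        "se_log": 0.5760772833510521,
        "beta_psd": 0.025988849039926105,
        "se_psd": 0.5804589850491808,
        "p_value": 0.9642883028178819,
        "maf": 0.10333333333333333
      },
      "5": {
        "marker_id": "snp_2_24600000",
        "beta_log": -0.7904113162344448,
        "se_log": 0.6319517373657773,
        "beta_psd": -0.796423264121746,
        "se_psd": 0.6367584257750885,
        "p_value": 0.21102704151449203,
        "maf": 0.10333333333333333
      },
      "6": {
        "marker_id": "snp_2_24600000",
        "beta_log": -0.7133828655711214,
        "se_log": 0.47614701346027505,
        "beta_psd": -0.7188089273232978,
        "se_psd": 0.4797686354851907,
        "p_value": 0.1340707079436253,
        "maf": 0.10333333333333333
      }
    },
    "inestimable": [],
    "p_interaction": 0.07479113747738247
  }
}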