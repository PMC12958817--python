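{
  "CL_NIS": [
    {
      "window": "chr2:24",
      "egv_pct": 40.340234610830436,
      "lead_snps": [
        [
          "snp_2_24851753",
          0.46416666666666667
        ],
        [
          "snp_2_24600000",
          0.30333333333333334
        ],
        [
          "snp_2_24061164",
          0.05333333333333334
        ]
      ]
    },
    {
      "window": "chr4:3",
      "egv_pct": 8.35210645906943,
      "lead_snps": [
        [
          "snp_4_3941320",
          0.19416666666666665
        ],
        [
          "snp_4_3599949",
          0.06
        ],
        [
          "snp_4_3447511",
          0.020833333333333332
        ]
      ]
    },
    {
      "window": "chr3:24",
      "egv_pct": 6.37702489479514,
      "lead_snps": [
        [
          "snp_3_24457934",
          0.11
        ],
        [
          "snp_3_24304422",
          0.09
        ],
        [
          "snp_3_24274198",
          0.03
        ],
        [
          "snp_3_24749537",
          0.02666666666666667
        ]
      ]
    },
    {
      "window": "chr1:38",
      "egv_pct": 6.112748407358664,
      "lead_snps": [
        [
          "snp_1_38048975",
          0.17333333333333334
        ],
        [
          "snp_1_38412162",
          0.015833333333333335
        ],
        [
          "snp_1_38119991",
          0.013333333333333334
        ]
      ]
    },
    {
      "window": "chr2:25",
      "egv_pct": 3.9852051590211293,
      "lead_snps": [
        [
          "snp_2_25442334",
          0.0925
        ],
        [
          "snp_2_25162254",
          0.015833333333333335
        ],
        [
          "snp_2_25871998",
          0.013333333333333334
        ],
        [
          "snp_2_25903494",
          0.01
        ]
      ]
    },
    {
      "window": "chr5:24",
      "egv_pct": 2.12259215906554,
      "lead_snps": [
        [
          "snp_5_24028538",
          0.055
        ]
      ]
    },
    {
      "window": "chr5:23",
      "egv_pct": 2.0615632528102625,
      "lead_snps": [
        [
          "snp_5_23298059",
          0.06416666666666666
        ]
      ]
    },
    {
      "window": "chr1:3",
      "egv_pct": 1.849809626004789,
      "lead_snps": [
        [
          "snp_1_3197036",
          0.07166666666666667
        ]
      ]
    },
    {
      "window": "chr5:49",
      "egv_pct": 1.761624526511084,
      "lead_snps": [
        [
          "snp_5_49840444",
          0.05416666666666667
        ],
        [
          "snp_5_49962495",
          0.015
        ]
      ]
    },
    {
      "window": "chr4:16",
      "egv_pct": 1.411678303718798,
      "lead_snps": [
        [
          "snp_4_16032773",
          0.024166666666666666
        ],
        [
          "snp_4_16816020",
          0.023333333333333334
        ],
        [
          "snp_4_16715118",
          0.0225
        ],
        [
          "snp_4_16782481",
          0.0225
        ]
      ]
    },
    {
      "window": "chr4:42",
      "egv_pct": 1.1452849014333715,
      "lead_snps": [
        [
          "snp_4_42390147",
          0.06
        ],
        [
          "snp_4_42264413",
          0.010833333333333334
        ]
      ]
    },
    {
      "window": "chr2:3",
      "egv_pct": 1.0513903183106839,
      "lead_snps": [
        [
          "snp_2_3701634",
          0.025833333333333333
        ],
        [
          "snp_2_3759862",
          0.0225
        ]
      ]
    }
  ],
  "CL_IS": [
    {
      "window": "chr2:24",
      "egv_pct": 45.98831044442526,
      "lead_snps": [
        [
          "snp_2_24600000",
          0.5008333333333334
        ],
        [
          "snp_2_24061164",
          0.395
        ]
      ]
    },
    {
      "window": "chr4:21",
      "egv_pct": 6.477582928418545,
      "lead_snps": [
        [
          "snp_4_21522516",
          0.17583333333333334
        ],
        [
          "snp_4_21386896",
          0.07083333333333333
        ],
        [
          "snp_4_21185184",
          0.013333333333333334
        ]
      ]
    },
    {
      "window": "chr4:35",
      "egv_pct": 3.575926648261546,
      "lead_snps": [
        [
          "snp_4_35191394",
          0.14416666666666667
        ]
      ]
    },
    {
      "window": "chr4:20",
      "egv_pct": 2.6809084584448613,
      "lead_snps": [
        [
          "snp_4_20181679",
          0.1075
        ]
      ]
    },
    {
      "window": "chr2:22",
      "egv_pct": 2.2350473729447877,
      "lead_snps": [
        [
          "snp_2_22836432",
          0.06833333333333333
        ]
      ]
    },
    {
      "window": "chr2:35",
      "egv_pct": 1.7918990664147831,
      "lead_snps": [
        [
          "snp_2_35053415",
          0.07666666666666666
        ]
      ]
    },
    {
      "window": "chr1:12",
      "egv_pct": 1.544914502212968,
      "lead_snps": [
        [
          "snp_1_12943602",
          0.06416666666666666
        ]
      ]
    },
    {
      "window": "chr4:19",
      "egv_pct": 1.5438946615120022,
      "lead_snps": [
        [
          "snp_4_19870607",
          0.055
        ],
        [
          "snp_4_19028696",
          0.015
        ]
      ]
    },
    {
      "window": "chr2:2",
      "egv_pct": 1.5099257570625242,
      "lead_snps": [
        [
          "snp_2_2221514",
          0.0725
        ]
      ]
    },
    {
      "window": "chr1:7",
      "egv_pct": 1.4878604025430149,
      "lead_snps": [
        [
          "snp_1_7428558",
          0.04583333333333333
        ],
        [
          "snp_1_7067847",
          0.04083333333333333
        ]
      ]
    },
    {
      "window": "chr3:24",
      "egv_pct": 1.2920988952290564,
      "lead_snps": [
        [
          "snp_3_24304422",
          0.050833333333333335
        ],
        [
          "snp_3_24274198",
          0.013333333333333334
        ]
      ]
    },
    {
      "window": "chr2:41",
      "egv_pct": 1.2818991705890657,
      "lead_snps": [
        [
          "snp_2_41587288",
          0.05416666666666667
        ],
        [
          "snp_2_41755376",
          0.02
        ]
      ]
    },
    {
      "window": "chr4:43",
      "egv_pct": 1.1997921774169233,
      "lead_snps": [
        [
          "snp_4_43484027",
          0.05333333333333334
        ],
        [
          "snp_4_43656454",
          0.01
        ]
      ]
    }
  ]
}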