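{
  "config": {
    "ad_threshold": 0.02,
    "cv_flag_threshold": 0.2,
    "egv_call_threshold": 1.0,
    "enrichment_opts": {
      "n_genes": 200,
      "n_perm": 150,
      "n_sets": 20,
      "set_size_range": [
        5,
        30
      ]
    },
    "fdr_threshold": 0.25,
    "gwas_opts": {
      "burn_in": 300,
      "chain_length": 1500,
      "pi": 0.99,
      "thin": 2
    },
    "n_individuals": 150,
    "n_markers": 500,
    "out_dir": "example_run",
    "pip_lead_threshold": 0.01,
    "pleio_window_bp": 250000,
    "preset": "cl_bivar",
    "seed": 1,
    "stages": {
      "enrichment": true,
      "finemap": true,
      "gwas": true,
      "pleiotropy": true,
      "preprocess": true,
      "simulate": true,
      "varcomp": true
    },
    "window_bp": 1000000
  },
  "config_hash": "cc2f18a06584a2b07a21ca008dc6d4c3ae1dffecae95413306b667b6fb6c6a7f",
  "stages": {
    "enrichment": {
      "config_hash": "cc2f18a06584a2b07a21ca008dc6d4c3ae1dffecae95413306b667b6fb6c6a7f",
      "hashes": {
        "enrichment.csv": "28dd2fe2a2f107023019fe4c1ddccf58f3642787acceac55502acf99d75acdfe",
        "enrichment_is.csv": "b470cdb7d7bf2eb1e2ede91d920e84a81aa8629ef9578a42261f143a565caef7",
        "enrichment_nis.csv": "a024634b27713bd1942ec6634a8505b855df93c5b0e01faffbe20deae4a74a03",
        "gene_sets.gmt": "496a435a5db6877939675fbaced5643ca55299f6156c614657e513e00c288ef0"
      },
      "outputs": [
        "example_run/enrichment.csv",
        "example_run/enrichment_is.csv",
        "example_run/enrichment_nis.csv",
        "example_run/gene_sets.gmt"
      ],
      "seed": 7,
      "status": "completed",
      "wall_seconds": 1.88
    },
    "finemap": {
      "config_hash": "cc2f18a06584a2b07a21ca008dc6d4c3ae1dffecae95413306b667b6fb6c6a7f",
      "hashes": {
        "finemap.json": "d2136464ee62689e6231c1d91abdb637cc4b54c04fb03452f5e10c8d889b174f"
      },
      "outputs": [
        "example_run/finemap.json"
      ],
      "seed": 6,
      "status": "completed",
      "wall_seconds": 1.441
    },
    "gwas": {
      "config_hash": "cc2f18a06584a2b07a21ca008dc6d4c3ae1dffecae95413306b667b6fb6c6a7f",
      "hashes": {
        "baseline_adjustment.json": "64ca1bae42dcbe80b1c9bca41d4a00ad690b4e60dd8cffa27dc7a3892cf2c144",
        "gwas_snps_CL_IS.csv": "c3a758703602d6fc2ec35c5272a8279a59c373a1df3edb1d4ff6f5644285943c",
        "gwas_snps_CL_NIS.csv": "a38e13103994e65a6fb47de64038c62e0c819dcc5fd086b1afd577ddfbcc4a76",
        "gwas_windows_CL_IS.csv": "0e61c1888db819c257adb399b0a580fcbf8afc313cf942040042070729b79799",
        "gwas_windows_CL_IS_adjusted.csv": "3e72e7155f7fc63bbea059e2073dc68ba0257742ede52b73bb2b44d764469bcc",
        "gwas_windows_CL_NIS.csv": "16b350a16217113d246ad8a950b327f7672935334e0e6df558a602471cffbfaa",
        "qtl_calls.json": "e3bd7915cef034d4b2b69ff36251c52846d6210deaecf2279b8c4f9ea0f3f2f4"
      },
      "outputs": [
        "example_run/gwas_snps_CL_NIS.csv",
        "example_run/gwas_windows_CL_NIS.csv",
        "example_run/gwas_snps_CL_IS.csv",
        "example_run/gwas_windows_CL_IS.csv",
        "example_run/gwas_windows_CL_IS_adjusted.csv",
        "example_run/baseline_adjustment.json",
        "example_run/qtl_calls.json"
      ],
      "seed": 4,
      "status": "completed",
      "wall_seconds": 6.726
    },
    "pleiotropy": {
      "config_hash": "cc2f18a06584a2b07a21ca008dc6d4c3ae1dffecae95413306b667b6fb6c6a7f",
      "hashes": {
        "pleiotropy.csv": "4bb4eeaa091a9459568a6ee32235ab3ab023e8bddc1b6f02807e70febf2df009"
      },
      "outputs": [
        "example_run/pleiotropy.csv"
      ],
      "seed": 5,
      "status": "completed",
      "wall_seconds": 3.843
    },
    "preprocess": {
      "config_hash": "cc2f18a06584a2b07a21ca008dc6d4c3ae1dffecae95413306b667b6fb6c6a7f",
      "hashes": {
        "traits.csv": "798113907968a52a0ee702c75199a98327df9cfcfea080c2b5e7bc7774282d17"
      },
      "outputs": [
        "example_run/traits.csv"
      ],
      "seed": 2,
      "status": "completed",
      "wall_seconds": 0.004
    },
    "simulate": {
      "config_hash": "cc2f18a06584a2b07a21ca008dc6d4c3ae1dffecae95413306b667b6fb6c6a7f",
      "hashes": {
        "genotypes.bed": "2fbc8bb898e4da5e99d922089b2de9b48d93439dff6a4776e80d2b3ae46d05c0",
        "genotypes.bim": "f74902079945030c35624ccc50fa553cbcf4ad9d8f18dc39230c202b01c46b48",
        "genotypes.fam": "fcb4e0f52d3a35c03e00b14f04e662ae5538dc55116168dbedc77c1369da80b7",
        "phenotypes.csv": "a6a8397ab75955d6e18287a1776dfaad24d280778f9c24c83d57af2b78f17a5f",
        "truth.json": "bb995c658263f9367d3dcacbe23f6bd4f08a85412eb3f7df0b24888e5b0614e6"
      },
      "outputs": [
        "example_run/genotypes.bed",
        "example_run/genotypes.bim",
        "example_run/genotypes.fam",
        "example_run/phenotypes.csv",
        "example_run/truth.json"
      ],
      "seed": 1,
      "status": "completed",
      "wall_seconds": 0.024
    },
    "varcomp": {
      "config_hash": "cc2f18a06584a2b07a21ca008dc6d4c3ae1dffecae95413306b667b6fb6c6a7f",
      "hashes": {
        "varcomp_bivariate.csv": "1f2d9308736b08403a1f639b6cf6a98d2038233b53f2d319262c61514f3341c1",
        "varcomp_univariate.csv": "dc4ab5e1180a9dc37ed721243ba9667abf8b6cb6669feb5283ace0e1590ef64b"
      },
      "outputs": [
        "example_run/varcomp_univariate.csv",
        "example_run/varcomp_bivariate.csv"
      ],
      "seed": 3,
      "status": "completed",
      "wall_seconds": 6.679
    }
  },
  "versions": {
    "numpy": "2.4.6",
    "pandas": "2.3.3"
  }
}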