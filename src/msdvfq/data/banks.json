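{
 "format": "msdvfq packaged data manifest v1",
 "checksums": {
  "items_25c.csv": "1c19863318ce431839f6662c1fc4982350bcd8d4eb9e4837e77346dea7372b78",
  "thresholds_25c.csv": "ff5dd8677fe9a6986dc7c2dde5f340b6ee07576f868c112f62bfec8fd131fb77",
  "items_vf.csv": "3c5bac9fef3a40ab22ebb0c24f8ca54b0b36f7ff29d0698ed054befe25c5cd8b",
  "thresholds_vf.csv": "72d8824949bac8bb7a352b64fb07234bad6488a5ca4477699a1b7e1e084ca0cc",
  "items_se.csv": "068f716b68769763223eed4eb973966dcd82c5fe3735516bc3d96895577fe208",
  "thresholds_se.csv": "15d70dd42342025092d5ac7f6dd941ed38b98db0a3183c33d9270158e8452b68",
  "recode_tables.json": "3768d973a30b1afad0d7c0356e1d98c1cb12f5e80bc3fe313c950cb03216a60a",
  "subscales.json": "f320e1cbf37d4b0d08ce0e3d0d01f7c6768119f3d35ca5325d8496c5171f3e79"
 }
}
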