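{
  "D6M": {
    "comment": "Lys with the side-chain amine acylated by N-hexadecanoyl-L-glutamic acid: the amine is not basic; the appended glutamate contributes an acidic carboxylate.",
    "basic_groups": [],
    "acidic_groups": [
      {"tag": "glu-carboxylate", "atoms": ["OE1", "OE2"], "pka_key": "GLU"}
    ]
  }
}
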