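[
  {
    "identity": {
      "gene": "PTPN11", "transcript": "NM_002834.5",
      "hgvs_c": "c.922A>G", "hgvs_p": "p.(Asn308Asp)",
      "consequence": "missense", "residue_position": 308,
      "ref_aa": "N", "alt_aa": "D"
    },
    "probands": [
      {"phenotype_category": "consistent", "de_novo": "confirmed"},
      {"phenotype_category": "consistent", "de_novo": "assumed"},
      {"phenotype_category": "consistent", "de_novo": "assumed"}
    ],
    "population": {"grpmax_faf": 0.0},
    "computational": {"revel": 0.94}
  }
]
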