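# Default RASopathy knowledge base.
#
# PROVISIONAL curated defaults, marked per entry.  Domain coordinates for
# the RAS-family genes follow the canonical G-domain motifs (P-Loop,
# switch 1, switch 2, SAK) with paralog numbering offsets; MRAS, RIT1 and
# RRAS2 lack the SAK motif.  Hotspot residue lists are a non-exhaustive
# starting set drawn from well-known recurrent RASopathy substitutions; a
# deploying laboratory should replace both with its own curated
# coordinates.  No hotspots are defined for LZTR1, PPP1CB, MAP2K1, MAP2K2,
# RAF1 or SHOC2, and no PM1 domains for SOS1/SOS2, LZTR1 or PPP1CB.
#
# Frequency thresholds (Grpmax filtering allele frequency): BA1 >= 0.0005,
# BS1 >= 0.00025 for every gene; PM2_Supporting below 0.000025 (0.0025%).
#
# Alignments are synthetic offset alignments (see files); the assay
# registry lists approved functional assays, with a mechanism mapping for
# the dual-mechanism gene LZTR1.

alignments:
  RAS: alignments/ras_family.synthetic.fasta
  RAF: alignments/raf_family.synthetic.fasta
  MAP2K: alignments/map2k_family.synthetic.fasta
  SOS: alignments/sos_family.synthetic.fasta

genes:
  - gene: PTPN11
    validity_tier: Definitive
    inheritance_modes: [AD]
    pp2_applicable: true
    pm1_domains: []
    pm5_strong_hotspots: [61, 63, 72, 76, 279, 308]
    provisional: true
    approved_assays:
      - {assay_id: phosphatase_activity, description: "in vitro phosphatase activity"}
      - {assay_id: erk_activation, description: "ERK phosphorylation in cells"}
    paralog_family: none

  - gene: BRAF
    validity_tier: Definitive
    inheritance_modes: [AD]
    pp2_applicable: true
    pm1_domains: []
    pm5_strong_hotspots: [257, 499]
    provisional: true
    approved_assays:
      - {assay_id: kinase_activity, description: "in vitro kinase activity"}
      - {assay_id: erk_activation, description: "ERK phosphorylation in cells"}
    paralog_family: RAF

  - gene: RAF1
    validity_tier: Definitive
    inheritance_modes: [AD]
    pm1_domains: []
    pm5_strong_hotspots: []
    approved_assays:
      - {assay_id: kinase_activity, description: "in vitro kinase activity"}
      - {assay_id: erk_activation, description: "ERK phosphorylation in cells"}
    paralog_family: RAF

  - gene: SOS1
    validity_tier: Definitive
    inheritance_modes: [AD]
    pm1_domains: []
    pm5_strong_hotspots: [552]
    provisional: true
    approved_assays:
      - {assay_id: erk_activation, description: "ERK phosphorylation in cells"}
      - {assay_id: ras_gef_activity, description: "nucleotide exchange activity"}
    paralog_family: SOS

  - gene: SOS2
    validity_tier: Definitive
    inheritance_modes: [AD]
    pm1_domains: []
    pm5_strong_hotspots: []
    approved_assays:
      - {assay_id: erk_activation, description: "ERK phosphorylation in cells"}
      - {assay_id: ras_gef_activity, description: "nucleotide exchange activity"}
    paralog_family: SOS

  - gene: KRAS
    validity_tier: Definitive
    inheritance_modes: [AD]
    pm1_domains:
      - {name: P-Loop, start: 10, end: 17}
      - {name: SW1, start: 28, end: 38}
      - {name: SW2, start: 57, end: 76}
      - {name: SAK, start: 145, end: 147}
    provisional: true
    pm5_strong_hotspots: []
    approved_assays:
      - {assay_id: gtpase_activity, description: "intrinsic/stimulated GTP hydrolysis"}
      - {assay_id: erk_activation, description: "ERK phosphorylation in cells"}
    paralog_family: RAS

  - gene: HRAS
    validity_tier: Definitive
    inheritance_modes: [AD]
    pm1_domains:
      - {name: P-Loop, start: 10, end: 17}
      - {name: SW1, start: 28, end: 38}
      - {name: SW2, start: 57, end: 76}
      - {name: SAK, start: 145, end: 147}
    provisional: true
    pm5_strong_hotspots: [12, 13, 117]
    approved_assays:
      - {assay_id: gtpase_activity, description: "intrinsic/stimulated GTP hydrolysis"}
      - {assay_id: erk_activation, description: "ERK phosphorylation in cells"}
    paralog_family: RAS

  - gene: NRAS
    validity_tier: Definitive
    inheritance_modes: [AD]
    pm1_domains:
      - {name: P-Loop, start: 10, end: 17}
      - {name: SW1, start: 28, end: 38}
      - {name: SW2, start: 57, end: 76}
      - {name: SAK, start: 145, end: 147}
    provisional: true
    pm5_strong_hotspots: []
    approved_assays:
      - {assay_id: gtpase_activity, description: "intrinsic/stimulated GTP hydrolysis"}
      - {assay_id: erk_activation, description: "ERK phosphorylation in cells"}
    paralog_family: RAS

  - gene: MRAS
    validity_tier: Moderate
    inheritance_modes: [AD]
    pm1_domains:
      - {name: P-Loop, start: 20, end: 27}
      - {name: SW1, start: 38, end: 48}
      - {name: SW2, start: 67, end: 86}
    provisional: true
    pm5_strong_hotspots: []
    approved_assays:
      - {assay_id: erk_activation, description: "ERK phosphorylation in cells"}
    paralog_family: RAS

  - gene: RIT1
    validity_tier: Definitive
    inheritance_modes: [AD]
    pm1_domains:
      - {name: P-Loop, start: 29, end: 36}
      - {name: SW1, start: 47, end: 57}
      - {name: SW2, start: 76, end: 95}
    provisional: true
    pm5_strong_hotspots: [57, 95]
    approved_assays:
      - {assay_id: erk_activation, description: "ERK phosphorylation in cells"}
    paralog_family: RAS

  - gene: RRAS2
    validity_tier: Definitive
    inheritance_modes: [AD]
    pm1_domains:
      - {name: P-Loop, start: 21, end: 28}
      - {name: SW1, start: 39, end: 49}
      - {name: SW2, start: 68, end: 87}
    provisional: true
    pm5_strong_hotspots: [72]
    approved_assays:
      - {assay_id: erk_activation, description: "ERK phosphorylation in cells"}
    paralog_family: RAS

  - gene: MAP2K1
    validity_tier: Definitive
    inheritance_modes: [AD]
    pp2_applicable: true
    pm1_domains: []
    pm5_strong_hotspots: []
    approved_assays:
      - {assay_id: kinase_activity, description: "in vitro kinase activity"}
      - {assay_id: erk_activation, description: "ERK phosphorylation in cells"}
    paralog_family: MAP2K

  - gene: MAP2K2
    validity_tier: Definitive
    inheritance_modes: [AD]
    pm1_domains: []
    pm5_strong_hotspots: []
    approved_assays:
      - {assay_id: kinase_activity, description: "in vitro kinase activity"}
      - {assay_id: erk_activation, description: "ERK phosphorylation in cells"}
    paralog_family: MAP2K

  - gene: SHOC2
    validity_tier: Definitive
    inheritance_modes: [AD]
    pm1_domains: []
    pm5_strong_hotspots: []
    approved_assays:
      - {assay_id: erk_activation, description: "ERK phosphorylation in cells"}
      - {assay_id: membrane_localization, description: "aberrant membrane targeting"}
    paralog_family: none

  - gene: LZTR1
    validity_tier: Definitive
    inheritance_modes: [AD, AR]
    pvs1_applicable: true
    pm3_applicable: true
    pm1_domains: []
    pm5_strong_hotspots: []
    approved_assays:
      - {assay_id: p_erk, description: "ERK phosphorylation", mechanism_if_abnormal: AD}
      - {assay_id: p_mek, description: "MEK phosphorylation", mechanism_if_abnormal: AD}
      - {assay_id: lztr1_stability, description: "LZTR1 protein stability", mechanism_if_abnormal: AR}
      - {assay_id: lztr1_localization, description: "LZTR1 subcellular localization", mechanism_if_abnormal: AR}
    paralog_family: none

  - gene: PPP1CB
    validity_tier: Definitive
    inheritance_modes: [AD]
    pp2_applicable: true
    pm1_domains: []
    pm5_strong_hotspots: []
    approved_assays: []
    paralog_family: none
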