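{
  "_comment": "SYNTHETIC stand-in for the LZTR1 transcript CDS exon structure (NM_006767-like: 21 coding exons, 2523 nt CDS). Exon lengths are approximate placeholders for the nonsense-mediated-decay 50-nt rule; replace with curated exon coordinates for production use.",
  "transcript": "LZTR1_synthetic",
  "cds_exon_lengths": [120, 120, 120, 120, 120, 120, 120, 120, 120, 120, 120, 120, 120, 120, 120, 120, 120, 120, 120, 120, 123]
}
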