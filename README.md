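# rasclass

A deterministic rules engine for clinical classification of germline
variants in the RASopathy genes — the Ras/MAPK-pathway disorders that
include Noonan syndrome, Costello syndrome and cardio-facio-cutaneous
syndrome.  It implements the updated ClinGen RASopathy expert-panel
specifications of the ACMG/AMP framework for 16 genes (*PTPN11*, *BRAF*,
*RAF1*, *SOS1*, *SOS2*, *KRAS*, *HRAS*, *NRAS*, *MRAS*, *RIT1*, *RRAS2*,
*MAP2K1*, *MAP2K2*, *SHOC2*, *LZTR1*, *PPP1CB*), for variant curators and
clinical laboratory scientists who want criterion calls and final tiers to
be reproducible and auditable rather than hand-assembled.

## What it computes

Structured evidence for one variant (an *evidence bundle*) is scored
criterion by criterion, and the applied criteria are combined into one of
the five tiers P / LP / VUS / LB / B:

* **Point-based case criteria.**  De novo occurrences (PS2/PM6), affected
  probands (PS4), healthy carriers (BS2) and alternate-molecular-cause
  observations (BP5/BP2) are scored per observation and binned into
  strengths, e.g. a confirmed de novo proband with a consistent RASopathy
  phenotype earns 2 points and an assumed de novo proband 1; a total ≥ 4
  gives PS2_VeryStrong.  Prenatal cases are restricted to the *limited*
  category and must show a qualifying feature (HCM, increased nuchal
  translucency, cystic hygroma, pleural effusion, hydrops).
* **Threshold criteria.**  Population frequency on the group-maximum
  filtering allele frequency (BA1 ≥ 0.0005, BS1 ≥ 0.00025,
  PM2_Supporting < 0.000025), with the FAF derived from allele counts as
  the one-sided 95% binomial lower bound when not supplied; REVEL
  (PP3 ≥ 0.7, BP4 ≤ 0.3, both Supporting only); missense constraint (PP2,
  four genes only); functional assays (PS3 capped at Moderate, two distinct
  approved assays required; BS3 never applied); protein-length changes
  (PM4; BP3 never applied).
* **Hotspots, domains and paralogs.**  PM1 for predefined functional
  domains (RAS-family P-Loop/SW1/SW2/SAK); PM5_Strong for predetermined
  mutational hotspots (≥ 2 distinct P/LP substitutions across ≥ 5 probands,
  no benign variation — also detectable at run time from case-count
  tables); PS1 for identical amino-acid changes, including at analogous
  residues of gene-family paralogs mapped through family alignments
  (e.g. *MRAS* p.Thr68 ↔ *HRAS* p.Thr58).  PM1 may combine with PM5 but
  never with PM5_Strong.
* **LZTR1 dual-mechanism routing.**  A decision tree chooses dominant or
  recessive criteria from case-level inheritance data, presumed
  loss-of-function consequence, or functional data; when none decide, the
  variant stays VUS.  The recessive route applies PVS1 (with the
  nonsense-mediated-decay 50-nt rule) and PM3 (SVI point scoring, halved
  for limited-phenotype probands).
* **Combination.**  The categorical ACMG/AMP combining rubric, counting
  strength-modified codes at their modified strength; genes with Moderate
  gene-disease validity (currently *MRAS*) are capped at Likely pathogenic.
* **Gene validity.**  A companion scorer for gene-disease validity
  case points (de novo missense 0.5; gain-of-function support 1.0;
  both 1.5; genetic cap 12, experimental cap 6) with
  Limited/Moderate/Strong/Definitive binning.

## Worked example

Three probands carry a *PTPN11* missense variant at the Asn308 hotspot:
one confirmed de novo, two assumed de novo, all with a clinical RASopathy
diagnosis; the variant is absent from population databases and REVEL is
0.94.

```
rasclass --log-level WARNING classify \
    --evidence docs/example_bundle.json --out out.json
```

The result (abridged from `out.json`):

```json
{
  "tier": "P",
  "applied_codes": ["PM2_Supporting", "PP3", "PS2_VeryStrong",
                    "PS4_Moderate", "PP2", "PM5_Strong"],
  "criteria": [
    {"code": "PS2", "points": 4.0, "rendered": "PS2_VeryStrong",
     "rationale": "obs[0]: +2 (confirmed de novo, consistent phenotype); obs[1]: +1 (assumed de novo, consistent phenotype); obs[2]: +1 (assumed de novo, consistent phenotype); total +4"}
  ]
}
```

The de novo tally is 2 + 1 + 1 = 4 points → PS2_VeryStrong; the same
probands give PS4 3 points → PS4_Moderate; Asn308 is a predetermined
hotspot outside any defined domain → PM5_Strong; with PM2_Supporting, PP2
and PP3 the rubric reaches **Pathogenic** (1 very strong + ≥ 2 moderate).

Other subcommands: `rasclass hotspots` (detect PM5_Strong residues from a
case-count TSV), `rasclass validity` (score a gene-validity evidence
table), `rasclass fixtures` (generate synthetic bundles with known
expected classifications).  The evidence-bundle JSON schema is published
at `docs/evidence_bundle.schema.json`; a TSV row-per-observation format is
also accepted.

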