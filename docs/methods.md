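# Methods

## Scope and model

`rasclass` operationalizes the updated RASopathy expert-panel
specifications of the ACMG/AMP germline classification framework as a
deterministic rules engine.  The engine's unit of work is an evidence
bundle: the variant's identity (gene, transcript, HGVS, consequence,
residue), proband and family observations, population frequency data,
in-silico scores, functional assay results, and in-trans/in-cis partner
observations.  Every criterion evaluator is a pure function of the bundle
and the gene's knowledge-base profile; the final tier is a pure function
of the applied criteria.  Identical inputs always produce identical
output, including audit text — there is no randomness anywhere in the
classification path.

Phenotype judgement is deliberately out of scope: whether a proband's
phenotype is "consistent with a RASopathy" is an expert clinical call, so
the category arrives as input and is never inferred from free text.
Likewise splice-impact predictions and consequence annotations are inputs;
the engine performs no sequence analysis.

## Point-based case criteria

Four criterion groups use per-observation tariffs summed and binned into
strengths, with thresholds inclusive at the printed value and totals
between bins taking the lower strength:

| group | tariff (per observation) | bins |
|---|---|---|
| PS2/PM6 | confirmed de novo: consistent 2, limited 1; assumed: 1 / 0.5; inconsistent or nonspecific 0 | ≥ 0.5 Supporting, ≥ 1 Moderate, ≥ 2 Strong, ≥ 4 VeryStrong |
| PS4 | consistent 1, limited 0.5, no info 0, well-phenotyped non-RASopathy −1 | ≥ 1 Supporting, ≥ 3 Moderate, ≥ 5 Strong |
| BS2 | healthy assessed hom −3, healthy assessed het −1, unaffected-only het −0.25 | ≤ −1 Supporting, ≤ −3 Strong (no Moderate bin) |
| BP5/BP2 | identified alternate molecular cause −1; P/LP cause in cis or confirmed trans −1 | ≤ −1 Supporting, ≤ −3 Strong (no Moderate bin) |

One code is emitted per group: PS2 wins over PM6 when any contributing
proband has confirmed parentage; BP2 wins over BP5 when any phase-based
observation contributed.  A negative PS4 total never becomes a benign
criterion — those observations are BP5's business.  A proband may
legitimately contribute to both PS2/PM6 and PS4 (independent criteria),
and an alternate-diagnosis proband to both PS4 (−1) and BP5 (−1); the
engine accepts this and flags the BP5/PS4 co-application in the result's
audit notes rather than silently suppressing either.

Prenatal probands are restricted to the limited category and must carry at
least one qualifying feature.  The feature list used is the five-item one
(HCM, increased nuchal translucency, cystic hygroma, pleural effusion,
hydrops).

## Threshold criteria

**Filtering allele frequency.**  When a precomputed group-maximum FAF is
absent, it is derived from per-population allele counts as the one-sided
exact binomial (Clopper–Pearson) lower confidence limit at 95%, the
published method behind the cardiodb allele-frequency calculator:
`beta.ppf(0.05, AC, AN − AC + 1)`, zero when AC = 0.  Bottlenecked
populations are excluded from the maximum and flagged for manual review.
BA1/BS1 boundaries are inclusive (≥ 0.0005 / ≥ 0.00025) and the
PM2_Supporting boundary exclusive (< threshold), matching how the values
are printed.  PM2 is emitted at Supporting only, never Moderate.

The PM2_Supporting threshold is a per-gene configuration value.  For
LZTR1 it is 0.000025 (0.0025%), the stated recessive-disease bound.  For
the other genes the specifications restate no value, so the shipped
default is also 0.000025 — one order of magnitude under BS1, the same
"effectively absent" level — and is clearly marked configurable in the
knowledge base.

**REVEL.**  PP3 at ≥ 0.7 and BP4 at ≤ 0.3, both boundaries inclusive, both
capped at Supporting because the underlying predictors favour
loss-of-function over the gain-of-function mechanism that dominates these
disorders.

**PS3.**  Distinct approved assays are counted by assay identifier, so
replicates of one assay count once: one abnormal result gives
PS3_Supporting, two or more give PS3_Moderate, which is the cap.  BS3 is
never applied (known pathogenic variants can read wild-type in these
assays depending on conditions), and PPP1CB has no approved assays at all.

**PM4/BP3.**  No benign repetitive region exists in the covered coding
sequences, so every in-frame indel or stop-loss takes PM4 and BP3 is never
applied.

## Hotspots, domains, paralogs

A residue qualifies as a PM5_Strong hotspot when it carries at least two
distinct P/LP substitutions, summing to at least five probands, with no
benign variation at the residue.  The detector applies exactly this triple
filter to a case-count table; the disqualifying benign variation is the
table's explicit flag (a row's own B/LB classification does not silently
disqualify — curators set the flag).  Shipped hotspot lists take
precedence over runtime detection because the curated list is explicitly
non-exhaustive and reviewed over time; runtime detection supplements genes
with no shipped entries.

PM1 covers predefined well-established domains only.  PM1 + PM5 may
co-apply; PM1 + PM5_Strong may not — when both qualify, PM5 drops to
Moderate.  PM5 in any form is never applied to splice-altering variants.
Baseline PM5 (a different P/LP missense at the codon) requires a
known-variant index; PS1 requires the identical change classified P (not
LP), in the same gene or at the analogous residue through the family
alignment.  PS1 for splice variants additionally requires the same
predicted splice impact label from the same tools, which in particular
makes an in-frame prediction never match an out-of-frame one.

Coordinates are 1-based inclusive protein residues (HGVS p. convention)
throughout, and alignment column maps are built once at load and are
bijective per gene over non-gap positions.

## LZTR1 routing and recessive criteria

Routing order: (1) case-level inheritance pattern — any biallelic affected
proband routes AR, any confirmed de novo heterozygote with consistent
phenotype routes AD, both present is a conflict and routes undetermined;
(2) presumed loss of function (nonsense, frameshift, canonical splice
predicted out-of-frame) routes AR; (3) functional data route by the
knowledge base's assay→mechanism map (p-ERK/p-MEK abnormal → dominant,
stability/localization abnormal → recessive), with disagreement routing
undetermined; (4) otherwise undetermined, and an undetermined route forces
the final tier to VUS regardless of accumulated criteria.  A single
observation suffices in step 1 because the tree asks only for a *clear*
pattern; the conflict rule exists because no precedence is stated.

PVS1 (LZTR1/AR only) uses the generic loss-of-function logic at the level
specifiable without panel-curated exon calls: premature stops at least
50 nt upstream of the last exon–exon junction are NMD-predicted and take
VeryStrong; NMD-escaping truncations and out-of-frame canonical splice
variants are reduced one level to Strong; predicted in-frame splice events
take no PVS1 at all, since a stable truncated protein may act through gain
of function.  Every PVS1 strength carries a "provisional" marker in its
rationale.  The stop position for the 50-nt rule is approximated as
3 × codon from the anchor residue; frameshifts without an anchor default
to NMD-predicted.  On the recessive route, a pathogenic partner in trans
is PM3 evidence (1 point confirmed trans, 0.5 suspected/unknown phase or
homozygous, halved for limited phenotype; bins 0.5/1/2/4) and is *not*
simultaneously counted toward benign BP2 — BP2's trans/cis rule applies on
the dominant route, where a second molecular cause argues against the
variant under classification.

## Combination

The categorical combining rubric is applied to the census of applied
criteria, with strength-modified codes counted at their modified strength
(a PS4 applied at Supporting is one supporting criterion).  Conflict —
both the pathogenic and benign rule sets satisfied — yields VUS with an
explicit note; no point-sum arbitration is attempted, as classification
here is categorical by design.  Two or more VeryStrong criteria with
nothing else satisfy no rubric row and fall through to VUS; this is a
known gap of the categorical rubric, left as-is rather than patched.
After the rubric, Moderate-validity genes (MRAS) cap P at LP, and an
undetermined LZTR1 route forces VUS.

## Gene validity

Case-level points follow the recuration rules: de novo missense 0.5,
missense with gain-of-function functional support 1.0, both together 1.5;
other case types default to 0.5 with a bounded per-case override
([0, 1.5]).  Genetic evidence caps at 12 points, experimental at 6.
Totals of 12–18 are Strong, or Definitive when the relationship is
replicated over time (a boolean input, not inferred); 7–11 Moderate;
below 7 Limited.  The bin boundaries and defaults are configuration
constants in `gene_validity.py`.

## Shipped knowledge base: curated vs placeholder

Gene-level facts encoded from the specifications: the supported gene set;
PVS1/PM3 restricted to LZTR1; PP2 restricted to BRAF/MAP2K1/PTPN11/PPP1CB;
no PM1 domains for SOS1/SOS2/LZTR1/PPP1CB; no hotspots for
LZTR1/PPP1CB/MAP2K1/MAP2K2/RAF1/SHOC2; SAK omitted for MRAS/RIT1/RRAS2;
PPP1CB's empty assay registry; validity tiers (all Definitive, MRAS
Moderate); the frequency thresholds.

Provisional placeholders, marked as such in the YAML: exact domain residue
ranges (canonical G-domain motifs with literature paralog offsets), the
hotspot residue lists (a non-exhaustive starting set of well-known
recurrent substitutions), the paralog alignments (synthetic offset
alignments — gap-prefixed placeholder sequences realizing the known
residue correspondences such as MRAS Thr68 ↔ HRAS Thr58, sufficient for
column mapping but not real sequences), and the LZTR1 exon structure
(`lztr1_transcript.synthetic.json`, a 21-exon stand-in summing to a
2523-nt CDS).  All are data files a laboratory replaces without touching
code; classification correctness must not silently depend on hard-coded
guesses.

## Synthetic data

The fixture generator emulates seven curation archetypes (multi-proband de
novo series, prenatal singletons, common variants, biallelic LZTR1 cases,
hotspot missense, conflicting evidence, alternate-diagnosis exome cases),
drawing observation counts and scores from a single seeded generator
within validity-preserving ranges.  Each bundle's expected criterion set
and tier are computed from rule tables transcribed locally in the fixture
module — deliberately duplicating rather than importing the engine's
tables, so a transcription error on either side surfaces as a golden-test
disagreement.  What the generator does not emulate: real allele-frequency
spectra, correlated evidence (e.g. frequency and REVEL co-varying),
curation noise such as ambiguous phenotype assignments, or genes' true
variant landscapes — so passing golden tests demonstrates rule fidelity,
not real-world calibration.

## Problem sizes and numerical choices

The test suite exercises: exhaustive tally sweeps on a 0.25-point grid
over [−6, 6] for all four binning tables; full rubric enumeration over all
censuses with up to four criteria per strength against the independent
transcription; 300 hypothesis-generated case-count tables (derandomized)
against a brute-force triple-filter oracle; 200 random (AC, AN) pairs
against a binomial-CDF root-finding oracle at 1e−6; the complete LZTR1
branch product; and 1100 generated bundles (five seeds) for golden
agreement.  FAF values are exact beta-quantile evaluations (no iteration
in the implementation; the root-finder lives only in the test oracle).
Strength bins use inclusive comparisons at exact binary-representable
thresholds (halves and quarters), so no tolerance is needed in binning.
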