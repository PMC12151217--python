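"""Domain types for RASopathy variant-classification evidence.

The engine classifies germline variants in the Ras/MAPK-pathway genes
associated with Noonan syndrome and related RASopathies.  All evidence for
one variant is collected into an :class:`EvidenceBundle`; every criterion
evaluator consumes pieces of the bundle and emits a
:class:`CriterionApplication`; the combiner folds those into a
:class:`ClassificationResult`.

Enums are closed: an unknown string in an input file is a parse error, never
silently coerced — a misspelled phenotype category must not quietly become a
zero-point observation in a clinical report.  Numeric *range* checks, by
contrast, are soft: they surface as violations from :func:`validate_bundle`
so a whole batch can be validated and reported at once.
"""

from __future__ import annotations

import enum
from typing import Optional

from pydantic import BaseModel, ConfigDict, Field

#: Genes covered by the RASopathy specifications implemented here.
#: NF1 and SPRED1 are intentionally absent (handled by a different panel).
SUPPORTED_GENES = frozenset(
    {
        "PTPN11", "BRAF", "RAF1", "SOS1", "SOS2", "KRAS", "HRAS", "NRAS",
        "MRAS", "RIT1", "RRAS2", "MAP2K1", "MAP2K2", "SHOC2", "LZTR1",
        "PPP1CB",
    }
)

#: Codes the engine evaluates itself; pre-evaluated passthrough criteria
#: must not collide with these.
ENGINE_CODES = frozenset(
    {
        "PS1", "PS2", "PM6", "PS3", "PS4", "PVS1", "PM1", "PM2_Supporting",
        "PM3", "PM4", "PM5", "PM5_Strong", "PP2", "PP3", "BA1", "BS1",
        "BS2", "BS3", "BP2", "BP3", "BP4", "BP5",
    }
)

ONE_LETTER_AA = frozenset("ACDEFGHIKLMNPQRSTVWY*X")


class Consequence(str, enum.Enum):
    missense = "missense"
    nonsense = "nonsense"
    frameshift = "frameshift"
    canonical_splice = "canonical_splice"
    splice_region = "splice_region"
    inframe_indel = "inframe_indel"
    stop_loss = "stop_loss"
    synonymous = "synonymous"
    other = "other"


#: Consequences that anchor to a specific protein residue and therefore
#: require residue_position/ref_aa/alt_aa.
RESIDUE_CONSEQUENCES = frozenset(
    {Consequence.missense, Consequence.inframe_indel, Consequence.stop_loss}
)


class PhenotypeCategory(str, enum.Enum):
    consistent = "consistent"
    limited = "limited"
    nonspecific_or_none = "nonspecific_or_none"
    inconsistent_alt_disorder = "inconsistent_alt_disorder"


class DeNovoStatus(str, enum.Enum):
    confirmed = "confirmed"
    assumed = "assumed"
    inherited = "inherited"
    unknown = "unknown"


class TestContext(str, enum.Enum):
    clinical = "clinical"
    prenatal = "prenatal"
    panel_no_info = "panel_no_info"
    exome_genome = "exome_genome"


class PrenatalFeature(str, enum.Enum):
    HCM = "HCM"
    increased_NT = "increased_NT"
    cystic_hygroma = "cystic_hygroma"
    pleural_effusion = "pleural_effusion"
    hydrops = "hydrops"


class Zygosity(str, enum.Enum):
    het = "het"
    hom = "hom"
    compound_het_confirmed_trans = "compound_het_confirmed_trans"
    compound_het_unknown_phase = "compound_het_unknown_phase"


class FamilyZygosity(str, enum.Enum):
    het = "het"
    hom = "hom"


class HealthStatus(str, enum.Enum):
    healthy_assessed = "healthy_assessed"
    unaffected_unassessed = "unaffected_unassessed"
    no_info_or_nonspecific = "no_info_or_nonspecific"


class AssayOutcome(str, enum.Enum):
    abnormal_expected = "abnormal_expected"
    normal = "normal"
    ambiguous = "ambiguous"


class PartnerClassification(str, enum.Enum):
    P = "P"
    LP = "LP"
    other = "other"


class Phase(str, enum.Enum):
    confirmed_trans = "confirmed_trans"
    suspected_trans = "suspected_trans"
    cis = "cis"
    unknown = "unknown"


class TransPhenotype(str, enum.Enum):
    consistent = "consistent"
    limited = "limited"


class Direction(str, enum.Enum):
    pathogenic = "pathogenic"
    benign = "benign"


class Strength(str, enum.Enum):
    standalone = "standalone"
    very_strong = "very_strong"
    strong = "strong"
    moderate = "moderate"
    supporting = "supporting"
    not_applicable = "not_applicable"


class Tier(str, enum.Enum):
    P = "P"
    LP = "LP"
    VUS = "VUS"
    LB = "LB"
    B = "B"


class MechanismRoute(str, enum.Enum):
    AD = "AD"
    AR = "AR"
    undetermined = "undetermined"


class _Model(BaseModel):
    model_config = ConfigDict(extra="forbid", validate_assignment=True)


class VariantIdentity(_Model):
    """HGVS-level identity of the variant being classified."""

    gene: str
    transcript: str
    hgvs_c: str
    hgvs_p: Optional[str] = None
    consequence: Consequence
    residue_position: Optional[int] = None
    ref_aa: Optional[str] = None
    alt_aa: Optional[str] = None


class ProbandObservation(_Model):
    """One affected (or putatively affected) individual carrying the variant.

    ``phenotype_category`` is assigned by the caller: consistency with a
    RASopathy is an expert clinical judgement the engine never infers from
    free text.
    """

    phenotype_category: PhenotypeCategory
    de_novo: DeNovoStatus = DeNovoStatus.unknown
    context: TestContext = TestContext.clinical
    prenatal_features: set[PrenatalFeature] = Field(default_factory=set)
    alt_cause_identified: bool = False
    zygosity: Zygosity = Zygosity.het


class FamilyObservation(_Model):
    """A relative genotyped during family studies, scored under BS2."""

    relationship: str = ""
    zygosity: FamilyZygosity
    health_status: HealthStatus


class SubpopulationCount(_Model):
    population: str
    allele_count: int = Field(ge=0)
    allele_number: int = Field(gt=0)
    bottlenecked: bool = False


class PopulationData(_Model):
    """Reference-population frequency data (gnomAD-style).

    ``grpmax_faf`` is the group-maximum filtering allele frequency when the
    caller already has it; otherwise it is derived from per-population
    allele counts (95% CI lower bound, bottlenecked populations excluded).
    """

    grpmax_faf: Optional[float] = None
    subpopulation_counts: list[SubpopulationCount] = Field(default_factory=list)
    bottlenecked_flag: bool = False


class AssayResult(_Model):
    assay_id: str
    result: AssayOutcome


class FunctionalEvidence(_Model):
    assays: list[AssayResult] = Field(default_factory=list)


class ComputationalEvidence(_Model):
    """In-silico predictions: REVEL for missense, splice labels for PS1."""

    revel: Optional[float] = None
    splice_predictions: dict[str, str] = Field(default_factory=dict)


class TransObservation(_Model):
    """An observation of the variant together with a partner variant.

    Used by the recessive-disease criterion PM3 (LZTR1 only) and by the
    benign co-occurrence criterion BP2.  ``partner_variant`` is an HGVS-ish
    reference string; a partner equal to the variant itself denotes a
    homozygous occurrence.
    """

    partner_variant: str
    partner_classification: PartnerClassification
    phase: Phase
    proband_phenotype: TransPhenotype = TransPhenotype.consistent


class CriterionApplication(_Model):
    """One ACMG/AMP code with its assigned direction, strength and audit trail.

    ``points`` carries the pre-binning tally where the criterion uses a
    point system (de novo counting, PS4, BS2, BP5/BP2, PM3); it is ``None``
    for purely categorical criteria.
    """

    code: str
    direction: Direction
    strength: Strength
    points: Optional[float] = None
    rationale: str = ""

    @property
    def applied(self) -> bool:
        return self.strength is not Strength.not_applicable

    def render(self) -> str:
        """VCEP-style notation, e.g. ``PS2_VeryStrong`` or ``PM2_P``."""
        if not self.applied:
            return f"{self.code} (not applied)"
        label = {
            Strength.standalone: "StandAlone",
            Strength.very_strong: "VeryStrong",
            Strength.strong: "Strong",
            Strength.moderate: "Moderate",
            Strength.supporting: "Supporting",
        }[self.strength]
        defaults = {
            ("PVS", Strength.very_strong), ("PS", Strength.strong),
            ("PM", Strength.moderate), ("PP", Strength.supporting),
            ("BA", Strength.standalone), ("BS", Strength.strong),
            ("BP", Strength.supporting),
        }
        prefix = self.code[:3] if self.code.startswith("PVS") else self.code[:2]
        if "_" in self.code or (prefix, self.strength) in defaults:
            return self.code
        return f"{self.code}_{label}"


class EvidenceBundle(_Model):
    """All structured evidence for one variant — the engine's input."""

    identity: VariantIdentity
    probands: list[ProbandObservation] = Field(default_factory=list)
    family: list[FamilyObservation] = Field(default_factory=list)
    population: PopulationData = Field(default_factory=PopulationData)
    functional: FunctionalEvidence = Field(default_factory=FunctionalEvidence)
    computational: ComputationalEvidence = Field(default_factory=ComputationalEvidence)
    trans_observations: list[TransObservation] = Field(default_factory=list)
    passthrough_criteria: list[CriterionApplication] = Field(default_factory=list)


class ClassificationResult(_Model):
    """Final five-tier call plus the complete criterion ledger."""

    tier: Tier
    criteria: list[CriterionApplication] = Field(default_factory=list)
    mechanism_route: MechanismRoute = MechanismRoute.AD
    capped_by_validity: bool = False
    notes: list[str] = Field(default_factory=list)

    def applied_codes(self) -> list[str]:
        return [c.render() for c in self.criteria if c.applied]


def validate_bundle(bundle: EvidenceBundle, knowledge_base=None) -> list[str]:
    """Check cross-field invariants; return human-readable violations.

    Pure: the same bundle always yields the same list.  An empty list means
    the bundle satisfies every invariant.  When a knowledge base is given,
    gene membership and assay-registry membership are checked too.
    """
    v: list[str] = []
    ident = bundle.identity

    if ident.gene not in SUPPORTED_GENES:
        v.append(f"identity.gene: {ident.gene!r} is not a supported RASopathy gene")
    if knowledge_base is not None and ident.gene not in knowledge_base:
        v.append(f"identity.gene: {ident.gene!r} absent from the knowledge base")

    residue_fields = (ident.residue_position, ident.ref_aa, ident.alt_aa)
    if ident.consequence in RESIDUE_CONSEQUENCES:
        if ident.residue_position is None:
            v.append(
                "identity.residue_position: required for residue-level "
                f"consequence {ident.consequence.value}"
            )
        if ident.ref_aa is None or ident.alt_aa is None:
            v.append(
                "identity.ref_aa/alt_aa: required for residue-level "
                f"consequence {ident.consequence.value}"
            )
    else:
        if any(f is not None for f in residue_fields):
            v.append(
                "identity.residue_position/ref_aa/alt_aa: must be null for "
                f"consequence {ident.consequence.value}"
            )
    if ident.residue_position is not None and ident.residue_position < 1:
        v.append("identity.residue_position: must be a positive 1-based residue")
    for name, aa in (("ref_aa", ident.ref_aa), ("alt_aa", ident.alt_aa)):
        if aa is not None and (len(aa) != 1 or aa not in ONE_LETTER_AA):
            v.append(f"identity.{name}: {aa!r} is not a one-letter amino-acid code")

    for i, p in enumerate(bundle.probands):
        if p.context is TestContext.prenatal:
            if p.phenotype_category not in (
                PhenotypeCategory.limited, PhenotypeCategory.nonspecific_or_none
            ):
                v.append(
                    f"probands[{i}].phenotype_category: prenatal cases are "
                    "restricted to the limited phenotype category"
                )
            elif (
                p.phenotype_category is PhenotypeCategory.limited
                and not p.prenatal_features
            ):
                v.append(
                    f"probands[{i}].prenatal_features: a prenatal limited case "
                    "must display at least one qualifying feature (HCM, "
                    "increased NT, cystic hygroma, pleural effusion, hydrops)"
                )

    pop = bundle.population
    if pop.grpmax_faf is not None and not 0.0 <= pop.grpmax_faf <= 1.0:
        v.append(f"population.grpmax_faf: {pop.grpmax_faf} outside [0, 1]")
    for i, sub in enumerate(pop.subpopulation_counts):
        if sub.allele_count > sub.allele_number:
            v.append(
                f"population.subpopulation_counts[{i}]: allele_count "
                f"{sub.allele_count} exceeds allele_number {sub.allele_number}"
            )

    revel = bundle.computational.revel
    if revel is not None and not 0.0 <= revel <= 1.0:
        v.append(f"computational.revel: {revel} outside [0, 1]")

    if knowledge_base is not None and ident.gene in knowledge_base:
        registry = {a.assay_id for a in knowledge_base[ident.gene].approved_assays}
        for i, a in enumerate(bundle.functional.assays):
            if a.assay_id not in registry:
                v.append(
                    f"functional.assays[{i}].assay_id: {a.assay_id!r} is not an "
                    f"approved assay for {ident.gene}"
                )

    for i, c in enumerate(bundle.passthrough_criteria):
        if c.code in ENGINE_CODES:
            v.append(
                f"passthrough_criteria[{i}].code: {c.code} is evaluated by the "
                "engine and cannot be supplied as passthrough"
            )

    return v


def bundle_json_schema() -> dict:
    """JSON schema for a single evidence bundle (published interface)."""
    return EvidenceBundle.model_json_schema()
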