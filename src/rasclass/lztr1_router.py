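"""LZTR1 dual-mechanism routing and the recessive-disease criteria.

LZTR1 variants can cause dominant Noonan syndrome (typically
dominant-negative missense) or recessive Noonan syndrome (loss-of-function
/ hypomorphic alleles), so a decision tree chooses which criteria set to
apply before any scoring happens:

1. Case-level data establishing a clear inheritance pattern win: biallelic
   affected probands route to AR, a confirmed de novo heterozygous proband
   with a consistent phenotype routes to AD.
2. Otherwise presumed loss-of-function variants (nonsense, frameshift,
   canonical splice predicted out-of-frame) route to AR.
3. Otherwise functional data (p-ERK, p-MEK, protein stability, subcellular
   localization) may indicate the mechanism, via the knowledge base's
   assay -> mechanism mapping.
4. Otherwise the route is undetermined and the final classification is
   forced to VUS regardless of accumulated criteria.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Optional

from .evidence_model import (
    AssayOutcome,
    Consequence,
    CriterionApplication,
    DeNovoStatus,
    Direction,
    EvidenceBundle,
    MechanismRoute,
    PartnerClassification,
    Phase,
    PhenotypeCategory,
    Strength,
    TransObservation,
    TransPhenotype,
    VariantIdentity,
    Zygosity,
)
from .knowledge_base import GeneProfile
from .case_scoring import PointTally, bin_points


class RouteBasis(str, Enum):
    inheritance_pattern = "inheritance_pattern"
    presumed_lof = "presumed_lof"
    functional_data = "functional_data"
    none = "none"


@dataclass(frozen=True)
class MechanismDecision:
    route: MechanismRoute
    basis: RouteBasis
    note: str = ""


LOF_CONSEQUENCES = (Consequence.nonsense, Consequence.frameshift)

#: Key under which an out-of-frame / in-frame splice-outcome prediction is
#: carried in ComputationalEvidence.splice_predictions.
SPLICE_FRAME_KEY = "frame"
OUT_OF_FRAME = "out_of_frame"
IN_FRAME = "in_frame"


def _presumed_lof(bundle: EvidenceBundle) -> bool:
    cons = bundle.identity.consequence
    if cons in LOF_CONSEQUENCES:
        return True
    if cons is Consequence.canonical_splice:
        frame = bundle.computational.splice_predictions.get(SPLICE_FRAME_KEY)
        return frame == OUT_OF_FRAME
    return False


def route_lztr1(bundle: EvidenceBundle, profile: GeneProfile) -> MechanismDecision:
    """Choose the AD or AR criteria set for an LZTR1 variant (see module
    docstring for the decision order).  Raises for any other gene."""
    if bundle.identity.gene != "LZTR1":
        raise ValueError("mechanism routing applies only to LZTR1 variants")

    biallelic = any(
        p.zygosity in (Zygosity.hom, Zygosity.compound_het_confirmed_trans)
        for p in bundle.probands
    )
    dominant = any(
        p.zygosity is Zygosity.het
        and p.de_novo is DeNovoStatus.confirmed
        and p.phenotype_category is PhenotypeCategory.consistent
        for p in bundle.probands
    )
    if biallelic and dominant:
        return MechanismDecision(
            MechanismRoute.undetermined, RouteBasis.none,
            "conflicting case-level inheritance signals (biallelic and "
            "dominant de novo observations)",
        )
    if biallelic:
        return MechanismDecision(
            MechanismRoute.AR, RouteBasis.inheritance_pattern,
            "biallelic affected proband(s)",
        )
    if dominant:
        return MechanismDecision(
            MechanismRoute.AD, RouteBasis.inheritance_pattern,
            "confirmed de novo heterozygous proband with consistent phenotype",
        )

    if _presumed_lof(bundle):
        return MechanismDecision(
            MechanismRoute.AR, RouteBasis.presumed_lof,
            f"presumed loss-of-function ({bundle.identity.consequence.value})",
        )

    mech_map = {
        a.assay_id: a.mechanism_if_abnormal
        for a in profile.approved_assays
        if a.mechanism_if_abnormal is not None
    }
    indicated = {
        mech_map[a.assay_id]
        for a in bundle.functional.assays
        if a.result is AssayOutcome.abnormal_expected and a.assay_id in mech_map
    }
    if len(indicated) == 1:
        route = indicated.pop()
        return MechanismDecision(
            route, RouteBasis.functional_data,
            f"functional data indicate the {route.value} mechanism",
        )
    if len(indicated) > 1:
        return MechanismDecision(
            MechanismRoute.undetermined, RouteBasis.none,
            "functional data indicate conflicting mechanisms",
        )

    return MechanismDecision(
        MechanismRoute.undetermined, RouteBasis.none,
        "no inheritance pattern, presumed-LoF consequence, or functional "
        "data; variant remains VUS",
    )


# --------------------------------------------------------------------------
# PVS1 (AR LZTR1 only)
# --------------------------------------------------------------------------

@dataclass
class TranscriptMeta:
    """CDS exon structure used for the nonsense-mediated-decay prediction.

    ``cds_exon_lengths`` are the coding-sequence lengths of each exon in
    transcript order (nt, including the stop codon in the last exon).
    """

    transcript: str
    cds_exon_lengths: list[int]

    @property
    def cds_length(self) -> int:
        return sum(self.cds_exon_lengths)

    @property
    def last_junction_cds_position(self) -> int:
        """CDS coordinate of the last exon-exon junction (nt upstream count
        boundary for the 50-nt NMD rule)."""
        return sum(self.cds_exon_lengths[:-1])

    @classmethod
    def from_json(cls, path) -> "TranscriptMeta":
        import json
        from pathlib import Path

        doc = json.loads(Path(path).read_text())
        return cls(
            transcript=doc["transcript"],
            cds_exon_lengths=list(doc["cds_exon_lengths"]),
        )


NMD_WINDOW_NT = 50


def predicts_nmd(stop_cds_position: int, meta: TranscriptMeta) -> bool:
    """50-nt rule: a premature stop more than ~50 nt upstream of the last
    exon-exon junction is predicted to trigger nonsense-mediated decay."""
    if len(meta.cds_exon_lengths) < 2:
        return False  # single-exon transcript: no junction, no NMD
    return stop_cds_position <= meta.last_junction_cds_position - NMD_WINDOW_NT


def evaluate_pvs1(
    identity: VariantIdentity,
    transcript_meta: TranscriptMeta,
    splice_predictions: Optional[dict[str, str]] = None,
) -> CriterionApplication:
    """Loss-of-function criterion, applicable only to LZTR1 (AR route).

    Nonsense/frameshift variants predicted to undergo NMD earn PVS1 at
    VeryStrong; NMD-escaping truncations and out-of-frame canonical splice
    variants are reduced one level to Strong.  A canonical splice variant
    predicted to produce an *in-frame* event is not scored under PVS1: a
    truncated-but-stable protein may act through gain of function.
    Strengths carry a "provisional" marker pending panel-curated exon-level
    calls.
    """
    if identity.gene != "LZTR1":
        raise ValueError("PVS1 is applicable only to LZTR1")

    provisional = " [provisional-Appendix]"
    cons = identity.consequence

    if cons in LOF_CONSEQUENCES:
        if identity.residue_position is not None:
            stop_nt = identity.residue_position * 3
            if predicts_nmd(stop_nt, transcript_meta):
                return CriterionApplication(
                    code="PVS1", direction=Direction.pathogenic,
                    strength=Strength.very_strong,
                    rationale=f"{cons.value} at codon {identity.residue_position}, "
                              f"NMD predicted (50-nt rule){provisional}",
                )
            return CriterionApplication(
                code="PVS1", direction=Direction.pathogenic,
                strength=Strength.strong,
                rationale=f"{cons.value} at codon {identity.residue_position} "
                          f"escapes NMD; strength reduced{provisional}",
            )
        # No anchor codon supplied: most truncations trigger NMD.
        return CriterionApplication(
            code="PVS1", direction=Direction.pathogenic,
            strength=Strength.very_strong,
            rationale=f"{cons.value}, truncation position unspecified, NMD "
                      f"assumed{provisional}",
        )

    if cons is Consequence.canonical_splice:
        frame = (splice_predictions or {}).get(SPLICE_FRAME_KEY)
        if frame == OUT_OF_FRAME:
            return CriterionApplication(
                code="PVS1", direction=Direction.pathogenic,
                strength=Strength.strong,
                rationale=f"canonical splice, out-of-frame event predicted"
                          f"{provisional}",
            )
        if frame == IN_FRAME:
            return _pvs1_na(
                "in-frame splicing event may yield a truncated protein with "
                "a gain-of-function mechanism"
            )
        return _pvs1_na("splice frame outcome unknown")

    return _pvs1_na(f"consequence {cons.value} is not loss-of-function")


def _pvs1_na(why: str) -> CriterionApplication:
    return CriterionApplication(
        code="PVS1", direction=Direction.pathogenic,
        strength=Strength.not_applicable, rationale=why,
    )


# --------------------------------------------------------------------------
# PM3 (AR LZTR1 only)
# --------------------------------------------------------------------------

PM3_BINS = [
    (4.0, Strength.very_strong),
    (2.0, Strength.strong),
    (1.0, Strength.moderate),
    (0.5, Strength.supporting),
]


def evaluate_pm3(
    trans_observations: list[TransObservation],
    identity: Optional[VariantIdentity] = None,
) -> CriterionApplication:
    """In-trans occurrence with a pathogenic partner in recessive disease.

    Per observation with a P/LP partner: 1.0 point for confirmed trans, 0.5
    for suspected trans or unknown phase, 0.5 for a homozygous occurrence
    (partner is the same variant); observations in cis earn nothing.
    Points are halved for probands with only limited phenotypic
    information.  Bins: >= 4 VeryStrong, >= 2 Strong, >= 1 Moderate,
    >= 0.5 Supporting.
    """
    tally = PointTally()
    for i, t in enumerate(trans_observations):
        if t.partner_classification not in (
            PartnerClassification.P, PartnerClassification.LP
        ):
            continue
        homozygous = (
            identity is not None and t.partner_variant == identity.hgvs_c
        )
        if homozygous:
            pts, why = 0.5, "homozygous occurrence"
        elif t.phase is Phase.confirmed_trans:
            pts, why = 1.0, "confirmed in trans with P/LP partner"
        elif t.phase in (Phase.suspected_trans, Phase.unknown):
            pts, why = 0.5, "suspected trans / phase unknown with P/LP partner"
        else:  # cis
            continue
        if t.proband_phenotype is TransPhenotype.limited:
            pts /= 2
            why += "; halved for limited phenotype"
        tally.add(i, pts, why)
    strength = bin_points(tally.points, PM3_BINS)
    return CriterionApplication(
        code="PM3", direction=Direction.pathogenic, strength=strength,
        points=tally.points, rationale=tally.describe(),
    )
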