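"""Criterion combination into a five-tier classification.

The categorical ACMG/AMP combining rubric is applied to the census of
applied criteria, counting each strength-modified code at its *modified*
strength (a PS4 applied at Supporting is one supporting criterion, not one
strong).  Two engine-level overrides follow the rubric: genes with a
Moderate gene-disease validity cap at Likely pathogenic, and an LZTR1
variant whose disease mechanism could not be determined is forced to VUS.

``classify_bundle`` is the end-to-end engine entry point: it routes the
mechanism, runs every evaluator relevant to the route, merges passthrough
criteria, and combines.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from . import case_scoring, lztr1_router, threshold_criteria
from .evidence_model import (
    ClassificationResult,
    CriterionApplication,
    Direction,
    EvidenceBundle,
    MechanismRoute,
    Strength,
    Tier,
    validate_bundle,
)
from .knowledge_base import (
    CaseCountTable,
    GeneProfile,
    KnowledgeBase,
    KnownVariantIndex,
    ValidityTier,
    detect_pm5_strong_hotspots,
)
from .lztr1_router import MechanismDecision, RouteBasis, TranscriptMeta


@dataclass(frozen=True)
class StrengthCensus:
    """Counts of applied criteria by direction and (modified) strength."""

    path_very_strong: int = 0
    path_strong: int = 0
    path_moderate: int = 0
    path_supporting: int = 0
    benign_standalone: int = 0
    benign_strong: int = 0
    benign_supporting: int = 0


def census(criteria: list[CriterionApplication]) -> StrengthCensus:
    counts = {
        (Direction.pathogenic, Strength.very_strong): 0,
        (Direction.pathogenic, Strength.strong): 0,
        (Direction.pathogenic, Strength.moderate): 0,
        (Direction.pathogenic, Strength.supporting): 0,
        (Direction.benign, Strength.standalone): 0,
        (Direction.benign, Strength.strong): 0,
        (Direction.benign, Strength.supporting): 0,
    }
    for c in criteria:
        key = (c.direction, c.strength)
        if key in counts:
            counts[key] += 1
    return StrengthCensus(
        path_very_strong=counts[(Direction.pathogenic, Strength.very_strong)],
        path_strong=counts[(Direction.pathogenic, Strength.strong)],
        path_moderate=counts[(Direction.pathogenic, Strength.moderate)],
        path_supporting=counts[(Direction.pathogenic, Strength.supporting)],
        benign_standalone=counts[(Direction.benign, Strength.standalone)],
        benign_strong=counts[(Direction.benign, Strength.strong)],
        benign_supporting=counts[(Direction.benign, Strength.supporting)],
    )


def _pathogenic_met(c: StrengthCensus) -> bool:
    vs, s, m, su = (
        c.path_very_strong, c.path_strong, c.path_moderate, c.path_supporting
    )
    if vs >= 1 and (s >= 1 or m >= 2 or (m >= 1 and su >= 1) or su >= 2):
        return True
    if s >= 2:
        return True
    if s >= 1 and (m >= 3 or (m >= 2 and su >= 2) or (m >= 1 and su >= 4)):
        return True
    return False


def _likely_pathogenic_met(c: StrengthCensus) -> bool:
    vs, s, m, su = (
        c.path_very_strong, c.path_strong, c.path_moderate, c.path_supporting
    )
    if vs >= 1 and m >= 1:
        return True
    if s >= 1 and 1 <= m <= 2:
        return True
    if s >= 1 and su >= 2:
        return True
    if m >= 3:
        return True
    if m >= 2 and su >= 2:
        return True
    if m >= 1 and su >= 4:
        return True
    return False


def _benign_met(c: StrengthCensus) -> bool:
    return c.benign_standalone >= 1 or c.benign_strong >= 2


def _likely_benign_met(c: StrengthCensus) -> bool:
    return (c.benign_strong >= 1 and c.benign_supporting >= 1) or (
        c.benign_supporting >= 2
    )


def tier_from_census(c: StrengthCensus) -> tuple[Tier, Optional[str]]:
    """Map a strength census to a tier via the combining rubric.

    Returns the tier and an optional note ("conflicting" when both the
    pathogenic and benign rule sets are satisfied).
    """
    patho = _pathogenic_met(c) or _likely_pathogenic_met(c)
    benign = _benign_met(c) or _likely_benign_met(c)
    if patho and benign:
        return Tier.VUS, "conflicting pathogenic and benign evidence"
    if _pathogenic_met(c):
        return Tier.P, None
    if _likely_pathogenic_met(c):
        return Tier.LP, None
    if _benign_met(c):
        return Tier.B, None
    if _likely_benign_met(c):
        return Tier.LB, None
    return Tier.VUS, None


def combine(
    criteria: list[CriterionApplication],
    profile: GeneProfile,
    route: MechanismDecision | None = None,
) -> ClassificationResult:
    """Combine criterion applications into the final classification.

    After the rubric: Moderate-validity genes cap Pathogenic at Likely
    pathogenic; an undetermined LZTR1 mechanism forces VUS.
    """
    cen = census(criteria)
    tier, conflict_note = tier_from_census(cen)
    notes = []
    if conflict_note:
        notes.append(conflict_note)

    capped = False
    if tier is Tier.P and profile.validity_tier is ValidityTier.Moderate:
        tier = Tier.LP
        capped = True
        notes.append(
            f"{profile.gene} gene-disease validity is Moderate: classification "
            "capped at Likely pathogenic"
        )

    mech = MechanismRoute.AD
    if route is not None:
        mech = route.route
        if route.note:
            notes.append(f"mechanism routing: {route.note}")
        if route.route is MechanismRoute.undetermined:
            tier = Tier.VUS
            capped = False
            notes.append(
                "LZTR1 disease mechanism undetermined: variant remains VUS"
            )

    return ClassificationResult(
        tier=tier,
        criteria=list(criteria),
        mechanism_route=mech,
        capped_by_validity=capped,
        notes=notes,
    )


# --------------------------------------------------------------------------
# End-to-end engine
# --------------------------------------------------------------------------

class BundleValidationError(ValueError):
    def __init__(self, violations: list[str]):
        super().__init__("; ".join(violations))
        self.violations = violations


def classify_bundle(
    bundle: EvidenceBundle,
    kb: KnowledgeBase,
    *,
    known_index: Optional[KnownVariantIndex] = None,
    case_table: Optional[CaseCountTable] = None,
    transcript_meta: Optional[TranscriptMeta] = None,
    strict: bool = True,
) -> ClassificationResult:
    """Classify one variant end to end.

    Routes the mechanism (LZTR1 only; all other genes use the dominant
    criteria set), evaluates every criterion relevant to the route, appends
    pre-evaluated passthrough criteria, and combines.  With ``strict`` a
    bundle violating any invariant raises :class:`BundleValidationError`.
    """
    violations = validate_bundle(bundle, kb)
    if violations and strict:
        raise BundleValidationError(violations)

    profile = kb[bundle.identity.gene]
    ident = bundle.identity

    route: Optional[MechanismDecision] = None
    if ident.gene == "LZTR1":
        route = lztr1_router.route_lztr1(bundle, profile)
    mechanism = route.route if route else MechanismRoute.AD

    hotspot_index = kb.hotspot_index()
    if case_table is not None:
        # Runtime-detected hotspots supplement the precomputed lists;
        # precomputed entries win where both exist for a gene.
        for gene, pos in detect_pm5_strong_hotspots(case_table):
            hotspot_index.setdefault(gene, set()).add(pos)

    alignment = kb.alignment_for(ident.gene)
    criteria: list[CriterionApplication] = []

    # Criteria applied on every route.
    verdict = threshold_criteria.evaluate_frequency(
        bundle.population, profile, mechanism
    )
    criteria.append(threshold_criteria.frequency_criterion(verdict))
    criteria.append(threshold_criteria.evaluate_computational(bundle.computational))
    criteria.append(threshold_criteria.evaluate_ps3(bundle.functional, profile))
    criteria.append(threshold_criteria.evaluate_pm4_bp3(ident))
    criteria.append(case_scoring.score_bs2(bundle.family))
    # On the recessive route a pathogenic partner in trans is part of the
    # disease genotype (PM3 evidence), not benign co-occurrence evidence, so
    # trans observations feed BP2 only on the dominant route.
    trans_for_bp = [] if mechanism is MechanismRoute.AR else bundle.trans_observations
    criteria.append(case_scoring.score_bp5_bp2(bundle.probands, trans_for_bp))

    if mechanism is MechanismRoute.AR:
        if transcript_meta is not None:
            criteria.append(
                lztr1_router.evaluate_pvs1(
                    ident, transcript_meta, bundle.computational.splice_predictions
                )
            )
        criteria.append(
            lztr1_router.evaluate_pm3(bundle.trans_observations, ident)
        )
    else:
        # Dominant-disease case criteria (also evaluated, harmlessly, when
        # the LZTR1 route is undetermined: the result is forced to VUS).
        criteria.append(case_scoring.score_de_novo(bundle.probands))
        criteria.append(case_scoring.score_ps4(bundle.probands))
        criteria.append(threshold_criteria.evaluate_pp2(profile, ident))
        criteria.extend(
            threshold_criteria.evaluate_pm1_pm5(
                ident, profile, hotspot_index, known_index, alignment
            )
        )
        criteria.append(
            threshold_criteria.evaluate_ps1(
                ident, profile, known_index, alignment,
                bundle.computational.splice_predictions,
            )
        )

    criteria.extend(bundle.passthrough_criteria)

    result = combine(criteria, profile, route)

    applied = {c.code for c in result.criteria if c.applied}
    if {"BP5", "BP2"} & applied and any(
        p.alt_cause_identified for p in bundle.probands
    ):
        ps4 = next((c for c in result.criteria if c.code == "PS4"), None)
        if ps4 is not None and any(
            pts < 0 for _, pts, _ in _ps4_negative_contributions(bundle)
        ):
            result.notes.append(
                "note: alternate-diagnosis proband(s) counted both as -1 under "
                "PS4 and under BP5/BP2 (independent criteria)"
            )
    if violations:
        result.notes.extend(f"validation: {v}" for v in violations)
    return result


def _ps4_negative_contributions(bundle: EvidenceBundle):
    from .case_scoring import PS4_POINTS

    out = []
    for i, p in enumerate(bundle.probands):
        pts = PS4_POINTS[p.phenotype_category]
        if pts < 0:
            out.append((i, pts, "non-RASopathy disorder"))
    return out
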