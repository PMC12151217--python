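"""Deterministic threshold criteria.

Population frequency (BA1 / BS1 / PM2_Supporting on the filtering allele
frequency), in-silico prediction (PP3 / BP4 on REVEL), missense constraint
(PP2), functional assays (PS3, capped at Moderate; BS3 never applied),
protein-length changes (PM4; BP3 never applied), and the structural
criteria PM1, PM5/PM5_Strong and PS1 including paralog mapping.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from scipy import stats

from .evidence_model import (
    AssayOutcome,
    ComputationalEvidence,
    Consequence,
    CriterionApplication,
    Direction,
    FunctionalEvidence,
    MechanismRoute,
    PopulationData,
    Strength,
    VariantIdentity,
)
from .knowledge_base import (
    GeneProfile,
    KnownVariantIndex,
    ParalogAlignment,
    in_pm1_domain,
    map_analogous_residue,
)

# REVEL thresholds recommended for supporting-level in-silico evidence;
# strength is never raised above Supporting because the underlying
# predictors favour loss-of-function over gain-of-function mechanisms.
PP3_REVEL_MIN = 0.7
BP4_REVEL_MAX = 0.3


def _na(code: str, direction: Direction, why: str) -> CriterionApplication:
    return CriterionApplication(
        code=code, direction=direction, strength=Strength.not_applicable,
        rationale=why,
    )


# --------------------------------------------------------------------------
# Population frequency
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class FrequencyVerdict:
    """Outcome of the frequency lattice: exactly one of BA1, BS1,
    PM2_Supporting, or none."""

    code: str  # "BA1" | "BS1" | "PM2_Supporting" | "none"
    faf_used: Optional[float]
    population: str
    note: str = ""


def filtering_allele_frequency(
    allele_count: int, allele_number: int, confidence: float = 0.95
) -> float:
    """One-sided lower confidence bound of the allele frequency.

    Exact (Clopper-Pearson style) binomial lower limit: the largest q such
    that observing >= AC alleles out of AN has probability ``1 - confidence``
    under Binomial(AN, q).  Zero observed alleles give a bound of 0.  This is
    the "filtering allele frequency" used to compare a variant's population
    frequency against disease-based thresholds without overstating rare
    observations.
    """
    if allele_number <= 0:
        raise ValueError("allele_number must be positive")
    if not 0 <= allele_count <= allele_number:
        raise ValueError("allele_count must lie in [0, allele_number]")
    if not 0.0 < confidence < 1.0:
        raise ValueError("confidence must be in (0, 1)")
    if allele_count == 0:
        return 0.0
    lower = stats.beta.ppf(
        1.0 - confidence, allele_count, allele_number - allele_count + 1
    )
    return float(min(max(lower, 0.0), 1.0))


def evaluate_frequency(
    pop: PopulationData,
    profile: GeneProfile,
    mechanism: MechanismRoute = MechanismRoute.AD,
    confidence: float = 0.95,
) -> FrequencyVerdict:
    """Classify the group-maximum filtering allele frequency.

    BA1 (stand-alone benign) at FAF >= the BA1 threshold, BS1 at FAF >= the
    BS1 threshold, PM2_Supporting when the FAF is *below* the gene's rarity
    threshold (AR LZTR1: 0.0025%); in between, no code.  BA1/BS1 boundaries
    are inclusive as printed; the PM2 boundary is exclusive.  When no
    pre-computed Grpmax FAF is supplied it is derived as the maximum
    95%-CI lower bound across non-bottlenecked populations; bottlenecked
    populations are excluded and flagged for manual review.
    """
    faf = pop.grpmax_faf
    population = "grpmax"
    note = ""
    if faf is None:
        candidates = [
            (filtering_allele_frequency(s.allele_count, s.allele_number, confidence),
             s.population)
            for s in pop.subpopulation_counts
            if not s.bottlenecked
        ]
        skipped = [s.population for s in pop.subpopulation_counts if s.bottlenecked]
        if skipped:
            note = (
                "bottlenecked population(s) excluded from Grpmax FAF, "
                "assess manually: " + ", ".join(skipped)
            )
        if candidates:
            faf, population = max(candidates)
    if faf is None:
        return FrequencyVerdict(
            "none", None, "none", note or "no population frequency data"
        )
    if faf >= profile.ba1_threshold:
        code = "BA1"
    elif faf >= profile.bs1_threshold:
        code = "BS1"
    elif faf < profile.pm2_threshold:
        code = "PM2_Supporting"
    else:
        code = "none"
    return FrequencyVerdict(code, faf, population, note)


def frequency_criterion(verdict: FrequencyVerdict) -> CriterionApplication:
    """Render a frequency verdict as a criterion application."""
    why = f"Grpmax FAF {verdict.faf_used!r} ({verdict.population})"
    if verdict.note:
        why += f"; {verdict.note}"
    if verdict.code == "BA1":
        return CriterionApplication(
            code="BA1", direction=Direction.benign,
            strength=Strength.standalone, rationale=why,
        )
    if verdict.code == "BS1":
        return CriterionApplication(
            code="BS1", direction=Direction.benign,
            strength=Strength.strong, rationale=why,
        )
    if verdict.code == "PM2_Supporting":
        # Rarity evidence is capped at Supporting; Moderate is never emitted.
        return CriterionApplication(
            code="PM2_Supporting", direction=Direction.pathogenic,
            strength=Strength.supporting, rationale=why,
        )
    return _na("PM2_Supporting", Direction.pathogenic, why)


# --------------------------------------------------------------------------
# In-silico and constraint criteria
# --------------------------------------------------------------------------

def evaluate_computational(comp: ComputationalEvidence) -> CriterionApplication:
    """PP3 at REVEL >= 0.7, BP4 at REVEL <= 0.3 (both boundaries inclusive,
    both Supporting only); scores strictly between, or absent, apply neither.
    """
    revel = comp.revel
    if revel is None:
        return _na("PP3", Direction.pathogenic, "no REVEL score")
    if revel >= PP3_REVEL_MIN:
        return CriterionApplication(
            code="PP3", direction=Direction.pathogenic,
            strength=Strength.supporting, rationale=f"REVEL {revel} >= 0.7",
        )
    if revel <= BP4_REVEL_MAX:
        return CriterionApplication(
            code="BP4", direction=Direction.benign,
            strength=Strength.supporting, rationale=f"REVEL {revel} <= 0.3",
        )
    return _na("PP3", Direction.pathogenic, f"REVEL {revel} between 0.3 and 0.7")


def evaluate_pp2(
    profile: GeneProfile, identity: VariantIdentity
) -> CriterionApplication:
    """PP2 (missense in a constrained gene): only for missense variants in
    the four genes with gnomAD missense z-score >= 3.09."""
    if identity.consequence is not Consequence.missense:
        return _na("PP2", Direction.pathogenic, "not a missense variant")
    if not profile.pp2_applicable:
        return _na(
            "PP2", Direction.pathogenic,
            f"{profile.gene} lacks the required missense constraint",
        )
    return CriterionApplication(
        code="PP2", direction=Direction.pathogenic,
        strength=Strength.supporting,
        rationale=f"missense in constrained gene {profile.gene}",
    )


# --------------------------------------------------------------------------
# Functional assays
# --------------------------------------------------------------------------

def evaluate_ps3(
    func: FunctionalEvidence, profile: GeneProfile
) -> CriterionApplication:
    """PS3 capped at Moderate: two or more *distinct* approved assays with
    the expected abnormal result give PS3_Moderate, exactly one gives
    PS3_Supporting.  Replicates of the same assay count once.  BS3 is never
    applied (known pathogenic variants can score wild-type in these assays),
    and no assays are approved for PPP1CB.
    """
    registry = {a.assay_id for a in profile.approved_assays}
    if not registry:
        return _na(
            "PS3", Direction.pathogenic,
            f"no approved functional assays for {profile.gene}",
        )
    abnormal = {
        a.assay_id
        for a in func.assays
        if a.assay_id in registry and a.result is AssayOutcome.abnormal_expected
    }
    if len(abnormal) >= 2:
        return CriterionApplication(
            code="PS3", direction=Direction.pathogenic,
            strength=Strength.moderate,
            rationale=(
                f"expected abnormal result in {len(abnormal)} distinct approved "
                f"assays ({', '.join(sorted(abnormal))}); capped at Moderate"
            ),
        )
    if len(abnormal) == 1:
        return CriterionApplication(
            code="PS3", direction=Direction.pathogenic,
            strength=Strength.supporting,
            rationale=f"expected abnormal result in one approved assay "
                      f"({next(iter(abnormal))})",
        )
    return _na("PS3", Direction.pathogenic, "no abnormal approved assay results")


# --------------------------------------------------------------------------
# Protein-length changes
# --------------------------------------------------------------------------

def evaluate_pm4_bp3(identity: VariantIdentity) -> CriterionApplication:
    """PM4 for in-frame indels and stop-loss variants.

    No benign repetitive region exists in any covered gene's coding
    sequence, so every in-frame length change is treated as falling in a
    non-repeat region and BP3 is never applied.
    """
    if identity.consequence in (Consequence.inframe_indel, Consequence.stop_loss):
        return CriterionApplication(
            code="PM4", direction=Direction.pathogenic,
            strength=Strength.moderate,
            rationale=f"protein length change ({identity.consequence.value}) "
                      "in a non-repeat region",
        )
    return _na("PM4", Direction.pathogenic, "no protein length change")


# --------------------------------------------------------------------------
# Hotspots, domains and paralogs: PM1, PM5/PM5_Strong, PS1
# --------------------------------------------------------------------------

SPLICE_CONSEQUENCES = (Consequence.canonical_splice, Consequence.splice_region)


def _analogous_positions(
    identity: VariantIdentity, alignment: Optional[ParalogAlignment]
) -> list[tuple[str, int]]:
    if alignment is None or identity.gene not in alignment.sequences:
        return []
    try:
        return map_analogous_residue(
            alignment, identity.gene, identity.residue_position
        )
    except ValueError:
        return []


def evaluate_pm1_pm5(
    identity: VariantIdentity,
    profile: GeneProfile,
    hotspot_index: Optional[dict[str, set[int]]] = None,
    known_index: Optional[KnownVariantIndex] = None,
    alignment: Optional[ParalogAlignment] = None,
) -> list[CriterionApplication]:
    """Evaluate domain membership (PM1) and hotspot/recurrence (PM5).

    PM1 applies to missense variants inside a predefined well-established
    functional domain.  PM5_Strong applies when the residue — or its
    analogous residue in a gene-family member — is a predetermined hotspot
    (>= 2 distinct P/LP changes across >= 5 probands, no benign variation);
    baseline PM5 (Moderate) applies when a different P/LP missense change is
    known at the residue.  PM1 and PM5 may be applied together, but
    PM1 + PM5_Strong may not: when both qualify, PM5 drops to Moderate.
    PM5 is never applied to variants that alter splicing.
    """
    if (
        identity.consequence is not Consequence.missense
        or identity.residue_position is None
    ):
        return [
            _na("PM1", Direction.pathogenic, "not a residue-level missense variant"),
            _na("PM5", Direction.pathogenic, "not a residue-level missense variant"),
        ]

    out: list[CriterionApplication] = []
    pos = identity.residue_position
    domain = in_pm1_domain(profile, pos)
    analogous = _analogous_positions(identity, alignment)

    hotspot_index = hotspot_index or {}
    hotspot_hits = []
    if pos in hotspot_index.get(identity.gene, set()):
        hotspot_hits.append((identity.gene, pos))
    for g, p in analogous:
        if p in hotspot_index.get(g, set()):
            hotspot_hits.append((g, p))

    pm5_moderate_hits: list[str] = []
    if known_index is not None:
        for aa, clf in known_index.pathogenic_missense_at(
            identity.gene, pos, min_class="LP"
        ):
            if aa != identity.alt_aa:
                pm5_moderate_hits.append(f"{identity.gene} p.{pos} ->{aa} ({clf})")
        for g, p in analogous:
            for aa, clf in known_index.pathogenic_missense_at(g, p, min_class="LP"):
                if aa != identity.alt_aa:
                    pm5_moderate_hits.append(f"{g} p.{p} ->{aa} ({clf})")

    if domain is not None:
        out.append(
            CriterionApplication(
                code="PM1", direction=Direction.pathogenic,
                strength=Strength.moderate,
                rationale=f"residue {pos} in well-established domain {domain}",
            )
        )
    else:
        out.append(_na("PM1", Direction.pathogenic,
                       f"residue {pos} outside defined domains"))

    hotspot_note = ", ".join(f"{g} p.{p}" for g, p in hotspot_hits)
    if hotspot_hits and domain is None:
        out.append(
            CriterionApplication(
                code="PM5_Strong", direction=Direction.pathogenic,
                strength=Strength.strong,
                rationale=f"predetermined mutational hotspot ({hotspot_note})",
            )
        )
    elif hotspot_hits and domain is not None:
        # PM5_Strong cannot be combined with PM1; drop to baseline PM5.
        out.append(
            CriterionApplication(
                code="PM5", direction=Direction.pathogenic,
                strength=Strength.moderate,
                rationale=f"hotspot ({hotspot_note}) reduced to PM5 Moderate "
                          "because PM1 is applied",
            )
        )
    elif pm5_moderate_hits:
        out.append(
            CriterionApplication(
                code="PM5", direction=Direction.pathogenic,
                strength=Strength.moderate,
                rationale="different P/LP missense at this residue: "
                          + "; ".join(pm5_moderate_hits),
            )
        )
    else:
        out.append(_na("PM5", Direction.pathogenic,
                       "no hotspot or known P/LP change at this residue"))
    return out


def evaluate_ps1(
    identity: VariantIdentity,
    profile: GeneProfile,
    known_index: Optional[KnownVariantIndex],
    alignment: Optional[ParalogAlignment] = None,
    splice_predictions: Optional[dict[str, str]] = None,
) -> CriterionApplication:
    """PS1: same amino-acid change previously classified pathogenic, in the
    same gene or at the analogous residue of a gene-family member.

    For splice variants, PS1 requires a known pathogenic splice variant at
    the same location *and* an identical predicted splice impact from the
    same in-silico tools — in particular an in-frame prediction never
    matches an out-of-frame one (the in-frame event may act through a
    gain-of-function mechanism).
    """
    if known_index is None:
        return _na("PS1", Direction.pathogenic, "no known-variant index supplied")

    if (
        identity.consequence is Consequence.missense
        and identity.residue_position is not None
    ):
        pos = identity.residue_position
        key = (identity.gene, pos, identity.alt_aa)
        if known_index.missense.get(key) == "P":
            return CriterionApplication(
                code="PS1", direction=Direction.pathogenic,
                strength=Strength.strong,
                rationale=f"identical change {identity.gene} p.{pos}"
                          f"{identity.alt_aa} previously classified P",
            )
        for g, p in _analogous_positions(identity, alignment):
            if known_index.missense.get((g, p, identity.alt_aa)) == "P":
                return CriterionApplication(
                    code="PS1", direction=Direction.pathogenic,
                    strength=Strength.strong,
                    rationale=f"same change at analogous residue {g} p.{p}"
                              f"{identity.alt_aa} classified P",
                )
        return _na("PS1", Direction.pathogenic,
                   "no identical pathogenic change at this or analogous residue")

    if identity.consequence in SPLICE_CONSEQUENCES:
        entry = known_index.splice.get((identity.gene, identity.hgvs_c))
        if entry is None:
            return _na("PS1", Direction.pathogenic,
                       "no known pathogenic splice variant at this location")
        clf, known_impact = entry
        if clf != "P":
            return _na("PS1", Direction.pathogenic,
                       "splice variant at this location is not classified P")
        labels = set((splice_predictions or {}).values())
        if known_impact and known_impact in labels:
            return CriterionApplication(
                code="PS1", direction=Direction.pathogenic,
                strength=Strength.strong,
                rationale=f"known P splice variant at {identity.hgvs_c} with "
                          f"matching predicted impact ({known_impact})",
            )
        return _na(
            "PS1", Direction.pathogenic,
            "predicted splice impact does not match the known P variant's",
        )

    return _na("PS1", Direction.pathogenic,
               "consequence not eligible for PS1")
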