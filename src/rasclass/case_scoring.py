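"""Point-based scoring of case observations: PS2/PM6, PS4, BS2, BP5/BP2.

Each observation earns a per-case point value from a phenotype-consistency
tariff; the combined total is binned into an ACMG/AMP strength.  Bin
thresholds are inclusive at the printed value (a total of exactly 4 de novo
points is VeryStrong); fractional totals between bins take the lower
strength.

Pathogenic tariffs are positive, benign tariffs negative, so a tally's sign
always matches its direction of evidence.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .evidence_model import (
    CriterionApplication,
    DeNovoStatus,
    Direction,
    FamilyObservation,
    FamilyZygosity,
    HealthStatus,
    PartnerClassification,
    Phase,
    PhenotypeCategory,
    ProbandObservation,
    Strength,
    TransObservation,
)


@dataclass
class PointTally:
    """A running point total with a per-observation audit trail."""

    contributions: list[tuple[int, float, str]] = field(default_factory=list)

    def add(self, index: int, points: float, reason: str) -> None:
        self.contributions.append((index, points, reason))

    @property
    def points(self) -> float:
        return sum(p for _, p, _ in self.contributions)

    def describe(self) -> str:
        if not self.contributions:
            return "no qualifying observations"
        parts = [f"obs[{i}]: {p:+g} ({r})" for i, p, r in self.contributions]
        return "; ".join(parts) + f"; total {self.points:+g}"


def bin_points(total: float, bins: list[tuple[float, Strength]]) -> Strength:
    """Map a point total to a strength; thresholds inclusive.

    ``bins`` is ordered strongest-first; for pathogenic tallies thresholds
    are minima (total >= t), for benign tallies maxima (total <= t, with
    negative thresholds).
    """
    for threshold, strength in bins:
        if threshold >= 0:
            if total >= threshold:
                return strength
        else:
            if total <= threshold:
                return strength
    return Strength.not_applicable


# Per-proband de novo tariff: (parentage, phenotype consistency) -> points.
DE_NOVO_POINTS: dict[tuple[DeNovoStatus, PhenotypeCategory], float] = {
    (DeNovoStatus.confirmed, PhenotypeCategory.consistent): 2.0,
    (DeNovoStatus.confirmed, PhenotypeCategory.limited): 1.0,
    (DeNovoStatus.assumed, PhenotypeCategory.consistent): 1.0,
    (DeNovoStatus.assumed, PhenotypeCategory.limited): 0.5,
}

DE_NOVO_BINS = [
    (4.0, Strength.very_strong),
    (2.0, Strength.strong),
    (1.0, Strength.moderate),
    (0.5, Strength.supporting),
]

PS4_POINTS: dict[PhenotypeCategory, float] = {
    PhenotypeCategory.consistent: 1.0,
    PhenotypeCategory.limited: 0.5,
    PhenotypeCategory.nonspecific_or_none: 0.0,
    PhenotypeCategory.inconsistent_alt_disorder: -1.0,
}

PS4_BINS = [
    (5.0, Strength.strong),
    (3.0, Strength.moderate),
    (1.0, Strength.supporting),
]

BS2_POINTS: dict[tuple[FamilyZygosity, HealthStatus], float] = {
    (FamilyZygosity.hom, HealthStatus.healthy_assessed): -3.0,
    (FamilyZygosity.het, HealthStatus.healthy_assessed): -1.0,
    (FamilyZygosity.het, HealthStatus.unaffected_unassessed): -0.25,
}

# No Moderate bin exists for BS2 or BP5/BP2.
BS2_BINS = [
    (-3.0, Strength.strong),
    (-1.0, Strength.supporting),
]

BP_BINS = [
    (-3.0, Strength.strong),
    (-1.0, Strength.supporting),
]


def score_de_novo(probands: list[ProbandObservation]) -> CriterionApplication:
    """Score de novo occurrences (PS2 when parentage confirmed, else PM6).

    Confirmed de novo with a consistent RASopathy phenotype earns 2 points,
    limited phenotype 1; assumed de novo earns half of each; inconsistent or
    nonspecific phenotypes earn nothing.  One combined code is emitted, PS2
    taking preference when any contributing proband has confirmed parentage.
    """
    tally = PointTally()
    any_confirmed = False
    for i, p in enumerate(probands):
        pts = DE_NOVO_POINTS.get((p.de_novo, p.phenotype_category), 0.0)
        if pts:
            tally.add(
                i, pts,
                f"{p.de_novo.value} de novo, {p.phenotype_category.value} phenotype",
            )
            if p.de_novo is DeNovoStatus.confirmed:
                any_confirmed = True
    strength = bin_points(tally.points, DE_NOVO_BINS)
    code = "PS2" if any_confirmed else "PM6"
    if strength is Strength.not_applicable:
        code = "PS2"
    return CriterionApplication(
        code=code,
        direction=Direction.pathogenic,
        strength=strength,
        points=tally.points,
        rationale=tally.describe(),
    )


def score_ps4(probands: list[ProbandObservation]) -> CriterionApplication:
    """Score proband counts toward PS4 (variant observed in affected cases).

    Well-phenotyped RASopathy cases earn 1 point, limited cases 0.5; cases
    with a well-phenotyped *non*-RASopathy disorder subtract 1 (they argue
    against the association — and may separately qualify under BP5).
    Negative totals never emit a benign criterion here.
    """
    tally = PointTally()
    for i, p in enumerate(probands):
        pts = PS4_POINTS[p.phenotype_category]
        if pts:
            tally.add(i, pts, f"{p.phenotype_category.value} phenotype")
    strength = bin_points(tally.points, PS4_BINS)
    return CriterionApplication(
        code="PS4",
        direction=Direction.pathogenic,
        strength=strength,
        points=tally.points,
        rationale=tally.describe(),
    )


def score_bs2(family: list[FamilyObservation]) -> CriterionApplication:
    """Score healthy carriers toward BS2.

    A healthy, clinically assessed homozygote is the strongest single
    observation (-3, Strong on its own); an assessed healthy heterozygote
    -1; a merely "unaffected" heterozygote -0.25; no information, nothing.
    """
    tally = PointTally()
    for i, f in enumerate(family):
        pts = BS2_POINTS.get((f.zygosity, f.health_status), 0.0)
        if pts:
            tally.add(i, pts, f"{f.health_status.value} {f.zygosity.value}")
    strength = bin_points(tally.points, BS2_BINS)
    return CriterionApplication(
        code="BS2",
        direction=Direction.benign,
        strength=strength,
        points=tally.points,
        rationale=tally.describe(),
    )


def score_bp5_bp2(
    probands: list[ProbandObservation],
    trans_observations: list[TransObservation],
) -> CriterionApplication:
    """Score alternate-molecular-cause observations (merged BP5/BP2 tally).

    Each of the following earns -1: a case whose phenotype has an identified
    alternate molecular cause (inconsistent phenotype with causative variant,
    or a cause in a different RASopathy gene), and a P/LP molecular cause
    found in cis or confirmed trans with the variant under classification.
    An inconsistent phenotype with *no* causative variant earns nothing.
    Points are additive across BP5 and BP2 but a single code is emitted:
    BP2 when any phase-based observation contributed, else BP5.
    """
    tally = PointTally()
    phase_based = False
    for i, p in enumerate(probands):
        if p.alt_cause_identified:
            tally.add(
                i, -1.0,
                f"alternate molecular cause identified "
                f"({p.phenotype_category.value} phenotype)",
            )
    offset = len(probands)
    for j, t in enumerate(trans_observations):
        if t.partner_classification in (
            PartnerClassification.P, PartnerClassification.LP
        ) and t.phase in (Phase.confirmed_trans, Phase.cis):
            tally.add(
                offset + j, -1.0,
                f"{t.partner_classification.value} molecular cause in "
                f"{'trans' if t.phase is Phase.confirmed_trans else 'cis'}",
            )
            phase_based = True
    strength = bin_points(tally.points, BP_BINS)
    code = "BP2" if phase_based else "BP5"
    return CriterionApplication(
        code=code,
        direction=Direction.benign,
        strength=strength,
        points=tally.points,
        rationale=tally.describe(),
    )
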