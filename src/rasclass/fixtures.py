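"""Deterministic synthetic-evidence generator with independent expectations.

Each scenario template builds an :class:`EvidenceBundle` with randomized but
validity-preserving fields *and* computes the expected criterion
applications and final tier from rule tables transcribed locally in this
module.  The local tables deliberately duplicate — never import — the
engine's tariffs, bins and combining rubric, so any divergence between the
two transcriptions is detectable by the golden-agreement test.

Scenarios
---------
``de_novo_strong``      dominant gene, confirmed/assumed de novo probands
``prenatal_limited``    single assumed de novo prenatal case
``benign_frequency``    population frequency at BA1 or BS1 levels
``lztr1_ar_biallelic``  LZTR1 frameshift with biallelic case data
``hotspot_missense``    missense at a RAS-domain hotspot residue
``conflicting``         strong de novo evidence against a BA1 frequency
``alt_diagnosis``       probands with an alternate molecular diagnosis
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .evidence_model import (
    ClassificationResult,
    ComputationalEvidence,
    Consequence,
    CriterionApplication,
    DeNovoStatus,
    Direction,
    EvidenceBundle,
    MechanismRoute,
    PartnerClassification,
    Phase,
    PhenotypeCategory,
    PopulationData,
    PrenatalFeature,
    ProbandObservation,
    Strength,
    TestContext,
    Tier,
    TransObservation,
    VariantIdentity,
    Zygosity,
)

SCENARIOS = (
    "de_novo_strong",
    "prenatal_limited",
    "benign_frequency",
    "lztr1_ar_biallelic",
    "hotspot_missense",
    "conflicting",
    "alt_diagnosis",
)


@dataclass
class FixtureSpec:
    seed: int
    n_variants: int
    scenario_mix: dict[str, float] = field(
        default_factory=lambda: {name: 1.0 for name in SCENARIOS}
    )

    def __post_init__(self):
        unknown = set(self.scenario_mix) - set(SCENARIOS)
        if unknown:
            raise ValueError(f"unknown scenario(s): {', '.join(sorted(unknown))}")
        if any(w < 0 for w in self.scenario_mix.values()):
            raise ValueError("scenario weights must be nonnegative")
        if sum(self.scenario_mix.values()) <= 0:
            raise ValueError("scenario weights must sum to a positive value")
        if self.n_variants < 1:
            raise ValueError("n_variants must be positive")


# --------------------------------------------------------------------------
# Locally transcribed rule tables (independent of the engine modules)
# --------------------------------------------------------------------------

# De novo points per proband: (confirmed?, phenotype) and strength bins.
_DN_POINTS = {("confirmed", "consistent"): 2.0, ("confirmed", "limited"): 1.0,
              ("assumed", "consistent"): 1.0, ("assumed", "limited"): 0.5}
_DN_BINS = [(4.0, Strength.very_strong), (2.0, Strength.strong),
            (1.0, Strength.moderate), (0.5, Strength.supporting)]
_PS4_BINS = [(5.0, Strength.strong), (3.0, Strength.moderate),
             (1.0, Strength.supporting)]
_BP_BINS = [(-3.0, Strength.strong), (-1.0, Strength.supporting)]
_PM3_BINS = [(4.0, Strength.very_strong), (2.0, Strength.strong),
             (1.0, Strength.moderate), (0.5, Strength.supporting)]

_BA1 = 0.0005
_BS1 = 0.00025
_PM2 = 0.000025

# Hotspot/domain facts used by the hotspot scenario (shipped KB values).
_HRAS_PLOOP = range(10, 18)
_HRAS_HOTSPOTS = (12, 13)


def _bin(total: float, bins) -> Strength:
    for threshold, strength in bins:
        if (threshold >= 0 and total >= threshold) or (
            threshold < 0 and total <= threshold
        ):
            return strength
    return Strength.not_applicable


def _expected_tier(applied: list[tuple[str, Strength, Direction]]) -> Tier:
    """Local transcription of the categorical combining rubric."""
    vs = sum(1 for _, s, d in applied
             if d is Direction.pathogenic and s is Strength.very_strong)
    st = sum(1 for _, s, d in applied
             if d is Direction.pathogenic and s is Strength.strong)
    m = sum(1 for _, s, d in applied
            if d is Direction.pathogenic and s is Strength.moderate)
    su = sum(1 for _, s, d in applied
             if d is Direction.pathogenic and s is Strength.supporting)
    sa = sum(1 for _, s, d in applied
             if d is Direction.benign and s is Strength.standalone)
    bs = sum(1 for _, s, d in applied
             if d is Direction.benign and s is Strength.strong)
    bp = sum(1 for _, s, d in applied
             if d is Direction.benign and s is Strength.supporting)

    p = (vs >= 1 and (st >= 1 or m >= 2 or (m >= 1 and su >= 1) or su >= 2)) \
        or st >= 2 \
        or (st >= 1 and (m >= 3 or (m >= 2 and su >= 2) or (m >= 1 and su >= 4)))
    lp = (vs >= 1 and m >= 1) or (st >= 1 and 1 <= m <= 2) \
        or (st >= 1 and su >= 2) or m >= 3 or (m >= 2 and su >= 2) \
        or (m >= 1 and su >= 4)
    b = sa >= 1 or bs >= 2
    lb = (bs >= 1 and bp >= 1) or bp >= 2

    if (p or lp) and (b or lb):
        return Tier.VUS
    if p:
        return Tier.P
    if lp:
        return Tier.LP
    if b:
        return Tier.B
    if lb:
        return Tier.LB
    return Tier.VUS


def _crit(code: str, strength: Strength, direction: Direction,
          points: float | None = None) -> CriterionApplication:
    return CriterionApplication(
        code=code, strength=strength, direction=direction, points=points,
        rationale="fixture expectation",
    )


def _result(applied: list[CriterionApplication],
            route: MechanismRoute = MechanismRoute.AD,
            tier: Tier | None = None) -> ClassificationResult:
    triples = [(c.code, c.strength, c.direction) for c in applied]
    return ClassificationResult(
        tier=tier if tier is not None else _expected_tier(triples),
        criteria=applied,
        mechanism_route=route,
    )


# --------------------------------------------------------------------------
# Scenario templates
# --------------------------------------------------------------------------

_AA = "ARNDCEQGHILKMFPSTWYV"


def _consistent_proband(de_novo: DeNovoStatus) -> ProbandObservation:
    return ProbandObservation(
        phenotype_category=PhenotypeCategory.consistent,
        de_novo=de_novo, context=TestContext.clinical,
    )


def _scenario_de_novo_strong(rng: np.random.Generator):
    n_conf = int(rng.integers(1, 3))
    n_assumed = int(rng.integers(0, 3))
    probands = [_consistent_proband(DeNovoStatus.confirmed)] * n_conf + [
        _consistent_proband(DeNovoStatus.assumed)
    ] * n_assumed
    revel = float(rng.uniform(0.75, 0.98))
    bundle = EvidenceBundle(
        identity=VariantIdentity(
            gene="PTPN11", transcript="NM_002834.5",
            hgvs_c=f"c.{int(rng.integers(300, 900))}A>G",
            hgvs_p="p.(synthetic)", consequence=Consequence.missense,
            residue_position=120, ref_aa="A",
            alt_aa=str(rng.choice(list("VLM"))),
        ),
        probands=probands,
        population=PopulationData(grpmax_faf=0.0),
        computational=ComputationalEvidence(revel=round(revel, 3)),
    )
    dn_points = 2.0 * n_conf + 1.0 * n_assumed
    ps4_points = float(n_conf + n_assumed)
    applied = [
        _crit("PS2", _bin(dn_points, _DN_BINS), Direction.pathogenic, dn_points),
        _crit("PM2_Supporting", Strength.supporting, Direction.pathogenic),
        _crit("PP3", Strength.supporting, Direction.pathogenic),
        _crit("PP2", Strength.supporting, Direction.pathogenic),
    ]
    ps4 = _bin(ps4_points, _PS4_BINS)
    if ps4 is not Strength.not_applicable:
        applied.append(_crit("PS4", ps4, Direction.pathogenic, ps4_points))
    return bundle, _result(applied)


def _scenario_prenatal_limited(rng: np.random.Generator):
    feature = PrenatalFeature(
        str(rng.choice([f.value for f in PrenatalFeature]))
    )
    bundle = EvidenceBundle(
        identity=VariantIdentity(
            gene="RAF1", transcript="NM_002880.4",
            hgvs_c=f"c.{int(rng.integers(100, 1800))}G>A",
            hgvs_p="p.(synthetic)", consequence=Consequence.missense,
            residue_position=400, ref_aa="G",
            alt_aa=str(rng.choice(list("SDR"))),
        ),
        probands=[
            ProbandObservation(
                phenotype_category=PhenotypeCategory.limited,
                de_novo=DeNovoStatus.assumed,
                context=TestContext.prenatal,
                prenatal_features={feature},
            )
        ],
        population=PopulationData(grpmax_faf=0.0),
        computational=ComputationalEvidence(revel=0.5),
    )
    applied = [
        _crit("PM6", Strength.supporting, Direction.pathogenic, 0.5),
        _crit("PM2_Supporting", Strength.supporting, Direction.pathogenic),
    ]
    return bundle, _result(applied, tier=Tier.VUS)


def _scenario_benign_frequency(rng: np.random.Generator):
    use_ba1 = bool(rng.integers(0, 2))
    if use_ba1:
        faf = float(rng.uniform(_BA1, 0.01))
        revel = None
    else:
        faf = float(rng.uniform(_BS1, _BA1 * 0.999))
        revel = float(rng.uniform(0.02, 0.28))
    bundle = EvidenceBundle(
        identity=VariantIdentity(
            gene="SOS1", transcript="NM_005633.4",
            hgvs_c=f"c.{int(rng.integers(100, 3900))}C>T",
            hgvs_p="p.(synthetic)", consequence=Consequence.missense,
            residue_position=700, ref_aa="P",
            alt_aa=str(rng.choice(list("SLT"))),
        ),
        population=PopulationData(grpmax_faf=faf),
        computational=ComputationalEvidence(
            revel=None if revel is None else round(revel, 3)
        ),
    )
    if use_ba1:
        applied = [_crit("BA1", Strength.standalone, Direction.benign)]
    else:
        applied = [
            _crit("BS1", Strength.strong, Direction.benign),
            _crit("BP4", Strength.supporting, Direction.benign),
        ]
    return bundle, _result(applied)


def _scenario_lztr1_ar_biallelic(rng: np.random.Generator):
    n_trans = int(rng.integers(1, 3))
    trans = [
        TransObservation(
            partner_variant=f"c.{int(rng.integers(100, 2400))}del",
            partner_classification=PartnerClassification.P,
            phase=Phase.confirmed_trans,
        )
        for _ in range(n_trans)
    ]
    bundle = EvidenceBundle(
        identity=VariantIdentity(
            gene="LZTR1", transcript="NM_006767.4",
            hgvs_c=f"c.{int(rng.integers(100, 700))}dup",
            hgvs_p="p.(synthetic fs)", consequence=Consequence.frameshift,
        ),
        probands=[
            ProbandObservation(
                phenotype_category=PhenotypeCategory.consistent,
                zygosity=Zygosity.compound_het_confirmed_trans,
            )
        ],
        population=PopulationData(grpmax_faf=0.0),
        trans_observations=trans,
    )
    pm3_points = 1.0 * n_trans
    applied = [
        _crit("PVS1", Strength.very_strong, Direction.pathogenic),
        _crit("PM3", _bin(pm3_points, _PM3_BINS), Direction.pathogenic, pm3_points),
        _crit("PM2_Supporting", Strength.supporting, Direction.pathogenic),
    ]
    return bundle, _result(applied, route=MechanismRoute.AR)


def _scenario_hotspot_missense(rng: np.random.Generator):
    pos = int(rng.choice(_HRAS_HOTSPOTS))
    assert pos in _HRAS_PLOOP  # PM1 and the hotspot co-apply: PM5 drops to Moderate
    bundle = EvidenceBundle(
        identity=VariantIdentity(
            gene="HRAS", transcript="NM_005343.4",
            hgvs_c=f"c.{pos * 3 - 1}G>T",
            hgvs_p=f"p.(Gly{pos}Val)", consequence=Consequence.missense,
            residue_position=pos, ref_aa="G", alt_aa="V",
        ),
        probands=[_consistent_proband(DeNovoStatus.confirmed)],
        population=PopulationData(grpmax_faf=0.0),
        computational=ComputationalEvidence(revel=float(rng.uniform(0.8, 0.99))),
    )
    applied = [
        _crit("PS2", Strength.strong, Direction.pathogenic, 2.0),
        _crit("PS4", Strength.supporting, Direction.pathogenic, 1.0),
        _crit("PM1", Strength.moderate, Direction.pathogenic),
        _crit("PM5", Strength.moderate, Direction.pathogenic),
        _crit("PM2_Supporting", Strength.supporting, Direction.pathogenic),
        _crit("PP3", Strength.supporting, Direction.pathogenic),
    ]
    return bundle, _result(applied)


def _scenario_conflicting(rng: np.random.Generator):
    bundle = EvidenceBundle(
        identity=VariantIdentity(
            gene="KRAS", transcript="NM_004985.5",
            hgvs_c=f"c.{int(rng.integers(250, 500))}T>C",
            hgvs_p="p.(synthetic)", consequence=Consequence.missense,
            residue_position=100, ref_aa="L", alt_aa="P",
        ),
        probands=[
            _consistent_proband(DeNovoStatus.confirmed),
            _consistent_proband(DeNovoStatus.confirmed),
            _consistent_proband(DeNovoStatus.assumed),
        ],
        population=PopulationData(grpmax_faf=float(rng.uniform(_BA1, 0.005))),
    )
    applied = [
        _crit("PS2", Strength.very_strong, Direction.pathogenic, 5.0),
        _crit("PS4", Strength.moderate, Direction.pathogenic, 3.0),
        _crit("BA1", Strength.standalone, Direction.benign),
    ]
    return bundle, _result(applied, tier=Tier.VUS)


def _scenario_alt_diagnosis(rng: np.random.Generator):
    k = int(rng.integers(1, 4))
    probands = [
        ProbandObservation(
            phenotype_category=PhenotypeCategory.inconsistent_alt_disorder,
            context=TestContext.exome_genome,
            alt_cause_identified=True,
        )
        for _ in range(k)
    ]
    bundle = EvidenceBundle(
        identity=VariantIdentity(
            gene="SOS1", transcript="NM_005633.4",
            hgvs_c=f"c.{int(rng.integers(100, 3900))}G>C",
            hgvs_p="p.(synthetic)", consequence=Consequence.missense,
            residue_position=900, ref_aa="E",
            alt_aa=str(rng.choice(list("KQD"))),
        ),
        probands=probands,
        population=PopulationData(
            grpmax_faf=float(rng.uniform(_PM2 * 1.2, _BS1 * 0.9))
        ),
        computational=ComputationalEvidence(
            revel=round(float(rng.uniform(0.02, 0.28)), 3)
        ),
    )
    applied = [
        _crit("BP5", _bin(-1.0 * k, _BP_BINS), Direction.benign, -1.0 * k),
        _crit("BP4", Strength.supporting, Direction.benign),
    ]
    return bundle, _result(applied, tier=Tier.LB)


_SCENARIO_FNS = {
    "de_novo_strong": _scenario_de_novo_strong,
    "prenatal_limited": _scenario_prenatal_limited,
    "benign_frequency": _scenario_benign_frequency,
    "lztr1_ar_biallelic": _scenario_lztr1_ar_biallelic,
    "hotspot_missense": _scenario_hotspot_missense,
    "conflicting": _scenario_conflicting,
    "alt_diagnosis": _scenario_alt_diagnosis,
}


def generate(
    spec: FixtureSpec,
) -> list[tuple[EvidenceBundle, ClassificationResult]]:
    """Generate ``spec.n_variants`` bundles with paired expectations.

    Reproducible from ``spec.seed``; a single seeded generator drives every
    random draw.
    """
    rng = np.random.default_rng(spec.seed)
    names = sorted(spec.scenario_mix)
    weights = np.array([spec.scenario_mix[n] for n in names], dtype=float)
    weights = weights / weights.sum()
    out = []
    for _ in range(spec.n_variants):
        name = str(rng.choice(names, p=weights))
        out.append(_SCENARIO_FNS[name](rng))
    return out
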