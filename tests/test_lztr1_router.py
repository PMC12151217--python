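"""LZTR1 mechanism routing, PVS1 (NMD rule) and PM3 point scoring."""

import itertools

import pytest

from rasclass import evaluate_pm3, evaluate_pvs1, route_lztr1
from rasclass.evidence_model import (
    AssayResult,
    ComputationalEvidence,
    Consequence,
    EvidenceBundle,
    FunctionalEvidence,
    MechanismRoute,
    Phase,
    ProbandObservation,
    Strength,
    TransObservation,
    VariantIdentity,
    Zygosity,
)
from rasclass.lztr1_router import RouteBasis, TranscriptMeta, predicts_nmd


def lztr1_identity(consequence=Consequence.missense, pos=200):
    residue = consequence in (
        Consequence.missense, Consequence.inframe_indel, Consequence.stop_loss
    )
    return VariantIdentity(
        gene="LZTR1", transcript="NM_006767.4", hgvs_c="c.600G>A",
        hgvs_p="p.(test)" if residue else None,
        consequence=consequence,
        residue_position=pos if residue else None,
        ref_aa="W" if residue else None,
        alt_aa="R" if residue else None,
    )


def bundle(consequence=Consequence.missense, probands=(), assays=(),
           splice_frame=None):
    comp = ComputationalEvidence(
        splice_predictions={"frame": splice_frame} if splice_frame else {}
    )
    return EvidenceBundle(
        identity=lztr1_identity(consequence),
        probands=list(probands),
        functional=FunctionalEvidence(
            assays=[AssayResult(assay_id=a, result=r) for a, r in assays]
        ),
        computational=comp,
    )


def biallelic_proband():
    return ProbandObservation(
        phenotype_category="consistent", zygosity=Zygosity.hom
    )


def dominant_proband():
    return ProbandObservation(
        phenotype_category="consistent", de_novo="confirmed",
        zygosity=Zygosity.het,
    )


# --------------------------------------------------------------------------
# Routing decision table
# --------------------------------------------------------------------------

def test_router_refuses_other_genes(kb):
    other = EvidenceBundle(
        identity=VariantIdentity(
            gene="HRAS", transcript="NM_005343.4", hgvs_c="c.35G>T",
            hgvs_p="p.(Gly12Val)", consequence=Consequence.missense,
            residue_position=12, ref_aa="G", alt_aa="V",
        )
    )
    with pytest.raises(ValueError):
        route_lztr1(other, kb["HRAS"])


def test_frameshift_without_case_data_routes_ar(kb):
    d = route_lztr1(bundle(Consequence.frameshift), kb["LZTR1"])
    assert d.route is MechanismRoute.AR
    assert d.basis is RouteBasis.presumed_lof


def test_missense_with_confirmed_de_novo_routes_ad(kb):
    d = route_lztr1(
        bundle(probands=[dominant_proband()]), kb["LZTR1"]
    )
    assert d.route is MechanismRoute.AD
    assert d.basis is RouteBasis.inheritance_pattern


def test_missense_without_any_data_is_undetermined(kb):
    d = route_lztr1(bundle(), kb["LZTR1"])
    assert d.route is MechanismRoute.undetermined
    assert d.basis is RouteBasis.none


def test_router_against_hand_transcribed_branch_table(kb):
    """Every combination of the four decision inputs against a decision
    table transcribed independently from the tree: case data first, then
    presumed LoF, then functional data, else undetermined."""
    lof_options = {
        None: False,
        Consequence.missense: False,
        Consequence.nonsense: True,
        Consequence.frameshift: True,
    }
    functional_options = {
        "none": (),
        "ad": (("p_erk", "abnormal_expected"),),
        "ar": (("lztr1_stability", "abnormal_expected"),),
        "conflict": (("p_erk", "abnormal_expected"),
                     ("lztr1_stability", "abnormal_expected")),
        "normal": (("p_erk", "normal"),),
    }
    for biallelic, dominant, cons, func in itertools.product(
        (False, True), (False, True),
        (Consequence.missense, Consequence.nonsense, Consequence.frameshift),
        functional_options,
    ):
        probands = ([biallelic_proband()] if biallelic else []) + (
            [dominant_proband()] if dominant else []
        )
        b = bundle(cons, probands, functional_options[func])
        got = route_lztr1(b, kb["LZTR1"]).route

        # Independent decision-table transcription:
        if biallelic and dominant:
            want = MechanismRoute.undetermined
        elif biallelic:
            want = MechanismRoute.AR
        elif dominant:
            want = MechanismRoute.AD
        elif lof_options[cons]:
            want = MechanismRoute.AR
        elif func == "ad":
            want = MechanismRoute.AD
        elif func == "ar":
            want = MechanismRoute.AR
        else:  # none / conflict / normal results
            want = MechanismRoute.undetermined
        assert got is want, (biallelic, dominant, cons, func)


def test_out_of_frame_splice_is_presumed_lof(kb):
    d = route_lztr1(
        bundle(Consequence.canonical_splice, splice_frame="out_of_frame"),
        kb["LZTR1"],
    )
    assert d.route is MechanismRoute.AR
    in_frame = route_lztr1(
        bundle(Consequence.canonical_splice, splice_frame="in_frame"),
        kb["LZTR1"],
    )
    assert in_frame.route is MechanismRoute.undetermined


def test_routing_is_deterministic(kb):
    b = bundle(Consequence.frameshift)
    assert route_lztr1(b, kb["LZTR1"]) == route_lztr1(b, kb["LZTR1"])


# --------------------------------------------------------------------------
# PVS1
# --------------------------------------------------------------------------

@pytest.fixture
def four_exon_meta():
    # CDS 300 + 300 + 300 + 300 nt; last junction at nt 900, NMD boundary 850.
    return TranscriptMeta(transcript="synthetic4", cds_exon_lengths=[300] * 4)


def test_pvs1_refuses_non_lztr1(four_exon_meta):
    hras = VariantIdentity(
        gene="HRAS", transcript="NM_005343.4", hgvs_c="c.34G>T",
        hgvs_p=None, consequence=Consequence.nonsense,
    )
    with pytest.raises(ValueError):
        evaluate_pvs1(hras, four_exon_meta)


def test_early_nonsense_predicted_nmd_is_very_strong(four_exon_meta):
    # codon 100 -> CDS nt 300 <= 850: NMD predicted.
    ident = lztr1_identity(Consequence.missense).model_copy(
        update=dict(consequence=Consequence.nonsense, residue_position=100,
                    ref_aa=None, alt_aa=None, hgvs_p=None)
    )
    app = evaluate_pvs1(ident, four_exon_meta)
    assert app.strength is Strength.very_strong


def test_last_exon_nonsense_escapes_nmd_and_is_reduced(four_exon_meta):
    # codon 320 -> CDS nt 960 > 850: escapes NMD; manual exon arithmetic:
    # the stop lies in exon 4, downstream of the last junction (nt 900).
    ident = lztr1_identity(Consequence.missense).model_copy(
        update=dict(consequence=Consequence.nonsense, residue_position=320,
                    ref_aa=None, alt_aa=None, hgvs_p=None)
    )
    app = evaluate_pvs1(ident, four_exon_meta)
    assert app.strength is Strength.strong


def test_nmd_boundary_arithmetic(four_exon_meta):
    assert predicts_nmd(850, four_exon_meta)
    assert not predicts_nmd(851, four_exon_meta)
    single = TranscriptMeta(transcript="s", cds_exon_lengths=[1200])
    assert not predicts_nmd(100, single)


def test_in_frame_splice_event_not_applicable(four_exon_meta):
    app = evaluate_pvs1(
        lztr1_identity(Consequence.canonical_splice), four_exon_meta,
        splice_predictions={"frame": "in_frame"},
    )
    assert app.strength is Strength.not_applicable
    out = evaluate_pvs1(
        lztr1_identity(Consequence.canonical_splice), four_exon_meta,
        splice_predictions={"frame": "out_of_frame"},
    )
    assert out.strength is Strength.strong


def test_pvs1_strengths_marked_provisional(four_exon_meta, transcript_meta):
    app = evaluate_pvs1(
        lztr1_identity(Consequence.frameshift, pos=None), transcript_meta
    )
    assert app.strength is Strength.very_strong
    assert "provisional" in app.rationale


# --------------------------------------------------------------------------
# PM3
# --------------------------------------------------------------------------

def trans(phase=Phase.confirmed_trans, clf="P", phenotype="consistent",
          partner="c.100del"):
    return TransObservation(
        partner_variant=partner, partner_classification=clf, phase=phase,
        proband_phenotype=phenotype,
    )


def test_one_confirmed_trans_partner_is_moderate():
    app = evaluate_pm3([trans()])
    assert app.points == 1.0
    assert app.strength is Strength.moderate


def test_limited_phenotype_halves_points():
    app = evaluate_pm3([trans(phenotype="limited")])
    assert app.points == 0.5
    assert app.strength is Strength.supporting


def test_four_confirmed_partners_reach_very_strong():
    app = evaluate_pm3([trans() for _ in range(4)])
    assert app.points == 4.0
    assert app.strength is Strength.very_strong


def test_homozygous_occurrence_scores_half_point():
    ident = lztr1_identity()
    app = evaluate_pm3(
        [trans(partner=ident.hgvs_c)], identity=ident
    )
    assert app.points == 0.5


def test_pm3_sums_against_svi_bin_table():
    """Tally sweep against the SVI bin table transcribed into the test."""
    def oracle(t):
        if t >= 4: return Strength.very_strong
        if t >= 2: return Strength.strong
        if t >= 1: return Strength.moderate
        if t >= 0.5: return Strength.supporting
        return Strength.not_applicable

    for n_confirmed in range(5):
        for n_suspected in range(5):
            obs = [trans() for _ in range(n_confirmed)] + [
                trans(phase=Phase.suspected_trans) for _ in range(n_suspected)
            ]
            total = 1.0 * n_confirmed + 0.5 * n_suspected
            app = evaluate_pm3(obs)
            assert app.points == total
            assert app.strength is oracle(total)


def test_cis_and_non_pathogenic_partners_score_nothing():
    assert evaluate_pm3([trans(phase=Phase.cis)]).points == 0.0
    assert evaluate_pm3([trans(clf="other")]).points == 0.0
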