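"""Threshold criteria: FAF, frequency lattice, REVEL, PP2, PS3, PM4,
PM1/PM5, PS1."""

import numpy as np
import pytest
from scipy import optimize, stats

from rasclass import (
    evaluate_computational,
    evaluate_frequency,
    evaluate_pm1_pm5,
    evaluate_pm4_bp3,
    evaluate_pp2,
    evaluate_ps1,
    evaluate_ps3,
    filtering_allele_frequency,
)
from rasclass.evidence_model import (
    AssayResult,
    ComputationalEvidence,
    Consequence,
    FunctionalEvidence,
    MechanismRoute,
    PopulationData,
    Strength,
    SubpopulationCount,
    VariantIdentity,
)
from rasclass.knowledge_base import KnownVariantIndex


def identity(gene="HRAS", consequence=Consequence.missense, pos=100,
             ref="A", alt="V", hgvs_c="c.1A>T"):
    residue = consequence in (
        Consequence.missense, Consequence.inframe_indel, Consequence.stop_loss
    )
    return VariantIdentity(
        gene=gene, transcript="NM_000000.0", hgvs_c=hgvs_c,
        hgvs_p="p.(test)" if residue else None,
        consequence=consequence,
        residue_position=pos if residue else None,
        ref_aa=ref if residue else None,
        alt_aa=alt if residue else None,
    )


# --------------------------------------------------------------------------
# Filtering allele frequency
# --------------------------------------------------------------------------

def faf_oracle(ac, an, confidence=0.95):
    """Exact binomial lower bound by root-finding on the CDF: the q with
    P(X >= ac | Bin(an, q)) = 1 - confidence."""
    if ac == 0:
        return 0.0
    def tail(q):
        return (1.0 - stats.binom.cdf(ac - 1, an, q)) - (1.0 - confidence)
    return optimize.brentq(tail, 1e-15, 1.0 - 1e-15, xtol=1e-14)


def test_zero_allele_count_gives_zero():
    assert filtering_allele_frequency(0, 5000) == 0.0


def test_known_bracket_for_large_count():
    faf = filtering_allele_frequency(1000, 10000)
    assert 0.09 < faf < 0.1


def test_faf_agrees_with_cdf_root_finding_oracle():
    rng = np.random.default_rng(11)
    for _ in range(200):
        an = int(rng.integers(10, 300_000))
        ac = int(rng.integers(0, min(an, 5000) + 1))
        assert filtering_allele_frequency(ac, an) == pytest.approx(
            faf_oracle(ac, an), abs=1e-6
        )


def test_faf_scaling_monotonicity_spot_check():
    assert filtering_allele_frequency(5, 10_000) < filtering_allele_frequency(
        50, 100_000
    )


def test_faf_input_validation():
    with pytest.raises(ValueError):
        filtering_allele_frequency(5, 0)
    with pytest.raises(ValueError):
        filtering_allele_frequency(10, 5)


# --------------------------------------------------------------------------
# Frequency lattice
# --------------------------------------------------------------------------

def verdict_code(kb, gene, faf, mechanism=MechanismRoute.AD):
    return evaluate_frequency(
        PopulationData(grpmax_faf=faf), kb[gene], mechanism
    ).code


def test_ba1_and_bs1_thresholds_inclusive(kb):
    assert verdict_code(kb, "PTPN11", 0.0005) == "BA1"
    assert verdict_code(kb, "PTPN11", 0.00025) == "BS1"
    assert verdict_code(kb, "PTPN11", 0.0003) == "BS1"


def test_ar_lztr1_rarity_threshold(kb):
    assert verdict_code(kb, "LZTR1", 0.00002, MechanismRoute.AR) == "PM2_Supporting"
    assert verdict_code(kb, "LZTR1", 0.000025, MechanismRoute.AR) == "none"


def test_lattice_against_interval_oracle(kb):
    profile = kb["PTPN11"]

    def oracle(faf):
        if faf >= profile.ba1_threshold: return "BA1"
        if faf >= profile.bs1_threshold: return "BS1"
        if faf < profile.pm2_threshold: return "PM2_Supporting"
        return "none"

    grid = np.concatenate([
        np.linspace(0, 0.001, 401),
        [profile.ba1_threshold, profile.bs1_threshold, profile.pm2_threshold],
    ])
    for faf in grid:
        assert verdict_code(kb, "PTPN11", float(faf)) == oracle(faf)


ORDER = {"PM2_Supporting": 0, "none": 1, "BS1": 2, "BA1": 3}


def test_increasing_faf_never_moves_verdict_toward_rarity(kb):
    grid = np.linspace(0, 0.002, 200)
    codes = [ORDER[verdict_code(kb, "KRAS", float(f))] for f in grid]
    assert codes == sorted(codes)


def test_faf_derived_from_subpopulations_excluding_bottlenecked(kb):
    pop = PopulationData(
        subpopulation_counts=[
            SubpopulationCount(population="nfe", allele_count=30,
                               allele_number=100_000),
            SubpopulationCount(population="asj", allele_count=400,
                               allele_number=10_000, bottlenecked=True),
        ]
    )
    verdict = evaluate_frequency(pop, kb["PTPN11"])
    assert verdict.population == "nfe"
    assert verdict.faf_used == pytest.approx(
        filtering_allele_frequency(30, 100_000)
    )
    assert "asj" in verdict.note


def test_no_frequency_data_yields_none_with_note(kb):
    verdict = evaluate_frequency(PopulationData(), kb["PTPN11"])
    assert verdict.code == "none"
    assert verdict.note


# --------------------------------------------------------------------------
# REVEL (PP3/BP4) and PP2
# --------------------------------------------------------------------------

@pytest.mark.parametrize(
    "revel, code, strength",
    [
        (0.7, "PP3", Strength.supporting),    # boundary inclusive
        (0.9, "PP3", Strength.supporting),
        (0.3, "BP4", Strength.supporting),    # boundary inclusive
        (0.1, "BP4", Strength.supporting),
        (0.5, "PP3", Strength.not_applicable),
        (None, "PP3", Strength.not_applicable),
    ],
)
def test_revel_thresholds(revel, code, strength):
    app = evaluate_computational(ComputationalEvidence(revel=revel))
    assert (app.code, app.strength) == (code, strength)


def test_pp3_never_exceeds_supporting():
    app = evaluate_computational(ComputationalEvidence(revel=0.999))
    assert app.strength is Strength.supporting


def test_pp2_gene_and_consequence_restrictions(kb):
    assert evaluate_pp2(kb["PTPN11"], identity("PTPN11")).strength \
        is Strength.supporting
    assert evaluate_pp2(kb["SOS1"], identity("SOS1")).strength \
        is Strength.not_applicable
    assert evaluate_pp2(
        kb["PTPN11"], identity("PTPN11", Consequence.nonsense)
    ).strength is Strength.not_applicable


# --------------------------------------------------------------------------
# PS3
# --------------------------------------------------------------------------

def assays(*pairs):
    return FunctionalEvidence(
        assays=[AssayResult(assay_id=a, result=r) for a, r in pairs]
    )


def test_two_distinct_abnormal_assays_cap_at_moderate(kb):
    app = evaluate_ps3(
        assays(("gtpase_activity", "abnormal_expected"),
               ("erk_activation", "abnormal_expected")),
        kb["HRAS"],
    )
    assert app.strength is Strength.moderate


def test_one_abnormal_assay_is_supporting(kb):
    app = evaluate_ps3(
        assays(("gtpase_activity", "abnormal_expected"),
               ("erk_activation", "normal")),
        kb["HRAS"],
    )
    assert app.strength is Strength.supporting


def test_replicates_of_one_assay_count_once(kb):
    app = evaluate_ps3(
        assays(("gtpase_activity", "abnormal_expected"),
               ("gtpase_activity", "abnormal_expected")),
        kb["HRAS"],
    )
    assert app.strength is Strength.supporting


def test_ppp1cb_never_applies_ps3(kb):
    app = evaluate_ps3(
        assays(("erk_activation", "abnormal_expected")), kb["PPP1CB"]
    )
    assert app.strength is Strength.not_applicable
    assert "PPP1CB" in app.rationale


# --------------------------------------------------------------------------
# PM4
# --------------------------------------------------------------------------

@pytest.mark.parametrize(
    "consequence, applies",
    [
        (Consequence.inframe_indel, True),
        (Consequence.stop_loss, True),
        (Consequence.missense, False),
        (Consequence.nonsense, False),
    ],
)
def test_pm4_for_protein_length_changes(consequence, applies):
    app = evaluate_pm4_bp3(identity("RRAS2", consequence, pos=24, ref="G", alt="G"))
    assert (app.strength is Strength.moderate) == applies
    assert app.code == "PM4"


# --------------------------------------------------------------------------
# PM1 / PM5 and PS1
# --------------------------------------------------------------------------

def applied_codes(apps):
    return {a.code: a.strength for a in apps if a.applied}


def test_domain_residue_with_known_other_change_gets_pm1_plus_pm5(kb):
    known = KnownVariantIndex(missense={("KRAS", 60, "R"): "P"})
    apps = evaluate_pm1_pm5(
        identity("KRAS", pos=60, ref="G", alt="W"), kb["KRAS"],
        hotspot_index=kb.hotspot_index(), known_index=known,
    )
    assert applied_codes(apps) == {
        "PM1": Strength.moderate, "PM5": Strength.moderate
    }


def test_hotspot_outside_domain_gets_pm5_strong_alone(kb):
    apps = evaluate_pm1_pm5(
        identity("HRAS", pos=117, ref="K", alt="R"), kb["HRAS"],
        hotspot_index=kb.hotspot_index(),
    )
    assert applied_codes(apps) == {"PM5_Strong": Strength.strong}


def test_hotspot_inside_domain_demotes_pm5_strong(kb):
    apps = evaluate_pm1_pm5(
        identity("HRAS", pos=12, ref="G", alt="V"), kb["HRAS"],
        hotspot_index=kb.hotspot_index(),
    )
    assert applied_codes(apps) == {
        "PM1": Strength.moderate, "PM5": Strength.moderate
    }
    assert "PM5_Strong" not in applied_codes(apps)


def test_splice_variant_never_gets_pm5(kb):
    apps = evaluate_pm1_pm5(
        identity("HRAS", Consequence.canonical_splice), kb["HRAS"],
        hotspot_index=kb.hotspot_index(),
    )
    assert applied_codes(apps) == {}


def test_analogous_hotspot_counts(kb):
    # HRAS 12 is a hotspot; KRAS 12 occupies the same alignment column and
    # sits in the KRAS P-Loop, so PM5 is demoted to Moderate alongside PM1.
    apps = evaluate_pm1_pm5(
        identity("KRAS", pos=12, ref="G", alt="D"), kb["KRAS"],
        hotspot_index=kb.hotspot_index(), alignment=kb.alignment_for("KRAS"),
    )
    assert applied_codes(apps) == {
        "PM1": Strength.moderate, "PM5": Strength.moderate
    }


def test_ps1_identical_change_in_same_gene(kb):
    known = KnownVariantIndex(missense={("HRAS", 100, "V"): "P"})
    app = evaluate_ps1(identity("HRAS", pos=100, alt="V"), kb["HRAS"], known)
    assert app.strength is Strength.strong


def test_ps1_mras_thr68ile_via_hras_analog(kb):
    known = KnownVariantIndex(missense={("HRAS", 58, "I"): "P"})
    app = evaluate_ps1(
        identity("MRAS", pos=68, ref="T", alt="I", hgvs_c="c.203C>T"),
        kb["MRAS"], known, alignment=kb.alignment_for("MRAS"),
    )
    assert app.strength is Strength.strong
    assert "HRAS" in app.rationale


def test_ps1_splice_requires_matching_predicted_impact(kb):
    known = KnownVariantIndex(
        splice={("HRAS", "c.111+1G>A"): ("P", "out_of_frame")}
    )
    match = evaluate_ps1(
        identity("HRAS", Consequence.canonical_splice, hgvs_c="c.111+1G>A"),
        kb["HRAS"], known,
        splice_predictions={"spliceai": "out_of_frame"},
    )
    assert match.strength is Strength.strong
    mismatch = evaluate_ps1(
        identity("HRAS", Consequence.canonical_splice, hgvs_c="c.111+1G>A"),
        kb["HRAS"], known,
        splice_predictions={"spliceai": "in_frame"},
    )
    assert mismatch.strength is Strength.not_applicable


def test_lp_does_not_support_ps1(kb):
    known = KnownVariantIndex(missense={("HRAS", 100, "V"): "LP"})
    app = evaluate_ps1(identity("HRAS", pos=100, alt="V"), kb["HRAS"], known)
    assert app.strength is Strength.not_applicable
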