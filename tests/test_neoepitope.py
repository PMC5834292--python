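"""Tests of missense handling, peptide enumeration, filters and risk flags."""

import pytest
from hypothesis import given, settings, strategies as st

from neotcr.neoepitope import (
    AffinityPrediction,
    HlaAnchorProfile,
    MissenseMutation,
    MissingPredictionError,
    NeoepitopeCandidate,
    apply_missense,
    builtin_pwm,
    candidates_from_mutation,
    enumerate_mutant_peptides,
    filter_by_affinity,
    filter_by_expression,
    flag_cross_reactivity,
    locate_substitution,
    parse_affinity_table,
    prediction_map,
    screen_mutations,
    toy_pwm_predict,
    write_affinity_table,
)

from oracles import window_oracle, window_count_closed_form


# ---------------------------------------------------------------------------
# CDS-level mutation application
# ---------------------------------------------------------------------------

def test_apply_missense_v_to_l():
    # GTG (Val) -> CTG (Leu): the RNF19B-class V->L event
    cds = "ATG" + "GCA" * 5 + "GTG" + "GCA" * 5 + "TAA"
    mutant_protein, res = apply_missense(cds, 19, "C", gene="RNF19B")
    assert isinstance(res, MissenseMutation)
    assert (res.ref_aa, res.alt_aa, res.position) == ("V", "L", 7)
    assert res.label == "RNF19B_V7L"
    assert mutant_protein[6] == "L"


def test_apply_missense_synonymous_and_stop():
    cds = "ATG" + "CTG" + "TAC" + "TAA"
    # CTG -> TTG: both Leu
    _, verdict = apply_missense(cds, 4, "T")
    assert verdict == "synonymous"
    # TAC -> TAA: stop gain
    _, verdict = apply_missense(cds, 9, "A")
    assert verdict == "stop_gain"


def test_apply_missense_rejects_internal_stop_reference():
    cds = "ATG" + "TAA" + "GCA" + "TAA"
    with pytest.raises(ValueError, match="stop"):
        apply_missense(cds, 7, "T")


def test_apply_missense_input_validation():
    cds = "ATGGCATAA"
    with pytest.raises(ValueError):
        apply_missense(cds, 0, "T")
    with pytest.raises(ValueError):
        apply_missense(cds, 4, "X")
    with pytest.raises(ValueError):
        apply_missense(cds, 4, "G")  # ref base


# ---------------------------------------------------------------------------
# peptide enumeration
# ---------------------------------------------------------------------------

def _mutation(n, p, ref="A", alt="F"):
    protein = ref * (p - 1) + ref + ref * (n - p)
    return MissenseMutation("G", protein, p, ref, alt)


def test_interior_mutation_yields_38_windows():
    windows = enumerate_mutant_peptides(_mutation(200, 100))
    assert len(windows) == 8 + 9 + 10 + 11 == 38


def test_terminal_mutation_yields_one_window_per_length():
    windows = enumerate_mutant_peptides(_mutation(200, 1))
    assert len(windows) == 4
    assert sorted(len(m) for m, _, _ in windows) == [8, 9, 10, 11]
    assert all(off == 1 for _, _, off in windows)


@given(n=st.integers(11, 30), p_frac=st.floats(0, 1))
@settings(max_examples=150, deadline=None)
def test_enumeration_matches_oracle_and_closed_form(n, p_frac):
    p = 1 + round(p_frac * (n - 1))
    mut = _mutation(n, p)
    got = enumerate_mutant_peptides(mut)
    expected = window_oracle(mut.mutant_protein, mut.protein, p, (8, 9, 10, 11))
    assert got == expected
    assert len(got) == window_count_closed_form(n, p, (8, 9, 10, 11))
    for m, w, off in got:
        diffs = [i for i, (a, b) in enumerate(zip(m, w)) if a != b]
        assert diffs == [off - 1]
        assert m[off - 1] == mut.alt_aa


def test_lypefiasi_window_recovered():
    """A 9-mer around an L->F substitution includes the planted peptide."""
    context = "MKT" + "LYPELIASI".replace("L", "L", 1) + "GRS"  # wild-type has L at the F slot
    wild = "MKT" + "LYPELIASI" + "GRS"
    pos = wild.index("LYPEL") + 5  # the residue that mutates L->F, 1-based
    mut = MissenseMutation("DPY19L4", wild, pos, "L", "F", mutant_rna_reads=12)
    nine_mers = [(m, off) for m, w, off in enumerate_mutant_peptides(mut, [9])]
    assert ("LYPEFIASI", 5) in nine_mers


# ---------------------------------------------------------------------------
# filters
# ---------------------------------------------------------------------------

def _candidate(mut_pep="KLABCDEFG", wt_pep=None, off=1, reads=5, allele="HLA-A*02:01"):
    mut_pep = "KLYPEFIAV" if mut_pep == "KLABCDEFG" else mut_pep
    wt_pep = wt_pep or ("R" + mut_pep[1:])
    return NeoepitopeCandidate("G", "G_X1Y", mut_pep, wt_pep, off, allele,
                               mutant_rna_reads=reads)


def test_affinity_filter_inclusive_thresholds():
    cands = [_candidate() for _ in range(3)]
    key = (cands[0].mut_peptide, cands[0].hla_allele)
    for ic50, threshold, kept in [(500.0, 500, True), (500.1, 500, False), (50.0, 50, True)]:
        got = filter_by_affinity([_candidate()], {key: ic50}, threshold)
        assert bool(got) is kept
    tiered = filter_by_affinity([_candidate()], {key: 50.0}, 500)
    assert tiered[0].tier == "priming"
    tiered = filter_by_affinity([_candidate()], {key: 120.0}, 500)
    assert tiered[0].tier == "discovery"


def test_affinity_filter_missing_prediction_raises():
    with pytest.raises(MissingPredictionError):
        filter_by_affinity([_candidate()], {}, 500)


def test_expression_filter():
    reads = (0, 1, 3, 0, 7)
    cands = [_candidate(reads=r) for r in reads]
    kept = filter_by_expression(cands)
    assert len(kept) == 3
    assert all(c.mutant_rna_reads >= 1 for c in kept)


def test_filters_idempotent_and_commutative():
    cands = [_candidate(reads=r) for r in (0, 2, 5)]
    table = {(c.mut_peptide, c.hla_allele): 100.0 for c in cands}
    once = filter_by_affinity(filter_by_expression(cands), table, 500)
    twice = filter_by_affinity(filter_by_expression(once), table, 500)
    swapped = filter_by_expression(filter_by_affinity(cands, table, 500))
    assert once == twice == swapped


# ---------------------------------------------------------------------------
# cross-reactivity risk
# ---------------------------------------------------------------------------

def test_rnf19b_like_anchor_substitution_is_high_risk():
    cand = NeoepitopeCandidate(
        "RNF19B", "RNF19B_V372L", "MLIGIPVYV", "MVIGIPVYV", 2, "HLA-A*02:01",
        wt_ic50_nm=40.0,
    )
    assert flag_cross_reactivity(cand, HlaAnchorProfile("HLA-A*02:01")) == "high"


def test_non_anchor_substitution_is_low_risk():
    # DPY19L4-like: substitution at peptide position 5, outside anchors {2, 9}
    cand = NeoepitopeCandidate(
        "DPY19L4", "DPY19L4_L143F", "LYPEFIASI", "LYPELIASI", 5, "HLA-A*24:02",
        wt_ic50_nm=10.0,
    )
    assert flag_cross_reactivity(cand, HlaAnchorProfile("HLA-A*24:02")) == "low"


def test_anchor_substitution_with_nonbinding_wildtype_is_low_risk():
    cand = NeoepitopeCandidate(
        "G", "G_A9V", "AAAAAAAAV", "AAAAAAAAA", 9, "HLA-A*02:01", wt_ic50_nm=5000.0
    )
    assert flag_cross_reactivity(cand, HlaAnchorProfile("HLA-A*02:01")) == "low"


@given(wt_ic50=st.floats(1.0, 10000.0), threshold=st.floats(1.0, 1000.0))
@settings(max_examples=100, deadline=None)
def test_risk_monotone_in_threshold(wt_ic50, threshold):
    """Lowering the wild-type binding threshold never converts low to high."""
    cand = NeoepitopeCandidate(
        "G", "G_A2V", "AVAAAAAAA", "AAAAAAAAA", 2, "HLA-A*02:01", wt_ic50_nm=wt_ic50
    )
    anchors = HlaAnchorProfile("HLA-A*02:01")
    loose = flag_cross_reactivity(cand, anchors, threshold)
    tight = flag_cross_reactivity(cand, anchors, threshold / 2)
    assert not (tight == "high" and loose == "low")


# ---------------------------------------------------------------------------
# toy PWM predictor
# ---------------------------------------------------------------------------

def test_toy_pwm_consensus_and_baseline():
    pwm = builtin_pwm("HLA-A*24:02", min_ic50_nm=1.0)
    consensus = pwm.consensus(9)
    assert pwm.predict(consensus).ic50_nm == pytest.approx(1.0)
    # every other peptide binds no better than the consensus
    assert pwm.predict("AAAAAAAAA").ic50_nm >= 1.0
    baseline = pwm.baseline_ic50(9)
    zero_pep = "".join(
        next(aa for aa in "ACDEFGHIKLMNPQRSTVWY" if col[aa] == 0.0)
        for col in pwm.matrices[9]
    )
    assert pwm.predict(zero_pep).ic50_nm == pytest.approx(baseline)


def test_toy_pwm_deterministic_and_validates_residues():
    a = toy_pwm_predict("MLIGIPVYV", "HLA-A*02:01")
    b = toy_pwm_predict("MLIGIPVYV", "HLA-A*02:01")
    assert a == b
    with pytest.raises(ValueError):
        toy_pwm_predict("MLIGIPVYB", "HLA-A*02:01")


# ---------------------------------------------------------------------------
# affinity table I/O
# ---------------------------------------------------------------------------

def test_affinity_table_round_trip(tmp_path):
    preds = [
        AffinityPrediction("LYPEFIASI", "HLA-A*24:02", 12.5),
        AffinityPrediction("MLIGIPVYV", "HLA-A*02:01", 8.0),
        AffinityPrediction("AAAAAAAA", "HLA-A*02:01", 4999.0),
    ]
    path = tmp_path / "aff.tsv"
    write_affinity_table(preds, path)
    got = parse_affinity_table(path)
    assert [(p.peptide, p.hla_allele) for p in got] == [
        (p.peptide, p.hla_allele) for p in preds
    ]
    empty = tmp_path / "empty.tsv"
    empty.write_text("peptide\thla_allele\tic50_nm\n")
    assert parse_affinity_table(empty) == []


def test_affinity_table_errors_name_the_line(tmp_path):
    path = tmp_path / "bad.tsv"
    path.write_text("peptide\thla_allele\tic50_nm\nLYPEFIASI\tHLA-A*24:02\t-1\n")
    with pytest.raises(ValueError, match=":2"):
        parse_affinity_table(path)


# ---------------------------------------------------------------------------
# full screening order
# ---------------------------------------------------------------------------

def test_screen_mutations_pipeline_order_and_annotations():
    wild = "MKT" + "LYPELIASI" + "GRSAAAA"
    mut = MissenseMutation("DPY19L4", wild, 8, "L", "F", mutant_rna_reads=3)
    silent = MissenseMutation("OTHER", wild, 8, "L", "W", mutant_rna_reads=0)
    pwm = builtin_pwm("HLA-A*24:02")
    kept = screen_mutations([mut, silent], "HLA-A*24:02", pwm=pwm)
    # the unexpressed mutation is filtered regardless of affinity
    assert all(c.gene == "DPY19L4" for c in kept)
    assert all(c.mut_ic50_nm is not None and c.mut_ic50_nm <= 500 for c in kept)
    assert all(c.wt_ic50_nm is not None for c in kept)
    assert all(c.cross_reactivity_risk in ("low", "high") for c in kept)
    assert all(c.tier in ("discovery", "priming") for c in kept)
    peptides = {c.mut_peptide for c in kept}
    assert "LYPEFIASI" in peptides


def test_screen_requires_some_predictor():
    with pytest.raises(ValueError):
        screen_mutations([], "HLA-A*02:01")


def test_locate_substitution():
    assert locate_substitution("MLIGIPVYV", "MVIGIPVYV") == 2
    with pytest.raises(ValueError):
        locate_substitution("AAAA", "AAAA")
    with pytest.raises(ValueError):
        locate_substitution("AAVV", "AAAA")
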