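import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from hrcoreg import synthetic
from hrcoreg.nmd import (
    FRAMESHIFT_DEL, FRAMESHIFT_INS, MISSENSE, NMD_ESCAPE, NMD_PREDICTED,
    NONSENSE, NOT_APPLICABLE, STOP_CODONS, NmdError, NmdRuleConfig,
    NMDPrediction, TranscriptModel, Variant, apply_variant,
    classify_variant, locate_ptc, predict_nmd, predictions_table,
)


def make_transcript(exons=(300, 300, 300, 300, 300), cds_start=50, seq=None):
    return TranscriptModel("TX", tuple(exons), cds_start, seq)


# -- coordinates -----------------------------------------------------------

def test_exon_local_round_trip_all_positions():
    t = make_transcript(exons=(7, 13, 5), cds_start=1)
    for pos in range(1, t.length + 1):
        exon_i, off = t.to_exon_local(pos)
        assert t.to_transcript(exon_i, off) == pos


def test_last_junction_position():
    t = make_transcript(exons=(100, 200, 50))
    assert t.last_junction == 300
    assert make_transcript(exons=(400,), cds_start=10).last_junction is None


def test_transcript_validation():
    with pytest.raises(NmdError, match="exon lengths"):
        make_transcript(exons=(10, 0))
    with pytest.raises(NmdError, match="CDS start"):
        make_transcript(exons=(10,), cds_start=11)
    with pytest.raises(NmdError, match="sequence length"):
        make_transcript(exons=(6,), cds_start=1, seq="ACGT")


# -- rule application ------------------------------------------------------

def test_rules_all_pass_for_internal_ptc():
    """24-exon transcript, PTC 300 nt downstream of start and 100 nt
    upstream of the last junction: NMD predicted."""
    t = make_transcript(exons=(100,) * 24, cds_start=10)
    ptc = t.last_junction - 99  # distance to junction = 100
    assert ptc - t.cds_start > 200
    p = predict_nmd(t, ptc)
    assert p.distance_to_last_junction == 100
    assert p.call == NMD_PREDICTED


def test_ptc_in_last_exon_escapes():
    t = make_transcript()
    p = predict_nmd(t, t.last_junction + 30)
    assert p.rule_junction is False
    assert p.call == NMD_ESCAPE


def test_two_exon_transcript_escapes():
    t = make_transcript(exons=(600, 600))
    p = predict_nmd(t, 400)  # junction distance 201, start distance 350
    assert p.rule_junction is True and p.rule_start_distance is True
    assert p.rule_exon_count is False
    assert p.call == NMD_ESCAPE


def test_start_proximal_ptc_escapes():
    t = make_transcript()
    p = predict_nmd(t, t.cds_start + 150)
    assert p.rule_start_distance is False
    assert p.call == NMD_ESCAPE


@pytest.mark.parametrize("threshold,call", [(50, NMD_PREDICTED),
                                            (55, NMD_ESCAPE)])
def test_junction_threshold_configurable(threshold, call):
    t = make_transcript()
    ptc = t.last_junction - 51  # junction distance exactly 52
    cfg = NmdRuleConfig(junction_threshold=threshold)
    assert predict_nmd(t, ptc, cfg).call == call


def test_upstream_moves_never_flip_prediction_to_escape():
    """Monotonicity: moving a PTC upstream (staying > 200 nt from the
    start codon) never turns NMD_predicted into NMD_escape."""
    t = make_transcript(exons=(200,) * 8, cds_start=30)
    positions = range(t.cds_start + 201, t.last_junction - 50)
    calls = [predict_nmd(t, p).call for p in positions]
    # predicted everywhere in this range, and in particular never
    # escape upstream of a predicted position
    first_pred = calls.index(NMD_PREDICTED)
    assert NMD_ESCAPE not in calls[:first_pred + 1]
    assert all(c == NMD_PREDICTED for c in calls)


# -- PTC location ----------------------------------------------------------

def brute_force_ptc(seq, cds_start):
    """Codon-scan oracle: first stop codon in frame from the CDS start."""
    seq = seq.upper().replace("U", "T")
    for i in range(cds_start - 1, len(seq) - 2, 3):
        if seq[i:i + 3] in STOP_CODONS:
            return i + 1
    return None


def test_nonsense_ptc_is_variant_position():
    t = make_transcript()
    v = Variant("TX", NONSENSE, position=500)
    ptc, mutant, nonstop = locate_ptc(t, v)
    assert ptc == 500 and mutant is t and not nonstop


def test_missense_is_not_applicable():
    t = make_transcript()
    v = Variant("TX", MISSENSE, position=500)
    p = classify_variant(t, v)
    assert p.call == NOT_APPLICABLE and p.ptc_position is None


def test_toy_insertion_shifts_onto_immediate_stop():
    """CDS ATG AAA GGG TAA with a T inserted after the ATG: the shifted
    frame reads TAA immediately, so the PTC sits right after the start
    codon; verified against the brute-force codon scan."""
    seq = "ATGAAAGGGTAA"
    t = TranscriptModel("toy", (len(seq),), 1, seq)
    v = Variant("toy", FRAMESHIFT_INS, position=3, length=1,
                inserted_sequence="T")
    ptc, mutant, _ = locate_ptc(t, v)
    assert ptc == 4
    assert ptc == brute_force_ptc(mutant.sequence, mutant.cds_start)
    assert mutant.sequence[ptc - 1:ptc + 2] in STOP_CODONS


@pytest.mark.parametrize("label", [
    "frameshift_ins_mid_cds", "frameshift_del_mid_cds",
])
def test_frameshift_ptc_matches_codon_scan_oracle(label):
    fixtures = {f.label: f for f in synthetic.simulate_transcript_fixtures(0)}
    f = fixtures[label]
    ptc, mutant, nonstop = locate_ptc(f.transcript, f.variant)
    assert not nonstop
    assert ptc == brute_force_ptc(mutant.sequence, mutant.cds_start)
    assert ptc >= f.variant.position  # stop created by the shift


def test_fixture_truth_table():
    """Hand-enumerated expected calls for the boundary-spanning fixtures."""
    expected = {
        "nonsense_all_rules_pass": NMD_PREDICTED,
        "nonsense_last_exon": NMD_ESCAPE,
        "nonsense_two_exon": NMD_ESCAPE,
        "nonsense_start_proximal": NMD_ESCAPE,
        "nonsense_junction_proximal": NMD_ESCAPE,
        "frameshift_ins_mid_cds": NMD_PREDICTED,
        "frameshift_del_mid_cds": NMD_PREDICTED,
        "missense": NOT_APPLICABLE,
        "inframe_exon_skip": NOT_APPLICABLE,
    }
    for f in synthetic.simulate_transcript_fixtures(0):
        assert classify_variant(f.transcript, f.variant).call == \
            expected[f.label], f.label


def test_nonstop_frameshift_flagged():
    # shifted frame engineered with no stop before the transcript end
    seq = "ATG" + "AAC" * 20
    t = TranscriptModel("ns", (len(seq),), 1, seq)
    v = Variant("ns", FRAMESHIFT_INS, position=3, length=1,
                inserted_sequence="A")
    ptc, _, nonstop = locate_ptc(t, v)
    assert ptc is None and nonstop
    assert classify_variant(t, v).call == NOT_APPLICABLE


def test_insertion_adjusts_exon_lengths_and_sequence():
    seq = "A" * 10 + "C" * 10
    t = TranscriptModel("TX", (10, 10), 1, seq)
    v = Variant("TX", FRAMESHIFT_INS, position=5, length=2,
                inserted_sequence="GG")
    mutant = apply_variant(t, v)
    assert mutant.exon_lengths == (12, 10)
    assert mutant.sequence == "A" * 5 + "GG" + "A" * 5 + "C" * 10


def test_deletion_adjusts_exon_lengths():
    t = TranscriptModel("TX", (10, 10), 1, "A" * 9 + "GC" + "T" * 9)
    v = Variant("TX", FRAMESHIFT_DEL, position=10, length=2)
    mutant = apply_variant(t, v)
    assert mutant.exon_lengths == (9, 9)
    assert mutant.sequence == "A" * 9 + "T" * 9


def test_predictions_table_layout():
    fixtures = synthetic.simulate_transcript_fixtures(0)
    table = predictions_table([(f.transcript, f.variant) for f in fixtures])
    assert len(table) == len(fixtures)
    assert {"call", "ptc_position", "rule_junction"} <= set(table.columns)


@given(st.integers(min_value=3, max_value=12),
       st.integers(min_value=60, max_value=200))
@settings(max_examples=25, derandomize=True)
def test_combined_call_equals_rule_conjunction(n_exons, exon_len):
    t = make_transcript(exons=(exon_len,) * n_exons, cds_start=20)
    rng = np.random.default_rng(n_exons * 1000 + exon_len)
    ptc = int(rng.integers(t.cds_start, t.length + 1))
    p = predict_nmd(t, ptc)
    assert (p.call == NMD_PREDICTED) == bool(
        p.rule_junction and p.rule_exon_count and p.rule_start_distance
    )
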