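"""Pseudogene evidence, TM counting, status rules and alignment trimming."""
import numpy as np
import pytest
from Bio.Seq import Seq
from hypothesis import given, settings, strategies as st

from ormine import (
    MIN_FUNCTIONAL_NT,
    STATUS_FUNCTIONAL,
    STATUS_PSEUDOGENE,
    STATUS_SUB7TM,
    classify_status,
    count_tm_domains,
    detect_pseudogene_features,
    simulate,
    trim_alignment,
)
from ormine.classify import FrameshiftEvidence, PseudogeneEvidence, TMTopology


REF = simulate.family_template_cds("4")  # 933 nt incl. terminal stop


def test_intact_sequence_has_no_evidence():
    ev = detect_pseudogene_features(REF, REF, "ref")
    assert not ev.has_premature_stop
    assert not ev.has_frameshift
    assert ev.length_nt == 933
    assert ev.anchored


def test_planted_premature_stop_detected():
    mutated = REF[:27] + "TGA" + REF[30:]  # codon 10 -> TGA
    ev = detect_pseudogene_features(mutated, REF, "ref")
    assert ev.has_premature_stop


def test_single_base_deletion_is_frameshift_with_three_frame_oracle():
    mutated = REF[:300] + REF[301:]
    ev = detect_pseudogene_features(mutated, REF, "ref")
    assert ev.has_frameshift
    assert any(l % 3 != 0 for l in ev.frameshift.indel_lengths)
    # independent oracle: after the deletion the frame matching the
    # reference C-terminus differs from the frame matching its start
    ref_prot = str(Seq(REF[:930]).translate())
    frames = [
        str(Seq(mutated[f : f + (len(mutated) - f) // 3 * 3]).translate())
        for f in range(3)
    ]
    head_frame = max(range(3), key=lambda f: _ident(frames[f][:80], ref_prot[:80]))
    tail_frame = max(
        range(3), key=lambda f: _ident(frames[f][-60:], ref_prot[-60:])
    )
    assert head_frame != tail_frame


def _ident(a: str, b: str) -> float:
    n = min(len(a), len(b))
    return sum(x == y for x, y in zip(a[:n], b[:n])) / max(n, 1)


def test_inframe_indel_is_not_a_frameshift():
    mutated = simulate.apply_operator(REF, "frameshift_indel", seed=5, arg=3)
    ev = detect_pseudogene_features(mutated, REF, "ref")
    assert not ev.has_frameshift


def test_unanchored_fallback_uses_longest_orf():
    rng = np.random.default_rng(0)
    junk = "".join("ACGT"[int(i)] for i in rng.integers(0, 4, 900))
    ev = detect_pseudogene_features(junk, REF, "ref")
    assert not ev.anchored


# ----------------------------------------------------------------------
# TM counting


def test_planted_seven_helices_counted():
    prot = simulate.planted_helix_protein(n_tm=7, tm_len=21, loop_len=10, seed=0)
    topo = count_tm_domains(prot)
    assert topo.tm_count == 7
    # ordered, non-overlapping intervals
    for (s1, e1), (s2, e2) in zip(topo.helices, topo.helices[1:]):
        assert s1 < e1 <= s2 < e2


def test_polarized_block_drops_to_six():
    prot = simulate.planted_helix_protein(n_tm=7, tm_len=21, loop_len=10, seed=0)
    topo7 = count_tm_domains(prot)
    s, e = topo7.helices[3]
    polarized = prot[:s] + "S" * (e - s) + prot[e:]
    assert count_tm_domains(polarized).tm_count == 6


def test_polyserine_has_no_helices():
    assert count_tm_domains("S" * 300).tm_count == 0


def test_tm_counter_input_validation():
    with pytest.raises(ValueError):
        count_tm_domains("M" * 50)
    with pytest.raises(ValueError):
        count_tm_domains("X" * 150)


# ----------------------------------------------------------------------
# status rules


def _clean_evidence(length: int) -> PseudogeneEvidence:
    return PseudogeneEvidence(False, FrameshiftEvidence("ref", [], []), length)


def test_length_649_is_pseudogene():
    rec = classify_status("x", REF[:649], _clean_evidence(649))
    assert rec.status == STATUS_PSEUDOGENE


def test_length_650_passes_the_length_rule():
    rec = classify_status(
        "x", REF[:650], _clean_evidence(650),
        tm_counter=lambda p: TMTopology([(0, 20)] * 7),
    )
    assert rec.status != STATUS_PSEUDOGENE


def test_full_length_seven_tm_is_functional():
    rec = classify_status("x", REF, _clean_evidence(933))
    assert rec.status == STATUS_FUNCTIONAL
    assert rec.tm_count == 7


def test_full_length_six_tm_is_sub7tm():
    rec = classify_status(
        "x", REF, _clean_evidence(933),
        tm_counter=lambda p: TMTopology([(0, 20)] * 6),
    )
    assert rec.status == STATUS_SUB7TM


def test_disruption_trumps_tm():
    ev = PseudogeneEvidence(True, FrameshiftEvidence("ref", [], []), 933)
    assert classify_status("x", REF, ev).status == STATUS_PSEUDOGENE


# ----------------------------------------------------------------------
# alignment trimming


def test_trim_removes_column_with_90pct_gaps():
    rows = ["A" + "C" for _ in range(10)]
    rows = [("-" if i < 9 else "A") + "C" for i in range(10)]
    out = trim_alignment(rows)
    assert out == ["C"] * 10


def test_trim_keeps_gapfree_alignment():
    rows = ["ACGT", "ACGT", "TGCA"]
    assert trim_alignment(rows) == rows


def test_trim_boundary_at_exactly_080():
    # column missing fractions: 0, 0.2, 0.8, 0.9, 1.0 over 10 rows
    fracs = [0, 2, 8, 9, 10]
    rows = []
    for r in range(10):
        rows.append("".join("-" if r < k else "A" for k in fracs))
    out = trim_alignment(rows)
    assert all(len(r) == 3 for r in out)  # 0, 0.2 and the 0.8 boundary kept


def test_trim_rejects_empty_and_ragged():
    with pytest.raises(ValueError):
        trim_alignment([])
    with pytest.raises(ValueError):
        trim_alignment(["AC", "A"])


@settings(max_examples=30, deadline=None, derandomize=True)
@given(
    st.lists(
        st.text(alphabet="ACGT-N", min_size=12, max_size=12), min_size=2, max_size=8
    )
)
def test_trim_is_idempotent(rows):
    once = trim_alignment(rows)
    if once and once[0]:
        assert trim_alignment(once) == once
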