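"""Protein alignment bookkeeping and the difference taxonomy."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from asmannot.core import ProteinRecord
from asmannot.proteins import (
    ProteinAlignment,
    align_proteins,
    classify_protein_pair,
    modified_identity,
)
from oracles import gotoh_free_end_score

AA = "ACDEFGHIKLMNPQRSTVWY"


def _random_protein(rng, n):
    return "".join(rng.choice(list(AA), size=n))


def _rec(seq, rid="p"):
    return ProteinRecord(rid, seq)


# --- alignment bookkeeping ----------------------------------------------


def test_self_alignment_counts():
    rng = np.random.default_rng(1)
    seq = _random_protein(rng, 80)
    a = align_proteins(_rec(seq), _rec(seq, "q"))
    assert a.columns == 80
    assert a.identical == 80
    assert a.gap_columns == 0
    assert (a.overhang_p_head, a.overhang_p_tail, a.overhang_q_head, a.overhang_q_tail) == (0, 0, 0, 0)


def test_tail_extension_appears_as_overhang():
    rng = np.random.default_rng(2)
    core = _random_protein(rng, 60)
    tail = _random_protein(rng, 15)
    a = align_proteins(_rec(core + tail), _rec(core, "q"))
    assert a.overhang_p_tail == 15
    assert a.identical == 60


def test_alignment_score_matches_gotoh_oracle():
    """The package's affine free-end-gap scores equal an independent DP."""
    rng = np.random.default_rng(3)
    for trial in range(25):
        n, m = rng.integers(5, 51, size=2)
        p = _random_protein(rng, n)
        q = _random_protein(rng, m)
        a = align_proteins(_rec(p), _rec(q, "q"))
        assert a.score == pytest.approx(gotoh_free_end_score(p, q)), f"trial {trial}"


def test_modified_identity_formula():
    # 100 columns, 10 of them gaps, 85 identical -> 85/90
    a = ProteinAlignment(100, 85, 10, 2, 5, 0, 0, 0, 0, 0.0)
    assert modified_identity(a) == pytest.approx(85 / 90)
    assert a.identity == pytest.approx(0.85)


def test_modified_identity_no_residue_columns():
    a = ProteinAlignment(10, 0, 10, 1, 10, 0, 0, 0, 0, 0.0)
    with pytest.raises(ZeroDivisionError):
        modified_identity(a)


# --- classification ------------------------------------------------------


@pytest.fixture(scope="module")
def base_protein():
    rng = np.random.default_rng(10)
    return _random_protein(rng, 200)


def test_identical(base_protein):
    assert classify_protein_pair(_rec(base_protein), _rec(base_protein, "q")) == "identical"


def test_near_identical_with_scattered_substitutions(base_protein):
    rng = np.random.default_rng(11)
    seq = list(base_protein)
    for pos in rng.choice(len(seq), size=6, replace=False):
        seq[pos] = "W" if seq[pos] != "W" else "Y"
    assert classify_protein_pair(_rec("".join(seq)), _rec(base_protein, "q")) == "near_identical"


def test_extension_is_longer_predicted(base_protein):
    rng = np.random.default_rng(12)
    pred = base_protein + _random_protein(rng, 25)
    assert classify_protein_pair(_rec(pred), _rec(base_protein, "q")) == "extension"


def test_truncation_is_shorter_predicted(base_protein):
    pred = base_protein[:-40]
    assert classify_protein_pair(_rec(pred), _rec(base_protein, "q")) == "truncation"


def test_divergent_ends_when_both_tails_unalignable(base_protein):
    rng = np.random.default_rng(13)
    pred = base_protein[:-40] + _random_protein(rng, 40)
    got = classify_protein_pair(_rec(pred), _rec(base_protein, "q"))
    assert got == "divergent_ends"


def test_gapped_for_internal_exon_sized_deletion(base_protein):
    pred = base_protein[:80] + base_protein[110:]  # clean 30-aa internal loss
    assert classify_protein_pair(_rec(pred), _rec(base_protein, "q")) == "gapped"


def test_different_for_low_identity(base_protein):
    rng = np.random.default_rng(14)
    seq = list(base_protein)
    idxs = rng.choice(len(seq), size=130, replace=False)
    for pos in idxs:
        choices = [c for c in AA if c != seq[pos]]
        seq[pos] = choices[int(rng.integers(len(choices)))]
    got = classify_protein_pair(_rec("".join(seq)), _rec(base_protein, "q"))
    assert got in ("different", "divergent_ends")  # ends may fail to align at 65% noise
    assert got != "near_identical"


def test_stop_codons_count_as_mismatches(base_protein):
    seq = base_protein[:100] + "*" + base_protein[101:]
    a = align_proteins(_rec(seq), _rec(base_protein, "q"))
    assert a.identical == 199  # the stop column is aligned but never identical


def test_frameshifted_conceptual_translation_not_near_identical():
    """A gene whose internal exons sit on an inverted contig translates to
    a protein with internal stops that never classifies as (near-)identical."""
    from asmannot.core import conceptual_translation
    from asmannot.scenarios import inverted_frameshift_scenario

    bundle = inverted_frameshift_scenario(seed=15)
    t = bundle.annot_b.transcripts[0]
    predicted = conceptual_translation(t, bundle.genome_b)
    model = _rec(bundle.proteins[t.id], "model")
    got = classify_protein_pair(predicted, model)
    assert got not in ("identical", "near_identical")


@settings(max_examples=40, deadline=None)
@given(st.text(alphabet=AA, min_size=1, max_size=60))
def test_classify_self_is_identical(seq):
    assert classify_protein_pair(_rec(seq), _rec(seq, "q")) == "identical"
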