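"""Structure comparability, compatibility margins, priority classes,
best-match assignment and rollups."""

import pytest

from asmannot.structures import (
    MatchClass,
    ROLLUP,
    assign_best_match,
    classify_pair,
    common_exons,
    exonic_overlap,
    is_comparable,
    is_compatible,
    reciprocal_one_to_one,
    summarize_classes,
    validate_unique,
)
from conftest import make_transcript


BASE = [(1000, 1200), (1500, 1700), (2000, 2200), (2500, 2700)]


def shift_exon(coords, idx, ds=0, de=0):
    out = [list(c) for c in coords]
    out[idx][0] += ds
    out[idx][1] += de
    return [tuple(c) for c in out]


# --- comparability -------------------------------------------------------


def test_identical_structures_comparable_and_compatible():
    a = make_transcript("a", "c", BASE)
    b = make_transcript("b", "c", BASE)
    assert is_comparable(a, b)
    assert is_compatible(a, b)
    assert classify_pair(a, b) == MatchClass.P2_IDENTICAL


def test_overlap_below_50bp_not_comparable():
    a = make_transcript("a", "c", [(1000, 1200)])
    b49 = make_transcript("b", "c", [(1152, 1400)])  # 49 bp overlap
    b50 = make_transcript("b", "c", [(1151, 1400)])  # 50 bp overlap
    assert not is_comparable(a, b49)
    assert is_comparable(a, b50)


def test_multi_exon_pairs_need_a_shared_intron():
    a = make_transcript("a", "c", BASE)
    # all boundaries shifted by 40 bp: plenty of exonic overlap, no shared intron
    b = make_transcript("b", "c", [(s + 40, e + 40) for s, e in BASE])
    assert exonic_overlap(a, b) > 500
    assert not is_comparable(a, b)
    # a single-exon partner is exempt from the intron requirement
    s = make_transcript("s", "c", [(1000, 1200)])
    assert is_comparable(s, a) and is_comparable(a, s)


# --- compatibility margin ------------------------------------------------


@pytest.mark.parametrize("shift,compatible", [(19, True), (20, True), (21, False)])
def test_boundary_margin_is_20bp(shift, compatible):
    a = make_transcript("a", "c", BASE)
    b = make_transcript("b", "c", shift_exon(BASE, 1, de=shift))
    assert is_compatible(a, b) is compatible
    assert is_compatible(b, a) is compatible  # symmetric


def test_missing_internal_exon_incompatible():
    a = make_transcript("a", "c", [BASE[0], BASE[2], BASE[3]])  # exon 2 absent
    b = make_transcript("b", "c", BASE)
    assert is_comparable(a, b)
    assert not is_compatible(a, b)
    assert classify_pair(a, b) == MatchClass.P7_COMPLEX


# --- priority classes ----------------------------------------------------


def test_name_and_evidence_give_p1():
    a = make_transcript("a", "c", BASE, gene_name="G", evidence="E1")
    b = make_transcript("b", "c", BASE, gene_name="G", evidence="E1")
    assert classify_pair(a, b) == MatchClass.P1_NAME_AND_EVIDENCE
    b2 = make_transcript("b2", "c", BASE, gene_name="G", evidence="E2")
    assert classify_pair(a, b2) == MatchClass.P2_IDENTICAL


def test_mapped_structure_overreaching_annotation_is_extension():
    # a carries one extra upstream exon beyond the annotated candidate
    a = make_transcript("a", "c", [(500, 700)] + BASE)
    b = make_transcript("b", "c", BASE)
    assert classify_pair(a, b) == MatchClass.P3_SINGLE_EXTENSION
    a2 = make_transcript("a2", "c", [(500, 700)] + BASE + [(3000, 3200)])
    assert classify_pair(a2, b) == MatchClass.P4_DOUBLE_EXTENSION


def test_mapped_structure_ending_short_is_truncation():
    # a lost its last exon relative to the annotation: the gene is truncated
    a = make_transcript("a", "c", BASE[:-1])
    b = make_transcript("b", "c", BASE)
    assert classify_pair(a, b) == MatchClass.P5_SINGLE_TRUNCATION
    a2 = make_transcript("a2", "c", BASE[1:-1])
    assert classify_pair(a2, b) == MatchClass.P6_TRUNCATION_OR_MIXED


def test_truncation_plus_extension_counts_with_p6():
    a = make_transcript("a", "c", [(500, 700)] + BASE[:-1])
    b = make_transcript("b", "c", BASE)
    assert classify_pair(a, b) == MatchClass.P6_TRUNCATION_OR_MIXED


def test_classification_exhaustive_and_exclusive():
    b = make_transcript("b", "c", BASE)
    variants = [
        make_transcript("v1", "c", BASE),
        make_transcript("v2", "c", BASE[:-1]),
        make_transcript("v3", "c", [(500, 700)] + BASE),
        make_transcript("v4", "c", [BASE[0], BASE[2], BASE[3]]),
        make_transcript("v5", "c", shift_exon(BASE, 1, de=25)),
    ]
    for v in variants:
        mc = classify_pair(v, b)
        assert mc in MatchClass
        assert ROLLUP[mc] in ("identical", "extensions", "truncations", "both", "complex")


def test_classify_requires_comparable():
    a = make_transcript("a", "c", [(1, 40)])
    b = make_transcript("b", "c", [(5000, 5100)])
    with pytest.raises(ValueError):
        classify_pair(a, b)


# --- best match ----------------------------------------------------------


def test_best_match_prefers_lower_priority():
    a = make_transcript("a", "c", BASE)
    p2 = make_transcript("p2", "c", BASE)
    p3 = make_transcript("p3", "c", BASE[:-1])  # a extends beyond this one
    bm = assign_best_match(a, [p3, p2])
    assert bm.candidate_id == "p2"
    assert bm.match_class == MatchClass.P2_IDENTICAL


def test_best_match_tie_broken_by_common_exons():
    a = make_transcript("a", "c", [BASE[0], BASE[2], BASE[3]])
    # c3 shares 3 exons with a; c1 shares the last intron but no exon
    c3 = make_transcript("c3", "c", [(990, 1200), BASE[1], BASE[2], BASE[3]])
    c1 = make_transcript("c1", "c", [(900, 1190), (1970, 2200), (2500, 2800)])
    assert classify_pair(a, c3) == classify_pair(a, c1) == MatchClass.P7_COMPLEX
    assert common_exons(a, c3) > common_exons(a, c1)
    bm = assign_best_match(a, [c1, c3])
    assert bm.candidate_id == "c3"


def test_best_match_empty_candidates_is_none():
    a = make_transcript("a", "c", BASE)
    assert assign_best_match(a, []) is None


def test_summary_rollup_counts_sum_to_total():
    a = make_transcript("a", "c", BASE)
    bms = [
        assign_best_match(make_transcript("m1", "c", BASE), [a]),
        assign_best_match(make_transcript("m2", "c", BASE[:-1]), [a]),
        assign_best_match(make_transcript("m3", "c", [BASE[0], BASE[2], BASE[3]]), [a]),
    ]
    s = summarize_classes(bms)
    assert s.total == 3
    assert s.counts["identical"] == 1
    assert s.counts["truncations"] == 1
    assert s.counts["complex"] == 1


# --- one-to-one correspondence -------------------------------------------


def test_reciprocal_one_to_one_clean_and_empty():
    ab = {"a1": "b1", "a2": "b2"}
    ba = {"b1": "a1", "b2": "a2"}
    assert reciprocal_one_to_one(ab, ba) == {("a1", "b1"), ("a2", "b2")}
    assert reciprocal_one_to_one({}, {}) == set()


def test_reciprocal_one_to_one_excludes_shared_targets():
    ab = {"a1": "b1", "a2": "b1"}  # two A genes hit the same B gene
    ba = {"b1": "a1"}
    assert reciprocal_one_to_one(ab, ba) == set()


def test_duplicated_gene_breaks_one_to_one():
    from asmannot.pipeline import PipelineConfig, compare_structures_direction
    from asmannot.scenarios import duplicated_gene_scenario

    bundle = duplicated_gene_scenario(seed=14)
    cfg = PipelineConfig()
    rep = compare_structures_direction(
        bundle.mrnas, bundle.annot_a, bundle.genome_b, bundle.annot_b, cfg
    )
    tid = bundle.annot_a.transcripts[0].id
    # both copies align equally well: the mapped transcript has two primary
    # alignments, so it cannot be in one-to-one correspondence
    primaries = [a for a in rep.alignments[tid] if a.is_primary]
    assert len(primaries) == 2
    best_ab = {q: bm.candidate_id for q, bm in rep.best_matches.items()}
    ba = {bm.candidate_id: q for q, bm in rep.best_matches.items()}
    # the duplicate copy is not anyone's reciprocal partner
    pairs = reciprocal_one_to_one(best_ab, ba)
    assert all(b in (tid, tid + "_dup") for _a, b in pairs) or pairs == set()


# --- validation of unique transcripts ------------------------------------


def test_validate_unique_sequence_search():
    import numpy as np

    rng = np.random.default_rng(3)
    big = "".join(rng.choice(list("ACGT"), size=600))
    small = big[200:296]  # a 96-bp gene fully contained in the other mRNA
    absent = "".join(rng.choice(list("ACGT"), size=300))
    hits = validate_unique({"q_same": big, "q_small": small, "q_absent": absent}, {"m": big})
    by_query = {h.query_id: h for h in hits}
    assert by_query["q_same"].identity >= 0.99 and by_query["q_same"].complete
    assert by_query["q_small"].complete  # complete hit for the contained gene
    assert "q_absent" not in by_query
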