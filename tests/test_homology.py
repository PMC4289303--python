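"""Gene-order encoding, repeated-motif detection (with brute-force oracle),
homology-unit assembly and the identity dotplot."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from trlocus import datasets
from trlocus.homology import (
    GeneOrderString,
    OrderToken,
    brute_force_repeats,
    build_homology_units,
    encode_gene_order,
    find_repeated_motifs,
    identity_dotplot,
    maximal_repeats,
    unit_coverage,
)


def make_string(labels, contig="c1"):
    return GeneOrderString(contig=contig, tokens=[
        OrderToken(label=l, strand="+", gene_id=f"{contig}.g{i}", index=i)
        for i, l in enumerate(labels)])


def test_encode_gene_order_follows_coordinates(default_sim):
    _, annotation, _ = default_sim
    (string,) = encode_gene_order(annotation)
    genes = sorted(annotation.v_genes(), key=lambda g: g.span.start)
    assert [t.gene_id for t in string.tokens] == [g.id for g in genes]
    assert [t.label for t in string.tokens] == [g.subgroup for g in genes]


def test_unassigned_genes_become_unmatchable_tokens(default_sim):
    _, annotation, _ = default_sim
    annotation.v_genes()[0].subgroup = "unassigned"
    annotation.v_genes()[1].subgroup = "unassigned"
    try:
        (string,) = encode_gene_order(annotation)
        placeholders = [t.label for t in string.tokens
                        if t.label.startswith("?")]
        assert len(placeholders) == 2 and len(set(placeholders)) == 2
    finally:
        # fixture is session-scoped; restore the labels
        annotation.v_genes()[0].subgroup = \
            annotation.v_genes()[0].id.rsplit("-", 1)[0]
        annotation.v_genes()[1].subgroup = \
            annotation.v_genes()[1].id.rsplit("-", 1)[0]


def test_all_distinct_labels_yield_no_motifs():
    assert find_repeated_motifs([make_string("ABCDEF")]) == []


def test_simple_repeat_found_with_three_instances():
    motifs = find_repeated_motifs([make_string("ABXABYAB")], min_len=2)
    (motif,) = [m for m in motifs if m.labels == ("A", "B")]
    assert [o.start for o in motif.instances] == [0, 3, 6]


def test_tandem_array_reports_primitive_motif():
    motifs = find_repeated_motifs([make_string("23" * 7)], min_len=2)
    two_three = [m for m in motifs if m.labels == ("2", "3")]
    assert len(two_three) == 1
    assert len(two_three[0].instances) == 7


@settings(max_examples=120, deadline=None, derandomize=True)
@given(st.lists(st.sampled_from("AABBC"), min_size=2, max_size=30))
def test_maximal_repeats_agree_with_brute_force(labels):
    seqs = [tuple(labels)]
    found = maximal_repeats(seqs, min_len=2, min_occ=2)
    oracle_all = brute_force_repeats([make_string(labels)], 2, 2)
    # every maximal repeat is a brute-force repeat ...
    assert set(found) <= oracle_all
    # ... every brute-force repeat extends to exactly one count-preserving
    # maximal repeat, computed by the independent count-based criterion
    for w in oracle_all:

        def occ(m):
            s = seqs[0]
            return sum(s[i:i + len(m)] == m
                       for i in range(len(s) - len(m) + 1))

        is_maximal = not any(
            occ(ext) == occ(w)
            for x in set(labels)
            for ext in ((x,) + w, w + (x,)))
        assert (w in found) == is_maximal


def test_unit_from_identical_instances_has_no_flags():
    string = make_string(list("ABC") + ["s0"] + list("ABC") + ["s1"])
    units = build_homology_units(find_repeated_motifs([string]), [string])
    (unit,) = units
    assert unit.consensus == ("A", "B", "C")
    assert len(unit.instances) == 2
    assert not unit.variable_content and not unit.post_replication_indel


def test_extra_gene_in_one_replicon_flags_post_replication_indel():
    base = ["33", "29", "28", "33", "34", "26", "33"]
    extra = ["33", "29", "28", "28", "33", "34", "26", "33"]
    string = make_string(base + ["s0"] + extra + ["s1"])
    units = build_homology_units(find_repeated_motifs([string]), [string],
                                 merge_edit_distance=2)
    units = [u for u in units if "29" in u.consensus]
    assert len(units) == 1
    assert len(units[0].instances) == 2
    assert units[0].post_replication_indel


def test_truncated_replicon_merges_and_counts_as_variable_content():
    base = list("ABCD")
    string = make_string(base + ["s0"] + base + ["s1"] + base[:3] + ["s2"])
    units = build_homology_units(find_repeated_motifs([string]), [string],
                                 merge_edit_distance=2)
    (unit,) = [u for u in units if u.consensus == ("A", "B", "C", "D")]
    assert len(unit.instances) == 3
    assert unit.variable_content


def test_simulated_units_recovered_exactly(default_sim):
    _, annotation, truth = default_sim
    strings = encode_gene_order(annotation)
    units = build_homology_units(find_repeated_motifs(strings), strings)
    recovered = {u.consensus: len(u.instances) for u in units}
    for true_unit in truth.true_units:
        motif = true_unit["motif"]
        assert recovered.get(motif) == len(true_unit["instances"])


def test_unit_coverage_counting(default_sim):
    _, annotation, _ = default_sim
    strings = encode_gene_order(annotation)
    units = build_homology_units(find_repeated_motifs(strings), strings)
    cov = unit_coverage(annotation, units)
    assert cov["total"] == len(annotation.v_genes())
    assert cov["fraction"] == pytest.approx(
        cov["genes_in_units"] / cov["total"])
    assert unit_coverage(annotation, [])["fraction"] == 0.0


def test_published_unit_playback_recovers_12_11_10_9_six_times():
    order = datasets.reference_gene_order()
    motifs = find_repeated_motifs([order])
    target = ("12", "11", "10", "9")
    hits = [m for m in motifs
            if any(m.labels[i:i + 4] == target
                   for i in range(len(m.labels) - 3))]
    assert hits and len(hits[0].instances) == 6


def test_dotplot_self_comparison_has_full_main_diagonal():
    rng = np.random.default_rng(1)
    seq = "".join(rng.choice(list("ACGT"), 3000))
    segments = identity_dotplot(seq, seq, k=12, min_run=1000)
    main = [s for s in segments if s.a_start == s.b_start == 0
            and s.strand == "+"]
    assert main and main[0].a_end == len(seq) and main[0].identity == 100.0


def test_dotplot_finds_planted_duplication():
    rng = np.random.default_rng(2)
    bg = "".join(rng.choice(list("ACGT"), 9000))
    block = "".join(rng.choice(list("ACGT"), 5000))
    seq = bg[:2000] + block + bg[2000:4000] + block + bg[4000:]
    segments = identity_dotplot(seq, seq, k=12, min_run=2000)
    off = [s for s in segments if s.a_start != s.b_start and s.strand == "+"]
    assert len(off) == 2
    assert all(abs((s.a_end - s.a_start) - 5000) < 200 for s in off)


def test_dotplot_reverse_complement_copy_on_minus_strand():
    rng = np.random.default_rng(3)
    block = "".join(rng.choice(list("ACGT"), 2000))
    rc = block.translate(str.maketrans("ACGT", "TGCA"))[::-1]
    filler = "".join(rng.choice(list("ACGT"), 1000))
    seq_b = filler + rc + filler
    segments = identity_dotplot(block, seq_b, k=12, min_run=1500)
    minus = [s for s in segments if s.strand == "-"]
    assert minus
    assert minus[0].b_start == pytest.approx(1000, abs=50)


def test_dotplot_rejects_tiny_word_size():
    with pytest.raises(ValueError):
        identity_dotplot("ACGTACGT", "ACGTACGT", k=4)
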