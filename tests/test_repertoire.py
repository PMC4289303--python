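"""Transcript-to-catalog matching, the 97% trichotomy, usage frequencies,
representation bias and dual usage."""

import numpy as np
import pytest

from trlocus.records import TranscriptRecord
from trlocus.repertoire import (
    dual_usage,
    match_transcripts,
    match_v_segment,
    percent_identity,
    representation_bias,
    summarize_matches,
    usage_frequencies,
)
from trlocus.simulate import mutate


@pytest.fixture()
def catalog(rng):
    base = "".join(rng.choice(list("ACGT"), 300))
    return {
        "g1": base,
        "g2": mutate(base, 30, np.random.default_rng(1)),
        "g3": "".join(rng.choice(list("ACGT"), 300)),
    }


def test_exact_catalog_sequence_is_identical(catalog):
    match = match_v_segment(catalog["g1"], catalog)
    assert match.best_hit == "g1"
    assert match.identity == 100.0 and match.category == "identical"


def test_exact_97_boundary_lands_in_middle_class(catalog):
    seq = mutate(catalog["g1"], 9, np.random.default_rng(2))  # 291/300 = 97.0
    match = match_v_segment(seq, catalog)
    assert match.identity == pytest.approx(97.0)
    assert match.category == "allelic_or_unassembled"


def test_below_97_is_novel(catalog):
    seq = mutate(catalog["g1"], 10, np.random.default_rng(3))  # 96.67%
    match = match_v_segment(seq, catalog)
    assert match.identity < 97.0 and match.category == "novel"


def test_tie_broken_by_catalog_order(rng):
    seq = "".join(rng.choice(list("ACGT"), 120))
    variant = mutate(seq, 2, rng)
    match = match_v_segment(variant, {"b_first": seq, "a_second": seq})
    assert match.best_hit == "b_first"


def test_match_deterministic_under_catalog_reordering_except_ties(catalog):
    seq = mutate(catalog["g2"], 4, np.random.default_rng(4))
    forward = match_v_segment(seq, catalog)
    reordered = dict(reversed(list(catalog.items())))
    assert match_v_segment(seq, reordered).identity == forward.identity
    assert match_v_segment(seq, reordered).best_hit == forward.best_hit


def test_empty_inputs_rejected(catalog):
    with pytest.raises(ValueError):
        match_v_segment("", catalog)
    with pytest.raises(ValueError):
        match_v_segment("ACGT", {})


def test_percent_identity_handles_unequal_lengths():
    assert percent_identity("ACGTACGT", "ACGTAACGT") >= 85.0


def test_summary_deduplicates_by_sequence(catalog):
    transcripts = [
        TranscriptRecord("t1", "TRA", catalog["g1"]),
        TranscriptRecord("t2", "TRA", catalog["g1"]),  # duplicate sequence
        TranscriptRecord("t3", "TRA", catalog["g2"]),
    ]
    matches = match_transcripts(transcripts, catalog)
    df = summarize_matches(matches, transcripts).set_index("category")
    assert df.loc["total", "count"] == 2
    assert df.loc["identical", "count"] == 2
    assert df.loc["identical", "percent"] == 100.0


def test_all_identical_transcripts_give_100_0_0(catalog):
    transcripts = [TranscriptRecord(f"t{i}", "TRA", seq)
                   for i, seq in enumerate(catalog.values())]
    matches = match_transcripts(transcripts, catalog)
    df = summarize_matches(matches, transcripts).set_index("category")
    assert df.loc["identical", "percent"] == 100.0
    assert df.loc["novel", "count"] == 0


def test_categories_partition_unique_sequences(default_sim,
                                               default_transcripts):
    _, annotation, _ = default_sim
    transcripts, truth = default_transcripts
    catalog = {g.id: g.v_exon for g in annotation.v_genes() if g.v_exon}
    matches = match_transcripts(transcripts, catalog)
    df = summarize_matches(matches, transcripts).set_index("category")
    assert df.loc["total", "count"] == (
        df.loc["identical", "count"] + df.loc["allelic_or_unassembled",
                                              "count"]
        + df.loc["novel", "count"])


def test_usage_single_subgroup_is_100(catalog):
    transcripts = [TranscriptRecord(f"t{i}", "TRA", catalog["g1"])
                   for i in range(5)]
    matches = match_transcripts(transcripts, catalog)
    usage = usage_frequencies(transcripts, matches, "TRA",
                              {"g1": "TRAVX", "g2": "TRAVX", "g3": "TRAV1"})
    assert usage == {"TRAVX": 100.0}


def test_usage_requires_productive_transcripts(catalog):
    transcripts = [TranscriptRecord("t1", "TRD", catalog["g1"],
                                    productive=False)]
    matches = match_transcripts(transcripts, catalog)
    with pytest.raises(ValueError):
        usage_frequencies(transcripts, matches, "TRD", {"g1": "TRDV1"})


def test_representation_bias_calls():
    df = representation_bias({"A": 25.0, "B": 25.0, "C": 25.0, "D": 25.0},
                             {"A": 25.0, "B": 25.0, "C": 25.0, "D": 25.0})
    assert set(df["call"]) == {"neutral"}
    df = representation_bias({"A": 23.0}, {"A": 8.0})
    assert df.iloc[0]["ratio"] == pytest.approx(2.875)
    assert df.iloc[0]["call"] == "over-represented"
    df = representation_bias({"A": 5.0}, {})
    assert df.iloc[0]["call"] == "undefined" and df.iloc[0]["ratio"] is None


def test_dual_usage_set_logic(catalog):
    smap = {"g1": "TRDV1", "g2": "TRAV33", "g3": "TRAVX"}
    tra = [TranscriptRecord("a1", "TRA", catalog["g3"]),
           TranscriptRecord("a2", "TRA", catalog["g1"]),
           TranscriptRecord("a3", "TRA", catalog["g2"])]
    trd = [TranscriptRecord("d1", "TRD", catalog["g1"]),
           TranscriptRecord("d2", "TRD", catalog["g2"], productive=False)]
    tra_m = match_transcripts(tra, catalog)
    trd_m = match_transcripts(trd, catalog)
    # the non-productive TRAV33 TRD transcript does not count
    assert dual_usage(tra, tra_m, trd, trd_m, smap) == {"TRDV1"}
    trd[1].productive = True
    assert dual_usage(tra, tra_m, trd, trd_m, smap) == {"TRDV1", "TRAV33"}
    # disjoint chain usage yields the empty set
    assert dual_usage(tra[:1], tra_m[:1], trd, trd_m, smap) == set()


def test_simulated_dual_subgroups_recovered():
    from trlocus.simulate import default_config, simulate_locus, \
        simulate_transcripts

    config = default_config(21)
    # concentrate usage so the shared subgroups are certainly sampled
    config.transcript_params.usage_weights = {
        "TRA": {"TRDV1": 50.0, "TRAV33": 50.0},
        "TRD": {"TRDV1": 50.0, "TRAV33": 50.0}}
    config.tra_subgroups = ["TRDV1", "TRAV33"]
    config.trd_subgroups = ["TRDV1", "TRAV33"]
    config.transcript_params.n_tra = 30
    config.transcript_params.n_trd = 30
    config.transcript_params.novel_fraction = 0.0
    annotation, truth = simulate_locus(config)
    transcripts, truth = simulate_transcripts(annotation, truth, config)
    catalog = {g.id: g.v_exon for g in annotation.v_genes() if g.v_exon}
    smap = {g.id: g.subgroup for g in annotation.v_genes()}
    tra = [t for t in transcripts if t.chain == "TRA"]
    trd = [t for t in transcripts if t.chain == "TRD"]
    shared = dual_usage(tra, match_transcripts(tra, catalog),
                        trd, match_transcripts(trd, catalog), smap)
    assert shared == {"TRDV1", "TRAV33"}


def test_novel_share_recovered_within_binomial_error(default_sim,
                                                     default_transcripts):
    _, annotation, _ = default_sim
    transcripts, truth = default_transcripts
    catalog = {g.id: g.v_exon for g in annotation.v_genes() if g.v_exon}
    matches = match_transcripts(transcripts, catalog)
    novel = sum(m.category == "novel" for m in matches)
    n = len(matches)
    se = np.sqrt(0.11 * 0.89 / n)
    assert abs(novel / n - 0.11) < 4 * se
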