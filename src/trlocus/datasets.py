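"""Reference tables for the bovine TRA/TRD locus (UMD3.1 assembly).

These are the published desk-scale numbers for the locus this pipeline is
designed around: per-subgroup V-gene competence counts, homology-unit
motifs with their replicon counts, expressed-repertoire match counts, and
cross-species functional repertoire sizes.  They serve as fixtures for the
bookkeeping operations (catalog summary, match trichotomy, unit coverage)
and as realistic targets for the simulator's study conditions.
"""

from __future__ import annotations

import itertools

import pandas as pd

from .homology import GeneOrderString, OrderToken
from .records import CompetenceCall, Lesion, TranscriptMatch

#: per-subgroup (total, functional, pseudogene, incomplete) V-gene counts of
#: the UMD3.1 bovine TRA/TRD annotation
BOVINE_V_SUBGROUP_COUNTS: dict[str, tuple[int, int, int, int]] = {
    "TRAV1": (1, 1, 0, 0),
    "TRAV2": (7, 5, 2, 0),
    "TRAV3": (7, 7, 0, 0),
    "TRAV4": (3, 2, 1, 0),
    "TRAV5": (2, 2, 0, 0),
    "TRAV6": (4, 0, 1, 3),
    "TRAV8": (14, 6, 8, 0),
    "TRAV9": (11, 1, 9, 1),
    "TRAV10": (6, 3, 3, 0),
    "TRAV11": (6, 0, 6, 0),
    "TRAV12": (6, 5, 1, 0),
    "TRAV13": (11, 8, 2, 1),
    "TRAV14": (9, 4, 4, 1),
    "TRAV16": (2, 2, 0, 0),
    "TRAV17": (3, 1, 2, 0),
    "TRAV18": (8, 3, 5, 0),
    "TRAV19": (7, 5, 2, 0),
    "TRAV20": (5, 5, 0, 0),
    "TRAV21": (4, 3, 1, 0),
    "TRAV22": (29, 14, 14, 1),
    "TRAV23": (24, 4, 20, 0),
    "TRAV24": (10, 1, 8, 1),
    "TRAV25": (22, 11, 10, 1),
    "TRAV26": (39, 22, 13, 4),
    "TRAV27": (1, 1, 0, 0),
    "TRAV28": (4, 3, 1, 0),
    "TRAV29": (3, 2, 1, 0),
    "TRAV33": (6, 2, 4, 0),
    "TRAV34": (3, 0, 3, 0),
    "TRAV35": (1, 1, 0, 0),
    "TRAV36": (1, 1, 0, 0),
    "TRAV37": (2, 0, 2, 0),
    "TRAV38": (6, 5, 1, 0),
    "TRAV39": (2, 1, 1, 0),
    "TRAV41": (1, 1, 0, 0),
    "TRAVX": (29, 23, 5, 1),
    "TRAVY": (7, 7, 0, 0),
    "TRDV1": (60, 48, 8, 4),
    "TRDV2": (1, 1, 0, 0),
    "TRDV3": (1, 1, 0, 0),
    "TRDVb3": (2, 2, 0, 0),
    "TRDVY": (1, 1, 0, 0),
}

#: homology units of the UMD3.1 bovine locus: consensus subgroup motif,
#: minimum replicon count and estimated size (kb)
BOVINE_HOMOLOGY_UNITS: list[dict] = [
    {"unit": 1, "motif": ("33", "29", "28", "33", "34", "26", "33"),
     "n_replicons": 2, "size_kb": 39},
    {"unit": 2, "motif": ("2", "3"), "n_replicons": 7, "size_kb": 15},
    {"unit": 3, "motif": ("38", "37"), "n_replicons": 2, "size_kb": 15},
    {"unit": 4, "motif": ("14", "13", "9"), "n_replicons": 5, "size_kb": 15},
    {"unit": 5, "motif": ("22", "8", "21", "20", "19", "X", "X", "X", "18",
                          "12", "11", "10", "9", "14", "13", "Y", "9"),
     "n_replicons": 6, "size_kb": 157},
    {"unit": 6, "motif": ("25", "19", "X", "X", "X", "X", "18", "17", "16"),
     "n_replicons": 3, "size_kb": 80},
    {"unit": 7, "motif": ("DV1", "22", "26", "25", "DV1", "23", "22", "8",
                          "21", "20"),
     "n_replicons": 5, "size_kb": 71},
    {"unit": 8, "motif": ("DV1", "23", "22", "26", "DV1", "25", "23", "22",
                          "26", "DV1", "25"),
     "n_replicons": 8, "size_kb": 63},
    {"unit": 9, "motif": ("DV1", "22", "8", "DV1", "26", "25", "24", "DV1",
                          "26", "DV1", "26"),
     "n_replicons": 7, "size_kb": 86},
    {"unit": 10, "motif": ("DV1", "23", "22", "24", "DV1", "23"),
     "n_replicons": 2, "size_kb": 43},
]

#: V genes located within homology units, of the locus total
GENES_IN_UNITS = 288
TOTAL_V_GENES = 371

#: expressed-repertoire match accounting: 341 unique chain sequences carried
#: 191 distinct expressed V-gene sequences splitting into the trichotomy
EXPRESSED_MATCH_COUNTS = {
    "unique_v_sequences": 191,
    "identical": 67,
    "allelic_or_unassembled": 103,
    "novel": 21,
    "unique_tra_chains": 198,
    "unique_trd_chains": 143,
}

#: functional V-gene repertoire sizes by species (maximum potential counts)
FUNCTIONAL_V_BY_SPECIES = {"bovine": 215, "human": 48, "murine": 87}

#: J-gene competence accounting for the locus
TRAJ_TOTAL = 62
TRAJ_FUNCTIONAL = 52


def catalog_counts_frame() -> pd.DataFrame:
    rows = [{"subgroup": label, "total": t, "functional": f,
             "pseudogene": p, "incomplete": i}
            for label, (t, f, p, i) in BOVINE_V_SUBGROUP_COUNTS.items()]
    return pd.DataFrame(rows)


def expand_catalog_counts(
        counts: dict[str, tuple[int, int, int, int]] | None = None,
) -> tuple[list[CompetenceCall], dict[str, str]]:
    """Transcribe per-subgroup counts into per-gene competence calls, for
    feeding the catalog summariser with the published accounting."""
    counts = counts if counts is not None else BOVINE_V_SUBGROUP_COUNTS
    calls, subgroup_map = [], {}
    for label, (total, functional, pseudo, incomplete) in counts.items():
        if functional + pseudo + incomplete != total:
            raise ValueError(f"{label}: counts do not sum to total")
        serial = itertools.count(1)
        for status, n in (("functional", functional),
                          ("pseudogene", pseudo),
                          ("incomplete", incomplete)):
            for _ in range(n):
                gene_id = f"{label}-{next(serial):03d}"
                lesions = []
                if status == "pseudogene":
                    lesions = [Lesion("unspecified")]
                elif status == "incomplete":
                    lesions = [Lesion("missing_sequence")]
                calls.append(CompetenceCall(gene_id=gene_id, status=status,
                                            lesions=lesions))
                subgroup_map[gene_id] = label
    return calls, subgroup_map


def expand_match_counts(counts: dict | None = None) -> list[TranscriptMatch]:
    """Transcribe the published match accounting into per-sequence matches
    (representative identities per category)."""
    counts = counts if counts is not None else EXPRESSED_MATCH_COUNTS
    matches = []
    serial = itertools.count(1)
    for category, ident in (("identical", 100.0),
                            ("allelic_or_unassembled", 98.3),
                            ("novel", 94.6)):
        for _ in range(counts[category]):
            matches.append(TranscriptMatch(
                transcript_id=f"seq-{next(serial):03d}",
                best_hit="catalog", identity=ident, category=category))
    return matches


def reference_gene_order() -> GeneOrderString:
    """Synthetic reconstruction of the locus gene order within homology
    units: each published unit motif repeated for its replicon count, with
    unique non-matchable filler tokens between arrays.

    This is a stand-in built from the published unit table (the full
    per-gene order of the assembly is not redistributed here); it preserves
    exactly the property the motif finder is asked to recover — each unit's
    motif recurring ``n_replicons`` times.
    """
    tokens: list[OrderToken] = []
    filler = itertools.count()
    idx = itertools.count()
    serial = itertools.count(1)
    for unit in BOVINE_HOMOLOGY_UNITS:
        for _ in range(unit["n_replicons"]):
            for label in unit["motif"]:
                tokens.append(OrderToken(label=label, strand="+",
                                         gene_id=f"g{next(serial):04d}",
                                         index=next(idx)))
        tokens.append(OrderToken(label=f"?f{next(filler)}", strand="+",
                                 gene_id=f"filler{next(filler)}",
                                 index=next(idx)))
    return GeneOrderString(contig="synthetic_unit_playback", tokens=tokens)
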