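"""Expressed-repertoire analysis: matching transcript V segments to the
genomic V-gene catalog, the identical / allelic-or-unassembled / novel
trichotomy, subgroup usage frequencies and representation bias, and
dual-usage detection.

The 97% nucleotide-identity convention separates products of distinct V
genes (< 97%) from allelic variants or unassembled close paralogues
(>= 97% but not identical).  Exactly 97.0% falls in the middle class; only
100% counts as an identical genome match.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import pandas as pd

from .records import TranscriptMatch, TranscriptRecord
from .subgroups import align_pair

IDENTICAL = "identical"
ALLELIC = "allelic_or_unassembled"
NOVEL = "novel"

_EPS = 1e-9


def percent_identity(seq_a: str, seq_b: str) -> float:
    """Percent identity from a global alignment under pairwise deletion.

    Equal-length inputs shortcut to a positionwise comparison, which the
    alignment parameters (gap open -4) would reproduce for the small
    divergences relevant here.
    """
    if not seq_a or not seq_b:
        raise ValueError("empty sequence")
    if len(seq_a) == len(seq_b):
        matches = sum(a == b for a, b in zip(seq_a, seq_b))
        return 100.0 * matches / len(seq_a)
    a, b = align_pair(seq_a, seq_b)
    sites = matches = 0
    for x, y in zip(a, b):
        if x == "-" or y == "-":
            continue
        sites += 1
        matches += x == y
    if sites == 0:
        raise ValueError("no comparable sites")
    return 100.0 * matches / sites


def categorize(identity: float, threshold: float = 97.0) -> str:
    if identity >= 100.0 - _EPS:
        return IDENTICAL
    if identity >= threshold - _EPS:
        return ALLELIC
    return NOVEL


def match_v_segment(seq: str, catalog: dict[str, str],
                    transcript_id: str = "",
                    threshold: float = 97.0) -> TranscriptMatch:
    """Best genomic hit for one expressed V segment.

    The best hit maximizes percent identity over the catalog; ties go to the
    gene listed first (genomic order).  The category follows the trichotomy
    with 97.0% inclusive in the middle class.
    """
    if not catalog:
        raise ValueError("empty catalog")
    best_id, best_ident = None, -1.0
    for gene_id, gene_seq in catalog.items():
        ident = percent_identity(seq, gene_seq)
        if ident > best_ident + _EPS:
            best_id, best_ident = gene_id, ident
    return TranscriptMatch(transcript_id=transcript_id, best_hit=best_id,
                           identity=round(best_ident, 4),
                           category=categorize(best_ident, threshold))


def match_transcripts(transcripts: Sequence[TranscriptRecord],
                      catalog: "dict[str, str]",
                      threshold: float = 97.0) -> list[TranscriptMatch]:
    return [match_v_segment(t.v_segment, catalog, transcript_id=t.id,
                            threshold=threshold)
            for t in transcripts]


def summarize_matches(matches: Sequence[TranscriptMatch],
                      transcripts: Optional[Sequence[TranscriptRecord]] = None,
                      ) -> pd.DataFrame:
    """Trichotomy counts and percentages over unique expressed V sequences.

    When ``transcripts`` are supplied, matches are first deduplicated by
    exact V-segment nucleotide sequence (the first transcript carrying each
    distinct sequence represents it); otherwise every match is counted.
    """
    if transcripts is not None:
        seq_of = {t.id: t.v_segment for t in transcripts}
        seen: set[str] = set()
        unique = []
        for match in matches:
            seq = seq_of[match.transcript_id]
            if seq not in seen:
                seen.add(seq)
                unique.append(match)
        matches = unique
    counts = {IDENTICAL: 0, ALLELIC: 0, NOVEL: 0}
    for match in matches:
        counts[match.category] += 1
    total = sum(counts.values())
    rows = [{"category": cat, "count": n,
             "percent": round(100.0 * n / total, 1) if total else 0.0}
            for cat, n in counts.items()]
    rows.append({"category": "total", "count": total,
                 "percent": 100.0 if total else 0.0})
    return pd.DataFrame(rows, columns=["category", "count", "percent"])


def usage_frequencies(transcripts: Sequence[TranscriptRecord],
                      matches: Sequence[TranscriptMatch],
                      chain: str,
                      subgroup_of_gene: dict[str, str]) -> dict[str, float]:
    """Per-subgroup percentage of the chain's productive transcripts.

    Every transcript takes the subgroup of its best genomic hit (novel
    transcripts still belong to an identified subgroup, just not to an
    annotated gene).
    """
    match_of = {m.transcript_id: m for m in matches}
    pool = [t for t in transcripts if t.chain == chain and t.productive]
    if not pool:
        raise ValueError(f"no productive transcripts for chain {chain}")
    counts: dict[str, int] = {}
    for t in pool:
        subgroup = subgroup_of_gene.get(match_of[t.id].best_hit, "unassigned")
        counts[subgroup] = counts.get(subgroup, 0) + 1
    return {s: round(100.0 * c / len(pool), 1)
            for s, c in sorted(counts.items())}


def representation_bias(expressed: dict[str, float],
                        genomic_functional: dict[str, float],
                        over_ratio: float = 2.0,
                        under_ratio: float = 0.5) -> pd.DataFrame:
    """Expressed-vs-genomic representation per subgroup.

    ratio = expressed% / genomic%; a subgroup is over-represented at
    ratio >= ``over_ratio``, under-represented at <= ``under_ratio``;
    subgroups absent from the genomic table are flagged undefined.
    """
    rows = []
    for subgroup in sorted(set(expressed) | set(genomic_functional)):
        e = expressed.get(subgroup, 0.0)
        g = genomic_functional.get(subgroup, 0.0)
        if g == 0:
            ratio, call = None, ("undefined" if e > 0 else "neutral")
        else:
            ratio = round(e / g, 3)
            call = ("over-represented" if ratio >= over_ratio
                    else "under-represented" if ratio <= under_ratio
                    else "neutral")
        rows.append({"subgroup": subgroup, "expressed_pct": e,
                     "genomic_pct": g, "ratio": ratio, "call": call})
    return pd.DataFrame(rows, columns=["subgroup", "expressed_pct",
                                       "genomic_pct", "ratio", "call"])


def dual_usage(tra_transcripts: Sequence[TranscriptRecord],
               tra_matches: Sequence[TranscriptMatch],
               trd_transcripts: Sequence[TranscriptRecord],
               trd_matches: Sequence[TranscriptMatch],
               subgroup_of_gene: dict[str, str]) -> set[str]:
    """Subgroups with at least one productive transcript in each chain."""

    def used(transcripts: Iterable[TranscriptRecord],
             matches: Sequence[TranscriptMatch]) -> set[str]:
        match_of = {m.transcript_id: m for m in matches}
        return {subgroup_of_gene.get(match_of[t.id].best_hit, "unassigned")
                for t in transcripts if t.productive}

    return (used(tra_transcripts, tra_matches)
            & used(trd_transcripts, trd_matches))


def matches_table(matches: Sequence[TranscriptMatch]) -> pd.DataFrame:
    return pd.DataFrame([vars(m) for m in matches],
                        columns=["transcript_id", "best_hit", "identity",
                                 "category"])


@dataclass
class RepertoireSummary:
    """Bundle of the stage outputs the report writer consumes."""

    matches: pd.DataFrame
    trichotomy: pd.DataFrame
    usage: dict[str, dict[str, float]]
    bias: Optional[pd.DataFrame] = None
    dual: Optional[set] = None
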