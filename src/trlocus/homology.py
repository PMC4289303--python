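"""Homology-unit discovery: repeated gene-order motifs, replicon alignment,
coverage statistics and a dotplot-style nucleotide identity profiler.

Loci expanded by tandem duplication of multi-gene segments leave a
fingerprint in the gene order: the subgroup-label sequence of the duplicated
segment recurs along the locus.  Units are found symbolically — maximal
exact repeated label subsequences, reduced to their primitive period so a
tandem array of k copies is reported as k replicons of the unit motif rather
than one long periodic repeat — and instances are resolved greedily
(leftmost, longest first, non-overlapping).  Sequence-level identity
(the dotplot) is confirmatory and does not define units.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import pandas as pd

from .records import LocusAnnotation


@dataclass(frozen=True)
class OrderToken:
    label: str
    strand: str
    gene_id: str
    index: int  # genomic order index within the contig


@dataclass
class GeneOrderString:
    contig: str
    tokens: list[OrderToken]

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(t.label for t in self.tokens)


@dataclass(frozen=True)
class Occurrence:
    string_idx: int
    start: int
    length: int

    @property
    def end(self) -> int:
        return self.start + self.length

    def overlaps(self, other: "Occurrence") -> bool:
        return (self.string_idx == other.string_idx
                and self.start < other.end and other.start < self.end)


@dataclass
class Motif:
    labels: tuple[str, ...]
    instances: list[Occurrence]


@dataclass
class RepliconInstance:
    contig: str
    start: int  # token index span within the contig's gene order
    end: int
    gene_ids: list[str]
    #: alignment of the instance against the unit consensus:
    #: ("match"|"missing"|"extra", consensus position | None, gene id | None)
    edits: list[tuple] = field(default_factory=list)


@dataclass
class HomologyUnit:
    id: int
    consensus: tuple[str, ...]
    instances: list[RepliconInstance]
    variable_content: bool = False
    post_replication_indel: bool = False

    @property
    def gene_ids(self) -> set[str]:
        return {g for inst in self.instances for g in inst.gene_ids}


def encode_gene_order(annotation: LocusAnnotation) -> list[GeneOrderString]:
    """One token string per contig, V genes in coordinate order.  Genes with
    no subgroup label become unique, never-matchable '?' tokens."""
    per_contig: dict[str, list] = {}
    for gene in annotation.v_genes():
        per_contig.setdefault(gene.contig, []).append(gene)
    strings = []
    unlabeled = itertools.count()
    for contig in sorted(per_contig):
        genes = sorted(per_contig[contig], key=lambda g: g.span.start)
        tokens = []
        for idx, gene in enumerate(genes):
            label = gene.subgroup
            if label in ("unassigned", "?", ""):
                label = f"?{next(unlabeled)}"
            tokens.append(OrderToken(label=label, strand=gene.strand,
                                     gene_id=gene.id, index=idx))
        strings.append(GeneOrderString(contig=contig, tokens=tokens))
    return strings


# ---------------------------------------------------------------------------
# Repeated motif detection
# ---------------------------------------------------------------------------

def _occurrences_of(labels: tuple[str, ...],
                    strings: Sequence[tuple[str, ...]]) -> list[Occurrence]:
    out = []
    L = len(labels)
    for s_idx, s in enumerate(strings):
        for start in range(len(s) - L + 1):
            if s[start:start + L] == labels:
                out.append(Occurrence(s_idx, start, L))
    return out


def _primitive_period(labels: tuple[str, ...]) -> int:
    """Smallest p with labels[i] == labels[i-p]; the motif's tandem period."""
    n = len(labels)
    for p in range(1, n):
        if all(labels[i] == labels[i - p] for i in range(p, n)):
            return p
    return n


def _greedy_non_overlapping(occs: list[Occurrence]) -> list[Occurrence]:
    chosen: list[Occurrence] = []
    for occ in sorted(occs, key=lambda o: (o.string_idx, o.start)):
        if not any(occ.overlaps(c) for c in chosen):
            chosen.append(occ)
    return chosen


def maximal_repeats(seqs: Sequence[tuple[str, ...]], min_len: int = 2,
                    min_occ: int = 2,
                    ) -> dict[tuple[str, ...], list[Occurrence]]:
    """All maximal repeats: label substrings with >= ``min_occ`` occurrences
    whose occurrences cannot all be extended by one identical label on
    either side."""
    counts: dict[tuple[str, ...], list[Occurrence]] = {}
    max_len = max((len(s) for s in seqs), default=0)
    for L in range(min_len, max_len + 1):
        for s_idx, s in enumerate(seqs):
            for start in range(len(s) - L + 1):
                window = s[start:start + L]
                counts.setdefault(window, []).append(Occurrence(s_idx, start, L))
    repeated = {m: occs for m, occs in counts.items() if len(occs) >= min_occ}

    def context(occ: Occurrence, side: int) -> Optional[str]:
        s = seqs[occ.string_idx]
        pos = occ.start - 1 if side < 0 else occ.end
        return s[pos] if 0 <= pos < len(s) else None

    maximal = {}
    for labels, occs in repeated.items():
        lefts = {context(o, -1) for o in occs}
        rights = {context(o, +1) for o in occs}
        if len(lefts) == 1 and None not in lefts:
            continue  # every occurrence extends identically leftwards
        if len(rights) == 1 and None not in rights:
            continue
        maximal[labels] = occs
    return maximal


def find_repeated_motifs(strings: Sequence[GeneOrderString],
                         min_len: int = 2,
                         min_occ: int = 2) -> list[Motif]:
    """All maximal exact repeated label subsequences with >= ``min_occ``
    occurrences, across and within contigs.

    A repeat is maximal when its occurrences cannot all be extended by the
    same label on either side.  Motifs that are tandem-periodic (at least
    two full periods) are reduced to their primitive period, so a tandem
    array is reported as its unit motif.  Occurrences are finally resolved
    greedily into leftmost, non-overlapping instances; motifs retaining
    fewer than ``min_occ`` instances are dropped.
    """
    if min_len < 1 or min_occ < 2:
        raise ValueError("min_len must be >= 1 and min_occ >= 2")
    seqs = [s.labels for s in strings]
    maximal = maximal_repeats(seqs, min_len, min_occ)

    reduced: dict[tuple[str, ...], list[Occurrence]] = {}
    for labels, occs in maximal.items():
        period = _primitive_period(labels)
        if period < len(labels) and len(labels) >= 2 * period:
            labels = labels[:period]
            if len(labels) < min_len:
                continue
            occs = _occurrences_of(labels, seqs)
        if labels not in reduced:
            reduced[labels] = occs

    motifs = []
    for labels in sorted(reduced, key=lambda m: (-len(m), m)):
        instances = _greedy_non_overlapping(reduced[labels])
        if len(instances) >= min_occ:
            motifs.append(Motif(labels=labels, instances=instances))
    return motifs


def brute_force_repeats(strings: Sequence[GeneOrderString],
                        min_len: int = 2,
                        min_occ: int = 2) -> set[tuple[str, ...]]:
    """Reference enumerator (no maximality or periodicity reduction): every
    label substring occurring >= min_occ times.  Used as a test oracle."""
    seqs = [s.labels for s in strings]
    counts: dict[tuple[str, ...], int] = {}
    for s in seqs:
        for L in range(min_len, len(s) + 1):
            for start in range(len(s) - L + 1):
                window = s[start:start + L]
                counts[window] = counts.get(window, 0) + 1
    return {m for m, c in counts.items() if c >= min_occ}


# ---------------------------------------------------------------------------
# Unit construction
# ---------------------------------------------------------------------------

def _edit_distance(a: Sequence[str], b: Sequence[str]) -> int:
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        cur = [i]
        for j, cb in enumerate(b, 1):
            cur.append(min(prev[j] + 1, cur[-1] + 1,
                           prev[j - 1] + (ca != cb)))
        prev = cur
    return prev[-1]


def _align_labels(consensus: Sequence[str], labels: Sequence[str],
                  ) -> list[tuple[Optional[int], Optional[int]]]:
    """Needleman-Wunsch on labels (match 0, mismatch/gap 1); returns aligned
    (consensus index, instance index) column pairs."""
    n, m = len(consensus), len(labels)
    score = [[0] * (m + 1) for _ in range(n + 1)]
    for i in range(n + 1):
        score[i][0] = i
    for j in range(m + 1):
        score[0][j] = j
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            score[i][j] = min(score[i - 1][j - 1]
                              + (consensus[i - 1] != labels[j - 1]),
                              score[i - 1][j] + 1,
                              score[i][j - 1] + 1)
    cols = []
    i, j = n, m
    while i > 0 or j > 0:
        if i > 0 and j > 0 and score[i][j] == score[i - 1][j - 1] + (
                consensus[i - 1] != labels[j - 1]):
            cols.append((i - 1, j - 1))
            i, j = i - 1, j - 1
        elif i > 0 and score[i][j] == score[i - 1][j] + 1:
            cols.append((i - 1, None))
            i -= 1
        else:
            cols.append((None, j - 1))
            j -= 1
    return cols[::-1]


def build_homology_units(motifs: Sequence[Motif],
                         strings: Sequence[GeneOrderString],
                         merge_edit_distance: int = 2,
                         min_motif_genes: int = 2) -> list[HomologyUnit]:
    """Assemble homology units from repeated motifs.

    Exact repeats fragment wherever a replicon gained or lost a gene, so
    instances of different motifs that overlap in the gene order are first
    merged into *composite* candidate replicons (tandem copies of one motif
    abut but never overlap, so arrays are not collapsed).  Composite label
    strings are then clustered greedily — most frequent string first, each
    absorbing composites within ``merge_edit_distance`` label edits (capped
    at half the consensus length) — and clusters with >= 2 replicons and a
    consensus of >= ``min_motif_genes`` labels become units.
    """
    # 1. composite candidate replicons: overlapping instances always merge;
    # abutting instances merge only when they come from *different* motifs
    # that overlap elsewhere (fragments of one replicon split by an indel).
    # Tandem copies of a single motif abut but never merge.
    per_string: dict[int, list[tuple[int, Occurrence]]] = {}
    for m_idx, motif in enumerate(motifs):
        for occ in motif.instances:
            per_string.setdefault(occ.string_idx, []).append((m_idx, occ))

    linked: set[frozenset[int]] = set()
    for occs in per_string.values():
        occs.sort(key=lambda mo: (mo[1].start, -mo[1].length))
        for k, (mi, oi) in enumerate(occs):
            for mj, oj in occs[k + 1:]:
                if oj.start >= oi.end:
                    break
                if mi != mj:
                    linked.add(frozenset((mi, mj)))

    composites: list[RepliconInstance] = []
    for s_idx, occs in sorted(per_string.items()):
        spans: list[tuple[int, int, set[int]]] = []
        for m_idx, occ in occs:
            if spans:
                start, end, members = spans[-1]
                overlap = occ.start < end
                joinable = (occ.start == end
                            and any(m_idx != m and
                                    frozenset((m_idx, m)) in linked
                                    for m in members))
                if overlap or joinable:
                    spans[-1] = (start, max(end, occ.end),
                                 members | {m_idx})
                    continue
            spans.append((occ.start, occ.end, {m_idx}))
        s = strings[s_idx]
        for a, b, _ in spans:
            composites.append(RepliconInstance(
                contig=s.contig, start=a, end=b,
                gene_ids=[t.gene_id for t in s.tokens[a:b]]))

    label_of = {}
    for inst in composites:
        s = next(x for x in strings if x.contig == inst.contig)
        label_of[id(inst)] = tuple(t.label
                                   for t in s.tokens[inst.start:inst.end])

    # 2. cluster composites by label-string edit distance
    freq: dict[tuple[str, ...], int] = {}
    first_pos: dict[tuple[str, ...], tuple] = {}
    for k, inst in enumerate(composites):
        labels = label_of[id(inst)]
        freq[labels] = freq.get(labels, 0) + 1
        first_pos.setdefault(labels, (inst.contig, inst.start, k))
    candidates = sorted(freq, key=lambda m: (-freq[m], -len(m),
                                             first_pos[m]))
    remaining = list(composites)
    units: list[HomologyUnit] = []
    for consensus in candidates:
        if len(consensus) < min_motif_genes:
            continue
        radius = min(merge_edit_distance, len(consensus) // 2)
        mine = [c for c in remaining
                if _edit_distance(consensus, label_of[id(c)]) <= radius]
        if len(mine) < 2:
            continue
        units.append(HomologyUnit(id=len(units) + 1, consensus=consensus,
                                  instances=mine))
        remaining = [c for c in remaining if c not in mine]

    # stable ids in genomic order of first instance
    units.sort(key=lambda u: min((i.contig, i.start) for i in u.instances))

    for unit in units:
        for inst in unit.instances:
            tokens = [t.label for t in
                      strings[[s.contig for s in strings].index(inst.contig)]
                      .tokens[inst.start:inst.end]]
            cols = _align_labels(unit.consensus, tokens)
            edits = []
            for ci, ti in cols:
                if ci is not None and ti is not None:
                    kind = ("match" if unit.consensus[ci] == tokens[ti]
                            else "mismatch")
                    edits.append((kind, ci, inst.gene_ids[ti]))
                elif ci is not None:
                    edits.append(("missing", ci, None))
                else:
                    edits.append(("extra", None, inst.gene_ids[ti]))
            inst.edits = edits
            missing_pos = [k for k, e in enumerate(edits) if e[0] == "missing"]
            extra_pos = [k for k, e in enumerate(edits) if e[0] == "extra"]
            # leading/trailing runs of gaps = variable 5'/3' extent
            lead = itertools.takewhile(
                lambda k: edits[k][0] in ("missing", "extra"),
                range(len(edits)))
            trail = itertools.takewhile(
                lambda k: edits[k][0] in ("missing", "extra"),
                reversed(range(len(edits))))
            edge = set(lead) | set(trail)
            if any(k in edge for k in missing_pos + extra_pos):
                unit.variable_content = True
            if any(k not in edge for k in missing_pos + extra_pos):
                unit.post_replication_indel = True
    for new_id, unit in enumerate(units, 1):
        unit.id = new_id
    return units


def unit_coverage(annotation: LocusAnnotation,
                  units: Sequence[HomologyUnit]) -> dict:
    """Fraction of V genes located inside homology-unit replicons (each gene
    counted once even when spanned by instances of several units)."""
    in_units: set[str] = set()
    for unit in units:
        in_units |= unit.gene_ids
    total = len(annotation.v_genes())
    n_in = len(in_units & {g.id for g in annotation.v_genes()})
    return {"genes_in_units": n_in, "total": total,
            "fraction": n_in / total if total else 0.0}


def units_table(units: Sequence[HomologyUnit],
                annotation: Optional[LocusAnnotation] = None) -> pd.DataFrame:
    """Unit report: motif, gene count, genomic size (kb), replicon count and
    variation flags."""
    rows = []
    for unit in units:
        size_kb = None
        if annotation is not None:
            spans = []
            for inst in unit.instances:
                genes = [annotation.gene(g) for g in inst.gene_ids]
                if genes:
                    spans.append(max(g.span.end for g in genes)
                                 - min(g.span.start for g in genes))
            size_kb = round(max(spans) / 1000.0, 1) if spans else None
        rows.append({"unit": unit.id, "motif": "-".join(unit.consensus),
                     "n_genes": len(unit.consensus), "size_kb": size_kb,
                     "n_replicons": len(unit.instances),
                     "variable_content": unit.variable_content,
                     "post_replication_indel": unit.post_replication_indel})
    return pd.DataFrame(rows, columns=["unit", "motif", "n_genes", "size_kb",
                                       "n_replicons", "variable_content",
                                       "post_replication_indel"])


# ---------------------------------------------------------------------------
# Dotplot
# ---------------------------------------------------------------------------

@dataclass
class DotplotSegment:
    a_start: int
    a_end: int
    b_start: int
    b_end: int
    strand: str
    identity: float  # percentage


_COMP = str.maketrans("ACGTN", "TGCAN")


def identity_dotplot(seq_a: str, seq_b: str, k: int = 12,
                     min_run: int = 100,
                     max_gap: Optional[int] = None) -> list[DotplotSegment]:
    """Diagonal segments of nucleotide identity between two sequences.

    Exact k-mer seed matches are chained along diagonals (joining seeds at
    most ``max_gap`` apart, default k) into segments of length >=
    ``min_run``; both strands are scanned.  Coordinates are 0-based
    half-open on the forward strands of both inputs.
    """
    if k < 8:
        raise ValueError("word size k must be >= 8")
    max_gap = k if max_gap is None else max_gap
    segments = []
    for strand, b in (("+", seq_b), ("-", seq_b.translate(_COMP)[::-1])):
        index: dict[str, list[int]] = {}
        for i in range(len(seq_a) - k + 1):
            index.setdefault(seq_a[i:i + k], []).append(i)
        diagonals: dict[int, list[int]] = {}
        for j in range(len(b) - k + 1):
            for i in index.get(b[j:j + k], ()):
                diagonals.setdefault(i - j, []).append(i)
        for diag, hits in diagonals.items():
            hits.sort()
            run_start = prev = hits[0]
            runs = []
            for i in hits[1:]:
                if i - (prev + k) > max_gap:
                    runs.append((run_start, prev + k))
                    run_start = i
                prev = i
            runs.append((run_start, prev + k))
            for a0, a1 in runs:
                if a1 - a0 < min_run:
                    continue
                b0, b1 = a0 - diag, a1 - diag
                matches = sum(x == y for x, y in zip(seq_a[a0:a1], b[b0:b1]))
                ident = round(100.0 * matches / (a1 - a0), 2)
                if strand == "-":
                    b0, b1 = len(seq_b) - b1, len(seq_b) - b0
                segments.append(DotplotSegment(a0, a1, b0, b1, strand, ident))
    segments.sort(key=lambda s: (s.a_start, s.b_start, s.strand))
    return segments


def dotplot_table(segments: Iterable[DotplotSegment]) -> pd.DataFrame:
    return pd.DataFrame([vars(s) for s in segments],
                        columns=["a_start", "a_end", "b_start", "b_end",
                                 "strand", "identity"])
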