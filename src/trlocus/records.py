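"""Domain types for the TRA/TRD locus analysis pipeline.

Coordinate convention: all in-memory intervals are 0-based half-open on the
forward strand of the contig.  Part *sequences* are always stored in coding
orientation (minus-strand parts are reverse-complemented on read), so
downstream sequence logic never needs to consider strand.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from typing import Iterator, Optional

DNA_ALPHABET = set("ACGTN")

# Canonical V-gene part names, in coding order along the gene.
V_PART_ORDER = ("l_exon", "intron", "v_exon", "rs")
# Canonical J-gene part names (the 12-RS lies 5' of the coding region; the
# splice donor is the first two intron bases 3' of the coding region).
J_PART_ORDER = ("rs", "coding", "donor")


@dataclass(frozen=True)
class Span:
    """0-based half-open interval on a contig's forward strand."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0 or self.end < self.start:
            raise ValueError(f"invalid span [{self.start}, {self.end})")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "Span") -> bool:
        return self.start < other.end and other.start < self.end


@dataclass
class GenePart:
    """One anatomical part of a gene (leader exon, intron, V exon, RS, ...).

    ``sequence`` is None when the part falls off a contig break (partial
    genes); such records classify as *incomplete*.
    """

    name: str
    span: Optional[Span]
    sequence: Optional[str]

    @property
    def present(self) -> bool:
        return self.sequence is not None


@dataclass
class GeneRecord:
    id: str
    contig: str
    span: Span
    strand: str
    parts: dict[str, GenePart] = field(default_factory=dict)

    def part_seq(self, name: str) -> Optional[str]:
        part = self.parts.get(name)
        return part.sequence if part is not None else None


@dataclass
class VGeneRecord(GeneRecord):
    """An annotated V gene: leader exon, intron, V exon and 23-RS."""

    subgroup: str = "unassigned"
    #: locus_chromosome | unassigned_contig | other
    location_class: str = "locus_chromosome"

    REQUIRED_PARTS = V_PART_ORDER

    @property
    def is_partial(self) -> bool:
        return any(
            name not in self.parts or not self.parts[name].present
            for name in self.REQUIRED_PARTS
        )

    @property
    def v_exon(self) -> Optional[str]:
        return self.part_seq("v_exon")


@dataclass
class JGeneRecord(GeneRecord):
    """An annotated J gene: 12-RS, coding region and 3' splice donor."""

    frame: int = 0

    REQUIRED_PARTS = J_PART_ORDER

    @property
    def is_partial(self) -> bool:
        return any(
            name not in self.parts or not self.parts[name].present
            for name in self.REQUIRED_PARTS
        )


@dataclass
class DGeneRecord(GeneRecord):
    pass


@dataclass
class CGeneRecord(GeneRecord):
    pass


@dataclass
class LocusAnnotation:
    """A locus: contig sequences plus the annotated gene records."""

    contigs: dict[str, str]
    genes: list[GeneRecord]
    provenance: str = ""

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        seen: set[str] = set()
        for gene in self.genes:
            if gene.id in seen:
                raise ValueError(f"duplicate gene id {gene.id!r}")
            seen.add(gene.id)
            if gene.contig not in self.contigs:
                raise ValueError(f"gene {gene.id}: unknown contig {gene.contig!r}")
            contig_len = len(self.contigs[gene.contig])
            if gene.span.end > contig_len:
                raise ValueError(
                    f"gene {gene.id}: span end {gene.span.end} exceeds contig "
                    f"length {contig_len}"
                )
            spans = [p.span for p in gene.parts.values() if p.span is not None]
            spans.sort(key=lambda s: s.start)
            for a, b in zip(spans, spans[1:]):
                if a.overlaps(b):
                    raise ValueError(f"gene {gene.id}: overlapping part intervals")

    def v_genes(self) -> list[VGeneRecord]:
        return [g for g in self.genes if isinstance(g, VGeneRecord)]

    def j_genes(self) -> list[JGeneRecord]:
        return [g for g in self.genes if isinstance(g, JGeneRecord)]

    def gene(self, gene_id: str) -> GeneRecord:
        for g in self.genes:
            if g.id == gene_id:
                return g
        raise KeyError(gene_id)

    def __iter__(self) -> Iterator[GeneRecord]:
        return iter(self.genes)


@dataclass
class Lesion:
    """One functionality-destroying defect found in (or planted into) a gene."""

    kind: str
    detail: str = ""
    position: Optional[int] = None

    def __str__(self) -> str:
        bits = [self.kind]
        if self.detail:
            bits.append(self.detail)
        if self.position is not None:
            bits.append(str(self.position))
        return ":".join(bits)


@dataclass
class CompetenceCall:
    """Functional-competence verdict for one gene.

    ``status`` is 'functional', 'pseudogene' or 'incomplete'.  A gene is
    functional iff no lesion was found and its sequence is complete; a
    missing_sequence lesion forces 'incomplete', which outranks 'pseudogene'.
    """

    gene_id: str
    status: str
    lesions: list[Lesion] = field(default_factory=list)
    translation: Optional[str] = None

    @property
    def lesion_kinds(self) -> frozenset[str]:
        return frozenset(l.kind for l in self.lesions)


@dataclass
class SubgroupReference:
    """Per-subgroup functional reference used for frame and residue mapping.

    ``anchors`` maps the standardised V-domain positions (conserved Cys-23,
    Trp-41, Cys-104) to 0-based indices of ``peptide``.
    """

    label: str
    v_exon_length: int
    peptide: str
    anchors: dict[int, int]


@dataclass
class TranscriptRecord:
    id: str
    chain: str  # 'TRA' | 'TRD'
    v_segment: str
    j_label: str = "unknown"
    productive: bool = True


@dataclass
class TranscriptMatch:
    transcript_id: str
    best_hit: str
    identity: float  # percentage, 0-100
    category: str  # identical | allelic_or_unassembled | novel


@dataclass
class RunConfig:
    """Run configuration shared by the CLI and the report writers."""

    identity_subgroup_threshold: float = 0.75
    transcript_identity_threshold: float = 0.97
    orthology_identity_floor: float = 0.631
    min_motif_genes: int = 2
    merge_edit_distance: int = 2
    bootstrap_replicates: int = 100
    over_representation_ratio: float = 2.0
    under_representation_ratio: float = 0.5
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("identity_subgroup_threshold", "transcript_identity_threshold",
                     "orthology_identity_floor"):
            value = getattr(self, name)
            if not 0 < value <= 1:
                raise ValueError(f"{name} must lie in (0, 1], got {value}")
        for name in ("min_motif_genes", "bootstrap_replicates"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        return cls(**json.loads(text))

    def digest(self) -> str:
        """Short stable hash of the configuration, stamped on every report."""
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]
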