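"""Birth-and-death simulator for a V(D)J locus expanded by homology-unit
duplication.

The generator emulates the statistical structure the analysis pipeline
assumes: an ancestral set of V genes (one template per subgroup, pairwise
unrelated), expanded by tandem duplication of multi-gene segments ("homology
units"), with per-copy nucleotide substitution and per-gene pseudogenizing
lesions drawn at subgroup-specific "death" rates.  Transcripts are sampled
from functional genes with a small, strictly positive allelic divergence,
except for a configurable fraction drawn from hidden genes diverged below
the 97%-identity convention and excluded from the written annotation
(emulating genes absent from a fragmented assembly).

Every gene template is functional by construction: the intron is GT..AG, the
spliced leader+V reading frame is open and encodes the conserved Cys/Trp/Cys
at V-domain positions 23/41/104, and the 23-RS matches the
heptamer/nonamer consensus.  Substitution noise never touches the sites that
carry these guarantees (nor ever creates a stop codon), so a gene is
non-functional exactly when a lesion was planted — which is what makes the
planted-lesion recovery tests exact.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Optional

import numpy as np
from Bio.Seq import Seq

from .records import (
    GenePart,
    JGeneRecord,
    LocusAnnotation,
    Span,
    SubgroupReference,
    TranscriptRecord,
    VGeneRecord,
)

# Gene anatomy constants (nt).  The leader exon holds the initiator ATG plus
# 15 codons; the V exon encodes the 104-position V domain, so the conserved
# anchors sit at spliced-peptide indices 38 (Cys-23), 56 (Trp-41) and 119
# (Cys-104).
L_EXON_LEN = 48
INTRON_LEN = 90
V_EXON_LEN = 312
RS23_SPACER = 23
RS12_SPACER = 12
HEPTAMER = "CACAGTG"
NONAMER = "ACAAAAACC"
J_CODING_CODONS = 20
#: spliced-translation indices of the conserved V-domain anchors
V_ANCHORS = {23: 38, 41: 56, 104: 119}
_ANCHOR_VEXON_CODONS = (22, 40, 103)

STOPS = {"TAA", "TAG", "TGA"}
_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}

#: lesion kinds the simulator can plant in V genes, with the competence
#: classifier lesion kinds and status each one must produce.
V_LESION_MENU: dict[str, tuple[frozenset[str], str]] = {
    "premature_stop": (frozenset({"premature_stop"}), "pseudogene"),
    "frameshift_del_1": (frozenset({"frameshift"}), "pseudogene"),
    "frameshift_del_2": (frozenset({"frameshift"}), "pseudogene"),
    "frameshift_del_4": (frozenset({"frameshift"}), "pseudogene"),
    "splice_donor_mut": (frozenset({"splice_donor"}), "pseudogene"),
    "splice_acceptor_mut": (frozenset({"splice_acceptor"}), "pseudogene"),
    "C23_mut": (frozenset({"C23_mut"}), "pseudogene"),
    "W41_mut": (frozenset({"W41_mut"}), "pseudogene"),
    "C104_mut": (frozenset({"C104_mut"}), "pseudogene"),
    "RS_heptamer_mut": (frozenset({"RS_heptamer"}), "pseudogene"),
    "truncation": (frozenset({"missing_sequence"}), "incomplete"),
}

J_LESION_MENU: dict[str, tuple[frozenset[str], str]] = {
    "missing_FGxG": (frozenset({"missing_FGxG"}), "pseudogene"),
    "premature_stop": (frozenset({"premature_stop"}), "pseudogene"),
    "RS_heptamer_mut": (frozenset({"RS_heptamer"}), "pseudogene"),
    "splice_donor_mut": (frozenset({"splice_donor"}), "pseudogene"),
}


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass
class SubgroupSpec:
    label: str
    n_ancestral: int = 1
    #: probability that a newly duplicated copy of a gene of this subgroup
    #: acquires a pseudogenizing lesion ("death" rate per duplication)
    death_prob: float = 0.3

    def __post_init__(self) -> None:
        if not 0 <= self.death_prob <= 1:
            raise ValueError("death_prob must lie in [0, 1]")
        if self.n_ancestral < 1:
            raise ValueError("n_ancestral must be >= 1")


@dataclass
class DuplicationSpec:
    """Tandem duplication of the gene-index span [start, end) of the current
    locus, repeated ``n_copies`` times."""

    start: int
    end: int
    n_copies: int
    substitution_rate: float = 0.006
    truncation_prob: float = 0.0

    def __post_init__(self) -> None:
        if self.substitution_rate < 0:
            raise ValueError("substitution_rate must be >= 0")
        if not 0 <= self.truncation_prob <= 1:
            raise ValueError("truncation_prob must lie in [0, 1]")


@dataclass
class TranscriptParams:
    n_tra: int = 198
    n_trd: int = 143
    #: uniform range for per-transcript allelic divergence (strictly > 0:
    #: at least one substitution is always applied)
    allelic_divergence: tuple[float, float] = (0.003, 0.025)
    novel_fraction: float = 0.11
    novel_divergence: tuple[float, float] = (0.05, 0.08)
    #: per-chain subgroup usage weights, e.g. {"TRD": {"TRDV1": 0.8, ...}};
    #: missing chains/subgroups default to uniform usage
    usage_weights: Optional[dict[str, dict[str, float]]] = None
    nonproductive_fraction: float = 0.0


@dataclass
class SimConfig:
    subgroups: list[SubgroupSpec]
    duplication_events: list[DuplicationSpec] = field(default_factory=list)
    lesion_menu: dict[str, float] = field(default_factory=lambda: {
        kind: (0.5 if kind == "truncation" else 1.0) for kind in V_LESION_MENU})
    transcript_params: TranscriptParams = field(default_factory=TranscriptParams)
    #: subgroup divergence of ancestral same-subgroup paralogues
    ancestral_divergence: float = 0.04
    n_j_genes: int = 20
    j_death_prob: float = 0.16
    #: subgroups whose genes rearrange into each chain (dual-usage subgroups
    #: appear in both lists); None = TRDV* to TRD, the rest to TRA
    tra_subgroups: Optional[list[str]] = None
    trd_subgroups: Optional[list[str]] = None
    rng_seed: int = 0

    def __post_init__(self) -> None:
        bad = set(self.lesion_menu) - set(V_LESION_MENU)
        if bad:
            raise ValueError(f"unknown lesion kinds in menu: {sorted(bad)}")


@dataclass
class SimTruth:
    """Ground-truth event log of a simulated locus."""

    ancestry: dict[str, str] = field(default_factory=dict)
    events: list[dict] = field(default_factory=list)
    #: gene id -> classifier lesion kinds the gene must produce
    planted_lesions: dict[str, list[str]] = field(default_factory=dict)
    expected_status: dict[str, str] = field(default_factory=dict)
    #: list of {"motif": tuple of labels, "instances": [[gene ids], ...]}
    true_units: list[dict] = field(default_factory=list)
    #: transcript id -> {"source", "subgroup", "expected_category"}
    transcript_origin: dict[str, dict] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Sequence-level helpers
# ---------------------------------------------------------------------------

def _label_seed(label: str, base_seed: int = 0) -> int:
    digest = hashlib.sha256(f"{base_seed}:{label}".encode()).digest()
    return int.from_bytes(digest[:4], "big")


def _random_codons(rng: np.random.Generator, n: int) -> str:
    bases = "ACGT"
    out = []
    while len(out) < n:
        codon = "".join(rng.choice(list(bases), size=3))
        if codon not in STOPS:
            out.append(codon)
    return "".join(out)


def _random_bases(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=n))


def mutate(seq: str, n_sub: int, rng: np.random.Generator,
           frozen: frozenset[int] = frozenset(), coding: bool = False) -> str:
    """Apply ``n_sub`` substitutions with a 2:1 transition bias, never at a
    frozen site and (for coding sequence, frame 0) never creating a stop."""
    chars = list(seq)
    candidates = [i for i in range(len(chars)) if i not in frozen]
    n_sub = min(n_sub, len(candidates))
    if n_sub == 0:
        return seq
    sites = rng.choice(len(candidates), size=n_sub, replace=False)
    for idx in sites:
        pos = candidates[idx]
        current = chars[pos]
        options, weights = [], []
        for base in "ACGT":
            if base == current:
                continue
            if coding:
                start = (pos // 3) * 3
                codon = chars[start:start + 3]
                codon[pos - start] = base
                if "".join(codon) in STOPS:
                    continue
            options.append(base)
            weights.append(2.0 if base == _TRANSITION[current] else 1.0)
        if not options:
            continue
        w = np.asarray(weights) / sum(weights)
        chars[pos] = options[rng.choice(len(options), p=w)]
    return "".join(chars)


def _mutate_rate(seq: str, rate: float, rng: np.random.Generator,
                 frozen: frozenset[int] = frozenset(), coding: bool = False) -> str:
    n = rng.binomial(len(seq), rate) if rate > 0 else 0
    return mutate(seq, n, rng, frozen, coding)


def translate(seq: str) -> str:
    """Frame-0 translation through stop codons ('*')."""
    trimmed = seq[: len(seq) - len(seq) % 3]
    return str(Seq(trimmed).translate())


# ---------------------------------------------------------------------------
# Gene templates
# ---------------------------------------------------------------------------

class _SimGene:
    """Mutable simulator-internal gene: part sequences + per-part frozen sites."""

    __slots__ = ("uid", "label", "kind", "parts", "frozen", "planted",
                 "expected_status", "ancestor", "frame")

    def __init__(self, uid: str, label: str, kind: str,
                 parts: dict[str, Optional[str]],
                 frozen: dict[str, set[int]]):
        self.uid = uid
        self.label = label
        self.kind = kind  # 'V' | 'J'
        self.parts = parts
        self.frozen = frozen
        self.planted: list[str] = []       # classifier lesion kinds
        self.expected_status = "functional"
        self.ancestor: Optional[str] = None
        self.frame = 0

    def copy(self, uid: str) -> "_SimGene":
        dup = _SimGene(uid, self.label, self.kind, dict(self.parts),
                       {k: set(v) for k, v in self.frozen.items()})
        dup.planted = list(self.planted)
        dup.expected_status = self.expected_status
        dup.ancestor = self.uid
        dup.frame = self.frame
        return dup

    def mutate(self, rate: float, rng: np.random.Generator) -> None:
        for name, seq in self.parts.items():
            if seq is None:
                continue
            coding = name in ("l_exon", "v_exon", "coding")
            self.parts[name] = _mutate_rate(seq, rate, rng,
                                            frozenset(self.frozen.get(name, ())),
                                            coding)


def _v_frozen_sites() -> dict[str, set[int]]:
    anchors = set()
    for codon in _ANCHOR_VEXON_CODONS:
        anchors.update(range(codon * 3, codon * 3 + 3))
    rs_len = len(HEPTAMER) + RS23_SPACER + len(NONAMER)
    return {
        "l_exon": {0, 1, 2},
        "intron": {0, 1, INTRON_LEN - 2, INTRON_LEN - 1},
        "v_exon": anchors,
        "rs": set(range(7)) | set(range(rs_len - 9, rs_len)),
    }


@lru_cache(maxsize=None)
def _v_base_parts(label: str, base_seed: int) -> tuple[tuple[str, str], ...]:
    rng = np.random.default_rng(_label_seed(label, base_seed))
    l_exon = "ATG" + _random_codons(rng, (L_EXON_LEN - 3) // 3)
    intron = "GT" + _random_bases(rng, INTRON_LEN - 4) + "AG"
    v = list(_random_codons(rng, V_EXON_LEN // 3))
    for codon_idx, aa_codon in zip(_ANCHOR_VEXON_CODONS, ("TGC", "TGG", "TGT")):
        v[codon_idx * 3:codon_idx * 3 + 3] = aa_codon
    v_exon = "".join(v)
    rs = HEPTAMER + _random_bases(rng, RS23_SPACER) + NONAMER
    return (("l_exon", l_exon), ("intron", intron),
            ("v_exon", v_exon), ("rs", rs))


def subgroup_reference(label: str, base_seed: int = 0) -> SubgroupReference:
    """Functional reference for a simulated subgroup (frame length, peptide
    and anchor indices), as consumed by the competence classifier."""
    parts = dict(_v_base_parts(label, base_seed))
    peptide = translate(parts["l_exon"] + parts["v_exon"])
    return SubgroupReference(label=label, v_exon_length=V_EXON_LEN,
                             peptide=peptide, anchors=dict(V_ANCHORS))


def _new_v_gene(uid: str, label: str, rng: np.random.Generator,
                divergence: float, base_seed: int) -> _SimGene:
    gene = _SimGene(uid, label, "V", dict(_v_base_parts(label, base_seed)),
                    _v_frozen_sites())
    gene.mutate(divergence, rng)
    return gene


def plant_v_lesion(gene: _SimGene, kind: str, rng: np.random.Generator) -> None:
    """Introduce the sequence defect for ``kind`` and record the classifier
    lesion kinds / status the gene must now produce."""
    if kind not in V_LESION_MENU:
        raise ValueError(f"unknown lesion kind {kind!r}")
    v = gene.parts["v_exon"]
    if kind == "premature_stop":
        choices = [c for c in range(4, len(v) // 3 - 1)
                   if c not in _ANCHOR_VEXON_CODONS
                   and not any(p in gene.frozen["v_exon"]
                               for p in range(c * 3, c * 3 + 3))]
        codon = int(rng.choice(choices))
        gene.parts["v_exon"] = v[:codon * 3] + "TAA" + v[codon * 3 + 3:]
        gene.frozen["v_exon"].update(range(codon * 3, codon * 3 + 3))
    elif kind.startswith("frameshift_del_"):
        n = int(kind.rsplit("_", 1)[1])
        pos = int(rng.integers(130, 290))
        gene.parts["v_exon"] = v[:pos] + v[pos + n:]
        gene.frozen["v_exon"] = {
            p if p < pos else p - n
            for p in gene.frozen["v_exon"] if p < pos or p >= pos + n}
    elif kind == "splice_donor_mut":
        intron = gene.parts["intron"]
        gene.parts["intron"] = "AT" + intron[2:]
    elif kind == "splice_acceptor_mut":
        intron = gene.parts["intron"]
        gene.parts["intron"] = intron[:-2] + "AC"
    elif kind in ("C23_mut", "W41_mut", "C104_mut"):
        codon_idx = _ANCHOR_VEXON_CODONS[("C23_mut", "W41_mut",
                                          "C104_mut").index(kind)]
        replacement = {"C23_mut": "CGC", "W41_mut": "CGG",
                       "C104_mut": "TAT"}[kind]
        gene.parts["v_exon"] = (v[:codon_idx * 3] + replacement
                                + v[codon_idx * 3 + 3:])
    elif kind == "RS_heptamer_mut":
        rs = gene.parts["rs"]
        gene.parts["rs"] = "GAC" + rs[3:]
    elif kind == "truncation":
        gene.parts["rs"] = None
    expected_kinds, status = V_LESION_MENU[kind]
    for k in sorted(expected_kinds):
        if k not in gene.planted:
            gene.planted.append(k)
    if status == "incomplete" or gene.expected_status == "incomplete":
        gene.expected_status = "incomplete"
    else:
        gene.expected_status = "pseudogene"


def make_v_gene_template(subgroup_label: str, rng: np.random.Generator,
                         plant_lesion: Optional[str] = None,
                         divergence: float = 0.06,
                         base_seed: int = 0) -> tuple[VGeneRecord, SubgroupReference]:
    """One simulated V gene of the given subgroup, as a standalone record.

    Returns the record together with the subgroup's functional reference.
    Without a planted lesion the record classifies as functional with an
    empty lesion list; with one it carries exactly that defect.
    """
    gene = _new_v_gene("t", subgroup_label, rng, divergence, base_seed)
    if plant_lesion is not None:
        plant_v_lesion(gene, plant_lesion, rng)
    record = _materialize_v(gene, contig="template", offset=0,
                            gene_id=f"{subgroup_label}-template")
    return record, subgroup_reference(subgroup_label, base_seed)


# --- J genes ---------------------------------------------------------------

@lru_cache(maxsize=None)
def _j_base_parts(label: str, base_seed: int) -> tuple[tuple[str, str], ...]:
    rng = np.random.default_rng(_label_seed("J:" + label, base_seed))
    motif_start = 9
    coding = list(_random_codons(rng, J_CODING_CODONS))
    for offset, codon in enumerate(("TTT", "GGA", "AGT", "GGA")):  # F-G-x-G
        idx = (motif_start + offset) * 3
        coding[idx:idx + 3] = codon
    rs = HEPTAMER + _random_bases(rng, RS12_SPACER) + NONAMER
    return (("rs", rs), ("coding", "".join(coding)), ("donor", "GT"))


def _j_frozen_sites() -> dict[str, set[int]]:
    rs_len = len(HEPTAMER) + RS12_SPACER + len(NONAMER)
    motif = set(range(9 * 3, 13 * 3))
    return {"rs": set(range(7)) | set(range(rs_len - 9, rs_len)),
            "coding": motif, "donor": {0, 1}}


def plant_j_lesion(gene: _SimGene, kind: str, rng: np.random.Generator) -> None:
    if kind not in J_LESION_MENU:
        raise ValueError(f"unknown J lesion kind {kind!r}")
    coding = gene.parts["coding"]
    if kind == "missing_FGxG":
        # break the first G of the F-G-x-G motif
        gene.parts["coding"] = coding[:10 * 3] + "AGA" + coding[10 * 3 + 3:]
    elif kind == "premature_stop":
        codon = int(rng.integers(2, 8))
        gene.parts["coding"] = (coding[:codon * 3] + "TAA"
                                + coding[codon * 3 + 3:])
        gene.frozen["coding"].update(range(codon * 3, codon * 3 + 3))
    elif kind == "RS_heptamer_mut":
        rs = gene.parts["rs"]
        gene.parts["rs"] = "GAC" + rs[3:]
    elif kind == "splice_donor_mut":
        gene.parts["donor"] = "AT"
    expected, status = J_LESION_MENU[kind]
    for k in sorted(expected):
        if k not in gene.planted:
            gene.planted.append(k)
    gene.expected_status = status


def make_j_gene_template(label: str, rng: np.random.Generator,
                         plant_lesion: Optional[str] = None,
                         divergence: float = 0.03,
                         base_seed: int = 0) -> JGeneRecord:
    gene = _SimGene("t", label, "J", dict(_j_base_parts(label, base_seed)),
                    _j_frozen_sites())
    gene.mutate(divergence, rng)
    if plant_lesion is not None:
        plant_j_lesion(gene, plant_lesion, rng)
    return _materialize_j(gene, contig="template", offset=0,
                          gene_id=f"{label}-template")


# ---------------------------------------------------------------------------
# Locus assembly
# ---------------------------------------------------------------------------

def _materialize_v(gene: _SimGene, contig: str, offset: int,
                   gene_id: str) -> VGeneRecord:
    parts: dict[str, GenePart] = {}
    pos = offset
    for name in ("l_exon", "intron", "v_exon", "rs"):
        seq = gene.parts.get(name)
        if seq is None:
            parts[name] = GenePart(name=name, span=None, sequence=None)
            continue
        parts[name] = GenePart(name=name, span=Span(pos, pos + len(seq)),
                               sequence=seq)
        pos += len(seq)
    return VGeneRecord(id=gene_id, contig=contig, span=Span(offset, pos),
                       strand="+", parts=parts, subgroup=gene.label,
                       location_class="locus_chromosome")


def _materialize_j(gene: _SimGene, contig: str, offset: int,
                   gene_id: str) -> JGeneRecord:
    parts: dict[str, GenePart] = {}
    pos = offset
    for name in ("rs", "coding", "donor"):
        seq = gene.parts.get(name)
        if seq is None:
            parts[name] = GenePart(name=name, span=None, sequence=None)
            continue
        parts[name] = GenePart(name=name, span=Span(pos, pos + len(seq)),
                               sequence=seq)
        pos += len(seq)
    return JGeneRecord(id=gene_id, contig=contig, span=Span(offset, pos),
                       strand="+", parts=parts, frame=gene.frame)


def _gene_length(gene: _SimGene) -> int:
    return sum(len(s) for s in gene.parts.values() if s is not None)


def simulate_locus(config: SimConfig) -> tuple[LocusAnnotation, SimTruth]:
    """Simulate an annotated locus plus its complete ground-truth log.

    With no duplication events and zero rates the locus contains exactly the
    ancestral genes, all functional.
    """
    rng = np.random.default_rng(config.rng_seed)
    truth = SimTruth()
    death_of = {s.label: s.death_prob for s in config.subgroups}

    serials: dict[str, int] = {}

    def new_id(label: str) -> str:
        serials[label] = serials.get(label, 0) + 1
        return f"{label}-{serials[label]:03d}"

    # ancestral genes, in subgroup list order
    genes: list[_SimGene] = []
    for spec in config.subgroups:
        for _ in range(spec.n_ancestral):
            uid = new_id(spec.label)
            gene = _new_v_gene(uid, spec.label, rng,
                               config.ancestral_divergence, config.rng_seed)
            genes.append(gene)

    menu_kinds = sorted(config.lesion_menu)
    menu_w = np.array([config.lesion_menu[k] for k in menu_kinds], dtype=float)
    menu_w = menu_w / menu_w.sum() if menu_w.sum() > 0 else None

    for ev_idx, event in enumerate(config.duplication_events):
        if not (0 <= event.start < event.end <= len(genes)):
            raise ValueError(
                f"duplication event {ev_idx}: span [{event.start}, {event.end}) "
                f"exceeds current locus of {len(genes)} genes")
        segment = genes[event.start:event.end]
        motif = tuple(g.label for g in segment)
        instances = [[g.uid for g in segment]]
        copies_log = []
        insert_at = event.end
        for _ in range(event.n_copies):
            copy = []
            for src in segment:
                dup = src.copy(new_id(src.label))
                dup.mutate(event.substitution_rate, rng)
                truth.ancestry[dup.uid] = src.uid
                if (menu_w is not None and dup.expected_status == "functional"
                        and rng.random() < death_of.get(dup.label, 0.0)):
                    kind = menu_kinds[rng.choice(len(menu_kinds), p=menu_w)]
                    plant_v_lesion(dup, kind, rng)
                copy.append(dup)
            if event.truncation_prob > 0 and rng.random() < event.truncation_prob:
                copy = copy[:-1]  # partial replication of the unit
            genes[insert_at:insert_at] = copy
            insert_at += len(copy)
            instances.append([g.uid for g in copy])
            copies_log.append([g.uid for g in copy])
        truth.events.append({"event": ev_idx, "motif": motif,
                             "source": instances[0], "copies": copies_log})
        for unit in truth.true_units:
            if unit["motif"] == motif:
                unit["instances"].extend(instances[1:])
                break
        else:
            truth.true_units.append({"motif": motif, "instances": instances})

    # J genes
    j_genes: list[_SimGene] = []
    j_menu = sorted(J_LESION_MENU)
    for i in range(config.n_j_genes):
        label = f"TRAJ{i + 1}"
        gene = _SimGene(label, label, "J",
                        dict(_j_base_parts(label, config.rng_seed)),
                        _j_frozen_sites())
        gene.mutate(0.02, rng)
        if rng.random() < config.j_death_prob:
            plant_j_lesion(gene, j_menu[int(rng.integers(len(j_menu)))], rng)
        j_genes.append(gene)

    # assemble the contig
    contig_id = "chr10_sim"
    chunks: list[str] = []
    records = []
    pos = 0
    for gene in genes + j_genes:
        spacer = _random_bases(rng, int(rng.integers(150, 400)))
        chunks.append(spacer)
        pos += len(spacer)
        if gene.kind == "V":
            record = _materialize_v(gene, contig_id, pos, gene.uid)
        else:
            record = _materialize_j(gene, contig_id, pos, gene.uid)
        records.append(record)
        block = "".join(s for s in gene.parts.values() if s is not None)
        chunks.append(block)
        pos += len(block)
        truth.planted_lesions[gene.uid] = sorted(gene.planted)
        truth.expected_status[gene.uid] = gene.expected_status
    chunks.append(_random_bases(rng, 200))

    annotation = LocusAnnotation(contigs={contig_id: "".join(chunks)},
                                 genes=records,
                                 provenance=f"trlocus simulate seed={config.rng_seed}")
    return annotation, truth


def references_for(config: SimConfig) -> dict[str, SubgroupReference]:
    """Functional per-subgroup references matching a simulated locus."""
    return {s.label: subgroup_reference(s.label, config.rng_seed)
            for s in config.subgroups}


# ---------------------------------------------------------------------------
# Transcripts
# ---------------------------------------------------------------------------

def _chain_subgroups(config: SimConfig) -> dict[str, list[str]]:
    labels = [s.label for s in config.subgroups]
    tra = config.tra_subgroups
    trd = config.trd_subgroups
    if tra is None:
        tra = [l for l in labels if not l.startswith("TRDV")]
    if trd is None:
        trd = [l for l in labels if l.startswith("TRDV")]
    return {"TRA": tra, "TRD": trd}


def simulate_transcripts(
        annotation: LocusAnnotation, truth: SimTruth, config: SimConfig,
) -> tuple[list[TranscriptRecord], SimTruth]:
    """Sample expressed V segments from the functional genes of a locus.

    Each transcript copies the V exon of a functional gene with a strictly
    positive allelic divergence below 3%, except that a ``novel_fraction``
    of transcripts derive from hidden genes: a functional gene diverged into
    the <97%-identity band and excluded from the annotation.  The hidden
    divergence is resampled until identity to every annotated V exon is
    below 96.8%, since lying below the 97% convention is what defines a
    gene as absent from the assembly.
    """
    from .repertoire import percent_identity  # local import, avoids a cycle

    params = config.transcript_params
    rng = np.random.default_rng(np.random.SeedSequence((config.rng_seed, 7)))
    chains = _chain_subgroups(config)

    functional: dict[str, list[VGeneRecord]] = {}
    for gene in annotation.v_genes():
        if truth.expected_status.get(gene.id) == "functional":
            functional.setdefault(gene.subgroup, []).append(gene)
    catalog = [g.v_exon for g in annotation.v_genes() if g.v_exon]

    frozen_v = frozenset(
        p for c in _ANCHOR_VEXON_CODONS for p in range(c * 3, c * 3 + 3))

    transcripts: list[TranscriptRecord] = []
    serial = 0
    for chain, n_wanted in (("TRA", params.n_tra), ("TRD", params.n_trd)):
        pool = [l for l in chains[chain] if functional.get(l)]
        if not pool:
            if n_wanted:
                raise ValueError(f"no functional genes available for {chain}")
            continue
        weights_cfg = (params.usage_weights or {}).get(chain, {})
        w = np.array([weights_cfg.get(l, 1.0) for l in pool], dtype=float)
        w /= w.sum()
        for _ in range(n_wanted):
            label = pool[rng.choice(len(pool), p=w)]
            source = functional[label][int(rng.integers(len(functional[label])))]
            seq = source.v_exon
            if rng.random() < params.novel_fraction:
                hidden, category = _hidden_variant(
                    seq, catalog, params.novel_divergence, frozen_v, rng,
                    percent_identity)
                v_segment, origin = hidden, "novel"
            else:
                d = rng.uniform(*params.allelic_divergence)
                # cap at the 3% band; zero divergence means a perfect copy
                n_sub = (0 if d <= 0 else
                         max(1, min(int(round(d * len(seq))),
                                    int(0.03 * len(seq)))))
                v_segment = mutate(seq, n_sub, rng, frozen_v, coding=True)
                origin = source.id
                category = "identical" if n_sub == 0 else "allelic_or_unassembled"
            serial += 1
            tid = f"{chain}-t{serial:04d}"
            productive = rng.random() >= params.nonproductive_fraction
            transcripts.append(TranscriptRecord(
                id=tid, chain=chain, v_segment=v_segment,
                productive=productive))
            truth.transcript_origin[tid] = {
                "source": origin, "subgroup": label,
                "expected_category": category}
    return transcripts, truth


def _hidden_variant(seq: str, catalog: list[str],
                    divergence: tuple[float, float],
                    frozen: frozenset[int], rng: np.random.Generator,
                    percent_identity, max_tries: int = 25) -> tuple[str, str]:
    for _ in range(max_tries):
        d = rng.uniform(*divergence)
        hidden = mutate(seq, int(round(d * len(seq))), rng, frozen, coding=True)
        if max(percent_identity(hidden, ref) for ref in catalog) < 96.8:
            return hidden, "novel"
    raise RuntimeError("could not place a hidden gene below the 97% band; "
                       "catalog too dense for the requested divergence")


# ---------------------------------------------------------------------------
# Default study conditions
# ---------------------------------------------------------------------------

def default_config(seed: int = 0) -> SimConfig:
    """Scaled-down default locus emulating the study conditions.

    Fifteen ancestral subgroups expand through four tandem homology-unit
    duplications (a 2-gene unit replicated to 7 copies, a 4-gene unit to 6,
    a 3-gene TRDV1-anchored unit to 5 and a 2-gene unit to 3), yielding 63
    V genes.  Death rates differ sharply between subgroups (TRDV1-like
    expansion retains ~80% functional genes while TRAV23-like collateral
    subgroups decay), matching the wide published spread of per-subgroup
    pseudogene proportions.  Transcript sampling uses the published
    repertoire sizes (198 TRA / 143 TRD chains, 11% of them from genes
    absent from the assembly) with TRD usage dominated by TRDV1, and the
    four dual-usage subgroups available to both chains.
    """
    subgroups = [
        SubgroupSpec("TRAV2", death_prob=0.15),
        SubgroupSpec("TRAV3", death_prob=0.0),
        SubgroupSpec("TRAV12", death_prob=0.2),
        SubgroupSpec("TRAV11", death_prob=0.85),
        SubgroupSpec("TRAV10", death_prob=0.5),
        SubgroupSpec("TRAV9", death_prob=0.85),
        SubgroupSpec("TRDV1", death_prob=0.2),
        SubgroupSpec("TRAV23", death_prob=0.8),
        SubgroupSpec("TRAV22", death_prob=0.5),
        SubgroupSpec("TRAVX", death_prob=0.2),
        SubgroupSpec("TRAV8", death_prob=0.5),
        SubgroupSpec("TRAV27", death_prob=0.0),
        SubgroupSpec("TRAV33", death_prob=0.0),
        SubgroupSpec("TRDVb3", death_prob=0.1),
        SubgroupSpec("TRDV3", death_prob=0.0),
    ]
    # gene indices refer to the evolving locus; each event inserts its
    # copies immediately after the duplicated segment
    events = [
        DuplicationSpec(0, 2, n_copies=6),    # TRAV2-3 tandem array
        DuplicationSpec(14, 18, n_copies=5),  # TRAV12-11-10-9
        DuplicationSpec(38, 41, n_copies=4),  # TRDV1-TRAV23-TRAV22
        DuplicationSpec(53, 55, n_copies=2),  # TRAVX-TRAV8
    ]
    transcripts = TranscriptParams(
        n_tra=198, n_trd=143,
        allelic_divergence=(0.003, 0.025),
        novel_fraction=0.11,
        novel_divergence=(0.05, 0.08),
        usage_weights={
            "TRA": {"TRAVX": 23.0, "TRAV3": 11.0, "TRAV2": 6.0,
                    "TRAV12": 6.0, "TRAV10": 5.0, "TRAV22": 5.0,
                    "TRAV8": 5.0, "TRAV27": 5.0, "TRAV33": 4.0,
                    "TRAV23": 3.0, "TRDV1": 2.0, "TRDV3": 1.0,
                    "TRDVb3": 1.0},
            "TRD": {"TRDV1": 70.0, "TRDVb3": 22.0, "TRDV3": 4.0,
                    "TRAV33": 4.0},
        })
    return SimConfig(
        subgroups=subgroups,
        duplication_events=events,
        transcript_params=transcripts,
        n_j_genes=20,
        j_death_prob=0.16,
        tra_subgroups=[s.label for s in subgroups
                       if not s.label.startswith("TRDV")]
                      + ["TRDV1", "TRDV3", "TRDVb3"],
        trd_subgroups=["TRDV1", "TRDV3", "TRDVb3", "TRAV33"],
        rng_seed=seed,
    )
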