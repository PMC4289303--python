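"""Readers and writers for the on-disk formats (FASTA, GFF3, TSV reports).

GFF3 dialect
------------
There is no single standard for encoding V/J gene anatomy in GFF3, so the
package uses a small, self-consistent dialect:

* gene features: ``V_gene_segment``, ``J_gene_segment``, ``D_gene_segment``,
  ``C_gene_segment`` with an ``ID`` attribute (plus ``subgroup`` and
  ``location_class`` for V genes, ``frame`` for J genes);
* child features carry a ``Parent`` attribute and one of the types
  ``five_prime_leader_exon``, ``V_exon``, ``recombination_signal``,
  ``J_exon``, ``splice_donor``.

The V-gene intron is not written explicitly: it is re-derived on read as the
interval between the leader exon and the V exon.  On disk coordinates are
1-based inclusive (GFF3); in memory they are 0-based half-open.  Minus-strand
part sequences are reverse-complemented on read so that all sequence-level
code sees coding orientation.
"""

from __future__ import annotations

import os
from pathlib import Path
from typing import Optional

import gffutils
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .records import (
    CGeneRecord,
    DGeneRecord,
    GenePart,
    GeneRecord,
    JGeneRecord,
    LocusAnnotation,
    RunConfig,
    Span,
    VGeneRecord,
)


class AnnotationError(ValueError):
    """Structured error naming the offending GFF3 feature/line."""


_GENE_TYPES = {
    "V_gene_segment": VGeneRecord,
    "J_gene_segment": JGeneRecord,
    "D_gene_segment": DGeneRecord,
    "C_gene_segment": CGeneRecord,
}

_V_PART_TYPES = {
    "five_prime_leader_exon": "l_exon",
    "V_exon": "v_exon",
    "recombination_signal": "rs",
}
_J_PART_TYPES = {
    "recombination_signal": "rs",
    "J_exon": "coding",
    "splice_donor": "donor",
}
_PART_TYPES = set(_V_PART_TYPES) | set(_J_PART_TYPES)


def _revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def _slice(contigs: dict[str, str], contig: str, span: Span, strand: str) -> str:
    raw = contigs[contig][span.start:span.end]
    return _revcomp(raw) if strand == "-" else raw


def read_fasta(path: str | os.PathLike) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: dict[str, str], path: str | os.PathLike,
                descriptions: Optional[dict[str, str]] = None) -> None:
    records = [
        SeqRecord(Seq(s), id=name,
                  description=(descriptions or {}).get(name, ""))
        for name, s in seqs.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_annotation(gff_path: str | os.PathLike,
                    fasta_path: str | os.PathLike) -> LocusAnnotation:
    """Read a locus annotation from a GFF3 file plus its contig FASTA."""
    contigs = read_fasta(fasta_path)
    db = gffutils.create_db(str(gff_path), dbfn=":memory:", force=True,
                            keep_order=True,
                            merge_strategy="create_unique")

    genes: dict[str, GeneRecord] = {}
    order: list[str] = []
    for feat in db.all_features():
        if feat.featuretype in _GENE_TYPES:
            if feat.seqid not in contigs:
                raise AnnotationError(
                    f"{feat.id}: contig {feat.seqid!r} absent from FASTA "
                    f"(line: {str(feat).strip()})")
            span = Span(feat.start - 1, feat.end)
            if span.end > len(contigs[feat.seqid]):
                raise AnnotationError(
                    f"{feat.id}: coordinates exceed contig length "
                    f"(line: {str(feat).strip()})")
            cls = _GENE_TYPES[feat.featuretype]
            kwargs = {}
            if cls is VGeneRecord:
                kwargs["subgroup"] = feat.attributes.get("subgroup", ["unassigned"])[0]
                kwargs["location_class"] = feat.attributes.get(
                    "location_class", ["locus_chromosome"])[0]
            if cls is JGeneRecord:
                kwargs["frame"] = int(feat.attributes.get("frame", ["0"])[0])
            gene = cls(id=feat.id, contig=feat.seqid, span=span,
                       strand=feat.strand, parts={}, **kwargs)
            genes[feat.id] = gene
            order.append(feat.id)
        elif feat.featuretype in _PART_TYPES:
            continue  # handled below once all parents are known
        else:
            raise AnnotationError(
                f"unknown feature type {feat.featuretype!r} "
                f"(line: {str(feat).strip()})")

    for feat in db.all_features():
        if feat.featuretype not in _PART_TYPES:
            continue
        parents = feat.attributes.get("Parent")
        if not parents or parents[0] not in genes:
            raise AnnotationError(
                f"part feature without known Parent "
                f"(line: {str(feat).strip()})")
        gene = genes[parents[0]]
        part_map = _V_PART_TYPES if isinstance(gene, VGeneRecord) else _J_PART_TYPES
        if feat.featuretype not in part_map:
            raise AnnotationError(
                f"part type {feat.featuretype!r} invalid for "
                f"{type(gene).__name__} (line: {str(feat).strip()})")
        name = part_map[feat.featuretype]
        span = Span(feat.start - 1, feat.end)
        if span.end > len(contigs[gene.contig]):
            raise AnnotationError(
                f"{gene.id}/{name}: coordinates exceed contig length "
                f"(line: {str(feat).strip()})")
        gene.parts[name] = GenePart(
            name=name, span=span,
            sequence=_slice(contigs, gene.contig, span, gene.strand))

    # Absent parts (contig breaks) become explicit placeholders so that
    # write -> read round-trips to an equal annotation.
    for gene in genes.values():
        if isinstance(gene, (VGeneRecord, JGeneRecord)):
            for name in gene.REQUIRED_PARTS:
                if name != "intron":
                    gene.parts.setdefault(name, GenePart(name, None, None))

    # Re-derive V-gene introns from the gap between leader exon and V exon.
    for gene in genes.values():
        if not isinstance(gene, VGeneRecord):
            continue
        l_exon, v_exon = gene.parts.get("l_exon"), gene.parts.get("v_exon")
        if l_exon is None or v_exon is None:
            continue
        # the intron lies between the two exons, whichever is genomically
        # first (on the minus strand the leader exon sits at higher coords)
        ispan = Span(min(l_exon.span.end, v_exon.span.end),
                     max(l_exon.span.start, v_exon.span.start))
        gene.parts["intron"] = GenePart(
            name="intron", span=ispan,
            sequence=_slice(contigs, gene.contig, ispan, gene.strand))
    for gene in genes.values():
        if isinstance(gene, VGeneRecord):
            gene.parts.setdefault("intron", GenePart("intron", None, None))

    return LocusAnnotation(contigs=contigs,
                           genes=[genes[i] for i in order],
                           provenance=str(gff_path))


def _gff_line(contig: str, ftype: str, span: Span, strand: str,
              attributes: dict[str, str]) -> str:
    attrs = ";".join(f"{k}={v}" for k, v in attributes.items())
    return "\t".join([contig, "trlocus", ftype, str(span.start + 1),
                      str(span.end), ".", strand, ".", attrs])


def write_annotation(annotation: LocusAnnotation,
                     gff_path: str | os.PathLike,
                     fasta_path: str | os.PathLike) -> None:
    """Write an annotation as GFF3 + FASTA (inverse of :func:`read_annotation`)."""
    write_fasta(annotation.contigs, fasta_path)
    lines = ["##gff-version 3"]
    type_of = {v: k for k, v in _V_PART_TYPES.items()}
    type_of_j = {v: k for k, v in _J_PART_TYPES.items()}
    for gene in annotation.genes:
        if isinstance(gene, VGeneRecord):
            ftype, part_types = "V_gene_segment", type_of
            attrs = {"ID": gene.id, "subgroup": gene.subgroup,
                     "location_class": gene.location_class}
        elif isinstance(gene, JGeneRecord):
            ftype, part_types = "J_gene_segment", type_of_j
            attrs = {"ID": gene.id, "frame": str(gene.frame)}
        elif isinstance(gene, DGeneRecord):
            ftype, part_types, attrs = "D_gene_segment", {}, {"ID": gene.id}
        else:
            ftype, part_types, attrs = "C_gene_segment", {}, {"ID": gene.id}
        lines.append(_gff_line(gene.contig, ftype, gene.span, gene.strand, attrs))
        for name, part in gene.parts.items():
            if name == "intron" or not part.present or part.span is None:
                continue  # intron is implicit; absent parts are not written
            lines.append(_gff_line(gene.contig, part_types[name], part.span,
                                   gene.strand,
                                   {"ID": f"{gene.id}.{name}", "Parent": gene.id}))
    Path(gff_path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# TSV reports
# ---------------------------------------------------------------------------

def write_table(df: pd.DataFrame, path: str | os.PathLike,
                config: Optional[RunConfig] = None) -> None:
    """Write a report table as TSV with a config/seed provenance header."""
    config = config or RunConfig()
    header = (f"# trlocus report\n"
              f"# config_digest={config.digest()} seed={config.rng_seed}\n")
    with open(path, "w") as fh:
        fh.write(header)
        df.to_csv(fh, sep="\t", index=False)


def read_table(path: str | os.PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def write_reports(results: dict[str, pd.DataFrame], out_dir: str | os.PathLike,
                  config: Optional[RunConfig] = None) -> list[Path]:
    """Write every stage result table under ``out_dir`` as ``<name>.tsv``.

    ``results`` maps report names (e.g. ``catalog_summary``) to data frames;
    an empty frame yields a headers-only file.  Output is deterministic for a
    fixed config/seed.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    for name in sorted(results):
        path = out / f"{name}.tsv"
        write_table(results[name], path, config)
        written.append(path)
    return written
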