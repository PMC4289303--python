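"""Rule-based functional-competence classification of V and J genes.

A V gene is called *functional* when (i) its intron carries GT..AG splice
sites, (ii) the conceptually spliced leader+V reading frame is open, in the
frame of its subgroup reference, (iii) the translation retains the conserved
Cys/Trp/Cys at standardised V-domain positions 23/41/104, (iv) its 23-RS
heptamer/nonamer are compatible with recombination and (v) the gene maps to
the locus chromosome or an unassigned contig.  Any violated rule yields a
machine-readable lesion and the call *pseudogene*; a gene whose sequence is
incomplete (a part lost to a contig break) is called *incomplete*, which
outranks pseudogene.

J genes are functional when their coding region retains the canonical
F-G-x-G motif with an open reading frame, a valid 12-RS and a GT splice
donor.
"""

from __future__ import annotations

import re
from typing import Optional

import pandas as pd
from Bio import Align

from .records import (
    CompetenceCall,
    JGeneRecord,
    Lesion,
    SubgroupReference,
    VGeneRecord,
)
from .simulate import HEPTAMER, NONAMER, translate

_peptide_aligner: Optional[Align.PairwiseAligner] = None


def _get_peptide_aligner() -> Align.PairwiseAligner:
    global _peptide_aligner
    if _peptide_aligner is None:
        aligner = Align.PairwiseAligner()
        aligner.mode = "global"
        aligner.match_score = 2.0
        aligner.mismatch_score = -1.0
        aligner.open_gap_score = -5.0
        aligner.extend_gap_score = -0.5
        _peptide_aligner = aligner
    return _peptide_aligner


# ---------------------------------------------------------------------------
# Individual checks
# ---------------------------------------------------------------------------

def check_splice(record: VGeneRecord) -> list[Lesion]:
    """Splice-site check: empty iff the intron begins GT and ends AG."""
    intron = record.part_seq("intron")
    if intron is None:
        return [Lesion("missing_sequence", detail="intron")]
    lesions = []
    if intron[:2] != "GT":
        lesions.append(Lesion("splice_donor", detail=intron[:2], position=0))
    if intron[-2:] != "AG":
        lesions.append(Lesion("splice_acceptor", detail=intron[-2:],
                              position=len(intron) - 2))
    return lesions


def check_orf(record: VGeneRecord,
              reference: Optional[SubgroupReference] = None,
              ) -> tuple[list[Lesion], Optional[str]]:
    """Open-reading-frame check on the conceptually spliced leader+V exon.

    Frameshifts are called relative to the subgroup reference V-exon length
    modulo 3 (duplicated pseudogene copies typically share a small deletion,
    so de-novo ORF search would mask the lesion).  A frameshift suppresses
    the stop-codon scan, whose frame is no longer meaningful.  Stop codons
    are otherwise reported positionally from a through-translation, so a
    premature stop does not cascade into spurious residue lesions.
    """
    l_exon = record.part_seq("l_exon")
    v_exon = record.part_seq("v_exon")
    missing = [Lesion("missing_sequence", detail=name)
               for name, seq in (("l_exon", l_exon), ("v_exon", v_exon))
               if seq is None]
    if missing:
        return missing, None
    if reference is not None:
        shift = (len(v_exon) - reference.v_exon_length) % 3
        if shift:
            return [Lesion("frameshift",
                           detail=f"v_exon_length={len(v_exon)}"
                                  f"_vs_ref={reference.v_exon_length}")], None
    spliced = l_exon + v_exon
    translation = translate(spliced)
    lesions = []
    if not translation.startswith("M"):
        lesions.append(Lesion("no_initiator", detail=translation[:1], position=0))
    for idx, aa in enumerate(translation):
        if aa == "*":
            lesions.append(Lesion("premature_stop", position=idx))
    return lesions, translation


def check_conserved_residues(translation: str,
                             imgt_map: dict[int, Optional[int]]) -> list[Lesion]:
    """Check the conserved Cys-23, Trp-41 and Cys-104 anchors.

    ``imgt_map`` maps the standardised positions 23/41/104 to 0-based indices
    of ``translation`` (None where the position could not be aligned, which
    counts as the corresponding lesion with detail "unalignable").
    """
    expected = {23: ("C", "C23_mut"), 41: ("W", "W41_mut"),
                104: ("C", "C104_mut")}
    lesions = []
    for pos, (aa, kind) in expected.items():
        idx = imgt_map.get(pos)
        if idx is None or idx >= len(translation):
            lesions.append(Lesion(kind, detail="unalignable"))
        elif translation[idx] != aa:
            lesions.append(Lesion(kind, detail=translation[idx], position=idx))
    return lesions


def map_anchor_positions(translation: str,
                         reference: SubgroupReference) -> dict[int, Optional[int]]:
    """Map the reference's anchor indices onto a candidate translation by
    global peptide alignment."""
    if translation == reference.peptide:
        return dict(reference.anchors)
    alignment = _get_peptide_aligner().align(reference.peptide, translation)[0]
    ref_to_query: dict[int, int] = {}
    for (rstart, rend), (qstart, qend) in zip(*alignment.aligned):
        for offset in range(rend - rstart):
            ref_to_query[rstart + offset] = qstart + offset
    return {pos: ref_to_query.get(idx)
            for pos, idx in reference.anchors.items()}


def check_rs(rs_seq: Optional[str], expected_spacer: int = 23) -> list[Lesion]:
    """Recombination-signal check (heptamer - spacer - nonamer).

    The heptamer must begin with the invariant CAC and match the CACAGTG
    consensus at >= 5/7 positions; the nonamer must match ACAAAAACC at
    >= 6/9; the spacer length must be within one base of 12 or 23.
    """
    if rs_seq is None:
        return [Lesion("missing_sequence", detail="rs")]
    if expected_spacer not in (12, 23):
        raise ValueError("expected_spacer must be 12 or 23")
    heptamer, nonamer = rs_seq[:7], rs_seq[-9:]
    spacer_len = len(rs_seq) - 16
    lesions = []
    hept_id = sum(a == b for a, b in zip(heptamer, HEPTAMER))
    if heptamer[:3] != "CAC" or hept_id < 5:
        lesions.append(Lesion("RS_heptamer", detail=heptamer))
    nona_id = sum(a == b for a, b in zip(nonamer, NONAMER))
    if nona_id < 6:
        lesions.append(Lesion("RS_nonamer", detail=nonamer))
    if abs(spacer_len - expected_spacer) > 1:
        lesions.append(Lesion("RS_spacer",
                              detail=f"{spacer_len}_vs_{expected_spacer}"))
    return lesions


# ---------------------------------------------------------------------------
# Aggregation
# ---------------------------------------------------------------------------

def classify_v_gene(record: VGeneRecord,
                    reference: Optional[SubgroupReference] = None,
                    ) -> CompetenceCall:
    """Aggregate all checks into one call for a V gene.

    Precedence: any missing part makes the gene *incomplete* (its remaining
    parts are still checked and lesions reported); otherwise any lesion
    makes it a *pseudogene*; otherwise it is *functional*.
    """
    lesions: list[Lesion] = []
    if record.location_class == "other":
        lesions.append(Lesion("unmapped_location", detail=record.contig))
    lesions.extend(check_splice(record))
    orf_lesions, translation = check_orf(record, reference)
    lesions.extend(orf_lesions)
    frameshifted = any(l.kind == "frameshift" for l in orf_lesions)
    if translation is not None and not frameshifted and reference is not None:
        imgt_map = map_anchor_positions(translation, reference)
        lesions.extend(check_conserved_residues(translation, imgt_map))
    if "rs" in record.parts and not record.parts["rs"].present:
        lesions.append(Lesion("missing_sequence", detail="rs"))
    elif record.part_seq("rs") is not None:
        lesions.extend(check_rs(record.part_seq("rs"), expected_spacer=23))
    else:
        lesions.append(Lesion("missing_sequence", detail="rs"))

    # deduplicate missing_sequence reports by part
    seen, unique = set(), []
    for lesion in lesions:
        key = (lesion.kind, lesion.detail, lesion.position)
        if key not in seen:
            seen.add(key)
            unique.append(lesion)
    status = _status(unique)
    return CompetenceCall(gene_id=record.id, status=status, lesions=unique,
                          translation=translation)


def classify_j_gene(record: JGeneRecord) -> CompetenceCall:
    """Functional iff the reading frame retains F-G-x-G with no internal
    stop, the 12-RS is valid and the splice donor is GT."""
    lesions: list[Lesion] = []
    coding = record.part_seq("coding")
    translation = None
    if coding is None:
        lesions.append(Lesion("missing_sequence", detail="coding"))
    else:
        translation = translate(coding[record.frame:])
        for idx, aa in enumerate(translation):
            if aa == "*":
                lesions.append(Lesion("premature_stop", position=idx))
        if not re.search(r"FG.G", translation):
            lesions.append(Lesion("missing_FGxG"))
    if "rs" in record.parts and not record.parts["rs"].present:
        lesions.append(Lesion("missing_sequence", detail="rs"))
    else:
        lesions.extend(check_rs(record.part_seq("rs"), expected_spacer=12))
    donor = record.part_seq("donor")
    if donor is None:
        lesions.append(Lesion("missing_sequence", detail="donor"))
    elif donor[:2] != "GT":
        lesions.append(Lesion("splice_donor", detail=donor[:2]))
    return CompetenceCall(gene_id=record.id, status=_status(lesions),
                          lesions=lesions, translation=translation)


def _status(lesions: list[Lesion]) -> str:
    kinds = {l.kind for l in lesions}
    if "missing_sequence" in kinds:
        return "incomplete"
    return "pseudogene" if kinds else "functional"


def _natural_key(label: str) -> tuple:
    return tuple(int(chunk) if chunk.isdigit() else chunk
                 for chunk in re.split(r"(\d+)", label))


def summarize_catalog(calls: list[CompetenceCall],
                      subgroup_map: dict[str, str]) -> pd.DataFrame:
    """Per-subgroup count table (total / functional / pseudogene / incomplete
    and percent functional), with a Total row appended.

    Percent functional uses the subgroup's full gene count (including
    incomplete genes) as denominator, rounded to one decimal.
    """
    rows = {}
    for call in calls:
        label = subgroup_map.get(call.gene_id, "unassigned")
        row = rows.setdefault(label, {"total": 0, "functional": 0,
                                      "pseudogene": 0, "incomplete": 0})
        row["total"] += 1
        row[call.status] += 1
    table = []
    for label in sorted(rows, key=_natural_key):
        row = rows[label]
        table.append({"subgroup": label, **row,
                      "percent_functional":
                          round(100.0 * row["functional"] / row["total"], 1)})
    totals = {"total": sum(r["total"] for r in rows.values()),
              "functional": sum(r["functional"] for r in rows.values()),
              "pseudogene": sum(r["pseudogene"] for r in rows.values()),
              "incomplete": sum(r["incomplete"] for r in rows.values())}
    table.append({"subgroup": "Total", **totals,
                  "percent_functional":
                      round(100.0 * totals["functional"] / totals["total"], 1)
                      if totals["total"] else 0.0})
    return pd.DataFrame(table, columns=["subgroup", "total", "functional",
                                        "pseudogene", "incomplete",
                                        "percent_functional"])


def calls_table(calls: list[CompetenceCall],
                subgroup_map: dict[str, str]) -> pd.DataFrame:
    """Per-gene TSV-ready table: id, subgroup, status, lesion list."""
    return pd.DataFrame(
        [{"gene_id": c.gene_id,
          "subgroup": subgroup_map.get(c.gene_id, "unassigned"),
          "status": c.status,
          "lesions": ";".join(str(l) for l in c.lesions)}
         for c in calls])
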