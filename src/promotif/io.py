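"""File I/O: FASTA promoters, GFF3 hit/module features, TSV and JSON.

GFF3 forbids negative coordinates, so features use 1-based positive
positions within each record and carry the ATG-relative start in an
``atg_offset`` attribute.  Motif hits are written as ``TF_binding_site``
features, conserved modules as ``conserved_region``.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .consensus import CCRM, AlignmentMatrix, ConsensusAnnotation
from .scan import AnnotatedPromoter, MotifHit, PromoterSequence

__all__ = [
    "read_promoters",
    "write_promoters",
    "read_alignment",
    "write_alignment",
    "write_hits_gff3",
    "read_hits_gff3",
    "write_hits_tsv",
    "consensus_to_json",
    "write_ccrms_gff3",
]


def read_promoters(
    path: str | Path, gene_delimiter: str = "|"
) -> list[PromoterSequence]:
    """Read promoter alleles from FASTA.

    Record ids of the form ``gene<delim>allele`` are split into the
    gene label and the allele id; ids without the delimiter keep an
    empty gene label.
    """
    promoters = []
    for record in SeqIO.parse(str(path), "fasta"):
        rid = record.id
        gene = ""
        if gene_delimiter in rid:
            gene, _, _ = rid.partition(gene_delimiter)
        promoters.append(
            PromoterSequence(seq_id=rid, residues=str(record.seq), gene=gene)
        )
    return promoters


def write_promoters(promoters: Iterable[PromoterSequence], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(p.residues), id=p.seq_id, description="")
        for p in promoters
    ]
    SeqIO.write(records, str(path), "fasta")


def read_alignment(path: str | Path) -> AlignmentMatrix:
    """Read an aligned FASTA (gap character ``-``)."""
    ids, rows = [], []
    for record in SeqIO.parse(str(path), "fasta"):
        ids.append(record.id)
        rows.append(str(record.seq))
    if not ids:
        raise ValueError(f"no records in aligned FASTA {path}")
    return AlignmentMatrix(member_ids=tuple(ids), rows=tuple(rows))


def write_alignment(alignment: AlignmentMatrix, path: str | Path) -> None:
    records = [
        SeqRecord(Seq(row), id=mid, description="")
        for mid, row in zip(alignment.member_ids, alignment.rows)
    ]
    SeqIO.write(records, str(path), "fasta")


def _gff_escape(value: str) -> str:
    return value.replace(";", "%3B").replace("=", "%3D").replace(",", "%2C")


def write_hits_gff3(
    annotated_set: Sequence[AnnotatedPromoter], path: str | Path
) -> None:
    """Write motif hits as GFF3 ``TF_binding_site`` features."""
    lines = ["##gff-version 3"]
    for ann in annotated_set:
        L = len(ann.promoter)
        lines.append(f"##sequence-region {ann.promoter.seq_id} 1 {L}")
        for i, h in enumerate(ann.hits, start=1):
            start1 = h.start + L + 1
            end1 = h.end + L + 1
            attrs = (
                f"ID={_gff_escape(ann.promoter.seq_id)}.hit{i};"
                f"Name={_gff_escape(h.motif_id)};"
                f"atg_offset={h.start};"
                f"matched_seq={h.matched_seq}"
            )
            lines.append(
                "\t".join(
                    [
                        ann.promoter.seq_id,
                        "promotif",
                        "TF_binding_site",
                        str(start1),
                        str(end1),
                        ".",
                        h.strand,
                        ".",
                        attrs,
                    ]
                )
            )
    Path(path).write_text("\n".join(lines) + "\n")


def read_hits_gff3(
    path: str | Path, promoters: Sequence[PromoterSequence] | None = None
) -> dict[str, AnnotatedPromoter]:
    """Round-trip reader for :func:`write_hits_gff3` output.

    When *promoters* is given their sequences back the annotations;
    otherwise minimal placeholder sequences of Ns are synthesized from
    the ``##sequence-region`` pragmas.
    """
    by_id = {p.seq_id: p for p in promoters or []}
    lengths: dict[str, int] = {}
    hits: dict[str, list[MotifHit]] = {}
    for line in Path(path).read_text().splitlines():
        if line.startswith("##sequence-region"):
            _, sid, _, end = line.split()
            lengths[sid] = int(end)
            hits.setdefault(sid, [])
            continue
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 9 or fields[2] != "TF_binding_site":
            continue
        sid, _, _, start1, end1, _, strand, _, attrs = fields
        adict = dict(kv.split("=", 1) for kv in attrs.split(";") if "=" in kv)
        L = lengths.get(sid) or len(by_id[sid])
        hits.setdefault(sid, []).append(
            MotifHit(
                motif_id=adict["Name"],
                start=int(start1) - L - 1,
                end=int(end1) - L - 1,
                strand=strand,  # type: ignore[arg-type]
                matched_seq=adict.get("matched_seq", ""),
            )
        )
    out = {}
    for sid, hlist in hits.items():
        promoter = by_id.get(sid) or PromoterSequence(
            seq_id=sid, residues="N" * lengths[sid]
        )
        out[sid] = AnnotatedPromoter(promoter=promoter, hits=tuple(hlist))
    return out


def write_hits_tsv(annotated_set: Sequence[AnnotatedPromoter], path: str | Path) -> None:
    lines = ["seq_id\tmotif_id\tstart\tend\tstrand\tmatched_seq"]
    for ann in annotated_set:
        for h in ann.hits:
            lines.append(
                f"{ann.promoter.seq_id}\t{h.motif_id}\t{h.start}\t{h.end}"
                f"\t{h.strand}\t{h.matched_seq}"
            )
    Path(path).write_text("\n".join(lines) + "\n")


def consensus_to_json(consensus: ConsensusAnnotation) -> str:
    def motif_dict(m):
        return {
            "motif_id": m.motif_id,
            "strand": m.strand,
            "ref_coordinate": m.ref_coordinate,
            "support": m.support,
            "length": m.length,
            "member_hits": [list(t) for t in sorted(m.member_hits)],
        }

    payload = {
        "set_id": consensus.set_id,
        "members": list(consensus.members),
        "params": {
            "tolerance": consensus.params.tolerance,
            "conserved_support": consensus.params.conserved_support,
            "majority_support": consensus.params.majority_support,
            "ccrm_max_gap": consensus.params.ccrm_max_gap,
            "ccrm_min_motifs": consensus.params.ccrm_min_motifs,
            "merge_tolerance": consensus.params.merge_tolerance,
        },
        "conserved": [motif_dict(m) for m in consensus.conserved],
        "majority": [motif_dict(m) for m in consensus.majority],
    }
    return json.dumps(payload, indent=2)


def write_ccrms_gff3(
    ccrms: Sequence[CCRM], set_id: str, ref_length: int, path: str | Path
) -> None:
    """Write modules as GFF3 ``conserved_region`` features (``ID=CCRM1..k``)."""
    lines = ["##gff-version 3", f"##sequence-region {set_id} 1 {ref_length}"]
    for c in ccrms:
        start1 = c.span[0] + ref_length + 1
        end1 = c.span[1] + ref_length + 1
        motifs = ",".join(m.motif_id for m in c.motifs)
        lines.append(
            "\t".join(
                [
                    set_id,
                    "promotif",
                    "conserved_region",
                    str(start1),
                    str(end1),
                    ".",
                    "+",
                    ".",
                    f"ID=CCRM{c.index};atg_offset={c.span[0]};motifs={_gff_escape(motifs)}",
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")
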