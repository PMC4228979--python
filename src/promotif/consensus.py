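"""Indel-aware consensus annotation and conserved cis-regulatory modules.

Promoter alleles differ by indels, so the "same" motif sits at slightly
different ATG-relative coordinates in different members.  This module
projects every member's hit coordinates into a common reference frame
using an alignment, clusters per-motif start positions within a small
tolerance, and classifies clusters by the fraction of members that
contribute:

* *conserved* — present in (by default) **all** members at the same
  shift-corrected coordinate ±tolerance;
* *majority* — present in more than half of the members but short of
  the conserved threshold (used for inter-motif distance reports).

Runs of conserved motifs separated by no more than ``ccrm_max_gap``
bases form conserved cis-regulatory modules (CCRMs), numbered from the
start codon outward.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Mapping, Sequence

import pandas as pd

from .scan import AnnotatedPromoter, PromoterSequence

__all__ = [
    "AlignmentMatrix",
    "OffsetMap",
    "ConsensusParams",
    "ConservedMotif",
    "ConsensusAnnotation",
    "CCRM",
    "build_offset_maps",
    "align_members",
    "find_conserved",
    "detect_ccrms",
    "merge_consensuses",
    "distance_report",
]

GAP = "-"


@dataclass
class AlignmentMatrix:
    """Equal-length gapped rows over a set of members, ATG-anchored.

    Ungapping row *i* reproduces member *i*'s residues; all rows end at
    the translation start codon, so alignment-frame coordinates are
    ATG-relative: column *j* of a width-*W* alignment has coordinate
    ``j − W``.
    """

    member_ids: tuple[str, ...]
    rows: tuple[str, ...]

    def __post_init__(self) -> None:
        self.member_ids = tuple(self.member_ids)
        self.rows = tuple(r.upper() for r in self.rows)
        if len(self.member_ids) != len(self.rows):
            raise ValueError("member_ids and rows disagree in length")
        if len(set(self.member_ids)) != len(self.member_ids):
            raise ValueError("duplicate member ids in alignment")
        widths = {len(r) for r in self.rows}
        if len(widths) > 1:
            raise ValueError(f"alignment rows have unequal lengths: {sorted(widths)}")
        for mid, row in zip(self.member_ids, self.rows):
            bad = set(row) - set("ACGTN" + GAP)
            if bad:
                raise ValueError(f"row {mid!r} has invalid characters {sorted(bad)}")

    @property
    def n(self) -> int:
        return len(self.rows)

    @property
    def width(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def row(self, member_id: str) -> str:
        return self.rows[self.member_ids.index(member_id)]

    def ungapped(self, member_id: str) -> str:
        return self.row(member_id).replace(GAP, "")

    def is_gapless(self) -> bool:
        return not any(GAP in r for r in self.rows)


@dataclass
class OffsetMap:
    """Member ATG-relative coordinate → reference-frame coordinate.

    Built from an alignment: each member base maps to the reference
    base in the same column, or — when the reference is gapped there —
    to the nearest reference base 5′ (more distal) of that column.
    The mapping is monotone non-decreasing and is the identity when the
    alignment is gapless (or when the member is the reference).
    """

    member_id: str
    mapping: dict[int, int]

    def __getitem__(self, coord: int) -> int:
        return self.mapping[coord]

    def get(self, coord: int, default: int | None = None) -> int | None:
        return self.mapping.get(coord, default)

    def is_identity(self) -> bool:
        return all(k == v for k, v in self.mapping.items())

    @classmethod
    def identity(cls, member_id: str, length: int) -> "OffsetMap":
        return cls(member_id, {c: c for c in range(-length, 0)})


def build_offset_maps(
    alignment: AlignmentMatrix, reference: str
) -> dict[str, OffsetMap]:
    """Project every member's coordinates into *reference*'s frame."""
    if reference not in alignment.member_ids:
        raise ValueError(f"unknown reference member {reference!r}")
    ref_row = alignment.row(reference)
    W = alignment.width
    ref_len = len(ref_row) - ref_row.count(GAP)

    # Reference coordinate carried by each column: the coordinate of the
    # reference base there, else the nearest reference base to the left
    # (5′/more distal); leading reference gaps fall back to the nearest
    # base 3′ so every column maps somewhere.
    ref_coord_at: list[int] = [0] * W
    seen = 0
    last = None
    for j, ch in enumerate(ref_row):
        if ch != GAP:
            seen += 1
            last = seen - ref_len - 1  # negative ATG-relative coordinate
        ref_coord_at[j] = last if last is not None else -ref_len
    maps: dict[str, OffsetMap] = {}
    for mid in alignment.member_ids:
        row = alignment.row(mid)
        mem_len = len(row) - row.count(GAP)
        mapping: dict[int, int] = {}
        seen = 0
        for j, ch in enumerate(row):
            if ch != GAP:
                seen += 1
                mapping[seen - mem_len - 1] = ref_coord_at[j]
        maps[mid] = OffsetMap(mid, mapping)
    return maps


def _pairwise_align(ref: str, other: str):
    """Global affine-gap alignment of *other* against *ref* (Biopython)."""
    from Bio import Align

    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -5
    aligner.extend_gap_score = -0.5
    alignment = aligner.align(ref, other)[0]
    return str(alignment[0]), str(alignment[1]), alignment.score


def align_members(
    promoters: Sequence[PromoterSequence], reference: str | None = None
) -> AlignmentMatrix:
    """Star alignment of promoter alleles against a reference member.

    Each member is globally aligned to the reference with affine gap
    penalties (match +1, mismatch −1, open −5, extend −0.5) and the
    pairwise alignments are stitched on shared reference columns.
    Insertions of different members at the same reference position are
    left-justified against each other (a star-alignment approximation).
    A pre-made aligned FASTA should be preferred when available.
    """
    if not promoters:
        raise ValueError("align_members needs at least one promoter")
    ids = [p.seq_id for p in promoters]
    if reference is None:
        reference = ids[0]
    if reference not in ids:
        raise ValueError(f"reference {reference!r} not among members")
    by_id = {p.seq_id: p for p in promoters}
    for p in promoters:
        if len(p) and p.residues.count("N") / len(p) > 0.10:
            import warnings

            warnings.warn(
                f"promoter {p.seq_id!r} has >10% N content; alignment may be poor",
                stacklevel=2,
            )
    ref_seq = by_id[reference].residues
    R = len(ref_seq)
    # Per member: inserted strings before each reference position (index
    # 0..R, R = trailing) and the member character at each reference
    # position (base or gap).
    inserts: dict[str, list[str]] = {}
    at_pos: dict[str, list[str]] = {}
    for mid in ids:
        if mid == reference:
            inserts[mid] = [""] * (R + 1)
            at_pos[mid] = list(ref_seq)
            continue
        ref_g, mem_g, _ = _pairwise_align(ref_seq, by_id[mid].residues)
        ins = [""] * (R + 1)
        ap = [GAP] * R
        p = 0
        for rc, mc in zip(ref_g, mem_g):
            if rc == GAP:
                ins[p] += mc
            else:
                ap[p] = mc
                p += 1
        inserts[mid] = ins
        at_pos[mid] = ap
    ins_width = [max(len(inserts[mid][p]) for mid in ids) for p in range(R + 1)]
    rows = []
    for mid in ids:
        parts = []
        for p in range(R):
            parts.append(inserts[mid][p].ljust(ins_width[p], GAP))
            parts.append(at_pos[mid][p])
        parts.append(inserts[mid][R].ljust(ins_width[R], GAP))
        rows.append("".join(parts))
    return AlignmentMatrix(member_ids=tuple(ids), rows=tuple(rows))


@dataclass(frozen=True)
class ConsensusParams:
    """Tunables of consensus building and CCRM detection (all in bp)."""

    tolerance: int = 5
    conserved_support: float = 1.0
    majority_support: float = 0.5
    ccrm_max_gap: int = 100
    ccrm_min_motifs: int = 2
    merge_tolerance: int = 10

    def __post_init__(self) -> None:
        if self.tolerance < 0 or self.merge_tolerance < 0:
            raise ValueError("tolerances must be >= 0")
        if not 0 < self.majority_support <= self.conserved_support <= 1:
            raise ValueError(
                "need 0 < majority_support <= conserved_support <= 1, got "
                f"{self.majority_support}, {self.conserved_support}"
            )
        if self.ccrm_max_gap < 0 or self.ccrm_min_motifs < 1:
            raise ValueError("invalid CCRM parameters")


@dataclass(frozen=True)
class ConservedMotif:
    """A motif position shared across members of a promoter set."""

    motif_id: str
    strand: str
    ref_coordinate: int
    support: float
    length: int
    member_hits: tuple[tuple[str, int], ...]  # (member_id, mapped start)

    def __post_init__(self) -> None:
        if not 0 < self.support <= 1:
            raise ValueError(f"support must be in (0, 1], got {self.support}")

    @property
    def end(self) -> int:
        return self.ref_coordinate + self.length - 1

    @property
    def members(self) -> tuple[str, ...]:
        return tuple(sorted({m for m, _ in self.member_hits}))


@dataclass
class ConsensusAnnotation:
    """Conserved and majority motifs of one promoter set."""

    set_id: str
    members: tuple[str, ...]
    conserved: tuple[ConservedMotif, ...]
    majority: tuple[ConservedMotif, ...]
    params: ConsensusParams

    def __post_init__(self) -> None:
        self.members = tuple(self.members)
        self.conserved = tuple(sorted(self.conserved, key=_cluster_key))
        self.majority = tuple(sorted(self.majority, key=_cluster_key))

    @property
    def qualifying(self) -> tuple[ConservedMotif, ...]:
        """Motifs with support above the majority threshold (both tiers)."""
        return tuple(sorted(self.conserved + self.majority, key=_cluster_key))


@dataclass(frozen=True)
class CCRM:
    """A conserved cis-regulatory module: clustered conserved motifs."""

    index: int  # 1-based, numbered from the start codon outward
    motifs: tuple[ConservedMotif, ...]
    span: tuple[int, int]


def _cluster_key(c: ConservedMotif) -> tuple:
    return (c.ref_coordinate, c.motif_id, c.strand)


def _median_toward_atg(values: Sequence[int]) -> int:
    """Median start; on even counts take the element nearer the start codon."""
    s = sorted(values)
    mid = len(s) // 2
    if len(s) % 2 == 1:
        return s[mid]
    return s[mid]  # upper median = less negative = nearer −1


def _cluster_starts(
    hits_by_member: Mapping[str, Sequence[tuple[str, str, int, int]]],
    n_members: int,
    tolerance: int,
) -> list[ConservedMotif]:
    """Single-linkage 1-D clustering of mapped starts per (motif, strand).

    *hits_by_member* maps member id to tuples ``(motif_id, strand,
    mapped_start, length)``.  In one dimension single linkage with link
    distance ≤ tolerance reduces to splitting the sorted starts at gaps
    greater than the tolerance.
    """
    pooled: dict[tuple[str, str], list[tuple[int, str, int]]] = {}
    for mid, hits in hits_by_member.items():
        for motif_id, strand, start, length in hits:
            pooled.setdefault((motif_id, strand), []).append((start, mid, length))
    clusters: list[ConservedMotif] = []
    for (motif_id, strand), items in pooled.items():
        items.sort()
        run: list[tuple[int, str, int]] = []
        for item in items:
            if run and item[0] - run[-1][0] > tolerance:
                clusters.append(_finish(motif_id, strand, run, n_members))
                run = []
            run.append(item)
        if run:
            clusters.append(_finish(motif_id, strand, run, n_members))
    return clusters


def _finish(
    motif_id: str, strand: str, run: list[tuple[int, str, int]], n_members: int
) -> ConservedMotif:
    starts = [s for s, _, _ in run]
    members = {m for _, m, _ in run}
    length = max(l for _, _, l in run)
    return ConservedMotif(
        motif_id=motif_id,
        strand=strand,
        ref_coordinate=_median_toward_atg(starts),
        support=len(members) / n_members,
        length=length,
        member_hits=tuple((m, s) for s, m, _ in run),
    )


def find_conserved(
    annotated: Mapping[str, AnnotatedPromoter] | Sequence[AnnotatedPromoter],
    offsets: Mapping[str, OffsetMap],
    params: ConsensusParams = ConsensusParams(),
    set_id: str = "set",
    strands: Literal["plus", "both"] = "plus",
) -> ConsensusAnnotation:
    """Cluster shift-corrected motif starts across members.

    Every annotation must be nested-resolved and every member must have
    an offset map.  Clusters with support ≥ ``conserved_support`` are
    conserved; clusters with support strictly above ``majority_support``
    but below the conserved threshold form the majority tier.
    """
    if not isinstance(annotated, Mapping):
        annotated = {a.promoter.seq_id: a for a in annotated}
    for mid, ann in annotated.items():
        if not ann.nested_resolved:
            raise ValueError(f"annotation for {mid!r} is not nested-resolved")
        if mid not in offsets:
            raise ValueError(f"member {mid!r} has no offset map")
    n_members = len(annotated)
    hits_by_member: dict[str, list[tuple[str, str, int, int]]] = {}
    for mid, ann in sorted(annotated.items()):
        mapped = []
        for h in ann.hits:
            if strands == "plus" and h.strand != "+":
                continue
            ref_start = offsets[mid].get(h.start)
            if ref_start is None:
                continue
            mapped.append((h.motif_id, h.strand, ref_start, h.length))
        hits_by_member[mid] = mapped
    clusters = _cluster_starts(hits_by_member, n_members, params.tolerance)
    conserved = [c for c in clusters if c.support >= params.conserved_support]
    majority = [
        c
        for c in clusters
        if params.majority_support < c.support < params.conserved_support
    ]
    return ConsensusAnnotation(
        set_id=set_id,
        members=tuple(sorted(annotated)),
        conserved=tuple(conserved),
        majority=tuple(majority),
        params=params,
    )


def detect_ccrms(
    consensus: ConsensusAnnotation, params: ConsensusParams | None = None
) -> list[CCRM]:
    """Group conserved motifs into modules.

    Walking from the motif nearest the start codon outward, a new
    module opens whenever the start-to-start gap to the previous motif
    exceeds ``ccrm_max_gap``; modules with fewer than
    ``ccrm_min_motifs`` motifs are discarded and survivors are numbered
    1..k from the start codon.
    """
    params = params or consensus.params
    motifs = sorted(consensus.conserved, key=lambda c: -c.ref_coordinate)
    groups: list[list[ConservedMotif]] = []
    for m in motifs:  # nearest −1 first
        if groups and groups[-1][-1].ref_coordinate - m.ref_coordinate <= params.ccrm_max_gap:
            groups[-1].append(m)
        else:
            groups.append([m])
    ccrms = []
    idx = 0
    for g in groups:
        if len(g) < params.ccrm_min_motifs:
            continue
        idx += 1
        ccrms.append(
            CCRM(
                index=idx,
                motifs=tuple(sorted(g, key=_cluster_key)),
                span=(min(c.ref_coordinate for c in g), max(c.end for c in g)),
            )
        )
    return ccrms


def merge_consensuses(
    consensuses: Sequence[ConsensusAnnotation],
    params: ConsensusParams = ConsensusParams(),
    set_id: str = "overall",
) -> ConsensusAnnotation:
    """Overall consensus across per-set consensuses.

    Each input's conserved motifs become pseudo-hits in a shared
    ATG-relative frame (identity offsets) and are re-clustered with
    ``merge_tolerance``; the merged conserved tier keeps only motifs
    present in every input.  Order of inputs does not matter.
    """
    if not consensuses:
        raise ValueError("merge_consensuses needs at least one consensus")
    hits_by_member = {
        c.set_id: [
            (m.motif_id, m.strand, m.ref_coordinate, m.length) for m in c.conserved
        ]
        for c in consensuses
    }
    n = len(consensuses)
    clusters = _cluster_starts(hits_by_member, n, params.merge_tolerance)
    conserved = [c for c in clusters if c.support >= 1.0]
    majority = [c for c in clusters if params.majority_support < c.support < 1.0]
    return ConsensusAnnotation(
        set_id=set_id,
        members=tuple(sorted(hits_by_member)),
        conserved=tuple(conserved),
        majority=tuple(majority),
        params=params,
    )


def distance_report(consensus: ConsensusAnnotation) -> pd.DataFrame:
    """Start-to-start distances between consecutive qualifying motifs.

    Qualifying = support above the majority threshold (conserved and
    majority tiers).  Returns an empty frame for fewer than two motifs.
    """
    motifs = sorted(consensus.qualifying, key=lambda c: c.ref_coordinate)
    records = []
    for a, b in zip(motifs, motifs[1:]):
        records.append(
            {
                "from_motif": a.motif_id,
                "from_coordinate": a.ref_coordinate,
                "to_motif": b.motif_id,
                "to_coordinate": b.ref_coordinate,
                "distance": b.ref_coordinate - a.ref_coordinate,
            }
        )
    return pd.DataFrame(
        records,
        columns=["from_motif", "from_coordinate", "to_motif", "to_coordinate", "distance"],
    )
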