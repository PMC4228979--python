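"""Promoter sequences, motif scanning, nested-hit resolution and counting.

Coordinates are ATG-relative throughout: position −1 is the base
immediately 5′ of the A of the start codon, there is no position 0, and
a promoter of length *L* spans −L..−1.  Minus-strand hits are reported
in plus-strand coordinates (leftmost base = start) with a strand flag.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import pandas as pd

from .catalog import MotifCatalog, iupac_matcher, reverse_complement_pattern

__all__ = [
    "PromoterSequence",
    "MotifHit",
    "AnnotatedPromoter",
    "scan",
    "resolve_nested",
    "count_matrix",
    "reverse_complement",
]

_RC = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}

DEFAULT_LENGTH_BOUNDS = (50, 20000)


def reverse_complement(seq: str) -> str:
    """Reverse-complement a concrete DNA string (A/C/G/T/N)."""
    return "".join(_RC[b] for b in reversed(seq.upper()))


@dataclass(frozen=True)
class PromoterSequence:
    """A promoter allele anchored at the translation start codon.

    ``residues[-1]`` is the base at ATG-relative position −1.  Residues
    are stored uppercase and restricted to A/C/G/T/N.
    """

    seq_id: str
    residues: str
    gene: str = ""
    atg_anchor: bool = True

    def __post_init__(self) -> None:
        object.__setattr__(self, "residues", self.residues.upper())
        bad = set(self.residues) - set("ACGTN")
        if bad:
            raise ValueError(
                f"promoter {self.seq_id!r} contains non-DNA characters: {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.residues)

    def check_length(self, bounds: tuple[int, int] = DEFAULT_LENGTH_BOUNDS) -> None:
        lo, hi = bounds
        if not lo <= len(self) <= hi:
            raise ValueError(
                f"promoter {self.seq_id!r} length {len(self)} outside bounds [{lo}, {hi}]"
            )

    def coordinate_of_index(self, index: int) -> int:
        """ATG-relative coordinate of 0-based string index."""
        return index - len(self.residues)

    def index_of_coordinate(self, coord: int) -> int:
        """0-based string index of ATG-relative coordinate (−L..−1)."""
        if not -len(self.residues) <= coord <= -1:
            raise ValueError(f"coordinate {coord} outside −{len(self.residues)}..−1")
        return coord + len(self.residues)

    def window_at(self, start: int, length: int) -> str:
        """Plus-strand window of *length* starting at ATG-relative *start*."""
        i = self.index_of_coordinate(start)
        return self.residues[i : i + length]


@dataclass(frozen=True, order=True)
class MotifHit:
    """One motif occurrence.

    ``start``/``end`` are ATG-relative coordinates of the 5′-most and
    3′-most plus-strand bases; ``matched_seq`` is the plus-strand
    substring (reverse-complement it for the minus-strand word).
    """

    start: int
    motif_id: str
    strand: Literal["+", "-"]
    end: int
    matched_seq: str

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if not self.start <= self.end <= -1:
            raise ValueError(
                f"invalid hit interval [{self.start}, {self.end}] (must end <= -1)"
            )
        if self.end - self.start + 1 != len(self.matched_seq):
            raise ValueError("hit interval length disagrees with matched_seq")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def contains(self, other: "MotifHit") -> bool:
        """Strict same-strand interval containment (this is the longer hit)."""
        return (
            self.strand == other.strand
            and self.start <= other.start
            and other.end <= self.end
            and self.length > other.length
        )


@dataclass
class AnnotatedPromoter:
    """A promoter with its motif hit list."""

    promoter: PromoterSequence
    hits: tuple[MotifHit, ...] = field(default_factory=tuple)
    nested_resolved: bool = False

    def __post_init__(self) -> None:
        self.hits = tuple(self.hits)

    def __len__(self) -> int:
        return len(self.hits)

    def hits_for(self, motif_id: str, strand: str | None = None) -> list[MotifHit]:
        return [
            h
            for h in self.hits
            if h.motif_id == motif_id and (strand is None or h.strand == strand)
        ]


def _sorted_hits(hits: Iterable[MotifHit]) -> tuple[MotifHit, ...]:
    return tuple(sorted(hits, key=lambda h: (h.start, h.motif_id, h.strand)))


def scan(
    promoter: PromoterSequence,
    catalog: MotifCatalog,
    strands: Literal["plus", "minus", "both"] = "both",
) -> AnnotatedPromoter:
    """Scan a promoter for every catalog motif.

    Every window matching a pattern yields one hit; overlapping
    self-matches are all reported.  A sequence shorter than the shortest
    pattern (or empty) yields an empty annotation.  Subject ``N`` bases
    never match.
    """
    if strands not in ("plus", "minus", "both"):
        raise ValueError(f"strands must be plus/minus/both, got {strands!r}")
    seq = promoter.residues
    L = len(seq)
    hits: list[MotifHit] = []
    for motif in catalog:
        w = len(motif)
        if L < w:
            continue
        if strands in ("plus", "both"):
            for i in iupac_matcher(motif.pattern).find_starts(seq):
                hits.append(
                    MotifHit(
                        motif_id=motif.motif_id,
                        start=i - L,
                        end=i + w - 1 - L,
                        strand="+",
                        matched_seq=seq[i : i + w],
                    )
                )
        if strands in ("minus", "both"):
            # A minus-strand occurrence is a plus-strand match of the
            # reverse-complemented pattern; coordinates stay plus-strand.
            rc = reverse_complement_pattern(motif.pattern)
            for i in iupac_matcher(rc).find_starts(seq):
                hits.append(
                    MotifHit(
                        motif_id=motif.motif_id,
                        start=i - L,
                        end=i + w - 1 - L,
                        strand="-",
                        matched_seq=seq[i : i + w],
                    )
                )
    return AnnotatedPromoter(promoter=promoter, hits=_sorted_hits(hits))


def resolve_nested(annotated: AnnotatedPromoter) -> AnnotatedPromoter:
    """Drop hits strictly contained within a longer same-strand hit.

    Containment is applied transitively: in a chain of nested hits only
    the longest survives.  Co-extensive equal-length hits of different
    motifs are all kept.  Idempotent.  TF family is ignored: interval
    containment alone triggers removal.
    """
    hits = annotated.hits
    kept: list[MotifHit] = []
    # Sort by start then decreasing length: a container always precedes
    # (or ties the start of) anything it contains.
    by_span = sorted(hits, key=lambda h: (h.start, -h.length))
    for h in by_span:
        if any(other.contains(h) for other in by_span if other is not h):
            continue
        kept.append(h)
    return AnnotatedPromoter(
        promoter=annotated.promoter,
        hits=_sorted_hits(kept),
        nested_resolved=True,
    )


def count_matrix(
    annotated_set: Sequence[AnnotatedPromoter],
    strand_filter: Literal["plus", "both"] = "plus",
    catalog: MotifCatalog | None = None,
) -> pd.DataFrame:
    """Motif × promoter count table with a ``Total`` row.

    Counts surviving (nested-resolved) hits per motif on the requested
    strand(s); unresolved annotations are rejected so nested motifs are
    never double-counted.  Row order follows the catalog when given,
    else the motifs observed (sorted).
    """
    if strand_filter not in ("plus", "both"):
        raise ValueError(f"strand_filter must be plus/both, got {strand_filter!r}")
    for ann in annotated_set:
        if not ann.nested_resolved:
            raise ValueError(
                f"annotation for {ann.promoter.seq_id!r} is not nested-resolved; "
                "run resolve_nested first"
            )
    columns = [ann.promoter.seq_id for ann in annotated_set]
    if catalog is not None:
        rows = catalog.motif_ids
    else:
        rows = sorted({h.motif_id for ann in annotated_set for h in ann.hits})
    table = pd.DataFrame(0, index=rows, columns=columns, dtype=int)
    for ann in annotated_set:
        for h in ann.hits:
            if strand_filter == "plus" and h.strand != "+":
                continue
            if h.motif_id in table.index:
                table.loc[h.motif_id, ann.promoter.seq_id] += 1
    total = table.sum(axis=0)
    total.name = "Total"
    table = pd.concat([table, total.to_frame().T]).astype(int)
    table.index.name = "motif_id"
    return table
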