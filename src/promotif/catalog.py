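"""Degenerate cis-motif catalogs and IUPAC matching.

A motif is a short (>= 3 nt) IUPAC consensus such as ``TGHAAARK`` or
``CANNTG``.  Catalogs bundle the motifs used for one annotation run; two
built-in presets cover the cis-elements classically implicated in seed
storage protein (SSP) gene regulation in cereals:

``table2``
    The full working catalog: 22 PLACE-derived motifs plus the two
    custom additions ``AACNNA`` (GAMYB-binding) and ``TATAWA`` (the
    TATA-box variant of SSP promoters) — 24 entries.
``table6``
    The 19-pattern counting catalog used for per-gene tallies; it drops
    the patterns that are wholly redundant for counting (``GATA``,
    ``TGTAAAG``, ``RTGASTCAT``, ``AACAAAC``, ``ACATGTCATCATGT``) and
    uses the shorter RY core ``CATGCA``.

The two presets deliberately disagree on the RY-repeat pattern
(``CATGCAY`` vs ``CATGCA``); the discrepancy is surfaced through the
separate presets rather than silently merged.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

__all__ = [
    "IUPAC_CODES",
    "MotifDefinition",
    "MotifCatalog",
    "load_catalog",
    "iupac_matcher",
    "reverse_complement_pattern",
]

#: IUPAC nucleotide codes mapped to the set of concrete bases they admit.
#: ``N`` in a *pattern* matches any base; an ``N`` in the *subject* is
#: handled conservatively by the matcher (it matches nothing).
IUPAC_CODES: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "W": frozenset("AT"),
    "S": frozenset("CG"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

_COMPLEMENT = {
    "A": "T", "C": "G", "G": "C", "T": "A",
    "R": "Y", "Y": "R", "W": "W", "S": "S",
    "K": "M", "M": "K", "B": "V", "V": "B",
    "D": "H", "H": "D", "N": "N",
}

TF_FAMILIES = ("DOF", "bZIP", "RY", "AACA-MYB", "GATA-MYB", "OTHER")


def _validate_pattern(pattern: str, *, context: str = "") -> None:
    if not pattern or len(pattern) < 3:
        raise ValueError(
            f"motif pattern must be at least 3 nt long, got {pattern!r}{context}"
        )
    for ch in pattern:
        if ch not in IUPAC_CODES:
            raise ValueError(
                f"invalid IUPAC code {ch!r} in pattern {pattern!r}{context}"
            )


def reverse_complement_pattern(pattern: str) -> str:
    """Reverse-complement an IUPAC pattern (``RTGAGTCAT`` -> ``ATGACTCAY``)."""
    _validate_pattern(pattern)
    return "".join(_COMPLEMENT[ch] for ch in reversed(pattern))


class Matcher:
    """Window matcher for one IUPAC pattern.

    Matching is against concrete subject windows of exactly the pattern
    length.  Subject characters outside A/C/G/T (including ``N``) match
    nothing, so ambiguous stretches in the input never inflate counts.
    """

    def __init__(self, pattern: str):
        _validate_pattern(pattern)
        self.pattern = pattern
        # Character classes contain concrete bases only, so a subject 'N'
        # can never satisfy any position.
        body = "".join(
            "[" + "".join(sorted(IUPAC_CODES[ch])) + "]" for ch in pattern
        )
        # Lookahead so that overlapping self-matches are all reported.
        self._finder = re.compile(r"(?=(" + body + r"))")
        self._exact = re.compile(body + r"\Z")

    def __len__(self) -> int:
        return len(self.pattern)

    def matches(self, window: str) -> bool:
        """Does this equal-length window match the pattern?"""
        if len(window) != len(self.pattern):
            raise ValueError(
                f"window length {len(window)} != pattern length {len(self.pattern)}"
            )
        return self._exact.match(window.upper()) is not None

    def find_starts(self, subject: str) -> list[int]:
        """All (overlapping) 0-based match start positions in *subject*."""
        return [m.start() for m in self._finder.finditer(subject.upper())]


def iupac_matcher(pattern: str) -> Matcher:
    """Build a :class:`Matcher` for an IUPAC consensus string."""
    return Matcher(pattern)


@dataclass(frozen=True)
class MotifDefinition:
    """One degenerate cis-motif.

    Parameters
    ----------
    motif_id : str
        Short unique label, e.g. ``"Pbox2"``.
    place_name : str
        The originating catalog entry name (e.g. ``"300CORE"``) or
        ``"custom"`` for motifs outside that catalog.
    pattern : str
        IUPAC consensus, length >= 3.
    tf_family : str
        One of ``DOF, bZIP, RY, AACA-MYB, GATA-MYB, OTHER``.
    source_note : str
        Free-text citation / provenance.
    """

    motif_id: str
    place_name: str
    pattern: str
    tf_family: str = "OTHER"
    source_note: str = ""

    def __post_init__(self) -> None:
        if not self.motif_id:
            raise ValueError("motif_id must be non-empty")
        _validate_pattern(self.pattern, context=f" (motif {self.motif_id!r})")
        if self.tf_family not in TF_FAMILIES:
            raise ValueError(
                f"unknown tf_family {self.tf_family!r} for motif {self.motif_id!r}; "
                f"expected one of {TF_FAMILIES}"
            )

    def __len__(self) -> int:
        return len(self.pattern)

    def matcher(self) -> Matcher:
        return iupac_matcher(self.pattern)


@dataclass
class MotifCatalog:
    """An ordered, uniquely-labelled collection of motif definitions."""

    name: str
    entries: tuple[MotifDefinition, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        self.entries = tuple(self.entries)
        seen: set[str] = set()
        for entry in self.entries:
            if entry.motif_id in seen:
                raise ValueError(f"duplicate motif_id {entry.motif_id!r} in catalog")
            seen.add(entry.motif_id)

    def __iter__(self) -> Iterator[MotifDefinition]:
        return iter(self.entries)

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, motif_id: str) -> bool:
        return any(e.motif_id == motif_id for e in self.entries)

    def get(self, motif_id: str) -> MotifDefinition:
        for entry in self.entries:
            if entry.motif_id == motif_id:
                return entry
        raise KeyError(motif_id)

    @property
    def motif_ids(self) -> list[str]:
        return [e.motif_id for e in self.entries]

    @property
    def patterns(self) -> list[str]:
        return [e.pattern for e in self.entries]

    def subset(self, motif_ids: Iterable[str], name: str | None = None) -> "MotifCatalog":
        wanted = list(motif_ids)
        return MotifCatalog(
            name=name or f"{self.name}-subset",
            entries=tuple(self.get(m) for m in wanted),
        )


def _d(motif_id, place_name, pattern, tf_family, note=""):
    return MotifDefinition(motif_id, place_name, pattern, tf_family, note)


def _table2_entries() -> tuple[MotifDefinition, ...]:
    return (
        # DOF-binding prolamin-box family
        _d("DofCore", "DOFCOREZM", "AAAG", "DOF", "DOF core"),
        _d("Pbox1", "PROLAMINBOXOSGLUB1", "TGCAAAG", "DOF", "prolamin box"),
        _d("Pbox2", "300CORE", "TGTAAAG", "DOF", "-300 core prolamin box"),
        _d("Pbox3", "-300ELEMENT", "TGHAAARK", "DOF", "-300 element"),
        # bZIP-binding GCN4-like / G-box family
        _d("GLM1", "GCN4OSGLUB1", "TGAGTCA", "bZIP", "GCN4-like motif core"),
        _d("GLM2", "-300MOTIFZMZEIN", "RTGAGTCAT", "bZIP", "GCN4-like motif"),
        _d("GLM3", "GLMHVCHORD", "RTGASTCAT", "bZIP", "GCN4-like motif"),
        _d("ACGTcore", "ACGTATERD1", "ACGT", "bZIP", "ACGT core"),
        _d("Gbox1", "ABREATCONSENSUS", "YACGTGGC", "bZIP", "G-box / ABRE"),
        _d("Gbox2", "ABRELATERD1", "ACGTG", "bZIP", "G-box core"),
        _d("CAAT", "CAATBOX1", "CAAT", "bZIP", "CAAT box"),
        # RY repeat (B3/FUSCA3)
        _d("RY", "RYREPEATLEGUMINBOX", "CATGCAY", "RY", "RY repeat legumin box"),
        # R2R3-MYB-binding AACA family
        _d("AACA1", "AACACOREOSGLUB1", "AACAAAC", "AACA-MYB", "AACA core"),
        _d("AACA2", "ANAERO1CONSENSUS", "AAACAAA", "AACA-MYB", "AACA motif"),
        _d("MYB1AT", "MYB1AT", "WAACCA", "AACA-MYB", "MYB1AT"),
        _d("AACA3", "custom", "AACNNA", "AACA-MYB", "GAMYB-binding, non-PLACE"),
        # R1MYB-binding GATA family
        _d("GATA1", "GATABOX", "GATA", "GATA-MYB", "GATA box"),
        _d("GATA2", "MYBST1", "GGATA", "GATA-MYB", "MYBST1 GGATA"),
        # Other
        _d("Ebox", "EBOXBNNAPA", "CANNTG", "OTHER", "E-box (bHLH)"),
        _d("CCAAT", "CCAATBOX1", "CCAAT", "OTHER", "CCAAT box (HAP/CBF)"),
        _d("ESP", "ESPASGL01", "ACATGTCATCATGT", "OTHER", "endosperm-specific palindrome"),
        _d("TATA", "custom", "TATAWA", "OTHER", "TATA-box variant, non-PLACE"),
        _d("Circadian", "CIACADIANLELHC", "CAANNNNATC", "OTHER", "circadian-responsive"),
        _d("Abox", "PALBOXAPC", "CCGTCC", "OTHER", "A-box, light responsive"),
    )


def _table6_entries() -> tuple[MotifDefinition, ...]:
    keep = [
        "DofCore", "Pbox1", "Pbox3",
        "ACGTcore", "Gbox2", "GLM2", "GLM1", "Gbox1", "CAAT",
        "AACA2", "MYB1AT", "AACA3",
        "GATA2",
        "Ebox", "CCAAT", "TATA", "Circadian", "Abox",
    ]
    table2 = {e.motif_id: e for e in _table2_entries()}
    entries = [table2[m] for m in keep]
    # The counting catalog uses the short RY core, not the CATGCAY form.
    entries.insert(
        keep.index("GATA2") + 1,
        _d("RY", "RYREPEATLEGUMINBOX", "CATGCA", "RY", "RY repeat core"),
    )
    return tuple(entries)


_PRESETS = {
    "table2": _table2_entries,
    "table6": _table6_entries,
}


def load_catalog(source: str | Path) -> MotifCatalog:
    """Load a motif catalog from a preset name or a JSON/TSV config file.

    JSON files hold a list of objects with keys ``motif_id, place_name,
    pattern, tf_family`` (``source_note`` optional).  TSV files have the
    same four columns, no header, ``#`` comments allowed.
    """
    key = str(source)
    if key in _PRESETS:
        return MotifCatalog(name=key, entries=_PRESETS[key]())
    path = Path(source)
    if not path.exists():
        raise ValueError(
            f"unknown catalog preset or missing file {source!r}; "
            f"presets: {sorted(_PRESETS)}"
        )
    if path.suffix.lower() == ".json":
        records = json.loads(path.read_text())
        entries = [
            MotifDefinition(
                motif_id=r["motif_id"],
                place_name=r.get("place_name", "custom"),
                pattern=r["pattern"],
                tf_family=r.get("tf_family", "OTHER"),
                source_note=r.get("source_note", ""),
            )
            for r in records
        ]
    else:
        entries = []
        for line in path.read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ValueError(f"malformed catalog line (need 4 columns): {line!r}")
            entries.append(MotifDefinition(parts[0], parts[1], parts[2], parts[3]))
    return MotifCatalog(name=path.stem, entries=tuple(entries))
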