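"""Synthetic promoter families with planted motif modules and truth records.

The generator emulates the structure of a resequenced promoter-allele
panel: families of a few to a few dozen alleles, roughly one
polymorphism per 100 bp, a singleton-rich haplotype structure (two
major haplotypes plus single-line variants), occasional 1-bp indels
and an optional large (e.g. 54-bp) deletion, and cis-motif modules
planted at fixed ATG-relative positions.

Every family comes with a machine-readable :class:`SyntheticTruth`
holding the ancestor, every applied mutation and the per-allele motif
placements after indel shifts, so scanning, consensus building, module
detection and diversity statistics can all be verified against ground
truth.  Replaying the truth on the ancestor reproduces each allele
byte-identically.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from typing import Literal, Sequence

import numpy as np

from .catalog import MotifCatalog, iupac_matcher, load_catalog
from .consensus import GAP, AlignmentMatrix
from .scan import PromoterSequence, resolve_nested, reverse_complement, scan

__all__ = [
    "Placement",
    "PlantedModule",
    "IndelSpec",
    "GeneratorConfig",
    "SyntheticTruth",
    "generate_family",
    "plant_renan_like",
    "replay",
]

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class Placement:
    """One planted concrete motif instance (ancestor frame)."""

    motif_id: str
    sequence: str  # concrete instance drawn from the motif's pattern
    start: int  # ATG-relative start, negative
    strand: Literal["+", "-"] = "+"
    nested_ok: bool = False

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def end(self) -> int:
        return self.start + self.length - 1


@dataclass(frozen=True)
class PlantedModule:
    module_id: str
    placements: tuple[Placement, ...]


@dataclass(frozen=True)
class IndelSpec:
    """A deletion of ``length`` bases carried by a subset of alleles.

    ``position`` is the ATG-relative start of the deleted span in the
    ancestor frame; ``None`` lets the generator draw it.
    """

    length: int
    carriers: tuple[int, ...]
    position: int | None = None


@dataclass
class GeneratorConfig:
    """Study conditions for one synthetic promoter family.

    Defaults mirror the kind of panel the generator emulates: 1-kb
    promoters, ~1 polymorphism per 100 bp (``snp_rate`` 0.01 per site),
    half of the polymorphic sites private to single lines, and a
    two-major-haplotypes-plus-singletons structure.
    """

    seed: int
    length: int = 1000
    n_alleles: int = 8
    planted_modules: tuple[PlantedModule, ...] = ()
    snp_rate: float = 0.01
    singleton_fraction: float = 0.5
    n_singleton_alleles: int | None = None
    indel_spec: tuple[IndelSpec, ...] = ()
    haplotype_structure: Literal[
        "two_major_plus_singletons", "star", "uniform"
    ] = "two_major_plus_singletons"
    protect_planted: bool = True
    background: Literal["random", "motif_free"] = "random"
    gc: float = 0.5
    gene: str = "synth"

    def __post_init__(self) -> None:
        self.planted_modules = tuple(self.planted_modules)
        self.indel_spec = tuple(self.indel_spec)
        if self.length < 1 or self.n_alleles < 1:
            raise ValueError("length and n_alleles must be positive")
        if not 0 <= self.snp_rate < 1:
            raise ValueError("snp_rate must be in [0, 1)")
        if not 0 <= self.singleton_fraction <= 1:
            raise ValueError("singleton_fraction must be in [0, 1]")
        if not 0 < self.gc < 1:
            raise ValueError("gc must be in (0, 1)")
        spans: list[tuple[int, int, bool]] = []
        for module in self.planted_modules:
            for p in module.placements:
                if p.start < -self.length or p.end > -1:
                    raise ValueError(
                        f"placement {p.motif_id} at {p.start} exceeds "
                        f"[-{self.length}, -1]"
                    )
                spans.append((p.start, p.end, p.nested_ok))
        spans.sort()
        for (s1, e1, n1), (s2, e2, n2) in zip(spans, spans[1:]):
            if s2 <= e1 and not (n1 or n2):
                raise ValueError(
                    f"overlapping placements at {s1} and {s2}; "
                    "set nested_ok to allow"
                )
        for spec in self.indel_spec:
            if spec.length < 1:
                raise ValueError("indel length must be >= 1")
            if any(not 0 <= c < self.n_alleles for c in spec.carriers):
                raise ValueError("indel carrier index out of range")

    @property
    def placements(self) -> tuple[Placement, ...]:
        return tuple(p for m in self.planted_modules for p in m.placements)

    def planted_catalog(self, base: MotifCatalog | None = None) -> MotifCatalog:
        """Catalog restricted to the planted motif definitions."""
        base = base or load_catalog("table2")
        ids = []
        for p in self.placements:
            if p.motif_id not in ids and p.motif_id in base:
                ids.append(p.motif_id)
        return base.subset(ids, name="planted")


@dataclass
class AlleleTruth:
    """Mutations applied to one allele, in ancestor coordinates."""

    member_id: str
    snps: tuple[tuple[int, str, str], ...]  # (0-based position, from, to)
    deletions: tuple[tuple[int, int], ...]  # (0-based start, length)
    placements: tuple[Placement, ...]  # allele-frame coordinates


@dataclass
class SyntheticTruth:
    """Ground truth for a generated family."""

    seed: int
    ancestor: str
    member_ids: tuple[str, ...]
    alleles: tuple[AlleleTruth, ...]
    modules: tuple[PlantedModule, ...]  # ancestor-frame placements
    expected_haplotype_counts: dict[str, int]
    expected_segregating_sites: int
    gene: str = "synth"

    @property
    def planted(self) -> tuple[Placement, ...]:
        return tuple(p for m in self.modules for p in m.placements)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, default=list)

    @classmethod
    def from_json(cls, text: str) -> "SyntheticTruth":
        raw = json.loads(text)
        return cls(
            seed=raw["seed"],
            ancestor=raw["ancestor"],
            member_ids=tuple(raw["member_ids"]),
            alleles=tuple(
                AlleleTruth(
                    member_id=a["member_id"],
                    snps=tuple((p, f, t) for p, f, t in a["snps"]),
                    deletions=tuple((s, l) for s, l in a["deletions"]),
                    placements=tuple(Placement(**p) for p in a["placements"]),
                )
                for a in raw["alleles"]
            ),
            modules=tuple(
                PlantedModule(
                    module_id=m["module_id"],
                    placements=tuple(Placement(**p) for p in m["placements"]),
                )
                for m in raw["modules"]
            ),
            expected_haplotype_counts=dict(raw["expected_haplotype_counts"]),
            expected_segregating_sites=raw["expected_segregating_sites"],
            gene=raw.get("gene", "synth"),
        )


def _planted_spans(config: GeneratorConfig) -> list[tuple[int, int]]:
    """0-based [start, end] index spans of planted placements."""
    L = config.length
    return [(p.start + L, p.end + L) for p in config.placements]


def _in_spans(pos: int, spans: Sequence[tuple[int, int]]) -> bool:
    return any(s <= pos <= e for s, e in spans)


def _build_ancestor(config: GeneratorConfig, rng: np.random.Generator) -> str:
    L = config.length
    p = np.array(
        [(1 - config.gc) / 2, config.gc / 2, config.gc / 2, (1 - config.gc) / 2]
    )
    chars = rng.choice(_BASES, size=L, p=p)
    for placement in config.placements:
        word = placement.sequence.upper()
        if placement.strand == "-":
            word = reverse_complement(word)
        i = placement.start + L
        chars[i : i + len(word)] = list(word)
    return _cleanup_background(config, chars, rng)


def _planted_key_set(config: GeneratorConfig) -> set[tuple[str, str, int]]:
    # Cleanup scans the plus strand, so only plus-strand placements can
    # be guaranteed recoverable.
    return {
        (p.motif_id, p.strand, p.start)
        for p in config.placements
        if p.strand == "+"
    }


def _cleanup_background(
    config: GeneratorConfig, chars: np.ndarray, rng: np.random.Generator
) -> str:
    """Redraw background bases until the planted annotation is clean.

    Always guarantees (against the planted-motif catalog) that no
    accidental longer hit strictly contains a planted one, so planted
    placements survive nested resolution.  In ``motif_free`` mode the
    stronger condition is enforced: the resolved plus-strand hit set
    equals the planted set exactly.
    """
    if not config.placements:
        return "".join(chars)
    catalog = config.planted_catalog()
    if len(catalog) == 0:
        return "".join(chars)
    L = config.length
    spans = _planted_spans(config)
    planted_keys = _planted_key_set(config)
    p = np.array(
        [(1 - config.gc) / 2, config.gc / 2, config.gc / 2, (1 - config.gc) / 2]
    )
    for _ in range(2000):
        seq = "".join(chars)
        promoter = PromoterSequence(seq_id="ancestor", residues=seq)
        resolved = resolve_nested(scan(promoter, catalog, strands="plus"))
        keys = {(h.motif_id, h.strand, h.start) for h in resolved.hits}
        missing = planted_keys - keys
        extra = keys - planted_keys
        if not missing and (config.background != "motif_free" or not extra):
            return seq
        offenders = []
        if missing:
            # A planted hit can only go missing when an accidental longer
            # hit strictly contains it; redraw those containers.
            offenders.extend(h for h in resolved.hits if (h.motif_id, h.strand, h.start) in extra)
        if config.background == "motif_free":
            offenders.extend(h for h in resolved.hits if (h.motif_id, h.strand, h.start) in extra)
        redrawn = False
        for h in offenders:
            for pos in range(h.start + L, h.end + 1 + L):
                if not _in_spans(pos, spans):
                    chars[pos] = rng.choice(_BASES, p=p)
                    redrawn = True
        if not redrawn:
            raise RuntimeError(
                "cannot clean background: an accidental hit lies entirely "
                "within planted spans"
            )
    raise RuntimeError("background cleanup did not converge")


def _singleton_pool(config: GeneratorConfig) -> list[int]:
    n = config.n_alleles
    if config.haplotype_structure != "two_major_plus_singletons":
        return []
    k = config.n_singleton_alleles
    if k is None:
        k = max(1, round(0.1 * n)) if n >= 3 else 0
    k = min(k, max(n - 2, 0))
    return list(range(n - k, n))


def _major_groups(config: GeneratorConfig) -> tuple[list[int], list[int]]:
    n = config.n_alleles
    singles = set(_singleton_pool(config))
    majors = [i for i in range(n) if i not in singles]
    n_b = max(1, round(0.4 * len(majors))) if len(majors) >= 2 else 0
    group_b = majors[len(majors) - n_b :]
    group_a = majors[: len(majors) - n_b]
    return group_a, group_b


def _site_carriers(
    config: GeneratorConfig, pos: int, ancestor_base: str
) -> tuple[str, tuple[int, ...]]:
    """Derived base and carrier alleles for one polymorphic site.

    Drawn from a site-indexed stream so that the set of selected sites
    (which depends on ``snp_rate``) never perturbs the outcome at other
    sites — raising the rate only adds sites.
    """
    n = config.n_alleles
    rng = np.random.default_rng([config.seed % (2**31), 202, pos])
    alternatives = [b for b in "ACGT" if b != ancestor_base]
    derived = alternatives[rng.integers(3)]
    structure = config.haplotype_structure
    if structure == "star":
        return derived, (int(rng.integers(n)),)
    if structure == "uniform":
        # Unstructured neutral infinite-sites sampling: derived-allele
        # count c drawn with P(c) ∝ 1/c, carriers uniform given c.
        weights = np.array([1.0 / c for c in range(1, n)])
        c = int(rng.choice(np.arange(1, n), p=weights / weights.sum()))
        carriers = rng.choice(n, size=c, replace=False)
        return derived, tuple(int(i) for i in sorted(carriers))
    # two_major_plus_singletons
    pool = _singleton_pool(config)
    group_a, group_b = _major_groups(config)
    singleton = bool(pool) and rng.random() < config.singleton_fraction
    if singleton or not group_b:
        pool = pool or list(range(n))
        carrier = pool[int(rng.integers(len(pool)))]
        return derived, (carrier,)
    # Haplotype-distinguishing site: the second major group (plus the
    # singleton alleles riding on its background) carries the derived base.
    half = [i for i in pool if i % 2 == 1]
    return derived, tuple(sorted(group_b + half))


def _resolve_indels(
    config: GeneratorConfig, spans: Sequence[tuple[int, int]]
) -> list[tuple[int, int, tuple[int, ...]]]:
    """(start index, length, carriers) for each deletion, non-overlapping."""
    L = config.length
    out: list[tuple[int, int, tuple[int, ...]]] = []
    taken: list[tuple[int, int]] = list(spans) if config.protect_planted else []
    for k, spec in enumerate(config.indel_spec):
        if spec.position is not None:
            start = spec.position + L
            if not 0 <= start <= L - spec.length:
                raise ValueError(f"indel at {spec.position} out of bounds")
            if config.protect_planted and any(
                s <= start + spec.length - 1 and start <= e for s, e in spans
            ):
                raise ValueError(
                    f"indel at {spec.position} overlaps a planted placement "
                    "while protect_planted is set"
                )
        else:
            rng = np.random.default_rng([config.seed % (2**31), 303, k])
            for _ in range(1000):
                start = int(rng.integers(0, L - spec.length + 1))
                cand = (start, start + spec.length - 1)
                if not any(s <= cand[1] and cand[0] <= e for s, e in taken):
                    break
            else:
                raise RuntimeError("could not place indel outside reserved spans")
        out.append((start, spec.length, tuple(sorted(set(spec.carriers)))))
        taken.append((start, start + spec.length - 1))
    out.sort()
    for (s1, l1, _), (s2, _, _) in zip(out, out[1:]):
        if s2 < s1 + l1:
            raise ValueError("overlapping indel specifications")
    return out


def _shift_placements(
    placements: Sequence[Placement],
    deletions: Sequence[tuple[int, int]],
    L: int,
) -> tuple[Placement, ...]:
    """Project ancestor-frame placements into one allele's frame."""
    removed = sum(l for _, l in deletions)
    allele_len = L - removed
    out = []
    for p in placements:
        i0 = p.start + L
        if any(s <= i0 + p.length - 1 and i0 <= s + l - 1 for s, l in deletions):
            continue  # placement destroyed by the deletion in this allele
        deleted_before = sum(l for s, l in deletions if s < i0)
        out.append(
            Placement(
                motif_id=p.motif_id,
                sequence=p.sequence,
                start=(i0 - deleted_before) - allele_len,
                strand=p.strand,
                nested_ok=p.nested_ok,
            )
        )
    return tuple(out)


def generate_family(
    config: GeneratorConfig,
) -> tuple[list[PromoterSequence], AlignmentMatrix, SyntheticTruth]:
    """Generate a promoter family, its exact alignment and its truth.

    The ancestor is a random background with the planted concrete motif
    instances overwritten at their placements; alleles derive from it
    according to the haplotype structure; the emitted alignment is
    exact by construction (gap columns at deletions).  Deterministic
    given ``config.seed``.
    """
    L, n = config.length, config.n_alleles
    rng = np.random.default_rng([config.seed % (2**31), 1])
    ancestor = _build_ancestor(config, rng)
    spans = _planted_spans(config)

    site_rng = np.random.default_rng([config.seed % (2**31), 101])
    u = site_rng.random(L)
    eligible = np.ones(L, dtype=bool)
    if config.protect_planted:
        for s, e in spans:
            eligible[s : e + 1] = False
    selected = sorted(int(i) for i in np.nonzero(eligible & (u < config.snp_rate))[0])

    snps: dict[int, list[tuple[int, str, str]]] = {i: [] for i in range(n)}
    for pos in selected:
        derived, carriers = _site_carriers(config, pos, ancestor[pos])
        for c in carriers:
            snps[c].append((pos, ancestor[pos], derived))

    indels = _resolve_indels(config, spans)
    deletions_of: dict[int, list[tuple[int, int]]] = {i: [] for i in range(n)}
    for start, length, carriers in indels:
        for c in carriers:
            deletions_of[c].append((start, length))

    member_ids = tuple(f"a{i + 1:02d}" for i in range(n))
    rows: list[str] = []
    allele_truths: list[AlleleTruth] = []
    for i in range(n):
        chars = list(ancestor)
        for pos, _, alt in snps[i]:
            chars[pos] = alt
        for start, length in deletions_of[i]:
            chars[start : start + length] = [GAP] * length
        rows.append("".join(chars))
        allele_truths.append(
            AlleleTruth(
                member_id=member_ids[i],
                snps=tuple(sorted(snps[i])),
                deletions=tuple(sorted(deletions_of[i])),
                placements=_shift_placements(
                    config.placements, sorted(deletions_of[i]), L
                ),
            )
        )
    alignment = AlignmentMatrix(member_ids=member_ids, rows=tuple(rows))
    promoters = [
        PromoterSequence(
            seq_id=member_ids[i],
            residues=rows[i].replace(GAP, ""),
            gene=config.gene,
        )
        for i in range(n)
    ]

    deletion_spans = [(s, s + l - 1) for s, l, _ in indels]
    expected_S = sum(1 for pos in selected if not _in_spans(pos, deletion_spans))
    vectors = []
    for i in range(n):
        vec = tuple(sorted(snps[i])) + tuple(("del", s, l) for s, l in sorted(deletions_of[i]))
        vectors.append(vec)
    from collections import Counter

    counts = Counter(vectors)
    first = {}
    for i, v in enumerate(vectors):
        first.setdefault(v, i)
    ordered = sorted(counts, key=lambda v: (-counts[v], first[v]))
    expected_haps = {f"h{i + 1}": counts[v] for i, v in enumerate(ordered)}

    truth = SyntheticTruth(
        seed=config.seed,
        ancestor=ancestor,
        member_ids=member_ids,
        alleles=tuple(allele_truths),
        modules=config.planted_modules,
        expected_haplotype_counts=expected_haps,
        expected_segregating_sites=expected_S,
        gene=config.gene,
    )
    return promoters, alignment, truth


def replay(truth: SyntheticTruth) -> list[PromoterSequence]:
    """Rebuild every allele from the truth record (round-trip exact)."""
    out = []
    for allele in truth.alleles:
        chars = list(truth.ancestor)
        for pos, ref, alt in allele.snps:
            if chars[pos] != ref:
                raise ValueError(
                    f"corrupted truth: position {pos} of ancestor is "
                    f"{chars[pos]!r}, expected {ref!r}"
                )
            chars[pos] = alt
        for start, length in sorted(allele.deletions, reverse=True):
            del chars[start : start + length]
        out.append(
            PromoterSequence(
                seq_id=allele.member_id, residues="".join(chars), gene=truth.gene
            )
        )
    return out


_CCRM5_MODULES: tuple[PlantedModule, ...] = (
    PlantedModule(
        "M1",
        (
            Placement("TATA", "TATATA", -90),
            Placement("CAAT", "CAAT", -70),
        ),
    ),
    PlantedModule(
        "M2",
        (
            Placement("Gbox1", "TACGTGGC", -277),
            Placement("Ebox", "CAGCTG", -259),
            Placement("CAAT", "CAAT", -240),
        ),
    ),
    PlantedModule(
        "M3",
        (
            Placement("GATA2", "GGATA", -420),
            Placement("GATA2", "GGATA", -400),
        ),
    ),
    # The composite GLM-GATA box: two GATA+GLM units separated by a
    # third GGATA motif.
    PlantedModule(
        "M4",
        (
            Placement("GATA2", "GGATA", -658),
            Placement("GLM1", "TGAGTCA", -647),
            Placement("GATA2", "GGATA", -638),
            Placement("GATA2", "GGATA", -632),
            Placement("GLM1", "TGAGTCA", -626),
        ),
    ),
    PlantedModule(
        "M5",
        (
            Placement("DofCore", "AAAG", -950),
            Placement("CCAAT", "CCAAT", -920),
        ),
    ),
)


def plant_renan_like(preset: str, seed: int = 0, **overrides) -> GeneratorConfig:
    """Preset generator configs with planted module layouts.

    ``ccrm5`` plants five modules of 2–5 motifs each (a TATA-variant +
    CAAT proximal pair, a G-box module, a GGATA pair, the composite
    GLM-GATA box and a distal DOF + CCAAT pair); ``glm_gata_box``
    plants only the composite box.  Both use a motif-free background
    with respect to the planted motif catalog so planted placements are
    exactly recoverable.
    """
    presets = {
        "ccrm5": _CCRM5_MODULES,
        "glm_gata_box": (_CCRM5_MODULES[3],),
    }
    if preset not in presets:
        raise ValueError(f"unknown preset {preset!r}; choose from {sorted(presets)}")
    defaults = dict(
        seed=seed,
        length=1000,
        n_alleles=6,
        planted_modules=presets[preset],
        snp_rate=0.01,
        background="motif_free",
        protect_planted=True,
    )
    defaults.update(overrides)
    return GeneratorConfig(**defaults)


# Sanity check at import time: every preset placement must match its
# catalog pattern.
def _check_presets() -> None:
    table2 = load_catalog("table2")
    for module in _CCRM5_MODULES:
        for p in module.placements:
            matcher = iupac_matcher(table2.get(p.motif_id).pattern)
            if not matcher.matches(p.sequence):
                raise AssertionError(
                    f"preset placement {p.motif_id} {p.sequence} does not "
                    "match its pattern"
                )


_check_presets()
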