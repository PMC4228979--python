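"""Promoter polymorphism calling, haplotypes and diversity statistics.

Input is an ATG-anchored :class:`~promotif.consensus.AlignmentMatrix`
of promoter alleles treated as haploid sequences.  The statistics
follow the classical population-genetics definitions:

* SNPs are called on gap-free alignment columns with ≥ 2 distinct
  bases; columns containing any gap (or an ambiguous base) are excluded
  from per-site statistics (complete-deletion rule), giving the valid
  length ``L_valid``.
* Indel events are maximal runs of gap-containing columns sharing an
  identical presence/absence pattern across rows; each run is one
  event whose length is recorded.  Indels are excluded from π/θ/S but
  participate in haplotype vectors and are reported separately.
* π is the mean pairwise difference per valid site, θ_W is Watterson's
  ``S/(a1·L)``, Hd is the unbiased haplotype heterozygosity and
  Tajima's D is the normalized difference between the π- and S-based
  estimators, with its significance class taken from the beta
  approximation to the null distribution of D.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy import stats

from .consensus import GAP, AlignmentMatrix

__all__ = [
    "PolymorphicSite",
    "PolymorphismTable",
    "HaplotypeTable",
    "DiversitySummary",
    "call_sites",
    "assign_haplotypes",
    "nucleotide_diversity",
    "watterson_theta",
    "haplotype_diversity",
    "tajimas_d",
    "diversity_report",
]

_BASES = ("A", "C", "G", "T")

TajimaClass = Literal["undefined", "NS", "P<0.05", "P<0.01"]


@dataclass(frozen=True)
class PolymorphicSite:
    """One called site: a SNP column or an indel event."""

    ref_coordinate: int  # alignment-frame ATG-relative start
    kind: Literal["SNP", "indel"]
    alleles: tuple[tuple[str, int], ...]  # (allele, count), counts sum to n
    singleton: bool
    length: int = 1  # indel event length in columns


@dataclass
class PolymorphismTable:
    """All polymorphic sites of an alignment."""

    sites: tuple[PolymorphicSite, ...]
    n: int
    L_valid: int

    @property
    def snps(self) -> tuple[PolymorphicSite, ...]:
        return tuple(s for s in self.sites if s.kind == "SNP")

    @property
    def indels(self) -> tuple[PolymorphicSite, ...]:
        return tuple(s for s in self.sites if s.kind == "indel")

    @property
    def S(self) -> int:
        return len(self.snps)

    @property
    def snp_singletons(self) -> int:
        return sum(1 for s in self.snps if s.singleton)


@dataclass
class HaplotypeTable:
    """Haplotype labels (h1, h2, … by descending frequency)."""

    assignment: dict[str, str]
    counts: dict[str, int]

    @property
    def H(self) -> int:
        return len(self.counts)

    @property
    def n(self) -> int:
        return sum(self.counts.values())

    @property
    def singleton_haplotypes(self) -> int:
        return sum(1 for c in self.counts.values() if c == 1)


@dataclass
class DiversitySummary:
    """One promoter set's diversity record (a table row)."""

    set_id: str
    n: int
    L_valid: int
    S: int
    indel_count: int
    singleton_count: int
    H: int
    Hd: float
    pi: float
    theta_w: float
    tajima_D: float  # NaN when undefined
    tajima_class: TajimaClass

    def __post_init__(self) -> None:
        assert self.pi >= 0 and self.theta_w >= 0
        assert 0 <= self.Hd <= 1 + 1e-12
        assert self.H <= self.n
        assert self.S <= max(self.L_valid, 0)

    def as_row(self) -> dict:
        return {
            "set_id": self.set_id,
            "n": self.n,
            "length_valid": self.L_valid,
            "polymorphic_sites": self.S,
            "singletons": self.singleton_count,
            "indels": self.indel_count,
            "haplotypes": self.H,
            "haplotype_diversity": round(self.Hd, 4),
            "pi": self.pi,
            "theta_w": self.theta_w,
            "tajima_D": self.tajima_D,
            "tajima_class": self.tajima_class,
        }


def _char_matrix(alignment: AlignmentMatrix) -> np.ndarray:
    return np.array([list(r) for r in alignment.rows], dtype="U1")


def _valid_columns(arr: np.ndarray) -> np.ndarray:
    """Columns where every row carries an unambiguous base (A/C/G/T)."""
    return np.all(np.isin(arr, _BASES), axis=0)


def call_sites(alignment: AlignmentMatrix) -> PolymorphismTable:
    """Call SNP columns and indel events from an alignment."""
    if alignment.n < 2:
        raise ValueError("need at least 2 sequences to call polymorphisms")
    arr = _char_matrix(alignment)
    n, W = arr.shape
    valid = _valid_columns(arr)
    sites: list[PolymorphicSite] = []
    for j in np.nonzero(valid)[0]:
        col = arr[:, j]
        counts = Counter(col.tolist())
        if len(counts) < 2:
            continue
        ordered = tuple(sorted(counts.items(), key=lambda kv: (-kv[1], kv[0])))
        minor = min(counts.values())
        sites.append(
            PolymorphicSite(
                ref_coordinate=j - W,
                kind="SNP",
                alleles=ordered,
                singleton=minor == 1,
            )
        )
    # Indel events: maximal runs of gap-containing columns with an
    # identical gap presence/absence pattern.
    gap = arr == GAP
    has_gap = gap.any(axis=0)
    j = 0
    while j < W:
        if not has_gap[j]:
            j += 1
            continue
        pattern = gap[:, j]
        k = j
        while k + 1 < W and has_gap[k + 1] and np.array_equal(gap[:, k + 1], pattern):
            k += 1
        carriers = int(pattern.sum())
        counts = (("-", carriers), ("present", n - carriers))
        sites.append(
            PolymorphicSite(
                ref_coordinate=j - W,
                kind="indel",
                alleles=tuple(sorted(counts, key=lambda kv: (-kv[1], kv[0]))),
                singleton=min(carriers, n - carriers) == 1,
                length=k - j + 1,
            )
        )
        j = k + 1
    sites.sort(key=lambda s: s.ref_coordinate)
    return PolymorphismTable(sites=tuple(sites), n=n, L_valid=int(valid.sum()))


def assign_haplotypes(alignment: AlignmentMatrix) -> HaplotypeTable:
    """Group members by their allele vector over all polymorphic sites.

    The vector covers SNP alleles and indel presence/absence; identical
    vectors share a label, labels are ordered by descending count with
    ties broken by first occurrence in the alignment.
    """
    if alignment.n < 1:
        raise ValueError("empty alignment")
    arr = _char_matrix(alignment)
    n, W = arr.shape
    if n == 1:
        return HaplotypeTable(assignment={alignment.member_ids[0]: "h1"}, counts={"h1": 1})
    table = call_sites(alignment)
    vectors: list[tuple] = []
    for i in range(n):
        vec = []
        for s in table.sites:
            j = s.ref_coordinate + W
            if s.kind == "SNP":
                vec.append(arr[i, j])
            else:
                vec.append(GAP if arr[i, j] == GAP else "present")
        vectors.append(tuple(vec))
    counts = Counter(vectors)
    first_seen = {}
    for i, v in enumerate(vectors):
        first_seen.setdefault(v, i)
    ordered = sorted(counts, key=lambda v: (-counts[v], first_seen[v]))
    label_of = {v: f"h{i + 1}" for i, v in enumerate(ordered)}
    assignment = {
        mid: label_of[v] for mid, v in zip(alignment.member_ids, vectors)
    }
    return HaplotypeTable(
        assignment=assignment,
        counts={label_of[v]: counts[v] for v in ordered},
    )


def _pairwise_difference_total(arr: np.ndarray, valid: np.ndarray) -> float:
    """Mean pairwise differences k̂ over valid columns (total, not per site)."""
    n = arr.shape[0]
    npairs = n * (n - 1) // 2
    total = 0
    for j in np.nonzero(valid)[0]:
        counts = Counter(arr[:, j].tolist())
        same = sum(c * (c - 1) // 2 for c in counts.values())
        total += npairs - same
    return total / npairs


def nucleotide_diversity(alignment: AlignmentMatrix) -> float:
    """π: mean pairwise differences per valid (gap-free) site."""
    if alignment.n < 2:
        raise ValueError("need at least 2 sequences")
    arr = _char_matrix(alignment)
    valid = _valid_columns(arr)
    L = int(valid.sum())
    if L == 0:
        raise ValueError("no gap-free columns (L_valid = 0)")
    return _pairwise_difference_total(arr, valid) / L


def _a1(n: int) -> float:
    return sum(1.0 / i for i in range(1, n))


def watterson_theta(S: int, n: int, L_valid: int) -> float:
    """Watterson's θ per site: ``S / (a1 · L)`` with ``a1 = Σ 1/i``."""
    if n < 2:
        raise ValueError("need n >= 2")
    if L_valid < 1:
        raise ValueError("need L_valid >= 1")
    if S < 0:
        raise ValueError("S must be >= 0")
    return S / (_a1(n) * L_valid)


def haplotype_diversity(counts: Sequence[int], n: int | None = None) -> float:
    """Unbiased haplotype diversity ``(n/(n−1)) (1 − Σ p_i²)``."""
    counts = [int(c) for c in counts]
    total = sum(counts)
    if n is None:
        n = total
    if n != total:
        raise ValueError(f"haplotype counts sum to {total}, expected n={n}")
    if n < 2:
        raise ValueError("need n >= 2")
    return (n / (n - 1)) * (1.0 - sum((c / n) ** 2 for c in counts))


def _tajima_constants(n: int) -> tuple[float, float]:
    """(e1, e2) from Tajima's (1989) variance formulas."""
    a1 = _a1(n)
    a2 = sum(1.0 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n**2 + n + 3) / (9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return e1, e2


def _tajima_class(D: float, n: int) -> TajimaClass:
    """Two-tailed significance class from the beta approximation.

    D is treated as a rescaled beta variate on [D_min, D_max] with mean
    0 and variance 1, where D_min and D_max are the extreme values
    attainable for a sample of size n.
    """
    a1 = _a1(n)
    e2 = _tajima_constants(n)[1]
    dmin = (2 / n - 1 / a1) / math.sqrt(e2)
    dmax = ((n + 1) / (2 * n) - 1 / a1) / math.sqrt(e2)
    span = dmax - dmin
    m = -dmin / span
    v = 1 / span**2
    shape = m * (1 - m) / v - 1
    alpha = m * shape
    beta = (1 - m) * shape
    x = (D - dmin) / span
    x = min(max(x, 0.0), 1.0)
    cdf = stats.beta.cdf(x, alpha, beta)
    p = 2 * min(cdf, 1 - cdf)
    if p < 0.01:
        return "P<0.01"
    if p < 0.05:
        return "P<0.05"
    return "NS"


def tajimas_d(alignment: AlignmentMatrix) -> tuple[float, TajimaClass]:
    """Tajima's D and its significance class.

    ``D = (k̂ − S/a1) / sqrt(e1·S + e2·S·(S−1))`` with k̂ the mean
    pairwise difference (total over valid columns).  With S = 0 the
    statistic is undefined: returns ``(nan, "undefined")``.
    """
    if alignment.n < 2:
        raise ValueError("need at least 2 sequences")
    arr = _char_matrix(alignment)
    n = arr.shape[0]
    valid = _valid_columns(arr)
    S = 0
    for j in np.nonzero(valid)[0]:
        if len(set(arr[:, j].tolist())) >= 2:
            S += 1
    if S == 0:
        return float("nan"), "undefined"
    khat = _pairwise_difference_total(arr, valid)
    e1, e2 = _tajima_constants(n)
    var = e1 * S + e2 * S * (S - 1)
    D = (khat - S / _a1(n)) / math.sqrt(var)
    return D, _tajima_class(D, n)


def diversity_report(alignment: AlignmentMatrix, set_id: str = "set") -> DiversitySummary:
    """Compose all per-set statistics into one summary record."""
    table = call_sites(alignment)
    haplotypes = assign_haplotypes(alignment)
    n, L = table.n, table.L_valid
    pi = nucleotide_diversity(alignment) if L > 0 else 0.0
    theta = watterson_theta(table.S, n, L) if L > 0 else 0.0
    D, klass = tajimas_d(alignment)
    return DiversitySummary(
        set_id=set_id,
        n=n,
        L_valid=L,
        S=table.S,
        indel_count=len(table.indels),
        singleton_count=table.snp_singletons,
        H=haplotypes.H,
        Hd=haplotype_diversity(list(haplotypes.counts.values())) if n >= 2 else 0.0,
        pi=pi,
        theta_w=theta,
        tajima_D=D,
        tajima_class=klass,
    )
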