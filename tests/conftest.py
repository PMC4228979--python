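"""Shared fixtures and independent brute-force oracles.

The oracles deliberately avoid the package's matching/clustering code
paths: IUPAC membership is re-declared here and matching is plain
window-by-window set lookup, so agreement between the two routes is
meaningful.
"""

from __future__ import annotations

import random

import pytest

from promotif import AnnotatedPromoter, MotifHit, PromoterSequence

# Independent IUPAC table (do not import from promotif.catalog).
ORACLE_IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "W": "AT", "S": "CG", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}
ORACLE_COMPLEMENT = str.maketrans("ACGTRYWSKMBDHVN", "TGCAYRWSMKVHDBN")


def oracle_window_matches(pattern: str, window: str) -> bool:
    if len(pattern) != len(window):
        return False
    return all(w in ORACLE_IUPAC[p] for p, w in zip(pattern, window))


def oracle_revcomp_pattern(pattern: str) -> str:
    return pattern.translate(ORACLE_COMPLEMENT)[::-1]


def oracle_scan(seq: str, patterns: dict[str, str], strands: str = "both"):
    """Exhaustive sliding-window scan; returns {(motif, strand, start)}.

    Minus-strand: a window carries the motif on the minus strand iff the
    window matches the reversed-complemented pattern.  Starts are
    ATG-relative (position −1 is the last base).
    """
    L = len(seq)
    found = set()
    for motif_id, pattern in patterns.items():
        w = len(pattern)
        for i in range(L - w + 1):
            window = seq[i : i + w]
            if strands in ("plus", "both") and oracle_window_matches(pattern, window):
                found.add((motif_id, "+", i - L))
            if strands in ("minus", "both") and oracle_window_matches(
                oracle_revcomp_pattern(pattern), window
            ):
                found.add((motif_id, "-", i - L))
    return found


def oracle_resolve(hits: list[MotifHit]) -> set[tuple]:
    """Pairwise strict-containment filter over all hit pairs."""
    keys = set()
    for h in hits:
        contained = any(
            o.strand == h.strand
            and o.start <= h.start
            and h.end <= o.end
            and (o.end - o.start) > (h.end - h.start)
            for o in hits
        )
        if not contained:
            keys.add((h.motif_id, h.strand, h.start))
    return keys


def oracle_offsets(rows: dict[str, str], reference: str) -> dict[str, dict[int, int]]:
    """Per-column projection of member coordinates onto the reference."""
    ref = rows[reference]
    width = len(ref)
    ref_len = len(ref.replace("-", ""))
    ref_coord = {}
    seen = 0
    last = None
    for j in range(width):
        if ref[j] != "-":
            seen += 1
            last = seen - ref_len - 1
        ref_coord[j] = last if last is not None else -ref_len
    out = {}
    for mid, row in rows.items():
        mem_len = len(row.replace("-", ""))
        mapping = {}
        seen = 0
        for j in range(width):
            if row[j] != "-":
                seen += 1
                mapping[seen - mem_len - 1] = ref_coord[j]
        out[mid] = mapping
    return out


def gotoh_score(a: str, b: str, match=1.0, mismatch=-1.0, open_=-5.0, extend=-0.5):
    """Textbook global affine-gap alignment score (Gotoh)."""
    n, m = len(a), len(b)
    NEG = float("-inf")
    M = [[NEG] * (m + 1) for _ in range(n + 1)]
    X = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in b (a consumed)
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in a (b consumed)
    M[0][0] = 0.0
    for i in range(1, n + 1):
        X[i][0] = open_ + (i - 1) * extend
    for j in range(1, m + 1):
        Y[0][j] = open_ + (j - 1) * extend
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = match if a[i - 1] == b[j - 1] else mismatch
            M[i][j] = max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1]) + s
            X[i][j] = max(M[i - 1][j] + open_, X[i - 1][j] + extend, Y[i - 1][j] + open_)
            Y[i][j] = max(M[i][j - 1] + open_, Y[i][j - 1] + extend, X[i][j - 1] + open_)
    return max(M[n][m], X[n][m], Y[n][m])


def random_dna(rng: random.Random, length: int) -> str:
    return "".join(rng.choice("ACGT") for _ in range(length))


@pytest.fixture
def rng() -> random.Random:
    return random.Random(20240621)


@pytest.fixture
def toy_promoter() -> PromoterSequence:
    return PromoterSequence(seq_id="toy", residues="TGCAAAGTATATAACGTGGCAAT")


def hit_keys(ann: AnnotatedPromoter) -> set[tuple]:
    return {(h.motif_id, h.strand, h.start) for h in ann.hits}
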