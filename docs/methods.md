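# Methods

`promotif` annotates plant promoter alleles with degenerate cis-motifs,
builds indel-aware consensus annotations across promoter sets, detects
conserved cis-regulatory modules (CCRMs), and computes the standard
promoter diversity statistics. This note records the model, the
parameters that matter, and the design choices made where more than one
reasonable convention exists.

## Coordinates

All positions are ATG-relative: −1 is the base immediately 5′ of the A
of the translation start codon, there is no position 0, and a promoter
of length *L* spans −L..−1. This matches the convention in which a
TATA box "at −90" means its first base is 90 bp upstream of the start
codon. GFF3 output cannot carry negative coordinates, so features are
written 1-based within the record with the ATG-relative start preserved
in an `atg_offset` attribute.

## Motif scanning

Motifs are IUPAC consensus strings (≥ 3 nt). Matching is implemented
as character classes over the concrete bases only, compiled to a
regular expression with a look-ahead so that overlapping self-matches
are all reported. Two consequences of that construction are
deliberate:

* a subject `N` matches nothing (conservative: ambiguous stretches in
  accession-derived sequence never inflate counts);
* every distinct start position counts as a separate hit — no greedy
  left-to-right consumption.

Minus-strand occurrences are found by scanning the plus strand with the
reverse-complemented pattern and are reported in plus-strand
coordinates with a strand flag. Count tables default to the plus
strand, the strand on which promoter annotations of this kind are
conventionally tabulated; minus-strand counting is available through a
flag.

Two built-in catalogs are provided. `table2` (24 motifs) is the full
working set of seed-storage-protein regulatory motifs — the DOF-binding
prolamin-box family, the bZIP-binding GCN4-like/G-box family, the RY
repeat, the AACA (R2R3-MYB) and GATA (R1MYB) families, and a handful of
general elements — plus two custom additions, `AACNNA` and `TATAWA`.
`table6` (19 motifs) is the counting subset that omits patterns wholly
redundant for tallies and uses the short RY core `CATGCA` instead of
`CATGCAY`; the two presets intentionally disagree there and neither is
silently merged into the other.

### Nested-hit resolution

Degenerate catalogs nest (e.g. the DOF core `AAAG` inside the prolamin
box `TGCAAAG`). Where one hit's interval is strictly contained in a
longer same-strand hit's interval, only the longest is kept, applied
transitively along containment chains. Containment alone triggers
removal — the transcription-factor family is not consulted — and
co-extensive equal-length hits of different motifs are all retained
(strict containment requires a strictly longer container, so ties
cannot arise). The operation is idempotent, and counting refuses
unresolved annotations to prevent double counting.

## Consensus and CCRMs

Promoter alleles differ by indels, which shift every motif 5′ of the
indel. Member hit coordinates are therefore projected into a common
reference frame through an alignment: each member base maps to the
reference base in its column, or, where the reference is gapped, to the
nearest reference base 5′ (more distal) of the column. Projection is
applied *before* coordinate comparison — i.e. indel correction first,
then the tolerance window.

Per (motif, strand), the mapped start positions are clustered by
single linkage; in one dimension this is simply splitting the sorted
starts wherever consecutive values are more than `tolerance` (default
5 bp) apart. A cluster's support is the fraction of distinct members
contributing. Support ≥ `conserved_support` (default 1.0 — present in
*all* members) makes a conserved motif; support strictly above
`majority_support` (default 0.5) but below the conserved threshold
makes the separate "majority" tier, which is what the inter-motif
distance report uses. The cluster representative is the median start,
ties rounded toward the start codon. With pure single linkage a long
chain of hits spaced just under the tolerance could in principle spread
a cluster beyond ±tolerance; this is accepted rather than patched,
because the clustering post-condition (link distance) is the defined
behavior and such chains do not arise at realistic motif densities.

CCRM detection walks the conserved motifs from the start codon outward
and opens a new module whenever the start-to-start gap exceeds
`ccrm_max_gap` (default 100 bp, the upper end of the classical
cis-regulatory-module length scale); modules with fewer than
`ccrm_min_motifs` (default 2) motifs are discarded and survivors are
numbered 1..k from the start codon. The gap and size defaults are
exposed in the parameters object because module boundaries are a
convention, not a measurement.

Consensuses of consensuses (e.g. x-type and y-type gene sets merged
into an overall annotation) treat each input's conserved motifs as
pseudo-hits with identity offsets and re-cluster with
`merge_tolerance` (default 10 bp — looser than the within-set 5 bp
because cross-set coordinates are medians, not raw hits). The merged
conserved tier keeps only motifs present in every input, and the
operation is invariant to input order.

### Internal aligner

A supplied aligned FASTA always takes precedence. The built-in
aligner is a convenience star alignment: each member is globally
aligned to the reference with affine gap penalties (match +1, mismatch
−1, open −5, extend −0.5 — gap-run-preserving scores appropriate for
allelic promoter variants), and pairwise alignments are stitched on
shared reference columns, left-justifying co-located insertions. It is
exact for the dominant case of indel-only allelic variation and is
validated against a textbook affine-gap dynamic-programming oracle; it
is not a full progressive MSA and should not be used for deeply
diverged sequences.

## Diversity statistics

Input alignments are treated as haploid allele sets (heterozygous
lines are out of scope). Calling follows the complete-deletion rule:

* SNPs: gap-free columns (and free of ambiguous bases) with ≥ 2
  distinct bases; `L_valid` counts those clean columns.
* Indels: maximal runs of gap-containing columns sharing one
  presence/absence pattern across rows count as a single event of the
  run's length. Indels are excluded from π/θ/S but enter haplotype
  vectors and are reported separately, matching the usual bookkeeping
  in promoter diversity tables.
* Singletons: sites whose minor allele occurs in exactly one line.

Haplotypes are the allele vectors over all polymorphic sites (SNP
bases plus indel presence/absence), labelled `h1, h2, …` by descending
frequency with ties broken by first occurrence.

Statistics use the classical estimators: π = mean pairwise differences
per valid site; Watterson's θ_W = S/(a₁·L) with a₁ = Σ_{i<n} 1/i;
haplotype diversity Hd = (n/(n−1))(1 − Σ p_i²); and Tajima's
D = (k̂ − S/a₁)/√(e₁S + e₂S(S−1)) with the published constants. With
S = 0, D is undefined and reported as such rather than raised. The
significance class (`NS`, `P<0.05`, `P<0.01`) uses Tajima's beta
approximation to the null distribution of D — D rescaled onto its
attainable range [D_min, D_max] as a beta variate with mean 0 and
variance 1, two-tailed — rather than coalescent simulation, which
would add a stochastic dependency for no gain at these sample sizes.

## Synthetic promoter families

The generator emulates a resequenced promoter-allele panel: promoters
of several hundred to ~1100 bp, roughly one polymorphism per 100 bp
(`snp_rate` default 0.01/site), a singleton-rich haplotype structure
(two major haplotypes plus single-line variants; `singleton_fraction`
default 0.5 of polymorphic sites private), occasional short deletions
and an optional large (e.g. 54-bp) deletion assigned to named carrier
alleles, and concrete motif instances planted at fixed ATG-relative
positions, grouped into modules.

Construction: a uniform-random background (GC configurable) receives
the planted words; alleles then derive from this ancestor. Polymorphic
sites are selected by a per-site Bernoulli draw from one uniform
stream, and each site's derived base and carrier set come from a
site-indexed stream — so raising the rate only *adds* sites, which
makes recovery-versus-rate sweeps monotone by construction. Haplotype
structures:

* `two_major_plus_singletons` — non-private sites distinguish two
  major allele groups (60:40 split); private sites go to a designated
  pool of singleton alleles.
* `star` — every site is private to one random allele.
* `uniform` — unstructured neutral infinite-sites sampling: the
  derived-allele count c is drawn with P(c) ∝ 1/c and carriers are a
  uniform subset, which gives E[π] = E[θ_W] and hence mean Tajima's D
  near zero. This is the generator's "no structure, no selection"
  regime.

Deletions are recorded as gap spans, so the emitted alignment is exact
by construction; per-allele planted placements are stored with their
indel-shifted coordinates, and replaying the truth record on the
ancestor reproduces each allele byte-identically.

Because a random background can spell out extra catalog motifs, truth
comparisons normally test *containment* of planted hits. Two
guarantees are layered on top. Always: no accidental longer hit may
strictly contain a planted one (offending background bases are
redrawn), so planted plus-strand hits survive nested resolution. In
`motif_free` mode the background is additionally resampled until, for
the planted-motif catalog, the resolved plus-strand hit set equals the
planted set exactly — feasible because the redraws are targeted at
offending windows. The `ccrm5` preset (five modules of 2–5 motifs:
TATA-variant+CAAT, a G-box module, a GGATA pair, the composite
GLM-GATA box, and a distal DOF+CCAAT pair) and the `glm_gata_box`
preset (the composite box alone) both use this mode. Within-module
placements of the *same* motif are spaced at least 6 bp apart because
the ±5 bp consensus tolerance would otherwise merge them into one
cluster by definition.

What the generator does *not* emulate: coalescent genealogies,
recombination, selection, mutation-rate heterogeneity, and sequencing
error. Passing recovery tests therefore demonstrates correctness of
the annotation/consensus machinery under controlled conditions, not
performance on real resequencing data.

## Problem sizes in the shipped checks

The test suite and `scripts/acceptance.py` run entirely from generated
data: 100 random sequences up to 1 kb for scanner-oracle agreement,
6–8-allele 1-kb families for module recovery, a 42-allele 750-bp panel
(two major haplotypes, three singleton lines, one 54-bp deletion) for
the diversity summary, and 200 replicates each for the
segregating-site and neutral-D calibration checks. These sizes mirror
the scale of a single-gene promoter resequencing panel. The
accession-based reproduction (public locus records of the wheat
high-molecular-weight glutenin genes) needs network access and is
provided separately as `scripts/renan_reproduction.py`.

## Known limitations

* The star aligner left-justifies co-located insertions from different
  members against each other; a curated alignment should be supplied
  when insertions are dense.
* Minus-strand planted placements are not covered by the background
  cleanup guarantee (cleanup scans the plus strand).
* Tajima significance classes from the beta approximation are
  approximate for very small n or very large S.
* Heterozygous input is not modelled; each sequence is one haploid
  allele.
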