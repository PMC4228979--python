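#!/usr/bin/env python
"""Opt-in reproduction of the published cv. Renan promoter annotation.

Requires network access (about 1 MB from NCBI).  Fetches the three
HMW-GS locus records DQ537335.1, DQ537336.1 and DQ537337.1 (Glu-A1,
Glu-B1, Glu-D1 of bread wheat cv. Renan), extracts the 1-kb region
upstream of each annotated start codon, and recomputes:

* the per-gene motif count table (19-pattern counting catalog, plus
  strand, nested hits resolved) — reference values include an all-ones
  TATAWA row, a GGATA row of (8, 7, 9, 7, 8, 7) and a Glu-A1-1 total
  of 39;
* the raw (unresolved) per-gene annotation counts with the 24-motif
  catalog (reference span 44–54) and the reduction achieved by nested
  resolution (reference 15–24%);
* the overall consensus across the x-type and y-type sets (reference:
  21 motifs in five conserved modules);
* the GCN4-like motif and RY-repeat positions in the 747-bp PrBx7
  fragment (reference −647 and −525).

Usage:
    python scripts/renan_reproduction.py --out results/renan.json
"""

from __future__ import annotations

import argparse
import json
from pathlib import Path

import promotif as pm
from promotif.cli import _extract_upstream, _fetch_genbank
from promotif.io import write_promoters

ACCESSIONS = ("DQ537335.1", "DQ537336.1", "DQ537337.1")
X_TYPE = ("Glu-A1-1", "Glu-B1-1", "Glu-D1-1")
Y_TYPE = ("Glu-A1-2", "Glu-B1-2", "Glu-D1-2")


def consensus_for(promoters, catalog, set_id):
    alignment = pm.align_members(promoters, reference=promoters[0].seq_id)
    offsets = pm.build_offset_maps(alignment, reference=promoters[0].seq_id)
    annotated = {
        p.seq_id: pm.resolve_nested(pm.scan(p, catalog, "both"))
        for p in promoters
    }
    return pm.find_conserved(annotated, offsets, set_id=set_id)


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--out", type=Path, required=True)
    parser.add_argument("--cache", type=Path, default=Path("scratch/renan"))
    parser.add_argument("--email", default="promotif@example.org")
    args = parser.parse_args()

    args.cache.mkdir(parents=True, exist_ok=True)
    records = _fetch_genbank(ACCESSIONS, args.email, args.cache)
    promoters, provenance = _extract_upstream(records, 1000, 747, {})
    write_promoters(promoters, args.cache / "renan_promoters.fasta")
    (args.cache / "provenance.json").write_text(json.dumps(provenance, indent=2))

    by_gene = {p.gene: p for p in promoters}
    genes = [g for g in X_TYPE + Y_TYPE if g in by_gene]

    results: dict[str, dict] = {}

    def put(key, value, n):
        results[key] = {"value": float(value), "n": int(n)}

    # Counting-catalog table (plus strand, nested-resolved).
    table6 = pm.load_catalog("table6")
    resolved = [
        pm.resolve_nested(pm.scan(by_gene[g], table6, "both")) for g in genes
    ]
    counts = pm.count_matrix(resolved, strand_filter="plus", catalog=table6)
    for i, gene in enumerate(genes):
        col = counts.columns[i]
        put(f"total_{gene}", counts.loc["Total", col], 1000)
        put(f"ggata_{gene}", counts.loc["GATA2", col], 1000)
        put(f"tatawa_{gene}", counts.loc["TATA", col], 1000)

    # Raw 24-motif annotation counts and the nested-resolution reduction.
    table2 = pm.load_catalog("table2")
    raw_counts, reductions = [], []
    for g in genes:
        raw = pm.scan(by_gene[g], table2, "both")
        res = pm.resolve_nested(raw)
        n_raw = sum(1 for h in raw.hits if h.strand == "+")
        n_res = sum(1 for h in res.hits if h.strand == "+")
        raw_counts.append(n_raw)
        reductions.append(100.0 * (n_raw - n_res) / n_raw)
    put("raw_count_min", min(raw_counts), len(genes))
    put("raw_count_max", max(raw_counts), len(genes))
    put("nested_reduction_min_pct", min(reductions), len(genes))
    put("nested_reduction_max_pct", max(reductions), len(genes))

    # Overall consensus: per-type consensuses merged.
    x_cons = consensus_for([by_gene[g] for g in X_TYPE if g in by_gene], table2, "x-type")
    y_cons = consensus_for([by_gene[g] for g in Y_TYPE if g in by_gene], table2, "y-type")
    overall = pm.merge_consensuses([x_cons, y_cons])
    ccrms = pm.detect_ccrms(overall, pm.ConsensusParams())
    put("overall_consensus_motifs", len(overall.conserved), 6)
    put("overall_ccrm_count", len(ccrms), 6)

    # PrBx7 fragment motif positions.
    prbx7 = next((p for p in promoters if p.gene == "PrBx7"), None)
    if prbx7 is not None:
        ann = pm.resolve_nested(pm.scan(prbx7, table2, "both"))
        glm = [h.start for h in ann.hits if h.motif_id in ("GLM1", "GLM2", "GLM3")
               and h.strand == "+"]
        ry = [h.start for h in ann.hits if h.motif_id == "RY" and h.strand == "+"]
        gata = sorted(h.start for h in ann.hits if h.motif_id in ("GATA1", "GATA2")
                      and h.strand == "+")
        if glm:
            put("prbx7_distal_glm_position", min(glm), 747)
        if ry:
            put("prbx7_ry_position", min(ry), 747)
        put("prbx7_gata_count", len(gata), 747)

    args.out.parent.mkdir(parents=True, exist_ok=True)
    args.out.write_text(json.dumps(results, indent=2) + "\n")
    print(json.dumps(results, indent=2))


if __name__ == "__main__":
    main()
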