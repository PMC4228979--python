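"""Synthetic family generation, truth records and recovery properties."""

import dataclasses

import pytest

from promotif import (
    GeneratorConfig,
    IndelSpec,
    Placement,
    PlantedModule,
    build_offset_maps,
    call_sites,
    assign_haplotypes,
    detect_ccrms,
    find_conserved,
    generate_family,
    plant_renan_like,
    replay,
    resolve_nested,
    scan,
)

from conftest import hit_keys


def _recovered_fraction(promoters, truth, catalog):
    """Fraction of per-allele planted placements present after scan+resolve."""
    by_id = {t.member_id: t for t in truth.alleles}
    total = found = 0
    for p in promoters:
        keys = hit_keys(resolve_nested(scan(p, catalog, "plus")))
        for placement in by_id[p.seq_id].placements:
            if placement.strand != "+":
                continue
            total += 1
            found += (placement.motif_id, "+", placement.start) in keys
    return found / total if total else 1.0


class TestDeterminismAndReplay:
    def test_same_seed_reproduces_family(self):
        cfg = GeneratorConfig(seed=42, length=400, n_alleles=6)
        p1, a1, t1 = generate_family(cfg)
        p2, a2, t2 = generate_family(dataclasses.replace(cfg))
        assert [x.residues for x in p1] == [x.residues for x in p2]
        assert a1.rows == a2.rows
        assert t1.ancestor == t2.ancestor

    def test_replay_round_trip_is_exact(self):
        cfg = GeneratorConfig(
            seed=7, length=500, n_alleles=8,
            indel_spec=(IndelSpec(length=3, carriers=(1, 2)),),
        )
        promoters, _, truth = generate_family(cfg)
        replayed = replay(truth)
        assert [p.residues for p in promoters] == [r.residues for r in replayed]

    def test_truth_json_round_trip(self):
        from promotif import SyntheticTruth

        cfg = plant_renan_like("glm_gata_box", seed=3, snp_rate=0.02)
        promoters, _, truth = generate_family(cfg)
        back = SyntheticTruth.from_json(truth.to_json())
        assert [p.residues for p in replay(back)] == [p.residues for p in promoters]

    def test_removing_one_mutation_changes_one_base(self):
        cfg = GeneratorConfig(seed=11, length=400, n_alleles=4, snp_rate=0.02)
        promoters, _, truth = generate_family(cfg)
        victim = next(a for a in truth.alleles if a.snps)
        edited = dataclasses.replace(victim, snps=victim.snps[1:])
        truth2 = dataclasses.replace(
            truth,
            alleles=tuple(edited if a is victim else a for a in truth.alleles),
        )
        replayed = {p.seq_id: p.residues for p in replay(truth2)}
        original = {p.seq_id: p.residues for p in promoters}
        diffs = [
            (mid, sum(x != y for x, y in zip(original[mid], replayed[mid])))
            for mid in original
        ]
        changed = [d for d in diffs if d[1] > 0]
        assert len(changed) == 1 and changed[0][1] == 1

    def test_replay_detects_corrupted_truth(self):
        cfg = GeneratorConfig(seed=5, length=300, n_alleles=4, snp_rate=0.02)
        _, _, truth = generate_family(cfg)
        victim = next(a for a in truth.alleles if a.snps)
        pos, ref, alt = victim.snps[0]
        bad = dataclasses.replace(
            victim, snps=((pos, "A" if ref != "A" else "C", alt),) + victim.snps[1:]
        )
        truth2 = dataclasses.replace(
            truth, alleles=tuple(bad if a is victim else a for a in truth.alleles)
        )
        with pytest.raises(ValueError, match="corrupted truth"):
            replay(truth2)


class TestFamilyStructure:
    def test_zero_rate_no_indels_gives_identical_alleles(self):
        cfg = GeneratorConfig(seed=1, length=300, n_alleles=5, snp_rate=0.0)
        promoters, alignment, _ = generate_family(cfg)
        assert len({p.residues for p in promoters}) == 1
        assert assign_haplotypes(alignment).H == 1

    def test_planted_deletion_called_as_single_indel(self):
        cfg = GeneratorConfig(
            seed=2, length=500, n_alleles=8, snp_rate=0.0,
            indel_spec=(IndelSpec(length=54, carriers=(3, 5)),),
        )
        _, alignment, _ = generate_family(cfg)
        table = call_sites(alignment)
        assert len(table.indels) == 1
        assert table.indels[0].length == 54
        assert table.L_valid == 500 - 54

    def test_segregating_columns_match_truth(self):
        for seed in (3, 4, 5):
            cfg = GeneratorConfig(seed=seed, length=800, n_alleles=10, snp_rate=0.01)
            _, alignment, truth = generate_family(cfg)
            assert call_sites(alignment).S == truth.expected_segregating_sites

    def test_two_major_haplotypes_plus_singletons(self):
        cfg = GeneratorConfig(
            seed=5, length=750, n_alleles=42, snp_rate=0.01, n_singleton_alleles=3
        )
        _, alignment, truth = generate_family(cfg)
        haps = assign_haplotypes(alignment)
        assert haps.counts == truth.expected_haplotype_counts
        counts = sorted(haps.counts.values(), reverse=True)
        assert counts[0] > 1 and counts[1] > 1  # two major haplotypes
        assert counts.count(1) >= 1  # plus singleton lines

    def test_config_validation(self):
        with pytest.raises(ValueError, match="exceeds"):
            GeneratorConfig(
                seed=0, length=100,
                planted_modules=(PlantedModule("m", (Placement("TATA", "TATATA", -200),)),),
            )
        with pytest.raises(ValueError, match="overlapping placements"):
            GeneratorConfig(
                seed=0, length=100,
                planted_modules=(
                    PlantedModule(
                        "m",
                        (
                            Placement("TATA", "TATATA", -50),
                            Placement("CAAT", "CAAT", -48),
                        ),
                    ),
                ),
            )
        with pytest.raises(ValueError, match="carrier"):
            GeneratorConfig(seed=0, indel_spec=(IndelSpec(2, carriers=(99,)),))


class TestPlantedRecovery:
    def test_all_placements_recovered_at_zero_rate(self):
        cfg = plant_renan_like("ccrm5", seed=9, snp_rate=0.0)
        promoters, _, truth = generate_family(cfg)
        assert _recovered_fraction(promoters, truth, cfg.planted_catalog()) == 1.0

    def test_recovery_degrades_monotonically_with_mutation_rate(self):
        rates = (0.0, 0.03, 0.08, 0.15)
        fractions = []
        for rate in rates:
            cfg = plant_renan_like(
                "ccrm5", seed=13, snp_rate=rate, protect_planted=False
            )
            promoters, _, truth = generate_family(cfg)
            fractions.append(
                _recovered_fraction(promoters, truth, cfg.planted_catalog())
            )
        assert fractions[0] == 1.0
        assert all(a >= b for a, b in zip(fractions, fractions[1:]))
        assert fractions[-1] < 1.0  # the sweep actually destroys motifs

    def test_offset_maps_restore_ancestor_coordinates(self):
        """After an indel shifts allele coordinates, mapping through the
        emitted alignment recovers the ancestor-frame placement starts."""
        cfg = plant_renan_like(
            "ccrm5", seed=17, snp_rate=0.01,
            indel_spec=(IndelSpec(length=10, carriers=(2, 4)),),
        )
        promoters, alignment, truth = generate_family(cfg)
        # allele a01 carries no deletion, so its frame is the ancestor frame
        maps = build_offset_maps(alignment, reference="a01")
        ancestor_starts = {
            (p.motif_id, p.start) for p in truth.planted if p.strand == "+"
        }
        for allele in truth.alleles:
            mapped = {
                (p.motif_id, maps[allele.member_id][p.start])
                for p in allele.placements
                if p.strand == "+"
            }
            assert mapped <= ancestor_starts

    def test_pipeline_recovers_five_modules_with_indel_and_snps(self):
        cfg = plant_renan_like(
            "ccrm5", seed=21, snp_rate=0.01, n_alleles=8,
            indel_spec=(IndelSpec(length=10, carriers=(2, 3)),),
        )
        promoters, alignment, truth = generate_family(cfg)
        catalog = cfg.planted_catalog()
        annotated = {
            p.seq_id: resolve_nested(scan(p, catalog, "plus")) for p in promoters
        }
        offsets = build_offset_maps(alignment, reference="a01")
        consensus = find_conserved(annotated, offsets)
        ccrms = detect_ccrms(consensus)
        assert len(ccrms) == len(truth.modules) == 5
        # truth modules are listed proximal-to-distal, matching CCRM numbering
        expected_sizes = [len(m.placements) for m in truth.modules]
        assert [len(c.motifs) for c in ccrms] == expected_sizes


class TestPresets:
    def test_ccrm5_plants_five_modules_of_two_to_five_motifs(self):
        cfg = plant_renan_like("ccrm5", seed=0)
        assert len(cfg.planted_modules) == 5
        for module in cfg.planted_modules:
            assert 2 <= len(module.placements) <= 5

    def test_glm_gata_box_composition(self):
        cfg = plant_renan_like("glm_gata_box", seed=0)
        placements = cfg.placements
        glms = [p for p in placements if p.sequence == "TGAGTCA"]
        ggatas = [p for p in placements if p.sequence == "GGATA"]
        assert len(glms) == 2
        assert len(ggatas) >= 3
        span = (min(p.start for p in placements), max(p.end for p in placements))
        assert all(span[0] <= p.start and p.end <= span[1] for p in ggatas)

    def test_unknown_preset_rejected(self):
        with pytest.raises(ValueError, match="unknown preset"):
            plant_renan_like("nope", seed=0)

    def test_motif_free_background_scans_to_planted_set_only(self):
        cfg = plant_renan_like("ccrm5", seed=23, snp_rate=0.0)
        promoters, _, truth = generate_family(cfg)
        catalog = cfg.planted_catalog()
        planted = {(p.motif_id, "+", p.start) for p in truth.planted}
        for p in promoters:
            assert hit_keys(resolve_nested(scan(p, catalog, "plus"))) == planted
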