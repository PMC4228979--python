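"""Offset maps, alignment, conserved-motif clustering and CCRMs."""

import pytest

from promotif import (
    AlignmentMatrix,
    ConsensusParams,
    ConservedMotif,
    PromoterSequence,
    align_members,
    build_offset_maps,
    detect_ccrms,
    distance_report,
    find_conserved,
    load_catalog,
    merge_consensuses,
    resolve_nested,
    scan,
)
from promotif.consensus import ConsensusAnnotation

from conftest import gotoh_score, oracle_offsets, random_dna


def _conserved(motif_id, coord, length=6, strand="+", support=1.0):
    return ConservedMotif(
        motif_id=motif_id, strand=strand, ref_coordinate=coord,
        support=support, length=length, member_hits=(("m", coord),),
    )


def _consensus(motifs, set_id="s", params=ConsensusParams()):
    return ConsensusAnnotation(
        set_id=set_id, members=("m",), conserved=tuple(motifs),
        majority=(), params=params,
    )


class TestOffsetMaps:
    def test_gapless_alignment_gives_identity_maps(self):
        aln = AlignmentMatrix(("a", "b"), ("ACGTACGT", "ACCTACGA"))
        maps = build_offset_maps(aln, "a")
        assert all(m.is_identity() for m in maps.values())

    def test_member_is_identity_to_itself_as_reference(self):
        aln = AlignmentMatrix(("a", "b"), ("ACGTAC--GT", "AC--ACGTGT"))
        assert build_offset_maps(aln, "a")["a"].is_identity()
        assert build_offset_maps(aln, "b")["b"].is_identity()

    def test_deletion_shifts_upstream_coordinates(self):
        """A 54-bp deletion shifts all member coordinates 5' of it by +54
        in the reference frame (the motifs sit more distally)."""
        ref = random_dna(__import__("random").Random(1), 200)
        deleted = ref[:100] + ref[154:]  # 54-bp deletion at index 100
        aln = AlignmentMatrix(("ref", "del"), (ref, deleted[:100] + "-" * 54 + deleted[100:]))
        maps = build_offset_maps(aln, "ref")
        m = maps["del"]
        # member coordinate −146 (index 0 of the member) maps 54 further out
        assert m[-146] == -200
        # coordinates 3' of the deletion are unshifted
        assert m[-1] == -1 and m[-46] == -46

    def test_reference_gap_maps_to_nearest_distal_base(self):
        # member has an insertion relative to the reference
        aln = AlignmentMatrix(("ref", "ins"), ("ACG---TAC", "ACGGGGTAC"))
        m = build_offset_maps(aln, "ref")["ins"]
        # the three inserted bases all map to the reference base 5' of them
        assert m[-6] == m[-5] == m[-4] == -4  # the G of ACG
        assert m[-9] == -6 and m[-3] == -3

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_column_walk_oracle(self, rng, seed):
        import random as _random

        r = _random.Random(seed)
        W = 60
        rows = {}
        for mid in ("a", "b", "c"):
            row = list(random_dna(r, W))
            for _ in range(2):  # two indels per member
                i = r.randrange(W - 5)
                for j in range(i, i + r.randrange(1, 5)):
                    row[j] = "-"
            rows[mid] = "".join(row)
        aln = AlignmentMatrix(tuple(rows), tuple(rows.values()))
        maps = build_offset_maps(aln, "a")
        expected = oracle_offsets(rows, "a")
        for mid in rows:
            assert maps[mid].mapping == expected[mid]

    def test_unknown_reference_rejected(self):
        aln = AlignmentMatrix(("a",), ("ACGT",))
        with pytest.raises(ValueError, match="unknown reference"):
            build_offset_maps(aln, "zzz")

    def test_unequal_rows_rejected(self):
        with pytest.raises(ValueError, match="unequal lengths"):
            AlignmentMatrix(("a", "b"), ("ACGT", "ACG"))


class TestAlignMembers:
    def test_identical_sequences_align_gapless(self):
        p = [PromoterSequence(i, "ACGTACGTACGT") for i in ("a", "b")]
        aln = align_members(p)
        assert aln.is_gapless()
        assert aln.ungapped("a") == aln.ungapped("b")

    def test_54bp_deletion_gives_single_gap_run(self):
        import random as _random

        ref = random_dna(_random.Random(3), 300)
        deleted = ref[:120] + ref[174:]
        p = [PromoterSequence("ref", ref), PromoterSequence("del", deleted)]
        aln = align_members(p, reference="ref")
        row = aln.row("del")
        runs = [len(s) for s in row.split("-") if s == ""]  # crude: count gaps
        assert row.count("-") == 54
        # one contiguous run
        import re

        assert len(re.findall(r"-+", row)) == 1

    def test_ungapping_reproduces_members(self):
        import random as _random

        r = _random.Random(9)
        seqs = {}
        base = random_dna(r, 150)
        for mid in ("a", "b", "c"):
            s = list(base)
            for _ in range(3):
                i = r.randrange(len(s) - 3)
                del s[i : i + r.randrange(1, 3)]
            seqs[mid] = "".join(s)
        p = [PromoterSequence(m, s) for m, s in seqs.items()]
        aln = align_members(p)
        for mid in seqs:
            assert aln.ungapped(mid) == seqs[mid]

    @pytest.mark.parametrize("seed", range(3))
    def test_pairwise_scores_match_affine_dp_oracle(self, seed):
        import random as _random

        from promotif.consensus import _pairwise_align

        r = _random.Random(seed * 31)
        a = random_dna(r, 40)
        b = list(a)
        del b[10:13]
        b[20] = "A" if b[20] != "A" else "C"
        b = "".join(b)
        _, _, score = _pairwise_align(a, b)
        assert score == pytest.approx(gotoh_score(a, b))

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            align_members([])


class TestFindConserved:
    def _annotate(self, promoters, catalog, strands="plus"):
        return {p.seq_id: resolve_nested(scan(p, catalog, strands)) for p in promoters}

    def test_single_promoter_everything_conserved(self):
        cat = load_catalog("table2")
        p = PromoterSequence("solo", "GGGTGCAAAGAGGCAATGGGTATATAGG")
        ann = self._annotate([p], cat)
        from promotif.consensus import OffsetMap

        offs = {"solo": OffsetMap.identity("solo", len(p))}
        cons = find_conserved(ann, offs, set_id="one")
        assert cons.majority == ()
        assert all(c.support == 1.0 for c in cons.conserved)
        assert {(c.motif_id, c.ref_coordinate) for c in cons.conserved} == {
            (h.motif_id, h.start) for h in ann["solo"].hits if h.strand == "+"
        }

    def test_two_identical_promoters_conserve_their_hit_set(self):
        cat = load_catalog("table2")
        seq = "GGGTGCAAAGAGGCAATGGGTATATAGG"
        promoters = [PromoterSequence(i, seq) for i in ("a", "b")]
        aln = align_members(promoters)
        offs = build_offset_maps(aln, "a")
        cons = find_conserved(self._annotate(promoters, cat), offs)
        assert cons.majority == ()
        assert {(c.motif_id, c.ref_coordinate) for c in cons.conserved} == {
            (h.motif_id, h.start)
            for h in self._annotate(promoters, cat)["a"].hits
            if h.strand == "+"
        }

    def test_unresolved_annotation_rejected(self):
        cat = load_catalog("table2")
        p = PromoterSequence("x", "GGGTGCAAAGAGG")
        ann = {"x": scan(p, cat, "plus")}
        from promotif.consensus import OffsetMap

        with pytest.raises(ValueError, match="not nested-resolved"):
            find_conserved(ann, {"x": OffsetMap.identity("x", len(p))})

    def test_missing_offset_map_rejected(self):
        cat = load_catalog("table2")
        p = PromoterSequence("x", "GGGTGCAAAGAGG")
        ann = {"x": resolve_nested(scan(p, cat, "plus"))}
        with pytest.raises(ValueError, match="no offset map"):
            find_conserved(ann, {})

    def test_permutation_invariance(self, rng):
        cat = load_catalog("table2")
        seqs = {f"m{i}": random_dna(rng, 300) for i in range(4)}
        promoters = [PromoterSequence(m, s) for m, s in seqs.items()]
        aln = align_members(promoters, reference="m0")
        offs = build_offset_maps(aln, "m0")
        ann = self._annotate(promoters, cat)
        fwd = find_conserved(ann, offs)
        rev = find_conserved(dict(reversed(list(ann.items()))), offs)
        assert fwd.conserved == rev.conserved
        assert fwd.majority == rev.majority

    def test_tolerance_monotonicity(self, rng):
        """The conserved set can only grow as the tolerance loosens."""
        cat = load_catalog("table2")
        base = random_dna(rng, 400)
        variants = {"a": base, "b": base[:200] + base[203:], "c": base[:90] + base[92:]}
        promoters = [PromoterSequence(m, s) for m, s in variants.items()]
        aln = align_members(promoters, reference="a")
        offs = build_offset_maps(aln, "a")
        ann = self._annotate(promoters, cat)
        previous: set = set()
        for tol in (0, 2, 5, 10, 20):
            cons = find_conserved(ann, offs, ConsensusParams(tolerance=tol))
            current = {(c.motif_id, c.strand) for c in cons.conserved}
            assert previous <= current
            previous = current


class TestCcrms:
    def test_two_proximal_motifs_form_one_module(self):
        cons = _consensus([_conserved("TATA", -95), _conserved("CAAT", -88, 4)])
        ccrms = detect_ccrms(cons)
        assert len(ccrms) == 1
        assert ccrms[0].index == 1 and len(ccrms[0].motifs) == 2

    def test_two_distant_singletons_form_no_module(self):
        cons = _consensus([_conserved("a", -100), _conserved("b", -900)])
        assert detect_ccrms(cons) == []

    def test_numbering_increases_with_distality(self):
        motifs = [
            _conserved("a", -90), _conserved("b", -60),
            _conserved("c", -500), _conserved("d", -450),
            _conserved("e", -950), _conserved("f", -900),
        ]
        ccrms = detect_ccrms(_consensus(motifs))
        assert [c.index for c in ccrms] == [1, 2, 3]
        spans = [c.span for c in ccrms]
        assert spans[0][0] > spans[1][0] > spans[2][0]

    def test_gap_parameter_controls_module_breaks(self):
        motifs = [_conserved("a", -100), _conserved("b", -250)]
        assert detect_ccrms(_consensus(motifs)) == []  # gap 150 > 100
        wide = ConsensusParams(ccrm_max_gap=200)
        assert len(detect_ccrms(_consensus(motifs), wide)) == 1

    def test_empty_consensus_gives_empty_list(self):
        assert detect_ccrms(_consensus([])) == []


class TestMergeAndDistances:
    def test_merging_single_consensus_is_identity(self):
        cons = _consensus([_conserved("a", -90), _conserved("b", -400)])
        merged = merge_consensuses([cons])
        assert {(m.motif_id, m.ref_coordinate) for m in merged.conserved} == {
            ("a", -90), ("b", -400)
        }

    def test_merge_is_order_invariant(self):
        c1 = _consensus([_conserved("a", -90), _conserved("b", -400)], "s1")
        c2 = _consensus([_conserved("a", -92), _conserved("c", -700)], "s2")
        m12 = merge_consensuses([c1, c2])
        m21 = merge_consensuses([c2, c1])
        assert m12.conserved == m21.conserved
        assert m12.majority == m21.majority

    def test_merge_keeps_only_motifs_present_in_all_inputs(self):
        c1 = _consensus([_conserved("a", -90), _conserved("b", -400)], "s1")
        c2 = _consensus([_conserved("a", -93), _conserved("c", -700)], "s2")
        merged = merge_consensuses([c1, c2])
        assert {m.motif_id for m in merged.conserved} == {"a"}
        assert {m.motif_id for m in merged.majority} == set()  # 0.5 not > 0.5

    def test_distance_report_single_motif_empty(self):
        assert distance_report(_consensus([_conserved("a", -90)])).empty

    def test_distance_report_arithmetic(self):
        table = distance_report(
            _consensus([_conserved("a", -130), _conserved("b", -90)])
        )
        assert len(table) == 1
        assert table.iloc[0]["distance"] == 40
        assert table.iloc[0]["from_motif"] == "a"
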