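"""Genome mapping, precursor excision, hairpin folding and scoring."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from centomir._seq import revcomp
from centomir.novel import (
    DiscoveryThresholds,
    HairpinCandidate,
    discover_novel,
    excise_precursor,
    fold_hairpin,
    hairpin_loop_penalty,
    map_to_genome,
    score_candidate,
    stack_energy,
)
from centomir.simulate import SimConfig, generate_reference
from conftest import random_dna


class TestMapToGenome:
    def test_planted_tag_found_once_with_strand(self, rng):
        tag = random_dna(rng, 22)
        genome = {"chr1": random_dna(rng, 500) + tag + random_dna(rng, 500)}
        (locus,) = map_to_genome(tag, genome)
        chrom, start, end, strand = locus
        assert strand == "+" and end - start + 1 == 22
        assert genome["chr1"][start - 1 : end] == tag

    def test_minus_strand_hit(self, rng):
        tag = random_dna(rng, 22)
        genome = {"chr1": random_dna(rng, 100) + revcomp(tag) + random_dna(rng, 100)}
        (locus,) = map_to_genome(tag, genome)
        assert locus[3] == "-"
        assert genome["chr1"][locus[1] - 1 : locus[2]] == revcomp(tag)

    def test_absent_tag_empty(self, rng):
        assert map_to_genome("A" * 25, {"chr1": random_dna(rng, 300)}) == []

    def test_empty_genome_rejected(self):
        with pytest.raises(ValueError, match="empty genome"):
            map_to_genome("ACGT", {})

    def test_matches_exhaustive_scan(self, rng):
        """Loci equal a brute-force scan of all positions on both strands."""
        genome = {"c1": random_dna(rng, 400), "c2": random_dna(rng, 400)}
        tag = genome["c1"][50:70]
        got = set(map_to_genome(tag, genome))
        expected = set()
        for chrom, text in genome.items():
            for strand, q in (("+", tag), ("-", revcomp(tag))):
                for i in range(len(text) - len(q) + 1):
                    if text[i : i + len(q)] == q:
                        expected.add((chrom, i + 1, i + len(q), strand))
        assert got == expected

    def test_multi_mapper_search_stops_at_limit(self):
        tag = "ACGTACGTACGTACGTAC"
        genome = {"chr1": ("TTTT" + tag) * 8}
        loci = map_to_genome(tag, genome, max_loci=3)
        assert len(loci) == 4  # max_loci + 1 is enough to prove multi-mapping


class TestExcise:
    def test_window_length_is_110(self, rng):
        genome = {"chr1": random_dna(rng, 1000)}
        windows = excise_precursor(("chr1", 500, 521, "+"), genome)
        for seq, lo, hi, truncated, arm in windows:
            assert len(seq) == 110 == hi - lo + 1
            assert not truncated
        assert {w[4] for w in windows} == {"5p", "3p"}

    def test_tag_contained_in_windows(self, rng):
        genome = {"chr1": random_dna(rng, 1000)}
        tag = genome["chr1"][499:521]
        for seq, *_ in excise_precursor(("chr1", 500, 521, "+"), genome):
            assert tag in seq

    def test_minus_strand_window_is_revcomp(self, rng):
        genome = {"chr1": random_dna(rng, 1000)}
        seq, lo, hi, _, _ = excise_precursor(("chr1", 500, 521, "-"), genome)[0]
        assert seq == revcomp(genome["chr1"][lo - 1 : hi])

    def test_chromosome_start_truncated_and_flagged(self, rng):
        genome = {"chr1": random_dna(rng, 200)}
        seq, lo, hi, truncated, _ = excise_precursor(("chr1", 3, 24, "+"), genome)[0]
        assert truncated and lo == 1 and len(seq) < 110


class TestFold:
    def test_poly_a_has_no_structure(self):
        mfe, structure = fold_hairpin("A" * 60)
        assert mfe == 0.0
        assert structure == "." * 60

    def test_gc_stem_matches_hand_summed_stack_energies(self):
        # 20-bp GC stem, 4-nt loop: 19 GC/GC stacks + hairpin(4)
        seq = "G" * 20 + "AAAA" + "C" * 20
        expected = 19 * stack_energy("GC", "GC") + hairpin_loop_penalty(4)
        mfe, structure = fold_hairpin(seq)
        assert mfe == pytest.approx(expected, abs=1e-9)
        assert expected < -25.0
        assert structure == "(" * 20 + "...." + ")" * 20

    def test_t_u_alphabet_equivalence(self):
        seq = "G" * 15 + "CTTACG" + "C" * 15 + "TTTT"
        assert fold_hairpin(seq)[0] == fold_hairpin(seq.replace("T", "U"))[0]

    def test_invalid_characters_rejected(self):
        with pytest.raises(ValueError, match="invalid"):
            fold_hairpin("ACGTX" * 10)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError, match="too short"):
            fold_hairpin("ACGT" * 5)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.text(alphabet="ACGU", min_size=40, max_size=70))
    def test_structure_brackets_balanced_and_nested(self, seq):
        mfe, structure = fold_hairpin(seq)
        assert mfe <= 0.0
        depth = 0
        for ch in structure:
            if ch == "(":
                depth += 1
            elif ch == ")":
                depth -= 1
            assert depth >= 0
        assert depth == 0

    def test_planted_precursor_folds_below_threshold(self):
        refs, _ = generate_reference(SimConfig(n_mirnas=3, seed=12))
        for r in refs:
            assert fold_hairpin(r.precursor)[0] < -25.0


class TestScoring:
    def _candidate(self, **kw):
        base = dict(
            tag="A" * 22, counts={"s": 100}, n_loci=1, mfe=-40.0, gc=0.5,
            signature_fraction=1.0, precursor_window="G" * 110,
        )
        base.update(kw)
        return HairpinCandidate(**base)

    def test_weak_fold_rejected_with_reason(self):
        out = score_candidate(self._candidate(mfe=-10.0))
        assert out.decision == "reject" and out.failed == ("mfe",)

    def test_boundary_mfe_not_accepted(self):
        # criterion is strictly less than -25
        assert "mfe" in score_candidate(self._candidate(mfe=-25.0)).failed

    def test_all_criteria_met_accepted(self):
        assert score_candidate(self._candidate()).decision == "accept"

    def test_multi_mapping_rejected(self):
        out = score_candidate(self._candidate(n_loci=9))
        assert "multi-mapping" in out.failed

    def test_gc_and_signature_gates(self):
        assert "gc" in score_candidate(self._candidate(gc=0.1)).failed
        assert "processing-signature" in score_candidate(
            self._candidate(signature_fraction=0.5)
        ).failed

    def test_rescoring_idempotent(self):
        once = score_candidate(self._candidate(mfe=-10.0))
        assert score_candidate(once) == once


class TestDiscovery:
    def test_planted_accepted_decoys_rejected(self, rng):
        cfg = SimConfig(n_mirnas=6, seed=13)
        refs, genome = generate_reference(cfg)
        text = genome["chr1"]
        decoys = []
        for r in refs[:4]:
            shuffled = list(r.precursor)
            rng.shuffle(shuffled)
            decoys.append("".join(shuffled))
        for d in decoys:
            text += random_dna(rng, 80) + d
        genome = {"chr1": text + random_dna(rng, 80)}
        tags = {}
        for r in refs:
            tags[r.mature] = {"s1": 80, "s2": 70}
            tags[r.mature[:-1]] = {"s1": 10}  # precise Drosha/Dicer 5' ends
        for d in decoys:
            # degradation-like support: 5' ends scattered across the locus
            for offset in (3, 6, 9, 12):
                tags[d[offset : offset + 22]] = {"s1": 25}
        candidates = discover_novel(tags, genome, [r.precursor for r in refs])
        by_tag = {c.tag: c for c in candidates}
        for r in refs:
            assert by_tag[r.mature].decision == "accept", by_tag[r.mature].failed
        for d in decoys:
            cand = by_tag[d[3:25]]
            assert cand.decision == "reject"
            assert {"mfe", "processing-signature"} & set(cand.failed)

    def test_recovered_window_contains_planted_stem(self):
        cfg = SimConfig(n_mirnas=2, seed=14)
        refs, genome = generate_reference(cfg)
        tags = {r.mature: {"s1": 50} for r in refs}
        candidates = discover_novel(tags, genome)
        by_tag = {c.tag: c for c in candidates}
        for r in refs:
            assert by_tag[r.mature].precursor_window == r.precursor
            assert by_tag[r.mature].arm == "5p"

    def test_low_read_tags_skipped(self, rng):
        genome = {"chr1": random_dna(rng, 300)}
        tags = {genome["chr1"][50:72]: {"s1": 3}}  # below min_reads
        assert discover_novel(tags, genome) == []

    def test_homology_reported_for_known_precursor(self):
        refs, genome = generate_reference(SimConfig(n_mirnas=1, seed=15))
        tags = {refs[0].mature: {"s1": 50}}
        (cand,) = discover_novel(tags, genome, [refs[0].precursor])
        assert cand.homology_to_known == pytest.approx(1.0)
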