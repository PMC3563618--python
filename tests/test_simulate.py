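"""Synthetic-data generator: references, libraries, age series, truth."""

import math

import numpy as np
import pytest

from centomir.simulate import (
    AgeSeriesConfig,
    SimConfig,
    generate_reference,
    generate_truth,
    isomir_sequence,
    simulate_age_series,
    simulate_count_matrix,
    simulate_library,
)


class TestReference:
    def test_precursor_locus_spans_110(self):
        refs, genome = generate_reference(SimConfig(n_mirnas=3, seed=1))
        for r in refs:
            chrom, start, end = r.locus
            assert end - start + 1 == 110 == len(r.precursor)
            assert 18 <= len(r.mature) <= 25
            assert r.mature in r.precursor

    def test_locus_sequence_matches_precursor(self):
        from centomir._seq import revcomp

        refs, genome = generate_reference(SimConfig(n_mirnas=5, seed=2))
        for r in refs:
            chrom, start, end = r.locus
            window = genome[chrom][start - 1 : end]
            assert window == (r.precursor if r.strand == "+" else revcomp(r.precursor))

    def test_loci_non_overlapping(self):
        refs, _ = generate_reference(SimConfig(n_mirnas=10, seed=3))
        spans = sorted((r.locus[1], r.locus[2]) for r in refs)
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            assert e1 < s2

    def test_empty_reference(self):
        refs, genome = generate_reference(SimConfig(n_mirnas=0))
        assert refs == [] and genome == {}

    def test_seeded_runs_identical(self, tmp_path):
        from centomir.simulate import write_dataset

        cfg = SimConfig(n_mirnas=4, reads_per_library=200, seed=7)
        d1, d2 = tmp_path / "a", tmp_path / "b"
        write_dataset(cfg, d1)
        write_dataset(cfg, d2)
        for name in ("mature.fasta", "genome.fasta", "control_1.fastq"):
            assert (d1 / name).read_bytes() == (d2 / name).read_bytes()

    def test_genome_too_short_raises(self):
        with pytest.raises(ValueError, match="too short"):
            generate_reference(SimConfig(n_mirnas=10, seed=1), genome_length=500)


class TestConfigValidation:
    def test_bad_isomir_proportions_rejected(self):
        with pytest.raises(ValueError, match="sum"):
            SimConfig(n_mirnas=1, isomir_profile={"x": (("canonical", 0.7),)})

    def test_nonpositive_fold_rejected(self):
        with pytest.raises(ValueError, match="fold"):
            SimConfig(de_plan=(("syn-miR-1", "control", 0.0),))

    def test_unknown_group_in_plan_rejected(self):
        with pytest.raises(ValueError, match="group"):
            SimConfig(de_plan=(("syn-miR-1", "martian", 2.0),))

    def test_plan_for_absent_mirna_rejected(self):
        cfg = SimConfig(n_mirnas=2, de_plan=(("syn-miR-99", "control", 2.0),))
        refs, _ = generate_reference(cfg)
        with pytest.raises(ValueError, match="absent"):
            generate_truth(cfg, refs)


class TestLibrary:
    def test_zero_reads_empty_library(self):
        cfg = SimConfig(n_mirnas=2, reads_per_library=0, seed=4)
        refs, _ = generate_reference(cfg)
        truth = generate_truth(cfg, refs)
        assert simulate_library(cfg, refs, truth, "control", 0) == []

    def test_unknown_group_rejected(self):
        cfg = SimConfig(n_mirnas=1, seed=4)
        refs, _ = generate_reference(cfg)
        truth = generate_truth(cfg, refs)
        with pytest.raises(ValueError, match="group"):
            simulate_library(cfg, refs, truth, "elves", 0)

    def test_reads_carry_adapter_and_fixed_length(self):
        cfg = SimConfig(n_mirnas=2, reads_per_library=100, seed=5, error_rate=0.0)
        refs, _ = generate_reference(cfg)
        truth = generate_truth(cfg, refs)
        records = simulate_library(cfg, refs, truth, "control", 0)
        assert len(records) == 100
        assert all(len(seq) == 36 and len(q) == 36 for _, seq, q in records)
        matures = {r.mature for r in refs}
        with_insert = sum(any(seq.startswith(m[:15]) for m in matures) for _, seq, _ in records)
        assert with_insert > 90  # most reads start with a planted insert

    def test_isomir_fraction_binomial_recovery(self):
        profile = {"syn-miR-1": (("canonical", 0.5), ("ntadd3:A", 0.5))}
        cfg = SimConfig(
            n_mirnas=1, reads_per_library=10_000, seed=6,
            isomir_profile=profile, error_rate=0.0,
        )
        refs, _ = generate_reference(cfg)
        truth = generate_truth(cfg, refs)
        records = simulate_library(cfg, refs, truth, "control", 0)
        added = refs[0].mature + "A"
        frac = sum(seq.startswith(added) for _, seq, _ in records) / len(records)
        se = math.sqrt(0.25 / 10_000)
        assert abs(frac - 0.5) <= 3 * se

    def test_low_quality_injection(self):
        cfg = SimConfig(n_mirnas=1, reads_per_library=500, seed=8,
                        low_q_fraction=1.0, low_q_count=4)
        refs, _ = generate_reference(cfg)
        truth = generate_truth(cfg, refs)
        records = simulate_library(cfg, refs, truth, "control", 0)
        assert all(q.count("#") == 4 for _, _, q in records)


class TestTruth:
    def test_weights_sum_to_one_and_share_folds_planted(self):
        cfg = SimConfig(
            n_mirnas=50, seed=9,
            de_plan=(("syn-miR-3", "centenarian", 4.0), ("syn-miR-7", "control", 2.0)),
        )
        refs, _ = generate_reference(cfg)
        truth = generate_truth(cfg, refs)
        for g in cfg.group_labels:
            assert truth[f"weight_{g}"].sum() == pytest.approx(1.0, abs=1e-12)
        ratio = truth["weight_centenarian"] / truth["weight_control"]
        assert ratio["syn-miR-3"] == pytest.approx(4.0, rel=1e-9)
        assert ratio["syn-miR-7"] == pytest.approx(0.5, rel=1e-9)
        # non-planted miRNAs share a single uniform compensation factor
        nulls = ratio.drop(["syn-miR-3", "syn-miR-7"])
        assert nulls.std() < 1e-12

    def test_capacity_exceeded_raises(self):
        cfg = SimConfig(
            n_mirnas=2, seed=9, abundance_range=(1e5, 1e6),
            de_plan=(("syn-miR-1", "centenarian", 50.0),),
        )
        refs, _ = generate_reference(cfg)
        with pytest.raises(ValueError, match="capacity"):
            generate_truth(cfg, refs)


class TestIsomirSequence:
    def test_labels_realized_from_precursor(self, let7a_ref):
        assert isomir_sequence(let7a_ref, "canonical") == let7a_ref.mature
        assert isomir_sequence(let7a_ref, "trim3:2") == let7a_ref.mature[:-2]
        assert isomir_sequence(let7a_ref, "ext3:1") == let7a_ref.mature + "C"
        assert isomir_sequence(let7a_ref, "ntadd3:A") == let7a_ref.mature + "A"

    def test_templated_addition_rejected(self, let7a_ref):
        with pytest.raises(ValueError, match="templated"):
            isomir_sequence(let7a_ref, "ntadd3:C")  # precursor continues with C


class TestAgeSeries:
    def test_flat_no_noise_all_equal(self):
        df = simulate_age_series(AgeSeriesConfig(mode="flat", noise_sd=0.0))
        assert df["value"].nunique() == 1

    def test_longevity_means_by_construction(self):
        cfg = AgeSeriesConfig(mode="longevity_associated", effect_size=0.3, noise_sd=0.0)
        df = simulate_age_series(cfg)
        means = df.groupby("age_group", sort=False)["value"].mean()
        assert np.allclose(means[list(cfg.group_labels)], [1.0, 0.7, 0.49, 1.0])

    def test_age_related_strictly_monotone(self):
        cfg = AgeSeriesConfig(mode="age_related", effect_size=0.2, noise_sd=0.0)
        df = simulate_age_series(cfg)
        means = df.groupby("age_group", sort=False)["value"].mean()
        assert (np.diff(means[list(cfg.group_labels)]) > 0).all()

    def test_group_sizes(self):
        cfg = AgeSeriesConfig()
        df = simulate_age_series(cfg)
        sizes = df.groupby("age_group")["sample"].count()
        assert sorted(sizes) == sorted(cfg.n_per_group)

    def test_invalid_mode_rejected(self):
        with pytest.raises(ValueError, match="mode"):
            AgeSeriesConfig(mode="sideways")

    def test_negative_noise_rejected(self):
        with pytest.raises(ValueError, match="noise"):
            AgeSeriesConfig(noise_sd=-0.1)


class TestCountMatrix:
    def test_column_sums_and_determinism(self):
        cfg = SimConfig(n_mirnas=40, reads_per_library=5000, seed=10)
        counts1, groups, _ = simulate_count_matrix(cfg)
        counts2, _, _ = simulate_count_matrix(cfg)
        assert (counts1.sum(axis=0) == 5000).all()
        assert counts1.equals(counts2)
        assert set(groups.values()) == set(cfg.group_labels)
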