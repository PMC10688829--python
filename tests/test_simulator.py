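"""Simulator: truth identity, determinism, error-rate and abundance moments."""

import numpy as np
import pytest

import strainspace as ss
from strainspace.simulate import (
    ReadProfile,
    SimulationConfig,
    Variant,
    apply_variants,
    simulate_population,
    simulate_reads,
)


def reapply_variants_oracle(ref, variants):
    """Independent string-splicing reapplication of a variant table."""
    out = []
    i = 0
    by_pos = {v.pos: v for v in variants}
    while i < len(ref):
        v = by_pos.get(i)
        if v is None:
            out.append(ref[i]); i += 1
        elif v.vtype == "snp":
            out.append(v.alt); i += 1
        elif v.vtype == "del":
            assert ref[i:i + len(v.ref)] == v.ref
            i += len(v.ref)
        else:
            out.append(ref[i] + v.alt); i += 1
    return "".join(out)


class TestSimulatePopulation:
    def test_clone_equals_reference(self):
        cfg = SimulationConfig(genome_length=2000, n_subpops=1,
                               snps_per_subpop=0, indels_per_subpop=0,
                               abundances=[1.0])
        b = simulate_population(cfg, 1)
        assert b.genomes["sp1"] == b.reference

    def test_variant_table_reproduces_genomes(self):
        cfg = SimulationConfig(genome_length=10000, n_subpops=2,
                               snps_per_subpop=60, indels_per_subpop=2,
                               abundances=[0.5, 0.5])
        b = simulate_population(cfg, 2)
        snp_rows = [v for v in b.variants if v.vtype == "snp"]
        assert len(snp_rows) == 120
        for sid in b.subpop_ids:
            mine = [v for v in b.variants if v.subpop_id == sid]
            assert reapply_variants_oracle(b.reference, mine) == b.genomes[sid]

    def test_determinism_and_seed_sensitivity(self):
        cfg = SimulationConfig(genome_length=5000, n_subpops=2,
                               snps_per_subpop=10, indels_per_subpop=1,
                               abundances=[0.6, 0.4])
        a = simulate_population(cfg, 7)
        b = simulate_population(cfg, 7)
        c = simulate_population(cfg, 8)
        assert a.reference == b.reference and a.variants == b.variants
        assert c.variants != a.variants

    def test_explicit_variants(self):
        cfg = SimulationConfig(genome_length=1000, n_subpops=1, abundances=[1.0])
        ins = Variant("", 500, "ins", "", "T")
        b = simulate_population(cfg, 3, explicit_variants=[[ins]])
        assert len(b.genomes["sp1"]) == 1001
        assert b.genomes["sp1"][501] == "T"

    def test_gc_content_respected(self):
        cfg = SimulationConfig(genome_length=50000, gc_content=0.7, n_subpops=1,
                               snps_per_subpop=0, indels_per_subpop=0,
                               abundances=[1.0])
        b = simulate_population(cfg, 4)
        gc = sum(b.reference.count(x) for x in "GC") / len(b.reference)
        assert abs(gc - 0.7) < 0.02


class TestSimulateReads:
    def test_zero_error_reads_are_substrings(self):
        cfg = SimulationConfig(genome_length=3000, n_subpops=1,
                               snps_per_subpop=0, indels_per_subpop=0,
                               abundances=[1.0])
        b = simulate_population(cfg, 5)
        simulate_reads(b, "perfect", 10, 6)
        assert b.reads
        for _, _, seq, _ in b.reads:
            assert seq in b.reference

    def test_true_alignments_replay_the_reads(self):
        """Walking each CIGAR against the reference must reproduce every
        read base that was not substituted or inserted."""
        cfg = SimulationConfig(genome_length=4000, n_subpops=2,
                               snps_per_subpop=10, indels_per_subpop=2,
                               abundances=[0.6, 0.4])
        b = simulate_population(cfg, 9)
        simulate_reads(b, "perfect", 15, 10)
        for aln, (_, sid, seq, _) in zip(b.alignments, b.reads):
            assert aln.read_length_from_cigar() == len(seq)
            # perfect reads from the clone structure must match the genome
            genome = b.genomes[sid]
            assert seq in genome

    def test_substitution_rate_moment(self):
        """Across >= 1e6 simulated bases the substitution count stays
        within four standard deviations of its binomial expectation."""
        cfg = SimulationConfig(genome_length=20000, n_subpops=1,
                               snps_per_subpop=0, indels_per_subpop=0,
                               abundances=[1.0])
        b = simulate_population(cfg, 11)
        profile = ReadProfile("subonly", 0.001, 0.0, 0.0, read_length=150)
        simulate_reads(b, profile, 60, 12)
        total = mismatches = 0
        for aln, (_, _, seq, _) in zip(b.alignments, b.reads):
            start, _ = aln.start, aln.cigar
            assert aln.cigar == [("M", len(seq))]
            ref_seg = b.reference[start:start + len(seq)]
            mismatches += sum(a != r for a, r in zip(seq, ref_seg))
            total += len(seq)
        assert total >= 1_000_000
        expect = total * 0.001
        sd = np.sqrt(total * 0.001 * 0.999)
        assert abs(mismatches - expect) <= 4 * sd

    def test_source_proportions_match_abundances(self):
        cfg = SimulationConfig(genome_length=20000, n_subpops=2,
                               snps_per_subpop=0, indels_per_subpop=0,
                               abundances=[0.7, 0.3])
        b = simulate_population(cfg, 13)
        simulate_reads(b, "perfect", 50, 14)
        n = len(b.reads)
        n_sp1 = sum(1 for r in b.reads if r[1] == "sp1")
        sd = np.sqrt(n * 0.7 * 0.3)
        assert abs(n_sp1 - 0.7 * n) <= 4 * sd

    def test_fixed_seed_byte_identical_outputs(self, tmp_path):
        cfg = SimulationConfig(genome_length=2000, n_subpops=2,
                               snps_per_subpop=5, indels_per_subpop=1,
                               abundances=[0.5, 0.5])
        texts = []
        for run in ("a", "b"):
            bundle = simulate_population(cfg, 21)
            simulate_reads(bundle, "short", 20, 22)
            out = tmp_path / run
            bundle.write(out)
            texts.append((out / "reads.fastq").read_bytes()
                         + (out / "truth.sam").read_bytes())
        assert texts[0] == texts[1]

    def test_depth_and_profile_validation(self):
        cfg = SimulationConfig(genome_length=1000, n_subpops=1,
                               snps_per_subpop=0, indels_per_subpop=0,
                               abundances=[1.0])
        b = simulate_population(cfg, 1)
        with pytest.raises(ValueError):
            simulate_reads(b, "short", 0, 2)
        with pytest.raises(KeyError):
            simulate_reads(b, "unknown_profile", 10, 2)

    def test_long_read_error_rate_total(self):
        """Raw long reads carry ~10% total error (indel-dominant)."""
        import edlib

        cfg = SimulationConfig(genome_length=30000, n_subpops=1,
                               snps_per_subpop=0, indels_per_subpop=0,
                               abundances=[1.0])
        b = simulate_population(cfg, 31)
        simulate_reads(b, "long_raw", 10, 32)
        edits = bases = 0
        for aln, (_, _, seq, _) in zip(b.alignments, b.reads):
            s, e = aln.reference_span()
            r = edlib.align(seq, b.reference[s:e], task="distance")
            edits += r["editDistance"]
            bases += len(seq)
        assert bases > 100_000
        assert 0.08 < edits / bases < 0.12


def test_sam_round_trip_matches_in_memory_alignments(tmp_path):
    from strainspace.pileup import build_counts, build_counts_from_sam

    cfg = SimulationConfig(genome_length=3000, n_subpops=2,
                           snps_per_subpop=8, indels_per_subpop=1,
                           abundances=[0.7, 0.3])
    b = simulate_population(cfg, 17)
    simulate_reads(b, "short", 25, 18)
    b.write(tmp_path)
    direct = build_counts(b.alignments, b.reference)
    via_sam = build_counts_from_sam(tmp_path / "truth.sam", b.reference)
    assert direct == via_sam
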