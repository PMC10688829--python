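"""Phasing: read profiles, greedy clustering, frequency linkage, FASTM build."""

import numpy as np
import pytest

import strainspace as ss
from strainspace.model import GAP, GappedCoordinate, SubpopulationSet
from strainspace.phasing import (
    ReadVariantProfile,
    SubpopCluster,
    build_fastm,
    cluster_reads,
    extract_read_profiles,
    link_by_frequency,
    variant_components,
)
from strainspace.pileup import AlignmentRecord, CountsTable, counts_to_fastv

C = GappedCoordinate
A, Cb, T, G = 0, 1, 2, 3


def profile(read_id, alleles):
    return ReadVariantProfile(read_id, {C(p): b for p, b in alleles.items()})


def two_strain_profiles(n_major=14, n_minor=6):
    """Fully separable fixture: sites 10 and 20, strain-specific alleles,
    every read covering both (linked) sites."""
    out = []
    for i in range(n_major):
        out.append(profile(f"maj{i:02d}", {10: A, 20: Cb}))
    for i in range(n_minor):
        out.append(profile(f"min{i:02d}", {10: T, 20: G}))
    return out


class TestExtractReadProfiles:
    REF = "ACGTACGTACGTACGTACGT"

    def test_read_without_variant_site_has_no_profile(self):
        alns = [AlignmentRecord("r1", "ref", 0, [("M", 5)], "ACGTA")]
        assert extract_read_profiles(alns, [C(10)]) == []

    def test_observed_states_at_sites(self):
        alns = [AlignmentRecord("r1", "ref", 8, [("M", 8)], "ACCTACGT")]
        profs = extract_read_profiles(alns, [C(10), C(12)])
        assert profs[0].alleles == {C(10): Cb, C(12): A}

    def test_deletion_records_gap_state(self):
        alns = [AlignmentRecord("r1", "ref", 8, [("M", 2), ("D", 2), ("M", 2)],
                                "ACAC")]
        profs = extract_read_profiles(alns, [C(10)])
        assert profs[0].alleles == {C(10): GAP}

    def test_insertion_sites_and_spanning_gap(self):
        ins_site = C(9, 1)
        with_ins = AlignmentRecord("r1", "ref", 8, [("M", 2), ("I", 1), ("M", 2)],
                                   "ACTGT")
        without = AlignmentRecord("r2", "ref", 8, [("M", 4)], "ACGT")
        profs = extract_read_profiles([with_ins, without], [ins_site])
        states = {p.read_id: p.alleles[ins_site] for p in profs}
        assert states == {"r1": T, "r2": GAP}

    def test_error_states_become_missing(self):
        alns = [AlignmentRecord("r1", "ref", 8, [("M", 8)], "ACCTACGT")]
        profs = extract_read_profiles(alns, [C(10), C(12)],
                                      error_states={(C(10), Cb)})
        assert profs[0].alleles == {C(12): A}

    def test_truth_profiles_match_source_genomes(self):
        """Error-free reads carry exactly their genome's alleles at every
        covered variant site."""
        cfg = ss.SimulationConfig(genome_length=4000, n_subpops=2,
                                  snps_per_subpop=12, indels_per_subpop=0,
                                  abundances=[0.6, 0.4])
        b = ss.simulate_population(cfg, 19)
        ss.simulate_reads(b, "perfect", 25, 20)
        sites = [C(v.pos) for v in b.variants]
        truth = {}
        for v in b.variants:
            truth[(v.subpop_id, v.pos)] = "ACTG-".index(v.alt)
            other = [s for s in b.subpop_ids if s != v.subpop_id][0]
            truth[(other, v.pos)] = "ACTG-".index(v.ref)
        by_read = {r[0]: r[1] for r in b.reads}
        for prof in extract_read_profiles(b.alignments, sites):
            sid = by_read[prof.read_id]
            for coord, state in prof.alleles.items():
                assert state == truth[(sid, coord.ref_pos)]


class TestClusterReads:
    def test_fully_separable_two_strains(self):
        clusters = cluster_reads(two_strain_profiles(), tau=0.1, m_min=2)
        assert len(clusters) == 2
        assert clusters[0].abundance == pytest.approx(0.7)
        assert clusters[1].abundance == pytest.approx(0.3)
        assert clusters[0].consensus == {C(10): A, C(20): Cb}

    def test_noisy_read_joins_majority_cluster(self):
        # ten linked sites; the noisy read flips a single allele and stays
        # within the tau = 0.1 mismatch tolerance of its home cluster
        profs = []
        for i in range(14):
            profs.append(profile(f"maj{i:02d}", {p: A for p in range(10)}))
        for i in range(6):
            profs.append(profile(f"min{i:02d}", {p: T for p in range(10)}))
        noisy_alleles = {p: A for p in range(10)}
        noisy_alleles[4] = G
        profs.append(profile("noisy", noisy_alleles))
        clusters = cluster_reads(profs, tau=0.1, m_min=2)
        assert len(clusters) == 2
        major = max(clusters, key=lambda c: c.n_reads)
        assert "noisy" in major.read_ids
        assert major.consensus[C(4)] == A

    def test_empty_profiles_rejected(self):
        with pytest.raises(ValueError):
            cluster_reads([])

    def test_weak_clusters_dissolved(self):
        profs = two_strain_profiles(n_major=20, n_minor=1)
        clusters = cluster_reads(profs, m_min=5, a_min=0.01)
        assert len(clusters) == 1
        assert clusters[0].abundance == 1.0

    def test_determinism(self):
        profs = two_strain_profiles()
        a = cluster_reads(profs)
        b = cluster_reads(list(reversed(profs)))
        assert [c.read_ids for c in a] == [c.read_ids for c in b]

    def test_three_strain_linked_simulation(self):
        """Three strains at 0.5/0.3/0.2 with 60 densely linked SNPs (each
        read spans discriminating sites of several strains) and deep
        short-read coverage separate into three clusters with abundance
        error at most 0.05."""
        cfg = ss.SimulationConfig(genome_length=900, n_subpops=3,
                                  snps_per_subpop=20, indels_per_subpop=0,
                                  abundances=[0.5, 0.3, 0.2], mean_depth=100,
                                  edge_margin=20)
        b = ss.simulate_population(cfg, 42)
        ss.simulate_reads(b, "short", 100, 43)
        res = ss.run_pipeline(b.alignments, b.reference, record_id="three")
        assert len(res.fastm.subpops) == 3
        for (sid, est), truth in zip(res.fastm.subpops, [0.5, 0.3, 0.2]):
            assert abs(est - truth) <= 0.05


class TestVariantComponents:
    def test_co_covered_sites_share_component(self):
        profs = [profile("a", {1: A, 2: Cb}), profile("b", {2: Cb, 3: T}),
                 profile("c", {9: G})]
        comp = variant_components(profs)
        assert comp[C(1)] == comp[C(2)] == comp[C(3)]
        assert comp[C(9)] != comp[C(1)]


def make_cluster(cid, comp, abundance, sites=(), alleles=A, n=100):
    return SubpopCluster(cluster_id=cid, read_ids=[f"{cid}_{i}" for i in range(n)],
                         consensus={C(p): alleles for p in sites},
                         abundance=abundance, component_id=comp)


class TestLinkByFrequency:
    def test_single_component_identity(self):
        clusters = [make_cluster("c1", 0, 0.7, sites=[5], alleles=A),
                    make_cluster("c2", 0, 0.3, sites=[5], alleles=T)]
        link = link_by_frequency(clusters)
        assert link.assignment == {"c1": "P1", "c2": "P2"}
        assert [round(a, 6) for _, a in link.subpops] == [0.7, 0.3]
        assert link.warnings == []

    def test_two_components_merge_by_frequency(self):
        clusters = [make_cluster("c1", 0, 0.7, sites=[5]),
                    make_cluster("c2", 0, 0.3, sites=[5], alleles=T),
                    make_cluster("c3", 1, 0.72, sites=[50]),
                    make_cluster("c4", 1, 0.28, sites=[50], alleles=T)]
        link = link_by_frequency(clusters, delta=0.05)
        assert len(link.subpops) == 2
        assert link.assignment["c1"] == link.assignment["c3"] == "P1"
        assert link.assignment["c2"] == link.assignment["c4"] == "P2"

    def test_equal_abundances_flagged_ambiguous(self):
        clusters = [make_cluster("c1", 0, 0.5, sites=[5]),
                    make_cluster("c2", 0, 0.5, sites=[5], alleles=T),
                    make_cluster("c3", 1, 0.5, sites=[50]),
                    make_cluster("c4", 1, 0.5, sites=[50], alleles=T)]
        link = link_by_frequency(clusters, delta=0.05)
        assert len(link.subpops) == 4          # kept separate
        assert link.warnings and "ambiguous" in link.warnings[0]

    def test_lone_component_clusters_are_uninformative(self):
        clusters = [make_cluster("c1", 0, 0.7, sites=[5]),
                    make_cluster("c2", 0, 0.3, sites=[5], alleles=T),
                    make_cluster("c3", 1, 1.0, sites=[50])]
        link = link_by_frequency(clusters)
        assert len(link.subpops) == 2
        assert "c3" not in link.assignment


class TestBuildFastm:
    def test_single_cluster_rows_equal_cleaned_columns(self):
        counts = CountsTable("ref", 3)
        counts.ref_counts[:] = [[10, 0, 0, 0, 0], [7, 3, 0, 0, 0], [0, 0, 0, 0, 0]]
        subpops = SubpopulationSet([("P1", 1.0)])
        rec = build_fastm([], counts, subpops, "x", profiles=[], assignment={})
        fv = counts_to_fastv(counts, "x")
        for (_, mat), (_, dist) in zip(rec.columns, fv.columns):
            assert mat.rows["P1"] == pytest.approx(dist.freqs)

    def test_fixed_snp_matrix(self):
        counts = CountsTable("ref", 1)
        counts.ref_counts[0] = [70, 30, 0, 0, 0]
        profs = ([profile(f"a{i}", {0: A}) for i in range(70)]
                 + [profile(f"b{i}", {0: Cb}) for i in range(30)])
        clusters = cluster_reads(profs, m_min=2)
        link = link_by_frequency(clusters)
        rec = build_fastm(clusters, counts, link.subpops, "x",
                          profiles=profs, assignment=link.assignment)
        mat = rec.columns[0][1]
        assert mat.rows["P1"] == pytest.approx((0.7, 0, 0, 0, 0))
        assert mat.rows["P2"] == pytest.approx((0, 0.3, 0, 0, 0))

    def test_marginalization_identity_on_pipeline(self, two_strain_result):
        from strainspace.model import marginalize_fastm

        res = two_strain_result
        fv = counts_to_fastv(res.cleaned_counts, res.fastm.id)
        mg = marginalize_fastm(res.fastm, validate=False)
        for (c1, d1), (c2, d2) in zip(mg.columns, fv.columns):
            assert c1 == c2
            assert max(abs(x - y) for x, y in zip(d1.freqs, d2.freqs)) <= 1e-6
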