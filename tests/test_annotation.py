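"""ORF calling, gene-model comparison, locus tags, GenBank output."""

import io

import numpy as np
import pytest
from Bio import SeqIO
from Bio.Seq import Seq

from strainspace.annotate import (
    AnnotationError,
    LocusFeature,
    OrfModel,
    annotate_record,
    assign_locus_tags,
    call_orfs,
    compare_gene_models,
    write_genbank_like,
)
from strainspace.model import (
    FastmPositionMatrix,
    FastmRecord,
    GappedCoordinate,
    SubpopulationSet,
)

STARTS = {"ATG", "GTG", "TTG"}
STOPS = {"TAA", "TAG", "TGA"}


def orfs_by_brute_force(seq, min_len):
    """Independent six-frame scan using Biopython reverse complements."""
    found = set()
    L = len(seq)
    for strand in ("+", "-"):
        s = seq if strand == "+" else str(Seq(seq).reverse_complement())
        for frame in range(3):
            codons = [s[i:i + 3] for i in range(frame, L - 2, 3)]
            start_idx = None
            for ci, codon in enumerate(codons):
                if codon in STOPS:
                    if start_idx is not None:
                        a = frame + 3 * start_idx
                        b = frame + 3 * ci + 3
                        if b - a >= min_len:
                            if strand == "+":
                                found.add((a + 1, b, "+"))
                            else:
                                found.add((L - b + 1, L - a, "-"))
                    start_idx = None
                elif start_idx is None and codon in STARTS:
                    start_idx = ci
    return found


class TestCallOrfs:
    def test_minimal_orf(self):
        orfs = call_orfs("ATGAAATAA", 9)
        assert [(o.start, o.stop, o.strand) for o in orfs] == [(1, 9, "+")]
        assert orfs[0].sequence == "ATGAAATAA"

    def test_no_stop_no_orf(self):
        assert call_orfs("ATG" + "AAA" * 50, 9) == []

    def test_reverse_strand_coordinates(self):
        seq = str(Seq("ATGAAATAA").reverse_complement())
        orfs = call_orfs(seq, 9)
        assert [(o.start, o.stop, o.strand) for o in orfs] == [(1, 9, "-")]

    def test_matches_brute_force_on_random_sequence(self):
        rng = np.random.default_rng(23)
        seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 10000))
        mine = {(o.start, o.stop, o.strand) for o in call_orfs(seq, 90)}
        assert mine == orfs_by_brute_force(seq, 90)

    def test_min_len_validation(self):
        with pytest.raises(ValueError):
            call_orfs("ATGTAA", 10)


def degenerate_fastm(sequences: dict[str, str], abundances: dict[str, float]):
    """A FASTM record whose rows pin each sub-population to a sequence.

    All sequences must be equal length (no indels): the gapped coordinates
    are then the plain reference coordinates.
    """
    (length,) = {len(s) for s in sequences.values()}
    subpops = SubpopulationSet(list(abundances.items()))
    columns = []
    for i in range(length):
        rows = {}
        for sid, seq in sequences.items():
            row = [0.0] * 5
            row["ACTG-".index(seq[i])] = abundances[sid]
            rows[sid] = tuple(row)
        columns.append((GappedCoordinate(i), FastmPositionMatrix(rows)))
    return FastmRecord("fixture", subpops, columns)


FILLER = "AAC" * 15          # no start/stop codon in any frame or strand


def build_fig_like_scenario():
    """Four sub-populations, one conserved ORF, and premature-stop model
    changes in the second and fourth sub-population."""
    orf1 = "ATG" + "GAA" * 31 + "TAA"                 # 99 nt, conserved
    orf2 = "ATG" + "GAA" * 48 + "TAA"                 # 150 nt
    base = FILLER + orf1 + FILLER + orf2 + FILLER
    seqs = {"P1": base, "P3": base}
    # P3 carries a synonymous change inside orf1 (GAA -> GAG): the gene
    # model is untouched
    p3 = list(base)
    p3[len(FILLER) + 3 + 5 * 3 + 2] = "G"
    seqs["P3"] = "".join(p3)
    # premature stops inside orf2 at different codons for P2 and P4
    for sid, codon_idx in (("P2", 40), ("P4", 45)):
        s = list(base)
        pos = len(FILLER) + len(orf1) + len(FILLER) + 3 * codon_idx
        s[pos:pos + 3] = "TAA"
        seqs[sid] = "".join(s)
    abundances = {"P1": 0.4, "P2": 0.3, "P3": 0.2, "P4": 0.1}
    return degenerate_fastm(seqs, abundances), len(FILLER), orf1, orf2


class TestCompareGeneModels:
    def test_synonymous_change_keeps_one_group(self):
        rec, offset, orf1, _ = build_fig_like_scenario()
        text, features = annotate_record(rec, min_orf_len=90)
        conserved = [f for f in features
                     if f.start == offset + 1 and f.stop == offset + len(orf1)]
        assert {f.appendix for f in conserved} == {"_P1", "_P2", "_P3", "_P4"}
        assert len({f.base_tag for f in conserved}) == 1

    def test_premature_stops_issue_new_tags(self):
        rec, offset, orf1, orf2 = build_fig_like_scenario()
        _, features = annotate_record(rec, min_orf_len=90)
        orf2_start = offset + len(orf1) + offset + 1
        groups = {}
        for f in features:
            if f.start == orf2_start:
                groups.setdefault((f.start, f.stop), set()).add(f.appendix)
        # full-length model shared by P1 and P3; each truncation its own
        assert groups[(orf2_start, orf2_start + 149)] == {"_P1", "_P3"}
        assert groups[(orf2_start, orf2_start + 122)] == {"_P2"}
        assert groups[(orf2_start, orf2_start + 137)] == {"_P4"}

    def test_single_subpop_every_orf_own_group(self):
        orfs = {"P1": [(OrfModel("P1", 1, 9, "+", "ATGAAATAA"),
                        GappedCoordinate(0), GappedCoordinate(8)),
                       (OrfModel("P1", 20, 28, "+", "ATGCCCTAA"),
                        GappedCoordinate(19), GappedCoordinate(27))]}
        groups = compare_gene_models(orfs)
        assert len(groups) == 2


class TestAssignLocusTags:
    def make_subpops(self):
        return SubpopulationSet([("P1", 0.7), ("P3", 0.2), ("P2", 0.1)])

    def test_shared_group_appendices_and_frequencies(self):
        subpops = self.make_subpops()
        groups = [{"start": GappedCoordinate(10), "stop": GappedCoordinate(100),
                   "strand": "+",
                   "orfs": {"P1": OrfModel("P1", 11, 101, "+", "ATG" + "A" * 84 + "TAA"),
                            "P3": OrfModel("P3", 11, 101, "+", "ATG" + "A" * 84 + "TAA")}}]
        features = assign_locus_tags(groups, subpops)
        tags = {f.locus_tag: f.frequency for f in features}
        assert tags == {"LT_000010_P1": 0.7, "LT_000010_P2": 0.2}
        # P3 has rank 2 by abundance, hence appendix _P2

    def test_tags_step_by_ten_and_are_stable(self):
        subpops = self.make_subpops()
        orf = OrfModel("P1", 1, 9, "+", "ATGAAATAA")
        groups = [{"start": GappedCoordinate(i * 50), "stop": GappedCoordinate(i * 50 + 8),
                   "strand": "+", "orfs": {"P1": orf}} for i in range(3)]
        a = assign_locus_tags(groups, subpops)
        b = assign_locus_tags(groups, subpops)
        assert [f.base_tag for f in a] == ["LT_000010", "LT_000020", "LT_000030"]
        assert a == b

    def test_empty_groups(self):
        assert assign_locus_tags([], self.make_subpops()) == []


class TestWriteGenbankLike:
    def test_single_feature_qualifiers(self):
        subpops = SubpopulationSet([("P1", 1.0)])
        feat = LocusFeature("LT_000010", "_P1", 1.0, 4, 12, "+", "P1")
        text = write_genbank_like("AAC" + "ATGAAATAA" + "AAC", [feat], subpops)
        assert text.count("     CDS ") == 1
        assert '/locus_tag="LT_000010_P1"' in text
        assert '/frequency="1.0000"' in text
        assert '/note="subpopulation=P1"' in text

    def test_parse_back_with_standard_parser(self):
        rec, *_ = build_fig_like_scenario()
        text, features = annotate_record(rec, min_orf_len=90)
        parsed = SeqIO.read(io.StringIO(text), "genbank")
        cds = [f for f in parsed.features if f.type == "CDS"]
        assert len(cds) == len(features)
        starts = sorted(int(f.location.start) + 1 for f in cds)
        assert starts == sorted(f.start for f in features)

    def test_out_of_range_feature_rejected(self):
        subpops = SubpopulationSet([("P1", 1.0)])
        feat = LocusFeature("LT_000010", "_P1", 1.0, 1, 99, "+", "P1")
        with pytest.raises(AnnotationError):
            write_genbank_like("ACGT", [feat], subpops)

    def test_base_tag_frequencies_sum_at_most_one(self):
        rec, *_ = build_fig_like_scenario()
        _, features = annotate_record(rec, min_orf_len=90)
        totals = {}
        for f in features:
            totals[f.base_tag] = totals.get(f.base_tag, 0.0) + f.frequency
        assert all(t <= 1.0 + 1e-9 for t in totals.values())
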