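"""Synthetic multi-sub-population genomes, reads, and truth alignments.

The simulator is the ground-truth generator for the whole pipeline: it
creates a random reference replicon, derives K sub-population genomes from
it as independent single-step variants of one ancestor (a star phylogeny —
the static-snapshot model of a strain genome space in which sub-populations
differ from the consensus by SNPs and small indels), draws reads from the
mixture at configured abundances with technology-specific error profiles,
and emits *true* alignments computed from the known edit scripts, so no
external aligner is needed downstream.

Read error profiles are anchored to published platform characteristics:

* ``short``    — Illumina-like 150 nt reads; substitutions 1e-3 per base,
  indels negligible (1e-5).
* ``long_raw`` — raw long reads (Nanopore/PacBio-like), lognormal lengths
  around 8 kb; ~10% total error dominated by indels
  (substitution 0.02, insertion 0.04, deletion 0.04).
* ``long_corrected`` — error-corrected long reads at ~3% total error in
  the same proportions.

Everything is deterministic under a fixed seed.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .formats import write_fasta, write_fastq
from .pileup import AlignmentRecord

_BASES = "ACGT"
_BASE_TO_I = {b: i for i, b in enumerate(_BASES)}


class SimulationError(ValueError):
    pass


@dataclass(frozen=True)
class Variant:
    """One truth variant of a sub-population genome against the reference.

    ``pos`` is 0-based.  For a SNP, ``ref`` is the reference base and
    ``alt`` the substituted base.  For an insertion, ``alt`` is the
    inserted sequence placed *after* the anchor base at ``pos`` (``ref`` is
    that anchor base).  For a deletion, ``ref`` is the deleted reference
    segment starting at ``pos`` and ``alt`` is empty.
    """

    subpop_id: str
    pos: int
    vtype: str          # snp | ins | del
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.vtype not in ("snp", "ins", "del"):
            raise ValueError(f"unknown variant type {self.vtype!r}")


@dataclass(frozen=True)
class ReadProfile:
    """Per-technology read length and error configuration."""

    name: str
    substitution: float
    insertion: float
    deletion: float
    read_length: int = 150              # fixed length for short reads
    lognormal_mean: Optional[float] = None  # mean length for long reads
    lognormal_sigma: float = 0.5
    qual_char: str = "?"                # constant Phred quality (Q30 = '?')

    @property
    def mean_length(self) -> float:
        return self.lognormal_mean if self.lognormal_mean else float(self.read_length)

    @classmethod
    def preset(cls, name: str) -> "ReadProfile":
        try:
            return _READ_PRESETS[name]
        except KeyError:
            raise KeyError(f"unknown read profile {name!r}; "
                           f"available: {sorted(_READ_PRESETS)}") from None


_READ_PRESETS = {
    "short": ReadProfile("short", 0.001, 1e-5, 1e-5, read_length=150, qual_char="?"),
    "long_raw": ReadProfile("long_raw", 0.02, 0.04, 0.04,
                            lognormal_mean=8000.0, qual_char="5"),
    "long_corrected": ReadProfile("long_corrected", 0.006, 0.012, 0.012,
                                  lognormal_mean=8000.0, qual_char="5"),
    "perfect": ReadProfile("perfect", 0.0, 0.0, 0.0, read_length=150, qual_char="I"),
}


@dataclass
class SimulationConfig:
    genome_length: int = 50000
    gc_content: float = 0.5
    n_subpops: int = 2
    snps_per_subpop: Union[int, Sequence[int]] = 30
    indels_per_subpop: Union[int, Sequence[int]] = 2
    indel_size_p: float = 0.5           # geometric size parameter
    indel_max_size: int = 10
    abundances: Optional[Sequence[float]] = None  # None: symmetric Dirichlet
    read_profile: str = "short"
    mean_depth: float = 100.0
    edge_margin: int = 50               # keep variants clear of replicon ends

    def per_subpop(self, value: Union[int, Sequence[int]]) -> list[int]:
        if isinstance(value, (int, np.integer)):
            return [int(value)] * self.n_subpops
        out = [int(v) for v in value]
        if len(out) != self.n_subpops:
            raise SimulationError(
                f"per-sub-population counts {out} do not match K={self.n_subpops}")
        return out

    def resolved_abundances(self, rng: np.random.Generator) -> np.ndarray:
        if self.abundances is None:
            ab = rng.dirichlet(np.ones(self.n_subpops))
        else:
            ab = np.asarray(self.abundances, dtype=float)
            if len(ab) != self.n_subpops:
                raise SimulationError("abundances do not match n_subpops")
            if abs(ab.sum() - 1.0) > 1e-6 or (ab <= 0).any():
                raise SimulationError("abundances must be positive and sum to 1")
        return ab


@dataclass
class TruthBundle:
    """Simulator output: everything needed to grade the pipeline."""

    ref_id: str
    reference: str
    subpop_ids: list[str]
    genomes: dict[str, str]
    refmaps: dict[str, np.ndarray]      # genome index -> ref index (-1: inserted)
    variants: list[Variant]
    abundances: dict[str, float]
    config: SimulationConfig
    reads: list[tuple[str, str, str, str]] = field(default_factory=list)
    # (read_id, subpop_id, seq, qual)
    alignments: list[AlignmentRecord] = field(default_factory=list)
    profile: Optional[ReadProfile] = None

    def variants_dataframe(self) -> pd.DataFrame:
        rows = [(v.subpop_id, v.pos + 1, v.vtype, v.ref, v.alt)
                for v in self.variants]
        return pd.DataFrame(rows, columns=["subpop", "ref_pos", "type", "ref", "alt"])

    def write(self, outdir: Union[str, Path]) -> None:
        """Write ref.fasta, subpop FASTAs, variants.tsv, abundances.json,
        reads.fastq and truth.sam into ``outdir``."""
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        write_fasta([(self.ref_id, self.reference)], out / "ref.fasta")
        for sid in self.subpop_ids:
            write_fasta([(sid, self.genomes[sid])], out / f"subpop_{sid}.fasta")
        self.variants_dataframe().to_csv(out / "variants.tsv", sep="\t", index=False)
        with open(out / "abundances.json", "w") as handle:
            json.dump(self.abundances, handle, indent=2, sort_keys=True)
            handle.write("\n")
        write_fastq([(r[0], r[2], r[3]) for r in self.reads], out / "reads.fastq")
        write_truth_sam(self, out / "truth.sam")


def write_truth_sam(bundle: TruthBundle, path: Union[str, Path]) -> None:
    import pysam

    header = {"HD": {"VN": "1.6", "SO": "unsorted"},
              "SQ": [{"SN": bundle.ref_id, "LN": len(bundle.reference)}]}
    with pysam.AlignmentFile(str(path), "wh", header=header) as handle:
        for aln, read in zip(bundle.alignments, bundle.reads):
            seg = pysam.AlignedSegment(handle.header)
            seg.query_name = aln.read_id
            seg.flag = 0
            seg.reference_id = 0
            seg.reference_start = aln.start
            seg.mapping_quality = aln.mapq
            seg.cigarstring = aln.cigar_string()
            seg.query_sequence = aln.seq
            seg.query_qualities = pysam.qualitystring_to_array(read[3])
            handle.write(seg)


# ---------------------------------------------------------------------------
# population simulation
# ---------------------------------------------------------------------------

def _random_reference(length: int, gc: float, rng: np.random.Generator) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])  # A C G T
    idx = rng.choice(4, size=length, p=p)
    return "".join(_BASES[i] for i in idx)


def _place_variants(
    ref: str,
    subpop_id: str,
    n_snps: int,
    n_indels: int,
    config: SimulationConfig,
    blocked: set[int],
    rng: np.random.Generator,
) -> list[Variant]:
    L = len(ref)
    lo, hi = config.edge_margin, L - config.edge_margin
    if hi - lo < 4 * (n_snps + n_indels * (config.indel_max_size + 2)):
        raise SimulationError("variant density infeasible for the genome length")
    out: list[Variant] = []

    def claim(a: int, b: int) -> bool:
        span = range(max(a, 0), min(b, L))
        if any(p in blocked for p in span):
            return False
        blocked.update(span)
        return True

    for _ in range(n_indels):
        for _attempt in range(1000):
            pos = int(rng.integers(lo, hi))
            size = min(int(rng.geometric(config.indel_size_p)), config.indel_max_size)
            is_ins = bool(rng.integers(2))
            a, b = (pos - 1, pos + 2) if is_ins else (pos - 1, pos + size + 1)
            if not claim(a, b):
                continue
            if is_ins:
                ins_seq = "".join(_BASES[i] for i in rng.integers(0, 4, size))
                out.append(Variant(subpop_id, pos, "ins", ref[pos], ins_seq))
            else:
                out.append(Variant(subpop_id, pos, "del", ref[pos:pos + size], ""))
            break
        else:
            raise SimulationError("could not place indel after 1000 attempts")

    for _ in range(n_snps):
        for _attempt in range(1000):
            pos = int(rng.integers(lo, hi))
            if not claim(pos - 1, pos + 2):
                continue
            alts = [b for b in _BASES if b != ref[pos]]
            alt = alts[int(rng.integers(3))]
            out.append(Variant(subpop_id, pos, "snp", ref[pos], alt))
            break
        else:
            raise SimulationError("could not place SNP after 1000 attempts")
    return sorted(out, key=lambda v: v.pos)


def apply_variants(ref: str, variants: Sequence[Variant]) -> tuple[str, np.ndarray]:
    """Apply a sorted variant list to the reference.

    Returns the derived genome and its *refmap*: for every genome position
    the 0-based reference position it descends from, or -1 for inserted
    bases.
    """
    by_pos = {v.pos: v for v in variants}
    if len(by_pos) != len(variants):
        raise SimulationError("variants collide at a position")
    seq: list[str] = []
    rmap: list[int] = []
    i = 0
    L = len(ref)
    while i < L:
        v = by_pos.get(i)
        if v is None:
            seq.append(ref[i]); rmap.append(i); i += 1
        elif v.vtype == "snp":
            seq.append(v.alt); rmap.append(i); i += 1
        elif v.vtype == "del":
            i += len(v.ref)
        else:  # ins: anchor base, then the inserted run
            seq.append(ref[i]); rmap.append(i)
            seq.extend(v.alt); rmap.extend([-1] * len(v.alt))
            i += 1
    return "".join(seq), np.asarray(rmap, dtype=np.int64)


def simulate_population(
    config: SimulationConfig,
    seed: int,
    *,
    explicit_variants: Optional[Sequence[Sequence[Variant]]] = None,
    ref_id: str = "ref",
) -> TruthBundle:
    """Generate the reference, sub-population genomes and truth variants.

    ``explicit_variants`` (one list per sub-population, ``subpop_id``
    ignored and rewritten) overrides random variant placement — used to
    plant specific scenarios.
    """
    rng = np.random.default_rng(seed)
    ref = _random_reference(config.genome_length, config.gc_content, rng)
    abundances = config.resolved_abundances(rng)
    subpop_ids = [f"sp{i + 1}" for i in range(config.n_subpops)]
    snps = config.per_subpop(config.snps_per_subpop)
    indels = config.per_subpop(config.indels_per_subpop)

    blocked: set[int] = set()
    genomes: dict[str, str] = {}
    refmaps: dict[str, np.ndarray] = {}
    all_variants: list[Variant] = []
    for i, sid in enumerate(subpop_ids):
        if explicit_variants is not None:
            variants = sorted((replace(v, subpop_id=sid)
                               for v in explicit_variants[i]), key=lambda v: v.pos)
        else:
            variants = _place_variants(ref, sid, snps[i], indels[i], config,
                                       blocked, rng)
        genome, rmap = apply_variants(ref, variants)
        genomes[sid], refmaps[sid] = genome, rmap
        all_variants.extend(variants)

    return TruthBundle(
        ref_id=ref_id,
        reference=ref,
        subpop_ids=subpop_ids,
        genomes=genomes,
        refmaps=refmaps,
        variants=sorted(all_variants, key=lambda v: (v.pos, v.subpop_id)),
        abundances={sid: float(a) for sid, a in zip(subpop_ids, abundances)},
        config=config,
    )


# ---------------------------------------------------------------------------
# read simulation
# ---------------------------------------------------------------------------

def _cigar_from_rmap(rmap_seg: np.ndarray) -> tuple[int, list[tuple[str, int]]]:
    """Alignment start and CIGAR of a genome segment against the reference.

    Leading/trailing inserted runs become soft clips.
    """
    ops: list[tuple[str, int]] = []
    prev = None
    start = -1
    for r in rmap_seg:
        r = int(r)
        if r < 0:
            ops.append(("I", 1))
        else:
            if prev is not None and r > prev + 1:
                ops.append(("D", r - prev - 1))
            if start < 0:
                start = r
            ops.append(("M", 1))
            prev = r
    return start, _compress_ops(ops)


def _compress_ops(ops: list[tuple[str, int]]) -> list[tuple[str, int]]:
    merged: list[tuple[str, int]] = []
    for op, l in ops:
        if l <= 0:
            continue
        if merged and merged[-1][0] == op:
            merged[-1] = (op, merged[-1][1] + l)
        else:
            merged.append((op, l))
    # unanchored runs at the ends: inserted bases soft-clip, deletions vanish
    lead_s = 0
    i = 0
    while i < len(merged) and merged[i][0] in ("I", "D", "S"):
        if merged[i][0] != "D":
            lead_s += merged[i][1]
        i += 1
    core = merged[i:]
    tail_s = 0
    while core and core[-1][0] in ("I", "D", "S"):
        op, l = core.pop()
        if op != "D":
            tail_s += l
    out = ([("S", lead_s)] if lead_s else []) + core
    if tail_s:
        out.append(("S", tail_s))
    return out


def _mutate_bases(seq: np.ndarray, positions: np.ndarray,
                  rng: np.random.Generator) -> None:
    # replace each position with a uniformly chosen different base
    shift = rng.integers(1, 4, size=positions.size)
    seq[positions] = (seq[positions] + shift) % 4


def simulate_reads(
    bundle: TruthBundle,
    profile: Union[str, ReadProfile],
    mean_depth: float,
    seed: int,
    *,
    min_read_length: int = 30,
) -> TruthBundle:
    """Draw reads from the mixture and record their true alignments.

    Source genomes are drawn by abundance; start positions are uniform with
    overhang at the replicon edges (overhanging reads are truncated, so
    expected coverage is flat across the replicon).  Fills
    ``bundle.reads`` and ``bundle.alignments`` in place and returns the
    bundle.
    """
    if mean_depth <= 0:
        raise SimulationError("mean depth must be positive")
    prof = ReadProfile.preset(profile) if isinstance(profile, str) else profile
    rng = np.random.default_rng(seed)
    ref_len = len(bundle.reference)
    n_reads = max(1, int(round(mean_depth * ref_len / prof.mean_length)))
    ab = np.array([bundle.abundances[s] for s in bundle.subpop_ids])
    sources = rng.choice(len(bundle.subpop_ids), size=n_reads, p=ab)

    bundle.reads = []
    bundle.alignments = []
    bundle.profile = prof
    for i in range(n_reads):
        sid = bundle.subpop_ids[int(sources[i])]
        genome = bundle.genomes[sid]
        rmap = bundle.refmaps[sid]
        Lg = len(genome)
        if prof.lognormal_mean:
            mu = math.log(prof.lognormal_mean) - prof.lognormal_sigma ** 2 / 2.0
            rl = int(rng.lognormal(mu, prof.lognormal_sigma))
            rl = max(min_read_length, min(rl, Lg))
        else:
            rl = min(prof.read_length, Lg)
        lo = -(rl - min_read_length)
        hi = Lg - min_read_length
        s0 = int(rng.integers(lo, hi + 1)) if hi >= lo else 0
        a, b = max(0, s0), min(Lg, s0 + rl)
        codes = np.array([_BASE_TO_I[c] for c in genome[a:b]], dtype=np.int64)
        seg_rmap = rmap[a:b]
        length = b - a

        n_sub = int(rng.binomial(length, prof.substitution)) if prof.substitution else 0
        n_ins = int(rng.binomial(length, prof.insertion)) if prof.insertion else 0
        n_del = int(rng.binomial(length, prof.deletion)) if prof.deletion else 0

        if n_ins == 0 and n_del == 0:
            if n_sub:
                pos = rng.choice(length, size=n_sub, replace=False)
                _mutate_bases(codes, pos, rng)
            seq = "".join(_BASES[c] for c in codes)
            if seg_rmap[0] >= 0 and int(seg_rmap[-1] - seg_rmap[0]) == length - 1 \
                    and (seg_rmap >= 0).all():
                start, cigar = int(seg_rmap[0]), [("M", length)]
            else:
                start, cigar = _cigar_from_rmap(seg_rmap)
        else:
            cols = _build_cols(codes, seg_rmap)
            _edit_cols(cols, n_sub, n_ins, n_del, rng)
            start, cigar, seq = _cols_to_alignment(cols)
        if start < 0 or not any(op == "M" for op, _ in cigar):
            continue  # read retains no aligned base
        read_id = f"r{i:06d}|{sid}"
        qual = prof.qual_char * len(seq)
        bundle.reads.append((read_id, sid, seq, qual))
        bundle.alignments.append(AlignmentRecord(
            read_id=read_id, ref_id=bundle.ref_id, start=start,
            cigar=cigar, seq=seq, mapq=60))
    return bundle


def _build_cols(codes: np.ndarray, rmap_seg: np.ndarray) -> list[list]:
    """Expand a genome segment into alignment columns.

    Columns are ``["M", base, ref_pos]``, ``["I", base, -1]`` or
    ``["D", run_length, first_ref_pos]``.
    """
    cols: list[list] = []
    prev = None
    for code, r in zip(codes, rmap_seg):
        r = int(r)
        if r < 0:
            cols.append(["I", int(code), -1])
        else:
            if prev is not None and r > prev + 1:
                cols.append(["D", r - prev - 1, prev + 1])
            cols.append(["M", int(code), r])
            prev = r
    return cols


def _edit_cols(cols: list[list], n_sub: int, n_ins: int, n_del: int,
               rng: np.random.Generator) -> None:
    """Inject sequencing errors into an alignment-column list in place."""
    base_idx = [i for i, c in enumerate(cols) if c[0] != "D"]
    if n_sub and base_idx:
        chosen = rng.choice(len(base_idx), size=min(n_sub, len(base_idx)),
                            replace=False)
        for j in chosen:
            i = base_idx[j]
            cols[i][1] = int((cols[i][1] + rng.integers(1, 4)) % 4)
    if n_del and base_idx:
        chosen = sorted(rng.choice(len(base_idx), size=min(n_del, len(base_idx)),
                                   replace=False).tolist(), reverse=True)
        for j in chosen:
            i = base_idx[j]
            if cols[i][0] == "M":
                cols[i] = ["D", 1, cols[i][2]]  # dropped base still consumes ref
            else:
                cols.pop(i)
    if n_ins:
        spots = sorted(rng.integers(0, len(cols) + 1, size=n_ins).tolist(),
                       reverse=True)
        for spot in spots:
            cols.insert(int(spot), ["I", int(rng.integers(4)), -1])


def _cols_to_alignment(cols: list[list]) -> tuple[int, list[tuple[str, int]], str]:
    seq_codes: list[int] = []
    ops: list[tuple[str, int]] = []
    start = -1
    for c in cols:
        if c[0] == "M":
            if start < 0:
                start = c[2]
            seq_codes.append(c[1])
            ops.append(("M", 1))
        elif c[0] == "I":
            seq_codes.append(c[1])
            ops.append(("I", 1))
        else:
            ops.append(("D", c[1]))
    seq = "".join(_BASES[b] for b in seq_codes)
    cigar = _compress_ops(ops)
    # soft-clipped leading columns do not consume reference; `start` is the
    # reference position of the first M column, which _compress_ops keeps
    return start, cigar, seq
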