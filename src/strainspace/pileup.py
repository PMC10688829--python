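"""Per-position, per-state observation counts on the gapped consensus.

The pileup walks CIGAR strings of reads aligned to a single reference
replicon and tallies, for every gapped-consensus column, how many reads
support each of the five states A, C, T, G, gap:

* match/mismatch ops increment the read base's count at the reference
  column;
* deletion ops increment the gap count at each deleted reference column;
* insertion ops create insertion columns ``(pos, k)`` after the reference
  base at ``pos`` and increment the inserted base's count there.

Reads that span an insertion locus without inserting implicitly vote for
"no insertion": at finalization a gap count is imputed at every insertion
column for each spanning read that did not insert that far, so the depth
of an insertion column equals its spanning-read count.  A read *spans* a
locus when its aligned reference interval covers both flanking reference
bases.  When different reads insert different lengths at one locus, the
locus gets as many insertion columns as the longest observed insertion and
shorter insertions pad with gap counts.

Counting is strand-pooled and order-independent: permuting the alignment
stream yields an identical table.  Soft/hard clips and reference skips
contribute nothing.  Unmapped, secondary and supplementary records are
excluded, as are records below the mapping-quality cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional, Union

import numpy as np
import pandas as pd

from .model import (
    GAP,
    N_STATES,
    STATES,
    FastvRecord,
    GappedCoordinate,
    StateDistribution,
)

# CIGAR operation codes follow the SAM specification.
_CONSUMES_READ = {"M", "I", "S", "=", "X"}
_CONSUMES_REF = {"M", "D", "N", "=", "X"}
_OP_CODES = "MIDNSHP=X"

_BASE_CODE = np.full(256, 5, dtype=np.uint8)
for _i, _b in enumerate("ACTG"):
    _BASE_CODE[ord(_b)] = _i
    _BASE_CODE[ord(_b.lower())] = _i


class PileupError(ValueError):
    pass


@dataclass
class AlignmentRecord:
    """A single read alignment: the subset of SAM needed for counting."""

    read_id: str
    ref_id: str
    start: int                      # 0-based leftmost reference position
    cigar: list[tuple[str, int]]    # [(op, length), ...]
    seq: str
    mapq: int = 60
    is_unmapped: bool = False
    is_secondary: bool = False
    is_supplementary: bool = False

    @property
    def countable(self) -> bool:
        return not (self.is_unmapped or self.is_secondary or self.is_supplementary)

    def read_length_from_cigar(self) -> int:
        return sum(l for op, l in self.cigar if op in _CONSUMES_READ)

    def reference_span(self) -> tuple[int, int]:
        """Half-open reference interval [start, end) consumed by the CIGAR."""
        return self.start, self.start + sum(
            l for op, l in self.cigar if op in _CONSUMES_REF)

    def cigar_string(self) -> str:
        return "".join(f"{l}{op}" for op, l in self.cigar)

    @classmethod
    def from_pysam(cls, seg) -> "AlignmentRecord":
        cigar = [(_OP_CODES[op], l) for op, l in (seg.cigartuples or [])]
        return cls(
            read_id=seg.query_name,
            ref_id=seg.reference_name or "*",
            start=seg.reference_start,
            cigar=cigar,
            seq=seg.query_sequence or "",
            mapq=seg.mapping_quality,
            is_unmapped=seg.is_unmapped,
            is_secondary=seg.is_secondary,
            is_supplementary=seg.is_supplementary,
        )


def read_sam(path: Union[str, Path]) -> list[AlignmentRecord]:
    """Read a SAM/BAM file into :class:`AlignmentRecord` objects."""
    import pysam

    with pysam.AlignmentFile(str(path), check_sq=False) as handle:
        return [AlignmentRecord.from_pysam(seg) for seg in handle]


class CountsTable:
    """Ordered map from gapped coordinates to five observation counts."""

    def __init__(self, ref_id: str, ref_len: int):
        self.ref_id = ref_id
        self.ref_len = int(ref_len)
        self.ref_counts = np.zeros((self.ref_len, N_STATES), dtype=np.int64)
        self.ins_counts: dict[tuple[int, int], np.ndarray] = {}

    # -- access ------------------------------------------------------------
    def coordinates(self) -> Iterator[GappedCoordinate]:
        """All columns in gapped-coordinate order (dense over the reference)."""
        ins_by_pos: dict[int, list[int]] = {}
        for (p, k) in self.ins_counts:
            ins_by_pos.setdefault(p, []).append(k)
        for p in range(self.ref_len):
            yield GappedCoordinate(p, 0)
            for k in sorted(ins_by_pos.get(p, ())):
                yield GappedCoordinate(p, k)

    def counts_at(self, coord: GappedCoordinate) -> np.ndarray:
        if coord.insert_index:
            key = (coord.ref_pos, coord.insert_index)
            if key not in self.ins_counts:
                raise KeyError(f"no insertion column at {coord.label()}")
            return self.ins_counts[key]
        if not (0 <= coord.ref_pos < self.ref_len):
            raise KeyError(f"reference position {coord.label()} out of range")
        return self.ref_counts[coord.ref_pos]

    def depth_at(self, coord: GappedCoordinate) -> int:
        return int(self.counts_at(coord).sum())

    def total_depth(self) -> int:
        total = int(self.ref_counts.sum())
        total += sum(int(c.sum()) for c in self.ins_counts.values())
        return total

    def copy(self) -> "CountsTable":
        out = CountsTable(self.ref_id, self.ref_len)
        out.ref_counts = self.ref_counts.copy()
        out.ins_counts = {k: v.copy() for k, v in self.ins_counts.items()}
        return out

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CountsTable):
            return NotImplemented
        return (self.ref_id == other.ref_id
                and self.ref_len == other.ref_len
                and np.array_equal(self.ref_counts, other.ref_counts)
                and set(self.ins_counts) == set(other.ins_counts)
                and all(np.array_equal(v, other.ins_counts[k])
                        for k, v in self.ins_counts.items()))

    # -- TSV round-trip ----------------------------------------------------
    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for coord in self.coordinates():
            c = self.counts_at(coord)
            rows.append((coord.ref_pos + 1, coord.insert_index,
                         *(int(x) for x in c)))
        return pd.DataFrame(rows, columns=["ref_pos", "insert_index",
                                           "A", "C", "T", "G", "gap"])

    def to_tsv(self, path: Union[str, Path]) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: Union[str, Path], ref_id: str = "ref") -> "CountsTable":
        df = pd.read_csv(path, sep="\t")
        required = ["ref_pos", "insert_index", "A", "C", "T", "G", "gap"]
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise PileupError(f"counts TSV lacks columns {missing}")
        if len(df) == 0:
            return cls(ref_id, 0)
        if (df["ref_pos"] < 1).any():
            raise PileupError("ref_pos is 1-based and must be >= 1")
        table = cls(ref_id, int(df["ref_pos"].max()))
        values = df[["A", "C", "T", "G", "gap"]].to_numpy(dtype=np.int64)
        if (values < 0).any():
            raise PileupError("negative counts in TSV")
        for (pos, k), counts in zip(
                df[["ref_pos", "insert_index"]].to_numpy(dtype=np.int64), values):
            if k == 0:
                table.ref_counts[pos - 1] = counts
            else:
                table.ins_counts[(int(pos) - 1, int(k))] = counts.copy()
        return table


def build_counts(
    alignments: Iterable[AlignmentRecord],
    reference: str,
    *,
    ref_id: Optional[str] = None,
    min_mapq: int = 1,
) -> CountsTable:
    """Tally per-column state counts from an alignment stream.

    ``reference`` is the replicon sequence the alignments refer to; every
    reference column appears in the output, covered or not.
    """
    ref_len = len(reference)
    table = CountsTable(ref_id or "ref", ref_len)
    counts = table.ref_counts
    # diff array for junction coverage: a read whose aligned interval is
    # [s, e) covers every junction p with s <= p <= e - 2
    jdiff = np.zeros(ref_len + 1, dtype=np.int64)
    ins_bases: dict[tuple[int, int], np.ndarray] = {}

    for aln in alignments:
        if not aln.countable or aln.mapq < min_mapq:
            continue
        if ref_id is not None and aln.ref_id != ref_id:
            raise PileupError(f"alignment {aln.read_id} targets {aln.ref_id!r}, "
                              f"expected {ref_id!r}")
        if aln.start < 0:
            raise PileupError(f"alignment {aln.read_id} has negative position")
        if aln.read_length_from_cigar() != len(aln.seq):
            raise PileupError(
                f"alignment {aln.read_id}: CIGAR consumes "
                f"{aln.read_length_from_cigar()} bases but read has {len(aln.seq)}")
        s, e = aln.reference_span()
        if e > ref_len:
            raise PileupError(f"alignment {aln.read_id} extends past the reference")
        if e - s >= 2:
            jdiff[s] += 1
            jdiff[e - 1] -= 1
        code = _BASE_CODE[np.frombuffer(aln.seq.encode("ascii"), dtype=np.uint8)]
        rpos, qpos = aln.start, 0
        for op, l in aln.cigar:
            if op in ("M", "=", "X"):
                sub = code[qpos:qpos + l]
                pos = np.arange(rpos, rpos + l)
                ok = sub < 4
                np.add.at(counts, (pos[ok], sub[ok]), 1)
                rpos += l
                qpos += l
            elif op == "D":
                counts[rpos:rpos + l, GAP] += 1
                rpos += l
            elif op == "I":
                anchor = rpos - 1
                if anchor >= 0:  # an insertion before the first base is unanchored
                    for k in range(1, l + 1):
                        key = (anchor, k)
                        if key not in ins_bases:
                            ins_bases[key] = np.zeros(N_STATES, dtype=np.int64)
                        b = code[qpos + k - 1]
                        if b < 4:
                            ins_bases[key][b] += 1
                qpos += l
            elif op in ("S",):
                qpos += l
            elif op == "N":
                rpos += l
            elif op in ("H", "P"):
                continue
            else:
                raise PileupError(f"unsupported CIGAR op {op!r} in {aln.read_id}")

    junction_cov = np.cumsum(jdiff)[:-1]  # junction_cov[p]: reads spanning p|p+1
    for (p, k), bases in sorted(ins_bases.items()):
        spanning = int(junction_cov[p]) if p < ref_len else 0
        inserted = int(bases.sum())
        col = bases.copy()
        col[GAP] = max(spanning - inserted, 0)
        table.ins_counts[(p, k)] = col
    return table


def build_counts_from_sam(
    sam_path: Union[str, Path],
    reference: str,
    *,
    ref_id: Optional[str] = None,
    min_mapq: int = 1,
) -> CountsTable:
    return build_counts(read_sam(sam_path), reference,
                        ref_id=ref_id, min_mapq=min_mapq)


def counts_to_fastv(counts: CountsTable, record_id: str,
                    description: str = "") -> FastvRecord:
    """Normalize a counts table into a FASTV record (freqs = counts/depth)."""
    columns = []
    for coord in counts.coordinates():
        c = counts.counts_at(coord)
        depth = int(c.sum())
        if depth == 0:
            columns.append((coord, StateDistribution.uncovered_column()))
        else:
            freqs = tuple(float(x) / depth for x in c)
            columns.append((coord, StateDistribution(freqs, coverage=depth)))
    return FastvRecord(id=record_id, description=description, columns=columns)
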