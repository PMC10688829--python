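"""In-memory model for per-position nucleotide state distributions.

A *strain genome space* is the collective of closely related genomes
(a consensus plus its sub-population variants) treated as one entity.
Positions live on a *gapped consensus* coordinate system: every reference
column plus extra insertion columns, so the consensus can be slightly
longer than any single member genome.

Each column carries the normalized frequency of the five states
A, C, T, G and gap.  Two record types exist:

* :class:`FastvRecord` — the pooled view: one five-state distribution per
  column, with no sub-population structure.
* :class:`FastmRecord` — the resolved view: one row per identified
  sub-population per column.  Rows store *joint* frequencies, i.e. the
  probability mass of "sub-population s AND state b", so the row sum equals
  the sub-population's abundance and the grand total of a covered column
  is 1.  Summing rows column-wise recovers the FASTV distribution.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional, Sequence, Union

import numpy as np

#: Canonical state order used everywhere: A, C, T, G, gap.
STATES: tuple[str, ...] = ("A", "C", "T", "G", "-")
STATE_INDEX: dict[str, int] = {s: i for i, s in enumerate(STATES)}
N_STATES = 5
GAP = 4

#: Tolerance for "frequencies sum to one" on in-memory (unrounded) records.
NORM_TOL = 1e-6
#: Tolerance for "row sum equals declared abundance" in FASTM matrices.
ROWSUM_TOL = 1e-4

_COORD_RE = re.compile(r"^(\d+)(?:\+(\d+))?$")


class ValidationError(ValueError):
    """Raised when a record violates its structural invariants."""

    def __init__(self, violations: Sequence["Violation"]):
        self.violations = list(violations)
        head = "; ".join(str(v) for v in self.violations[:3])
        more = "" if len(self.violations) <= 3 else f" (+{len(self.violations) - 3} more)"
        super().__init__(f"{len(self.violations)} invariant violation(s): {head}{more}")


@dataclass(frozen=True, order=True)
class GappedCoordinate:
    """A column on the gapped consensus.

    ``ref_pos`` is 0-based internally; serialization is 1-based.
    ``insert_index`` is 0 for the reference column itself and k >= 1 for the
    k-th insertion column after ``ref_pos``.  Total order is lexicographic
    on (ref_pos, insert_index), so insertion columns sort between their
    anchor reference column and the next one.
    """

    ref_pos: int
    insert_index: int = 0

    def __post_init__(self) -> None:
        if self.insert_index < 0:
            raise ValueError(f"insert_index must be >= 0, got {self.insert_index}")

    @property
    def is_insertion(self) -> bool:
        return self.insert_index > 0

    def label(self) -> str:
        """1-based serialization label, e.g. ``"12"`` or ``"12+2"``."""
        if self.insert_index:
            return f"{self.ref_pos + 1}+{self.insert_index}"
        return str(self.ref_pos + 1)

    @classmethod
    def from_label(cls, label: str) -> "GappedCoordinate":
        m = _COORD_RE.match(label.strip())
        if not m:
            raise ValueError(f"malformed coordinate label {label!r}")
        pos = int(m.group(1))
        if pos < 1:
            raise ValueError(f"coordinate labels are 1-based, got {label!r}")
        k = int(m.group(2)) if m.group(2) else 0
        if m.group(2) is not None and k < 1:
            raise ValueError(f"insertion index must be >= 1 in label {label!r}")
        return cls(pos - 1, k)


@dataclass(frozen=True)
class StateDistribution:
    """Normalized five-state frequencies at one column.

    ``coverage`` is the number of observations supporting the column;
    ``None`` means unknown (e.g. parsed from a file without a coverage
    annotation).  A column with ``coverage == 0`` — or all-zero
    frequencies — is *uncovered* and carries the zero vector.
    """

    freqs: tuple[float, float, float, float, float]
    coverage: Optional[int] = None

    def __post_init__(self) -> None:
        if len(self.freqs) != N_STATES:
            raise ValueError("a state distribution has exactly five values")
        object.__setattr__(self, "freqs", tuple(float(f) for f in self.freqs))

    @property
    def uncovered(self) -> bool:
        return self.coverage == 0 or sum(self.freqs) == 0.0

    def argmax_state(self) -> int:
        """Index of the most frequent state; ties break in canonical order."""
        return int(np.argmax(self.freqs))

    @classmethod
    def uncovered_column(cls) -> "StateDistribution":
        return cls((0.0, 0.0, 0.0, 0.0, 0.0), coverage=0)


@dataclass
class FastvRecord:
    """The FASTV in-memory model: pooled per-column state distributions."""

    id: str
    description: str = ""
    columns: list[tuple[GappedCoordinate, StateDistribution]] = field(default_factory=list)

    def __iter__(self) -> Iterator[tuple[GappedCoordinate, StateDistribution]]:
        return iter(self.columns)

    def __len__(self) -> int:
        return len(self.columns)


@dataclass(frozen=True)
class SubpopulationSet:
    """Ordered set of sub-populations with abundances summing to one.

    Ordering is by decreasing abundance, ties broken lexicographically by
    id; construction enforces the order.
    """

    members: tuple[tuple[str, float], ...]

    def __init__(self, members: Iterable[tuple[str, float]], *, tol: float = NORM_TOL):
        ordered = sorted(((str(i), float(a)) for i, a in members), key=lambda m: (-m[1], m[0]))
        object.__setattr__(self, "members", tuple(ordered))
        ids = [i for i, _ in self.members]
        if len(set(ids)) != len(ids):
            raise ValueError(f"duplicate sub-population ids in {ids}")
        for i, a in self.members:
            if not (0.0 < a <= 1.0):
                raise ValueError(f"abundance of {i!r} is {a}, outside (0, 1]")
        total = sum(a for _, a in self.members)
        if self.members and abs(total - 1.0) > tol:
            raise ValueError(f"abundances sum to {total:.6g}, expected 1 within {tol:g}")

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(i for i, _ in self.members)

    def abundance(self, subpop_id: str) -> float:
        for i, a in self.members:
            if i == subpop_id:
                return a
        raise KeyError(f"unknown sub-population {subpop_id!r}")

    def __len__(self) -> int:
        return len(self.members)

    def __contains__(self, subpop_id: str) -> bool:
        return any(i == subpop_id for i, _ in self.members)

    def __iter__(self) -> Iterator[tuple[str, float]]:
        return iter(self.members)


@dataclass
class FastmPositionMatrix:
    """One FASTM column: a joint (sub-population x state) frequency matrix."""

    rows: dict[str, tuple[float, float, float, float, float]]

    def grand_total(self) -> float:
        return float(sum(sum(r) for r in self.rows.values()))

    @property
    def uncovered(self) -> bool:
        return self.grand_total() == 0.0

    def marginal(self) -> tuple[float, ...]:
        out = np.zeros(N_STATES)
        for r in self.rows.values():
            out += np.asarray(r, dtype=float)
        return tuple(float(x) for x in out)


@dataclass
class FastmRecord:
    """The FASTM in-memory model: per-column sub-population x state matrices.

    FASTM content is post-error-filtering by definition: sequencing errors
    are assumed to have been removed before a record is built.
    """

    id: str
    subpops: SubpopulationSet
    columns: list[tuple[GappedCoordinate, FastmPositionMatrix]] = field(default_factory=list)
    description: str = ""

    def __iter__(self) -> Iterator[tuple[GappedCoordinate, FastmPositionMatrix]]:
        return iter(self.columns)

    def __len__(self) -> int:
        return len(self.columns)


@dataclass(frozen=True)
class Violation:
    """One invariant violation: where, which rule, and what was observed."""

    coordinate: Optional[GappedCoordinate]
    rule: str
    observed: str

    def __str__(self) -> str:
        where = self.coordinate.label() if self.coordinate is not None else "record"
        return f"[{where}] {self.rule}: {self.observed}"


def _check_monotone(columns: Sequence[tuple[GappedCoordinate, object]], out: list[Violation]) -> None:
    prev: Optional[GappedCoordinate] = None
    for coord, _ in columns:
        if prev is not None and coord <= prev:
            out.append(Violation(coord, "coordinates strictly increasing",
                                 f"{coord.label()} follows {prev.label()}"))
        prev = coord


def validate_record(
    rec: Union[FastvRecord, FastmRecord],
    *,
    norm_tol: float = NORM_TOL,
    rowsum_tol: float = ROWSUM_TOL,
    check_rowsums: bool = True,
) -> list[Violation]:
    """Check every structural invariant of a FASTV or FASTM record.

    Returns the (possibly empty) list of violations; never raises.
    ``rowsum_tol`` controls the FASTM "row sum equals declared abundance"
    check, which can be disabled entirely with ``check_rowsums=False`` for
    records whose per-column rows reflect local read sampling rather than
    the genome-wide abundance.
    """
    out: list[Violation] = []
    _check_monotone(rec.columns, out)
    if isinstance(rec, FastvRecord):
        for coord, dist in rec.columns:
            for f in dist.freqs:
                if not (0.0 <= f <= 1.0):
                    out.append(Violation(coord, "frequency in [0, 1]", f"{f!r}"))
            total = sum(dist.freqs)
            if dist.coverage == 0 and total != 0.0:
                out.append(Violation(coord, "uncovered column is all-zero", f"sum={total:.6g}"))
            elif not dist.uncovered and abs(total - 1.0) > norm_tol:
                out.append(Violation(coord, "frequencies sum to 1", f"sum={total:.6g}"))
        return out

    # FASTM
    declared = set(rec.subpops.ids)
    for coord, mat in rec.columns:
        if set(mat.rows) != declared:
            out.append(Violation(coord, "rows match declared sub-populations",
                                 f"rows={sorted(mat.rows)} declared={sorted(declared)}"))
            continue
        for sid, row in mat.rows.items():
            for f in row:
                if not (0.0 <= f <= 1.0):
                    out.append(Violation(coord, "frequency in [0, 1]", f"{sid}: {f!r}"))
        total = mat.grand_total()
        if mat.uncovered:
            continue
        if abs(total - 1.0) > norm_tol:
            out.append(Violation(coord, "grand total sums to 1", f"sum={total:.6g}"))
        if check_rowsums:
            for sid, a in rec.subpops:
                rs = sum(mat.rows[sid])
                if abs(rs - a) > rowsum_tol:
                    out.append(Violation(coord, "row sum equals abundance",
                                         f"{sid}: row sum {rs:.6g} vs abundance {a:.6g}"))
    return out


def _require_valid(rec: Union[FastvRecord, FastmRecord], **kwargs) -> None:
    violations = validate_record(rec, **kwargs)
    if violations:
        raise ValidationError(violations)


def marginalize_fastm(rec: FastmRecord, *, validate: bool = True) -> FastvRecord:
    """Sum FASTM rows column-wise to recover the pooled FASTV view.

    FASTV is the sub-population marginal of FASTM: it captures positional
    variation but no longer differentiates sub-populations.  Structural and
    normalization invariants of the input are enforced; the per-column
    row-sum-versus-abundance check is not (it does not affect the marginal).
    """
    if validate:
        _require_valid(rec, check_rowsums=False)
    columns = []
    for coord, mat in rec.columns:
        if mat.uncovered:
            columns.append((coord, StateDistribution.uncovered_column()))
        else:
            columns.append((coord, StateDistribution(mat.marginal())))
    return FastvRecord(id=rec.id, description=rec.description, columns=columns)


def subpop_consensus_with_coords(
    rec: FastmRecord, subpop_id: str
) -> tuple[str, list[GappedCoordinate]]:
    """Consensus sequence of one sub-population plus its source coordinates.

    Per column the argmax state of that sub-population's (renormalized) row
    is taken; gap-argmax and zero-mass columns are dropped.  Ties break in
    canonical state order.
    """
    if subpop_id not in rec.subpops:
        raise KeyError(f"unknown sub-population {subpop_id!r}; "
                       f"record declares {list(rec.subpops.ids)}")
    seq: list[str] = []
    coords: list[GappedCoordinate] = []
    for coord, mat in rec.columns:
        row = mat.rows[subpop_id]
        if sum(row) == 0.0:
            continue
        best = int(np.argmax(row))
        if best == GAP:
            continue
        seq.append(STATES[best])
        coords.append(coord)
    return "".join(seq), coords


def subpop_consensus(rec: FastmRecord, subpop_id: str) -> str:
    """Ungapped consensus nucleotide sequence of one sub-population."""
    return subpop_consensus_with_coords(rec, subpop_id)[0]


def overall_consensus_with_coords(
    rec: FastvRecord, *, keep_insertions: bool = False
) -> tuple[str, list[GappedCoordinate]]:
    """Pooled consensus and the coordinates of its retained columns.

    Gap-majority columns are dropped.  Insertion columns are dropped unless
    ``keep_insertions`` is set, in which case non-gap-majority insertion
    columns are retained and the consensus can exceed the reference length
    ("slightly larger" than any member genome).  Uncovered reference
    columns yield ``N`` so reference coordinates stay in register;
    uncovered insertion columns are dropped.
    """
    seq: list[str] = []
    coords: list[GappedCoordinate] = []
    for coord, dist in rec.columns:
        if coord.is_insertion and not keep_insertions:
            continue
        if dist.uncovered:
            if not coord.is_insertion:
                seq.append("N")
                coords.append(coord)
            continue
        best = dist.argmax_state()
        if best == GAP:
            continue
        seq.append(STATES[best])
        coords.append(coord)
    return "".join(seq), coords


def overall_consensus(rec: FastvRecord, *, keep_insertions: bool = False) -> str:
    """Pooled consensus nucleotide sequence (see
    :func:`overall_consensus_with_coords`)."""
    return overall_consensus_with_coords(rec, keep_insertions=keep_insertions)[0]
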