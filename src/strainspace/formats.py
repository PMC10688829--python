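"""Readers and writers for the FASTV and FASTM text formats, plus FASTA/FASTQ.

The formats are line-oriented UTF-8 in the FASTA family: ``>`` opens a
record, ``#`` opens a position block in FASTM.  Frequencies are written
with a fixed decimal precision (default 4); coordinates are serialized
1-based, insertion columns as ``pos+k`` (the k-th inserted column after
reference position ``pos``).

FASTV comes in two dialects:

* **Dialect A** — one parenthesized five-tuple per column in the canonical
  state order A, C, T, G, gap, e.g. ``(0.7000,0.3000,0.0000,0.0000,0.0000)``.
  Reference columns are implicit consecutive positions starting at 1;
  insertion columns carry an explicit leading ``pos+k`` label.
* **Dialect B** — a human-readable notation: an explicit position label
  followed by ``STATE=freq`` tokens for the states that occur, omitting
  zero-frequency states, e.g. ``12 A=0.7000 C=0.3000``.

FASTM writes one block per position: ``#<coordinate>`` followed by one row
per sub-population, ``<subpop_id> fA fC fT fG f-``, in declared
sub-population order.  The header carries the sub-population set:
``>id subpops=sp1:0.7000,sp2:0.3000``.

An optional ``cov=<depth>`` annotation preserves per-column coverage; it is
off by default so that output matches the minimal grammar above.
A full grammar description ships in ``docs/formats.md``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .model import (
    GAP,
    N_STATES,
    STATES,
    STATE_INDEX,
    FastmPositionMatrix,
    FastmRecord,
    FastvRecord,
    GappedCoordinate,
    StateDistribution,
    SubpopulationSet,
    ValidationError,
    Violation,
    validate_record,
)

FASTV_A = "FASTV_A"
FASTV_B = "FASTV_B"
FASTM = "FASTM"

_IUPAC = set("ACGTUNRYSWKMBDHV")


def _decimals(token: str) -> int:
    return len(token.partition(".")[2].rstrip())


class FormatError(ValueError):
    """Malformed FASTV/FASTM text; carries the offending line number."""

    def __init__(self, message: str, line: Optional[int] = None):
        self.line = line
        super().__init__(message if line is None else f"line {line}: {message}")


@dataclass(frozen=True)
class FormatDialect:
    """Serialization parameters: dialect name, decimal precision, units."""

    name: str = FASTV_A
    precision: int = 4
    percent: bool = False
    with_coverage: bool = False

    def __post_init__(self) -> None:
        if self.name not in (FASTV_A, FASTV_B, FASTM):
            raise ValueError(f"unknown dialect {self.name!r}")
        if self.precision < 2:
            raise ValueError("precision must be >= 2")

    def fmt(self, value: float) -> str:
        v = value * 100.0 if self.percent else value
        return f"{v:.{self.precision}f}"

    def norm_tol(self) -> float:
        # Five values each rounded to `precision` decimals can shift a unit
        # column sum by up to 2.5e-precision; allow a small extra margin.
        return 3.0 * 10.0 ** (-self.precision)


# ---------------------------------------------------------------------------
# FASTV
# ---------------------------------------------------------------------------

def write_fastv(rec: FastvRecord, dialect: FormatDialect = FormatDialect()) -> str:
    """Serialize a FASTV record; byte-deterministic for a given dialect."""
    violations = validate_record(rec, norm_tol=dialect.norm_tol())
    if violations:
        raise ValidationError(violations)
    if dialect.name not in (FASTV_A, FASTV_B):
        raise ValueError(f"write_fastv cannot write dialect {dialect.name}")
    header = f">{rec.id} {rec.description}".rstrip()
    lines = [header]
    for coord, dist in rec.columns:
        if dialect.name == FASTV_A:
            body = "(" + ",".join(dialect.fmt(f) for f in dist.freqs) + ")"
            line = f"{coord.label()} {body}" if coord.is_insertion else body
        else:
            tokens = [f"{STATES[i]}={dialect.fmt(f)}"
                      for i, f in enumerate(dist.freqs) if f != 0.0]
            line = " ".join([coord.label()] + tokens)
        if dialect.with_coverage and dist.coverage is not None:
            line += f" cov={dist.coverage}"
        lines.append(line)
    return "\n".join(lines) + "\n"


def _parse_header(line: str, lineno: int) -> tuple[str, str]:
    if not line.startswith(">"):
        raise FormatError("record must start with '>'", lineno)
    parts = line[1:].split(None, 1)
    if not parts:
        raise FormatError("empty record header", lineno)
    return parts[0], parts[1] if len(parts) > 1 else ""

def _split_coverage(tokens: list[str]) -> tuple[list[str], Optional[int]]:
    if tokens and tokens[-1].startswith("cov="):
        return tokens[:-1], int(tokens[-1][4:])
    return tokens, None


def _finish_column(freqs: list[float], coverage: Optional[int], norm_tol: float,
                   lineno: int) -> StateDistribution:
    total = sum(freqs)
    if abs(total - 100.0) <= 100.0 * norm_tol:      # percent-scaled column
        freqs = [f / 100.0 for f in freqs]
        total /= 100.0
    if total == 0.0:
        return StateDistribution.uncovered_column() if coverage in (None, 0) else \
            StateDistribution(tuple(freqs), coverage)
    if abs(total - 1.0) > norm_tol:
        raise FormatError(f"column frequencies sum to {total:.4f}, not 1", lineno)
    return StateDistribution(tuple(freqs), coverage)


def parse_fastv(text: str) -> FastvRecord:
    """Parse FASTV text, auto-detecting dialect A or B from the first
    data line (A columns are parenthesized five-tuples)."""
    lines = text.splitlines()
    data = [(i + 1, ln.strip()) for i, ln in enumerate(lines) if ln.strip()]
    if not data:
        raise FormatError("empty input")
    lineno, header = data[0]
    rec_id, desc = _parse_header(header, lineno)
    columns: list[tuple[GappedCoordinate, StateDistribution]] = []
    next_ref = 0  # 0-based position of the next implicit reference column
    for lineno, line in data[1:]:
        if line.startswith(">"):
            raise FormatError("multi-record FASTV input not supported", lineno)
        tokens, coverage = _split_coverage(line.split())
        if "(" in line:  # dialect A
            if tokens and tokens[-1].startswith("("):
                body = tokens[-1]
                label = tokens[0] if len(tokens) > 1 else None
            else:
                raise FormatError("malformed dialect-A column", lineno)
            if label is not None:
                coord = GappedCoordinate.from_label(label)
                if not coord.is_insertion:
                    next_ref = coord.ref_pos + 1
            else:
                coord = GappedCoordinate(next_ref)
                next_ref += 1
            if not (body.startswith("(") and body.endswith(")")):
                raise FormatError("dialect-A column must be parenthesized", lineno)
            parts = body[1:-1].split(",")
            if len(parts) != N_STATES:
                raise FormatError(f"expected 5 values, got {len(parts)}", lineno)
            try:
                freqs = [float(p) for p in parts]
            except ValueError as exc:
                raise FormatError(f"bad frequency value: {exc}", lineno) from None
            precision = max((_decimals(p) for p in parts), default=4)
        else:  # dialect B
            if not tokens:
                raise FormatError("empty column line", lineno)
            coord = GappedCoordinate.from_label(tokens[0])
            if not coord.is_insertion:
                next_ref = coord.ref_pos + 1
            freqs = [0.0] * N_STATES
            precision = max((_decimals(t.partition("=")[2]) for t in tokens[1:]),
                            default=4)
            for tok in tokens[1:]:
                if "=" not in tok:
                    raise FormatError(f"malformed token {tok!r}", lineno)
                state, _, value = tok.partition("=")
                if state not in STATE_INDEX:
                    raise FormatError(f"unknown state {state!r}", lineno)
                try:
                    freqs[STATE_INDEX[state]] = float(value)
                except ValueError as exc:
                    raise FormatError(f"bad frequency value: {exc}", lineno) from None
        # tolerance keyed to the apparent precision of the printed values
        norm_tol = max(1e-6, 3.0 * 10.0 ** (-max(precision, 2)))
        columns.append((coord, _finish_column(freqs, coverage, norm_tol, lineno)))
    rec = FastvRecord(id=rec_id, description=desc, columns=columns)
    violations = [v for v in validate_record(rec) if "sum to 1" not in v.rule]
    if violations:
        raise ValidationError(violations)
    return rec


# ---------------------------------------------------------------------------
# FASTM
# ---------------------------------------------------------------------------

def write_fastm(rec: FastmRecord, dialect: FormatDialect = FormatDialect(FASTM),
                *, check_rowsums: bool = True) -> str:
    """Serialize a FASTM record.

    ``check_rowsums=False`` skips the row-sum-versus-abundance invariant,
    which pipeline-built records relax at variant columns (per-column rows
    there reflect local read sampling, not the genome-wide abundance).
    """
    violations = validate_record(rec, norm_tol=dialect.norm_tol(),
                                 check_rowsums=check_rowsums)
    if violations:
        raise ValidationError(violations)
    sub = ",".join(f"{sid}:{a:.{dialect.precision}f}" for sid, a in rec.subpops)
    header = f">{rec.id} subpops={sub}"
    if rec.description:
        header += f" {rec.description}"
    lines = [header]
    for coord, mat in rec.columns:
        lines.append(f"#{coord.label()}")
        for sid, _ in rec.subpops:
            row = mat.rows[sid]
            lines.append(sid + " " + " ".join(dialect.fmt(f) for f in row))
    return "\n".join(lines) + "\n"


def parse_fastm(text: str, *, strict_rowsums: bool = False) -> FastmRecord:
    """Parse FASTM text written by :func:`write_fastm`.

    Row ids are checked against the header sub-population set; row sums are
    checked against declared abundances (warning by default, error when
    ``strict_rowsums`` is set, at a tolerance that accounts for the printed
    precision).
    """
    lines = text.splitlines()
    data = [(i + 1, ln.strip()) for i, ln in enumerate(lines) if ln.strip()]
    if not data:
        raise FormatError("empty input")
    lineno, header = data[0]
    rec_id, desc = _parse_header(header, lineno)
    sub_spec = None
    rest = []
    for tok in desc.split():
        if tok.startswith("subpops="):
            sub_spec = tok[len("subpops="):]
        else:
            rest.append(tok)
    if sub_spec is None:
        raise FormatError("FASTM header lacks a subpops= declaration", lineno)
    members = []
    for item in sub_spec.split(","):
        sid, _, a = item.partition(":")
        if not sid or not a:
            raise FormatError(f"malformed sub-population entry {item!r}", lineno)
        members.append((sid, float(a)))
    precision = max(len(a.partition(":")[2].partition(".")[2]) for a in sub_spec.split(","))
    try:
        subpops = SubpopulationSet(members, tol=max(1e-6, len(members) * 10.0 ** -precision))
    except ValueError as exc:
        raise FormatError(str(exc), lineno) from None

    norm_tol = 3.0 * 10.0 ** (-precision) if precision else 1e-2
    rowsum_tol = max(1e-4, norm_tol)
    declared = set(subpops.ids)
    rowsum_notes: list[str] = []
    columns: list[tuple[GappedCoordinate, FastmPositionMatrix]] = []
    current: Optional[GappedCoordinate] = None
    rows: dict[str, tuple[float, ...]] = {}
    block_line = lineno

    def close_block() -> None:
        if current is None:
            return
        if set(rows) != declared:
            missing = declared - set(rows)
            raise FormatError(
                f"block {current.label()} rows {sorted(rows)} do not match "
                f"declared sub-populations (missing {sorted(missing)})", block_line)
        mat = FastmPositionMatrix(rows=dict(rows))
        total = mat.grand_total()
        if total != 0.0 and abs(total - 1.0) > norm_tol:
            raise FormatError(
                f"block {current.label()} grand total {total:.4f} != 1", block_line)
        if total != 0.0:
            for sid, a in subpops:
                rs = sum(mat.rows[sid])
                if abs(rs - a) > rowsum_tol:
                    msg = (f"block {current.label()}: row sum {rs:.4f} of {sid!r} "
                           f"deviates from declared abundance {a:.4f}")
                    if strict_rowsums:
                        raise FormatError(msg, block_line)
                    rowsum_notes.append(msg)
        columns.append((current, mat))

    for lineno, line in data[1:]:
        if line.startswith("#"):
            close_block()
            current = GappedCoordinate.from_label(line[1:])
            rows = {}
            block_line = lineno
        else:
            if current is None:
                raise FormatError("row outside a position block", lineno)
            parts = line.split()
            if len(parts) != 1 + N_STATES:
                raise FormatError(f"expected id + 5 values, got {len(parts)} fields", lineno)
            sid = parts[0]
            if sid not in declared:
                raise FormatError(
                    f"undeclared sub-population {sid!r} in block {current.label()}", lineno)
            if sid in rows:
                raise FormatError(f"duplicate row {sid!r} in block {current.label()}", lineno)
            try:
                values = [float(p) for p in parts[1:]]
            except ValueError as exc:
                raise FormatError(f"bad frequency value: {exc}", lineno) from None
            total = sum(values)
            if abs(total - subpops.abundance(sid) * 100.0) <= 100.0 * rowsum_tol and total > 1.5:
                values = [v / 100.0 for v in values]  # percent-scaled row
            rows[sid] = tuple(values)
    close_block()
    if rowsum_notes:
        warnings.warn(
            f"{len(rowsum_notes)} column(s) with row sums deviating from the "
            f"declared abundances (local read sampling at variant columns); "
            f"first: {rowsum_notes[0]}", stacklevel=2)
    rec = FastmRecord(id=rec_id, subpops=subpops, columns=columns,
                      description=" ".join(rest))
    violations = [v for v in validate_record(rec, check_rowsums=False)
                  if "sum" not in v.rule]
    if violations:
        raise ValidationError(violations)
    return rec


def detect_format(text: str) -> str:
    """Classify text as FASTV_A, FASTV_B or FASTM from its first lines."""
    data = [ln.strip() for ln in text.splitlines() if ln.strip()]
    if not data:
        raise FormatError("empty input")
    if "subpops=" in data[0]:
        return FASTM
    for ln in data[1:]:
        if ln.startswith("#"):
            return FASTM
        return FASTV_A if "(" in ln else FASTV_B
    return FASTV_A


def records_equal(a, b, *, precision: int = 4) -> bool:
    """Equality of two records at a decimal precision.

    Frequencies and abundances compare within half an ulp of the printed
    precision; coverage compares only when both sides carry it.
    """
    tol = 0.5 * 10.0 ** (-precision) + 1e-12
    if type(a) is not type(b) or a.id != b.id or len(a) != len(b):
        return False
    if isinstance(a, FastvRecord):
        for (ca, da), (cb, db) in zip(a.columns, b.columns):
            if ca != cb:
                return False
            if da.uncovered != db.uncovered:
                return False
            if any(abs(x - y) > tol for x, y in zip(da.freqs, db.freqs)):
                return False
            if da.coverage is not None and db.coverage is not None \
                    and da.coverage != db.coverage:
                return False
        return True
    if a.subpops.ids != b.subpops.ids:
        return False
    for (sa, aa), (sb, ab) in zip(a.subpops, b.subpops):
        if sa != sb or abs(aa - ab) > tol:
            return False
    for (ca, ma), (cb, mb) in zip(a.columns, b.columns):
        if ca != cb or set(ma.rows) != set(mb.rows):
            return False
        for sid in ma.rows:
            if any(abs(x - y) > tol for x, y in zip(ma.rows[sid], mb.rows[sid])):
                return False
    return True


# ---------------------------------------------------------------------------
# FASTA / FASTQ plumbing
# ---------------------------------------------------------------------------

def read_fasta(path: Union[str, Path]) -> list[tuple[str, str, str]]:
    """Read FASTA as (id, description, sequence) triples.

    Non-IUPAC characters are kept but trigger a warning.
    """
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        bad = set(seq) - _IUPAC
        if bad:
            warnings.warn(f"record {rec.id}: non-IUPAC characters {sorted(bad)}",
                          stacklevel=2)
        out.append((rec.id, rec.description, seq))
    return out


def write_fasta(records: Iterable[tuple[str, str]], path: Union[str, Path],
                *, wrap: int = 70) -> None:
    """Write (id, sequence) pairs as FASTA wrapped at ``wrap`` columns."""
    with open(path, "w") as handle:
        for rec_id, seq in records:
            handle.write(f">{rec_id}\n")
            for i in range(0, len(seq), wrap):
                handle.write(seq[i:i + wrap] + "\n")


def read_fastq(path: Union[str, Path]) -> list[tuple[str, str, str]]:
    """Read FASTQ as (id, sequence, quality-string) triples.

    A quality string whose length does not match its sequence is an error.
    """
    out = []
    for rec in SeqIO.parse(str(path), "fastq"):
        quals = rec.letter_annotations["phred_quality"]
        if len(quals) != len(rec.seq):
            raise FormatError(f"record {rec.id}: quality/sequence length mismatch")
        qual = "".join(chr(q + 33) for q in quals)
        out.append((rec.id, str(rec.seq), qual))
    return out


def write_fastq(records: Iterable[tuple[str, str, str]], path: Union[str, Path]) -> None:
    with open(path, "w") as handle:
        for rec_id, seq, qual in records:
            if len(seq) != len(qual):
                raise FormatError(f"record {rec_id}: quality/sequence length mismatch")
            handle.write(f"@{rec_id}\n{seq}\n+\n{qual}\n")
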