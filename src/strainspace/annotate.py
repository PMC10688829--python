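"""Sub-population-aware ORF calling and GenBank-like feature output.

Every sub-population consensus is scanned for open reading frames; ORFs
are then compared *across* sub-populations in the shared gapped-consensus
coordinate space.  Two ORFs share a gene model iff they have identical
(start, stop, strand) there — a synonymous or otherwise model-preserving
variant keeps the locus tag, while a moved start, premature stop or
frameshift issues a new one.

Locus tags are assigned in positional order with step 10 (``LT_000010``,
``LT_000020`` ...).  Each (model, sub-population) pair becomes one CDS
feature tagged ``<base>_P<k>`` (k = the sub-population's 1-based rank by
abundance) and annotated with the sub-population's normalized frequency.
``/frequency`` is a nonstandard qualifier specific to this format.

ORF calling uses the standard bacterial genetic code (translation table
11) with start codons ATG/GTG/TTG and a default minimum length of 90 nt.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from typing import Optional, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import SeqFeature, SimpleLocation
from Bio.SeqRecord import SeqRecord

from .model import (
    FastmRecord,
    GappedCoordinate,
    marginalize_fastm,
    overall_consensus_with_coords,
    subpop_consensus_with_coords,
)

START_CODONS = ("ATG", "GTG", "TTG")
STOP_CODONS = ("TAA", "TAG", "TGA")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class AnnotationError(ValueError):
    pass


@dataclass(frozen=True)
class OrfModel:
    """One open reading frame on a sub-population consensus.

    ``start``/``stop`` are 1-based inclusive positions on that consensus,
    always with start < stop on the forward strand coordinate system; for
    strand '-', the reading direction runs stop -> start.
    """

    subpop_id: str
    start: int
    stop: int
    strand: str          # '+' or '-'
    sequence: str        # reading-direction nucleotide sequence

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if len(self.sequence) % 3 != 0:
            raise ValueError("ORF length must be a multiple of 3")


@dataclass(frozen=True)
class LocusFeature:
    """One (gene model, sub-population) annotation entry."""

    base_tag: str        # e.g. LT_000010
    appendix: str        # e.g. _P2
    frequency: float     # the sub-population's abundance
    start: int           # 1-based inclusive, on the emitted consensus
    stop: int
    strand: str
    subpop_id: str

    @property
    def locus_tag(self) -> str:
        return self.base_tag + self.appendix


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def call_orfs(seq: str, min_len: int = 90, *, subpop_id: str = "") -> list[OrfModel]:
    """All maximal start-to-stop ORFs in the six frames, length >= min_len.

    Maximal means the earliest start codon after the previous in-frame stop
    is used; overlapping ORFs from different frames or strands are all
    reported.  Deterministic order by (start, strand).
    """
    if min_len < 3 or min_len % 3 != 0:
        raise ValueError("min_len must be a positive multiple of 3")
    seq = seq.upper()
    L = len(seq)
    out: list[OrfModel] = []
    for strand in ("+", "-"):
        s = seq if strand == "+" else _revcomp(seq)
        for frame in range(3):
            start: Optional[int] = None
            for i in range(frame, L - 2, 3):
                codon = s[i:i + 3]
                if codon in STOP_CODONS:
                    if start is not None and (i + 3 - start) >= min_len:
                        orf = s[start:i + 3]
                        if strand == "+":
                            a, b = start + 1, i + 3
                        else:
                            a, b = L - (i + 3) + 1, L - start
                        out.append(OrfModel(subpop_id, a, b, strand, orf))
                    start = None
                elif start is None and codon in START_CODONS:
                    start = i
    out.sort(key=lambda o: (o.start, o.strand, o.stop))
    return out


def compare_gene_models(
    orfs_by_subpop: dict[str, list[tuple[OrfModel, GappedCoordinate, GappedCoordinate]]],
) -> list[dict]:
    """Group ORFs that share a gene model across sub-populations.

    Input: per sub-population, ORFs with their start/stop projected into
    the shared gapped-consensus space.  Two ORFs share a model iff their
    projected (start, stop, strand) are identical; each equivalence class
    is one locus group.
    """
    groups: dict[tuple[GappedCoordinate, GappedCoordinate, str], dict] = {}
    for sid, orfs in orfs_by_subpop.items():
        for orf, gstart, gstop in orfs:
            key = (gstart, gstop, orf.strand)
            g = groups.setdefault(key, {"start": gstart, "stop": gstop,
                                        "strand": orf.strand, "orfs": {}})
            g["orfs"][sid] = orf
    return sorted(groups.values(), key=lambda g: (g["start"], g["stop"], g["strand"]))


def assign_locus_tags(
    groups: Sequence[dict],
    subpops,
    prefix: str = "LT_",
    *,
    consensus_position: Optional[dict[GappedCoordinate, int]] = None,
) -> list[LocusFeature]:
    """Issue base tags in positional order (step 10) and one feature per
    (group, sub-population) with the ``_P<k>`` appendix and the
    sub-population's abundance as frequency."""
    rank = {sid: i + 1 for i, (sid, _) in enumerate(subpops)}
    features: list[LocusFeature] = []
    seen: set[tuple[str, str]] = set()
    for gi, group in enumerate(groups):
        base = f"{prefix}{(gi + 1) * 10:06d}"
        if consensus_position is not None:
            try:
                start = consensus_position[group["start"]]
                stop = consensus_position[group["stop"]]
            except KeyError as exc:
                raise AnnotationError(
                    f"gene model coordinate {exc} absent from the emitted "
                    "consensus") from None
        else:
            start, stop = group["start"], group["stop"]
            if isinstance(start, GappedCoordinate):
                start, stop = start.ref_pos + 1, stop.ref_pos + 1
        for sid in subpops.ids:
            orf = group["orfs"].get(sid)
            if orf is None:
                continue
            appendix = f"_P{rank[sid]}"
            if (base, appendix) in seen:
                raise AnnotationError(f"duplicate locus tag {base}{appendix}")
            seen.add((base, appendix))
            features.append(LocusFeature(
                base_tag=base, appendix=appendix,
                frequency=subpops.abundance(sid),
                start=start, stop=stop, strand=group["strand"], subpop_id=sid))
    return features


def write_genbank_like(
    consensus: str,
    features: Sequence[LocusFeature],
    subpops,
    *,
    record_id: str = "strainspace",
    definition: str = "strain genome space consensus with sub-population features",
) -> str:
    """Render a GenBank flat file whose ORIGIN is the insertion-retaining
    overall consensus and whose CDS features carry sub-population locus
    tags and frequencies."""
    for f in features:
        if not (1 <= f.start <= f.stop <= len(consensus)):
            raise AnnotationError(
                f"feature {f.locus_tag} [{f.start}, {f.stop}] outside the "
                f"consensus (length {len(consensus)})")
    rec = SeqRecord(Seq(consensus), id=record_id, name=record_id[:16],
                    description=definition,
                    annotations={"molecule_type": "DNA", "topology": "linear"})
    for f in sorted(features, key=lambda f: (f.start, f.stop, f.appendix)):
        loc = SimpleLocation(f.start - 1, f.stop, strand=1 if f.strand == "+" else -1)
        rec.features.append(SeqFeature(loc, type="CDS", qualifiers={
            "locus_tag": [f.locus_tag],
            "note": [f"subpopulation={f.subpop_id}"],
            "frequency": [f"{f.frequency:.4f}"],
        }))
    buf = io.StringIO()
    SeqIO.write(rec, buf, "genbank")
    return buf.getvalue()


def annotate_record(
    rec: FastmRecord,
    *,
    min_orf_len: int = 90,
    prefix: str = "LT_",
    record_id: Optional[str] = None,
) -> tuple[str, list[LocusFeature]]:
    """Full annotation of a FASTM record: per-sub-population ORF calling,
    cross-sub-population gene-model comparison, locus-tag assignment, and
    GenBank-like rendering.  Returns (flat-file text, features)."""
    orfs_by_subpop: dict[str, list[tuple[OrfModel, GappedCoordinate, GappedCoordinate]]] = {}
    for sid in rec.subpops.ids:
        seq, coords = subpop_consensus_with_coords(rec, sid)
        orfs = call_orfs(seq, min_orf_len, subpop_id=sid)
        orfs_by_subpop[sid] = [
            (orf, coords[orf.start - 1], coords[orf.stop - 1]) for orf in orfs]
    groups = compare_gene_models(orfs_by_subpop)

    fastv = marginalize_fastm(rec, validate=False)
    consensus, cons_coords = overall_consensus_with_coords(fastv, keep_insertions=True)
    position = {c: i + 1 for i, c in enumerate(cons_coords)}
    features = assign_locus_tags(groups, rec.subpops, prefix,
                                 consensus_position=position)
    text = write_genbank_like(consensus, features, rec.subpops,
                              record_id=record_id or rec.id)
    return text, features
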