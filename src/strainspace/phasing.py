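"""Read-based sub-population phasing and FASTM construction.

Reads that belong to one sub-population share the alleles that distinguish
it, so reads can be grouped by the variant-site states they carry:

1. :func:`extract_read_profiles` reduces each read to its observed states
   at the variant sites (sites with at least two non-error states).
2. :func:`cluster_reads` groups the profiles with a deterministic greedy
   seed-and-extend: profiles are processed in decreasing order of
   covered-site count (ties by read id); a read joins the first cluster it
   shares a site with at agreement >= 1 - tau, else opens a new cluster;
   clusters sharing at least one site whose consensus vectors conflict
   nowhere are merged to a fixpoint; clusters below the size or abundance
   floor are dissolved and their reads reassigned.
3. :func:`link_by_frequency` identifies haplotype groups from *different*
   read-linkage components (sites joined when co-covered by a read) as one
   sub-population when their abundance estimates are close — the
   frequency-matching idea: sub-populations leave the same abundance
   footprint everywhere in the genome, so similar variant frequencies in
   unlinked regions point to the same sub-population.
4. :func:`build_fastm` distributes the cleaned per-column frequency mass
   over the sub-populations, using member-read evidence at variant columns
   and abundance shares elsewhere, so that summing rows always reproduces
   the pooled cleaned distribution exactly.

Reads are weighted equally (not by covered-site count) for abundance
estimation, which is unbiased under uniform coverage.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from .model import (
    GAP,
    N_STATES,
    STATES,
    FastmPositionMatrix,
    FastmRecord,
    GappedCoordinate,
    SubpopulationSet,
)
from .pileup import AlignmentRecord, CountsTable, counts_to_fastv


@dataclass
class ReadVariantProfile:
    """The states one read exhibits at the variant sites it covers."""

    read_id: str
    alleles: dict[GappedCoordinate, int]  # state index per covered variant site

    def __len__(self) -> int:
        return len(self.alleles)


@dataclass
class SubpopCluster:
    """A group of reads attributed to one haplotype."""

    cluster_id: str
    read_ids: list[str]
    consensus: dict[GappedCoordinate, int]
    abundance: float
    component_id: int = 0

    @property
    def n_reads(self) -> int:
        return len(self.read_ids)


@dataclass
class LinkResult:
    subpops: SubpopulationSet
    assignment: dict[str, str]          # cluster_id -> subpop_id
    warnings: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# read profiles
# ---------------------------------------------------------------------------

def extract_read_profiles(
    alignments: Iterable[AlignmentRecord],
    variant_sites: Sequence[GappedCoordinate],
    error_states: Optional[set[tuple[GappedCoordinate, int]]] = None,
    *,
    min_mapq: int = 1,
) -> list[ReadVariantProfile]:
    """One profile per read covering at least one variant site.

    States that were classified as sequencing error at a site are recorded
    as missing for the read that exhibits them.
    """
    error_states = error_states or set()
    ref_sites: dict[int, GappedCoordinate] = {
        c.ref_pos: c for c in variant_sites if not c.is_insertion}
    ins_sites: dict[int, list[GappedCoordinate]] = {}
    for c in variant_sites:
        if c.is_insertion:
            ins_sites.setdefault(c.ref_pos, []).append(c)

    from .pileup import _BASE_CODE  # shared base encoding

    profiles: list[ReadVariantProfile] = []
    for aln in alignments:
        if not aln.countable or aln.mapq < min_mapq:
            continue
        s, e = aln.reference_span()
        alleles: dict[GappedCoordinate, int] = {}
        insertions: dict[int, list[int]] = {}  # anchor -> inserted state codes
        code = _BASE_CODE[np.frombuffer(aln.seq.encode("ascii"), dtype=np.uint8)]
        rpos, qpos = aln.start, 0
        for op, l in aln.cigar:
            if op in ("M", "=", "X"):
                for p in range(rpos, rpos + l):
                    site = ref_sites.get(p)
                    if site is not None:
                        b = int(code[qpos + (p - rpos)])
                        if b < 4:
                            alleles[site] = b
                rpos += l
                qpos += l
            elif op == "D":
                for p in range(rpos, rpos + l):
                    site = ref_sites.get(p)
                    if site is not None:
                        alleles[site] = GAP
                rpos += l
            elif op == "I":
                anchor = rpos - 1
                if anchor in ins_sites:
                    insertions[anchor] = [int(c) for c in code[qpos:qpos + l]]
                qpos += l
            elif op in ("S",):
                qpos += l
            elif op == "N":
                rpos += l
        for anchor, sites in ins_sites.items():
            if not (s <= anchor and anchor + 1 <= e - 1):
                continue  # read does not span the insertion junction
            inserted = insertions.get(anchor, [])
            for site in sites:
                k = site.insert_index
                if k <= len(inserted):
                    b = inserted[k - 1]
                    if b < 4:
                        alleles[site] = b
                else:
                    alleles[site] = GAP
        if error_states:
            alleles = {c: b for c, b in alleles.items()
                       if (c, b) not in error_states}
        if alleles:
            profiles.append(ReadVariantProfile(aln.read_id, alleles))
    return profiles


def variant_components(profiles: Sequence[ReadVariantProfile]) -> dict[GappedCoordinate, int]:
    """Connected components of the variant-site graph (sites joined when
    co-covered by at least one read).  Components are numbered by their
    leftmost site."""
    parent: dict[GappedCoordinate, GappedCoordinate] = {}

    def find(x: GappedCoordinate) -> GappedCoordinate:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for prof in profiles:
        sites = sorted(prof.alleles)
        for site in sites:
            parent.setdefault(site, site)
        for a, b in zip(sites, sites[1:]):
            ra, rb = find(a), find(b)
            if ra != rb:
                parent[max(ra, rb)] = min(ra, rb)
    roots = sorted({find(s) for s in parent})
    root_no = {r: i for i, r in enumerate(roots)}
    return {s: root_no[find(s)] for s in parent}


# ---------------------------------------------------------------------------
# clustering
# ---------------------------------------------------------------------------

class _Cluster:
    __slots__ = ("counts", "members")

    def __init__(self) -> None:
        self.counts: dict[GappedCoordinate, np.ndarray] = {}
        self.members: list[str] = []

    def consensus_at(self, site: GappedCoordinate) -> int:
        return int(np.argmax(self.counts[site]))

    def agreement(self, alleles: dict[GappedCoordinate, int]) -> tuple[int, int]:
        shared = matches = 0
        for site, b in alleles.items():
            c = self.counts.get(site)
            if c is None:
                continue
            shared += 1
            if int(np.argmax(c)) == b:
                matches += 1
        return shared, matches

    def add(self, read_id: str, alleles: dict[GappedCoordinate, int]) -> None:
        self.members.append(read_id)
        for site, b in alleles.items():
            if site not in self.counts:
                self.counts[site] = np.zeros(N_STATES, dtype=np.int64)
            self.counts[site][b] += 1

    def remove(self, read_id: str, alleles: dict[GappedCoordinate, int]) -> None:
        self.members.remove(read_id)
        for site, b in alleles.items():
            self.counts[site][b] -= 1
            if not self.counts[site].any():
                del self.counts[site]

    def absorb(self, other: "_Cluster") -> None:
        self.members.extend(other.members)
        for site, c in other.counts.items():
            if site in self.counts:
                self.counts[site] += c
            else:
                self.counts[site] = c.copy()


def cluster_reads(
    profiles: Sequence[ReadVariantProfile],
    tau: float = 0.1,
    m_min: int = 5,
    a_min: float = 0.01,
) -> list[SubpopCluster]:
    """Deterministic greedy clustering of read variant profiles.

    ``tau`` is the per-read mismatch tolerance against a cluster consensus,
    ``m_min``/``a_min`` the minimum member count and abundance below which
    a cluster is dissolved and its reads reassigned (or left unassigned).
    """
    if not (0.0 <= tau < 0.5):
        raise ValueError(f"tau must be in [0, 0.5), got {tau}")
    if m_min < 1:
        raise ValueError("m_min must be >= 1")
    if not profiles:
        raise ValueError("empty profile list")
    ordered = sorted(profiles, key=lambda p: (-len(p), p.read_id))
    prof_by_id = {p.read_id: p for p in ordered}

    clusters: list[_Cluster] = []
    for prof in ordered:
        placed = False
        for cl in clusters:
            shared, matches = cl.agreement(prof.alleles)
            if shared and matches >= (1.0 - tau) * shared:
                cl.add(prof.read_id, prof.alleles)
                placed = True
                break
        if not placed:
            cl = _Cluster()
            cl.add(prof.read_id, prof.alleles)
            clusters.append(cl)

    # refinement: reassign each read to its best-agreement cluster until a
    # fixpoint (ties keep the current assignment, so equally consistent
    # reads never oscillate); this undoes chimeric seeds the single greedy
    # pass can lock in when reads cover few sites each
    home = {}
    for cl in clusters:
        for rid in cl.members:
            home[rid] = cl
    site_index: dict[GappedCoordinate, set[int]] = {}
    cluster_no = {id(cl): i for i, cl in enumerate(clusters)}
    for i, cl in enumerate(clusters):
        for site in cl.counts:
            site_index.setdefault(site, set()).add(i)
    for _round in range(25):
        moved = False
        for prof in ordered:
            cur = home[prof.read_id]
            cand_nos = sorted({i for s in prof.alleles
                               for i in site_index.get(s, ())})
            best, best_frac = cur, -1.0
            cur_shared, cur_matches = cur.agreement(prof.alleles)
            if cur_shared:
                best_frac = cur_matches / cur_shared
            for i in cand_nos:
                cl = clusters[i]
                if cl is cur or not cl.members:
                    continue
                shared, matches = cl.agreement(prof.alleles)
                if shared and matches / shared > best_frac + 1e-12:
                    best, best_frac = cl, matches / shared
            if best is not cur:
                cur.remove(prof.read_id, prof.alleles)
                best.add(prof.read_id, prof.alleles)
                home[prof.read_id] = best
                no = cluster_no[id(best)]
                for s in prof.alleles:
                    site_index.setdefault(s, set()).add(no)
                moved = True
        if not moved:
            break
    clusters = [cl for cl in clusters if cl.members]

    # merge clusters that share at least one site and whose consensus
    # vectors agree at a fraction >= 1 - tau of the shared sites (the same
    # tolerance that admits reads, so a single error-corrupted boundary
    # site cannot block the merge of two fragments of one haplotype);
    # clusters with disjoint site sets are never merged here — identifying
    # those as one haplotype is the job of the abundance matching in
    # link_by_frequency
    comp = variant_components(profiles)

    def comp_id(c: _Cluster) -> int:
        return min(comp[s] for s in c.counts) if c.counts else 0

    changed = True
    while changed:
        changed = False
        i = 0
        while i < len(clusters):
            j = i + 1
            while j < len(clusters):
                a, b = clusters[i], clusters[j]
                shared = [s for s in b.counts if s in a.counts]
                conflicts = sum(1 for s in shared
                                if a.consensus_at(s) != b.consensus_at(s))
                if shared and conflicts <= tau * len(shared):
                    a.absorb(b)
                    del clusters[j]
                    changed = True
                else:
                    j += 1
            i += 1

    # a cluster's local abundance is its read share among the assigned
    # reads that cover at least one of its sites — the reads that could
    # have joined it
    def local_abundance(c: _Cluster, assigned: set[str]) -> float:
        denom = sum(1 for p in ordered
                    if p.read_id in assigned
                    and any(s in c.counts for s in p.alleles))
        return len(c.members) / denom if denom else 0.0

    # drop weak clusters (size or local abundance floor), reassigning
    # their reads to the best survivor
    all_ids = {p.read_id for p in ordered}
    keep = [c for c in clusters
            if len(c.members) >= m_min
            and local_abundance(c, all_ids) >= a_min]
    dropped = [c for c in clusters if c not in keep]
    if keep:
        for cl in dropped:
            for read_id in cl.members:
                prof = prof_by_id[read_id]
                best = None
                best_frac = -1.0
                for cand in keep:
                    shared, matches = cand.agreement(prof.alleles)
                    if shared == 0:
                        continue
                    frac = matches / shared
                    if frac > best_frac:
                        best, best_frac = cand, frac
                if best is not None and best_frac >= 1.0 - tau:
                    best.add(read_id, prof.alleles)
    clusters = keep

    assigned_ids = {r for c in clusters for r in c.members}
    out = []
    for c in clusters:
        consensus = {s: c.consensus_at(s) for s in c.counts}
        out.append(SubpopCluster(
            cluster_id="", read_ids=sorted(c.members), consensus=consensus,
            abundance=local_abundance(c, assigned_ids), component_id=comp_id(c)))
    out.sort(key=lambda c: (-c.abundance, c.read_ids[0] if c.read_ids else ""))
    for i, c in enumerate(out):
        c.cluster_id = f"c{i + 1:03d}"
    return out


# ---------------------------------------------------------------------------
# frequency linkage across unlinked components
# ---------------------------------------------------------------------------

def link_by_frequency(
    clusters: Sequence[SubpopCluster],
    delta: float = 0.05,
) -> LinkResult:
    """Match haplotype groups with similar abundances into sub-populations.

    Clusters are processed in decreasing abundance; a run of clusters whose
    consecutive abundance estimates are compatible forms one candidate
    sub-population.  Two neighbouring estimates are compatible when they
    differ by at most ``delta`` plus one combined binomial standard error
    of the two estimates — ``delta`` is the systematic matching tolerance,
    the standard-error term absorbs the sampling noise of estimates backed
    by finitely many reads.

    Within a candidate, clusters that share a variant site are necessarily
    distinct haplotypes (they disagree there, or they would already have
    been merged): site-disjoint clusters of a candidate are united into one
    sub-population, site-sharing ones stay separate.  When a candidate
    mixes both — several site-sharing pairs whose pairing with the
    site-disjoint rest cannot be resolved by frequency alone — the match
    is ambiguous: the clusters involved are kept as separate
    sub-populations and a warning is recorded.

    Sub-population abundances are means over their matched clusters,
    renormalized to one.
    """
    if not clusters:
        raise ValueError("no clusters to link")

    # a component containing a single cluster is monomorphic after
    # clustering (its local abundance is 1 by construction) and carries no
    # frequency information; where polymorphic components exist, such
    # clusters are set aside — their reads stay unassigned
    from collections import Counter

    comp_counts = Counter(c.component_id for c in clusters)
    informative = [c for c in clusters if comp_counts[c.component_id] > 1]
    if informative:
        clusters = informative

    def se(c: SubpopCluster) -> float:
        return (c.abundance * (1.0 - c.abundance) / max(c.n_reads, 1)) ** 0.5

    order = sorted(clusters, key=lambda c: (-c.abundance, c.cluster_id))
    chains: list[list[SubpopCluster]] = [[order[0]]]
    for c in order[1:]:
        prev = chains[-1][-1]
        tol = delta + (se(prev) ** 2 + se(c) ** 2) ** 0.5
        if prev.abundance - c.abundance <= tol:
            chains[-1].append(c)
        else:
            chains.append([c])

    warnings_out: list[str] = []
    groups: list[list[SubpopCluster]] = []
    for chain in chains:
        sharing = {c.cluster_id: False for c in chain}
        for i, a in enumerate(chain):
            for b in chain[i + 1:]:
                if set(a.consensus) & set(b.consensus):
                    sharing[a.cluster_id] = sharing[b.cluster_id] = True
        disjoint = [c for c in chain if not sharing[c.cluster_id]]
        involved = [c for c in chain if sharing[c.cluster_id]]
        if disjoint:
            groups.append(disjoint)
        groups.extend([c] for c in involved)
        if involved and (disjoint or len({c.component_id for c in involved}) > 1):
            warnings_out.append(
                "ambiguous frequency match among clusters "
                f"{[c.cluster_id for c in involved]} (abundances "
                f"{[round(c.abundance, 4) for c in involved]}); kept separate")

    raw = [float(np.mean([c.abundance for c in g])) for g in groups]
    total = sum(raw)
    members = []
    assignment: dict[str, str] = {}
    order_idx = sorted(range(len(groups)), key=lambda i: (-raw[i], groups[i][0].cluster_id))
    for rank, i in enumerate(order_idx):
        sid = f"P{rank + 1}"
        members.append((sid, raw[i] / total))
        for c in groups[i]:
            assignment[c.cluster_id] = sid
    return LinkResult(SubpopulationSet(members), assignment, warnings_out)


# ---------------------------------------------------------------------------
# FASTM construction
# ---------------------------------------------------------------------------

def build_fastm(
    clusters: Sequence[SubpopCluster],
    cleaned_counts: CountsTable,
    subpops: SubpopulationSet,
    record_id: str,
    *,
    profiles: Sequence[ReadVariantProfile],
    assignment: dict[str, str],
    description: str = "",
) -> FastmRecord:
    """Distribute cleaned per-column frequencies over sub-populations.

    At variant columns the pooled mass of each state is split between
    sub-populations in proportion to ``abundance x member-read support``;
    at non-variant columns every sub-population receives its abundance
    share of the pooled distribution.  By construction the column-wise sum
    of rows equals the pooled cleaned distribution exactly, so
    marginalizing the result reproduces ``counts_to_fastv(cleaned_counts)``.
    """
    sub_ids = list(subpops.ids)
    ab = np.array([subpops.abundance(s) for s in sub_ids])
    read_subpop: dict[str, int] = {}
    for cl in clusters:
        sid = assignment.get(cl.cluster_id)
        if sid is None:
            continue
        si = sub_ids.index(sid)
        for read_id in cl.read_ids:
            read_subpop[read_id] = si

    # per-variant-column member-read state support, per sub-population
    support: dict[GappedCoordinate, np.ndarray] = {}
    for prof in profiles:
        si = read_subpop.get(prof.read_id)
        if si is None:
            continue
        for coord, b in prof.alleles.items():
            if coord not in support:
                support[coord] = np.zeros((len(sub_ids), N_STATES))
            support[coord][si, b] += 1.0

    columns = []
    for coord in cleaned_counts.coordinates():
        c = cleaned_counts.counts_at(coord).astype(float)
        depth = c.sum()
        if depth == 0:
            rows = {s: (0.0,) * N_STATES for s in sub_ids}
            columns.append((coord, FastmPositionMatrix(rows)))
            continue
        pooled = c / depth
        sup = support.get(coord)
        if sup is None:
            mat = ab[:, None] * pooled[None, :]
        else:
            weights = ab[:, None] * sup  # abundance-weighted read support
            colsum = weights.sum(axis=0)
            share = np.where(colsum > 0, weights / np.where(colsum > 0, colsum, 1.0),
                             ab[:, None] * np.ones(N_STATES)[None, :])
            mat = share * pooled[None, :]
        rows = {s: tuple(float(x) for x in mat[i]) for i, s in enumerate(sub_ids)}
        columns.append((coord, FastmPositionMatrix(rows)))
    return FastmRecord(id=record_id, subpops=subpops, columns=columns,
                       description=description)
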