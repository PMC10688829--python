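"""End-to-end orchestration: alignments -> counts -> calls -> FASTM.

This is the reference wiring of the individual modules:

1. pileup on the gapped consensus (:mod:`strainspace.pileup`),
2. exact-binomial separation of sequencing error from sub-population
   variation, with FDR control (:mod:`strainspace.stats`),
3. error removal from the counts,
4. read phasing, abundance linkage and FASTM construction
   (:mod:`strainspace.phasing`).

A run with no surviving variant site degenerates gracefully to a single
sub-population of abundance one.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

from .model import FastmPositionMatrix, FastmRecord, FastvRecord, SubpopulationSet
from .phasing import (
    LinkResult,
    ReadVariantProfile,
    SubpopCluster,
    build_fastm,
    cluster_reads,
    extract_read_profiles,
    link_by_frequency,
)
from .pileup import AlignmentRecord, CountsTable, build_counts, counts_to_fastv
from .stats import (
    ErrorModel,
    VariantCall,
    classify_states,
    clean_counts,
    error_states,
    variant_sites,
)


@dataclass
class PipelineResult:
    counts: CountsTable
    calls: list[VariantCall]
    cleaned_counts: CountsTable
    fastv: FastvRecord
    profiles: list[ReadVariantProfile]
    clusters: list[SubpopCluster]
    link: Optional[LinkResult]
    fastm: FastmRecord

    @property
    def subpops(self) -> SubpopulationSet:
        return self.fastm.subpops


def run_pipeline(
    alignments: Sequence[AlignmentRecord],
    reference: str,
    *,
    record_id: str = "sample",
    error_model: Union[str, ErrorModel] = "short",
    alpha: float = 0.05,
    tau: float = 0.1,
    delta: float = 0.05,
    m_min: int = 5,
    a_min: float = 0.01,
    min_mapq: int = 1,
) -> PipelineResult:
    """Run the full deconvolution pipeline on an in-memory alignment list."""
    model = ErrorModel.preset(error_model) if isinstance(error_model, str) \
        else error_model
    counts = build_counts(alignments, reference, min_mapq=min_mapq)
    calls = classify_states(counts, model, alpha)
    cleaned = clean_counts(counts, calls)
    fastv = counts_to_fastv(cleaned, record_id)
    sites = variant_sites(calls)
    errs = error_states(calls)

    profiles = extract_read_profiles(alignments, sites, errs,
                                     min_mapq=min_mapq) if sites else []
    if profiles:
        clusters = cluster_reads(profiles, tau=tau, m_min=m_min, a_min=a_min)
        link = link_by_frequency(clusters, delta=delta)
        fastm = build_fastm(clusters, cleaned, link.subpops, record_id,
                            profiles=profiles, assignment=link.assignment)
    else:
        clusters = []
        link = None
        subpops = SubpopulationSet([("P1", 1.0)])
        fastm = build_fastm([], cleaned, subpops, record_id,
                            profiles=[], assignment={})
    return PipelineResult(counts=counts, calls=calls, cleaned_counts=cleaned,
                          fastv=fastv, profiles=profiles, clusters=clusters,
                          link=link, fastm=fastm)
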