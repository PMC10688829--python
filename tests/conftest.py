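"""Shared fixtures and random-record generators for the test suite."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

import strainspace as ss
from strainspace.model import (
    FastmPositionMatrix,
    FastmRecord,
    FastvRecord,
    GappedCoordinate,
    StateDistribution,
    SubpopulationSet,
)

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("suite")


# ---------------------------------------------------------------------------
# random valid records (integer frequency grids, exact at a decimal precision)
# ---------------------------------------------------------------------------

def random_coordinates(rng: np.random.Generator, n_ref: int,
                       p_insertion: float = 0.15) -> list[GappedCoordinate]:
    coords = []
    for p in range(n_ref):
        coords.append(GappedCoordinate(p))
        k = 0
        while rng.random() < p_insertion and k < 3:
            k += 1
            coords.append(GappedCoordinate(p, k))
    return coords


def random_fastv_record(rng: np.random.Generator, *, n_ref: int = 20,
                        precision: int = 4, rec_id: str = "rand",
                        p_uncovered: float = 0.1) -> FastvRecord:
    """A valid FASTV record whose frequencies are exact multiples of
    10**-precision, so serialization at that precision is lossless."""
    unit = 10 ** precision
    columns = []
    for coord in random_coordinates(rng, n_ref):
        if rng.random() < p_uncovered:
            columns.append((coord, StateDistribution.uncovered_column()))
            continue
        weights = rng.dirichlet(np.full(5, 0.4))
        units = rng.multinomial(unit, weights)
        freqs = tuple(int(u) / unit for u in units)
        columns.append((coord, StateDistribution(freqs, coverage=int(rng.integers(1, 500)))))
    return FastvRecord(id=rec_id, description="randomized record", columns=columns)


def random_fastm_record(rng: np.random.Generator, *, n_subpops: int = 3,
                        n_ref: int = 12, precision: int = 4,
                        rec_id: str = "randm") -> FastmRecord:
    """A valid FASTM record with abundances and joint frequencies on the
    10**-precision grid (row sums equal abundances exactly)."""
    unit = 10 ** precision
    cuts = np.sort(rng.choice(np.arange(1, unit), size=n_subpops - 1, replace=False))
    parts = np.diff(np.concatenate([[0], cuts, [unit]]))
    ids = [f"sp{i + 1}" for i in range(n_subpops)]
    subpops = SubpopulationSet([(i, int(u) / unit) for i, u in zip(ids, parts)])
    units_by_id = {i: int(u) for i, u in zip(ids, parts)}
    columns = []
    for coord in random_coordinates(rng, n_ref):
        if rng.random() < 0.08:
            rows = {i: (0.0,) * 5 for i in ids}
        else:
            rows = {}
            for i in ids:
                w = rng.dirichlet(np.full(5, 0.4))
                ru = rng.multinomial(units_by_id[i], w)
                rows[i] = tuple(int(u) / unit for u in ru)
        columns.append((coord, FastmPositionMatrix(rows)))
    return FastmRecord(id=rec_id, subpops=subpops, columns=columns)


# ---------------------------------------------------------------------------
# simulated study fixtures
# ---------------------------------------------------------------------------

TWO_STRAIN_CONFIG = dict(
    genome_length=20000,
    n_subpops=2,
    snps_per_subpop=30,          # 60 truth SNPs in the mixture
    indels_per_subpop=[2, 1],    # 3 small indels
    abundances=[0.7, 0.3],
    read_profile="short",
    mean_depth=100.0,
)


@pytest.fixture(scope="session")
def two_strain_bundle() -> ss.TruthBundle:
    """Two-strain mixture at the reference study conditions, seed 42."""
    cfg = ss.SimulationConfig(**TWO_STRAIN_CONFIG)
    bundle = ss.simulate_population(cfg, 42)
    ss.simulate_reads(bundle, cfg.read_profile, cfg.mean_depth, 43)
    return bundle


@pytest.fixture(scope="session")
def two_strain_result(two_strain_bundle) -> ss.PipelineResult:
    return ss.run_pipeline(two_strain_bundle.alignments,
                           two_strain_bundle.reference,
                           record_id="two_strain")
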