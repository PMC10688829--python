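"""Separating sequencing error from sub-population variation.

The statistical core is a one-sided exact binomial test: at a column with
depth ``n``, a non-consensus state observed ``k`` times is tested against
the technology's error rate ``e`` appropriate for that state —

* a base at a reference column: ``substitution_rate / 3`` (substitution
  errors are split uniformly over the three alternative bases);
* a gap at a reference column: ``deletion_rate``;
* a base at an insertion column: ``insertion_rate``;
* a gap at an insertion column (reads lacking an otherwise fixed
  insertion): ``deletion_rate``.

The p-value is ``P(X >= k)`` for ``X ~ Binomial(n, e)``.  Benjamini-
Hochberg false-discovery-rate control is applied jointly across all
column x alternative-state tests of a table — including the unobserved
(zero-count) alternatives, which enter with p = 1 so that the family size
reflects every test the scan performs.  A state is called a
``subpopulation_variant`` when its q-value is at most ``alpha``; otherwise
it is classified as ``error``.  The majority state of each column is the
``consensus``.

``min_coverage`` inverts the test: the smallest depth at which a variant
segregating at frequency ``f`` is detected with the requested power, given
the error rate and the per-test significance level.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats as sps

from .model import GAP, N_STATES, STATES, GappedCoordinate
from .pileup import CountsTable

CONSENSUS = "consensus"
SUBPOP_VARIANT = "subpopulation_variant"
ERROR = "error"


@dataclass(frozen=True)
class ErrorModel:
    """Technology-specific per-base error rates.

    ``substitution_rate`` is the probability that a read base is *any*
    wrong base; the per-specific-alternative rate is a third of it.
    """

    substitution_rate: float
    insertion_rate: float
    deletion_rate: float
    technology_label: str = "custom"

    def __post_init__(self) -> None:
        for name in ("substitution_rate", "insertion_rate", "deletion_rate"):
            r = getattr(self, name)
            if not (0.0 <= r < 0.5):
                raise ValueError(f"{name} must be in [0, 0.5), got {r}")

    @property
    def per_alternative_substitution(self) -> float:
        return self.substitution_rate / 3.0

    @classmethod
    def preset(cls, name: str) -> "ErrorModel":
        try:
            return _PRESETS[name]
        except KeyError:
            raise KeyError(
                f"unknown error-model preset {name!r}; "
                f"available: {sorted(_PRESETS)}") from None


#: Presets anchored to published platform characteristics: raw long reads
#: run at ~10% total error, dominated by indels; error-corrected long reads
#: at about 3%; short-read (Illumina-like) data are substitution-dominated
#: with a low base-calling error rate.
_PRESETS = {
    "short": ErrorModel(0.001, 1e-5, 1e-5, "short"),
    "long_raw": ErrorModel(0.02, 0.04, 0.04, "long_raw"),
    "long_corrected": ErrorModel(0.006, 0.012, 0.012, "long_corrected"),
}


@dataclass(frozen=True)
class VariantCall:
    coordinate: GappedCoordinate
    state: str                      # one of A, C, T, G, -
    count: int
    frequency: float
    p_value: float
    q_value: float
    classification: str             # consensus | subpopulation_variant | error


def binomial_tail(k: int, n: int, e: float) -> float:
    """Exact upper binomial tail ``P(X >= k)`` for ``X ~ Binomial(n, e)``."""
    if not (0 <= k <= n):
        raise ValueError(f"require 0 <= k <= n, got k={k}, n={n}")
    if not (0.0 <= e < 1.0):
        raise ValueError(f"require 0 <= e < 1, got e={e}")
    if k == 0:
        return 1.0
    return float(sps.binom.sf(k - 1, n, e))


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return sps.false_discovery_control(p, method="bh")


def _state_error_rates(model: ErrorModel, is_insertion: bool) -> np.ndarray:
    e = np.empty(N_STATES)
    e[:4] = model.insertion_rate if is_insertion else model.per_alternative_substitution
    e[GAP] = model.deletion_rate
    return e


def classify_states(
    counts: CountsTable,
    model: ErrorModel,
    alpha: float = 0.05,
) -> list[VariantCall]:
    """Classify every observed state of every covered column.

    Returns one :class:`VariantCall` per (column, state) with count > 0;
    zero-count alternatives contribute to the BH family but emit no call.
    """
    if not (0.0 < alpha < 1.0):
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    coords = list(counts.coordinates())
    if not coords:
        raise ValueError("empty counts table")

    mat = np.stack([counts.counts_at(c) for c in coords])      # (n_cols, 5)
    depth = mat.sum(axis=1)
    covered = depth > 0
    cons = mat.argmax(axis=1)                                  # canonical tie-break
    is_ins = np.array([c.is_insertion for c in coords])

    # p-values for every (covered column, non-consensus state)
    e_ref = _state_error_rates(model, False)
    e_insc = _state_error_rates(model, True)
    erate = np.where(is_ins[:, None], e_insc[None, :], e_ref[None, :])
    with np.errstate(divide="ignore"):
        pmat = sps.binom.sf(mat - 1, depth[:, None], erate)
    pmat = np.where(mat == 0, 1.0, pmat)                       # tail at k=0 is 1

    test_mask = covered[:, None] & (np.arange(N_STATES)[None, :] != cons[:, None])
    qmat = np.ones_like(pmat)
    qmat[test_mask] = bh_adjust(pmat[test_mask])

    calls: list[VariantCall] = []
    for i, coord in enumerate(coords):
        if not covered[i]:
            continue
        n = int(depth[i])
        for b in range(N_STATES):
            k = int(mat[i, b])
            if k == 0:
                continue
            if b == cons[i]:
                calls.append(VariantCall(coord, STATES[b], k, k / n, 1.0, 1.0,
                                         CONSENSUS))
            else:
                q = float(qmat[i, b])
                cls_ = SUBPOP_VARIANT if q <= alpha else ERROR
                calls.append(VariantCall(coord, STATES[b], k, k / n,
                                         float(pmat[i, b]), q, cls_))
    return calls


def clean_counts(counts: CountsTable, calls: Iterable[VariantCall]) -> CountsTable:
    """Zero the counts of error-classified states; depth follows the counts.

    Consensus and subpopulation_variant states are untouched.
    """
    out = counts.copy()
    for call in calls:
        if call.classification != ERROR:
            continue
        col = out.counts_at(call.coordinate)
        b = STATES.index(call.state)
        if col[b] != call.count:
            raise ValueError(
                f"call/table mismatch at {call.coordinate.label()} state "
                f"{call.state}: table has {col[b]}, call has {call.count}")
        col[b] = 0
    return out


def variant_sites(calls: Iterable[VariantCall]) -> list[GappedCoordinate]:
    """Columns with at least two non-error states (consensus + variant)."""
    sites = {c.coordinate for c in calls if c.classification == SUBPOP_VARIANT}
    return sorted(sites)


def error_states(calls: Iterable[VariantCall]) -> set[tuple[GappedCoordinate, int]]:
    """(coordinate, state index) pairs classified as sequencing error."""
    return {(c.coordinate, STATES.index(c.state))
            for c in calls if c.classification == ERROR}


def min_coverage(
    f: float,
    e: float,
    alpha: float = 0.05,
    power: float = 0.95,
    *,
    n_max: int = 10000,
) -> int:
    """Smallest depth at which a frequency-``f`` variant is detectable.

    For each depth ``n`` the critical count is
    ``k*(n) = min{k : P(X >= k | n, e) <= alpha}``; the returned value is
    the smallest ``n`` whose detection probability
    ``P(X >= k*(n)) for X ~ Binomial(n, f)`` reaches ``power``.  The
    detection model treats the observed variant count as Binomial(n, f),
    ignoring second-order error contamination.
    """
    if not (0.0 <= e < 1.0) or not (0.0 < f <= 1.0):
        raise ValueError("require 0 <= e < 1 and 0 < f <= 1")
    if not (0.0 < alpha < 1.0) or not (0.0 < power < 1.0):
        raise ValueError("alpha and power must be in (0, 1)")
    if f <= e:
        raise ValueError(
            f"infeasible: variant frequency f={f} does not exceed error rate e={e}")
    ns = np.arange(1, n_max + 1)
    # scipy isf: smallest j with P(X > j) <= alpha; the critical count is j + 1
    kstar = sps.binom.isf(alpha, ns, e).astype(np.int64) + 1
    kstar = np.minimum(kstar, ns + 1)      # kstar > n: no rejection possible
    detect = np.where(kstar <= ns, sps.binom.sf(np.minimum(kstar, ns) - 1, ns, f), 0.0)
    feasible = (kstar <= ns) & (detect >= power)
    idx = np.flatnonzero(feasible)
    if idx.size == 0:
        raise ValueError(
            f"no depth up to {n_max} reaches power {power} for f={f}, e={e}, "
            f"alpha={alpha}")
    return int(ns[idx[0]])


def calls_to_dataframe(calls: Sequence[VariantCall]) -> pd.DataFrame:
    rows = [(c.coordinate.ref_pos + 1, c.coordinate.insert_index, c.state,
             c.count, c.frequency, c.p_value, c.q_value, c.classification)
            for c in calls]
    return pd.DataFrame(rows, columns=["ref_pos", "insert_index", "state", "count",
                                       "frequency", "p_value", "q_value",
                                       "classification"])


def calls_from_dataframe(df: pd.DataFrame) -> list[VariantCall]:
    return [VariantCall(GappedCoordinate(int(r.ref_pos) - 1, int(r.insert_index)),
                        str(r.state), int(r.count), float(r.frequency),
                        float(r.p_value), float(r.q_value), str(r.classification))
            for r in df.itertuples()]
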