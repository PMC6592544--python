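"""Read-count-aware variant of the neighbor-enrichment test.

Instead of the plain neighbor count ``d``, the test statistic becomes a sum
of transformed read counts over the neighbors, ``s = sum_i f(c_i)``.  Under
the null, each neighbor's abundance is an independent draw from the
empirical distribution ``P_f`` of transformed abundances, so

    P(s | d) = P_f convolved with itself d times,   P(s|0) = delta at 0,
    P(s | sigma) = sum_d P(s | d) P(d | sigma),

with ``P(d | sigma)`` the same Poisson null as the basic method.  Because
clone sizes follow a power law, the default transform is ``f(c) = log c``
and the distribution is discretized on a fixed-width logarithmic grid.  The
indicator transform ``f(c) = 1`` for any observed clone recovers the basic
method exactly (``s = d``), and the pipeline delegates to it in that case so
the reduction is bit-exact.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy import stats

from .core import (
    AliceConfig,
    HitRecord,
    _adjust,
    _count_from_map,
    data_length_counts,
    eligible_aa_counts,
    length_dependent_q,
    run_alice,
)
from .genmodel import GenModel, PgenCache, neighborhood_pgen
from .io import Repertoire, VJClass, partition_by_vj
from .seqs import neighborhood

_PROB_TOL = 1e-9
#: Poisson tail mass beyond which the d-mixture is truncated
_TAIL_EPS = 1e-12

TRANSFORMS: dict[str, Callable[[int], float]] = {
    "indicator": lambda c: 1.0 if c > 0 else 0.0,
    "identity": lambda c: float(c),
    "log": lambda c: math.log(c),
}


@dataclass
class AbundanceDistribution:
    """Discretized distribution of transformed clone abundances f(c).

    Values are binned on a uniform grid of width ``width``; bin ``k`` holds
    transformed abundances rounding to ``k * width``.  ``offset`` is the
    index of the first bin with nonzero probability.
    """

    transform: str
    width: float
    offset: int
    probabilities: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.probabilities, dtype=float)
        if (p < 0).any() or abs(p.sum() - 1.0) > _PROB_TOL:
            raise ValueError("probabilities must be nonnegative and sum to 1")
        self.probabilities = p

    @property
    def bin_edges(self) -> np.ndarray:
        k = np.arange(self.offset, self.offset + self.probabilities.size + 1)
        return (k - 0.5) * self.width

    @property
    def mean(self) -> float:
        k = np.arange(self.offset, self.offset + self.probabilities.size)
        return float((k * self.width * self.probabilities).sum())

    def bin_index(self, value: float) -> int:
        return int(round(value / self.width))


def empirical_abundance_distribution(
    rep: Repertoire,
    transform: str = "log",
    min_reads: int = 2,
    width: float = 0.1,
) -> AbundanceDistribution:
    """Empirical P_f over the neighbor-eligible clonotypes of a repertoire.

    Pooled over the whole sample (not per VJ class) and computed once per
    run; only clonotypes passing the neighbor read filter contribute, since
    only those can appear in any ``s``.  The log transform requires counts
    >= 1 (guaranteed by the filter).
    """
    if transform not in TRANSFORMS:
        raise ValueError(f"unknown transform {transform!r}")
    counts = [c.read_count for c in rep.clonotypes if c.read_count >= min_reads]
    if not counts:
        raise ValueError("no neighbor-eligible clonotypes in repertoire")
    if transform == "log" and min(counts) < 1:
        raise ValueError("log transform requires read counts >= 1")
    f = TRANSFORMS[transform]
    if transform == "identity":
        width = 1.0  # counts are integers; keep the grid exact
    idx = np.array([round(f(c) / width) for c in counts], dtype=int)
    lo, hi = int(idx.min()), int(idx.max())
    probs = np.bincount(idx - lo, minlength=hi - lo + 1).astype(float)
    probs /= probs.sum()
    return AbundanceDistribution(transform, width, lo, probs)


@dataclass
class ConvolvedNull:
    """Conditional statistics P(s|d) for d = 0..d_max on a shared grid."""

    pf: AbundanceDistribution
    offsets: list[int]
    distributions: list[np.ndarray]

    @property
    def d_max(self) -> int:
        return len(self.distributions) - 1

    def tail(self, d: int, s_index: int) -> float:
        """P(S_d >= s_index * width) for the d-fold convolution."""
        probs, off = self.distributions[d], self.offsets[d]
        start = max(s_index - off, 0)
        if start >= probs.size:
            return 0.0
        return float(probs[start:].sum())


def convolve_null(pf: AbundanceDistribution, d_max: int) -> ConvolvedNull:
    """Iterated discrete convolution of P_f: P(s|d) for d = 0..d_max.

    ``P(s|0)`` is a point mass at 0; each further conditional is the
    convolution of the previous one with P_f (grid offsets add).
    """
    if d_max < 1:
        raise ValueError("d_max must be >= 1")
    offsets = [0]
    dists = [np.array([1.0])]
    for _ in range(d_max):
        offsets.append(offsets[-1] + pf.offset)
        dists.append(np.convolve(dists[-1], pf.probabilities))
    return ConvolvedNull(pf, offsets, dists)


def required_d_max(lam: float, tail_eps: float = _TAIL_EPS) -> int:
    """Smallest d with Poisson(lam) upper-tail mass below ``tail_eps``."""
    if lam <= 0:
        return 1
    d = max(1, int(lam))
    while stats.poisson.sf(d, lam) >= tail_eps:
        d += 1
    return d


def abundance_pvalue(
    s_obs: float, lam: float, null: ConvolvedNull, d_max_check: bool = True
) -> float:
    """Upper-tail probability P(s >= s_obs) under the Poisson mixture.

    The mixture over d is truncated at ``null.d_max``; the remaining Poisson
    tail mass is added in full (conservative).  Raises when the supplied
    null does not cover the Poisson tail at this lambda.
    """
    if lam < 0:
        raise ValueError("lambda must be nonnegative")
    if d_max_check and lam > 0 and stats.poisson.sf(null.d_max, lam) >= _TAIL_EPS:
        raise ValueError(
            f"d_max={null.d_max} leaves Poisson tail mass >= {_TAIL_EPS} "
            f"at lambda={lam}; rebuild the null with a larger d_max"
        )
    s_index = int(math.ceil(s_obs / null.pf.width - 1e-9))
    if lam == 0.0:
        return 1.0 if s_index <= 0 else 0.0
    if s_index <= min(null.offsets):
        return 1.0  # below every attainable s: the full mass lies above
    pmf = stats.poisson.pmf(np.arange(null.d_max + 1), lam)
    p = sum(
        float(pmf[d]) * null.tail(d, s_index) for d in range(null.d_max + 1)
    )
    p += float(stats.poisson.sf(null.d_max, lam))
    return min(max(p, 0.0), 1.0)


def run_alice_abundance(
    rep: Repertoire,
    model: GenModel,
    cfg: AliceConfig | None = None,
    pgen_cache: PgenCache | None = None,
) -> list[HitRecord]:
    """Abundance-aware pipeline: the basic run with d replaced by s.

    Same filters, gate, zero-neighborhood discard, BH adjustment, and
    significance threshold as :func:`~alicetcr.core.run_alice`; only the test
    statistic and its null change.  With the indicator transform the method
    collapses to the basic one (s = d) and this function delegates to it,
    annotating ``s_obs = d_obs``.
    """
    cfg = cfg or AliceConfig()
    transform = cfg.abundance_transform
    if transform in ("off", "indicator"):
        records = run_alice(rep, model, cfg, pgen_cache)
        for r in records:
            r.s_obs = float(r.d_obs)
        return records
    if pgen_cache is None:
        pgen_cache = PgenCache(model, cfg.n_sim, cfg.seed)
    pf = empirical_abundance_distribution(
        rep, transform, cfg.min_neighbor_reads, cfg.log_bin_width
    )
    records: list[HitRecord] = []
    for vjclass in partition_by_vj(rep):
        records.extend(_test_class_abundance(vjclass, cfg, pgen_cache, pf))
    lam_max = max((r.lam for r in records if r.tested), default=0.0)
    null = convolve_null(pf, max(required_d_max(lam_max), 1))
    for r in records:
        if r.tested:
            r.p_raw = abundance_pvalue(r.s_obs, r.lam, null)
    _adjust(records, cfg)
    return records


def _test_class_abundance(
    vjclass: VJClass, cfg: AliceConfig, pgen_cache: PgenCache, pf: AbundanceDistribution
) -> list[HitRecord]:
    from .core import HitRecord, null_lambda  # local alias for clarity

    f = TRANSFORMS[pf.transform]
    aa_counts = eligible_aa_counts(vjclass, cfg.min_neighbor_reads)
    by_aa: dict[str, list[int]] = {}
    for c in vjclass.members:
        if c.read_count >= cfg.min_neighbor_reads:
            by_aa.setdefault(c.cdr3_aa, []).append(c.read_count)
    sigmas = sorted({c.cdr3_aa for c in vjclass.members})
    gated = [
        (s, d) for s in sigmas if (d := _count_from_map(aa_counts, s)) > cfg.d_gate
    ]
    if not gated:
        return []
    table = pgen_cache.table(vjclass.vj)
    q_by_length = None
    if cfg.use_length_dependent_q:
        q_by_length = length_dependent_q(
            data_length_counts(vjclass), table.length_counts, cfg.q
        )
    out: list[HitRecord] = []
    for sigma, d in gated:
        nb_pgen = neighborhood_pgen(table, sigma)
        if nb_pgen == 0.0:
            out.append(
                HitRecord(
                    sigma, *vjclass.vj, d_obs=d, lam=0.0, p_raw=float("nan"),
                    p_adj=float("nan"), significant=False, tested=False,
                    zero_neighborhood=True, n_class=vjclass.n,
                )
            )
            continue
        # s is accumulated on the same grid P_f lives on, so observed and
        # null statistics are exactly comparable
        s_idx = sum(
            pf.bin_index(f(c))
            for s2 in neighborhood(sigma)
            for c in by_aa.get(s2, ())
        )
        lam = null_lambda(vjclass, sigma, table, cfg, q_by_length)
        out.append(
            HitRecord(
                sigma, *vjclass.vj, d_obs=d, lam=lam, p_raw=1.0, p_adj=1.0,
                significant=False, n_class=vjclass.n, neighborhood_pgen=nb_pgen,
                s_obs=s_idx * pf.width,
            )
        )
    return out
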