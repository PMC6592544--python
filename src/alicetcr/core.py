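"""The neighbor-enrichment test: Poisson null, filters, FDR, and the d/n baseline.

For each amino-acid CDR3 ``sigma`` present in a VJ class of ``n`` unique
nucleotide clonotypes, the observed neighbor count ``d(sigma)`` is the number
of nucleotide clonotypes (with more than one read) whose amino-acid sequence
lies in the one-mismatch neighborhood of ``sigma`` — including other
nucleotide variants of ``sigma`` itself.  Under the null hypothesis that the
repertoire is a sample from recombination alone, ``d`` is Poisson with mean

    lambda = n * Q * sum_{sigma' ~ sigma} P_gen(sigma'),

where ``Q`` is the thymic-selection rescaling factor (a fraction ``1/Q`` of
generated sequences is eliminated before entering the periphery; default
``Q = 9.41``).  Sequences with ``d(sigma) > 2`` are tested; upper-tail
Poisson p-values are Benjamini-Hochberg adjusted, and adjusted p below
``alpha`` (default 0.001) marks a hit.  Sequences whose Monte-Carlo-estimated
neighborhood probability is zero are discarded before testing (they carry no
usable null and typically reflect sequencing artifacts).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .genmodel import GenModel, PgenCache, PgenTable, neighborhood_pgen
from .io import Repertoire, VJClass, partition_by_vj
from .seqs import neighborhood

logger = logging.getLogger(__name__)

#: smallest positive double; p-values are floored here instead of under-flowing to 0
_TINY = 5e-324


@dataclass
class AliceConfig:
    """Tunable parameters of the neighbor-enrichment pipeline.

    Defaults follow the published configuration: selection factor
    ``q = 9.41`` (averaged over VJ combinations), neighbors require more than
    one read (``min_neighbor_reads = 2``), only sequences with ``d > 2`` are
    tested (``d_gate = 2``), and hits are BH-adjusted p < 0.001.
    """

    q: float = 9.41
    use_length_dependent_q: bool = False
    min_neighbor_reads: int = 2
    d_gate: int = 2
    alpha: float = 0.001
    n_sim: int = 1_000_000
    seed: int = 0
    bh_scope: str = "global"  # or "per_vj"
    abundance_transform: str = "off"  # off | indicator | identity | log
    log_bin_width: float = 0.1

    def __post_init__(self) -> None:
        if self.q <= 0:
            raise ValueError("q must be positive")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.d_gate < 0:
            raise ValueError("d_gate must be >= 0")
        if self.min_neighbor_reads < 1:
            raise ValueError("min_neighbor_reads must be >= 1")
        if self.n_sim < 1:
            raise ValueError("n_sim must be >= 1")
        if self.bh_scope not in ("global", "per_vj"):
            raise ValueError("bh_scope must be 'global' or 'per_vj'")
        if self.abundance_transform not in ("off", "indicator", "identity", "log"):
            raise ValueError("unknown abundance transform")
        if self.log_bin_width <= 0:
            raise ValueError("log_bin_width must be positive")


@dataclass
class HitRecord:
    """One tested amino-acid CDR3 with its statistics."""

    sigma: str
    v_gene: str
    j_gene: str
    d_obs: int
    lam: float
    p_raw: float
    p_adj: float
    significant: bool
    tested: bool = True
    zero_neighborhood: bool = False
    n_class: int = 0
    neighborhood_pgen: float = 0.0
    s_obs: float | None = None


def hits_to_frame(hits: Sequence[HitRecord]) -> pd.DataFrame:
    """Tabulate hit records (column order matches the hits TSV)."""
    return pd.DataFrame(
        {
            "sigma": [h.sigma for h in hits],
            "v": [h.v_gene for h in hits],
            "j": [h.j_gene for h in hits],
            "d_obs": [h.d_obs for h in hits],
            "lambda": [h.lam for h in hits],
            "p_raw": [h.p_raw for h in hits],
            "p_adj": [h.p_adj for h in hits],
            "significant": [h.significant for h in hits],
            "tested": [h.tested for h in hits],
            "zero_neighborhood": [h.zero_neighborhood for h in hits],
            "n_class": [h.n_class for h in hits],
            "neighborhood_pgen": [h.neighborhood_pgen for h in hits],
            "s_obs": [h.s_obs for h in hits],
        }
    )


def write_hits(hits: Sequence[HitRecord], path) -> None:
    hits_to_frame(hits).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# neighbor counting
# ---------------------------------------------------------------------------


def eligible_aa_counts(vjclass: VJClass, min_reads: int) -> dict[str, int]:
    """Map amino-acid CDR3 -> number of neighbor-eligible nucleotide clonotypes.

    A nucleotide clonotype is neighbor-eligible when its read count is at
    least ``min_reads`` (singletons are excluded by default because they are
    enriched in sequencing errors).
    """
    counts: dict[str, int] = {}
    for c in vjclass.members:
        if c.read_count >= min_reads:
            counts[c.cdr3_aa] = counts.get(c.cdr3_aa, 0) + 1
    return counts


def count_neighbors(vjclass: VJClass, sigma: str, min_reads: int = 2) -> int:
    """Observed neighbor count d(sigma) within one VJ class.

    Counts distinct nucleotide clonotypes with ``read_count >= min_reads``
    whose amino-acid CDR3 is within Hamming distance 1 of ``sigma`` (same
    length); nucleotide variants of ``sigma`` itself are valid neighbors.
    """
    if all(c.cdr3_aa != sigma for c in vjclass.members):
        raise ValueError(f"{sigma!r} does not occur in class {vjclass.vj}")
    counts = eligible_aa_counts(vjclass, min_reads)
    return _count_from_map(counts, sigma)


def _count_from_map(aa_counts: Mapping[str, int], sigma: str) -> int:
    return sum(aa_counts.get(s, 0) for s in neighborhood(sigma))


# ---------------------------------------------------------------------------
# null mean and p-values
# ---------------------------------------------------------------------------


def poisson_pvalue(d_obs: int, lam: float) -> float:
    """Upper-tail Poisson probability P(d >= d_obs | lambda), computed stably.

    Uses the survival function; for means so small that the tail underflows,
    the leading term is evaluated in log space and the result floored at the
    smallest positive double rather than returning exactly 0.
    """
    if d_obs < 0 or lam < 0:
        raise ValueError("d_obs and lambda must be nonnegative")
    if d_obs == 0:
        return 1.0
    if lam == 0.0:
        return 0.0
    p = float(stats.poisson.sf(d_obs - 1, lam))
    if p == 0.0:
        log_lead = -lam + d_obs * math.log(lam) - math.lgamma(d_obs + 1)
        p = math.exp(log_lead) if log_lead > -745 else 0.0
        p = max(p, _TINY)
    return min(p, 1.0)


def null_lambda(
    vjclass: VJClass,
    sigma: str,
    pgen_table: PgenTable,
    cfg: AliceConfig,
    q_by_length: Mapping[int, float] | None = None,
) -> float:
    """Null mean lambda = n * Q_eff * neighborhood P_gen for one sequence."""
    if pgen_table.vj != vjclass.vj:
        raise ValueError(f"table VJ {pgen_table.vj} != class VJ {vjclass.vj}")
    q_eff = cfg.q
    if cfg.use_length_dependent_q:
        if q_by_length is None:
            q_by_length = length_dependent_q(
                data_length_counts(vjclass), pgen_table.length_counts, cfg.q
            )
        q_eff = q_by_length[len(sigma)]
    return vjclass.n * q_eff * neighborhood_pgen(pgen_table, sigma)


def data_length_counts(vjclass: VJClass) -> dict[int, int]:
    """CDR3 amino-acid length histogram over a class's unique clonotypes."""
    out: dict[int, int] = {}
    for c in vjclass.members:
        out[len(c.cdr3_aa)] = out.get(len(c.cdr3_aa), 0) + 1
    return out


def length_dependent_q(
    data_length_counts: Mapping[int, int],
    gen_length_counts: Mapping[int, int],
    q: float,
    pseudocount: int = 1,
) -> dict[int, float]:
    """Per-length selection factors Q_L for one VJ class.

    With ``R_L = P_data(L) / P_gen(L)``, each length gets

        Q_L = Q * R_L / sum_L' R_L' * P_data(L'),

    so lengths over-represented in the data relative to the recombination
    model carry a larger selection factor while the average over the data's
    length distribution stays Q.  Computed in exact rational arithmetic on
    the integer counts, so matched data/model length distributions yield
    ``Q_L == Q`` bit-exactly.  Lengths present in the data but never
    simulated get a pseudocount in the model histogram (logged).
    """
    if not data_length_counts:
        raise ValueError("empty data length distribution")
    if not gen_length_counts:
        raise ValueError("empty simulated length distribution")
    gen = dict(gen_length_counts)
    regularized = [L for L in data_length_counts if gen.get(L, 0) == 0]
    for L in regularized:
        gen[L] = pseudocount
    if regularized:
        logger.info(
            "length-dependent Q: pseudocount applied to lengths %s", regularized
        )
    nd = sum(data_length_counts.values())
    ng = sum(gen.values())
    ratio = {
        L: Fraction(c * ng, nd * gen[L]) for L, c in data_length_counts.items()
    }
    denom = sum(
        ratio[L] * Fraction(c, nd) for L, c in data_length_counts.items()
    )
    # r/denom stays rational until the very end, so matched distributions
    # give float(r/denom) == 1.0 and Q_L == Q to the bit
    return {L: q * float(r / denom) for L, r in ratio.items()}


def benjamini_hochberg(p_values: Iterable[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if (p <= 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# the pipeline
# ---------------------------------------------------------------------------


def run_alice(
    rep: Repertoire,
    model: GenModel,
    cfg: AliceConfig | None = None,
    pgen_cache: PgenCache | None = None,
) -> list[HitRecord]:
    """Run the full neighbor-enrichment pipeline on a collapsed repertoire.

    For every VJ class, every distinct amino-acid CDR3 with an observed
    neighbor count above the d-gate is tested against its Poisson null;
    raw p-values are BH-adjusted (globally by default) and hits flagged at
    ``cfg.alpha``.  Sequences with Monte-Carlo neighborhood probability 0
    are discarded before adjustment and returned flagged, untested.

    A :class:`~alicetcr.genmodel.PgenCache` may be supplied to reuse
    Monte-Carlo tables across runs; otherwise one is created from
    ``cfg.n_sim``/``cfg.seed``.  The run is deterministic given the seed.
    """
    cfg = cfg or AliceConfig()
    if pgen_cache is None:
        pgen_cache = PgenCache(model, cfg.n_sim, cfg.seed)
    records: list[HitRecord] = []
    for vjclass in partition_by_vj(rep):
        records.extend(_test_class(vjclass, cfg, pgen_cache))
    _adjust(records, cfg)
    return records


def _test_class(
    vjclass: VJClass, cfg: AliceConfig, pgen_cache: PgenCache
) -> list[HitRecord]:
    aa_counts = eligible_aa_counts(vjclass, cfg.min_neighbor_reads)
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
    out = []
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
        lam = null_lambda(vjclass, sigma, table, cfg, q_by_length)
        out.append(
            HitRecord(
                sigma, *vjclass.vj, d_obs=d, lam=lam,
                p_raw=poisson_pvalue(d, lam), p_adj=1.0, significant=False,
                n_class=vjclass.n, neighborhood_pgen=nb_pgen,
            )
        )
    return out


def _adjust(records: list[HitRecord], cfg: AliceConfig) -> None:
    """BH-adjust tested records in place, globally or per VJ class."""
    if cfg.bh_scope == "global":
        families = [[r for r in records if r.tested]]
    else:
        by_vj: dict[tuple[str, str], list[HitRecord]] = {}
        for r in records:
            if r.tested:
                by_vj.setdefault((r.v_gene, r.j_gene), []).append(r)
        families = list(by_vj.values())
    for family in families:
        if not family:
            continue
        adj = benjamini_hochberg([r.p_raw for r in family])
        for r, pa in zip(family, adj):
            r.p_adj = float(pa)
            r.significant = bool(pa < cfg.alpha)


# ---------------------------------------------------------------------------
# naive d/n baseline
# ---------------------------------------------------------------------------


@dataclass
class DHit:
    sigma: str
    v_gene: str
    j_gene: str
    d_obs: int
    n_class: int

    @property
    def d_over_n(self) -> float:
        return self.d_obs / self.n_class


def d_hits_baseline(
    vjclasses: Sequence[VJClass],
    threshold: float | None = None,
    k: int | None = None,
    min_neighbor_reads: int = 2,
    d_gate: int = 0,
) -> tuple[list[DHit], float]:
    """Naive neighbor-density baseline: select sequences by d(sigma)/n alone.

    Either select every sequence with ``d/n >= threshold``, or calibrate by
    count: given a target hit count ``k``, use the k-th largest d/n as the
    threshold (all ties included, so the returned set may exceed ``k``).
    Returns ``(hits, threshold_used)``.  No recombination model is involved —
    this is the baseline the Poisson test improves upon.
    """
    if (threshold is None) == (k is None):
        raise ValueError("provide exactly one of threshold or k")
    if threshold is not None and threshold < 0:
        raise ValueError("threshold must be >= 0")
    candidates: list[DHit] = []
    for vjclass in vjclasses:
        aa_counts = eligible_aa_counts(vjclass, min_neighbor_reads)
        for sigma in sorted({c.cdr3_aa for c in vjclass.members}):
            d = _count_from_map(aa_counts, sigma)
            if d > d_gate:
                candidates.append(DHit(sigma, *vjclass.vj, d_obs=d, n_class=vjclass.n))
    if k is not None:
        if k <= 0:
            return [], float("inf")
        ratios = sorted((c.d_over_n for c in candidates), reverse=True)
        if not ratios:
            return [], float("inf")
        threshold = ratios[min(k, len(ratios)) - 1]
    hits = [c for c in candidates if c.d_over_n >= threshold]
    hits.sort(key=lambda h: (-h.d_over_n, h.sigma))
    return hits, float(threshold)
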