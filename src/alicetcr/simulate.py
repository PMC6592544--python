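"""Synthetic repertoires with known ground truth.

A null repertoire is a set of distinct nucleotide rearrangements sampled from
the generative recombination model with power-law (zipf) read counts — the
situation in which the neighbor-enrichment test should find nothing.  On top
of that, convergent-response clusters can be planted: groups of clonotypes
whose amino-acid CDR3s sit within one substitution of a low-generation-
probability seed, with read counts high enough to pass the neighbor filter.
Optionally, sequencing errors are injected as singleton one-nucleotide
variants of existing clonotypes — the artifact the singleton filter targets.

Every clonotype carries exactly one ground-truth label: ``null``, ``planted``
(with a cluster id), or ``error``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special

from .genmodel import (
    GenModel,
    PgenCache,
    PgenTable,
    _sample_vj_batch,
    build_pgen_table,
    neighborhood_pgen,
)
from .io import Clonotype, Repertoire
from .seqs import CODONS_FOR_AA, AA_ALPHABET, translate

NT_LETTERS = "ACGT"


@dataclass
class PlantedCluster:
    """Specification of one convergent-response cluster.

    ``size`` clonotypes are added, all within Hamming distance 1 (amino
    acids) of a seed sequence and in its VJ class.  Member read counts are
    ``max(1, round(base_count * inflation))`` — at least 2 by default so the
    cluster is visible to the statistic; ``base_count=1, inflation=1`` gives
    a "stealth" cluster of singletons that the neighbor filter removes.
    """

    size: int = 15
    inflation: float = 1.0
    base_count: int = 2
    seed_selection: str = "low_pgen"  # or "random"
    min_neighborhood_pgen: float = 1e-5
    #: pin the cluster to one VJ class ((V, J) pair); None picks by model usage.
    #: Pinning different clusters to different classes keeps their neighbor
    #: statistics independent.
    vj: tuple[str, str] | None = None

    def __post_init__(self) -> None:
        if self.vj is not None:
            self.vj = tuple(self.vj)


@dataclass
class SyntheticScenario:
    """Full description of a synthetic repertoire."""

    model: GenModel
    n_clonotypes: int = 5000
    count_exponent: float = 2.5
    count_max: int = 10_000
    clusters: list[PlantedCluster] = field(default_factory=list)
    error_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_clonotypes < 0:
            raise ValueError("n_clonotypes must be >= 0")
        if self.count_exponent <= 1:
            raise ValueError("count_exponent must exceed 1")
        if not 0 <= self.error_rate <= 0.01:
            raise ValueError("error_rate must lie in [0, 0.01]")


# ---------------------------------------------------------------------------
# power-law read counts
# ---------------------------------------------------------------------------


def sample_powerlaw_counts(
    n: int, exponent: float, count_max: int, rng: np.random.Generator
) -> np.ndarray:
    """Zipf-distributed counts, rejection-truncated at ``count_max``."""
    out = np.empty(n, dtype=int)
    filled = 0
    while filled < n:
        draw = rng.zipf(exponent, size=n - filled)
        ok = draw <= count_max
        take = int(ok.sum())
        out[filled : filled + take] = draw[ok]
        filled += take
    return out


def fit_powerlaw_exponent(counts: Sequence[int], bounds=(1.05, 8.0)) -> float:
    """Maximum-likelihood zipf exponent of a sample of positive integers."""
    c = np.asarray(counts, dtype=float)
    if (c < 1).any():
        raise ValueError("counts must be >= 1")
    slog = np.log(c).sum()

    def nll(a: float) -> float:
        return a * slog + c.size * np.log(special.zeta(a, 1))

    res = optimize.minimize_scalar(nll, bounds=bounds, method="bounded")
    return float(res.x)


# ---------------------------------------------------------------------------
# null repertoire
# ---------------------------------------------------------------------------


def generate_null_repertoire(
    scenario: SyntheticScenario,
) -> tuple[Repertoire, pd.DataFrame]:
    """Sample ``n_clonotypes`` distinct nucleotide rearrangements from the model.

    Clonotypes are accepted in draw order until the requested number of
    distinct productive nucleotide sequences is reached; read counts come
    from the power law.  Deterministic given ``scenario.seed``.
    """
    model = scenario.model
    rng = np.random.default_rng(scenario.seed)
    n = scenario.n_clonotypes
    seen: dict[tuple[str, str, str], tuple[str, str, str, str]] = {}
    if n > 0:
        pairs = list(model.vj_usage)
        usage = np.array([model.vj_usage[p] for p in pairs])
        usage = usage / usage.sum()
        max_rounds = 60
        for _ in range(max_rounds):
            batch = max(2 * (n - len(seen)), 2000)
            per_pair = rng.multinomial(batch, usage)
            for (v, j), b in zip(pairs, per_pair):
                if b == 0:
                    continue
                groups, _ = _sample_vj_batch(model, v, j, int(b), rng)
                for mat, aa in groups:
                    for nt_row, aa_row in zip(mat, aa):
                        nt = "".join(NT_LETTERS[x] for x in nt_row)
                        key = (nt, v, j)
                        if key not in seen:
                            seen[key] = (nt, aa_row.tobytes().decode(), v, j)
            if len(seen) >= n:
                break
        else:
            raise RuntimeError(
                f"model too small: only {len(seen)} distinct clonotypes "
                f"found for a target of {n}"
            )
    picked = list(seen.values())[:n]
    counts = sample_powerlaw_counts(n, scenario.count_exponent, scenario.count_max, rng)
    clonotypes = [
        Clonotype(nt, aa, v, j, int(c))
        for (nt, aa, v, j), c in zip(picked, counts)
    ]
    rep = Repertoire(
        clonotypes,
        sample_id=f"synthetic-{scenario.seed}",
        provenance={"generator": "null", "seed": scenario.seed},
    )
    truth = _truth_frame(clonotypes, "null")
    return rep, truth


def _truth_frame(clonotypes, label, cluster_id=None) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "cdr3nt": [c.cdr3_nt for c in clonotypes],
            "cdr3aa": [c.cdr3_aa for c in clonotypes],
            "v": [c.v_gene for c in clonotypes],
            "j": [c.j_gene for c in clonotypes],
            "label": label,
            "cluster_id": cluster_id if cluster_id is not None else -1,
        }
    )


# ---------------------------------------------------------------------------
# planted clusters
# ---------------------------------------------------------------------------


def _nt_for_aa(aa: str, rng: np.random.Generator) -> str:
    return "".join(
        CODONS_FOR_AA[a][rng.integers(len(CODONS_FOR_AA[a]))] for a in aa
    )


def select_cluster_seed(
    table: PgenTable,
    rng: np.random.Generator,
    selection: str = "low_pgen",
    min_neighborhood_pgen: float = 1e-5,
    n_candidates: int = 400,
) -> str:
    """Pick a seed amino-acid CDR3 for a planted cluster.

    ``low_pgen`` picks, among generated sequences, the one whose one-mismatch
    neighborhood probability is lowest while staying above a floor — an
    "unexpected" region of sequence space where recombination alone would
    essentially never build a cluster, yet whose null is measurable (a
    neighborhood never seen in the Monte Carlo would be discarded by the
    zero-neighborhood filter, not detected).  Note the criterion is the
    *neighborhood* probability, not the seed's own P_gen: a rare variant of a
    very common sequence has low P_gen but a crowded neighborhood, and a
    cluster planted there would be Poisson-expected.
    """
    seqs = sorted(table.counts)
    if not seqs:
        raise ValueError("empty P_gen table")
    idx = rng.permutation(len(seqs))[: min(n_candidates, len(seqs))]
    eligible = [
        (nb, s)
        for s in (seqs[i] for i in sorted(idx))
        if (nb := neighborhood_pgen(table, s)) >= min_neighborhood_pgen
    ]
    if not eligible:
        raise ValueError(
            "no candidate seed with neighborhood P_gen >= "
            f"{min_neighborhood_pgen} among {len(idx)} candidates"
        )
    if selection == "random":
        return eligible[int(rng.integers(len(eligible)))][1]
    if selection != "low_pgen":
        raise ValueError(f"unknown seed selection {selection!r}")
    return min(eligible)[1]


def plant_response_cluster(
    rep: Repertoire,
    model: GenModel,
    cluster: PlantedCluster,
    rng: np.random.Generator,
    pgen: PgenCache | PgenTable | None = None,
    vj: tuple[str, str] | None = None,
    cluster_id: int = 0,
) -> tuple[Repertoire, pd.DataFrame]:
    """Add one convergent cluster of ``cluster.size`` clonotypes to ``rep``.

    The first member carries the seed amino-acid sequence itself; the rest
    are single-substitution variants, so the seed's neighbor count in the
    augmented repertoire is at least ``cluster.size``.  All nucleotide
    sequences are distinct (codon choices randomized) and absent from the
    existing repertoire.
    """
    if cluster.size < 1:
        raise ValueError("cluster size must be >= 1")
    if vj is None:
        pairs = list(model.vj_usage)
        usage = np.array([model.vj_usage[p] for p in pairs])
        vj = pairs[int(rng.choice(len(pairs), p=usage / usage.sum()))]
    if pgen is None:
        pgen = build_pgen_table(model, vj, 200_000, int(rng.integers(2**31)))
    table = pgen.table(vj) if isinstance(pgen, PgenCache) else pgen
    seed_aa = select_cluster_seed(
        table, rng, cluster.seed_selection, cluster.min_neighborhood_pgen
    )
    existing = {c.key for c in rep.clonotypes}
    count = max(1, round(cluster.base_count * cluster.inflation))
    members: list[Clonotype] = []
    aa_list = [seed_aa]
    while len(aa_list) < cluster.size:
        pos = int(rng.integers(len(seed_aa)))
        new = AA_ALPHABET[int(rng.integers(20))]
        if new == seed_aa[pos]:
            continue
        aa_list.append(seed_aa[:pos] + new + seed_aa[pos + 1 :])
    for aa in aa_list:
        for _attempt in range(200):
            nt = _nt_for_aa(aa, rng)
            key = (nt, vj[0], vj[1])
            if key not in existing:
                existing.add(key)
                members.append(Clonotype(nt, aa, vj[0], vj[1], count))
                break
        else:
            raise RuntimeError(
                f"could not construct {cluster.size} distinct nucleotide "
                f"variants for seed {seed_aa}"
            )
    assert all(translate(m.cdr3_nt) == m.cdr3_aa for m in members)
    out = Repertoire(
        rep.clonotypes + members, rep.sample_id, dict(rep.provenance)
    )
    out.provenance.setdefault("planted", []).append(
        {"seed": seed_aa, "vj": list(vj), "size": cluster.size, "count": count}
    )
    return out, _truth_frame(members, "planted", cluster_id)


# ---------------------------------------------------------------------------
# sequencing-error injection
# ---------------------------------------------------------------------------


def inject_sequencing_errors(
    rep: Repertoire, error_rate: float, rng: np.random.Generator
) -> tuple[Repertoire, pd.DataFrame]:
    """Spawn singleton one-mismatch nucleotide variants of existing clonotypes.

    For each clonotype the expected number of error variants is
    ``read_count * len(cdr3_nt) * error_rate`` (Poisson), capped at the
    number of possible single-substitution variants; each error variant gets
    read count 1 — the artifact the ``min_neighbor_reads`` filter removes.
    Error variants may be out of frame for amino-acid purposes; here the
    substituted codon is re-translated, and variants creating stops are
    dropped (they would be filtered as non-canonical anyway).
    """
    if not 0 <= error_rate <= 0.01:
        raise ValueError("error_rate must lie in [0, 0.01]")
    if error_rate == 0:
        return rep, _truth_frame([], "error")
    existing = {c.key for c in rep.clonotypes}
    errors: list[Clonotype] = []
    for c in rep.clonotypes:
        n_err = int(rng.poisson(c.read_count * len(c.cdr3_nt) * error_rate))
        n_err = min(n_err, 3 * len(c.cdr3_nt))
        for _ in range(n_err):
            pos = int(rng.integers(len(c.cdr3_nt)))
            new = NT_LETTERS[int(rng.integers(4))]
            if new == c.cdr3_nt[pos]:
                continue
            nt = c.cdr3_nt[:pos] + new + c.cdr3_nt[pos + 1 :]
            key = (nt, c.v_gene, c.j_gene)
            if key in existing:
                continue
            if len(nt) % 3 == 0:
                aa = translate(nt)
                if "*" in aa:
                    continue
            else:  # CDR3 tables are in-frame by construction; keep the guard
                continue
            existing.add(key)
            errors.append(Clonotype(nt, aa, c.v_gene, c.j_gene, 1))
    out = Repertoire(rep.clonotypes + errors, rep.sample_id, dict(rep.provenance))
    out.provenance["injected_errors"] = len(errors)
    return out, _truth_frame(errors, "error")


# ---------------------------------------------------------------------------
# full scenarios
# ---------------------------------------------------------------------------


def generate_repertoire(
    scenario: SyntheticScenario,
    pgen: PgenCache | None = None,
) -> tuple[Repertoire, pd.DataFrame]:
    """Generate a full scenario: null background, planted clusters, errors.

    Returns the repertoire and a complete ground-truth table (one row per
    clonotype, labels ``null`` / ``planted`` / ``error``).
    """
    rep, truth = generate_null_repertoire(scenario)
    rng = np.random.default_rng(np.random.SeedSequence([scenario.seed, 1]))
    frames = [truth]
    for cid, cluster in enumerate(scenario.clusters):
        rep, t = plant_response_cluster(
            rep, scenario.model, cluster, rng, pgen=pgen, vj=cluster.vj,
            cluster_id=cid,
        )
        frames.append(t)
    if scenario.error_rate > 0:
        rep, t = inject_sequencing_errors(rep, scenario.error_rate, rng)
        frames.append(t)
    truth = pd.concat(frames, ignore_index=True)
    return rep, truth
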