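"""Generative V(D)J recombination model and Monte-Carlo P_gen estimation.

The null hypothesis of the neighbor-enrichment test is that the repertoire is
a sample from the stochastic recombination process alone.  This module defines
a parameterizable model of that process — germline segment choice, exonuclease
trimming, junctional insertions — samples CDR3 rearrangements from it, and
estimates amino-acid generation probabilities P_gen(sigma) per VJ class by
counting translated Monte-Carlo draws, following the fixed-VJ simulation
strategy: draw a large number of rearrangements with the V and J held fixed,
translate the productive ones, and use the empirical frequency of each
distinct amino-acid CDR3 as its P_gen estimate.

P_gen estimates are normalized by the total number of draws (productive and
nonproductive alike); the ``productive_only`` flag restricts which draws enter
the numerator counts, never the denominator.
"""

from __future__ import annotations

import io
import zlib
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np

from .seqs import (
    NUCLEOTIDES,
    STOP,
    encode_nt,
    is_canonical_aa,
    neighborhood,
    translate,
    translate_matrix,
)

_PROB_TOL = 1e-9


class ModelError(ValueError):
    """Invalid generative-model parameters."""


def _check_prob_vector(name: str, p: np.ndarray) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ModelError(f"{name}: expected a non-empty 1-D probability vector")
    if (p < 0).any():
        raise ModelError(f"{name}: negative probability")
    if abs(p.sum() - 1.0) > _PROB_TOL:
        raise ModelError(f"{name}: probabilities sum to {p.sum()!r}, not 1")
    return p


@dataclass
class GenModel:
    """Parameter set of the generative V(D)J recombination process.

    Parameters
    ----------
    v_segments
        Map V-gene name -> germline nucleotide suffix contributing to the
        CDR3 (starting at the conserved cysteine codon).
    j_segments
        Map J-gene name -> germline nucleotide prefix contributing to the
        CDR3 (ending at the conserved phenylalanine codon).
    vj_usage
        Joint probability of each (V, J) pair; must sum to 1.
    v_trim, j_trim
        Deletion-length probability vectors, indexed by number of trimmed
        nucleotides.  Keyed by segment name, with ``"*"`` as the default
        applying to every segment without its own entry.
    ins_len
        Probability vector over junctional insertion lengths (VJ junction;
        for VDJ models this is the VD junction and ``ins_len_dj`` the DJ one).
    ins_nt
        Insertion nucleotide model.  Order 0: a length-4 vector of A/C/G/T
        probabilities.  Order 1 (Markov): a 4x4 row-stochastic transition
        matrix; the first inserted nucleotide is drawn from ``ins_nt_first``.
    d_segments, vdj_usage, d5_trim, d3_trim, ins_len_dj
        Optional explicit-D extension.  When ``d_segments`` is given,
        ``vdj_usage`` (over (V, D, J) triples) replaces ``vj_usage`` for
        segment choice and the junction is V — ins — trimmed D — ins — J.
    """

    v_segments: dict[str, str]
    j_segments: dict[str, str]
    vj_usage: dict[tuple[str, str], float]
    v_trim: dict[str, np.ndarray]
    j_trim: dict[str, np.ndarray]
    ins_len: np.ndarray
    ins_nt: np.ndarray
    ins_nt_first: np.ndarray | None = None
    d_segments: dict[str, str] | None = None
    vdj_usage: dict[tuple[str, str, str], float] | None = None
    d5_trim: dict[str, np.ndarray] | None = None
    d3_trim: dict[str, np.ndarray] | None = None
    ins_len_dj: np.ndarray | None = None
    name: str = "unnamed"

    def __post_init__(self) -> None:
        if not self.v_segments or not self.j_segments:
            raise ModelError("model needs at least one V and one J segment")
        for seg_map in (self.v_segments, self.j_segments, self.d_segments or {}):
            for nm, seq in seg_map.items():
                if not seq or any(c not in NUCLEOTIDES for c in seq.upper()):
                    raise ModelError(f"segment {nm}: invalid nucleotide sequence")
        usage = np.array(list(self.vj_usage.values()), dtype=float)
        _check_prob_vector("vj_usage", usage)
        for v, j in self.vj_usage:
            if v not in self.v_segments or j not in self.j_segments:
                raise ModelError(f"vj_usage refers to unknown segment ({v}, {j})")
        self.ins_len = _check_prob_vector("ins_len", self.ins_len)
        self.ins_nt = np.asarray(self.ins_nt, dtype=float)
        if self.ins_nt.ndim == 1:
            _check_prob_vector("ins_nt", self.ins_nt)
        elif self.ins_nt.shape == (4, 4):
            for r in range(4):
                _check_prob_vector(f"ins_nt row {r}", self.ins_nt[r])
            if self.ins_nt_first is None:
                raise ModelError("order-1 insertion model requires ins_nt_first")
            self.ins_nt_first = _check_prob_vector("ins_nt_first", self.ins_nt_first)
        else:
            raise ModelError("ins_nt must be a length-4 vector or a 4x4 matrix")
        for attr in ("v_trim", "j_trim"):
            dists = getattr(self, attr)
            if "*" not in dists:
                raise ModelError(f"{attr}: missing default entry '*'")
            for key, vec in dists.items():
                dists[key] = _check_prob_vector(f"{attr}[{key}]", vec)
        if self.d_segments is not None:
            if self.vdj_usage is None or self.ins_len_dj is None:
                raise ModelError("D segments require vdj_usage and ins_len_dj")
            _check_prob_vector(
                "vdj_usage", np.array(list(self.vdj_usage.values()), dtype=float)
            )
            self.ins_len_dj = _check_prob_vector("ins_len_dj", self.ins_len_dj)
            for attr in ("d5_trim", "d3_trim"):
                dists = getattr(self, attr)
                if dists is None or "*" not in dists:
                    raise ModelError(f"{attr}: missing default entry '*'")
                for key, vec in dists.items():
                    dists[key] = _check_prob_vector(f"{attr}[{key}]", vec)

    # -- helpers ---------------------------------------------------------

    @property
    def has_d(self) -> bool:
        return self.d_segments is not None

    @property
    def ins_order(self) -> int:
        return 0 if self.ins_nt.ndim == 1 else 1

    def trim_dist(self, kind: str, segment: str) -> np.ndarray:
        dists = getattr(self, f"{kind}_trim")
        return dists.get(segment, dists["*"])

    def vj_pairs(self) -> list[tuple[str, str]]:
        """All (V, J) pairs with nonzero usage."""
        if self.has_d:
            pairs = {}
            for (v, _d, j), p in self.vdj_usage.items():
                pairs[(v, j)] = pairs.get((v, j), 0.0) + p
            return sorted(p for p, w in pairs.items() if w > 0)
        return sorted(p for p, w in self.vj_usage.items() if w > 0)

    def digest(self) -> str:
        """Stable content digest, used as a cache key."""
        buf = io.StringIO()
        for nm in sorted(self.v_segments):
            buf.write(f"V {nm} {self.v_segments[nm]}\n")
        for nm in sorted(self.j_segments):
            buf.write(f"J {nm} {self.j_segments[nm]}\n")
        for key in sorted(self.vj_usage):
            buf.write(f"VJ {key} {self.vj_usage[key]:.12g}\n")
        for attr in ("v_trim", "j_trim"):
            for key in sorted(getattr(self, attr)):
                vec = getattr(self, attr)[key]
                buf.write(f"{attr} {key} {np.array2string(vec, precision=12)}\n")
        buf.write(f"ins_len {np.array2string(self.ins_len, precision=12)}\n")
        buf.write(f"ins_nt {np.array2string(self.ins_nt, precision=12)}\n")
        if self.d_segments:
            for nm in sorted(self.d_segments):
                buf.write(f"D {nm} {self.d_segments[nm]}\n")
            for key in sorted(self.vdj_usage):
                buf.write(f"VDJ {key} {self.vdj_usage[key]:.12g}\n")
        return f"{zlib.crc32(buf.getvalue().encode()):08x}"


def toy_beta_model() -> GenModel:
    """Small self-contained TCR-beta-like model used throughout tests and demos.

    Two V suffixes beginning at the conserved Cys codon, two J prefixes ending
    at the conserved Phe codon, geometric-ish trimming of up to 4 nt on each
    side and 0-6 junctional insertions with a mildly GC-biased composition.
    The resulting CDR3 space holds on the order of 10^5 distinct productive
    amino-acid sequences — large enough for realistic neighbor statistics,
    small enough that 10^6 Monte-Carlo draws resolve individual P_gen values.
    """
    return GenModel(
        name="toy-beta",
        v_segments={
            "TRBV1": "TGTGCCAGCAGT",  # C A S S
            "TRBV2": "TGTGCCACCAGC",  # C A T S
        },
        j_segments={
            "TRBJ1": "AACTATGGCTACACCTTC",  # N Y G Y T F
            "TRBJ2": "AGCTACGAGCAGTACTTC",  # S Y E Q Y F
        },
        vj_usage={
            ("TRBV1", "TRBJ1"): 0.35,
            ("TRBV1", "TRBJ2"): 0.15,
            ("TRBV2", "TRBJ1"): 0.20,
            ("TRBV2", "TRBJ2"): 0.30,
        },
        v_trim={"*": np.array([0.35, 0.25, 0.20, 0.12, 0.08])},
        j_trim={"*": np.array([0.30, 0.25, 0.20, 0.15, 0.10])},
        ins_len=np.array([0.10, 0.18, 0.22, 0.20, 0.14, 0.09, 0.07]),
        ins_nt=np.array([0.22, 0.28, 0.30, 0.20]),
    )


@dataclass
class Rearrangement:
    """One sampled recombination product."""

    cdr3_nt: str
    cdr3_aa: str | None  # None when nonproductive
    v_gene: str
    j_gene: str
    productive: bool


def sample_rearrangement(
    model: GenModel,
    vj: tuple[str, str] | None = None,
    rng: np.random.Generator | None = None,
) -> Rearrangement:
    """Draw a single rearrangement from the model.

    Segment identities are chosen from the usage table (or held fixed at
    ``vj``), trimming lengths and insertion length/letters from their
    distributions; the product is translated when in frame.  Out-of-frame or
    stop-containing products are returned tagged nonproductive.
    """
    rng = np.random.default_rng() if rng is None else rng
    if model.has_d:
        return _sample_vdj_single(model, vj, rng)
    if vj is None:
        pairs = list(model.vj_usage)
        probs = np.array([model.vj_usage[p] for p in pairs])
        v, j = pairs[rng.choice(len(pairs), p=probs)]
    else:
        v, j = vj
        if model.vj_usage.get((v, j), 0.0) <= 0.0:
            raise ModelError(f"VJ pair {vj} has zero usage")
    v_seq, j_seq = model.v_segments[v], model.j_segments[j]
    tv = _draw_trim(model.trim_dist("v", v), len(v_seq), rng)
    tj = _draw_trim(model.trim_dist("j", j), len(j_seq), rng)
    m = rng.choice(model.ins_len.size, p=model.ins_len)
    ins = _draw_insert(model, int(m), rng)
    nt = v_seq[: len(v_seq) - tv] + ins + j_seq[tj:]
    return _finish(nt, v, j)


def _draw_trim(dist: np.ndarray, seg_len: int, rng: np.random.Generator) -> int:
    t = int(rng.choice(dist.size, p=dist))
    return min(t, seg_len)


def _draw_insert(model: GenModel, m: int, rng: np.random.Generator) -> str:
    if m == 0:
        return ""
    if model.ins_order == 0:
        idx = rng.choice(4, size=m, p=model.ins_nt)
    else:
        idx = np.empty(m, dtype=int)
        idx[0] = rng.choice(4, p=model.ins_nt_first)
        for k in range(1, m):
            idx[k] = rng.choice(4, p=model.ins_nt[idx[k - 1]])
    return "".join(NUCLEOTIDES[i] for i in idx)


def _finish(nt: str, v: str, j: str) -> Rearrangement:
    if len(nt) % 3 != 0:
        return Rearrangement(nt, None, v, j, productive=False)
    aa = translate(nt)
    if STOP in aa:
        return Rearrangement(nt, None, v, j, productive=False)
    return Rearrangement(nt, aa, v, j, productive=True)


def _sample_vdj_single(
    model: GenModel, vj: tuple[str, str] | None, rng: np.random.Generator
) -> Rearrangement:
    triples = list(model.vdj_usage)
    probs = np.array([model.vdj_usage[t] for t in triples], dtype=float)
    if vj is not None:
        mask = np.array([(t[0], t[2]) == tuple(vj) for t in triples])
        if not mask.any() or probs[mask].sum() <= 0:
            raise ModelError(f"VJ pair {vj} has zero usage")
        probs = np.where(mask, probs, 0.0)
        probs = probs / probs.sum()
    v, d, j = triples[rng.choice(len(triples), p=probs)]
    v_seq, d_seq, j_seq = model.v_segments[v], model.d_segments[d], model.j_segments[j]
    tv = _draw_trim(model.trim_dist("v", v), len(v_seq), rng)
    tj = _draw_trim(model.trim_dist("j", j), len(j_seq), rng)
    t5 = _draw_trim(model.trim_dist("d5", d), len(d_seq), rng)
    t3 = _draw_trim(model.trim_dist("d3", d), max(0, len(d_seq) - t5), rng)
    d_mid = d_seq[t5 : len(d_seq) - t3]
    m_vd = int(rng.choice(model.ins_len.size, p=model.ins_len))
    m_dj = int(rng.choice(model.ins_len_dj.size, p=model.ins_len_dj))
    nt = (
        v_seq[: len(v_seq) - tv]
        + _draw_insert(model, m_vd, rng)
        + d_mid
        + _draw_insert(model, m_dj, rng)
        + j_seq[tj:]
    )
    return _finish(nt, v, j)


# ---------------------------------------------------------------------------
# Vectorized fixed-VJ batch sampling (VJ-only models)
# ---------------------------------------------------------------------------


def _sample_vj_batch(
    model: GenModel,
    v: str,
    j: str,
    n: int,
    rng: np.random.Generator,
    keep_stops: bool = False,
) -> tuple[list[tuple[np.ndarray, np.ndarray]], int]:
    """Sample ``n`` fixed-VJ rearrangements; return in-frame draws.

    Returns ``(groups, n_productive)`` where each group is a pair
    ``(nt_codes, aa_bytes)`` of matrices sharing one CDR3 length.
    Out-of-frame draws count toward ``n`` but are dropped; stop-containing
    in-frame draws are dropped unless ``keep_stops``.
    """
    v_codes = encode_nt(model.v_segments[v])
    j_codes = encode_nt(model.j_segments[j])
    lv, lj = v_codes.size, j_codes.size
    tv = rng.choice(model.trim_dist("v", v).size, size=n, p=model.trim_dist("v", v))
    tj = rng.choice(model.trim_dist("j", j).size, size=n, p=model.trim_dist("j", j))
    tv = np.minimum(tv, lv)
    tj = np.minimum(tj, lj)
    m = rng.choice(model.ins_len.size, size=n, p=model.ins_len)

    # insertion letters, drawn flat then sliced per draw
    total_ins = int(m.sum())
    if model.ins_order == 0:
        ins_flat = rng.choice(4, size=total_ins, p=model.ins_nt).astype(np.uint8)
    else:
        ins_flat = _markov_insert_flat(model, m, rng)
    offsets = np.concatenate(([0], np.cumsum(m)[:-1]))

    length = lv - tv + m + lj - tj
    keep = length % 3 == 0

    groups: list[tuple[np.ndarray, np.ndarray]] = []
    n_productive = 0
    key = (tv * (model.ins_len.size * (tj.max() + 1)) + m * (tj.max() + 1) + tj)
    for k in np.unique(key[keep]):
        sel = np.flatnonzero((key == k) & keep)
        g_tv, g_m, g_tj = int(tv[sel[0]]), int(m[sel[0]]), int(tj[sel[0]])
        width = lv - g_tv + g_m + lj - g_tj
        mat = np.empty((sel.size, width), dtype=np.uint8)
        mat[:, : lv - g_tv] = v_codes[: lv - g_tv]
        if g_m:
            mat[:, lv - g_tv : lv - g_tv + g_m] = ins_flat[
                offsets[sel][:, None] + np.arange(g_m)
            ]
        mat[:, lv - g_tv + g_m :] = j_codes[g_tj:]
        aa = translate_matrix(mat)
        prod = ~(aa == ord(STOP)).any(axis=1)
        n_productive += int(prod.sum())
        sel_rows = np.ones(aa.shape[0], dtype=bool) if keep_stops else prod
        if sel_rows.any():
            groups.append((mat[sel_rows], aa[sel_rows]))
    return groups, n_productive


def _markov_insert_flat(
    model: GenModel, m: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Order-1 insertion letters for all draws, flattened in draw order."""
    n = m.size
    max_m = int(m.max()) if n else 0
    cols = np.full((n, max_m), 255, dtype=np.uint8)
    if max_m:
        active = m > 0
        u = rng.random(n)
        cols[active, 0] = np.searchsorted(
            np.cumsum(model.ins_nt_first), u[active], side="right"
        )
        cum = np.cumsum(model.ins_nt, axis=1)
        for pos in range(1, max_m):
            active = m > pos
            if not active.any():
                break
            prev = cols[active, pos - 1].astype(int)
            u = rng.random(int(active.sum()))
            cols[active, pos] = (cum[prev] < u[:, None]).sum(axis=1)
    flat = np.empty(int(m.sum()), dtype=np.uint8)
    off = 0
    for i in range(n):
        if m[i]:
            flat[off : off + m[i]] = cols[i, : m[i]]
            off += int(m[i])
    return flat


# ---------------------------------------------------------------------------
# P_gen tables
# ---------------------------------------------------------------------------


@dataclass
class PgenTable:
    """Per-VJ-class Monte-Carlo estimate of amino-acid generation probabilities.

    ``pgen(sigma) = counts[sigma] / n_sim``; sequences never generated have
    P_gen estimate 0.  ``length_counts`` records the CDR3 amino-acid length
    distribution of the productive draws (used by the length-dependent
    selection-factor option).
    """

    vj: tuple[str, str]
    n_sim: int
    seed: int
    counts: dict[str, int]
    n_productive: int
    length_counts: dict[int, int] = field(default_factory=dict)
    model_digest: str = ""

    def pgen(self, sigma: str) -> float:
        return self.counts.get(sigma, 0) / self.n_sim

    def neighborhood_counts(self, sigma: str) -> int:
        return sum(self.counts.get(s, 0) for s in neighborhood(sigma))

    def total_pgen(self) -> float:
        return sum(self.counts.values()) / self.n_sim

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# vj={self.vj[0]},{self.vj[1]} n_sim={self.n_sim} ")
            fh.write(f"seed={self.seed} n_productive={self.n_productive} ")
            fh.write(f"model={self.model_digest}\n")
            fh.write("sequence\tcount\n")
            for s in sorted(self.counts):
                fh.write(f"{s}\t{self.counts[s]}\n")

    @classmethod
    def from_tsv(cls, path) -> "PgenTable":
        with open(path) as fh:
            meta = fh.readline()
            if not meta.startswith("#"):
                raise ValueError("missing metadata header")
            kv = dict(tok.split("=", 1) for tok in meta[1:].split())
            header = fh.readline().strip().split("\t")
            if header != ["sequence", "count"]:
                raise ValueError("unexpected column header")
            counts = {}
            for line in fh:
                s, c = line.rstrip("\n").split("\t")
                counts[s] = int(c)
        v, j = kv["vj"].split(",")
        table = cls(
            vj=(v, j),
            n_sim=int(kv["n_sim"]),
            seed=int(kv["seed"]),
            counts=counts,
            n_productive=int(kv["n_productive"]),
            model_digest=kv.get("model", ""),
        )
        for s, c in counts.items():
            table.length_counts[len(s)] = table.length_counts.get(len(s), 0) + c
        return table


def build_pgen_table(
    model: GenModel,
    vj: tuple[str, str],
    n_sim: int,
    seed: int,
    productive_only: bool = True,
    chunk: int = 1_000_000,
) -> PgenTable:
    """Monte-Carlo P_gen table for one VJ class.

    Draws ``n_sim`` rearrangements with the V and J fixed, translates them,
    and counts distinct amino-acid CDR3s.  Estimates are normalized by
    ``n_sim`` (all draws), so P_gen values are probabilities of the full
    recombination process, not of the productive subset.  With
    ``productive_only=False`` in-frame stop-containing products are counted
    as well (their sequences contain ``'*'``).  Deterministic given ``seed``.
    """
    if n_sim < 1:
        raise ValueError("n_sim must be >= 1")
    v, j = vj
    if model.has_d:
        ok = any((t[0], t[2]) == (v, j) for t in model.vdj_usage)
    else:
        ok = model.vj_usage.get((v, j), 0.0) > 0.0
    if not ok:
        raise ModelError(f"VJ pair {vj} has zero usage")
    rng = np.random.default_rng(seed)
    counts: dict[str, int] = {}
    length_counts: dict[int, int] = {}
    n_productive = 0
    remaining = n_sim
    while remaining > 0:
        batch = min(chunk, remaining)
        remaining -= batch
        if model.has_d:
            for _ in range(batch):
                r = _sample_vdj_single(model, vj, rng)
                if not r.productive:
                    continue
                n_productive += 1
                counts[r.cdr3_aa] = counts.get(r.cdr3_aa, 0) + 1
                L = len(r.cdr3_aa)
                length_counts[L] = length_counts.get(L, 0) + 1
            continue
        groups, n_prod = _sample_vj_batch(
            model, v, j, batch, rng, keep_stops=not productive_only
        )
        n_productive += n_prod
        for _mat, aa in groups:
            L = aa.shape[1]
            view = np.ascontiguousarray(aa).view(f"V{L}").ravel()
            uniq, cnt = np.unique(view, return_counts=True)
            length_counts[L] = length_counts.get(L, 0) + int(cnt.sum())
            for u, c in zip(uniq, cnt):
                s = u.tobytes().decode()
                counts[s] = counts.get(s, 0) + int(c)
    return PgenTable(
        vj=(v, j),
        n_sim=n_sim,
        seed=seed,
        counts=counts,
        n_productive=n_productive,
        length_counts=length_counts,
        model_digest=model.digest(),
    )


def neighborhood_pgen(table: PgenTable, sigma: str) -> float:
    """Summed P_gen over the one-mismatch neighborhood of ``sigma``.

    The neighborhood is sigma itself plus all 19*len(sigma) same-length
    single-substitution variants; variants never generated contribute 0.
    """
    if not is_canonical_aa(sigma):
        raise ValueError(f"non-canonical amino-acid sequence {sigma!r}")
    return table.neighborhood_counts(sigma) / table.n_sim


class PgenCache:
    """Lazy per-VJ P_gen tables for one (model, n_sim, seed) configuration.

    The table for each VJ class is built on first request and memoized.
    Per-class RNG seeds are derived from the master seed and the class name so
    that every class is independent yet the whole cache is reproducible.
    """

    def __init__(self, model: GenModel, n_sim: int, seed: int) -> None:
        self.model = model
        self.n_sim = int(n_sim)
        self.seed = int(seed)
        self._tables: dict[tuple[str, str], PgenTable] = {}

    def class_seed(self, vj: tuple[str, str]) -> int:
        mix = zlib.crc32(f"{vj[0]}|{vj[1]}".encode())
        return int(np.random.SeedSequence([self.seed, mix]).generate_state(1)[0] % (2**31))

    def table(self, vj: tuple[str, str]) -> PgenTable:
        vj = (vj[0], vj[1])
        if vj not in self._tables:
            self._tables[vj] = build_pgen_table(
                self.model, vj, self.n_sim, self.class_seed(vj)
            )
        return self._tables[vj]


# ---------------------------------------------------------------------------
# Exchangeable exact-P_gen backend registry
# ---------------------------------------------------------------------------

PgenBackend = Callable[[str, tuple[str, str]], float]

_PGEN_BACKENDS: dict[str, PgenBackend] = {}


class BackendError(RuntimeError):
    """Requested P_gen backend is not registered."""


def register_pgen_backend(name: str, fn: PgenBackend) -> None:
    """Register an exchangeable P_gen backend (e.g., an exact DP evaluator).

    A backend maps ``(sigma, (v, j)) -> P_gen`` and must return nonnegative
    values agreeing with Monte-Carlo estimates within sampling error.
    """
    _PGEN_BACKENDS[name] = fn


def get_pgen_backend(name: str) -> PgenBackend:
    if name not in _PGEN_BACKENDS:
        raise BackendError(
            f"P_gen backend {name!r} is not registered "
            f"(available: {sorted(_PGEN_BACKENDS) or 'none'})"
        )
    return _PGEN_BACKENDS[name]


def monte_carlo_backend(table_for_vj: Mapping[tuple[str, str], PgenTable]) -> PgenBackend:
    """Wrap a set of Monte-Carlo tables as a P_gen backend."""

    def _backend(sigma: str, vj: tuple[str, str]) -> float:
        return table_for_vj[tuple(vj)].pgen(sigma)

    return _backend
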