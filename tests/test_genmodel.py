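"""Generative model sampling and Monte-Carlo P_gen estimation.

The key oracle here is exhaustive enumeration: for a model with finitely
many (trim, insertion) outcomes, the exact amino-acid distribution can be
computed by iterating every combination, and the Monte-Carlo estimate must
agree within binomial sampling error.
"""

import itertools

import numpy as np
import pytest

from alicetcr import (
    GenModel,
    build_pgen_table,
    get_pgen_backend,
    neighborhood_pgen,
    register_pgen_backend,
    sample_rearrangement,
)
from alicetcr.genmodel import BackendError, ModelError, PgenTable, monte_carlo_backend
from alicetcr.modelio import load_model, save_model
from alicetcr.seqs import NUCLEOTIDES, STOP, translate


def test_degenerate_model_always_yields_cf(degenerate_model):
    rng = np.random.default_rng(0)
    for _ in range(20):
        r = sample_rearrangement(degenerate_model, rng=rng)
        assert (r.cdr3_nt, r.cdr3_aa, r.productive) == ("TGTTTT", "CF", True)


def test_fixed_single_insertion_is_always_nonproductive(degenerate_model):
    model = GenModel(
        **{**degenerate_model.__dict__, "ins_len": np.array([0.0, 1.0]), "name": "frame"}
    )
    rng = np.random.default_rng(1)
    for _ in range(20):
        r = sample_rearrangement(model, rng=rng)
        assert len(r.cdr3_nt) == 7
        assert not r.productive and r.cdr3_aa is None


def test_vj_usage_matches_empirical_frequencies(toy_model):
    rng = np.random.default_rng(2)
    n = 20_000
    counts = {}
    for _ in range(n):
        r = sample_rearrangement(toy_model, rng=rng)
        counts[(r.v_gene, r.j_gene)] = counts.get((r.v_gene, r.j_gene), 0) + 1
    for vj, p in toy_model.vj_usage.items():
        se = np.sqrt(p * (1 - p) / n)
        assert abs(counts.get(vj, 0) / n - p) < 3 * se, vj


def test_zero_usage_vj_is_domain_error(toy_model):
    with pytest.raises(ModelError):
        sample_rearrangement(toy_model, vj=("TRBV1", "nope"))
    with pytest.raises(ModelError):
        build_pgen_table(toy_model, ("TRBV1", "nope"), 100, seed=0)


def test_pgen_table_degenerate_model(degenerate_model):
    table = build_pgen_table(degenerate_model, ("V", "J"), 1000, seed=0)
    assert table.counts == {"CF": 1000}
    assert table.pgen("CF") == 1.0
    assert table.n_productive == 1000


def test_pgen_table_two_equiprobable_j(degenerate_model):
    model = GenModel(
        **{
            **degenerate_model.__dict__,
            "j_segments": {"J1": "TTT", "J2": "TGG"},
            "vj_usage": {("V", "J1"): 0.5, ("V", "J2"): 0.5},
            "name": "two-j",
        }
    )
    n = 40_000
    rng_counts = {}
    rng = np.random.default_rng(3)
    for _ in range(n):
        r = sample_rearrangement(model, rng=rng)
        rng_counts[r.cdr3_aa] = rng_counts.get(r.cdr3_aa, 0) + 1
    se = np.sqrt(0.25 / n)
    assert abs(rng_counts["CF"] / n - 0.5) < 3 * se
    assert abs(rng_counts["CW"] / n - 0.5) < 3 * se


def test_n_sim_zero_rejected(degenerate_model):
    with pytest.raises(ValueError):
        build_pgen_table(degenerate_model, ("V", "J"), 0, seed=0)


def test_determinism_identical_tables(toy_model):
    a = build_pgen_table(toy_model, ("TRBV1", "TRBJ1"), 50_000, seed=7)
    b = build_pgen_table(toy_model, ("TRBV1", "TRBJ1"), 50_000, seed=7)
    assert a.counts == b.counts and a.n_productive == b.n_productive


def test_two_seeds_agree_within_sampling_error(toy_model):
    n = 200_000
    a = build_pgen_table(toy_model, ("TRBV1", "TRBJ1"), n, seed=11)
    b = build_pgen_table(toy_model, ("TRBV1", "TRBJ1"), n, seed=12)
    sigma = "CASSNYGYTF"  # high-probability sequence, present in both
    pa, pb = a.pgen(sigma), b.pgen(sigma)
    se = np.sqrt(pa * (1 - pa) / n + pb * (1 - pb) / n)
    assert abs(pa - pb) < 4 * se


# ---------------------------------------------------------------------------
# exhaustive enumeration oracle
# ---------------------------------------------------------------------------


def enumerate_exact_aa_distribution(model: GenModel, vj) -> dict[str, float]:
    """Exact amino-acid CDR3 probabilities by enumerating every outcome.

    Iterates all (v-trim, insertion length, insertion letters, j-trim)
    combinations — feasible only for tiny models.  Probabilities are
    normalized by all draws, so out-of-frame/stop outcomes simply leave
    total mass below 1.
    """
    v, j = vj
    v_seq, j_seq = model.v_segments[v], model.j_segments[j]
    tv_dist = model.trim_dist("v", v)
    tj_dist = model.trim_dist("j", j)
    out: dict[str, float] = {}
    for tv, p_tv in enumerate(tv_dist):
        for tj, p_tj in enumerate(tj_dist):
            for m, p_m in enumerate(model.ins_len):
                base = p_tv * p_tj * p_m
                if base == 0:
                    continue
                for letters in itertools.product(range(4), repeat=m):
                    p_ins = np.prod([model.ins_nt[x] for x in letters]) if m else 1.0
                    nt = (
                        v_seq[: len(v_seq) - tv]
                        + "".join(NUCLEOTIDES[x] for x in letters)
                        + j_seq[tj:]
                    )
                    if len(nt) % 3 != 0:
                        continue
                    aa = translate(nt)
                    if STOP in aa:
                        continue
                    out[aa] = out.get(aa, 0.0) + base * p_ins
    return out


@pytest.fixture(scope="module")
def tiny_model():
    return GenModel(
        name="tiny",
        v_segments={"V": "TGTGCA"},
        j_segments={"J": "TACTTT"},
        vj_usage={("V", "J"): 1.0},
        v_trim={"*": np.array([0.6, 0.3, 0.1])},
        j_trim={"*": np.array([0.5, 0.3, 0.2])},
        ins_len=np.array([0.4, 0.3, 0.2, 0.1]),
        ins_nt=np.array([0.1, 0.4, 0.3, 0.2]),
    )


def test_monte_carlo_converges_to_exact_enumeration(tiny_model):
    exact = enumerate_exact_aa_distribution(tiny_model, ("V", "J"))
    assert 0 < sum(exact.values()) < 1
    n = 300_000
    table = build_pgen_table(tiny_model, ("V", "J"), n, seed=5)
    for aa, p in exact.items():
        if p < 1e-4:
            continue
        se = np.sqrt(p * (1 - p) / n)
        assert abs(table.pgen(aa) - p) < 4 * se, aa
    # no sequence outside the enumerable set should ever be generated
    assert set(table.counts) <= set(exact)


def test_productive_samples_translate_correctly(toy_model):
    rng = np.random.default_rng(8)
    for _ in range(200):
        r = sample_rearrangement(toy_model, rng=rng)
        if r.productive:
            assert translate(r.cdr3_nt) == r.cdr3_aa
            assert STOP not in r.cdr3_aa


# ---------------------------------------------------------------------------
# neighborhoods
# ---------------------------------------------------------------------------


def test_neighborhood_pgen_on_cf_only_model(degenerate_model):
    table = build_pgen_table(degenerate_model, ("V", "J"), 1000, seed=0)
    assert neighborhood_pgen(table, "CF") == 1.0
    assert neighborhood_pgen(table, "CW") == 1.0  # CF is a 1-mismatch variant of CW
    assert neighborhood_pgen(table, "AAAA") == 0.0  # length-preserving
    with pytest.raises(ValueError):
        neighborhood_pgen(table, "C*")


def test_neighborhood_pgen_dominates_pgen(toy_model):
    table = build_pgen_table(toy_model, ("TRBV2", "TRBJ2"), 100_000, seed=9)
    for sigma in list(table.counts)[:100]:
        assert neighborhood_pgen(table, sigma) >= table.pgen(sigma)


# ---------------------------------------------------------------------------
# model file format, VDJ mode, backend registry
# ---------------------------------------------------------------------------


def test_model_file_roundtrip(tmp_path, toy_model):
    path = tmp_path / "toy.model"
    save_model(toy_model, path)
    loaded = load_model(path)
    assert loaded.digest() == toy_model.digest()
    assert loaded.vj_usage == toy_model.vj_usage


def test_model_file_rejects_missing_header(tmp_path):
    path = tmp_path / "bad.model"
    path.write_text("[v_segments]\nV\tTGT\n")
    with pytest.raises(ModelError, match="header"):
        load_model(path)


def test_markov1_insertions_follow_transition_matrix():
    eye_ish = np.array([
        [0.97, 0.01, 0.01, 0.01],
        [0.01, 0.97, 0.01, 0.01],
        [0.01, 0.01, 0.97, 0.01],
        [0.01, 0.01, 0.01, 0.97],
    ])
    model = GenModel(
        name="markov",
        v_segments={"V": "TGT"},
        j_segments={"J": "TTT"},
        vj_usage={("V", "J"): 1.0},
        v_trim={"*": np.array([1.0])},
        j_trim={"*": np.array([1.0])},
        ins_len=np.array([0.0, 0.0, 0.0, 1.0]),  # always 3 insertions
        ins_nt=eye_ish,
        ins_nt_first=np.array([0.25, 0.25, 0.25, 0.25]),
    )
    table = build_pgen_table(model, ("V", "J"), 20_000, seed=13)
    # near-identity transitions make homopolymer insertions dominate
    homo = sum(
        table.counts.get("C" + translate(3 * b) + "F", 0) for b in NUCLEOTIDES
    )
    assert homo / sum(table.counts.values()) > 0.8


def test_vdj_mode_degenerate():
    model = GenModel(
        name="vdj",
        v_segments={"V": "TGT"},
        j_segments={"J": "TTT"},
        d_segments={"D": "GGG"},
        vj_usage={("V", "J"): 1.0},
        vdj_usage={("V", "D", "J"): 1.0},
        v_trim={"*": np.array([1.0])},
        j_trim={"*": np.array([1.0])},
        d5_trim={"*": np.array([1.0])},
        d3_trim={"*": np.array([1.0])},
        ins_len=np.array([1.0]),
        ins_len_dj=np.array([1.0]),
        ins_nt=np.array([0.25, 0.25, 0.25, 0.25]),
    )
    r = sample_rearrangement(model, rng=np.random.default_rng(0))
    assert r.cdr3_nt == "TGTGGGTTT" and r.cdr3_aa == "CGF"
    table = build_pgen_table(model, ("V", "J"), 100, seed=0)
    assert table.counts == {"CGF": 100}


def test_pgen_backend_registry(degenerate_model):
    with pytest.raises(BackendError):
        get_pgen_backend("no-such-backend")
    table = build_pgen_table(degenerate_model, ("V", "J"), 1000, seed=0)
    register_pgen_backend("mc-test", monte_carlo_backend({("V", "J"): table}))
    backend = get_pgen_backend("mc-test")
    assert backend("CF", ("V", "J")) == 1.0


def test_invalid_probability_vectors_rejected(degenerate_model):
    with pytest.raises(ModelError):
        GenModel(
            **{**degenerate_model.__dict__, "ins_len": np.array([0.5, 0.4]), "name": "bad"}
        )


def test_pgen_table_tsv_roundtrip(tmp_path, degenerate_model):
    table = build_pgen_table(degenerate_model, ("V", "J"), 1000, seed=4)
    path = tmp_path / "table.tsv"
    table.to_tsv(path)
    loaded = PgenTable.from_tsv(path)
    assert loaded.counts == table.counts
    assert (loaded.vj, loaded.n_sim, loaded.seed) == (table.vj, table.n_sim, table.seed)
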