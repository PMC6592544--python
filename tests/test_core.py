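"""Poisson null, filters, BH adjustment, and the d/n baseline.

Oracles: direct series summation for the Poisson upper tail, brute-force
pairwise Hamming counting for neighbors, and the textbook step-up for BH.
"""

import math

import numpy as np
import pytest

from alicetcr import (
    AliceConfig,
    benjamini_hochberg,
    count_neighbors,
    d_hits_baseline,
    length_dependent_q,
    null_lambda,
    poisson_pvalue,
    run_alice,
)
from alicetcr.core import _adjust, data_length_counts
from alicetcr.genmodel import PgenTable
from alicetcr.io import Repertoire, partition_by_vj

from conftest import make_repertoire


def poisson_upper_tail_series(d, lam, terms=2000):
    """Independent oracle: sum e^-lam lam^k / k! for k >= d, term by term."""
    if d == 0:
        return 1.0
    if lam == 0:
        return 0.0
    log_term = -lam + d * math.log(lam) - math.lgamma(d + 1)
    term = math.exp(log_term)
    total = 0.0
    for k in range(d, d + terms):
        total += term
        term *= lam / (k + 1)
        if term < total * 1e-18 and term < 1e-300:
            break
    return total


def bh_step_up(p):
    """Independent oracle: textbook Benjamini-Hochberg step-up adjustment."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    adj = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(adj[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


# ---------------------------------------------------------------------------
# poisson_pvalue
# ---------------------------------------------------------------------------


def test_poisson_pvalue_boundaries():
    assert poisson_pvalue(0, 0.0) == 1.0
    assert poisson_pvalue(0, 123.0) == 1.0
    assert poisson_pvalue(1, 0.0) == 0.0
    with pytest.raises(ValueError):
        poisson_pvalue(-1, 1.0)
    with pytest.raises(ValueError):
        poisson_pvalue(1, -0.5)


def test_poisson_pvalue_frozen_example():
    # lam=0.5, d=3: 1 - e^-0.5 (1 + 0.5 + 0.125)
    expected = 1.0 - math.exp(-0.5) * 1.625
    assert poisson_pvalue(3, 0.5) == pytest.approx(expected, abs=1e-15)
    assert poisson_pvalue(3, 0.5) == pytest.approx(0.014388, abs=1e-6)


@pytest.mark.parametrize("lam", [1e-6, 1e-3, 0.5, 2.0, 10.0, 50.0])
def test_poisson_pvalue_matches_series_oracle(lam):
    for d in range(0, 101, 7):
        assert poisson_pvalue(d, lam) == pytest.approx(
            poisson_upper_tail_series(d, lam), abs=1e-12
        )


def test_poisson_pvalue_never_underflows_to_zero():
    p = poisson_pvalue(100, 1e-14)
    assert 0.0 < p <= 1.0


def test_poisson_pvalue_monotonicity():
    lams = [1e-4, 0.1, 1.0, 10.0]
    for lam in lams:
        ps = [poisson_pvalue(d, lam) for d in range(30)]
        assert all(a >= b for a, b in zip(ps, ps[1:]))
    for d in [1, 3, 10]:
        ps = [poisson_pvalue(d, lam) for lam in np.linspace(0.01, 20, 40)]
        assert all(a <= b + 1e-15 for a, b in zip(ps, ps[1:]))


@pytest.mark.parametrize("lam", [0.1, 5.0, 50.0])
def test_poisson_pmf_normalizes(lam):
    term = math.exp(-lam)
    total = 0.0
    k = 0
    while term > 1e-20 or k < lam:
        total += term
        k += 1
        term *= lam / k
    assert total == pytest.approx(1.0, abs=1e-12)


# ---------------------------------------------------------------------------
# Benjamini-Hochberg
# ---------------------------------------------------------------------------


def test_bh_textbook_example():
    adj = benjamini_hochberg([0.001, 0.01, 0.02, 0.05])
    assert np.allclose(adj, [0.004, 0.02, 0.02 + 2 / 300, 0.05], atol=1e-12)


def test_bh_edge_cases():
    assert benjamini_hochberg([0.3]) == pytest.approx([0.3])
    assert np.allclose(benjamini_hochberg([0.2, 0.2, 0.2]), [0.2, 0.2, 0.2])
    with pytest.raises(ValueError):
        benjamini_hochberg([0.0, 0.5])
    with pytest.raises(ValueError):
        benjamini_hochberg([1.5])
    assert benjamini_hochberg([]).size == 0


def test_bh_matches_step_up_oracle_on_random_vectors():
    rng = np.random.default_rng(42)
    for _ in range(50):
        p = rng.uniform(1e-8, 1.0, size=rng.integers(1, 40))
        assert np.allclose(benjamini_hochberg(p), bh_step_up(p), atol=1e-12)


# ---------------------------------------------------------------------------
# neighbor counting
# ---------------------------------------------------------------------------


CLASS_ROWS = [
    ("TGTTTTGGT", "CFG", "V", "J", 5),
    ("TGCTTTGGT", "CFG", "V", "J", 3),
    ("TGTTTTGCT", "CFA", "V", "J", 2),
]


def test_count_neighbors_example():
    (vjclass,) = partition_by_vj(make_repertoire(CLASS_ROWS))
    assert count_neighbors(vjclass, "CFG", min_reads=2) == 3


def test_count_neighbors_excludes_singletons():
    rows = CLASS_ROWS[:2] + [("TGTTTTGCT", "CFA", "V", "J", 1)]
    (vjclass,) = partition_by_vj(make_repertoire(rows))
    assert count_neighbors(vjclass, "CFG", min_reads=2) == 2


def test_count_neighbors_self_neighborhood():
    (vjclass,) = partition_by_vj(make_repertoire([("TGTTTT", "CF", "V", "J", 10)]))
    assert count_neighbors(vjclass, "CF") == 1


def test_count_neighbors_absent_sigma_is_error():
    (vjclass,) = partition_by_vj(make_repertoire(CLASS_ROWS))
    with pytest.raises(ValueError):
        count_neighbors(vjclass, "WWW")


def test_count_neighbors_monotone_in_min_reads():
    rng = np.random.default_rng(0)
    from alicetcr.seqs import AA_ALPHABET

    rows = [
        (
            f"NT{i}", "".join(rng.choice(list(AA_ALPHABET), 4)), "V", "J",
            int(rng.integers(1, 6)),
        )
        for i in range(80)
    ]
    (vjclass,) = partition_by_vj(make_repertoire(rows))
    for sigma in {r[1] for r in rows}:
        ds = [count_neighbors(vjclass, sigma, mr) for mr in (1, 2, 3, 4)]
        assert all(a >= b for a, b in zip(ds, ds[1:]))


# ---------------------------------------------------------------------------
# null mean and length-dependent Q
# ---------------------------------------------------------------------------


def _table_with(sigma, pgen, vj=("V", "J"), n_sim=1_000_000):
    return PgenTable(
        vj=vj, n_sim=n_sim, seed=0,
        counts={sigma: int(round(pgen * n_sim))}, n_productive=n_sim,
    )


def test_null_lambda_arithmetic():
    (vjclass,) = partition_by_vj(
        make_repertoire([(f"NT{i}", "CFGW", "V", "J", 2) for i in range(100)])
    )
    table = _table_with("CFGW", 1e-4)
    cfg = AliceConfig()
    assert null_lambda(vjclass, "CFGW", table, cfg) == pytest.approx(0.0941, rel=1e-12)
    empty = PgenTable(vj=("V", "J"), n_sim=1_000_000, seed=0, counts={}, n_productive=0)
    assert null_lambda(vjclass, "CFGW", empty, cfg) == 0.0


def test_length_dependent_q_identity_when_distributions_match():
    counts = {8: 321, 9: 1234, 10: 55}
    q_by_len = length_dependent_q(counts, counts, q=9.41)
    assert all(qv == 9.41 for qv in q_by_len.values())
    # matching *proportions* with different totals is also exact
    scaled = {L: 7 * c for L, c in counts.items()}
    q_by_len = length_dependent_q(counts, scaled, q=9.41)
    assert all(qv == 9.41 for qv in q_by_len.values())


def test_length_dependent_q_worked_example():
    # P_data = (0.5, 0.5), P_gen = (0.25, 0.75): R = (2, 2/3),
    # denominator = 4/3, so Q_L = Q * (1.5, 0.5)
    q_by_len = length_dependent_q({8: 2, 9: 2}, {8: 1, 9: 3}, q=9.41)
    assert q_by_len[8] == pytest.approx(9.41 * 1.5, rel=1e-15)
    assert q_by_len[9] == pytest.approx(9.41 * 0.5, rel=1e-15)


def test_length_dependent_q_pseudocount_for_unseen_length():
    q_by_len = length_dependent_q({8: 5, 9: 5}, {8: 100}, q=9.41)
    assert np.isfinite(q_by_len[9]) and q_by_len[9] > 0


def test_length_dependent_q_empty_inputs_rejected():
    with pytest.raises(ValueError):
        length_dependent_q({}, {8: 1}, 9.41)
    with pytest.raises(ValueError):
        length_dependent_q({8: 1}, {}, 9.41)


# ---------------------------------------------------------------------------
# pipeline-level behavior
# ---------------------------------------------------------------------------


def test_run_alice_empty_repertoire(toy_model):
    assert run_alice(Repertoire([]), toy_model, AliceConfig(n_sim=1000)) == []


def test_alpha_monotonicity_of_hit_set(toy_model, pgen_cache):
    from alicetcr import PlantedCluster, SyntheticScenario, generate_repertoire

    scenario = SyntheticScenario(
        model=toy_model, n_clonotypes=2000, seed=5,
        clusters=[PlantedCluster(size=10)],
    )
    rep, _ = generate_repertoire(scenario, pgen=pgen_cache)
    records = run_alice(rep, toy_model, AliceConfig(seed=20250), pgen_cache)
    hit_sets = []
    for alpha in (1e-5, 1e-3, 0.05):
        _adjust(records, AliceConfig(alpha=alpha, seed=20250))
        hit_sets.append({r.sigma for r in records if r.significant})
    assert hit_sets[0] <= hit_sets[1] <= hit_sets[2]


def test_bh_scope_per_vj_vs_global(toy_model, pgen_cache):
    from alicetcr import SyntheticScenario, generate_null_repertoire

    rep, _ = generate_null_repertoire(
        SyntheticScenario(model=toy_model, n_clonotypes=1500, seed=9)
    )
    glob = run_alice(rep, toy_model, AliceConfig(seed=20250), pgen_cache)
    per = run_alice(
        rep, toy_model, AliceConfig(seed=20250, bh_scope="per_vj"), pgen_cache
    )
    assert [r.sigma for r in glob] == [r.sigma for r in per]
    assert [r.p_raw for r in glob] == [r.p_raw for r in per]  # raw p unaffected


def test_length_distribution_helper():
    (vjclass,) = partition_by_vj(make_repertoire(CLASS_ROWS))
    assert data_length_counts(vjclass) == {3: 3}


# ---------------------------------------------------------------------------
# d/n baseline
# ---------------------------------------------------------------------------


def _baseline_classes():
    rows = [
        ("NT1", "CFGW", "V", "J", 5),
        ("NT2", "CFGW", "V", "J", 3),
        ("NT3", "CFGA", "V", "J", 2),
        ("NT4", "WWWW", "V", "J", 9),
    ]
    return partition_by_vj(make_repertoire(rows))


def test_d_hits_threshold_zero_returns_all():
    hits, thr = d_hits_baseline(_baseline_classes(), threshold=0.0)
    assert {h.sigma for h in hits} == {"CFGW", "CFGA", "WWWW"}
    assert thr == 0.0


def test_d_hits_top_k_selects_largest_ratio():
    # distinct d/n ratios: 1.0 (AAAA), 2/3 (CCCC, CCCA), 1/3 (GGGG)
    rows = [
        ("NT1", "AAAA", "V1", "J", 2),
        ("NT2", "CCCC", "V2", "J", 2),
        ("NT3", "CCCA", "V2", "J", 2),
        ("NT4", "GGGG", "V2", "J", 2),
    ]
    hits, thr = d_hits_baseline(partition_by_vj(make_repertoire(rows)), k=1)
    assert [h.sigma for h in hits] == ["AAAA"]
    assert thr == hits[0].d_over_n == 1.0


def test_d_hits_ties_all_included():
    rows = [
        ("NT1", "AAAA", "V", "J", 2),
        ("NT2", "AAAC", "V", "J", 2),
        ("NT3", "CCCC", "V", "J", 2),
        ("NT4", "CCCA", "V", "J", 2),
    ]
    classes = partition_by_vj(make_repertoire(rows))
    hits, _ = d_hits_baseline(classes, k=1)
    assert len(hits) == 4  # all tied at d/n = 2/4


def test_d_hits_argument_validation():
    with pytest.raises(ValueError):
        d_hits_baseline(_baseline_classes())
    with pytest.raises(ValueError):
        d_hits_baseline(_baseline_classes(), threshold=0.1, k=2)
    with pytest.raises(ValueError):
        d_hits_baseline(_baseline_classes(), threshold=-1.0)


def test_config_validation():
    with pytest.raises(ValueError):
        AliceConfig(alpha=2.0)
    with pytest.raises(ValueError):
        AliceConfig(q=-1.0)
    with pytest.raises(ValueError):
        AliceConfig(bh_scope="nope")
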