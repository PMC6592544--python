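"""Shared fixtures: toy model, Monte-Carlo table cache, repertoire builders.

The Monte-Carlo P_gen cache is session-scoped: tables depend only on the
model, the number of draws, and the Monte-Carlo seed, so every test that
needs the full-resolution null shares one set of tables while varying its
repertoire seeds.
"""

from __future__ import annotations

import numpy as np
import pytest

from alicetcr import (
    AliceConfig,
    Clonotype,
    GenModel,
    PgenCache,
    Repertoire,
    toy_beta_model,
)

#: Monte-Carlo seed for the shared table cache (independent of repertoire seeds)
MC_SEED = 20250
N_SIM = 1_000_000


@pytest.fixture(scope="session")
def toy_model() -> GenModel:
    return toy_beta_model()


@pytest.fixture(scope="session")
def pgen_cache(toy_model) -> PgenCache:
    """Full-resolution (1e6 draws/class) Monte-Carlo tables for the toy model."""
    cache = PgenCache(toy_model, N_SIM, MC_SEED)
    for vj in toy_model.vj_pairs():
        cache.table(vj)
    return cache


@pytest.fixture()
def default_cfg() -> AliceConfig:
    return AliceConfig(n_sim=N_SIM, seed=MC_SEED)


def make_repertoire(rows, sample_id="test") -> Repertoire:
    """Build a repertoire from (cdr3_nt, cdr3_aa, v, j, count) tuples."""
    return Repertoire([Clonotype(*row) for row in rows], sample_id=sample_id)


@pytest.fixture()
def degenerate_model() -> GenModel:
    """One V suffix, one J prefix, no trimming, no insertions: always 'CF'."""
    return GenModel(
        name="degenerate",
        v_segments={"V": "TGT"},
        j_segments={"J": "TTT"},
        vj_usage={("V", "J"): 1.0},
        v_trim={"*": np.array([1.0])},
        j_trim={"*": np.array([1.0])},
        ins_len=np.array([1.0]),
        ins_nt=np.array([0.25, 0.25, 0.25, 0.25]),
    )
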