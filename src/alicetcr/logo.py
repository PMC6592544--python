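"""Position-weight-matrix selection model for clusters of responding sequences.

A cluster of same-length hit CDR3s is compared against the recombination
background through the factorized selection model

    P_sel(sigma) = (1/Z) * P_gen(sigma) * exp(sum_i s_i(sigma_i)),

where ``s_i(a)`` is the selection coefficient of amino acid ``a`` at position
``i``.  Coefficients are fit by L2-regularized gradient ascent on the
likelihood; after every update the coefficients at each position are shifted
by a common constant so that ``sum_a P_gen(sigma_i = a) exp(s_i(a)) = 1``.
Under that constraint the predicted positional frequency is simply
``P_sel_i(a) = P_gen_i(a) exp(s_i(a))``.

Two logo representations are provided: the classical information-content
logo (dominated by germline-encoded conservation) and the selection logo
with letter heights ``P_data_i(a) * s_i(a)``, which highlights enrichment
relative to what recombination alone produces — depleted residues get
negative heights and are drawn below the axis.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .seqs import AA_ALPHABET, AA_INDEX

BACKGROUND_PSEUDO = 1e-6


class ConvergenceError(RuntimeError):
    """Gradient ascent failed to converge within the iteration cap."""


def positional_frequencies(sequences: Sequence[str]) -> np.ndarray:
    """L x 20 positional amino-acid frequency matrix of same-length sequences."""
    if not sequences:
        raise ValueError("empty sequence set")
    L = len(sequences[0])
    if any(len(s) != L for s in sequences):
        raise ValueError("sequences have mixed lengths")
    freqs = np.zeros((L, 20))
    for s in sequences:
        for i, a in enumerate(s):
            if a not in AA_INDEX:
                raise ValueError(f"non-canonical amino acid {a!r} in {s!r}")
            freqs[i, AA_INDEX[a]] += 1
    return freqs / len(sequences)


@dataclass
class SelectionModel:
    """Converged per-position selection coefficients with their inputs.

    ``z`` is the residual normalization of the factorized model,
    ``prod_i sum_a P_gen_i(a) exp(s_i(a))`` — exactly 1 only when positions
    are independent under the background; it is reported, not forced to 1.
    """

    s: np.ndarray  # L x 20
    background: np.ndarray  # L x 20, possibly pseudocount-regularized
    data_freqs: np.ndarray  # L x 20
    z: float
    n_iter: int
    background_regularized: bool = False

    @property
    def L(self) -> int:
        return self.s.shape[0]

    def predicted_freqs(self) -> np.ndarray:
        """P_sel_i(a) = P_gen_i(a) * exp(s_i(a)) under the normalization."""
        return self.background * np.exp(self.s)


def _regularize_background(background: np.ndarray) -> tuple[np.ndarray, bool]:
    bg = np.asarray(background, dtype=float)
    touched = bool((bg <= 0).any())
    if touched:
        bg = np.maximum(bg, BACKGROUND_PSEUDO)
    bg = bg / bg.sum(axis=1, keepdims=True)
    return bg, touched


def fit_selection(
    data_freqs: np.ndarray,
    background: np.ndarray,
    epsilon: float = 0.5,
    reg_lambda: float = 0.02,
    tol: float = 1e-6,
    max_iter: int = 100_000,
    s_init: np.ndarray | None = None,
) -> SelectionModel:
    """Fit the selection coefficients by regularized gradient ascent.

    Starting from ``s = 0`` (or ``s_init``), iterate

        s_i(a) <- s_i(a) + epsilon * [P_data_i(a) - P_sel_i(a)
                                      - 2 * reg_lambda * s_i(a)],

    renormalize each position (common additive shift so the constrained sum
    equals 1), and stop when the summed squared change of s between accepted
    iterates drops below ``tol``.  Background cells at exactly 0 get a small
    pseudo-probability (renormalized, flagged on the result) so the
    normalization constraint stays well defined.
    """
    data = np.asarray(data_freqs, dtype=float)
    bg, touched = _regularize_background(background)
    if data.shape != bg.shape or data.ndim != 2 or data.shape[1] != 20:
        raise ValueError("data and background must be conformable L x 20 matrices")
    s = np.zeros_like(bg) if s_init is None else np.array(s_init, dtype=float)
    s = _normalize(s, bg)
    for it in range(1, max_iter + 1):
        p_sel = bg * np.exp(s)
        s_new = s + epsilon * (data - p_sel - 2.0 * reg_lambda * s)
        s_new = _normalize(s_new, bg)
        delta = float(((s_new - s) ** 2).sum())
        s = s_new
        if delta < tol:
            z = float(np.prod((bg * np.exp(s)).sum(axis=1)))
            return SelectionModel(s, bg, data, z, it, touched)
    raise ConvergenceError(
        f"no convergence after {max_iter} iterations "
        f"(last squared update {delta:.3e}, tol {tol:.1e})"
    )


def _normalize(s: np.ndarray, bg: np.ndarray) -> np.ndarray:
    """Shift each position's coefficients so sum_a P_gen_i(a) e^{s_i(a)} = 1."""
    norms = (bg * np.exp(s)).sum(axis=1, keepdims=True)
    return s - np.log(norms)


def selection_logo_heights(model: SelectionModel) -> np.ndarray:
    """Letter heights P_data_i(a) * s_i(a); negative for depleted residues."""
    return model.data_freqs * model.s


def classical_logo_heights(data_freqs: np.ndarray) -> np.ndarray:
    """Standard information-content logo heights (bits).

    Per-position information is ``log2(20) - H(p)``; each letter's height is
    its frequency times that information.
    """
    p = np.asarray(data_freqs, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(p > 0, p * np.log2(p), 0.0)
    info = np.log2(20) + plogp.sum(axis=1)
    return p * info[:, None]


def heights_frame(heights: np.ndarray):
    """Tabulate an L x 20 heights (or coefficients) matrix for TSV export."""
    import pandas as pd

    df = pd.DataFrame(heights, columns=list(AA_ALPHABET))
    df.insert(0, "position", np.arange(1, heights.shape[0] + 1))
    return df


def render_logo(heights: np.ndarray, path, title: str = "") -> None:
    """Render a (selection or classical) logo as stacked letter bars.

    Plotting is optional; matplotlib is imported lazily.  Letters with
    negative heights stack below the axis.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    L = heights.shape[0]
    fig, ax = plt.subplots(figsize=(max(4, 0.6 * L), 3))
    for i in range(L):
        pos_base = 0.0
        neg_base = 0.0
        order = np.argsort(-np.abs(heights[i]))
        for a in order:
            h = heights[i, a]
            if h == 0:
                continue
            base = pos_base if h > 0 else neg_base
            ax.bar(i + 1, h, bottom=base, width=0.8, alpha=0.85)
            ax.text(
                i + 1, base + h / 2, AA_ALPHABET[a],
                ha="center", va="center", fontsize=7,
            )
            if h > 0:
                pos_base += h
            else:
                neg_base += h
    ax.axhline(0.0, color="black", lw=0.8)
    ax.set_xlabel("CDR3 position")
    ax.set_ylabel("letter height")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
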