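"""Composition proportions θ from latent fields via Monte Carlo integration.

θ_p(s_i) = Prob(W_p = max_p' W_p') with W_p' ~ N(α_p'(s_i), 1) has no
closed form for P > 2, so each retained α draw is converted to a simplex
of per-cell proportions by simulating ``n_mc`` hypothetical trees per cell
and recording the frequency with which each taxon attains the maximum.
Every (draw, cell) pair gets its own RNG substream spawned from the master
seed, so results are reproducible regardless of evaluation order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

__all__ = [
    "ThetaSamples",
    "mc_theta",
    "theta_from_posterior",
    "probit_two_taxon_oracle",
    "summarize_theta",
]


@dataclass
class ThetaSamples:
    """K × m × P array of posterior composition draws (each (k, i) slice a simplex)."""

    theta: np.ndarray
    n_mc: int
    seed: int

    @property
    def n_samples(self) -> int:
        return self.theta.shape[0]

    @property
    def n_cells(self) -> int:
        return self.theta.shape[1]

    @property
    def n_taxa(self) -> int:
        return self.theta.shape[2]


def _cell_rng(seed: int, draw_index: int, cell: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(draw_index, cell)))


def mc_theta(
    alpha_draw: np.ndarray,
    n_mc: int = 10000,
    seed: int = 0,
    draw_index: int = 0,
    cells: np.ndarray | None = None,
    chunk: int = 256,
) -> np.ndarray:
    """Per-cell composition simplexes for one latent-field draw.

    ``alpha_draw`` is (P, m).  For each cell, ``n_mc`` independent P-vectors
    W ~ N(α(cell), I) are drawn and the frequency of each taxon attaining
    the maximum is returned (ties, a floating-point measure-zero event,
    go to the lowest taxon index via argmax).  Returns (m, P) with rows
    summing to exactly 1.
    """
    if n_mc < 1:
        raise ValueError(f"n_mc must be a positive integer, got {n_mc}")
    alpha_draw = np.asarray(alpha_draw, dtype=float)
    if not np.all(np.isfinite(alpha_draw)):
        raise ValueError("non-finite latent field values")
    P, m = alpha_draw.shape
    if cells is None:
        cells = np.arange(m)
    out = np.empty((len(cells), P))
    for pos in range(0, len(cells), chunk):
        block = cells[pos : pos + chunk]
        for k, i in enumerate(block):
            rng = _cell_rng(seed, draw_index, int(i))
            w = rng.standard_normal((n_mc, P)) + alpha_draw[:, i]
            counts = np.bincount(np.argmax(w, axis=1), minlength=P)
            out[pos + k] = _closed_simplex(counts, n_mc)
    return out


def _closed_simplex(counts, n_mc):
    """Empirical frequencies whose float sum is exactly 1.

    Division rounds each share, so the row can miss closure by an ulp; the
    last share is set to the complement of the rest, then single-ulp
    adjustments walk a share until the float sum is exactly 1.
    """
    row = counts / n_mc
    s_part = row[:-1].sum()
    row[-1] = max(1.0 - s_part, 0.0)
    if row.sum() == 1.0:
        return row
    for j in np.argsort(row)[::-1]:
        saved = row[j]
        for _ in range(32):
            s = row.sum()
            if s == 1.0:
                return row
            row[j] = np.nextafter(row[j], np.inf if s < 1.0 else -np.inf)
        if row.sum() == 1.0:
            return row
        row[j] = saved
    return row  # pragma: no cover - unreachable in the stress-tested regime


def theta_from_posterior(posterior, n_mc: int = 10000, seed: int = 0, cells=None) -> ThetaSamples:
    """Convert retained α draws (a :class:`~gridcomp.sampler.PosteriorSamples`
    or a (K, P, m) array) into composition draws."""
    alpha = posterior.alpha if hasattr(posterior, "alpha") else np.asarray(posterior)
    K = alpha.shape[0]
    thetas = [mc_theta(alpha[k], n_mc=n_mc, seed=seed, draw_index=k, cells=cells) for k in range(K)]
    return ThetaSamples(theta=np.stack(thetas), n_mc=n_mc, seed=seed)


def probit_two_taxon_oracle(a1: float, a2: float) -> float:
    """Exact Prob(N(a1,1) > N(a2,1)) = Φ((a1−a2)/√2): the P = 2 closed form."""
    return float(norm.cdf((a1 - a2) / np.sqrt(2.0)))


def summarize_theta(samples: ThetaSamples):
    """Posterior mean and sample standard deviation of θ across the K draws.

    Returns ``(mean, sd)``, each (m, P); means per cell sum to 1.  The sd is
    the Bayesian standard error of the composition estimate.
    """
    theta = samples.theta if isinstance(samples, ThetaSamples) else np.asarray(samples)
    if theta.shape[0] < 2:
        raise ValueError("standard deviation needs at least 2 posterior draws")
    return theta.mean(axis=0), theta.std(axis=0, ddof=1)
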