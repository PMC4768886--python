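"""Latent-variable MCMC for the spatial multinomial-probit composition model.

Each tree j at cell i carries P latent Gaussian utilities
W_ijp ~ N(α_p(s_i), 1); the observed taxon is the argmax.  The sampler
alternates:

1. truncated-normal Gibbs draws of all W (the observed taxon's utility is
   truncated below at the max of the others; the rest truncated above at it);
2. a sweep of township-tree membership draws c_tj (change of support);
3. sufficient statistics: per-cell tree counts A and per-cell W means w̄;
4. per taxon, a Gibbs draw of the whole field α_p from its Gaussian full
   conditional N((A+Q_p)⁻¹(A w̄_p + Q_p μ_p 1), (A+Q_p)⁻¹), followed by
   "cross-level" joint Metropolis updates of the hyperparameter blocks
   (log σ_p for CAR; μ_p then (log σ_p, log ρ_p) for SPDE) in which a
   proposed block is paired with a fresh full-conditional α_p draw — the
   acceptance ratio then reduces to the α-marginalized posterior ratio of
   the block given W.

Field draws use the square-root-noise construction: α = M⁻¹(b + A^{1/2}ε₁
+ Q_p^{1/2}ε₂) with M = A + Q_p, which is an exact draw and needs only an
SPD solve plus sparse square roots of Q_p (the ICAR's edge incidence
matrix, or the symmetric aI − C factor of the SPDE template).  In the
row-major lattice ordering A + Q_p is banded, so the solve and the
log-determinant come from a banded Cholesky factorization.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg as sla
import scipy.sparse as sp
import scipy.sparse.csgraph as csgraph
import scipy.sparse.linalg as spla
from numba import njit

from .geometry import CellAdjacency, GridSpec, TownshipOverlap, cardinal_adjacency
from .priors import (
    FOUR_PI,
    HyperParams,
    HyperpriorBounds,
    PrecisionTemplate,
    build_car_precision,
    build_spde_precision,
    hyperprior_logdensity,
    lattice_adjacency_eigenvalues,
    spde_template_logdet,
)

logger = logging.getLogger(__name__)

__all__ = [
    "MCMCConfig",
    "SuffStats",
    "LatentState",
    "PosteriorSamples",
    "ProbitGibbsSampler",
    "gibbs_update_W",
    "compute_suff_stats",
    "alpha_conditional_mean",
    "gibbs_update_alpha",
    "marginal_hyper_logpost",
    "membership_probabilities",
    "gibbs_update_membership",
    "run_sampler",
]


# --------------------------------------------------------------------------
# configuration and state containers
# --------------------------------------------------------------------------


@dataclass
class MCMCConfig:
    """Chain lengths, seed, adaptation schedule, and Monte Carlo settings."""

    n_iter: int = 2000
    n_burn: int = 500
    n_keep: int = 250
    seed: int = 0
    adapt: bool = True
    adapt_batch: int = 50
    target_accept_scalar: float = 0.44
    target_accept_vector: float = 0.23
    n_mc_theta: int = 10000
    taxon_min_count: int = 1
    ridge: float = 1e-8
    spde_joint_block: bool = False  # True: single (mu, log sigma, log rho) block
    hyper_sweeps: int = 1  # cross-level block sweeps per iteration

    def __post_init__(self):
        if not (0 <= self.n_burn < self.n_iter):
            raise ValueError("need 0 <= n_burn < n_iter")
        if not (1 <= self.n_keep <= self.n_iter - self.n_burn):
            raise ValueError("need 1 <= n_keep <= n_iter - n_burn")


@dataclass
class SuffStats:
    """Per-cell tree counts A (diagonal) and per-cell W means w̄ (m × P)."""

    A: np.ndarray
    wbar: np.ndarray

    @property
    def n_trees(self) -> int:
        return int(self.A.sum())


@dataclass
class LatentState:
    """Everything the chain carries between iterations."""

    W: np.ndarray  # (n_trees, P)
    alpha: np.ndarray  # (P, m)
    tree_cell: np.ndarray  # (n_trees,) current cell of each tree
    tree_town: np.ndarray  # (n_trees,) township position, -1 for gridded trees
    taxa: np.ndarray  # (n_trees,) observed taxon index
    hp: HyperParams
    adapt: dict = field(default_factory=dict)


@dataclass
class PosteriorSamples:
    """Retained posterior draws and chain diagnostics."""

    alpha: np.ndarray  # (K, P, m)
    sigma: np.ndarray  # (K, P)
    mu: np.ndarray | None  # (K, P) for SPDE
    rho: np.ndarray | None  # (K, P) for SPDE
    kind: str
    taxa_kept: np.ndarray  # indices into the original taxon list
    acceptance: dict  # block name -> per-taxon acceptance rate
    config: MCMCConfig
    grid: GridSpec

    @property
    def n_samples(self) -> int:
        return self.alpha.shape[0]

    @property
    def n_taxa(self) -> int:
        return self.alpha.shape[1]


# --------------------------------------------------------------------------
# truncated-normal and W kernels (numba)
# --------------------------------------------------------------------------


@njit(cache=True)
def _tn_tail(s):
    """Draw from a standard normal truncated to (s, inf).

    Plain rejection for low cutoffs; Robert's translated-exponential
    rejection otherwise.  Stable for s well beyond 40.
    """
    if s < 0.45:
        while True:
            x = np.random.standard_normal()
            if x > s:
                return x
    lam = 0.5 * (s + math.sqrt(s * s + 4.0))
    while True:
        x = s + np.random.exponential() / lam
        d = x - lam
        if np.random.random() < math.exp(-0.5 * d * d):
            return x


@njit(cache=True)
def _tn_lower(mu, a):
    """N(mu, 1) truncated below at a."""
    return mu + _tn_tail(a - mu)


@njit(cache=True)
def _tn_upper(mu, b):
    """N(mu, 1) truncated above at b."""
    return mu - _tn_tail(mu - b)


@njit(cache=True)
def _w_sweep(W, taxa, cells, alpha):
    n, P = W.shape
    for j in range(n):
        y = taxa[j]
        i = cells[j]
        mx = -np.inf
        for p in range(P):
            if p != y and W[j, p] > mx:
                mx = W[j, p]
        wy = _tn_lower(alpha[y, i], mx)
        W[j, y] = wy
        for p in range(P):
            if p != y:
                W[j, p] = _tn_upper(alpha[p, i], wy)


@njit(cache=True)
def _seed_numba(seed):
    np.random.seed(seed)


def gibbs_update_W(W, taxa, cells, alpha, rng) -> None:
    """In-place Gibbs sweep over all latent utilities.

    For each tree with observed taxon y: W_y ~ N(α_y, 1) truncated below at
    max_{p≠y} W_p, then every other W_p ~ N(α_p, 1) truncated above at the
    new W_y, so argmax_p W_p = y holds on exit.
    """
    if not np.all(np.isfinite(alpha)):
        raise FloatingPointError("non-finite latent field values entering W update")
    _seed_numba(int(rng.integers(0, 2**31 - 1)))
    _w_sweep(W, taxa, cells, alpha)


# --------------------------------------------------------------------------
# sufficient statistics
# --------------------------------------------------------------------------


def compute_suff_stats(W, cells, m) -> SuffStats:
    """Per-cell counts and W means at the current tree-to-cell assignment."""
    A = np.bincount(cells, minlength=m).astype(np.float64)
    P = W.shape[1]
    wbar = np.empty((m, P))
    denom = np.where(A > 0, A, 1.0)
    for p in range(P):
        wbar[:, p] = np.bincount(cells, weights=W[:, p], minlength=m) / denom
    wbar[A == 0, :] = 0.0
    return SuffStats(A=A, wbar=wbar)


# --------------------------------------------------------------------------
# SPD factorizations (banded Cholesky with sparse fallback)
# --------------------------------------------------------------------------

_SPLU_OPTS = dict(permc_spec="MMD_AT_PLUS_A", diag_pivot_thresh=0.0, options=dict(SymmetricMode=True))


class _BandedFactor:
    """Cholesky factor of a banded SPD matrix with solve and log-determinant.

    Calls the LAPACK banded routines directly; the matrices here are small
    enough that wrapper overhead would otherwise dominate.
    """

    def __init__(self, ab_upper):
        c, info = sla.lapack.dpbtrf(ab_upper, lower=0)
        if info != 0:
            raise np.linalg.LinAlgError(f"banded Cholesky failed (info={info})")
        self._c = c
        self.logdet = float(2.0 * np.sum(np.log(c[-1])))

    def solve(self, b):
        x, info = sla.lapack.dpbtrs(self._c, b, lower=0)
        if info != 0:
            raise np.linalg.LinAlgError(f"banded solve failed (info={info})")
        return x


def banded_upper(M) -> np.ndarray:
    """LAPACK upper banded storage of a symmetric sparse matrix."""
    M = M.tocsr()
    coo = M.tocoo()
    k = int(np.max(coo.col - coo.row)) if coo.nnz else 0
    m = M.shape[0]
    ab = np.zeros((k + 1, m))
    for off in range(k + 1):
        diag = M.diagonal(off)
        if np.any(diag):
            ab[k - off, off:] = diag
    return ab


def _factorize(M, ridge_scale=1e-8):
    """Factor a sparse SPD matrix: banded Cholesky, SuperLU ridge fallback.

    Returns ``(factor, logdet)`` where ``factor.solve`` solves M x = b.
    """
    try:
        f = _BandedFactor(banded_upper(M))
        if np.isfinite(f.logdet):
            return f, f.logdet
    except np.linalg.LinAlgError:
        pass
    eps = ridge_scale * M.diagonal().max()
    logger.warning("singular conditional precision; adding ridge %.3e", eps)
    lu = spla.splu((M + eps * sp.identity(M.shape[0])).tocsc(), **_SPLU_OPTS)
    return lu, float(np.sum(np.log(np.abs(lu.U.diagonal()))))


def _factorize_banded(ab_template, scale, A, ridge_scale=1e-8):
    """Factor A + Q_template/scale directly in banded storage."""
    ab = ab_template / scale
    ab[-1] += A
    try:
        f = _BandedFactor(ab)
        if np.isfinite(f.logdet):
            return f, f.logdet
    except np.linalg.LinAlgError:
        pass
    eps = ridge_scale * ab[-1].max()
    logger.warning("singular conditional precision; adding ridge %.3e", eps)
    ab[-1] += eps
    f = _BandedFactor(ab)
    return f, f.logdet


# --------------------------------------------------------------------------
# alpha full conditional
# --------------------------------------------------------------------------


def alpha_conditional_mean(stats: SuffStats, Qp, taxon: int, mu_p: float = 0.0):
    """Mean of the α_p full conditional, (A+Q_p)⁻¹(A w̄_p + Q_p μ_p 1).

    Evaluated in the numerically stable centered form
    μ_p + (A+Q_p)⁻¹ A (w̄_p − μ_p 1), which is identical because
    (A+Q_p) μ_p 1 = A μ_p 1 + Q_p μ_p 1.
    """
    M = Qp + sp.diags(stats.A)
    b = stats.A * (stats.wbar[:, taxon] - mu_p)
    lu, _ = _factorize(M)
    return mu_p + lu.solve(b)


def gibbs_update_alpha(stats: SuffStats, Qp, root, taxon: int, rng, mu_p: float = 0.0, lu=None):
    """Exact draw from α_p ~ N((A+Q_p)⁻¹(A w̄_p + Q_p μ_p 1), (A+Q_p)⁻¹).

    ``root`` is any sparse R with R.T @ R = Q_p (already scaled).  Pass a
    prefactorized ``lu`` of A + Q_p to reuse it across draws.  The draw is
    α = μ_p + M⁻¹(A(w̄_p − μ_p) + A^{1/2}ε₁ + R'ε₂), whose exact
    distribution is the stated Gaussian.
    """
    m = Qp.shape[0]
    if lu is None:
        lu, _ = _factorize(Qp + sp.diags(stats.A))
    b = stats.A * (stats.wbar[:, taxon] - mu_p)
    noise = np.sqrt(stats.A) * rng.standard_normal(m) + root.T @ rng.standard_normal(root.shape[0])
    return mu_p + lu.solve(b + noise)


# --------------------------------------------------------------------------
# cross-level (alpha-marginalized) hyperparameter posterior
# --------------------------------------------------------------------------


def marginal_hyper_logpost(
    stats: SuffStats,
    kind: str,
    template: PrecisionTemplate,
    taxon: int,
    sigma: float,
    mu: float = 0.0,
    rho: float | None = None,
    grid: GridSpec | None = None,
    eigs: np.ndarray | None = None,
    rank_deficiency: int = 1,
    bounds: HyperpriorBounds = HyperpriorBounds(),
    spde_logdet_template: float | None = None,
    ab_template: np.ndarray | None = None,
    return_factor: bool = False,
):
    """Log posterior of one taxon's hyperparameter block given W, with α integrated out.

    Up to an additive constant that does not depend on the block:
    ½ log|Q_p| − ½ log|A+Q_p| + ½ b'(A+Q_p)⁻¹b − ½ Σ_i A_ii (w̄_ip − μ)²
    with b = A(w̄_p − μ1) (the centered form of the Gaussian marginal of W
    given the block, numerically stable for extreme Q_p scales), plus the
    uniform-prior support indicator and the log-Jacobians of the log-scale
    parameterization of σ (and ρ).  For the improper ICAR the determinant
    term uses the generalized determinant of rank m − k.  Returns −inf
    outside the prior support; with ``return_factor`` also returns the
    factorization of A + Q_p for reuse in the paired field draw.
    """

    def _fail():
        return (-np.inf, None) if return_factor else -np.inf

    hp = HyperParams(
        sigma=np.array([sigma]),
        mu=np.array([mu]) if kind == "spde" else None,
        rho=np.array([rho]) if kind == "spde" else None,
    )
    if hyperprior_logdensity(hp, kind, bounds) == -np.inf:
        return _fail()
    if not np.isfinite(sigma) or sigma**2 == 0.0 or not np.isfinite(1.0 / sigma**2):
        return _fail()

    m = len(stats.A)
    if template is not None and template.n_cells != m:
        raise ValueError("template size does not match sufficient statistics")
    if kind == "car":
        if not (1e-125 < sigma < 1e125):
            return _fail()
        scale = sigma**2
        half_logdet_Q = -0.5 * (m - rank_deficiency) * 2.0 * np.log(sigma)
        b = stats.A * stats.wbar[:, taxon]
        mean_term = 0.0
    else:
        if rho is None:
            raise ValueError("SPDE block requires rho")
        if template is not None and (
            template.rho is None or not np.isclose(template.rho, rho)
        ):
            raise ValueError(
                f"template was built for rho={template.rho}; rebuild it for rho={rho}"
            )
        scale = sigma**2 * FOUR_PI * rho**2
        if not (1e-250 < scale < 1e250):
            return _fail()
        if spde_logdet_template is None:
            if grid is None:
                raise ValueError("grid (or a precomputed template log-determinant) is required")
            spde_logdet_template = spde_template_logdet(grid, rho, eigs)
        half_logdet_Q = 0.5 * (spde_logdet_template - m * np.log(scale))
        b = stats.A * (stats.wbar[:, taxon] - mu)
        mean_term = -0.5 * float(stats.A @ (stats.wbar[:, taxon] - mu) ** 2)

    if ab_template is not None:
        lu, logdet_M = _factorize_banded(ab_template, scale, stats.A)
    else:
        if template is None:
            raise ValueError("either a template or its banded storage is required")
        lu, logdet_M = _factorize(template.Q / scale + sp.diags(stats.A))
    quad = 0.5 * float(b @ lu.solve(b))
    # uniform priors on sigma (and rho) sampled on the log scale: +log sigma (+log rho)
    jac = np.log(sigma) + (np.log(rho) if kind == "spde" else 0.0)
    out = float(half_logdet_Q - 0.5 * logdet_M + quad + mean_term + jac)
    # numerically untenable values (overflow in the quadratic form) are rejected
    if not np.isfinite(out):
        return _fail()
    return (out, lu) if return_factor else out


# --------------------------------------------------------------------------
# township membership updates
# --------------------------------------------------------------------------


def membership_probabilities(w_row, alpha, cells, psi):
    """Posterior cell probabilities for one township tree: ∝ ψ_i Π_p N(W_p; α_p(i), 1).

    Computed in log space; never assigns mass outside the township support.
    """
    logw = np.log(psi) - 0.5 * np.sum((w_row[:, None] - alpha[:, cells]) ** 2, axis=0)
    logw -= logw.max()
    w = np.exp(logw)
    return w / w.sum()


@njit(cache=True)
def _membership_sweep(W, tree_cell, tree_town, ov_ptr, ov_cells, ov_logpsi, alpha):
    n, P = W.shape
    for j in range(n):
        t = tree_town[j]
        if t < 0:
            continue
        lo, hi = ov_ptr[t], ov_ptr[t + 1]
        k = hi - lo
        if k == 1:
            tree_cell[j] = ov_cells[lo]
            continue
        best = -np.inf
        logw = np.empty(k)
        for c in range(k):
            cell = ov_cells[lo + c]
            s = ov_logpsi[lo + c]
            for p in range(P):
                d = W[j, p] - alpha[p, cell]
                s -= 0.5 * d * d
            logw[c] = s
            if s > best:
                best = s
        tot = 0.0
        for c in range(k):
            logw[c] = math.exp(logw[c] - best)
            tot += logw[c]
        u = np.random.random() * tot
        acc = 0.0
        pick = k - 1
        for c in range(k):
            acc += logw[c]
            if u <= acc:
                pick = c
                break
        tree_cell[j] = ov_cells[lo + pick]


def gibbs_update_membership(state: LatentState, overlap_arrays, rng) -> None:
    """One sweep of c_tj draws over all township trees (in place)."""
    ov_ptr, ov_cells, ov_logpsi = overlap_arrays
    _seed_numba(int(rng.integers(0, 2**31 - 1)))
    _membership_sweep(
        state.W, state.tree_cell, state.tree_town, ov_ptr, ov_cells, ov_logpsi, state.alpha
    )


def _overlap_arrays(overlap: TownshipOverlap):
    ptr = np.zeros(overlap.n_townships + 1, dtype=np.int64)
    for t in range(overlap.n_townships):
        ptr[t + 1] = ptr[t] + len(overlap.cells[t])
    cells = np.concatenate(overlap.cells) if overlap.n_townships else np.empty(0, dtype=np.int64)
    logpsi = (
        np.log(np.concatenate(overlap.weights)) if overlap.n_townships else np.empty(0)
    )
    return ptr, cells.astype(np.int64), logpsi


# --------------------------------------------------------------------------
# adaptation
# --------------------------------------------------------------------------


class _AdaptiveBlock:
    """Robbins–Monro scale adaptation with Haario-style covariance for 2/3-D blocks."""

    def __init__(self, dim, target, batch=50):
        self.dim = dim
        self.target = target
        self.batch = batch
        self.log_scale = 0.0 if dim == 1 else np.log(2.38 / np.sqrt(dim))
        self.accepted = 0
        self.proposed = 0
        self.n_batches = 0
        self.frozen = False
        # running moments of the chain for covariance adaptation
        self._n = 0
        self._mean = np.zeros(dim)
        self._m2 = np.zeros((dim, dim))
        self._chol = None

    def propose(self, x, rng):
        x = np.atleast_1d(np.asarray(x, dtype=float))
        s = np.exp(self.log_scale)
        if self.dim == 1:
            return x + s * rng.standard_normal(1)
        if self._chol is None or not self.frozen:
            self._chol = np.linalg.cholesky(self.covariance())
        return x + s * (self._chol @ rng.standard_normal(self.dim))

    def covariance(self):
        if self._n < 2 * self.batch:
            return np.eye(self.dim)
        emp = self._m2 / (self._n - 1)
        return emp + 1e-6 * np.eye(self.dim)

    def record(self, x, accepted):
        x = np.atleast_1d(np.asarray(x, dtype=float))
        self.proposed += 1
        self.accepted += int(accepted)
        if not self.frozen:
            self._n += 1
            d = x - self._mean
            self._mean += d / self._n
            self._m2 += np.outer(d, x - self._mean)
            if self.proposed % self.batch == 0:
                self.n_batches += 1
                rate = self.accepted / self.proposed
                step = min(0.1, 1.0 / np.sqrt(self.n_batches))
                self.log_scale += step if rate > self.target else -step

    @property
    def rate(self):
        return self.accepted / self.proposed if self.proposed else np.nan


# --------------------------------------------------------------------------
# the full sampler
# --------------------------------------------------------------------------


def _expand_trees(grid_counts, township_counts, overlap, rng):
    """Per-tree taxon/location arrays from count tables.

    Township trees get an initial cell drawn from the overlap prior ψ.
    """
    taxa_list = []
    cell_list = []
    town_list = []
    if grid_counts is not None:
        cells_nz, taxa_nz = np.nonzero(grid_counts)
        for i, p in zip(cells_nz, taxa_nz):
            n = int(grid_counts[i, p])
            taxa_list.append(np.full(n, p, dtype=np.int64))
            cell_list.append(np.full(n, i, dtype=np.int64))
            town_list.append(np.full(n, -1, dtype=np.int64))
    if township_counts is not None and overlap is not None and overlap.n_townships:
        for t in range(township_counts.shape[0]):
            for p in np.nonzero(township_counts[t])[0]:
                n = int(township_counts[t, p])
                taxa_list.append(np.full(n, p, dtype=np.int64))
                c0 = rng.choice(overlap.cells[t], size=n, p=overlap.weights[t])
                cell_list.append(c0.astype(np.int64))
                town_list.append(np.full(n, t, dtype=np.int64))
    if not taxa_list:
        raise ValueError("no trees in the dataset")
    return (
        np.concatenate(taxa_list),
        np.concatenate(cell_list),
        np.concatenate(town_list),
    )


class ProbitGibbsSampler:
    """The assembled chain: data expansion, spatial templates, and one-iteration steps.

    Most users call :func:`run_sampler`; the class surface exists so that
    individual transitions can be composed externally (e.g. prior-invariance
    testing, custom retention schedules).
    """

    def __init__(
        self,
        grid_counts,
        kind: str,
        grid: GridSpec,
        township_counts=None,
        overlap: TownshipOverlap | None = None,
        config: MCMCConfig | None = None,
        bounds: HyperpriorBounds = HyperpriorBounds(),
        adj: CellAdjacency | None = None,
    ):
        if kind not in ("car", "spde"):
            raise ValueError(f"model kind must be 'car' or 'spde', got {kind!r}")
        self.kind = kind
        self.grid = grid
        self.config = config or MCMCConfig()
        self.bounds = bounds
        self.rng = np.random.default_rng(self.config.seed)
        self.m = grid.n_cells
        self.it = 0

        P_all = grid_counts.shape[1] if grid_counts is not None else township_counts.shape[1]
        totals = np.zeros(P_all)
        if grid_counts is not None:
            if grid_counts.shape[0] != self.m:
                raise ValueError("grid_counts rows must cover the buffered lattice")
            totals += grid_counts.sum(axis=0)
        if township_counts is not None:
            totals += township_counts.sum(axis=0)
        self.taxa_kept = np.nonzero(totals >= max(self.config.taxon_min_count, 1))[0]
        dropped = np.setdiff1d(np.arange(P_all), self.taxa_kept)
        if dropped.size:
            logger.warning(
                "dropping %d taxa with fewer than %d trees: %s",
                dropped.size, self.config.taxon_min_count, dropped.tolist(),
            )
        self.P = self.taxa_kept.size
        if self.P < 2:
            raise ValueError(f"need at least 2 taxa with data, have {self.P}")

        gcounts = grid_counts[:, self.taxa_kept] if grid_counts is not None else None
        tcounts = township_counts[:, self.taxa_kept] if township_counts is not None else None
        taxa, cells, towns = _expand_trees(gcounts, tcounts, overlap, self.rng)
        self.state = self._init_state(taxa, cells, towns)
        self._has_townships = bool((towns >= 0).any())
        self._ov_arrays = (
            _overlap_arrays(overlap) if (overlap is not None and self._has_townships) else None
        )

        self.adj = adj or cardinal_adjacency(grid)
        if kind == "car":
            self.template = build_car_precision(self.adj)
            self.ncomp, _ = csgraph.connected_components(self.adj.C, directed=False)
            self._incidence = self.adj.incidence()
            self._ab_car = banded_upper(self.template.Q)
            self._eigs = None
        else:
            self.ncomp = 1
            self._eigs = lattice_adjacency_eigenvalues(grid)
            # Q(rho) = a^2 I - 2a C + C^2: cache the three banded pieces so a
            # proposal's banded template is a scalar combination, not a
            # sparse rebuild
            C = self.adj.C.tocsr()
            C2 = (C @ C).tocsr()
            self._eye = sp.identity(self.m, format="csr")
            k = 2 * grid.total_nx
            self._abI = np.zeros((k + 1, self.m))
            self._abI[-1] = 1.0
            self._abC = self._pad_banded(banded_upper(C), k)
            self._abC2 = self._pad_banded(banded_upper(C2), k)
            self._spde_cache = {}
            self.template = self._spde_template(1.0)

        if kind == "car":
            self.blocks = {"sigma": [self._mk_block(1) for _ in range(self.P)]}
        elif self.config.spde_joint_block:
            self.blocks = {"joint": [self._mk_block(3) for _ in range(self.P)]}
        else:
            self.blocks = {
                "mu": [self._mk_block(1) for _ in range(self.P)],
                "sigrho": [self._mk_block(2) for _ in range(self.P)],
            }
        self.stats = compute_suff_stats(self.state.W, self.state.tree_cell, self.m)

    # -- setup helpers ----------------------------------------------------

    def _mk_block(self, dim):
        cfg = self.config
        target = cfg.target_accept_scalar if dim == 1 else cfg.target_accept_vector
        return _AdaptiveBlock(dim, target, cfg.adapt_batch)

    def _init_state(self, taxa, cells, towns) -> LatentState:
        n = taxa.size
        P = self.P
        alpha = np.zeros((P, self.m))
        W = self.rng.standard_normal((n, P))
        # rank-adjust so the observed taxon is the strict max
        wmax_other = np.where(np.arange(P)[None, :] == taxa[:, None], -np.inf, W).max(axis=1)
        obs = W[np.arange(n), taxa]
        bump = np.where(obs > wmax_other, 0.0, wmax_other - obs + 0.5)
        W[np.arange(n), taxa] += bump
        hp = HyperParams(
            sigma=np.ones(P),
            mu=np.zeros(P) if self.kind == "spde" else None,
            rho=np.ones(P) if self.kind == "spde" else None,
        )
        return LatentState(W=W, alpha=alpha, tree_cell=cells.copy(), tree_town=towns, taxa=taxa, hp=hp)

    @staticmethod
    def _pad_banded(ab, k):
        out = np.zeros((k + 1, ab.shape[1]))
        out[k + 1 - ab.shape[0] :] = ab
        return out

    def _spde_ab(self, rho):
        """Banded storage and log-determinant of the unscaled template Q(ρ)."""
        a = 4.0 + 1.0 / rho**2
        ab = (a * a) * self._abI - (2.0 * a) * self._abC + self._abC2
        return ab, spde_template_logdet(self.grid, rho, self._eigs)

    def _spde_template(self, rho):
        """Sparse template (with its symmetric root) for a given range, cached."""
        key = round(float(rho), 12)
        if key not in self._spde_cache:
            if len(self._spde_cache) > 8:
                self._spde_cache.clear()
            self._spde_cache[key] = build_spde_precision(self.adj, rho)
        return self._spde_cache[key]

    # -- pieces used by step() --------------------------------------------

    def scaled_Q_root(self, p, sigma=None, rho=None):
        """Scaled precision Q_p and sparse root R (R'R = Q_p) at the given block values."""
        sigma = self.state.hp.sigma[p] if sigma is None else sigma
        if self.kind == "car":
            return self.template.Q / sigma**2, self._incidence / sigma
        rho = self.state.hp.rho[p] if rho is None else rho
        tmpl = self._spde_template(rho)
        c = sigma**2 * FOUR_PI * rho**2
        return tmpl.Q / c, tmpl.root / np.sqrt(c)

    def logpost(self, p, sigma, mu, rho):
        """Marginal block log-posterior at the current sufficient statistics."""
        if self.kind == "car":
            return marginal_hyper_logpost(
                self.stats, "car", self.template, p, sigma,
                rank_deficiency=self.ncomp, bounds=self.bounds,
                ab_template=self._ab_car, return_factor=True,
            )
        if not (self.bounds.rho_min < rho < self.bounds.rho_max):
            return -np.inf, None
        ab, tmpl_logdet = self._spde_ab(rho)
        return marginal_hyper_logpost(
            self.stats, "spde", None, p, sigma, mu=mu, rho=rho, grid=self.grid,
            eigs=self._eigs, bounds=self.bounds, spde_logdet_template=tmpl_logdet,
            ab_template=ab, return_factor=True,
        )

    def _spde_root(self, rho):
        """Symmetric factor aI − C of the unscaled template, cached per range."""
        key = ("root", round(float(rho), 12))
        if key not in self._spde_cache:
            if len(self._spde_cache) > 16:
                self._spde_cache.clear()
            a = 4.0 + 1.0 / rho**2
            self._spde_cache[key] = (a * self._eye - self.adj.C).tocsr()
        return self._spde_cache[key]

    def _draw_alpha(self, p, sigma, mu, rho, lu):
        """Full-conditional field draw without materializing scaled matrices."""
        stats = self.stats
        mu_p = mu if self.kind == "spde" else 0.0
        b = stats.A * (stats.wbar[:, p] - mu_p)
        z1 = self.rng.standard_normal(self.m)
        if self.kind == "car":
            z2 = self.rng.standard_normal(self._incidence.shape[0])
            noise = np.sqrt(stats.A) * z1 + (self._incidence.T @ z2) / sigma
        else:
            root = self._spde_root(rho)
            z2 = self.rng.standard_normal(self.m)
            c = sigma**2 * FOUR_PI * rho**2
            noise = np.sqrt(stats.A) * z1 + (root.T @ z2) / np.sqrt(c)
        return mu_p + lu.solve(b + noise)

    def set_hyperparams(self, sigma=None, mu=None, rho=None):
        if sigma is not None:
            self.state.hp.sigma[:] = sigma
        if self.kind == "spde":
            if mu is not None:
                self.state.hp.mu[:] = mu
            if rho is not None:
                self.state.hp.rho[:] = rho

    def draw_hyperparams_from_prior(self):
        """Uniform hyperprior draws within the configured bounds (Geweke tooling)."""
        b = self.bounds
        self.state.hp.sigma[:] = self.rng.uniform(1e-3, b.sigma_max, self.P)
        if self.kind == "spde":
            self.state.hp.mu[:] = self.rng.uniform(-b.mu_abs_max, b.mu_abs_max, self.P)
            self.state.hp.rho[:] = self.rng.uniform(b.rho_min, b.rho_max, self.P)

    def draw_fields_from_prior(self):
        """α_p ~ N(μ_p, Q_p⁻¹) for the current hyperparameters (SPDE only)."""
        if self.kind != "spde":
            raise ValueError("the intrinsic CAR prior is improper; no unconstrained prior draw")
        for p in range(self.P):
            rho = self.state.hp.rho[p]
            tmpl = self._spde_template(rho)
            lu = spla.splu(tmpl.root.tocsc())
            s = np.sqrt(self.state.hp.sigma[p] ** 2 * FOUR_PI * rho**2)
            self.state.alpha[p] = self.state.hp.mu[p] + s * lu.solve(self.rng.standard_normal(self.m))

    def regenerate_data(self):
        """Redraw each tree's taxon from the current fields (Geweke tooling).

        W is drawn unconstrained from N(α, 1) and the observed taxon reset
        to its argmax, which is exactly the data model.
        """
        alpha_at_tree = self.state.alpha[:, self.state.tree_cell].T
        self.state.W = alpha_at_tree + self.rng.standard_normal(self.state.W.shape)
        self.state.taxa = np.argmax(self.state.W, axis=1).astype(np.int64)

    # -- one full MCMC iteration ------------------------------------------

    def step(self):
        cfg = self.config
        state = self.state
        if cfg.adapt and self.it == cfg.n_burn:
            for bl in self.blocks.values():
                for b in bl:
                    b.frozen = True

        gibbs_update_W(state.W, state.taxa, state.tree_cell, state.alpha, self.rng)
        if self._ov_arrays is not None:
            gibbs_update_membership(state, self._ov_arrays, self.rng)
        self.stats = compute_suff_stats(state.W, state.tree_cell, self.m)

        for p in range(self.P):
            self._update_taxon(p)
        self.it += 1

    def _update_taxon(self, p):
        kind = self.kind
        state = self.state
        sigma = state.hp.sigma[p]
        mu = state.hp.mu[p] if kind == "spde" else 0.0
        rho = state.hp.rho[p] if kind == "spde" else None

        lp, lu = self.logpost(p, sigma, mu, rho)
        state.alpha[p] = self._draw_alpha(p, sigma, mu, rho, lu)

        def try_accept(block, cur_x, make_hp):
            nonlocal lp, lu, sigma, mu, rho
            prop = block.propose(cur_x, self.rng)
            s2, m2, r2 = make_hp(prop)
            lp2, lu2 = self.logpost(p, s2, m2, r2)
            accepted = np.log(self.rng.random()) < lp2 - lp
            if accepted:
                sigma, mu, rho = s2, m2, r2
                lp, lu = lp2, lu2
                state.alpha[p] = self._draw_alpha(p, s2, m2, r2, lu2)
            block.record(prop if accepted else cur_x, accepted)

        for _ in range(max(self.config.hyper_sweeps, 1)):
            if kind == "car":
                try_accept(
                    self.blocks["sigma"][p], np.log(sigma),
                    lambda v: (float(np.exp(v[0])), 0.0, None),
                )
            elif self.config.spde_joint_block:
                try_accept(
                    self.blocks["joint"][p], np.array([mu, np.log(sigma), np.log(rho)]),
                    lambda v: (float(np.exp(v[1])), float(v[0]), float(np.exp(v[2]))),
                )
            else:
                try_accept(
                    self.blocks["mu"][p], np.array([mu]),
                    lambda v: (sigma, float(v[0]), rho),
                )
                try_accept(
                    self.blocks["sigrho"][p], np.array([np.log(sigma), np.log(rho)]),
                    lambda v: (float(np.exp(v[0])), mu, float(np.exp(v[1]))),
                )

        state.hp.sigma[p] = sigma
        if kind == "spde":
            state.hp.mu[p] = mu
            state.hp.rho[p] = rho

    # -- driver ------------------------------------------------------------

    def run(self) -> PosteriorSamples:
        cfg = self.config
        keep_iters = np.round(np.linspace(cfg.n_burn, cfg.n_iter - 1, cfg.n_keep)).astype(int)
        keep_map = {int(it): k for k, it in enumerate(keep_iters)}
        K = cfg.n_keep
        out_alpha = np.empty((K, self.P, self.m))
        out_sigma = np.empty((K, self.P))
        out_mu = np.empty((K, self.P)) if self.kind == "spde" else None
        out_rho = np.empty((K, self.P)) if self.kind == "spde" else None

        for it in range(cfg.n_iter):
            self.step()
            if it in keep_map:
                k = keep_map[it]
                out_alpha[k] = self.state.alpha
                out_sigma[k] = self.state.hp.sigma
                if self.kind == "spde":
                    out_mu[k] = self.state.hp.mu
                    out_rho[k] = self.state.hp.rho
            if (it + 1) % 1000 == 0:
                rates = {n: np.round([b.rate for b in bl], 3).tolist() for n, bl in self.blocks.items()}
                logger.info("iteration %d/%d; acceptance rates %s", it + 1, cfg.n_iter, rates)

        if not np.all(np.isfinite(out_alpha)):
            raise FloatingPointError("non-finite values in retained draws")
        return PosteriorSamples(
            alpha=out_alpha, sigma=out_sigma, mu=out_mu, rho=out_rho,
            kind=self.kind, taxa_kept=self.taxa_kept,
            acceptance={n: np.array([b.rate for b in bl]) for n, bl in self.blocks.items()},
            config=cfg, grid=self.grid,
        )


def run_sampler(
    grid_counts,
    kind: str,
    grid: GridSpec,
    township_counts=None,
    overlap: TownshipOverlap | None = None,
    config: MCMCConfig | None = None,
    bounds: HyperpriorBounds = HyperpriorBounds(),
    adj: CellAdjacency | None = None,
) -> PosteriorSamples:
    """Run the full latent-variable chain and return retained draws.

    ``grid_counts`` is an (m, P) integer array over the buffered lattice
    (buffer rows zero); township data enter as a (T, P) count array plus a
    :class:`~gridcomp.geometry.TownshipOverlap`.  Taxa whose total count
    falls below ``config.taxon_min_count`` are dropped with a warning.
    Retained draws are ``config.n_keep`` evenly spaced post-burn-in
    iterations; the run is fully reproducible from ``config.seed``.
    """
    return ProbitGibbsSampler(
        grid_counts, kind, grid,
        township_counts=township_counts, overlap=overlap,
        config=config, bounds=bounds, adj=adj,
    ).run()
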