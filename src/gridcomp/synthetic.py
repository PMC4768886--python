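"""Synthetic datasets with the statistical structure the model assumes.

Generates smooth per-taxon latent fields from the CAR or SPDE prior,
multinomial tree counts per cell (Poisson numbers of trees per cell,
emulating survey densities of roughly 124 trees per cell), sparse-coverage
regimes in which most cells carry no data, and irregular areal
("township") aggregation with known hidden truth — everything reproducible
end-to-end from one master seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse.linalg as spla

from .composition import mc_theta, probit_two_taxon_oracle
from .geometry import GridSpec, TownshipOverlap, build_grid, cardinal_adjacency, normalize_overlap
from .priors import FOUR_PI, build_car_precision, build_spde_precision

__all__ = ["Scenario", "SyntheticDataset", "draw_alpha_fields", "draw_counts", "make_townships", "make_scenario", "PRESETS"]


@dataclass(frozen=True)
class Scenario:
    """Ground-truth generating conditions for one synthetic dataset."""

    nx: int = 25
    ny: int = 25
    buffer_width: int = 0
    n_taxa: int = 3
    kind: str = "spde"
    sigma_true: float = 1.0
    rho_true: float = 3.0
    mu_true: float = 0.0
    trees_per_cell: float = 124.0
    zero_truncated: bool = True
    missing_fraction: float = 0.0
    township_blocks: tuple | None = None  # (bx, by) cells per block, or None
    township_jitter: int = 1
    theta_n_mc: int = 20000
    seed: int = 0

    def __post_init__(self):
        if self.n_taxa < 2:
            raise ValueError("need at least 2 taxa")
        if self.kind not in ("car", "spde"):
            raise ValueError(f"kind must be 'car' or 'spde', got {self.kind!r}")
        if self.sigma_true <= 0 or self.rho_true <= 0:
            raise ValueError("true hyperparameters must be positive")
        if not (0.0 <= self.missing_fraction < 1.0):
            raise ValueError("missing_fraction must be in [0, 1)")
        if self.trees_per_cell <= 0:
            raise ValueError("trees_per_cell must be positive")


@dataclass
class SyntheticDataset:
    """A generated dataset plus its hidden truth."""

    scenario: Scenario
    grid: GridSpec
    grid_counts: np.ndarray  # (m, P), zero in buffer/missing cells
    missing_mask: np.ndarray  # (m,) True where gridded data were removed
    township_counts: np.ndarray | None
    overlap: TownshipOverlap | None
    alpha_true: np.ndarray  # (P, m)
    theta_true: np.ndarray  # (m, P)
    cell_counts_true: np.ndarray  # (m, P) counts before aggregation/masking


def draw_alpha_fields(scenario: Scenario, grid: GridSpec | None = None, rng=None) -> np.ndarray:
    """Exact draws of the P latent fields from the scenario's spatial prior.

    SPDE fields are N(μ, σ²4πρ² Q(ρ)⁻¹) sampled through the sparse
    symmetric factor of Q; CAR fields are drawn from the proper part of the
    intrinsic prior (level pinned at zero) via dense eigendecomposition.
    Returns (P, m).
    """
    grid = grid or build_grid(scenario.nx, scenario.ny, scenario.buffer_width)
    rng = np.random.default_rng(scenario.seed) if rng is None else rng
    adj = cardinal_adjacency(grid)
    m = grid.n_cells
    P = scenario.n_taxa
    alpha = np.empty((P, m))
    if scenario.kind == "spde":
        tmpl = build_spde_precision(adj, scenario.rho_true)
        lu = spla.splu(tmpl.root.tocsc())
        s = np.sqrt(scenario.sigma_true**2 * FOUR_PI * scenario.rho_true**2)
        for p in range(P):
            alpha[p] = scenario.mu_true + s * lu.solve(rng.standard_normal(m))
    else:
        if m > 5000:
            raise ValueError("CAR truth draws use a dense eigendecomposition; grid too large")
        Q = build_car_precision(adj).Q.toarray()
        lam, V = np.linalg.eigh(Q)
        pos = lam > 1e-10 * lam.max()
        half_cov = V[:, pos] / np.sqrt(lam[pos])
        for p in range(P):
            alpha[p] = scenario.sigma_true * (half_cov @ rng.standard_normal(pos.sum()))
    return alpha


def true_theta(alpha: np.ndarray, scenario: Scenario, rng=None) -> np.ndarray:
    """Per-cell composition implied by the latent fields.

    P = 2 uses the closed-form probit probability; otherwise Monte Carlo
    with ``scenario.theta_n_mc`` hypothetical trees per cell.
    """
    P, m = alpha.shape
    if P == 2:
        t1 = np.array([probit_two_taxon_oracle(alpha[0, i], alpha[1, i]) for i in range(m)])
        return np.column_stack([t1, 1.0 - t1])
    seed = int(np.random.default_rng(scenario.seed).integers(2**31 - 1)) if rng is None else int(rng.integers(2**31 - 1))
    return mc_theta(alpha, n_mc=scenario.theta_n_mc, seed=seed)


def draw_counts(alpha: np.ndarray, scenario: Scenario, grid: GridSpec, rng) -> tuple:
    """Multinomial per-cell counts from the latent fields.

    Tree numbers are Poisson(``trees_per_cell``), zero-truncated by default;
    the missing-cell mask then zeroes out the chosen fraction of core
    cells (masked cells lose their data entirely, emulating unsurveyed
    cells; all-zero observed rows are retained as observed-but-empty).
    Returns ``(counts, missing_mask, theta, counts_before_masking)``.
    """
    theta = true_theta(alpha, scenario, rng)
    m, P = theta.shape
    core = grid.core_mask
    n_i = np.zeros(m, dtype=np.int64)
    n_core = int(core.sum())
    draws = rng.poisson(scenario.trees_per_cell, size=n_core)
    if scenario.zero_truncated:
        while True:
            z = draws == 0
            if not z.any():
                break
            draws[z] = rng.poisson(scenario.trees_per_cell, size=int(z.sum()))
    n_i[core] = draws
    counts = np.zeros((m, P), dtype=np.int64)
    for i in np.nonzero(core)[0]:
        counts[i] = rng.multinomial(n_i[i], theta[i])
    full = counts.copy()
    missing = np.zeros(m, dtype=bool)
    if scenario.missing_fraction > 0:
        core_idx = np.nonzero(core)[0]
        n_miss = int(round(scenario.missing_fraction * core_idx.size))
        held = rng.choice(core_idx, size=n_miss, replace=False)
        missing[held] = True
        counts[held] = 0
    return counts, missing, theta, full


def make_townships(
    cell_counts: np.ndarray,
    grid: GridSpec,
    block_dims: tuple,
    seed: int = 0,
    jitter: int = 0,
):
    """Aggregate core-cell counts into rectangular township blocks.

    Blocks tile the core grid with nominal size ``block_dims`` = (bx, by);
    a positive ``jitter`` shifts interior block boundaries by up to that
    many cells so townships are irregular.  Per-tree cell identities are
    discarded — only township totals and uniform-by-area overlap weights
    survive.  Returns ``(township_counts, overlap, block_of_cell)``.
    """
    bx, by = block_dims
    if bx < 1 or by < 1:
        raise ValueError("block dimensions must be >= 1")
    rng = np.random.default_rng(seed)

    def boundaries(n, b):
        cuts = list(range(b, n, b))
        if jitter:
            for k in range(len(cuts)):
                lo = (cuts[k - 1] if k else 0) + 1
                hi = (cuts[k + 1] if k + 1 < len(cuts) else n) - 1
                c = cuts[k] + int(rng.integers(-jitter, jitter + 1))
                cuts[k] = min(max(c, lo), hi)
        return [0] + cuts + [n]

    xb = boundaries(grid.nx, bx)
    yb = boundaries(grid.ny, by)
    P = cell_counts.shape[1]
    towns = []
    for iy in range(len(yb) - 1):
        for ix in range(len(xb) - 1):
            cx, cy = np.meshgrid(np.arange(xb[ix], xb[ix + 1]), np.arange(yb[iy], yb[iy + 1]))
            towns.append(grid.core_index(cx.ravel(), cy.ravel()))
    T = len(towns)
    township_counts = np.zeros((T, P), dtype=np.int64)
    raw = []
    block_of_cell = np.full(grid.n_cells, -1, dtype=np.int64)
    for t, cells in enumerate(towns):
        township_counts[t] = cell_counts[cells].sum(axis=0)
        block_of_cell[cells] = t
        for c in cells:
            raw.append((t, int(c), 1.0))
    overlap = normalize_overlap(raw, grid)
    return township_counts, overlap, block_of_cell


PRESETS = {
    "dense_grid": dict(missing_fraction=0.0, trees_per_cell=150.0),
    "sparse_95": dict(missing_fraction=0.95, trees_per_cell=150.0),
    "sparse_80": dict(missing_fraction=0.80, trees_per_cell=150.0),
    "township_east": dict(nx=20, ny=20, township_blocks=(4, 4), trees_per_cell=124.0),
    "mixed_domain": dict(township_blocks=(5, 5), trees_per_cell=124.0),
}


def make_scenario(name: str, **overrides) -> SyntheticDataset:
    """Build a preset dataset-with-truth bundle.

    Presets mirror the survey regimes: ``dense_grid`` (full coverage),
    ``sparse_95``/``sparse_80`` (most cells unobserved), ``township_east``
    (areal data only) and ``mixed_domain`` (gridded west half, township
    east half).  Keyword overrides replace any :class:`Scenario` field.
    """
    if name not in PRESETS:
        raise ValueError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")
    params = dict(PRESETS[name])
    params.update(overrides)
    scenario = Scenario(**params)
    grid = build_grid(scenario.nx, scenario.ny, scenario.buffer_width)
    rng = np.random.default_rng(scenario.seed)
    alpha = draw_alpha_fields(scenario, grid, rng)
    counts, missing, theta, full = draw_counts(alpha, scenario, grid, rng)

    township_counts = None
    overlap = None
    grid_counts = counts
    if name == "township_east" or (name != "mixed_domain" and scenario.township_blocks):
        township_counts, overlap, _ = make_townships(
            full, grid, scenario.township_blocks, seed=int(rng.integers(2**31 - 1)),
            jitter=scenario.township_jitter,
        )
        grid_counts = np.zeros_like(counts)
    elif name == "mixed_domain":
        east = np.zeros(grid.n_cells, dtype=bool)
        ix, _ = grid.cell_coords(np.arange(grid.n_cells))
        east[(ix >= grid.buffer_width + scenario.nx // 2) & grid.core_mask] = True
        east_counts = np.where(east[:, None], full, 0)
        township_counts, overlap, _ = make_townships(
            east_counts, grid, scenario.township_blocks, seed=int(rng.integers(2**31 - 1)),
            jitter=scenario.township_jitter,
        )
        nonempty = township_counts.sum(axis=1) > 0
        township_counts = township_counts[nonempty]
        overlap_ids = [overlap.ids[t] for t in np.nonzero(nonempty)[0]]
        overlap = TownshipOverlap(
            ids=overlap_ids,
            cells=[overlap.cells[t] for t in np.nonzero(nonempty)[0]],
            weights=[overlap.weights[t] for t in np.nonzero(nonempty)[0]],
        )
        grid_counts = np.where(east[:, None], 0, counts)

    return SyntheticDataset(
        scenario=scenario,
        grid=grid,
        grid_counts=grid_counts,
        missing_mask=missing,
        township_counts=township_counts,
        overlap=overlap,
        alpha_true=alpha,
        theta_true=theta,
        cell_counts_true=full,
    )
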