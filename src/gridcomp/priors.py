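"""Spatial precision matrices (intrinsic CAR and SPDE/Matérn ν=1) and hyperpriors.

Two Gaussian Markov random field priors for the per-taxon latent fields
α_p on the lattice:

* the intrinsic CAR (ICAR): precision Q = D − C, an improper prior of rank
  m − 1 penalizing differences between cardinal neighbors, scaled per taxon
  by 1/σ_p²;

* the lattice GMRF approximation of a Gaussian process with Matérn ν=1
  correlation: with a = 4 + 1/ρ², Q(ρ) = (aI − C)², whose interior stencil
  has diagonal 4 + a², cardinal entries −2a, diagonal-neighbor entries 2
  and second-order cardinal entries 1.  The per-taxon precision is
  Q(ρ_p)/(σ_p²·4πρ_p²), and the field has a free mean μ_p.

Hyperpriors are uniform: σ_p on (0, 1000], μ_p on [−10, 10] (SPDE only),
ρ_p on (0.1, e⁵) in grid-cell units.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.special import gamma as gamma_fn, kv

from .geometry import CellAdjacency, GridSpec

__all__ = [
    "PrecisionTemplate",
    "HyperParams",
    "HyperpriorBounds",
    "MaternSpec",
    "build_car_precision",
    "build_spde_precision",
    "scale_precision",
    "matern_correlation",
    "hyperprior_logdensity",
    "spde_template_logdet",
]

FOUR_PI = 4.0 * np.pi


@dataclass(frozen=True)
class PrecisionTemplate:
    """Unscaled sparse GMRF precision over the buffered lattice.

    ``kind`` is ``"car"`` (Q = D − C, rank m−1) or ``"spde"``
    (Q = (aI − C)², positive definite).  For the SPDE kind, ``rho`` records
    the range used to build it and ``root`` holds the symmetric factor
    aI − C with root @ root = Q (used for exact square-root noise).
    """

    Q: sp.csr_matrix
    kind: str
    rho: float | None = None
    root: sp.csr_matrix | None = None

    @property
    def n_cells(self) -> int:
        return self.Q.shape[0]


@dataclass(frozen=True)
class HyperpriorBounds:
    """Support of the uniform hyperpriors (all open/closed per the defaults)."""

    sigma_max: float = 1000.0
    mu_abs_max: float = 10.0
    rho_min: float = 0.1
    rho_max: float = float(np.exp(5.0))


@dataclass
class HyperParams:
    """Per-taxon hyperparameters: field scale σ_p, and for SPDE mean μ_p and range ρ_p."""

    sigma: np.ndarray
    mu: np.ndarray | None = None
    rho: np.ndarray | None = None

    def copy(self) -> "HyperParams":
        return HyperParams(
            sigma=self.sigma.copy(),
            mu=None if self.mu is None else self.mu.copy(),
            rho=None if self.rho is None else self.rho.copy(),
        )


@dataclass(frozen=True)
class MaternSpec:
    """Matérn correlation parameters: range ρ (with the √(2ν)d/ρ scaling) and smoothness ν."""

    rho: float
    nu: float

    def __post_init__(self):
        if self.rho <= 0:
            raise ValueError(f"range rho must be positive, got {self.rho}")
        if self.nu <= 0:
            raise ValueError(f"smoothness nu must be positive, got {self.nu}")


def build_car_precision(adj: CellAdjacency) -> PrecisionTemplate:
    """Intrinsic CAR precision template Q = D − C (zero row sums, rank m−1)."""
    D = sp.diags(adj.degrees)
    Q = (D - adj.C).tocsr()
    return PrecisionTemplate(Q=Q, kind="car")


def build_spde_precision(adj: CellAdjacency, rho: float) -> PrecisionTemplate:
    """Matérn ν=1 lattice precision template Q(ρ) = (aI − C)², a = 4 + 1/ρ²."""
    if rho <= 0:
        raise ValueError(f"range rho must be positive, got {rho}")
    a = 4.0 + 1.0 / rho**2
    m = adj.n_cells
    G = (a * sp.identity(m, format="csr") - adj.C).tocsr()
    Q = (G @ G).tocsr()
    return PrecisionTemplate(Q=Q, kind="spde", rho=float(rho), root=G)


def scale_precision(template: PrecisionTemplate, hp: HyperParams, taxon: int) -> sp.csr_matrix:
    """Per-taxon precision: Q/σ_p² (CAR) or Q(ρ_p)/(σ_p²·4πρ_p²) (SPDE)."""
    sigma = float(hp.sigma[taxon])
    if sigma <= 0:
        raise ValueError(f"sigma must be positive, got {sigma}")
    if template.kind == "car":
        return template.Q / sigma**2
    if template.kind == "spde":
        if hp.rho is None:
            raise ValueError("SPDE scaling requires a range parameter rho")
        rho = float(hp.rho[taxon])
        if template.rho is not None and not np.isclose(rho, template.rho):
            raise ValueError(
                f"template was built for rho={template.rho}, asked to scale for rho={rho}"
            )
        return template.Q / (sigma**2 * FOUR_PI * rho**2)
    raise ValueError(f"unknown template kind {template.kind!r}")


def matern_correlation(spec: MaternSpec, d) -> np.ndarray:
    """Matérn correlation R(d) = 2^{1−ν}/Γ(ν) (√(2ν)d/ρ)^ν K_ν(√(2ν)d/ρ); R(0)=1."""
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ValueError("distances must be nonnegative")
    u = np.sqrt(2.0 * spec.nu) * d / spec.rho
    with np.errstate(invalid="ignore"):
        r = (2.0 ** (1.0 - spec.nu) / gamma_fn(spec.nu)) * u**spec.nu * kv(spec.nu, u)
    r = np.where(u == 0.0, 1.0, r)
    return r if r.ndim else float(r)


def hyperprior_logdensity(
    hp: HyperParams, kind: str, bounds: HyperpriorBounds = HyperpriorBounds()
) -> float:
    """Log hyperprior density up to a constant: 0 inside the support, −∞ outside.

    The support is σ_p ∈ (0, sigma_max]; for the SPDE model additionally
    μ_p ∈ [−mu_abs_max, mu_abs_max] and ρ_p ∈ (rho_min, rho_max).
    """
    sigma = np.atleast_1d(hp.sigma)
    if np.any(sigma <= 0) or np.any(sigma > bounds.sigma_max):
        return -np.inf
    if kind == "spde":
        if hp.mu is None or hp.rho is None:
            raise ValueError("SPDE hyperparameters require mu and rho")
        mu = np.atleast_1d(hp.mu)
        rho = np.atleast_1d(hp.rho)
        if np.any(np.abs(mu) > bounds.mu_abs_max):
            return -np.inf
        if np.any(rho <= bounds.rho_min) or np.any(rho >= bounds.rho_max):
            return -np.inf
    elif kind != "car":
        raise ValueError(f"unknown model kind {kind!r}")
    return 0.0


def lattice_adjacency_eigenvalues(grid: GridSpec) -> np.ndarray:
    """Eigenvalues of the cardinal adjacency C of the buffered lattice.

    For an n-cell path graph the adjacency eigenvalues are 2cos(kπ/(n+1));
    the lattice spectrum is the pairwise sum over the two axes.  Used for a
    closed-form log-determinant of the SPDE template.
    """
    nx, ny = grid.total_nx, grid.total_ny
    lx = 2.0 * np.cos(np.pi * np.arange(1, nx + 1) / (nx + 1))
    ly = 2.0 * np.cos(np.pi * np.arange(1, ny + 1) / (ny + 1))
    return (lx[None, :] + ly[:, None]).ravel()


def spde_template_logdet(grid: GridSpec, rho: float, eigs: np.ndarray | None = None) -> float:
    """log det Q(ρ) for the SPDE template, via the closed-form lattice spectrum."""
    if rho <= 0:
        raise ValueError(f"range rho must be positive, got {rho}")
    if eigs is None:
        eigs = lattice_adjacency_eigenvalues(grid)
    a = 4.0 + 1.0 / rho**2
    return float(2.0 * np.sum(np.log(a - eigs)))
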