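"""Readers and writers: count tables, overlap tables, run configs, posterior products.

Count data are delimited text with a header — gridded tables have columns
``cell_x, cell_y`` plus one column per taxon; township tables have
``township_id`` plus taxon columns; the overlap table has
``township_id, cell_x, cell_y, area``.  The posterior composition product
is a netCDF-4 file (HDF5 with dimension scales, written through h5py)
with dimensions x, y and sample, one variable per taxon, buffer cells
excluded, and metadata recording the model kind, seed and config digest.
"""

from __future__ import annotations

import hashlib
import re
from dataclasses import dataclass

import h5py
import numpy as np
import pandas as pd
import yaml

from .composition import ThetaSamples
from .geometry import GridSpec, TownshipOverlap, build_grid, normalize_overlap
from .priors import HyperpriorBounds
from .sampler import MCMCConfig, PosteriorSamples

__all__ = [
    "DatasetBundle",
    "RunConfig",
    "read_dataset",
    "write_dataset",
    "load_config",
    "write_posterior",
    "read_posterior",
    "write_posterior_store",
    "read_posterior_store",
]

FORMAT_VERSION = "1.0"
_COORD_COLS = ("cell_x", "cell_y")


@dataclass
class DatasetBundle:
    """Validated in-memory dataset: arrays over the buffered lattice plus names."""

    grid: GridSpec
    taxa: list
    grid_counts: np.ndarray | None  # (m, P)
    township_counts: np.ndarray | None  # (T, P)
    overlap: TownshipOverlap | None

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)


@dataclass
class RunConfig:
    """Run configuration: grid layout, model choice, chain lengths, priors."""

    nx: int = 25
    ny: int = 25
    buffer_width: int = 0
    origin_x: float = 0.0
    origin_y: float = 0.0
    cell_size: float = 8000.0
    model: str = "car"
    iterations: int = 2000
    burnin: int = 500
    keep: int = 250
    seed: int = 0
    adapt: bool = True
    target_accept_scalar: float = 0.44
    target_accept_vector: float = 0.23
    taxon_min_count: int = 1
    n_mc_theta: int = 10000
    sigma_max: float = 1000.0
    mu_abs_max: float = 10.0
    rho_min: float = 0.1
    rho_max: float = float(np.exp(5.0))
    log_density_floor: float = 1e-5

    def grid_spec(self) -> GridSpec:
        return build_grid(self.nx, self.ny, self.buffer_width, self.origin_x, self.origin_y, self.cell_size)

    def mcmc_config(self) -> MCMCConfig:
        return MCMCConfig(
            n_iter=self.iterations,
            n_burn=self.burnin,
            n_keep=self.keep,
            seed=self.seed,
            adapt=self.adapt,
            target_accept_scalar=self.target_accept_scalar,
            target_accept_vector=self.target_accept_vector,
            n_mc_theta=self.n_mc_theta,
            taxon_min_count=self.taxon_min_count,
        )

    def bounds(self) -> HyperpriorBounds:
        return HyperpriorBounds(self.sigma_max, self.mu_abs_max, self.rho_min, self.rho_max)

    def digest(self) -> str:
        payload = yaml.safe_dump(self.__dict__, sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def load_config(path) -> RunConfig:
    """Load a YAML run config; unknown keys are rejected."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    valid = set(RunConfig.__dataclass_fields__)
    unknown = set(raw) - valid
    if unknown:
        raise ValueError(f"unknown config keys in {path}: {sorted(unknown)}")
    return RunConfig(**raw)


def _taxon_columns(df: pd.DataFrame, skip) -> list:
    return [c for c in df.columns if c not in skip]


def _validate_counts(df: pd.DataFrame, taxa, path):
    for col in taxa:
        vals = df[col]
        bad = vals.index[(vals < 0) | (vals != vals.astype(int))]
        if len(bad):
            line = int(bad[0]) + 2  # header is line 1
            raise ValueError(f"{path}:{line}: invalid count {vals[bad[0]]!r} in column {col!r}")


def read_grid_counts(path, grid: GridSpec, taxa=None):
    """Read a gridded count table into an (m, P) array over the buffered lattice."""
    df = pd.read_csv(path)
    for c in _COORD_COLS:
        if c not in df.columns:
            raise ValueError(f"{path}: missing required column {c!r}")
    taxa = taxa or _taxon_columns(df, _COORD_COLS)
    _validate_counts(df, taxa, path)
    cx = df["cell_x"].to_numpy()
    cy = df["cell_y"].to_numpy()
    outside = (cx < 0) | (cx >= grid.nx) | (cy < 0) | (cy >= grid.ny)
    if outside.any():
        line = int(np.nonzero(outside)[0][0]) + 2
        raise ValueError(f"{path}:{line}: cell ({cx[outside][0]}, {cy[outside][0]}) outside the core grid")
    counts = np.zeros((grid.n_cells, len(taxa)), dtype=np.int64)
    idx = grid.core_index(cx, cy)
    for j, col in enumerate(taxa):
        np.add.at(counts[:, j], idx, df[col].to_numpy().astype(np.int64))
    return counts, taxa


def read_township_counts(path, taxa=None):
    """Read a township count table into (ids, (T, P) array)."""
    df = pd.read_csv(path)
    if "township_id" not in df.columns:
        raise ValueError(f"{path}: missing required column 'township_id'")
    taxa = taxa or _taxon_columns(df, ("township_id",))
    _validate_counts(df, taxa, path)
    ids = df["township_id"].tolist()
    counts = df[list(taxa)].to_numpy().astype(np.int64)
    return ids, counts, taxa


def read_overlap(path, grid: GridSpec) -> TownshipOverlap:
    """Read and normalize a township-to-cell overlap table."""
    df = pd.read_csv(path)
    needed = {"township_id", "cell_x", "cell_y", "area"}
    missing = needed - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing required columns {sorted(missing)}")
    neg = df.index[df["area"] < 0]
    if len(neg):
        raise ValueError(f"{path}:{int(neg[0]) + 2}: negative overlap area")
    return normalize_overlap(df, grid)


def read_dataset(
    grid: GridSpec,
    grid_counts_path=None,
    township_counts_path=None,
    overlap_path=None,
) -> DatasetBundle:
    """Assemble and validate a :class:`DatasetBundle` from table files.

    Taxon columns must agree by name across the gridded and township
    tables; township data require an overlap table whose ids cover every
    township with counts.
    """
    taxa = None
    grid_counts = None
    township_counts = None
    overlap = None
    if grid_counts_path is not None:
        grid_counts, taxa = read_grid_counts(grid_counts_path, grid)
    if township_counts_path is not None:
        ids, township_counts, t_taxa = read_township_counts(township_counts_path)
        if taxa is not None and list(t_taxa) != list(taxa):
            raise ValueError(
                f"taxon columns differ between tables: {list(taxa)} vs {list(t_taxa)}"
            )
        taxa = taxa or t_taxa
        if overlap_path is None:
            raise ValueError("township counts require an overlap table")
        overlap = read_overlap(overlap_path, grid)
        known = set(overlap.ids)
        for t, tid in enumerate(ids):
            if tid not in known:
                raise ValueError(f"township {tid!r} has counts but no overlap weights")
        # reorder overlap to match the count table
        order = [overlap.index_of(tid) for tid in ids]
        overlap = TownshipOverlap(
            ids=[overlap.ids[i] for i in order],
            cells=[overlap.cells[i] for i in order],
            weights=[overlap.weights[i] for i in order],
        )
    if taxa is None:
        raise ValueError("no input tables given")
    return DatasetBundle(
        grid=grid, taxa=list(taxa), grid_counts=grid_counts,
        township_counts=township_counts, overlap=overlap,
    )


def write_grid_counts(path, counts: np.ndarray, grid: GridSpec, taxa, include_empty=False):
    """Write an (m, P) buffered-lattice count array as a core-grid table."""
    core = np.nonzero(grid.core_mask)[0]
    ix, iy = grid.cell_coords(core)
    rows = counts[core]
    if not include_empty:
        keep = rows.sum(axis=1) > 0
        core, ix, iy, rows = core[keep], ix[keep], iy[keep], rows[keep]
    df = pd.DataFrame({"cell_x": ix - grid.buffer_width, "cell_y": iy - grid.buffer_width})
    for j, t in enumerate(taxa):
        df[t] = rows[:, j]
    df.to_csv(path, index=False)


def write_township_counts(path, counts: np.ndarray, ids, taxa):
    df = pd.DataFrame({"township_id": ids})
    for j, t in enumerate(taxa):
        df[t] = counts[:, j]
    df.to_csv(path, index=False)


def write_overlap(path, overlap: TownshipOverlap, grid: GridSpec):
    recs = []
    for t in range(overlap.n_townships):
        ix, iy = grid.cell_coords(overlap.cells[t])
        for x, y, w in zip(ix, iy, overlap.weights[t]):
            recs.append((overlap.ids[t], x - grid.buffer_width, y - grid.buffer_width, w))
    pd.DataFrame(recs, columns=["township_id", "cell_x", "cell_y", "area"]).to_csv(path, index=False)


def write_dataset(out_dir, bundle: DatasetBundle, include_empty=False):
    """Write all tables of a bundle into a directory; returns the paths."""
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    if bundle.grid_counts is not None:
        paths["grid_counts"] = out / "grid_counts.csv"
        write_grid_counts(paths["grid_counts"], bundle.grid_counts, bundle.grid, bundle.taxa, include_empty)
    if bundle.township_counts is not None:
        paths["township_counts"] = out / "township_counts.csv"
        write_township_counts(
            paths["township_counts"], bundle.township_counts,
            bundle.overlap.ids, bundle.taxa,
        )
        paths["overlap"] = out / "overlap.csv"
        write_overlap(paths["overlap"], bundle.overlap, bundle.grid)
    return paths


# --------------------------------------------------------------------------
# posterior products
# --------------------------------------------------------------------------


def _safe_name(taxon: str) -> str:
    s = re.sub(r"[^0-9A-Za-z]+", "_", str(taxon)).strip("_")
    return s or "taxon"


def write_posterior(theta_samples, grid: GridSpec, taxa, path, metadata=None):
    """Write composition draws as a netCDF-4 product.

    Dimensions are x, y and sample; one variable per taxon holds the K
    retained posterior draws of that taxon's proportion at each core cell
    (buffer cells are excluded).  Coordinate variables carry cell-centroid
    projection coordinates.
    """
    theta = theta_samples.theta if isinstance(theta_samples, ThetaSamples) else np.asarray(theta_samples)
    K, m, P = theta.shape
    if m != grid.n_cells:
        raise ValueError("theta draws do not match the grid")
    if P != len(taxa):
        raise ValueError(f"{P} taxa in draws but {len(taxa)} names")
    xs, ys = grid.core_centroids()
    core = np.nonzero(grid.core_mask)[0]
    with h5py.File(path, "w") as f:
        f.attrs["Conventions"] = "CF-1.8"
        f.attrs["format_version"] = FORMAT_VERSION
        for k, v in (metadata or {}).items():
            f.attrs[k] = v
        dx = f.create_dataset("x", data=np.asarray(xs, dtype="f8"))
        dx.make_scale("x")
        dx.attrs["units"] = "m"
        dy = f.create_dataset("y", data=np.asarray(ys, dtype="f8"))
        dy.make_scale("y")
        dy.attrs["units"] = "m"
        ds = f.create_dataset("sample", data=np.arange(1, K + 1, dtype="i4"))
        ds.make_scale("sample")
        ds.attrs["long_name"] = "retained MCMC sample"
        for j, taxon in enumerate(taxa):
            # core cells are ordered row-major in y, x -> (K, ny, nx) -> (x, y, sample)
            arr = theta[:, core, j].reshape(K, grid.ny, grid.nx).transpose(2, 1, 0)
            d = f.create_dataset(_safe_name(taxon), data=arr, compression="gzip", compression_opts=4)
            d.dims[0].attach_scale(dx)
            d.dims[1].attach_scale(dy)
            d.dims[2].attach_scale(ds)
            d.attrs["long_name"] = f"posterior composition proportion: {taxon}"


def read_posterior(path):
    """Read a posterior product back as ``(theta, taxa, x, y)``; theta is (K, ny*nx, P)."""
    with h5py.File(path, "r") as f:
        xs = f["x"][:]
        ys = f["y"][:]
        taxa = [k for k in f.keys() if k not in ("x", "y", "sample")]
        arrs = [f[t][:] for t in taxa]
    K = arrs[0].shape[2]
    theta = np.stack(
        [a.transpose(2, 1, 0).reshape(K, -1) for a in arrs], axis=2
    )
    return theta, taxa, xs, ys


def write_posterior_store(path, posterior: PosteriorSamples, taxa, metadata=None):
    """Persist retained α and hyperparameter draws (the fit output) to HDF5."""
    with h5py.File(path, "w") as f:
        f.attrs["kind"] = posterior.kind
        f.attrs["format_version"] = FORMAT_VERSION
        for k, v in (metadata or {}).items():
            f.attrs[k] = v
        g = posterior.grid
        f.attrs["grid"] = np.array([g.nx, g.ny, g.buffer_width])
        f.attrs["grid_origin"] = np.array([g.origin_x, g.origin_y, g.cell_size])
        f.create_dataset("alpha", data=posterior.alpha, compression="gzip")
        f.create_dataset("sigma", data=posterior.sigma)
        if posterior.mu is not None:
            f.create_dataset("mu", data=posterior.mu)
            f.create_dataset("rho", data=posterior.rho)
        f.create_dataset("taxa_kept", data=posterior.taxa_kept)
        f.create_dataset(
            "taxa", data=np.array([str(t) for t in taxa], dtype=h5py.string_dtype())
        )


def read_posterior_store(path):
    """Read a fit store back into a :class:`PosteriorSamples` plus taxon names."""
    with h5py.File(path, "r") as f:
        gx = f.attrs["grid"]
        go = f.attrs["grid_origin"]
        grid = build_grid(int(gx[0]), int(gx[1]), int(gx[2]), float(go[0]), float(go[1]), float(go[2]))
        post = PosteriorSamples(
            alpha=f["alpha"][:],
            sigma=f["sigma"][:],
            mu=f["mu"][:] if "mu" in f else None,
            rho=f["rho"][:] if "rho" in f else None,
            kind=f.attrs["kind"],
            taxa_kept=f["taxa_kept"][:],
            acceptance={},
            config=None,
            grid=grid,
        )
        taxa = [t.decode() if isinstance(t, bytes) else t for t in f["taxa"][:]]
    return post, taxa
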