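"""Holdout designs and predictive scoring rules for model comparison.

Two holdout experiment kinds mirror the model-comparison design: holding
out *all* trees from a random subset of cells (interpolation to unsampled
cells) and holding out individual trees at random (estimation where data
exist).  Predictions θ̃ are scored with the multi-category Brier score, the
log predictive density under a multinomial likelihood, tree-weighted RMSPE
and MAE of proportions, and coverage/length of central predictive
intervals.  All metrics can be evaluated at the posterior-mean composition
or per retained posterior draw; per-draw values support posterior
probabilities that one model beats another.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln

from .composition import ThetaSamples

__all__ = [
    "HoldoutDesign",
    "MetricReport",
    "make_holdout",
    "brier",
    "log_pred_density",
    "rmspe_mae",
    "interval_metrics",
    "compare_models",
    "metric_report",
]

LOG_DENSITY_FLOOR = 1e-5


@dataclass
class HoldoutDesign:
    """A train/test partition of an (m, P) count table.

    ``train`` + ``test`` equals the input counts exactly; for cells-kind
    holdouts ``held_cells`` lists the cells whose data were removed.
    """

    kind: str
    fraction: float
    seed: int
    train: np.ndarray
    test: np.ndarray
    held_cells: np.ndarray


@dataclass
class MetricReport:
    """Metric values at the posterior-mean θ and per posterior draw."""

    point: dict = field(default_factory=dict)
    per_sample: dict = field(default_factory=dict)
    interval: dict = field(default_factory=dict)

    @property
    def n_samples(self) -> int:
        arrays = list(self.per_sample.values())
        return len(arrays[0]) if arrays else 0


def make_holdout(
    counts: np.ndarray,
    kind: str,
    fraction: float,
    region_mask: np.ndarray | None = None,
    seed: int = 0,
) -> HoldoutDesign:
    """Partition an (m, P) count table into train/test.

    ``cells``: remove all trees from round(fraction × n) randomly sampled
    cells *with data* inside ``region_mask``.  ``trees``: remove individual
    trees uniformly at random (without replacement) from cells inside the
    mask.  Reproducible from ``seed``.
    """
    if not (0.0 <= fraction < 1.0):
        raise ValueError(f"holdout fraction must be in [0, 1), got {fraction}")
    counts = np.asarray(counts)
    m, P = counts.shape
    rng = np.random.default_rng(seed)
    mask = np.ones(m, dtype=bool) if region_mask is None else np.asarray(region_mask, dtype=bool)

    train = counts.copy()
    test = np.zeros_like(counts)
    if kind == "cells":
        candidates = np.nonzero(mask & (counts.sum(axis=1) > 0))[0]
        n_hold = int(round(fraction * candidates.size))
        held = np.sort(rng.choice(candidates, size=n_hold, replace=False))
        test[held] = counts[held]
        train[held] = 0
    elif kind == "trees":
        cell_idx, taxon_idx = np.nonzero(counts * mask[:, None])
        reps = counts[cell_idx, taxon_idx]
        tree_cell = np.repeat(cell_idx, reps)
        tree_taxon = np.repeat(taxon_idx, reps)
        n_total = tree_cell.size
        n_hold = int(round(fraction * n_total))
        held_trees = rng.choice(n_total, size=n_hold, replace=False)
        np.add.at(test, (tree_cell[held_trees], tree_taxon[held_trees]), 1)
        train = counts - test
        held = np.unique(tree_cell[held_trees])
    else:
        raise ValueError(f"holdout kind must be 'cells' or 'trees', got {kind!r}")
    return HoldoutDesign(kind=kind, fraction=fraction, seed=seed, train=train, test=test, held_cells=held)


def _check_theta(test_counts, theta):
    test_counts = np.asarray(test_counts)
    theta = np.asarray(theta)
    if theta.shape != test_counts.shape:
        raise ValueError(f"theta shape {theta.shape} does not match counts {test_counts.shape}")
    bad = (test_counts.sum(axis=1) > 0) & ~np.all(np.isfinite(theta), axis=1)
    if bad.any():
        raise ValueError(f"held-out trees in cells without predictions: {np.nonzero(bad)[0][:5]}")
    return test_counts, theta


def brier(test_counts: np.ndarray, theta: np.ndarray) -> float:
    """Multi-category Brier score averaged over held-out trees.

    (1/n) Σ_i Σ_j Σ_p (y_ijp − θ̃_p(s_i))² with one-hot tree indicators;
    evaluated from counts as Σ_i Σ_p [Y_ip(1−θ̃_ip)² + (n_i−Y_ip)θ̃_ip²]/n.
    """
    Y, theta = _check_theta(test_counts, theta)
    n_i = Y.sum(axis=1)
    n = n_i.sum()
    if n == 0:
        raise ValueError("no held-out trees")
    sq = Y * (1.0 - theta) ** 2 + (n_i[:, None] - Y) * theta**2
    return float(sq.sum() / n)


def log_pred_density(test_counts: np.ndarray, theta: np.ndarray, floor: float = LOG_DENSITY_FLOOR) -> float:
    """Sum over held-out cells of log Multinom(Y_i; n_i, θ̃(s_i)).

    Predicted proportions of exactly 0 where the held-out count is positive
    are replaced by ``floor`` (default 1/100000) so the density stays finite.
    """
    Y, theta = _check_theta(test_counts, theta)
    use = Y.sum(axis=1) > 0
    Y = Y[use]
    th = theta[use].copy()
    th[(th == 0.0) & (Y > 0)] = floor
    n_i = Y.sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(Y > 0, Y * np.log(th), 0.0)
    return float(
        np.sum(gammaln(n_i + 1)) - np.sum(gammaln(Y + 1)) + np.sum(terms)
    )


def rmspe_mae(test_counts: np.ndarray, theta: np.ndarray):
    """Tree-weighted RMSPE and MAE of predicted vs held-out empirical proportions.

    RMSPE = sqrt((1/(Pn)) Σ_i Σ_p n_i (θ̂_ip − θ̃_ip)²),
    MAE   = (1/(Pn)) Σ_i Σ_p n_i |θ̂_ip − θ̃_ip|,
    with θ̂ the empirical proportions of the held-out trees; cells with no
    held-out trees contribute nothing.
    """
    Y, theta = _check_theta(test_counts, theta)
    n_i = Y.sum(axis=1)
    use = n_i > 0
    Y, theta, n_i = Y[use], theta[use], n_i[use]
    n = n_i.sum()
    if n == 0:
        raise ValueError("no held-out trees")
    P = Y.shape[1]
    emp = Y / n_i[:, None]
    diff = emp - theta
    rmspe = float(np.sqrt(np.sum(n_i[:, None] * diff**2) / (P * n)))
    mae = float(np.sum(n_i[:, None] * np.abs(diff)) / (P * n))
    return rmspe, mae


def interval_metrics(
    theta_samples,
    test_counts: np.ndarray,
    level: float = 0.95,
    min_trees: int = 50,
    seed: int = 0,
):
    """Coverage and length of central predictive intervals for held-out proportions.

    For each cell with at least ``min_trees`` held-out trees and each
    taxon, a predictive sample of proportions is built by drawing, per
    posterior θ draw, a multinomial count vector of size n_i; interval
    endpoints are the (1±level)/2 quantiles on the proportion scale.
    Coverage pools over (cell, taxon) pairs.  Returns
    ``(coverage, mean_length, median_length)``.
    """
    theta = theta_samples.theta if isinstance(theta_samples, ThetaSamples) else np.asarray(theta_samples)
    Y = np.asarray(test_counts)
    K, m, P = theta.shape
    if Y.shape != (m, P):
        raise ValueError("count table does not match theta draws")
    n_i = Y.sum(axis=1)
    eligible = np.nonzero(n_i >= max(min_trees, 1))[0]
    if eligible.size == 0:
        import warnings

        warnings.warn("no cells meet the minimum held-out tree count; interval metrics undefined")
        return np.nan, np.nan, np.nan
    rng = np.random.default_rng(seed)
    lo_q, hi_q = (1.0 - level) / 2.0, 1.0 - (1.0 - level) / 2.0
    hits = []
    lengths = []
    for i in eligible:
        n = int(n_i[i])
        # one multinomial predictive draw per posterior sample
        draws = np.empty((K, P))
        for k in range(K):
            draws[k] = rng.multinomial(n, theta[k, i]) / n
        lo = np.quantile(draws, lo_q, axis=0)
        hi = np.quantile(draws, hi_q, axis=0)
        emp = Y[i] / n
        hits.append((emp >= lo) & (emp <= hi))
        lengths.append(hi - lo)
    hits = np.concatenate(hits)
    lengths = np.concatenate(lengths)
    return float(hits.mean()), float(lengths.mean()), float(np.median(lengths))


def compare_models(report_a: MetricReport, report_b: MetricReport) -> dict:
    """Posterior probability, per metric, that model A's value is lower than B's.

    Ties count one half.  Requires both reports to carry per-sample values
    for the same metrics over the same number of retained draws.
    """
    out = {}
    for name, a in report_a.per_sample.items():
        if name not in report_b.per_sample:
            continue
        b = report_b.per_sample[name]
        a = np.asarray(a)
        b = np.asarray(b)
        if a.shape != b.shape:
            raise ValueError(f"per-sample arrays for {name!r} have mismatched lengths")
        out[name] = float(np.mean((a < b) + 0.5 * (a == b)))
    if not out:
        raise ValueError("no common per-sample metrics to compare")
    return out


def metric_report(
    theta_samples,
    design: HoldoutDesign,
    level: float = 0.95,
    min_trees: int = 50,
    floor: float = LOG_DENSITY_FLOOR,
    seed: int = 0,
) -> MetricReport:
    """Score one model's θ draws against a holdout: point and per-draw metrics."""
    theta = theta_samples.theta if isinstance(theta_samples, ThetaSamples) else np.asarray(theta_samples)
    Y = design.test
    mean_theta = theta.mean(axis=0)
    rep = MetricReport()
    rmspe_pt, mae_pt = rmspe_mae(Y, mean_theta)
    rep.point = {
        "brier": brier(Y, mean_theta),
        "neg_log_density": -log_pred_density(Y, mean_theta, floor),
        "rmspe": rmspe_pt,
        "mae": mae_pt,
    }
    K = theta.shape[0]
    per = {name: np.empty(K) for name in ("brier", "neg_log_density", "rmspe", "mae")}
    for k in range(K):
        per["brier"][k] = brier(Y, theta[k])
        per["neg_log_density"][k] = -log_pred_density(Y, theta[k], floor)
        r, a = rmspe_mae(Y, theta[k])
        per["rmspe"][k] = r
        per["mae"][k] = a
    rep.per_sample = per
    cov, mean_len, med_len = interval_metrics(theta, Y, level=level, min_trees=min_trees, seed=seed)
    rep.interval = {"coverage": cov, "mean_length": mean_len, "median_length": med_len}
    return rep
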