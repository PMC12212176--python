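"""Polychoric correlation estimation for ordinal item data.

Two-step estimator: per-item thresholds are fixed at inverse-normal
quantiles of the marginal category proportions, then the latent
bivariate-normal correlation of each item pair is found by maximising
the multinomial likelihood of the observed contingency table over the
single parameter rho.  Rectangle probabilities of the standard bivariate
normal are evaluated by Gauss-Legendre quadrature of the conditional
normal CDF, which is fast enough to assemble full item matrices inside
simulation loops (a cross-check against ``scipy.stats.multivariate_normal``
lives in the test suite).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import ndtr, ndtri

logger = logging.getLogger(__name__)

#: clip infinite integration limits; Phi(8) is 1 within 6e-16
_ZMAX = 8.0
#: optimiser box keeps rho bounded away from singularity
_RHO_BOUND = 0.999

_GL_NODES, _GL_WEIGHTS = np.polynomial.legendre.leggauss(48)


class DegenerateItemError(ValueError):
    """An item whose observed responses occupy a single category."""


def estimate_thresholds(category_counts: np.ndarray) -> np.ndarray:
    """Thresholds from marginal counts: ``tau_k = ndtri(cum_prop_k)``.

    Parameters
    ----------
    category_counts
        Non-negative counts over the item's ordered categories.

    Returns
    -------
    Strictly increasing cut-points, one fewer than the number of
    categories carrying positive mass at either end (interior empty
    categories yield tied cut-points and are rejected).
    """
    counts = np.asarray(category_counts, dtype=float)
    if counts.ndim != 1 or np.any(counts < 0):
        raise ValueError("category_counts must be a 1-D non-negative vector")
    n = counts.sum()
    if n <= 0 or np.count_nonzero(counts) < 2:
        raise DegenerateItemError(
            f"item has all its mass in one category (counts={counts.tolist()})"
        )
    cum = np.cumsum(counts)[:-1] / n
    thresholds = ndtri(cum)
    # interior zero-count categories create tied thresholds
    keep = np.isfinite(thresholds)
    thresholds = np.unique(thresholds[keep])
    return thresholds


def _bvn_rect_probs(lo_x, hi_x, lo_y, hi_y, rho: float) -> np.ndarray:
    """P(lo_x < X < hi_x, lo_y < Y < hi_y) for standard bivariate normal.

    Vectorised over cells: integrates ``phi(x) * [Phi((hi_y - rho x)/s) -
    Phi((lo_y - rho x)/s)]`` over each x-interval with Gauss-Legendre
    nodes; s = sqrt(1 - rho^2).
    """
    lo_x = np.clip(np.asarray(lo_x, dtype=float), -_ZMAX, _ZMAX)
    hi_x = np.clip(np.asarray(hi_x, dtype=float), -_ZMAX, _ZMAX)
    lo_y = np.clip(np.asarray(lo_y, dtype=float), -_ZMAX, _ZMAX)
    hi_y = np.clip(np.asarray(hi_y, dtype=float), -_ZMAX, _ZMAX)
    s = np.sqrt(max(1.0 - rho * rho, 1e-12))
    mid = 0.5 * (hi_x + lo_x)[..., None]
    half = 0.5 * (hi_x - lo_x)[..., None]
    x = mid + half * _GL_NODES  # (..., nodes)
    inner = ndtr((hi_y[..., None] - rho * x) / s) - ndtr((lo_y[..., None] - rho * x) / s)
    integrand = np.exp(-0.5 * x * x) / np.sqrt(2.0 * np.pi) * inner
    return np.maximum((integrand * _GL_WEIGHTS).sum(axis=-1) * half[..., 0], 0.0)


def _cell_bounds(thresholds: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    edges = np.concatenate(([-np.inf], thresholds, [np.inf]))
    return edges[:-1], edges[1:]


def table_probabilities(
    thresholds_a: np.ndarray, thresholds_b: np.ndarray, rho: float
) -> np.ndarray:
    """Cell probabilities of the discretised bivariate normal."""
    lo_a, hi_a = _cell_bounds(np.asarray(thresholds_a, dtype=float))
    lo_b, hi_b = _cell_bounds(np.asarray(thresholds_b, dtype=float))
    ka, kb = lo_a.size, lo_b.size
    LO_X = np.repeat(lo_a, kb)
    HI_X = np.repeat(hi_a, kb)
    LO_Y = np.tile(lo_b, ka)
    HI_Y = np.tile(hi_b, ka)
    return _bvn_rect_probs(LO_X, HI_X, LO_Y, HI_Y, rho).reshape(ka, kb)


def polychoric_rho(
    table: np.ndarray,
    thresholds_a: np.ndarray | None = None,
    thresholds_b: np.ndarray | None = None,
    xatol: float = 1e-6,
) -> float:
    """ML polychoric correlation for a two-way category count table.

    Thresholds default to the inverse-normal quantiles of the table's
    own margins.  The likelihood is maximised over rho in
    (-0.999, 0.999) by bounded scalar optimisation; if the optimiser
    fails, the Spearman correlation of the table is returned as a
    flagged fallback.
    """
    table = np.asarray(table, dtype=float)
    if table.ndim != 2:
        raise ValueError("table must be two-dimensional")
    if thresholds_a is None:
        thresholds_a = estimate_thresholds(table.sum(axis=1))
    if thresholds_b is None:
        thresholds_b = estimate_thresholds(table.sum(axis=0))
    # drop empty marginal rows/cols so cells align with thresholds
    table = table[table.sum(axis=1) > 0][:, table.sum(axis=0) > 0]

    def neg_loglik(rho: float) -> float:
        p = table_probabilities(thresholds_a, thresholds_b, rho)
        return -float(np.sum(table * np.log(np.maximum(p, 1e-300))))

    res = optimize.minimize_scalar(
        neg_loglik,
        bounds=(-_RHO_BOUND, _RHO_BOUND),
        method="bounded",
        options={"xatol": xatol},
    )
    if not res.success:  # pragma: no cover - bounded Brent essentially always converges
        logger.warning("polychoric optimiser failed; falling back to Spearman")
        return _table_spearman(table)
    return float(res.x)


def _table_spearman(table: np.ndarray) -> float:
    rows, cols = np.nonzero(table)
    reps = table[rows, cols].astype(int)
    r = stats.spearmanr(np.repeat(rows, reps), np.repeat(cols, reps)).statistic
    return float(r) if np.isfinite(r) else 0.0


@dataclass
class PolychoricMatrix:
    """Pairwise polychoric correlations with per-item thresholds."""

    rho: np.ndarray
    thresholds: dict[object, np.ndarray]
    n_pairs: np.ndarray
    item_ids: list = field(default_factory=list)
    #: magnitude of the nearest-PSD eigenvalue repair (0 when none needed)
    repair_delta: float = 0.0
    excluded_items: list = field(default_factory=list)


def polychoric_matrix(data: pd.DataFrame, min_eig: float = -1e-8) -> PolychoricMatrix:
    """Assemble the pairwise-complete polychoric correlation matrix.

    ``data`` holds one column of ordinal codes per item; NaN marks a
    missing response.  Items observed in a single category are excluded
    with a warning.  If the assembled matrix has an eigenvalue below
    ``min_eig`` it is repaired by clipping negative eigenvalues at zero
    and renormalising the diagonal; the repair magnitude is recorded.
    """
    cols = list(data.columns)
    usable, excluded, thresholds = [], [], {}
    for c in cols:
        counts = data[c].value_counts()
        if counts.size < 2:
            logger.warning("item %s has a single observed category; excluded", c)
            excluded.append(c)
            continue
        usable.append(c)
    p = len(usable)
    if p < 2:
        raise ValueError("need at least two non-degenerate items")
    rho = np.eye(p)
    n_pairs = np.zeros((p, p), dtype=int)
    codes = {c: data[c].to_numpy(dtype=float) for c in usable}
    levels = {c: np.unique(codes[c][~np.isnan(codes[c])]) for c in usable}
    for c in usable:
        counts = np.array([(codes[c] == lv).sum() for lv in levels[c]], dtype=float)
        thresholds[c] = estimate_thresholds(counts)
    for i in range(p):
        for j in range(i + 1, p):
            a, b = usable[i], usable[j]
            mask = ~np.isnan(codes[a]) & ~np.isnan(codes[b])
            n_pairs[i, j] = n_pairs[j, i] = int(mask.sum())
            ia = np.searchsorted(levels[a], codes[a][mask])
            ib = np.searchsorted(levels[b], codes[b][mask])
            table = np.zeros((levels[a].size, levels[b].size))
            np.add.at(table, (ia, ib), 1.0)
            # thresholds re-derived from the pair's own margins so empty
            # margin categories in the subsample stay consistent
            r = polychoric_rho(table)
            rho[i, j] = rho[j, i] = r
    np.fill_diagonal(n_pairs, (~np.isnan(np.column_stack(list(codes.values())))).sum(axis=0))

    repair_delta = 0.0
    eigvals = np.linalg.eigvalsh(rho)
    if eigvals.min() < min_eig:
        repair_delta = float(-eigvals.min())
        logger.warning("polychoric matrix not PSD (min eig %.3g); repaired", eigvals.min())
        w, v = np.linalg.eigh(rho)
        w = np.clip(w, 0.0, None)
        fixed = (v * w) @ v.T
        d = np.sqrt(np.clip(np.diag(fixed), 1e-12, None))
        rho = fixed / np.outer(d, d)
        np.fill_diagonal(rho, 1.0)
    return PolychoricMatrix(
        rho=rho,
        thresholds=thresholds,
        n_pairs=n_pairs,
        item_ids=usable,
        repair_delta=repair_delta,
        excluded_items=excluded,
    )
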