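"""Ordinal exploratory factor analysis of questionnaire items.

The analysis runs on the polychoric correlation matrix of the item
ranks: eigenvalues decide how many factors to keep (retention rule:
eigenvalue strictly greater than 2, the rule used when these sleep
dimensions were derived; configurable), principal-axis factoring with
iterated communalities extracts the loadings, and a varimax (default)
or promax rotation makes them interpretable.  Items are assigned to the
factor on which they load most strongly in absolute value, which for
MOS-SS data reproduces the SQ / DTS split.

``OrdinalFactorModel`` / ``FactorResults`` follow the statsmodels
model/fit/results idiom; the module-level functions (``scree``,
``extract_factors``, ``rotate``, ``variance_explained``,
``assign_items``) expose the individual steps.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.multivariate.factor_rotation import promax as _sm_promax
from statsmodels.multivariate.factor_rotation import rotate_factors

from .polychoric import PolychoricMatrix, polychoric_matrix

logger = logging.getLogger(__name__)

DEFAULT_RETENTION_THRESHOLD = 2.0
#: communality ceiling for Heywood cases
_HEYWOOD_CAP = 0.998


def scree(matrix: np.ndarray | PolychoricMatrix, threshold: float = DEFAULT_RETENTION_THRESHOLD):
    """Descending eigenvalues and the retained-factor count.

    ``n_retained`` counts eigenvalues strictly greater than *threshold*
    (default 2.0).
    """
    corr = matrix.rho if isinstance(matrix, PolychoricMatrix) else np.asarray(matrix, float)
    eig = np.sort(np.linalg.eigvalsh(corr))[::-1]
    return eig, int(np.sum(eig > threshold))


def extract_factors(
    matrix: np.ndarray | PolychoricMatrix,
    k: int,
    max_iter: int = 100,
    tol: float = 1e-6,
) -> np.ndarray:
    """Principal-axis factoring with iterated communalities.

    Communalities start at squared multiple correlations, the reduced
    matrix is eigendecomposed, and the loop runs until the largest
    communality change falls below *tol* (or *max_iter*).  Heywood
    communalities are capped at 0.998 and logged.  Column signs are
    fixed so each column's largest-|loading| entry is positive.
    """
    corr = matrix.rho if isinstance(matrix, PolychoricMatrix) else np.asarray(matrix, float)
    p = corr.shape[0]
    if not (1 <= k < p):
        raise ValueError(f"k={k} must satisfy 1 <= k < p={p}")
    try:
        h = 1.0 - 1.0 / np.diag(np.linalg.inv(corr))
        h = np.clip(h, 0.0, _HEYWOOD_CAP)
    except np.linalg.LinAlgError:
        h = np.full(p, 0.5)
    loadings = np.zeros((p, k))
    for _ in range(max_iter):
        reduced = corr.copy()
        np.fill_diagonal(reduced, h)
        w, v = np.linalg.eigh(reduced)
        idx = np.argsort(w)[::-1][:k]
        lam = np.clip(w[idx], 0.0, None)
        loadings = v[:, idx] * np.sqrt(lam)
        h_new = np.sum(loadings**2, axis=1)
        if np.any(h_new > 1.0):
            logger.warning("Heywood case: communality above 1 capped at %.3f", _HEYWOOD_CAP)
            h_new = np.clip(h_new, None, _HEYWOOD_CAP)
        if np.max(np.abs(h_new - h)) < tol:
            h = h_new
            break
        h = h_new
    return _fix_signs(loadings)


def _fix_signs(loadings: np.ndarray) -> np.ndarray:
    out = loadings.copy()
    for j in range(out.shape[1]):
        i = np.argmax(np.abs(out[:, j]))
        if out[i, j] < 0:
            out[:, j] = -out[:, j]
    return out


def rotate(loadings: np.ndarray, method: str = "varimax"):
    """Rotate loadings; returns ``(rotated, factor_corr)``.

    ``factor_corr`` is the identity for orthogonal rotations and the
    factor intercorrelation matrix for promax (kappa = 4).  Orthogonal
    rotation preserves row communalities.
    """
    loadings = np.asarray(loadings, float)
    k = loadings.shape[1]
    if method == "none" or k == 1:
        return _fix_signs(loadings), np.eye(k)
    if method == "varimax":
        rot, _ = rotate_factors(loadings, "varimax")
        return _fix_signs(rot), np.eye(k)
    if method == "promax":
        rot, T = _sm_promax(loadings, k=4)
        phi = np.linalg.inv(T.T @ T)
        d = np.sqrt(np.diag(phi))
        return _fix_signs(rot), phi / np.outer(d, d)
    raise ValueError(f"unknown rotation {method!r}")


def variance_explained(loadings: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-factor and cumulative proportions of total variance.

    Orthogonal-case arithmetic: column sums of squared loadings divided
    by the number of items.
    """
    loadings = np.asarray(loadings, float)
    p = loadings.shape[0]
    per = np.sum(loadings**2, axis=0) / p
    return per, np.cumsum(per)


def assign_items(loadings: np.ndarray, item_ids=None) -> dict:
    """Assign each item to its max-|loading| factor (ties -> lower index)."""
    loadings = np.asarray(loadings, float)
    if item_ids is None:
        item_ids = list(range(loadings.shape[0]))
    out = {}
    for i, item in enumerate(item_ids):
        row = np.abs(loadings[i])
        best = int(np.argmax(row))  # argmax takes the first maximum
        if np.sum(row == row[best]) > 1:
            logger.warning("item %s loads equally on several factors; assigned to %d", item, best)
        out[item] = best
    return out


class OrdinalFactorModel:
    """Ordinal factor analysis of an item-rank table.

    Parameters
    ----------
    data
        DataFrame of ordinal item codes, one column per item, NaN for
        missing (pairwise-complete polychoric estimation).
    corr
        Alternatively, a precomputed correlation matrix (with
        ``item_ids``); ``data`` and ``corr`` are mutually exclusive.
    """

    def __init__(self, data: pd.DataFrame | None = None, corr: np.ndarray | None = None,
                 item_ids=None):
        if (data is None) == (corr is None):
            raise ValueError("provide exactly one of data or corr")
        self.data = data
        self._corr = None if corr is None else np.asarray(corr, float)
        self._item_ids = item_ids

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, columns=None,
                       orient: bool = True) -> "OrdinalFactorModel":
        """Build from a wide cohort table of MOS item columns.

        With ``orient=True`` (default) negative-experience items are
        reversed (``6 - r``) first, so every item codes worse-high and
        loadings come out positive within their factor.
        """
        if columns is None:
            columns = [c for c in df.columns if c.startswith("mos_q")]
        data = df[list(columns)].copy()
        if orient:
            from .instruments import REVERSED_ITEMS

            for c in columns:
                if c.startswith("mos_q") and int(c.removeprefix("mos_q")) in REVERSED_ITEMS:
                    data[c] = 6 - data[c]
        return cls(data=data)

    def fit(
        self,
        n_factors: int | None = None,
        rotation: str = "varimax",
        retention_threshold: float = DEFAULT_RETENTION_THRESHOLD,
        max_iter: int = 100,
        tol: float = 1e-6,
    ) -> "FactorResults":
        if self.data is not None:
            poly = polychoric_matrix(self.data)
            corr, item_ids = poly.rho, poly.item_ids
        else:
            poly = None
            corr = self._corr
            item_ids = list(self._item_ids) if self._item_ids is not None \
                else list(range(corr.shape[0]))
        eig, n_retained = scree(corr, retention_threshold)
        k = n_factors if n_factors is not None else max(n_retained, 1)
        unrotated = extract_factors(corr, k, max_iter=max_iter, tol=tol)
        rotated, phi = rotate(unrotated, rotation)
        # order factors by explained variance, largest first
        per, _ = variance_explained(rotated)
        order = np.argsort(per)[::-1]
        rotated = rotated[:, order]
        phi = phi[np.ix_(order, order)]
        per, cum = variance_explained(rotated)
        return FactorResults(
            model=self,
            polychoric=poly,
            corr=corr,
            item_ids=item_ids,
            eigenvalues=eig,
            retention_threshold=retention_threshold,
            n_retained=n_retained,
            loadings=rotated,
            unrotated_loadings=unrotated,
            rotation=rotation,
            factor_corr=phi,
            variance_per_factor=per,
            variance_cumulative=cum,
            assignment=assign_items(rotated, item_ids),
        )


@dataclass
class FactorResults:
    """Fitted ordinal factor solution."""

    model: OrdinalFactorModel
    polychoric: PolychoricMatrix | None
    corr: np.ndarray
    item_ids: list
    eigenvalues: np.ndarray
    retention_threshold: float
    n_retained: int
    loadings: np.ndarray
    unrotated_loadings: np.ndarray
    rotation: str
    factor_corr: np.ndarray
    variance_per_factor: np.ndarray
    variance_cumulative: np.ndarray
    assignment: dict = field(default_factory=dict)

    @property
    def communalities(self) -> np.ndarray:
        return np.sum(self.unrotated_loadings**2, axis=1)

    def loadings_table(self, scale: int = 100) -> pd.DataFrame:
        """Loadings scaled by 100 and rounded, publication style."""
        cols = [f"factor_{j + 1}" for j in range(self.loadings.shape[1])]
        tab = pd.DataFrame(
            np.round(self.loadings * scale).astype(int), index=self.item_ids, columns=cols
        )
        tab["assigned"] = [f"factor_{self.assignment[i] + 1}" for i in self.item_ids]
        return tab

    def to_dict(self) -> dict:
        return {
            "eigenvalues": [float(x) for x in self.eigenvalues],
            "retention_threshold": self.retention_threshold,
            "n_retained": self.n_retained,
            "rotation": self.rotation,
            "item_ids": [str(i) for i in self.item_ids],
            "loadings": [[float(x) for x in row] for row in self.loadings],
            "variance_per_factor": [float(x) for x in self.variance_per_factor],
            "variance_cumulative": [float(x) for x in self.variance_cumulative],
            "assignment": {str(k): int(v) for k, v in self.assignment.items()},
            "psd_repair_delta": float(self.polychoric.repair_delta) if self.polychoric else 0.0,
        }

    def summary(self) -> str:
        lines = ["Ordinal factor analysis"]
        lines.append(
            f"  items: {len(self.item_ids)}   rotation: {self.rotation}   "
            f"retained (eigenvalue > {self.retention_threshold:g}): {self.n_retained}"
        )
        lines.append("  eigenvalues: " + ", ".join(f"{e:.3f}" for e in self.eigenvalues))
        lines.append(
            "  variance explained: "
            + ", ".join(f"{v:.1%}" for v in self.variance_per_factor)
            + f"  (cumulative {self.variance_cumulative[-1]:.1%})"
        )
        lines.append(self.loadings_table().to_string())
        return "\n".join(lines)

    def plot_scree(self, ax=None):
        """Scree plot of eigenvalues with the retention threshold line."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        x = np.arange(1, self.eigenvalues.size + 1)
        ax.plot(x, self.eigenvalues, "o-")
        ax.axhline(self.retention_threshold, ls="--", color="grey")
        ax.set_xlabel("factor")
        ax.set_ylabel("eigenvalue")
        return ax
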