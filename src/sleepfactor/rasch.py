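"""Polytomous Rasch (partial credit) model with joint maximum likelihood.

For person ``n`` with location ``beta`` (logits) responding to item
``i`` with location ``delta`` and mean-centred category thresholds
``tau_1..tau_m``, the probability of category score ``x`` in ``0..m`` is

    P(x) = exp(-sum_{k<=x} tau_k + x (beta - delta)) / normalising sum

with the empty threshold sum for ``x = 0``.  For ``m = 1`` this is the
dichotomous Rasch model.

Estimation is joint maximum likelihood (JML): alternating Newton steps
on the item category parameters and the person locations, each with
step-halving so the log-likelihood never decreases.  Identification
fixes the mean item location at zero and mean-centres each item's
thresholds.  Persons with incomplete response vectors and persons at
the score floor or ceiling (extreme scores, which have no finite ML
location) are excluded before fitting and reported by reason.  A
``(K-1)/K`` shrinkage of the item parameters (K = number of items)
corrects the classic JML spread bias; person locations are re-estimated
once against the corrected items.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp

logger = logging.getLogger(__name__)

_BETA_BOX = 12.0  # logit box for person Newton steps


class DegenerateDataError(ValueError):
    """No persons remain estimable after exclusions."""


@dataclass
class PcmItem:
    """One partial-credit item: location delta and mean-centred thresholds tau."""

    item_id: object
    m: int
    delta: float
    tau: np.ndarray

    def __post_init__(self) -> None:
        self.tau = np.asarray(self.tau, dtype=float)
        if self.tau.size != self.m:
            raise ValueError(f"item {self.item_id}: len(tau)={self.tau.size} != m={self.m}")

    @property
    def disordered(self) -> bool:
        """True when the thresholds are not strictly increasing."""
        return bool(np.any(np.diff(self.tau) <= 0))

    @property
    def threshold_locations(self) -> np.ndarray:
        """Absolute category boundary locations delta + tau on the logit scale."""
        return self.delta + self.tau


def pcm_probability(beta, item: PcmItem, x: int | None = None):
    """Category probabilities of the partial credit model.

    Parameters
    ----------
    beta
        Scalar or array of person locations (logits).
    item
        The item parameters.
    x
        A category score in ``0..m``; when omitted, the full probability
        vector over categories is returned (last axis).

    Probabilities are computed with max-subtraction (log-sum-exp) so
    extreme locations cannot overflow.
    """
    beta = np.asarray(beta, dtype=float)
    if x is not None and not (0 <= x <= item.m):
        raise ValueError(f"category {x} outside 0..{item.m} for item {item.item_id}")
    cats = np.arange(item.m + 1)
    cumtau = np.concatenate(([0.0], np.cumsum(item.tau)))
    logits = beta[..., None] * cats - item.delta * cats - cumtau
    logp = logits - logsumexp(logits, axis=-1, keepdims=True)
    p = np.exp(logp)
    if x is None:
        return p
    return p[..., x]


def _category_logits(zeta: np.ndarray, beta: np.ndarray) -> np.ndarray:
    """(n, m+1) unnormalised log-numerators for one item; zeta_0 = 0."""
    cats = np.arange(zeta.size)
    return beta[:, None] * cats + zeta[None, :]


def _zeta_from_item(delta: float, tau: np.ndarray) -> np.ndarray:
    # numerator exp(x beta + zeta_x) with zeta_x = -x delta - cumsum(tau)_x
    cats = np.arange(tau.size + 1)
    return -cats * delta - np.concatenate(([0.0], np.cumsum(tau)))

def _item_from_zeta(item_id, zeta: np.ndarray) -> PcmItem:
    d = zeta[:-1] - zeta[1:]  # d_k = delta + tau_k
    delta = float(np.mean(d))
    return PcmItem(item_id, zeta.size - 1, delta, d - delta)


@dataclass
class RaschFit:
    """JML estimates: person locations, item parameters, diagnostics."""

    persons: pd.Series  # beta per included person id
    items: list[PcmItem]
    loglik: float
    converged: bool
    iterations: int
    n_excluded: dict[str, int]
    excluded_ids: dict[str, list]
    loglik_path: np.ndarray
    collapsed: dict[object, str] = field(default_factory=dict)
    bias_correction: float = 1.0

    @property
    def item_index(self) -> dict:
        return {it.item_id: it for it in self.items}

    def threshold_disorder(self) -> dict:
        """Item id -> True when its thresholds are disordered ("dislocated")."""
        return {it.item_id: it.disordered for it in self.items}

    def all_threshold_locations(self) -> np.ndarray:
        return np.concatenate([it.threshold_locations for it in self.items])

    def targeting_spread(self) -> float:
        """SD of all item threshold locations: how widely the instrument's
        category boundaries spread over the logit scale."""
        return float(np.std(self.all_threshold_locations(), ddof=0))

    def person_item_distribution(self, bin_width: float = 0.25) -> "PersonItemDistribution":
        """Person and item-threshold histograms on a shared logit axis."""
        betas = self.persons.to_numpy(dtype=float)
        betas = betas[np.isfinite(betas)]
        thr = self.all_threshold_locations()
        lo = np.floor(min(betas.min(), thr.min()) / bin_width) * bin_width
        hi = np.ceil(max(betas.max(), thr.max()) / bin_width) * bin_width
        edges = np.arange(lo, hi + bin_width / 2, bin_width)
        if edges.size < 2:
            edges = np.array([lo, lo + bin_width])
        person_counts, _ = np.histogram(betas, bins=edges)
        threshold_counts, _ = np.histogram(thr, bins=edges)
        return PersonItemDistribution(edges, person_counts, threshold_counts)

    def summary(self) -> str:
        lines = ["Partial credit model (joint maximum likelihood)"]
        lines.append(
            f"  persons included: {len(self.persons)}   items: {len(self.items)}   "
            f"log-likelihood: {self.loglik:.3f}"
        )
        lines.append(
            f"  converged: {self.converged} in {self.iterations} iterations; "
            f"excluded persons: {self.n_excluded}"
        )
        rows = []
        for it in self.items:
            rows.append(
                f"  item {it.item_id}: delta={it.delta:+.3f}  tau="
                + ", ".join(f"{t:+.3f}" for t in it.tau)
                + ("  [disordered]" if it.disordered else "")
            )
        lines.extend(rows)
        spread = self.targeting_spread()
        lines.append(f"  threshold-location spread (SD): {spread:.3f} logits")
        return "\n".join(lines)

    def plot_person_item(self, bin_width: float = 0.25, ax=None):
        """Person-item location distribution (persons above, thresholds below)."""
        import matplotlib.pyplot as plt

        dist = self.person_item_distribution(bin_width)
        if ax is None:
            _, ax = plt.subplots()
        centers = 0.5 * (dist.bin_edges[:-1] + dist.bin_edges[1:])
        ax.bar(centers, dist.person_counts, width=bin_width * 0.9, label="persons")
        ax.bar(centers, -dist.threshold_counts, width=bin_width * 0.9, label="item thresholds")
        ax.axhline(0.0, color="black", lw=0.8)
        ax.set_xlabel("location (logits)")
        ax.set_ylabel("count")
        ax.legend()
        return ax


@dataclass
class PersonItemDistribution:
    bin_edges: np.ndarray
    person_counts: np.ndarray
    threshold_counts: np.ndarray


class PartialCreditModel:
    """Partial credit model for a persons x items integer score matrix.

    Parameters
    ----------
    data
        DataFrame (or 2-D array) of category scores ``0..m`` with one
        column per item; NaN marks a missing response.  Rows with any
        missing entry are excluded from estimation (strict policy), as
        are rows at the score floor or ceiling.
    """

    def __init__(self, data, item_ids=None, person_ids=None):
        if isinstance(data, pd.DataFrame):
            self.scores = data.to_numpy(dtype=float)
            self.item_ids = list(data.columns) if item_ids is None else list(item_ids)
            self.person_ids = list(data.index) if person_ids is None else list(person_ids)
        else:
            self.scores = np.asarray(data, dtype=float)
            n, p = self.scores.shape
            self.item_ids = list(range(p)) if item_ids is None else list(item_ids)
            self.person_ids = list(range(n)) if person_ids is None else list(person_ids)
        if self.scores.ndim != 2 or self.scores.shape[1] < 2:
            raise ValueError("need a persons x items matrix with at least 2 items")

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, items, person_col: str = "patient_id"):
        """Build from a wide cohort table using the given item columns."""
        person_ids = df[person_col].tolist() if person_col in df.columns else list(df.index)
        return cls(df[list(items)], item_ids=list(items), person_ids=person_ids)

    def fit(
        self,
        max_iter: int = 200,
        tol: float = 1e-5,
        bias_correction: bool = True,
    ) -> RaschFit:
        """Joint maximum likelihood fit.

        Alternates Newton updates of item category parameters and person
        locations (grouped by raw score, the sufficient statistic for
        beta under complete data), with step-halving so the joint
        log-likelihood is non-decreasing across iterations.  Convergence
        when the largest parameter change falls below *tol*.
        """
        X = self.scores
        complete = ~np.isnan(X).any(axis=1)
        Xc = X[complete].astype(int) if complete.any() else X[complete]
        kept_ids = [pid for pid, ok in zip(self.person_ids, complete) if ok]
        excluded_ids = {
            "incomplete": [pid for pid, ok in zip(self.person_ids, complete) if not ok]
        }

        # collapse unobserved categories per item (adjacent merge, from below)
        collapsed: dict[object, str] = {}
        m = np.zeros(len(self.item_ids), dtype=int)
        if Xc.shape[0] > 0:
            for j, item in enumerate(self.item_ids):
                observed = np.unique(Xc[:, j])
                full = np.arange(observed.min(), observed.max() + 1)
                top = int(Xc[:, j].max())
                recode = np.searchsorted(observed, Xc[:, j])
                if observed.size != top + 1 or observed.min() != 0:
                    collapsed[item] = (
                        f"observed categories {observed.tolist()} recoded to 0..{observed.size - 1}"
                    )
                    logger.warning("item %s: structural zero categories; %s", item, collapsed[item])
                Xc[:, j] = recode
                m[j] = observed.size - 1
                if m[j] < 1:
                    raise DegenerateDataError(f"item {item} has a single observed category")
        raw = Xc.sum(axis=1) if Xc.size else np.array([], dtype=int)
        max_raw = int(m.sum())
        extreme = (raw == 0) | (raw == max_raw) if Xc.size else np.array([], dtype=bool)
        excluded_ids["extreme"] = [pid for pid, ex in zip(kept_ids, extreme) if ex]
        kept_ids = [pid for pid, ex in zip(kept_ids, extreme) if not ex]
        Xe = Xc[~extreme] if Xc.size else Xc
        n_excluded = {k: len(v) for k, v in excluded_ids.items()}
        if Xe.shape[0] == 0:
            raise DegenerateDataError(
                "no estimable persons: all records are incomplete or at extreme scores"
            )

        K = len(self.item_ids)
        raw = Xe.sum(axis=1)
        # persons share beta by raw score
        unique_raw, person_group = np.unique(raw, return_inverse=True)
        G = unique_raw.size
        beta_g = np.log((unique_raw + 0.5) / (max_raw - unique_raw + 0.5))
        zetas = [np.zeros(mi + 1) for mi in m]
        counts = [np.bincount(Xe[:, j], minlength=m[j] + 1).astype(float) for j in range(K)]
        group_sizes = np.bincount(person_group, minlength=G).astype(float)

        def loglik(zs, bg) -> float:
            total = 0.0
            beta = bg[person_group]
            for j in range(K):
                lg = _category_logits(zs[j], beta)
                total += float(lg[np.arange(Xe.shape[0]), Xe[:, j]].sum()
                               - logsumexp(lg, axis=1).sum())
            return total

        ll = loglik(zetas, beta_g)
        path = [ll]
        converged = False
        it = 0
        for it in range(1, max_iter + 1):
            max_change = 0.0

            # --- item block: Newton on each item's zeta (category log-numerators)
            beta = beta_g[person_group]
            for j in range(K):
                zeta = zetas[j]
                lg = _category_logits(zeta, beta)
                P = np.exp(lg - logsumexp(lg, axis=1, keepdims=True))
                grad = counts[j] - P.sum(axis=0)
                # Hessian of the item log-likelihood in zeta: -(diag(sum P) - sum P P^T)
                H = np.einsum("ni,nj->ij", P, P) - np.diag(P.sum(axis=0))
                Hfree = H[1:, 1:]  # zeta_0 is fixed at 0
                gfree = grad[1:]
                try:
                    step = np.linalg.solve(Hfree, -gfree)
                except np.linalg.LinAlgError:
                    step = gfree * 0.1
                step = np.clip(step, -2.0, 2.0)
                new = zeta.copy()
                scale = 1.0
                base = _item_loglik(zeta, beta, Xe[:, j])
                for _ in range(20):
                    new[1:] = zeta[1:] + scale * step
                    if _item_loglik(new, beta, Xe[:, j]) >= base - 1e-12:
                        break
                    scale *= 0.5
                else:
                    new = zeta.copy()
                max_change = max(max_change, float(np.max(np.abs(new - zeta))))
                zetas[j] = new

            # --- identification: centre mean item location at zero
            deltas = np.array([_item_from_zeta(iid, z).delta
                               for iid, z in zip(self.item_ids, zetas)])
            c = float(deltas.mean())
            if abs(c) > 0:
                for j in range(K):
                    zetas[j] = zetas[j] + np.arange(m[j] + 1) * c
                beta_g = beta_g - c

            # --- person block: 1-D Newton per raw-score group
            expected, info = _score_expectation(zetas, beta_g)
            grad_b = unique_raw - expected
            step_b = np.where(info > 1e-10, grad_b / info, 0.0)
            step_b = np.clip(step_b, -2.0, 2.0)
            new_beta = np.clip(beta_g + step_b, -_BETA_BOX, _BETA_BOX)
            # step-halving on the person-block log-likelihood
            scale = 1.0
            base = _person_loglik(zetas, beta_g, unique_raw, group_sizes)
            for _ in range(20):
                cand = np.clip(beta_g + scale * step_b, -_BETA_BOX, _BETA_BOX)
                if _person_loglik(zetas, cand, unique_raw, group_sizes) >= base - 1e-12:
                    new_beta = cand
                    break
                scale *= 0.5
            else:
                new_beta = beta_g
            max_change = max(max_change, float(np.max(np.abs(new_beta - beta_g))))
            beta_g = new_beta

            ll = loglik(zetas, beta_g)
            path.append(ll)
            if max_change < tol:
                converged = True
                break

        items = [_item_from_zeta(iid, z) for iid, z in zip(self.item_ids, zetas)]
        correction = (K - 1) / K if bias_correction else 1.0
        if bias_correction:
            for k_i, it_obj in enumerate(items):
                it_obj.delta *= correction
                it_obj.tau = it_obj.tau * correction
                zetas[k_i] = _zeta_from_item(it_obj.delta, it_obj.tau)
            # re-estimate person locations against the corrected items
            beta_g = _solve_betas(zetas, unique_raw, beta_g)
            ll = loglik(zetas, beta_g)

        persons = pd.Series(beta_g[person_group], index=pd.Index(kept_ids, name="person_id"),
                            name="beta")
        return RaschFit(
            persons=persons,
            items=items,
            loglik=ll,
            converged=converged,
            iterations=it,
            n_excluded=n_excluded,
            excluded_ids=excluded_ids,
            loglik_path=np.asarray(path),
            collapsed=collapsed,
            bias_correction=correction,
        )


def _item_loglik(zeta: np.ndarray, beta: np.ndarray, x: np.ndarray) -> float:
    lg = _category_logits(zeta, beta)
    return float(lg[np.arange(x.size), x].sum() - logsumexp(lg, axis=1).sum())


def _score_expectation(zetas, beta_g):
    """Expected raw score and its variance (Fisher info for beta) per group."""
    G = beta_g.size
    expected = np.zeros(G)
    info = np.zeros(G)
    for z in zetas:
        cats = np.arange(z.size)
        lg = beta_g[:, None] * cats + z[None, :]
        P = np.exp(lg - logsumexp(lg, axis=1, keepdims=True))
        mu = P @ cats
        expected += mu
        info += P @ cats**2 - mu**2
    return expected, info


def _person_loglik(zetas, beta_g, unique_raw, group_sizes) -> float:
    total = 0.0
    for z in zetas:
        cats = np.arange(z.size)
        lg = beta_g[:, None] * cats + z[None, :]
        total -= float(group_sizes @ logsumexp(lg, axis=1))
    total += float(group_sizes @ (unique_raw * beta_g))
    return total


def _solve_betas(zetas, unique_raw, beta_init, tol: float = 1e-10, max_iter: int = 100):
    """Newton solve of E[raw score | beta] = observed raw score per group."""
    beta = beta_init.copy()
    for _ in range(max_iter):
        expected, info = _score_expectation(zetas, beta)
        step = np.where(info > 1e-12, (unique_raw - expected) / info, 0.0)
        step = np.clip(step, -2.0, 2.0)
        beta = np.clip(beta + step, -_BETA_BOX, _BETA_BOX)
        if np.max(np.abs(step)) < tol:
            break
    return beta


def fit_pcm(data, item_ids=None, person_ids=None, **kwargs) -> RaschFit:
    """Convenience wrapper: ``PartialCreditModel(data).fit(**kwargs)``."""
    return PartialCreditModel(data, item_ids=item_ids, person_ids=person_ids).fit(**kwargs)


def person_item_distribution(fit: RaschFit, bin_width: float = 0.25) -> PersonItemDistribution:
    return fit.person_item_distribution(bin_width)


def threshold_disorder(fit: RaschFit) -> dict:
    return fit.threshold_disorder()


def targeting_spread(fit: RaschFit) -> float:
    return fit.targeting_spread()
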