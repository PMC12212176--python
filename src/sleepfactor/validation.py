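"""Validation statistics for the sleep scores.

Correlations (Pearson for continuous pairs, Spearman for ordinal),
paired baseline-to-follow-up change tests (signed-rank with the
SAS-style centred S statistic), two-group Student's t comparisons,
cut-off confusion tables against external labels, and a null screen of
biomarker columns against the scores.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

CONFIDENCE_LEVEL = 0.95


@dataclass(frozen=True)
class CorrelationResult:
    method: str
    r: float
    r_squared: float
    n: int
    p_value: float


@dataclass(frozen=True)
class SignedRankResult:
    """Centred signed-rank statistic S = (sum of positive ranks) - n(n+1)/4."""

    s: float
    p_value: float
    n_nonzero: int


@dataclass(frozen=True)
class CutoffTable:
    """2x2 cross-tabulation of (score >= cutoff) against a binary label.

    ``counts[i, j]``: i indexes the flag (0 = below cutoff, 1 = at or
    above), j indexes the label (0 / 1).
    """

    counts: np.ndarray
    cutoff: int
    sensitivity: float
    specificity: float

    @property
    def n(self) -> int:
        return int(self.counts.sum())


def _pairwise_complete(x, y):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    mask = np.isfinite(x) & np.isfinite(y)
    return x[mask], y[mask]


def correlate(x, y, method: str = "pearson") -> CorrelationResult:
    """Pearson or Spearman correlation on pairwise-complete observations.

    Spearman rank-transforms with average ties; two-sided p-values come
    from the t approximation (scipy's default for both methods).
    """
    if method not in ("pearson", "spearman"):
        raise ValueError(f"unknown method {method!r}")
    x, y = _pairwise_complete(x, y)
    n = x.size
    if n < 3:
        raise ValueError(f"need at least 3 complete pairs, got {n}")
    if method == "pearson":
        res = stats.pearsonr(x, y)
    else:
        res = stats.spearmanr(x, y)
    r = float(res.statistic)
    return CorrelationResult(method, r, r * r, n, float(res.pvalue))


def _signed_rank_exact_p(dranks2: np.ndarray, w2: float) -> float:
    """Exact two-sided p of the positive-rank sum via convolution.

    ``dranks2`` holds doubled mid-ranks (integers even under ties), so
    the null distribution of the doubled positive-rank sum is a simple
    0/1-inclusion convolution.
    """
    total = int(dranks2.sum())
    dist = np.zeros(total + 1)
    dist[0] = 1.0
    for r in dranks2:
        new = dist.copy()
        new[r:] += dist[: total + 1 - r]
        dist = new
    dist /= dist.sum()
    w2 = int(round(w2))
    lower = dist[: w2 + 1].sum()
    upper = dist[w2:].sum()
    return float(min(1.0, 2.0 * min(lower, upper)))


def wilcoxon_signed_rank(pre, post, exact_n: int = 25) -> SignedRankResult:
    """Paired signed-rank test on differences ``post - pre``.

    Zero differences are dropped; absolute differences are ranked with
    average ties.  The reported statistic is the centred
    ``S = sum(positive ranks) - n(n+1)/4`` (so S is 0 under exact
    symmetry and changes sign when pre and post are swapped).  The
    two-sided p-value is exact (convolution over the tie-adjusted rank
    distribution) for ``n <= exact_n``, otherwise the Student-t
    approximation ``t = S sqrt((n-1) / (n V - S^2))`` with
    ``V = sum(rank^2) / 4`` on ``n - 1`` degrees of freedom.
    """
    pre, post = _pairwise_complete(pre, post)
    d = post - pre
    d = d[d != 0]
    n = d.size
    if n == 0:
        return SignedRankResult(0.0, 1.0, 0)
    ranks = stats.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    s = w_plus - n * (n + 1) / 4.0
    if n <= exact_n:
        dranks2 = np.round(2 * ranks).astype(int)
        p = _signed_rank_exact_p(dranks2, 2 * w_plus)
    else:
        v = float(np.sum(ranks**2)) / 4.0
        denom = n * v - s * s
        if denom <= 0:
            p = 0.0
        else:
            t = s * np.sqrt((n - 1) / denom)
            p = float(2.0 * stats.t.sf(abs(t), df=n - 1))
    return SignedRankResult(float(s), p, n)


@dataclass(frozen=True)
class GroupTTestResult:
    t: float
    p_value: float
    means: tuple[float, float]
    ci: tuple[tuple[float, float], tuple[float, float]]
    n: tuple[int, int]
    welch: bool


def group_ttest(values, groups, welch: bool = False) -> GroupTTestResult:
    """Two-sided Student's t-test (pooled variance; Welch optional).

    Returns the statistic, p, and per-group means with 95% confidence
    intervals.  Groups of fewer than two members have no defined
    variance and raise.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    mask = np.isfinite(values)
    values, groups = values[mask], groups[mask]
    labels = np.unique(groups)
    if labels.size != 2:
        raise ValueError(f"need exactly two groups, got {labels.tolist()}")
    a = values[groups == labels[0]]
    b = values[groups == labels[1]]
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least two members for a defined variance")
    res = stats.ttest_ind(a, b, equal_var=not welch)
    cis = []
    for g in (a, b):
        sem = stats.sem(g)
        half = stats.t.ppf(0.5 + CONFIDENCE_LEVEL / 2, df=g.size - 1) * sem
        cis.append((float(g.mean() - half), float(g.mean() + half)))
    return GroupTTestResult(
        t=float(res.statistic),
        p_value=float(res.pvalue),
        means=(float(a.mean()), float(b.mean())),
        ci=(cis[0], cis[1]),
        n=(int(a.size), int(b.size)),
        welch=welch,
    )


def cutoff_confusion(scores, labels, cutoff: int) -> CutoffTable:
    """Cross-tabulate (score >= cutoff) against a binary label.

    Sensitivity = flagged fraction among label 1; specificity =
    unflagged fraction among label 0.  Pairs with a missing score or
    label are dropped.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=float)
    mask = np.isfinite(scores) & np.isfinite(labels)
    scores, labels = scores[mask], labels[mask].astype(int)
    if not np.isin(labels, (0, 1)).all():
        raise ValueError("labels must be binary 0/1")
    flag = (scores >= cutoff).astype(int)
    counts = np.zeros((2, 2), dtype=int)
    np.add.at(counts, (flag, labels), 1)
    pos = counts[:, 1].sum()
    neg = counts[:, 0].sum()
    sens = counts[1, 1] / pos if pos else float("nan")
    spec = counts[0, 0] / neg if neg else float("nan")
    return CutoffTable(counts=counts, cutoff=int(cutoff), sensitivity=float(sens),
                       specificity=float(spec))


def biomarker_null_screen(
    scored: pd.DataFrame,
    biomarker_cols=None,
    score_cols=("sq", "dts"),
    log_transform: bool = True,
    alpha: float = 0.05,
    benjamini_hochberg: bool = False,
) -> pd.DataFrame:
    """Correlate each biomarker with each score, per timepoint.

    Pearson correlation on (by default) log-transformed biomarker
    values.  Raw p-values are reported; a Benjamini-Hochberg adjusted
    column is added only on request, since the screen is meant as a
    per-test null check.
    """
    if biomarker_cols is None:
        biomarker_cols = [c for c in scored.columns if c.startswith("biomarker_")]
    timepoints = (
        scored["timepoint"].unique().tolist() if "timepoint" in scored.columns else [None]
    )
    rows = []
    for tp in timepoints:
        sub = scored if tp is None else scored[scored["timepoint"] == tp]
        for bc in biomarker_cols:
            vals = sub[bc].to_numpy(dtype=float)
            if log_transform:
                vals = np.where(vals > 0, np.log(np.where(vals > 0, vals, 1.0)), np.nan)
            for sc in score_cols:
                try:
                    res = correlate(vals, sub[sc].to_numpy(dtype=float), "pearson")
                except ValueError:
                    continue
                rows.append(
                    {
                        "timepoint": tp,
                        "biomarker": bc,
                        "score": sc,
                        "r": res.r,
                        "r_squared": res.r_squared,
                        "n": res.n,
                        "p_value": res.p_value,
                        "significant": res.p_value < alpha,
                    }
                )
    out = pd.DataFrame(rows)
    if benjamini_hochberg and len(out):
        from statsmodels.stats.multitest import multipletests

        out["p_adjusted"] = multipletests(out["p_value"], method="fdr_bh")[1]
        out["significant_adjusted"] = out["p_adjusted"] < alpha
    return out
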