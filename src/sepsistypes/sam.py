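"""Two-class unpaired significance analysis of microarrays (SAM).

Per gene the moderated relative difference is

    d_i = (mean2_i - mean1_i) / (s_i + s0)

with s_i the pooled standard error and s0 an exchangeability constant
chosen to minimize, over a percentile grid of s, the coefficient of
variation of the spread of d across s-windows.  The null distribution of
d comes from label permutations; the per-gene q-value is the estimated
false discovery rate at that gene's own |d| threshold (median false-call
count over permutations, scaled by the null-proportion estimate pi0,
divided by the observed call count, made monotone in |d|).  A q-value of
exactly 0 means the median permutation produced no statistic as extreme.

Sign convention: class labels are sorted; positive d means higher
expression in the second class.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from scipy.special import comb

from .errors import ParameterError
from .io import ExpressionMatrix, require_complete

__all__ = ["SamResult", "sam_two_class", "select_q_zero"]


@dataclass
class SamResult:
    gene_ids: list[str]
    d: np.ndarray
    s: np.ndarray
    q_values: np.ndarray
    selected: np.ndarray  # q_value == 0
    s0: float
    pi0: float
    n_permutations: int
    seed: int | None
    classes: tuple  # (class coded 1, class coded 2); positive d = higher in class 2

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {"gene_id": self.gene_ids, "d": self.d, "s": self.s, "q_value": self.q_values,
             "selected": self.selected}
        )


def _pooled_stats(V: np.ndarray, idx2: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Mean difference (class2 - class1) and pooled SE per gene.

    idx2 is a boolean matrix (n_perms x n_samples) marking class-2 membership.
    Returns (G x P) arrays.
    """
    n = V.shape[1]
    n2 = idx2.sum(axis=1)  # per permutation
    n1 = n - n2
    tot = V.sum(axis=1, keepdims=True)
    tot2 = (V**2).sum(axis=1, keepdims=True)
    S2 = V @ idx2.T  # G x P sums of class-2 values
    S1 = tot - S2
    Q2 = (V**2) @ idx2.T
    Q1 = tot2 - Q2
    m1, m2 = S1 / n1, S2 / n2
    ss = (Q1 - n1 * m1**2) + (Q2 - n2 * m2**2)
    ss = np.maximum(ss, 0.0)  # guard rounding
    se = np.sqrt((1.0 / n1 + 1.0 / n2) * ss / (n - 2))
    return m2 - m1, se


def _choose_s0(r: np.ndarray, s: np.ndarray) -> float:
    """Tusher's coefficient-of-variation rule on the percentile grid 0,5,...,100."""
    alphas = np.arange(0, 105, 5)
    s0_candidates = np.percentile(s, alphas)
    # ~100 windows of genes ordered by s
    order = np.argsort(s, kind="stable")
    n_windows = min(100, max(2, len(s) // 10))
    windows = np.array_split(order, n_windows)
    best_cv, best_s0 = np.inf, float(np.median(s))
    for s0 in s0_candidates:
        dd = r / (s + s0)
        mads = []
        for w in windows:
            x = dd[w]
            med = np.median(x)
            mads.append(np.median(np.abs(x - med)) * 1.4826)
        mads = np.asarray(mads)
        mean = mads.mean()
        if mean <= 0:
            continue
        cv = mads.std(ddof=1) / mean
        if cv < best_cv:
            best_cv, best_s0 = cv, float(s0)
    return best_s0


def _permutation_indicators(
    labels12: np.ndarray, n_permutations: int, rng: np.random.Generator
) -> np.ndarray:
    """Boolean (P x n) class-2 indicator matrix of permuted labelings.

    Uses all distinct labelings when there are at most ``n_permutations``
    of them, otherwise draws uniform random permutations.
    """
    n = len(labels12)
    n2 = int((labels12 == 2).sum())
    n_distinct = comb(n, n2, exact=True)
    if n_distinct <= n_permutations:
        out = np.zeros((n_distinct, n), dtype=bool)
        for p, pos in enumerate(itertools.combinations(range(n), n2)):
            out[p, list(pos)] = True
        return out
    out = np.zeros((n_permutations, n), dtype=bool)
    base = labels12 == 2
    for p in range(n_permutations):
        out[p] = rng.permutation(base)
    return out


def sam_two_class(
    m: ExpressionMatrix,
    labels: np.ndarray,
    n_permutations: int = 200,
    seed: int | None = None,
    s0_percentile: float | None = None,
    s0_fixed: float | None = None,
    force_pi0_one: bool = False,
) -> SamResult:
    """Run two-class unpaired SAM on an imputed matrix.

    ``labels`` may use any two values; they are sorted and coded so that a
    positive d means higher expression in the larger-coded class.
    ``s0_percentile`` overrides the automatic coefficient-of-variation
    choice with a fixed percentile of s, and ``s0_fixed`` pins s0 to a
    constant (0 recovers the unmoderated t-like statistic).
    ``force_pi0_one`` disables the null-proportion shrinkage.
    """
    require_complete(m, "SAM")
    labels = np.asarray(labels)
    if labels.shape[0] != m.n_samples:
        raise ParameterError("labels length must equal the number of samples")
    classes = np.unique(labels)
    if len(classes) != 2:
        raise ParameterError(f"SAM needs exactly 2 classes, got {len(classes)}")
    labels12 = np.where(labels == classes[0], 1, 2)
    if min((labels12 == 1).sum(), (labels12 == 2).sum()) < 2:
        raise ParameterError("each class needs at least 2 samples")

    V = m.values
    obs2 = (labels12 == 2)[None, :]
    r, s = _pooled_stats(V, obs2)
    r, s = r[:, 0], s[:, 0]

    if s0_fixed is not None:
        s0 = float(s0_fixed)
    elif s0_percentile is not None:
        s0 = float(np.percentile(s, s0_percentile))
    else:
        s0 = _choose_s0(r, s)
    if s0 <= 0 and np.any(s == 0) and s0_fixed is None:
        s0 = float(np.min(s[s > 0])) if np.any(s > 0) else 1.0
    d = r / (s + s0)

    rng = np.random.default_rng(seed)
    perms = _permutation_indicators(labels12, n_permutations, rng)
    r_null, s_null = _pooled_stats(V, perms)
    d_null = r_null / (s_null + s0)  # G x P

    abs_d = np.abs(d)
    abs_null = np.abs(d_null)
    P = d_null.shape[1]

    # observed calls and per-permutation false calls at each gene's own |d|
    order = np.argsort(-abs_d, kind="stable")
    thresholds = abs_d[order]
    calls = np.searchsorted(-thresholds, -thresholds, side="right")  # ties counted together
    false = np.empty((P, len(thresholds)))
    for p in range(P):
        col = np.sort(abs_null[:, p])
        false[p] = len(col) - np.searchsorted(col, thresholds, side="left")
    median_false = np.median(false, axis=0)

    if force_pi0_one:
        pi0 = 1.0
    else:
        q50 = np.median(abs_null)
        pi0 = float(min(1.0, 2.0 * np.mean(abs_d <= q50)))

    fdr_sorted = np.minimum(1.0, pi0 * median_false / np.maximum(calls, 1))
    # q non-decreasing as |d| decreases: min FDR over less stringent thresholds
    q_sorted = np.minimum.accumulate(fdr_sorted[::-1])[::-1]
    q = np.empty_like(q_sorted)
    q[order] = q_sorted

    return SamResult(
        gene_ids=list(m.gene_ids),
        d=d,
        s=s,
        q_values=q,
        selected=q == 0.0,
        s0=s0,
        pi0=pi0,
        n_permutations=P,
        seed=seed,
        classes=(classes[0], classes[1]),
    )


def select_q_zero(result: SamResult) -> list[str]:
    """Gene IDs with q-value exactly 0, ordered by |d| descending."""
    idx = np.nonzero(result.selected)[0]
    idx = idx[np.argsort(-np.abs(result.d[idx]), kind="stable")]
    return [result.gene_ids[i] for i in idx]
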