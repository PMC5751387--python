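"""Unsupervised feature selection by representation entropy and MICI.

Representation entropy (RE) of a feature subset is the Shannon entropy of the
normalized eigenvalue spectrum of the subset's correlation matrix: it is 0
when one feature linearly explains the rest (rank 1) and ln(d) when the d
features are mutually uncorrelated.  The Maximal Information Compression
Index (MICI) of a feature pair is the smallest eigenvalue of their 2x2
covariance matrix: 0 iff the pair is linearly dependent.

Selection runs in two processes:

1. *Threshold estimation.*  Random subsets covering 10-80 % of the features
   are drawn; their RE values are pooled; values not significantly below the
   maximum (one-sided Z-screen, p >= 0.05) are retained and the retained
   value closest to all others (minimal total standardized distance, i.e. the
   univariate Mahalanobis medoid) becomes the RE threshold.

2. *Redundancy elimination.*  Repeatedly find the working-set pair with the
   smallest MICI; the two members plus all previously rejected features
   compete: the candidate that maximizes the RE of (working set minus the
   pair, plus candidate) survives, the rest are rejected; the threshold is
   re-estimated with the new RE appended to the history.  The loop stops when
   the working set's RE exceeds the threshold — unless an exactly
   linearly-dependent pair (MICI ~ 0) remains, which is always removed — or
   when fewer than 3 features remain.

Every run is deterministic given the seed, and the returned
:class:`SelectionLedger` records subsets drawn, thresholds, and each
replacement, so alternative readings of the competition rule can be compared.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SelectionLedger",
    "representation_entropy",
    "re_from_corr",
    "mici",
    "re_threshold",
    "select_features",
]


@dataclass
class SelectionLedger:
    """Full record of one feature-selection run."""

    selected: list[str]
    threshold_history: list[float]
    re_history: list[float]
    removed_pairs: list[dict] = field(default_factory=list)
    rng_seed: int | None = None
    config: dict = field(default_factory=dict)


def re_from_corr(corr: np.ndarray) -> float:
    """Representation entropy from a correlation (or covariance) matrix."""
    corr = np.asarray(corr, dtype=float)
    lam = np.linalg.eigvalsh(corr)
    lam = np.clip(lam, 0.0, None)
    s = lam.sum()
    if s <= 0:
        return 0.0
    lt = lam / s
    nz = lt > 0
    return float(-(lt[nz] * np.log(lt[nz])).sum())


def representation_entropy(sub) -> float:
    """RE of a feature matrix (rows = observations, columns = features).

    Based on the correlation matrix, so the value is invariant to feature
    rescaling; bounded by [0, ln d].  Constant columns carry no variance and
    enter with zero correlation to everything (their eigenvalue contributes
    like an independent feature).
    """
    X = np.asarray(sub, dtype=float)
    if X.ndim != 2 or X.shape[1] < 2 or X.shape[0] < 2:
        raise ValueError("need >= 2 observations and >= 2 features")
    sd = X.std(axis=0)
    ok = sd > 0
    d = X.shape[1]
    corr = np.eye(d)
    if ok.sum() >= 2:
        corr_ok = np.corrcoef(X[:, ok], rowvar=False)
        corr[np.ix_(ok, ok)] = corr_ok
    return re_from_corr(corr)


def mici(x, y) -> float:
    """Maximal information compression index of a feature pair.

    Smallest eigenvalue of the 2x2 covariance of (x, y):

        lam2 = (vx + vy - sqrt((vx + vy)^2 - 4 vx vy (1 - rho^2))) / 2

    Zero iff the two features are linearly dependent; symmetric in x, y.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    vx, vy = x.var(), y.var()
    if vx == 0 or vy == 0:
        raise ValueError("MICI requires non-constant features")
    cxy = ((x - x.mean()) * (y - y.mean())).mean()
    rho2 = cxy * cxy / (vx * vy)
    disc = (vx + vy) ** 2 - 4.0 * vx * vy * (1.0 - rho2)
    return float((vx + vy - np.sqrt(max(disc, 0.0))) / 2.0)


def re_threshold(re_values, p: float = 0.05) -> float:
    """RE threshold: Z-screen against the maximum, then the medoid.

    Values whose standardized deficit from the maximum is not significant at
    the one-sided level ``p`` are retained; among those, the value with the
    minimal total standardized (univariate Mahalanobis) distance to the other
    retained values is returned.  All-equal collections return that value.
    """
    v = np.asarray(re_values, dtype=float)
    if v.size < 1:
        raise ValueError("re_threshold needs at least one value")
    sd = v.std(ddof=1) if v.size > 1 else 0.0
    if sd == 0:
        return float(v[0])
    zcrit = stats.norm.ppf(1.0 - p)
    keep = v[(v.max() - v) / sd <= zcrit]
    # medoid: minimal summed absolute distance; scaling by sd does not change it
    dists = np.abs(keep[:, None] - keep[None, :]).sum(axis=1)
    return float(keep[np.argmin(dists)])


def _subset_sizes(d: int, fractions) -> list[int]:
    return sorted({max(2, int(round(f * d))) for f in fractions if round(f * d) <= d})


def select_features(
    fm: pd.DataFrame,
    n_subsets: int = 200,
    fractions: tuple[float, ...] = (0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8),
    seed: int | None = None,
    mici_tol: float = 1e-9,
    p: float = 0.05,
) -> SelectionLedger:
    """Run the two-process RE/MICI selection on a feature matrix.

    Parameters
    ----------
    fm
        DataFrame, rows = observations, columns = named features (>= 4).
    n_subsets
        Random subsets drawn per cluster fraction for the threshold pool.
    mici_tol
        Pairs whose MICI falls below ``mici_tol * mean feature variance`` are
        treated as exact linear dependencies and always eliminated.

    Returns
    -------
    :class:`SelectionLedger` with the surviving feature names and the full
    iteration record.  Deterministic given ``seed``.
    """
    if not isinstance(fm, pd.DataFrame):
        fm = pd.DataFrame(np.asarray(fm, dtype=float))
        fm.columns = [f"f{i}" for i in range(fm.shape[1])]
    names = list(fm.columns)
    if len(set(names)) != len(names):
        raise ValueError("feature names must be unique")
    X = fm.to_numpy(dtype=float)
    if X.shape[1] < 4:
        raise ValueError("need at least 4 features")
    if not np.all(np.isfinite(X)):
        raise ValueError("feature matrix contains non-finite values")
    d = X.shape[1]
    rng = np.random.default_rng(seed)

    # one pass over the data; everything else works off these moments
    sd = X.std(axis=0)
    Z = (X - X.mean(axis=0)) / np.where(sd > 0, sd, 1.0)
    corr = np.corrcoef(X, rowvar=False)
    corr = np.where(np.isfinite(corr), corr, 0.0)
    np.fill_diagonal(corr, 1.0)
    var = X.var(axis=0)

    def re_of(idx: list[int]) -> float:
        return re_from_corr(corr[np.ix_(idx, idx)])

    def mici_of(i: int, j: int) -> float:
        vx, vy, rho2 = var[i], var[j], corr[i, j] ** 2
        disc = (vx + vy) ** 2 - 4.0 * vx * vy * (1.0 - rho2)
        return float((vx + vy - np.sqrt(max(disc, 0.0))) / 2.0)

    # -- process 1: pooled-subset RE threshold --------------------------------
    pool: list[float] = []
    for size in _subset_sizes(d, fractions):
        for _ in range(n_subsets):
            pool.append(re_of(list(rng.choice(d, size=size, replace=False))))
    threshold = re_threshold(pool, p)
    abs_tol = mici_tol * max(float(var.mean()), 1e-30)

    working = list(range(d))
    rejected: list[int] = []
    ledger = SelectionLedger(
        selected=[],
        threshold_history=[threshold],
        re_history=[re_of(working)],
        rng_seed=seed,
        config={"n_subsets": n_subsets, "fractions": list(fractions),
                "mici_tol": mici_tol, "p": p},
    )

    # -- process 2: redundancy elimination ------------------------------------
    for _ in range(d):
        if len(working) < 3:
            break
        pairs = [(a, b) for ii, a in enumerate(working) for b in working[ii + 1 :]]
        m_vals = [mici_of(a, b) for a, b in pairs]
        i_min = int(np.argmin(m_vals))  # ties break lexicographically
        a, b = pairs[i_min]
        m_min = m_vals[i_min]
        if ledger.re_history[-1] > threshold and m_min > abs_tol:
            break
        base = [f for f in working if f not in (a, b)]
        candidates = [a, b] + [r for r in rejected if r not in (a, b)]
        scores = [re_of(base + [c]) for c in candidates]
        winner = candidates[int(np.argmax(scores))]
        working = base + [winner]
        working.sort()
        rejected = sorted(set(rejected + [c for c in (a, b) if c != winner]) - {winner})
        ledger.removed_pairs.append(
            {"pair": (names[a], names[b]), "mici": m_min,
             "winner": names[winner], "re_after": re_of(working)}
        )
        ledger.re_history.append(re_of(working))
        threshold = re_threshold(pool + ledger.re_history, p)
        ledger.threshold_history.append(threshold)

    ledger.selected = [names[i] for i in working]
    return ledger
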