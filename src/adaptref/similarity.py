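"""Sliding-window similarity between EEG channels.

The adaptive filters rank neighbor electrodes by how interchangeable their
signal is with the target electrode's.  Interchangeability is measured by
Lin's concordance correlation coefficient (CCC)

    rho_c = 2 s_xy / (s_x^2 + s_y^2 + (mean x - mean y)^2)

with biased (divide-by-n) moment estimates.  The CCC combines precision
(Pearson correlation) with accuracy (agreement of means and variances), so
|rho_c| <= |r| always, with equality only when the two windows share mean and
variance.  All quantities are evaluated on a sliding window of ``n`` samples
that ends at the current sample: window k covers samples [k-n+1, k],
0-based inclusive.

Degenerate (flat) windows occur in synthetic tests and in clipped hardware
segments; they are mapped to the conventions documented on each function
rather than NaN so they cannot poison the filter state.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["ccc", "pearson_r", "ccc_to_neighbors", "sliding_ccc"]


def _moments(x: np.ndarray, y: np.ndarray):
    mx, my = x.mean(), y.mean()
    dx, dy = x - mx, y - my
    n = x.size
    return mx, my, dx @ dx / n, dy @ dy / n, dx @ dy / n


def ccc(x, y) -> float:
    """Concordance correlation coefficient of two equal-length windows.

    Returns a value in [-1, 1].  Conventions for degenerate windows: two
    constant windows of equal value agree perfectly (1.0); a zero denominator
    with unequal constants means no agreement (0.0).

    Raises
    ------
    ValueError
        If the windows differ in length or are shorter than 2 samples.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"window length mismatch: {x.size} vs {y.size}")
    if x.size < 2:
        raise ValueError("windows must hold at least 2 samples")
    mx, my, vx, vy, cxy = _moments(x, y)
    denom = vx + vy + (mx - my) ** 2
    if denom == 0.0:
        # both windows constant: equal constants agree perfectly
        return 1.0 if mx == my else 0.0
    return float(2.0 * cxy / denom)


def pearson_r(x, y) -> float:
    """Product-moment correlation; 0.0 when either window is constant."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"window length mismatch: {x.size} vs {y.size}")
    if x.size < 2:
        raise ValueError("windows must hold at least 2 samples")
    _, _, vx, vy, cxy = _moments(x, y)
    if vx == 0.0 or vy == 0.0:
        return 0.0
    return float(cxy / np.sqrt(vx * vy))


def is_degenerate(x) -> bool:
    """True when the window is constant (zero variance)."""
    x = np.asarray(x, dtype=float)
    return bool(np.all(x == x.flat[0]))


def ccc_to_neighbors(buffer: np.ndarray, target: int, neighbors, n: int | None = None):
    """CCC between the target's trailing window and each neighbor's.

    Parameters
    ----------
    buffer
        Array (channels, samples) holding at least ``n`` samples.
    target
        Channel index of the electrode of interest.
    neighbors
        Channel indices, in the order the result should follow.
    n
        Window length; defaults to the whole buffer.

    Returns
    -------
    ndarray of rho_c values, one per neighbor.
    """
    buffer = np.asarray(buffer, dtype=float)
    if n is None:
        n = buffer.shape[1]
    if buffer.shape[1] < n:
        raise ValueError(
            f"buffer holds {buffer.shape[1]} samples, window needs {n} (warm-up)"
        )
    win = buffer[:, -n:]
    return np.array([ccc(win[target], win[j]) for j in neighbors])


def sliding_ccc(data: np.ndarray, target: int, neighbors, n: int) -> np.ndarray:
    """Vectorized per-sample CCC between target and neighbors.

    Parameters
    ----------
    data
        Array (channels, T).
    target, neighbors
        Channel indices.
    n
        Window length (samples).

    Returns
    -------
    ndarray (len(neighbors), T - n + 1); column t is the CCC of the windows
    ending at sample ``t + n - 1``.
    """
    data = np.asarray(data, dtype=float)
    neighbors = list(neighbors)
    wx = sliding_window_view(data[target], n)            # (W, n)
    wn = sliding_window_view(data[neighbors], n, axis=1)  # (J, W, n)
    mx = wx.mean(axis=1)
    mn = wn.mean(axis=2)
    dx = wx - mx[:, None]
    dn = wn - mn[:, :, None]
    vx = np.einsum("wk,wk->w", dx, dx) / n
    vn = np.einsum("jwk,jwk->jw", dn, dn) / n
    cxy = np.einsum("wk,jwk->jw", dx, dn) / n
    denom = vx[None, :] + vn + (mx[None, :] - mn) ** 2
    out = np.zeros_like(denom)
    ok = denom > 0.0
    out[ok] = 2.0 * cxy[ok] / denom[ok]
    # equal-constant convention (both windows flat at the same value)
    flat = ~ok
    if np.any(flat):
        eq = np.isclose(mn, mx[None, :])
        out[flat & eq] = 1.0
    return out
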