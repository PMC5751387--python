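"""Neighbor selection — stage 1 of the adaptive filter.

For every output sample the filter decides which neighbor electrodes may
contribute to the common-interference estimate.  The decision combines two
statistics:

* ``Vstd`` — the spread of the instantaneous amplitudes of the candidate
  electrodes around the target's amplitude.  A quiet sample (Vstd below an
  adaptive threshold) keeps all candidates; a noisy one (electrode pops,
  cable movement, localized bursts) triggers similarity-based screening.
* per-neighbor CCC — neighbors whose sliding-window CCC with the target
  exceeds an adaptive threshold survive the screening.

The Vstd threshold adapts between the running minimum and maximum of Vstd
seen so far; the running maximum is capped at ``cap_ratio`` times the running
minimum so a single huge artifact cannot make the threshold sticky.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SelectionState",
    "SelectionResult",
    "vstd",
    "vstd_threshold",
    "ccc_threshold",
    "select_neighbors",
]

#: floor for the running Vstd minimum (microvolts) so the threshold's
#: denominator cannot blow up on an all-flat stretch
VSTD_EPS = 1e-6


@dataclass
class SelectionState:
    """Running Vstd extremes of one target electrode."""

    vstd_min: float = np.inf
    vstd_max: float = 0.0
    n_updates: int = 0

    def update(self, value: float) -> None:
        self.vstd_min = max(min(self.vstd_min, value), VSTD_EPS)
        self.vstd_max = max(self.vstd_max, value, VSTD_EPS)
        self.n_updates += 1


@dataclass
class SelectionResult:
    """Outcome of one per-sample selection decision."""

    selected: list[int]
    vstd_ik: float
    vstd_th: float
    ccc_values: np.ndarray
    ccc_th: float | None
    all_pass: bool
    fallback: bool = False  # no neighbor beat the CCC threshold; best kept
    degenerate_threshold: bool = False  # Vstd threshold degenerated to +inf


def vstd(sample_values, target: int) -> float:
    """Spread of instantaneous amplitudes around the target electrode.

        Vstd = sqrt( sum_j (V_j - V_target)^2 / (N - 1) )

    summed over all N electrodes of the candidate set (the target's own term
    is zero).  Positively homogeneous: scaling all amplitudes scales Vstd.
    """
    v = np.asarray(sample_values, dtype=float)
    if v.size < 2:
        raise ValueError("Vstd needs at least 2 electrodes")
    d = v - v[target]
    return float(np.sqrt(d @ d / (v.size - 1)))


def vstd_threshold(vstd_ik: float, state: SelectionState, cap_ratio: float = 10.0):
    """Adaptive Vstd threshold.

    With m = running minimum and M* = min(running maximum, cap_ratio * m):

        TH = 2 m + (M* - m) (M* - vstd_ik) / (M* - 2 m)

    Values of Vstd near the running minimum push the threshold up toward the
    maximum (selection rarely engages), values near the maximum pull it down
    to 2 m (selection engages).  When M* <= 2 m the geometry degenerates and
    the threshold is +inf (accept all), flagged in the second return value.

    Returns
    -------
    (threshold, degenerate_flag)
    """
    if state.n_updates < 1:
        raise ValueError("selection state has no prior Vstd update")
    m = max(state.vstd_min, VSTD_EPS)
    m_star = min(state.vstd_max, cap_ratio * m)
    if m_star <= 2.0 * m:
        return np.inf, True
    return 2.0 * m + (m_star - m) * (m_star - vstd_ik) / (m_star - 2.0 * m), False


def ccc_threshold(ccc_values, tol: float = 0.05) -> float:
    """Adaptive CCC threshold.

    With rho_M the median of the neighbor CCCs and D the median absolute
    deviation |rho_M - rho_j|:

        TH = rho_M - D - tol   if D <= tol   (values all very close: keep all)
        TH = rho_M - D         otherwise

    The deviation is taken in absolute value: the signed median deviation is
    ~0 for any near-symmetric set, which would make the second branch
    unreachable.
    """
    v = np.asarray(ccc_values, dtype=float)
    if v.size < 1:
        raise ValueError("ccc_threshold needs at least one neighbor value")
    rho_m = float(np.median(v))
    dev = float(np.median(np.abs(rho_m - v)))
    if dev <= tol:
        return rho_m - dev - tol
    return rho_m - dev


def select_neighbors(
    sample_values,
    ccc_values,
    state: SelectionState,
    cap_ratio: float = 10.0,
    ccc_tol: float = 0.05,
    target: int = 0,
) -> SelectionResult:
    """Per-sample neighbor admission decision.

    Parameters
    ----------
    sample_values
        Instantaneous amplitudes of the candidate set, target first by
        default (``target`` gives its index).  Neighbor j of ``ccc_values``
        corresponds to ``sample_values[j + 1]`` when target is 0.
    ccc_values
        Sliding-window CCC of each neighbor with the target.
    state
        Running Vstd extremes; updated in place (update precedes the
        threshold evaluation, so the current sample is included).

    Returns a :class:`SelectionResult` whose ``selected`` holds neighbor
    indices (0-based positions within ``ccc_values``).
    """
    ccc_values = np.asarray(ccc_values, dtype=float)
    v = vstd(sample_values, target)
    state.update(v)
    th, degen = vstd_threshold(v, state, cap_ratio)
    n_nb = ccc_values.size
    if v < th:
        return SelectionResult(
            selected=list(range(n_nb)),
            vstd_ik=v,
            vstd_th=th,
            ccc_values=ccc_values,
            ccc_th=None,
            all_pass=True,
            degenerate_threshold=degen,
        )
    cth = ccc_threshold(ccc_values, ccc_tol)
    keep = [j for j in range(n_nb) if ccc_values[j] > cth]
    fallback = False
    if not keep:
        # target-only transient: keep the single most similar neighbor so the
        # output never divides by zero and stays referenced
        keep = [int(np.argmax(ccc_values))]
        fallback = True
    return SelectionResult(
        selected=keep,
        vstd_ik=v,
        vstd_th=th,
        ccc_values=ccc_values,
        ccc_th=cth,
        all_pass=False,
        fallback=fallback,
    )
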