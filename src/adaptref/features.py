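"""Per-window feature bank for movement-planning decoding.

Twelve features per channel, computed on sliding 250 ms windows of the
spatially filtered (reference-free) EEG:

======  =======================================================================
RF      mean filtered amplitude over the window (microvolts)
MAV     mean absolute value
WL      waveform length, sum of successive absolute differences
FDH     Higuchi fractal dimension (kmax configurable, default 8)
FDSH    mean of the Sevcik and Higuchi fractal-dimension estimates
BP_*    band power in 0.1-4, 8-12, 13-17, 18-24, 26-30, 30-50, 50-70 Hz
======  =======================================================================

Band power is FFT power mass over half-open bands [lo, hi); windows are
zero-padded to 1 Hz bin spacing so the 0.1-4 Hz band resolves at 250 ms
windows (resolution-limited; see the methods note).  Fractal dimensions are
scale-invariant; MAV and WL scale linearly with amplitude and BP
quadratically.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "BANDS",
    "FEATURE_NAMES",
    "higuchi_fd",
    "sevcik_fd",
    "band_power",
    "extract_features",
    "sliding_features",
]

BANDS: tuple[tuple[float, float], ...] = (
    (0.1, 4.0), (8.0, 12.0), (13.0, 17.0), (18.0, 24.0),
    (26.0, 30.0), (30.0, 50.0), (50.0, 70.0),
)

FEATURE_NAMES: tuple[str, ...] = (
    "RF", "MAV", "WL", "FDH", "FDSH",
    *[f"BP_{lo:g}-{hi:g}" for lo, hi in BANDS],
)


def higuchi_fd(x, kmax: int = 8) -> float:
    """Higuchi fractal dimension.

    Slope of log mean curve length L(k) against log(1/k) for lag k = 1..kmax,
    by least squares.  Near 1 for smooth curves, near 2 for white noise.
    """
    x = np.asarray(x, dtype=float)
    N = x.size
    if N < 2 * kmax:
        raise ValueError(f"window of {N} samples too short for kmax={kmax}")
    lk = np.empty(kmax)
    for k in range(1, kmax + 1):
        lengths = []
        for m in range(k):
            idx = np.arange(m, N, k)
            if idx.size < 2:
                continue
            dist = np.abs(np.diff(x[idx])).sum()
            # normalization maps the subsampled length back to the full scale
            lengths.append(dist * (N - 1) / ((idx.size - 1) * k))
        lk[k - 1] = np.mean(lengths) / k
    logs = np.log(np.maximum(lk, 1e-300))
    logk = np.log(1.0 / np.arange(1, kmax + 1))
    slope = np.polyfit(logk, logs, 1)[0]
    return float(slope)


def sevcik_fd(x) -> float:
    """Sevcik fractal dimension.

    Abscissa normalized to [0, 1], amplitude normalized to [0, 1]; with L the
    length of the normalized path,

        D = 1 + ln(L) / ln(2 (N - 1)).

    A constant window returns 1 (a flat curve has no roughness).  The
    estimate converges to 1 on straight lines only slowly (~1.05 at N = 1000).
    """
    x = np.asarray(x, dtype=float)
    N = x.size
    if N < 2:
        raise ValueError("window must hold at least 2 samples")
    rng = x.max() - x.min()
    if rng == 0:
        return 1.0
    y = (x - x.min()) / rng
    dx = 1.0 / (N - 1)
    L = float(np.sum(np.hypot(dx, np.diff(y))))
    return float(1.0 + np.log(L) / np.log(2.0 * (N - 1)))


def band_power(x, fs: float, band, pad_to_hz: float = 1.0) -> float:
    """FFT power mass of ``x`` in the half-open band [lo, hi) Hz.

    The window is zero-padded so the bin spacing is at most ``pad_to_hz``.
    Normalized such that the sum over non-overlapping bands covering
    [0, fs/2] equals the mean signal power (Parseval).
    """
    lo, hi = band
    if not 0 <= lo < hi:
        raise ValueError(f"invalid band {band}")
    if hi > fs / 2:
        raise ValueError(f"band {band} exceeds the Nyquist frequency {fs / 2}")
    x = np.asarray(x, dtype=float)
    n = x.size
    n_fft = max(n, int(np.ceil(fs / pad_to_hz)))
    X = np.fft.rfft(x, n_fft)
    freqs = np.fft.rfftfreq(n_fft, 1.0 / fs)
    p = np.abs(X) ** 2
    scale = np.full(p.size, 2.0)
    scale[0] = 1.0
    if n_fft % 2 == 0:
        scale[-1] = 1.0
    sel = (freqs >= lo) & (freqs < hi)
    return float(np.sum(scale[sel] * p[sel]) / (n_fft * n))


def extract_features(
    window: np.ndarray, fs: float, channels: list[str], kmax: int = 8,
    rf: str = "mean",
) -> dict[tuple[str, str], float]:
    """Full 12-feature bank on one multichannel window.

    Parameters
    ----------
    window
        Array (channels, n_samples); for a 250 ms window n = round(0.25 fs).
    rf
        Definition of the RF feature: ``"mean"`` (default) or ``"last"``
        (amplitude of the final sample).

    Returns
    -------
    dict keyed by (channel, feature name); 12 x len(channels) entries.
    """
    window = np.atleast_2d(np.asarray(window, dtype=float))
    if window.shape[0] != len(channels):
        raise ValueError("window rows do not match the channel list")
    out: dict[tuple[str, str], float] = {}
    for ci, ch in enumerate(channels):
        x = window[ci]
        fdh = higuchi_fd(x, kmax)
        fds = sevcik_fd(x)
        out[(ch, "RF")] = float(x.mean()) if rf == "mean" else float(x[-1])
        out[(ch, "MAV")] = float(np.abs(x).mean())
        out[(ch, "WL")] = float(np.abs(np.diff(x)).sum())
        out[(ch, "FDH")] = fdh
        out[(ch, "FDSH")] = 0.5 * (fdh + fds)
        for band, name in zip(BANDS, FEATURE_NAMES[5:]):
            out[(ch, name)] = band_power(x, fs, band)
    return out


def sliding_features(
    data: np.ndarray,
    fs: float,
    channels: list[str],
    window_ms: float = 250.0,
    stride: int = 1,
    kmax: int = 8,
    rf: str = "mean",
):
    """Feature matrix over sliding windows of a (channels, T) record.

    Window w ends at sample ``(w * stride) + n - 1``; at stride 1 a T-sample
    record yields T - n + 1 rows.  Returns a pandas DataFrame whose columns
    are ``"<channel>:<feature>"`` plus an ``end_sample`` index column.
    """
    import pandas as pd

    data = np.atleast_2d(np.asarray(data, dtype=float))
    n = int(round(window_ms * fs / 1000.0))
    T = data.shape[1]
    if T < n:
        raise ValueError(f"record of {T} samples shorter than the {n}-sample window")
    rows = []
    ends = []
    for start in range(0, T - n + 1, stride):
        feats = extract_features(data[:, start : start + n], fs, channels, kmax, rf)
        rows.append({f"{ch}:{name}": v for (ch, name), v in feats.items()})
        ends.append(start + n - 1)
    df = pd.DataFrame(rows)
    df.insert(0, "end_sample", ends)
    return df
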