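"""Multiple-origin mean-square-displacement curves.

The FFT route computes, for every lag tau, exactly the average over all time
origins t of |r(t+tau) - r(t)|^2 (the classic S1 - 2*S2 split), summed over
dimensions and averaged over particles — identical to the direct double loop
but O(T log T).
"""

from __future__ import annotations

import numpy as np

from .errors import GeometryError

__all__ = ["msd_curve", "fit_diffusion"]


def _autocorr_fft(x: np.ndarray) -> np.ndarray:
    """Per-column autocorrelation sum_t x[t] x[t+tau] (no normalization)."""
    t = x.shape[0]
    n = 1 << (2 * t - 1).bit_length()
    f = np.fft.rfft(x, n=n, axis=0)
    return np.fft.irfft(f * np.conj(f), n=n, axis=0)[:t].real


def msd_curve(positions: np.ndarray) -> np.ndarray:
    """MSD(tau) for tau = 0..T-1 from positions of shape (T, N, d).

    Averaged over all origins and all N particles; summed over the d spatial
    dimensions.
    """
    pos = np.asarray(positions, dtype=float)
    if pos.ndim == 2:
        pos = pos[:, None, :]
    t, n, d = pos.shape
    sq = np.square(pos).sum(axis=2)  # (T, N)
    acf = _autocorr_fft(pos.reshape(t, n * d)).reshape(t, n, d).sum(axis=2)
    s1 = np.empty_like(sq)
    running = 2.0 * sq.sum(axis=0)
    for tau in range(t):
        if tau > 0:
            running = running - sq[tau - 1] - sq[t - tau]
        s1[tau] = running
    counts = (t - np.arange(t))[:, None]
    msd = (s1 - 2.0 * acf) / counts
    msd[0] = 0.0
    return msd.mean(axis=1)


def check_unwrapped(positions: np.ndarray, box: np.ndarray) -> None:
    """Reject wrapped trajectories: any per-step jump beyond L/2 in a used dim."""
    pos = np.asarray(positions, dtype=float)
    if pos.shape[0] < 2:
        return
    steps = np.abs(np.diff(pos, axis=0))
    half = np.asarray(box, dtype=float)[: pos.shape[-1]] / 2.0
    if np.any(steps > half):
        raise GeometryError(
            "per-step displacement exceeds half a box length: coordinates look "
            "wrapped; unwrap the trajectory before estimating diffusion"
        )


def fit_diffusion(
    lags_ps: np.ndarray,
    msd: np.ndarray,
    n_dim: int,
    fit_window: tuple[float, float] = (0.1, 0.5),
) -> tuple[float, float, slice]:
    """Least-squares slope of MSD over lag fractions -> (D, SE(D), window).

    D = slope / (2 * n_dim) in nm^2/ps when lags are in ps and MSD in nm^2.
    """
    n = len(lags_ps)
    lo = max(int(np.floor(fit_window[0] * n)), 1)
    hi = max(int(np.ceil(fit_window[1] * n)), lo + 2)
    hi = min(hi, n)
    window = slice(lo, hi)
    x = lags_ps[window]
    y = msd[window]
    a = np.vstack([x, np.ones_like(x)]).T
    coef, res, *_ = np.linalg.lstsq(a, y, rcond=None)
    slope = coef[0]
    dof = max(len(x) - 2, 1)
    ssr = float(res[0]) if len(res) else float(np.sum((y - a @ coef) ** 2))
    var_slope = ssr / dof / float(np.sum((x - x.mean()) ** 2))
    d = slope / (2.0 * n_dim)
    d_se = np.sqrt(var_slope) / (2.0 * n_dim)
    return float(d), float(d_se), window
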