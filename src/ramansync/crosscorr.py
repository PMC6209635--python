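"""Normalized cross-correlation and integer lag estimation.

The similarity of two equal-length signals ``r`` (reference) and ``s``
(query) as a function of the integer lag ``j`` is

    c(j) = sum_i (r(i) - rbar)(s(i+j) - sbar)
           / sqrt( sum_i (r(i) - rbar)^2 * sum_i (s(i+j) - sbar)^2 )

where the sums run over the indices at which both signals are defined (the
overlap) and the means/norms are taken over that same overlap, so that
``c(j)`` is a true Pearson coefficient at every lag. ``c`` is maximized at
the lag that best aligns the two signals.

Sign convention: a positive lag means the query is displaced toward HIGHER
index relative to the reference; applying a correction of ``-lag`` aligns
it. This convention is used everywhere in the package.

``xcorr_direct`` is the slow reference implementation; ``xcorr_fft``
computes the identical quantity through frequency-domain convolution of the
products plus running prefix sums for the per-lag means and norms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import correlate

__all__ = [
    "CrossCorrelation",
    "xcorr_direct",
    "xcorr_fft",
    "best_lag",
    "n_tied",
    "estimate_lag",
]

# overlaps with variance below this (absolute, after mean removal) are
# treated as constant: c(j) := 0 there, identically in both routes
_VAR_FLOOR = 1e-30


@dataclass(frozen=True)
class CrossCorrelation:
    """Cross-correlation values over a symmetric range of integer lags."""

    lags: np.ndarray  # integer offsets, -max_lag..+max_lag
    values: np.ndarray  # c(j) per lag, in [-1, 1]
    best_lag: int
    best_value: float


def _validate(ref: np.ndarray, qry: np.ndarray, max_lag: int) -> tuple[np.ndarray, np.ndarray]:
    ref = np.asarray(ref, dtype=float)
    qry = np.asarray(qry, dtype=float)
    if ref.ndim != 1 or qry.ndim != 1:
        raise ValueError("inputs must be 1-D vectors")
    if ref.size != qry.size:
        raise ValueError(f"length mismatch: {ref.size} vs {qry.size}")
    if ref.size < 2:
        raise ValueError("need at least 2 points")
    if not (1 <= max_lag <= ref.size - 1):
        raise ValueError(f"max_lag must be in [1, {ref.size - 1}], got {max_lag}")
    if np.ptp(ref) == 0 or np.ptp(qry) == 0:
        raise ValueError("constant input has no defined correlation")
    return ref, qry


def _finish(lags: np.ndarray, values: np.ndarray) -> CrossCorrelation:
    values = np.clip(values, -1.0, 1.0)
    best = int(np.argmax(values))
    return CrossCorrelation(lags, values, int(lags[best]), float(values[best]))


def xcorr_direct(ref: np.ndarray, qry: np.ndarray, max_lag: int) -> CrossCorrelation:
    """Reference implementation: per-lag Pearson over the overlap."""
    ref, qry = _validate(ref, qry, max_lag)
    lags = np.arange(-max_lag, max_lag + 1)
    values = np.empty(lags.size)
    n = ref.size
    for k, j in enumerate(lags):
        if j >= 0:
            a, b = ref[: n - j], qry[j:]
        else:
            a, b = ref[-j:], qry[: n + j]
        a = a - a.mean()
        b = b - b.mean()
        va, vb = a @ a, b @ b
        values[k] = 0.0 if va < _VAR_FLOOR or vb < _VAR_FLOOR else a @ b / np.sqrt(va * vb)
    return _finish(lags, values)


def xcorr_fft(ref: np.ndarray, qry: np.ndarray, max_lag: int) -> CrossCorrelation:
    """FFT-accelerated computation of the identical quantity.

    The raw product sums ``sum_i r(i) s(i+j)`` over all lags come from one
    frequency-domain correlation; the per-lag overlap means and norms come
    from prefix sums, giving the Pearson coefficient at every lag in
    O(L log L) instead of O(L * max_lag).
    """
    ref, qry = _validate(ref, qry, max_lag)
    n = ref.size
    lags = np.arange(-max_lag, max_lag + 1)

    # full[n-1+j] = sum_i ref[i] * qry[i+j]
    full = correlate(qry, ref, mode="full", method="fft")
    s_rq = full[n - 1 + lags]

    pr = np.concatenate(([0.0], np.cumsum(ref)))
    pq = np.concatenate(([0.0], np.cumsum(qry)))
    pr2 = np.concatenate(([0.0], np.cumsum(ref * ref)))
    pq2 = np.concatenate(([0.0], np.cumsum(qry * qry)))

    n_ov = n - np.abs(lags)
    pos = lags >= 0
    # overlap of ref: [0, n-j) for j>=0, [-j, n) for j<0; of qry the mirror
    s_r = np.where(pos, pr[n_ov], pr[n] - pr[n - n_ov])
    s_r2 = np.where(pos, pr2[n_ov], pr2[n] - pr2[n - n_ov])
    s_q = np.where(pos, pq[n] - pq[n - n_ov], pq[n_ov])
    s_q2 = np.where(pos, pq2[n] - pq2[n - n_ov], pq2[n_ov])

    num = s_rq - s_r * s_q / n_ov
    v_r = s_r2 - s_r * s_r / n_ov
    v_q = s_q2 - s_q * s_q / n_ov
    ok = (v_r >= _VAR_FLOOR) & (v_q >= _VAR_FLOOR)
    values = np.zeros(lags.size)
    values[ok] = num[ok] / np.sqrt(v_r[ok] * v_q[ok])
    return _finish(lags, values)


#: lags whose values agree within this are considered tied; matches the
#: guaranteed FFT/direct agreement scale
TIE_TOL = 1e-9


def best_lag(cc: CrossCorrelation, tie_tol: float = TIE_TOL) -> int:
    """Lag maximizing ``cc``; near-exact ties (within ``tie_tol``) break
    toward the smallest absolute lag (preferring "no shift"), then toward
    the negative lag."""
    top = cc.values.max()
    cand = cc.lags[cc.values >= top - tie_tol]
    order = np.lexsort((cand, np.abs(cand)))
    return int(cand[order[0]])


def n_tied(cc: CrossCorrelation, tie_tol: float = TIE_TOL) -> int:
    """Number of lags tied (within ``tie_tol``) with the maximum."""
    return int(np.sum(cc.values >= cc.values.max() - tie_tol))


def estimate_lag(
    ref: np.ndarray, qry: np.ndarray, max_lag: int, *, tie_tol: float = TIE_TOL
) -> int:
    """Integer displacement of ``qry`` relative to ``ref`` (FFT route)."""
    return best_lag(xcorr_fft(ref, qry, max_lag), tie_tol)
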