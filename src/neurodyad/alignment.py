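"""Within-infant alignment of the four iterations of an action via
normalized cross-correlation of the alpha-band GFP, followed by response-
window extraction and iteration averaging.

Lag convention: ``lag_k`` is the time offset of iteration *k*'s content
relative to the reference iteration — positive when the response occurs
later.  The response window for iteration *k* is therefore
``[delay + lag_k, delay + lag_k + length)`` within its 10-s epoch.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

DEFAULT_MAX_LAG_MS = 2000.0
DEFAULT_DELAY_MS = 2000.0
DEFAULT_WINDOW_MS = 5000.0
GFP_SMOOTH_MS = 150.0  # moving-average width for the rectification ripple


class AlignmentError(RuntimeError):
    pass


class ActionDropped(AlignmentError):
    """Fewer than 2 usable iterations for an action."""


@dataclass
class AlignedAction:
    action_id: int
    lags_ms: dict[int, float]          # iteration -> lag (reference has 0)
    mean_left: float
    mean_right: float
    n_iterations_used: int


def _normalized(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=np.float64)
    x = x - x.mean()
    sd = x.std()
    return x / sd if sd > 0 else x


def _smooth(x: np.ndarray, width: int) -> np.ndarray:
    if width <= 1:
        return x
    kernel = np.ones(width) / width
    return np.convolve(x, kernel, mode="same")


def cross_correlation_lag(ref: np.ndarray, other: np.ndarray, max_lag: int) -> int:
    """Integer-sample lag of ``other`` relative to ``ref`` maximizing the
    Pearson correlation over the overlapping segments, searched over
    ``[-max_lag, +max_lag]``; ties break toward the smallest ``|lag|``.

    Positive lag means ``other``'s content occurs later than ``ref``'s.
    Normalizing per overlap (rather than dividing the raw product sum by the
    overlap length) avoids the outward bias a shrinking overlap induces on
    hump-shaped series.
    """
    a = np.asarray(ref, dtype=np.float64)
    b = np.asarray(other, dtype=np.float64)
    n, m = len(a), len(b)
    if n < 2 or m < 2:
        raise AlignmentError("series too short to correlate")
    max_lag = int(min(max_lag, m - 2, n - 2))

    # For lag l, the overlap pairs a[t] with b[t + l].  All per-overlap sums
    # come from cumulative sums; the cross term from np.correlate.
    full = np.correlate(b, a, mode="full")  # index k <-> l = k - (n - 1)
    lags = np.arange(-(n - 1), m)
    ca = np.concatenate([[0.0], np.cumsum(a)])
    caa = np.concatenate([[0.0], np.cumsum(a * a)])
    cb = np.concatenate([[0.0], np.cumsum(b)])
    cbb = np.concatenate([[0.0], np.cumsum(b * b)])

    keep = np.abs(lags) <= max_lag
    lags, s_ab = lags[keep], full[keep]

    # overlap in a-index space: t in [max(0, -l), min(n, m - l))
    lo = np.maximum(0, -lags)
    hi = np.minimum(n, m - lags)
    cnt = (hi - lo).astype(np.float64)
    s_a = ca[hi] - ca[lo]
    s_aa = caa[hi] - caa[lo]
    s_b = cb[hi + lags] - cb[lo + lags]
    s_bb = cbb[hi + lags] - cbb[lo + lags]

    var_a = s_aa - s_a * s_a / cnt
    var_b = s_bb - s_b * s_b / cnt
    cov = s_ab - s_a * s_b / cnt
    with np.errstate(invalid="ignore", divide="ignore"):
        score = cov / np.sqrt(var_a * var_b)
    score[~np.isfinite(score)] = -np.inf
    # stable smallest-|lag| tie-break: sort candidates by (-score, |lag|)
    order = np.lexsort((np.abs(lags), -score))
    return int(lags[order[0]])


def align_iterations(
    gfps: dict[int, np.ndarray],
    sample_rate: float,
    max_lag_ms: float = DEFAULT_MAX_LAG_MS,
    smooth_ms: float = GFP_SMOOTH_MS,
) -> dict[int, float]:
    """Lag (ms) per iteration against the first usable iteration.

    The GFP of a narrow-band signal carries a rectification ripple at twice
    the carrier frequency; a short moving average (``smooth_ms``) removes it
    so the correlation peak tracks the response envelope, not the carrier
    cycle.  Set ``smooth_ms=0`` to correlate the raw GFP.
    """
    if len(gfps) < 2:
        raise ActionDropped(f"only {len(gfps)} usable iteration(s); need >= 2")
    max_lag = int(round(max_lag_ms / 1000.0 * sample_rate))
    width = int(round(smooth_ms / 1000.0 * sample_rate))
    iters = sorted(gfps)
    prepared = {k: _smooth(np.asarray(gfps[k], dtype=np.float64), width) for k in iters}
    ref = iters[0]
    lags = {ref: 0.0}
    for k in iters[1:]:
        lag = cross_correlation_lag(prepared[ref], prepared[k], max_lag)
        lags[k] = lag * 1000.0 / sample_rate
    return lags


def extract_window(
    env,
    lag_ms: float,
    delay_ms: float = DEFAULT_DELAY_MS,
    length_ms: float = DEFAULT_WINDOW_MS,
    edge_trim: float = 0.05,
    max_window_masked: float = 0.5,
) -> tuple[float, float]:
    """Mean left/right envelope over ``[delay + lag, delay + lag + length)``,
    clamped into the epoch; masked samples and Hilbert edge samples excluded.

    Raises :class:`AlignmentError` if more than ``max_window_masked`` of the
    window is masked.
    """
    rate = env.sample_rate
    n = len(env.left)
    start = int(round((delay_ms + lag_ms) / 1000.0 * rate))
    length = int(round(length_ms / 1000.0 * rate))
    start = min(max(start, 0), max(n - length, 0))  # clamp, preserving length
    stop = min(start + length, n)

    valid = ~env.mask.copy()
    trim = edge_trim_samples(n, edge_trim)
    if trim:
        valid[:trim] = False
        valid[-trim:] = False
    sel = np.zeros(n, dtype=bool)
    sel[start:stop] = True
    window_mask_frac = float(env.mask[start:stop].mean()) if stop > start else 1.0
    if window_mask_frac > max_window_masked:
        raise AlignmentError(
            f"{window_mask_frac:.2f} of the response window is masked"
        )
    use = sel & valid
    if not use.any():
        raise AlignmentError("no usable samples in the response window")
    return float(env.left[use].mean()), float(env.right[use].mean())


def edge_trim_samples(n: int, fraction: float) -> int:
    return int(round(n * fraction))


def average_action(
    action_id: int,
    windows: dict[int, tuple[float, float]],
    lags_ms: dict[int, float],
) -> AlignedAction:
    """Unweighted mean of per-iteration window means; needs >= 2 iterations."""
    if len(windows) < 2:
        raise ActionDropped(
            f"action {action_id}: only {len(windows)} usable iteration(s)"
        )
    lefts = [w[0] for w in windows.values()]
    rights = [w[1] for w in windows.values()]
    return AlignedAction(
        action_id=action_id,
        lags_ms={k: lags_ms.get(k, float("nan")) for k in windows},
        mean_left=float(np.mean(lefts)),
        mean_right=float(np.mean(rights)),
        n_iterations_used=len(windows),
    )
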