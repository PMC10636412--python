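"""Frontal asymmetry score: (L - R) / (L + R) on mean alpha-envelope
amplitude, plus action-1 baseline subtraction.

Sign convention: positive = left-lateralized envelope amplitude.  (Under the
common inverse-activity reading of alpha, a positive score would indicate
*right*-hemisphere activation; this package reports the raw index and leaves
interpretation to the caller.)
"""

from __future__ import annotations

import math
from dataclasses import dataclass


class FASError(ValueError):
    pass


@dataclass
class FASRecord:
    """Per-infant asymmetry: raw values for actions 1-4 and deltas 2-4."""

    infant_id: str
    raw_fas: dict[int, float]      # action -> FAS, absent if not computable
    delta_fas: dict[int, float]    # action (2-4) -> FAS - FAS(action 1)
    n_iterations_used: dict[int, int] | None = None
    baseline_missing: bool = False


def compute_fas(mean_left: float, mean_right: float) -> float:
    """(L - R) / (L + R) for non-negative cluster amplitudes; bounded in
    [-1, 1], zero when L == R, positive when L > R."""
    if mean_left < 0 or mean_right < 0:
        raise FASError("cluster envelope means must be non-negative")
    total = mean_left + mean_right
    if total == 0:
        raise FASError("both cluster means are zero; FAS undefined")
    return (mean_left - mean_right) / total


def baseline_subtract(raw_fas: dict[int, float]) -> tuple[dict[int, float], bool]:
    """FAS(a) - FAS(1) for a in {2, 3, 4}.  Missing actions propagate; a
    missing action-1 baseline empties the deltas and sets the flag."""
    if 1 not in raw_fas or raw_fas[1] is None or math.isnan(raw_fas[1]):
        return {}, True
    base = raw_fas[1]
    deltas = {
        a: raw_fas[a] - base
        for a in (2, 3, 4)
        if a in raw_fas and raw_fas[a] is not None and not math.isnan(raw_fas[a])
    }
    return deltas, False


def build_record(
    infant_id: str,
    raw_fas: dict[int, float],
    n_iterations_used: dict[int, int] | None = None,
) -> FASRecord:
    deltas, missing = baseline_subtract(raw_fas)
    return FASRecord(
        infant_id=infant_id,
        raw_fas=dict(raw_fas),
        delta_fas=deltas,
        n_iterations_used=n_iterations_used,
        baseline_missing=missing,
    )


def log_ratio_asymmetry(mean_left: float, mean_right: float) -> float:
    """Documented utility: ln(L) - ln(R).  Not used by the main pipeline."""
    if mean_left <= 0 or mean_right <= 0:
        raise FASError("log-ratio asymmetry needs strictly positive means")
    return math.log(mean_left) - math.log(mean_right)
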