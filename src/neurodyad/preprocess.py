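"""Preprocessing chain: notch, order-1 Butterworth bandpass, bad-channel
policy, average re-reference, epoch segmentation, amplitude-artifact masking.

All filters are applied forward-backward (zero phase): phase distortion ahead
of Hilbert-envelope extraction would bias the cross-correlation alignment.
The effective magnitude response is therefore the squared one-pass response.

Fixed stage order: notch -> bandpass -> bad-channel detection ->
interpolation -> average reference -> segmentation -> amplitude elimination.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .io import EEGRecording, EventSchedule, ACTION_DURATION_MS
from .montage import Montage

AMPLITUDE_THRESHOLD_UV = 120.0
MAX_BAD_CHANNELS = 35
MASK_PAD_MS = 100.0
MAX_MASKED_FRACTION = 0.5
FLAT_SD_UV = 0.1
EXTREME_FRACTION = 0.2


class PreprocessError(RuntimeError):
    pass


class SegmentExclusion(PreprocessError):
    """Raised when a recording fails the bad-channel ceiling (> max_bad)."""


@dataclass
class ActionEpoch:
    """One 10-s action segment with a per-sample artifact mask."""

    data: np.ndarray  # channels x samples, uV
    sample_rate: float
    channel_labels: list[str]
    action_id: int
    iteration: int
    run: int
    trial: int
    usable: bool = True
    unusable_reason: str = ""
    mask: np.ndarray = field(default=None, repr=False)  # True = rejected sample

    def __post_init__(self) -> None:
        if self.mask is None:
            self.mask = np.zeros(self.data.shape[1], dtype=bool)

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def masked_fraction(self) -> float:
        return float(self.mask.mean()) if self.mask.size else 0.0

    def channel(self, label: str) -> np.ndarray:
        return self.data[self.channel_labels.index(label)]


def _filtfilt(rec: EEGRecording, b: np.ndarray, a: np.ndarray) -> EEGRecording:
    out = signal.filtfilt(b, a, rec.data, axis=1)
    return rec.copy_with(data=out)


def notch_filter(rec: EEGRecording, freq: float = 60.0, quality: float = 30.0) -> EEGRecording:
    """IIR notch at ``freq`` (zero-phase)."""
    if rec.sample_rate <= 2 * freq:
        raise PreprocessError(
            f"sample rate {rec.sample_rate} Hz too low for a {freq} Hz notch"
        )
    b, a = signal.iirnotch(freq, quality, fs=rec.sample_rate)
    return _filtfilt(rec, b, a)


def bandpass_filter(
    rec: EEGRecording, low: float = 0.3, high: float = 40.0, order: int = 1
) -> EEGRecording:
    """Butterworth bandpass of the stated order, zero-phase."""
    nyq = rec.sample_rate / 2.0
    if not 0 < low < high < nyq:
        raise PreprocessError(f"invalid band [{low}, {high}] at rate {rec.sample_rate}")
    b, a = signal.butter(order, [low, high], btype="bandpass", fs=rec.sample_rate)
    return _filtfilt(rec, b, a)


def detect_bad_channels(
    rec: EEGRecording,
    flat_sd: float = FLAT_SD_UV,
    amp_threshold: float = AMPLITUDE_THRESHOLD_UV,
    extreme_fraction: float = EXTREME_FRACTION,
) -> set[str]:
    """Channels that are flat (SD < flat_sd) or extreme (|x| > threshold for
    more than ``extreme_fraction`` of samples)."""
    sd = rec.data.std(axis=1)
    frac = (np.abs(rec.data) > amp_threshold).mean(axis=1)
    bad = (sd < flat_sd) | (frac > extreme_fraction)
    return {rec.channel_labels[i] for i in np.flatnonzero(bad)}


def interpolate_channels(
    rec: EEGRecording, bad: set[str], montage: Montage, max_bad: int = MAX_BAD_CHANNELS
) -> EEGRecording:
    """Replace each bad channel by the unweighted mean of its good montage
    neighbors.  More than ``max_bad`` bad channels is a segment-exclusion
    condition, not an interpolation problem."""
    if len(bad) > max_bad:
        raise SegmentExclusion(
            f"{len(bad)} unusable channels exceeds the {max_bad}-electrode ceiling"
        )
    if not bad:
        return rec.copy_with()
    out = rec.data.copy()
    interpolated = set()
    for label in sorted(bad):
        nbrs = [n for n in montage.neighbors(label) if n not in bad and n in rec.channel_labels]
        if not nbrs:
            continue  # no clean neighbor; stays flagged
        idx = [rec.channel_index(n) for n in nbrs]
        out[rec.channel_index(label)] = rec.data[idx].mean(axis=0)
        interpolated.add(label)
    remaining = set(bad) - interpolated
    return rec.copy_with(data=out, bad_channels=remaining)


def rereference_average(rec: EEGRecording) -> EEGRecording:
    """Subtract the per-sample mean over good channels; idempotent."""
    good = [i for i, l in enumerate(rec.channel_labels) if l not in rec.bad_channels]
    if not good:
        raise PreprocessError("no good channels to build an average reference")
    mean = rec.data[good].mean(axis=0, keepdims=True)
    return rec.copy_with(data=rec.data - mean, reference="average")


def segment_epochs(rec: EEGRecording, sched: EventSchedule) -> list[ActionEpoch]:
    """Cut one half-open [onset, onset + 10 s) epoch per event.  Events whose
    window runs past end-of-recording yield unusable epochs."""
    dur = int(round(ACTION_DURATION_MS / 1000.0 * rec.sample_rate))
    epochs = []
    for ev in sched:
        stop = ev.onset_sample + dur
        truncated = stop > rec.n_samples
        seg = rec.data[:, ev.onset_sample : min(stop, rec.n_samples)]
        if truncated:
            seg = np.pad(seg, ((0, 0), (0, stop - rec.n_samples)))
        epochs.append(
            ActionEpoch(
                data=seg.copy(),
                sample_rate=rec.sample_rate,
                channel_labels=list(rec.channel_labels),
                action_id=ev.action_id,
                iteration=ev.iteration,
                run=ev.run,
                trial=ev.trial,
                usable=not truncated,
                unusable_reason="truncated" if truncated else "",
            )
        )
    return epochs


def eliminate_amplitude_artifacts(
    epoch: ActionEpoch,
    threshold: float = AMPLITUDE_THRESHOLD_UV,
    scope_labels: list[str] | None = None,
    pad_ms: float = MASK_PAD_MS,
    max_masked: float = MAX_MASKED_FRACTION,
) -> ActionEpoch:
    """Mask samples where any in-scope channel exceeds |threshold|, extending
    each excursion by ``pad_ms`` on both sides.  An epoch more than
    ``max_masked`` masked becomes unusable.

    ``scope_labels`` restricts the check (e.g. to the analysis clusters);
    ``None`` checks every channel.
    """
    if scope_labels is None:
        scoped = epoch.data
    else:
        idx = [epoch.channel_labels.index(l) for l in scope_labels]
        scoped = epoch.data[idx]
    hot = (np.abs(scoped) > threshold).any(axis=0)
    pad = int(round(pad_ms / 1000.0 * epoch.sample_rate))
    if pad > 0 and hot.any():
        hot = np.convolve(hot.astype(int), np.ones(2 * pad + 1, dtype=int), mode="same") > 0
    epoch.mask = epoch.mask | hot
    if epoch.masked_fraction > max_masked:
        epoch.usable = False
        epoch.unusable_reason = epoch.unusable_reason or (
            f"masked_fraction {epoch.masked_fraction:.2f} > {max_masked}"
        )
    return epoch


def preprocess_recording(
    rec: EEGRecording,
    montage: Montage,
    notch_freq: float = 60.0,
    band: tuple[float, float] = (0.3, 40.0),
    band_order: int = 1,
    max_bad: int = MAX_BAD_CHANNELS,
) -> tuple[EEGRecording, dict]:
    """Run the continuous-recording stages in the fixed order and return the
    cleaned recording plus a stage report (counts for the run log)."""
    rec = notch_filter(rec, notch_freq)
    rec = bandpass_filter(rec, *band, order=band_order)
    bad = detect_bad_channels(rec)
    rec = interpolate_channels(rec, bad, montage, max_bad=max_bad)
    rec = rereference_average(rec)
    report = {
        "n_bad_detected": len(bad),
        "bad_channels": sorted(bad),
        "n_uninterpolated": len(rec.bad_channels),
    }
    return rec, report
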