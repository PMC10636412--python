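"""Synthetic dyad sessions with known ground truth.

Generates the full structured-interaction paradigm: 2 runs x 2 trials x 4
actions (10-s actions, 15-s pauses, 2-min inter-run break), a 128-channel
recording with lateralized alpha bursts, onset jitter, blink-like artifacts
and bad channels, plus behavioral codes and dyad metadata whose trends are
controlled by the same parameters.

Alpha bursts are Hann-windowed sinusoids so the envelope ground truth is
analytic: during action ``a`` the left-cluster burst amplitude is
``burst_amp * (1 + asymmetry)`` and the right ``burst_amp * (1 - asymmetry)``,
which makes the injected asymmetry the exact (noise-free) value of
``(L - R) / (L + R)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import EEGRecording, Event, EventSchedule, ACTION_DURATION_MS
from .montage import Montage, build_grid_montage

ACTION_MS = 10_000
PAUSE_MS = 15_000
INTER_RUN_GAP_MS = 120_000
N_RUNS = 2
N_TRIALS = 2
N_ACTIONS = 4
WECS_DOMAINS = ("facial", "sensitivity", "vocal")


class SimConfigError(ValueError):
    """Invalid simulation parameters."""


@dataclass
class SimParams:
    n_channels: int = 128
    sample_rate: float = 1000.0
    asymmetry_per_action: tuple[float, float, float, float] = (0.0, 0.0, 0.0, 0.0)
    jitter_sd: float = 200.0           # ms
    response_delay_mean: float = 2000.0  # ms
    alpha_freq: float = 7.5            # Hz
    burst_amp: float = 20.0            # uV, pre-asymmetry burst amplitude
    burst_dur_range: tuple[float, float] = (3000.0, 8000.0)  # ms
    noise_sd: float = 5.0              # uV
    artifact_rate: float = 0.0         # events/min, >120 uV deflections
    n_bad_channels: int = 0
    drowsy_iteration_prob: float = 0.0
    wecs_effect: float = 0.0           # latent-scale slope per action index
    irritable: bool = False
    random_phase: bool = True          # randomize burst carrier phase per iteration
    seed: int = 0

    def validate(self) -> None:
        if len(self.asymmetry_per_action) != N_ACTIONS:
            raise SimConfigError("asymmetry_per_action must have exactly 4 entries")
        if any(not -1.0 <= a <= 1.0 for a in self.asymmetry_per_action):
            raise SimConfigError("asymmetry values must lie in [-1, 1]")
        if not self.sample_rate > 80.0:
            raise SimConfigError("sample_rate must exceed 2 x 40 Hz")
        if self.jitter_sd < 0:
            raise SimConfigError("jitter_sd must be >= 0")
        if not 6.0 <= self.alpha_freq <= 9.0:
            raise SimConfigError("alpha_freq must lie in [6, 9] Hz")
        if not 0.0 <= self.drowsy_iteration_prob <= 1.0:
            raise SimConfigError("drowsy_iteration_prob must lie in [0, 1]")
        if self.noise_sd < 0 or self.artifact_rate < 0 or self.n_bad_channels < 0:
            raise SimConfigError("noise_sd, artifact_rate, n_bad_channels must be >= 0")


@dataclass
class GroundTruth:
    """What was injected, for recovery oracles."""

    true_fas_per_action: tuple[float, float, float, float]
    true_lags_ms: np.ndarray = field(repr=False)  # actions x iterations onset delays
    burst_durations_ms: np.ndarray = field(repr=False)
    artifact_times: list[int] = field(default_factory=list)
    bad_channel_labels: set[str] = field(default_factory=set)

    def to_dict(self) -> dict:
        return {
            "true_fas_per_action": list(self.true_fas_per_action),
            "true_lags_ms": self.true_lags_ms.tolist(),
            "burst_durations_ms": self.burst_durations_ms.tolist(),
            "artifact_times": [int(t) for t in self.artifact_times],
            "bad_channel_labels": sorted(self.bad_channel_labels),
        }


def build_schedule(params: SimParams) -> EventSchedule:
    """Paradigm timing: 16 events, 25-s onset spacing within a run, 2-min gap."""
    params.validate()
    rate = params.sample_rate
    ms_to_samp = lambda ms: int(round(ms / 1000.0 * rate))
    events = []
    t_ms = 0.0
    for run in (1, 2):
        for trial in (1, 2):
            for action in range(1, N_ACTIONS + 1):
                iteration = (run - 1) * N_TRIALS + trial
                events.append(Event(ms_to_samp(t_ms), action, iteration, run, trial))
                t_ms += ACTION_MS + PAUSE_MS
        t_ms += INTER_RUN_GAP_MS
    return EventSchedule(events, sample_rate=rate)


def session_length_samples(params: SimParams) -> int:
    sched = build_schedule(params)
    last = sched.events[-1].onset_sample
    return last + int(round((ACTION_MS + PAUSE_MS) / 1000.0 * params.sample_rate))


def generate_session(
    params: SimParams, montage: Montage | None = None
) -> tuple[EEGRecording, EventSchedule, GroundTruth]:
    """Simulate one infant's recording plus the schedule and ground truth."""
    params.validate()
    if montage is None:
        montage = build_grid_montage()
    if params.n_channels != montage.n_channels:
        raise SimConfigError(
            f"params.n_channels={params.n_channels} but montage has {montage.n_channels}"
        )
    rng = np.random.default_rng(params.seed)
    rate = params.sample_rate
    sched = build_schedule(params)
    n_samples = session_length_samples(params)
    labels = list(montage.labels)

    # broadband background: white + one-pole "pink-ish" noise, iid across
    # channels; drawn and filtered in float32 (the recursion is ~50x faster)
    from scipy.signal import lfilter

    white = rng.standard_normal((params.n_channels, n_samples), dtype=np.float32)
    pink = lfilter(
        np.array([1.0], dtype=np.float32),
        np.array([1.0, -0.95], dtype=np.float32),
        rng.standard_normal((params.n_channels, n_samples), dtype=np.float32),
        axis=1,
    )
    pink *= np.float32(1.0 / max(float(pink.std()), 1e-12))
    data = (np.float32(params.noise_sd) * (np.float32(0.7) * white + np.float32(0.3) * pink)).astype(
        np.float64
    )

    left_idx = [labels.index(l) for l in montage.left_cluster]
    right_idx = [labels.index(l) for l in montage.right_cluster]

    true_lags = np.zeros((N_ACTIONS, N_RUNS * N_TRIALS))
    # one burst duration per action, shared by its iterations: iterations are
    # then time-shifted copies, which is what the alignment stage assumes
    action_dur_ms = rng.uniform(*params.burst_dur_range, size=N_ACTIONS)
    burst_durs = np.tile(action_dur_ms[:, None], (1, N_RUNS * N_TRIALS))
    t_axis = np.arange(n_samples) / rate

    for ev in sched:
        a = ev.action_id - 1
        it = ev.iteration - 1
        jitter_ms = rng.normal(0.0, params.jitter_sd) if params.jitter_sd > 0 else 0.0
        delay_ms = params.response_delay_mean + jitter_ms
        true_lags[a, it] = delay_ms
        dur_ms = action_dur_ms[a]

        start = ev.onset_sample + int(round(delay_ms / 1000.0 * rate))
        length = int(round(dur_ms / 1000.0 * rate))
        stop = min(start + length, n_samples)
        if start >= n_samples or stop <= start:
            continue
        seg = np.arange(start, stop)
        envelope = np.hanning(length)[: stop - start]
        phase = rng.uniform(0, 2 * np.pi) if params.random_phase else 0.0
        carrier = np.sin(2 * np.pi * params.alpha_freq * (t_axis[seg] - t_axis[start]) + phase)
        burst = envelope * carrier
        asym = params.asymmetry_per_action[a]
        data[left_idx, start:stop] += params.burst_amp * (1.0 + asym) * burst
        data[right_idx, start:stop] += params.burst_amp * (1.0 - asym) * burst

    # blink-like artifacts: 200-400 ms biphasic deflections, 150-300 uV, on
    # the frontal rows of the grid (which include the analysis clusters, so
    # artifacts are guaranteed to trip the 120 uV rule)
    artifact_times: list[int] = []
    if params.artifact_rate > 0:
        n_art = rng.poisson(params.artifact_rate * n_samples / rate / 60.0)
        frontal_labels = set(montage.left_cluster) | set(montage.right_cluster)
        for lab in list(frontal_labels):
            frontal_labels.update(montage.neighbors(lab))
        frontal = np.array(sorted(labels.index(l) for l in frontal_labels))
        for _ in range(n_art):
            center = int(rng.integers(0, n_samples))
            dur = int(round(rng.uniform(200, 400) / 1000.0 * rate))
            amp = rng.uniform(150, 300) * rng.choice([-1.0, 1.0])
            lo, hi = max(0, center - dur // 2), min(n_samples, center + dur // 2)
            if hi <= lo:
                continue
            tt = np.linspace(0, 2 * np.pi, hi - lo)
            data[np.ix_(frontal, np.arange(lo, hi))] += amp * np.sin(tt)
            artifact_times.append(center)

    bad_labels: set[str] = set()
    if params.n_bad_channels > 0:
        # never corrupt cluster channels: ground-truth asymmetry must survive
        eligible = [i for i in range(params.n_channels) if i not in set(left_idx + right_idx)]
        chosen = rng.choice(eligible, size=params.n_bad_channels, replace=False)
        for i in chosen:
            if rng.random() < 0.5:
                data[i] = 0.0  # flat / disconnected
            else:
                data[i] = rng.choice([-1.0, 1.0]) * 500.0  # railed
            bad_labels.add(labels[i])

    rec = EEGRecording(data, rate, labels, reference="vertex")
    sched = EventSchedule(sched.events, n_samples=n_samples, sample_rate=rate)
    truth = GroundTruth(
        true_fas_per_action=tuple(params.asymmetry_per_action),
        true_lags_ms=true_lags,
        burst_durations_ms=burst_durs,
        artifact_times=sorted(artifact_times),
        bad_channel_labels=bad_labels,
    )
    return rec, sched, truth


# ---------------------------------------------------------------------------
# Behavioral codes


_CUTPOINTS = (-0.6, 0.6)  # latent-normal thresholds separating scores 1|2|3


def generate_wecs(params: SimParams, truth: GroundTruth | None = None) -> dict:
    """Draw per-(action, iteration, domain) scores from an ordered-categorical
    model; the latent mean rises by ``wecs_effect`` per action unless the
    infant is irritable (flat).  Returns the ``behavior`` module's record dict.
    """
    params.validate()
    rng = np.random.default_rng(params.seed + 1_000_003)
    scores: dict[tuple[int, int, str], int] = {}
    state: dict[tuple[int, int], str] = {}
    effect = 0.0 if params.irritable else params.wecs_effect
    for action in range(1, N_ACTIONS + 1):
        for iteration in range(1, N_RUNS * N_TRIALS + 1):
            drowsy = rng.random() < params.drowsy_iteration_prob
            state[(action, iteration)] = "drowsy" if drowsy else "consolable_ok"
            for domain in WECS_DOMAINS:
                latent = effect * (action - 1) + rng.standard_normal()
                score = 1 + int(latent > _CUTPOINTS[0]) + int(latent > _CUTPOINTS[1])
                if drowsy and domain == "sensitivity":
                    score = 0
                scores[(action, iteration, domain)] = score
    return {"scores": scores, "state": state}


def generate_metadata(params: SimParams, infant_id: str = "sim") -> dict:
    """Dyad-level coder/questionnaire inputs consistent with ``irritable``."""
    rng = np.random.default_rng(params.seed + 2_000_003)
    if params.irritable:
        if rng.random() < 0.5:
            consoling, inconsolable = int(rng.integers(2, 5)), False
        else:
            consoling, inconsolable = int(rng.integers(0, 3)), True
    else:
        consoling, inconsolable = int(rng.integers(0, 2)), False
    return {
        "infant_id": infant_id,
        "consoling_events": consoling,
        "ever_inconsolable": inconsolable,
        "mibs": int(rng.integers(0, 5)),
        "epds": int(rng.integers(0, 8)),
    }
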