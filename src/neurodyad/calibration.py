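"""Monte-Carlo validation batches: ground-truth recovery and statistical
calibration.  Shared by the test suite and the acceptance report so both
measure the same quantities the same way.

The recovery batches run the full neural chain on a reduced-size synthetic
montage (48 channels, 250 Hz) to stay within desk-scale runtimes; cluster
geometry and every analysis threshold are identical to the full-size setup.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import behavior as bh
from . import simulate as sim
from . import stats as st
from .montage import Montage, build_grid_montage
from .pipeline import RunConfig, analyze_session

RECOVERY_ASYMMETRY_GRID = (-0.5, -0.3, 0.3, 0.5)
RECOVERY_JITTER_SD_MS = 300.0
RECOVERY_SAMPLE_RATE = 250.0


def small_montage() -> Montage:
    """48-channel grid montage with the standard 7-channel frontal clusters."""
    return build_grid_montage(rows=4, cols=12, name="synthetic-48")


@dataclass
class RecoveryBatch:
    """Pooled ground-truth-vs-recovered quantities over seeds."""

    injected_asymmetry: list[float] = field(default_factory=list)
    recovered_fas: list[float] = field(default_factory=list)
    lag_errors_ms: list[float] = field(default_factory=list)
    n_sessions: int = 0

    @property
    def lag_within_50ms_fraction(self) -> float:
        e = np.asarray(self.lag_errors_ms)
        return float((e <= 50.0).mean())

    @property
    def spearman_rho(self) -> float:
        from scipy.stats import spearmanr

        return float(
            spearmanr(self.injected_asymmetry, self.recovered_fas).statistic
        )

    @property
    def sign_match_fraction(self) -> float:
        inj = np.asarray(self.injected_asymmetry)
        rec = np.asarray(self.recovered_fas)
        nonnull = inj != 0
        return float((np.sign(inj[nonnull]) == np.sign(rec[nonnull])).mean())


def run_recovery_batch(
    n_seeds: int = 50,
    base_seed: int = 0,
    montage: Montage | None = None,
    sample_rate: float = RECOVERY_SAMPLE_RATE,
    jitter_sd: float = RECOVERY_JITTER_SD_MS,
    asym_grid: tuple[float, ...] = RECOVERY_ASYMMETRY_GRID,
    config: RunConfig | None = None,
) -> RecoveryBatch:
    """Simulate ``n_seeds`` sessions (asymmetry grid permuted over actions per
    seed, onset jitter injected), run the full pipeline, and pool injected vs
    recovered asymmetry and lag errors."""
    montage = montage or small_montage()
    config = config or RunConfig()
    batch = RecoveryBatch()
    for k in range(n_seeds):
        seed = base_seed + k
        rng = np.random.default_rng(seed + 777)
        asym = tuple(float(a) for a in rng.permutation(asym_grid))
        params = sim.SimParams(
            n_channels=montage.n_channels,
            sample_rate=sample_rate,
            asymmetry_per_action=asym,
            jitter_sd=jitter_sd,
            seed=seed,
        )
        rec, sched, truth = sim.generate_session(params, montage)
        res = analyze_session(rec, sched, montage, config, infant_id=f"seed{seed}")
        for action in (1, 2, 3, 4):
            rel = truth.true_lags_ms[action - 1] - truth.true_lags_ms[action - 1][0]
            for it, lag in res.lags_ms.get(action, {}).items():
                if it != 1:
                    batch.lag_errors_ms.append(abs(lag - rel[it - 1]))
            if action in res.fas.raw_fas:
                batch.injected_asymmetry.append(asym[action - 1])
                batch.recovered_fas.append(res.fas.raw_fas[action])
        batch.n_sessions += 1
    return batch


# ---------------------------------------------------------------------------
# Statistical calibration (behavioral side only; no EEG needed)


def _wecs_cohort_frame(
    effects: list[float], seed: int, domain: str = "facial"
) -> pd.DataFrame:
    """Per-(infant, action) mean scores for infants with the given latent
    trend effects (one entry per infant)."""
    rows = []
    for i, eff in enumerate(effects):
        params = sim.SimParams(wecs_effect=eff, seed=seed * 1_000_000 + i)
        w = sim.generate_wecs(params)
        rec = bh.WECSRecord(f"i{i}", w["scores"], w["state"])
        for (action, dom), v in bh.aggregate_wecs(rec).items():
            if dom == domain:
                rows.append(
                    {"infant_id": f"i{i}", "action": action, domain: v, "grp": eff != 0.0}
                )
    return pd.DataFrame(rows)


def trend_rejection_rate(
    effect: float, n_infants: int, n_reps: int, base_seed: int, alpha: float = 0.05
) -> float:
    """Fraction of replicate cohorts where the pooled trend test rejects."""
    hits = 0
    for r in range(n_reps):
        df = _wecs_cohort_frame([effect] * n_infants, base_seed + r)
        hits += st.trend_across_actions(df, "facial").p < alpha
    return hits / n_reps


def interaction_rejection_rate(
    effect_a: float,
    effect_b: float,
    n_each: int,
    n_reps: int,
    base_seed: int,
    alpha: float = 0.05,
) -> float:
    """Fraction of replicates where the group-by-action interaction rejects."""
    hits = 0
    for r in range(n_reps):
        seed = base_seed + r
        df = _wecs_cohort_frame(
            [effect_a] * n_each + [effect_b] * n_each, seed
        )
        # group label: first half vs second half of the infant list
        ids = sorted(df["infant_id"].unique(), key=lambda s: int(s[1:]))
        first = set(ids[:n_each])
        df = df.assign(grp=df["infant_id"].isin(first))
        hits += st.interaction_test(df, "facial", "grp").p < alpha
    return hits / n_reps
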