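"""End-to-end orchestration: simulate -> preprocess -> envelope -> align ->
FAS -> behavior -> stats, with per-stage exclusion accounting and
seed-deterministic outputs."""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import alignment as al
from . import behavior as bh
from . import envelope as ev
from . import fas as fa
from . import preprocess as pp
from . import simulate as sim
from . import stats as st
from .io import EEGRecording, EventSchedule, write_table
from .montage import Montage, default_montage


@dataclass
class RunConfig:
    """Analysis thresholds; defaults follow the published protocol values."""

    notch_hz: float = 60.0
    band: tuple[float, float] = (0.3, 40.0)
    band_order: int = 1
    alpha_band: tuple[float, float] = (6.0, 9.0)
    alpha_order: int = 4
    amp_uv: float = 120.0
    max_bad: int = 35
    max_masked: float = 0.5
    max_lag_ms: float = 2000.0
    delay_ms: float = 2000.0
    window_ms: float = 5000.0
    gfp_smooth_ms: float = 150.0
    artifact_scope: str = "cluster"  # "cluster" | "global"
    exclude_drowsy: bool = False
    fdr: bool = False

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


@dataclass
class SessionResult:
    infant_id: str
    fas: fa.FASRecord
    lags_ms: dict[int, dict[int, float]]          # action -> iteration -> lag
    exclusions: list[str] = field(default_factory=list)
    preprocess_report: dict = field(default_factory=dict)


def analyze_session(
    rec: EEGRecording,
    sched: EventSchedule,
    montage: Montage | None = None,
    config: RunConfig | None = None,
    infant_id: str = "infant",
) -> SessionResult:
    """Full neural chain for one infant: filtered recording to FAS record."""
    montage = montage or default_montage()
    config = config or RunConfig()
    exclusions: list[str] = []

    clean, report = pp.preprocess_recording(
        rec,
        montage,
        notch_freq=config.notch_hz,
        band=config.band,
        band_order=config.band_order,
        max_bad=config.max_bad,
    )
    epochs = pp.segment_epochs(clean, sched)
    scope = (
        list(montage.left_cluster) + list(montage.right_cluster)
        if config.artifact_scope == "cluster"
        else None
    )
    for ep in epochs:
        if ep.usable:
            pp.eliminate_amplitude_artifacts(
                ep, threshold=config.amp_uv, scope_labels=scope, max_masked=config.max_masked
            )
        if not ep.usable:
            exclusions.append(
                f"epoch action={ep.action_id} iteration={ep.iteration}: {ep.unusable_reason}"
            )

    raw_fas: dict[int, float] = {}
    n_used: dict[int, int] = {}
    all_lags: dict[int, dict[int, float]] = {}
    for action in (1, 2, 3, 4):
        usable = [e for e in epochs if e.action_id == action and e.usable]
        envs = {}
        for ep in usable:
            envs[ep.iteration] = ev.compute_cluster_envelope(
                ep,
                montage,
                band=config.alpha_band,
                order=config.alpha_order,
                bad_channels=clean.bad_channels,
            )
        try:
            lags = al.align_iterations(
                {k: e.gfp for k, e in envs.items()},
                clean.sample_rate,
                max_lag_ms=config.max_lag_ms,
                smooth_ms=config.gfp_smooth_ms,
            )
        except al.ActionDropped as exc:
            exclusions.append(f"action {action}: {exc}")
            continue
        windows = {}
        for k, env in envs.items():
            try:
                windows[k] = al.extract_window(
                    env,
                    lags[k],
                    delay_ms=config.delay_ms,
                    length_ms=config.window_ms,
                    max_window_masked=config.max_masked,
                )
            except al.AlignmentError as exc:
                exclusions.append(f"action {action} iteration {k}: {exc}")
        try:
            agg = al.average_action(action, windows, lags)
        except al.ActionDropped as exc:
            exclusions.append(f"action {action}: {exc}")
            continue
        all_lags[action] = agg.lags_ms
        n_used[action] = agg.n_iterations_used
        try:
            raw_fas[action] = fa.compute_fas(agg.mean_left, agg.mean_right)
        except fa.FASError as exc:
            exclusions.append(f"action {action}: {exc}")

    record = fa.build_record(infant_id, raw_fas, n_used)
    return SessionResult(
        infant_id=infant_id,
        fas=record,
        lags_ms=all_lags,
        exclusions=exclusions,
        preprocess_report=report,
    )


# ---------------------------------------------------------------------------
# Cohort-level simulate-and-analyze


@dataclass
class CohortResult:
    fas_table: pd.DataFrame       # infant_id, action, raw_fas, delta_fas, n_iterations_used
    wecs_table: pd.DataFrame      # infant_id, action, domain, mean_score
    meta_table: pd.DataFrame
    trends: pd.DataFrame
    interactions: pd.DataFrame
    grand_average: pd.DataFrame
    report: dict


def simulate_cohort(
    n_infants: int,
    base_params: sim.SimParams,
    seed: int,
    irritable_fraction: float = 0.0,
) -> list[tuple[str, sim.SimParams]]:
    """Per-infant parameter sets: deterministic per-infant seeds derived from
    the cohort seed; the first ``round(n * fraction)`` infants are irritable."""
    from dataclasses import replace

    n_irr = int(round(n_infants * irritable_fraction))
    out = []
    for i in range(n_infants):
        params = replace(
            base_params, seed=seed * 1_000_000 + i, irritable=i < n_irr
        )
        out.append((f"infant{i:03d}", params))
    return out


def run_cohort(
    infants: list[tuple[str, sim.SimParams]],
    montage: Montage | None = None,
    config: RunConfig | None = None,
    with_eeg: bool = True,
) -> CohortResult:
    """Simulate and analyze a cohort; ``with_eeg=False`` runs the behavioral
    side only (used by the statistical-calibration suites)."""
    montage = montage or default_montage()
    config = config or RunConfig()

    fas_rows, wecs_rows, metas = [], [], []
    exclusion_log: dict[str, list[str]] = {}
    for infant_id, params in infants:
        if with_eeg:
            rec, sched, _truth = sim.generate_session(params, montage)
            res = analyze_session(rec, sched, montage, config, infant_id=infant_id)
            exclusion_log[infant_id] = res.exclusions
            for action in (1, 2, 3, 4):
                fas_rows.append(
                    {
                        "infant_id": infant_id,
                        "action": action,
                        "raw_fas": res.fas.raw_fas.get(action, np.nan),
                        "delta_fas": res.fas.delta_fas.get(action, np.nan),
                        "n_iterations_used": (res.fas.n_iterations_used or {}).get(action, 0),
                    }
                )
        wec = sim.generate_wecs(params)
        rec_w = bh.WECSRecord(infant_id, wec["scores"], wec["state"])
        agg = bh.aggregate_wecs(rec_w, exclude_drowsy=config.exclude_drowsy)
        for (action, domain), v in sorted(agg.items()):
            wecs_rows.append(
                {"infant_id": infant_id, "action": action, "domain": domain, "mean_score": v}
            )
        metas.append(bh.DyadMeta(**sim.generate_metadata(params, infant_id)))

    fas_table = pd.DataFrame(
        fas_rows,
        columns=["infant_id", "action", "raw_fas", "delta_fas", "n_iterations_used"],
    )
    wecs_table = pd.DataFrame(
        wecs_rows, columns=["infant_id", "action", "domain", "mean_score"]
    )
    meta_table = bh.meta_to_frame(metas)

    trends, interactions, grand = compute_statistics(
        fas_table, wecs_table, meta_table, config
    )
    report = {
        "config_hash": config.config_hash(),
        "n_infants": len(infants),
        "depression_covariate_used": bh.any_depression_risk(metas),
        "exclusions": exclusion_log,
    }
    return CohortResult(fas_table, wecs_table, meta_table, trends, interactions, grand, report)


def compute_statistics(
    fas_table: pd.DataFrame,
    wecs_table: pd.DataFrame,
    meta_table: pd.DataFrame,
    config: RunConfig | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Trend, interaction, and grand-average analyses over cohort tables."""
    config = config or RunConfig()
    meta_cols = meta_table.set_index("infant_id")[["irritable", "bonded_group"]]

    wide = wecs_table.pivot_table(
        index=["infant_id", "action"], columns="domain", values="mean_score"
    ).reset_index()
    wide = wide.join(meta_cols, on="infant_id")

    trend_rows = []
    for domain in bh.DOMAINS:
        if domain not in wide.columns:
            continue
        trend_rows.append(asdict(st.trend_across_actions(wide, domain, group="all")))
        for flag, lab in ((False, "non_irritable"), (True, "irritable")):
            sub = wide[wide["irritable"] == flag]
            if sub["action"].nunique() >= 2 and len(sub) >= 3:
                trend_rows.append(asdict(st.trend_across_actions(sub, domain, group=lab)))

    if not fas_table.empty and fas_table["delta_fas"].notna().any():
        fdf = fas_table[fas_table["action"] >= 2].join(meta_cols, on="infant_id")
        try:
            trend_rows.append(
                asdict(st.trend_across_actions(fdf, "delta_fas", group="all"))
            )
        except st.StatsError:
            pass
        for flag, lab in ((False, "non_irritable"), (True, "irritable")):
            sub = fdf[fdf["irritable"] == flag]
            try:
                trend_rows.append(asdict(st.trend_across_actions(sub, "delta_fas", group=lab)))
            except st.StatsError:
                pass
    trends = pd.DataFrame(trend_rows)

    inter_rows = []
    for group_col in ("irritable", "bonded_group"):
        if wide[group_col].nunique() == 2:
            for domain in bh.DOMAINS:
                if domain in wide.columns:
                    try:
                        inter_rows.append(asdict(st.interaction_test(wide, domain, group_col)))
                    except st.StatsError:
                        pass
    interactions = pd.DataFrame(inter_rows)

    grand_rows = []
    if not fas_table.empty and fas_table["raw_fas"].notna().any():
        fas_means = fas_table.groupby("action")["raw_fas"].mean().to_dict()
        for domain in bh.DOMAINS:
            sub = wecs_table[wecs_table["domain"] == domain]
            wecs_means = sub.groupby("action")["mean_score"].mean().to_dict()
            try:
                r, p = st.grand_average_correlation(fas_means, wecs_means)
                grand_rows.append({"domain": domain, "r": r, "p": p, "n_points": 4})
            except st.StatsError:
                pass
    grand = pd.DataFrame(grand_rows)
    return trends, interactions, grand


def write_cohort_result(result: CohortResult, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_table(result.fas_table, out / "fas.csv")
    write_table(result.wecs_table, out / "wecs_aggregated.csv")
    write_table(result.meta_table, out / "metadata.csv")
    write_table(result.trends, out / "trends.csv")
    write_table(result.interactions, out / "interactions.csv")
    write_table(result.grand_average, out / "grand_average.csv")
    (out / "run_report.json").write_text(json.dumps(result.report, indent=2, default=str))
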