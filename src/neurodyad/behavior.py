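"""Behavioral-coding aggregation and dyad classification.

Three coded domains per (action, iteration): facial expressiveness,
sensitivity to mother, vocal communication, each scored 1 (absent),
2 (mixed) or 3 (clearly present); sensitivity is coded 0 for a markedly
drowsy iteration.  Iterations coded "inconsolable" are dropped from the
per-action means.  Dyad-level classifications: irritability from consoling
counts, bondedness and depression risk from questionnaire totals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

DOMAINS = ("facial", "sensitivity", "vocal")
STATES = ("consolable_ok", "drowsy", "inconsolable")
MIBS_LESS_BONDED_MIN = 2
EPDS_AT_RISK_MIN = 10


class BehaviorValidationError(ValueError):
    pass


@dataclass
class WECSRecord:
    infant_id: str
    scores: dict[tuple[int, int, str], int]  # (action, iteration, domain) -> 0..3
    state: dict[tuple[int, int], str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for (action, iteration, domain), v in self.scores.items():
            if domain not in DOMAINS:
                raise BehaviorValidationError(f"unknown domain {domain!r}")
            if v not in (0, 1, 2, 3):
                raise BehaviorValidationError(
                    f"score {v} for ({action},{iteration},{domain}) outside 0..3"
                )
            if v == 0:
                if domain != "sensitivity":
                    raise BehaviorValidationError("only sensitivity may be coded 0")
                if self.state.get((action, iteration)) != "drowsy":
                    raise BehaviorValidationError(
                        "sensitivity 0 requires a drowsy state flag"
                    )
        for key, s in self.state.items():
            if s not in STATES:
                raise BehaviorValidationError(f"unknown state {s!r} at {key}")


@dataclass
class DyadMeta:
    infant_id: str
    consoling_events: int
    ever_inconsolable: bool
    mibs: int
    epds: int

    def __post_init__(self) -> None:
        if not 0 <= self.mibs <= 24:
            raise BehaviorValidationError(f"MIBS {self.mibs} outside 0..24")
        if not 0 <= self.epds <= 30:
            raise BehaviorValidationError(f"EPDS {self.epds} outside 0..30")
        if self.consoling_events < 0:
            raise BehaviorValidationError("consoling_events must be >= 0")

    @property
    def irritable(self) -> bool:
        return classify_irritability(self)

    @property
    def bonded_group(self) -> str:
        return classify_bondedness(self)

    @property
    def depression_risk(self) -> bool:
        return screen_depression(self)


def aggregate_wecs(
    rec: WECSRecord, exclude_drowsy: bool = False
) -> dict[tuple[int, str], float]:
    """Mean score per (action, domain) over iterations, dropping inconsolable
    iterations.  Drowsy sensitivity-0 codes are included as coded unless
    ``exclude_drowsy``.  A cell with no retained iterations is absent."""
    sums: dict[tuple[int, str], list[int]] = {}
    for (action, iteration, domain), v in rec.scores.items():
        state = rec.state.get((action, iteration), "consolable_ok")
        if state == "inconsolable":
            continue
        if exclude_drowsy and state == "drowsy":
            continue
        sums.setdefault((action, domain), []).append(v)
    return {k: float(np.mean(v)) for k, v in sums.items()}


def classify_irritability(meta: DyadMeta) -> bool:
    """Irritable iff ever inconsolable, or needed consoling more than once."""
    return meta.ever_inconsolable or meta.consoling_events > 1


def classify_bondedness(meta: DyadMeta) -> str:
    """'more' bonded for MIBS 0-1, 'less' for MIBS >= 2."""
    return "less" if meta.mibs >= MIBS_LESS_BONDED_MIN else "more"


def screen_depression(meta: DyadMeta) -> bool:
    """At-risk iff EPDS >= 10."""
    return meta.epds >= EPDS_AT_RISK_MIN


def any_depression_risk(metas: list[DyadMeta]) -> bool:
    """Cohort gate: the depression covariate is dropped when no dyad screens
    at risk."""
    return any(screen_depression(m) for m in metas)


# ---------------------------------------------------------------------------
# Table conversion


def wecs_from_frame(df: pd.DataFrame) -> dict[str, WECSRecord]:
    """Build records from a long table with columns infant_id, action,
    iteration, domain, score, state."""
    out: dict[str, WECSRecord] = {}
    for infant_id, grp in df.groupby("infant_id", sort=True):
        scores, state = {}, {}
        for r in grp.itertuples():
            scores[(int(r.action), int(r.iteration), str(r.domain))] = int(r.score)
            state[(int(r.action), int(r.iteration))] = str(r.state)
        out[str(infant_id)] = WECSRecord(str(infant_id), scores, state)
    return out


def wecs_to_frame(records: list[WECSRecord]) -> pd.DataFrame:
    rows = []
    for rec in records:
        for (action, iteration, domain), v in sorted(rec.scores.items()):
            rows.append(
                {
                    "infant_id": rec.infant_id,
                    "action": action,
                    "iteration": iteration,
                    "domain": domain,
                    "score": v,
                    "state": rec.state.get((action, iteration), "consolable_ok"),
                }
            )
    return pd.DataFrame(rows)


def meta_to_frame(metas: list[DyadMeta]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "infant_id": m.infant_id,
                "consoling_events": m.consoling_events,
                "ever_inconsolable": m.ever_inconsolable,
                "mibs": m.mibs,
                "epds": m.epds,
                "irritable": m.irritable,
                "bonded_group": m.bonded_group,
                "depression_risk": m.depression_risk,
            }
            for m in metas
        ]
    )


def meta_from_frame(df: pd.DataFrame) -> list[DyadMeta]:
    return [
        DyadMeta(
            infant_id=str(r.infant_id),
            consoling_events=int(r.consoling_events),
            ever_inconsolable=bool(r.ever_inconsolable),
            mibs=int(r.mibs),
            epds=int(r.epds),
        )
        for r in df.itertuples()
    ]
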