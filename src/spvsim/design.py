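"""Randomized trial schedules for the obstacle-course experiment.

Each participant completes two experimental sessions of 18 trials.  A
session starts with two control trials under normal camera vision (one per
scene complexity), followed by 16 simulated-phosphene-vision (SPV) trials
in randomized order: the six CED resolutions (10, 18, 26, 34, 42, 50) and
the two surface-boundary resolutions (26, 42), each at both complexities.
Across the two sessions this yields 4 camera, 24 CED-SPV and 8
boundary-SPV trials per participant.

Route-layout assignment honours the study's matching constraints: the two
complexity variants of a condition within a session use the same base
layout in mirrored orientations, and each boundary-SPV trial uses the same
layout as the CED trial at the same resolution, session and complexity, so
the method comparison is route-matched.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np
import pandas as pd

__all__ = [
    "ConditionSpec",
    "TrialSlot",
    "CED_RESOLUTIONS",
    "BOUNDARY_RESOLUTIONS",
    "COMPLEXITIES",
    "build_trial_schedule",
    "build_study_schedule",
    "verify_schedule",
    "schedule_to_frame",
    "ScheduleReport",
]

CED_RESOLUTIONS = (10, 18, 26, 34, 42, 50)
BOUNDARY_RESOLUTIONS = (26, 42)
COMPLEXITIES = ("plain", "complex")
N_BASE_LAYOUTS = 7


@dataclass(frozen=True)
class ConditionSpec:
    """One vision condition: camera (normal vision), CED-based SPV, or
    surface-boundary-based SPV, at a phosphene resolution and complexity."""

    vision: str                # camera | ced_spv | boundary_spv
    resolution: Optional[int]  # grid side; None for camera
    complexity: str            # plain | complex

    def __post_init__(self) -> None:
        if self.vision not in ("camera", "ced_spv", "boundary_spv"):
            raise ValueError(f"unknown vision {self.vision!r}")
        if self.complexity not in COMPLEXITIES:
            raise ValueError(f"unknown complexity {self.complexity!r}")
        if self.vision == "camera":
            if self.resolution is not None:
                raise ValueError("camera condition has no resolution")
        elif self.vision == "ced_spv":
            if self.resolution not in CED_RESOLUTIONS:
                raise ValueError(f"ced resolution must be one of {CED_RESOLUTIONS}")
        elif self.resolution not in BOUNDARY_RESOLUTIONS:
            raise ValueError(f"boundary resolution must be one of {BOUNDARY_RESOLUTIONS}")


@dataclass(frozen=True)
class TrialSlot:
    """One scheduled mobility trial."""

    participant_id: str
    session: int
    index_in_session: int
    condition: ConditionSpec
    layout_id: int
    mirrored: bool


def build_trial_schedule(
    participant_id: str,
    seed: int,
    n_layouts: int = N_BASE_LAYOUTS,
) -> list[TrialSlot]:
    """Build the 36-trial schedule (2 sessions x 18 trials) for one
    participant.  Deterministic given ``seed``."""
    if n_layouts < 1:
        raise ValueError("layout library must contain at least one base layout")
    rng = np.random.default_rng(seed)
    slots: list[TrialSlot] = []
    for session in (1, 2):
        # one base layout + orientation per (method-agnostic) resolution slot;
        # boundary trials reuse the CED assignment at the same resolution
        res_layout = {r: int(rng.integers(n_layouts)) for r in CED_RESOLUTIONS}
        res_orient = {r: bool(rng.integers(2)) for r in CED_RESOLUTIONS}
        cam_layout = int(rng.integers(n_layouts))
        cam_orient = bool(rng.integers(2))

        def slot_for(vision: str, res: Optional[int], complexity: str) -> tuple[int, bool]:
            if vision == "camera":
                base, orient = cam_layout, cam_orient
            else:
                base, orient = res_layout[res], res_orient[res]
            # complexity pair: same layout, mirrored orientations
            mirrored = orient if complexity == "plain" else not orient
            return base, mirrored

        camera_conditions = [ConditionSpec("camera", None, c) for c in COMPLEXITIES]
        rng.shuffle(camera_conditions)
        spv_conditions = [
            ConditionSpec("ced_spv", r, c) for r in CED_RESOLUTIONS for c in COMPLEXITIES
        ] + [
            ConditionSpec("boundary_spv", r, c)
            for r in BOUNDARY_RESOLUTIONS
            for c in COMPLEXITIES
        ]
        rng.shuffle(spv_conditions)

        for idx, cond in enumerate(camera_conditions + spv_conditions, start=1):
            layout_id, mirrored = slot_for(cond.vision, cond.resolution, cond.complexity)
            slots.append(
                TrialSlot(
                    participant_id=participant_id,
                    session=session,
                    index_in_session=idx,
                    condition=cond,
                    layout_id=layout_id,
                    mirrored=mirrored,
                )
            )
    return slots


def build_study_schedule(n_participants: int = 20, seed: int = 0) -> list[TrialSlot]:
    """Schedules for a full study cohort; per-participant seeds are derived
    from ``seed``."""
    rng = np.random.default_rng(seed)
    slots: list[TrialSlot] = []
    for p in range(n_participants):
        sub_seed = int(rng.integers(2**31 - 1))
        slots.extend(build_trial_schedule(f"P{p + 1:02d}", sub_seed))
    return slots


def schedule_to_frame(slots: Iterable[TrialSlot]) -> pd.DataFrame:
    """Flatten TrialSlots to a DataFrame (CSV-ready)."""
    rows = [
        {
            "participant_id": s.participant_id,
            "session": s.session,
            "index_in_session": s.index_in_session,
            "vision": s.condition.vision,
            "resolution": s.condition.resolution,
            "complexity": s.condition.complexity,
            "layout_id": s.layout_id,
            "mirrored": s.mirrored,
        }
        for s in slots
    ]
    return pd.DataFrame(rows)


@dataclass
class ScheduleReport:
    """Constraint-check report: list of (constraint name, passed, offenders)."""

    checks: list[tuple[str, bool, list]]

    @property
    def passed(self) -> bool:
        return all(ok for _, ok, _ in self.checks)

    def failures(self) -> list[tuple[str, list]]:
        return [(name, off) for name, ok, off in self.checks if not ok]


def verify_schedule(slots: list[TrialSlot]) -> ScheduleReport:
    """Check a schedule against the trial-count and matching constraints."""
    if not slots:
        raise ValueError("empty schedule")
    checks: list[tuple[str, bool, list]] = []
    df = schedule_to_frame(slots)

    for pid, sub in df.groupby("participant_id"):
        counts = sub["vision"].value_counts()
        expected = {"camera": 4, "ced_spv": 24, "boundary_spv": 8}
        for vision, want in expected.items():
            got = int(counts.get(vision, 0))
            checks.append(
                (f"{pid}: {vision} trial count == {want}", got == want, [] if got == want else [got])
            )
        for session, ses in sub.groupby("session"):
            idx = sorted(ses["index_in_session"])
            checks.append(
                (f"{pid} s{session}: 18 contiguous trials", idx == list(range(1, 19)), idx if idx != list(range(1, 19)) else [])
            )
            first_two = ses.sort_values("index_in_session").head(2)["vision"].tolist()
            ok = first_two == ["camera", "camera"]
            checks.append((f"{pid} s{session}: starts with two camera trials", ok, [] if ok else first_two))
            # complexity pairs share a base layout in mirrored orientations
            for (vision, res), grp in ses.groupby(["vision", "resolution"], dropna=False):
                if len(grp) != 2:
                    checks.append(
                        (f"{pid} s{session}: {vision}/{res} measured at both complexities", False, grp.index.tolist())
                    )
                    continue
                a, b = grp.iloc[0], grp.iloc[1]
                ok = (
                    {a["complexity"], b["complexity"]} == {"plain", "complex"}
                    and a["layout_id"] == b["layout_id"]
                    and a["mirrored"] != b["mirrored"]
                )
                checks.append(
                    (f"{pid} s{session}: {vision}/{res} complexity pair route-matched+mirrored", ok,
                     [] if ok else grp.index.tolist())
                )
            # boundary trials route-matched to the CED trial of same res/complexity
            bnd = ses[ses["vision"] == "boundary_spv"]
            ced = ses[ses["vision"] == "ced_spv"]
            for _, row in bnd.iterrows():
                match = ced[(ced["resolution"] == row["resolution"]) & (ced["complexity"] == row["complexity"])]
                ok = len(match) == 1 and bool(
                    (match.iloc[0]["layout_id"] == row["layout_id"])
                    and (match.iloc[0]["mirrored"] == row["mirrored"])
                )
                checks.append(
                    (f"{pid} s{session}: boundary/{row['resolution']}/{row['complexity']} matched to CED", ok,
                     [] if ok else [int(row['layout_id'])])
                )
    return ScheduleReport(checks=checks)
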