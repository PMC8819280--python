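"""Synthetic behavioral trial data for the mobility experiment.

The human study's raw data are not public, so this module generates trial
records with the statistical structure the analysis pipeline assumes:
condition-level means for the three endpoints (trial duration, collision
count, 10-point subjective rating), additive participant random effects
with the reported between-participant dispersions (7.748 s duration,
0.251 collisions, 0.783 rating), a second-session practice effect
(SPV trials 3.468 s faster), Poisson collision counts with log-normal
participant frailty, and discrete bounded ratings.

The per-condition means beyond the published anchors (camera-vision mean
duration 16.74 s, overall SPV duration around 31 s, zero collisions under
camera vision) are structural defaults: monotone improvement with
phosphene resolution, a complexity penalty at low resolutions that
reverses at 50 x 50, and slightly worse boundary-SPV than CED.  They make
the generator a stand-in with the qualitative shape of the study, not a
reconstruction of its numbers.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .design import (
    BOUNDARY_RESOLUTIONS,
    CED_RESOLUTIONS,
    COMPLEXITIES,
    ConditionSpec,
    TrialSlot,
    schedule_to_frame,
)

__all__ = [
    "BehavioralModelParams",
    "default_condition_means",
    "sample_trials",
]

# (duration_s, collision_rate, rating) per condition
_CED_DURATION_PLAIN = {10: 42.0, 18: 35.0, 26: 30.0, 34: 27.0, 42: 25.5, 50: 25.0}
_CED_DURATION_COMPLEX_DELTA = {10: 9.0, 18: 6.0, 26: 3.5, 34: 1.0, 42: 0.0, 50: -1.5}
_CED_COLLISIONS_PLAIN = {10: 2.0, 18: 1.2, 26: 0.6, 34: 0.4, 42: 0.3, 50: 0.25}
_CED_COLLISIONS_COMPLEX = {10: 3.0, 18: 2.2, 26: 1.3, 34: 0.55, 42: 0.32, 50: 0.28}
_CED_RATING_PLAIN = {10: 3.2, 18: 4.6, 26: 6.0, 34: 6.8, 42: 7.3, 50: 7.5}
_CED_RATING_COMPLEX = {10: 2.2, 18: 3.4, 26: 5.3, 34: 6.5, 42: 7.2, 50: 7.7}
_BOUNDARY = {
    # (resolution, complexity) -> (duration, collisions, rating)
    (26, "plain"): (32.0, 0.70, 5.5),
    (26, "complex"): (34.0, 1.20, 5.0),
    (42, "plain"): (27.5, 0.35, 6.9),
    (42, "complex"): (28.0, 0.40, 6.8),
}
_CAMERA = (16.74, 0.0, 9.363)


def default_condition_means() -> dict[ConditionSpec, tuple[float, float, float]]:
    """Default endpoint means per condition.

    Anchored to the published camera-vision mean duration (16.74 s) and
    rating (9.363), with the SPV conditions averaging near the published
    overall duration (~31 s); all values can be overridden via
    :class:`BehavioralModelParams`."""
    means: dict[ConditionSpec, tuple[float, float, float]] = {}
    for c in COMPLEXITIES:
        means[ConditionSpec("camera", None, c)] = _CAMERA
    for r in CED_RESOLUTIONS:
        means[ConditionSpec("ced_spv", r, "plain")] = (
            _CED_DURATION_PLAIN[r], _CED_COLLISIONS_PLAIN[r], _CED_RATING_PLAIN[r]
        )
        means[ConditionSpec("ced_spv", r, "complex")] = (
            _CED_DURATION_PLAIN[r] + _CED_DURATION_COMPLEX_DELTA[r],
            _CED_COLLISIONS_COMPLEX[r],
            _CED_RATING_COMPLEX[r],
        )
    for (r, c), v in _BOUNDARY.items():
        means[ConditionSpec("boundary_spv", r, c)] = v
    return means


@dataclass(frozen=True)
class BehavioralModelParams:
    """Generator settings.

    ``participant_sd`` are the between-participant standard deviations of
    the endpoint means (duration s, collisions, rating);
    ``session2_duration_shift_s`` is added to SPV durations in session 2
    (negative = faster); ``residual_sd`` are the within-condition trial
    noise scales for duration (s) and rating (points).  Collisions are
    Poisson with a log-normal participant frailty of log-scale sd
    ``collision_frailty_sd``."""

    condition_means: dict = field(default_factory=default_condition_means)
    participant_sd: tuple[float, float, float] = (7.748, 0.251, 0.783)
    session2_duration_shift_s: float = -3.468
    residual_sd: tuple[float, float] = (6.0, 1.0)
    collision_frailty_sd: float = 0.30
    min_duration_s: float = 3.0
    force_zero_camera_collisions: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        for cond, (dur, rate, rating) in self.condition_means.items():
            if dur <= 0:
                raise ValueError(f"duration mean must be positive ({cond})")
            if rate < 0:
                raise ValueError(f"collision rate must be >= 0 ({cond})")
            if not 1 <= rating <= 10:
                raise ValueError(f"rating mean must be in [1, 10] ({cond})")

    def with_complexity_effect(self, scale: float) -> "BehavioralModelParams":
        """Rescale the plain-vs-complex difference of every SPV condition by
        ``scale`` (0 gives a null generator with no complexity effect)."""
        means = dict(self.condition_means)
        pooled: dict[tuple, dict[str, tuple[float, float, float]]] = {}
        for cond, v in means.items():
            if cond.vision == "camera":
                continue
            pooled.setdefault((cond.vision, cond.resolution), {})[cond.complexity] = v
        for (vision, res), pair in pooled.items():
            plain, complx = np.array(pair["plain"]), np.array(pair["complex"])
            mid = (plain + complx) / 2
            means[ConditionSpec(vision, res, "plain")] = tuple(mid + scale * (plain - mid))
            means[ConditionSpec(vision, res, "complex")] = tuple(mid + scale * (complx - mid))
        return replace(self, condition_means=means)


def sample_trials(
    schedule: list[TrialSlot] | pd.DataFrame,
    params: BehavioralModelParams | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Draw synthetic TrialRecords for a schedule.

    duration = condition mean + participant effect + session-2 shift (SPV)
    + Gaussian residual, floored at ``min_duration_s``; collisions ~
    Poisson(rate * participant frailty), optionally forced to zero for
    camera vision; rating = condition mean + participant effect + residual,
    rounded and clipped to [1, 10].  Deterministic given the seed."""
    params = params or BehavioralModelParams()
    df = schedule if isinstance(schedule, pd.DataFrame) else schedule_to_frame(schedule)
    rng = np.random.default_rng(params.seed if seed is None else seed)

    sd_dur, sd_coll, sd_rating = params.participant_sd
    res_dur, res_rating = params.residual_sd

    out = df.copy()
    n = len(df)

    # per-trial condition means, via a lookup keyed on (vision, res, complexity)
    key = list(
        zip(
            df["vision"],
            [None if pd.isna(r) else int(r) for r in df["resolution"]],
            df["complexity"],
        )
    )
    table = {
        (c.vision, c.resolution, c.complexity): v for c, v in params.condition_means.items()
    }
    try:
        means = np.array([table[k] for k in key])
    except KeyError as exc:
        raise ValueError(f"no condition means for scheduled condition {exc}") from None

    pid_codes, _ = pd.factorize(df["participant_id"])
    n_participants = pid_codes.max() + 1
    eff_dur = rng.normal(0.0, sd_dur, size=n_participants)
    eff_rating = rng.normal(0.0, sd_rating, size=n_participants)
    frailty = np.exp(rng.normal(0.0, params.collision_frailty_sd, size=n_participants))

    is_camera = (df["vision"] == "camera").to_numpy()
    is_spv_s2 = (~is_camera) & (df["session"].to_numpy() == 2)

    dur = means[:, 0] + eff_dur[pid_codes] + rng.normal(0.0, res_dur, size=n)
    dur = dur + np.where(is_spv_s2, params.session2_duration_shift_s, 0.0)
    out["duration_s"] = np.maximum(dur, params.min_duration_s)

    coll = rng.poisson(means[:, 1] * frailty[pid_codes])
    if params.force_zero_camera_collisions:
        coll = np.where(is_camera, 0, coll)
    out["collisions"] = coll.astype(int)

    rating = means[:, 2] + eff_rating[pid_codes] + rng.normal(0.0, res_rating, size=n)
    out["rating"] = np.clip(np.rint(rating), 1, 10).astype(int)
    return out
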