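"""Behavioral statistics for the mobility experiment.

Implements the analysis pipeline end to end: within-participant
standardization of the three endpoints, an advisory Shapiro-Wilk normality
screen, planned paired comparisons with the Wilcoxon signed-rank test
under Bonferroni control (family of 6 complexity comparisons -> per-test
threshold 0.05/6 ~ 0.0083; family of 4 method comparisons -> 0.05/4 =
0.0125), the practice-effect correlation between trial number and
duration, and the restoration-percentage metric that expresses a
condition's performance on a 0-100 scale anchored at the worst SPV
condition (floor) and normal camera vision (ceiling).

The signed-rank test is implemented here rather than delegated, so that
its zero-difference and tie policy is explicit: zero differences are
dropped (Wilcoxon's original rule), ties get mid-ranks, the null
distribution is enumerated exactly over all sign patterns for up to 15
informative pairs, and a tie-corrected, continuity-corrected normal
approximation is used beyond that.  ``scipy.stats.wilcoxon`` serves as an
independent cross-check in the test suite.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .design import BOUNDARY_RESOLUTIONS, CED_RESOLUTIONS

__all__ = [
    "DegenerateDataError",
    "NoInformationError",
    "ENDPOINTS",
    "standardize_within_participant",
    "wilcoxon_signed_rank",
    "PlannedComparison",
    "ComparisonResult",
    "StatsReport",
    "complexity_family",
    "method_family",
    "run_planned_comparisons",
    "shapiro_wilk_screen",
    "learning_effect",
    "restoration_percentage",
    "speed_accuracy_slopes",
]

ENDPOINTS = ("duration_s", "collisions", "rating")
EXACT_WILCOXON_MAX_N = 15


class DegenerateDataError(ValueError):
    """A participant/endpoint with zero spread cannot be standardized."""


class NoInformationError(ValueError):
    """All paired differences are zero; the signed-rank test is undefined."""


def standardize_within_participant(
    records: pd.DataFrame, endpoints: Sequence[str] = ENDPOINTS
) -> pd.DataFrame:
    """Z-score each endpoint within each participant (over all of the
    participant's trials, controls included).

    Returns a copy with ``z_<endpoint>`` columns.  A participant whose
    trials show zero spread in an endpoint raises
    :class:`DegenerateDataError` naming participant and endpoint."""
    out = records.copy()
    for ep in endpoints:
        zcol = f"z_{ep}"
        zs = np.empty(len(records))
        for pid, sub in records.groupby("participant_id"):
            if len(sub) < 2:
                raise DegenerateDataError(f"participant {pid}: fewer than 2 trials")
            x = sub[ep].to_numpy(dtype=float)
            sd = x.std(ddof=1)
            if sd == 0:
                raise DegenerateDataError(
                    f"participant {pid}: zero spread in endpoint {ep!r}"
                )
            zs[records.index.get_indexer(sub.index)] = (x - x.mean()) / sd
        out[zcol] = zs
    return out


def _exact_two_sided_p(ranks: np.ndarray, w_plus: float) -> float:
    """Two-sided p by exact enumeration of all 2^m sign patterns."""
    m = len(ranks)
    patterns = (np.arange(2**m)[:, None] >> np.arange(m)) & 1  # (2^m, m) of {0,1}
    w_all = patterns @ ranks
    tol = 1e-9
    p_ge = np.mean(w_all >= w_plus - tol)
    p_le = np.mean(w_all <= w_plus + tol)
    return float(min(1.0, 2.0 * min(p_ge, p_le)))


def wilcoxon_signed_rank(
    x: Sequence[float],
    y: Optional[Sequence[float]] = None,
    *,
    mode: Literal["auto", "exact", "approx"] = "auto",
) -> tuple[float, float]:
    """Paired Wilcoxon signed-rank test; returns (W+, two-sided p).

    ``x`` holds paired differences (or first-condition values when ``y``
    is given).  Zero differences are dropped; ties among the absolute
    differences receive mid-ranks.  With ``mode='auto'``, the null is
    enumerated exactly for up to 15 informative pairs; otherwise a normal
    approximation with tie correction and continuity correction is used.
    """
    d = np.asarray(x, dtype=float)
    if y is not None:
        d = d - np.asarray(y, dtype=float)
    d = d[d != 0]
    m = len(d)
    if m == 0:
        raise NoInformationError("all paired differences are zero")
    ranks = sps.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())

    use_exact = mode == "exact" or (mode == "auto" and m <= EXACT_WILCOXON_MAX_N)
    if use_exact:
        return w_plus, _exact_two_sided_p(ranks, w_plus)

    mean = ranks.sum() / 2.0
    var = float(np.sum(ranks**2)) / 4.0  # mid-ranks make this the tie-corrected variance
    dev = w_plus - mean
    z = (dev - 0.5 * np.sign(dev)) / math.sqrt(var) if var > 0 else 0.0
    p = 2.0 * sps.norm.sf(abs(z))
    return w_plus, float(min(1.0, p))


@dataclass(frozen=True)
class PlannedComparison:
    """One planned paired comparison of per-participant condition means."""

    endpoint: str                    # raw column; z_<endpoint> is analyzed
    label: str
    condition_a: dict
    condition_b: dict
    family_size: int

    def __post_init__(self) -> None:
        if self.family_size < 1:
            raise ValueError("family_size must be >= 1")


@dataclass
class ComparisonResult:
    comparison: PlannedComparison
    n_pairs: int
    w_statistic: Optional[float]
    p_value: Optional[float]
    adjusted_alpha: float
    significant: Optional[bool]
    error: Optional[str] = None


@dataclass
class StatsReport:
    alpha: float
    results: list[ComparisonResult]
    displayed_thresholds: dict[int, float] = field(default_factory=dict)

    def to_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "endpoint": r.comparison.endpoint,
                    "comparison": r.comparison.label,
                    "n": r.n_pairs,
                    "W": r.w_statistic,
                    "p": r.p_value,
                    "adjusted_alpha": r.adjusted_alpha,
                    "significant": r.significant,
                    "error": r.error,
                }
                for r in self.results
            ]
        )


def complexity_family(endpoint: str) -> list[PlannedComparison]:
    """Six planned comparisons: plain vs complex with CED at each
    resolution (per-test threshold alpha/6)."""
    return [
        PlannedComparison(
            endpoint=endpoint,
            label=f"ced {r}x{r}: plain vs complex",
            condition_a={"vision": "ced_spv", "resolution": r, "complexity": "plain"},
            condition_b={"vision": "ced_spv", "resolution": r, "complexity": "complex"},
            family_size=6,
        )
        for r in CED_RESOLUTIONS
    ]


def method_family(endpoint: str) -> list[PlannedComparison]:
    """Four planned comparisons: boundary-SPV vs CED at each measured
    resolution and complexity (per-test threshold alpha/4)."""
    return [
        PlannedComparison(
            endpoint=endpoint,
            label=f"{r}x{r} {c}: boundary vs ced",
            condition_a={"vision": "boundary_spv", "resolution": r, "complexity": c},
            condition_b={"vision": "ced_spv", "resolution": r, "complexity": c},
            family_size=4,
        )
        for r in BOUNDARY_RESOLUTIONS
        for c in ("plain", "complex")
    ]


def _condition_means(df: pd.DataFrame, zcol: str, selector: dict) -> pd.Series:
    sub = df
    for k, v in selector.items():
        sub = sub[sub[k] == v]
    if sub.empty:
        raise KeyError(f"no trials match selector {selector}")
    return sub.groupby("participant_id")[zcol].mean()


def run_planned_comparisons(
    z: pd.DataFrame, family: list[PlannedComparison], alpha: float = 0.05
) -> StatsReport:
    """Wilcoxon signed-rank tests on paired per-participant condition
    means of the standardized endpoints, Bonferroni-adjusted.

    A comparison whose differences carry no information is reported with
    an error entry rather than raising."""
    results = []
    thresholds: dict[int, float] = {}
    for comp in family:
        zcol = f"z_{comp.endpoint}"
        if zcol not in z.columns:
            raise KeyError(f"standardized column {zcol} missing; run standardization first")
        a = _condition_means(z, zcol, comp.condition_a)
        b = _condition_means(z, zcol, comp.condition_b)
        paired = pd.concat([a, b], axis=1, keys=["a", "b"], join="inner")
        if len(paired) < len(a) or len(paired) < len(b):
            missing = set(a.index).symmetric_difference(b.index)
            raise ValueError(f"unpaired participants for {comp.label}: {sorted(missing)}")
        adjusted = alpha / comp.family_size
        thresholds[comp.family_size] = round(adjusted, 4)
        try:
            w, p = wilcoxon_signed_rank(paired["a"].to_numpy(), paired["b"].to_numpy())
            results.append(
                ComparisonResult(comp, len(paired), w, p, adjusted, bool(p < adjusted))
            )
        except NoInformationError as exc:
            results.append(
                ComparisonResult(comp, len(paired), None, None, adjusted, None, error=str(exc))
            )
    return StatsReport(alpha=alpha, results=results, displayed_thresholds=thresholds)


def shapiro_wilk_screen(
    z: pd.DataFrame, endpoints: Sequence[str] = ENDPOINTS
) -> dict[str, tuple[float, float]]:
    """Advisory Shapiro-Wilk screen of the per-participant condition-mean
    distributions; the pipeline proceeds with rank tests regardless."""
    out = {}
    for ep in endpoints:
        zcol = f"z_{ep}"
        means = z.groupby(["participant_id", "vision", "resolution", "complexity"],
                          dropna=False)[zcol].mean().to_numpy()
        means = means[np.isfinite(means)]
        if len(means) < 3:
            raise ValueError(f"need >= 3 values for normality screen of {ep}")
        if np.ptp(means) == 0:
            raise ValueError(f"constant sample for endpoint {ep}")
        w, p = sps.shapiro(means)
        out[ep] = (float(w), float(p))
    return out


def learning_effect(records: pd.DataFrame) -> tuple[float, float, float]:
    """Practice effect: (pearson_r, p, session_shift_s).

    ``pearson_r`` correlates the overall trial number with the
    within-participant standardized duration, pooled across participants;
    ``session_shift_s`` is the mean session-1 minus session-2 SPV trial
    duration (positive = faster second session)."""
    if len(records) < 3:
        raise ValueError("need at least 3 trials")
    df = records.copy()
    df["trial_number"] = (df["session"] - 1) * df.groupby(["participant_id", "session"])[
        "index_in_session"
    ].transform("max") + df["index_in_session"]
    if "z_duration_s" not in df.columns:
        df = standardize_within_participant(df, endpoints=("duration_s",))
    x = df["trial_number"].to_numpy(dtype=float)
    yv = df["z_duration_s"].to_numpy(dtype=float)
    if np.ptp(x) == 0 or np.ptp(yv) == 0:
        raise ValueError("zero variance in trial number or duration")
    r, p = sps.pearsonr(x, yv)
    spv = df[df["vision"] != "camera"]
    shift = float(
        spv.loc[spv["session"] == 1, "duration_s"].mean()
        - spv.loc[spv["session"] == 2, "duration_s"].mean()
    )
    return float(r), float(p), shift


def restoration_percentage(
    x: float,
    floor: float,
    ceiling: float,
    direction: Literal["lower_is_better", "higher_is_better"],
) -> float:
    """Performance restored relative to a floor (worst SPV condition) and a
    ceiling (normal camera vision), as a percentage.  Not clamped; values
    outside [0, 100] are meaningful (worse than floor / better than
    ceiling)."""
    if floor == ceiling:
        raise ValueError("floor and ceiling must differ")
    if direction == "lower_is_better":
        return 100.0 * (floor - x) / (floor - ceiling)
    if direction == "higher_is_better":
        return 100.0 * (x - floor) / (ceiling - floor)
    raise ValueError(f"unknown direction {direction!r}")


def speed_accuracy_slopes(records: pd.DataFrame) -> pd.DataFrame:
    """Least-squares slope of collisions on duration per SPV condition,
    with sign; a screen for a speed-accuracy trade-off."""
    rows = []
    spv = records[records["vision"] != "camera"]
    for (vision, res, cpx), grp in spv.groupby(["vision", "resolution", "complexity"]):
        if len(grp) < 3 or grp["duration_s"].std() == 0:
            continue
        slope = float(np.polyfit(grp["duration_s"], grp["collisions"], 1)[0])
        rows.append(
            {"vision": vision, "resolution": res, "complexity": cpx,
             "slope": slope, "sign": int(np.sign(slope))}
        )
    return pd.DataFrame(rows)
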