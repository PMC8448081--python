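"""Reliable change indices and within-person differential change patterns.

The index for one participant and outcome is the difference score
(pre - post) divided by the standard error of the difference (SEdiff).
Two SEdiff variants are supported:

``difference`` (default)
    SEdiff = SD of the difference scores x sqrt(1 - r), with r the
    pre/post Pearson correlation, both estimated from the analysed
    sample itself.

``baseline``
    The classic Jacobson-Truax form, SD at baseline x sqrt(2 (1 - r)).

Indices are orientation-normalised so that positive always means
improvement regardless of the scale's direction; |index| > 1.96
(strict) marks a reliable change.  Each participant's reliable
improvements across the configured well-being and distress outcome sets
are then crossed into one of four patterns: ``both``,
``wellbeing_only``, ``distress_only``, ``none``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, DegenerateStatisticsError, InputError
from .scales import OUTCOME_DIRECTIONS, OUTCOMES

__all__ = [
    "RELIABLY_IMPROVED",
    "NO_RELIABLE_CHANGE",
    "RELIABLY_DETERIORATED",
    "PATTERNS",
    "DEFAULT_GROUPING",
    "DEFAULT_THRESHOLD",
    "SEDiff",
    "RCIResult",
    "ChangePattern",
    "PatternFrequencies",
    "SubgroupBreakdown",
    "se_diff",
    "se_diff_baseline",
    "rci_score",
    "classify_reliable",
    "change_pattern",
    "pattern_frequencies",
    "subgroup_pattern_frequencies",
    "compute_reliable_change",
]

RELIABLY_IMPROVED = "reliably_improved"
NO_RELIABLE_CHANGE = "no_reliable_change"
RELIABLY_DETERIORATED = "reliably_deteriorated"

PATTERNS = ("both", "wellbeing_only", "distress_only", "none")
DIMENSIONS = ("wellbeing", "distress", "excluded")

#: Default outcome grouping: the dual-factor pattern crosses the two
#: well-being outcomes against the three distress subscales; resilience
#: is excluded from the pattern but still reported per outcome.
DEFAULT_GROUPING: Mapping[str, str] = {
    "overall_wellbeing": "wellbeing",
    "life_satisfaction": "wellbeing",
    "dass_depression": "distress",
    "dass_anxiety": "distress",
    "dass_stress": "distress",
    "resilience": "excluded",
}

DEFAULT_THRESHOLD = 1.96
SEDIFF_VARIANTS = ("difference", "baseline")


@dataclass(frozen=True)
class SEDiff:
    """SEdiff value plus a degeneracy flag (zero SEdiff -> RCI undefined)."""

    value: float
    degenerate: bool = False


def se_diff(sd_diff: float, r_prepost: float) -> SEDiff:
    """SEdiff = sd_diff * sqrt(1 - r_prepost).

    ``sd_diff`` is the SD of the difference scores and ``r_prepost`` the
    pre/post correlation.  A zero result (sd_diff = 0 or r = 1) is
    returned flagged degenerate rather than raising; downstream RCI
    computation refuses degenerate SEdiffs.
    """
    if sd_diff < 0:
        raise InputError(f"sd_diff must be >= 0, got {sd_diff}")
    if r_prepost > 1:
        raise InputError(f"pre/post correlation must be <= 1, got {r_prepost}")
    value = float(sd_diff * math.sqrt(1.0 - r_prepost))
    return SEDiff(value=value, degenerate=(value == 0.0))


def se_diff_baseline(sd_pre: float, r_prepost: float) -> SEDiff:
    """Classic variant: SEdiff = sd_pre * sqrt(2 (1 - r_prepost))."""
    if sd_pre < 0:
        raise InputError(f"sd_pre must be >= 0, got {sd_pre}")
    if r_prepost > 1:
        raise InputError(f"pre/post correlation must be <= 1, got {r_prepost}")
    value = float(sd_pre * math.sqrt(2.0 * (1.0 - r_prepost)))
    return SEDiff(value=value, degenerate=(value == 0.0))


def rci_score(pre: float, post: float, sediff, direction: str) -> float:
    """Orientation-normalised reliable change index.

    The raw index is (pre - post) / SEdiff; for ``higher_is_better``
    scales the sign is flipped so that positive always means
    improvement.  Magnitude is unaffected by orientation.
    """
    value = sediff.value if isinstance(sediff, SEDiff) else float(sediff)
    if value <= 0:
        raise DegenerateStatisticsError(
            f"SEdiff is {value}; reliable change index undefined"
        )
    if direction not in ("higher_is_better", "lower_is_better"):
        raise InputError(f"unknown direction {direction!r}")
    raw = (pre - post) / value
    return float(raw if direction == "lower_is_better" else -raw)


def classify_reliable(rci_value: float, threshold: float = DEFAULT_THRESHOLD) -> str:
    """Tri-state classification with strict inequalities at the threshold."""
    if not np.isfinite(rci_value):
        raise InputError(f"non-finite RCI value {rci_value}")
    if rci_value > threshold:
        return RELIABLY_IMPROVED
    if rci_value < -threshold:
        return RELIABLY_DETERIORATED
    return NO_RELIABLE_CHANGE


@dataclass(frozen=True)
class RCIResult:
    participant_id: str
    outcome: str
    pre_score: float
    post_score: float
    diff: float  # pre - post
    se_diff: float
    rci_value: float
    classification: str


@dataclass(frozen=True)
class ChangePattern:
    participant_id: str
    improved_wellbeing: bool
    improved_distress: bool
    pattern: str


def _validate_grouping(grouping: Mapping[str, str], outcomes: Iterable[str]) -> None:
    for outcome in outcomes:
        if outcome not in grouping:
            raise ConfigError(f"outcome {outcome!r} missing from grouping map")
        if grouping[outcome] not in DIMENSIONS:
            raise ConfigError(
                f"grouping[{outcome!r}] must be one of {DIMENSIONS}, "
                f"got {grouping[outcome]!r}"
            )


def change_pattern(
    rci_results: Sequence[RCIResult],
    grouping: Mapping[str, str] = DEFAULT_GROUPING,
) -> ChangePattern:
    """Dual-factor pattern for one participant's per-outcome RCI results."""
    if not rci_results:
        raise InputError("change_pattern needs at least one RCIResult")
    pids = {r.participant_id for r in rci_results}
    if len(pids) != 1:
        raise InputError(f"RCI results span multiple participants: {sorted(pids)}")
    _validate_grouping(grouping, (r.outcome for r in rci_results))
    improved = {
        dim: any(
            r.classification == RELIABLY_IMPROVED
            for r in rci_results
            if grouping[r.outcome] == dim
        )
        for dim in ("wellbeing", "distress")
    }
    if improved["wellbeing"] and improved["distress"]:
        pattern = "both"
    elif improved["wellbeing"]:
        pattern = "wellbeing_only"
    elif improved["distress"]:
        pattern = "distress_only"
    else:
        pattern = "none"
    return ChangePattern(
        participant_id=pids.pop(),
        improved_wellbeing=improved["wellbeing"],
        improved_distress=improved["distress"],
        pattern=pattern,
    )


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


@dataclass(frozen=True)
class PatternFrequencies:
    """Pattern counts with exact fractions and display percentages.

    Pattern percentages use the number of participants with any reliable
    improvement as denominator; ``none`` is reported against the full
    sample.  ``any_reliable_*`` fields cover reliable change in either
    direction on any outcome (available when per-outcome results are
    supplied).
    """

    counts: Mapping[str, int]
    n_participants: int
    improvement_denominator: int
    fractions: Mapping[str, float]
    percent_display: Mapping[str, int]
    any_reliable_count: Optional[int] = None
    any_reliable_fraction: Optional[float] = None
    any_reliable_percent_display: Optional[int] = None


def pattern_frequencies(
    patterns: Sequence[ChangePattern],
    rci_results: Optional[Sequence[RCIResult]] = None,
) -> PatternFrequencies:
    """Tabulate dual-factor patterns across participants.

    Exact fractions are retained alongside integer display percentages
    (round half up).
    """
    if not patterns:
        raise InputError("pattern_frequencies needs a nonempty pattern set")
    counts = {p: 0 for p in PATTERNS}
    for pat in patterns:
        counts[pat.pattern] += 1
    n = len(patterns)
    denom = n - counts["none"]
    fractions: dict[str, float] = {}
    display: dict[str, int] = {}
    for p in ("both", "wellbeing_only", "distress_only"):
        frac = counts[p] / denom if denom else 0.0
        fractions[p] = frac
        display[p] = _round_half_up(100 * frac)
    fractions["none"] = counts["none"] / n
    display["none"] = _round_half_up(100 * counts["none"] / n)

    any_count = any_frac = any_disp = None
    if rci_results is not None:
        changed = {
            r.participant_id
            for r in rci_results
            if r.classification != NO_RELIABLE_CHANGE
        }
        known = {p.participant_id for p in patterns}
        any_count = len(changed & known)
        any_frac = any_count / n
        any_disp = _round_half_up(100 * any_frac)
    return PatternFrequencies(
        counts=counts,
        n_participants=n,
        improvement_denominator=denom,
        fractions=fractions,
        percent_display=display,
        any_reliable_count=any_count,
        any_reliable_fraction=any_frac,
        any_reliable_percent_display=any_disp,
    )


@dataclass(frozen=True)
class SubgroupBreakdown:
    distress_type: str
    denominator: int
    counts: Mapping[str, int]
    fractions: Mapping[str, float]
    percent_display: Mapping[str, int]


def subgroup_pattern_frequencies(
    rci_results: Sequence[RCIResult],
    baseline_flags: Mapping[str, Mapping[str, Optional[bool]]],
    distress_type: str,
    grouping: Mapping[str, str] = DEFAULT_GROUPING,
) -> SubgroupBreakdown:
    """Pattern breakdown for one distress type.

    Restricted to participants who met that subscale's baseline
    threshold AND showed a reliable improvement on at least one outcome;
    within the subgroup, the distress dimension is narrowed to the named
    subscale (other distress outcomes are excluded from the pattern).

    ``baseline_flags`` maps participant id to a per-outcome flag mapping
    (e.g. ``ProblematicFlags.flags``).
    """
    if distress_type not in ("depression", "anxiety", "stress"):
        raise ConfigError(f"unknown distress_type {distress_type!r}")
    target = f"dass_{distress_type}"
    by_pid: dict[str, list[RCIResult]] = {}
    for r in rci_results:
        by_pid.setdefault(r.participant_id, []).append(r)
    restricted = dict(grouping)
    for outcome, dim in grouping.items():
        if dim == "distress" and outcome != target:
            restricted[outcome] = "excluded"
    if restricted.get(target) != "distress":
        raise ConfigError(f"{target} is not in the distress dimension of the grouping")

    counts = {p: 0 for p in PATTERNS}
    denom = 0
    for pid, results in by_pid.items():
        flags = baseline_flags.get(pid)
        if flags is None or flags.get(target) is not True:
            continue
        if not any(r.classification == RELIABLY_IMPROVED for r in results):
            continue
        denom += 1
        counts[change_pattern(results, restricted).pattern] += 1
    fractions = {p: (counts[p] / denom if denom else 0.0) for p in PATTERNS}
    display = {p: _round_half_up(100 * fractions[p]) for p in PATTERNS}
    return SubgroupBreakdown(
        distress_type=distress_type,
        denominator=denom,
        counts=counts,
        fractions=fractions,
        percent_display=display,
    )


@dataclass
class ReliableChangeTables:
    """Tidy per-outcome and per-participant reliable-change results."""

    rci: pd.DataFrame  # one row per participant x outcome
    patterns: pd.DataFrame  # one row per participant
    results: list[RCIResult]
    pattern_objects: list[ChangePattern]
    sediff: Mapping[str, SEDiff]
    variant: str
    threshold: float
    degenerate_outcomes: list[str] = field(default_factory=list)


def compute_reliable_change(
    wide: pd.DataFrame,
    outcomes: Sequence[str] = OUTCOMES,
    directions: Optional[Mapping[str, str]] = None,
    grouping: Mapping[str, str] = DEFAULT_GROUPING,
    variant: str = "difference",
    threshold: float = DEFAULT_THRESHOLD,
) -> ReliableChangeTables:
    """Sample-level reliable-change analysis.

    ``wide`` must have one row per participant with a ``participant_id``
    column and ``pre_<outcome>`` / ``post_<outcome>`` columns, complete
    cases only.  SEdiff is estimated per outcome from this sample (SD of
    differences and pre/post Pearson correlation; or baseline SD under
    the ``baseline`` variant).  Outcomes whose SEdiff degenerates are
    skipped and listed in ``degenerate_outcomes``.
    """
    if variant not in SEDIFF_VARIANTS:
        raise ConfigError(f"unknown SEdiff variant {variant!r}")
    directions = directions or OUTCOME_DIRECTIONS
    _validate_grouping(grouping, outcomes)
    if "participant_id" not in wide.columns:
        raise InputError("wide table must have a participant_id column")
    if len(wide) < 2:
        raise InputError("reliable change needs at least 2 participants")

    results: list[RCIResult] = []
    sediffs: dict[str, SEDiff] = {}
    degenerate: list[str] = []
    for outcome in outcomes:
        pre_col, post_col = f"pre_{outcome}", f"post_{outcome}"
        for col in (pre_col, post_col):
            if col not in wide.columns:
                raise InputError(f"missing column {col!r}")
        pre = wide[pre_col].to_numpy(dtype=float)
        post = wide[post_col].to_numpy(dtype=float)
        if np.isnan(pre).any() or np.isnan(post).any():
            raise InputError(f"{outcome}: missing scores; complete cases required")
        diffs = pre - post
        r = _pearson(pre, post)
        if variant == "difference":
            sd = float(np.std(diffs, ddof=1))
            sediff = se_diff(sd, r)
        else:
            sd = float(np.std(pre, ddof=1))
            sediff = se_diff_baseline(sd, r)
        sediffs[outcome] = sediff
        if sediff.degenerate:
            degenerate.append(outcome)
            continue
        for pid, pre_i, post_i, diff_i in zip(
            wide["participant_id"], pre, post, diffs
        ):
            value = rci_score(pre_i, post_i, sediff, directions[outcome])
            results.append(
                RCIResult(
                    participant_id=str(pid),
                    outcome=outcome,
                    pre_score=float(pre_i),
                    post_score=float(post_i),
                    diff=float(diff_i),
                    se_diff=sediff.value,
                    rci_value=value,
                    classification=classify_reliable(value, threshold),
                )
            )

    by_pid: dict[str, list[RCIResult]] = {}
    for r_ in results:
        by_pid.setdefault(r_.participant_id, []).append(r_)
    patterns = [
        change_pattern(rlist, grouping) for rlist in by_pid.values()
    ]
    rci_df = pd.DataFrame(
        [vars(r_) for r_ in results],
        columns=[
            "participant_id", "outcome", "pre_score", "post_score",
            "diff", "se_diff", "rci_value", "classification",
        ],
    )
    pattern_df = pd.DataFrame(
        [vars(p) for p in patterns],
        columns=["participant_id", "improved_wellbeing", "improved_distress", "pattern"],
    )
    return ReliableChangeTables(
        rci=rci_df,
        patterns=pattern_df,
        results=results,
        pattern_objects=patterns,
        sediff=sediffs,
        variant=variant,
        threshold=threshold,
        degenerate_outcomes=degenerate,
    )


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    sx, sy = np.std(x, ddof=1), np.std(y, ddof=1)
    if sx == 0 or sy == 0:
        # constant series: correlation undefined; treat as 0 so SEdiff
        # falls back to the raw difference-score SD
        return 0.0
    return float(np.corrcoef(x, y)[0, 1])
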