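"""Instrument definitions, scoring, severity cutoffs and internal consistency.

Four instruments ship as package defaults (see ``data/instruments.yaml``):
the 14-item well-being continuum measure (``mhcsf``), the 5-item life
satisfaction scale (``swls``), the 21-item distress scale with three
7-item subscales (``dass21``, scored as doubled sums so the standard
42-point severity bands apply), and the 6-item resilience scale (``brs``,
scored as the item mean with items 2, 4, 6 reverse-coded).

Scoring, reverse-coding keys, cutoff tables and "problematic" label sets
are all data (:class:`ScaleDefinition`), not code, so studies using
different bounds can override them from a YAML file.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import yaml

from .errors import ConfigError, DegenerateStatisticsError, InputError

__all__ = [
    "OUTCOMES",
    "WELLBEING_OUTCOMES",
    "DISTRESS_OUTCOMES",
    "OUTCOME_DIRECTIONS",
    "ScaleDefinition",
    "ScaleScores",
    "OutcomePanel",
    "ProblematicFlags",
    "score_scale",
    "severity_category",
    "classify_problematic",
    "cronbach_alpha",
    "default_scales",
    "outcome_scales",
    "load_scales",
]

SCORING_RULES = ("sum", "sum_times_two", "mean")
DIRECTIONS = ("higher_is_better", "lower_is_better")

#: Analysis outcomes, in canonical order.
OUTCOMES = (
    "overall_wellbeing",
    "life_satisfaction",
    "dass_depression",
    "dass_anxiety",
    "dass_stress",
    "resilience",
)
WELLBEING_OUTCOMES = ("overall_wellbeing", "life_satisfaction", "resilience")
DISTRESS_OUTCOMES = ("dass_depression", "dass_anxiety", "dass_stress")
OUTCOME_DIRECTIONS = {
    name: ("lower_is_better" if name in DISTRESS_OUTCOMES else "higher_is_better")
    for name in OUTCOMES
}

#: Maps each analysis outcome to (instrument name, subscale name or None).
OUTCOME_SOURCES = {
    "overall_wellbeing": ("mhcsf", None),
    "life_satisfaction": ("swls", None),
    "dass_depression": ("dass21", "depression"),
    "dass_anxiety": ("dass21", "anxiety"),
    "dass_stress": ("dass21", "stress"),
    "resilience": ("brs", None),
}


@dataclass(frozen=True)
class ScaleDefinition:
    """Declarative description of one instrument.

    Parameters
    ----------
    name
        Identifier used in error messages and column prefixes
        (item columns are ``<name>_<item#>``).
    item_count, item_min, item_max
        Number of items and per-item response bounds.
    scoring_rule
        ``sum``, ``sum_times_two`` or ``mean``.
    direction
        ``higher_is_better`` or ``lower_is_better``; drives the
        orientation of reliable-change indices downstream.
    reverse_coded
        1-based indices of reverse-coded items.
    subscales
        Optional map of subscale name to 1-based item index list.
    cutoffs
        Ordered ``(label, inclusive lower bound)`` pairs on the total
        score.  The first bound must equal the scale minimum and bounds
        must be strictly increasing.
    problematic_labels
        Cutoff labels counted as "problematic" (failing the healthy
        criterion).
    subscale_cutoffs
        Optional per-subscale cutoff tables (used by the distress scale,
        whose three subscales have distinct severity bands).
    """

    name: str
    item_count: int
    item_min: int
    item_max: int
    scoring_rule: str
    direction: str
    reverse_coded: tuple[int, ...] = ()
    subscales: Optional[Mapping[str, tuple[int, ...]]] = None
    cutoffs: tuple[tuple[str, float], ...] = ()
    problematic_labels: frozenset[str] = field(default_factory=frozenset)
    subscale_cutoffs: Optional[Mapping[str, tuple[tuple[str, float], ...]]] = None

    def __post_init__(self) -> None:
        if self.item_count < 1:
            raise ConfigError(f"{self.name}: item_count must be positive")
        if self.item_min >= self.item_max:
            raise ConfigError(f"{self.name}: item_min must be < item_max")
        if self.scoring_rule not in SCORING_RULES:
            raise ConfigError(
                f"{self.name}: unknown scoring_rule {self.scoring_rule!r}"
            )
        if self.direction not in DIRECTIONS:
            raise ConfigError(f"{self.name}: unknown direction {self.direction!r}")
        for idx in self.reverse_coded:
            if not 1 <= idx <= self.item_count:
                raise ConfigError(f"{self.name}: reverse-coded item {idx} out of range")
        if self.subscales:
            seen: set[int] = set()
            for sub, items in self.subscales.items():
                for idx in items:
                    if not 1 <= idx <= self.item_count:
                        raise ConfigError(
                            f"{self.name}/{sub}: item index {idx} out of range"
                        )
                    if idx in seen:
                        raise ConfigError(
                            f"{self.name}: item {idx} appears in two subscales"
                        )
                    seen.add(idx)
        if self.cutoffs:
            self._validate_cutoff_table(self.cutoffs, self.score_min)
        if self.subscale_cutoffs:
            if not self.subscales:
                raise ConfigError(f"{self.name}: subscale_cutoffs without subscales")
            for sub, table in self.subscale_cutoffs.items():
                if sub not in self.subscales:
                    raise ConfigError(f"{self.name}: cutoffs for unknown subscale {sub}")
                lo, _ = self.score_bounds(len(self.subscales[sub]))
                self._validate_cutoff_table(table, lo, context=f"{self.name}/{sub}")

    def _validate_cutoff_table(
        self,
        table: Sequence[tuple[str, float]],
        score_min: float,
        context: Optional[str] = None,
    ) -> None:
        ctx = context or self.name
        bounds = [b for _, b in table]
        if bounds[0] != score_min:
            raise ConfigError(
                f"{ctx}: first cutoff bound {bounds[0]} must equal scale minimum {score_min}"
            )
        if any(b2 <= b1 for b1, b2 in zip(bounds, bounds[1:])):
            raise ConfigError(f"{ctx}: cutoff bounds must be strictly increasing")

    # -- score bounds -------------------------------------------------

    def score_bounds(self, n_items: Optional[int] = None) -> tuple[float, float]:
        """Attainable (min, max) total score for ``n_items`` items."""
        k = self.item_count if n_items is None else n_items
        if self.scoring_rule == "sum":
            return float(k * self.item_min), float(k * self.item_max)
        if self.scoring_rule == "sum_times_two":
            return float(2 * k * self.item_min), float(2 * k * self.item_max)
        return float(self.item_min), float(self.item_max)

    @property
    def score_min(self) -> float:
        return self.score_bounds()[0]

    @property
    def score_max(self) -> float:
        return self.score_bounds()[1]

    # -- derived definitions ------------------------------------------

    def subscale_definition(self, subscale: str) -> "ScaleDefinition":
        """A standalone definition for one subscale (own items and cutoffs)."""
        if not self.subscales or subscale not in self.subscales:
            raise ConfigError(f"{self.name}: no subscale named {subscale!r}")
        items = tuple(self.subscales[subscale])
        cutoffs: tuple[tuple[str, float], ...] = ()
        if self.subscale_cutoffs and subscale in self.subscale_cutoffs:
            cutoffs = tuple((str(l), float(b)) for l, b in self.subscale_cutoffs[subscale])
        rev = tuple(
            pos + 1
            for pos, idx in enumerate(items)
            if idx in self.reverse_coded
        )
        return ScaleDefinition(
            name=f"{self.name}_{subscale}",
            item_count=len(items),
            item_min=self.item_min,
            item_max=self.item_max,
            scoring_rule=self.scoring_rule,
            direction=self.direction,
            reverse_coded=rev,
            cutoffs=cutoffs,
            problematic_labels=self.problematic_labels,
        )

    # -- (de)serialisation --------------------------------------------

    def to_dict(self) -> dict:
        d: dict = {
            "item_count": self.item_count,
            "item_min": self.item_min,
            "item_max": self.item_max,
            "scoring_rule": self.scoring_rule,
            "direction": self.direction,
        }
        if self.reverse_coded:
            d["reverse_coded"] = list(self.reverse_coded)
        if self.subscales:
            d["subscales"] = {k: list(v) for k, v in self.subscales.items()}
        if self.cutoffs:
            d["cutoffs"] = [[l, b] for l, b in self.cutoffs]
        if self.problematic_labels:
            d["problematic_labels"] = sorted(self.problematic_labels)
        if self.subscale_cutoffs:
            d["subscale_cutoffs"] = {
                k: [[l, b] for l, b in v] for k, v in self.subscale_cutoffs.items()
            }
        return d

    @classmethod
    def from_dict(cls, name: str, d: Mapping) -> "ScaleDefinition":
        try:
            return cls(
                name=name,
                item_count=int(d["item_count"]),
                item_min=int(d["item_min"]),
                item_max=int(d["item_max"]),
                scoring_rule=str(d["scoring_rule"]),
                direction=str(d["direction"]),
                reverse_coded=tuple(d.get("reverse_coded", ())),
                subscales=(
                    {k: tuple(v) for k, v in d["subscales"].items()}
                    if d.get("subscales")
                    else None
                ),
                cutoffs=tuple(
                    (str(l), float(b)) for l, b in d.get("cutoffs", ())
                ),
                problematic_labels=frozenset(d.get("problematic_labels", ())),
                subscale_cutoffs=(
                    {
                        k: tuple((str(l), float(b)) for l, b in v)
                        for k, v in d["subscale_cutoffs"].items()
                    }
                    if d.get("subscale_cutoffs")
                    else None
                ),
            )
        except KeyError as exc:  # missing required field
            raise ConfigError(f"scale {name!r}: missing field {exc}") from exc


@dataclass(frozen=True)
class ScaleScores:
    """Total and per-subscale scores for one response vector."""

    total: float
    subscales: Mapping[str, float] = field(default_factory=dict)


@dataclass(frozen=True)
class OutcomePanel:
    """The six analysis outcomes for one participant at one timepoint.

    Missing scores are ``None`` — never silently zero.
    """

    participant_id: str
    cohort: str  # "student" | "general"
    timepoint: str  # "pre" | "post"
    overall_wellbeing: Optional[float] = None
    life_satisfaction: Optional[float] = None
    dass_depression: Optional[float] = None
    dass_anxiety: Optional[float] = None
    dass_stress: Optional[float] = None
    resilience: Optional[float] = None

    def score(self, outcome: str) -> Optional[float]:
        if outcome not in OUTCOMES:
            raise InputError(f"unknown outcome {outcome!r}")
        value = getattr(self, outcome)
        if value is not None and np.isnan(value):
            return None
        return value


@dataclass(frozen=True)
class ProblematicFlags:
    """Per-outcome "problematic at baseline" flags plus composites.

    ``flags[outcome]`` is ``True``/``False`` or ``None`` when the outcome
    was missing.  ``any_distress`` is the OR over the three distress
    subscale flags; ``problematic_any`` the OR over all six.  A composite
    is ``None`` only when it cannot be determined (some inputs missing
    and none of the known ones ``True``).
    """

    participant_id: str
    flags: Mapping[str, Optional[bool]]
    any_distress: Optional[bool]
    problematic_any: Optional[bool]


def _coded_responses(responses: Sequence[float], scale: ScaleDefinition) -> np.ndarray:
    values = np.asarray(responses, dtype=float)
    if values.ndim != 1 or len(values) != scale.item_count:
        raise InputError(
            f"{scale.name}: expected {scale.item_count} responses, got {len(values)}"
        )
    for i, v in enumerate(values, start=1):
        if np.isnan(v):
            raise InputError(f"{scale.name}: item {i} is missing")
        if not scale.item_min <= v <= scale.item_max:
            raise InputError(
                f"{scale.name}: item {i} response {v} outside "
                f"[{scale.item_min}, {scale.item_max}]"
            )
    coded = values.copy()
    for idx in scale.reverse_coded:
        coded[idx - 1] = scale.item_min + scale.item_max - values[idx - 1]
    return coded


def _apply_rule(values: np.ndarray, rule: str) -> float:
    if rule == "sum":
        return float(np.sum(values))
    if rule == "sum_times_two":
        return float(2.0 * np.sum(values))
    return float(np.mean(values))


def score_scale(responses: Sequence[float], scale: ScaleDefinition) -> ScaleScores:
    """Score one response vector: total plus per-subscale scores.

    Reverse-coded items (per ``scale.reverse_coded``) are recoded before
    the scoring rule is applied; subscales use the same rule restricted
    to their items.
    """
    coded = _coded_responses(responses, scale)
    total = _apply_rule(coded, scale.scoring_rule)
    subs = {}
    if scale.subscales:
        for sub, items in scale.subscales.items():
            subs[sub] = _apply_rule(coded[[i - 1 for i in items]], scale.scoring_rule)
    return ScaleScores(total=total, subscales=subs)


def severity_category(score: float, scale: ScaleDefinition) -> str:
    """Label of the highest cutoff whose (inclusive) lower bound <= score."""
    if not scale.cutoffs:
        raise InputError(f"{scale.name}: no cutoff table configured")
    if not np.isfinite(score):
        raise InputError(f"{scale.name}: non-finite score")
    if not scale.score_min <= score <= scale.score_max:
        raise InputError(
            f"{scale.name}: score {score} outside [{scale.score_min}, {scale.score_max}]"
        )
    label = scale.cutoffs[0][0]
    for cand, bound in scale.cutoffs:
        if score >= bound:
            label = cand
    return label


def classify_problematic(
    panel: OutcomePanel,
    scales: Optional[Mapping[str, ScaleDefinition]] = None,
) -> ProblematicFlags:
    """Flag each outcome as problematic (failing its healthy criterion).

    An outcome is problematic when its severity label is in the scale's
    ``problematic_labels`` — i.e. below the high well-being / high life
    satisfaction / normal resilience bound, or at/above the mild
    distress bound.
    """
    scales = scales or outcome_scales()
    flags: dict[str, Optional[bool]] = {}
    for outcome in OUTCOMES:
        value = panel.score(outcome)
        if value is None:
            flags[outcome] = None
        else:
            label = severity_category(value, scales[outcome])
            flags[outcome] = label in scales[outcome].problematic_labels
    return ProblematicFlags(
        participant_id=panel.participant_id,
        flags=flags,
        any_distress=_or_with_missing([flags[o] for o in DISTRESS_OUTCOMES]),
        problematic_any=_or_with_missing([flags[o] for o in OUTCOMES]),
    )


def _or_with_missing(values: Iterable[Optional[bool]]) -> Optional[bool]:
    values = list(values)
    if any(v is True for v in values):
        return True
    if any(v is None for v in values):
        return None
    return False


def cronbach_alpha(item_matrix) -> float:
    """Cronbach's alpha for a participants x items score matrix.

    alpha = k/(k-1) * (1 - sum of item variances / variance of item sums),
    with unbiased (ddof=1) sample variances.

    Raises
    ------
    InputError
        Fewer than 2 items or 2 participants, or missing cells.
    DegenerateStatisticsError
        Zero variance of the total score (alpha undefined).
    """
    m = np.asarray(item_matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] < 2 or m.shape[1] < 2:
        raise InputError("cronbach_alpha needs >=2 participants and >=2 items")
    if np.isnan(m).any():
        raise InputError("cronbach_alpha requires complete cases (no missing cells)")
    k = m.shape[1]
    total_var = np.var(m.sum(axis=1), ddof=1)
    if total_var <= 0:
        raise DegenerateStatisticsError(
            "total-score variance is zero; alpha is undefined"
        )
    item_var = np.var(m, axis=0, ddof=1).sum()
    return float(k / (k - 1) * (1.0 - item_var / total_var))


# -- default definitions ----------------------------------------------


def _parse_scales(raw: Mapping) -> dict[str, ScaleDefinition]:
    return {name: ScaleDefinition.from_dict(name, d) for name, d in raw.items()}


def default_scales() -> dict[str, ScaleDefinition]:
    """The four packaged instrument definitions, freshly parsed."""
    text = (
        resources.files("dualchange").joinpath("data/instruments.yaml").read_text()
    )
    return _parse_scales(yaml.safe_load(text))


def load_scales(path, base: Optional[Mapping[str, ScaleDefinition]] = None):
    """Load scale definitions from YAML/JSON, overriding packaged defaults."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, Mapping):
        raise ConfigError(f"{path}: expected a mapping of scale definitions")
    scales = dict(base if base is not None else default_scales())
    scales.update(_parse_scales(raw))
    return scales


def outcome_scales(
    scales: Optional[Mapping[str, ScaleDefinition]] = None,
) -> dict[str, ScaleDefinition]:
    """Per-outcome effective definitions for the six analysis outcomes.

    Distress outcomes get standalone definitions derived from the parent
    21-item scale so each carries its own severity band.
    """
    scales = scales or default_scales()
    out: dict[str, ScaleDefinition] = {}
    for outcome, (instrument, subscale) in OUTCOME_SOURCES.items():
        if instrument not in scales:
            raise ConfigError(f"scale {instrument!r} not defined")
        base = scales[instrument]
        out[outcome] = base.subscale_definition(subscale) if subscale else base
    return out


def score_items_frame(df, scales: Optional[Mapping[str, ScaleDefinition]] = None):
    """Score item-level columns ``<scale>_<item#>`` into outcome columns.

    Returns ``(scored_df, item_columns)`` where ``scored_df`` has the six
    outcome columns appended and ``item_columns`` maps scale name to the
    column list used (for downstream alpha computation).
    """
    import pandas as pd

    scales = scales or default_scales()
    df = df.copy()
    item_columns: dict[str, list[str]] = {}
    for name, scale in scales.items():
        cols = [f"{name}_{i}" for i in range(1, scale.item_count + 1)]
        if not all(c in df.columns for c in cols):
            continue
        item_columns[name] = cols
        totals = []
        subs: dict[str, list[float]] = {s: [] for s in (scale.subscales or {})}
        for _, row in df[cols].iterrows():
            scored = score_scale(row.to_list(), scale)
            totals.append(scored.total)
            for s, v in scored.subscales.items():
                subs[s].append(v)
        df[f"{name}_total"] = totals
        for s, v in subs.items():
            df[f"{name}_{s}"] = v
    # map scored columns onto canonical outcome names where available
    rename = {
        "mhcsf_total": "overall_wellbeing",
        "swls_total": "life_satisfaction",
        "dass21_depression": "dass_depression",
        "dass21_anxiety": "dass_anxiety",
        "dass21_stress": "dass_stress",
        "brs_total": "resilience",
    }
    for src, dst in rename.items():
        if src in df.columns and dst not in df.columns:
            df[dst] = df[src]
    return df, item_columns
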