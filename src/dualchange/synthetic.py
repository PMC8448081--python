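"""Synthetic cohort and item-response generation.

Cohorts carry the statistical structure the analysis assumes: six
outcomes with configurable pre means/SDs (defaults match the published
pre/post summary table of the emulated study), a sign-structured
cross-outcome correlation matrix (well-being outcomes inter-correlate
positively, distress outcomes positively, cross-dimension negatively),
per-outcome pre/post correlations, a latent correlation between the
well-being and distress change factors, and a student subgroup with
worse baselines.  Everything is deterministic under a fixed seed.

The Gaussian margins are intentionally unbounded by default: the
published distress means/SDs place 5-17% of the mass below the scale
floor, so hard clipping would distort both the target moments and the
covariance structure.  ``bounds_mode="clip"`` is available, and the
fraction of draws outside each scale's bounds is always reported.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, InputError
from .scales import (
    DISTRESS_OUTCOMES,
    OUTCOME_DIRECTIONS,
    OUTCOMES,
    ScaleDefinition,
    outcome_scales,
)

__all__ = [
    "SimulationConfig",
    "CohortResult",
    "build_outcome_correlation",
    "generate_cohort",
    "generate_item_level",
    "write_cohort",
]

# Published pre/post summary statistics of the emulated cohort (n=89),
# used as generator defaults.
DEFAULT_PRE_MEANS = {
    "overall_wellbeing": 45.81,
    "life_satisfaction": 22.01,
    "dass_depression": 10.00,
    "dass_anxiety": 6.54,
    "dass_stress": 13.03,
    "resilience": 3.27,
}
DEFAULT_PRE_SDS = {
    "overall_wellbeing": 11.18,
    "life_satisfaction": 5.93,
    "dass_depression": 8.91,
    "dass_anxiety": 6.77,
    "dass_stress": 8.18,
    "resilience": 0.76,
}
DEFAULT_POST_MEANS = {
    "overall_wellbeing": 49.39,
    "life_satisfaction": 24.46,
    "dass_depression": 7.91,
    "dass_anxiety": 5.33,
    "dass_stress": 10.67,
    "resilience": 3.45,
}
DEFAULT_POST_SDS = {
    "overall_wellbeing": 12.19,
    "life_satisfaction": 6.48,
    "dass_depression": 7.37,
    "dass_anxiety": 5.71,
    "dass_stress": 7.94,
    "resilience": 0.75,
}


def _as_outcome_map(value, name: str) -> dict[str, float]:
    if isinstance(value, Mapping):
        missing = set(OUTCOMES) - set(value)
        if missing:
            raise ConfigError(f"{name}: missing outcomes {sorted(missing)}")
        return {o: float(value[o]) for o in OUTCOMES}
    return {o: float(value) for o in OUTCOMES}


@dataclass
class SimulationConfig:
    """Parameters of the cohort generator.

    ``pre_means``/``pre_sds`` and ``post_means``/``post_sds`` are
    cohort-level targets; the student baseline shift is applied as a
    within-cohort contrast that preserves the cohort-level moments.
    ``true_change``, when given, overrides ``post_means`` as
    ``pre + change``.
    """

    n_participants: int = 89
    student_fraction: float = 32 / 89
    pre_means: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_PRE_MEANS))
    pre_sds: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_PRE_SDS))
    post_means: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_POST_MEANS))
    post_sds: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_POST_SDS))
    true_change: Optional[Mapping[str, float]] = None
    pre_post_correlation: float | Mapping[str, float] = 0.7
    cross_outcome_corr: float = 0.5  # magnitude; signs follow outcome direction
    change_factor_corr: float = -0.5  # well-being vs distress change innovations
    innovation_within_corr: float = 0.5
    student_shift_sd: float = 0.5  # baseline worsening for students, in SD units
    missing_post_fraction: float = 0.0
    bounds_mode: str = "none"  # "none" | "clip"
    round_scores: bool = False
    lognormal_distress: bool = False  # optional skewed-margin stress test
    seed: int = 0

    def resolved(self) -> "SimulationConfig":
        """Validate and normalise all fields; returns a canonical copy."""
        if self.n_participants < 1:
            raise ConfigError("n_participants must be >= 1")
        if not 0 <= self.student_fraction <= 1:
            raise ConfigError("student_fraction must be in [0, 1]")
        if not 0 <= self.missing_post_fraction < 1:
            raise ConfigError("missing_post_fraction must be in [0, 1)")
        if self.bounds_mode not in ("none", "clip"):
            raise ConfigError(f"unknown bounds_mode {self.bounds_mode!r}")
        pre_means = _as_outcome_map(self.pre_means, "pre_means")
        pre_sds = _as_outcome_map(self.pre_sds, "pre_sds")
        post_sds = _as_outcome_map(self.post_sds, "post_sds")
        if self.true_change is not None:
            change = _as_outcome_map(self.true_change, "true_change")
            post_means = {o: pre_means[o] + change[o] for o in OUTCOMES}
        else:
            post_means = _as_outcome_map(self.post_means, "post_means")
        r = _as_outcome_map(self.pre_post_correlation, "pre_post_correlation")
        for o, v in r.items():
            if not -1 < v < 1:
                raise ConfigError(f"pre_post_correlation[{o}] must be in (-1, 1)")
        for name, sds in (("pre_sds", pre_sds), ("post_sds", post_sds)):
            for o, v in sds.items():
                if v <= 0:
                    raise ConfigError(f"{name}[{o}] must be > 0")
        cfg = SimulationConfig(
            n_participants=int(self.n_participants),
            student_fraction=float(self.student_fraction),
            pre_means=pre_means,
            pre_sds=pre_sds,
            post_means=post_means,
            post_sds=post_sds,
            true_change=None,
            pre_post_correlation=r,
            cross_outcome_corr=float(self.cross_outcome_corr),
            change_factor_corr=float(self.change_factor_corr),
            innovation_within_corr=float(self.innovation_within_corr),
            student_shift_sd=float(self.student_shift_sd),
            missing_post_fraction=float(self.missing_post_fraction),
            bounds_mode=self.bounds_mode,
            round_scores=bool(self.round_scores),
            lognormal_distress=bool(self.lognormal_distress),
            seed=int(self.seed),
        )
        # fail before sampling if either implied correlation matrix is invalid
        build_outcome_correlation(cfg.cross_outcome_corr, -abs(cfg.cross_outcome_corr))
        build_outcome_correlation(cfg.innovation_within_corr, cfg.change_factor_corr)
        return cfg

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimulationConfig":
        unknown = set(d) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigError(f"unknown simulation config keys: {sorted(unknown)}")
        return cls(**d)


@dataclass
class CohortResult:
    """Generated long-format cohort plus generation provenance."""

    data: pd.DataFrame
    config: SimulationConfig
    truncation: Mapping[str, float]  # fraction of draws outside scale bounds
    clipped: Mapping[str, float]  # fraction actually altered (clip mode)


def build_outcome_correlation(
    within: float,
    cross: float,
    outcomes: Sequence[str] = OUTCOMES,
) -> np.ndarray:
    """Sign-structured correlation matrix over the outcomes.

    Pairs in the same dimension (both well-being-like or both distress)
    get ``within``; cross-dimension pairs get ``cross`` (expected
    negative).  Raises :class:`ConfigError` if not positive definite.
    """
    signs = np.array(
        [1.0 if OUTCOME_DIRECTIONS[o] == "higher_is_better" else -1.0 for o in outcomes]
    )
    same = np.equal.outer(signs, signs)
    R = np.where(same, within, cross)
    np.fill_diagonal(R, 1.0)
    try:
        np.linalg.cholesky(R)
    except np.linalg.LinAlgError as exc:
        raise ConfigError(
            f"implied outcome correlation matrix (within={within}, cross={cross}) "
            "is not positive definite"
        ) from exc
    return R


def generate_cohort(config: SimulationConfig) -> CohortResult:
    """Draw a long-format participant x timepoint cohort.

    Pre scores come from a multivariate normal with the configured
    cohort-level means/SDs and sign-structured correlations; each post
    score is a pre-dependent draw achieving the configured pre/post
    correlation, post SD and mean change, with innovations correlated
    across outcomes through the change-factor structure.  Students are
    shifted toward worse baselines (both timepoints) with the general
    group counter-shifted so cohort-level moments are preserved.
    """
    cfg = config.resolved()
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_participants
    k = len(OUTCOMES)

    R_pre = build_outcome_correlation(
        cfg.cross_outcome_corr, -abs(cfg.cross_outcome_corr)
    )
    R_innov = build_outcome_correlation(
        cfg.innovation_within_corr, cfg.change_factor_corr
    )
    L_pre = np.linalg.cholesky(R_pre)
    L_innov = np.linalg.cholesky(R_innov)

    n_students = int(round(cfg.student_fraction * n))
    is_student = np.zeros(n, dtype=bool)
    is_student[rng.permutation(n)[:n_students]] = True

    # Directional per-outcome shift (worse for students), mean-preserving
    # across the cohort; within-group SDs shrink so mixture SD hits target.
    f = n_students / n
    delta_sd = cfg.student_shift_sd
    worse_sign = np.array(
        [-1.0 if OUTCOME_DIRECTIONS[o] == "higher_is_better" else 1.0 for o in OUTCOMES]
    )
    mix_factor = np.sqrt(max(1.0 - f * (1 - f) * delta_sd**2, 1e-9)) if 0 < f < 1 else 1.0
    group_offset = np.where(
        is_student[:, None], (1 - f) * delta_sd, -f * delta_sd
    ) * worse_sign[None, :]

    pre_means = np.array([cfg.pre_means[o] for o in OUTCOMES])
    pre_sds = np.array([cfg.pre_sds[o] for o in OUTCOMES])
    post_means = np.array([cfg.post_means[o] for o in OUTCOMES])
    post_sds = np.array([cfg.post_sds[o] for o in OUTCOMES])
    r = np.array([cfg.pre_post_correlation[o] for o in OUTCOMES])

    z = rng.standard_normal((n, k)) @ L_pre.T
    pre_group_mean = pre_means[None, :] + group_offset * pre_sds[None, :]
    pre = pre_group_mean + z * (pre_sds * mix_factor)[None, :]

    eps = rng.standard_normal((n, k)) @ L_innov.T
    slope = r * post_sds / pre_sds
    innov_sd = post_sds * mix_factor * np.sqrt(1.0 - r**2)
    post_group_mean = post_means[None, :] + group_offset * post_sds[None, :]
    post = post_group_mean + (pre - pre_group_mean) * slope[None, :] + eps * innov_sd[None, :]

    if cfg.lognormal_distress:
        # replace distress margins by moment-matched shifted lognormals
        for j, o in enumerate(OUTCOMES):
            if o in DISTRESS_OUTCOMES:
                for arr, mu, sd in ((pre, pre_means[j], pre_sds[j]),
                                    (post, post_means[j], post_sds[j])):
                    u = (arr[:, j] - arr[:, j].mean()) / max(arr[:, j].std(), 1e-12)
                    sigma = 0.6
                    ln = np.exp(sigma * u)
                    ln = (ln - ln.mean()) / ln.std() * sd + mu
                    arr[:, j] = ln

    scales = outcome_scales()
    truncation: dict[str, float] = {}
    clipped: dict[str, float] = {}
    for j, o in enumerate(OUTCOMES):
        lo, hi = scales[o].score_bounds()
        out = np.mean((pre[:, j] < lo) | (pre[:, j] > hi)) / 2 + np.mean(
            (post[:, j] < lo) | (post[:, j] > hi)
        ) / 2
        truncation[o] = float(out)
        if cfg.bounds_mode == "clip":
            pre[:, j] = np.clip(pre[:, j], lo, hi)
            post[:, j] = np.clip(post[:, j], lo, hi)
            clipped[o] = float(out)
        else:
            clipped[o] = 0.0
        if cfg.round_scores and scales[o].scoring_rule != "mean":
            pre[:, j] = np.round(pre[:, j])
            post[:, j] = np.round(post[:, j])

    ids = [f"P{i + 1:04d}" for i in range(n)]
    cohorts = np.where(is_student, "student", "general")
    rows = []
    drop_post = set()
    if cfg.missing_post_fraction > 0:
        n_drop = int(round(cfg.missing_post_fraction * n))
        drop_post = set(rng.permutation(n)[:n_drop])
    for i in range(n):
        rows.append(
            {"participant_id": ids[i], "cohort": cohorts[i], "timepoint": "pre",
             **{o: pre[i, j] for j, o in enumerate(OUTCOMES)}}
        )
        if i not in drop_post:
            rows.append(
                {"participant_id": ids[i], "cohort": cohorts[i], "timepoint": "post",
                 **{o: post[i, j] for j, o in enumerate(OUTCOMES)}}
            )
    data = pd.DataFrame(rows)
    return CohortResult(data=data, config=cfg, truncation=truncation, clipped=clipped)


def write_cohort(result: CohortResult, path) -> None:
    """Write cohort CSV with a provenance header comment and side-car JSON."""
    path = str(path)
    provenance = {
        "generator": "dualchange.synthetic.generate_cohort",
        "config": result.config.to_dict(),
        "truncation": dict(result.truncation),
    }
    with open(path, "w") as fh:
        fh.write(f"# generated by dualchange (seed={result.config.seed})\n")
        result.data.to_csv(fh, index=False)
    with open(path + ".json", "w") as fh:
        json.dump(provenance, fh, indent=2, sort_keys=True)
        fh.write("\n")


def generate_item_level(
    scale: ScaleDefinition,
    target_alpha: float,
    n: int,
    seed: int = 0,
) -> pd.DataFrame:
    """Item responses from a one-factor model with population alpha = target.

    For ``k`` parallel items with inter-item correlation ``rho``,
    alpha = k rho / (1 + (k-1) rho); loadings are chosen by inverting
    this, with a small pre-compensation for the variance added when
    responses are discretised to the item range.
    """
    if n < 2:
        raise InputError("generate_item_level needs n >= 2 (alpha undefined for n=1)")
    if not 0 <= target_alpha < 1:
        raise InputError(f"target_alpha must be in [0, 1), got {target_alpha}")
    k = scale.item_count
    rho = target_alpha / (k - (k - 1) * target_alpha)
    # discretisation adds ~1/12 rounding variance per item; pre-compensate
    half_range = (scale.item_max - scale.item_min) / 2.0
    spread = half_range / 2.2
    rho_gen = rho * (spread**2 + 1.0 / 12.0) / spread**2
    if rho_gen >= 0.999:
        att = spread**2 / (spread**2 + 1.0 / 12.0)
        alpha_max = k * att / (1 + (k - 1) * att)
        raise InputError(
            f"target_alpha={target_alpha} unattainable for {k} items on "
            f"[{scale.item_min}, {scale.item_max}]; attainable bound ~{alpha_max:.3f}"
        )
    rng = np.random.default_rng(seed)
    factor = rng.standard_normal(n)
    noise = rng.standard_normal((n, k))
    latent = np.sqrt(rho_gen) * factor[:, None] + np.sqrt(1 - rho_gen) * noise
    center = (scale.item_min + scale.item_max) / 2.0
    items = np.clip(
        np.round(center + spread * latent), scale.item_min, scale.item_max
    ).astype(int)
    cols = [f"{scale.name}_{i}" for i in range(1, k + 1)]
    return pd.DataFrame(items, columns=cols)
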