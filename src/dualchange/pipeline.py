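"""End-to-end analysis pipeline: config, orchestration and outputs.

``run_pipeline`` takes a :class:`RunConfig` (input CSV or simulation
parameters plus analysis options), enforces complete-case inclusion,
and produces a result bundle: a pre/post summary table with univariate
tests, the multivariate test block, reliable-change tables and pattern
frequencies, distress-type subgroup breakdowns, a baseline-stratified
comparison table, the outcome correlation matrix, and optional
internal-consistency coefficients when item-level input is supplied.
Every default, exclusion and degenerate stage is recorded in the run
log, which suffices to reproduce the run.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import group_stats, reliable_change as rc, scales as sc, synthetic
from .errors import ConfigError, DataError, DegenerateStatisticsError, InputError

__all__ = [
    "RunConfig",
    "ResultBundle",
    "run_pipeline",
    "format_report",
    "wide_from_long",
]


def wide_from_long(long: pd.DataFrame) -> pd.DataFrame:
    """Pivot a long participant x timepoint table to one row per participant.

    Keeps only participants present at both timepoints with all six
    outcomes observed (complete cases); columns become ``pre_<outcome>``
    and ``post_<outcome>``.
    """
    pre = long[long["timepoint"] == "pre"].set_index("participant_id")
    post = long[long["timepoint"] == "post"].set_index("participant_id")
    common = pre.index.intersection(post.index)
    cols = list(sc.OUTCOMES)
    keep = [
        pid
        for pid in common
        if not (pre.loc[pid, cols].isna().any() or post.loc[pid, cols].isna().any())
    ]
    wide = pd.DataFrame({"participant_id": [str(p) for p in keep]})
    if "cohort" in long.columns:
        wide["cohort"] = pre.loc[keep, "cohort"].to_numpy()
    for o in sc.OUTCOMES:
        wide[f"pre_{o}"] = pre.loc[keep, o].to_numpy(dtype=float)
        wide[f"post_{o}"] = post.loc[keep, o].to_numpy(dtype=float)
    return wide

REQUIRED_COLUMNS = ("participant_id", "timepoint")


@dataclass
class RunConfig:
    """Validated configuration of one analysis run."""

    input_csv: Optional[str] = None
    simulate: Optional[synthetic.SimulationConfig] = None
    scales_file: Optional[str] = None
    sediff_variant: str = "difference"
    grouping: Mapping[str, str] = field(default_factory=lambda: dict(rc.DEFAULT_GROUPING))
    rci_threshold: float = rc.DEFAULT_THRESHOLD
    outlier_threshold: float = 3.29
    exclude: tuple[str, ...] = ()
    ttest_mode: str = "welch"
    transform_check: bool = False
    output_dir: Optional[str] = None
    seed: int = 0

    def validate(self) -> "RunConfig":
        if (self.input_csv is None) == (self.simulate is None):
            raise ConfigError("exactly one of input_csv or simulate must be set")
        if self.sediff_variant not in rc.SEDIFF_VARIANTS:
            raise ConfigError(f"unknown sediff_variant {self.sediff_variant!r}")
        if self.ttest_mode not in ("welch", "pooled"):
            raise ConfigError(f"unknown ttest_mode {self.ttest_mode!r}")
        if self.rci_threshold <= 0:
            raise ConfigError("rci_threshold must be > 0")
        if self.outlier_threshold <= 0:
            raise ConfigError("outlier_threshold must be > 0")
        for outcome in sc.OUTCOMES:
            if outcome not in self.grouping:
                raise ConfigError(f"grouping is missing outcome {outcome!r}")
            if self.grouping[outcome] not in rc.DIMENSIONS:
                raise ConfigError(f"invalid grouping for {outcome!r}")
        return self

    def to_dict(self) -> dict:
        d = {
            "input_csv": self.input_csv,
            "simulate": self.simulate.to_dict() if self.simulate else None,
            "scales_file": self.scales_file,
            "sediff_variant": self.sediff_variant,
            "grouping": dict(self.grouping),
            "rci_threshold": self.rci_threshold,
            "outlier_threshold": self.outlier_threshold,
            "exclude": list(self.exclude),
            "ttest_mode": self.ttest_mode,
            "transform_check": self.transform_check,
            "output_dir": self.output_dir,
            "seed": self.seed,
        }
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "RunConfig":
        known = set(cls.__dataclass_fields__)
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown run config keys: {sorted(unknown)}")
        kwargs = dict(d)
        if kwargs.get("simulate") is not None:
            kwargs["simulate"] = synthetic.SimulationConfig.from_dict(kwargs["simulate"])
        if kwargs.get("exclude") is not None:
            kwargs["exclude"] = tuple(str(x) for x in kwargs["exclude"])
        kwargs = {k: v for k, v in kwargs.items() if v is not None or k in ("input_csv",)}
        cfg = cls(**kwargs)
        return cfg.validate()

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if not isinstance(raw, Mapping):
            raise ConfigError(f"{path}: expected a mapping")
        return cls.from_dict(raw)


@dataclass
class ResultBundle:
    config: RunConfig
    table2: pd.DataFrame
    table3: pd.DataFrame
    rci: pd.DataFrame
    patterns: pd.DataFrame
    frequencies: rc.PatternFrequencies
    subgroups: Mapping[str, rc.SubgroupBreakdown]
    manova: Mapping[str, Optional[group_stats.ManovaResult]]
    correlations: group_stats.CorrelationResult
    alphas: Mapping[str, float]
    outlier_flags: pd.Series
    run_log: dict
    cohort: Optional[pd.DataFrame] = None

    def write(self, outdir) -> None:
        os.makedirs(outdir, exist_ok=True)

        def path(name: str) -> str:
            return os.path.join(outdir, name)

        self.table2.to_csv(path("table2.csv"), index=False)
        self.table3.to_csv(path("table3.csv"), index=False)
        self.rci.to_csv(path("rci.csv"), index=False)
        self.patterns.to_csv(path("patterns.csv"), index=False)
        self.correlations.matrix.to_csv(path("correlations_pre.csv"))
        if self.cohort is not None:
            self.cohort.to_csv(path("cohort.csv"), index=False)
        freq = self.frequencies
        summary = {
            "frequencies": {
                "counts": dict(freq.counts),
                "n_participants": freq.n_participants,
                "improvement_denominator": freq.improvement_denominator,
                "fractions": dict(freq.fractions),
                "percent_display": dict(freq.percent_display),
                "any_reliable_count": freq.any_reliable_count,
                "any_reliable_fraction": freq.any_reliable_fraction,
                "any_reliable_percent_display": freq.any_reliable_percent_display,
            },
            "subgroups": {
                k: {
                    "denominator": v.denominator,
                    "counts": dict(v.counts),
                    "fractions": dict(v.fractions),
                    "percent_display": dict(v.percent_display),
                }
                for k, v in self.subgroups.items()
            },
            "manova": {
                k: (vars(v) if v is not None else None) for k, v in self.manova.items()
            },
            "alphas": dict(self.alphas),
        }
        with open(path("summary.json"), "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True)
            fh.write("\n")
        with open(path("run_log.json"), "w") as fh:
            json.dump(self.run_log, fh, indent=2, sort_keys=True)
            fh.write("\n")
        with open(path("report.txt"), "w") as fh:
            fh.write(format_report(self))


def _clamp(value: float, scale: sc.ScaleDefinition) -> float:
    lo, hi = scale.score_bounds()
    return min(max(value, lo), hi)


def _load_long(cfg: RunConfig, log: dict):
    scale_defs = sc.default_scales()
    if cfg.scales_file:
        scale_defs = sc.load_scales(cfg.scales_file, base=scale_defs)
        log["scales_file"] = cfg.scales_file
    cohort_df = None
    if cfg.simulate is not None:
        sim = replace(cfg.simulate, seed=cfg.seed)
        result = synthetic.generate_cohort(sim)
        long = result.data
        cohort_df = result.data
        log["simulated"] = True
        log["simulation"] = sim.resolved().to_dict()
        log["truncation"] = dict(result.truncation)
    else:
        try:
            long = pd.read_csv(cfg.input_csv, comment="#")
        except (OSError, ValueError) as exc:
            raise DataError(f"cannot read input {cfg.input_csv!r}: {exc}") from exc
        log["simulated"] = False
        log["input_csv"] = cfg.input_csv
    for col in REQUIRED_COLUMNS:
        if col not in long.columns:
            raise DataError(f"input is missing required column {col!r}")
    if "cohort" not in long.columns:
        long = long.copy()
        long["cohort"] = "general"
        log["note_cohort"] = "no cohort column; all participants treated as 'general'"

    item_columns: dict[str, list[str]] = {}
    if not all(o in long.columns for o in sc.OUTCOMES):
        long, item_columns = sc.score_items_frame(long, scale_defs)
        missing = [o for o in sc.OUTCOMES if o not in long.columns]
        if missing:
            raise DataError(
                f"input provides neither scale-level nor item-level data for {missing}"
            )
    return long, scale_defs, item_columns, cohort_df


def _pivot_complete(long: pd.DataFrame, cfg: RunConfig, log: dict) -> pd.DataFrame:
    bad_tp = set(long["timepoint"].unique()) - {"pre", "post"}
    if bad_tp:
        raise DataError(f"unknown timepoint labels {sorted(bad_tp)}")
    wide_parts = {}
    for tp in ("pre", "post"):
        part = long[long["timepoint"] == tp].set_index("participant_id")
        dup = part.index[part.index.duplicated()]
        if len(dup):
            raise DataError(f"duplicate {tp} rows for participants {sorted(set(dup))[:5]}")
        wide_parts[tp] = part
    pre, post = wide_parts["pre"], wide_parts["post"]
    common = pre.index.intersection(post.index)
    complete_ids = [
        pid
        for pid in common
        if not (
            pd.isna([pre.loc[pid, o] for o in sc.OUTCOMES]).any()
            or pd.isna([post.loc[pid, o] for o in sc.OUTCOMES]).any()
        )
    ]
    all_ids = long["participant_id"].astype(str).unique()
    log["n_input_participants"] = int(len(all_ids))
    log["n_complete_cases"] = len(complete_ids)
    log["n_excluded_incomplete"] = int(len(all_ids)) - len(complete_ids)
    excluded = [pid for pid in complete_ids if str(pid) in set(cfg.exclude)]
    log["excluded_by_config"] = [str(p) for p in excluded]
    complete_ids = [pid for pid in complete_ids if str(pid) not in set(cfg.exclude)]
    if len(complete_ids) < 2:
        raise DataError("fewer than 2 participants with both timepoints")
    wide = pd.DataFrame({"participant_id": [str(p) for p in complete_ids]})
    wide["cohort"] = pre.loc[complete_ids, "cohort"].to_numpy()
    for o in sc.OUTCOMES:
        wide[f"pre_{o}"] = pre.loc[complete_ids, o].to_numpy(dtype=float)
        wide[f"post_{o}"] = post.loc[complete_ids, o].to_numpy(dtype=float)
    return wide


def run_pipeline(config: RunConfig) -> ResultBundle:
    """Run the full analysis; deterministic given config + seed."""
    cfg = config.validate()
    log: dict = {"config": cfg.to_dict(), "defaults": {
        "sediff_variant": cfg.sediff_variant,
        "rci_threshold": cfg.rci_threshold,
        "outlier_threshold": cfg.outlier_threshold,
        "ttest_mode": cfg.ttest_mode,
        "grouping": dict(cfg.grouping),
    }, "notes": []}
    long, scale_defs, item_columns, cohort_df = _load_long(cfg, log)
    wide = _pivot_complete(long, cfg, log)
    outcome_defs = sc.outcome_scales(scale_defs)
    n = len(wide)

    # outlier flags (report only; exclusion is an explicit config action)
    score_cols = [f"{tp}_{o}" for o in sc.OUTCOMES for tp in ("pre", "post")]
    outlier_flags = group_stats.flag_univariate_outliers(
        wide[score_cols], threshold=cfg.outlier_threshold
    )
    outlier_flags.index = wide["participant_id"]
    log["outliers_flagged"] = [
        str(p) for p, flagged in outlier_flags.items() if flagged
    ]

    # baseline problematic flags
    flags_by_pid: dict[str, Mapping[str, Optional[bool]]] = {}
    problematic_pre: dict[str, np.ndarray] = {o: np.zeros(n, dtype=bool) for o in sc.OUTCOMES}
    problematic_post: dict[str, np.ndarray] = {o: np.zeros(n, dtype=bool) for o in sc.OUTCOMES}
    for i, row in wide.iterrows():
        for stash, prefix in ((problematic_pre, "pre"), (problematic_post, "post")):
            panel = sc.OutcomePanel(
                participant_id=row["participant_id"],
                cohort=row["cohort"],
                timepoint=prefix,
                **{
                    o: _clamp(row[f"{prefix}_{o}"], outcome_defs[o])
                    for o in sc.OUTCOMES
                },
            )
            pf = sc.classify_problematic(panel, outcome_defs)
            for o in sc.OUTCOMES:
                stash[o][i] = bool(pf.flags[o])
            if prefix == "pre":
                flags_by_pid[row["participant_id"]] = pf.flags

    # Table-2 analogue: summary stats + univariate repeated-measures tests
    t2_rows = []
    for o in sc.OUTCOMES:
        pre_v = wide[f"pre_{o}"].to_numpy(dtype=float)
        post_v = wide[f"post_{o}"].to_numpy(dtype=float)
        try:
            res = group_stats.paired_rm_anova(pre_v, post_v)
            f_stat, p_val, eta = res.f_stat, res.p_value, res.partial_eta_sq
        except DegenerateStatisticsError:
            f_stat = p_val = eta = math.nan
            log["notes"].append(f"paired test degenerate for {o}")
        t2_rows.append(
            {
                "outcome": o,
                "pre_mean": pre_v.mean(),
                "pre_sd": np.std(pre_v, ddof=1),
                "pre_problematic_n": int(problematic_pre[o].sum()),
                "post_mean": post_v.mean(),
                "post_sd": np.std(post_v, ddof=1),
                "post_problematic_n": int(problematic_post[o].sum()),
                "f_stat": f_stat,
                "df_num": 1,
                "df_den": n - 1,
                "p_value": p_val,
                "partial_eta_sq": eta,
            }
        )
    table2 = pd.DataFrame(t2_rows)

    # MANOVA block
    diffs = np.column_stack(
        [wide[f"post_{o}"] - wide[f"pre_{o}"] for o in sc.OUTCOMES]
    )
    pre_mat = np.column_stack([wide[f"pre_{o}"] for o in sc.OUTCOMES])
    manova: dict[str, Optional[group_stats.ManovaResult]] = {}
    try:
        manova["time"] = group_stats.one_sample_manova(diffs)
    except (DataError, DegenerateStatisticsError) as exc:
        manova["time"] = None
        log["notes"].append(f"time MANOVA unavailable: {exc}")
    groups = wide["cohort"].to_numpy()
    if len(pd.unique(groups)) == 2:
        for key, mat in (("baseline_group", pre_mat), ("time_by_group", diffs)):
            try:
                manova[key] = group_stats.two_group_manova(mat, groups)
            except (DataError, DegenerateStatisticsError) as exc:
                manova[key] = None
                log["notes"].append(f"{key} MANOVA unavailable: {exc}")
    else:
        manova["baseline_group"] = None
        manova["time_by_group"] = None
        log["notes"].append("single cohort label; group MANOVAs skipped")

    # reliable change
    tables = rc.compute_reliable_change(
        wide,
        grouping=cfg.grouping,
        variant=cfg.sediff_variant,
        threshold=cfg.rci_threshold,
    )
    if tables.degenerate_outcomes:
        log["notes"].append(
            f"degenerate SEdiff for outcomes: {tables.degenerate_outcomes}"
        )
    frequencies = rc.pattern_frequencies(tables.pattern_objects, tables.results)
    subgroups = {
        dt: rc.subgroup_pattern_frequencies(
            tables.results, flags_by_pid, dt, grouping=cfg.grouping
        )
        for dt in ("depression", "anxiety", "stress")
    }

    # Table-3 analogue: baseline-stratified change comparisons
    t3_rows = []
    for o in sc.OUTCOMES:
        flags = problematic_pre[o]
        pre_v = wide[f"pre_{o}"].to_numpy(dtype=float)
        post_v = wide[f"post_{o}"].to_numpy(dtype=float)
        try:
            res = group_stats.baseline_stratified_change_test(
                o, pre_v, post_v, flags, mode=cfg.ttest_mode
            )
        except (DataError, DegenerateStatisticsError) as exc:
            log["notes"].append(f"stratified test unavailable for {o}: {exc}")
            continue
        try:
            u_stat, u_p = group_stats.mann_whitney_check(post_v - pre_v, flags)
        except (DataError, DegenerateStatisticsError):
            u_stat = u_p = math.nan
        row = vars(res).copy()
        row["mann_whitney_u"] = u_stat
        row["mann_whitney_p"] = u_p
        t3_rows.append(row)
    table3 = pd.DataFrame(t3_rows)

    # correlations at baseline
    pre_frame = pd.DataFrame(pre_mat, columns=list(sc.OUTCOMES))
    correlations = group_stats.outcome_correlations(pre_frame, sc.OUTCOMES)

    # internal consistency (only with item-level input)
    alphas: dict[str, float] = {}
    if item_columns:
        pre_rows = long[long["timepoint"] == "pre"]
        for name, cols in item_columns.items():
            block = pre_rows[cols].dropna()
            try:
                alphas[name] = sc.cronbach_alpha(block.to_numpy(dtype=float))
            except (DegenerateStatisticsError, InputError) as exc:
                log["notes"].append(f"alpha unavailable for {name}: {exc}")

    log["n_analyzed"] = n
    return ResultBundle(
        config=cfg,
        table2=table2,
        table3=table3,
        rci=tables.rci,
        patterns=tables.patterns,
        frequencies=frequencies,
        subgroups=subgroups,
        manova=manova,
        correlations=correlations,
        alphas=alphas,
        outlier_flags=outlier_flags,
        run_log=log,
        cohort=cohort_df,
    )


def _fmt_p(p: float) -> str:
    if math.isnan(p):
        return "NA"
    return "<.001" if p < 0.001 else f"{p:.3f}"


def format_report(bundle: ResultBundle) -> str:
    """Publication-style text rendering of the result bundle."""
    lines = []
    lines.append("Pre/post summary and univariate tests")
    lines.append("-" * 72)
    header = (
        f"{'outcome':<20}{'pre M (SD)':>16}{'post M (SD)':>16}"
        f"{'F (df)':>12}{'P':>8}{'eta^2':>7}"
    )
    lines.append(header)
    for _, r in bundle.table2.iterrows():
        pre = f"{r['pre_mean']:.2f} ({r['pre_sd']:.2f})"
        post = f"{r['post_mean']:.2f} ({r['post_sd']:.2f})"
        fdf = f"{r['f_stat']:.2f} (1)" if not math.isnan(r["f_stat"]) else "NA"
        eta = f"{r['partial_eta_sq']:.2f}" if not math.isnan(r["partial_eta_sq"]) else "NA"
        lines.append(
            f"{r['outcome']:<20}{pre:>16}{post:>16}{fdf:>12}"
            f"{_fmt_p(r['p_value']):>8}{eta:>7}"
        )
    lines.append("")
    lines.append("Multivariate tests")
    lines.append("-" * 72)
    for key, res in bundle.manova.items():
        if res is None:
            lines.append(f"{key:<16} unavailable")
        else:
            lines.append(
                f"{key:<16} F({res.df_num},{res.df_den})={res.f_stat:.2f}, "
                f"P={_fmt_p(res.p_value)}, Wilks lambda={res.wilks_lambda:.2f}, "
                f"partial eta^2={res.partial_eta_sq:.2f}"
            )
    lines.append("")
    freq = bundle.frequencies
    lines.append("Reliable change patterns")
    lines.append("-" * 72)
    if freq.any_reliable_count is not None:
        lines.append(
            f"any reliable change: {freq.any_reliable_count}/{freq.n_participants} "
            f"({freq.any_reliable_percent_display}%)"
        )
    denom = freq.improvement_denominator
    for p in ("both", "wellbeing_only", "distress_only"):
        lines.append(
            f"{p:<16} {freq.counts[p]}/{denom} ({freq.percent_display[p]}%)"
        )
    lines.append(f"{'none':<16} {freq.counts['none']}/{freq.n_participants}")
    lines.append("")
    lines.append("Baseline-stratified change comparisons")
    lines.append("-" * 72)
    for _, r in bundle.table3.iterrows():
        lines.append(
            f"{r['outcome']:<20} t({r['df']:.0f})={r['t_stat']:.2f}, "
            f"P={_fmt_p(r['p_value'])}, d={abs(r['cohen_d']):.2f} "
            f"(n={r['n_problematic']}/{r['n_healthy']}, {r['mode']})"
        )
    lines.append("")
    return "\n".join(lines)
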