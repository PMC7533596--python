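"""Run orchestration: calibration -> kinematics -> displacement -> statistics.

A run is driven by one YAML config (:class:`RunConfig`).  Every knob the
source protocol leaves unspecified (classification tolerances, stillness
criterion, the D-equation scaling variant, per-step vs per-mouse unit of
analysis) surfaces here with a documented default.  Outputs are delimited
tables plus a plain-text report with a provenance block; identical config
and inputs give byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import io as gio
from .displacement import DVariant, curves_from_step, group_distance_summary, curve_distance
from .gait import (
    MARKERS, StepTrace, check_step_counts, classify_step_pair,
    pair_steps, step_kinematics, step_type_distribution,
)
from .groupstats import GroupSample, TestResult, kruskal_wallis, multiple_t_bonferroni, wilcoxon_pairwise
from .openfield import ArenaGeometry, compute_metrics

__all__ = [
    "RunConfig", "RunReport", "validate_inputs",
    "run_tunnel_analysis", "run_openfield_analysis",
    "analyze_gait", "analyze_openfield",
]

_KNOWN_KEYS = {
    "annotations", "calibration", "tracks", "group_table", "units",
    "gait_fps", "track_fps", "time_tol", "length_tol",
    "still_speed_threshold", "still_min_duration", "d_variant", "rezero",
    "step_filters", "markers", "sides", "arena_width", "arena_depth",
    "reference_group", "seed", "emit_pairs", "equal_var",
}


@dataclass
class RunConfig:
    """Configuration of one analysis run.

    Defaults for protocol-unspecified knobs: tolerances 0.15, stillness
    0.5 cm/s over 0.5 s, D variant ``mean_both``, per-step x re-zeroing on.
    """

    annotations: str | None = None
    calibration: str | None = None
    tracks: str | None = None
    group_table: str | None = None
    units: str = "mm"  # "mm" or "px" (px applies the calibration homography)
    gait_fps: float = 240.0
    track_fps: float = 30.0
    time_tol: float = 0.15
    length_tol: float = 0.15
    still_speed_threshold: float = 0.5
    still_min_duration: float = 0.5
    d_variant: DVariant = "mean_both"
    rezero: bool = True
    step_filters: tuple[str, ...] = ("all", "TypeA")
    markers: tuple[str, ...] = MARKERS
    sides: tuple[str, ...] = ("left", "right")
    arena_width: float = 45.0
    arena_depth: float = 32.0
    reference_group: str = "control"
    seed: int = 0
    emit_pairs: bool = False
    equal_var: bool = False

    def __post_init__(self) -> None:
        if self.units not in ("mm", "px"):
            raise ValueError("units must be 'mm' or 'px'")
        if self.units == "px" and self.annotations and not self.calibration:
            raise ValueError("pixel units require a calibration file")
        for f in ("step_filters", "markers", "sides"):
            setattr(self, f, tuple(getattr(self, f)))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(raw) - _KNOWN_KEYS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def canonical(self) -> str:
        return json.dumps(asdict(self), sort_keys=True, default=str)


@dataclass
class RunReport:
    tables: dict[str, pd.DataFrame]
    provenance: dict[str, str]
    warnings: list[str] = field(default_factory=list)

    def write(self, outdir) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        for name in sorted(self.tables):
            gio.write_table(self.tables[name], out / f"{name}.csv")
        lines = ["# run report", ""]
        lines += [f"{k}: {v}" for k, v in sorted(self.provenance.items())]
        lines.append("")
        lines.append(f"warnings ({len(self.warnings)}):")
        lines += [f"  - {w}" for w in self.warnings]
        (out / "report.txt").write_text("\n".join(lines) + "\n")


def _provenance(config: RunConfig, extra: Mapping[str, str] | None = None) -> dict[str, str]:
    from . import __version__
    canon = config.canonical()
    prov = {
        "config_hash": hashlib.sha256(canon.encode()).hexdigest(),
        "gaitkit_version": __version__,
        "seed": str(config.seed),
    }
    for key in ("annotations", "calibration", "tracks", "group_table"):
        p = getattr(config, key)
        if p and Path(p).exists():
            prov[f"sha256_{key}"] = hashlib.sha256(Path(p).read_bytes()).hexdigest()
    if extra:
        prov.update(extra)
    return prov


def validate_inputs(config: RunConfig) -> list[dict[str, str]]:
    """Schema-check every referenced input file.

    Returns findings as dicts with ``level`` (error/warning/info), ``file``,
    ``line`` (1-based, header = line 1; empty when not row-specific) and
    ``message``.  Well-formed inputs give an empty list of errors; step
    counts outside 5-7 per hindlimb produce warnings, not errors.
    """
    findings: list[dict[str, str]] = []

    def add(level: str, file: str, line: str, message: str) -> None:
        findings.append({"level": level, "file": str(file), "line": line,
                         "message": message})

    for key in ("annotations", "calibration", "tracks", "group_table"):
        p = getattr(config, key)
        if p and not Path(p).exists():
            add("error", p, "", f"{key} file does not exist")

    if config.annotations and Path(config.annotations).exists():
        df = pd.read_csv(config.annotations)
        missing = [c for c in gio.ANNOTATION_COLUMNS if c not in df.columns]
        if missing:
            add("error", config.annotations, "1", f"missing columns {missing}")
        else:
            bad = ~df["marker"].isin(MARKERS)
            for idx in df.index[bad]:
                add("error", config.annotations, str(idx + 2),
                    f"unknown marker name {df.loc[idx, 'marker']!r}")
            bad_side = ~df["side"].isin(("left", "right"))
            for idx in df.index[bad_side]:
                add("error", config.annotations, str(idx + 2),
                    f"unknown side {df.loc[idx, 'side']!r}")
            for col in ("x", "y"):
                vals = pd.to_numeric(df[col], errors="coerce")
                for idx in df.index[vals.isna()]:
                    add("error", config.annotations, str(idx + 2),
                        f"non-numeric {col} value {df.loc[idx, col]!r}")
            if not (bad.any() or bad_side.any()):
                counts = (
                    df.drop_duplicates(["mouse_id", "side", "step"])
                    .groupby(["mouse_id", "side"]).size()
                )
                for (mouse, side), n in counts.items():
                    if not 5 <= n <= 7:
                        add("warning", config.annotations, "",
                            f"{mouse} {side}: {n} steps (expected 5-7)")
                n_left = counts.xs("left", level="side").sum() if "left" in counts.index.get_level_values(1) else 0
                n_right = counts.xs("right", level="side").sum() if "right" in counts.index.get_level_values(1) else 0
                add("info", config.annotations, "",
                    f"hindlimb steps: {n_left} left, {n_right} right")
            if config.group_table and Path(config.group_table).exists():
                groups = gio.read_group_table(config.group_table)
                missing_mice = sorted(set(df["mouse_id"].astype(str)) - set(groups))
                if missing_mice:
                    add("error", config.group_table, "",
                        f"mice missing from group table: {missing_mice}")

    if config.calibration and Path(config.calibration).exists():
        try:
            gio.load_homography(config.calibration)
        except (ValueError, KeyError) as exc:
            add("error", config.calibration, "", str(exc))

    if config.tracks and Path(config.tracks).exists():
        tdf = pd.read_csv(config.tracks)
        missing = [c for c in gio.TRACK_COLUMNS if c not in tdf.columns]
        if missing:
            add("error", config.tracks, "1", f"missing columns {missing}")
    return findings


# ---------------------------------------------------------------------------
# analysis on in-memory objects
# ---------------------------------------------------------------------------

def _kinematics_table(steps: Sequence[StepTrace]) -> pd.DataFrame:
    rows = []
    for s in sorted(steps, key=lambda s: (s.mouse_id, s.side, s.step_index)):
        k = step_kinematics(s)
        rows.append({
            "mouse_id": s.mouse_id, "group": s.group, "side": s.side,
            "step": s.step_index, "duration_s": k.duration,
            "stride_length_mm": k.stride_length, "speed_mm_s": k.speed,
        })
    return pd.DataFrame(rows)


def _classify_all(
    steps: Sequence[StepTrace], baseline: float, time_tol: float, length_tol: float
) -> pd.DataFrame:
    by_mouse: dict[str, dict[str, list[StepTrace]]] = {}
    for s in steps:
        by_mouse.setdefault(s.mouse_id, {"left": [], "right": []})[s.side].append(s)
    rows = []
    for mouse in sorted(by_mouse):
        group = by_mouse[mouse]["left"][0].group if by_mouse[mouse]["left"] else \
            by_mouse[mouse]["right"][0].group
        for ls, rs in pair_steps(by_mouse[mouse]["left"], by_mouse[mouse]["right"]):
            label = classify_step_pair(
                step_kinematics(ls), step_kinematics(rs),
                baseline_length=baseline, time_tol=time_tol, length_tol=length_tol,
            ).label
            rows.append({
                "mouse_id": mouse, "group": group,
                "left_step": ls.step_index, "right_step": rs.step_index,
                "label": label,
            })
    return pd.DataFrame(rows)


def _stats_rows(results: Sequence[TestResult], analysis: str,
                sizes: Mapping[str, int]) -> list[dict]:
    rows = []
    for r in results:
        comp = " vs ".join(r.comparison)
        rows.append({
            "analysis": analysis, "comparison": comp,
            "statistic": r.statistic, "p_raw": r.p_raw,
            "p_adjusted": r.p_adjusted, "method": r.method,
            "n_a": sizes.get(r.comparison[0], len(r.comparison)) if len(r.comparison) == 2 else sum(sizes.values()),
            "n_b": sizes.get(r.comparison[1], 0) if len(r.comparison) == 2 else 0,
        })
    return rows


def _pairwise_t_family(
    values_by_group: Mapping[str, np.ndarray], analysis: str, equal_var: bool,
) -> list[dict]:
    """All pairwise Welch t-tests among the groups, Bonferroni over the family."""
    labels = sorted(values_by_group)
    pairs = [(a, b) for i, a in enumerate(labels) for b in labels[i + 1:]]
    samples = {}
    for g in labels:
        vals = np.asarray(values_by_group[g], dtype=float)
        samples[g] = GroupSample(g, vals) if len(vals) >= 2 else None
    comparisons, kept = [], []
    degenerate = []
    for a, b in pairs:
        sa, sb = samples[a], samples[b]
        if sa is None or sb is None or (
            np.var(sa.values) == 0 and np.var(sb.values) == 0
        ):
            degenerate.append((a, b))
            continue
        comparisons.append((sa, sb))
        kept.append((a, b))
    rows = []
    sizes = {g: len(values_by_group[g]) for g in labels}
    if comparisons:
        rows += _stats_rows(
            multiple_t_bonferroni(comparisons, equal_var=equal_var), analysis, sizes
        )
    for a, b in degenerate:
        rows.append({
            "analysis": analysis, "comparison": f"{a} vs {b}",
            "statistic": float("nan"), "p_raw": float("nan"),
            "p_adjusted": float("nan"), "method": "degenerate",
            "n_a": sizes[a], "n_b": sizes[b],
        })
    return rows


def analyze_gait(
    steps: Sequence[StepTrace],
    groups: Mapping[str, str],
    config: RunConfig | None = None,
) -> RunReport:
    """Full tunnel-walk analysis on in-memory step traces."""
    config = config or RunConfig()
    warnings_log = list(check_step_counts(steps))

    missing = sorted({s.mouse_id for s in steps} - set(groups))
    if missing:
        raise ValueError(f"mice missing from group table: {missing}")

    kin = _kinematics_table(steps)
    kin["group"] = [groups[m] for m in kin["mouse_id"]]

    ref = config.reference_group
    ctrl_strides = kin.loc[kin["group"] == ref, "stride_length_mm"]
    if ctrl_strides.empty:
        raise ValueError(f"no steps in reference group {ref!r}")
    baseline = float(ctrl_strides.median())

    classes = _classify_all(steps, baseline, config.time_tol, config.length_tol)
    classes["group"] = [groups[m] for m in classes["mouse_id"]]
    dist = step_type_distribution(classes[["group", "label"]])
    dist = dist.reset_index(names="group")

    # speed statistics: per-step values pooled within group (unit of analysis
    # follows the ordinate of the speed figures); per side, all vs Type-A steps
    typea = {
        (r.mouse_id, r.left_step, "left") for r in classes.itertuples() if r.label == "A"
    } | {
        (r.mouse_id, r.right_step, "right") for r in classes.itertuples() if r.label == "A"
    }
    speed_rows: list[dict] = []
    for side in config.sides:
        sub = kin[kin["side"] == side]
        for filt in config.step_filters:
            if filt == "TypeA":
                mask = [
                    (r.mouse_id, r.step, r.side) in typea for r in sub.itertuples()
                ]
                fsub = sub[np.array(mask, dtype=bool)] if len(sub) else sub
            else:
                fsub = sub
            vals = {g: gsub["speed_mm_s"].to_numpy()
                    for g, gsub in fsub.groupby("group")}
            if len(vals) >= 2:
                speed_rows += _pairwise_t_family(
                    vals, f"speed_{side}_{filt}", config.equal_var
                )
    speed_stats = pd.DataFrame(speed_rows)

    # displacement-curve summaries per marker/side/filter
    dsum_frames = []
    pair_rows = []
    for side in config.sides:
        side_steps = [s for s in steps if s.side == side]
        for filt in config.step_filters:
            if filt == "TypeA":
                fsteps = [
                    s for s in side_steps
                    if (s.mouse_id, s.step_index, s.side) in typea
                ]
            else:
                fsteps = side_steps
            for marker in config.markers:
                curves = [
                    curves_from_step(s, rezero=config.rezero, markers=[marker])[marker]
                    for s in fsteps
                ]
                if not curves:
                    continue
                mice_present = {c.mouse_id for c in curves}
                n_ref = sum(1 for m in mice_present if groups[m] == ref)
                if n_ref < 2:
                    warnings_log.append(
                        f"distance summary skipped for {marker}/{side}/{filt}: "
                        f"reference group has {n_ref} mice with curves"
                    )
                    continue
                dsum_frames.append(group_distance_summary(
                    curves, groups, ref, step_filter=filt, variant=config.d_variant,
                ))
                if config.emit_pairs:
                    by_mouse: dict[str, list] = {}
                    for c in curves:
                        by_mouse.setdefault(c.mouse_id, []).append(c)
                    for ma in sorted(by_mouse):
                        for mb in sorted(by_mouse):
                            if groups[mb] != ref or ma == mb:
                                continue
                            for ca in sorted(by_mouse[ma], key=lambda c: c.provenance):
                                for cb in sorted(by_mouse[mb], key=lambda c: c.provenance):
                                    d = curve_distance(ca, cb, variant=config.d_variant)
                                    pair_rows.append({
                                        "marker": marker, "side": side,
                                        "step_filter": filt,
                                        "mouse_a": ma, "step_a": ca.step_index,
                                        "mouse_b": mb, "step_b": cb.step_index,
                                        "D": d.D,
                                    })
    distance_summary = (
        pd.concat(dsum_frames, ignore_index=True) if dsum_frames else pd.DataFrame()
    )

    dstat_rows: list[dict] = []
    if not distance_summary.empty:
        for (marker, side, filt), sub in distance_summary.groupby(
            ["marker", "side", "step_filter"]
        ):
            for metric in ("D_min", "D_max"):
                vals = {g: gsub[metric].to_numpy()
                        for g, gsub in sub.groupby("group")}
                if len(vals) >= 2:
                    dstat_rows += _pairwise_t_family(
                        vals, f"{metric}_{marker}_{side}_{filt}", config.equal_var
                    )
    distance_stats = pd.DataFrame(dstat_rows)

    tables = {
        "step_kinematics": kin,
        "step_classes": classes,
        "step_type_distribution": dist,
        "speed_stats": speed_stats,
        "distance_summary": distance_summary,
        "distance_stats": distance_stats,
    }
    if config.emit_pairs:
        tables["pair_distances"] = pd.DataFrame(pair_rows)
    return RunReport(tables=tables, provenance=_provenance(config),
                     warnings=warnings_log)


def run_tunnel_analysis(config: RunConfig) -> RunReport:
    """File-driven tunnel-walk analysis (applies calibration for pixel units)."""
    if not config.annotations or not config.group_table:
        raise ValueError("tunnel analysis requires annotations and group_table paths")
    df = gio.read_step_annotations(config.annotations)
    h = None
    if config.units == "px":
        h = gio.load_homography(config.calibration)
    steps = gio.step_traces_from_frame(df, fps=config.gait_fps, homography=h)
    groups = gio.read_group_table(config.group_table)
    return analyze_gait(steps, groups, config)


def analyze_openfield(tracks, config: RunConfig | None = None) -> RunReport:
    """Open-field metrics and group statistics on in-memory tracks."""
    config = config or RunConfig()
    rows = []
    for t in sorted(tracks, key=lambda t: t.mouse_id):
        m = compute_metrics(t, config.still_speed_threshold, config.still_min_duration)
        rows.append({
            "mouse_id": t.mouse_id, "group": t.group,
            "total_distance_cm": m.total_distance,
            "moving_time_s": m.moving_time, "still_time_s": m.still_time,
            "speed_cm_s": m.speed, "periphery_time_s": m.periphery_time,
            "duration_s": m.duration,
        })
    metrics = pd.DataFrame(rows)

    stat_rows: list[dict] = []
    for metric in ("total_distance_cm", "speed_cm_s", "periphery_time_s"):
        vals = {g: sub[metric].to_numpy() for g, sub in metrics.groupby("group")}
        samples = [GroupSample(g, v) for g, v in sorted(vals.items()) if len(v) >= 2]
        sizes = {g: len(v) for g, v in vals.items()}
        if len(samples) >= 2:
            stat_rows += _stats_rows([kruskal_wallis(samples)], metric, sizes)
            labels = [s.label for s in samples]
            pair_results = []
            for i, a in enumerate(samples):
                for b in samples[i + 1:]:
                    pair_results.append(wilcoxon_pairwise(a, b))
            m_ = len(pair_results)
            pair_results = [
                TestResult(r.statistic, r.p_raw, min(1.0, m_ * r.p_raw),
                           r.comparison, r.method)
                for r in pair_results
            ]
            stat_rows += _stats_rows(pair_results, metric, sizes)
    stats = pd.DataFrame(stat_rows)
    return RunReport(
        tables={"openfield_metrics": metrics, "openfield_stats": stats},
        provenance=_provenance(config),
    )


def run_openfield_analysis(config: RunConfig) -> RunReport:
    if not config.tracks:
        raise ValueError("open-field analysis requires a tracks path")
    arena = ArenaGeometry(width=config.arena_width, depth=config.arena_depth)
    groups = gio.read_group_table(config.group_table) if config.group_table else None
    tracks = gio.read_centroid_tracks(
        config.tracks, fps=config.track_fps, arena=arena, groups=groups
    )
    return analyze_openfield(tracks, config)
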