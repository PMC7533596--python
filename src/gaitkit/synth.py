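"""Synthetic gait and open-field data with known ground truth.

No marker recordings are publicly deposited for this kind of study, so the
pipeline is exercised end-to-end on simulated data that carries the
statistical structure the analysis assumes:

* per-group step-speed distributions (defaults follow the study's printed
  all-steps means/SDs: control 27.72, cortex-injured 24.38,
  hippocampus-injured 20.66, EV-treated 30.53 mm/s, SD ~ 7);
* a stance/swing metatarsus template -- slow near-linear progression while
  the paw is planted, then a fast smoothstep advance with a half-sine
  vertical lift during swing -- with knee and ankle as offset, softened
  copies;
* a genuine step-type mixture, induced by per-pair "short step" events and
  per-limb duration/length jitter rather than by post-hoc labelling;
* smooth per-step curve-shape perturbations whose amplitude scales
  per-group, so curve-distance variability is controllable;
* bounded correlated random walks in the open-field arena with a wall
  attraction parameter (thigmotaxis) and scheduled still bouts.

Every mouse draws from its own pseudo-random stream derived from the
master seed by stable hashing, so adding mice to a config never perturbs
the data of existing ones, and identical configs give byte-identical
output files.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .gait import GROUPS, StepTrace
from .openfield import ArenaGeometry, CentroidTrack

__all__ = [
    "SyntheticConfig",
    "OpenFieldConfig",
    "GaitDataset",
    "OpenFieldDataset",
    "generate_gait",
    "generate_openfield",
    "inject_group_effect",
]


def _default_speed_means() -> dict[str, float]:
    return {"control": 27.72, "CI": 24.38, "HI": 20.66, "HIEV": 30.53}


def _default_shape_scale() -> dict[str, float]:
    return {"control": 1.0, "CI": 1.0, "HI": 0.6, "HIEV": 1.0}


def _default_short_prob() -> dict[str, float]:
    return {"control": 0.05, "CI": 0.45, "HI": 0.35, "HIEV": 0.10}


def _default_asym_sd() -> dict[str, float]:
    return {"control": 0.05, "CI": 0.08, "HI": 0.12, "HIEV": 0.06}


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the tunnel-walk gait generator.

    Speeds are mm/s, lengths mm, durations fractions of the step cycle.
    ``shape_variance_scale`` multiplies the SD of the smooth per-step curve
    perturbation; ``short_step_prob`` is the chance a left/right pair is a
    shortened ("Type B-like") pair; ``limb_asym_sd`` is the SD of the
    per-limb log-normal duration/length jitter that produces timing and
    length asymmetries (Types C/D).
    """

    n_mice_per_group: int = 5
    steps_per_side: tuple[int, int] = (5, 7)
    fps: float = 240.0
    groups: tuple[str, ...] = GROUPS
    group_speed_mean: Mapping[str, float] = field(default_factory=_default_speed_means)
    group_speed_sd: float = 7.0
    stride_length_mean: float = 30.0
    stride_length_sd: float = 4.0
    duty_factor: float = 0.6
    stance_fraction: float = 0.1
    phase_lag: float = 0.4
    swing_lift: float = 5.0
    shape_variance_scale: Mapping[str, float] = field(default_factory=_default_shape_scale)
    shape_perturb_sd: float = 0.8
    short_step_prob: Mapping[str, float] = field(default_factory=_default_short_prob)
    short_step_factor: float = 0.6
    limb_asym_sd: Mapping[str, float] = field(default_factory=_default_asym_sd)
    coordinate_noise_sd: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.duty_factor < 1.0:
            raise ValueError("duty_factor must lie in (0, 1): swing time must be positive")
        if not 0.0 <= self.stance_fraction < 1.0:
            raise ValueError("stance_fraction must lie in [0, 1)")
        lo, hi = self.steps_per_side
        if not (1 <= lo <= hi):
            raise ValueError("steps_per_side must be an increasing range >= 1")
        for name in ("fps", "stride_length_mean", "swing_lift", "group_speed_sd",
                     "stride_length_sd", "shape_perturb_sd"):
            if getattr(self, name) < 0 or (name == "fps" and self.fps <= 0):
                raise ValueError(f"{name} must be non-negative (fps positive)")
        if self.coordinate_noise_sd < 0:
            raise ValueError("coordinate_noise_sd must be non-negative")
        for g in self.groups:
            if g not in self.group_speed_mean:
                raise ValueError(f"no speed mean for group {g!r}")
            if self.group_speed_mean[g] <= 0:
                raise ValueError(f"speed mean for {g!r} must be positive")
        if not 0.0 < self.short_step_factor <= 1.0:
            raise ValueError("short_step_factor must lie in (0, 1]")
        if not 0.0 <= self.phase_lag < 1.0:
            raise ValueError("phase_lag must lie in [0, 1)")


#: marker offsets relative to the metatarsus, mm (proximal markers sit
#: behind and above), and how strongly each marker expresses the swing lift
MARKER_OFFSETS = {"metatarsus": (0.0, 5.0), "ankle": (-4.0, 13.0), "knee": (-8.0, 23.0)}
MARKER_LIFT_GAIN = {"metatarsus": 1.0, "ankle": 0.6, "knee": 0.3}


@dataclass
class GaitDataset:
    steps: list[StepTrace]
    ground_truth: pd.DataFrame
    config: SyntheticConfig

    def to_annotation_frame(self) -> pd.DataFrame:
        """Long-format annotation table: one row per frame per marker."""
        recs = []
        for s in self.steps:
            for marker in ("knee", "ankle", "metatarsus"):
                arr = s.marker(marker)
                for f, (x, y) in zip(s.frames, arr):
                    recs.append((s.mouse_id, s.group, s.side, s.step_index,
                                 int(f), marker, x, y))
        return pd.DataFrame(
            recs, columns=["mouse_id", "group", "side", "step",
                           "frame", "marker", "x", "y"]
        )

    def group_table(self) -> pd.DataFrame:
        rows = sorted({(s.mouse_id, s.group) for s in self.steps})
        return pd.DataFrame(rows, columns=["mouse_id", "group"])

    def write(self, outdir) -> None:
        from pathlib import Path
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.to_annotation_frame().to_csv(out / "gait_annotations.csv", index=False)
        self.ground_truth.to_csv(out / "gait_ground_truth.csv", index=False)
        self.group_table().to_csv(out / "groups.csv", index=False)


def _mouse_rng(seed: int, mouse_id: str) -> np.random.Generator:
    """Stable per-mouse stream: master seed + CRC32 of the mouse id."""
    return np.random.default_rng(
        np.random.SeedSequence([seed, zlib.crc32(mouse_id.encode())])
    )


def _smoothstep(v: np.ndarray) -> np.ndarray:
    return v * v * (3.0 - 2.0 * v)


def _progression(u: np.ndarray, duty: float, stance_frac: float) -> np.ndarray:
    """Fraction of the stride covered by cycle time u in [0, 1]."""
    prog = np.where(
        u < duty,
        stance_frac * (u / duty),
        stance_frac + (1.0 - stance_frac) * _smoothstep((u - duty) / (1.0 - duty)),
    )
    return prog


def _shape_perturbation(rng: np.random.Generator, u: np.ndarray, sd: float) -> np.ndarray:
    """Smooth random curve perturbation vanishing at both step boundaries."""
    out = np.zeros_like(u)
    for j in (1, 2, 3):
        out += rng.normal(0.0, sd / j) * np.sin(j * np.pi * u)
    return out


def _synth_step_trace(
    rng: np.random.Generator,
    cfg: SyntheticConfig,
    *,
    mouse_id: str,
    group: str,
    side: str,
    step_index: int,
    start_frame: int,
    x0: float,
    speed: float,
    duration: float,
) -> tuple[StepTrace, float, int]:
    """One hindlimb step; returns (trace, stride, n_frames).

    Duration is quantized to the frame grid first and the stride set to
    ``speed * quantized_duration``, so the speed the analysis recovers from
    a noise-free trace equals the sampled speed exactly.
    """
    n = max(int(round(duration * cfg.fps)), 7) + 1
    t_q = (n - 1) / cfg.fps
    stride = speed * t_q
    u = np.linspace(0.0, 1.0, n)
    prog = _progression(u, cfg.duty_factor, cfg.stance_fraction)
    swing = np.clip((u - cfg.duty_factor) / (1.0 - cfg.duty_factor), 0.0, 1.0)
    lift = np.sin(np.pi * swing) * (u >= cfg.duty_factor)

    scale = cfg.shape_variance_scale.get(group, 1.0)
    markers = {}
    for name in ("knee", "ankle", "metatarsus"):
        ox, oy = MARKER_OFFSETS[name]
        gx = cfg.shape_perturb_sd * scale
        base_x = x0 + ox + stride * prog + _shape_perturbation(rng, u, gx)
        base_y = (oy + cfg.swing_lift * MARKER_LIFT_GAIN[name] * lift
                  + _shape_perturbation(rng, u, 0.5 * gx))
        xy = np.column_stack([base_x, base_y])
        if cfg.coordinate_noise_sd > 0:
            xy = xy + rng.normal(0.0, cfg.coordinate_noise_sd, xy.shape)
        markers[name] = xy

    trace = StepTrace(
        mouse_id=mouse_id, group=group, side=side, step_index=step_index,
        fps=cfg.fps, frames=start_frame + np.arange(n),
        knee=markers["knee"], ankle=markers["ankle"],
        metatarsus=markers["metatarsus"],
    )
    return trace, stride, n


def generate_gait(config: SyntheticConfig) -> GaitDataset:
    """Generate a full tunnel-walk cohort with per-step ground truth.

    For each left/right step pair a common target speed and stride are
    drawn from the group distribution; a short-step event (both strides
    scaled down) and independent per-limb log-normal jitter then shape the
    realized pair, so the step-type mixture emerges from the kinematics
    themselves.  The right-limb cycle lags the left by ``phase_lag`` of
    the cycle, giving classification a realistic pairing problem.
    """
    steps: list[StepTrace] = []
    truth_rows = []
    for group in config.groups:
        mean = config.group_speed_mean[group]
        short_p = config.short_step_prob.get(group, 0.0)
        asym = config.limb_asym_sd.get(group, 0.0)
        for m in range(config.n_mice_per_group):
            mouse_id = f"{group}_m{m + 1:02d}"
            rng = _mouse_rng(config.seed, mouse_id)
            lo, hi = config.steps_per_side
            n_steps = int(rng.integers(lo, hi + 1))
            frame_left = 0
            x_left = 20.0
            x_right = 20.0 + config.stride_length_mean / 2.0
            for k in range(1, n_steps + 1):
                pair_speed = max(float(rng.normal(mean, config.group_speed_sd)), 5.0)
                pair_stride = max(
                    float(rng.normal(config.stride_length_mean, config.stride_length_sd)),
                    5.0,
                )
                is_short = bool(rng.random() < short_p)
                if is_short:
                    pair_stride *= config.short_step_factor
                pair_start = frame_left
                for side in ("left", "right"):
                    s_limb = pair_speed * math.exp(float(rng.normal(0.0, asym)))
                    t_limb = (pair_stride / pair_speed) * math.exp(
                        float(rng.normal(0.0, asym))
                    )
                    if side == "left":
                        start = pair_start
                        x0 = x_left
                    else:
                        start = pair_start + int(round(config.phase_lag * t_limb * config.fps))
                        x0 = x_right
                    trace, stride, n = _synth_step_trace(
                        rng, config,
                        mouse_id=mouse_id, group=group, side=side,
                        step_index=k, start_frame=start, x0=x0,
                        speed=s_limb, duration=t_limb,
                    )
                    steps.append(trace)
                    truth_rows.append({
                        "mouse_id": mouse_id, "group": group, "side": side,
                        "step": k, "speed": s_limb,
                        "duration": (n - 1) / config.fps, "stride_length": stride,
                        "short_pair": is_short, "start_frame": start,
                    })
                    if side == "left":
                        frame_left += n - 1
                        x_left += stride
                    else:
                        x_right += stride
    truth = pd.DataFrame(truth_rows)
    return GaitDataset(steps=steps, ground_truth=truth, config=config)


def inject_group_effect(
    config: SyntheticConfig,
    effect: str,
    value: float,
    groups: Sequence[str] | None = None,
) -> SyntheticConfig:
    """Return a config with a group-level effect applied.

    ``speed_delta`` adds ``value`` mm/s to the group speed means;
    ``shape_variance`` multiplies the curve-shape perturbation scale;
    ``step_type_shift`` adds ``value`` to the short-step probability
    (clamped to [0, 1]).
    """
    targets = list(groups) if groups is not None else list(config.groups)
    unknown = set(targets) - set(config.groups)
    if unknown:
        raise ValueError(f"unknown groups {sorted(unknown)}")
    if effect == "speed_delta":
        means = dict(config.group_speed_mean)
        for g in targets:
            means[g] = means[g] + value
        return replace(config, group_speed_mean=means)
    if effect == "shape_variance":
        scales = dict(config.shape_variance_scale)
        for g in targets:
            scales[g] = scales.get(g, 1.0) * value
        return replace(config, shape_variance_scale=scales)
    if effect == "step_type_shift":
        probs = dict(config.short_step_prob)
        for g in targets:
            probs[g] = min(max(probs.get(g, 0.0) + value, 0.0), 1.0)
        return replace(config, short_step_prob=probs)
    raise ValueError(f"unknown effect {effect!r}")


# ---------------------------------------------------------------------------
# open field
# ---------------------------------------------------------------------------

def _default_of_speed() -> dict[str, float]:
    return {"control": 8.2, "CI": 6.9, "HI": 4.9, "HIEV": 7.1}


def _default_of_speed_sd() -> dict[str, float]:
    return {"control": 2.3, "CI": 1.3, "HI": 0.9, "HIEV": 1.8}


def _default_wall_attraction() -> dict[str, float]:
    return {"control": 0.05, "CI": 0.04, "HI": -0.05, "HIEV": 0.03}


def _default_still_total() -> dict[str, float]:
    # 600 s minus printed distance / printed moving speed
    return {"control": 99.0, "CI": 85.0, "HI": 55.0, "HIEV": 120.0}


@dataclass(frozen=True)
class OpenFieldConfig:
    """Parameters of the open-field random-walk generator.

    ``wall_attraction`` in [-1, 1] biases the heading toward the nearest
    wall (positive, thigmotaxis) or the arena center (negative); 0 gives a
    plain correlated walk whose long-run occupancy approaches the uniform
    area fractions.  Still bouts are scheduled with known onsets and
    durations and freeze the position exactly.
    """

    n_mice_per_group: int = 5
    groups: tuple[str, ...] = GROUPS
    duration_s: float = 600.0
    fps: float = 30.0
    arena: ArenaGeometry = field(default_factory=ArenaGeometry)
    group_speed_mean: Mapping[str, float] = field(default_factory=_default_of_speed)
    group_speed_sd: Mapping[str, float] = field(default_factory=_default_of_speed_sd)
    wall_attraction: Mapping[str, float] = field(default_factory=_default_wall_attraction)
    still_total_s: Mapping[str, float] = field(default_factory=_default_still_total)
    n_still_bouts: int = 6
    turn_sd: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration_s <= 0 or self.fps <= 0:
            raise ValueError("duration_s and fps must be positive")
        for g in self.groups:
            v = self.group_speed_mean.get(g, 0.0)
            if v <= 0:
                raise ValueError(f"open-field speed mean for {g!r} must be positive")
            step = v / self.fps
            if step >= min(self.arena.width, self.arena.depth) / 2:
                raise ValueError("arena smaller than the walk step size")
            w = self.wall_attraction.get(g, 0.0)
            if not -1.0 <= w <= 1.0:
                raise ValueError("wall_attraction must lie in [-1, 1]")


@dataclass
class OpenFieldDataset:
    tracks: list[CentroidTrack]
    ground_truth: pd.DataFrame
    config: OpenFieldConfig

    def to_frame(self) -> pd.DataFrame:
        recs = []
        for t in self.tracks:
            for f, (x, y) in enumerate(t.points):
                recs.append((t.mouse_id, t.group, f, x, y))
        return pd.DataFrame(recs, columns=["mouse_id", "group", "frame", "x_cm", "y_cm"])

    def write(self, outdir) -> None:
        from pathlib import Path
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.to_frame().to_csv(out / "openfield_tracks.csv", index=False)
        self.ground_truth.to_csv(out / "openfield_ground_truth.csv", index=False)


def _schedule_still_bouts(
    rng: np.random.Generator, n_frames: int, total_still_s: float,
    n_bouts: int, fps: float, min_bout_s: float = 1.0,
) -> list[tuple[int, int]]:
    """Bout (start, stop) frame ranges totalling ~``total_still_s`` seconds."""
    if total_still_s <= 0:
        return []
    n_bouts = max(min(n_bouts, int(total_still_s // min_bout_s)), 1)
    props = rng.dirichlet(np.ones(n_bouts) * 4.0)
    lengths = np.maximum((props * total_still_s * fps).round().astype(int),
                         int(min_bout_s * fps))
    block = n_frames // n_bouts
    bouts = []
    for i, ln in enumerate(lengths):
        ln = min(ln, block - 2)
        lo = i * block
        start = lo + int(rng.integers(1, max(block - ln - 1, 2)))
        bouts.append((start, start + ln))
    return bouts


def _walk_track(
    rng: np.random.Generator, cfg: OpenFieldConfig,
    speed: float, wall_w: float, bouts: list[tuple[int, int]],
) -> np.ndarray:
    n = int(round(cfg.duration_s * cfg.fps))
    arena = cfg.arena
    w_, d_ = arena.width, arena.depth
    dt = 1.0 / cfg.fps
    still = np.zeros(n, dtype=bool)
    for a, b in bouts:
        still[a:b] = True
    turns = rng.normal(0.0, cfg.turn_sd, n)

    pts = np.empty((n, 2))
    x, y = w_ / 2.0, d_ / 2.0
    theta = rng.uniform(0.0, 2.0 * math.pi)
    aw = abs(wall_w)
    for i in range(n):
        if still[i]:
            pts[i] = (x, y)
            continue
        theta += turns[i]
        hx, hy = math.cos(theta), math.sin(theta)
        if aw > 0:
            # bias toward a preferred contour: a ring `margin` cm inside the
            # walls (thigmotaxis, w > 0) or the arena center block (w < 0);
            # strength grows with the distance error so the walker cruises
            # along the preferred region instead of pressing into boundaries
            margin = 4.0
            dists = (x, w_ - x, y, d_ - y)
            k = dists.index(min(dists))
            dw = dists[k]
            to_wall = ((-1.0, 0.0), (1.0, 0.0), (0.0, -1.0), (0.0, 1.0))[k]
            if wall_w > 0:
                err = dw - margin  # positive: too far from the wall
                strength = aw * min(abs(err) / margin, 1.0)
                sgn = 1.0 if err > 0 else -1.0
                bx, by = sgn * to_wall[0], sgn * to_wall[1]
            else:
                bx, by = w_ / 2.0 - x, d_ / 2.0 - y
                norm = math.hypot(bx, by)
                # no pull once inside the central block
                inside = (w_ / 4.0 <= x <= 3.0 * w_ / 4.0
                          and d_ / 4.0 <= y <= 3.0 * d_ / 4.0)
                if norm > 1e-9 and not inside:
                    bx, by = bx / norm, by / norm
                    strength = aw
                else:
                    bx, by, strength = 0.0, 0.0, 0.0
            hx = (1.0 - strength) * hx + strength * bx
            hy = (1.0 - strength) * hy + strength * by
            norm = math.hypot(hx, hy)
            if norm > 1e-9:
                hx, hy = hx / norm, hy / norm
        x += speed * dt * hx
        y += speed * dt * hy
        # specular reflection: fold the position and flip the heading
        if x < 0.0:
            x, hx = -x, -hx
        elif x > w_:
            x, hx = 2.0 * w_ - x, -hx
        if y < 0.0:
            y, hy = -y, -hy
        elif y > d_:
            y, hy = 2.0 * d_ - y, -hy
        theta = math.atan2(hy, hx)
        pts[i] = (x, y)
    return pts


def generate_openfield(config: OpenFieldConfig) -> OpenFieldDataset:
    """Generate open-field centroid tracks with scheduled still bouts."""
    tracks: list[CentroidTrack] = []
    rows = []
    n_frames = int(round(config.duration_s * config.fps))
    for group in config.groups:
        for m in range(config.n_mice_per_group):
            mouse_id = f"{group}_m{m + 1:02d}"
            rng = _mouse_rng(config.seed ^ 0x0F0F0F, mouse_id)
            speed = max(
                float(rng.normal(config.group_speed_mean[group],
                                 config.group_speed_sd.get(group, 0.0))),
                1.5,
            )
            wall_w = config.wall_attraction.get(group, 0.0)
            bouts = _schedule_still_bouts(
                rng, n_frames, config.still_total_s.get(group, 0.0),
                config.n_still_bouts, config.fps,
            )
            pts = _walk_track(rng, config, speed, wall_w, bouts)
            tracks.append(CentroidTrack(
                mouse_id=mouse_id, group=group, fps=config.fps,
                points=pts, arena=config.arena,
            ))
            rows.append({
                "mouse_id": mouse_id, "group": group,
                "speed_cm_s": speed, "wall_attraction": wall_w,
                "still_s_true": sum(b - a for a, b in bouts) / config.fps,
                "n_bouts": len(bouts),
            })
    return OpenFieldDataset(
        tracks=tracks, ground_truth=pd.DataFrame(rows), config=config
    )
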