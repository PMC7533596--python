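import numpy as np
import pytest

from gaitkit.gait import pair_steps, step_kinematics, classify_step_pair
from gaitkit.openfield import moving_speed, periphery_time
from gaitkit.synth import (
    OpenFieldConfig,
    SyntheticConfig,
    generate_gait,
    generate_openfield,
    inject_group_effect,
)


def small_cfg(**kw):
    kw.setdefault("n_mice_per_group", 3)
    kw.setdefault("seed", 11)
    return SyntheticConfig(**kw)


class TestGaitGenerator:
    def test_same_seed_gives_byte_identical_files(self, tmp_path):
        cfg = small_cfg()
        d1, d2 = tmp_path / "a", tmp_path / "b"
        generate_gait(cfg).write(d1)
        generate_gait(cfg).write(d2)
        for name in ("gait_annotations.csv", "gait_ground_truth.csv", "groups.csv"):
            assert (d1 / name).read_bytes() == (d2 / name).read_bytes()

    def test_noise_free_symmetric_limbs_are_type_a_with_exact_speed(self):
        cfg = SyntheticConfig(
            seed=3, n_mice_per_group=2, groups=("control",),
            coordinate_noise_sd=0.0, group_speed_sd=0.0, stride_length_sd=0.0,
            shape_perturb_sd=0.0,
            short_step_prob={"control": 0.0}, limb_asym_sd={"control": 0.0},
        )
        ds = generate_gait(cfg)
        by_mouse = {}
        for s in ds.steps:
            k = step_kinematics(s)
            assert k.speed == pytest.approx(27.72, abs=1e-9)
            by_mouse.setdefault(s.mouse_id, {"left": [], "right": []})[s.side].append(s)
        baseline = float(np.median([step_kinematics(s).stride_length
                                    for s in ds.steps]))
        for sides in by_mouse.values():
            pairs = pair_steps(sides["left"], sides["right"])
            assert len(pairs) == len(sides["left"])
            for l, r in pairs:
                label = classify_step_pair(
                    step_kinematics(l), step_kinematics(r), baseline).label
                assert label == "A"

    def test_ground_truth_matches_recovered_kinematics(self):
        ds = generate_gait(small_cfg(coordinate_noise_sd=0.0, shape_perturb_sd=0.0))
        gt = ds.ground_truth.set_index(["mouse_id", "side", "step"])
        for s in ds.steps:
            k = step_kinematics(s)
            row = gt.loc[(s.mouse_id, s.side, s.step_index)]
            assert k.speed == pytest.approx(row["speed"], rel=1e-9)
            assert k.duration == pytest.approx(row["duration"], rel=1e-12)

    def test_generated_steps_pass_input_validators(self):
        from gaitkit.io import step_traces_from_frame

        ds = generate_gait(small_cfg())
        df = ds.to_annotation_frame()
        rebuilt = step_traces_from_frame(df, fps=ds.config.fps)
        assert len(rebuilt) == len(ds.steps)
        orig = {(s.mouse_id, s.side, s.step_index): s for s in ds.steps}
        for r in rebuilt:
            s = orig[(r.mouse_id, r.side, r.step_index)]
            np.testing.assert_allclose(r.metatarsus, s.metatarsus)

    def test_adding_mice_does_not_perturb_existing_ones(self):
        a = generate_gait(small_cfg(n_mice_per_group=2, groups=("control",)))
        b = generate_gait(small_cfg(n_mice_per_group=4, groups=("control",)))
        sa = {(s.mouse_id, s.side, s.step_index): s for s in a.steps}
        for s in b.steps:
            key = (s.mouse_id, s.side, s.step_index)
            if key in sa:
                np.testing.assert_array_equal(s.metatarsus, sa[key].metatarsus)

    def test_speed_recovery_is_unbiased(self):
        """Per-step speed estimates recover the configured group mean."""
        est = []
        for seed in range(25):
            cfg = SyntheticConfig(seed=seed, n_mice_per_group=5,
                                  groups=("control",), steps_per_side=(6, 6))
            ds = generate_gait(cfg)
            est.extend(step_kinematics(s).speed for s in ds.steps)
        assert abs(np.mean(est) - 27.72) < 0.5

    def test_infeasible_duty_factor_rejected(self):
        with pytest.raises(ValueError, match="swing time"):
            small_cfg(duty_factor=1.0)


class TestInjectEffect:
    def test_zero_speed_delta_is_identity(self):
        cfg = small_cfg()
        assert inject_group_effect(cfg, "speed_delta", 0.0) == cfg

    def test_speed_delta_shifts_group_mean(self):
        cfg = inject_group_effect(small_cfg(), "speed_delta", -7.0,
                                  groups=["control"])
        assert cfg.group_speed_mean["control"] == pytest.approx(20.72)

    def test_shape_variance_scales_multiplier(self):
        cfg = inject_group_effect(small_cfg(), "shape_variance", 3.0)
        assert cfg.shape_variance_scale["control"] == pytest.approx(3.0)

    def test_step_type_shift_clamped(self):
        cfg = inject_group_effect(small_cfg(), "step_type_shift", 2.0)
        assert cfg.short_step_prob["control"] == 1.0

    def test_unknown_effect_rejected(self):
        with pytest.raises(ValueError, match="unknown effect"):
            inject_group_effect(small_cfg(), "contrast", 1.0)


def of_cfg(**kw):
    kw.setdefault("n_mice_per_group", 1)
    kw.setdefault("seed", 5)
    return OpenFieldConfig(**kw)


class TestOpenFieldGenerator:
    def test_zero_still_bouts_give_zero_still_time(self):
        cfg = of_cfg(groups=("control",), duration_s=120.0,
                     still_total_s={"control": 0.0})
        ds = generate_openfield(cfg)
        m = moving_speed(ds.tracks[0])
        assert m.still_time == 0.0

    def test_configured_still_time_recovered_within_one_second(self):
        cfg = of_cfg(groups=("control",), still_total_s={"control": 120.0})
        ds = generate_openfield(cfg)
        truth = ds.ground_truth.iloc[0]
        m = moving_speed(ds.tracks[0])
        assert m.still_time == pytest.approx(truth["still_s_true"], abs=1.0)
        assert abs(truth["still_s_true"] - 120.0) <= 2.0  # rounding to frames

    def test_unbiased_walk_approaches_periphery_area_fraction(self):
        """With no wall attraction, periphery occupancy tends to the
        periphery area fraction (0.75) in long runs."""
        fracs = []
        for seed in range(10):
            cfg = of_cfg(seed=seed, groups=("control",),
                         wall_attraction={"control": 0.0},
                         still_total_s={"control": 0.0})
            ds = generate_openfield(cfg)
            t = ds.tracks[0]
            fracs.append(periphery_time(t) / t.duration)
        assert np.mean(fracs) == pytest.approx(0.75, abs=0.05)

    def test_wall_attraction_orders_periphery_time(self):
        ds = generate_openfield(of_cfg(n_mice_per_group=2))
        rep = {g: np.mean([periphery_time(t) for t in ds.tracks if t.group == g])
               for g in ("control", "HI")}
        assert rep["control"] > rep["HI"]

    def test_tracks_stay_inside_arena(self):
        ds = generate_openfield(of_cfg(n_mice_per_group=2))
        for t in ds.tracks:
            assert t.points[:, 0].min() >= 0 and t.points[:, 0].max() <= 45
            assert t.points[:, 1].min() >= 0 and t.points[:, 1].max() <= 32

    def test_determinism(self, tmp_path):
        cfg = of_cfg(duration_s=60.0)
        d1, d2 = tmp_path / "a", tmp_path / "b"
        generate_openfield(cfg).write(d1)
        generate_openfield(cfg).write(d2)
        assert (d1 / "openfield_tracks.csv").read_bytes() == \
            (d2 / "openfield_tracks.csv").read_bytes()

    def test_arena_smaller_than_step_rejected(self):
        from gaitkit.openfield import ArenaGeometry
        with pytest.raises(ValueError, match="arena smaller"):
            of_cfg(arena=ArenaGeometry(width=3.0, depth=3.0, nx=4, ny=4),
                   fps=1.0, group_speed_mean={"control": 8.0, "CI": 6.9,
                                              "HI": 4.9, "HIEV": 7.1})
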