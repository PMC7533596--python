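import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gaitkit.displacement import (
    N_CYCLE_SAMPLES,
    curve_distance,
    curves_from_step,
    group_distance_summary,
    normalize_curve,
    pairwise_distances,
    subject_min_max,
)

from conftest import make_curve, make_step, random_curve


def norm(frames, x, y=None, **kw):
    y = np.zeros_like(x) if y is None else y
    kw.setdefault("marker", "metatarsus")
    kw.setdefault("side", "right")
    return normalize_curve(np.asarray(frames), np.column_stack([x, y]), **kw)


class TestNormalization:
    def test_reproduces_evenly_spaced_knots(self, rng):
        x = rng.normal(size=N_CYCLE_SAMPLES)
        y = rng.normal(size=N_CYCLE_SAMPLES)
        c = norm(np.arange(N_CYCLE_SAMPLES), x, y)
        np.testing.assert_allclose(c.x, x, atol=1e-12)
        np.testing.assert_allclose(c.y, y, atol=1e-12)

    @pytest.mark.parametrize("n_frames", [4, 7, 23])
    def test_reproduces_cubic_polynomials(self, n_frames):
        t = np.linspace(0, 1, n_frames)
        x = 2 * t**3 - 3 * t**2 + 4 * t - 1
        c = norm(np.arange(n_frames), x)
        g = np.linspace(0, 1, N_CYCLE_SAMPLES)
        np.testing.assert_allclose(c.x, 2 * g**3 - 3 * g**2 + 4 * g - 1, atol=1e-9)

    def test_sine_resampled_from_61_frames(self):
        t = np.linspace(0, 1, 61)
        c = norm(np.arange(61), np.sin(2 * np.pi * t))
        g = np.linspace(0, 1, N_CYCLE_SAMPLES)
        assert np.abs(c.x - np.sin(2 * np.pi * g)).max() < 1e-3

    def test_endpoints_equal_raw_endpoints(self, rng):
        x = rng.normal(size=17)
        c = norm(np.arange(17), x)
        assert c.x[0] == x[0] and c.x[-1] == x[-1]

    def test_uneven_frame_spacing_uses_time_parameter(self):
        frames = np.array([0, 1, 2, 3, 10])
        x = frames.astype(float) * 2.0  # linear in frame index
        c = norm(frames, x)
        np.testing.assert_allclose(c.x, np.linspace(0, 20, N_CYCLE_SAMPLES), atol=1e-9)

    def test_too_few_frames_rejected(self):
        with pytest.raises(ValueError, match="at least 4"):
            norm([0, 1, 2], np.zeros(3))

    def test_duplicate_frames_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            norm([0, 1, 1, 2], np.zeros(4))


def naive_distance(a, b):
    """Double-loop restatement of the D statistic."""
    total = 0.0
    for i in range(N_CYCLE_SAMPLES):
        total += (a.x[i] - b.x[i]) ** 2
    for i in range(N_CYCLE_SAMPLES):
        total += (a.y[i] - b.y[i]) ** 2
    return total / 200.0


class TestDistance:
    def test_identical_curves_give_zero(self, rng):
        a = random_curve(rng)
        assert curve_distance(a, a).D == 0.0

    def test_uniform_x_offset_closed_form(self, rng):
        a = random_curve(rng)
        b = make_curve(a.x + 2.0, a.y, mouse="m2")
        assert curve_distance(a, b).D == pytest.approx(2.0, rel=1e-12)

    @given(delta=st.floats(-50, 50, allow_nan=False))
    @settings(max_examples=100, deadline=None)
    def test_offset_delta_squared_over_two(self, delta):
        rng = np.random.default_rng(7)
        a = random_curve(rng)
        b = make_curve(a.x + delta, a.y, mouse="m2")
        assert curve_distance(a, b).D == pytest.approx(delta**2 / 2, rel=1e-9, abs=1e-12)

    def test_symmetry_and_translation_invariance(self, rng):
        for _ in range(50):
            a, b = random_curve(rng), random_curve(rng, mouse="m2")
            dab = curve_distance(a, b).D
            assert curve_distance(b, a).D == dab
            shift = rng.normal(size=2)
            a2 = make_curve(a.x + shift[0], a.y + shift[1])
            b2 = make_curve(b.x + shift[0], b.y + shift[1], mouse="m2")
            assert curve_distance(a2, b2).D == pytest.approx(dab, rel=1e-9)

    def test_matches_double_loop_oracle(self, rng):
        for _ in range(50):
            a, b = random_curve(rng), random_curve(rng, mouse="m2")
            assert curve_distance(a, b).D == pytest.approx(
                naive_distance(a, b), rel=1e-12)

    def test_marker_and_side_mismatch_rejected(self, rng):
        a = random_curve(rng)
        with pytest.raises(ValueError, match="marker"):
            curve_distance(a, random_curve(rng, marker="knee"))
        with pytest.raises(ValueError, match="side"):
            curve_distance(a, random_curve(rng, side="left"))

    def test_x_scaled_variant(self, rng):
        a = random_curve(rng)
        b = random_curve(rng, mouse="m2")
        d = curve_distance(a, b, variant="x_scaled_only").D
        expected = np.sum((a.x - b.x) ** 2) / 200 + np.sum((a.y - b.y) ** 2)
        assert d == pytest.approx(expected, rel=1e-12)


class TestPairwise:
    def test_single_identical_pair(self, rng):
        a = random_curve(rng)
        b = make_curve(a.x, a.y, mouse="m2")
        assert [p.D for p in pairwise_distances([a], [b])] == [0.0]

    def test_constructed_offsets_give_delta_squared_table(self, rng):
        base = random_curve(rng)
        mk = lambda off, mouse, step: make_curve(base.x + off, base.y,
                                                 mouse=mouse, step=step)
        a = [mk(0.0, "a", 1), mk(1.0, "a", 2)]
        b = [mk(0.0, "b", 1), mk(3.0, "b", 2)]
        ds = [p.D for p in pairwise_distances(a, b)]
        assert ds == pytest.approx([0.0, 4.5, 0.5, 2.0], rel=1e-9, abs=1e-12)

    def test_matches_nested_loop_oracle(self, rng):
        a = [random_curve(rng, mouse="a", step=i) for i in range(1, 4)]
        b = [random_curve(rng, mouse="b", step=i) for i in range(1, 5)]
        got = [(p.curve_a, p.curve_b, p.D) for p in pairwise_distances(a, b)]
        want = [(ca.provenance, cb.provenance, naive_distance(ca, cb))
                for ca in a for cb in b]
        for (ga, gb, gd), (wa, wb, wd) in zip(got, want):
            assert (ga, gb) == (wa, wb)
            assert gd == pytest.approx(wd, rel=1e-12)

    def test_empty_set_rejected(self, rng):
        with pytest.raises(ValueError, match="non-empty"):
            pairwise_distances([], [random_curve(rng)])


def enumerate_min_max(subject, curves_by_mouse, ref_ids, exclude_self):
    """Exhaustive enumeration oracle, tie-break by lexicographic provenance."""
    best = []
    for rid in ref_ids:
        if exclude_self and rid == subject:
            continue
        for a in curves_by_mouse[subject]:
            for b in curves_by_mouse[rid]:
                best.append((naive_distance(a, b), a.provenance, b.provenance))
    dmin = min(d for d, _, _ in best)
    dmax = max(d for d, _, _ in best)
    argmin = min((a, b) for d, a, b in best if d == dmin)
    argmax = min((a, b) for d, a, b in best if d == dmax)
    return dmin, dmax, argmin, argmax


class TestSubjectMinMax:
    def test_identical_step_gives_zero_min(self, rng):
        a = random_curve(rng, mouse="s", step=1)
        b = make_curve(a.x, a.y, mouse="r", step=1)
        c = random_curve(rng, mouse="r", step=2)
        s = subject_min_max("s", {"s": [a], "r": [b, c]}, ["r"])
        assert s.D_min == 0.0

    def test_extremes_of_known_distance_set(self, rng):
        base = random_curve(rng, mouse="s")
        # offsets sqrt(2*d) realize distances {1, 2, 3, 4}
        ref = [make_curve(base.x + np.sqrt(2 * d), base.y, mouse="r", step=i)
               for i, d in enumerate([1, 2, 3, 4], start=1)]
        s = subject_min_max("s", {"s": [base], "r": ref}, ["r"])
        assert s.D_min == pytest.approx(1.0, rel=1e-9)
        assert s.D_max == pytest.approx(4.0, rel=1e-9)

    def test_matches_enumeration_oracle_with_self_exclusion(self, rng):
        mice = ["m1", "m2", "m3", "m4"]
        curves = {
            m: [random_curve(rng, mouse=m, step=i) for i in range(1, 4)]
            for m in mice
        }
        for subject in mice:
            s = subject_min_max(subject, curves, mice, exclude_self=True)
            dmin, dmax, argmin, argmax = enumerate_min_max(
                subject, curves, mice, True)
            assert s.D_min == pytest.approx(dmin, rel=1e-12)
            assert s.D_max == pytest.approx(dmax, rel=1e-12)
            assert (s.argmin, s.argmax) == (argmin, argmax)

    def test_empty_reference_after_exclusion_rejected(self, rng):
        a = random_curve(rng, mouse="s")
        with pytest.raises(ValueError, match="no comparison pairs"):
            subject_min_max("s", {"s": [a]}, ["s"], exclude_self=True)


class TestGroupSummary:
    def test_two_identical_control_mice_give_zero(self, rng):
        a = random_curve(rng, mouse="c1")
        b = make_curve(a.x, a.y, mouse="c2")
        out = group_distance_summary([a, b], {"c1": "control", "c2": "control"})
        assert (out["D_min"] == 0).all() and (out["D_max"] == 0).all()

    def test_three_offset_mice_match_hand_enumeration(self, rng):
        base = random_curve(rng)
        curves = [make_curve(base.x + off, base.y, mouse=m)
                  for m, off in [("c1", 0.0), ("c2", 1.0), ("h1", 2.0)]]
        groups = {"c1": "control", "c2": "control", "h1": "HI"}
        out = group_distance_summary(curves, groups).set_index("mouse_id")
        # distances: c1-c2 = 0.5, h1-c1 = 2.0, h1-c2 = 0.5
        assert out.loc["c1", "D_min"] == pytest.approx(0.5)
        assert out.loc["c1", "D_max"] == pytest.approx(0.5)
        assert out.loc["h1", "D_min"] == pytest.approx(0.5)
        assert out.loc["h1", "D_max"] == pytest.approx(2.0)

    def test_reference_group_of_one_rejected(self, rng):
        a = random_curve(rng, mouse="c1")
        with pytest.raises(ValueError, match=">= 2 mice"):
            group_distance_summary([a], {"c1": "control"})

    def test_min_leq_mean_leq_max(self, rng):
        curves = [random_curve(rng, mouse=f"m{i}", step=s)
                  for i in range(4) for s in range(1, 4)]
        groups = {f"m{i}": ("control" if i < 2 else "HI") for i in range(4)}
        out = group_distance_summary(curves, groups)
        assert (out["D_min"] <= out["D_max"]).all()


def test_rezeroed_curves_start_at_metatarsus_origin():
    x = np.linspace(100, 130, 61)
    s = make_step(x, frames=np.arange(61))
    c = curves_from_step(s)["metatarsus"]
    assert c.x[0] == pytest.approx(0.0, abs=1e-12)
    c_abs = curves_from_step(s, rezero=False)["metatarsus"]
    assert c_abs.x[0] == pytest.approx(100.0)
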