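import numpy as np
import pytest

from gaitkit.displacement import N_CYCLE_SAMPLES, NormalizedCurve
from gaitkit.gait import StepTrace
from gaitkit.openfield import ArenaGeometry, CentroidTrack


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_curve(x, y=None, marker="metatarsus", side="right", mouse="m1", step=1):
    x = np.asarray(x, dtype=float)
    if y is None:
        y = np.zeros(N_CYCLE_SAMPLES)
    return NormalizedCurve(
        marker=marker, side=side, mouse_id=mouse, step_index=step,
        x=x, y=np.asarray(y, dtype=float),
    )


def random_curve(rng, mouse="m1", step=1, marker="metatarsus", side="right"):
    return make_curve(
        rng.normal(size=N_CYCLE_SAMPLES), rng.normal(size=N_CYCLE_SAMPLES),
        marker=marker, side=side, mouse=mouse, step=step,
    )


def make_step(
    met_x, met_y=None, fps=240.0, mouse="m1", group="control", side="left",
    step=1, frames=None,
):
    """StepTrace with a prescribed metatarsus track; knee/ankle are offsets."""
    met_x = np.asarray(met_x, dtype=float)
    n = len(met_x)
    met_y = np.full(n, 5.0) if met_y is None else np.asarray(met_y, dtype=float)
    frames = np.arange(n) if frames is None else np.asarray(frames)
    met = np.column_stack([met_x, met_y])
    return StepTrace(
        mouse_id=mouse, group=group, side=side, step_index=step, fps=fps,
        frames=frames, metatarsus=met,
        ankle=met + np.array([-4.0, 8.0]), knee=met + np.array([-8.0, 18.0]),
    )


def make_track(points, mouse="m1", group="control", fps=30.0, arena=None):
    return CentroidTrack(
        mouse_id=mouse, group=group, fps=fps,
        points=np.asarray(points, dtype=float),
        arena=arena or ArenaGeometry(),
    )


@pytest.fixture
def arena():
    return ArenaGeometry()
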