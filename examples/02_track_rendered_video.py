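"""Render a synthetic video and track the marker grid through it.

Demonstrates the registration stage: a 30-node orthogonal grid is placed on
the first frame and each node is followed by normalized cross-correlation
with sub-pixel (parabolic) refinement. Because the video is rendered from
known trajectories, the tracking error is measurable exactly.
"""

import numpy as np

from cardiokin.synthgen import (
    BeatWaveformParams,
    ConditionParams,
    render_frames,
    synth_trajectories,
)
from cardiokin.tracking import MarkerGrid, place_marker_grid, track_all
from cardiokin.trajectories import TimeBase

shape = (256, 352)
grid = place_marker_grid(shape[1], shape[0], rows=5, cols=6, margin=30)
tb = TimeBase(fs=25.0, n_frames=150)  # 6 s, kept short for a quick demo

params = BeatWaveformParams(A0=6.0, noise_sigma=0.0)
truth, _ = synth_trajectories(ConditionParams("CTRL", between_cv=0.0), params,
                              grid.positions, (175.5, 127.5), tb, seed=1)

stack = render_frames(truth, shape=shape, noise="poisson-gaussian",
                      spot_amplitude=3000.0, background=200.0, seed=1)
tracked = track_all(stack, MarkerGrid(grid.positions, 5, 6, 30))

xt, yt = tracked.positions()
xg, yg = truth.positions()
rms = np.sqrt(np.mean((xt - xg) ** 2 + (yt - yg) ** 2))
mean_q = np.nanmean([np.nanmean(tr.quality) for tr in tracked.trajectories])
print(f"rendered {stack.frames.shape} stack, tracked {tracked.n_markers} markers")
print(f"RMS tracking error vs ground truth: {rms:.3f} px")
print(f"mean template correlation: {mean_q:.3f}; "
      f"lost frames: {sum(tr.n_lost for tr in tracked.trajectories)}")
# sub-0.1 px RMS means the tracker resolves motion ~30x finer than a pixel
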