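import numpy as np
import pandas as pd
import pytest


def _track_points(axon_id, track_id, direction, x0, speed_um_min, duration_s,
                  frame_interval=2.0):
    """Frame-sampled points of a constant-velocity track (+ exact endpoint)."""
    t = np.arange(0.0, duration_s, frame_interval)
    t = np.append(t, duration_s)
    v = direction * speed_um_min / 60.0
    return pd.DataFrame(
        {
            "axon_id": axon_id,
            "track_id": track_id,
            "direction": direction,
            "t_s": t,
            "x_um": x0 + v * t,
        }
    )


@pytest.fixture
def make_track():
    return _track_points


@pytest.fixture
def six_track_fixture(make_track):
    """Six tracks: two clean, four violating exactly one quality rule each.

    With pixel size 0.103 µm: rule (1) needs net displacement < 0.206 µm,
    rule (2) speed < 1.5 µm/min, rule (3) speed > 20 µm/min, rule (4)
    fewer than 4 frames.
    """
    parts = [
        make_track("a1", "clean_slow", 1, 10.0, 5.0, 18.0),      # survives
        make_track("a1", "clean_fast", -1, 20.0, 10.0, 10.0),    # survives
        # 0.18 µm over 6 s = 1.8 µm/min, 4+1 frames: only rule 1
        make_track("a1", "tiny_disp", 1, 12.0, 1.8, 6.0),
        # 0.5 µm over 30 s = 1.0 µm/min: only rule 2
        make_track("a1", "too_slow", 1, 14.0, 1.0, 30.0),
        # 25 µm/min over 8 s: only rule 3
        make_track("a1", "too_fast", -1, 30.0, 25.0, 8.0),
        # 3 frames (4 s at 2 s/frame, no sub-frame endpoint): only rule 4
        make_track("a1", "too_short", 1, 16.0, 5.0, 4.0).iloc[:3],
    ]
    df = pd.concat(parts, ignore_index=True)
    survivors = {"clean_slow", "clean_fast"}
    removals = {1: 1, 2: 1, 3: 1, 4: 1}
    return df, survivors, removals
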