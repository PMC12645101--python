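import numpy as np
import pandas as pd
import pytest

from paircohesion import REFERENCE_CURVE, generate_receiver_array


@pytest.fixture
def printed_curve():
    """Reference calibration: distance = 10**(-1.27009 - 0.03302*RSS)."""
    return REFERENCE_CURVE


@pytest.fixture
def small_array():
    """3x3 receiver lattice at 100 m spacing."""
    return generate_receiver_array(3, 3, 100.0, jitter_sd=0.0, seed=0)


def locs_frame(receivers, coords, tag_id="A", window_s=15.0, t0=0.0):
    """Strongest-method estimate table from a per-window receiver sequence.

    ``receivers`` is a list of receiver ids (None = unlocalized window,
    omitted); ``coords`` maps receiver id -> (x, y).
    """
    rows = []
    for i, rid in enumerate(receivers):
        if rid is None:
            continue
        x, y = coords[rid]
        rows.append(
            {
                "tag_id": tag_id,
                "window_start": t0 + i * window_s,
                "x": float(x),
                "y": float(y),
                "method": "strongest",
                "n_receivers": 1,
                "receiver_id": rid,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["tag_id", "window_start", "x", "y", "method", "n_receivers", "receiver_id"],
    )


@pytest.fixture
def make_locs():
    return locs_frame


SQUARE_COORDS = {
    "A": (0.0, 0.0),
    "B": (100.0, 0.0),
    "C": (100.0, 100.0),
    "D": (0.0, 100.0),
}


@pytest.fixture
def square_coords():
    return dict(SQUARE_COORDS)
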