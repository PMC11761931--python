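import numpy as np
import pandas as pd
import pytest


def make_records(y, x=None, bird_id="b1", box_l=100.0, box_w=60.0, head_dx=60.0,
                 frames=None):
    """Detection records for a bird whose centre follows (x, y)."""
    y = np.asarray(y, float)
    n = len(y)
    x = np.arange(n) * 15.0 if x is None else np.asarray(x, float)
    frames = np.arange(n) if frames is None else np.asarray(frames)
    return pd.DataFrame({
        "bird_id": bird_id, "frame": frames, "conf": 0.9,
        "x_min": x - box_l / 2, "y_min": y - box_w / 2,
        "x_max": x + box_l / 2, "y_max": y + box_w / 2,
        "head_x": x + head_dx, "head_y": y,
    })


@pytest.fixture(scope="session")
def small_population():
    """A 60-bird cohort with its extracted features and classes."""
    from broilerwalk.features import extract_features_table
    from broilerwalk.phenotypes import classify_population
    from broilerwalk.synthetic import SimConfig, simulate_population

    det, phe, gt = simulate_population(SimConfig(seed=11), 60)
    feats, lw = extract_features_table(det)
    classified = classify_population(phe)
    return {"detections": det, "phenotypes": phe, "ground_truth": gt,
            "features": feats, "lw": lw, "classified": classified}


@pytest.fixture(scope="session")
def distorted_camera():
    from broilerwalk.geometry import CameraModel

    return CameraModel(fx=600.0, fy=590.0, cx=322.0, cy=238.0, k1=-0.1,
                       width=640, height=480)
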