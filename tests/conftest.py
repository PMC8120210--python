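import numpy as np
import pytest

from ehtkit import force_trace as ft
from ehtkit import morphometry as mo
from ehtkit import synthetic as sy


@pytest.fixture(scope="session")
def clean_trace():
    """Noiseless 60 s / 1 Hz / 2 mN paced trace with its ground truth."""
    return sy.generate_force_trace(sy.TraceParams(noise_sd=0.0, rng_seed=0))


@pytest.fixture(scope="session")
def clean_beats(clean_trace):
    trace, _ = clean_trace
    return ft.detect_beats(trace, pacing_rate=1.0)


@pytest.fixture(scope="session")
def small_image():
    """~57-cell noiseless tissue scan (1024^2 px at 0.1 um/px)."""
    params = sy.ImageParams(
        canvas_size=(1024, 1024),
        orientation_sd=10.0,
        myocyte_fraction=0.69,
        sarcomere_period=2.19,
        rng_seed=1,
    )
    channels, labels, gt = sy.generate_tissue_image(params)
    return params, channels, labels, gt


@pytest.fixture(scope="session")
def analyzed_image(small_image):
    _, channels, labels, gt = small_image
    cells, section, ws = mo.analyze_tissue(channels, pixel_size=0.1)
    return cells, section, ws, labels, gt


def mean_jaccard(gt_labels: np.ndarray, seg: np.ndarray) -> float:
    """Mean per-cell Jaccard overlap of a segmentation against truth."""
    scores = []
    for cid in range(1, gt_labels.max() + 1):
        g = gt_labels == cid
        hit = seg[g]
        vals, counts = np.unique(hit[hit > 0], return_counts=True)
        if vals.size == 0:
            scores.append(0.0)
            continue
        s = seg == vals[np.argmax(counts)]
        scores.append(float((g & s).sum() / (g | s).sum()))
    return float(np.mean(scores))
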