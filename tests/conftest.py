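import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from imccn import (SegmentationConfig, default_panel, generate_tissue,
                   render_image, segment_cells)

settings.register_profile(
    "suite", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("suite")


@pytest.fixture(scope="session")
def clean_panel3():
    """3-type panel with every stochastic degradation switched off."""
    return default_panel(3, poisson_scale=0.0, background=0.0,
                         expression_cv=0.0)


@pytest.fixture(scope="session")
def tissue50():
    return generate_tissue(50, 3, seed=1, field_size=(300, 300))


@pytest.fixture(scope="session")
def rendered50(tissue50, clean_panel3):
    """Noise-free 50-cell image plus its ground-truth mask."""
    image, truth = render_image(tissue50, clean_panel3, seed=1)
    return image, truth


@pytest.fixture(scope="session")
def segmented50(rendered50):
    image, _ = rendered50
    return segment_cells(image, SegmentationConfig("DNA", ("Membrane",)))


def iou_per_cell(pred_labels: np.ndarray, truth: np.ndarray) -> list[float]:
    """Best-match intersection-over-union of each predicted cell vs truth."""
    ious = []
    for lab in range(1, pred_labels.max() + 1):
        pred = pred_labels == lab
        hits = np.bincount(truth[pred])
        hits[0] = 0
        best = hits.argmax()
        tr = truth == best
        ious.append((pred & tr).sum() / (pred | tr).sum())
    return ious
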