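import numpy as np
import pytest

from speckscreen import synthgen


@pytest.fixture
def small_field_spec():
    """Compact stimulated field: fast to render and analyze in unit tests."""
    def make(seed=0, **overrides):
        params = dict(
            width_px=512,
            height_px=512,
            n_cells=80,
            speck_fraction=0.4,
            bright_cell_fraction=0.1,
            seed=seed,
        )
        params.update(overrides)
        return synthgen.FieldSpec(**params)
    return make


def brute_force_dilate(labels: np.ndarray, r_px: int) -> np.ndarray:
    """Per-pixel nearest-labeled-pixel assignment; exact ties to lower label."""
    h, w = labels.shape
    out = labels.copy()
    coords = {}
    for lab in np.unique(labels):
        if lab > 0:
            coords[int(lab)] = np.argwhere(labels == lab)
    for y in range(h):
        for x in range(w):
            if labels[y, x] > 0:
                continue
            best_d, best_lab = None, 0
            for lab in sorted(coords):
                pts = coords[lab]
                d = ((pts[:, 0] - y) ** 2 + (pts[:, 1] - x) ** 2).min()
                if d <= r_px * r_px and (best_d is None or d < best_d):
                    best_d, best_lab = d, lab
            out[y, x] = best_lab
    return out
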