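import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

import codeit as ci

# Small lawn shared across modules: big enough for interior cells and a
# donor-sized (>1,000 um^3) central cell, small enough for fast tests.
SMALL_SHAPE = (18, 128, 128)
SMALL_CELLS = 14


@pytest.fixture(scope="session")
def cfg():
    return ci.QuantConfig()


@pytest.fixture(scope="session")
def small_lawn():
    return ci.generate_lawn(ci.LawnSpec(shape=SMALL_SHAPE, n_cells=SMALL_CELLS, seed=7))


@pytest.fixture(scope="session")
def painted(small_lawn):
    """(channels, ground truth, transfer spec) for the small lawn."""
    spec = ci.random_transfer_spec(small_lawn, seed=11, n_target_cells=4)
    channels, gt = ci.paint_donor_and_transfer(small_lawn, spec)
    return channels, gt, spec


@pytest.fixture(scope="session")
def segmented(small_lawn):
    return ci.segment_stack(
        small_lawn.channels["membrane"], small_lawn.channels["nuclei"]
    )


def jaccard_per_cell(gt_labels: np.ndarray, seg_labels: np.ndarray) -> np.ndarray:
    """Per ground-truth cell, Jaccard with its best-overlapping segment."""
    out = []
    for g in np.unique(gt_labels[gt_labels > 0]):
        gm = gt_labels == g
        ids, counts = np.unique(seg_labels[gm], return_counts=True)
        best = ids[np.argmax(counts)]
        if best == 0:
            out.append(0.0)
            continue
        sm = seg_labels == best
        out.append((gm & sm).sum() / (gm | sm).sum())
    return np.asarray(out)
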