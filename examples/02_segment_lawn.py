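"""Segment a synthetic acceptor lawn in 3D and score it against ground truth.

Runs the four-stage membrane-based segmentation (anisotropic smoothing,
nucleus markers, marker-controlled watershed, region classification) and
reports the per-cell Jaccard overlap with the generator's label map.
"""

import numpy as np

import codeit as ci

lawn = ci.generate_lawn(ci.LawnSpec(seed=42))
labels = ci.segment_stack(lawn.channels["membrane"], lawn.channels["nuclei"])

jaccards = []
for g in np.unique(lawn.labels[lawn.labels > 0]):
    gm = lawn.labels == g
    ids, counts = np.unique(labels[gm], return_counts=True)
    best = ids[np.argmax(counts)]
    sm = labels == best
    jaccards.append((gm & sm).sum() / (gm | sm).sum() if best else 0.0)

print(f"ground-truth cells: {lawn.spec.n_cells}, segmented: {labels.max()}")
print(f"per-cell Jaccard vs ground truth: min {min(jaccards):.3f}, "
      f"mean {np.mean(jaccards):.3f}")
# Jaccard ~1 means each watershed region matches its ground-truth cell almost
# voxel-for-voxel; the quantification downstream only needs ~0.8.
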