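"""Independent brute-force oracles used to validate the pipeline.

These deliberately re-derive results voxel by voxel (or candidate by
candidate) in straight-line code that shares nothing with the library's
vectorised implementations.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def _per_cell_transfer(intens, labels, dilated_donor, threshold, max_label):
    counts = np.zeros(max_label + 1, dtype=np.int64)
    sums = np.zeros(max_label + 1, dtype=np.int64)
    nz, ny, nx = intens.shape
    for z in range(nz):
        for y in range(ny):
            for x in range(nx):
                lab = labels[z, y, x]
                if lab <= 0:
                    continue
                if dilated_donor[z, y, x]:
                    continue
                v = intens[z, y, x]
                if v > threshold:
                    counts[lab] += 1
                    sums[lab] += v
    return counts, sums


def per_cell_transfer_oracle(
    intens: np.ndarray, labels: np.ndarray, dilated_donor: np.ndarray, threshold: int
) -> tuple[np.ndarray, np.ndarray]:
    """Triple-loop per-cell (supra-threshold voxel count, intensity sum)."""
    return _per_cell_transfer(
        intens.astype(np.int64),
        labels.astype(np.int64),
        dilated_donor.astype(np.bool_),
        int(threshold),
        int(labels.max()),
    )


def pseudo_donor_oracle(labels: np.ndarray, voxel_size) -> int:
    """Exhaustive centroid-distance search for the most central cell."""
    vs = np.asarray(voxel_size)
    center = (np.asarray(labels.shape) - 1) / 2.0 * vs
    best, best_d = None, np.inf
    for lab in sorted(int(l) for l in np.unique(labels) if l > 0):
        com = np.argwhere(labels == lab).mean(axis=0) * vs
        d = float(np.sqrt(((com - center) ** 2).sum()))
        if d < best_d - 1e-12:
            best, best_d = lab, d
    return best


def donor_roi_oracle(donors, nuclei, exclusion_distance, nuclei_radius, min_nuclei):
    """Brute-force donor qualification over all donor pairs and nucleus counts.

    Returns the set of qualifying donor indices.
    """
    donors = np.asarray(donors).reshape(-1, 2)
    nuclei = np.asarray(nuclei).reshape(-1, 2)
    keep = set()
    for i in range(len(donors)):
        ok = True
        for j in range(len(donors)):
            if i == j:
                continue
            d = float(np.hypot(*(donors[i] - donors[j])))
            if d < exclusion_distance:
                ok = False
        n = 0
        for k in range(len(nuclei)):
            if float(np.hypot(*(nuclei[k] - donors[i]))) <= nuclei_radius:
                n += 1
        if ok and n >= min_nuclei:
            keep.add(i)
    return keep


def control_roi_valid(
    pos, donors, nuclei, others, exclusion_distance, nuclei_radius, min_nuclei, field_extent
) -> bool:
    """Re-check all three control-acceptance predicates for one position."""
    donors = np.asarray(donors).reshape(-1, 2)
    for d in donors:
        if float(np.hypot(*(d - pos))) < exclusion_distance:
            return False
    n = 0
    for k in np.asarray(nuclei).reshape(-1, 2):
        if float(np.hypot(*(k - pos))) <= nuclei_radius:
            n += 1
    if n < min_nuclei:
        return False
    for o in others:
        if (
            abs(o.center_um[0] - pos[0]) < (o.field_extent + field_extent) / 2
            and abs(o.center_um[1] - pos[1]) < (o.field_extent + field_extent) / 2
        ):
            return False
    return True


def diffuse_1d_oracle(profile: np.ndarray, iterations: int, k: float, dt: float) -> np.ndarray:
    """Reference 1D Perona-Malik diffusion with Neumann boundaries."""
    u = profile.astype(np.float64).copy()
    for _ in range(iterations):
        new = u.copy()
        for i in range(len(u)):
            fwd = (u[i + 1] - u[i]) if i + 1 < len(u) else 0.0
            bwd = (u[i] - u[i - 1]) if i > 0 else 0.0
            g_f = np.exp(-((fwd / k) ** 2))
            g_b = np.exp(-((bwd / k) ** 2))
            new[i] = u[i] + dt * (g_f * fwd - g_b * bwd)
        u = new
    return u
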