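"""3D acceptor-cell segmentation from the membrane channel.

Four stages, in the style of membrane-based whole-cell segmenters:
edge-preserving anisotropic (Perona–Malik) smoothing of the membrane
channel, nucleus-based marker generation from the nuclear channel,
marker-controlled watershed with the membrane intensity as the topographic
surface, and classification of the watershed regions into cells versus
background. The result is a label map that partitions the stack into
background (0) and 26-connected cell regions (>= 1).

Internal parameters (smoothing iterations, marker thresholds, plausibility
limits) are design choices of this package, frozen in
:class:`SegmentationParams` so that results are reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from scipy import ndimage as ndi
from skimage.segmentation import watershed

from .errors import NoMarkersError, SegmentationError
from .image_model import VoxelStack, voxel_volume


@dataclass(frozen=True)
class SegmentationParams:
    """Frozen defaults for the four segmentation stages.

    ``smoothing_iterations``/``conductance`` control the Perona–Malik
    diffusion (conductance in grayscale units: edges much stronger than this
    are preserved). Markers are nuclei: voxels above
    ``marker_intensity_threshold`` grouped 26-connectedly, components smaller
    than ``marker_min_volume`` (um^3) dropped. Classification removes regions
    larger than ``max_region_volume`` (um^3) or whose boundary carries less
    than ``min_boundary_intensity`` mean membrane signal.
    """

    smoothing_iterations: int = 3
    conductance: float = 30.0
    time_step: float = 1.0 / 7.0
    marker_intensity_threshold: int = 120
    marker_min_volume: float = 20.0
    background_intensity_threshold: int = 60
    min_boundary_intensity: float = 40.0
    max_region_volume: float = 30_000.0

    def __post_init__(self) -> None:
        if self.smoothing_iterations < 0:
            raise ValueError("smoothing_iterations must be >= 0")
        if self.conductance <= 0 or self.time_step <= 0:
            raise ValueError("conductance and time_step must be positive")
        if not self.marker_min_volume < self.max_region_volume:
            raise ValueError("marker_min_volume must be below max_region_volume")


class Markers(NamedTuple):
    """Watershed seeds: labels 1..n are nuclei, ``background_label`` the medium."""

    labels: np.ndarray
    n_foreground: int
    background_label: int


def smooth_anisotropic(stack: VoxelStack, params: SegmentationParams) -> VoxelStack:
    """Edge-preserving Perona–Malik diffusion of an 8-bit stack.

    Classic scheme with exponential conductance g(d) = exp(-(d/K)^2) over the
    six axial neighbour differences; zero iterations returns the input
    unchanged. Output is clipped to [0, 255].
    """
    if params.smoothing_iterations == 0:
        return stack
    u = stack.intensities.astype(np.float64)
    k2 = params.conductance**2
    dt = params.time_step
    for _ in range(params.smoothing_iterations):
        flux = np.zeros_like(u)
        for axis in range(3):
            fwd = np.diff(u, axis=axis, append=np.take(u, [-1], axis=axis))
            bwd = np.diff(u, axis=axis, prepend=np.take(u, [0], axis=axis))
            flux += fwd * np.exp(-(fwd**2) / k2) - bwd * np.exp(-(bwd**2) / k2)
        u += dt * flux
    out = np.clip(np.rint(u), 0, 255).astype(np.uint8)
    return VoxelStack(out, stack.voxel_size)


_STRUCT26 = np.ones((3, 3, 3), bool)


def generate_markers(
    nuclei: VoxelStack,
    params: SegmentationParams,
    membrane: VoxelStack | None = None,
) -> Markers:
    """Nucleus markers plus a background marker for the watershed.

    Foreground markers are 26-connected components of supra-threshold nuclear
    signal, with components below the minimum nucleus volume removed.
    The background marker is the low-intensity space connected to the axial
    (z) stack faces — the medium above and the substrate below the lawn.
    The lateral faces are deliberately not used: they slice through cells at
    the field border and would expose cell interiors as "background". When
    the membrane channel is supplied it defines that space (cell surfaces
    seal cells off from the medium); otherwise the nuclear channel is used.
    """
    vv = voxel_volume(nuclei)
    binary = nuclei.intensities > params.marker_intensity_threshold
    lab, n = ndi.label(binary, structure=_STRUCT26)
    if n == 0:
        raise NoMarkersError("no markers: no supra-threshold nuclear signal")
    counts = np.bincount(lab.ravel())
    keep = np.flatnonzero(counts * vv >= params.marker_min_volume)
    keep = keep[keep > 0]
    if keep.size == 0:
        raise NoMarkersError("no markers: all nuclear components below minimum volume")
    remap = np.zeros(n + 1, dtype=np.int32)
    remap[keep] = np.arange(1, keep.size + 1)
    markers = remap[lab]

    bg_source = membrane if membrane is not None else nuclei
    low = bg_source.intensities <= params.background_intensity_threshold
    border_connected = np.zeros_like(low)
    bg_lab, _ = ndi.label(low, structure=_STRUCT26)
    border_labels = set()
    for face in (bg_lab[0], bg_lab[-1]):
        border_labels.update(np.unique(face).tolist())
    border_labels.discard(0)
    if border_labels:
        border_connected = np.isin(bg_lab, list(border_labels))
    bg_label = keep.size + 1
    markers[border_connected & (markers == 0)] = bg_label
    return Markers(markers, n_foreground=keep.size, background_label=bg_label)


def watershed_cells(membrane: VoxelStack, markers: Markers) -> np.ndarray:
    """Marker-controlled watershed on the membrane intensity surface.

    Each foreground marker grows into exactly one region. The background
    marker region (the medium) is excluded from flooding, so cells climb
    and keep their own membrane shells instead of ceding ridge voxels to a
    competing background basin; the medium and any unreachable pockets are
    labelled 0. The skimage flooding order is deterministic, so repeated
    runs give identical partitions.
    """
    if markers.n_foreground == 0:
        raise NoMarkersError("no foreground markers")
    seeds = np.where(markers.labels == markers.background_label, 0, markers.labels)
    mask = markers.labels != markers.background_label
    lab = watershed(membrane.intensities, markers=seeds, mask=mask)
    return lab.astype(np.int32)


def classify_regions(
    label_map: np.ndarray, membrane: VoxelStack, params: SegmentationParams
) -> np.ndarray:
    """Reject watershed regions that are not plausible cells.

    A region is kept only if its volume does not exceed the maximum plausible
    cell volume and its surface carries membrane signal (mean intensity on
    the region's boundary shell at least ``min_boundary_intensity``) —
    basins of the medium have no membrane boundary and are reclassified to
    background. Survivors are renumbered contiguously from 1; the operation
    is idempotent.
    """
    vv = voxel_volume(membrane)
    labels = np.unique(label_map)
    labels = labels[labels > 0]
    if labels.size == 0:
        raise SegmentationError("classification rejected all regions: no cells found")
    out = np.zeros_like(label_map, dtype=np.int32)
    next_label = 1
    counts = np.bincount(label_map.ravel())
    for lab in labels:
        if counts[lab] * vv > params.max_region_volume:
            continue
        region = label_map == lab
        shell = region & ~ndi.binary_erosion(region)
        mean_boundary = float(membrane.intensities[shell].mean()) if shell.any() else 0.0
        if mean_boundary < params.min_boundary_intensity:
            continue
        out[region] = next_label
        next_label += 1
    if next_label == 1:
        raise SegmentationError("classification rejected all regions: no cells found")
    return out


def segment_stack(
    membrane: VoxelStack,
    nuclei: VoxelStack,
    params: SegmentationParams | None = None,
) -> np.ndarray:
    """Full pipeline: smooth -> markers -> watershed -> classify."""
    params = params or SegmentationParams()
    smoothed = smooth_anisotropic(membrane, params)
    markers = generate_markers(nuclei, params, membrane=smoothed)
    lab = watershed_cells(smoothed, markers)
    return classify_regions(lab, smoothed, params)
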