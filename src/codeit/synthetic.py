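"""Synthetic co-culture stacks and well mosaics with complete ground truth.

The generator emulates the screening acquisition: a confluent monolayer
("lawn") of acceptor cells on a substrate, imaged as a 3D stack with nuclear,
membrane and DiD channels; a single donor cell rendered with roughly half its
volume at detector saturation; punctate supra-threshold transfer signal
painted into neighbouring acceptor cells at known intensities; sub-threshold
autofluorescence noise; and 2D low-resolution well mosaics with configurable
donor placement and nuclear density for ROI selection.

Cell geometry is a Voronoi tessellation of jittered nucleus centres, clipped
to a slab so that cells sit on a virtual substrate with medium above. The
quantification method never depends on cell shape — only on label partitions,
volumes and intensities — so this crude geometry is sufficient to exercise
every pipeline stage against exact ground truth.

All generators are deterministic given their seed: one seeded
``numpy.random.Generator`` per top-level call, no global state.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.ndimage import binary_dilation, binary_erosion
from scipy.spatial import cKDTree
from skimage.segmentation import find_boundaries

from .errors import InvalidSpecError
from .image_model import ChannelSet, VoxelStack, voxel_volume

#: Default acquisition geometry: 1.01 um z-steps; xy pixel pitch chosen to
#: match a ~228 um field imaged at 512 px (40x objective at zoom 1.7).
DEFAULT_VOXEL_SIZE = (1.01, 0.445, 0.445)


@dataclass(frozen=True)
class LawnSpec:
    """Parameters of a synthetic confluent acceptor lawn."""

    shape: tuple[int, int, int] = (20, 256, 256)
    voxel_size: tuple[float, float, float] = DEFAULT_VOXEL_SIZE
    n_cells: int = 50
    mean_cell_diameter: float = 14.0
    membrane_intensity: int = 200
    nucleus_intensity: int = 220
    background_noise_max: int = 60
    slab_z: tuple[int, int] = (2, 14)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise InvalidSpecError("n_cells must be >= 1")
        if not 0 <= self.background_noise_max < 100:
            raise InvalidSpecError(
                "background_noise_max must stay below the DiD transfer threshold"
            )
        z0, z1 = self.slab_z
        if not 0 <= z0 < z1 <= self.shape[0]:
            raise InvalidSpecError(f"slab_z {self.slab_z} outside stack of nz={self.shape[0]}")


@dataclass(frozen=True)
class Punctum:
    """One spherical transfer punctum inside an acceptor cell."""

    target_label: int
    center_um: tuple[float, float, float]  # (z, y, x)
    radius_um: float
    intensity: int


@dataclass(frozen=True)
class TransferSpec:
    """Donor identity and the puncta to paint into acceptor cells."""

    donor_label: int
    puncta: tuple[Punctum, ...] = ()
    donor_saturated_fraction: float = 0.5
    donor_rim_intensity: int = 180

    def __post_init__(self) -> None:
        if not 0.0 <= self.donor_saturated_fraction <= 1.0:
            raise InvalidSpecError("donor_saturated_fraction must be in [0, 1]")


@dataclass(frozen=True)
class GroundTruth:
    """Exact painted transfer per cell, recomputable by brute force."""

    label_map: np.ndarray
    donor_label: int
    transfer_intensity: dict[int, int]  # cell label -> sum of painted grayscale
    transfer_voxels: dict[int, int]  # cell label -> painted voxel count
    cell_volume_um3: dict[int, float]
    punctum_voxels: dict[int, np.ndarray]  # label -> (n, 3) painted voxel indices


@dataclass(frozen=True)
class SyntheticLawn:
    """A generated lawn: channels, ground-truth labels and nucleus centres."""

    channels: ChannelSet
    labels: np.ndarray
    nucleus_centers_um: np.ndarray  # (n, 3) in (z, y, x) um
    spec: LawnSpec


def _poisson_disc_2d(
    rng: np.random.Generator,
    extent_yx: tuple[float, float],
    n: int,
    min_sep: float,
    margin: float,
) -> np.ndarray:
    """Dart-throwing Poisson-disc sample of n (y, x) points."""
    pts: list[np.ndarray] = []
    attempts = 0
    budget = 500 * n
    lo = np.array([margin, margin])
    hi = np.array(extent_yx) - margin
    if np.any(hi <= lo):
        raise InvalidSpecError("stack too small for requested cell diameter")
    while len(pts) < n:
        if attempts >= budget:
            raise InvalidSpecError(
                f"cannot place {n} non-overlapping nuclei (min separation {min_sep} um)"
            )
        attempts += 1
        p = rng.uniform(lo, hi)
        if all(np.hypot(*(p - q)) >= min_sep for q in pts):
            pts.append(p)
    return np.array(pts)


def generate_lawn(spec: LawnSpec) -> SyntheticLawn:
    """Generate a confluent acceptor lawn with membrane, nuclei and DiD noise.

    Nucleus centres are Poisson-disc sampled in the xy plane at mid-slab
    height (small z jitter); cell regions are the 3D Voronoi cells of those
    centres clipped to the slab. The membrane channel carries a bright
    1–2 voxel shell at every inter-cell and cell–background boundary, the
    nuclei channel bright ellipsoids at the centres, and the DiD channel
    uniform sub-threshold noise.
    """
    rng = np.random.default_rng(spec.seed)
    nz, ny, nx = spec.shape
    dz, dy, dx = spec.voxel_size
    z0, z1 = spec.slab_z

    min_sep = 0.72 * spec.mean_cell_diameter
    yx = _poisson_disc_2d(
        rng, (ny * dy, nx * dx), spec.n_cells, min_sep, margin=0.15 * spec.mean_cell_diameter
    )
    z_mid = (z0 + z1 - 1) / 2.0 * dz
    zc = z_mid + rng.uniform(-0.5, 0.5, size=spec.n_cells) * dz
    centers = np.column_stack([zc, yx])  # (n, 3) um

    # Voronoi assignment of slab voxels to nearest nucleus centre (um metric).
    zz, yy, xx = np.meshgrid(
        np.arange(z0, z1) * dz, np.arange(ny) * dy, np.arange(nx) * dx, indexing="ij"
    )
    coords = np.column_stack([zz.ravel(), yy.ravel(), xx.ravel()])
    _, nearest = cKDTree(centers).query(coords, workers=-1)
    labels = np.zeros(spec.shape, dtype=np.int32)
    labels[z0:z1] = (nearest + 1).reshape(z1 - z0, ny, nx)

    # Membrane: shell on the cell side of every label boundary.
    shell = find_boundaries(labels, mode="thick") & (labels > 0)
    membrane = rng.integers(0, 21, size=spec.shape).astype(np.int16)
    membrane[shell] = spec.membrane_intensity

    # Nuclei: ellipsoids at the centres.
    nuclei = rng.integers(0, 21, size=spec.shape).astype(np.int16)
    rz_um, rxy_um = 2.4, 3.4
    for cz, cy, cx in centers:
        zs = np.arange(max(0, int((cz - rz_um) / dz)), min(nz, int((cz + rz_um) / dz) + 2))
        ys = np.arange(max(0, int((cy - rxy_um) / dy)), min(ny, int((cy + rxy_um) / dy) + 2))
        xs = np.arange(max(0, int((cx - rxy_um) / dx)), min(nx, int((cx + rxy_um) / dx) + 2))
        gz, gy, gx = np.meshgrid(zs * dz - cz, ys * dy - cy, xs * dx - cx, indexing="ij")
        inside = (gz / rz_um) ** 2 + (gy / rxy_um) ** 2 + (gx / rxy_um) ** 2 <= 1.0
        sub = nuclei[np.ix_(zs, ys, xs)]
        sub[inside] = spec.nucleus_intensity
        nuclei[np.ix_(zs, ys, xs)] = sub

    did = rng.integers(0, spec.background_noise_max + 1, size=spec.shape).astype(np.int16)

    def _stack(a: np.ndarray) -> VoxelStack:
        return VoxelStack(np.clip(a, 0, 255).astype(np.uint8), spec.voxel_size)

    channels = ChannelSet(
        {"nuclei": _stack(nuclei), "membrane": _stack(membrane), "did": _stack(did)}
    )
    return SyntheticLawn(channels, labels, centers, spec)


def generate_control_stack(spec: LawnSpec, n_dim_puncta: int = 8) -> SyntheticLawn:
    """Generate a donor-free background lawn (control field).

    Identical to :func:`generate_lawn` but additionally scatters a few dim,
    sub-threshold DiD puncta to mimic autofluorescent debris. No voxel in the
    DiD channel exceeds the transfer threshold, so quantification through the
    pseudo-donor path measures pure background.
    """
    lawn = generate_lawn(spec)
    rng = np.random.default_rng(spec.seed + 986_243)
    did = lawn.channels["did"].intensities.copy()
    z0, z1 = spec.slab_z
    nz, ny, nx = spec.shape
    for _ in range(n_dim_puncta):
        cz = rng.integers(z0, z1)
        cy = rng.integers(2, ny - 2)
        cx = rng.integers(2, nx - 2)
        did[cz, cy - 1 : cy + 2, cx - 1 : cx + 2] = rng.integers(
            max(1, spec.background_noise_max - 20), min(100, spec.background_noise_max + 30)
        )
    np.clip(did, 0, 99, out=did)  # strictly below the default DiD threshold
    channels = ChannelSet(
        {
            "nuclei": lawn.channels["nuclei"],
            "membrane": lawn.channels["membrane"],
            "did": VoxelStack(did.astype(np.uint8), spec.voxel_size),
        }
    )
    return SyntheticLawn(channels, lawn.labels, lawn.nucleus_centers_um, spec)


def _sphere_voxels(
    center_um: Sequence[float],
    radius_um: float,
    shape: tuple[int, int, int],
    voxel_size: tuple[float, float, float],
) -> np.ndarray:
    """Indices (n, 3) of voxels whose centres lie within radius of a point."""
    vs = np.asarray(voxel_size)
    c = np.asarray(center_um)
    lo = np.maximum(0, np.floor((c - radius_um) / vs).astype(int))
    hi = np.minimum(np.asarray(shape), np.ceil((c + radius_um) / vs).astype(int) + 1)
    if np.any(hi <= lo):
        return np.empty((0, 3), dtype=int)
    grids = np.meshgrid(*[np.arange(l, h) for l, h in zip(lo, hi)], indexing="ij")
    idx = np.column_stack([g.ravel() for g in grids])
    dist2 = ((idx * vs - c) ** 2).sum(axis=1)
    return idx[dist2 <= radius_um**2]


_CUBE3 = np.ones((3, 3, 3), bool)


def paint_donor_and_transfer(
    lawn: SyntheticLawn,
    spec: TransferSpec,
    did_threshold: int = 100,
) -> tuple[ChannelSet, GroundTruth]:
    """Paint the donor cell and transfer puncta into a lawn's DiD channel.

    The donor cell receives ``donor_saturated_fraction`` of its volume at the
    intensity maximum (the voxels nearest its centroid) and a bright
    sub-saturation rim elsewhere, mimicking the half-saturated acquisition of
    donor cells. Each punctum is rendered as a sphere of constant intensity;
    the returned :class:`GroundTruth` records the exact painted per-cell sums.

    Puncta must lie entirely inside their target cell, outside the one-voxel-
    dilated donor mask, not overlap each other, and exceed the transfer
    threshold — violations raise :class:`InvalidSpecError`.
    """
    labels = lawn.labels
    vs = lawn.channels.voxel_size
    vv = voxel_volume(lawn.channels["did"])
    if spec.donor_label not in np.unique(labels):
        raise InvalidSpecError(f"donor label {spec.donor_label} not present in label map")

    did = lawn.channels["did"].intensities.astype(np.int16).copy()

    donor_mask = labels == spec.donor_label
    donor_idx = np.argwhere(donor_mask)
    centroid = donor_idx.mean(axis=0) * np.asarray(vs)
    d2 = (((donor_idx * np.asarray(vs)) - centroid) ** 2).sum(axis=1)
    order = np.argsort(d2, kind="stable")
    k = int(round(spec.donor_saturated_fraction * len(donor_idx)))
    sat = donor_idx[order[:k]]
    rim = donor_idx[order[k:]]
    did[tuple(sat.T)] = 255
    if len(rim):
        did[tuple(rim.T)] = spec.donor_rim_intensity
    dilated_donor = binary_dilation(donor_mask, structure=_CUBE3)

    painted = np.zeros_like(labels, dtype=bool)
    intensity_sum: dict[int, int] = {}
    voxel_count: dict[int, int] = {}
    punctum_vox: dict[int, list[np.ndarray]] = {}
    for p in spec.puncta:
        if p.intensity <= did_threshold:
            raise InvalidSpecError(
                f"punctum intensity {p.intensity} not above threshold {did_threshold}"
            )
        vox = _sphere_voxels(p.center_um, p.radius_um, labels.shape, vs)
        if len(vox) == 0:
            raise InvalidSpecError(f"punctum at {p.center_um} covers no voxels")
        sel = tuple(vox.T)
        if np.any(labels[sel] != p.target_label):
            raise InvalidSpecError(
                f"punctum at {p.center_um} extends outside cell {p.target_label}"
            )
        if np.any(dilated_donor[sel]):
            raise InvalidSpecError(f"punctum at {p.center_um} overlaps the dilated donor")
        if np.any(painted[sel]):
            raise InvalidSpecError(f"punctum at {p.center_um} overlaps another punctum")
        painted[sel] = True
        did[sel] = p.intensity
        intensity_sum[p.target_label] = intensity_sum.get(p.target_label, 0) + int(
            p.intensity
        ) * len(vox)
        voxel_count[p.target_label] = voxel_count.get(p.target_label, 0) + len(vox)
        punctum_vox.setdefault(p.target_label, []).append(vox)

    cell_labels, counts = np.unique(labels[labels > 0], return_counts=True)
    volumes = {int(l): float(c) * vv for l, c in zip(cell_labels, counts)}
    gt = GroundTruth(
        label_map=labels,
        donor_label=spec.donor_label,
        transfer_intensity={l: intensity_sum.get(l, 0) for l in map(int, cell_labels)},
        transfer_voxels={l: voxel_count.get(l, 0) for l in map(int, cell_labels)},
        cell_volume_um3=volumes,
        punctum_voxels={l: np.vstack(v) for l, v in punctum_vox.items()},
    )
    channels = ChannelSet(
        {
            "nuclei": lawn.channels["nuclei"],
            "membrane": lawn.channels["membrane"],
            "did": VoxelStack(np.clip(did, 0, 255).astype(np.uint8), vs),
        }
    )
    return channels, gt


def eligible_acceptors(
    lawn: SyntheticLawn, donor_label: int, min_volume_um3: float = 100.0
) -> list[int]:
    """Cell labels that quantification will include: non-donor, not touching
    the lateral image boundary, and at least the minimum cell volume."""
    labels = lawn.labels
    vv = voxel_volume(lawn.channels["did"])
    boundary = set()
    for face in (labels[:, 0, :], labels[:, -1, :], labels[:, :, 0], labels[:, :, -1]):
        boundary.update(np.unique(face).tolist())
    out = []
    for lab in np.unique(labels[labels > 0]):
        lab = int(lab)
        if lab == donor_label or lab in boundary:
            continue
        if np.count_nonzero(labels == lab) * vv < min_volume_um3:
            continue
        out.append(lab)
    return out


def random_transfer_spec(
    lawn: SyntheticLawn,
    seed: int,
    n_target_cells: int = 8,
    puncta_per_cell: tuple[int, int] = (1, 3),
    intensity_range: tuple[int, int] = (150, 255),
    radius_um: float = 1.0,
    did_threshold: int = 100,
) -> TransferSpec:
    """Sample a valid :class:`TransferSpec` for a lawn.

    The donor is the cell whose centroid is nearest the stack centre (the
    acquisition centres fields on donors). Target cells are drawn from the
    acceptors that quantification includes; puncta are placed at least two
    voxels inside their cell and clear of the dilated donor, so segmentation
    errors of one voxel cannot reassign ground-truth transfer.
    """
    rng = np.random.default_rng(seed)
    labels = lawn.labels
    vs = np.asarray(lawn.channels.voxel_size)
    center = lawn.channels["did"].center_um()
    from scipy.ndimage import center_of_mass

    cells = np.unique(labels[labels > 0])
    coms = center_of_mass(np.ones_like(labels), labels, cells)
    centroids = {int(l): np.asarray(c) * vs for l, c in zip(cells, coms)}
    donor = min(centroids, key=lambda l: float(np.linalg.norm(centroids[l] - center)))

    donor_zone = binary_dilation(labels == donor, structure=_CUBE3, iterations=3)
    candidates = eligible_acceptors(lawn, donor)
    if not candidates:
        raise InvalidSpecError("no eligible acceptor cells in lawn")
    n_target = min(n_target_cells, len(candidates))
    targets = rng.choice(np.array(candidates), size=n_target, replace=False)

    puncta: list[Punctum] = []
    occupied = np.zeros_like(labels, dtype=bool)
    for lab in targets:
        lab = int(lab)
        interior = binary_erosion(labels == lab, iterations=2) & ~donor_zone
        n_puncta = rng.integers(puncta_per_cell[0], puncta_per_cell[1] + 1)
        placed = 0
        pool = np.argwhere(interior)
        tries = 0
        while placed < n_puncta and tries < 60 and len(pool):
            tries += 1
            c_idx = pool[rng.integers(len(pool))]
            c_um = tuple(c_idx * vs)
            vox = _sphere_voxels(c_um, radius_um, labels.shape, vs)
            sel = tuple(vox.T)
            if not np.all(interior[sel]) or np.any(occupied[sel]):
                continue
            occupied[sel] = True
            puncta.append(
                Punctum(
                    lab,
                    c_um,
                    radius_um,
                    int(rng.integers(max(intensity_range[0], did_threshold + 1),
                                     intensity_range[1] + 1)),
                )
            )
            placed += 1
    return TransferSpec(donor_label=int(donor), puncta=tuple(puncta))


# ---------------------------------------------------------------------------
# Well mosaics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class WellSpec:
    """A 2D well for low-resolution mosaic rendering.

    Positions are stage coordinates in um, ``(x, y)``, with the origin at the
    top-left corner of the first tile. The published scanning template uses
    775 um tiles of 512 px, i.e. ~1.51 um per low-resolution pixel.
    """

    extent_um: tuple[float, float] = (1550.0, 1550.0)  # (width x, height y)
    tile_size_um: float = 775.0
    um_per_px: float = 775.0 / 512.0
    donor_positions: tuple[tuple[float, float], ...] = ()
    nucleus_positions: tuple[tuple[float, float], ...] = ()
    background_noise_max: int = 25
    donor_peak: int = 255
    donor_core_radius_um: float = 8.0  # saturated blob core, like a real donor
    nucleus_peak: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        w, h = self.extent_um
        for x, y in tuple(self.donor_positions) + tuple(self.nucleus_positions):
            if not (0 <= x < w and 0 <= y < h):
                raise InvalidSpecError(f"position ({x}, {y}) outside well extent {self.extent_um}")

    @property
    def grid(self) -> tuple[int, int]:
        """(rows, cols) of the tile grid covering the extent."""
        w, h = self.extent_um
        return (
            int(np.ceil(h / self.tile_size_um)),
            int(np.ceil(w / self.tile_size_um)),
        )


@dataclass(frozen=True)
class WellMosaic:
    """Rendered tiles plus the ground truth used to validate ROI selection."""

    tiles: dict[str, list[list[np.ndarray]]]  # channel -> [row][col] 2D arrays
    grid: tuple[int, int]
    tile_size_um: float
    um_per_px: float
    donor_positions: np.ndarray  # (n, 2) stage um, (x, y)
    nucleus_positions: np.ndarray


def random_well_spec(
    seed: int,
    extent_um: tuple[float, float] = (1550.0, 1550.0),
    n_donors: int = 4,
    nucleus_density_per_um2: float = 4.0e-4,
    margin_um: float = 40.0,
) -> WellSpec:
    """Random donors and a confluent-density nucleus field for one well.

    The default nucleus density corresponds to the plating density of the
    screening co-cultures (~35,000 cells/cm^2).
    """
    rng = np.random.default_rng(seed)
    w, h = extent_um
    n_nuclei = rng.poisson(nucleus_density_per_um2 * w * h)
    nuclei = np.column_stack(
        [rng.uniform(margin_um, w - margin_um, n_nuclei),
         rng.uniform(margin_um, h - margin_um, n_nuclei)]
    )
    # Donors sit on top of the lawn; keep them inside the margin too.
    donors = np.column_stack(
        [rng.uniform(margin_um, w - margin_um, n_donors),
         rng.uniform(margin_um, h - margin_um, n_donors)]
    )
    return WellSpec(
        extent_um=extent_um,
        donor_positions=tuple(map(tuple, donors)),
        nucleus_positions=tuple(map(tuple, nuclei)),
        seed=seed,
    )


def _render_spots(
    canvas: np.ndarray,
    positions_um: np.ndarray,
    um_per_px: float,
    sigma_um: float,
    peak: int,
    core_radius_um: float = 0.0,
) -> None:
    """Draw spots as a flat core of ``peak`` with a Gaussian halo outside."""
    sigma_px = sigma_um / um_per_px
    core_px = core_radius_um / um_per_px
    half = int(np.ceil(core_px + 3 * sigma_px))
    ax = np.arange(-half, half + 1)
    gy, gx = np.meshgrid(ax, ax, indexing="ij")
    dist = np.hypot(gy, gx)
    kernel = peak * np.exp(-np.maximum(dist - core_px, 0.0) ** 2 / (2 * sigma_px**2))
    h, w = canvas.shape
    for x_um, y_um in positions_um:
        cx, cy = int(round(x_um / um_per_px)), int(round(y_um / um_per_px))
        y0, y1 = max(0, cy - half), min(h, cy + half + 1)
        x0, x1 = max(0, cx - half), min(w, cx + half + 1)
        ky0, kx0 = y0 - (cy - half), x0 - (cx - half)
        patch = kernel[ky0 : ky0 + (y1 - y0), kx0 : kx0 + (x1 - x0)]
        canvas[y0:y1, x0:x1] = np.maximum(canvas[y0:y1, x0:x1], patch)


def generate_well_mosaic(spec: WellSpec) -> WellMosaic:
    """Render a well as per-channel low-resolution tiles plus ground truth.

    Nuclei are rendered as Gaussian spots in the nuclear channel and donors
    as bright Gaussian blobs in the DiD channel, on top of uniform noise.
    The super-image is split into a row-major grid of equally sized tiles.
    """
    rng = np.random.default_rng(spec.seed)
    rows, cols = spec.grid
    tile_px = int(round(spec.tile_size_um / spec.um_per_px))
    h_px, w_px = rows * tile_px, cols * tile_px

    donors = np.asarray(spec.donor_positions, dtype=float).reshape(-1, 2)
    nuclei = np.asarray(spec.nucleus_positions, dtype=float).reshape(-1, 2)

    channels: dict[str, np.ndarray] = {}
    for name, positions, sigma, peak, core in (
        ("nuclei", nuclei, 3.5, spec.nucleus_peak, 0.0),
        ("did", donors, 4.0, spec.donor_peak, spec.donor_core_radius_um),
    ):
        canvas = rng.integers(0, spec.background_noise_max + 1, size=(h_px, w_px)).astype(
            np.float64
        )
        _render_spots(canvas, positions, spec.um_per_px, sigma, peak, core)
        channels[name] = np.clip(canvas, 0, 255).astype(np.uint8)

    tiles = {
        name: [
            [img[r * tile_px : (r + 1) * tile_px, c * tile_px : (c + 1) * tile_px]
             for c in range(cols)]
            for r in range(rows)
        ]
        for name, img in channels.items()
    }
    return WellMosaic(
        tiles=tiles,
        grid=(rows, cols),
        tile_size_um=tile_px * spec.um_per_px,
        um_per_px=spec.um_per_px,
        donor_positions=donors,
        nucleus_positions=nuclei,
    )
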