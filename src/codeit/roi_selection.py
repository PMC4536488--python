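"""Selection of high-resolution acquisition positions from well-scale mosaics.

A whole well is scanned at low resolution in the nuclear and DiD channels and
assembled into a super-image. Donor cells appear as bright DiD blobs; a
position qualifies for high-resolution imaging only if the donor is isolated
(no other donor within 200 um) and sits in a confluent lawn (at least 15
nuclei within a 200 um radius). Donor-free control positions are sampled at
random under the same distance and density requirements, without spatial
overlap of any two selected high-resolution fields. The module ends at the
exported coordinate list; microscope control is out of scope.

Distance rules are inclusive at the boundary ("at least 200 um" means a
distance of exactly 200 um qualifies).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage as ndi
from skimage.feature import peak_local_max

from .errors import CodeitError
from .image_model import QuantConfig


@dataclass(frozen=True)
class SuperImage:
    """Assembled whole-well image with its stage-coordinate mapping.

    Stage position of pixel ``(row, col)`` is
    ``origin + (col * um_per_px, row * um_per_px)`` in ``(x, y)`` um.
    """

    nuclei: np.ndarray
    did: np.ndarray
    um_per_px: float
    origin_um: tuple[float, float] = (0.0, 0.0)
    grid: tuple[int, int] = (1, 1)

    def __post_init__(self) -> None:
        if self.um_per_px <= 0:
            raise ValueError("um_per_px must be positive")
        if self.nuclei.shape != self.did.shape:
            raise ValueError("channel shapes differ")

    @property
    def extent_um(self) -> tuple[float, float]:
        """(width x, height y) of the well in um."""
        h, w = self.did.shape
        return w * self.um_per_px, h * self.um_per_px


@dataclass(frozen=True)
class RoiCandidate:
    """A proposed high-resolution acquisition position."""

    center_um: tuple[float, float]  # stage (x, y)
    kind: str  # 'donor' | 'control'
    nearest_donor_distance: float
    nuclei_in_radius: int
    field_extent: float


def assemble_superimage(
    tiles: dict[str, list[list[np.ndarray]]],
    um_per_px: float,
    origin_um: tuple[float, float] = (0.0, 0.0),
) -> SuperImage:
    """Place a complete rectangular grid of tiles row-major, without blending.

    ``tiles`` maps channel name ('nuclei', 'did') to a [row][col] nested list
    of equally shaped 2D arrays. Missing tiles or inconsistent shapes are
    errors.
    """
    for role in ("nuclei", "did"):
        if role not in tiles:
            raise CodeitError(f"missing channel {role!r} in tiles")
    grids = {}
    grid_shape = None
    for role in ("nuclei", "did"):
        rows = tiles[role]
        if not rows or any(len(r) != len(rows[0]) for r in rows):
            raise CodeitError(f"{role}: tile grid is not rectangular")
        tile_shape = rows[0][0].shape
        for r in rows:
            for t in r:
                if t is None:
                    raise CodeitError(f"{role}: missing tile")
                if t.shape != tile_shape:
                    raise CodeitError(f"{role}: inconsistent tile shapes")
        grids[role] = np.block([[np.asarray(t) for t in row] for row in rows])
        if grid_shape is None:
            grid_shape = (len(rows), len(rows[0]))
    return SuperImage(
        nuclei=grids["nuclei"], did=grids["did"], um_per_px=um_per_px,
        origin_um=origin_um, grid=grid_shape,
    )


def find_donors_2d(si: SuperImage, cfg: QuantConfig) -> np.ndarray:
    """Donor centroids in stage um, (n, 2) as (x, y).

    Donors are 8-connected components of DiD signal above the donor intensity
    level whose area reaches the minimum blob area (``donor_min_area``, um^2);
    debris specks below it are ignored.
    """
    binary = si.did > cfg.donor_intensity_threshold
    lab, n = ndi.label(binary, structure=np.ones((3, 3), bool))
    if n == 0:
        return np.empty((0, 2))
    px_area = si.um_per_px**2
    counts = np.bincount(lab.ravel())
    keep = [i for i in range(1, n + 1) if counts[i] * px_area >= cfg.donor_min_area]
    if not keep:
        return np.empty((0, 2))
    coms = ndi.center_of_mass(binary, lab, keep)  # (row, col)
    ox, oy = si.origin_um
    return np.array([(ox + c * si.um_per_px, oy + r * si.um_per_px) for r, c in coms])


def detect_nuclei_2d(si: SuperImage, cfg: QuantConfig) -> np.ndarray:
    """Nucleus positions in stage um, (n, 2) as (x, y).

    Nuclei are local maxima of the nuclear channel above the detection
    threshold, separated by at least one nuclear diameter.
    """
    min_dist_px = max(1, int(round(cfg.nucleus_min_separation / si.um_per_px)))
    peaks = peak_local_max(
        si.nuclei.astype(float),
        min_distance=min_dist_px,
        threshold_abs=cfg.nucleus_detect_threshold,
        exclude_border=False,
    )
    if peaks.size == 0:
        return np.empty((0, 2))
    ox, oy = si.origin_um
    return np.column_stack(
        [ox + peaks[:, 1] * si.um_per_px, oy + peaks[:, 0] * si.um_per_px]
    )


def count_nuclei(
    nuclei_positions: np.ndarray, center_um: tuple[float, float], radius_um: float
) -> int:
    """Nuclei within Euclidean distance <= radius of the centre (inclusive)."""
    if len(nuclei_positions) == 0:
        return 0
    d = np.linalg.norm(np.asarray(nuclei_positions) - np.asarray(center_um), axis=1)
    return int(np.count_nonzero(d <= radius_um))


def select_donor_rois(
    donors: np.ndarray, nuclei_positions: np.ndarray, cfg: QuantConfig
) -> list[RoiCandidate]:
    """Keep each donor that is isolated and sits in a dense-enough lawn.

    A donor qualifies iff every other donor is at least ``exclusion_distance``
    away and at least ``min_nuclei`` nuclei lie within ``nuclei_radius`` of
    its centroid.
    """
    donors = np.asarray(donors).reshape(-1, 2)
    selected = []
    for i, d in enumerate(donors):
        others = np.delete(donors, i, axis=0)
        nearest = float(np.min(np.linalg.norm(others - d, axis=1))) if len(others) else np.inf
        if nearest < cfg.exclusion_distance:
            continue
        n_nuc = count_nuclei(nuclei_positions, tuple(d), cfg.nuclei_radius)
        if n_nuc < cfg.min_nuclei:
            continue
        selected.append(
            RoiCandidate(
                center_um=(float(d[0]), float(d[1])),
                kind="donor",
                nearest_donor_distance=nearest,
                nuclei_in_radius=n_nuc,
                field_extent=cfg.field_extent,
            )
        )
    return selected


def _footprints_overlap(a: RoiCandidate, b: RoiCandidate) -> bool:
    """Axis-aligned square fields overlap iff both centre gaps are below the
    mean half-extent sum (touching edges do not count as overlap)."""
    half = (a.field_extent + b.field_extent) / 2.0
    return (
        abs(a.center_um[0] - b.center_um[0]) < half
        and abs(a.center_um[1] - b.center_um[1]) < half
    )


def select_control_rois(
    si: SuperImage,
    donors: np.ndarray,
    selected: list[RoiCandidate],
    cfg: QuantConfig,
    seed: int,
    nuclei_positions: np.ndarray | None = None,
    attempt_budget: int = 2000,
) -> list[RoiCandidate]:
    """Up to ``max_controls`` random donor-free positions.

    Candidate centres are drawn uniformly over the well and accepted iff no
    donor lies within the exclusion distance, the nucleus count in the
    density radius reaches the minimum, and the high-resolution field
    footprint does not overlap any previously selected field (donor or
    control). Deterministic given the seed; may return fewer than the
    maximum if the attempt budget is exhausted.
    """
    rng = np.random.default_rng(seed)
    if nuclei_positions is None:
        nuclei_positions = detect_nuclei_2d(si, cfg)
    donors = np.asarray(donors).reshape(-1, 2)
    w, h = si.extent_um
    ox, oy = si.origin_um
    accepted: list[RoiCandidate] = []
    taken = list(selected)
    for _ in range(attempt_budget):
        if len(accepted) >= cfg.max_controls:
            break
        pos = (float(ox + rng.uniform(0, w)), float(oy + rng.uniform(0, h)))
        nearest = (
            float(np.min(np.linalg.norm(donors - pos, axis=1))) if len(donors) else np.inf
        )
        if nearest < cfg.exclusion_distance:
            continue
        n_nuc = count_nuclei(nuclei_positions, pos, cfg.nuclei_radius)
        if n_nuc < cfg.min_nuclei:
            continue
        cand = RoiCandidate(
            center_um=pos,
            kind="control",
            nearest_donor_distance=nearest,
            nuclei_in_radius=n_nuc,
            field_extent=cfg.field_extent,
        )
        if any(_footprints_overlap(cand, t) for t in taken):
            continue
        accepted.append(cand)
        taken.append(cand)
    return accepted


def select_rois(
    si: SuperImage, cfg: QuantConfig, seed: int
) -> tuple[list[RoiCandidate], list[RoiCandidate]]:
    """Full DonorFind-style pass: donors, then random controls."""
    donors = find_donors_2d(si, cfg)
    nuclei = detect_nuclei_2d(si, cfg)
    donor_rois = select_donor_rois(donors, nuclei, cfg)
    control_rois = select_control_rois(si, donors, donor_rois, cfg, seed, nuclei)
    return donor_rois, control_rois


CSV_COLUMNS = ("kind", "x_um", "y_um", "nearest_donor_distance", "nuclei_in_radius")


def export_coordinates(rois: list[RoiCandidate], path: str | Path) -> None:
    """Write the acquisition coordinate list as CSV.

    Donors first, ordered by y then x; controls follow in acceptance order.
    An empty list produces a header-only file.
    """
    donors = sorted(
        (r for r in rois if r.kind == "donor"),
        key=lambda r: (r.center_um[1], r.center_um[0]),
    )
    controls = [r for r in rois if r.kind == "control"]
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(CSV_COLUMNS)
        for r in donors + controls:
            nearest = "" if np.isinf(r.nearest_donor_distance) else repr(
                float(r.nearest_donor_distance)
            )
            writer.writerow(
                [r.kind, repr(float(r.center_um[0])), repr(float(r.center_um[1])),
                 nearest, r.nuclei_in_radius]
            )


def read_coordinates(path: str | Path) -> list[RoiCandidate]:
    """Read an :func:`export_coordinates` CSV back into candidates."""
    out = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            out.append(
                RoiCandidate(
                    center_um=(float(row["x_um"]), float(row["y_um"])),
                    kind=row["kind"],
                    nearest_donor_distance=(
                        float(row["nearest_donor_distance"])
                        if row["nearest_donor_distance"]
                        else float("inf")
                    ),
                    nuclei_in_radius=int(row["nuclei_in_radius"]),
                    field_extent=0.0,
                )
            )
    return out
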