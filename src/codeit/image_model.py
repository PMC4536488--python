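"""Core image data types, stack I/O and intensity-scale handling.

The quantification method operates on multi-channel 3D confocal stacks with
channels for the nuclear stain (Hoechst), the membrane stain (WGA-AF), the
transfer marker (DiD) and an optional protein marker (EGFP). All physical
filters downstream (donor minimum volume, acceptor minimum volume, isolation
distances) are expressed in micrometres, so every stack carries its voxel
size explicitly. Intensity thresholds are defined on the 8-bit scale
(values "of 256"); stacks acquired at higher bit depth must be rescaled with
:func:`normalize_to_8bit` before quantification.

Axis order is fixed as ``(z, y, x)`` with 0-based indices throughout the
package; micron positions are ``index * voxel_size`` from the stack origin.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import tifffile
import yaml

from .errors import (
    ImageIOError,
    MissingChannelError,
    MissingVoxelSizeError,
    UnsupportedBitDepthError,
)

#: Channel roles required for every quantification stack.
REQUIRED_ROLES = ("nuclei", "membrane", "did")
#: All recognised channel roles; ``egfp`` is optional.
ALL_ROLES = REQUIRED_ROLES + ("egfp",)

_SUPPORTED_SCALE_MAX = (255, 4095, 65535)


@dataclass(frozen=True)
class VoxelStack:
    """One channel of a 3D acquisition.

    Parameters
    ----------
    intensities
        Non-negative integer voxel values, shape ``(nz, ny, nx)``.
    voxel_size
        ``(dz, dy, dx)`` in micrometres, all strictly positive.
    scale_max
        Maximum representable intensity (255 for 8-bit data).
    """

    intensities: np.ndarray
    voxel_size: tuple[float, float, float]
    scale_max: int = 255

    def __post_init__(self) -> None:
        arr = np.asarray(self.intensities)
        if arr.ndim != 3:
            raise ValueError(f"expected a 3D (z, y, x) array, got ndim={arr.ndim}")
        if arr.size and (arr.min() < 0 or arr.max() > self.scale_max):
            raise ValueError(
                f"intensities outside [0, {self.scale_max}]: "
                f"range [{arr.min()}, {arr.max()}]"
            )
        if len(self.voxel_size) != 3 or any(d <= 0 for d in self.voxel_size):
            raise ValueError(f"voxel_size must be 3 positive floats, got {self.voxel_size}")
        object.__setattr__(self, "intensities", arr)
        object.__setattr__(self, "voxel_size", tuple(float(d) for d in self.voxel_size))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.intensities.shape

    def center_um(self) -> np.ndarray:
        """Geometric centre of the stack in micrometres, (z, y, x)."""
        return (np.asarray(self.shape) - 1) / 2.0 * np.asarray(self.voxel_size)


def voxel_volume(stack: VoxelStack) -> float:
    """Volume of one voxel in cubic micrometres (dz * dy * dx)."""
    dz, dy, dx = stack.voxel_size
    return dz * dy * dx


def normalize_to_8bit(stack: VoxelStack) -> VoxelStack:
    """Rescale a stack linearly to the 8-bit range used by all thresholds.

    Supported input scales are 8-, 12- and 16-bit. Values are mapped by
    ``round_half_up(v * 255 / scale_max)``; 8-bit input is returned unchanged.
    """
    if stack.scale_max == 255:
        return stack
    if stack.scale_max not in _SUPPORTED_SCALE_MAX:
        raise UnsupportedBitDepthError(
            f"unsupported intensity scale scale_max={stack.scale_max}; "
            f"expected one of {_SUPPORTED_SCALE_MAX}"
        )
    scaled = np.floor(
        stack.intensities.astype(np.float64) * (255.0 / stack.scale_max) + 0.5
    ).astype(np.uint8)
    return VoxelStack(scaled, stack.voxel_size, scale_max=255)


@dataclass(frozen=True)
class ChannelSet:
    """The channels of one acquisition, keyed by role.

    ``nuclei``, ``membrane`` and ``did`` are mandatory for quantification
    stacks; ``egfp`` is present only when a protein marker was acquired.
    All member stacks share shape and voxel size.
    """

    channels: Mapping[str, VoxelStack]

    def __post_init__(self) -> None:
        chans = dict(self.channels)
        for role in chans:
            if role not in ALL_ROLES:
                raise ValueError(f"unknown channel role {role!r}")
        for role in REQUIRED_ROLES:
            if role not in chans:
                raise MissingChannelError(f"required channel {role!r} missing")
        ref = chans["membrane"]
        for role, st in chans.items():
            if st.shape != ref.shape or st.voxel_size != ref.voxel_size:
                raise ValueError(
                    f"channel {role!r} shape/voxel_size differs from membrane channel"
                )
        object.__setattr__(self, "channels", chans)

    def __getitem__(self, role: str) -> VoxelStack:
        return self.channels[role]

    def __contains__(self, role: str) -> bool:
        return role in self.channels

    def get(self, role: str) -> VoxelStack | None:
        return self.channels.get(role)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.channels["membrane"].shape

    @property
    def voxel_size(self) -> tuple[float, float, float]:
        return self.channels["membrane"].voxel_size

    def normalized(self) -> "ChannelSet":
        """All channels rescaled to 8-bit."""
        return ChannelSet({r: normalize_to_8bit(s) for r, s in self.channels.items()})


@dataclass(frozen=True)
class QuantConfig:
    """Tunable parameters of the quantification and acquisition method.

    Grayscale values are on the 8-bit scale. Defaults are the published
    operating point of the method: transfer thresholds 100/256 for DiD and
    100 (alternatively 160) for EGFP, a 1,000 um^3 minimum donor volume,
    a 100 um^3 minimum acceptor-cell volume, one-voxel donor dilation,
    200 um donor-isolation and nucleus-count radii, at least 15 nuclei per
    field and up to 15 control positions per well.
    """

    did_threshold: int = 100
    egfp_threshold: int = 100
    donor_min_volume: float = 1000.0
    cell_min_volume: float = 100.0
    closing_radius: int = 2
    dilation_radius: int = 1
    exclusion_distance: float = 200.0
    nuclei_radius: float = 200.0
    min_nuclei: int = 15
    max_controls: int = 15
    # Donor-detection intensity level. Not a published number: donors are
    # acquired with ~half their volume at detector saturation, so
    # near-saturation is the intended signature.
    donor_intensity_threshold: int = 250
    # Closing applied per z-slice by default; True switches to a 3D ball.
    closing_3d: bool = False
    # ROI-selection knobs (low-resolution well scan).
    field_extent: float = 228.0
    donor_min_area: float = 50.0
    nucleus_detect_threshold: int = 80
    nucleus_min_separation: float = 10.0

    def __post_init__(self) -> None:
        positive = {
            "did_threshold": self.did_threshold,
            "egfp_threshold": self.egfp_threshold,
            "donor_min_volume": self.donor_min_volume,
            "cell_min_volume": self.cell_min_volume,
            "closing_radius": self.closing_radius,
            "dilation_radius": self.dilation_radius,
            "exclusion_distance": self.exclusion_distance,
            "nuclei_radius": self.nuclei_radius,
            "min_nuclei": self.min_nuclei,
            "max_controls": self.max_controls,
            "donor_intensity_threshold": self.donor_intensity_threshold,
            "field_extent": self.field_extent,
            "donor_min_area": self.donor_min_area,
        }
        for name, value in positive.items():
            if value <= 0:
                raise ValueError(f"{name} must be strictly positive, got {value}")
        for name in ("did_threshold", "egfp_threshold", "donor_intensity_threshold"):
            if getattr(self, name) > 255:
                raise ValueError(f"{name} exceeds the 8-bit scale maximum (255)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "QuantConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        data = {k: getattr(self, k) for k in self.__dataclass_fields__}
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)


def _read_voxel_size(tif: tifffile.TiffFile) -> tuple[float, float, float] | None:
    """Voxel size (dz, dy, dx) in um from OME or ImageJ metadata, if present."""
    try:
        if tif.ome_metadata:
            import xml.etree.ElementTree as ET

            root = ET.fromstring(tif.ome_metadata)
            ns = {"ome": root.tag.split("}")[0].strip("{")}
            px = root.find(".//ome:Pixels", ns)
            if px is not None:
                dz = px.get("PhysicalSizeZ")
                dy = px.get("PhysicalSizeY")
                dx = px.get("PhysicalSizeX")
                if dz and dy and dx:
                    return float(dz), float(dy), float(dx)
    except Exception:
        pass
    ij = tif.imagej_metadata
    if ij and "spacing" in ij:
        page = tif.pages[0]
        res = page.tags.get("YResolution"), page.tags.get("XResolution")
        if all(r is not None for r in res):
            dy = res[0].value[1] / res[0].value[0]
            dx = res[1].value[1] / res[1].value[0]
            return float(ij["spacing"]), float(dy), float(dx)
    return None


def read_channel_set(
    path: str | Path,
    channel_map: Mapping[str, int],
    voxel_size: tuple[float, float, float] | None = None,
) -> ChannelSet:
    """Read a multi-channel TIFF / OME-TIFF z-stack into a :class:`ChannelSet`.

    Parameters
    ----------
    path
        Multi-channel z-stack with axes (C, Z, Y, X) or (Z, C, Y, X).
    channel_map
        Mapping from role (``nuclei``/``membrane``/``did``/``egfp``) to
        channel index. Must cover the three required roles.
    voxel_size
        Explicit ``(dz, dy, dx)`` in um, overriding file metadata. If the
        file carries no voxel-size metadata and no override is given, a
        :class:`MissingVoxelSizeError` is raised — never a silent default.
    """
    path = Path(path)
    for role in REQUIRED_ROLES:
        if role not in channel_map:
            raise MissingChannelError(f"channel_map must map required role {role!r}")
    try:
        with tifffile.TiffFile(path) as tif:
            series = tif.series[0]
            data = series.asarray()
            axes = series.axes
            meta_vs = _read_voxel_size(tif)
    except (FileNotFoundError, tifffile.TiffFileError, IndexError) as exc:
        raise ImageIOError(f"cannot read stack {path}: {exc}") from exc

    vs = voxel_size if voxel_size is not None else meta_vs
    if vs is None:
        raise MissingVoxelSizeError(
            f"{path} carries no voxel-size metadata; pass voxel_size explicitly"
        )

    # Normalise axis order to (C, Z, Y, X).
    if data.ndim != 4:
        raise ImageIOError(f"{path}: expected a 4D multi-channel z-stack, got axes {axes!r}")
    if axes in ("CZYX", "QZYX"):
        pass
    elif axes in ("ZCYX", "ZQYX"):
        data = np.moveaxis(data, 1, 0)
    else:
        # Fall back on the shorter of the first two axes being channels.
        if data.shape[0] > data.shape[1]:
            data = np.moveaxis(data, 1, 0)
    n_channels = data.shape[0]
    scale_max = 65535 if data.dtype.itemsize == 2 else 255

    channels: dict[str, VoxelStack] = {}
    for role, idx in channel_map.items():
        if not 0 <= idx < n_channels:
            raise ImageIOError(
                f"{path}: channel index {idx} for role {role!r} out of range "
                f"(file has {n_channels} channels)"
            )
        channels[role] = VoxelStack(data[idx], vs, scale_max=scale_max)
    return ChannelSet(channels)


def write_channel_set(
    channels: ChannelSet, path: str | Path, order: tuple[str, ...] | None = None
) -> None:
    """Write a :class:`ChannelSet` as an OME-TIFF with voxel-size metadata.

    Channel order defaults to (nuclei, membrane, did[, egfp]); the same
    ``channel_map`` indices then round-trip through :func:`read_channel_set`.
    """
    if order is None:
        order = tuple(r for r in ALL_ROLES if r in channels)
    stacks = [channels[r] for r in order]
    data = np.stack([s.intensities for s in stacks]).astype(
        np.uint16 if stacks[0].scale_max > 255 else np.uint8
    )
    dz, dy, dx = channels.voxel_size
    tifffile.imwrite(
        path,
        data,
        ome=True,
        metadata={
            "axes": "CZYX",
            "PhysicalSizeZ": dz,
            "PhysicalSizeY": dy,
            "PhysicalSizeX": dx,
            "PhysicalSizeZUnit": "µm",
            "PhysicalSizeYUnit": "µm",
            "PhysicalSizeXUnit": "µm",
        },
    )


def default_channel_map(has_egfp: bool = False) -> dict[str, int]:
    """Channel indices matching :func:`write_channel_set`'s default order."""
    cmap = {"nuclei": 0, "membrane": 1, "did": 2}
    if has_egfp:
        cmap["egfp"] = 3
    return cmap
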