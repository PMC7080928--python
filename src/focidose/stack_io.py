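"""Multi-channel confocal z-stack containers and TIFF I/O.

A stack is a set of named 3D intensity volumes (axis order ``(z, y, x)``,
0-based indices) sharing one voxel geometry.  The default geometry matches
a typical high-NA confocal acquisition: 1024 x 1024 frames with 140 nm
lateral pixels and 581 nm optical sections, 10 sections per stack.

Stacks are stored as plain multi-page TIFF, either channel-interleaved
(page order z0c0, z0c1, z1c0, ...) or channel-blocked (all pages of
channel 0, then channel 1, ...).  Voxel size is carried in the TIFF
resolution tags and the ImageJ-style metadata block; string metadata
round-trips through the ImageDescription JSON.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace

import numpy as np
import tifffile

logger = logging.getLogger(__name__)

#: default lateral pixel width (nm)
DEFAULT_DX_NM = 140.0
#: default axial step (nm)
DEFAULT_DZ_NM = 581.0
#: default frame size (pixels) and number of optical sections
DEFAULT_NX = DEFAULT_NY = 1024
DEFAULT_NZ = 10


@dataclass(frozen=True)
class VoxelGeometry:
    """Voxel dimensions and grid size of a z-stack."""

    dx_nm: float = DEFAULT_DX_NM
    dy_nm: float = DEFAULT_DX_NM
    dz_nm: float = DEFAULT_DZ_NM
    nx: int = DEFAULT_NX
    ny: int = DEFAULT_NY
    nz: int = DEFAULT_NZ

    def __post_init__(self) -> None:
        for name in ("dx_nm", "dy_nm", "dz_nm", "nx", "ny", "nz"):
            if getattr(self, name) <= 0:
                raise ValueError(f"VoxelGeometry.{name} must be strictly positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        """Volume shape in ``(z, y, x)`` order."""
        return (self.nz, self.ny, self.nx)

    @property
    def z_aspect(self) -> float:
        """Axial step expressed in units of the lateral pixel width."""
        return self.dz_nm / self.dx_nm

    def with_shape(self, nz: int, ny: int, nx: int) -> "VoxelGeometry":
        return replace(self, nz=nz, ny=ny, nx=nx)


@dataclass
class ChannelStack:
    """Named 3D intensity volumes sharing one voxel geometry.

    Volumes are non-negative integer arrays of shape ``geometry.shape``.
    ``metadata`` carries free-form provenance (animal id, group, tissue...).
    """

    channels: dict[str, np.ndarray]
    geometry: VoxelGeometry
    metadata: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.channels) == 0:
            raise ValueError("ChannelStack needs at least one channel")
        for name, vol in self.channels.items():
            vol = np.asarray(vol)
            if vol.shape != self.geometry.shape:
                raise ValueError(
                    f"channel {name!r} has shape {vol.shape}, geometry says "
                    f"{self.geometry.shape}"
                )
            if not np.issubdtype(vol.dtype, np.integer):
                raise ValueError(f"channel {name!r} must be an integer dtype")
            if vol.min() < 0:
                raise ValueError(f"channel {name!r} contains negative intensities")
            self.channels[name] = vol

    @property
    def channel_names(self) -> list[str]:
        return list(self.channels)

    def channel(self, name: str) -> np.ndarray:
        try:
            return self.channels[name]
        except KeyError:
            raise KeyError(
                f"unknown channel {name!r}; stack has {self.channel_names}"
            ) from None


@dataclass
class Image2D:
    """A single 2D non-negative intensity image with pixel geometry."""

    pixels: np.ndarray
    dx_nm: float = DEFAULT_DX_NM
    dy_nm: float = DEFAULT_DX_NM

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ValueError("Image2D.pixels must be 2D")
        if self.pixels.min() < 0:
            raise ValueError("Image2D intensities must be non-negative")


def max_intensity_projection(stack: ChannelStack, channel: str) -> Image2D:
    """Project a channel along z by per-pixel maximum.

    This is the projection the liver protocol applies to the nuclear-stain
    channel before building the 2D nucleus mask.
    """
    vol = stack.channel(channel)
    return Image2D(
        pixels=vol.max(axis=0),
        dx_nm=stack.geometry.dx_nm,
        dy_nm=stack.geometry.dy_nm,
    )


def _pages_to_volumes(
    pages: np.ndarray, n_channels: int, layout: str
) -> list[np.ndarray]:
    n_pages = pages.shape[0]
    nz = n_pages // n_channels
    if layout == "interleaved":
        return [pages[c::n_channels] for c in range(n_channels)]
    if layout == "blocked":
        return [pages[c * nz : (c + 1) * nz] for c in range(n_channels)]
    raise ValueError(f"unknown layout {layout!r}; use 'interleaved' or 'blocked'")


def read_stack(
    path,
    channel_names: list[str],
    geometry_override: VoxelGeometry | None = None,
    layout: str = "interleaved",
) -> ChannelStack:
    """Read a multi-page TIFF into a :class:`ChannelStack`.

    The page count must be ``nz * len(channel_names)``; pages are split per
    the declared ``layout``.  Voxel geometry comes from the embedded
    resolution tags and ImageJ ``spacing`` when present, else from
    ``geometry_override``, else from the documented defaults (with a logged
    warning).
    """
    if not channel_names:
        raise ValueError("channel_names must be non-empty")
    try:
        with tifffile.TiffFile(path) as tif:
            pages = tif.asarray()
            meta: dict[str, str] = {}
            dx = dy = dz = None
            page0 = tif.pages[0]
            res_unit = page0.tags.get("ResolutionUnit")
            xres = page0.tags.get("XResolution")
            yres = page0.tags.get("YResolution")
            if xres is not None and yres is not None and res_unit is not None:
                unit_nm = {2: 2.54e7, 3: 1e7}.get(int(res_unit.value))
                if unit_nm:
                    xr = xres.value[0] / xres.value[1]
                    yr = yres.value[0] / yres.value[1]
                    if xr > 0 and yr > 0:
                        dx = unit_nm / xr
                        dy = unit_nm / yr
            desc = page0.tags.get("ImageDescription")
            if desc is not None:
                try:
                    parsed = json.loads(desc.value)
                except (json.JSONDecodeError, TypeError):
                    parsed = None
                if isinstance(parsed, dict):
                    meta = {str(k): str(v) for k, v in parsed.get(
                        "focidose_metadata", {}).items()}
                    if "dz_nm" in parsed:
                        dz = float(parsed["dz_nm"])
    except (OSError, tifffile.TiffFileError) as exc:
        raise OSError(f"cannot read TIFF stack {path}: {exc}") from exc

    if pages.ndim == 2:
        pages = pages[None]
    n_channels = len(channel_names)
    if pages.shape[0] % n_channels:
        raise ValueError(
            f"page count {pages.shape[0]} is not divisible by "
            f"{n_channels} channels"
        )
    nz = pages.shape[0] // n_channels
    ny, nx = pages.shape[1:]

    if dx is None or dz is None:
        if geometry_override is not None:
            geo = geometry_override.with_shape(nz, ny, nx)
        else:
            logger.warning(
                "no voxel geometry in %s and no override given; assuming "
                "defaults (%.0f nm x/y, %.0f nm z)", path, DEFAULT_DX_NM,
                DEFAULT_DZ_NM,
            )
            geo = VoxelGeometry(nz=nz, ny=ny, nx=nx)
    else:
        geo = VoxelGeometry(dx_nm=dx, dy_nm=dy or dx, dz_nm=dz, nz=nz, ny=ny, nx=nx)

    volumes = _pages_to_volumes(pages, n_channels, layout)
    return ChannelStack(
        channels=dict(zip(channel_names, volumes)), geometry=geo, metadata=meta
    )


def write_stack(stack: ChannelStack, path, layout: str = "interleaved") -> None:
    """Write a stack as a multi-page TIFF that :func:`read_stack` inverts
    bit-exactly (same layout and channel order required)."""
    geo = stack.geometry
    vols = [stack.channels[name] for name in stack.channel_names]
    if layout == "interleaved":
        pages = np.stack(vols, axis=1).reshape((-1,) + geo.shape[1:])
    elif layout == "blocked":
        pages = np.concatenate(vols, axis=0)
    else:
        raise ValueError(f"unknown layout {layout!r}")

    desc = json.dumps({"focidose_metadata": stack.metadata,
                       "channels": stack.channel_names, "layout": layout,
                       "dz_nm": geo.dz_nm})
    try:
        tifffile.imwrite(
            path,
            pages,
            photometric="minisblack",
            resolution=(1e7 / geo.dx_nm, 1e7 / geo.dy_nm),
            resolutionunit="CENTIMETER",
            description=desc,
        )
    except OSError as exc:
        raise OSError(f"cannot write TIFF stack {path}: {exc}") from exc
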