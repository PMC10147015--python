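"""Multichannel anisotropic z-stack container and channel arithmetic.

Conventions used throughout the package (stated here once):

* arrays are indexed ``(z, y, x)``, 0-based;
* the physical coordinate of voxel ``(k, j, i)`` is its *center*,
  ``((k + 0.5) * vz, (j + 0.5) * vy, (i + 0.5) * vx)`` in micrometres;
* all geometry downstream works in physical µm — nothing assumes
  isotropic voxels.
"""

from __future__ import annotations

import xml.etree.ElementTree as ET
from dataclasses import dataclass, field

import numpy as np
import tifffile
from scipy import ndimage


class ChannelMismatchError(ValueError):
    """The file does not contain the requested channels."""


class MissingVoxelSizeError(ValueError):
    """No physical voxel size in the file metadata and no override given."""


@dataclass
class ImageStack:
    """A named multichannel 3D intensity field with physical voxel sizes.

    Parameters
    ----------
    channels
        Mapping channel name -> ``(z, y, x)`` array.  All channels must
        share one shape.
    voxel_size_um
        ``(vz, vy, vx)`` voxel pitch in µm, all positive.
    bit_depth
        Integer bit depth of the source data (16 for the acquisition
        geometry this package emulates).
    provenance
        Free-text note on where the stack came from.
    """

    channels: dict[str, np.ndarray]
    voxel_size_um: tuple[float, float, float]
    bit_depth: int = 16
    provenance: str = ""

    def __post_init__(self) -> None:
        shapes = {ch.shape for ch in self.channels.values()}
        if len(shapes) > 1:
            raise ValueError(f"channels differ in shape: {shapes}")
        vz, vy, vx = self.voxel_size_um
        if not (vz > 0 and vy > 0 and vx > 0):
            raise ValueError(f"voxel sizes must be positive, got {self.voxel_size_um}")
        self.voxel_size_um = (float(vz), float(vy), float(vx))

    @property
    def shape(self) -> tuple[int, int, int]:
        return next(iter(self.channels.values())).shape

    @property
    def channel_names(self) -> list[str]:
        return list(self.channels)

    def voxel_volume_um3(self) -> float:
        vz, vy, vx = self.voxel_size_um
        return vz * vy * vx

    def to_float(self) -> "ImageStack":
        """Return a copy with channels scaled to [0, 1] by full bit range."""
        scale = float(2**self.bit_depth - 1)
        return ImageStack(
            channels={k: v.astype(np.float64) / scale for k, v in self.channels.items()},
            voxel_size_um=self.voxel_size_um,
            bit_depth=self.bit_depth,
            provenance=self.provenance,
        )


def write_stack(stack: ImageStack, path) -> None:
    """Write an :class:`ImageStack` as OME-TIFF (axes CZYX, sizes in µm)."""
    names = stack.channel_names
    data = np.stack([stack.channels[n] for n in names], axis=0)
    vz, vy, vx = stack.voxel_size_um
    tifffile.imwrite(
        path,
        data,
        ome=True,
        metadata={
            "axes": "CZYX",
            "Channel": {"Name": names},
            "PhysicalSizeX": vx,
            "PhysicalSizeXUnit": "µm",
            "PhysicalSizeY": vy,
            "PhysicalSizeYUnit": "µm",
            "PhysicalSizeZ": vz,
            "PhysicalSizeZUnit": "µm",
        },
    )


def _ome_voxel_size(ome_xml: str):
    root = ET.fromstring(ome_xml)
    ns = root.tag.split("}")[0] + "}" if root.tag.startswith("{") else ""
    px = root.find(f".//{ns}Pixels")
    if px is None:
        return None, None
    sx, sy, sz = (px.get(k) for k in ("PhysicalSizeX", "PhysicalSizeY", "PhysicalSizeZ"))
    names = [c.get("Name") or "" for c in px.findall(f"{ns}Channel")]
    if sx is None or sy is None or sz is None:
        return None, names
    return (float(sz), float(sy), float(sx)), names


def read_stack(path, channel_names=None, voxel_size_um=None) -> ImageStack:
    """Read a TIFF / OME-TIFF z-stack.

    Parameters
    ----------
    path
        TIFF or OME-TIFF file with axes resolving to (C)ZYX.
    channel_names
        Names to assign to the channels, in order.  Required for plain
        TIFFs; for OME-TIFFs defaults to the names in the metadata.
    voxel_size_um
        ``(vz, vy, vx)`` override.  Mandatory when the file metadata
        carries no physical voxel size — never silently defaulted.
    """
    with tifffile.TiffFile(path) as tf:
        series = tf.series[0]
        data = series.asarray()
        axes = series.axes
        meta_size, meta_names = (None, None)
        if tf.ome_metadata:
            meta_size, meta_names = _ome_voxel_size(tf.ome_metadata)
        bits = int(data.dtype.itemsize * 8) if data.dtype.kind in "ui" else 16

    if data.ndim == 3:
        if "C" in axes and "Z" not in axes:  # CYX single-slice
            data = data[:, None, :, :]
        else:
            data = data[None, ...]  # single channel ZYX
    elif data.ndim == 4:
        if axes.startswith("Z"):  # ZCYX -> CZYX
            data = np.swapaxes(data, 0, 1)
    else:
        raise ValueError(f"cannot interpret TIFF with axes {axes!r}")

    n_chan = data.shape[0]
    if channel_names is None:
        channel_names = meta_names if meta_names else [f"ch{i}" for i in range(n_chan)]
    if len(channel_names) > n_chan:
        raise ChannelMismatchError(
            f"requested {len(channel_names)} channels but file has {n_chan}"
        )
    if voxel_size_um is None:
        if meta_size is None:
            raise MissingVoxelSizeError(
                f"{path}: no physical voxel size in metadata; pass voxel_size_um"
            )
        voxel_size_um = meta_size

    channels = {name: data[i] for i, name in enumerate(channel_names)}
    return ImageStack(
        channels=channels,
        voxel_size_um=tuple(float(v) for v in voxel_size_um),
        bit_depth=bits,
        provenance=f"read from {path}",
    )


def _minmax(a: np.ndarray) -> np.ndarray:
    a = a.astype(np.float64)
    lo, hi = a.min(), a.max()
    if hi == lo:
        return np.zeros_like(a)
    return (a - lo) / (hi - lo)


def colocalization_channel(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Voxelwise geometric mean of min-max-normalized channels.

    High only where *both* inputs are high, which is what makes it usable
    for rendering soma bodies with confluent intensity from the nuclear
    (DAPI) and membrane (Iba1) channels.  Result lies in [0, 1]; a voxel
    where either input is at its minimum maps to 0, a voxel where both
    are at their maxima maps to 1.
    """
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    return np.sqrt(_minmax(a) * _minmax(b))


def subtract_background(
    ch: np.ndarray, radius_um: float, voxel_size_um: tuple[float, float, float]
) -> np.ndarray:
    """Rolling-ball-equivalent background subtraction, per slice.

    A greyscale morphological opening with an elliptical disk of the given
    physical radius is removed from each z-slice; the axial direction is
    left untouched because at 0.8 µm slicing a 3D structuring element of
    sensible lateral radius would span very few slices.  Output is clipped
    at zero; a flat background maps to ~0.
    """
    if radius_um <= 0:
        raise ValueError("radius_um must be positive")
    _, vy, vx = voxel_size_um
    ry = max(1, int(round(radius_um / vy)))
    rx = max(1, int(round(radius_um / vx)))
    yy, xx = np.mgrid[-ry : ry + 1, -rx : rx + 1]
    disk = (yy / ry) ** 2 + (xx / rx) ** 2 <= 1.0
    footprint = disk[None, :, :]  # depth-1: per-slice opening in one call
    opened = ndimage.grey_opening(ch.astype(np.float64), footprint=footprint)
    return np.clip(ch.astype(np.float64) - opened, 0.0, None)


def mask_voxels(ch: np.ndarray, mask: np.ndarray, value: float = 0) -> np.ndarray:
    """Return a copy of *ch* with voxels under any nonzero label set to *value*."""
    if ch.shape != mask.shape:
        raise ValueError(f"shape mismatch: {ch.shape} vs {mask.shape}")
    out = ch.copy()
    out[mask != 0] = value
    return out
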