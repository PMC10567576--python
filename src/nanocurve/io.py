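"""OME-TIFF input/output with channel-role metadata and ground-truth sidecars."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import tifffile

from .errors import ConfigError
from .synth.specs import GroundTruth

__all__ = ["ImageData", "read_image", "write_ome_tiff", "read_ground_truth", "write_ground_truth"]

#: canonical axis order; a file's axes are permuted into this order
CANONICAL = "TZCYX"


@dataclass
class ImageData:
    """A multichannel image/stack with normalised axes and role tags."""

    data: np.ndarray
    axes: str  # subset of "TZCYX", in canonical order
    roles: tuple[str, ...] | None = None
    pixel_size_um: float | None = None
    voxel_size_um: tuple[float, float, float] | None = None  # (dz, dy, dx)
    frame_interval_s: float | None = None

    @property
    def n_channels(self) -> int:
        return self.data.shape[self.axes.index("C")] if "C" in self.axes else 1

    def channel(self, role: str) -> np.ndarray:
        """The (y, x) / (z, y, x) / (t, y, x) array for a channel role."""
        if self.roles is None:
            raise ConfigError("no channel roles recorded for this image")
        if role not in self.roles:
            raise ConfigError(f"channel role {role!r} missing (have {self.roles})")
        if "C" not in self.axes:
            return self.data
        return np.take(self.data, self.roles.index(role), axis=self.axes.index("C"))

    def require_pixel_size(self) -> float:
        if self.pixel_size_um is None:
            raise ConfigError(
                "pixel size requested but missing: provide PhysicalSizeX metadata "
                "or a pixel_size_um config entry"
            )
        return self.pixel_size_um


def write_ome_tiff(
    path: str | Path,
    data: np.ndarray,
    axes: str,
    roles: tuple[str, ...] | None = None,
    pixel_size_um: float | None = None,
    voxel_size_um: tuple[float, float, float] | None = None,
) -> None:
    """Write an OME-TIFF tagging each channel with its role name."""
    meta: dict = {"axes": axes}
    if roles is not None:
        meta["Channel"] = {"Name": list(roles)}
    if pixel_size_um is not None:
        meta["PhysicalSizeX"] = pixel_size_um
        meta["PhysicalSizeY"] = pixel_size_um
    if voxel_size_um is not None:
        dz, dy, dx = voxel_size_um
        meta["PhysicalSizeZ"] = dz
        meta["PhysicalSizeY"] = dy
        meta["PhysicalSizeX"] = dx
    tifffile.imwrite(str(path), np.asarray(data, dtype=np.float32), ome=True, metadata=meta)


def read_image(
    path: str | Path,
    roles: tuple[str, ...] | None = None,
    pixel_size_um: float | None = None,
) -> ImageData:
    """Read a TIFF/OME-TIFF and normalise its axes to (T?, Z?, C?, Y, X).

    Channel roles come from OME channel names unless overridden; physical
    pixel sizes come from OME metadata unless overridden.
    """
    with tifffile.TiffFile(str(path)) as tf:
        series = tf.series[0]
        data = series.asarray()
        axes = series.axes.upper().replace("S", "C").replace("Q", "")
        ome = tf.ome_metadata

    # squeeze axes tifffile reports that we do not model
    keep = [i for i, a in enumerate(axes) if a in CANONICAL]
    if len(keep) != data.ndim:
        data = data.reshape([data.shape[i] for i in keep])
        axes = "".join(axes[i] for i in keep)
    order = [axes.index(a) for a in CANONICAL if a in axes]
    data = np.transpose(data, order)
    axes = "".join(a for a in CANONICAL if a in axes)

    file_roles = None
    px = pixel_size_um
    vz = None
    if ome:
        import xml.etree.ElementTree as ET

        root = ET.fromstring(ome)
        ns = {"ome": root.tag.split("}")[0].strip("{")}
        names = [c.get("Name") for c in root.iter(f"{{{ns['ome']}}}Channel")]
        if names and all(n is not None for n in names):
            file_roles = tuple(names)
        pix = root.find(f".//{{{ns['ome']}}}Pixels")
        if pix is not None:
            sx = pix.get("PhysicalSizeX")
            sz = pix.get("PhysicalSizeZ")
            sy = pix.get("PhysicalSizeY")
            if px is None and sx is not None:
                px = float(sx)
            if sz is not None and sy is not None and sx is not None:
                vz = (float(sz), float(sy), float(sx))
    return ImageData(
        data=data,
        axes=axes,
        roles=roles if roles is not None else file_roles,
        pixel_size_um=px,
        voxel_size_um=vz,
    )


def write_ground_truth(path: str | Path, gt: GroundTruth) -> None:
    Path(path).write_text(gt.to_json())


def read_ground_truth(path: str | Path) -> GroundTruth:
    return GroundTruth.from_json(Path(path).read_text())
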