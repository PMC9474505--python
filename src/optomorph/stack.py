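"""Core voxel containers and TIFF I/O.

Conventions used throughout the package:

* 3D arrays are indexed ``(z, y, x)``; the **apical** surface of a
  monolayer is at low ``z`` (slice 0) and ``z`` increases basally.
* Physical sizes are micrometres; ``voxel_size`` is ``(z, y, x)`` µm.
* Label images/volumes use ``0`` for background; cell labels are
  positive integers.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import tifffile


@dataclass
class ImageStack:
    """A 3D fluorescence stack with physical voxel sizes.

    Parameters
    ----------
    data:
        Voxel intensities, shape ``(z, y, x)``.
    voxel_size:
        Physical voxel edge lengths ``(z, y, x)`` in µm.
    channel:
        Optional channel name (e.g. ``"membrane"``).
    timepoint:
        Optional frame index within a timelapse.
    apical_axis_direction:
        ``"low-z"`` (default) records that slice 0 is the apical side.
    """

    data: np.ndarray
    voxel_size: tuple[float, float, float]
    channel: str | None = None
    timepoint: int | None = None
    apical_axis_direction: str = "low-z"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"ImageStack data must be 3D (z,y,x), got {self.data.ndim}D")
        vs = tuple(float(v) for v in self.voxel_size)
        if len(vs) != 3 or any(v <= 0 for v in vs):
            raise ValueError(f"voxel_size must be three positive lengths, got {self.voxel_size}")
        self.voxel_size = vs
        if not np.all(np.isfinite(self.data)):
            raise ValueError("ImageStack intensities must be finite")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def is_isotropic(self) -> bool:
        z, y, x = self.voxel_size
        return bool(np.isclose(z, y) and np.isclose(y, x))

    def with_data(self, data: np.ndarray, voxel_size=None) -> "ImageStack":
        return replace(self, data=data, voxel_size=voxel_size or self.voxel_size)


@dataclass
class LabelVolume:
    """Integer-labelled voxel volume (0 = background).

    ``voxel_size`` follows the same ``(z, y, x)`` µm convention as
    :class:`ImageStack`.  ``isotropic`` records whether the volume was
    produced on (or rescaled to) a 1:1:1 voxel grid.
    """

    labels: np.ndarray
    voxel_size: tuple[float, float, float]
    apical_axis_direction: str = "low-z"

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("LabelVolume must be 3D (z,y,x)")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("labels must be an integer array")
        self.voxel_size = tuple(float(v) for v in self.voxel_size)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.labels.shape

    @property
    def is_isotropic(self) -> bool:
        z, y, x = self.voxel_size
        return bool(np.isclose(z, y) and np.isclose(y, x))

    @property
    def voxel_volume(self) -> float:
        z, y, x = self.voxel_size
        return z * y * x

    def ids(self) -> np.ndarray:
        """Sorted nonzero label ids present in the volume."""
        u = np.unique(self.labels)
        return u[u > 0]


def write_stack(path, stack: ImageStack) -> None:
    """Write a stack as an ImageJ-style TIFF carrying voxel sizes.

    x/y resolution goes into the TIFF resolution tags, z spacing into the
    ImageJ metadata, so FIJI and :func:`read_stack` both recover it.
    """
    vz, vy, vx = stack.voxel_size
    data = stack.data
    if data.dtype == np.float64:
        data = data.astype(np.float32)
    tifffile.imwrite(
        str(path),
        data,
        imagej=True,
        resolution=(1.0 / vx, 1.0 / vy),
        metadata={"spacing": vz, "unit": "um", "axes": "ZYX"},
    )


def read_stack(path, channel: str | None = None) -> ImageStack:
    """Read a TIFF written by :func:`write_stack` (voxel sizes required).

    Raises
    ------
    ValueError
        If the file does not carry voxel-size metadata; the pixel size is
        never silently assumed.
    """
    with tifffile.TiffFile(str(path)) as tf:
        data = tf.asarray()
        try:
            ij = tf.imagej_metadata or {}
            vz = float(ij["spacing"])
            page = tf.pages[0]
            xr = page.tags["XResolution"].value
            yr = page.tags["YResolution"].value
            vx = xr[1] / xr[0]
            vy = yr[1] / yr[0]
        except (KeyError, TypeError) as exc:
            raise ValueError(
                f"{path}: missing voxel-size metadata; re-save with explicit "
                "x-y resolution and z spacing"
            ) from exc
    if data.ndim == 2:
        data = data[None]
    return ImageStack(data=data, voxel_size=(vz, vy, vx), channel=channel)


def write_labels(path, vol: LabelVolume) -> None:
    """Write a label volume as a 16-bit label TIFF with voxel metadata."""
    if vol.labels.max() >= 2**16:
        raise ValueError("more than 65535 labels; cannot write 16-bit label TIFF")
    vz, vy, vx = vol.voxel_size
    tifffile.imwrite(
        str(path),
        vol.labels.astype(np.uint16),
        imagej=True,
        resolution=(1.0 / vx, 1.0 / vy),
        metadata={"spacing": vz, "unit": "um", "axes": "ZYX"},
    )


def read_labels(path) -> LabelVolume:
    stack = read_stack(path)
    return LabelVolume(stack.data.astype(np.int32), stack.voxel_size)
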