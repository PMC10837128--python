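"""Core data model, TIFF I/O, configuration and light preprocessing.

The whole pipeline works on isotropic 3D voxel lattices in ``(z, y, x)``
order.  Physical coordinates in micrometres are always
``index * voxel_size_um``.  Anisotropic data is rejected rather than
silently resampled.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping

import numpy as np
import tifffile
import yaml

logger = logging.getLogger("lobule3d")

#: Channel names understood by the pipeline.  ``v_*`` are virtual channels
#: predicted from phalloidin; ``cv_mask``/``pv_mask`` are the large-vein masks.
KNOWN_CHANNELS = (
    "dapi",
    "phalloidin",
    "cd13",
    "flk1",
    "desmin",
    "f480",
    "v_cd13",
    "v_flk1",
    "cv_mask",
    "pv_mask",
)

CONFIG_VERSION = 1


def configure_logging(level: int = logging.INFO) -> None:
    """Send structured pipeline logs to stderr (idempotent)."""
    root = logging.getLogger("lobule3d")
    if not root.handlers:
        handler = logging.StreamHandler(sys.stderr)
        handler.setFormatter(
            logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s")
        )
        root.addHandler(handler)
    root.setLevel(level)


class StageTimer:
    """Context manager logging wall-clock duration of a pipeline stage."""

    def __init__(self, stage: str) -> None:
        self.stage = stage
        self.elapsed_s: float | None = None

    def __enter__(self) -> "StageTimer":
        self._t0 = time.perf_counter()
        logger.info("stage %s: start", self.stage)
        return self

    def __exit__(self, *exc) -> None:
        self.elapsed_s = time.perf_counter() - self._t0
        logger.info("stage %s: done in %.2f s", self.stage, self.elapsed_s)


# ---------------------------------------------------------------------------
# Errors
# ---------------------------------------------------------------------------


class Lobule3DError(Exception):
    """Base class for all package errors."""


class ChannelCountMismatchError(Lobule3DError):
    """Number of pages/channels in the file disagrees with the names given."""


class NonVolumetricDataError(Lobule3DError):
    """Input data is not a 3D (or channels x 3D) lattice."""


class AnisotropicVoxelError(Lobule3DError):
    """Voxel size metadata is anisotropic; the pipeline requires isotropy."""


class EmptyImageError(Lobule3DError):
    """Operation received an image with no channels/voxels."""


class ConstantImageError(Lobule3DError):
    """Degenerate constant image where a spread-based operation is undefined."""


class ConfigError(Lobule3DError):
    """Invalid or unserializable pipeline configuration."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class VoxelGrid:
    """A scalar 3D intensity lattice with isotropic physical voxel size.

    Parameters
    ----------
    data:
        3D array in ``(z, y, x)`` order.
    voxel_size_um:
        Isotropic voxel edge length in micrometres (> 0).
    origin_um:
        Physical position of voxel ``(0, 0, 0)``, ``(z, y, x)`` in um.
    """

    data: np.ndarray
    voxel_size_um: float
    origin_um: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3 or min(self.data.shape) < 1:
            raise NonVolumetricDataError(
                f"expected a 3D lattice, got shape {self.data.shape}"
            )
        if not self.voxel_size_um > 0:
            raise ValueError("voxel_size_um must be positive")
        self.origin_um = np.asarray(self.origin_um, dtype=float)
        if np.issubdtype(self.data.dtype, np.floating) and not np.all(
            np.isfinite(self.data)
        ):
            raise ValueError("intensity values must be finite")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume_um3(self) -> float:
        return float(self.voxel_size_um) ** 3

    def astype(self, dtype) -> "VoxelGrid":
        return VoxelGrid(self.data.astype(dtype), self.voxel_size_um, self.origin_um)


@dataclass
class MultiChannelImage:
    """A set of co-registered :class:`VoxelGrid` channels keyed by name."""

    channels: dict[str, VoxelGrid]

    def __post_init__(self) -> None:
        if not self.channels:
            raise EmptyImageError("image must contain at least one channel")
        shapes = {g.shape for g in self.channels.values()}
        sizes = {round(g.voxel_size_um, 9) for g in self.channels.values()}
        if len(shapes) != 1 or len(sizes) != 1:
            raise ValueError("all channels must share shape and voxel size")

    def __getitem__(self, name: str) -> VoxelGrid:
        return self.channels[name]

    def __contains__(self, name: str) -> bool:
        return name in self.channels

    def __iter__(self) -> Iterator[str]:
        return iter(self.channels)

    @property
    def shape(self) -> tuple[int, int, int]:
        return next(iter(self.channels.values())).shape

    @property
    def voxel_size_um(self) -> float:
        return next(iter(self.channels.values())).voxel_size_um

    @property
    def names(self) -> list[str]:
        return list(self.channels)


@dataclass
class LabelMap:
    """Integer 3D label lattice: a binary mask or an instance segmentation."""

    labels: np.ndarray
    voxel_size_um: float
    kind: str = "instance"  # "binary_mask" | "instance"

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise NonVolumetricDataError("labels must be a 3D lattice")
        if not np.issubdtype(self.labels.dtype, np.integer):
            if np.issubdtype(self.labels.dtype, np.bool_):
                self.labels = self.labels.astype(np.uint8)
            else:
                raise ValueError("labels must be integer-valued")
        if self.kind not in ("binary_mask", "instance"):
            raise ValueError(f"unknown label-map kind {self.kind!r}")
        if self.labels.size and self.labels.min() < 0:
            raise ValueError("labels must be non-negative (0 = background)")
        if self.kind == "binary_mask" and self.labels.size and self.labels.max() > 1:
            raise ValueError("binary_mask may only contain {0, 1}")
        if not self.voxel_size_um > 0:
            raise ValueError("voxel_size_um must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    @property
    def mask(self) -> np.ndarray:
        """Boolean foreground view."""
        return self.labels > 0

    @property
    def n_labels(self) -> int:
        return int(len(np.unique(self.labels[self.labels > 0])))

    def as_grid(self) -> VoxelGrid:
        return VoxelGrid(self.labels, self.voxel_size_um)


def binary_map(mask: np.ndarray, voxel_size_um: float) -> LabelMap:
    """Wrap a boolean array as a binary-mask :class:`LabelMap`."""
    return LabelMap(np.asarray(mask, bool).astype(np.uint8), voxel_size_um, "binary_mask")


@dataclass
class PipelineConfig:
    """All tunables of the reconstruction pipeline (YAML round-trippable)."""

    version: int = CONFIG_VERSION
    voxel_size_um: float = 0.3
    n_zones: int = 10
    proximity_threshold_um: float = 2.0
    contact_radius_um: float = 0.3
    random_seed: int = 0
    # segmentation
    block_size_voxels: int = 64
    opening_radius: int = 0
    closing_radius: int = 1
    min_object_volume_um3: float = 0.5
    watershed_h_um: float = 0.3
    mesh_smoothing_iterations: int = 10
    mesh_relaxation: float = 0.1
    # preprocessing
    normalize_percentiles: tuple[float, float] = (1.0, 99.0)
    gaussian_sigma_um: float = 0.0  # optional denoise hook, off by default
    # morphometry
    elongation_formula: str = "one_minus_min_over_max"  # or "as_printed"
    hsc_kc_nucleus_overlap: float = 0.5
    # zonation
    zonation_mode: str = "distance_transform"  # or "straight_axis"
    # channel routing: use virtual channels for segmentation when True
    use_virtual_channels: bool = False
    channel_map: dict = field(
        default_factory=lambda: {"bc": "cd13", "sinusoids": "flk1"}
    )

    def __post_init__(self) -> None:
        if self.n_zones < 2:
            raise ConfigError("n_zones must be >= 2")
        if not self.proximity_threshold_um > 0:
            raise ConfigError("proximity_threshold_um must be positive")
        if self.block_size_voxels < 16:
            raise ConfigError("block_size_voxels must be >= 16")

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["normalize_percentiles"] = list(self.normalize_percentiles)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        d = yaml.safe_load(Path(path).read_text())
        if not isinstance(d, dict):
            raise ConfigError(f"config file {path} is not a mapping")
        if "normalize_percentiles" in d:
            d["normalize_percentiles"] = tuple(d["normalize_percentiles"])
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        try:
            return cls(**d)
        except TypeError as e:  # pragma: no cover - defensive
            raise ConfigError(str(e)) from e

    def content_hash(self) -> str:
        import hashlib

        d = dataclasses.asdict(self)
        d["normalize_percentiles"] = list(self.normalize_percentiles)
        blob = json.dumps(d, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


# ---------------------------------------------------------------------------
# TIFF I/O
# ---------------------------------------------------------------------------


def write_image(image: MultiChannelImage, path: str | Path) -> None:
    """Write a multi-channel stack as a single TIFF (axes ``CZYX``).

    Channel names and the voxel size are stored in the TIFF description so
    that :func:`read_image` can restore them.  Integer data round-trips
    bit-identically.
    """
    if not image.channels:
        raise EmptyImageError("cannot write an image with no channels")
    names = image.names
    stack = np.stack([image[n].data for n in names])
    meta = {"channels": names, "voxel_size_um": float(image.voxel_size_um)}
    tifffile.imwrite(
        Path(path), stack, metadata=meta, photometric="minisblack"
    )


def read_image(
    path: str | Path,
    channel_names: list[str] | None = None,
    voxel_size_um: float | None = None,
) -> MultiChannelImage:
    """Read a multi-channel TIFF stack.

    Parameters
    ----------
    path:
        TIFF file with axes ``(C, Z, Y, X)`` or a plain 3D stack (one
        channel).
    channel_names:
        Names for the channels; must match the channel count.  If omitted,
        names stored in the file metadata are used.
    voxel_size_um:
        Override when the file has no voxel-size metadata.

    Raises
    ------
    FileNotFoundError, ChannelCountMismatchError, NonVolumetricDataError
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with tifffile.TiffFile(path) as tif:
        data = tif.asarray()
        meta: Mapping = {}
        if tif.shaped_metadata:
            meta = tif.shaped_metadata[0]
    if data.ndim == 3:
        data = data[None]
    if data.ndim != 4:
        raise NonVolumetricDataError(
            f"expected 3D or (C, Z, Y, X) data, got shape {data.shape}"
        )
    n_ch = data.shape[0]
    if channel_names is None:
        channel_names = list(meta.get("channels", []))
        if not channel_names:
            channel_names = [f"ch{i}" for i in range(n_ch)]
    if len(channel_names) != n_ch:
        raise ChannelCountMismatchError(
            f"file has {n_ch} channels but {len(channel_names)} names given"
        )
    vs = meta.get("voxel_size_um")
    if vs is None:
        vs = voxel_size_um
    if vs is None:
        raise ConfigError(
            f"{path} has no voxel-size metadata; pass voxel_size_um explicitly"
        )
    if np.ndim(vs) > 0:
        sizes = np.atleast_1d(np.asarray(vs, float))
        if not np.allclose(sizes, sizes[0]):
            raise AnisotropicVoxelError(f"anisotropic voxel size {vs!r}")
        vs = float(sizes[0])
    return MultiChannelImage(
        {n: VoxelGrid(data[i], float(vs)) for i, n in enumerate(channel_names)}
    )


def write_labels(labels: LabelMap, path: str | Path) -> None:
    """Write a label map as a uint32 TIFF (uint8 for binary masks)."""
    dtype = np.uint8 if labels.kind == "binary_mask" else np.uint32
    meta = {
        "voxel_size_um": float(labels.voxel_size_um),
        "label_kind": labels.kind,
    }
    tifffile.imwrite(
        Path(path),
        labels.labels.astype(dtype),
        metadata=meta,
        photometric="minisblack",
    )


def read_labels(path: str | Path, voxel_size_um: float | None = None) -> LabelMap:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with tifffile.TiffFile(path) as tif:
        data = tif.asarray()
        meta = tif.shaped_metadata[0] if tif.shaped_metadata else {}
    vs = meta.get("voxel_size_um", voxel_size_um)
    if vs is None:
        raise ConfigError(f"{path} has no voxel-size metadata")
    kind = meta.get("label_kind", "instance")
    return LabelMap(data, float(vs), kind)


# ---------------------------------------------------------------------------
# Light preprocessing
# ---------------------------------------------------------------------------


def normalize_channel(
    grid: VoxelGrid,
    method: str = "percentile",
    percentiles: tuple[float, float] = (1.0, 99.0),
) -> VoxelGrid:
    """Normalize intensities.

    ``percentile``: affinely map the given low/high percentiles to 0/1 and
    clip; a constant image maps to all zeros.  ``zscore``: subtract the mean
    and divide by the standard deviation; undefined (raises) for a constant
    image.
    """
    data = np.asarray(grid.data, dtype=np.float32)
    if method == "percentile":
        lo, hi = np.percentile(data, percentiles)
        if hi <= lo:
            return VoxelGrid(np.zeros_like(data), grid.voxel_size_um, grid.origin_um)
        out = np.clip((data - lo) / (hi - lo), 0.0, 1.0)
        return VoxelGrid(out, grid.voxel_size_um, grid.origin_um)
    if method == "zscore":
        sd = float(data.std())
        if sd == 0.0:
            raise ConstantImageError("z-score undefined for a constant image")
        out = (data - data.mean()) / sd
        return VoxelGrid(out, grid.voxel_size_um, grid.origin_um)
    raise ValueError(f"unknown normalization method {method!r}")


def smooth_channel(grid: VoxelGrid, sigma_um: float) -> VoxelGrid:
    """Optional Gaussian denoising hook (no-op for ``sigma_um <= 0``)."""
    if sigma_um <= 0:
        return grid
    from scipy.ndimage import gaussian_filter

    sig = sigma_um / grid.voxel_size_um
    return VoxelGrid(
        gaussian_filter(np.asarray(grid.data, np.float32), sig),
        grid.voxel_size_um,
        grid.origin_um,
    )
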