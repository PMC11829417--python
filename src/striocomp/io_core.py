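"""Volume and table I/O, analysis configuration, and run logging.

All volumes move through the pipeline as :class:`VolumeGrid` objects: a 3-D
data lattice plus the physical voxel size, the physical coordinate of the
center of voxel (0, 0, 0), and anatomical axis labels.  Geometry everywhere
downstream (centroids, offsets) is computed in physical millimetres from
voxel centers, never in index units.

The synthetic/canonical anatomical frame is fixed as::

    x : medial -> lateral
    y : caudal -> rostral
    z : ventral -> dorsal

Real NIfTI input is reoriented to the scanner-canonical (RAS-like) frame on
load and tagged with these labels, so "more medial / rostral / ventral" is
assertable by coordinate sign throughout the package.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import nibabel as nib
import numpy as np
import yaml

logger = logging.getLogger("striocomp")

#: canonical anatomical axis tags used by every geometry operation
CANONICAL_AXES = (
    "x=medial->lateral",
    "y=caudal->rostral",
    "z=ventral->dorsal",
)


@dataclass
class VolumeGrid:
    """A 3-D scalar or integer lattice with physical geometry attached.

    Parameters
    ----------
    data
        3-D array of voxel values.
    voxel_size_mm
        Physical edge length of a voxel along each axis, strictly positive.
    origin
        Physical coordinate (mm) of the *center* of voxel (0, 0, 0).
    axis_labels
        Anatomical orientation tags; must be present before any geometry
        operation is run on the grid.
    """

    data: np.ndarray
    voxel_size_mm: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    axis_labels: tuple[str, str, str] = CANONICAL_AXES

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(
                f"expected 3D volume, got {self.data.ndim}D array of shape "
                f"{self.data.shape}"
            )
        self.voxel_size_mm = tuple(float(v) for v in self.voxel_size_mm)
        if len(self.voxel_size_mm) != 3 or any(v <= 0 for v in self.voxel_size_mm):
            raise ValueError(
                f"voxel_size_mm must be 3 strictly positive values, got "
                f"{self.voxel_size_mm}"
            )
        self.origin = tuple(float(v) for v in self.origin)
        if self.axis_labels is None or len(self.axis_labels) != 3:
            raise ValueError("axis_labels must supply one orientation tag per axis")
        self.axis_labels = tuple(self.axis_labels)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.voxel_size_mm))

    def voxel_centers_mm(self, indices: np.ndarray) -> np.ndarray:
        """Physical center coordinates (mm) for an (N, 3) array of indices."""
        idx = np.atleast_2d(np.asarray(indices, dtype=float))
        return idx * np.asarray(self.voxel_size_mm) + np.asarray(self.origin)

    def same_grid_as(self, other: "VolumeGrid") -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.voxel_size_mm, other.voxel_size_mm)
            and np.allclose(self.origin, other.origin)
        )

    def with_data(self, data: np.ndarray) -> "VolumeGrid":
        """A new grid sharing this grid's geometry with different voxel data."""
        return VolumeGrid(
            data=data,
            voxel_size_mm=self.voxel_size_mm,
            origin=self.origin,
            axis_labels=self.axis_labels,
        )

    def checksum(self) -> str:
        h = hashlib.sha256()
        h.update(np.ascontiguousarray(self.data).tobytes())
        h.update(repr((self.voxel_size_mm, self.origin)).encode())
        return h.hexdigest()[:12]


@dataclass
class RegionMask:
    """A binary region-of-interest on a :class:`VolumeGrid`."""

    grid: VolumeGrid
    region_name: str

    def __post_init__(self) -> None:
        values = np.unique(self.grid.data)
        if not np.isin(values, (0, 1)).all():
            raise ValueError(
                f"mask '{self.region_name}' has non-binary values {values[:5]}"
            )
        if self.grid.data.dtype != bool:
            self.grid = self.grid.with_data(self.grid.data.astype(bool))

    @property
    def indices(self) -> np.ndarray:
        """(N, 3) voxel indices of member voxels, lexicographically ordered."""
        return np.argwhere(self.grid.data)

    @property
    def n_voxels(self) -> int:
        return int(self.grid.data.sum())


def validate_nucleus_partition(
    striatum: RegionMask, caudate: RegionMask, putamen: RegionMask
) -> None:
    """Enforce caudate ∪ putamen = striatum and caudate ∩ putamen = ∅."""
    c, p, s = caudate.grid.data, putamen.grid.data, striatum.grid.data
    if (c & p).any():
        raise ValueError("caudate and putamen masks overlap")
    if not ((c | p) == s).all():
        raise ValueError("caudate ∪ putamen does not equal the striatal mask")


# ---------------------------------------------------------------------------
# analysis configuration
# ---------------------------------------------------------------------------


@dataclass
class AnalysisConfig:
    """Thresholds and constants shared by every pipeline stage.

    Downstream modules receive these numbers *only* through this object;
    no stage hard-codes a classification or volumetry threshold.
    """

    bias_threshold: float = 0.55
    high_threshold: float = 0.95
    indeterminate_band: tuple[float, float] = (0.45, 0.55)
    equal_volume_target: int = 83
    histogram_bin_width: float = 0.01
    zone_percentile: float = 5.0
    fdr_q: float = 0.05
    dsc_amplitude_retention: float = 0.75
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not (0.5 < self.bias_threshold <= self.high_threshold <= 1.0):
            raise ValueError(
                "require 0.5 < bias_threshold <= high_threshold <= 1.0; got "
                f"bias_threshold={self.bias_threshold}, "
                f"high_threshold={self.high_threshold}"
            )
        lo, hi = self.indeterminate_band
        if not np.isclose(lo + hi, 1.0):
            raise ValueError(
                f"indeterminate_band must be symmetric about 0.5, got ({lo}, {hi})"
            )
        if not np.isclose(hi, self.bias_threshold):
            raise ValueError(
                "indeterminate_band upper edge must equal bias_threshold; got "
                f"{hi} vs bias_threshold={self.bias_threshold}"
            )
        if self.equal_volume_target <= 0:
            raise ValueError(
                f"equal_volume_target must be positive, got {self.equal_volume_target}"
            )
        span = 1.0 - self.bias_threshold
        n_bins = span / self.histogram_bin_width
        if abs(n_bins - round(n_bins)) > 1e-9:
            raise ValueError(
                f"histogram_bin_width={self.histogram_bin_width} does not divide "
                f"the biased range [{self.bias_threshold}, 1.0] evenly"
            )
        if not (0 < self.zone_percentile < 100):
            raise ValueError(f"zone_percentile must be in (0, 100), got {self.zone_percentile}")
        if not (0 < self.fdr_q < 1):
            raise ValueError(f"fdr_q must be in (0, 1), got {self.fdr_q}")
        if not (0 < self.dsc_amplitude_retention <= 1):
            raise ValueError(
                f"dsc_amplitude_retention must be in (0, 1], got "
                f"{self.dsc_amplitude_retention}"
            )

    @property
    def n_biased_bins(self) -> int:
        """Number of histogram bins covering the biased range [0.55, 1.00]."""
        return int(round((1.0 - self.bias_threshold) / self.histogram_bin_width))

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["indeterminate_band"] = list(d["indeterminate_band"])
        return d


def load_config(
    path: str | Path | None = None, overrides: Mapping | None = None
) -> AnalysisConfig:
    """Build an :class:`AnalysisConfig` from a YAML/JSON file and/or overrides.

    Either argument may be omitted; defaults cover the remainder.  Invariant
    violations raise ``ValueError`` naming the offending key where possible.
    """
    raw: dict = {}
    if path is not None:
        text = Path(path).read_text()
        loaded = yaml.safe_load(text) or {}
        if not isinstance(loaded, dict):
            raise ValueError(f"config file {path} must contain a mapping")
        raw.update(loaded)
    if overrides:
        raw.update(overrides)

    known = {f.name for f in dataclasses.fields(AnalysisConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    if "indeterminate_band" in raw:
        raw["indeterminate_band"] = tuple(raw["indeterminate_band"])
    cfg = AnalysisConfig(**raw)
    logger.info("resolved config: %s", json.dumps(cfg.to_dict()))
    return cfg


# ---------------------------------------------------------------------------
# NIfTI I/O
# ---------------------------------------------------------------------------


def _affine_from_grid(grid: VolumeGrid) -> np.ndarray:
    aff = np.diag(list(grid.voxel_size_mm) + [1.0])
    aff[:3, 3] = grid.origin
    return aff


def read_volume(path: str | Path) -> VolumeGrid:
    """Read a 3-D NIfTI volume (optionally gzipped) into a :class:`VolumeGrid`.

    The image is reoriented to the closest canonical (RAS-like) frame so that
    axis signs match the package's anatomical convention.  Non-3-D images and
    images without a decodable orientation fail loudly.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"volume not found: {path}")
    img = nib.load(str(path))
    if img.ndim != 3:
        raise ValueError(f"expected 3D volume, got {img.ndim}D image at {path}")
    try:
        nib.orientations.aff2axcodes(img.affine)
    except Exception as exc:  # pragma: no cover - nibabel raises rarely here
        raise ValueError(f"cannot determine orientation of {path}: {exc}") from exc
    if np.linalg.det(img.affine[:3, :3]) == 0:
        raise ValueError(f"ambiguous orientation (singular affine) in {path}")
    img = nib.as_closest_canonical(img)
    data = np.asarray(img.dataobj)
    zooms = img.header.get_zooms()[:3]
    origin = tuple(float(v) for v in img.affine[:3, 3])
    return VolumeGrid(
        data=data,
        voxel_size_mm=tuple(float(z) for z in zooms),
        origin=origin,
        axis_labels=CANONICAL_AXES,
    )


def write_volume(grid: VolumeGrid, path: str | Path) -> Path:
    """Write a :class:`VolumeGrid` as NIfTI-1, preserving geometry exactly.

    Floating-point data is stored as float (never quantized); boolean and
    integer label maps are stored as small integer types.
    """
    path = Path(path)
    data = grid.data
    if data.dtype == bool:
        data = data.astype(np.uint8)
    elif np.issubdtype(data.dtype, np.integer):
        if data.dtype.itemsize > 4:  # NIfTI-1 has no portable 64-bit int
            data = data.astype(np.int32)
    else:
        data = data.astype(np.float64)
    img = nib.Nifti1Image(data, _affine_from_grid(grid))
    img.header.set_zooms(grid.voxel_size_mm)
    try:
        nib.save(img, str(path))
    except OSError as exc:
        raise OSError(f"cannot write volume to {path}: {exc}") from exc
    return path


# ---------------------------------------------------------------------------
# run logging
# ---------------------------------------------------------------------------


@dataclass
class RunLog:
    """Accumulates input checksums, resolved config and stage summaries."""

    config: AnalysisConfig
    entries: list = field(default_factory=list)

    def record(self, stage: str, **info) -> None:
        entry = {"stage": stage, **info}
        self.entries.append(entry)
        logger.info("%s: %s", stage, json.dumps(info, default=str))

    def record_input(self, stage: str, name: str, grid: VolumeGrid) -> None:
        self.record(stage, input=name, checksum=grid.checksum(), shape=grid.shape)

    def dump(self, path: str | Path) -> None:
        payload = {"config": self.config.to_dict(), "entries": self.entries}
        Path(path).write_text(json.dumps(payload, indent=2, default=str))
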