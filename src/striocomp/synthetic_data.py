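"""Synthetic striosome/matrix phantoms and the forward model to count data.

The striosome is a branched, labyrinthine structure embedded in matrix, with
coronal-plane tubule diameters of roughly 0.5-1.25 mm and enrichment toward
the rostral, medial and ventral striatum.  The generator grows clustered
random-walk tubules inside an ellipsoidal striatal envelope on a
high-resolution lattice (default 0.25 mm, so the thinnest tubule spans two
voxels), dilates them to per-branch diameters, and labels the remaining
interior as matrix.

Three tissue-level perturbations of a phantom are supported, applied to the
case member of each simulated pair:

* ``A`` (striosome volume loss) - a fraction of branches is deleted; tubule
  thickness is untouched.
* ``B`` (architecture simplification) - the labyrinth is rebuilt from fewer
  branches whose diameters are inflated to conserve striosome volume within
  2% ("thicker tubes, fewer branches").
* ``C`` (matrix expansion) - the matrix envelope dilates; the striosome
  label set is bit-identical to the input.

Downsampling to the diffusion grid (2 mm isotropic) yields the per-voxel
striosome tissue fraction f, and a strictly decreasing logistic forward
model maps f to the probability of matrix-favoring connectivity, from which
noisy streamline counts are drawn.  A full cohort simulation wires these
stages into matched case/control pairs with demographics, compartment-
dependent FA, and a group-level streamline deficit in cases.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy.special import expit

from .cohort_stats import SubjectRecord, age_window_months
from .io_core import CANONICAL_AXES, RegionMask, VolumeGrid
from .parcellation import CountPair, ProbabilityMap, compute_probability


class PerturbationError(ValueError):
    """A perturbation could not honor its conservation contract."""


# ---------------------------------------------------------------------------
# parameters
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PhantomParams:
    """Geometry of the synthetic striatum and its striosome labyrinth.

    The envelope is an ellipsoid whose long axis is rostro-caudal (y); the
    default semi-axes give a 40 mm rostro-caudal extent and a tissue volume
    close to a human hemistriatum at 2 mm resolution.  Gradient weights are
    log-density slopes per normalized axis unit; positive values enrich the
    striosome medially (-x), rostrally (+y) and ventrally (-z).
    """

    envelope_semi_axes_mm: tuple[float, float, float] = (10.0, 20.0, 8.0)
    highres_mm: float = 0.25
    voxel_mm: float = 2.0
    striosome_fraction: float = 0.15
    fraction_tolerance: float = 0.10
    diameter_range_mm: tuple[float, float] = (0.5, 1.25)
    max_inflated_diameter_mm: float = 1.9  # scenario-B headroom, < voxel_mm
    branch_length_mm: float = 12.0
    branches_per_cluster: int = 12
    cluster_spread_mm: float = 1.2
    gradient_weights: tuple[float, float, float] = (1.0, 1.0, 1.0)
    persistence: float = 0.7  # velocity AR(1) momentum of the tubule walk
    attraction: float = 0.12  # pull toward the cluster center per step

    def __post_init__(self) -> None:
        if self.voxel_mm % self.highres_mm > 1e-9:
            raise ValueError("voxel_mm must be an integer multiple of highres_mm")
        lo, hi = self.diameter_range_mm
        if not (0 < lo <= hi):
            raise ValueError(f"bad diameter range {self.diameter_range_mm}")
        if lo < 2 * self.highres_mm:
            raise ValueError(
                "minimum tubule diameter must span at least two high-res voxels"
            )
        if not (0 < self.striosome_fraction < 0.5):
            raise ValueError("striosome_fraction must be in (0, 0.5)")

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        """High-res lattice shape: covers the envelope dilated by up to 50%
        extra matrix volume, rounded up to a multiple of the downsampling
        factor."""
        factor = int(round(self.voxel_mm / self.highres_mm))
        shape = []
        for a in self.envelope_semi_axes_mm:
            half_extent = a * (1.5) ** (1.0 / 3.0) + 1.0  # mm, with margin
            n = int(math.ceil(2 * half_extent / self.highres_mm))
            n = int(math.ceil(n / factor) * factor)
            shape.append(n)
        return tuple(shape)

    @property
    def origin_mm(self) -> tuple[float, float, float]:
        """Physical center of voxel (0,0,0); envelope centered at (0,0,0) mm."""
        return tuple(
            -(n - 1) / 2.0 * self.highres_mm for n in self.grid_shape
        )


@dataclass(frozen=True)
class PerturbationSpec:
    """Which tissue-level alteration to apply, and how strongly."""

    scenario: str  # 'A' | 'B' | 'C'
    magnitude: float
    seed: int = 0

    def __post_init__(self) -> None:
        if self.scenario not in ("A", "B", "C"):
            raise ValueError(f"scenario must be 'A', 'B' or 'C', got {self.scenario!r}")
        if not (0 < self.magnitude <= 0.5):
            raise ValueError(f"magnitude must be in (0, 0.5], got {self.magnitude}")


@dataclass(frozen=True)
class ForwardModel:
    """Logistic map from striosome fraction to matrix-favoring probability.

    ``p_matrix(f) = expit(steepness * (midpoint - f))``: strictly decreasing
    in f, equal to 0.5 at the midpoint, and >= 0.95 at f = 0 under the
    default calibration.  Streamline counts are the per-voxel budget split
    by p with independent multiplicative log-normal noise on each target
    class.
    """

    midpoint: float = 0.5
    steepness: float = 10.0
    noise_sigma: float = 0.05
    budget: int = 5000

    def __post_init__(self) -> None:
        if self.steepness <= 0:
            raise ValueError("steepness must be positive (mapping must decrease in f)")
        if not (0 < self.midpoint < 1):
            raise ValueError("midpoint must be in (0, 1)")
        if self.budget <= 0:
            raise ValueError("streamline budget must be positive")
        if self.p_matrix(0.0) < 0.95:
            raise ValueError(
                "calibration contract: p_matrix(0) must reach at least 0.95"
            )

    def p_matrix(self, f) -> np.ndarray | float:
        return expit(self.steepness * (self.midpoint - np.asarray(f, dtype=float)))


# ---------------------------------------------------------------------------
# phantom container
# ---------------------------------------------------------------------------


@dataclass
class Branch:
    points_mm: np.ndarray  # (T, 3) physical coordinates of the skeleton
    radius_mm: float
    cluster: int


@dataclass
class TissuePhantom:
    """High-res compartment label grid plus the skeleton that generated it."""

    labels: VolumeGrid  # 0 exterior, 1 matrix, 2 striosome
    branches: list[Branch]
    params: PhantomParams
    envelope_scale: float = 1.0  # >1 after scenario-C dilation
    scenario: str | None = None
    magnitude: float = 0.0
    seed: int = 0

    EXTERIOR, MATRIX, STRIOSOME = 0, 1, 2

    @property
    def striosome_voxels(self) -> int:
        return int((self.labels.data == self.STRIOSOME).sum())

    @property
    def matrix_voxels(self) -> int:
        return int((self.labels.data == self.MATRIX).sum())

    @property
    def striosome_volume_mm3(self) -> float:
        return self.striosome_voxels * self.labels.voxel_volume_mm3

    @property
    def striosome_fraction(self) -> float:
        tissue = self.striosome_voxels + self.matrix_voxels
        return self.striosome_voxels / tissue if tissue else 0.0


@dataclass
class FractionMap:
    """Diffusion-grid striosome tissue fraction with its striatal mask."""

    f: VolumeGrid  # striosome fraction of tissue per diffusion voxel
    striatum: RegionMask  # tissue-dominated diffusion voxels
    tissue_fraction: VolumeGrid  # tissue (non-exterior) fraction per voxel
    source_seed: int = 0


# ---------------------------------------------------------------------------
# geometry helpers (cached across subjects)
# ---------------------------------------------------------------------------


@lru_cache(maxsize=32)
def _interior_mask(
    shape: tuple[int, int, int],
    semi_axes_mm: tuple[float, float, float],
    highres_mm: float,
    origin_mm: tuple[float, float, float],
    erosion_mm: float = 0.0,
) -> np.ndarray:
    """Boolean ellipsoid-interior mask, optionally eroded by `erosion_mm`."""
    axes = [
        (origin_mm[i] + highres_mm * np.arange(shape[i])) for i in range(3)
    ]
    semi = np.asarray(semi_axes_mm) - erosion_mm
    if (semi <= 0).any():
        raise ValueError("erosion exceeds envelope semi-axes")
    q = (
        (axes[0][:, None, None] / semi[0]) ** 2
        + (axes[1][None, :, None] / semi[1]) ** 2
        + (axes[2][None, None, :] / semi[2]) ** 2
    )
    return q <= 1.0


@lru_cache(maxsize=64)
def _ball_offsets(radius_vox_q: int) -> np.ndarray:
    """(O, 3) integer offsets of a voxel ball of radius radius_vox_q / 4."""
    r = radius_vox_q / 4.0
    n = int(math.floor(r))
    rng = np.arange(-n, n + 1)
    ox, oy, oz = np.meshgrid(rng, rng, rng, indexing="ij")
    keep = ox**2 + oy**2 + oz**2 <= r**2 + 1e-9
    return np.stack([ox[keep], oy[keep], oz[keep]], axis=1).astype(np.int64)


def _stamp_branches(
    label: np.ndarray, branches: list[Branch], params: PhantomParams,
    radius_scale: float = 1.0,
) -> None:
    """Mark striosome voxels by stamping balls along every branch skeleton."""
    shape = label.shape
    origin = np.asarray(params.origin_mm)
    h = params.highres_mm
    by_radius: dict[int, list[np.ndarray]] = {}
    for br in branches:
        r_vox = br.radius_mm * radius_scale / h
        key = max(4, int(round(r_vox * 4)))  # quantize radius to 1/4 voxel
        idx = np.rint((br.points_mm - origin) / h).astype(np.int64)
        by_radius.setdefault(key, []).append(idx)
    strides = np.array(
        [shape[1] * shape[2], shape[2], 1], dtype=np.int64
    )
    flat = label.reshape(-1)
    for key, idx_list in by_radius.items():
        pts = np.concatenate(idx_list, axis=0)
        offs = _ball_offsets(key)
        vox = pts[:, None, :] + offs[None, :, :]  # (P, O, 3)
        np.clip(vox[..., 0], 0, shape[0] - 1, out=vox[..., 0])
        np.clip(vox[..., 1], 0, shape[1] - 1, out=vox[..., 1])
        np.clip(vox[..., 2], 0, shape[2] - 1, out=vox[..., 2])
        flat_idx = (vox @ strides).ravel()
        flat[flat_idx] = TissuePhantom.STRIOSOME


def _cumulative_branch_volumes(
    branches: list[Branch], params: PhantomParams, envelope_scale: float = 1.0
) -> np.ndarray:
    """Striosome voxel count after stamping each successive branch prefix."""
    shape = params.grid_shape
    semi = tuple(a * envelope_scale for a in params.envelope_semi_axes_mm)
    interior = _interior_mask(shape, semi, params.highres_mm, params.origin_mm)
    claimed = np.zeros(shape, dtype=bool).reshape(-1)
    interior_flat = interior.reshape(-1)
    strides = np.array([shape[1] * shape[2], shape[2], 1], dtype=np.int64)
    origin = np.asarray(params.origin_mm)
    h = params.highres_mm
    out = np.empty(len(branches), dtype=np.int64)
    total = 0
    for i, br in enumerate(branches):
        key = max(4, int(round(br.radius_mm / h * 4)))
        idx = np.rint((br.points_mm - origin) / h).astype(np.int64)
        offs = _ball_offsets(key)
        vox = idx[:, None, :] + offs[None, :, :]
        for ax in range(3):
            np.clip(vox[..., ax], 0, shape[ax] - 1, out=vox[..., ax])
        flat_idx = np.unique((vox @ strides).ravel())
        flat_idx = flat_idx[interior_flat[flat_idx] & ~claimed[flat_idx]]
        claimed[flat_idx] = True
        total += len(flat_idx)
        out[i] = total
    return out


# ---------------------------------------------------------------------------
# phantom generation
# ---------------------------------------------------------------------------


def _gradient_logdensity(points_mm: np.ndarray, params: PhantomParams) -> np.ndarray:
    """Unnormalized log density of striosome seeds at physical points (mm)."""
    semi = np.asarray(params.envelope_semi_axes_mm)
    w = np.asarray(params.gradient_weights)
    unit = points_mm / semi  # each coordinate in [-1, 1] inside the envelope
    # enriched medially (-x), rostrally (+y), ventrally (-z)
    return -w[0] * unit[:, 0] + w[1] * unit[:, 1] - w[2] * unit[:, 2]


def _sample_cluster_centers(
    n: int, params: PhantomParams, rng: np.random.Generator, margin_mm: float
) -> np.ndarray:
    """Rejection-sample cluster centers from the gradient-weighted density."""
    semi = np.asarray(params.envelope_semi_axes_mm) - margin_mm
    centers = np.empty((0, 3))
    max_logd = float(np.sum(np.abs(params.gradient_weights)))
    while len(centers) < n:
        cand = rng.uniform(-semi, semi, size=(max(4 * n, 64), 3))
        inside = ((cand / semi) ** 2).sum(axis=1) <= 1.0
        cand = cand[inside]
        logd = _gradient_logdensity(cand, params)
        accept = rng.random(len(cand)) < np.exp(logd - max_logd)
        centers = np.vstack([centers, cand[accept]])
    return centers[:n]


def _grow_branches(
    centers: np.ndarray,
    params: PhantomParams,
    rng: np.random.Generator,
) -> list[Branch]:
    """Grow clustered persistent random-walk tubule skeletons.

    All branches advance in lock-step (vectorized across branches): the
    velocity follows an AR(1) momentum process plus a weak attraction to the
    branch's cluster center, and positions are confined to the envelope
    eroded by the maximum tubule radius.
    """
    step = params.highres_mm
    n_steps = int(round(params.branch_length_mm / step))
    margin = params.diameter_range_mm[1] / 2 + step
    semi = np.asarray(params.envelope_semi_axes_mm) - margin
    n_clusters = len(centers)
    n_branches = n_clusters * params.branches_per_cluster
    cluster_idx = np.repeat(np.arange(n_clusters), params.branches_per_cluster)
    anchors = centers[cluster_idx]
    x = anchors + rng.normal(0.0, params.cluster_spread_mm, size=(n_branches, 3))
    # keep seeds inside the eroded envelope
    q = ((x / semi) ** 2).sum(axis=1, keepdims=True)
    x = np.where(q > 1.0, x / np.sqrt(q), x)
    v = rng.normal(size=(n_branches, 3))
    v *= step / np.linalg.norm(v, axis=1, keepdims=True)
    rho = params.persistence
    paths = np.empty((n_steps, n_branches, 3))
    noise = rng.normal(size=(n_steps, n_branches, 3))
    for t in range(n_steps):
        kick = noise[t]
        kick *= step / np.linalg.norm(kick, axis=1, keepdims=True)
        v = rho * v + (1 - rho) * kick + params.attraction * (anchors - x)
        v *= step / np.linalg.norm(v, axis=1, keepdims=True)
        x = x + v
        q = ((x / semi) ** 2).sum(axis=1, keepdims=True)
        outside = q[:, 0] > 1.0
        if outside.any():
            x[outside] /= np.sqrt(q[outside])
            v[outside] *= -0.5  # bounce back inward
        paths[t] = x
    diam = rng.uniform(*params.diameter_range_mm, size=n_branches)
    return [
        Branch(points_mm=paths[:, b, :].copy(), radius_mm=diam[b] / 2.0, cluster=int(cluster_idx[b]))
        for b in range(n_branches)
    ]


def _render(
    branches: list[Branch],
    params: PhantomParams,
    envelope_scale: float = 1.0,
    radius_scale: float = 1.0,
) -> VolumeGrid:
    """Rasterize branches into a fresh label grid inside the (scaled) envelope."""
    shape = params.grid_shape
    semi = tuple(a * envelope_scale for a in params.envelope_semi_axes_mm)
    interior = _interior_mask(shape, semi, params.highres_mm, params.origin_mm)
    label = np.where(interior, TissuePhantom.MATRIX, TissuePhantom.EXTERIOR).astype(
        np.uint8
    )
    _stamp_branches(label, branches, params, radius_scale=radius_scale)
    # stamping may graze the envelope edge after clipping; confine striosome
    label[~interior] = TissuePhantom.EXTERIOR
    return VolumeGrid(
        data=label,
        voxel_size_mm=(params.highres_mm,) * 3,
        origin=params.origin_mm,
        axis_labels=CANONICAL_AXES,
    )


def generate_phantom(
    params: PhantomParams = PhantomParams(), seed: int = 0
) -> TissuePhantom:
    """Grow a striosome labyrinth phantom hitting the target volume fraction.

    Branch clusters are added batch by batch — stamping incrementally onto
    one label grid — until the striosome tissue fraction reaches the
    configured target within its tolerance; the gradient weights shape where
    clusters land.
    """
    rng = np.random.default_rng(seed)
    shape = params.grid_shape
    interior = _interior_mask(
        shape, params.envelope_semi_axes_mm, params.highres_mm, params.origin_mm
    )
    interior_count = int(interior.sum())
    target = params.striosome_fraction * interior_count
    # initial batch size from the expected per-branch tubule volume
    lo, hi = params.diameter_range_mm
    mean_r2 = (lo**2 + lo * hi + hi**2) / 12.0  # E[(d/2)^2] for d ~ U[lo, hi]
    per_branch = math.pi * mean_r2 * params.branch_length_mm / params.highres_mm**3
    margin = params.diameter_range_mm[1] / 2 + params.cluster_spread_mm
    label = np.where(interior, TissuePhantom.MATRIX, TissuePhantom.EXTERIOR).astype(
        np.uint8
    )
    branches: list[Branch] = []
    n_clusters = max(2, int(0.7 * target / per_branch) // params.branches_per_cluster)
    achieved = 0
    for _ in range(20):
        centers = _sample_cluster_centers(n_clusters, params, rng, margin)
        new_branches = _grow_branches(centers, params, rng)
        _stamp_branches(label, new_branches, params)
        branches.extend(new_branches)
        label[~interior] = TissuePhantom.EXTERIOR  # confine striosome to envelope
        previous = achieved
        achieved = int((label == TissuePhantom.STRIOSOME).sum())
        if achieved >= target * (1 - params.fraction_tolerance):
            break
        deficit = target - achieved
        # effective yield of the last batch accounts for overlap/confinement
        yield_per_cluster = max(
            0.2 * per_branch * params.branches_per_cluster,
            (achieved - previous) / n_clusters,
        )
        n_clusters = max(1, math.ceil(0.9 * deficit / yield_per_cluster))
    achieved_frac = (label == TissuePhantom.STRIOSOME).sum() / interior_count
    if abs(achieved_frac - params.striosome_fraction) > 0.35 * params.striosome_fraction:
        raise ValueError(
            f"infeasible volume-fraction/diameter combination: achieved "
            f"{achieved_frac:.3f} vs target {params.striosome_fraction:.3f}"
        )
    if len(branches) < 20:
        raise ValueError(
            "envelope too small for >= 20 branches at the configured diameter"
        )
    grid = VolumeGrid(
        data=label,
        voxel_size_mm=(params.highres_mm,) * 3,
        origin=params.origin_mm,
        axis_labels=CANONICAL_AXES,
    )
    return TissuePhantom(
        labels=grid, branches=branches, params=params, seed=seed
    )


# ---------------------------------------------------------------------------
# perturbations
# ---------------------------------------------------------------------------


def apply_perturbation(phantom: TissuePhantom, spec: PerturbationSpec) -> TissuePhantom:
    """Apply one of the three hypothesized tissue-level alterations."""
    rng = np.random.default_rng(spec.seed)
    params = phantom.params

    if spec.scenario == "A":
        # delete randomly-chosen branches until a magnitude-fraction of
        # striosome *volume* is lost; tubule thickness untouched.  Because
        # tubules overlap inside labyrinth knots, the deleted branch count
        # exceeds the volume fraction removed.  With a fixed deletion order
        # kept volume is monotone in the kept-prefix length, so one
        # cumulative stamping pass locates the cut exactly.
        order = rng.permutation(len(phantom.branches))
        target = (1.0 - spec.magnitude) * phantom.striosome_voxels
        cumulative = _cumulative_branch_volumes(
            [phantom.branches[i] for i in order], params, phantom.envelope_scale
        )
        n_keep = int(np.argmin(np.abs(cumulative - target))) + 1
        kept = [phantom.branches[i] for i in sorted(order[:n_keep])]
        grid = _render(kept, params, envelope_scale=phantom.envelope_scale)
        return replace(
            phantom, labels=grid, branches=kept, scenario="A", magnitude=spec.magnitude
        )

    if spec.scenario == "B":
        # rebuild the labyrinth from scratch: fewer branches concentrated in
        # fewer clusters, diameters inflated to conserve striosome volume to 2%
        n_keep = max(2, int(round((1 - spec.magnitude) * len(phantom.branches))))
        n_clusters = max(2, n_keep // params.branches_per_cluster)
        grow_params = params
        margin = params.diameter_range_mm[1] / 2 + params.cluster_spread_mm
        centers = _sample_cluster_centers(n_clusters, grow_params, rng, margin)
        rebuilt = _grow_branches(centers, grow_params, rng)
        target = phantom.striosome_voxels
        scale = math.sqrt(len(phantom.branches) / len(rebuilt))
        achieved_grid = None
        for _ in range(8):
            max_diam = 2 * scale * max(br.radius_mm for br in rebuilt)
            if max_diam > params.max_inflated_diameter_mm:
                raise PerturbationError(
                    f"scenario B: inflated tubule diameter {max_diam:.2f} mm exceeds "
                    f"the configured maximum {params.max_inflated_diameter_mm} mm"
                )
            achieved_grid = _render(
                rebuilt, params, envelope_scale=phantom.envelope_scale, radius_scale=scale
            )
            achieved = int((achieved_grid.data == TissuePhantom.STRIOSOME).sum())
            err = achieved / target - 1.0
            if abs(err) <= 0.02:
                break
            # tubule volume scales ~ radius^2; correct multiplicatively
            scale *= math.sqrt(max(0.25, min(4.0, target / achieved)))
        else:
            raise PerturbationError(
                "scenario B: could not conserve striosome volume within 2%"
            )
        new_branches = [
            replace(br, radius_mm=br.radius_mm * scale) for br in rebuilt
        ]
        return replace(
            phantom,
            labels=achieved_grid,
            branches=new_branches,
            scenario="B",
            magnitude=spec.magnitude,
        )

    # scenario C: dilate the matrix envelope; striosome labels bit-identical
    matrix = phantom.matrix_voxels
    strio = phantom.striosome_voxels
    old_interior = matrix + strio
    new_interior = strio + matrix * (1 + spec.magnitude)
    scale = phantom.envelope_scale * (new_interior / old_interior) ** (1.0 / 3.0)
    shape = params.grid_shape
    semi = tuple(a * scale for a in params.envelope_semi_axes_mm)
    interior = _interior_mask(shape, semi, params.highres_mm, params.origin_mm)
    label = np.where(interior, TissuePhantom.MATRIX, TissuePhantom.EXTERIOR).astype(np.uint8)
    strio_mask = phantom.labels.data == TissuePhantom.STRIOSOME
    label[strio_mask] = TissuePhantom.STRIOSOME
    grid = phantom.labels.with_data(label)
    return replace(
        phantom,
        labels=grid,
        envelope_scale=scale,
        scenario="C",
        magnitude=spec.magnitude,
    )


# ---------------------------------------------------------------------------
# voxelization and the forward model
# ---------------------------------------------------------------------------


def voxelize(phantom: TissuePhantom, voxel_mm: float | None = None) -> FractionMap:
    """Downsample the label grid to diffusion resolution.

    Per diffusion voxel, ``f`` is the striosome share of *tissue* high-res
    voxels; diffusion voxels dominated by exterior (tissue fraction <= 0.5)
    are masked out of the striatum.
    """
    params = phantom.params
    voxel_mm = params.voxel_mm if voxel_mm is None else voxel_mm
    ratio = voxel_mm / params.highres_mm
    if abs(ratio - round(ratio)) > 1e-9:
        raise ValueError(
            f"voxel size {voxel_mm} mm is not an integer multiple of the "
            f"high-res spacing {params.highres_mm} mm"
        )
    k = int(round(ratio))
    data = phantom.labels.data
    shape = data.shape
    if any(s % k for s in shape):
        raise ValueError("high-res grid shape not divisible by the downsampling factor")
    blocks = data.reshape(
        shape[0] // k, k, shape[1] // k, k, shape[2] // k, k
    )
    strio = (blocks == TissuePhantom.STRIOSOME).sum(axis=(1, 3, 5))
    tissue = (blocks != TissuePhantom.EXTERIOR).sum(axis=(1, 3, 5))
    with np.errstate(invalid="ignore", divide="ignore"):
        f = np.where(tissue > 0, strio / np.maximum(tissue, 1), 0.0)
    tissue_frac = tissue / k**3
    striatum = tissue_frac > 0.5
    origin = tuple(
        o + (k - 1) / 2.0 * params.highres_mm for o in phantom.labels.origin
    )
    geometry = dict(
        voxel_size_mm=(voxel_mm,) * 3, origin=origin, axis_labels=CANONICAL_AXES
    )
    fgrid = VolumeGrid(data=f, **geometry)
    return FractionMap(
        f=fgrid,
        striatum=RegionMask(VolumeGrid(data=striatum, **geometry), "striatum"),
        tissue_fraction=VolumeGrid(data=tissue_frac, **geometry),
        source_seed=phantom.seed,
    )


def fractions_to_counts(
    fraction_map: FractionMap,
    model: ForwardModel = ForwardModel(),
    seed: int = 0,
    budget_scale: float = 1.0,
) -> CountPair:
    """Draw noisy streamline counts whose expected ratio recovers p_matrix.

    Counts toward each composite target are the voxel budget split by the
    forward-model probability, each side multiplied by independent mean-one
    log-normal noise and rounded.
    """
    rng = np.random.default_rng(seed)
    f = fraction_map.f.data
    striatum = fraction_map.striatum.grid.data
    p = model.p_matrix(f)
    budget = model.budget * budget_scale
    if budget <= 0:
        raise ValueError("streamline budget must be positive")
    sigma = model.noise_sigma
    mean_one = math.exp(-(sigma**2) / 2.0)
    noise_m = np.exp(sigma * rng.standard_normal(f.shape)) * mean_one
    noise_s = np.exp(sigma * rng.standard_normal(f.shape)) * mean_one
    cm = np.rint(budget * p * noise_m) * striatum
    cs = np.rint(budget * (1.0 - p) * noise_s) * striatum
    return CountPair(
        counts_matrix=fraction_map.f.with_data(cm),
        counts_striosome=fraction_map.f.with_data(cs),
        striatum=fraction_map.striatum,
    )


def split_nuclei(striatum: RegionMask) -> tuple[RegionMask, RegionMask]:
    """Split the striatal mask into synthetic 'caudate' and 'putamen' halves.

    The rostral half along y plays the caudate and the caudal half the
    putamen; the split plane is the voxel row that balances the two counts.
    This is a labeling convenience for nucleus-wise accounting, not an
    anatomical segmentation.
    """
    data = striatum.grid.data
    ys = np.nonzero(data.any(axis=(0, 2)))[0]
    cum = np.cumsum(data.sum(axis=(0, 2))[ys])
    split = ys[np.searchsorted(cum, cum[-1] / 2.0)]
    caudate = np.zeros_like(data)
    caudate[:, split + 1 :, :] = True
    caudate &= data
    putamen = data & ~caudate
    return (
        RegionMask(striatum.grid.with_data(caudate), "caudate"),
        RegionMask(striatum.grid.with_data(putamen), "putamen"),
    )


# ---------------------------------------------------------------------------
# cohort simulation
# ---------------------------------------------------------------------------


@dataclass
class SimulatedSubject:
    record: SubjectRecord
    pmap: ProbabilityMap
    fraction_map: FractionMap
    fa_map: VolumeGrid
    waytotal_bait_matrix: float
    waytotal_bait_striosome: float


@dataclass
class SimulatedCohort:
    pairs: list[tuple[SimulatedSubject, SimulatedSubject]]  # (case, control)
    scenario: str | None
    magnitude: float
    seed: int
    model: ForwardModel
    params: PhantomParams
    demographics: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def cases(self) -> list[SimulatedSubject]:
        return [c for c, _ in self.pairs]

    @property
    def controls(self) -> list[SimulatedSubject]:
        return [c for _, c in self.pairs]


def _simulate_demographics(
    n_pairs: int, rng: np.random.Generator
) -> pd.DataFrame:
    """Matched-pair demographics honoring the age-window matching rules."""
    races = np.array(["White", "Black", "Asian", "Native American", "More than one"])
    race_p = np.array([0.81, 0.08, 0.06, 0.01, 0.04])
    studies = np.array(["study1", "study2", "study3", "study4_5"])
    study_p = np.array([0.556, 0.232, 0.150, 0.062])
    rows = []
    for i in range(n_pairs):
        age = float(np.clip(rng.lognormal(np.log(170.0), 0.35), 78, 508))
        window = age_window_months(age)
        gap = float(rng.uniform(-window, window))
        sex = "F" if rng.random() < 0.30 else "M"
        race = str(rng.choice(races, p=race_p))
        study = str(rng.choice(studies, p=study_p))
        diagnosis = "ADOS-high" if rng.random() < 0.779 else "ADOS-mid"
        has_css = rng.random() < 0.728
        css = float(np.clip(np.rint(rng.normal(7.1, 1.35)), 3, 10)) if has_css else None
        rows.append(
            {
                "pair_id": f"pair{i:03d}",
                "case_age_months": age,
                "control_age_months": max(78.0, age + gap),
                "sex": sex,
                "race_label": race,
                "study_id": study,
                "diagnosis": diagnosis,
                "css": css,
            }
        )
    return pd.DataFrame(rows)


def _make_fa_map(
    fraction_map: FractionMap,
    rng: np.random.Generator,
    fa_striosome: float = 0.213,
    fa_gap: float = 0.042,
    fa_noise: float = 0.01,
) -> VolumeGrid:
    """FA rises with matrix content: pure matrix ~ (1 + fa_gap) x striosome FA."""
    f = fraction_map.f.data
    fa = fa_striosome * (1.0 + fa_gap * (1.0 - f))
    fa = fa + rng.normal(0.0, fa_noise * fa_striosome, size=f.shape)
    return fraction_map.f.with_data(np.clip(fa, 0.0, 1.0))


def simulate_subject(
    seed: int,
    perturbation: PerturbationSpec | None = None,
    params: PhantomParams = PhantomParams(),
    model: ForwardModel = ForwardModel(),
    record: SubjectRecord | None = None,
    budget_scale: float = 1.0,
    fa_gap: float = 0.042,
) -> SimulatedSubject:
    """Phantom -> (perturbation) -> fraction map -> counts -> probability map."""
    phantom = generate_phantom(params, seed=seed)
    if perturbation is not None:
        phantom = apply_perturbation(phantom, replace(perturbation, seed=seed + 1))
    fmap = voxelize(phantom)
    pair = fractions_to_counts(fmap, model, seed=seed + 2, budget_scale=budget_scale)
    caudate, putamen = split_nuclei(fmap.striatum)
    if record is None:
        record = SubjectRecord(
            subject_id=f"s{seed}",
            age_months=180.0,
            sex="M",
            race_label="White",
            study_id="study1",
            diagnosis="TD",
        )
    pmap = compute_probability(
        pair, subject_id=record.subject_id, caudate=caudate, putamen=putamen
    )
    rng = np.random.default_rng(seed + 3)
    fa_map = _make_fa_map(fmap, rng, fa_gap=fa_gap)
    total_m = float(pair.counts_matrix.data.sum())
    total_s = float(pair.counts_striosome.data.sum())
    return SimulatedSubject(
        record=record,
        pmap=pmap,
        fraction_map=fmap,
        fa_map=fa_map,
        waytotal_bait_matrix=total_m,
        waytotal_bait_striosome=total_s,
    )


def simulate_cohort(
    n_pairs: int,
    scenario: str | None = None,
    magnitude: float = 0.2,
    seed: int = 0,
    params: PhantomParams = PhantomParams(),
    model: ForwardModel = ForwardModel(),
    case_streamline_deficit: float = 0.10,
    fa_gap: float = 0.042,
) -> SimulatedCohort:
    """Simulate matched case/control pairs under one perturbation scenario.

    Cases receive the scenario perturbation (``scenario=None`` gives a null
    cohort) plus a global streamline-count deficit; controls are
    unperturbed.  All randomness fans out deterministically from `seed`.
    """
    if n_pairs < 2:
        raise ValueError("n_pairs must be >= 2")
    rng = np.random.default_rng(seed)
    demo = _simulate_demographics(n_pairs, rng)
    spec = (
        None
        if scenario is None
        else PerturbationSpec(scenario=scenario, magnitude=magnitude)
    )
    pairs = []
    base = seed * 1_000 % (2**31 - 100_000)
    for i, row in demo.iterrows():
        case_record = SubjectRecord(
            subject_id=f"case_{row.pair_id}",
            age_months=row.case_age_months,
            sex=row.sex,
            race_label=row.race_label,
            study_id=row.study_id,
            diagnosis=row.diagnosis,
            css=row.css if pd.notna(row.css) else None,
        )
        control_record = SubjectRecord(
            subject_id=f"ctrl_{row.pair_id}",
            age_months=row.control_age_months,
            sex=row.sex,
            race_label=row.race_label,
            study_id=row.study_id,
            diagnosis="TD",
        )
        case = simulate_subject(
            seed=base + 10 * i,
            perturbation=spec,
            params=params,
            model=model,
            record=case_record,
            budget_scale=1.0 - case_streamline_deficit,
            fa_gap=fa_gap,
        )
        control = simulate_subject(
            seed=base + 10 * i + 5,
            perturbation=None,
            params=params,
            model=model,
            record=control_record,
            budget_scale=1.0,
            fa_gap=fa_gap,
        )
        pairs.append((case, control))
    return SimulatedCohort(
        pairs=pairs,
        scenario=scenario,
        magnitude=magnitude if scenario else 0.0,
        seed=seed,
        model=model,
        params=params,
        demographics=demo,
    )
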