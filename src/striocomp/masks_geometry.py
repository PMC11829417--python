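"""Equal-volume most-discriminating compartment masks and centroid geometry.

Tractography seeded from masks of unequal size is biased toward the larger
mask, so downstream quantification uses per-subject, per-hemisphere masks of
*equal* voxel count for the two compartments: voxels are accepted in order of
descending own-compartment probability, starting at 1.0, until a preset
target volume (default 83 diffusion voxels) is reached.  If either
compartment has fewer than the target number of qualifying voxels
(p >= bias threshold), both masks are truncated to the smaller count N so the
fairness contract |matrix mask| = |striosome mask| always holds.

Voxel positions are summarized relative to the centroid of the nucleus each
voxel occupies (caudate or putamen, per hemisphere), in physical mm, so that
the placement of a nucleus within the hemisphere cannot leak into
compartment-position statistics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_core import AnalysisConfig, RegionMask
from .parcellation import ProbabilityMap


@dataclass
class EqualVolumeMasks:
    """Volume-matched top-probability masks for the two compartments."""

    matrix_mask: RegionMask
    striosome_mask: RegionMask
    achieved_volume: int
    target_volume: int
    last_accepted_p: dict[str, float]  # probability of last-accepted voxel

    def __post_init__(self) -> None:
        if self.matrix_mask.n_voxels != self.striosome_mask.n_voxels:
            raise ValueError("equal-volume contract violated: mask sizes differ")
        if self.achieved_volume > self.target_volume:
            raise ValueError("achieved volume exceeds target")


def _top_n_mask(p_own: np.ndarray, candidates: np.ndarray, n: int) -> np.ndarray:
    """Boolean mask of the top-n candidate voxels by own-compartment probability.

    Ties are broken by lexicographic (C-order) voxel index, which is the
    order np.argwhere/flat indices produce; deterministic across runs.
    """
    flat_idx = np.flatnonzero(candidates)
    if n == 0 or flat_idx.size == 0:
        return np.zeros(p_own.shape, dtype=bool)
    vals = p_own.flat[flat_idx]
    # stable sort on -p keeps lexicographic index order within ties
    order = np.argsort(-vals, kind="stable")[:n]
    keep = flat_idx[order]
    out = np.zeros(p_own.shape, dtype=bool)
    out.flat[keep] = True
    return out


def build_equal_volume_masks(
    pmap: ProbabilityMap, config: AnalysisConfig
) -> EqualVolumeMasks:
    """Select the top-probability voxels of each compartment at equal volume.

    Qualifying voxels have own-compartment probability >= bias_threshold.
    Acceptance proceeds from probability 1.0 downward until
    min(target, available) voxels are kept; when either compartment falls
    short of the target, both masks are truncated to
    N = min(available_matrix, available_striosome).
    """
    p = pmap.p_matrix.data
    defined = pmap.defined_mask
    thr = config.bias_threshold
    cand_m = defined & (p >= thr)
    cand_s = defined & (1.0 - p >= thr)
    avail_m = int(cand_m.sum())
    avail_s = int(cand_s.sum())
    n = min(config.equal_volume_target, avail_m, avail_s)
    if n == 0:
        warnings.warn(
            "a compartment has zero qualifying voxels; equal-volume masks are empty",
            stacklevel=2,
        )
    mask_m = _top_n_mask(p, cand_m, n)
    mask_s = _top_n_mask(1.0 - p, cand_s, n)
    last_p = {
        "matrix": float(p[mask_m].min()) if n else float("nan"),
        "striosome": float((1.0 - p)[mask_s].min()) if n else float("nan"),
    }
    template = pmap.p_matrix
    return EqualVolumeMasks(
        matrix_mask=RegionMask(template.with_data(mask_m), "matrix_equal_volume"),
        striosome_mask=RegionMask(template.with_data(mask_s), "striosome_equal_volume"),
        achieved_volume=n,
        target_volume=config.equal_volume_target,
        last_accepted_p=last_p,
    )


def equal_volume_tail_fraction(sd: float = 1.5) -> float:
    """Normal-tail fraction behind an equal-volume target derivation.

    Documented helper: the target mask volume corresponds to the probability
    mass of one tail beyond ±`sd` standard deviations of a normal
    distribution (half of the outside-±sd mass).  It is provided for
    transparency only; the default target of 83 voxels is a configuration
    constant, not re-derived from a template segmentation at run time.
    """
    from scipy.stats import norm

    return float(norm.sf(sd))


def centroid_offsets(
    mask: RegionMask,
    nucleus_masks: dict[str, RegionMask],
    compartment: str = "",
) -> pd.DataFrame:
    """Per-voxel (dx, dy, dz) in mm relative to the voxel's own nucleus centroid.

    The centroid of each nucleus is the mean physical center of *all* its
    member voxels (not only mask voxels), so offsets over an entire nucleus
    sum to zero by construction.  Every mask voxel must belong to exactly one
    nucleus.
    """
    grid = mask.grid
    mask_idx = mask.indices
    assigned = np.zeros(len(mask_idx), dtype=bool)
    frames = []
    for name, nucleus in nucleus_masks.items():
        if not grid.same_grid_as(nucleus.grid):
            raise ValueError(f"nucleus {name!r} not on the mask grid")
        member = nucleus.grid.data[tuple(mask_idx.T)]
        overlap = assigned & member
        if overlap.any():
            raise ValueError("nucleus masks overlap on a mask voxel")
        assigned |= member
        if not member.any():
            continue
        centroid = grid.voxel_centers_mm(nucleus.indices).mean(axis=0)
        centers = grid.voxel_centers_mm(mask_idx[member])
        offsets = centers - centroid
        frames.append(
            pd.DataFrame(
                {
                    "nucleus": name,
                    "compartment": compartment,
                    "dx_mm": offsets[:, 0],
                    "dy_mm": offsets[:, 1],
                    "dz_mm": offsets[:, 2],
                }
            )
        )
    if not assigned.all():
        raise ValueError(
            f"{int((~assigned).sum())} mask voxels fall outside all nuclei"
        )
    if not frames:
        return pd.DataFrame(
            columns=["nucleus", "compartment", "dx_mm", "dy_mm", "dz_mm"]
        )
    return pd.concat(frames, ignore_index=True)


def mean_offsets(offsets: pd.DataFrame) -> np.ndarray:
    """Per-axis mean offset (mm) of a voxel-offset table."""
    if len(offsets) == 0:
        return np.full(3, np.nan)
    return offsets[["dx_mm", "dy_mm", "dz_mm"]].mean().to_numpy()


def group_offset_distance(
    mean_offsets_a: np.ndarray, mean_offsets_b: np.ndarray
) -> float:
    """Distance in mm between two mean voxel locations.

    Read as the Euclidean norm of the 3-vector difference between the group
    means (the ÷sqrt(3) per-axis RMS variant is not used; see docs/methods.md).
    """
    a = np.asarray(mean_offsets_a, dtype=float)
    b = np.asarray(mean_offsets_b, dtype=float)
    if a.shape != (3,) or b.shape != (3,):
        raise ValueError("mean offsets must be 3-vectors on the same axis convention")
    return float(np.linalg.norm(a - b))
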