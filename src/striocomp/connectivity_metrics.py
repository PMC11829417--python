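"""Overlap, FA and streamline-count metrics for alternate-explanation checks.

A compartment-volume difference detected by connectivity-based parcellation
could in principle be produced by factors other than tissue composition:
systematically different white-matter microstructure (FA) in one
compartment, or a group-level skew in overall structural connectivity
(streamline counts).  This module provides the three quantities used to
probe those explanations: the Dice similarity coefficient between
compartment-seeded streamline volumes, mean scalar (FA) per equal-volume
compartment mask, and paired case/control streamline-count comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io_core import VolumeGrid
from .masks_geometry import EqualVolumeMasks


@dataclass
class StreamlineVolumePair:
    """Streamline visitation amplitude from the two compartment seeds."""

    projection_from_matrix_seed: VolumeGrid
    projection_from_striosome_seed: VolumeGrid
    amplitude_retention: float = 0.75  # keep uppermost 75% of nonzero voxels

    def __post_init__(self) -> None:
        a = self.projection_from_matrix_seed
        b = self.projection_from_striosome_seed
        if not a.same_grid_as(b):
            raise ValueError("projection volumes are on different grids")
        if (np.asarray(a.data) < 0).any() or (np.asarray(b.data) < 0).any():
            raise ValueError("negative streamline amplitudes")
        if not (0 < self.amplitude_retention <= 1):
            raise ValueError(
                f"amplitude_retention must be in (0, 1], got {self.amplitude_retention}"
            )


@dataclass
class CompartmentScalarSummary:
    """Mean scalar (e.g. FA) within the matrix-like and striosome-like masks."""

    mean_matrix: float
    mean_striosome: float
    subject_id: str = ""

    @property
    def ratio(self) -> float:
        return self.mean_matrix / self.mean_striosome

    @property
    def percent_difference(self) -> float:
        """Matrix mean relative to striosome mean, in percent."""
        return 100.0 * (self.mean_matrix - self.mean_striosome) / self.mean_striosome


def _binarize_top_fraction(data: np.ndarray, retention: float) -> np.ndarray:
    """Keep the top `retention` fraction of nonzero-amplitude voxels by value."""
    nz = data[data > 0]
    if nz.size == 0:
        return np.zeros(data.shape, dtype=bool)
    # the cut leaves the uppermost `retention` of nonzero voxels above it
    cut = np.quantile(nz, 1.0 - retention)
    return data >= np.maximum(cut, np.finfo(float).tiny)


def dice_overlap(pair: StreamlineVolumePair) -> float:
    """Dice similarity coefficient of the two binarized projection volumes.

    DSC = 2|A ∩ B| / (|A| + |B|) after per-volume amplitude thresholding
    that retains the uppermost fraction (default 75%) of nonzero voxels.
    Returns NaN when both volumes are empty after thresholding ("no signal",
    distinct from "no overlap").
    """
    a = _binarize_top_fraction(
        np.asarray(pair.projection_from_matrix_seed.data, dtype=float),
        pair.amplitude_retention,
    )
    b = _binarize_top_fraction(
        np.asarray(pair.projection_from_striosome_seed.data, dtype=float),
        pair.amplitude_retention,
    )
    denom = int(a.sum()) + int(b.sum())
    if denom == 0:
        return float("nan")
    return 2.0 * int((a & b).sum()) / denom


def scalar_by_compartment(
    scalar_map: VolumeGrid, masks: EqualVolumeMasks, subject_id: str = ""
) -> CompartmentScalarSummary:
    """Mean scalar value within each equal-volume compartment mask.

    Only mask voxels with finite scalar values enter the means; the result
    is invariant to voxel visitation order.
    """
    data = np.asarray(scalar_map.data, dtype=float)

    def mask_mean(mask) -> float:
        vals = data[mask.grid.data]
        vals = vals[np.isfinite(vals)]
        if vals.size == 0:
            raise ValueError(f"mask {mask.region_name!r} has no defined scalar voxels")
        return float(vals.mean())

    return CompartmentScalarSummary(
        mean_matrix=mask_mean(masks.matrix_mask),
        mean_striosome=mask_mean(masks.striosome_mask),
        subject_id=subject_id,
    )


def paired_count_comparison(
    counts: pd.DataFrame, direction_col: str = "direction"
) -> pd.DataFrame:
    """Compare paired case/control streamline totals per tractography direction.

    ``counts`` must contain columns pair_id, direction, case_total,
    control_total (long form, one row per pair per direction).  Per
    direction: percent case-vs-control difference, a paired two-tailed
    t-test, and the within-subject matrix:striosome ratio comparison when
    both compartment directions are present.
    """
    required = {"pair_id", direction_col, "case_total", "control_total"}
    missing = required - set(counts.columns)
    if missing:
        raise ValueError(f"count table missing columns: {sorted(missing)}")
    rows = []
    for direction, sub in counts.groupby(direction_col, sort=True):
        if sub["pair_id"].duplicated().any():
            raise ValueError(f"duplicate pair rows for direction {direction!r}")
        case = sub["case_total"].to_numpy(dtype=float)
        ctrl = sub["control_total"].to_numpy(dtype=float)
        diffs = case - ctrl
        p = 1.0 if np.allclose(diffs, 0) else float(stats.ttest_rel(case, ctrl).pvalue)
        rows.append(
            {
                "direction": direction,
                "n_pairs": len(sub),
                "pct_difference": 100.0 * (case.mean() - ctrl.mean()) / ctrl.mean(),
                "t_statistic": (
                    0.0 if np.allclose(diffs, 0) else float(stats.ttest_rel(case, ctrl).statistic)
                ),
                "p_value": p,
            }
        )
    report = pd.DataFrame(rows)

    directions = set(counts[direction_col])
    ratio_pair = {"matrix", "striosome"} & directions
    if ratio_pair == {"matrix", "striosome"}:
        wide_case = counts.pivot(index="pair_id", columns=direction_col, values="case_total")
        wide_ctrl = counts.pivot(index="pair_id", columns=direction_col, values="control_total")
        r_case = (wide_case["matrix"] / wide_case["striosome"]).to_numpy(dtype=float)
        r_ctrl = (wide_ctrl["matrix"] / wide_ctrl["striosome"]).to_numpy(dtype=float)
        diffs = r_case - r_ctrl
        p = 1.0 if np.allclose(diffs, 0) else float(stats.ttest_rel(r_case, r_ctrl).pvalue)
        ratio_row = pd.DataFrame(
            [
                {
                    "direction": "matrix:striosome ratio",
                    "n_pairs": len(r_case),
                    "pct_difference": 100.0 * (r_case.mean() - r_ctrl.mean()) / r_ctrl.mean(),
                    "t_statistic": (
                        0.0 if np.allclose(diffs, 0) else float(stats.ttest_rel(r_case, r_ctrl).statistic)
                    ),
                    "p_value": p,
                }
            ]
        )
        report = pd.concat([report, ratio_row], ignore_index=True)
    return report
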