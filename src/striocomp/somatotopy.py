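"""Leave-one-out somatotopic contribution maps and zone volumetry.

With ten bait regions (five matrix-favoring, five striosome-favoring), the
contribution of a single region to the matrix-like probability map is the
voxelwise difference between the full-roster map and the map recomputed with
that region left out: ``dP = p_full - p_reduced`` for a matrix-favoring
region, and the inverse ``dP = p_reduced - p_full`` for a striosome-favoring
region (the sites where the region most suppresses matrix-like probability).

Each region's somatotopic zone keeps its most-enriched voxels via a
percentile threshold on positive contributions; disjointness across zones is
then enforced by assigning every surviving voxel to the region of maximal
contribution.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io_core import AnalysisConfig, RegionMask, VolumeGrid


MATRIX_FAVORING = "matrix-favoring"
STRIOSOME_FAVORING = "striosome-favoring"

#: the ten-bait roster used throughout; order is the deterministic tie-break
DEFAULT_ROSTER = (
    ("primary_sensory", MATRIX_FAVORING),
    ("vlc_vplo_thalamus", MATRIX_FAVORING),
    ("supplementary_motor", MATRIX_FAVORING),
    ("primary_motor", MATRIX_FAVORING),
    ("globus_pallidus_interna", MATRIX_FAVORING),
    ("mediodorsal_thalamus", STRIOSOME_FAVORING),
    ("posterior_orbitofrontal", STRIOSOME_FAVORING),
    ("anterior_insula", STRIOSOME_FAVORING),
    ("basolateral_amygdala", STRIOSOME_FAVORING),
    ("basal_operculum", STRIOSOME_FAVORING),
)


@dataclass
class ContributionMap:
    """Per-voxel contribution of one left-out bait region."""

    region_name: str
    region_class: str
    delta: VolumeGrid
    striatum: RegionMask
    group: str = "control-average"

    def __post_init__(self) -> None:
        if self.region_class not in (MATRIX_FAVORING, STRIOSOME_FAVORING):
            raise ValueError(f"unknown region class {self.region_class!r}")


@dataclass
class SomatotopicZones:
    """Pairwise-disjoint dominant-region zone masks."""

    zones: dict[str, RegionMask]
    percentile: float
    assignment_rule: str = "argmax contribution after percentile threshold"

    def __post_init__(self) -> None:
        total = 0
        union = None
        for mask in self.zones.values():
            total += mask.n_voxels
            union = mask.grid.data if union is None else union | mask.grid.data
        if union is not None and total != int(union.sum()):
            raise ValueError("zones overlap: sum of zone sizes exceeds union")


def region_contribution(
    p_full: VolumeGrid,
    p_reduced: VolumeGrid,
    region_name: str,
    region_class: str,
    striatum: RegionMask,
    roster: tuple = DEFAULT_ROSTER,
    group: str = "control-average",
) -> ContributionMap:
    """Difference a full-roster map against a leave-one-out map.

    Negative contributions are retained; thresholding happens in
    :func:`threshold_zones`.
    """
    names = {name for name, _ in roster}
    if region_name not in names:
        raise ValueError(f"region {region_name!r} not in the bait roster")
    if not p_full.same_grid_as(p_reduced):
        raise ValueError("full and reduced probability maps are on different grids")
    if region_class == MATRIX_FAVORING:
        delta = p_full.data - p_reduced.data
    elif region_class == STRIOSOME_FAVORING:
        delta = p_reduced.data - p_full.data
    else:
        raise ValueError(f"unknown region class {region_class!r}")
    delta = np.where(striatum.grid.data, delta, 0.0)
    return ContributionMap(
        region_name=region_name,
        region_class=region_class,
        delta=p_full.with_data(delta),
        striatum=striatum,
        group=group,
    )


def threshold_zones(
    contribution_maps: list[ContributionMap], config: AnalysisConfig
) -> SomatotopicZones:
    """Build disjoint somatotopic zones from per-region contribution maps.

    Per region, voxels whose contribution is at or above the configured
    percentile of that region's *positive* contributions survive; each
    surviving voxel is then assigned to the region with the maximal
    contribution there (ties broken by roster order, i.e. list position).
    """
    if not contribution_maps:
        raise ValueError("no contribution maps supplied")
    striatum = contribution_maps[0].striatum
    shape = contribution_maps[0].delta.shape
    survivor_stack = []
    delta_stack = []
    for cmap in contribution_maps:
        d = cmap.delta.data
        pos = d[striatum.grid.data & (d > 0)]
        if pos.size == 0:
            warnings.warn(
                f"region {cmap.region_name!r}: contribution nonpositive everywhere; "
                "zone is empty",
                stacklevel=2,
            )
            survivor_stack.append(np.zeros(shape, dtype=bool))
        else:
            cut = np.percentile(pos, config.zone_percentile)
            survivor_stack.append(striatum.grid.data & (d >= cut) & (d > 0))
        delta_stack.append(d)
    deltas = np.stack(delta_stack)  # (R, X, Y, Z)
    survivors = np.stack(survivor_stack)
    # argmax over regions; earlier roster position wins ties automatically
    masked = np.where(survivors, deltas, -np.inf)
    any_survivor = survivors.any(axis=0)
    winner = np.argmax(masked, axis=0)
    zones = {}
    template = contribution_maps[0].delta
    for i, cmap in enumerate(contribution_maps):
        zone = any_survivor & (winner == i)
        zones[cmap.region_name] = RegionMask(
            template.with_data(zone), f"zone_{cmap.region_name}"
        )
    return SomatotopicZones(zones=zones, percentile=config.zone_percentile)


def zone_volumetry(
    zones: SomatotopicZones,
    pmaps_case: list,
    pmaps_control: list,
    config: AnalysisConfig,
) -> pd.DataFrame:
    """Per-zone matrix-like volume (p >= high threshold), case vs control.

    Zones are fixed (derived from a control-group average) before volumetry.
    Case volume is normalized to the control cohort mean (control = 100%);
    the paired two-tailed t-test p-value per zone feeds the fourth test
    family of the cohort statistics module.  Cohorts must be paired: list
    position i of the case maps corresponds to position i of the controls.
    """
    if len(pmaps_case) != len(pmaps_control):
        raise ValueError("case and control cohorts are unpaired (length mismatch)")
    rows = []
    for name, zone in zones.zones.items():
        if zone.n_voxels == 0:
            warnings.warn(f"zone {name!r} is empty; volumetry row is NaN", stacklevel=2)
            rows.append(
                {
                    "zone": name,
                    "zone_voxels": 0,
                    "mean_case": np.nan,
                    "mean_control": np.nan,
                    "normalized_case_pct": np.nan,
                    "p_value": np.nan,
                }
            )
            continue
        zmask = zone.grid.data

        def vol(pmap) -> int:
            p = pmap.p_matrix.data
            return int(((p >= config.high_threshold) & zmask & pmap.defined_mask).sum())

        case_v = np.array([vol(pm) for pm in pmaps_case], dtype=float)
        ctrl_v = np.array([vol(pm) for pm in pmaps_control], dtype=float)
        diffs = case_v - ctrl_v
        if np.allclose(diffs, 0):
            p_val = 1.0
        else:
            p_val = float(stats.ttest_rel(case_v, ctrl_v).pvalue)
        mean_ctrl = float(ctrl_v.mean())
        rows.append(
            {
                "zone": name,
                "zone_voxels": zone.n_voxels,
                "mean_case": float(case_v.mean()),
                "mean_control": mean_ctrl,
                "normalized_case_pct": (
                    100.0 * case_v.mean() / mean_ctrl if mean_ctrl > 0 else np.nan
                ),
                "p_value": p_val,
            }
        )
    return pd.DataFrame(rows)
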