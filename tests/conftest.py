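"""Shared fixtures: configs and small hand-built probability maps."""

import numpy as np
import pytest

from striocomp.io_core import CANONICAL_AXES, AnalysisConfig, RegionMask, VolumeGrid
from striocomp.parcellation import CountPair, ProbabilityMap, compute_probability


@pytest.fixture
def config() -> AnalysisConfig:
    return AnalysisConfig()


def make_grid(data, voxel=2.0, origin=None):
    data = np.asarray(data)
    if origin is None:
        origin = (0.0, 0.0, 0.0)
    return VolumeGrid(
        data=data,
        voxel_size_mm=(voxel,) * 3,
        origin=origin,
        axis_labels=CANONICAL_AXES,
    )


def pmap_from_values(values, subject_id="toy", with_nuclei=False):
    """Probability map over a flat line of striatal voxels with given p values.

    Values may include np.nan to mark undefined (zero-count) voxels.
    """
    values = np.asarray(values, dtype=float)
    n = values.size
    shape = (n, 1, 1)
    striatum = np.ones(shape, dtype=bool)
    undefined = np.isnan(values).reshape(shape)
    p = np.nan_to_num(values).reshape(shape)
    caudate = putamen = None
    if with_nuclei:
        cau = np.zeros(shape, dtype=bool)
        cau[: n // 2] = True
        caudate = RegionMask(make_grid(cau), "caudate")
        putamen = RegionMask(make_grid(striatum & ~cau), "putamen")
    return ProbabilityMap(
        p_matrix=make_grid(p),
        striatum=RegionMask(make_grid(striatum), "striatum"),
        caudate=caudate,
        putamen=putamen,
        undefined=undefined,
        subject_id=subject_id,
    )


def pmap_from_counts(counts_matrix, counts_striosome):
    cm = np.asarray(counts_matrix, dtype=float).reshape(-1, 1, 1)
    cs = np.asarray(counts_striosome, dtype=float).reshape(-1, 1, 1)
    striatum = RegionMask(make_grid(np.ones(cm.shape, dtype=bool)), "striatum")
    pair = CountPair(
        counts_matrix=make_grid(cm),
        counts_striosome=make_grid(cs),
        striatum=striatum,
    )
    return compute_probability(pair)
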