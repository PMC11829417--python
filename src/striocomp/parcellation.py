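"""Connection probabilities, compartment classification, volumetry, histograms.

Classification-targets tractography assigns every striatal voxel a single
probability ``p_matrix`` in [0, 1] of connecting to the matrix-favoring
composite target (``p_striosome = 1 - p_matrix``).  Voxels with
``p_matrix >= bias_threshold`` are matrix-like, voxels with
``p_matrix <= 1 - bias_threshold`` are striosome-like, and voxels strictly
inside the symmetric band around 0.5 are indeterminate.  The band endpoints
belong to the biased classes, keeping the three classes disjoint.

Voxels whose two streamline counts are both zero carry no connectivity
evidence; they are flagged undefined and excluded from every denominator
rather than imputed.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import IntEnum

import numpy as np
import pandas as pd

from .io_core import AnalysisConfig, RegionMask, VolumeGrid, validate_nucleus_partition


class Label(IntEnum):
    """Voxel classes of a striatal parcellation (stored as an integer map)."""

    OUTSIDE = 0
    MATRIX_LIKE = 1
    STRIOSOME_LIKE = 2
    INDETERMINATE = 3
    UNDEFINED = 4


@dataclass
class CountPair:
    """Path-length-corrected streamline counts toward the two composite targets."""

    counts_matrix: VolumeGrid
    counts_striosome: VolumeGrid
    striatum: RegionMask

    def __post_init__(self) -> None:
        if not self.counts_matrix.same_grid_as(self.counts_striosome):
            raise ValueError("count volumes are not on the same grid")
        if not self.counts_matrix.same_grid_as(self.striatum.grid):
            raise ValueError("counts and striatal mask are not on the same grid")
        for name, grid in (
            ("counts_matrix", self.counts_matrix),
            ("counts_striosome", self.counts_striosome),
        ):
            if (np.asarray(grid.data) < 0).any():
                raise ValueError(f"{name} contains negative streamline counts")
        if self.striatum.n_voxels == 0:
            raise ValueError("striatal mask is empty")


@dataclass
class ProbabilityMap:
    """Per-voxel probability of matrix-favoring connectivity inside the striatum."""

    p_matrix: VolumeGrid
    striatum: RegionMask
    caudate: RegionMask | None = None
    putamen: RegionMask | None = None
    undefined: np.ndarray | None = None  # boolean, zero-total-count voxels
    subject_id: str = ""
    hemisphere: str = ""

    def __post_init__(self) -> None:
        if self.undefined is None:
            self.undefined = np.zeros(self.p_matrix.shape, dtype=bool)
        inside = self.striatum.grid.data & ~self.undefined
        p = self.p_matrix.data[inside]
        if p.size and (p.min() < 0 or p.max() > 1):
            raise ValueError("probabilities outside [0, 1] inside the striatal mask")
        if self.caudate is not None and self.putamen is not None:
            validate_nucleus_partition(self.striatum, self.caudate, self.putamen)

    @property
    def defined_mask(self) -> np.ndarray:
        return self.striatum.grid.data & ~self.undefined

    def nucleus_mask(self, nucleus: str) -> np.ndarray:
        if nucleus == "striatum":
            return self.striatum.grid.data
        if nucleus == "caudate":
            if self.caudate is None:
                raise ValueError("no caudate mask attached")
            return self.caudate.grid.data
        if nucleus == "putamen":
            if self.putamen is None:
                raise ValueError("no putamen mask attached")
            return self.putamen.grid.data
        raise ValueError(f"unknown nucleus {nucleus!r}")


@dataclass
class Parcellation:
    """Integer label map over the striatum plus the thresholds that made it."""

    labels: VolumeGrid
    bias_threshold: float
    indeterminate_band: tuple[float, float]
    subject_id: str = ""

    def count(self, label: Label) -> int:
        return int((self.labels.data == label).sum())

    def counts(self) -> dict[str, int]:
        return {lab.name.lower(): self.count(lab) for lab in Label if lab != Label.OUTSIDE}


@dataclass
class HistogramTable:
    """Voxel counts in fixed-width probability bins over the biased range."""

    compartment: str
    bin_edges: np.ndarray
    counts: np.ndarray
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if len(self.counts) != len(self.bin_edges) - 1:
            raise ValueError("counts/bin_edges length mismatch")

    @property
    def n_bins(self) -> int:
        return len(self.counts)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "compartment": self.compartment,
                "bin_left": self.bin_edges[:-1],
                "bin_right": self.bin_edges[1:],
                "count": self.counts,
                "subject_id": self.subject_id,
            }
        )


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def compute_probability(
    pair: CountPair, subject_id: str = "", hemisphere: str = "",
    caudate: RegionMask | None = None, putamen: RegionMask | None = None,
) -> ProbabilityMap:
    """Convert a pair of streamline-count volumes into a probability map.

    ``p_matrix = counts_matrix / (counts_matrix + counts_striosome)`` per
    striatal voxel.  The ratio construction bounds p in [0, 1]; no post-hoc
    clipping is applied.  Zero-total voxels are flagged undefined.
    """
    cm = np.asarray(pair.counts_matrix.data, dtype=float)
    cs = np.asarray(pair.counts_striosome.data, dtype=float)
    striatum = pair.striatum.grid.data
    total = cm + cs
    undefined = striatum & (total == 0)
    p = np.zeros_like(cm)
    valid = striatum & (total > 0)
    p[valid] = cm[valid] / total[valid]
    return ProbabilityMap(
        p_matrix=pair.counts_matrix.with_data(p),
        striatum=pair.striatum,
        caudate=caudate,
        putamen=putamen,
        undefined=undefined,
        subject_id=subject_id,
        hemisphere=hemisphere,
    )


def classify(pmap: ProbabilityMap, config: AnalysisConfig) -> Parcellation:
    """Label every striatal voxel matrix-like / striosome-like / indeterminate.

    Matrix-like iff ``p >= bias_threshold``; striosome-like iff
    ``p <= 1 - bias_threshold``; indeterminate on the open interval between;
    undefined voxels stay undefined.
    """
    p = pmap.p_matrix.data
    striatum = pmap.striatum.grid.data
    labels = np.zeros(p.shape, dtype=np.uint8)
    eps = 1e-9  # 1 - 0.55 is not exactly 0.45 in floating point
    hi = config.bias_threshold - eps
    lo = 1.0 - config.bias_threshold + eps
    defined = pmap.defined_mask
    labels[defined & (p >= hi)] = Label.MATRIX_LIKE
    labels[defined & (p <= lo)] = Label.STRIOSOME_LIKE
    labels[defined & (p > lo) & (p < hi)] = Label.INDETERMINATE
    labels[striatum & pmap.undefined] = Label.UNDEFINED
    return Parcellation(
        labels=pmap.p_matrix.with_data(labels),
        bias_threshold=config.bias_threshold,
        indeterminate_band=config.indeterminate_band,
        subject_id=pmap.subject_id,
    )


def compartment_volumes(
    pmap: ProbabilityMap,
    thresholds: tuple[float, ...] = (0.95, 0.55),
    nuclei: tuple[str, ...] = ("striatum", "caudate", "putamen"),
) -> pd.DataFrame:
    """Voxel counts per compartment x probability threshold x nucleus.

    For each threshold t, matrix-like volume counts voxels with ``p >= t``
    and striosome-like volume counts voxels with ``p <= 1 - t``.  The
    within-subject difference M-S is reported per threshold and nucleus.
    Undefined voxels never enter a count.
    """
    for t in thresholds:
        if not (0.5 < t <= 1.0):
            raise ValueError(f"threshold {t} outside (0.5, 1.0]")
    if pmap.caudate is None or pmap.putamen is None:
        nuclei = tuple(n for n in nuclei if n == "striatum")
    p = pmap.p_matrix.data
    defined = pmap.defined_mask
    rows = []
    for nucleus in nuclei:
        region = pmap.nucleus_mask(nucleus) & defined
        pr = p[region]
        eps = 1e-9
        for t in thresholds:
            m = int((pr >= t - eps).sum())
            s = int((pr <= 1.0 - t + eps).sum())
            rows.append(
                {
                    "subject_id": pmap.subject_id,
                    "nucleus": nucleus,
                    "threshold": t,
                    "matrix_like": m,
                    "striosome_like": s,
                    "m_minus_s": m - s,
                }
            )
    return pd.DataFrame(rows)


def biased_bin_edges(config: AnalysisConfig) -> np.ndarray:
    """Edges of the fixed-width bins spanning [bias_threshold, 1.0]."""
    n = config.n_biased_bins
    return config.bias_threshold + config.histogram_bin_width * np.arange(n + 1)


def probability_histogram(
    pmap: ProbabilityMap, compartment: str, config: AnalysisConfig
) -> HistogramTable:
    """Histogram a compartment's own-class probabilities over the biased range.

    Bins are left-closed/right-open except the final bin, which is closed on
    the right so that probability 1.0 is counted.  Totals equal the
    compartment's biased-voxel count at the minimum classification threshold.
    """
    if compartment not in ("matrix", "striosome"):
        raise ValueError(f"compartment must be 'matrix' or 'striosome', got {compartment!r}")
    p = pmap.p_matrix.data[pmap.defined_mask]
    own = p if compartment == "matrix" else 1.0 - p
    own = own[own >= config.bias_threshold]
    edges = biased_bin_edges(config)
    # np.histogram's final bin is already closed on the right
    counts, _ = np.histogram(own, bins=edges)
    return HistogramTable(
        compartment=compartment,
        bin_edges=edges,
        counts=counts,
        subject_id=pmap.subject_id,
    )


def full_range_histogram(pmap: ProbabilityMap, n_bins: int = 100) -> HistogramTable:
    """100-bin histogram of p_matrix over [0, 1] (fslstats-style variant)."""
    p = pmap.p_matrix.data[pmap.defined_mask]
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    counts, _ = np.histogram(p, bins=edges)
    return HistogramTable(
        compartment="matrix_full_range",
        bin_edges=edges,
        counts=counts,
        subject_id=pmap.subject_id,
    )
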