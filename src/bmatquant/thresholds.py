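"""HU histograms, per-voxel ROC analysis and diagnostic cutpoint derivation.

The diagnostic question is whether a marrow voxel is fat (yellow marrow,
BMAT) or haematopoietic (red marrow, RM). Fat attenuates less than water, so
the positive (BMAT) class is the *low*-HU class and the classification rule
is oriented as ``predict positive iff HU < t``. Under that rule sensitivity
is non-decreasing and specificity non-increasing as the threshold ``t``
rises.

The optimal cutpoint maximizes Youden's J = sensitivity + specificity - 1
(the standard reading of "greatest sensitivity and specificity"); a
closest-to-(0,1) criterion is available as an alternative. Ties are broken
toward the lowest threshold, which favors specificity for the fat class.
For two equal-variance Gaussian classes the analytic Youden optimum is the
midpoint of the class means — the property the default phantom distributions
are built around (115 HU for fat vs red marrow, 300 HU for red marrow vs
bone).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from bmatquant.errors import ConfigurationError, EmptyRegionError
from bmatquant.volumes import VOIMask, VoxelVolume, validate_alignment

__all__ = [
    "DEFAULT_HU_RANGE",
    "HUHistogram",
    "CohortHistogramSummary",
    "ROCCurve",
    "ThresholdScheme",
    "extract_voi_hu",
    "build_histogram",
    "summarize_cohort",
    "compute_roc",
    "optimal_threshold",
]

#: Default histogram/ROC range in integer HU.
DEFAULT_HU_RANGE = (-500, 1500)


def extract_voi_hu(ct: VoxelVolume, mask: VOIMask, region: str) -> np.ndarray:
    """Return the multiset of integer HU at voxels labeled ``region``.

    Alignment between volume and mask is validated first; an empty region is
    an error (a VOI that selects nothing is a drawing mistake, not data).
    """
    validate_alignment(ct, mask)
    idx = mask.region_indices(region)
    if idx.size == 0:
        raise EmptyRegionError(f"region {region!r} contains no voxels")
    return np.asarray(ct.values.ravel()[idx], dtype=np.int64)


@dataclass
class HUHistogram:
    """1-HU-wide histogram of a voxel HU sample over a fixed integer range.

    ``values`` are the integer HU bin centers ``lo..hi`` inclusive; in-range
    counts plus ``out_of_range_count`` equal ``total_voxels``.
    """

    values: np.ndarray  # integer HU bin centers
    counts: np.ndarray
    out_of_range_count: int
    total_voxels: int
    region: str = ""

    @property
    def proportions(self) -> np.ndarray:
        """Per-bin proportion of all sampled voxels (in- and out-of-range)."""
        return self.counts / self.total_voxels

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"hu": self.values, "count": self.counts})


def build_histogram(
    sample: np.ndarray,
    hu_range: tuple[int, int] = DEFAULT_HU_RANGE,
    region: str = "",
) -> HUHistogram:
    """Bin an integer HU sample into 1-HU bins over ``hu_range`` (inclusive).

    Values outside the range are excluded from the bins but tallied in
    ``out_of_range_count`` so voxel totals are conserved.
    """
    sample = np.asarray(sample)
    if sample.size == 0:
        raise EmptyRegionError("cannot histogram an empty HU sample")
    sample = sample.astype(np.int64)
    lo, hi = int(hu_range[0]), int(hu_range[1])
    if hi <= lo:
        raise ConfigurationError(f"invalid HU range {hu_range}")
    in_range = (sample >= lo) & (sample <= hi)
    counts = np.bincount(sample[in_range] - lo, minlength=hi - lo + 1)
    return HUHistogram(
        values=np.arange(lo, hi + 1, dtype=np.int64),
        counts=counts,
        out_of_range_count=int(sample.size - in_range.sum()),
        total_voxels=int(sample.size),
        region=region,
    )


@dataclass
class CohortHistogramSummary:
    """Across-subject mean and SEM of per-bin HU proportions.

    Each subject's histogram is normalized by its own voxel total first, so
    subjects with different VOI sizes contribute equally.
    """

    values: np.ndarray
    mean_proportion: np.ndarray
    sem: np.ndarray
    n_subjects: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"hu": self.values, "mean_proportion": self.mean_proportion, "sem": self.sem}
        )


def summarize_cohort(histograms: list[HUHistogram]) -> CohortHistogramSummary:
    """Summarize per-subject histograms as mean +/- SEM per bin."""
    if len(histograms) < 2:
        raise ConfigurationError("cohort summary needs at least 2 subjects (SEM undefined for 1)")
    ref = histograms[0].values
    for h in histograms[1:]:
        if h.values.shape != ref.shape or not np.array_equal(h.values, ref):
            raise ConfigurationError("histograms have mismatched bin grids")
    props = np.vstack([h.proportions for h in histograms])
    n = len(histograms)
    sd = props.std(axis=0, ddof=1)
    return CohortHistogramSummary(
        values=ref.copy(),
        mean_proportion=props.mean(axis=0),
        sem=sd / np.sqrt(n),
        n_subjects=n,
    )


@dataclass
class ROCCurve:
    """ROC over an ascending integer-HU threshold grid.

    At threshold ``t``: sensitivity = P(HU_pos < t), specificity =
    P(HU_neg >= t); ``youden_j = sensitivity + specificity - 1``. The AUC is
    the trapezoid area over the (1 - specificity, sensitivity) curve, which
    on a grid covering the full data range equals the Mann-Whitney estimate
    P(pos < neg) + 0.5 P(tie).
    """

    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    n_pos: int
    n_neg: int

    @property
    def youden_j(self) -> np.ndarray:
        return self.sensitivity + self.specificity - 1.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "threshold_hu": self.thresholds,
                "sensitivity": self.sensitivity,
                "specificity": self.specificity,
                "youden_j": self.youden_j,
            }
        )


def compute_roc(
    pos_sample: np.ndarray,
    neg_sample: np.ndarray,
    threshold_grid: np.ndarray | None = None,
) -> ROCCurve:
    """ROC between a positive (low-HU, fat) and negative (high-HU) voxel class.

    Parameters
    ----------
    pos_sample, neg_sample
        Integer HU samples; the rule ``positive iff HU < t`` is applied at
        every grid threshold.
    threshold_grid
        Ascending integer thresholds. Default: every integer from the pooled
        minimum to the pooled maximum + 1, so the curve spans (0,0) to (1,1).
    """
    pos = np.asarray(pos_sample, dtype=np.int64).ravel()
    neg = np.asarray(neg_sample, dtype=np.int64).ravel()
    if pos.size == 0 or neg.size == 0:
        raise EmptyRegionError("both ROC classes must be non-empty")
    if threshold_grid is None:
        lo = int(min(pos.min(), neg.min()))
        hi = int(max(pos.max(), neg.max()))
        grid = np.arange(lo, hi + 2, dtype=np.int64)
    else:
        grid = np.asarray(threshold_grid, dtype=np.int64).ravel()
        if grid.size == 0 or np.any(np.diff(grid) <= 0):
            raise ConfigurationError("threshold grid must be non-empty and strictly ascending")

    pos_sorted = np.sort(pos)
    neg_sorted = np.sort(neg)
    # count of values < t via binary search on the sorted samples
    sens = np.searchsorted(pos_sorted, grid, side="left") / pos.size
    neg_below = np.searchsorted(neg_sorted, grid, side="left")
    spec = (neg.size - neg_below) / neg.size  # exact count ratio, not 1 - fpr
    auc = float(np.trapezoid(sens, neg_below / neg.size))
    return ROCCurve(
        thresholds=grid,
        sensitivity=sens,
        specificity=spec,
        auc=auc,
        n_pos=int(pos.size),
        n_neg=int(neg.size),
    )


def optimal_threshold(roc: ROCCurve, criterion: str = "youden") -> int:
    """Optimal integer cutpoint of a ROC curve.

    ``youden`` (default) maximizes J = sens + spec - 1; ``closest_topleft``
    minimizes the Euclidean distance to the perfect classifier (0, 1) in ROC
    space. Ties are broken toward the lowest threshold.
    """
    if criterion == "youden":
        score = roc.youden_j
        best = int(np.argmax(score))  # argmax returns first (lowest) maximizer
    elif criterion == "closest_topleft":
        d2 = (1.0 - roc.specificity) ** 2 + (1.0 - roc.sensitivity) ** 2
        best = int(np.argmin(d2))
    else:
        raise ConfigurationError(f"unknown criterion {criterion!r}")
    return int(roc.thresholds[best])


@dataclass(frozen=True)
class ThresholdScheme:
    """Diagnostic HU cutpoints partitioning marrow-VOI voxels.

    Defaults are the clinical scheme: voxels in [-200, 115) HU are yellow
    marrow (BMAT), [115, 300] red marrow, above 300 bone; below -200 is
    out of range (air/artefact).
    """

    yellow_low: int = -200
    bmat_rm: int = 115
    rm_bone: int = 300

    def __post_init__(self) -> None:
        if not self.yellow_low < self.bmat_rm < self.rm_bone:
            raise ConfigurationError(
                f"thresholds must satisfy yellow_low < bmat_rm < rm_bone, got "
                f"({self.yellow_low}, {self.bmat_rm}, {self.rm_bone})"
            )

    def to_dict(self) -> dict[str, int]:
        return {
            "yellow_low": int(self.yellow_low),
            "bmat_rm": int(self.bmat_rm),
            "rm_bone": int(self.rm_bone),
        }
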