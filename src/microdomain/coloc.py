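"""Threshold-based colocalization metrics.

Mander's coefficients quantify fractional signal overlap between two
channels: M1 is the fraction of channel-A intensity (background-subtracted,
floored at zero) that lies in pixels where channel B is above its
threshold, and M2 the symmetric quantity. Both range from 0 (no overlap)
to 1 (complete overlap). The companion area metric is |A ∩ B| / |A| on the
binary masks, and the masked-intensity fraction is the fraction of a
channel's total (cellular) intensity falling inside a reference mask, as
used to measure the share of a protein residing in marker-positive
junctions.

Thresholds follow an explicit rule rather than manual adjustment: k times
the mean of the background-subtracted image (k = 1.5 for a puncta channel,
1.0 for a reference channel that should be segmented in full), or an
absolute value. Background is the field median per channel. All metrics
are invariant to multiplying a channel by a positive constant when the
relative (k-times-mean) threshold mode is used.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .core import ImageField, ParameterError

__all__ = [
    "ThresholdSpec",
    "ColocResult",
    "threshold_mask",
    "manders_coefficients",
    "overlap_area_fraction",
    "masked_intensity_fraction",
]


@dataclass(frozen=True)
class ThresholdSpec:
    """Thresholding rule for one channel.

    ``k_times_mean``: threshold = k * mean of the background-subtracted,
    zero-floored image. ``absolute``: threshold = ``value`` (applied after
    background subtraction).
    """

    mode: str = "k_times_mean"
    k: float = 1.5
    value: float = 0.0

    def __post_init__(self) -> None:
        if self.mode not in ("k_times_mean", "absolute"):
            raise ParameterError("mode must be 'k_times_mean' or 'absolute'")
        if not (self.k > 0):
            raise ParameterError("k must be positive")


@dataclass
class ColocResult:
    """Mander's coefficients and overlap-area fractions for a channel pair.

    ``m1`` is the fraction of A's above-threshold intensity in B's mask;
    ``m2`` the converse. ``undefined`` flags an empty above-threshold set
    in one of the channels, in which case the affected metrics are NaN.
    """

    m1: float
    m2: float
    overlap_area_fraction_AonB: float
    overlap_area_fraction_BonA: float
    thresholds_used: tuple[float, float]
    undefined: bool = False

    def summary(self) -> str:
        return "\n".join(
            [
                "Colocalization metrics",
                "----------------------",
                f"M1 (A in B-mask)        : {self.m1:.4f}",
                f"M2 (B in A-mask)        : {self.m2:.4f}",
                f"area overlap |A∩B|/|A|  : {self.overlap_area_fraction_AonB:.4f}",
                f"area overlap |A∩B|/|B|  : {self.overlap_area_fraction_BonA:.4f}",
                f"thresholds (A, B)       : {self.thresholds_used[0]:.2f}, "
                f"{self.thresholds_used[1]:.2f}",
            ]
            + (["note: one channel had an empty mask"] if self.undefined else [])
        )


def _subtract_background(image: ImageField) -> np.ndarray:
    """Median-background-subtracted intensities, floored at zero."""
    px = image.pixels
    return np.clip(px - float(np.median(px)), 0.0, None)


def threshold_mask(
    image: ImageField, spec: Optional[ThresholdSpec] = None
) -> tuple[np.ndarray, float]:
    """Binary mask of pixels above the channel threshold.

    Returns ``(mask, threshold)``. The comparison is strict, so a channel
    with no signal above its (possibly zero) threshold yields an empty
    mask; that case is warned about.
    """
    if spec is None:
        spec = ThresholdSpec()
    pos = _subtract_background(image)
    if spec.mode == "k_times_mean":
        thr = spec.k * float(pos.mean())
    else:
        thr = float(spec.value)
    mask = pos > thr
    if not mask.any():
        warnings.warn("threshold produced an empty mask", stacklevel=2)
    return mask, thr


def manders_coefficients(
    chA: ImageField,
    chB: ImageField,
    specA: Optional[ThresholdSpec] = None,
    specB: Optional[ThresholdSpec] = None,
) -> ColocResult:
    """Mander's M1/M2 plus overlap-area fractions for two channels.

    M1 = sum of A over B-above-threshold pixels / sum of A over
    A-above-threshold pixels (intensities background-subtracted and floored
    at zero); M2 symmetric. Raises on shape mismatch; an empty mask flags
    the result as undefined rather than raising.
    """
    if chA.shape != chB.shape:
        raise ParameterError("channels must have equal shape")
    a = _subtract_background(chA)
    b = _subtract_background(chB)
    mask_a, thr_a = threshold_mask(chA, specA)
    mask_b, thr_b = threshold_mask(chB, specB)

    sum_a = float(a[mask_a].sum())
    sum_b = float(b[mask_b].sum())
    undefined = (not mask_a.any()) or (not mask_b.any()) or sum_a == 0 or sum_b == 0
    if undefined:
        nan = float("nan")
        return ColocResult(nan, nan, nan, nan, (thr_a, thr_b), undefined=True)

    m1 = float(a[mask_a & mask_b].sum()) / sum_a
    m2 = float(b[mask_a & mask_b].sum()) / sum_b
    inter = float((mask_a & mask_b).sum())
    return ColocResult(
        m1=m1,
        m2=m2,
        overlap_area_fraction_AonB=inter / float(mask_a.sum()),
        overlap_area_fraction_BonA=inter / float(mask_b.sum()),
        thresholds_used=(thr_a, thr_b),
    )


def overlap_area_fraction(maskA: np.ndarray, maskB: np.ndarray) -> float:
    """|A ∩ B| / |A| for two binary masks; NaN (with warning) if |A| = 0."""
    maskA = np.asarray(maskA, dtype=bool)
    maskB = np.asarray(maskB, dtype=bool)
    if maskA.shape != maskB.shape:
        raise ParameterError("masks must have equal shape")
    denom = int(maskA.sum())
    if denom == 0:
        warnings.warn("overlap fraction undefined for an empty reference mask", stacklevel=2)
        return float("nan")
    return float((maskA & maskB).sum()) / denom


def masked_intensity_fraction(
    image: ImageField, mask: np.ndarray, cell_mask: Optional[np.ndarray] = None
) -> float:
    """Fraction of (cellular) intensity inside a reference mask.

    Background-subtracted, zero-floored intensity summed inside ``mask``
    divided by the sum inside ``cell_mask`` (the whole field when absent).
    Raises on a zero denominator.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != image.shape:
        raise ParameterError("mask must match the image shape")
    pos = _subtract_background(image)
    if cell_mask is None:
        denom = float(pos.sum())
    else:
        cell_mask = np.asarray(cell_mask, dtype=bool)
        if cell_mask.shape != image.shape:
            raise ParameterError("cell_mask must match the image shape")
        denom = float(pos[cell_mask].sum())
    if denom <= 0:
        raise ParameterError("total intensity in the normalization region is zero")
    return float(pos[mask].sum()) / denom
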