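"""Spatial overlap between feature distributions: Sørensen–Dice and trimming.

Two frequency matrices are compared on their *supports* -- the sets of
canvas pixels where the count reaches a threshold -- using the
Sørensen–Dice coefficient ``2|A ∩ B| / (|A| + |B|)``.  Two variants are
reported:

* **absolute**: support = every pixel with at least one count, so the
  coefficient reflects everywhere either feature was ever seen;
* **trimmed**: each matrix is first thresholded at the level that best
  approximates the median of its cumulative frequency distribution, i.e.
  the threshold retaining closest to half of the matrix's total mass, so
  sporadic low-frequency locations are discarded and only each feature's
  core territory is compared.

A two-colour overlay image (feature A blue, feature B red, overlap white)
visualises either variant.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Literal

import numpy as np

from .aggregation import FrequencyMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "SupportSet",
    "support_set",
    "dice",
    "trim_threshold",
    "dice_trimmed",
    "overlay",
    "DiceReport",
    "compare",
]

TrimStatistic = Literal["mass", "pixels"]


@dataclass(frozen=True)
class SupportSet:
    """Boolean canvas of pixels whose count reaches a threshold."""

    pixels: np.ndarray  # bool, canvas x canvas
    threshold: int
    feature_label: str

    @property
    def size(self) -> int:
        return int(self.pixels.sum())


def support_set(fm: FrequencyMatrix, threshold: int = 1) -> SupportSet:
    if threshold < 1:
        raise ValueError("threshold must be >= 1")
    return SupportSet(
        pixels=fm.counts >= threshold,
        threshold=threshold,
        feature_label=fm.feature_label,
    )


def dice(a: SupportSet, b: SupportSet) -> float:
    """Sørensen–Dice coefficient of two pixel supports.

    Defined as 0 (with a warning) when both supports are empty.
    """
    if a.pixels.shape != b.pixels.shape:
        raise ValueError("supports must share a canvas")
    na, nb = a.size, b.size
    if na == 0 and nb == 0:
        warnings.warn("Dice of two empty supports defined as 0", stacklevel=2)
        return 0.0
    inter = int((a.pixels & b.pixels).sum())
    return 2.0 * inter / (na + nb)


def trim_threshold(fm: FrequencyMatrix, statistic: TrimStatistic = "mass") -> int:
    """Threshold retaining closest to half the cumulative frequency.

    For every candidate ``t`` in ``1..max_count`` the retained quantity is

    * ``mass`` (default): ``R(t) = sum of counts v with v >= t``;
    * ``pixels``: ``R(t) = number of pixels with v >= t``;

    and the returned threshold minimises ``|R(t) - R(1) / 2|``, ties broken
    toward the smaller ``t`` (retaining more data).  Exhaustive search over
    the (at most ``max_count``) candidates is exact and cheap because only
    the distinct nonzero values matter.
    """
    values = fm.counts[fm.counts > 0]
    if values.size == 0:
        raise ValueError("cannot trim an all-zero frequency matrix")
    if statistic not in ("mass", "pixels"):
        raise ValueError(f"unknown trim statistic {statistic!r}")
    max_count = int(values.max())
    ts = np.arange(1, max_count + 1)
    # R(t) via a reverse cumulative histogram of the nonzero values.
    hist = np.bincount(values.astype(np.int64), minlength=max_count + 1)[1:]
    if statistic == "pixels":
        retained = hist[::-1].cumsum()[::-1].astype(np.float64)
    else:
        mass_per_value = hist * np.arange(1, max_count + 1, dtype=np.int64)
        retained = mass_per_value[::-1].cumsum()[::-1].astype(np.float64)
    target = retained[0] / 2.0
    best = int(ts[np.argmin(np.abs(retained - target))])  # argmin takes first tie
    return best


def dice_trimmed(
    fa: FrequencyMatrix,
    fb: FrequencyMatrix,
    statistic: TrimStatistic = "mass",
    shared_threshold: bool = False,
) -> float:
    """Dice of the supports after trimming each matrix at its own threshold.

    With ``shared_threshold`` the larger of the two thresholds is applied
    to both matrices instead.
    """
    ta = trim_threshold(fa, statistic)
    tb = trim_threshold(fb, statistic)
    if shared_threshold:
        ta = tb = max(ta, tb)
    return dice(support_set(fa, ta), support_set(fb, tb))


def overlay(
    fa: FrequencyMatrix, fb: FrequencyMatrix, trimmed: bool = False,
    statistic: TrimStatistic = "mass",
) -> np.ndarray:
    """Two-colour overlap image: only-A blue, only-B red, both white.

    Returns an (H, W, 3) uint8 RGB array; background stays black.  With
    ``trimmed`` the thresholded supports are shown instead of the absolute
    ones (an all-zero matrix contributes an empty support either way).
    """
    if fa.counts.shape != fb.counts.shape:
        raise ValueError("matrices must share a canvas")

    def _sup(fm: FrequencyMatrix) -> np.ndarray:
        if fm.total_mass == 0:
            return np.zeros(fm.counts.shape, dtype=bool)
        t = trim_threshold(fm, statistic) if trimmed else 1
        return fm.counts >= t

    sa, sb = _sup(fa), _sup(fb)
    img = np.zeros(fa.counts.shape + (3,), dtype=np.uint8)
    img[sa & ~sb] = (0, 0, 255)
    img[sb & ~sa] = (255, 0, 0)
    img[sa & sb] = (255, 255, 255)
    return img


@dataclass(frozen=True)
class DiceReport:
    """One row of the similarity report for a feature pair."""

    feature_a: str
    feature_b: str
    absolute: float
    threshold_a: int
    threshold_b: int
    trimmed: float


def compare(
    fa: FrequencyMatrix, fb: FrequencyMatrix, statistic: TrimStatistic = "mass"
) -> DiceReport:
    """Absolute and trimmed Dice for one feature pair, with thresholds."""
    return DiceReport(
        feature_a=fa.feature_label,
        feature_b=fb.feature_label,
        absolute=dice(support_set(fa, 1), support_set(fb, 1)),
        threshold_a=trim_threshold(fa, statistic),
        threshold_b=trim_threshold(fb, statistic),
        trimmed=dice_trimmed(fa, fb, statistic),
    )
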