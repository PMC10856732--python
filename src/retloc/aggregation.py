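"""Frequency matrices: accumulation, laterality mirroring, normalisation.

After colocation, each canvas pixel of each warped binary mask marks
whether one image shows a given feature there.  Summing warped masks over
images gives a per-feature *frequency matrix*: element (y, x) counts the
images exhibiting the feature at that canonical location.  Left- and
right-eye matrices are built separately and combined by mirroring the
left matrix horizontally onto the right-eye frame and adding.  For
display, matrices are rescaled so values span 0-255.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from .geometry import CANVAS_SIZE

__all__ = [
    "Group",
    "FrequencyMatrix",
    "accumulate",
    "mirror_combine",
    "normalize_255",
    "stratify",
]


class Group(str, enum.Enum):
    LEFT = "left"
    RIGHT = "right"
    COMBINED = "combined"


@dataclass(frozen=True)
class FrequencyMatrix:
    """Per-feature image counts on the canonical canvas."""

    counts: np.ndarray
    feature_label: str
    group: Group
    n_images: int
    grade_filter: Optional[str] = None

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.ndim != 2:
            raise ValueError("counts must be 2-D")
        if (counts < 0).any():
            raise ValueError("counts must be non-negative")
        if not np.issubdtype(counts.dtype, np.integer):
            counts = counts.astype(np.int64)
        object.__setattr__(self, "counts", counts)
        if self.n_images < 0:
            raise ValueError("n_images must be >= 0")

    @property
    def canvas(self) -> int:
        return self.counts.shape[0]

    @property
    def total_mass(self) -> int:
        return int(self.counts.sum())


def accumulate(
    warped_masks: Sequence[np.ndarray],
    feature_label: str,
    group: Group,
    canvas: int = CANVAS_SIZE,
    grade_filter: Optional[str] = None,
) -> FrequencyMatrix:
    """Sum canvas-sized binary masks element-wise into a frequency matrix."""
    total = np.zeros((canvas, canvas), dtype=np.int64)
    for i, mask in enumerate(warped_masks):
        mask = np.asarray(mask)
        if mask.shape != (canvas, canvas):
            raise ValueError(
                f"mask #{i} has shape {mask.shape}, expected {(canvas, canvas)}"
            )
        if not np.isin(mask, (0, 1)).all():
            raise ValueError(f"mask #{i} is not binary")
        total += mask
    return FrequencyMatrix(
        counts=total,
        feature_label=feature_label,
        group=Group(group),
        n_images=len(warped_masks),
        grade_filter=grade_filter,
    )


def mirror_combine(left: FrequencyMatrix, right: FrequencyMatrix) -> FrequencyMatrix:
    """Mirror the left-eye matrix onto the right-eye frame and add.

    The mirror is a full-canvas horizontal flip, ``x' = (canvas - 1) - x``.
    Because the canonical left-eye landmark targets are the exact mirror of
    the right-eye targets, this flip lands the left-eye disc and macula on
    the right-eye targets; being a bijection of the canvas, it conserves
    total mass exactly.
    """
    if left.group is not Group.LEFT or right.group is not Group.RIGHT:
        raise ValueError("mirror_combine expects (LEFT, RIGHT) matrices")
    if left.feature_label != right.feature_label:
        raise ValueError(
            f"feature mismatch: {left.feature_label!r} vs {right.feature_label!r}"
        )
    if left.counts.shape != right.counts.shape:
        raise ValueError("canvas size mismatch")
    if left.grade_filter != right.grade_filter:
        raise ValueError("grade filter mismatch")
    combined = np.fliplr(left.counts) + right.counts
    return FrequencyMatrix(
        counts=combined,
        feature_label=right.feature_label,
        group=Group.COMBINED,
        n_images=left.n_images + right.n_images,
        grade_filter=right.grade_filter,
    )


def normalize_255(fm: FrequencyMatrix) -> np.ndarray:
    """Rescale counts to integers in [0, 255] (floor scaling).

    The pixel with the highest count maps to exactly 255; an all-zero
    matrix stays all-zero.
    """
    counts = fm.counts
    peak = int(counts.max(initial=0))
    if peak == 0:
        return np.zeros_like(counts, dtype=np.uint8)
    return (counts.astype(np.int64) * 255 // peak).astype(np.uint8)


def stratify(
    entries: Iterable[tuple[Optional[str], Mapping[str, np.ndarray]]],
    grade: str,
    feature_labels: Sequence[str],
    laterality_of: Optional[Sequence[Group]] = None,
    canvas: int = CANVAS_SIZE,
) -> dict[str, FrequencyMatrix]:
    """Build per-feature combined matrices from images of one ICDR grade.

    Parameters
    ----------
    entries
        Iterable of ``(effective_grade, {feature_label: warped_mask})``
        pairs, one per image, with grades already post-audit.
    grade
        The ICDR grade to keep (``none``/``mild``/``moderate``/``severe``/
        ``pdr``).
    feature_labels
        Features to aggregate; features absent from an image contribute
        nothing for that image.
    laterality_of
        Optional per-entry laterality (:class:`Group` LEFT/RIGHT), aligned
        with ``entries``; left-eye masks are mirrored before summation.
        When omitted all masks are treated as right-eye.

    Notes
    -----
    Ungraded images are excluded from every stratified output (they still
    appear in all-severity maps, which do not pass through this function).
    """
    from .grading import GRADE_ORDER  # local import to avoid a cycle

    if grade not in GRADE_ORDER:
        raise ValueError(f"unknown ICDR grade {grade!r}")
    entries = list(entries)
    sides = list(laterality_of) if laterality_of is not None else [Group.RIGHT] * len(entries)
    if len(sides) != len(entries):
        raise ValueError("laterality_of length must match entries")

    out: dict[str, FrequencyMatrix] = {}
    for label in feature_labels:
        total = np.zeros((canvas, canvas), dtype=np.int64)
        n = 0
        for (g, masks), side in zip(entries, sides):
            if g != grade:
                continue
            n += 1
            mask = masks.get(label)
            if mask is None:
                continue
            mask = np.asarray(mask, dtype=np.int64)
            if mask.shape != (canvas, canvas):
                raise ValueError(f"mask for {label!r} not canvas-sized")
            total += np.fliplr(mask) if Group(side) is Group.LEFT else mask
        out[label] = FrequencyMatrix(
            counts=total,
            feature_label=label,
            group=Group.COMBINED,
            n_images=n,
            grade_filter=grade,
        )
    return out
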