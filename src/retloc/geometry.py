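"""Canonical disc-macula frame and two-landmark similarity registration.

Fundus photographs differ in centration, rotation, field of view,
laterality and resolution, so lesion positions cannot be compared across
images directly.  The remedy implemented here is anatomical colocation: a
4-DOF similarity transform (uniform scale, rotation, translation -- no
shear, no reflection) is fitted per image so that the optic disc and
macula land on fixed canonical positions on a square canvas.  Two point
correspondences determine such a transform uniquely, via the closed form
over complex numbers

    a = (d' - m') / (d - m),     b = m' - a * m,

where ``d, m`` are the source disc/macula and ``d', m'`` the canonical
targets, points read as ``x + i*y``.  ``a`` encodes scale and rotation,
``b`` the translation.

The canonical geometry follows the convention of a 250 px horizontal
disc-macula separation with the macula 25 px below the disc (the
disc-fovea angle) on an 1100 x 1100 canvas.  Left- and right-eye targets
are exact horizontal mirrors of each other, which makes the later
mirror-and-add combination of lateralities exact at the landmarks.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = [
    "CANVAS_SIZE",
    "DISC_MACULA_SEPARATION",
    "MACULA_VERTICAL_OFFSET",
    "Laterality",
    "Point2D",
    "LandmarkRecord",
    "CanonicalFrame",
    "SimilarityTransform",
    "DegenerateLandmarkError",
    "compute_colocation_transform",
    "warp_mask",
]

#: Edge length of the square canonical canvas, in pixels.
CANVAS_SIZE = 1100
#: Horizontal disc-to-macula distance on the canvas, in pixels.
DISC_MACULA_SEPARATION = 250.0
#: How far below the disc the macula sits (y grows downward), in pixels.
MACULA_VERTICAL_OFFSET = 25.0


class DegenerateLandmarkError(ValueError):
    """Raised when disc and macula are too close to define a transform."""


class Laterality(str, enum.Enum):
    LEFT = "L"
    RIGHT = "R"

    @classmethod
    def parse(cls, value: "str | Laterality") -> "Laterality":
        if isinstance(value, Laterality):
            return value
        v = str(value).strip().upper()
        if v in ("L", "LEFT", "OS"):
            return cls.LEFT
        if v in ("R", "RIGHT", "OD"):
            return cls.RIGHT
        raise ValueError(f"unknown laterality: {value!r}")


@dataclass(frozen=True)
class Point2D:
    """A continuous pixel position; x rightward, y downward, 0-based."""

    x: float
    y: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise ValueError(f"non-finite point: ({self.x}, {self.y})")

    def as_complex(self) -> complex:
        return complex(self.x, self.y)

    @staticmethod
    def from_complex(z: complex) -> "Point2D":
        return Point2D(z.real, z.imag)

    def distance_to(self, other: "Point2D") -> float:
        return math.hypot(self.x - other.x, self.y - other.y)


@dataclass(frozen=True)
class LandmarkRecord:
    """Manually recorded disc/macula positions for one source image."""

    image_id: str
    disc: Point2D
    macula: Point2D
    laterality: Laterality
    source_width: int
    source_height: int
    grade: Optional[str] = None

    def __post_init__(self) -> None:
        if self.source_width <= 0 or self.source_height <= 0:
            raise ValueError("source dimensions must be positive")
        for name, p in (("disc", self.disc), ("macula", self.macula)):
            if not (0 <= p.x < self.source_width and 0 <= p.y < self.source_height):
                raise ValueError(
                    f"{name} {p} outside source frame "
                    f"{self.source_width}x{self.source_height} "
                    f"for image {self.image_id!r}"
                )
        if self.disc.distance_to(self.macula) < 1.0:
            raise DegenerateLandmarkError(
                f"disc and macula nearly coincident in image {self.image_id!r}"
            )


def _default_right_targets(canvas: int) -> tuple[Point2D, Point2D]:
    # Right eye: disc nasal (image-right of the macula) in an erect fundus
    # photo.  Placement chosen so the disc-macula midpoint sits near the
    # canvas centre and the left-eye mirror lands on integer coordinates.
    return Point2D(675.0, 537.0), Point2D(425.0, 562.0)


@dataclass(frozen=True)
class CanonicalFrame:
    """Fixed landmark targets per laterality on a square canvas.

    Left targets are the exact horizontal mirror of right targets under
    ``x' = (canvas - 1) - x``; vertical positions are shared.
    """

    canvas: int = CANVAS_SIZE
    disc_right: Point2D = field(default=None)  # type: ignore[assignment]
    macula_right: Point2D = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.disc_right is None or self.macula_right is None:
            d, m = _default_right_targets(self.canvas)
            object.__setattr__(self, "disc_right", self.disc_right or d)
            object.__setattr__(self, "macula_right", self.macula_right or m)
        sep = abs(self.disc_right.x - self.macula_right.x)
        drop = self.macula_right.y - self.disc_right.y
        if abs(sep - DISC_MACULA_SEPARATION) > 1e-9:
            raise ValueError(
                f"disc-macula horizontal separation {sep} != "
                f"{DISC_MACULA_SEPARATION}"
            )
        if abs(drop - MACULA_VERTICAL_OFFSET) > 1e-9:
            raise ValueError(
                f"macula vertical offset {drop} != {MACULA_VERTICAL_OFFSET}"
            )

    def _mirror(self, p: Point2D) -> Point2D:
        return Point2D((self.canvas - 1) - p.x, p.y)

    @property
    def disc_left(self) -> Point2D:
        return self._mirror(self.disc_right)

    @property
    def macula_left(self) -> Point2D:
        return self._mirror(self.macula_right)

    def targets(self, laterality: Laterality) -> tuple[Point2D, Point2D]:
        """Return ``(disc_target, macula_target)`` for one laterality."""
        lat = Laterality.parse(laterality)
        if lat is Laterality.RIGHT:
            return self.disc_right, self.macula_right
        return self.disc_left, self.macula_left


@dataclass(frozen=True)
class SimilarityTransform:
    """Orientation-preserving similarity ``p -> a*p + b`` over complex points.

    ``a = scale * exp(i * rotation)`` holds the linear part; ``b`` the
    translation.  Reflections are excluded by construction (``scale > 0``,
    determinant ``scale**2 > 0``).
    """

    a: complex
    b: complex

    def __post_init__(self) -> None:
        if abs(self.a) <= 0.0 or not (
            math.isfinite(self.a.real)
            and math.isfinite(self.a.imag)
            and math.isfinite(self.b.real)
            and math.isfinite(self.b.imag)
        ):
            raise ValueError("invalid similarity coefficients")

    @classmethod
    def from_params(
        cls, scale: float, rotation: float, translation: "Point2D | tuple[float, float]"
    ) -> "SimilarityTransform":
        if scale <= 0:
            raise ValueError("scale must be positive")
        tx, ty = (translation.x, translation.y) if isinstance(translation, Point2D) else translation
        return cls(a=scale * complex(math.cos(rotation), math.sin(rotation)), b=complex(tx, ty))

    @classmethod
    def identity(cls) -> "SimilarityTransform":
        return cls(a=1 + 0j, b=0j)

    @property
    def scale(self) -> float:
        return abs(self.a)

    @property
    def rotation(self) -> float:
        return math.atan2(self.a.imag, self.a.real)

    @property
    def translation(self) -> Point2D:
        return Point2D(self.b.real, self.b.imag)

    def apply(self, p: Point2D) -> Point2D:
        return Point2D.from_complex(self.a * p.as_complex() + self.b)

    def apply_xy(self, xs: np.ndarray, ys: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Vectorised forward map of coordinate arrays."""
        ar, ai = self.a.real, self.a.imag
        return ar * xs - ai * ys + self.b.real, ai * xs + ar * ys + self.b.imag

    def invert(self) -> "SimilarityTransform":
        inv_a = 1.0 / self.a
        return SimilarityTransform(a=inv_a, b=-inv_a * self.b)

    def compose(self, inner: "SimilarityTransform") -> "SimilarityTransform":
        """Return the transform ``p -> self(inner(p))``."""
        return SimilarityTransform(a=self.a * inner.a, b=self.a * inner.b + self.b)


def compute_colocation_transform(
    lm: LandmarkRecord, frame: CanonicalFrame | None = None
) -> SimilarityTransform:
    """Fit the similarity transform sending an image's landmarks onto the frame.

    Solves the two-point correspondence exactly: with the source disc and
    macula as complex numbers ``d`` and ``m`` and the laterality-specific
    canonical targets ``d'`` and ``m'``, the unique orientation-preserving
    similarity is ``a = (d' - m') / (d - m)``, ``b = m' - a * m``.

    Raises
    ------
    DegenerateLandmarkError
        If disc and macula are closer than one source pixel.
    """
    frame = frame or CanonicalFrame()
    d, m = lm.disc.as_complex(), lm.macula.as_complex()
    if abs(d - m) < 1.0:
        raise DegenerateLandmarkError(
            f"disc and macula nearly coincident in image {lm.image_id!r}"
        )
    d_t, m_t = frame.targets(lm.laterality)
    a = (d_t.as_complex() - m_t.as_complex()) / (d - m)
    b = m_t.as_complex() - a * m
    return SimilarityTransform(a=a, b=b)


def warp_mask(
    mask: np.ndarray, transform: SimilarityTransform, canvas: int = CANVAS_SIZE
) -> np.ndarray:
    """Resample a binary mask onto the canonical canvas.

    Inverse-mapping nearest neighbour: each canvas pixel centre is pulled
    back through ``transform.invert()`` and takes the value of the nearest
    source pixel, or 0 outside the source frame.  Nearest neighbour keeps
    the output strictly binary without a re-binarisation threshold.

    Parameters
    ----------
    mask
        2-D array valued in {0, 1}, indexed ``[y, x]``.
    transform
        Source-to-canvas similarity.
    canvas
        Output edge length.
    """
    mask = np.asarray(mask)
    if mask.ndim != 2:
        raise ValueError("mask must be 2-D")
    if not np.isin(mask, (0, 1)).all():
        raise ValueError("mask must be binary (0/1)")
    inv = transform.invert()
    xs, ys = np.meshgrid(
        np.arange(canvas, dtype=np.float64), np.arange(canvas, dtype=np.float64)
    )
    sx, sy = inv.apply_xy(xs, ys)
    ix = np.rint(sx).astype(np.int64)
    iy = np.rint(sy).astype(np.int64)
    h, w = mask.shape
    inside = (ix >= 0) & (ix < w) & (iy >= 0) & (iy < h)
    out = np.zeros((canvas, canvas), dtype=np.uint8)
    out[inside] = mask[iy[inside], ix[inside]]
    return out
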