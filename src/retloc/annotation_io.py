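"""Readers and writers for the dataset artifacts.

Formats handled:

* single-channel (or RGB) PNG lesion/vessel masks, white-on-black, one
  file per feature per image -- any nonzero value counts as foreground;
* Pascal-VOC XML bounding boxes in the LabelImg dialect, used for the
  features annotated as boxes rather than pixel masks (IRMA, venous
  beading, NVD, NVE);
* the landmark table CSV (disc/macula positions, laterality, grade);
* count-matrix CSVs (exact integer round trip) and 8-bit heatmap PNGs.

Directory layout convention: ``<root>/<feature>/<image_id>.png`` for
masks, ``<root>/boxes/<image_id>.xml`` for box files, and
``<root>/landmarks.csv``.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Optional

import imageio.v3 as iio
import numpy as np
from lxml import etree

from .geometry import LandmarkRecord, Laterality, Point2D

logger = logging.getLogger(__name__)

__all__ = [
    "LabeledBox",
    "MaskFormatError",
    "VocParseError",
    "FEATURE_ALIASES",
    "normalize_feature_label",
    "read_mask_png",
    "write_mask_png",
    "read_voc_boxes",
    "boxes_to_mask",
    "read_landmarks_csv",
    "write_landmarks_csv",
    "write_counts_csv",
    "read_counts_csv",
    "write_heatmap_png",
]


class MaskFormatError(ValueError):
    """Raised for images that cannot be interpreted as binary masks."""


class VocParseError(ValueError):
    """Raised for malformed Pascal-VOC annotation files."""


# Canonical feature vocabulary with case-insensitive aliases.  Extend via
# the ``extra_aliases`` argument of :func:`normalize_feature_label`.
FEATURE_ALIASES: dict[str, str] = {
    "ma": "microaneurysm",
    "microaneurysm": "microaneurysm",
    "microaneurysms": "microaneurysm",
    "hem": "hemorrhage",
    "he": "hemorrhage",
    "haemorrhage": "hemorrhage",
    "hemorrhage": "hemorrhage",
    "hemorrhages": "hemorrhage",
    "ex": "exudate",
    "exudate": "exudate",
    "exudates": "exudate",
    "hard_exudate": "exudate",
    "cws": "cotton_wool_spot",
    "se": "cotton_wool_spot",
    "soft_exudate": "cotton_wool_spot",
    "cotton_wool_spot": "cotton_wool_spot",
    "cotton_wool_spots": "cotton_wool_spot",
    "artery": "arteriole",
    "arteriole": "arteriole",
    "arterioles": "arteriole",
    "vein": "venule",
    "venule": "venule",
    "venules": "venule",
    "irma": "irma",
    "vb": "venous_beading",
    "venous_beading": "venous_beading",
    "nvd": "nvd",
    "nve": "nve",
}


def normalize_feature_label(
    label: str, extra_aliases: Optional[Mapping[str, str]] = None
) -> str:
    """Map a raw label to the canonical vocabulary (case-insensitive).

    Unknown labels are passed through lower-cased with spaces collapsed to
    underscores, so user-defined features remain usable.
    """
    key = label.strip().lower().replace(" ", "_")
    if extra_aliases:
        lowered = {k.strip().lower(): v for k, v in extra_aliases.items()}
        if key in lowered:
            return lowered[key]
    return FEATURE_ALIASES.get(key, key)


@dataclass(frozen=True)
class LabeledBox:
    """A LabelImg bounding box with inclusive integer pixel bounds."""

    label: str
    x_min: int
    y_min: int
    x_max: int
    y_max: int

    def __post_init__(self) -> None:
        if self.x_min > self.x_max or self.y_min > self.y_max:
            raise ValueError(f"inverted box bounds: {self}")

    @property
    def area(self) -> int:
        return (self.x_max - self.x_min + 1) * (self.y_max - self.y_min + 1)


# ---------------------------------------------------------------------------
# Masks
# ---------------------------------------------------------------------------

def read_mask_png(path: "str | Path") -> np.ndarray:
    """Read a mask image; any nonzero value in any channel is foreground.

    Returns a 2-D uint8 array valued in {0, 1}.
    """
    path = Path(path)
    try:
        img = iio.imread(path)
    except Exception as exc:  # pragma: no cover - imageio error text varies
        raise MaskFormatError(f"cannot read mask image {path}: {exc}") from exc
    arr = np.asarray(img)
    if arr.ndim == 3:
        arr = arr.max(axis=2)
    elif arr.ndim != 2:
        raise MaskFormatError(f"unsupported mask shape {arr.shape} in {path}")
    return (arr != 0).astype(np.uint8)


def write_mask_png(mask: np.ndarray, path: "str | Path") -> None:
    """Write a 0/1 mask as an 8-bit black/white PNG."""
    mask = np.asarray(mask)
    if not np.isin(mask, (0, 1)).all():
        raise MaskFormatError("mask must be binary (0/1)")
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    iio.imwrite(Path(path), (mask.astype(np.uint8) * 255))


# ---------------------------------------------------------------------------
# Pascal-VOC boxes
# ---------------------------------------------------------------------------

def read_voc_boxes(path: "str | Path") -> list[LabeledBox]:
    """Parse LabelImg Pascal-VOC XML into boxes, labels kept verbatim.

    Raises :class:`VocParseError` on malformed XML or an ``object`` element
    missing its name or bounding box; the error names the object index.
    """
    path = Path(path)
    try:
        tree = etree.parse(str(path))
    except (etree.XMLSyntaxError, OSError) as exc:
        raise VocParseError(f"cannot parse VOC file {path}: {exc}") from exc
    boxes: list[LabeledBox] = []
    for idx, obj in enumerate(tree.getroot().iter("object")):
        name_el = obj.find("name")
        bnd = obj.find("bndbox")
        if name_el is None or name_el.text is None or bnd is None:
            raise VocParseError(
                f"object #{idx} in {path} lacks a name or bndbox element"
            )
        try:
            coords = {
                tag: int(round(float(bnd.findtext(tag))))
                for tag in ("xmin", "ymin", "xmax", "ymax")
            }
        except (TypeError, ValueError) as exc:
            raise VocParseError(
                f"object #{idx} in {path} has invalid bndbox coordinates"
            ) from exc
        boxes.append(
            LabeledBox(
                label=name_el.text.strip(),
                x_min=coords["xmin"],
                y_min=coords["ymin"],
                x_max=coords["xmax"],
                y_max=coords["ymax"],
            )
        )
    return boxes


def boxes_to_mask(
    boxes: Iterable[LabeledBox],
    label: str,
    width: int,
    height: int,
    extra_aliases: Optional[Mapping[str, str]] = None,
) -> np.ndarray:
    """Rasterise the union of boxes matching ``label`` into a binary mask.

    Boxes are inclusive pixel ranges (LabelImg convention); overlaps are
    not double-counted.  Boxes extending past the frame are clipped with a
    warning rather than rejected.
    """
    target = normalize_feature_label(label, extra_aliases)
    mask = np.zeros((height, width), dtype=np.uint8)
    for box in boxes:
        if normalize_feature_label(box.label, extra_aliases) != target:
            continue
        x0, y0 = max(box.x_min, 0), max(box.y_min, 0)
        x1, y1 = min(box.x_max, width - 1), min(box.y_max, height - 1)
        if (x0, y0, x1, y1) != (box.x_min, box.y_min, box.x_max, box.y_max):
            logger.warning(
                "box %s clipped to %dx%d frame", box, width, height
            )
        if x0 > x1 or y0 > y1:
            continue
        mask[y0 : y1 + 1, x0 : x1 + 1] = 1
    return mask


# ---------------------------------------------------------------------------
# Landmark table
# ---------------------------------------------------------------------------

LANDMARK_HEADER = [
    "image_id",
    "laterality",
    "disc_x",
    "disc_y",
    "macula_x",
    "macula_y",
    "grade",
    "source_width",
    "source_height",
]

ICDR_VOCABULARY = {"none", "mild", "moderate", "severe", "pdr", "ungraded"}


def read_landmarks_csv(path: "str | Path") -> list[LandmarkRecord]:
    """Read the landmark table (UTF-8 CSV with named header columns)."""
    records: list[LandmarkRecord] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        missing = {c for c in LANDMARK_HEADER[:6] if c not in (reader.fieldnames or [])}
        if missing:
            raise ValueError(f"landmark table {path} missing columns: {sorted(missing)}")
        for row in reader:
            grade = (row.get("grade") or "").strip().lower() or None
            if grade is not None and grade not in ICDR_VOCABULARY:
                raise ValueError(
                    f"unknown ICDR grade {grade!r} for image {row['image_id']!r}"
                )
            records.append(
                LandmarkRecord(
                    image_id=row["image_id"],
                    disc=Point2D(float(row["disc_x"]), float(row["disc_y"])),
                    macula=Point2D(float(row["macula_x"]), float(row["macula_y"])),
                    laterality=Laterality.parse(row["laterality"]),
                    source_width=int(row.get("source_width") or 1100),
                    source_height=int(row.get("source_height") or 1100),
                    grade=grade,
                )
            )
    return records


def write_landmarks_csv(records: Iterable[LandmarkRecord], path: "str | Path") -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(LANDMARK_HEADER)
        for r in records:
            writer.writerow(
                [
                    r.image_id,
                    r.laterality.value,
                    repr(r.disc.x) if r.disc.x != int(r.disc.x) else int(r.disc.x),
                    repr(r.disc.y) if r.disc.y != int(r.disc.y) else int(r.disc.y),
                    repr(r.macula.x) if r.macula.x != int(r.macula.x) else int(r.macula.x),
                    repr(r.macula.y) if r.macula.y != int(r.macula.y) else int(r.macula.y),
                    r.grade or "",
                    r.source_width,
                    r.source_height,
                ]
            )


# ---------------------------------------------------------------------------
# Count matrices and heatmaps
# ---------------------------------------------------------------------------

def write_counts_csv(matrix: np.ndarray, path: "str | Path") -> None:
    """Persist a non-negative integer count matrix as plain CSV."""
    matrix = np.asarray(matrix)
    if matrix.ndim != 2 or (matrix < 0).any():
        raise ValueError("count matrix must be 2-D and non-negative")
    if not np.issubdtype(matrix.dtype, np.integer):
        if not np.equal(np.mod(matrix, 1), 0).all():
            raise ValueError("count matrix must be integer-valued")
        matrix = matrix.astype(np.int64)
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    np.savetxt(path, matrix, fmt="%d", delimiter=",")


def read_counts_csv(path: "str | Path") -> np.ndarray:
    """Read a count matrix written by :func:`write_counts_csv` exactly."""
    return np.loadtxt(path, delimiter=",", dtype=np.int64, ndmin=2)


def write_heatmap_png(matrix: np.ndarray, path: "str | Path") -> None:
    """Write a 0-255 heatmap as lossless 8-bit grayscale PNG."""
    matrix = np.asarray(matrix)
    if matrix.ndim != 2:
        raise ValueError("heatmap must be 2-D")
    if (matrix < 0).any() or (matrix > 255).any():
        raise ValueError("heatmap values must lie in [0, 255]")
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    iio.imwrite(Path(path), matrix.astype(np.uint8))
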