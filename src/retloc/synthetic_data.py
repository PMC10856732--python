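"""Synthetic fundus annotation datasets with known spatial ground truth.

Real lesion-segmentation datasets (DDR for lesions; RITE and IOSTAR for
vessels) cannot ship with the package, so this module simulates the whole
acquisition chain with a *known* spatial distribution per feature,
letting the pipeline's heatmap recovery be validated against truth:

1. each feature's location frequency is a Gaussian-mixture density on the
   canonical right-eye canvas (:class:`DensitySpec`);
2. a synthetic camera draws laterality, source resolution and a jittered
   similarity transform (canonical -> source), placing the disc/macula
   landmarks wherever that camera puts the canonical targets;
3. lesions are Poisson in number, their centres sampled from the mixture
   (mirrored for left eyes), pushed into source coordinates and rendered
   as filled disks.

Running the colocation pipeline on such a dataset should recover a count
matrix proportional to the generating density blurred by the lesion-disk
kernel; :func:`true_density_matrix` provides the comparison target.

Default densities qualitatively mimic the posterior-pole patterns seen in
diabetic retinopathy: diffuse microaneurysms, exudates concentrated at
and temporal to the fovea, cotton wool spots in a peridisc arc sparing
the temporal macula, and venous beading along the proximal vascular
arcades.  They are illustrative shapes, not fits to any measured map.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from scipy import stats
from skimage.draw import disk as draw_disk

from .geometry import (
    CANVAS_SIZE,
    CanonicalFrame,
    LandmarkRecord,
    Laterality,
    Point2D,
    SimilarityTransform,
)

__all__ = [
    "MixtureComponent",
    "DensitySpec",
    "AcquisitionSpec",
    "SyntheticEye",
    "default_density_specs",
    "sample_eye",
    "render_feature_masks",
    "true_density_matrix",
    "generate_dataset",
    "write_dataset",
]


@dataclass(frozen=True)
class MixtureComponent:
    weight: float
    mean: Point2D
    cov: tuple[tuple[float, float], tuple[float, float]]

    def __post_init__(self) -> None:
        if self.weight <= 0:
            raise ValueError("component weight must be positive")
        c = np.asarray(self.cov, dtype=float)
        if c.shape != (2, 2) or abs(c[0, 1] - c[1, 0]) > 1e-9:
            raise ValueError("covariance must be symmetric 2x2")
        if np.linalg.eigvalsh(c).min() <= 0:
            raise ValueError("covariance must be positive definite")


@dataclass(frozen=True)
class DensitySpec:
    """Gaussian-mixture lesion density in canonical right-eye coordinates."""

    feature_label: str
    components: tuple[MixtureComponent, ...]
    lesion_count_rate: float = 5.0  # Poisson mean lesions per image
    lesion_radius: tuple[int, int] = (3, 8)  # inclusive pixel range

    def __post_init__(self) -> None:
        w = sum(c.weight for c in self.components)
        if abs(w - 1.0) > 1e-9:
            raise ValueError(f"component weights sum to {w}, expected 1")
        if self.lesion_count_rate < 0:
            raise ValueError("lesion rate must be >= 0")
        lo, hi = self.lesion_radius
        if not (1 <= lo <= hi):
            raise ValueError("lesion radius range must satisfy 1 <= lo <= hi")


@dataclass(frozen=True)
class AcquisitionSpec:
    """Synthetic camera: how many eyes, with what geometric jitter.

    The camera transform maps canonical canvas coordinates into source
    image coordinates, so scale > 1 means the source image is *larger*
    than canonical.  Jitter defaults are modest (scale 0.8-1.25, rotation
    within ±5 degrees, ±40 px translation) to emulate the centration,
    rotation and resolution variation of macula-centred 45-degree
    photography without pushing landmarks out of frame.
    """

    n_images: int = 100
    right_eye_fraction: float = 0.51  # matches a roughly balanced clinic mix
    source_size_range: tuple[int, int] = (900, 1400)
    scale_range: tuple[float, float] = (0.8, 1.25)
    rotation_range_deg: tuple[float, float] = (-5.0, 5.0)
    translation_jitter: float = 40.0
    max_retries: int = 50

    def __post_init__(self) -> None:
        if self.n_images < 0:
            raise ValueError("n_images must be >= 0")
        if not 0.0 <= self.right_eye_fraction <= 1.0:
            raise ValueError("right_eye_fraction must be in [0, 1]")
        if self.scale_range[0] <= 0 or self.scale_range[0] > self.scale_range[1]:
            raise ValueError("invalid scale range")


@dataclass(frozen=True)
class SyntheticEye:
    """One simulated image: landmarks, the true camera, per-feature masks."""

    landmark: LandmarkRecord
    camera_transform: SimilarityTransform  # canonical -> source
    masks: dict[str, np.ndarray] = field(default_factory=dict)
    true_grade: Optional[str] = None


def default_density_specs(canvas: int = CANVAS_SIZE) -> list[DensitySpec]:
    """Illustrative per-feature densities on the right-eye canonical frame.

    Coordinates reference the canonical right-eye landmarks: macula at
    (425, 562), disc at (675, 537); "temporal" is toward smaller x.
    """
    mac = Point2D(425.0, 562.0)
    disc = Point2D(675.0, 537.0)

    def iso(s: float) -> tuple[tuple[float, float], tuple[float, float]]:
        return ((s * s, 0.0), (0.0, s * s))

    # Lesion rates reflect typical multiplicity in affected eyes (dozens of
    # microaneurysms/exudate flecks, a handful of cotton wool spots), which
    # also gives density-recovery validation adequate counting statistics.
    diffuse = DensitySpec(
        "microaneurysm",
        (MixtureComponent(1.0, Point2D(mac.x + 60, mac.y - 10), iso(180.0)),),
        lesion_count_rate=25.0,
        lesion_radius=(2, 4),
    )
    exudate = DensitySpec(
        "exudate",
        (
            MixtureComponent(0.7, Point2D(mac.x - 60, mac.y), iso(70.0)),
            MixtureComponent(0.3, mac, iso(110.0)),
        ),
        lesion_count_rate=20.0,
        lesion_radius=(2, 6),
    )
    # Peridisc arc sparing the temporal macula: components above, below and
    # nasal to the disc.
    cws = DensitySpec(
        "cotton_wool_spot",
        (
            MixtureComponent(0.35, Point2D(disc.x - 40, disc.y - 150), iso(80.0)),
            MixtureComponent(0.35, Point2D(disc.x - 40, disc.y + 150), iso(80.0)),
            MixtureComponent(0.30, Point2D(disc.x + 120, disc.y), iso(90.0)),
        ),
        lesion_count_rate=5.0,
        lesion_radius=(4, 9),
    )
    hemorrhage = DensitySpec(
        "hemorrhage",
        (
            MixtureComponent(0.6, Point2D(mac.x - 80, mac.y), iso(120.0)),
            MixtureComponent(0.4, Point2D(mac.x + 80, mac.y), iso(170.0)),
        ),
        lesion_count_rate=15.0,
        lesion_radius=(2, 7),
    )
    # Proximal superior/inferior arcades near the disc.
    vb = DensitySpec(
        "venous_beading",
        (
            MixtureComponent(0.5, Point2D(disc.x - 60, disc.y - 120), iso(60.0)),
            MixtureComponent(0.5, Point2D(disc.x - 60, disc.y + 120), iso(60.0)),
        ),
        lesion_count_rate=1.5,
        lesion_radius=(3, 6),
    )
    return [diffuse, exudate, cws, hemorrhage, vb]


def _mirror_point(p: Point2D, canvas: int) -> Point2D:
    return Point2D((canvas - 1) - p.x, p.y)


def sample_eye(
    acq: AcquisitionSpec,
    rng: np.random.Generator,
    frame: CanonicalFrame | None = None,
    image_id: str = "synthetic",
) -> SyntheticEye:
    """Draw one synthetic eye: laterality, source frame, camera, landmarks.

    The camera transform is a random similarity from canonical to source
    coordinates; the landmark positions are simply the canonical targets
    for the drawn laterality pushed through it.  Draws that place a
    landmark outside the source frame are rejected and resampled, up to
    ``acq.max_retries`` times.
    """
    frame = frame or CanonicalFrame()
    laterality = (
        Laterality.RIGHT if rng.random() < acq.right_eye_fraction else Laterality.LEFT
    )
    disc_t, mac_t = frame.targets(laterality)
    for _ in range(acq.max_retries):
        side = int(rng.integers(acq.source_size_range[0], acq.source_size_range[1] + 1))
        width = height = side
        scale = rng.uniform(*acq.scale_range) * side / frame.canvas
        rotation = math.radians(rng.uniform(*acq.rotation_range_deg))
        # Centre the canonical mid-landmark point in the source frame, then
        # jitter the translation.
        mid = Point2D((disc_t.x + mac_t.x) / 2.0, (disc_t.y + mac_t.y) / 2.0)
        a = scale * complex(math.cos(rotation), math.sin(rotation))
        target_mid = complex(
            width / 2.0 + rng.uniform(-acq.translation_jitter, acq.translation_jitter),
            height / 2.0 + rng.uniform(-acq.translation_jitter, acq.translation_jitter),
        )
        camera = SimilarityTransform(a=a, b=target_mid - a * mid.as_complex())
        disc = camera.apply(disc_t)
        mac = camera.apply(mac_t)
        if all(0 <= p.x < width and 0 <= p.y < height for p in (disc, mac)):
            lm = LandmarkRecord(
                image_id=image_id,
                disc=disc,
                macula=mac,
                laterality=laterality,
                source_width=width,
                source_height=height,
            )
            return SyntheticEye(landmark=lm, camera_transform=camera)
    raise RuntimeError(
        f"could not place landmarks inside the frame after {acq.max_retries} draws"
    )


def render_feature_masks(
    eye: SyntheticEye,
    specs: Sequence[DensitySpec],
    rng: np.random.Generator,
    canvas: int = CANVAS_SIZE,
) -> dict[str, np.ndarray]:
    """Sample lesions per feature and rasterise them in source coordinates.

    Lesion count ~ Poisson(rate); centres drawn from the mixture (mirrored
    through the canvas flip for left eyes), mapped through the camera
    transform, and rendered as filled disks clipped to the frame.  Disk
    radii are scaled by the camera scale so lesion size tracks resolution.
    """
    lm = eye.landmark
    out: dict[str, np.ndarray] = {}
    for spec in specs:
        mask = np.zeros((lm.source_height, lm.source_width), dtype=np.uint8)
        n_lesions = int(rng.poisson(spec.lesion_count_rate))
        if n_lesions:
            weights = np.array([c.weight for c in spec.components])
            comp_idx = rng.choice(len(spec.components), size=n_lesions, p=weights)
            for ci in comp_idx:
                comp = spec.components[ci]
                xy = rng.multivariate_normal(
                    (comp.mean.x, comp.mean.y), np.asarray(comp.cov)
                )
                centre = Point2D(float(xy[0]), float(xy[1]))
                if lm.laterality is Laterality.LEFT:
                    centre = _mirror_point(centre, canvas)
                src = eye.camera_transform.apply(centre)
                radius = (
                    int(rng.integers(spec.lesion_radius[0], spec.lesion_radius[1] + 1))
                    * eye.camera_transform.scale
                )
                rr, cc = draw_disk(
                    (src.y, src.x), max(radius, 1.0), shape=mask.shape
                )
                mask[rr, cc] = 1
        out[spec.feature_label] = mask
    return out


def true_density_matrix(spec: DensitySpec, canvas: int = CANVAS_SIZE) -> np.ndarray:
    """Mixture density evaluated at pixel centres, normalised to sum 1."""
    xs, ys = np.meshgrid(np.arange(canvas, dtype=float), np.arange(canvas, dtype=float))
    pts = np.stack([xs.ravel(), ys.ravel()], axis=1)
    dens = np.zeros(pts.shape[0])
    for comp in spec.components:
        dens += comp.weight * stats.multivariate_normal.pdf(
            pts, mean=(comp.mean.x, comp.mean.y), cov=np.asarray(comp.cov)
        )
    dens = dens.reshape(canvas, canvas)
    total = dens.sum()
    if total <= 0:
        raise ValueError("density vanished on the canvas; check component means")
    return dens / total


def generate_dataset(
    acq: AcquisitionSpec,
    specs: Sequence[DensitySpec],
    seed: int,
    frame: CanonicalFrame | None = None,
) -> list[SyntheticEye]:
    """Generate a full synthetic dataset deterministically from one seed."""
    rng = np.random.default_rng(seed)
    frame = frame or CanonicalFrame()
    eyes: list[SyntheticEye] = []
    for i in range(acq.n_images):
        eye = sample_eye(acq, rng, frame, image_id=f"synth-{i:05d}")
        masks = render_feature_masks(eye, specs, rng, canvas=frame.canvas)
        grade = _grade_from_masks(masks)
        eyes.append(
            SyntheticEye(
                landmark=LandmarkRecord(
                    image_id=eye.landmark.image_id,
                    disc=eye.landmark.disc,
                    macula=eye.landmark.macula,
                    laterality=eye.landmark.laterality,
                    source_width=eye.landmark.source_width,
                    source_height=eye.landmark.source_height,
                    grade=grade,
                ),
                camera_transform=eye.camera_transform,
                masks=masks,
                true_grade=grade,
            )
        )
    return eyes


def _grade_from_masks(masks: dict[str, np.ndarray]) -> str:
    """ICDR grade implied by which synthetic features were actually drawn."""
    from .grading import FeatureFindings, min_consistent_grade

    def has(label: str) -> bool:
        m = masks.get(label)
        return m is not None and bool(m.any())

    findings = FeatureFindings(
        microaneurysms=has("microaneurysm"),
        hemorrhages=has("hemorrhage"),
        exudates=has("exudate"),
        cotton_wool_spots=has("cotton_wool_spot"),
        irma=has("irma"),
        nvd=has("nvd"),
        nve=has("nve"),
        vb_quadrants=2 if has("venous_beading") else 0,
    )
    return min_consistent_grade(findings)


#: Features persisted as VOC boxes rather than pixel masks, mirroring how
#: IRMA/VB/NVD/NVE were annotated with LabelImg in real data.
BOX_FEATURES = {"irma", "venous_beading", "nvd", "nve"}


def write_dataset(eyes: Sequence[SyntheticEye], root: "str | Path") -> None:
    """Persist a synthetic dataset in the standard directory layout.

    Pixel-mask features go to ``<root>/<feature>/<image_id>.png``;
    box-type features (IRMA, venous beading, NVD, NVE) are written as
    Pascal-VOC XML covering each mask's connected components with their
    bounding boxes; landmarks to ``<root>/landmarks.csv``.
    """
    from lxml import etree
    from skimage.measure import label as cc_label, regionprops

    from .annotation_io import write_landmarks_csv, write_mask_png

    root = Path(root)
    root.mkdir(parents=True, exist_ok=True)
    for eye in eyes:
        voc_objects: list[tuple[str, int, int, int, int]] = []
        for feat, mask in eye.masks.items():
            if feat in BOX_FEATURES:
                for region in regionprops(cc_label(mask)):
                    y0, x0, y1, x1 = region.bbox  # half-open
                    voc_objects.append((feat, x0, y0, x1 - 1, y1 - 1))
            else:
                write_mask_png(mask, root / feat / f"{eye.landmark.image_id}.png")
        if voc_objects:
            ann = etree.Element("annotation")
            etree.SubElement(ann, "filename").text = f"{eye.landmark.image_id}.jpg"
            size = etree.SubElement(ann, "size")
            etree.SubElement(size, "width").text = str(eye.landmark.source_width)
            etree.SubElement(size, "height").text = str(eye.landmark.source_height)
            for feat, x0, y0, x1, y1 in voc_objects:
                obj = etree.SubElement(ann, "object")
                etree.SubElement(obj, "name").text = feat
                bnd = etree.SubElement(obj, "bndbox")
                etree.SubElement(bnd, "xmin").text = str(x0)
                etree.SubElement(bnd, "ymin").text = str(y0)
                etree.SubElement(bnd, "xmax").text = str(x1)
                etree.SubElement(bnd, "ymax").text = str(y1)
            box_dir = root / "boxes"
            box_dir.mkdir(exist_ok=True)
            (box_dir / f"{eye.landmark.image_id}.xml").write_bytes(
                etree.tostring(ann, pretty_print=True)
            )
    write_landmarks_csv([e.landmark for e in eyes], root / "landmarks.csv")
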