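"""Synthetic CT-like lesion phantoms for testing the 2.5D method.

Each phantom volume contains one bright elliptical lesion visible on a run
of consecutive slices. The *middle* lesion slice is drawn from a sampler
shared by both classes, so its marginal appearance distribution is identical
by construction and a single-slice classifier cannot beat chance on
lesion-centered crops. Class identity is carried only by how the lesion
moves between slices:

* ``tubular`` (the appendix-like positive class): the lesion center drifts
  by a fixed step along one random but consistent direction — like a tube
  crossing the imaging plane obliquely;
* ``focal`` (the diverticulum-like negative class): the center is displaced
  by the same step length in an independently resampled direction on every
  slice — positionally incoherent inflammation.

Annotations box each slice's lesion with a fixed margin, so every crop is
lesion-centered and the only class signal a fused triplet sees is the
relative displacement of the red/blue channels. Stored values encode HU with
slope 1, intercept -1024, exercising the real rescale path.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .cohort import Manifest, ManifestRecord
from .io import (
    DEFAULT_LABEL_MAP,
    BoxAnnotation,
    CTVolume,
    write_annotation_table,
    write_dicom_series,
)

__all__ = ["PhantomSpec", "generate_phantom_volume", "generate_cohort", "CLASS_NAMES"]

CLASS_NAMES = ("tubular", "focal")


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and intensity parameters of the synthetic volumes.

    Units: HU for intensities, pixels for in-plane lengths. Defaults give a
    24-slice 96 x 96 volume with a 5-slice lesion of +60 HU contrast over a
    30 HU soft-tissue background with 8 HU Gaussian noise, drifting 3 px per
    slice.
    """

    volume_shape: tuple[int, int, int] = (24, 96, 96)  # (n_slices, rows, cols)
    lesion_radius_px_range: tuple[float, float] = (4.0, 7.0)
    drift_px: float = 3.0
    lesion_contrast_hu: float = 60.0
    background_hu: float = 30.0
    noise_sigma_hu: float = 8.0
    n_lesion_slices: int = 5
    box_margin_px: int = 4
    slice_thickness_mm: float = 3.0

    def __post_init__(self) -> None:
        if self.drift_px < 0:
            raise ValueError("drift_px must be >= 0")
        if self.n_lesion_slices < 1 or self.n_lesion_slices > self.volume_shape[0]:
            raise ValueError("n_lesion_slices must fit inside the volume")
        reach = (
            self.lesion_radius_px_range[1]
            + self.box_margin_px
            + self.drift_px * (self.n_lesion_slices // 2 + 1)
        )
        if 2 * reach >= min(self.volume_shape[1:]):
            raise ValueError("lesion cannot be guaranteed to fit inside the volume")


def _soft_ellipse(
    shape: tuple[int, int], center: np.ndarray, axes: tuple[float, float], angle: float
) -> np.ndarray:
    """Anti-aliased elliptical bump in [0, 1] (soft edge ~1 px wide)."""
    rows, cols = np.mgrid[0 : shape[0], 0 : shape[1]].astype(np.float64)
    dy, dx = rows - center[0], cols - center[1]
    ca, sa = np.cos(angle), np.sin(angle)
    u = (ca * dx + sa * dy) / axes[1]
    v = (-sa * dx + ca * dy) / axes[0]
    d = np.sqrt(u * u + v * v)
    # (1 - d) * r approximates the signed distance (px) to the boundary
    return np.clip((1.0 - d) * float(max(axes)) + 0.5, 0.0, 1.0)


def _lesion_centers(
    class_label: str, middle: np.ndarray, n_slices: int, drift: float, rng: np.random.Generator
) -> tuple[list[np.ndarray], np.ndarray]:
    """Per-slice lesion centers (row, col) and the tubular drift direction."""
    half_lo = (n_slices - 1) // 2
    theta = rng.uniform(0.0, 2.0 * np.pi)
    direction = np.array([np.sin(theta), np.cos(theta)])
    centers = [np.array(middle, dtype=float) for _ in range(n_slices)]
    if class_label == "tubular":
        for j in range(n_slices):
            centers[j] = middle + (j - half_lo) * drift * direction
    else:
        # random walk out from the middle slice, step length = drift
        for j in range(half_lo + 1, n_slices):
            phi = rng.uniform(0.0, 2.0 * np.pi)
            centers[j] = centers[j - 1] + drift * np.array([np.sin(phi), np.cos(phi)])
        for j in range(half_lo - 1, -1, -1):
            phi = rng.uniform(0.0, 2.0 * np.pi)
            centers[j] = centers[j + 1] + drift * np.array([np.sin(phi), np.cos(phi)])
    return centers, direction


def generate_phantom_volume(
    class_label: str,
    spec: PhantomSpec = PhantomSpec(),
    rng: np.random.Generator | None = None,
    patient_id: str = "phantom",
) -> tuple[CTVolume, list[BoxAnnotation]]:
    """Simulate one volume of the given class with per-slice box annotations.

    The middle-slice lesion (position, semi-axes, orientation) is drawn from
    the class-shared sampler; only the cross-slice placement differs between
    classes. Placement is rejection-sampled (bounded retries) so the lesion
    and its annotation box stay inside the volume on every slice.
    """
    if class_label not in CLASS_NAMES:
        raise ValueError(f"class_label must be one of {CLASS_NAMES}")
    if rng is None:
        rng = np.random.default_rng(0)
    n_slices, n_rows, n_cols = spec.volume_shape

    start = int(rng.integers(0, n_slices - spec.n_lesion_slices + 1))
    middle_offset = (spec.n_lesion_slices - 1) // 2

    # Shared middle-slice sampler: identical marginal appearance for both
    # classes. The placement margin covers the worst-case cross-slice
    # excursion, so the first draw is accepted for either class and the
    # accepted middle-slice distribution is exactly class-independent.
    margin = (
        spec.lesion_radius_px_range[1]
        + spec.box_margin_px
        + spec.drift_px * (spec.n_lesion_slices // 2 + 1)
    )
    a = rng.uniform(*spec.lesion_radius_px_range)
    b = rng.uniform(*spec.lesion_radius_px_range)
    angle = rng.uniform(0.0, np.pi)

    for _attempt in range(100):
        middle = np.array(
            [
                rng.uniform(margin, n_rows - 1 - margin),
                rng.uniform(margin, n_cols - 1 - margin),
            ]
        )
        centers, _direction = _lesion_centers(
            class_label, middle, spec.n_lesion_slices, spec.drift_px, rng
        )
        reach = max(a, b) + spec.box_margin_px
        if all(
            reach <= c[0] <= n_rows - 1 - reach and reach <= c[1] <= n_cols - 1 - reach
            for c in centers
        ):
            break
    else:
        raise RuntimeError("could not place lesion inside the volume")

    hu = spec.background_hu + rng.normal(0.0, spec.noise_sigma_hu, size=spec.volume_shape)
    annotations = []
    for j, center in enumerate(centers):
        slice_idx = start + j
        hu[slice_idx] += spec.lesion_contrast_hu * _soft_ellipse(
            (n_rows, n_cols), center, (a, b), angle
        )
        half = max(a, b) + spec.box_margin_px
        y0, x0 = int(np.floor(center[0] - half)), int(np.floor(center[1] - half))
        y1, x1 = int(np.ceil(center[0] + half)), int(np.ceil(center[1] + half))
        annotations.append(
            BoxAnnotation(
                patient_id=patient_id,
                slice_index=slice_idx,
                box=(x0, y0, x1 - x0, y1 - y0),
                label=DEFAULT_LABEL_MAP[class_label],
            )
        )

    stored = np.rint(hu + 1024.0).astype(np.int16)
    volume = CTVolume(
        patient_id=patient_id,
        slices=stored,
        rescale_slope=1.0,
        rescale_intercept=-1024.0,
        pixel_spacing=(0.7, 0.7),
        slice_positions=[i * spec.slice_thickness_mm for i in range(n_slices)],
        slice_thickness=spec.slice_thickness_mm,
    )
    for ann in annotations:
        ann.validate_against(volume)
    return volume, annotations


def generate_cohort(
    n_patients_per_class: int,
    spec: PhantomSpec = PhantomSpec(),
    seed: int = 0,
    out_dir: str | Path | None = None,
) -> tuple[dict[str, CTVolume], list[BoxAnnotation], Manifest]:
    """Generate a two-class phantom cohort (one volume per synthetic patient).

    Returns the volumes, the annotations, and a manifest with one record per
    annotated slice (``image_ref`` = ``patient_id:slice_index``). When
    ``out_dir`` is given, also writes each volume as a DICOM series under
    ``out_dir/dicom/<patient_id>/`` plus ``annotations.csv`` and
    ``manifest.csv`` — the same formats the I/O layer reads back.
    """
    if n_patients_per_class < 1:
        raise ValueError("need >= 1 patient per class")
    volumes: dict[str, CTVolume] = {}
    annotations: list[BoxAnnotation] = []
    records: list[ManifestRecord] = []
    for c_idx, class_label in enumerate(CLASS_NAMES):
        for i in range(n_patients_per_class):
            patient_id = f"{class_label[:3]}{i:04d}"
            rng = np.random.default_rng((seed, c_idx, i))
            volume, anns = generate_phantom_volume(class_label, spec, rng, patient_id)
            volumes[patient_id] = volume
            annotations.extend(anns)
            for ann in anns:
                records.append(
                    ManifestRecord(
                        image_ref=f"{patient_id}:{ann.slice_index}",
                        patient_id=patient_id,
                        label=ann.label,
                    )
                )
    manifest = Manifest(records)
    if out_dir is not None:
        out_dir = Path(out_dir)
        for patient_id, volume in volumes.items():
            write_dicom_series(volume, out_dir / "dicom" / patient_id)
        write_annotation_table(annotations, out_dir / "annotations.csv")
        manifest.to_csv(out_dir / "manifest.csv")
    return volumes, annotations, manifest
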