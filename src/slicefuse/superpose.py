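"""RGB slice superposition (2.5D encoding) plus augmentation and balancing.

A superposition image packs three consecutive axial slice crops into the
channels of one 8-bit RGB image:

* red   = previous slice,
* green = the annotated (current) slice,
* blue  = next slice,

all cropped at the *current* slice's annotation box, windowed to display
intensities and resized to a square model resolution. A 2D classifier fed
such images sees the cross-slice evolution of the lesion — the information a
3D network would extract from the stack — at 2D cost.

The "original image" baseline arm replicates the current-slice crop across
all three channels so both arms share one classifier input shape.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage
from skimage.transform import resize as _sk_resize

from .io import BoxAnnotation, CTVolume, WindowSpec, _round_half_away, window_to_uint8

__all__ = [
    "SuperpositionImage",
    "AugmentParams",
    "extract_triplet",
    "crop_window_resize",
    "make_superposition",
    "make_single_slice",
    "augment_image",
    "balance_classes",
]

#: Square input resolutions of the three standard pretrained backbones.
DEFAULT_RESOLUTIONS = (224, 260, 380)


@dataclass(frozen=True)
class SuperpositionImage:
    """An H x W x 3 fused image with fixed channel semantics (R=prev, G=cur, B=next)."""

    pixels: np.ndarray
    resolution: int
    source: tuple[str, int, str]  # (patient_id, slice_index, label)
    fake: bool = False

    def __post_init__(self) -> None:
        p = self.pixels
        if p.ndim != 3 or p.shape != (self.resolution, self.resolution, 3):
            raise ValueError(f"expected {self.resolution}^2 x3 image, got {p.shape}")
        if p.dtype != np.uint8:
            raise ValueError("pixels must be uint8")

    @property
    def patient_id(self) -> str:
        return self.source[0]

    @property
    def label(self) -> str:
        return self.source[2]


@dataclass(frozen=True)
class AugmentParams:
    """Ranges for the geometric augmentations (rotation, shifts, zoom).

    Shifts are fractions of the image side, applied to width and height
    independently; zoom is a magnification factor about the image center.
    """

    rotation_deg_range: tuple[float, float] = (-15.0, 15.0)
    shift_frac_range: tuple[float, float] = (-0.10, 0.10)
    zoom_range: tuple[float, float] = (0.9, 1.1)
    seed: int = 0

    def __post_init__(self) -> None:
        for lo, hi in (self.rotation_deg_range, self.shift_frac_range, self.zoom_range):
            if lo > hi:
                raise ValueError("ranges must be ordered (lo <= hi)")
        if self.zoom_range[0] <= 0:
            raise ValueError("zoom bounds must be > 0")

    def draw(self, rng: np.random.Generator) -> dict[str, float]:
        """Sample one concrete transform from the ranges."""
        return {
            "rotation_deg": rng.uniform(*self.rotation_deg_range),
            "shift_x_frac": rng.uniform(*self.shift_frac_range),
            "shift_y_frac": rng.uniform(*self.shift_frac_range),
            "zoom": rng.uniform(*self.zoom_range),
        }


def extract_triplet(volume: CTVolume, slice_index: int) -> tuple[int, int, int]:
    """Indices of the (previous, current, next) slices, clamped at volume edges."""
    n = volume.n_slices
    if n < 1:
        raise ValueError("empty volume")
    i = int(slice_index)
    if not 0 <= i < n:
        raise IndexError(f"slice_index {i} outside [0, {n})")
    return (max(i - 1, 0), i, min(i + 1, n - 1))


def crop_window_resize(
    volume: CTVolume,
    slice_index: int,
    box: tuple[int, int, int, int],
    window: WindowSpec,
    resolution: int,
) -> np.ndarray:
    """Crop one slice at ``box``, convert to HU, window to 8 bits, resize.

    Resizing is bilinear on the windowed intensities; the result is
    re-quantized with the same half-away-from-zero rule.
    """
    x0, y0, w, h = box
    rows, cols = volume.shape
    if x0 < 0 or y0 < 0 or x0 + w > cols or y0 + h > rows:
        raise ValueError(f"box {box} outside slice bounds {(rows, cols)}")
    crop = volume.hu(slice_index)[y0 : y0 + h, x0 : x0 + w]
    display = window_to_uint8(crop, window)
    if display.shape == (resolution, resolution):
        return display
    resized = _sk_resize(
        display.astype(np.float64),
        (resolution, resolution),
        order=1,
        mode="edge",
        anti_aliasing=False,
        preserve_range=True,
    )
    return _round_half_away(np.clip(resized, 0, 255)).astype(np.uint8)


def make_superposition(
    volume: CTVolume,
    annotation: BoxAnnotation,
    window: WindowSpec = WindowSpec(),
    resolution: int = 224,
) -> SuperpositionImage:
    """Fuse the (prev, current, next) crops of ``annotation`` into one RGB image.

    All three slices are cropped at the current slice's box, so any in-plane
    displacement of the lesion between slices is preserved inside the crop.
    Deterministic for fixed inputs.
    """
    annotation.validate_against(volume)
    prev_i, cur_i, next_i = extract_triplet(volume, annotation.slice_index)
    channels = [
        crop_window_resize(volume, i, annotation.box, window, resolution)
        for i in (prev_i, cur_i, next_i)
    ]
    return SuperpositionImage(
        pixels=np.stack(channels, axis=-1),
        resolution=resolution,
        source=(annotation.patient_id, annotation.slice_index, annotation.label),
    )


def make_single_slice(
    volume: CTVolume,
    annotation: BoxAnnotation,
    window: WindowSpec = WindowSpec(),
    resolution: int = 224,
) -> SuperpositionImage:
    """Baseline arm: the current-slice crop replicated across all 3 channels."""
    annotation.validate_against(volume)
    g = crop_window_resize(volume, annotation.slice_index, annotation.box, window, resolution)
    return SuperpositionImage(
        pixels=np.stack([g, g, g], axis=-1),
        resolution=resolution,
        source=(annotation.patient_id, annotation.slice_index, annotation.label),
    )


def _affine_matrix(
    rotation_deg: float, shift_x: float, shift_y: float, zoom: float, shape: tuple[int, int]
) -> tuple[np.ndarray, np.ndarray]:
    """Inverse (output -> input) affine map for rotation -> shift -> zoom.

    The transform is taken about the image center ``(H-1)/2, (W-1)/2`` in
    (row, col) coordinates, so a 180 degree rotation of an even-sized image is
    an exact index reversal.
    """
    h, w = shape
    center = np.array([(h - 1) / 2.0, (w - 1) / 2.0])
    theta = np.deg2rad(rotation_deg)
    rot = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
    # forward map: p -> zoom * rot(p - c) + c + t ; invert for ndimage
    t = np.array([shift_y, shift_x])
    inv = rot.T / zoom
    offset = center - inv @ (center + t)
    return inv, offset


def augment_image(
    image: np.ndarray,
    params: AugmentParams | None = None,
    draw: dict[str, float] | None = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Apply one random geometric transform (rotation, shifts, zoom) to an image.

    ``draw`` supplies the concrete transform; if absent it is sampled from
    ``params`` with ``rng`` (or a Generator seeded from ``params.seed``). The
    same map (bilinear interpolation, reflect padding) is applied to every
    channel, so channel alignment — the carrier of the 2.5D signal — is
    preserved. Output has the input's shape and dtype.
    """
    if draw is None:
        if params is None:
            raise ValueError("either params or draw must be given")
        if rng is None:
            rng = np.random.default_rng(params.seed)
        draw = params.draw(rng)
    zoom = float(draw["zoom"])
    if zoom <= 0:
        raise ValueError("zoom must be > 0")
    img = np.asarray(image)
    h, w = img.shape[:2]
    matrix, offset = _affine_matrix(
        float(draw["rotation_deg"]),
        float(draw["shift_x_frac"]) * w,
        float(draw["shift_y_frac"]) * h,
        zoom,
        (h, w),
    )
    planes = img[..., None] if img.ndim == 2 else img
    out = np.empty_like(planes, dtype=np.float64)
    for c in range(planes.shape[2]):
        out[..., c] = ndimage.affine_transform(
            planes[..., c].astype(np.float64),
            matrix,
            offset=offset,
            order=1,
            mode="reflect",
        )
    if np.issubdtype(img.dtype, np.integer):
        info = np.iinfo(img.dtype)
        out = _round_half_away(np.clip(out, info.min, info.max))
    result = out[..., 0] if img.ndim == 2 else out
    return result.astype(img.dtype)


def balance_classes(
    records: list[SuperpositionImage],
    params: AugmentParams | None = None,
    target_ratio: float = 1.0,
    seed: int | None = None,
) -> list[SuperpositionImage]:
    """Oversample the minority class with augmented copies until parity.

    Intended for TRAINING records only. Synthesizes
    ``round(target_ratio * majority_count) - minority_count`` augmented
    copies of minority records (cycling through them, fresh random draws each
    time), appends them flagged ``fake=True``, and never removes originals.
    """
    if params is None:
        params = AugmentParams()
    labels = [r.label for r in records]
    counts: dict[str, int] = {}
    for lab in labels:
        counts[lab] = counts.get(lab, 0) + 1
    if len(counts) < 2:
        raise ValueError("balancing needs records from both classes")
    minority_label = min(counts, key=lambda k: (counts[k], k))
    majority = max(counts.values())
    minority = counts[minority_label]
    if minority == 0:
        raise ValueError("empty minority class")
    n_fake = int(round(target_ratio * majority)) - minority
    if n_fake <= 0:
        return list(records)
    rng = np.random.default_rng(params.seed if seed is None else seed)
    pool = [r for r in records if r.label == minority_label]
    fakes = []
    for j in range(n_fake):
        src = pool[j % len(pool)]
        pixels = augment_image(src.pixels, draw=params.draw(rng))
        fakes.append(replace(src, pixels=pixels, fake=True))
    return list(records) + fakes
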