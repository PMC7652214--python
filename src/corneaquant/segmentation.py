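"""Green-channel extraction and binary segmentation of the cornea band.

Stained tissue is darker than the slide background, so after Otsu
thresholding on the green channel the *low*-intensity class is tissue.
Morphological cleanup (small-object removal, hole filling, closing)
precedes selection of the largest connected component, which is taken to
be the cornea.
"""

from __future__ import annotations

import numpy as np
from skimage import measure, morphology

__all__ = [
    "SegmentationError",
    "extract_green",
    "otsu_threshold",
    "segment_cornea",
]


class SegmentationError(RuntimeError):
    """Raised when no cornea region survives thresholding/filtering."""


def extract_green(image: np.ndarray) -> np.ndarray:
    """Return the green channel of an H×W×3 RGB image, unchanged.

    All quantification downstream operates on the green channel only.
    """
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError(
            f"expected an H×W×3 RGB image, got shape {image.shape}"
        )
    return image[:, :, 1]


def otsu_threshold(image: np.ndarray) -> int:
    """Otsu threshold over the 256-bin grey histogram.

    Returns the integer threshold t maximizing the between-class variance
    of the split {pixels <= t} vs {pixels > t}; among ties the smallest t
    is returned.  Raises on a constant image, where no split exists.
    """
    image = np.asarray(image)
    vals = np.clip(np.rint(image), 0, 255).astype(np.int64).ravel()
    if vals.max() == vals.min():
        raise ValueError("constant image: Otsu threshold is undefined")
    hist = np.bincount(vals, minlength=256).astype(float)
    n = hist.sum()
    w0 = np.cumsum(hist) / n  # P(class low) for t = 0..255
    mu = np.cumsum(hist * np.arange(256)) / n
    mu_t = mu[-1]
    w1 = 1.0 - w0
    with np.errstate(divide="ignore", invalid="ignore"):
        between = (mu_t * w0 - mu) ** 2 / (w0 * w1)
    between[~np.isfinite(between)] = -np.inf
    return int(np.argmax(between))  # argmax takes the smallest maximizer


def segment_cornea(
    green: np.ndarray,
    min_object_area: float | None = None,
    closing_radius: int = 5,
) -> np.ndarray:
    """Binary cornea mask from the green channel.

    Steps: Otsu binarization (tissue = low class); removal of objects and
    holes smaller than ``min_object_area`` (default 0.1% of the image);
    morphological closing with a disk of ``closing_radius``; largest
    connected component (8-connectivity).  Raises
    :class:`SegmentationError`, naming the stage, if the mask empties.
    """
    green = np.asarray(green)
    t = otsu_threshold(green)
    tissue = green <= t
    if not tissue.any():
        raise SegmentationError("thresholding produced an empty mask")

    if min_object_area is None:
        min_object_area = 0.001 * green.size
    min_object_area = int(max(1, min_object_area))

    # "smaller than min_object_area" == size <= min_object_area - 1
    tissue = morphology.remove_small_objects(
        tissue, max_size=min_object_area - 1, connectivity=2
    )
    if not tissue.any():
        raise SegmentationError("small-object removal emptied the mask")
    tissue = morphology.remove_small_holes(tissue, max_size=min_object_area - 1)
    if closing_radius > 0:
        tissue = morphology.closing(tissue, morphology.disk(closing_radius))
        # closing can re-open tiny pockets at the border; re-fill
        tissue = morphology.remove_small_holes(
            tissue, max_size=min_object_area - 1
        )

    labels = measure.label(tissue, connectivity=2)
    if labels.max() == 0:
        raise SegmentationError("morphological cleanup emptied the mask")
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    return labels == int(np.argmax(counts))
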