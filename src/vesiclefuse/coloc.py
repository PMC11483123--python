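"""Pixel- and object-based two-channel colocalization (Pearson, Manders M1/M2).

Matches the JACoP-style readouts: Pearson's correlation of pixel
intensities, Manders' overlap coefficients above per-channel thresholds
(Otsu by default), and an object-based containment fraction between
segmented puncta.  Analysis can be restricted to a neurite mask so empty
background does not inflate the correlation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.ndimage as ndi
from skimage.filters import threshold_otsu

__all__ = ["ColocResult", "pearson", "manders", "object_containment", "colocalize"]


@dataclass(frozen=True)
class ColocResult:
    pearson_r: float
    manders_m1: float
    manders_m2: float
    threshold_a: float
    threshold_b: float
    object_frac_ab: float | None = None
    object_frac_ba: float | None = None


def _masked(image: np.ndarray, mask: np.ndarray | None) -> np.ndarray:
    image = np.asarray(image, dtype=float)
    if mask is None:
        return image.ravel()
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != image.shape:
        raise ValueError("mask shape must match images")
    if not mask.any():
        raise ValueError("mask is empty")
    return image[mask]


def pearson(image_a: np.ndarray, image_b: np.ndarray,
            mask: np.ndarray | None = None) -> float:
    """Pearson correlation of pixel intensities within the mask."""
    if np.shape(image_a) != np.shape(image_b):
        raise ValueError("images must have equal shapes")
    a = _masked(image_a, mask)
    b = _masked(image_b, mask)
    if np.std(a) == 0 or np.std(b) == 0:
        raise ValueError("zero variance in a channel; Pearson undefined")
    return float(np.corrcoef(a, b)[0, 1])


def manders(image_a: np.ndarray, image_b: np.ndarray,
            threshold_a: float | None = None, threshold_b: float | None = None,
            mask: np.ndarray | None = None) -> tuple[float, float]:
    """Manders M1/M2 above per-channel thresholds (Otsu when not given).

    M1 = fraction of supra-threshold A intensity lying where B is
    supra-threshold; M2 symmetric.
    """
    if np.shape(image_a) != np.shape(image_b):
        raise ValueError("images must have equal shapes")
    a = _masked(image_a, mask)
    b = _masked(image_b, mask)
    ta = threshold_otsu(a) if threshold_a is None else threshold_a
    tb = threshold_otsu(b) if threshold_b is None else threshold_b
    fa, fb = a > ta, b > tb
    if not fa.any() or not fb.any():
        raise ValueError("no supra-threshold pixels in a channel")
    m1 = float(a[fa & fb].sum() / a[fa].sum())
    m2 = float(b[fa & fb].sum() / b[fb].sum())
    return m1, m2


def object_containment(labels_a: np.ndarray, labels_b: np.ndarray,
                       dilate_px: int = 1) -> tuple[float, float]:
    """Fraction of A puncta containing a B punctum centroid, and vice versa.

    A punctum "contains" the other channel when at least one centroid of
    the other channel falls inside its footprint dilated by ``dilate_px``.
    Inputs are labeled images (0 = background), e.g. from
    :func:`vesiclefuse.morpho.detect_puncta`.
    """

    def frac(lab_src: np.ndarray, lab_other: np.ndarray) -> float:
        ids = np.unique(lab_src)
        ids = ids[ids > 0]
        if len(ids) == 0:
            raise ValueError("no puncta in denominator channel")
        centroids = ndi.center_of_mass(lab_other > 0, lab_other,
                                       np.unique(lab_other[lab_other > 0]))
        pts = np.rint(np.asarray(centroids)).astype(int) if len(centroids) else \
            np.empty((0, 2), dtype=int)
        hit = 0
        for i in ids:
            foot = lab_src == i
            if dilate_px:
                foot = ndi.binary_dilation(foot, iterations=dilate_px)
            if any(foot[r, c] for r, c in pts
                   if 0 <= r < foot.shape[0] and 0 <= c < foot.shape[1]):
                hit += 1
        return hit / len(ids)

    return frac(labels_a, labels_b), frac(labels_b, labels_a)


def colocalize(image_a: np.ndarray, image_b: np.ndarray,
               mask: np.ndarray | None = None,
               threshold_a: float | None = None,
               threshold_b: float | None = None,
               labels_a: np.ndarray | None = None,
               labels_b: np.ndarray | None = None) -> ColocResult:
    """All pixel-based coefficients (plus object fractions when labels given)."""
    a = _masked(image_a, mask)
    b = _masked(image_b, mask)
    ta = threshold_otsu(a) if threshold_a is None else threshold_a
    tb = threshold_otsu(b) if threshold_b is None else threshold_b
    r = pearson(image_a, image_b, mask)
    m1, m2 = manders(image_a, image_b, ta, tb, mask)
    fab = fba = None
    if labels_a is not None and labels_b is not None:
        fab, fba = object_containment(labels_a, labels_b)
    return ColocResult(r, m1, m2, float(ta), float(tb), fab, fba)
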