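"""Hyperspectral image handling: spectral-class segmentation and ROI spectra.

Pixels are partitioned into spectral classes by seeded k-means on
L2-normalized spectra, which distinguishes background, single sheets and
sheet-overlap regions by spectrum shape and brightness.  Region-of-
interest spectra are pixelwise sums over a mask, handed to the lineshape
fitter for susceptibility extraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.cluster import KMeans
from sklearn.utils.validation import check_is_fitted

from .cube import HyperspectralCube, load_cube, save_cube  # noqa: F401 (re-export)
from .lineshape import ANALYSIS_CENTER, Spectrum

__all__ = [
    "LabelMap",
    "SpectralClassSegmenter",
    "segment_spectral_classes",
    "sum_roi",
    "roi_mask_from_box",
]


@dataclass
class LabelMap:
    """Per-pixel spectral-class labels; class 0 is the background."""

    labels: np.ndarray
    class_spectra: np.ndarray  # (k, n_wavenumber) mean spectrum per class
    pixel_counts: np.ndarray
    no_structure: bool = False
    meta: dict = field(default_factory=dict)

    def mask(self, label: int) -> np.ndarray:
        return self.labels == label


class SpectralClassSegmenter(BaseEstimator):
    """Seeded k-means segmentation of cube pixels by normalized spectrum.

    Each pixel spectrum is standardized (mean removed, unit variance — the
    standard normal variate transform), which suppresses the flat detector
    baseline so that clustering sees band shape and relative strength.

    Parameters
    ----------
    n_classes : int, default 2
        Number of spectral classes (including background).
    polarization : str, default "SSS"
        Polarization combination whose plane is clustered.
    random_state : int or None
        Seed for the k-means initialization (deterministic given a seed).

    After :meth:`fit`, ``labels_`` holds the per-pixel classes relabelled
    so that class 0 has the lowest mean 2910 cm-1 intensity (background)
    and the remaining classes are ordered by increasing brightness.
    ``no_structure_`` flags segmentations whose classes are not separated
    beyond what k-means carves out of pure noise.
    """

    def __init__(self, n_classes: int = 2, polarization: str = "SSS", random_state=None):
        self.n_classes = n_classes
        self.polarization = polarization
        self.random_state = random_state

    def fit(self, cube: HyperspectralCube):
        if self.n_classes < 2:
            raise ValueError("need at least 2 spectral classes")
        plane = cube.plane(self.polarization)
        ny, nx, nw = plane.shape
        if self.n_classes > ny * nx:
            raise ValueError(
                f"n_classes={self.n_classes} exceeds pixel count {ny * nx}"
            )
        X = plane.reshape(-1, nw)
        centered = X - X.mean(axis=1, keepdims=True)
        scale = centered.std(axis=1, keepdims=True) * np.sqrt(nw)
        Xn = np.divide(centered, scale, out=np.zeros_like(X), where=scale > 0)
        km = KMeans(
            n_clusters=self.n_classes,
            n_init=10,
            random_state=None if self.random_state is None else int(self.random_state),
        ).fit(Xn)
        raw = km.labels_.reshape(ny, nx)
        i2910 = int(np.argmin(np.abs(cube.wavenumber - ANALYSIS_CENTER)))
        brightness = np.array(
            [plane[raw == c, i2910].mean() for c in range(self.n_classes)]
        )
        order = np.argsort(brightness)  # background = dimmest at 2910
        relabel = np.empty(self.n_classes, dtype=int)
        relabel[order] = np.arange(self.n_classes)
        self.labels_ = relabel[raw]
        self.class_spectra_ = np.stack(
            [X[self.labels_.ravel() == c].mean(axis=0) for c in range(self.n_classes)]
        )
        self.pixel_counts_ = np.bincount(
            self.labels_.ravel(), minlength=self.n_classes
        )
        centers = km.cluster_centers_
        seps = [
            np.linalg.norm(centers[i] - centers[j])
            for i in range(self.n_classes)
            for j in range(i + 1, self.n_classes)
        ]
        # normalized-spectrum centroids of noise-only classes sit within
        # O(1/sqrt(n_wavenumber)) of each other; real spectral classes are O(1)
        self.max_class_separation_ = float(max(seps))
        self.no_structure_ = self.max_class_separation_ < 0.5
        return self

    def predict(self, cube: HyperspectralCube) -> np.ndarray:
        check_is_fitted(self, "labels_")
        return self.labels_

    def label_map(self, cube: HyperspectralCube) -> LabelMap:
        check_is_fitted(self, "labels_")
        return LabelMap(
            labels=self.labels_,
            class_spectra=self.class_spectra_,
            pixel_counts=self.pixel_counts_,
            no_structure=self.no_structure_,
            meta={
                "polarization": self.polarization,
                "n_classes": self.n_classes,
                "max_class_separation": self.max_class_separation_,
            },
        )


def segment_spectral_classes(
    cube: HyperspectralCube, k: int, seed=None, polarization: str = "SSS"
) -> LabelMap:
    """Cluster cube pixels into ``k`` spectral classes (background = 0)."""
    seg = SpectralClassSegmenter(n_classes=k, polarization=polarization, random_state=seed)
    return seg.fit(cube).label_map(cube)


def sum_roi(cube: HyperspectralCube, mask: np.ndarray, polarization: str) -> Spectrum:
    """Pixelwise sum spectrum over a region of interest.

    The mask may be boolean (image-shaped) or an (n, 2) array of (y, x)
    indices.  The pixel count is recorded in the spectrum's provenance.
    """
    plane = cube.plane(polarization)
    ny, nx, _ = plane.shape
    mask = np.asarray(mask)
    if mask.dtype == bool:
        if mask.shape != (ny, nx):
            raise ValueError(f"boolean mask shape {mask.shape} != image shape {(ny, nx)}")
        sel = mask
    else:
        if mask.ndim != 2 or mask.shape[1] != 2:
            raise ValueError("index mask must be (n, 2) of (y, x) pairs")
        if (
            mask[:, 0].min() < 0 or mask[:, 0].max() >= ny
            or mask[:, 1].min() < 0 or mask[:, 1].max() >= nx
        ):
            raise ValueError("mask indices out of image bounds")
        sel = np.zeros((ny, nx), dtype=bool)
        sel[mask[:, 0], mask[:, 1]] = True
    n_pixels = int(sel.sum())
    if n_pixels == 0:
        raise ValueError("empty ROI mask")
    summed = plane[sel].sum(axis=0)
    return Spectrum(
        wavenumber=cube.wavenumber,
        intensity=summed,
        polarization=polarization,
        provenance={"n_pixels": n_pixels},
    )


def roi_mask_from_box(shape, box, base_mask: np.ndarray | None = None) -> np.ndarray:
    """Rectangular ROI ``(y0, y1, x0, x1)`` intersected with an optional mask.

    Emulates drawing an analysis box around one sheet and keeping only the
    pixels its spectral class occupies.
    """
    ny, nx = shape
    y0, y1, x0, x1 = box
    if not (0 <= y0 < y1 <= ny and 0 <= x0 < x1 <= nx):
        raise ValueError(f"box {box} outside image bounds {(ny, nx)}")
    m = np.zeros((ny, nx), dtype=bool)
    m[y0:y1, x0:x1] = True
    if base_mask is not None:
        m &= np.asarray(base_mask, dtype=bool)
    return m
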