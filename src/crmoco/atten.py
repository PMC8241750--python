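"""MR-based 4-tissue attenuation correction map.

The motion-compensated water/fat image is segmented into air, lung, fat
and soft tissue by k-means clustering in the (|W|, |F|) feature plane;
clusters are identified post hoc from their centroids (air = smallest
total magnitude, lung = next, fat = larger fat fraction of the remaining
two).  Stent-induced signal voids — small air/lung-class components fully
enclosed by the body — are inpainted from their surroundings before linear
attenuation coefficients at 511 keV are assigned per class.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy import ndimage
from sklearn.cluster import KMeans

from ._utils import warp_image

log = logging.getLogger(__name__)

CLS_AIR, CLS_LUNG, CLS_FAT, CLS_SOFT = 0, 1, 2, 3
CLASS_NAMES = {CLS_AIR: "air", CLS_LUNG: "lung", CLS_FAT: "fat", CLS_SOFT: "soft"}


@dataclass
class TissueClassMap:
    classes: np.ndarray  # int per pixel in {0..3}
    centroids: np.ndarray  # (4, 2) mean (|W|, |F|) per class, class-ordered
    pixel_size: float


@dataclass
class MuAssignment:
    """Class -> linear attenuation coefficient (1/cm) at 511 keV.

    Standard literature values; must satisfy soft > fat > lung > air >= 0.
    """

    mu: dict = dc_field(default_factory=lambda: {
        CLS_AIR: 0.0, CLS_LUNG: 0.0224, CLS_FAT: 0.0864, CLS_SOFT: 0.0975,
    })

    def validate(self):
        if any(v < 0 for v in self.mu.values()):
            raise ValueError("attenuation coefficients must be >= 0")
        if not (self.mu[CLS_SOFT] > self.mu[CLS_FAT] > self.mu[CLS_LUNG] >= self.mu[CLS_AIR]):
            raise ValueError("expected soft > fat > lung > air ordering")


@dataclass
class MuMap:
    mu: np.ndarray  # 1/cm
    pixel_size: float
    provenance: str  # "reference" | "static" | "warped-to-bin <i>"


def segment_tissues(image, seed: int = 0) -> TissueClassMap:
    """k-means (k=4) segmentation of a water/fat image into the four
    attenuation classes.  ``image`` needs ``water``/``fat`` attributes
    (complex ok) and ``pixel_size``."""
    w = np.abs(np.asarray(image.water))
    f = np.abs(np.asarray(image.fat))
    if not (np.all(np.isfinite(w)) and np.all(np.isfinite(f))):
        raise ValueError("image magnitudes must be finite")
    feats = np.stack([w.ravel(), f.ravel()], axis=1)
    if np.unique(feats, axis=0).shape[0] < 4:
        raise ValueError("fewer than 4 distinct feature values; cannot segment")
    km = KMeans(n_clusters=4, init="k-means++", n_init=4, random_state=seed)
    raw = km.fit_predict(feats)
    cent = km.cluster_centers_
    total = cent.sum(axis=1)
    order = np.argsort(total)
    remap = np.empty(4, dtype=int)
    remap[order[0]] = CLS_AIR
    remap[order[1]] = CLS_LUNG
    a, b = order[2], order[3]
    frac = cent[:, 1] / np.maximum(cent.sum(axis=1), 1e-12)
    fat_cl, soft_cl = (a, b) if frac[a] > frac[b] else (b, a)
    remap[fat_cl] = CLS_FAT
    remap[soft_cl] = CLS_SOFT
    classes = remap[raw].reshape(w.shape)
    centroids = np.zeros((4, 2))
    for k in range(4):
        centroids[remap[k]] = cent[k]
    return TissueClassMap(classes=classes.astype(np.int16), centroids=centroids,
                          pixel_size=float(image.pixel_size))


def inpaint_stent(classes: TissueClassMap, max_area_mm2: float = 200.0) -> TissueClassMap:
    """Reassign small signal-void components to their surroundings.

    Air/lung components that lie strictly inside the body mask (largest
    non-air component, hole-filled) and are smaller than ``max_area_mm2``
    take the majority class of a one-pixel dilated boundary ring.
    Idempotent; lungs are untouched through the size/enclosure criteria.
    """
    cls = classes.classes.copy()
    px_area = classes.pixel_size**2
    body = cls != CLS_AIR
    lab_body, n_body = ndimage.label(body)
    if n_body == 0:
        return TissueClassMap(cls, classes.centroids.copy(), classes.pixel_size)
    sizes = ndimage.sum_labels(np.ones_like(lab_body), lab_body, np.arange(1, n_body + 1))
    body_mask = ndimage.binary_fill_holes(lab_body == (1 + int(np.argmax(sizes))))
    interior = ndimage.binary_erosion(body_mask)
    void_like = np.isin(cls, (CLS_AIR, CLS_LUNG))
    lab_v, n_v = ndimage.label(void_like)
    for i in range(1, n_v + 1):
        comp = lab_v == i
        area = comp.sum() * px_area
        if area > max_area_mm2:
            continue
        if not np.all(interior[comp]):
            continue  # touches the body boundary: not an enclosed void
        ring = ndimage.binary_dilation(comp, iterations=2) & ~comp & body_mask
        if not np.any(ring):
            continue
        vals, counts = np.unique(cls[ring], return_counts=True)
        target = int(vals[np.argmax(counts)])
        if np.all(cls[comp] == target):
            continue
        cls[comp] = target
        log.info("inpainted void component of %.0f mm^2 with class %s",
                 area, CLASS_NAMES[target])
    return TissueClassMap(cls, classes.centroids.copy(), classes.pixel_size)


def assign_mu(classes: TissueClassMap, table: MuAssignment | None = None) -> MuMap:
    table = table or MuAssignment()
    table.validate()
    present = np.unique(classes.classes)
    missing = [int(c) for c in present if int(c) not in table.mu]
    if missing:
        raise KeyError(f"no attenuation value for class(es) {missing}")
    lut = np.zeros(int(max(table.mu)) + 1)
    for k, v in table.mu.items():
        lut[k] = v
    return MuMap(mu=lut[classes.classes], pixel_size=classes.pixel_size,
                 provenance="reference")


def warp_mu(mu: MuMap, field) -> MuMap:
    """Warp the reference-state mu-map into a motion state along the
    pull-back displacement field (linear interpolation, air fill)."""
    disp = field.disp if hasattr(field, "disp") else np.asarray(field)
    if disp.shape[1:] != mu.mu.shape:
        raise ValueError("displacement field and mu-map grids differ")
    out = warp_image(mu.mu, disp, mu.pixel_size, order=1, cval=0.0)
    return MuMap(mu=np.maximum(out, 0.0), pixel_size=mu.pixel_size,
                 provenance="warped")
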