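"""Nucleus segmentation from maximum-intensity projections.

Implements the liver-protocol mask pipeline: Otsu threshold on the MIP of
the nuclear-stain channel (with a multiplicative user adjustment), a
binary median filter over a 2-pixel-radius disk, distance-transform
watershed to separate touching nuclei, hole filling, small-object and
border policies, and consecutive relabelling.  The resulting 2D outlines
are extruded unchanged across z to define the volumes in which foci are
counted.

Cell-class assignment is either manual (the reference procedure: classes
assigned by eye from shape and staining) or an automatic convenience rule
on measured shape/intensity features: elongated nuclei are called
non-hepatocytes; large, circular nuclei with bright heterochromatin are
called hepatocytes; everything else is left unassigned.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.filters import threshold_otsu
from skimage.morphology import local_maxima, reconstruction
from skimage.measure import regionprops_table
from skimage.segmentation import watershed as _watershed

from .stack_io import Image2D

logger = logging.getLogger(__name__)

UNASSIGNED = "unassigned"


@dataclass(frozen=True)
class SegmentationParams:
    """Parameters of the mask pipeline.

    ``threshold_adjust`` multiplies the automatic Otsu level (the "user
    adjustable" knob of the reference procedure).  ``median_radius_px=2``
    selects the 13-pixel Euclidean disk.  ``seed_min_distance_px`` is the
    minimum separation of watershed seeds on the distance transform.
    """

    threshold_method: str = "otsu"
    threshold_adjust: float = 1.0
    median_radius_px: int = 2
    min_area_px: int = 50
    border_policy: str = "exclude"
    watershed_enabled: bool = True
    seed_min_distance_px: int = 5
    watershed_h_px: float = 1.5

    def __post_init__(self) -> None:
        if self.threshold_adjust <= 0:
            raise ValueError("threshold_adjust must be > 0")
        if self.median_radius_px < 0 or self.min_area_px < 0:
            raise ValueError("median_radius_px and min_area_px must be >= 0")
        if self.threshold_method != "otsu":
            raise ValueError("only 'otsu' thresholding is implemented")
        if self.border_policy not in ("exclude", "keep"):
            raise ValueError("border_policy must be 'exclude' or 'keep'")


@dataclass(frozen=True)
class ClassifierThresholds:
    """Feature cut-offs for the automatic cell-class rule."""

    hepatocyte_min_circularity: float = 0.8
    hepatocyte_min_area_px: float = 1200.0
    hepatocyte_min_heterochromatin: float = 1.18
    non_hepatocyte_min_elongation: float = 1.6


@dataclass
class NucleusLabelMap:
    """A 2D label image with per-nucleus features and class calls.

    ``labels`` uses 0 for background and consecutive positive integers for
    nuclei.  ``features`` has one row per label: area, centroid, perimeter,
    circularity (4*pi*area/perimeter^2), elongation (major/minor axis),
    mean nuclear-stain intensity and heterochromatin contrast (0.95
    quantile over median intensity inside the footprint).
    """

    labels: np.ndarray
    features: pd.DataFrame

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        present = np.unique(self.labels)
        present = present[present > 0]
        expected = np.arange(1, len(present) + 1)
        if not np.array_equal(present, expected):
            raise ValueError("labels must be consecutive positive integers")
        if set(self.features["label"]) != set(present.tolist()):
            raise ValueError("features rows must match labels present")

    @property
    def n_nuclei(self) -> int:
        return len(self.features)


def auto_threshold(image: Image2D, params: SegmentationParams | None = None) -> float:
    """Otsu's between-class-variance-maximising level times the user
    adjustment factor."""
    params = params or SegmentationParams()
    pixels = np.asarray(image.pixels)
    if np.all(pixels == pixels.flat[0]):
        raise ValueError("cannot auto-threshold a constant image")
    level = float(threshold_otsu(pixels))
    # place the level strictly between the two classes: midway between the
    # top of the background class and the smallest value above it
    above = pixels[pixels > level]
    if above.size:
        level = (level + float(above.min())) / 2.0
    return level * params.threshold_adjust


def disk_offsets(radius: int) -> np.ndarray:
    """Integer (dy, dx) offsets of the Euclidean disk, centre included."""
    r = int(radius)
    dy, dx = np.mgrid[-r : r + 1, -r : r + 1]
    keep = dy ** 2 + dx ** 2 <= r ** 2
    return np.stack([dy[keep], dx[keep]], axis=1)


def binary_median_filter(mask: np.ndarray, radius: int) -> np.ndarray:
    """Median filter of a binary mask over the Euclidean disk of ``radius``.

    Edge pixels use only their in-bounds neighbourhood.  On an even-sized
    (edge-clipped) neighbourhood the median of the two central order
    statistics is 0.5, which rounds up to foreground — i.e. the output is
    foreground iff at least half the neighbourhood is foreground.
    """
    mask = np.asarray(mask, dtype=bool)
    if radius == 0:
        return mask.copy()
    offs = disk_offsets(radius)
    r = radius
    footprint = np.zeros((2 * r + 1, 2 * r + 1), dtype=float)
    footprint[offs[:, 0] + r, offs[:, 1] + r] = 1.0
    fg = ndi.correlate(mask.astype(float), footprint, mode="constant", cval=0.0)
    n = ndi.correlate(np.ones_like(mask, dtype=float), footprint,
                      mode="constant", cval=0.0)
    return fg * 2.0 >= n


def fill_holes(mask: np.ndarray) -> np.ndarray:
    """Set to foreground every background component not connected to the
    image border."""
    return ndi.binary_fill_holes(np.asarray(mask, dtype=bool))


def _split_watershed(mask: np.ndarray, params: SegmentationParams) -> np.ndarray:
    """Distance-transform watershed of a binary mask into labels.

    Seeds are h-maxima of the distance transform (regional maxima after
    suppressing peaks shallower than ``watershed_h_px``), so a flat ridge —
    an elongated nucleus, or an annulus — stays one seed while genuinely
    touching round objects keep separate seeds.  Seed components closer
    than ``seed_min_distance_px`` (centroid distance) are merged.
    """
    if not mask.any():
        return np.zeros(mask.shape, dtype=np.int32)
    distance = ndi.distance_transform_edt(mask)
    # regional maxima of the h-reconstruction: peaks shallower than h merge
    # into their neighbour's plateau instead of seeding separately
    rec = reconstruction(distance - params.watershed_h_px, distance,
                         method="dilation")
    peaks = local_maxima(rec, connectivity=2) & mask
    markers, n = ndi.label(peaks, structure=np.ones((3, 3), dtype=bool))
    if n == 0:
        return ndi.label(mask)[0]
    if n > 1 and params.seed_min_distance_px > 0:
        cents = np.array(ndi.center_of_mass(peaks, markers,
                                            range(1, n + 1)))
        parent = list(range(n))

        def find(i):
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        for i in range(n):
            for j in range(i + 1, n):
                if np.linalg.norm(cents[i] - cents[j]) < \
                        params.seed_min_distance_px:
                    ri, rj = find(i), find(j)
                    if ri != rj:
                        parent[rj] = ri
        remap = np.zeros(n + 1, dtype=np.int32)
        roots = sorted({find(i) for i in range(n)})
        for new, root in enumerate(roots, start=1):
            for i in range(n):
                if find(i) == root:
                    remap[i + 1] = new
        markers = remap[markers]
    return _watershed(-distance, markers=markers, mask=mask)


def _fill_holes_per_label(labels: np.ndarray) -> np.ndarray:
    out = labels.copy()
    for region_slice, lab in zip(ndi.find_objects(labels),
                                 range(1, labels.max() + 1)):
        if region_slice is None:
            continue
        sub = out[region_slice]
        filled = ndi.binary_fill_holes(sub == lab)
        sub[filled & (sub == 0)] = lab
    return out


def _measure_features(labels: np.ndarray, mip: np.ndarray) -> pd.DataFrame:
    if labels.max() == 0:
        return pd.DataFrame(
            columns=["label", "area_px", "centroid_y", "centroid_x",
                     "perimeter_px", "circularity", "elongation",
                     "mean_intensity", "heterochromatin_contrast",
                     "cell_class"]
        )
    props = regionprops_table(
        labels, intensity_image=mip,
        properties=("label", "area", "centroid", "perimeter",
                    "axis_major_length", "axis_minor_length",
                    "intensity_mean"),
    )
    df = pd.DataFrame(props).rename(columns={
        "area": "area_px",
        "centroid-0": "centroid_y",
        "centroid-1": "centroid_x",
        "perimeter": "perimeter_px",
        "intensity_mean": "mean_intensity",
    })
    with np.errstate(divide="ignore", invalid="ignore"):
        df["circularity"] = np.where(
            df["perimeter_px"] > 0,
            4.0 * np.pi * df["area_px"] / df["perimeter_px"] ** 2,
            np.nan,
        )
        df["elongation"] = np.where(
            df["axis_minor_length"] > 0,
            df["axis_major_length"] / df["axis_minor_length"],
            np.inf,
        )
    contrast = []
    for lab in df["label"]:
        vals = mip[labels == lab]
        med = np.median(vals)
        contrast.append(float(np.quantile(vals, 0.95) / med) if med > 0 else np.inf)
    df["heterochromatin_contrast"] = contrast
    df["cell_class"] = UNASSIGNED
    return df.drop(columns=["axis_major_length", "axis_minor_length"])


def build_nucleus_label_map(
    mip: Image2D, params: SegmentationParams | None = None
) -> NucleusLabelMap:
    """Run the full mask pipeline on a nuclear-stain MIP.

    Order: binarize at the (adjusted) Otsu level; binary median filter;
    watershed split; fill holes; drop regions below ``min_area_px``; apply
    the border policy; relabel consecutively and measure features.
    """
    params = params or SegmentationParams()
    pixels = np.asarray(mip.pixels)
    level = auto_threshold(mip, params)
    mask = pixels > level
    mask = binary_median_filter(mask, params.median_radius_px)

    if params.watershed_enabled:
        labels = _split_watershed(mask, params)
    else:
        labels = ndi.label(mask)[0]
    labels = _fill_holes_per_label(labels)

    # area filter
    if params.min_area_px > 0 and labels.max() > 0:
        counts = np.bincount(labels.ravel())
        too_small = np.flatnonzero(counts < params.min_area_px)
        labels[np.isin(labels, too_small[too_small > 0])] = 0

    if params.border_policy == "exclude" and labels.max() > 0:
        border = np.unique(np.concatenate([
            labels[0], labels[-1], labels[:, 0], labels[:, -1]
        ]))
        labels[np.isin(labels, border[border > 0])] = 0

    # consecutive relabel (permutes labels only; footprints untouched)
    present = np.unique(labels)
    present = present[present > 0]
    remap = np.zeros(labels.max() + 1, dtype=np.int32)
    remap[present] = np.arange(1, len(present) + 1)
    labels = remap[labels]

    if labels.max() == 0:
        logger.warning("segmentation produced an empty label map")
    return NucleusLabelMap(labels=labels, features=_measure_features(labels, pixels))


def classify_nuclei(
    labelmap: NucleusLabelMap,
    rule: str = "manual",
    manual_labels: dict[int, str] | None = None,
    thresholds: ClassifierThresholds | None = None,
) -> NucleusLabelMap:
    """Assign a cell class per nucleus.

    ``rule='manual'`` copies the provided label→class mapping verbatim
    (the reference procedure).  ``rule='auto'`` applies feature cut-offs:
    elongation >= e_min → non-hepatocyte; else circularity, area and
    heterochromatin contrast all above their cut-offs → hepatocyte; else
    unassigned.
    """
    df = labelmap.features.copy()
    if rule == "manual":
        manual_labels = manual_labels or {}
        known = set(df["label"].tolist())
        for lab in manual_labels:
            if lab not in known:
                raise KeyError(f"manual class for unknown label {lab}")
        df["cell_class"] = [
            manual_labels.get(lab, UNASSIGNED) for lab in df["label"]
        ]
    elif rule == "auto":
        thr = thresholds or ClassifierThresholds()
        classes = []
        for _, row in df.iterrows():
            if row["elongation"] >= thr.non_hepatocyte_min_elongation:
                classes.append("non_hepatocyte")
            elif (
                row["circularity"] >= thr.hepatocyte_min_circularity
                and row["area_px"] >= thr.hepatocyte_min_area_px
                and row["heterochromatin_contrast"]
                >= thr.hepatocyte_min_heterochromatin
            ):
                classes.append("hepatocyte")
            else:
                classes.append(UNASSIGNED)
        df["cell_class"] = classes
    else:
        raise ValueError("rule must be 'manual' or 'auto'")
    return NucleusLabelMap(labels=labelmap.labels, features=df)


def extrude_labels_to_3d(labelmap: NucleusLabelMap, nz: int) -> np.ndarray:
    """Copy the 2D outlines unchanged across ``nz`` sections."""
    if nz < 1:
        raise ValueError("nz must be >= 1")
    return np.broadcast_to(
        labelmap.labels, (nz,) + labelmap.labels.shape
    ).copy()


@dataclass
class RoiSet:
    """Manually drawn regions of interest (testis mode).

    Each ROI is a polygon in (y, x) pixel coordinates with the number of
    nuclei it contains (supplied by the annotator).  ``to_mask`` rasterises
    the polygons into a 2D label image.
    """

    polygons: dict[str, np.ndarray]
    nucleus_counts: dict[str, int] = field(default_factory=dict)

    def to_mask(self, shape: tuple[int, int]) -> np.ndarray:
        from skimage.draw import polygon as _polygon

        mask = np.zeros(shape, dtype=np.int32)
        for i, (name, poly) in enumerate(sorted(self.polygons.items()), start=1):
            poly = np.asarray(poly, dtype=float)
            if poly.ndim != 2 or poly.shape[1] != 2:
                raise ValueError(f"ROI {name!r} must be an (n, 2) array")
            rr, cc = _polygon(poly[:, 0], poly[:, 1], shape=shape)
            mask[rr, cc] = i
        return mask
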