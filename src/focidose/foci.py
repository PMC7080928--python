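"""3D γ-H2AX focus detection in confocal z-stacks.

A focus is a coherent 3D region with exactly one local-maximum centre,
where a local maximum is a single voxel — or a connected plateau of
equal-intensity voxels — whose outside neighbours are all strictly
dimmer.  For each maximum, the local background is read off a spherical
shell of voxels six voxels (by default) from the maximum, and the focus
region is grown as the connected set of voxels above
``background + alpha * (peak - background)``.  Regions are kept only if
they are *larger than* ``min_voxels`` (strictly; 8 voxels for liver,
20 for testis).  Regions that end up containing several maxima are
either split along intensity watershed lines seeded at the maxima
(default) or rejected outright.

All radii and sizes are in voxel-index units: with a 581 nm z-step over
140 nm pixels the 6-voxel shell is strongly anisotropic in physical
space, matching a protocol that counts voxels throughout.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.measure import label as cc_label
from skimage.segmentation import watershed as _watershed

logger = logging.getLogger(__name__)

#: skimage connectivity rank per neighbour count in 3D
_CONN_RANK = {6: 1, 18: 2, 26: 3}


def _neighbor_offsets(connectivity: int) -> np.ndarray:
    offs = []
    for dz in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dx in (-1, 0, 1):
                if (dz, dy, dx) == (0, 0, 0):
                    continue
                order = abs(dz) + abs(dy) + abs(dx)
                if connectivity == 6 and order > 1:
                    continue
                if connectivity == 18 and order > 2:
                    continue
                offs.append((dz, dy, dx))
    return np.array(offs, dtype=np.int64)


@dataclass(frozen=True)
class FociParams:
    """Detection parameters.

    ``min_voxels``: strict lower size bound (region kept iff size is
    larger).  ``background_radius_vox``: shell radius r; shell voxels are
    those at Euclidean index distance within ``shell_tolerance`` of r
    (``shell_mode='ball'`` uses the filled ball instead).
    ``growth_fraction``: region threshold is
    ``background + alpha * (peak - background)``.
    ``min_prominence``: maxima with ``peak - background`` at or below this
    value (intensity units) do not seed foci.  0 disables the cut; on
    noisy data a few noise standard deviations is the usual choice —
    without it, weak shot-noise maxima grow percolating half-prominence
    regions that the single-maximum rule must then discard one by one.
    ``merge_tolerance``: when several maxima share one coherent region,
    a maximum whose peak rises less than this above the saddle towards a
    brighter maximum is treated as part of that maximum (a noise wiggle
    on its flank) rather than as a separate focus centre.  0 keeps every
    distinct maximum separate.
    """

    min_voxels: int = 8
    background_radius_vox: float = 6.0
    connectivity: int = 26
    growth_fraction: float = 0.5
    multi_max_policy: str = "split"
    background_stat: str = "mean"
    shell_tolerance: float = 0.5
    shell_mode: str = "shell"
    min_prominence: float = 0.0
    merge_tolerance: float = 0.0

    def __post_init__(self) -> None:
        if self.min_voxels < 1:
            raise ValueError("min_voxels must be >= 1")
        if self.background_radius_vox < 1:
            raise ValueError("background_radius_vox must be >= 1")
        if self.connectivity not in _CONN_RANK:
            raise ValueError("connectivity must be 6, 18 or 26")
        if not 0.0 < self.growth_fraction <= 1.0:
            raise ValueError("growth_fraction must be in (0, 1]")
        if self.multi_max_policy not in ("split", "reject"):
            raise ValueError("multi_max_policy must be 'split' or 'reject'")
        if self.background_stat not in ("mean", "median"):
            raise ValueError("background_stat must be 'mean' or 'median'")
        if self.shell_mode not in ("shell", "ball"):
            raise ValueError("shell_mode must be 'shell' or 'ball'")


TESTIS_PARAMS = FociParams(min_voxels=20)
LIVER_PARAMS = FociParams(min_voxels=8)


@dataclass
class LocalMaximum:
    """One local maximum: a voxel or an equal-intensity plateau."""

    voxels: np.ndarray  # (n, 3) int indices
    value: float
    centroid: tuple[float, float, float]
    representative: tuple[int, int, int]  # plateau voxel nearest the centroid


@dataclass
class Focus:
    id: int
    z: int
    y: int
    x: int
    peak: float
    background: float
    region: np.ndarray  # (n, 3) voxel indices
    size_vox: int
    nucleus_id: int = 0


@dataclass
class FociSet:
    foci: list[Focus]
    params: FociParams
    analysis_mode: str = "per_nucleus"
    source: str = ""

    def __len__(self) -> int:
        return len(self.foci)

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            {"focus_id": f.id, "z": f.z, "y": f.y, "x": f.x, "peak": f.peak,
             "background": f.background, "size_vox": f.size_vox,
             "nucleus_id": f.nucleus_id}
            for f in self.foci
        ]
        cols = ["focus_id", "z", "y", "x", "peak", "background", "size_vox",
                "nucleus_id"]
        return pd.DataFrame(rows, columns=cols)

    def write_csv(self, path, sidecar: bool = True) -> None:
        path = Path(path)
        self.to_dataframe().to_csv(path, index=False)
        if sidecar:
            meta = {"params": asdict(self.params),
                    "analysis_mode": self.analysis_mode, "source": self.source,
                    "n_foci": len(self.foci)}
            path.with_suffix(".json").write_text(json.dumps(meta, indent=2))


def find_local_maxima_3d(
    volume: np.ndarray, connectivity: int = 26, mask: np.ndarray | None = None
) -> list[LocalMaximum]:
    """Plateau-aware local maxima of a 3D volume.

    A maximum is a maximal connected set of equal-intensity voxels whose
    outside neighbours are all strictly lower; border voxels compare only
    in-bounds neighbours.  With ``mask`` given, only maxima whose
    representative voxel is inside the mask are returned (the comparison
    itself still uses the full volume).
    """
    volume = np.asarray(volume)
    if volume.size == 0:
        raise ValueError("volume is empty")
    offs = _neighbor_offsets(connectivity)
    footprint = np.zeros((3, 3, 3), dtype=bool)
    footprint[tuple((offs + 1).T)] = True
    footprint[1, 1, 1] = True
    # mode='nearest' replicates the edge voxel itself, which the
    # centre-inclusive footprint already contains: border voxels therefore
    # compare only in-bounds neighbours
    neigh_max = ndi.maximum_filter(volume, footprint=footprint, mode="nearest")
    candidates = volume >= neigh_max  # voxel >= all in-bounds neighbours
    if not candidates.any():
        return []

    # fast path: a candidate with no equal-valued neighbour anywhere is a
    # strict singleton maximum and needs no plateau analysis
    has_equal = np.zeros(volume.shape, dtype=bool)
    nz, ny, nx = volume.shape
    for dz, dy, dx in offs:
        a = volume[max(dz, 0) : nz + min(dz, 0),
                   max(dy, 0) : ny + min(dy, 0),
                   max(dx, 0) : nx + min(dx, 0)]
        b = volume[max(-dz, 0) : nz + min(-dz, 0),
                   max(-dy, 0) : ny + min(-dy, 0),
                   max(-dx, 0) : nx + min(-dx, 0)]
        eq = a == b
        has_equal[max(-dz, 0) : nz + min(-dz, 0),
                  max(-dy, 0) : ny + min(-dy, 0),
                  max(-dx, 0) : nx + min(-dx, 0)] |= eq

    out: list[LocalMaximum] = []
    singles = candidates & ~has_equal
    if mask is not None:
        singles &= mask
    for vz, vy, vx in np.argwhere(singles):
        vox = np.array([[vz, vy, vx]], dtype=np.int64)
        out.append(LocalMaximum(
            voxels=vox, value=float(volume[vz, vy, vx]),
            centroid=(float(vz), float(vy), float(vx)),
            representative=(int(vz), int(vy), int(vx)),
        ))

    plateau_cand = candidates & has_equal
    if not plateau_cand.any():
        return out
    cand_labels = cc_label(plateau_cand, connectivity=_CONN_RANK[connectivity])
    n_comp = cand_labels.max()
    # a candidate component is a plateau maximum only if no outside
    # neighbour shares its value (an equal outside neighbour means the true
    # equal-value plateau extends to a voxel that itself has a higher
    # neighbour, so the plateau is not a maximum); detected vectorised via
    # shifted comparisons
    bad = np.zeros(n_comp + 1, dtype=bool)
    for dz, dy, dx in offs:
        a_sl = (slice(max(dz, 0), nz + min(dz, 0)),
                slice(max(dy, 0), ny + min(dy, 0)),
                slice(max(dx, 0), nx + min(dx, 0)))
        b_sl = (slice(max(-dz, 0), nz + min(-dz, 0)),
                slice(max(-dy, 0), ny + min(-dy, 0)),
                slice(max(-dx, 0), nx + min(-dx, 0)))
        lab_b = cand_labels[b_sl]
        conflict = (volume[a_sl] == volume[b_sl]) & (lab_b > 0) & \
            (cand_labels[a_sl] != lab_b)
        if conflict.any():
            bad[np.unique(lab_b[conflict])] = True
    keep_ids = ~bad
    keep_ids[0] = False
    if mask is not None:
        # only components that touch the mask can yield an in-mask maximum
        touch = np.zeros(n_comp + 1, dtype=bool)
        touch[np.unique(cand_labels[mask & plateau_cand])] = True
        keep_ids &= touch
    if not keep_ids.any():
        return out
    surviving = keep_ids[cand_labels]
    vox_all = np.argwhere(surviving)
    labs_all = cand_labels[surviving]
    order = np.argsort(labs_all, kind="stable")
    vox_all = vox_all[order]
    labs_all = labs_all[order]
    bounds = np.flatnonzero(np.diff(labs_all)) + 1
    for vox in np.split(vox_all, bounds):
        value = volume[tuple(vox[0])]
        centroid = vox.mean(axis=0)
        rep = vox[np.argmin(((vox - centroid) ** 2).sum(axis=1))]
        if mask is not None and not mask[tuple(rep)]:
            continue
        out.append(LocalMaximum(
            voxels=vox, value=float(value),
            centroid=tuple(float(c) for c in centroid),
            representative=tuple(int(v) for v in rep),
        ))
    return out


def _shell_offsets(params: FociParams) -> np.ndarray:
    r = params.background_radius_vox
    tol = params.shell_tolerance
    m = int(math.ceil(r + tol))
    dz, dy, dx = np.mgrid[-m : m + 1, -m : m + 1, -m : m + 1]
    dist = np.sqrt(dz ** 2 + dy ** 2 + dx ** 2)
    if params.shell_mode == "shell":
        keep = (dist >= r - tol) & (dist <= r + tol)
    else:  # filled ball
        keep = dist <= r + tol
    return np.stack([dz[keep], dy[keep], dx[keep]], axis=1)


def background_at_maximum(
    volume: np.ndarray, maximum: LocalMaximum, params: FociParams | None = None,
    _offsets: np.ndarray | None = None,
) -> float:
    """Background level on the shell around a maximum's centroid.

    Near borders only in-bounds shell voxels contribute; a volume too
    small to contain any shell voxel raises ``ValueError``.
    """
    params = params or FociParams()
    offs = _offsets if _offsets is not None else _shell_offsets(params)
    centre = np.rint(np.asarray(maximum.centroid)).astype(np.int64)
    pos = centre[None, :] + offs
    inb = np.all((pos >= 0) & (pos < np.array(volume.shape)), axis=1)
    pos = pos[inb]
    if pos.shape[0] == 0:
        raise ValueError(
            "no in-bounds shell voxels: volume smaller than the background shell"
        )
    vals = volume[tuple(pos.T)]
    if params.background_stat == "mean":
        return float(np.mean(vals))
    return float(np.median(vals))


def grow_focus_region(
    volume: np.ndarray,
    maximum: LocalMaximum,
    background: float,
    params: FociParams | None = None,
    mask: np.ndarray | None = None,
) -> np.ndarray:
    """Connected region above ``background + alpha*(peak - background)``
    containing the maximum; optionally clipped to ``mask`` (boolean)."""
    params = params or FociParams()
    peak = maximum.value
    thr = background + params.growth_fraction * (peak - background)
    seed = maximum.representative
    if volume[seed] < thr or (mask is not None and not mask[seed]):
        return np.empty((0, 3), dtype=np.int64)
    # on-the-fly flood fill: regions are small, so testing voxels lazily is
    # far cheaper than thresholding the whole volume per maximum
    offs = [tuple(d) for d in _neighbor_offsets(params.connectivity)]
    nz, ny, nx = volume.shape
    visited = {seed}
    stack = [seed]
    while stack:
        vz, vy, vx = stack.pop()
        for dz, dy, dx in offs:
            w = (vz + dz, vy + dy, vx + dx)
            if w in visited:
                continue
            if not (0 <= w[0] < nz and 0 <= w[1] < ny and 0 <= w[2] < nx):
                continue
            if volume[w] >= thr and (mask is None or mask[w]):
                visited.add(w)
                stack.append(w)
    return np.array(sorted(visited), dtype=np.int64)


class _LabelEquals:
    """Lazy boolean view ``label_volume == label`` (avoids materialising a
    full-volume mask for every maximum during region growth)."""

    def __init__(self, labels: np.ndarray, label: int) -> None:
        self._labels = labels
        self._label = label

    def __getitem__(self, idx) -> bool:
        return bool(self._labels[idx] == self._label)


def detect_foci(
    volume: np.ndarray,
    params: FociParams | None = None,
    mask: np.ndarray | None = None,
    analysis_mode: str = "per_nucleus",
    source: str = "",
) -> FociSet:
    """Full focus detection on one channel volume.

    ``mask`` is an optional 3D label volume (e.g. extruded nucleus
    outlines): maxima are restricted to labelled voxels and each region is
    grown within its own label.  Without a mask the whole volume is
    searched.
    """
    params = params or FociParams()
    volume = np.asarray(volume)
    label_mask = None if mask is None else np.asarray(mask)
    bool_mask = None if label_mask is None else label_mask > 0

    maxima = find_local_maxima_3d(volume, params.connectivity, mask=bool_mask)
    shell = _shell_offsets(params)

    candidates: list[tuple[LocalMaximum, float, np.ndarray]] = []
    claimed: dict[tuple[int, int, int], list[int]] = {}
    for maximum in maxima:
        try:
            bg = background_at_maximum(volume, maximum, params, _offsets=shell)
        except ValueError:
            logger.warning("skipping maximum at %s: degenerate background shell",
                           maximum.representative)
            continue
        if maximum.value <= bg + params.min_prominence:
            continue
        grow_mask = None
        if label_mask is not None:
            grow_mask = _LabelEquals(
                label_mask, label_mask[maximum.representative]
            )
        region = grow_focus_region(volume, maximum, bg, params, mask=grow_mask)
        if region.shape[0] == 0:
            continue
        # cheap strict-size pre-filter cannot be applied yet: splitting can
        # only shrink regions, but merged regions must be reconciled first
        idx = len(candidates)
        candidates.append((maximum, bg, region))
        for v in map(tuple, region):
            claimed.setdefault(v, []).append(idx)

    # group candidates whose regions share voxels
    parent = list(range(len(candidates)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for owners in claimed.values():
        for other in owners[1:]:
            ra, rb = find(owners[0]), find(other)
            if ra != rb:
                parent[rb] = ra

    groups: dict[int, list[int]] = {}
    for i in range(len(candidates)):
        groups.setdefault(find(i), []).append(i)

    foci: list[Focus] = []
    for members in groups.values():
        if len(members) == 1:
            maximum, bg, region = candidates[members[0]]
            _append_focus(foci, maximum, bg, region, params)
            continue
        union = sorted({tuple(v) for m in members
                        for v in candidates[m][2]})
        union = np.array(union, dtype=np.int64)
        survivors = _consolidate_maxima(
            volume, union, [candidates[m][0] for m in members],
            params,
        )
        members = [members[i] for i in survivors]
        if len(members) == 1:
            maximum, bg, region = candidates[members[0]]
            _append_focus(foci, maximum, bg, region, params)
            continue
        if params.multi_max_policy == "reject":
            continue
        # split the union of overlapping regions along intensity watershed
        # lines seeded at the surviving maxima
        lo = union.min(axis=0)
        hi = union.max(axis=0) + 1
        sub_shape = tuple(hi - lo)
        sub_mask = np.zeros(sub_shape, dtype=bool)
        sub_mask[tuple((union - lo).T)] = True
        markers = np.zeros(sub_shape, dtype=np.int32)
        for k, m in enumerate(members, start=1):
            rep = np.array(candidates[m][0].representative) - lo
            markers[tuple(rep)] = k
        sub_vol = volume[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
        ws = _watershed(-sub_vol.astype(np.float64), markers=markers,
                        mask=sub_mask,
                        connectivity=np.ones((3, 3, 3), dtype=bool))
        for k, m in enumerate(members, start=1):
            maximum, bg, region = candidates[m]
            keep = ws[tuple((region - lo).T)] == k
            part = region[keep]
            if part.shape[0] == 0:
                continue
            # keep the connectivity-component containing the maximum
            part = _component_containing(part, maximum.representative, params)
            _append_focus(foci, maximum, bg, part, params)

    foci.sort(key=lambda f: (f.z, f.y, f.x))
    for i, f in enumerate(foci, start=1):
        f.id = i
    return FociSet(foci=foci, params=params, analysis_mode=analysis_mode,
                   source=source)


def _consolidate_maxima(
    volume: np.ndarray,
    union: np.ndarray,
    maxima: list[LocalMaximum],
    params: FociParams,
) -> list[int]:
    """Persistence-based consolidation of maxima sharing one region.

    Voxels of the union are activated in descending intensity order under
    the detection connectivity; when the basins of two maxima meet at a
    saddle, the dimmer maximum survives as a separate focus centre only
    if it rises at least ``merge_tolerance`` above the saddle, otherwise
    it is absorbed (a noise wiggle on the brighter focus' flank).
    Returns indices (into ``maxima``) of the surviving maxima; with
    ``merge_tolerance = 0`` every maximum survives.
    """
    tol = params.merge_tolerance
    if tol <= 0 or len(maxima) <= 1:
        return list(range(len(maxima)))
    index_of = {tuple(v): i for i, v in enumerate(map(tuple, union))}
    values = volume[tuple(union.T)].astype(np.float64)
    # leader per maximum: (value at representative, tie-broken by position)
    leader_at: dict[int, int] = {}
    for mi, m in enumerate(maxima):
        vi = index_of.get(m.representative)
        if vi is not None:
            leader_at[vi] = mi
    order = sorted(range(len(union)),
                   key=lambda i: (-values[i], tuple(union[i])))
    offs = [tuple(d) for d in _neighbor_offsets(params.connectivity)]

    parent = list(range(len(union)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    # per-root: the best (highest) maximum currently leading the component
    comp_leader: dict[int, int] = {}
    active = np.zeros(len(union), dtype=bool)
    survivors: list[int] = []

    def leader_value(mi: int) -> tuple[float, tuple[int, ...]]:
        return (maxima[mi].value, maxima[mi].representative)

    for vi in order:
        active[vi] = True
        if vi in leader_at:
            comp_leader[vi] = leader_at[vi]
        v = values[vi]
        z, y, x = union[vi]
        for dz, dy, dx in offs:
            wi = index_of.get((z + dz, y + dy, x + dx))
            if wi is None or not active[wi]:
                continue
            ra, rb = find(vi), find(wi)
            if ra == rb:
                continue
            la, lb = comp_leader.get(ra), comp_leader.get(rb)
            if la is not None and lb is not None:
                if leader_value(la) < leader_value(lb):
                    la, lb = lb, la
                # lb is the dimmer leader meeting la's basin at level v
                if maxima[lb].value - v >= tol:
                    survivors.append(lb)
                keep = la
            else:
                keep = la if la is not None else lb
            parent[rb] = ra
            if keep is not None:
                comp_leader[find(ra)] = keep
            comp_leader.pop(rb, None)
    # leaders of the final components survive unconditionally
    final = {find(i) for i in range(len(union))}
    for r in final:
        if r in comp_leader:
            survivors.append(comp_leader[r])
    return sorted(set(survivors))


def _component_containing(
    region: np.ndarray, seed: tuple[int, int, int], params: FociParams
) -> np.ndarray:
    vox = set(map(tuple, region))
    if seed not in vox:
        return region
    offs = _neighbor_offsets(params.connectivity)
    comp = {seed}
    stack = [seed]
    while stack:
        v = stack.pop()
        for d in offs:
            w = (v[0] + d[0], v[1] + d[1], v[2] + d[2])
            if w in vox and w not in comp:
                comp.add(w)
                stack.append(w)
    return np.array(sorted(comp), dtype=np.int64)


def _append_focus(
    foci: list[Focus], maximum: LocalMaximum, bg: float, region: np.ndarray,
    params: FociParams,
) -> None:
    if region.shape[0] <= params.min_voxels:  # strict: larger-than filter
        return
    z, y, x = maximum.representative
    foci.append(Focus(
        id=0, z=int(z), y=int(y), x=int(x), peak=float(maximum.value),
        background=float(bg), region=region, size_vox=int(region.shape[0]),
    ))


def assign_foci_to_nuclei(
    fociset: FociSet, label_volume: np.ndarray
) -> pd.DataFrame:
    """Per-nucleus focus counts.

    A focus belongs to the nucleus whose label covers its maximum voxel;
    foci outside every label get ``nucleus_id = 0`` and are excluded from
    the per-nucleus table.  Every label present in the volume gets a row,
    zero-count nuclei included.
    """
    label_volume = np.asarray(label_volume)
    counts: dict[int, int] = {
        int(lab): 0 for lab in np.unique(label_volume) if lab > 0
    }
    for f in fociset.foci:
        lab = int(label_volume[f.z, f.y, f.x])
        f.nucleus_id = lab
        if lab > 0:
            counts[lab] += 1
    return pd.DataFrame(
        {"nucleus_id": list(counts), "n_foci": list(counts.values())}
    ).sort_values("nucleus_id", ignore_index=True)


def foci_per_nucleus_roi(
    fociset: FociSet, n_nuclei: int
) -> float:
    """Testis-mode summary: total foci in the analysed volume divided by
    the number of nuclei it contains."""
    if n_nuclei < 1:
        raise ValueError("n_nuclei must be >= 1")
    return len(fociset) / n_nuclei
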