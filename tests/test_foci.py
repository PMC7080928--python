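import itertools
import math

import numpy as np
import pytest

from focidose.foci import (
    FociParams,
    _neighbor_offsets,
    assign_foci_to_nuclei,
    background_at_maximum,
    detect_foci,
    find_local_maxima_3d,
    foci_per_nucleus_roi,
    grow_focus_region,
)
from focidose.synthetic import _render_gaussian


# ---------------------------------------------------------------------------
# independent brute-force oracles


def brute_force_maxima(vol, connectivity):
    """Enumerate maximal equal-intensity connected sets whose outside
    neighbours are all strictly lower."""
    offs = _neighbor_offsets(connectivity)
    shape = vol.shape
    seen = set()
    out = set()
    for idx in np.ndindex(shape):
        if idx in seen:
            continue
        v = vol[idx]
        comp = {idx}
        stack = [idx]
        while stack:
            c = stack.pop()
            for o in offs:
                w = (c[0] + o[0], c[1] + o[1], c[2] + o[2])
                if all(0 <= w[k] < shape[k] for k in range(3)) and \
                        w not in comp and vol[w] == v:
                    comp.add(w)
                    stack.append(w)
        seen |= comp
        is_max = True
        for c in comp:
            for o in offs:
                w = (c[0] + o[0], c[1] + o[1], c[2] + o[2])
                if all(0 <= w[k] < shape[k] for k in range(3)) and \
                        w not in comp and vol[w] >= v:
                    is_max = False
                    break
            if not is_max:
                break
        if is_max:
            out.add(frozenset(comp))
    return out


def brute_force_shell(vol, center, params):
    """Explicit enumeration of shell voxels and their statistic."""
    r, tol = params.background_radius_vox, params.shell_tolerance
    vals = []
    for idx in np.ndindex(vol.shape):
        d = math.dist(idx, center)
        if r - tol <= d <= r + tol:
            vals.append(vol[idx])
    stat = np.mean if params.background_stat == "mean" else np.median
    return float(stat(vals))


def brute_force_flood(vol, seed, threshold, connectivity):
    """Flood fill of voxels >= threshold from the seed."""
    from scipy import ndimage as ndi
    from focidose.foci import _CONN_RANK
    from skimage.measure import label as cc_label

    above = vol >= threshold
    lab = cc_label(above, connectivity=_CONN_RANK[connectivity])
    return set(map(tuple, np.argwhere(lab == lab[seed])))


# ---------------------------------------------------------------------------


class TestFindLocalMaxima:
    def test_single_bright_voxel(self):
        vol = np.full((5, 5, 5), 3, dtype=int)
        vol[2, 3, 1] = 9
        maxima = find_local_maxima_3d(vol, 26)
        assert len(maxima) == 1
        assert maxima[0].representative == (2, 3, 1)

    def test_plateau_counts_once(self):
        """A connected equal-intensity plateau is one maximum, not one per
        voxel."""
        vol = np.zeros((5, 7, 7), dtype=int)
        vol[2, 3, 2:5] = 8  # 3-voxel line plateau
        maxima = find_local_maxima_3d(vol, 26)
        assert len(maxima) == 1
        assert maxima[0].voxels.shape[0] == 3
        assert maxima[0].centroid == (2.0, 3.0, 3.0)

    def test_plateau_touching_higher_region_is_not_maximum(self):
        vol = np.zeros((3, 5, 5), dtype=int)
        vol[1, 2, 1:3] = 5  # plateau
        vol[1, 2, 3] = 7    # adjacent strictly higher voxel
        maxima = find_local_maxima_3d(vol, 26)
        assert len(maxima) == 1
        assert maxima[0].value == 7.0

    @pytest.mark.parametrize("connectivity", [6, 18, 26])
    @pytest.mark.parametrize("seed", range(6))
    def test_matches_brute_force_enumeration(self, connectivity, seed):
        rng = np.random.default_rng(seed)
        shape = tuple(rng.integers(3, 9, size=3))
        vol = rng.integers(0, 5, size=shape)
        mine = {
            frozenset(map(tuple, m.voxels))
            for m in find_local_maxima_3d(vol, connectivity)
        }
        assert mine == brute_force_maxima(vol, connectivity)

    def test_mask_restricts_representatives(self, rng):
        vol = rng.integers(0, 50, size=(6, 8, 8))
        mask = np.zeros(vol.shape, dtype=bool)
        mask[:, :4, :] = True
        inside = find_local_maxima_3d(vol, 26, mask=mask)
        assert all(mask[m.representative] for m in inside)
        all_max = find_local_maxima_3d(vol, 26)
        reps = {m.representative for m in all_max if mask[m.representative]}
        assert {m.representative for m in inside} == reps


class TestBackgroundAtMaximum:
    def _max_at(self, vol, pos):
        maxima = find_local_maxima_3d(vol, 26)
        return next(m for m in maxima if m.representative == pos)

    def test_constant_shell_value(self):
        vol = np.full((16, 16, 16), 7, dtype=int)
        vol[8, 8, 8] = 50
        m = self._max_at(vol, (8, 8, 8))
        assert background_at_maximum(vol, m) == 7.0

    def test_corner_maximum_uses_in_bounds_octant(self):
        vol = np.full((10, 10, 10), 4, dtype=int)
        vol[0, 0, 0] = 99
        m = self._max_at(vol, (0, 0, 0))
        assert background_at_maximum(vol, m) == 4.0

    @pytest.mark.parametrize("stat", ["mean", "median"])
    def test_matches_shell_enumeration(self, rng, stat):
        params = FociParams(background_stat=stat)
        vol = rng.integers(0, 100, size=(14, 15, 16))
        vol[7, 7, 7] = 1000
        m = self._max_at(vol, (7, 7, 7))
        assert background_at_maximum(vol, m, params) == pytest.approx(
            brute_force_shell(vol, (7, 7, 7), params)
        )

    def test_degenerate_shell_raises(self):
        vol = np.zeros((2, 2, 2), dtype=int)
        vol[0, 0, 0] = 5
        m = self._max_at(vol, (0, 0, 0))
        with pytest.raises(ValueError, match="shell"):
            background_at_maximum(vol, m)

    def test_ball_mode_includes_interior(self):
        params = FociParams(shell_mode="ball")
        vol = np.full((16, 16, 16), 3, dtype=int)
        vol[8, 8, 8] = 60
        m = self._max_at(vol, (8, 8, 8))
        # ball includes the peak itself, so the mean exceeds the rim value
        assert background_at_maximum(vol, m, params) > 3.0


class TestGrowFocusRegion:
    def test_gaussian_blob_equals_flood_fill_oracle(self):
        vol_f = np.zeros((12, 20, 20))
        _render_gaussian(vol_f, 6.0, 10.0, 10.0, 200.0, 2.0)
        vol = np.rint(vol_f).astype(int)
        params = FociParams()
        (m,) = [x for x in find_local_maxima_3d(vol, 26)
                if x.representative == (6, 10, 10)]
        bg = 0.0
        region = grow_focus_region(vol, m, bg, params)
        thr = bg + 0.5 * (m.value - bg)
        oracle = brute_force_flood(vol, (6, 10, 10), thr, 26)
        assert set(map(tuple, region)) == oracle

    def test_peak_alone_above_threshold(self):
        vol = np.zeros((5, 5, 5), dtype=int)
        vol[2, 2, 2] = 100
        (m,) = find_local_maxima_3d(vol, 26)
        region = grow_focus_region(vol, m, 0.0, FociParams(growth_fraction=0.9))
        assert set(map(tuple, region)) == {(2, 2, 2)}

    def test_alpha_one_returns_plateau(self):
        vol = np.zeros((5, 7, 7), dtype=int)
        vol[2, 3, 2:5] = 8
        (m,) = find_local_maxima_3d(vol, 26)
        region = grow_focus_region(vol, m, 0.0, FociParams(growth_fraction=1.0))
        assert set(map(tuple, region)) == {(2, 3, 2), (2, 3, 3), (2, 3, 4)}

    def test_smaller_alpha_never_shrinks_region(self):
        vol_f = np.zeros((10, 16, 16))
        _render_gaussian(vol_f, 5.0, 8.0, 8.0, 150.0, 1.8)
        vol = np.rint(vol_f).astype(int)
        (m,) = [x for x in find_local_maxima_3d(vol, 26)
                if x.value == vol.max()]
        sizes = []
        for alpha in (0.9, 0.7, 0.5, 0.3):
            r = grow_focus_region(vol, m, 0.0,
                                  FociParams(growth_fraction=alpha))
            sizes.append(r.shape[0])
        assert sizes == sorted(sizes)


class TestDetectFoci:
    def _field_with_gaussian(self, centers, amp=300.0, sigma=1.5,
                             shape=(10, 32, 32), background=10.0):
        vol_f = np.full(shape, background)
        for c in centers:
            _render_gaussian(vol_f, *c, amp, sigma)
        return np.rint(vol_f).astype(int)

    def test_constant_volume_no_foci(self):
        vol = np.full((8, 20, 20), 5, dtype=int)
        assert len(detect_foci(vol, FociParams())) == 0

    def test_strict_size_filter(self):
        """A focus is reported iff its region is strictly larger than
        min_voxels, for both protocol thresholds."""
        vol = self._field_with_gaussian([(5.0, 16.0, 16.0)])
        base = detect_foci(vol, FociParams(min_voxels=1))
        assert len(base) == 1
        size = base.foci[0].size_vox
        assert size > 20  # sanity: sits between the protocol thresholds
        for mv in (8, 20):
            assert len(detect_foci(vol, FociParams(min_voxels=mv))) == 1
        # exactly at the region size the strict 'larger than' excludes it
        assert len(detect_foci(vol, FociParams(min_voxels=size))) == 0
        assert len(detect_foci(vol, FociParams(min_voxels=size - 1))) == 1

    def test_two_separated_foci_split_policy(self):
        vol = self._field_with_gaussian(
            [(5.0, 12.0, 12.0), (5.0, 12.0, 22.0)])
        fs = detect_foci(vol, FociParams(multi_max_policy="split"))
        assert len(fs) == 2
        regions = [set(map(tuple, f.region)) for f in fs.foci]
        assert not regions[0] & regions[1]

    def test_reject_policy_drops_shared_region(self):
        # two peaks close enough that their half-prominence regions join
        vol = self._field_with_gaussian(
            [(5.0, 14.0, 14.0), (5.0, 14.0, 18.0)], sigma=2.0)
        split = detect_foci(vol, FociParams(multi_max_policy="split"))
        reject = detect_foci(vol, FociParams(multi_max_policy="reject"))
        assert len(reject) <= len(split)
        if len(split) == 2:
            assert len(reject) == 0

    def test_min_voxels_monotonicity(self):
        rng = np.random.default_rng(3)
        vol_f = np.full((10, 48, 48), 80.0)
        for _ in range(6):
            c = rng.uniform([2, 6, 6], [7, 42, 42])
            _render_gaussian(vol_f, *c, rng.uniform(150, 400), 1.5)
        vol = np.rint(rng.poisson(vol_f)).astype(int)
        counts = [
            len(detect_foci(vol, FociParams(min_voxels=mv, min_prominence=45)))
            for mv in (1, 4, 8, 16, 24, 40)
        ]
        assert counts == sorted(counts, reverse=True)

    def test_mask_restriction_is_subset(self):
        vol = self._field_with_gaussian(
            [(5.0, 10.0, 10.0), (5.0, 22.0, 22.0)])
        mask = np.zeros(vol.shape, dtype=np.int32)
        mask[:, :16, :16] = 1
        unmasked = detect_foci(vol, FociParams())
        masked = detect_foci(vol, FociParams(), mask=mask)
        pos_unmasked = {(f.z, f.y, f.x) for f in unmasked.foci}
        pos_masked = {(f.z, f.y, f.x) for f in masked.foci}
        assert pos_masked <= pos_unmasked
        assert len(masked) == 1

    def test_merge_tolerance_zero_keeps_distinct_maxima(self):
        # close enough that the two half-prominence regions share voxels
        vol = self._field_with_gaussian(
            [(5.0, 12.0, 12.0), (5.0, 12.0, 17.0)], sigma=2.0)
        strict = detect_foci(vol, FociParams(merge_tolerance=0.0))
        loose = detect_foci(vol, FociParams(merge_tolerance=1e6))
        assert len(strict) >= len(loose)
        assert len(loose) == 1


class TestAssignFoci:
    def test_counts_including_zero_nuclei(self):
        vol = self._vol = np.full((6, 20, 20), 5, dtype=int)
        vol_f = vol.astype(float)
        _render_gaussian(vol_f, 3.0, 5.0, 5.0, 200.0, 1.5)
        _render_gaussian(vol_f, 3.0, 5.0, 12.0, 200.0, 1.5)
        vol = np.rint(vol_f).astype(int)
        labels = np.zeros(vol.shape, dtype=np.int32)
        labels[:, :10, :] = 1   # both foci inside nucleus 1
        labels[:, 12:, :] = 2   # nucleus 2 has none
        fs = detect_foci(vol, FociParams(), mask=labels)
        counts = assign_foci_to_nuclei(fs, labels)
        lookup = dict(zip(counts.nucleus_id, counts.n_foci))
        assert lookup == {1: 2, 2: 0}

    def test_focus_outside_labels_excluded(self):
        vol_f = np.full((6, 20, 20), 5.0)
        _render_gaussian(vol_f, 3.0, 15.0, 15.0, 200.0, 1.5)
        vol = np.rint(vol_f).astype(int)
        labels = np.zeros(vol.shape, dtype=np.int32)
        labels[:, :8, :8] = 1
        fs = detect_foci(vol, FociParams())  # unmasked detection
        counts = assign_foci_to_nuclei(fs, labels)
        assert dict(zip(counts.nucleus_id, counts.n_foci)) == {1: 0}
        assert all(f.nucleus_id == 0 for f in fs.foci)

    def test_roi_mode_average(self):
        vol_f = np.full((6, 24, 24), 5.0)
        for x in (6.0, 12.0, 18.0):
            _render_gaussian(vol_f, 3.0, 12.0, x, 200.0, 1.3)
        vol = np.rint(vol_f).astype(int)
        fs = detect_foci(vol, FociParams(min_voxels=8),
                         analysis_mode="per_roi")
        assert foci_per_nucleus_roi(fs, n_nuclei=2) == pytest.approx(
            len(fs) / 2)
        with pytest.raises(ValueError):
            foci_per_nucleus_roi(fs, 0)


class TestFociSetIO:
    def test_csv_and_sidecar_round_trip(self, tmp_path):
        import json
        import pandas as pd

        vol_f = np.full((6, 20, 20), 5.0)
        _render_gaussian(vol_f, 3.0, 10.0, 10.0, 200.0, 1.5)
        fs = detect_foci(np.rint(vol_f).astype(int), FociParams())
        out = tmp_path / "foci.csv"
        fs.write_csv(out)
        df = pd.read_csv(out)
        assert len(df) == 1
        assert set(df.columns) >= {"focus_id", "z", "y", "x", "peak",
                                   "background", "size_vox", "nucleus_id"}
        sidecar = json.loads(out.with_suffix(".json").read_text())
        assert sidecar["params"]["min_voxels"] == 8
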