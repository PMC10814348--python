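"""Hemispheric asymmetry statistic for kinetic parameter maps.

Given a k_PL map, the map is linearly interpolated by a factor of 2
in-plane, z-normalized (zero mean, unit SD) over the analysis region,
and restricted to a symmetric brain mask; lesion and resection-cavity
masks are excluded together with their midline reflections so only
normal-appearing tissue is compared.

For mirrored point sets P_L and P_R about the left-right midline l, the
local asymmetry of a point p is

    s(p; l) = min_{q in opposite hemisphere} || f_p - f_q ||

where the feature vector f concatenates the 3x3 in-plane patch around
the point with its (mirrored-frame) coordinates scaled by an empirical
weight w.  Global asymmetry S is the mean of s over P_L ∪ P_R; S = 0
iff the included data are mirror-identical, larger S means stronger
hemispheric asymmetry.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.spatial.distance import cdist

__all__ = ["PreparedMap", "AsymmetryResult", "prepare_map", "local_asymmetry", "global_asymmetry"]


@dataclass
class PreparedMap:
    """Interpolated, normalized map with symmetric analysis masks."""

    values: np.ndarray  # (slice, row, col), 2x in-plane of the input
    symmetric_mask: np.ndarray  # brain ∩ reflected brain
    excluded_mask: np.ndarray  # (lesion ∪ cavity) ∪ reflection
    reflect_sum: int  # column reflection: c -> reflect_sum - c
    degenerate: bool = False  # constant input map (SD 0)

    @property
    def midline(self) -> float:
        """Column coordinate of the mid-sagittal plane."""
        return self.reflect_sum / 2.0

    def included(self) -> np.ndarray:
        return self.symmetric_mask & ~self.excluded_mask


@dataclass
class AsymmetryResult:
    """Local asymmetry map and its global summary."""

    s_map: np.ndarray  # NaN where not evaluated
    S: float
    S_per_slice: np.ndarray
    n_points: int
    w: float
    per_slice_n: np.ndarray = field(default_factory=lambda: np.array([]))


def _reflect_cols(mask: np.ndarray, reflect_sum: int) -> np.ndarray:
    """Reflect a volume about the midline column plane."""
    nc = mask.shape[-1]
    src = reflect_sum - np.arange(nc)
    valid = (src >= 0) & (src < nc)
    out = np.zeros_like(mask)
    out[..., valid] = mask[..., src[valid]]
    return out


def prepare_map(
    kpl_map: np.ndarray,
    brain_mask: np.ndarray,
    lesion_mask: np.ndarray | None = None,
    cavity_mask: np.ndarray | None = None,
    midline: float | None = None,
    upsample: int = 2,
) -> PreparedMap:
    """Interpolate, normalize, and mask a parameter map for asymmetry analysis.

    Parameters
    ----------
    kpl_map, brain_mask, lesion_mask, cavity_mask
        Volumes on a common (slice, row, column) grid.
    midline
        Column coordinate of the mid-sagittal plane on the *input* grid;
        defaults to the column center of the brain-mask bounding box.
    upsample
        In-plane linear interpolation factor (2 by default).

    Notes
    -----
    Z-normalization statistics are computed over the symmetric mask with
    exclusions removed.  A constant map is flagged degenerate and its
    normalized values set to zero.
    """
    kpl_map = np.asarray(kpl_map, dtype=float)
    brain_mask = np.asarray(brain_mask, dtype=bool)
    if brain_mask.shape != kpl_map.shape:
        raise ValueError("brain mask must match the map grid")
    zoom = (1, upsample, upsample)
    values = ndimage.zoom(np.nan_to_num(kpl_map), zoom, order=1, grid_mode=True, mode="nearest")
    brain = ndimage.zoom(brain_mask.astype(float), zoom, order=0, grid_mode=True, mode="nearest") > 0.5

    excl = np.zeros_like(brain_mask)
    for m in (lesion_mask, cavity_mask):
        if m is not None:
            m = np.asarray(m, dtype=bool)
            if m.shape != kpl_map.shape:
                raise ValueError("exclusion masks must match the map grid")
            excl |= m
    excl_up = ndimage.zoom(excl.astype(float), zoom, order=0, grid_mode=True, mode="nearest") > 0.5

    if midline is None:
        cols = np.where(brain.any(axis=(0, 1)))[0]
        if len(cols) == 0:
            raise ValueError("empty brain mask")
        reflect_sum = int(cols[0] + cols[-1])
    else:
        reflect_sum = int(round(2 * midline * upsample + (upsample - 1)))

    symmetric = brain & _reflect_cols(brain, reflect_sum)
    excluded = excl_up | _reflect_cols(excl_up, reflect_sum)

    included = symmetric & ~excluded
    if not included.any():
        raise ValueError("no voxels remain after masking")
    mu = values[included].mean()
    sd = values[included].std()
    degenerate = sd == 0
    values = np.zeros_like(values) if degenerate else (values - mu) / sd
    return PreparedMap(
        values=values,
        symmetric_mask=symmetric,
        excluded_mask=excluded,
        reflect_sum=reflect_sum,
        degenerate=degenerate,
    )


def _slice_features(
    vals2d: np.ndarray,
    ok2d: np.ndarray,
    side_pts: np.ndarray,
    reflect_sum: int,
    w: float,
    flip: bool,
) -> tuple[np.ndarray, np.ndarray]:
    """Feature vectors (patch + weighted mirrored coords) for one hemisphere.

    Points whose 3x3 patch leaves the grid or touches a non-included
    voxel are dropped.  ``flip`` column-reverses the patch so that a
    mirror-symmetric pair yields identical features; coordinates are
    expressed in the mirrored (right-hemisphere) frame for both sides.
    """
    nr, nc = vals2d.shape
    keep, feats = [], []
    for r, c in side_pts:
        if not (1 <= r < nr - 1 and 1 <= c < nc - 1):
            continue
        if not ok2d[r - 1 : r + 2, c - 1 : c + 2].all():
            continue
        patch = vals2d[r - 1 : r + 2, c - 1 : c + 2]
        if flip:
            patch = patch[:, ::-1]
        mirrored_c = reflect_sum - c if flip else c
        feats.append(np.concatenate([patch.ravel(), [w * r, w * mirrored_c]]))
        keep.append((r, c))
    if not feats:
        return np.empty((0, 11)), np.empty((0, 2), dtype=int)
    return np.asarray(feats), np.asarray(keep)


def local_asymmetry(prepared: PreparedMap, w: float = 1.0) -> np.ndarray:
    """Map of s(p): nearest-feature distance to the opposite hemisphere.

    Every included point on either side of the midline is compared
    against all valid points of the opposite hemisphere in the same
    slice; the returned volume holds the minimum feature distance and
    NaN wherever s was not evaluated (midline points, incomplete
    patches, or an empty opposite hemisphere).
    """
    if w < 0:
        raise ValueError("coordinate weight w must be >= 0")
    included = prepared.included()
    s_map = np.full(prepared.values.shape, np.nan)
    mid = prepared.midline
    for z in range(prepared.values.shape[0]):
        ok = included[z]
        if not ok.any():
            continue
        pts = np.argwhere(ok)
        left = pts[pts[:, 1] < mid]
        right = pts[pts[:, 1] > mid]
        fl, kl = _slice_features(prepared.values[z], ok, left, prepared.reflect_sum, w, flip=True)
        fr, kr = _slice_features(prepared.values[z], ok, right, prepared.reflect_sum, w, flip=False)
        if len(fl) and len(fr):
            d = cdist(fl, fr)
            s_map[z, kl[:, 0], kl[:, 1]] = d.min(axis=1)
            s_map[z, kr[:, 0], kr[:, 1]] = d.min(axis=0)
    return s_map


def global_asymmetry(s_map: np.ndarray) -> AsymmetryResult:
    """Mean local asymmetry, overall and per slice.

    S averages s over every evaluated point of both hemispheres; slices
    without evaluated points report NaN in the per-slice summary.
    """
    finite = np.isfinite(s_map)
    n = int(finite.sum())
    if n == 0:
        raise ValueError("no evaluated asymmetry points (N = 0)")
    per_slice = np.array(
        [s_map[z][finite[z]].mean() if finite[z].any() else np.nan for z in range(s_map.shape[0])]
    )
    per_n = np.array([int(finite[z].sum()) for z in range(s_map.shape[0])])
    return AsymmetryResult(
        s_map=s_map,
        S=float(s_map[finite].mean()),
        S_per_slice=per_slice,
        n_points=n,
        w=np.nan,
        per_slice_n=per_n,
    )
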