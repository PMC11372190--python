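"""Brute-force oracles, independent of the implementation paths they check."""

import numpy as np


def grid_points_mm(shape, spacing):
    ax = [np.arange(n) * sp for n, sp in zip(shape, spacing)]
    gx, gy, gz = np.meshgrid(*ax, indexing="ij")
    return np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])


def brute_force_distance(mask, spacing, chunk=2048):
    """Exhaustive nearest-mask-voxel distance (mm): every outside voxel is
    compared against every mask voxel (O(n^2) enumeration, chunked)."""
    from scipy.spatial.distance import cdist

    mask = np.asarray(mask, dtype=bool)
    pts = grid_points_mm(mask.shape, spacing)
    mask_pts = pts[mask.ravel()]
    out = np.zeros(len(pts))
    outside = np.flatnonzero(~mask.ravel())
    for start in range(0, len(outside), chunk):
        idx = outside[start : start + chunk]
        out[idx] = cdist(pts[idx], mask_pts).min(axis=1)
    return out.reshape(mask.shape)


def brute_force_nearest_arc(points_mm, cl_points, cl_arc, chunk=4096):
    """Exhaustive nearest-centerline-point arc-length; first point on ties.

    Plain squared-distance broadcasting keeps exact ties bit-identical to
    the voxel rule (argmin returns the first, smallest-arc-length match)."""
    points_mm = np.asarray(points_mm, dtype=float)
    cl_points = np.asarray(cl_points, dtype=float)
    out = np.empty(len(points_mm))
    for start in range(0, len(points_mm), chunk):
        block = points_mm[start : start + chunk]
        d2 = ((block[:, None, :] - cl_points[None, :, :]) ** 2).sum(axis=2)
        out[start : start + chunk] = cl_arc[np.argmin(d2, axis=1)]
    return out


def brute_force_section_measure(hu, mask, spacing, cl_points, cl_arc, intervals,
                                section, band, fat_range=(-190.0, -30.0),
                                dist=None, arc=None):
    """Enumerate every voxel and test all four membership criteria.

    Returns (mean HU, volume cm3) of the adipose voxels outside the mask whose
    exhaustive nearest-mask distance lies in ``band`` and whose exhaustive
    nearest-centerline arc-length falls in the ``section`` interval (with the
    aneurysmal interval taking precedence).
    """
    mask = np.asarray(mask, dtype=bool)
    pts = grid_points_mm(mask.shape, spacing)
    if dist is None:
        dist = brute_force_distance(mask, spacing).ravel()
    else:
        dist = np.asarray(dist, dtype=float).ravel()
    if arc is None:
        arc = brute_force_nearest_arc(pts, cl_points, cl_arc)
    else:
        arc = np.asarray(arc, dtype=float).ravel()
    hu_flat = np.asarray(hu, dtype=float).ravel()

    def in_section(s):
        if "aneurysmal" in intervals:
            lo, hi = intervals["aneurysmal"]
            if lo <= s <= hi:
                return section == "aneurysmal"
        lo, hi = intervals[section]
        return lo <= s <= hi if section != "aneurysmal" else False

    values = []
    for i in range(len(pts)):
        if mask.ravel()[i]:
            continue
        if not (band[0] <= dist[i] < band[1]):
            continue
        if not (fat_range[0] <= hu_flat[i] <= fat_range[1]):
            continue
        if not in_section(arc[i]):
            continue
        values.append(hu_flat[i])
    voxvol = float(np.prod(spacing))
    mean = float(np.mean(values)) if values else np.nan
    return mean, len(values) * voxvol / 1000.0


def two_sample_t(a, b):
    """Equal-variance two-sample t statistic and two-sided p, closed form."""
    from scipy.stats import t as tdist

    a, b = np.asarray(a, float), np.asarray(b, float)
    na, nb = len(a), len(b)
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    t = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / na + 1 / nb))
    p = 2 * tdist.sf(abs(t), na + nb - 2)
    return t, p


def paired_t(x, y):
    """Paired t statistic and two-sided p, closed form."""
    from scipy.stats import t as tdist

    d = np.asarray(x, float) - np.asarray(y, float)
    n = len(d)
    t = d.mean() / (d.std(ddof=1) / np.sqrt(n))
    p = 2 * tdist.sf(abs(t), n - 1)
    return t, p
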