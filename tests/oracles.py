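"""Independent brute-force oracles used to cross-check the implementation.

Everything here is written from the definitions (exhaustive enumeration,
all-pairs minima, explicit partial-likelihood maximization) and deliberately
shares no code path with the package.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize_scalar

from svzprox.mask_io import MaskVolume


def world_coords(mask: MaskVolume) -> np.ndarray:
    """Foreground voxel centers in world mm, one affine multiply per voxel."""
    A = mask.affine
    pts = []
    for ijk in np.argwhere(mask.data > 0):
        h = A @ np.array([ijk[0], ijk[1], ijk[2], 1.0])
        pts.append(h[:3])
    return np.array(pts)


def bf_volume_cm3(mask: MaskVolume) -> float:
    count = sum(1 for v in mask.data.ravel() if v > 0)
    return count * abs(np.linalg.det(mask.affine[:3, :3])) / 1000.0


def bf_centroid(mask: MaskVolume) -> np.ndarray:
    pts = world_coords(mask)
    return pts.sum(axis=0) / len(pts)


def bf_min_distance(a: MaskVolume, b: MaskVolume) -> float:
    """Exhaustive all-pairs minimum distance between foreground voxel centers."""
    pa, pb = world_coords(a), world_coords(b)
    diff = pa[:, None, :] - pb[None, :, :]
    return float(np.sqrt((diff**2).sum(axis=2)).min())


def bf_ts(tumor: MaskVolume, ventricle: MaskVolume) -> float:
    if np.any((tumor.data > 0) & (ventricle.data > 0)):
        return 0.0
    return bf_min_distance(tumor, ventricle)


def bf_cs(tumor: MaskVolume, ventricle: MaskVolume) -> float:
    c = bf_centroid(tumor)
    ijk = np.round(np.linalg.inv(ventricle.affine) @ np.array([*c, 1.0]))[:3].astype(int)
    if (
        np.all(ijk >= 0)
        and np.all(ijk < np.array(ventricle.shape))
        and ventricle.data[tuple(ijk)] > 0
    ):
        return 0.0
    pv = world_coords(ventricle)
    return float(np.sqrt(((pv - c) ** 2).sum(axis=1)).min())


def random_mask_pair(rng: np.random.Generator, shape=(14, 14, 8),
                     spacing=(0.6, 0.6, 5.0), max_voxels=200):
    """Two random scattered masks on a shared anisotropic grid."""
    affine = np.diag([*spacing, 1.0])
    n_vox = int(np.prod(shape))
    masks = []
    for _ in range(2):
        k = int(rng.integers(1, min(max_voxels, n_vox // 2)))
        flat = rng.choice(n_vox, size=k, replace=False)
        data = np.zeros(n_vox, dtype=np.uint8)
        data[flat] = 1
        masks.append(MaskVolume(data.reshape(shape), affine))
    return masks[0], masks[1]


def logrank_two_group(times, events, group) -> tuple[float, float]:
    """Unweighted two-group log-rank statistic from the O-E / variance sums."""
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    group = np.asarray(group)
    levels = np.unique(group)
    assert len(levels) == 2
    o = e = v = 0.0
    for t in np.unique(times[events == 1]):
        at_risk = times >= t
        n = at_risk.sum()
        n1 = (at_risk & (group == levels[0])).sum()
        d = ((times == t) & (events == 1)).sum()
        d1 = ((times == t) & (events == 1) & (group == levels[0])).sum()
        o += d1
        e += d * n1 / n
        if n > 1:
            v += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    chi2 = (o - e) ** 2 / v
    return float(chi2), float(o - e)


def cox_beta_no_ties(times, events, x) -> float:
    """Maximum partial-likelihood coefficient for one covariate, untied data."""
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    x = np.asarray(x, float)
    assert len(np.unique(times)) == len(times), "oracle assumes no ties"

    def neg_pl(beta):
        ll = 0.0
        for i in np.flatnonzero(events == 1):
            risk = times >= times[i]
            ll += beta * x[i] - np.log(np.sum(np.exp(beta * x[risk])))
        return -ll

    res = minimize_scalar(neg_pl, bounds=(-5, 5), method="bounded",
                          options={"xatol": 1e-10})
    return float(res.x)
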