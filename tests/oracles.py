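"""Brute-force reference implementations used to check the geometry
primitives. Deliberately written as plain loops / first-principles
enumeration, independent of the library code paths they verify."""

from __future__ import annotations

import numpy as np

_OFFSETS_6 = [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)]


def neighbor_offsets(connectivity: int):
    out = []
    for dz in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dx in (-1, 0, 1):
                if (dz, dy, dx) == (0, 0, 0):
                    continue
                n_nonzero = sum(1 for d in (dz, dy, dx) if d != 0)
                if connectivity == 6 and n_nonzero > 1:
                    continue
                if connectivity == 18 and n_nonzero > 2:
                    continue
                out.append((dz, dy, dx))
    return out


def flood_fill_components(mask: np.ndarray, connectivity: int) -> np.ndarray:
    """Label connected components by explicit flood fill, labels in
    raster-scan order of each component's first voxel."""
    mask = mask.astype(bool)
    labels = np.zeros(mask.shape, dtype=np.int32)
    offsets = neighbor_offsets(connectivity)
    next_label = 0
    for idx in np.ndindex(mask.shape):
        if mask[idx] and labels[idx] == 0:
            next_label += 1
            stack = [idx]
            labels[idx] = next_label
            while stack:
                z, y, x = stack.pop()
                for dz, dy, dx in offsets:
                    n = (z + dz, y + dy, x + dx)
                    if all(0 <= n[i] < mask.shape[i] for i in range(3)):
                        if mask[n] and labels[n] == 0:
                            labels[n] = next_label
                            stack.append(n)
    return labels


def volume_um3(mask: np.ndarray, spacing) -> float:
    n = 0
    for idx in np.ndindex(mask.shape):
        if mask[idx]:
            n += 1
    return n * spacing[0] * spacing[1] * spacing[2]


def percent_volume(obj_mask: np.ndarray, tissue: np.ndarray) -> float:
    n_obj = 0
    n_tis = 0
    for idx in np.ndindex(tissue.shape):
        if tissue[idx]:
            n_tis += 1
            if obj_mask[idx]:
                n_obj += 1
    # count objects only inside tissue, as the definition states
    n_obj = sum(
        1 for idx in np.ndindex(tissue.shape) if tissue[idx] and obj_mask[idx]
    )
    return 100.0 * n_obj / n_tis


def contact_area_um2(a: np.ndarray, b: np.ndarray, spacing) -> float:
    total = 0.0
    sz, sy, sx = spacing
    face = {0: sy * sx, 1: sz * sx, 2: sz * sy}
    for idx in np.ndindex(a.shape):
        if not a[idx]:
            continue
        z, y, x = idx
        for ax, (dz, dy, dx) in zip(
            (0, 0, 1, 1, 2, 2), _OFFSETS_6
        ):
            n = (z + dz, y + dy, x + dx)
            if all(0 <= n[i] < a.shape[i] for i in range(3)) and b[n]:
                total += face[ax]
    return total


def centroid_um(mask: np.ndarray, spacing) -> np.ndarray:
    pts = [
        [(idx[i] + 0.5) * spacing[i] for i in range(3)]
        for idx in np.ndindex(mask.shape)
        if mask[idx]
    ]
    return np.mean(np.asarray(pts), axis=0)


def min_distance_um(point, target: np.ndarray, spacing) -> float:
    best = np.inf
    for idx in np.ndindex(target.shape):
        if target[idx]:
            c = [(idx[i] + 0.5) * spacing[i] for i in range(3)]
            d = np.sqrt(sum((c[i] - point[i]) ** 2 for i in range(3)))
            best = min(best, d)
    return best


def overlap_fraction(mask: np.ndarray, region: np.ndarray) -> float:
    n = 0
    k = 0
    for idx in np.ndindex(mask.shape):
        if mask[idx]:
            n += 1
            if region[idx]:
                k += 1
    return k / n


def surface_coverage_pct(surface: np.ndarray, cover: np.ndarray) -> float:
    """Covered iff a cover voxel is an 18-neighbour (face or edge) of
    the surface voxel, or the voxel itself (tolerance of one step)."""
    covered = 0
    total = 0
    cover_idx = np.argwhere(cover)
    for idx in np.ndindex(surface.shape):
        if not surface[idx]:
            continue
        total += 1
        for c in cover_idx:
            d = np.abs(c - np.asarray(idx))
            if d.max() <= 1 and (d > 0).sum() <= 2:
                covered += 1
                break
    return 100.0 * covered / total


def ellipsoid_descriptors(mask: np.ndarray, spacing) -> tuple[float, float]:
    """Elongation and sparseness from explicit moment sums."""
    pts = np.array(
        [
            [(idx[i] + 0.5) * spacing[i] for i in range(3)]
            for idx in np.ndindex(mask.shape)
            if mask[idx]
        ]
    )
    mean = pts.mean(axis=0)
    cov = np.zeros((3, 3))
    for p in pts - mean:
        cov += np.outer(p, p)
    cov /= len(pts)
    eig = np.sort(np.linalg.eigvalsh(cov))[::-1]
    a, b, c = np.sqrt(5.0 * eig)
    vol = len(pts) * spacing[0] * spacing[1] * spacing[2]
    return a / b, (4.0 / 3.0) * np.pi * a * b * c / vol
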