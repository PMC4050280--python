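"""Particle picking on vesicle tomograms.

The picking rule operates on the dark-density convention: candidate
particles are strict 26-neighbourhood local minima of a binned, Gaussian
filtered tomogram, deeper than ``mean - k_sd * SD`` of the whole
preprocessed map, and within a stated distance of a (spherical) membrane
model. Initial orientations are the outward membrane normals.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage, optimize

from .core_io import DensityMap, ParticleTable, VesicleModel, matrix_to_euler, euler_to_matrix


def preprocess(density: DensityMap, bin_factor: int = 4,
               gaussian_sigma: float = 2.0) -> DensityMap:
    """Block-mean bin then Gaussian-smooth (sigma in binned voxels).

    Dimensions not divisible by ``bin_factor`` are truncated to the largest
    multiple (documented pad-and-crop rule: trailing voxels are dropped).
    The voxel size scales by ``bin_factor``; physical coordinates of voxel
    centres remain consistent with the unbinned map, so picked positions
    are directly usable on the full-resolution tomogram.
    """
    if bin_factor < 1 or int(bin_factor) != bin_factor:
        raise ValueError("bin_factor must be a positive integer")
    b = int(bin_factor)
    g = density.grid
    if b > 1:
        nx, ny, nz = (s // b for s in g.shape)
        if min(nx, ny, nz) < 2:
            raise ValueError("bin_factor too large for map dimensions")
        g = g[: nx * b, : ny * b, : nz * b]
        g = g.reshape(nx, b, ny, b, nz, b).mean(axis=(1, 3, 5))
    out = g.astype(np.float32)
    if gaussian_sigma > 0:
        out = ndimage.gaussian_filter(out, gaussian_sigma)
    return DensityMap(out, density.voxel_size * b, density.origin.copy())


def detect_minima(density: DensityMap, k_sd: float = 2.0) -> np.ndarray:
    """Positions (n, 3) in Å of strict local minima below ``mean - k_sd*SD``.

    A voxel qualifies when it is strictly lower than all of its 26
    neighbours and its value is strictly below the threshold; statistics
    are over the whole map. One-voxel border excluded (its neighbourhood is
    incomplete). A constant map yields no detections.
    """
    g = density.grid
    mu, sd = float(g.mean()), float(g.std())
    thresh = mu - k_sd * sd
    footprint = np.ones((3, 3, 3), bool)
    footprint[1, 1, 1] = False
    neigh_min = ndimage.minimum_filter(g, footprint=footprint, mode="nearest")
    is_min = (g < neigh_min) & (g < thresh)
    is_min[0, :, :] = is_min[-1, :, :] = False
    is_min[:, 0, :] = is_min[:, -1, :] = False
    is_min[:, :, 0] = is_min[:, :, -1] = False
    idx = np.argwhere(is_min)
    # deterministic order: lowest linear index first
    order = np.lexsort((idx[:, 2], idx[:, 1], idx[:, 0]))
    idx = idx[order]
    return density.origin + (idx + 0.5) * density.voxel_size


def minima_values(density: DensityMap, positions: np.ndarray) -> np.ndarray:
    """Map values at voxel-centre positions (nearest voxel lookup)."""
    if len(positions) == 0:
        return np.zeros(0)
    idx = np.rint(density.position_to_index(np.atleast_2d(positions))).astype(int)
    idx = np.clip(idx, 0, np.array(density.shape) - 1)
    return density.grid[idx[:, 0], idx[:, 1], idx[:, 2]].astype(float)


def suppress_close_minima(positions: np.ndarray, values: np.ndarray,
                          min_sep: float) -> np.ndarray:
    """Non-maximum suppression: keep the deepest minimum within ``min_sep``.

    Candidates are visited deepest-first; a candidate is kept when no
    already-kept position lies within ``min_sep`` Å. Returns kept positions.
    """
    positions = np.atleast_2d(positions)
    if len(positions) == 0:
        return positions
    order = np.argsort(values, kind="stable")
    kept: list[np.ndarray] = []
    for i in order:
        p = positions[i]
        if not kept or np.min(np.linalg.norm(np.array(kept) - p, axis=1)) >= min_sep:
            kept.append(p)
    return np.array(kept)


def filter_membrane_proximity(positions: np.ndarray,
                              vesicles: list[VesicleModel],
                              d_max: float = 150.0,
                              d_min: float = 0.0) -> np.ndarray:
    """Keep positions within ``d_max`` Å of any vesicle surface.

    ``d_min`` optionally excludes the membrane band itself (candidates
    closer than ``d_min`` to the surface), which suppresses shell-ripple
    detections when picking above a subtracted membrane.
    """
    if not vesicles:
        raise ValueError("at least one vesicle model is required")
    if d_max < 0 or d_min < 0:
        raise ValueError("distance bounds must be non-negative")
    positions = np.atleast_2d(positions)
    if len(positions) == 0:
        return positions
    dists = np.stack([v.surface_distance(positions) for v in vesicles], axis=1)
    dmin = dists.min(axis=1)
    return positions[(dmin <= d_max) & (dmin >= d_min)]


def refine_anchor_positions(density: DensityMap, positions: np.ndarray,
                            vesicles: list[VesicleModel],
                            search_radius: float = 110.0,
                            band_half_width: float = 25.0) -> np.ndarray:
    """Snap each candidate to the deepest membrane-band voxel nearby.

    The tail-membrane junction is the darkest point of the membrane band
    (protein and shell densities add there), so the minimum of the *raw*
    smoothed map over voxels within ``search_radius`` of the candidate and
    within ``band_half_width`` of the sphere surface localizes the
    particle's membrane anchor. Candidates with no band voxels in reach
    are radially projected instead.
    """
    positions = np.atleast_2d(positions)
    which = nearest_vesicle(positions, vesicles)
    r_vox = int(np.ceil(search_radius / density.voxel_size))
    offs = np.arange(-r_vox, r_vox + 1)
    OX, OY, OZ = np.meshgrid(offs, offs, offs, indexing="ij")
    near = (OX**2 + OY**2 + OZ**2) * density.voxel_size**2 <= search_radius**2
    shape = np.array(density.shape)
    out = np.zeros_like(positions, dtype=float)
    for i, p in enumerate(positions):
        v = vesicles[which[i]]
        ci = np.rint(density.position_to_index(p)).astype(int)
        ix, iy, iz = ci[0] + OX, ci[1] + OY, ci[2] + OZ
        ok = near & (ix >= 0) & (ix < shape[0]) & (iy >= 0) & \
            (iy < shape[1]) & (iz >= 0) & (iz < shape[2])
        pts = np.stack([ix, iy, iz], axis=-1)[ok] * density.voxel_size \
            + density.origin + density.voxel_size / 2.0
        in_band = np.abs(np.linalg.norm(pts - v.centre, axis=1) - v.radius) \
            <= band_half_width
        if not in_band.any():
            d = p - v.centre
            out[i] = v.centre + v.radius * d / np.linalg.norm(d)
            continue
        vals = density.grid[ix[ok], iy[ok], iz[ok]][in_band]
        out[i] = pts[in_band][np.argmin(vals)]
    return out


def nearest_vesicle(positions: np.ndarray,
                    vesicles: list[VesicleModel]) -> np.ndarray:
    """Index of the nearest vesicle (by surface distance) for each position."""
    positions = np.atleast_2d(positions)
    dists = np.stack([v.surface_distance(positions) for v in vesicles], axis=1)
    return dists.argmin(axis=1)


def init_orientations(positions: np.ndarray,
                      vesicles: list[VesicleModel]) -> ParticleTable:
    """Initial particle table: orientation = outward membrane normal.

    The rotation takes template +z onto the outward radial unit vector at
    each position; the in-plane spin is zero by convention.
    """
    positions = np.atleast_2d(positions)
    which = nearest_vesicle(positions, vesicles)
    eulers = np.zeros((len(positions), 3))
    for i, (p, vi) in enumerate(zip(positions, which)):
        n = vesicles[vi].outward_normal(p[None, :])[0]
        phi = np.degrees(np.arctan2(n[1], n[0]))
        theta = np.degrees(np.arccos(np.clip(n[2], -1.0, 1.0)))
        eulers[i] = matrix_to_euler(euler_to_matrix(phi, theta, 0.0))
    return ParticleTable.from_arrays(positions, eulers,
                                     extra={"vesicle": which})


def subtract_radial_background(density: DensityMap, vesicles: list[VesicleModel],
                               r_min: float = -80.0, r_max: float = 200.0) -> DensityMap:
    """Remove each vesicle's rotationally symmetric density component.

    For every vesicle, the mean density as a function of radius (binned at
    one voxel) is computed over the window ``[radius + r_min, radius +
    r_max]`` and subtracted from the voxels in that window. This removes
    the membrane shell and the angular mean of the protein layer, leaving
    the anisotropic (per-particle) signal that drives masked alignment;
    the orientation-free symmetric component carries no pose information.
    """
    out = density.copy()
    g = out.grid
    axes = [density.voxel_centers_axis(i) for i in range(3)]
    bw = density.voxel_size
    for ves in vesicles:
        lo, hi = ves.radius + r_min, ves.radius + r_max
        nbin = int(np.ceil((hi - lo) / bw))
        sums = np.zeros(nbin)
        counts = np.zeros(nbin)
        chunk = max(1, int(4e6 // (g.shape[1] * g.shape[2])))
        sel_cache = []
        for i0 in range(0, g.shape[0], chunk):
            X = axes[0][i0:i0 + chunk, None, None] - ves.centre[0]
            Y = axes[1][None, :, None] - ves.centre[1]
            Z = axes[2][None, None, :] - ves.centre[2]
            r = np.sqrt(X**2 + Y**2 + Z**2)
            sel = (r >= lo) & (r < hi)
            b = ((r[sel] - lo) / bw).astype(int)
            sums += np.bincount(b, weights=g[i0:i0 + chunk][sel], minlength=nbin)
            counts += np.bincount(b, minlength=nbin)
            sel_cache.append((i0, sel, b))
        prof = np.where(counts > 0, sums / np.maximum(counts, 1), 0.0)
        for i0, sel, b in sel_cache:
            g[i0:i0 + chunk][sel] -= prof[b].astype(np.float32)
    return out


class SphereFitError(ValueError):
    """Raised when a sphere cannot be fitted to the supplied points."""


def fit_vesicle_sphere(surface_points: np.ndarray | None = None,
                       density: DensityMap | None = None,
                       n_samples: int = 500,
                       seed: int = 0) -> VesicleModel:
    """Least-squares sphere fit (algebraic, then geometric refinement).

    Point mode requires >= 4 non-coplanar points. Map mode samples points
    at the strongest negative radial gradient magnitude: random rays from
    the density-weighted centroid, taking the darkest radius per ray.
    """
    if surface_points is None and density is None:
        raise SphereFitError("provide surface points or a map")
    if surface_points is None:
        surface_points = _sample_shell_points(density, n_samples, seed)
    pts = np.atleast_2d(np.asarray(surface_points, float))
    if len(pts) < 4:
        raise SphereFitError("at least 4 points are required")
    # coplanarity check
    centred = pts - pts.mean(axis=0)
    if np.linalg.matrix_rank(centred, tol=1e-6 * max(1.0, np.abs(pts).max())) < 3:
        raise SphereFitError("points are coplanar; sphere is ill-determined")
    # algebraic fit: |p|^2 = 2 p.c + (r^2 - |c|^2)
    A = np.hstack([2 * pts, np.ones((len(pts), 1))])
    b = (pts**2).sum(axis=1)
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    centre = sol[:3]
    radius = float(np.sqrt(max(sol[3] + centre @ centre, 1e-12)))

    def residuals(params: np.ndarray) -> np.ndarray:
        c, r = params[:3], params[3]
        return np.linalg.norm(pts - c, axis=1) - r

    fit = optimize.least_squares(residuals, np.r_[centre, radius], method="lm")
    c, r = fit.x[:3], float(fit.x[3])
    if r <= 0:
        raise SphereFitError("fitted radius is non-positive")
    return VesicleModel(centre=c, radius=r)


def _sample_shell_points(density: DensityMap, n_samples: int, seed: int) -> np.ndarray:
    g = density.grid
    w = np.clip(-g, 0, None).astype(float)
    if w.sum() <= 0:
        raise SphereFitError("map has no dark density to locate a shell")
    idx = np.indices(g.shape, dtype=float)
    centroid = np.array([(idx[d] * w).sum() / w.sum() for d in range(3)])
    rng = np.random.default_rng(seed)
    dirs = rng.standard_normal((n_samples, 3))
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    rmax = min(
        centroid.min(), (np.array(g.shape) - 1 - centroid).min()
    )
    radii = np.linspace(1.0, max(rmax, 2.0), 64)
    pts = []
    for d in dirs:
        line = centroid[None, :] + radii[:, None] * d[None, :]
        vals = ndimage.map_coordinates(g, line.T, order=1, mode="nearest")
        k = int(np.argmin(vals))
        if vals[k] < 0:
            pts.append(centroid + radii[k] * d)
    if len(pts) < 4:
        raise SphereFitError("could not sample enough shell points")
    pts = np.array(pts)
    return density.origin + (pts + 0.5) * density.voxel_size
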