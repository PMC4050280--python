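"""Post-averaging geometry: tilt statistics, packing, back-plotting and
volume-thresholded measurement of the averaged density."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .core_io import DensityMap, ParticleTable, VesicleModel
from .picking import nearest_vesicle


# --------------------------------------------------------------------------- #
# orientation statistics
# --------------------------------------------------------------------------- #


@dataclass
class TiltStatistics:
    tilt: np.ndarray          # per-particle tilt from the membrane normal, deg
    azimuth: np.ndarray       # tangential direction of the tilt, deg in [0, 360)
    mean: float
    sd: float
    rayleigh_z: float         # Rayleigh uniformity statistic for azimuths
    rayleigh_p: float


def rayleigh_test(angles_deg: np.ndarray) -> tuple[float, float]:
    """Rayleigh test of circular uniformity; returns (z, p).

    z = n * R_bar^2 with R_bar the mean resultant length; p uses the
    standard finite-n correction.
    """
    a = np.radians(np.asarray(angles_deg, float))
    n = len(a)
    if n == 0:
        raise ValueError("no angles supplied")
    rbar = np.hypot(np.cos(a).mean(), np.sin(a).mean())
    z = n * rbar**2
    p = np.exp(-z) * (
        1 + (2 * z - z**2) / (4 * n) - (24 * z - 132 * z**2 + 76 * z**3 - 9 * z**4)
        / (288 * n**2)
    )
    return float(z), float(min(max(p, 0.0), 1.0))


def anchor_points(particles: ParticleTable,
                  vesicles: list[VesicleModel]) -> np.ndarray:
    """Membrane anchor of each particle: its long axis traced back to the
    nearest vesicle sphere.

    The anchor is the intersection of the ray ``position - t * axis`` with
    the sphere (closest intersection); when the axis misses the sphere the
    radial projection of the position is used instead. For particles whose
    position already lies on the membrane this is the position itself.
    """
    if len(particles) == 0:
        return np.zeros((0, 3))
    pos = particles.positions
    rots = particles.rotation_matrices()
    axes = rots @ np.array([0.0, 0.0, 1.0])
    which = nearest_vesicle(pos, vesicles)
    out = np.zeros_like(pos)
    for i in range(len(particles)):
        v = vesicles[which[i]]
        d = pos[i] - v.centre
        if np.linalg.norm(d) < 1e-9:
            raise ValueError("particle at the vesicle centre: normal undefined")
        ad = axes[i] @ d
        disc = ad * ad - (d @ d - v.radius**2)
        if disc >= 0:
            roots = np.array([ad - np.sqrt(disc), ad + np.sqrt(disc)])
            t = roots[np.argmin(np.abs(roots))]
            out[i] = pos[i] - t * axes[i]
        else:
            nd = np.linalg.norm(d)
            if nd < 1e-9:
                raise ValueError("particle at the vesicle centre")
            out[i] = v.centre + v.radius * d / nd
    return out


def tilt_statistics(particles: ParticleTable,
                    vesicles: list[VesicleModel]) -> TiltStatistics:
    """Tilt of each particle's long axis from the outward membrane normal.

    The normal is evaluated at the particle's anchor (the axis traced back
    to the membrane sphere, see :func:`anchor_points`), not at its
    instantaneous centre. The azimuth is the direction of the axis's
    tangential component in a deterministic tangent basis.
    """
    if len(particles) == 0:
        raise ValueError("no particles")
    pos = particles.positions
    which = nearest_vesicle(pos, vesicles)
    rots = particles.rotation_matrices()
    axes = rots @ np.array([0.0, 0.0, 1.0])
    anchors = anchor_points(particles, vesicles)
    tilts = np.zeros(len(particles))
    azimuths = np.zeros(len(particles))
    for i in range(len(particles)):
        v = vesicles[which[i]]
        normal = v.outward_normal(anchors[i][None, :])[0]
        a = axes[i]
        tilts[i] = np.degrees(np.arccos(np.clip(a @ normal, -1.0, 1.0)))
        # deterministic tangent basis at the anchor
        helper = np.array([0.0, 0.0, 1.0])
        if abs(normal[2]) > 0.999:
            helper = np.array([1.0, 0.0, 0.0])
        e1 = np.cross(helper, normal)
        e1 /= np.linalg.norm(e1)
        e2 = np.cross(normal, e1)
        azimuths[i] = np.degrees(np.arctan2(a @ e2, a @ e1)) % 360.0
    z, p = rayleigh_test(azimuths)
    return TiltStatistics(
        tilt=tilts, azimuth=azimuths,
        mean=float(tilts.mean()), sd=float(tilts.std(ddof=1)) if len(tilts) > 1 else 0.0,
        rayleigh_z=z, rayleigh_p=p,
    )


# --------------------------------------------------------------------------- #
# packing
# --------------------------------------------------------------------------- #


@dataclass
class NNResult:
    distances: np.ndarray     # per-particle nearest-neighbour distance, Å
    minimum: float
    median: float
    histogram: tuple[np.ndarray, np.ndarray]  # counts, bin edges


def nn_distances(particles: ParticleTable, bin_width: float = 5.0) -> NNResult:
    """Euclidean centre-to-centre nearest-neighbour distance per particle."""
    if len(particles) < 2:
        raise ValueError("at least two particles are required")
    pos = particles.positions
    tree = cKDTree(pos)
    d, _ = tree.query(pos, k=2)
    dist = d[:, 1]
    edges = np.arange(0.0, dist.max() + bin_width, bin_width)
    counts, edges = np.histogram(dist, bins=edges)
    return NNResult(distances=dist, minimum=float(dist.min()),
                    median=float(np.median(dist)), histogram=(counts, edges))


# --------------------------------------------------------------------------- #
# back-plotting
# --------------------------------------------------------------------------- #


def backplot(average_map: DensityMap, membrane_map: DensityMap | None,
             particles: ParticleTable,
             tomogram_dims: tuple[int, int, int],
             voxel_size: float,
             origin: np.ndarray | None = None) -> DensityMap:
    """Composite map: membrane plus the average resampled at each pose.

    The average map's own origin defines its frame (centre voxel at the
    particle position); placements falling outside the composite raise
    with the offending ids.
    """
    origin = np.zeros(3) if origin is None else np.asarray(origin, float)
    grid = np.zeros(tomogram_dims, dtype=np.float32)
    out = DensityMap(grid, voxel_size, origin)
    if membrane_map is not None:
        if membrane_map.grid.shape != grid.shape:
            raise ValueError("membrane map dimensions must match the composite")
        grid += membrane_map.grid

    tmpl = average_map
    corners = np.array([
        [x, y, z]
        for x in (tmpl.origin[0], tmpl.origin[0] + tmpl.shape[0] * tmpl.voxel_size)
        for y in (tmpl.origin[1], tmpl.origin[1] + tmpl.shape[1] * tmpl.voxel_size)
        for z in (tmpl.origin[2], tmpl.origin[2] + tmpl.shape[2] * tmpl.voxel_size)
    ])
    rots = particles.rotation_matrices()
    positions = particles.positions
    bad: list[int] = []
    plans = []
    for i in range(len(particles)):
        ci = out.position_to_index(positions[i])
        if np.any(ci < 0) or np.any(ci >= np.array(tomogram_dims)):
            bad.append(int(particles.df["id"].iloc[i]))
            continue
        world = (rots[i] @ corners.T).T + positions[i]
        lo = np.floor(out.position_to_index(world.min(axis=0)) - 1).astype(int)
        hi = np.ceil(out.position_to_index(world.max(axis=0)) + 2).astype(int) + 1
        # overhanging box corners are clipped; only a centre outside the
        # composite is an error
        lo = np.maximum(lo, 0)
        hi = np.minimum(hi, tomogram_dims)
        plans.append((i, lo, hi))
    if bad:
        raise ValueError(f"placements outside the composite dims: ids {bad}")
    for i, lo, hi in plans:
        sub_axes = [origin[d] + (np.arange(lo[d], hi[d]) + 0.5) * voxel_size
                    for d in range(3)]
        P = np.stack(np.meshgrid(*sub_axes, indexing="ij"), axis=-1) - positions[i]
        q = P @ rots[i]
        frac = (q - tmpl.origin) / tmpl.voxel_size - 0.5
        vals = ndimage.map_coordinates(
            tmpl.grid, np.moveaxis(frac, -1, 0), order=1, mode="constant", cval=0.0
        )
        grid[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] += vals.astype(np.float32)
    return out


# --------------------------------------------------------------------------- #
# volume thresholding and extent measurement
# --------------------------------------------------------------------------- #


def threshold_by_volume(density: DensityMap, target_volume: float) -> float:
    """Iso-level enclosing ``target_volume`` (Å^3) of the darkest voxels.

    Dark convention: the enclosed set is {voxels <= level}. The level is
    the k-th darkest value with k = round(target / voxel volume), so the
    enclosed voxel-count volume matches the target to within half a voxel.
    """
    vv = density.voxel_volume()
    total = density.grid.size * vv
    if not 0 < target_volume < total:
        raise ValueError(
            f"target volume {target_volume} outside (0, {total}) for this box"
        )
    k = int(round(target_volume / vv))
    k = max(k, 1)
    flat = density.grid.ravel()
    level = float(np.partition(flat, k - 1)[k - 1])
    return level


@dataclass
class Extents:
    length: float                 # largest principal-axis extent, Å
    cross_axes: tuple[float, float]  # remaining two extents (descending), Å
    n_voxels: int


def measure_extents(density: DensityMap, iso_level: float,
                    membrane_normal: np.ndarray | None = None) -> Extents:
    """Extents of the largest 26-connected component at or below the level.

    Extents are max-minus-min projections onto the component's principal
    axes plus one voxel (voxels are cubes, not points). When
    ``membrane_normal`` is given, the two cross-section extents are
    evaluated over the distal ('head') half of the component along the
    long axis oriented away from the membrane.
    """
    sel = density.grid <= iso_level
    if not sel.any():
        raise ValueError("no voxels at or below the iso-level")
    labels, n = ndimage.label(sel, structure=np.ones((3, 3, 3), int))
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, np.arange(1, n + 1))
    biggest = 1 + int(np.argmax(sizes))
    idx = np.argwhere(labels == biggest).astype(float)
    pts = density.origin + (idx + 0.5) * density.voxel_size
    centred = pts - pts.mean(axis=0)
    cov = centred.T @ centred / len(pts)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    axes = evecs[:, order]  # columns: long, mid, short

    proj_long = centred @ axes[:, 0]
    length = float(proj_long.max() - proj_long.min()) + density.voxel_size

    if membrane_normal is not None:
        nrm = np.asarray(membrane_normal, float)
        nrm = nrm / np.linalg.norm(nrm)
        if axes[:, 0] @ nrm < 0:
            proj_long = -proj_long
        distal = proj_long > (proj_long.max() + proj_long.min()) / 2.0
        sub = centred[distal]
    else:
        sub = centred
    c1 = sub @ axes[:, 1]
    c2 = sub @ axes[:, 2]
    e1 = float(c1.max() - c1.min()) + density.voxel_size
    e2 = float(c2.max() - c2.min()) + density.voxel_size
    cross = (max(e1, e2), min(e1, e2))
    return Extents(length=length, cross_axes=cross, n_voxels=len(pts))


# --------------------------------------------------------------------------- #
# landmark-to-membrane distances
# --------------------------------------------------------------------------- #


def landmark_membrane_histogram(
    particles: ParticleTable,
    landmarks: np.ndarray,
    vesicles: list[VesicleModel],
    bin_width: float = 5.0,
) -> list[dict]:
    """Distance from posed template-frame landmarks to the membrane surface.

    For each landmark (template-frame Å) and particle, the landmark is
    transformed by the particle pose and its unsigned distance to the
    nearest vesicle sphere surface recorded; one histogram per landmark.
    """
    if len(particles) == 0:
        raise ValueError("no particles")
    landmarks = np.atleast_2d(np.asarray(landmarks, float))
    pos = particles.positions
    rots = particles.rotation_matrices()
    which = nearest_vesicle(pos, vesicles)
    out = []
    for lm in landmarks:
        world = pos + rots @ lm
        d = np.array([
            vesicles[which[i]].surface_distance(world[i][None, :])[0]
            for i in range(len(particles))
        ])
        edges = np.arange(0.0, d.max() + bin_width, bin_width)
        counts, edges = np.histogram(d, bins=edges)
        out.append({
            "landmark": lm,
            "distances": d,
            "histogram": (counts, edges),
            "mean": float(d.mean()),
        })
    return out
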