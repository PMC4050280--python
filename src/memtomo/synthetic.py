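"""Synthetic vesicle tomograms with ground truth.

The generator emulates the statistical structure a membrane-fusogen
subtomogram analysis rests on: spherical vesicles bearing an elongated,
membrane-anchored protein phantom; protein long axes tilted from the local
membrane normal by a truncated Gaussian with uniform azimuth; hard-core
packing on the membrane surface; a Fourier-space missing wedge from the
limited tilt range; and additive white Gaussian noise.

Density is dark (negative) on a zero background throughout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import fft as sfft
from scipy import ndimage, stats

from .core_io import (
    DensityMap,
    ParticleTable,
    TiltGeometry,
    VesicleModel,
    euler_to_matrix,
    matrix_to_euler,
)


class PackingError(RuntimeError):
    """Hard-core placement failed; reports the count achieved."""

    def __init__(self, requested: int, achieved: int):
        super().__init__(
            f"hard-core packing infeasible: placed {achieved} of {requested} particles"
        )
        self.requested = requested
        self.achieved = achieved


class PlacementError(ValueError):
    """A particle footprint falls outside the tomogram box."""


@dataclass
class ProteinTemplate:
    """Elongated membrane-protein phantom.

    The phantom is an ellipsoidal distal head (the two cross-section
    semi-axes are ``head_axes/2``, the axial semi-extent is ``length/4`` so
    the head occupies the distal half) joined to a proximal cylindrical
    tail. The long axis is template +z; the membrane anchor point is the
    template-frame origin (0, 0, 0); density is <= 0 inside.
    """

    map: DensityMap
    length: float
    head_axes: tuple[float, float]
    tail_radius: float

    @property
    def axis(self) -> np.ndarray:
        return np.array([0.0, 0.0, 1.0])

    def analytic_volume(self) -> float:
        """Closed-form interior volume (ellipsoid + cylinder - lens overlap).

        The cylinder runs from z=0 to the ellipsoid centre plane; the
        overlap is the cylinder core of the lower half-ellipsoid.
        """
        a, b = self.head_axes[0] / 2.0, self.head_axes[1] / 2.0
        c = self.length / 4.0
        z0 = self.length - c
        ellipsoid = 4.0 / 3.0 * np.pi * a * b * c
        cylinder = np.pi * self.tail_radius**2 * z0
        # overlap: cylinder x lower half ellipsoid, integrate cross-sections
        zs = np.linspace(z0 - c, z0, 2001)
        s = np.sqrt(np.clip(1 - ((zs - z0) / c) ** 2, 0, 1))
        ae, be = a * s, b * s
        overlap_area = np.array(
            [_ellipse_circle_area(ai, bi, self.tail_radius) for ai, bi in zip(ae, be)]
        )
        overlap = np.trapezoid(overlap_area, zs)
        return ellipsoid + cylinder - overlap


def _ellipse_circle_area(a: float, b: float, r: float) -> float:
    """Area of intersection of an origin-centred ellipse (a, b) and circle r."""
    if a <= 0 or b <= 0:
        return 0.0
    if r >= max(a, b):
        return np.pi * a * b
    if r <= min(a, b):
        return np.pi * r * r
    # numeric: polar integration of min(r, ellipse radius)
    t = np.linspace(0, 2 * np.pi, 721)
    re = a * b / np.sqrt((b * np.cos(t)) ** 2 + (a * np.sin(t)) ** 2)
    rr = np.minimum(re, r)
    return float(np.trapezoid(0.5 * rr * rr, t))


def make_protein_template(
    length: float,
    head_axes: tuple[float, float] = (60.0, 40.0),
    tail_radius: float = 10.0,
    voxel_size: float = 3.8,
    depth: float = 1.0,
) -> ProteinTemplate:
    """Build the phantom on a grid with anti-aliased (coverage-weighted) edges.

    Parameters are in Å. ``depth`` is the interior density magnitude (the
    stored values are ``-depth`` inside). The total extent along +z equals
    ``length`` to within one voxel.
    """
    if length <= 0 or min(head_axes) <= 0 or tail_radius <= 0 or voxel_size <= 0:
        raise ValueError("all template dimensions must be positive")
    a, b = head_axes[0] / 2.0, head_axes[1] / 2.0
    c = length / 4.0
    if length <= 2 * c - 1e-9:
        raise ValueError("length must exceed the head extent along the axis")
    if min(head_axes[0], head_axes[1], length) <= 2 * voxel_size:
        raise ValueError("all dimensions must exceed two voxels")
    z0 = length - c  # ellipsoid centre height

    margin = 2 * voxel_size
    half_xy = max(a, b, tail_radius) + margin
    nx = int(np.ceil(2 * half_xy / voxel_size))
    nz = int(np.ceil((length + 2 * margin) / voxel_size))
    origin = np.array([-half_xy, -half_xy, -margin])
    xs = origin[0] + (np.arange(nx) + 0.5) * voxel_size
    zs = origin[2] + (np.arange(nz) + 0.5) * voxel_size
    X, Y, Z = np.meshgrid(xs, xs, zs, indexing="ij")

    # signed-distance approximations, negative inside
    f = np.sqrt((X / a) ** 2 + (Y / b) ** 2 + ((Z - z0) / c) ** 2)
    grad = np.sqrt((X / a**2) ** 2 + (Y / b**2) ** 2 + ((Z - z0) / c**2) ** 2)
    d_head = (f - 1.0) * f / np.maximum(grad, 1e-12)

    r_xy = np.sqrt(X**2 + Y**2)
    d_side = r_xy - tail_radius
    d_cap = np.maximum(-Z, Z - z0)  # cylinder spans z in [0, z0]
    d_tail = np.where(
        (d_side > 0) & (d_cap > 0),
        np.sqrt(d_side**2 + d_cap**2),
        np.maximum(d_side, d_cap),
    )

    d = np.minimum(d_head, d_tail)  # union
    coverage = np.clip(0.5 - d / voxel_size, 0.0, 1.0)
    grid = (-depth * coverage).astype(np.float32)
    return ProteinTemplate(
        map=DensityMap(grid, voxel_size, origin),
        length=float(length),
        head_axes=(float(head_axes[0]), float(head_axes[1])),
        tail_radius=float(tail_radius),
    )


def make_synthetic_chain(n_residues: int = 60, seed: int = 0):
    """Synthetic multi-domain mini-protein for fitting exercises.

    A gently bent backbone (N, CA, C per residue) threading through space,
    residues numbered 1..n on chain A. Suitable for constructing targets
    with known hinge rotations and residue-pair distances.
    """
    from .core_io import AtomicModel

    rng = np.random.default_rng(seed)
    xyz, names, resnum, elements, resnames = [], [], [], [], []
    for i in range(n_residues):
        t = i / max(n_residues - 1, 1)
        base = np.array([20 * np.sin(2 * t), 6 * np.cos(3 * t), 60 * t])
        for atom, el, off in (("N", "N", [-0.8, 0.4, -0.5]),
                              ("CA", "C", [0.0, 0.0, 0.0]),
                              ("C", "C", [0.9, -0.3, 0.6])):
            xyz.append(base + off + rng.normal(0, 0.05, 3))
            names.append(atom)
            elements.append(el)
            resnum.append(i + 1)
            resnames.append("ALA")
    n = len(xyz)
    return AtomicModel(
        serial=np.arange(1, n + 1), element=elements, atom_name=names,
        residue_name=resnames, residue_number=np.array(resnum),
        chain=["A"] * n, xyz=np.array(xyz),
        mass=np.where(np.array(elements) == "N", 14.007, 12.011),
    )


@dataclass
class SceneTruth:
    """Ground truth for a synthetic scene.

    ``particles`` carries the usual pose columns plus ``tilt_true`` and
    ``azimuth_true`` (deg); positions are the membrane anchor points.
    """

    vesicles: list[VesicleModel]
    particles: ParticleTable


def place_particles(
    vesicle: VesicleModel,
    n: int,
    min_centre_dist: float = 100.0,
    tilt_mean: float = 33.0,
    tilt_sd: float = 17.0,
    seed: int | np.random.Generator = 0,
    max_attempts: int = 10_000,
) -> SceneTruth:
    """Place ``n`` anchors on the vesicle surface with hard-core packing.

    Anchors are uniform on the sphere, rejected when any centre-to-centre
    (3D chord) distance falls below ``min_centre_dist``. Each particle's
    long axis is the outward normal tilted by an angle drawn from a
    Gaussian(tilt_mean, tilt_sd) truncated to [0, 90), about a uniformly
    random tangent direction (azimuth). Ground-truth tilt/azimuth are
    recorded in the returned table.
    """
    if n < 1:
        raise ValueError("n must be at least 1")
    if min_centre_dist < 0:
        raise ValueError("min_centre_dist must be non-negative")
    if tilt_sd < 0:
        raise ValueError("tilt_sd must be non-negative")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed

    anchors = np.zeros((n, 3))
    placed = 0
    for i in range(n):
        ok = False
        for _ in range(max_attempts):
            u = rng.standard_normal(3)
            u /= np.linalg.norm(u)
            p = vesicle.centre + vesicle.radius * u
            if placed == 0 or np.min(
                np.linalg.norm(anchors[:placed] - p, axis=1)
            ) >= min_centre_dist:
                anchors[i] = p
                placed += 1
                ok = True
                break
        if not ok:
            raise PackingError(n, placed)

    if tilt_sd == 0:
        tilts = np.full(n, float(tilt_mean))
    else:
        a, b = (0.0 - tilt_mean) / tilt_sd, (90.0 - tilt_mean) / tilt_sd
        tilts = stats.truncnorm.rvs(
            a, b, loc=tilt_mean, scale=tilt_sd, size=n, random_state=rng
        )
    azimuths = rng.uniform(0.0, 360.0, size=n)

    normals = (anchors - vesicle.centre) / vesicle.radius
    eulers = np.zeros((n, 3))
    for i in range(n):
        nx, ny, nz = normals[i]
        r_normal = euler_to_matrix(np.degrees(np.arctan2(ny, nx)),
                                   np.degrees(np.arccos(np.clip(nz, -1, 1))), 0.0)
        r_local = euler_to_matrix(azimuths[i], tilts[i], 0.0)
        eulers[i] = matrix_to_euler(r_normal @ r_local)

    particles = ParticleTable.from_arrays(
        anchors,
        eulers,
        extra={"tilt_true": tilts, "azimuth_true": azimuths},
    )
    return SceneTruth(vesicles=[vesicle], particles=particles)


def render_tomogram(
    scene: SceneTruth,
    template: ProteinTemplate,
    membrane_thickness: float = 45.0,
    box_dims: tuple[int, int, int] = (256, 256, 256),
    voxel_size: float = 7.6,
    origin: np.ndarray | None = None,
    membrane_depth: float = 1.0,
    bilayer: bool = False,
    leaflet_separation: float = 35.0,
) -> DensityMap:
    """Render the scene: dark spherical membrane shell(s) plus one phantom
    per particle, resampled at its pose by trilinear interpolation.

    With ``bilayer=True`` the membrane is two thin leaflet shells whose
    mid-radii are ``leaflet_separation`` apart; otherwise a single shell of
    ``membrane_thickness``.
    """
    if origin is None:
        origin = np.zeros(3)
    origin = np.asarray(origin, float)
    grid = np.zeros(box_dims, dtype=np.float32)
    out = DensityMap(grid, voxel_size, origin)

    axes = [out.voxel_centers_axis(i) for i in range(3)]
    # membrane shells, slab-wise in x to bound memory
    for ves in scene.vesicles:
        if bilayer:
            half = (membrane_thickness - leaflet_separation) / 2.0
            shells = [(ves.radius - leaflet_separation / 2.0, half),
                      (ves.radius + leaflet_separation / 2.0, half)]
        else:
            shells = [(ves.radius, membrane_thickness / 2.0)]
        chunk = max(1, int(4e6 // (box_dims[1] * box_dims[2])))
        for i0 in range(0, box_dims[0], chunk):
            X = axes[0][i0:i0 + chunk, None, None] - ves.centre[0]
            Y = axes[1][None, :, None] - ves.centre[1]
            Z = axes[2][None, None, :] - ves.centre[2]
            r = np.sqrt(X**2 + Y**2 + Z**2)
            for mid, half_t in shells:
                cov = np.clip((half_t - np.abs(r - mid)) / voxel_size + 0.5, 0.0, 1.0)
                grid[i0:i0 + chunk] -= (membrane_depth * cov).astype(np.float32)

    # particles
    tmpl = template.map
    corners = np.array([
        [x, y, z]
        for x in (tmpl.origin[0], tmpl.origin[0] + tmpl.shape[0] * tmpl.voxel_size)
        for y in (tmpl.origin[1], tmpl.origin[1] + tmpl.shape[1] * tmpl.voxel_size)
        for z in (tmpl.origin[2], tmpl.origin[2] + tmpl.shape[2] * tmpl.voxel_size)
    ])
    rots = scene.particles.rotation_matrices()
    positions = scene.particles.positions
    bad_ids = []
    plans = []
    for idx in range(len(scene.particles)):
        world = (rots[idx] @ corners.T).T + positions[idx]
        lo = out.position_to_index(world.min(axis=0)) - 1
        hi = out.position_to_index(world.max(axis=0)) + 2
        lo_i = np.floor(lo).astype(int)
        hi_i = np.ceil(hi).astype(int) + 1
        if np.any(lo_i < 0) or np.any(hi_i > np.array(box_dims)):
            bad_ids.append(int(scene.particles.df["id"].iloc[idx]))
            continue
        plans.append((idx, lo_i, hi_i))
    if bad_ids:
        raise PlacementError(f"particles outside the box: ids {bad_ids}")

    for idx, lo_i, hi_i in plans:
        sub_axes = [
            origin[d] + (np.arange(lo_i[d], hi_i[d]) + 0.5) * voxel_size
            for d in range(3)
        ]
        P = np.stack(
            np.meshgrid(*sub_axes, indexing="ij"), axis=-1
        ) - positions[idx]
        q = P @ rots[idx]  # == R^-1 @ p for each point
        frac = (q - tmpl.origin) / tmpl.voxel_size - 0.5
        vals = ndimage.map_coordinates(
            tmpl.grid, np.moveaxis(frac, -1, 0), order=1, mode="constant", cval=0.0
        )
        grid[lo_i[0]:hi_i[0], lo_i[1]:hi_i[1], lo_i[2]:hi_i[2]] += vals.astype(np.float32)

    return out


def wedge_mask(shape: tuple[int, int, int], geometry: TiltGeometry,
               rfft_last: bool = True) -> np.ndarray:
    """Boolean mask of *retained* Fourier coefficients for the tilt range.

    The beam is along z. A coefficient is measured when the angle of its
    (in-plane-perpendicular, z) frequency components from the untilted
    plane lies within [tilt_min, tilt_max] (folded to a line direction).
    """
    kz = sfft.rfftfreq(shape[2]) if rfft_last else sfft.fftfreq(shape[2])
    if geometry.tilt_axis == "y":
        kp = sfft.fftfreq(shape[0])[:, None, None]
        kzg = kz[None, None, :]
    else:
        kp = sfft.fftfreq(shape[1])[None, :, None]
        kzg = kz[None, None, :]
    ang = np.degrees(np.arctan2(kzg, kp))
    # fold to line directions in (-90, 90]
    ang = np.where(ang > 90.0, ang - 180.0, ang)
    ang = np.where(ang <= -90.0, ang + 180.0, ang)
    keep = (ang >= geometry.tilt_min) & (ang <= geometry.tilt_max)
    return np.broadcast_to(keep, (shape[0], shape[1], len(kz))).copy()


def apply_missing_wedge(density: DensityMap, geometry: TiltGeometry) -> DensityMap:
    """Zero the Fourier coefficients unsampled by the tilt range.

    Idempotent: applying the mask twice equals applying it once.
    """
    spec = sfft.rfftn(density.grid.astype(np.float32))
    keep = wedge_mask(density.shape, geometry, rfft_last=True)
    spec *= keep
    out = sfft.irfftn(spec, s=density.shape).astype(np.float32)
    return DensityMap(out, density.voxel_size, density.origin.copy())


def add_noise(density: DensityMap, snr: float,
              seed: int | np.random.Generator = 0) -> DensityMap:
    """Additive white Gaussian noise at a stated signal-to-noise ratio.

    Noise variance = var(signal over the support of nonzero signal) / snr.
    ``snr=inf`` returns an unchanged copy.
    """
    if not snr > 0:
        raise ValueError("snr must be positive")
    if np.isinf(snr):
        return density.copy()
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    support = density.grid != 0
    if not support.any():
        raise ValueError("map has no nonzero signal to define SNR against")
    sigma = float(np.std(density.grid[support])) / np.sqrt(snr)
    noise = rng.standard_normal(density.shape, dtype=np.float32) * np.float32(sigma)
    return DensityMap(density.grid + noise, density.voxel_size, density.origin.copy())
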