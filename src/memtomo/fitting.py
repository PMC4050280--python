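"""Fitting atomic models into EM density.

Density synthesis renders each atom as a mass-weighted 3D Gaussian with
real-space SD ``resolution / (2 pi sqrt(2))``, negative (dark) to match
the map convention used throughout this package. Rigid fitting is a
deterministic grid search maximizing the about-the-mean cross-correlation
coefficient (CCC) over the model's own footprint. Flexible fitting treats
each domain as a rigid body rotating about a hinge pivot, alternately
optimized on a shrinking rotation-vector grid; the zero rotation is always
in the search space, so the flexible CCC can never fall below the rigid
one. No stereochemical regularization is applied at the hinge junctions;
validation is by CCC and recovered angles.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, optimize
from scipy.spatial.transform import Rotation

from .averaging import masked_correlation, rotation_grid
from .core_io import (
    AtomicModel,
    DensityMap,
    DomainAssignment,
    VesicleModel,
    matrix_to_euler,
)

BACKBONE_ATOMS = ("N", "CA", "C")
GLU_CARBOXYLATE = ("OE1", "OE2")
LYS_AMINE = ("NZ",)


@dataclass
class FitResult:
    rotation: tuple[float, float, float]      # Z-Y-Z Euler, deg
    translation: np.ndarray                   # Å
    ccc: float
    hinge_rotations: dict[str, float] = field(default_factory=dict)  # deg

    def __post_init__(self) -> None:
        if not -1.0 - 1e-9 <= self.ccc <= 1.0 + 1e-9:
            raise ValueError("ccc must lie in [-1, 1]")


# --------------------------------------------------------------------------- #
# density synthesis
# --------------------------------------------------------------------------- #


def model_to_map(
    model: AtomicModel,
    resolution: float,
    voxel_size: float,
    origin: np.ndarray | None = None,
    shape: tuple[int, int, int] | None = None,
) -> DensityMap:
    """Render the model as dark mass-weighted Gaussians at the stated
    resolution. Without an explicit grid, a box with a 3-sigma margin
    around the model is used."""
    if len(model) == 0:
        raise ValueError("empty model")
    if resolution < 2 * voxel_size:
        raise ValueError("resolution must be at least twice the voxel size")
    sigma = resolution / (2.0 * np.pi * np.sqrt(2.0))
    margin = 4.0 * sigma + voxel_size
    if origin is None or shape is None:
        lo = model.xyz.min(axis=0) - margin
        hi = model.xyz.max(axis=0) + margin
        origin = lo
        shape = tuple(int(np.ceil(d / voxel_size)) for d in hi - lo)
    origin = np.asarray(origin, float)
    grid = np.zeros(shape, dtype=np.float64)
    _splat(grid, origin, voxel_size, model.xyz, model.mass, sigma)
    return DensityMap(grid.astype(np.float32), voxel_size, origin)


def _splat(grid: np.ndarray, origin: np.ndarray, voxel_size: float,
           xyz: np.ndarray, mass: np.ndarray, sigma: float) -> None:
    half = int(np.ceil(3.5 * sigma / voxel_size))
    norm = 1.0 / ((2 * np.pi) ** 1.5 * sigma**3)
    offs = np.arange(-half, half + 1)
    OX, OY, OZ = np.meshgrid(offs, offs, offs, indexing="ij")
    shape = np.array(grid.shape)
    for p, m in zip(xyz, mass):
        ci = (p - origin) / voxel_size - 0.5
        c0 = np.rint(ci).astype(int)
        ix, iy, iz = c0[0] + OX, c0[1] + OY, c0[2] + OZ
        ok = (
            (ix >= 0) & (ix < shape[0]) & (iy >= 0) & (iy < shape[1])
            & (iz >= 0) & (iz < shape[2])
        )
        if not ok.any():
            continue
        dx = (ix - ci[0]) * voxel_size
        dy = (iy - ci[1]) * voxel_size
        dz = (iz - ci[2]) * voxel_size
        g = np.exp(-(dx**2 + dy**2 + dz**2) / (2 * sigma**2))
        np.add.at(grid, (ix[ok], iy[ok], iz[ok]),
                  (-m * norm * voxel_size**3) * g[ok])


def model_footprint(synth: DensityMap, fraction: float = 0.1) -> np.ndarray:
    """Binary footprint: voxels with |density| >= fraction of the maximum."""
    mag = np.abs(synth.grid)
    return (mag >= fraction * mag.max()).astype(np.float32)


def model_map_ccc(model: AtomicModel, density: DensityMap,
                  resolution: float) -> float:
    """About-the-mean CCC between map and model density over the footprint."""
    synth = model_to_map(model, resolution, density.voxel_size,
                         origin=density.origin, shape=density.shape)
    return masked_correlation(density.grid, synth.grid, model_footprint(synth))


# --------------------------------------------------------------------------- #
# rigid-body fitting
# --------------------------------------------------------------------------- #


def rigid_fit(
    model: AtomicModel,
    density: DensityMap,
    resolution: float,
    initial_rotation: tuple[float, float, float] = (0.0, 0.0, 0.0),
    initial_translation: np.ndarray | tuple = (0.0, 0.0, 0.0),
    ang_half: float = 10.0,
    ang_step: float = 5.0,
    shift_half: float = 10.0,
    shift_step: float = 5.0,
) -> tuple[FitResult, AtomicModel]:
    """Grid search maximizing the footprint CCC of the posed model.

    Rotations are applied about the model centroid on top of the initial
    transform; zero search ranges evaluate the initial pose only. Returns
    the best fit and the transformed model.
    """
    centroid = model.xyz.mean(axis=0)
    R0 = Rotation.from_euler("ZYZ", initial_rotation, degrees=True).as_matrix()
    t0 = np.asarray(initial_translation, float)

    if ang_half > 0:
        deltas = rotation_grid(ang_half, ang_step)
    else:
        deltas = np.eye(3)[None]
    if shift_half > 0:
        s = np.arange(-shift_half, shift_half + 1e-9, shift_step)
    else:
        s = np.array([0.0])
    shifts = np.stack(np.meshgrid(s, s, s, indexing="ij"), axis=-1).reshape(-1, 3)

    best = (-np.inf, np.eye(3), np.zeros(3))
    for Rd in deltas:
        R = Rd @ R0
        xyz_rot = (model.xyz - centroid) @ R.T + centroid + t0
        synth0 = model_to_map(model.with_xyz(xyz_rot), resolution,
                              density.voxel_size, origin=density.origin,
                              shape=density.shape)
        if not np.any(synth0.grid):
            continue
        for sh in shifts:
            g = synth0.grid
            if np.max(np.abs(sh)) > 1e-12:
                g = ndimage.shift(g, sh / density.voxel_size, order=1,
                                  mode="constant", cval=0.0)
            mag = np.abs(g)
            if mag.max() <= 0:
                continue
            fp = (mag >= 0.1 * mag.max()).astype(np.float32)
            try:
                ccc = masked_correlation(density.grid, g, fp)
            except ValueError:
                continue
            if ccc > best[0]:
                best = (ccc, R, t0 + sh)
    ccc, R, t = best
    if not np.isfinite(ccc):
        raise ValueError("degenerate footprint: no candidate produced a score")
    xyz_fit = (model.xyz - centroid) @ R.T + centroid + t
    fitted = model.with_xyz(xyz_fit)
    return FitResult(rotation=matrix_to_euler(R), translation=t,
                     ccc=float(ccc)), fitted


# --------------------------------------------------------------------------- #
# hinge-restricted flexible fitting
# --------------------------------------------------------------------------- #


def hinge_pivot(model: AtomicModel, domains: DomainAssignment,
                hinge_key: str) -> np.ndarray:
    """Pivot point: midpoint of the hinge residues' backbone positions."""
    residues = domains.hinges[hinge_key]
    mask = model.select(residue_numbers=residues, atom_names=BACKBONE_ATOMS)
    if not mask.any():
        mask = model.select(residue_numbers=residues)
    if not mask.any():
        raise ValueError(f"hinge residues {residues} absent from the model")
    return model.xyz[mask].mean(axis=0)


def _moving_mask(model: AtomicModel, domains: DomainAssignment,
                 domain: str, hinge_key: str) -> np.ndarray:
    # the hinge residues follow the distal (moving) domain
    mask = domains.domain_mask(model, domain)
    mask |= model.select(residue_numbers=domains.hinges[hinge_key])
    return mask


def hinge_flexible_fit(
    model: AtomicModel,
    domains: DomainAssignment,
    density: DensityMap,
    resolution: float,
    n_iterations: int = 4,
    max_angle: float = 25.0,
    grid_points: int = 7,
    n_refine: int = 3,
) -> tuple[FitResult, AtomicModel]:
    """Alternately rotate domains II and III about their hinge pivots.

    Each half-step searches a rotation-vector grid (axis x angle encoded
    as a 3-vector of degrees, magnitude capped at ``max_angle``) shrinking
    over ``n_refine`` passes, keeping domain I fixed; hinge residues move
    with their domain. The model is assumed already rigid-fitted into the
    map. Returns the fit (with per-hinge rotation magnitudes) and the
    fitted model.
    """
    if any(d not in domains.domains for d in ("I", "II", "III")):
        raise ValueError("domains I, II and III must be assigned")
    xyz = model.xyz.copy()
    applied = {"I-II": np.zeros(3), "I-III": np.zeros(3)}

    for _ in range(max(n_iterations, 0)):
        for hinge_key, dom in (("I-II", "II"), ("I-III", "III")):
            pivot = hinge_pivot(model, domains, hinge_key)
            moving = _moving_mask(model, domains, dom, hinge_key)
            base = model.with_xyz(xyz)
            base_moving = xyz[moving].copy()

            def score(rotvec_deg: np.ndarray) -> float:
                R = Rotation.from_rotvec(rotvec_deg, degrees=True).as_matrix()
                trial = xyz.copy()
                trial[moving] = (base_moving - pivot) @ R.T + pivot
                return model_map_ccc(base.with_xyz(trial), density, resolution)

            best_v = np.zeros(3)
            best_s = score(best_v)
            half = max_angle
            for _pass in range(n_refine):
                if half <= 0:
                    break
                ax = np.linspace(-half, half, grid_points)
                for vx in ax:
                    for vy in ax:
                        for vz in ax:
                            v = best_v + np.array([vx, vy, vz])
                            if np.linalg.norm(v) > max_angle + 1e-9:
                                continue
                            s = score(v)
                            if s > best_s + 1e-12:
                                best_s, best_v = s, v
                half = 2.0 * half / (grid_points - 1)
            R = Rotation.from_rotvec(best_v, degrees=True).as_matrix()
            xyz[moving] = (base_moving - pivot) @ R.T + pivot
            applied[hinge_key] = applied[hinge_key] + best_v

    fitted = model.with_xyz(xyz)
    ccc = model_map_ccc(fitted, density, resolution)
    hinge_rot = {k: float(np.linalg.norm(v)) for k, v in applied.items()}
    return FitResult(rotation=(0.0, 0.0, 0.0), translation=np.zeros(3),
                     ccc=float(ccc), hinge_rotations=hinge_rot), fitted


# --------------------------------------------------------------------------- #
# domain rotation comparison
# --------------------------------------------------------------------------- #


def _kabsch(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Rotation R and centroids such that b ~ (a - ca) @ R.T + cb."""
    ca, cb = a.mean(axis=0), b.mean(axis=0)
    rot, _ = Rotation.align_vectors(b - cb, a - ca)
    return rot.as_matrix(), ca, cb


def _common_backbone(model_a: AtomicModel, model_b: AtomicModel,
                     domains: DomainAssignment,
                     domain: str) -> tuple[np.ndarray, np.ndarray]:
    lo, hi = domains.residues(domain)

    def keymap(m: AtomicModel) -> dict:
        out = {}
        for i in range(len(m)):
            if lo <= m.residue_number[i] <= hi and m.atom_name[i] in BACKBONE_ATOMS:
                out[(m.chain[i], int(m.residue_number[i]), m.atom_name[i])] = i
        return out

    ka, kb = keymap(model_a), keymap(model_b)
    common = sorted(set(ka) & set(kb))
    if len(common) < 3:
        raise ValueError(
            f"fewer than 3 common backbone atoms in domain {domain}"
        )
    ia = [ka[k] for k in common]
    ib = [kb[k] for k in common]
    return model_a.xyz[ia], model_b.xyz[ib]


def domain_rotation_between(model_a: AtomicModel, model_b: AtomicModel,
                            domains: DomainAssignment,
                            fixed_domain: str, moving_domain: str) -> float:
    """Hinge rotation (deg) of ``moving_domain`` between two conformations.

    ``model_b`` is superposed onto ``model_a`` by least squares over the
    fixed domain's backbone; the residual optimal rotation between the
    moving domains is returned as an axis-angle magnitude. Invariant to
    any global rigid motion applied to either model.
    """
    fa, fb = _common_backbone(model_a, model_b, domains, fixed_domain)
    R, ca, cb = _kabsch(fb, fa)  # takes b-frame into a-frame
    b_aligned = model_b.with_xyz((model_b.xyz - cb) @ R.T + ca)
    ma, mb = _common_backbone(model_a, b_aligned, domains, moving_domain)
    Rm, _, _ = _kabsch(ma, mb)
    angle = np.degrees(np.linalg.norm(Rotation.from_matrix(Rm).as_rotvec()))
    return float(angle)


# --------------------------------------------------------------------------- #
# residue-pair distances
# --------------------------------------------------------------------------- #


def residue_pair_distance(
    model: AtomicModel,
    residue_a: tuple[str | None, int, tuple[str, ...]],
    residue_b: tuple[str | None, int, tuple[str, ...]],
) -> float:
    """Minimum pairwise distance (Å) between two named atom sets.

    Each residue spec is (chain or None, residue number, atom names);
    e.g. a Glu-carboxylate / Lys-amine salt bridge uses
    ``(chain, 245, GLU_CARBOXYLATE)`` and ``(chain, 400, LYS_AMINE)``.
    """
    coords = []
    for chain, num, names in (residue_a, residue_b):
        mask = model.select(chain=chain, residue_numbers=[num],
                            atom_names=list(names))
        if not mask.any():
            raise ValueError(
                f"residue {num} (chain {chain}) with atoms {names} not found"
            )
        coords.append(model.xyz[mask])
    a, b = coords
    d = np.linalg.norm(a[:, None, :] - b[None, :, :], axis=-1)
    return float(d.min())


# --------------------------------------------------------------------------- #
# bilayer placement
# --------------------------------------------------------------------------- #


class NoBilayerError(ValueError):
    """The radial profile does not show two leaflet dips."""


@dataclass
class BilayerFit:
    leaflet_radii: tuple[float, float]   # inner, outer peak radius, Å
    separation: float                    # Å
    amplitudes: tuple[float, float]


def radial_profile(density: DensityMap, vesicle: VesicleModel,
                   r_min: float, r_max: float,
                   bin_width: float | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Mean density vs radius from the vesicle centre within a window."""
    bw = density.voxel_size if bin_width is None else bin_width
    axes = [density.voxel_centers_axis(i) for i in range(3)]
    sums = None
    counts = None
    nbin = int(np.ceil((r_max - r_min) / bw))
    chunk = max(1, int(4e6 // (density.shape[1] * density.shape[2])))
    for i0 in range(0, density.shape[0], chunk):
        X = axes[0][i0:i0 + chunk, None, None] - vesicle.centre[0]
        Y = axes[1][None, :, None] - vesicle.centre[1]
        Z = axes[2][None, None, :] - vesicle.centre[2]
        r = np.sqrt(X**2 + Y**2 + Z**2)
        sel = (r >= r_min) & (r < r_max)
        b = ((r[sel] - r_min) / bw).astype(int)
        v = density.grid[i0:i0 + chunk][sel]
        s = np.bincount(b, weights=v, minlength=nbin)
        c = np.bincount(b, minlength=nbin)
        sums = s if sums is None else sums + s
        counts = c if counts is None else counts + c
    valid = counts > 0
    radii = r_min + (np.arange(nbin) + 0.5) * bw
    prof = np.full(nbin, np.nan)
    prof[valid] = sums[valid] / counts[valid]
    return radii[valid], prof[valid]


def fit_bilayer_profile(radii: np.ndarray, profile: np.ndarray) -> BilayerFit:
    """Two-Gaussian (two-leaflet) least-squares fit of a radial dip profile."""
    radii = np.asarray(radii, float)
    profile = np.asarray(profile, float)
    # initial guesses from the two deepest separated local minima
    mins = [i for i in range(1, len(profile) - 1)
            if profile[i] < profile[i - 1] and profile[i] <= profile[i + 1]]
    mins.sort(key=lambda i: profile[i])
    picked: list[int] = []
    for i in mins:
        if all(abs(radii[i] - radii[j]) > 10.0 for j in picked):
            picked.append(i)
        if len(picked) == 2:
            break
    if len(picked) < 2:
        raise NoBilayerError("fewer than two leaflet dips in the radial profile")
    picked.sort()
    i1, i2 = picked

    def model(r, r1, a1, s1, r2, a2, s2, c):
        return (c - np.abs(a1) * np.exp(-((r - r1) ** 2) / (2 * s1**2))
                - np.abs(a2) * np.exp(-((r - r2) ** 2) / (2 * s2**2)))

    p0 = [radii[i1], -profile[i1], 8.0, radii[i2], -profile[i2], 8.0, 0.0]
    try:
        popt, _ = optimize.curve_fit(model, radii, profile, p0=p0, maxfev=20_000)
    except RuntimeError as exc:
        raise NoBilayerError(f"two-leaflet fit failed: {exc}") from exc
    r1, a1, _, r2, a2, _, _ = popt
    lo, hi = sorted((float(r1), float(r2)))
    if hi - lo < 1.0:
        raise NoBilayerError("fitted leaflets coincide; no bilayer resolved")
    amps = (abs(a1), abs(a2)) if r1 < r2 else (abs(a2), abs(a1))
    return BilayerFit(leaflet_radii=(lo, hi), separation=hi - lo,
                      amplitudes=(float(amps[0]), float(amps[1])))


def place_bilayer(density: DensityMap, vesicle: VesicleModel,
                  window: tuple[float, float] | float = 80.0) -> BilayerFit:
    """Locate the two leaflet radii of a vesicle membrane in the map.

    ``window`` is either (r_min, r_max) or a half-width about the nominal
    vesicle radius. Raises :class:`NoBilayerError` when the radial profile
    does not resolve two dips.
    """
    if np.isscalar(window):
        r_min = max(vesicle.radius - float(window), 0.0)
        r_max = vesicle.radius + float(window)
    else:
        r_min, r_max = window
    radii, prof = radial_profile(density, vesicle, r_min, r_max)
    return fit_bilayer_profile(radii, prof)
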