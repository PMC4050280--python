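"""Subtomogram extraction, alignment, averaging, FSC and classification.

Alignment is a deterministic angular grid search about each particle's
current pose combined with an FFT translation search, against a reference
that is re-averaged after every iteration. Gold-standard discipline:
even/odd half-sets are refined against their own references and only meet
in the final Fourier shell correlation.

All comparisons happen in the template (reference) frame: the subvolume is
rotated by the inverse of the particle pose, candidate delta rotations are
applied to the reference, and the winning delta is composed onto the pose.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import fft as sfft
from scipy import ndimage, optimize

from .core_io import (
    DensityMap,
    FSCCurve,
    ParticleTable,
    euler_to_matrix,
    matrix_to_euler,
)

# --------------------------------------------------------------------------- #
# geometry helpers
# --------------------------------------------------------------------------- #


def rotate_map(grid: np.ndarray, rotation: np.ndarray, order: int = 1,
               cval: float | None = None) -> np.ndarray:
    """Resample ``out(x) = grid(R @ (x - c) + c)`` about the box centre.

    With ``R`` equal to a particle's pose matrix this brings a subvolume
    into the template frame. The pivot is the centre voxel ``n // 2`` —
    the voxel extraction centres content on. Out-of-footprint voxels take
    ``cval`` (default: the grid mean).
    """
    c = (np.array(grid.shape) // 2).astype(float)
    if cval is None:
        cval = float(grid.mean())
    return ndimage.affine_transform(
        grid, rotation, offset=c - rotation @ c, order=order,
        mode="constant", cval=cval,
    )


def box_origin(box_size: int, voxel_size: float) -> np.ndarray:
    """Origin placing the centre voxel's centre at physical (0, 0, 0)."""
    c = box_size // 2
    return np.full(3, -(c + 0.5) * voxel_size)


def extract_subvolume(tomogram: DensityMap, position: np.ndarray,
                      box_size: int, pad: bool = False) -> DensityMap:
    """Axis-aligned crop of ``box_size``^3 voxels centred at ``position`` (Å).

    Integer-voxel positions are copied exactly; sub-voxel positions are
    resampled by trilinear interpolation. With ``pad=True`` out-of-bounds
    voxels are filled with the tomogram mean, otherwise they are an error.
    No rotation is applied at extraction.
    """
    if box_size > min(tomogram.shape):
        raise ValueError("box larger than tomogram")
    ci = tomogram.position_to_index(np.asarray(position, float))
    c = box_size // 2
    lo = ci - c
    frac = lo - np.rint(lo)
    inside = np.all(np.rint(lo) >= 0) and np.all(
        np.rint(lo) + box_size <= np.array(tomogram.shape)
    )
    if not inside and not pad:
        raise ValueError(
            f"subvolume at {np.asarray(position)} exceeds tomogram bounds; "
            "enable padding to fill with the map mean"
        )
    if np.max(np.abs(frac)) < 1e-6:
        lo_i = np.rint(lo).astype(int)
        if inside:
            g = tomogram.grid[
                lo_i[0]:lo_i[0] + box_size,
                lo_i[1]:lo_i[1] + box_size,
                lo_i[2]:lo_i[2] + box_size,
            ].copy()
        else:
            g = np.full((box_size,) * 3, tomogram.grid.mean(), dtype=np.float32)
            src_lo = np.maximum(lo_i, 0)
            src_hi = np.minimum(lo_i + box_size, tomogram.shape)
            dst_lo = src_lo - lo_i
            dst_hi = dst_lo + (src_hi - src_lo)
            if np.all(src_hi > src_lo):
                g[dst_lo[0]:dst_hi[0], dst_lo[1]:dst_hi[1], dst_lo[2]:dst_hi[2]] = \
                    tomogram.grid[src_lo[0]:src_hi[0], src_lo[1]:src_hi[1],
                                  src_lo[2]:src_hi[2]]
    else:
        idx = np.stack(np.meshgrid(*[np.arange(box_size)] * 3, indexing="ij"))
        coords = idx + lo.reshape(3, 1, 1, 1)
        g = ndimage.map_coordinates(
            tomogram.grid, coords, order=1, mode="constant",
            cval=float(tomogram.grid.mean()),
        ).astype(np.float32)
    origin = np.asarray(position, float) + box_origin(box_size, tomogram.voxel_size)
    return DensityMap(g.astype(np.float32), tomogram.voxel_size, origin)


# --------------------------------------------------------------------------- #
# correlation
# --------------------------------------------------------------------------- #


class UndefinedScoreError(ValueError):
    """Masked region has zero variance; the correlation is undefined."""


def masked_correlation(a: np.ndarray, b: np.ndarray,
                       mask: np.ndarray | None = None) -> float:
    """Normalized about-the-mean correlation over (soft-)masked voxels."""
    if a.shape != b.shape:
        raise ValueError("volumes must share dimensions")
    if mask is None:
        w = np.ones_like(a, dtype=float)
    else:
        w = np.asarray(mask, float)
        if w.shape != a.shape:
            raise ValueError("mask must share dimensions with the volumes")
    wsum = w.sum()
    if wsum <= 0:
        raise UndefinedScoreError("mask selects no voxels")
    am = (w * a).sum() / wsum
    bm = (w * b).sum() / wsum
    da, db = a - am, b - bm
    va = (w * da * da).sum()
    vb = (w * db * db).sum()
    if va <= 0 or vb <= 0:
        raise UndefinedScoreError("zero variance in the masked region")
    return float((w * da * db).sum() / np.sqrt(va * vb))


def cc_score(subvolume: DensityMap, reference: DensityMap,
             rotation: tuple[float, float, float] = (0.0, 0.0, 0.0),
             shift: np.ndarray | tuple = (0.0, 0.0, 0.0),
             mask: np.ndarray | None = None) -> float:
    """Correlation between a subvolume and the rotated+shifted reference.

    ``rotation`` is the Z-Y-Z pose taking the reference into the subvolume
    frame; ``shift`` is in Å. The mask is defined in the reference frame:
    the subvolume is brought into that frame (inverse pose) and compared
    under the static mask.
    """
    if subvolume.shape != reference.shape:
        raise ValueError("subvolume and reference must share dimensions")
    R = euler_to_matrix(*rotation)
    shift_vox = np.asarray(shift, float) / subvolume.voxel_size
    g = subvolume.grid
    if np.max(np.abs(shift_vox)) > 1e-9:
        g = ndimage.shift(g, -shift_vox, order=1, mode="constant",
                          cval=float(g.mean()))
    sub_t = rotate_map(g, R)
    return masked_correlation(sub_t, reference.grid, mask)


# --------------------------------------------------------------------------- #
# masks and rotation grids
# --------------------------------------------------------------------------- #


def cylinder_mask(box_size: int, voxel_size: float, radius: float = 50.0,
                  z_min: float = 25.0, z_max: float = 140.0,
                  edge_width: float = 10.0) -> np.ndarray:
    """Soft cylindrical mask along template +z with a cosine edge.

    Excludes the membrane slab (z < z_min) and neighbouring particles
    (r > radius); coordinates are Å in the reference frame whose centre
    voxel sits at (0, 0, 0).
    """
    origin = box_origin(box_size, voxel_size)
    ax = origin[0] + (np.arange(box_size) + 0.5) * voxel_size
    X, Y, Z = np.meshgrid(ax, ax, ax, indexing="ij")
    r = np.sqrt(X**2 + Y**2)

    def soft_edge(d: np.ndarray) -> np.ndarray:
        # d <= 0 inside, ramps to 0 over edge_width
        t = np.clip(d / max(edge_width, 1e-9), 0.0, 1.0)
        return 0.5 * (1.0 + np.cos(np.pi * t))

    m = soft_edge(r - radius) * soft_edge(z_min - Z) * soft_edge(Z - z_max)
    return m.astype(np.float32)


def rotation_grid(half_range: float, step: float,
                  spin_half_range: float | None = None) -> np.ndarray:
    """Delta-rotation candidates covering a cone of ``half_range`` degrees.

    Candidates are rings of axis tilts at multiples of ``step`` up to
    ``half_range``, each ring sampled in azimuth at roughly ``step``
    angular spacing, crossed with in-plane spins {-step, 0, +step} (spins
    up to ``spin_half_range`` at the identity). Returned as (n, 3, 3)
    matrices; the identity is first, scan order is deterministic.
    """
    if step <= 0:
        raise ValueError("step must be positive")
    if step > half_range + 1e-9 and half_range > 0:
        raise ValueError("step must not exceed the half-range")
    spin_half = half_range if spin_half_range is None else spin_half_range
    mats = [np.eye(3)]
    spins = [s for s in np.arange(step, spin_half + 1e-9, step)]
    for s in spins:
        for sign in (1.0, -1.0):
            mats.append(euler_to_matrix(0.0, 0.0, sign * s))
    ring_spins = [0.0, step, -step]
    for tilt in np.arange(step, half_range + 1e-9, step):
        n_az = max(6, int(round(360.0 * np.sin(np.radians(tilt)) / step)))
        for az in np.arange(n_az) * (360.0 / n_az):
            base = euler_to_matrix(az, tilt, -az)
            for sp in ring_spins:
                mats.append(base @ euler_to_matrix(0.0, 0.0, sp))
    return np.array(mats)


# --------------------------------------------------------------------------- #
# schedules
# --------------------------------------------------------------------------- #


@dataclass
class AlignmentSchedule:
    """Per-iteration search parameters.

    ``ang_half``/``ang_step`` in degrees, ``shift_half`` in Å,
    ``lowpass_frac`` as a fraction of Nyquist applied to the reference
    (None disables). Half-ranges must be non-increasing and cutoffs
    non-decreasing across iterations.
    """

    ang_half: list[float]
    ang_step: list[float]
    shift_half: list[float]
    lowpass_frac: list[float | None] = field(default_factory=list)
    masked: bool = False

    def __post_init__(self) -> None:
        n = len(self.ang_half)
        if not (len(self.ang_step) == len(self.shift_half) == n):
            raise ValueError("schedule lists must have equal length")
        if not self.lowpass_frac:
            self.lowpass_frac = [None] * n
        for h, s in zip(self.ang_half, self.ang_step):
            if h > 0 and s > h + 1e-9:
                raise ValueError("angular step must not exceed the half-range")
        if any(b > a + 1e-9 for a, b in zip(self.ang_half, self.ang_half[1:])):
            raise ValueError("angular half-ranges must be non-increasing")
        cuts = [c for c in self.lowpass_frac if c is not None]
        if any(b < a - 1e-9 for a, b in zip(cuts, cuts[1:])):
            raise ValueError("low-pass cutoffs must be non-decreasing")

    def __len__(self) -> int:
        return len(self.ang_half)

    @classmethod
    def stage_a(cls) -> "AlignmentSchedule":
        """Unmasked picking-refinement stage: five translation-only
        iterations that score the picks against the global average and
        correct small centring errors; shifts are kept tight so the
        anchor-centred box convention survives into the masked stage, and
        the membrane-normal initial orientations are left untouched."""
        return cls(
            ang_half=[0.0] * 5,
            ang_step=[1.0] * 5,
            shift_half=[4.0] * 5,
            lowpass_frac=[0.25, 0.3, 0.35, 0.4, 0.5],
            masked=False,
        )

    @classmethod
    def stage_b(cls) -> "AlignmentSchedule":
        """Masked refinement: six iterations, finer sampling, rising cutoff."""
        half = [30.0, 20.0, 15.0, 10.0, 6.0, 4.0]
        return cls(
            ang_half=half,
            ang_step=[h / 3.0 for h in half],
            shift_half=[8.0] * 6,
            lowpass_frac=list(np.linspace(0.25, 0.75, 6)),
            masked=True,
        )


def lowpass_gaussian(grid: np.ndarray, voxel_size: float,
                     cutoff: float) -> np.ndarray:
    """Gaussian low-pass: amplitudes times ``exp(-f^2 / (2 cutoff^2))``."""
    spec = sfft.rfftn(grid.astype(np.float32))
    f2 = _freq2_grid(grid.shape, voxel_size)
    spec *= np.exp(-f2 / (2.0 * cutoff**2))
    return sfft.irfftn(spec, s=grid.shape).astype(np.float32)


def _freq2_grid(shape: tuple[int, ...], voxel_size: float) -> np.ndarray:
    fx = sfft.fftfreq(shape[0], d=voxel_size)[:, None, None]
    fy = sfft.fftfreq(shape[1], d=voxel_size)[None, :, None]
    fz = sfft.rfftfreq(shape[2], d=voxel_size)[None, None, :]
    return fx**2 + fy**2 + fz**2


# --------------------------------------------------------------------------- #
# alignment
# --------------------------------------------------------------------------- #


def _normalized_for_fft(vol: np.ndarray, mask: np.ndarray | None) -> np.ndarray:
    if mask is None:
        v = vol - vol.mean()
    else:
        wsum = mask.sum()
        v = (vol - (mask * vol).sum() / wsum) * mask
    n = np.linalg.norm(v)
    return v / n if n > 0 else v


def _shift_window(n: int, w: int) -> np.ndarray:
    w = min(w, n // 2 - 1)
    return np.r_[np.arange(0, w + 1), np.arange(n - w, n)]


def _half_spectrum_weights(box: int) -> np.ndarray:
    """Multiplicity of each rfft coefficient in the full Hermitian spectrum
    (2 for interior planes of the halved axis, 1 for the self-conjugate
    kz=0 and, for even boxes, the Nyquist plane)."""
    nz = box // 2 + 1
    w = np.full((box, box, nz), 2.0)
    w[:, :, 0] = 1.0
    if box % 2 == 0:
        w[:, :, -1] = 1.0
    return w


def membrane_frame_drift(particles: ParticleTable, vesicles) -> np.ndarray:
    """Collective rotation of the consensus (template) frame away from the
    membrane-normal frame.

    For each particle the pose is expressed relative to the outward-normal
    frame at its position; with uniform tilt azimuths these relative
    rotations scatter symmetrically about the identity, so their chordal
    mean (projected back to SO(3)) estimates the common drift ``D`` such
    that ``R_p = R_normal @ delta_i @ D``. Right-multiplying every pose by
    ``D^-1`` re-anchors the consensus frame to the membrane without
    touching relative alignment.
    """
    from scipy.spatial.transform import Rotation

    from .picking import nearest_vesicle

    pos = particles.positions
    which = nearest_vesicle(pos, vesicles)
    rots = particles.rotation_matrices()
    rel = np.zeros((len(particles), 3, 3))
    for i in range(len(particles)):
        nrm = vesicles[which[i]].outward_normal(pos[i][None, :])[0]
        phi = np.degrees(np.arctan2(nrm[1], nrm[0]))
        theta = np.degrees(np.arccos(np.clip(nrm[2], -1.0, 1.0)))
        Rn = Rotation.from_euler("ZYZ", [phi, theta, 0.0],
                                 degrees=True).as_matrix()
        rel[i] = Rn.T @ rots[i]
    M = rel.mean(axis=0)
    U, _, Vt = np.linalg.svd(M)
    return U @ np.diag([1.0, 1.0, np.linalg.det(U @ Vt)]) @ Vt


def undrift(particles: ParticleTable, vesicles) -> ParticleTable:
    """Remove the collective membrane-frame drift from all poses."""
    D = membrane_frame_drift(particles, vesicles)
    rots = particles.rotation_matrices()
    eulers = np.array([matrix_to_euler(rots[i] @ D.T)
                       for i in range(len(particles))])
    return particles.with_updates(eulers=eulers)


def rotated_wedge_mask(box: int, pose: np.ndarray, tilt_max: float = 60.0,
                       tilt_axis: str = "y") -> np.ndarray:
    """Missing-wedge support of a subvolume after rotation into the
    template frame by the inverse of ``pose``.

    A template-frame frequency k is sampled when its tomogram-frame image
    ``pose @ k`` lies outside the missing wedge. Returned on the rfft grid
    (last axis halved). Used for wedge-compensated correlation: zeroing
    the unsampled region on both sides of the comparison removes the bias
    that otherwise drags orientations toward the common wedge direction.
    """
    kx = sfft.fftfreq(box)
    kz = sfft.rfftfreq(box)
    KX, KY, KZ = np.meshgrid(kx, kx, kz, indexing="ij")
    k = np.stack([KX, KY, KZ])
    kp = np.tensordot(pose, k, axes=(1, 0))
    perp = kp[0] if tilt_axis == "y" else kp[1]
    ang = np.degrees(np.arctan2(np.abs(kp[2]), np.abs(perp)))
    return ang <= tilt_max


def align_particles(
    particles: ParticleTable,
    tomogram: DensityMap,
    reference: DensityMap | None,
    schedule: AlignmentSchedule,
    mask: np.ndarray | None = None,
    box_size: int | None = None,
    update_reference: bool = True,
    wedge: "object | None" = None,
    anchor_vesicles: "list | None" = None,
    reference_top_frac: float = 1.0,
    chunk: int = 96,
) -> tuple[ParticleTable, list[dict]]:
    """Iterative constrained alignment of particles against a reference.

    Per iteration, every particle's subvolume (rotated into the template
    frame by its inverse pose) is scored against the reference rotated by
    each candidate delta on the angular grid, with the best translation
    found by windowed FFT cross-correlation; the best (delta, shift) is
    composed onto the pose and the reference is re-averaged from the
    updated table. With a ``wedge`` (:class:`~memtomo.core_io.TiltGeometry`)
    the correlation is wedge-compensated: each particle's comparison is
    restricted to the Fourier region its tilt range actually sampled,
    which removes the orientation bias toward the common wedge direction.
    With ``anchor_vesicles`` the collective drift of the consensus frame
    away from the membrane-normal frame is removed after every iteration
    (the membrane is the external frame reference for tilt statistics).
    Returns the updated table and a per-iteration run log with the mean
    correlation.
    """
    if len(particles) == 0:
        raise ValueError("empty particle set")
    if reference is None:
        if box_size is None:
            raise ValueError("either a reference or a box_size is required")
        reference = average_particles(particles, tomogram, box_size)
    box = reference.shape[0]
    vs = tomogram.voxel_size
    if mask is not None and mask.shape != reference.shape:
        raise ValueError("mask dimensions must match the reference")

    table = particles
    log: list[dict] = []
    for it in range(len(schedule)):
        ref_grid = reference.grid
        frac = schedule.lowpass_frac[it]
        if frac is not None:
            ref_grid = lowpass_gaussian(ref_grid, vs, frac * 0.5 / vs)
        use_mask = mask if schedule.masked else None

        deltas = rotation_grid(schedule.ang_half[it], schedule.ang_step[it])
        refs_f = []
        for R_d in deltas:
            rd = rotate_map(ref_grid, np.linalg.inv(R_d),
                            cval=float(ref_grid.mean()))
            refs_f.append(sfft.rfftn(_normalized_for_fft(rd, use_mask)))
        refs_f = np.array(refs_f)
        if wedge is not None:
            # per-candidate power spectra for wedge-restricted normalization
            refs_p = _half_spectrum_weights(box) * np.abs(refs_f) ** 2
            refs_p = refs_p.reshape(len(deltas), -1)

        w_vox = max(0, int(round(schedule.shift_half[it] / vs)))
        win = _shift_window(box, w_vox)
        shift_lookup = np.where(win <= box // 2, win, win - box)

        n = len(table)
        rots = table.rotation_matrices()
        positions = table.positions
        best_cc = np.full(n, -np.inf)
        best_delta = np.zeros(n, dtype=int)
        best_shift = np.zeros((n, 3))

        hsw = _half_spectrum_weights(box) if wedge is not None else None
        for c0 in range(0, n, chunk):
            c1 = min(c0 + chunk, n)
            subs_f = []
            wmasks = []
            for i in range(c0, c1):
                sub = extract_subvolume(tomogram, positions[i], box, pad=True)
                sub_t = rotate_map(sub.grid, rots[i])
                sf = sfft.rfftn(_normalized_for_fft(sub_t, use_mask))
                if wedge is not None:
                    wm = rotated_wedge_mask(box, rots[i], wedge.tilt_max,
                                            wedge.tilt_axis)
                    sf *= wm
                    # unit real-space norm via Parseval on the half-spectrum
                    nrm = np.sqrt((hsw * np.abs(sf) ** 2).sum()) / box ** 1.5
                    if nrm > 0:
                        sf /= nrm
                    wmasks.append((hsw * wm).ravel())
                subs_f.append(sf)
            subs_f = np.array(subs_f)
            if wedge is not None:
                # ||W_i b_j||: in-wedge norm of every reference candidate,
                # one row per particle in the chunk
                denom = np.sqrt(np.array(wmasks) @ refs_p.T) / box ** 1.5
                denom = np.maximum(denom, 1e-12)
            for j in range(len(deltas)):
                cc = sfft.irfftn(
                    subs_f * np.conj(refs_f[j])[None], s=(box,) * 3, axes=(1, 2, 3)
                )
                ccw = cc[:, win[:, None, None], win[None, :, None],
                         win[None, None, :]]
                flat = ccw.reshape(len(ccw), -1)
                kbest = flat.argmax(axis=1)
                vals = flat[np.arange(len(flat)), kbest]
                if wedge is not None:
                    vals = vals / denom[:, j]
                upd = vals > best_cc[c0:c1]
                if upd.any():
                    kx, ky, kz = np.unravel_index(kbest[upd], ccw.shape[1:])
                    rows = np.arange(c0, c1)[upd]
                    best_cc[rows] = vals[upd]
                    best_delta[rows] = j
                    best_shift[rows] = np.stack(
                        [shift_lookup[kx], shift_lookup[ky], shift_lookup[kz]],
                        axis=1,
                    ) * vs

        # compose updates: new pose R_p' = R_p @ R_delta; the correlation
        # peak at lag s means the content sits at +s in the template frame,
        # so the particle centre moves by +R_p @ s (current-pose frame).
        new_eulers = np.zeros((n, 3))
        new_pos = positions.copy()
        for i in range(n):
            R_new = rots[i] @ deltas[best_delta[i]]
            new_eulers[i] = matrix_to_euler(R_new)
            new_pos[i] = positions[i] + rots[i] @ best_shift[i]
        table = table.with_updates(positions=new_pos, eulers=new_eulers,
                                   cc=np.clip(best_cc, -1.0, 1.0))
        if anchor_vesicles is not None:
            table = undrift(table, anchor_vesicles)
        if update_reference:
            ref_table = table
            if reference_top_frac < 1.0 and len(table) > 4:
                cc = table.df["cc"].to_numpy(float)
                k = max(4, int(round(reference_top_frac * len(table))))
                keep = np.argsort(-cc, kind="stable")[:k]
                ref_table = ParticleTable(
                    table.df.iloc[sorted(keep)].reset_index(drop=True))
            reference = average_particles(ref_table, tomogram, box)
        log.append({
            "iteration": it,
            "mean_cc": float(np.mean(np.clip(best_cc, -1, 1))),
            "n_candidates": int(len(deltas)),
            "masked": bool(schedule.masked),
        })
    return table, log


# --------------------------------------------------------------------------- #
# averaging, selection, splitting
# --------------------------------------------------------------------------- #


def average_particles(particles: ParticleTable, tomogram: DensityMap,
                      box_size: int) -> DensityMap:
    """Voxel-wise mean of subvolumes rotated into the template frame."""
    if len(particles) == 0:
        raise ValueError("cannot average an empty particle set")
    acc = np.zeros((box_size,) * 3, dtype=np.float64)
    rots = particles.rotation_matrices()
    for i, pos in enumerate(particles.positions):
        sub = extract_subvolume(tomogram, pos, box_size, pad=True)
        acc += rotate_map(sub.grid, rots[i])
    acc /= len(particles)
    return DensityMap(acc.astype(np.float32), tomogram.voxel_size,
                      box_origin(box_size, tomogram.voxel_size))


def select_above_mean(particles: ParticleTable) -> ParticleTable:
    """Retain particles with cc strictly above the arithmetic mean cc."""
    cc = particles.df["cc"].to_numpy(float)
    if np.isnan(cc).any():
        raise ValueError("all particles must carry a cc score")
    return ParticleTable(particles.df[cc > cc.mean()].reset_index(drop=True))


def split_even_odd(particles: ParticleTable) -> tuple[ParticleTable, ParticleTable]:
    """Partition by parity of the 0-based record index (even first)."""
    df = particles.df.reset_index(drop=True)
    even = df.iloc[0::2].reset_index(drop=True)
    odd = df.iloc[1::2].reset_index(drop=True)
    return ParticleTable(even), ParticleTable(odd)


def remove_duplicates(particles: ParticleTable, min_dist: float) -> ParticleTable:
    """Greedy duplicate removal: keep the higher-cc particle of any pair
    closer than ``min_dist`` Å (unscored particles rank last)."""
    if len(particles) == 0:
        return particles
    cc = particles.df["cc"].to_numpy(float)
    cc = np.where(np.isnan(cc), -np.inf, cc)
    order = np.argsort(-cc, kind="stable")
    pos = particles.positions
    kept: list[int] = []
    for i in order:
        if not kept or np.min(
            np.linalg.norm(pos[kept] - pos[i], axis=1)
        ) >= min_dist:
            kept.append(i)
    kept = sorted(kept)
    return ParticleTable(particles.df.iloc[kept].reset_index(drop=True))


# --------------------------------------------------------------------------- #
# FSC and filtering
# --------------------------------------------------------------------------- #


def compute_fsc(map_a: DensityMap, map_b: DensityMap) -> FSCCurve:
    """Fourier shell correlation over shells one Fourier voxel wide."""
    if map_a.shape != map_b.shape:
        raise ValueError("maps must share dimensions")
    if not np.isclose(map_a.voxel_size, map_b.voxel_size):
        raise ValueError("maps must share voxel size")
    n = map_a.shape[0]
    fa = sfft.fftn(map_a.grid.astype(np.float64))
    fb = sfft.fftn(map_b.grid.astype(np.float64))
    ix = [sfft.fftfreq(s) * s for s in map_a.shape]
    r = np.sqrt(
        ix[0][:, None, None] ** 2 + ix[1][None, :, None] ** 2
        + ix[2][None, None, :] ** 2
    )
    shell = np.rint(r).astype(int).ravel()
    nmax = n // 2
    valid = shell <= nmax
    shell = shell[valid]
    cross = (fa * np.conj(fb)).ravel()[valid]
    pa = (np.abs(fa) ** 2).ravel()[valid]
    pb = (np.abs(fb) ** 2).ravel()[valid]
    num = np.bincount(shell, weights=cross.real, minlength=nmax + 1)
    da = np.bincount(shell, weights=pa, minlength=nmax + 1)
    db = np.bincount(shell, weights=pb, minlength=nmax + 1)
    den = np.sqrt(da * db)
    vals = np.divide(num, den, out=np.zeros_like(num), where=den > 0)
    freqs = np.arange(nmax + 1) / (n * map_a.voxel_size)
    return FSCCurve(freqs, vals)


@dataclass
class Resolution:
    resolution: float  # Å
    crossed: bool      # False when the curve never drops below threshold


def resolution_at(curve: FSCCurve, threshold: float) -> Resolution:
    """Resolution (Å) at the first downward threshold crossing.

    Linear interpolation between shells; when the curve never crosses, the
    Nyquist resolution is returned with ``crossed=False``.
    """
    if not 0 < threshold < 1:
        raise ValueError("threshold must lie in (0, 1)")
    f, v = curve.frequencies, curve.values
    if len(f) == 0:
        raise ValueError("empty FSC curve")
    for i in range(len(v) - 1):
        if v[i] >= threshold > v[i + 1]:
            t = (v[i] - threshold) / (v[i] - v[i + 1])
            fc = f[i] + t * (f[i + 1] - f[i])
            return Resolution(resolution=float(1.0 / fc), crossed=True)
    if v[0] < threshold:
        fc = f[1] if len(f) > 1 and f[0] == 0 else f[0]
        return Resolution(resolution=float(1.0 / fc) if fc > 0 else np.inf,
                          crossed=True)
    fny = f[-1]
    return Resolution(resolution=float(1.0 / fny) if fny > 0 else np.inf,
                      crossed=False)


def lowpass_by_fsc(density: DensityMap, curve: FSCCurve,
                   unity_level: float = 0.99) -> DensityMap:
    """Low-pass with a Gaussian whose width matches the FSC decay.

    Fits ``G(f) = exp(-f^2 / (2 sigma_f^2))`` to the FSC values by least
    squares and multiplies the Fourier amplitudes by G. A curve that never
    decays below ``unity_level`` leaves the map unchanged (the sigma -> inf
    cap); a non-decaying fit raises.
    """
    f, v = curve.frequencies, np.clip(curve.values, 0.0, 1.0)
    if np.all(v >= unity_level):
        return density.copy()

    def model(freq: np.ndarray, sigma: float) -> np.ndarray:
        return np.exp(-(freq**2) / (2.0 * sigma**2))

    f_half = _half_level_freq(f, v)
    try:
        popt, _ = optimize.curve_fit(
            model, f, v, p0=[max(f_half / 1.177, 1e-6)], maxfev=10_000
        )
    except RuntimeError as exc:
        raise ValueError(f"FSC curve does not decay as a Gaussian: {exc}") from exc
    sigma_f = float(abs(popt[0]))
    if sigma_f <= 0 or model(f[-1], sigma_f) > unity_level:
        raise ValueError(
            "FSC curve is non-decaying; fitted Gaussian width is unbounded"
        )
    spec = sfft.rfftn(density.grid.astype(np.float32))
    f2 = _freq2_grid(density.shape, density.voxel_size)
    spec *= np.exp(-f2 / (2.0 * sigma_f**2))
    out = sfft.irfftn(spec, s=density.shape).astype(np.float32)
    return DensityMap(out, density.voxel_size, density.origin.copy())


def _half_level_freq(f: np.ndarray, v: np.ndarray) -> float:
    for i in range(len(v) - 1):
        if v[i] >= 0.5 > v[i + 1]:
            t = (v[i] - 0.5) / (v[i] - v[i + 1])
            return float(f[i] + t * (f[i + 1] - f[i]))
    return float(f[-1])


def align_maps(map_a: DensityMap, map_b: DensityMap,
               ang_half: float = 6.0, ang_step: float = 2.0,
               shift_half: float = 15.0) -> tuple[DensityMap, float]:
    """Rigidly align ``map_b`` onto ``map_a`` by a small grid search.

    Used to register the two independent half-set reconstructions before
    their FSC. Returns the transformed map and the best correlation.
    """
    if map_a.shape != map_b.shape:
        raise ValueError("maps must share dimensions")
    box = map_a.shape[0]
    vs = map_a.voxel_size
    a_f = np.conj(sfft.rfftn(_normalized_for_fft(map_a.grid, None)))
    w_vox = max(0, int(round(shift_half / vs)))
    win = _shift_window(box, w_vox)
    lut = np.where(win <= box // 2, win, win - box)
    best = (-np.inf, np.eye(3), np.zeros(3))
    for R in rotation_grid(ang_half, ang_step):
        rb = rotate_map(map_b.grid, np.linalg.inv(R))
        cc = sfft.irfftn(sfft.rfftn(_normalized_for_fft(rb, None)) * a_f,
                         s=(box,) * 3)
        ccw = cc[np.ix_(win, win, win)]
        k = np.unravel_index(np.argmax(ccw), ccw.shape)
        val = float(ccw[k])
        if val > best[0]:
            best = (val, R, np.array([lut[k[0]], lut[k[1]], lut[k[2]]], float))
    _, R, shift_vox = best
    out = rotate_map(map_b.grid, np.linalg.inv(R))
    out = ndimage.shift(out, -shift_vox, order=1, mode="constant",
                        cval=float(out.mean()))
    cc_final = masked_correlation(map_a.grid, out)
    return DensityMap(out.astype(np.float32), vs, map_a.origin.copy()), cc_final


# --------------------------------------------------------------------------- #
# PCA classification
# --------------------------------------------------------------------------- #


class DegenerateVarianceError(ValueError):
    """All aligned subvolumes are identical; classification is undefined."""


def pca_classify(subvolumes: np.ndarray, mask: np.ndarray | None,
                 n_components: int = 5, k_classes: int = 2,
                 seed: int = 0) -> tuple[np.ndarray, dict[int, int]]:
    """PCA on masked voxel vectors followed by k-means on component scores.

    ``subvolumes`` is (n, bx, by, bz), all aligned to the common frame.
    Returns (labels, per-class counts).
    """
    from sklearn.cluster import KMeans
    from sklearn.decomposition import PCA

    vols = np.asarray(subvolumes, dtype=float)
    n = len(vols)
    if k_classes > n:
        raise ValueError("more classes than subvolumes")
    if mask is not None:
        sel = np.asarray(mask) > 0.5
        X = vols[:, sel]
    else:
        X = vols.reshape(n, -1)
    if X.std(axis=0).max() <= 1e-12:
        raise DegenerateVarianceError("subvolumes have zero variance")
    n_comp = min(n_components, n - 1, X.shape[1])
    scores = PCA(n_components=n_comp, random_state=seed).fit_transform(X)
    km = KMeans(n_clusters=k_classes, n_init=10, random_state=seed).fit(scores)
    labels = km.labels_
    counts = {int(k): int((labels == k).sum()) for k in range(k_classes)}
    return labels, counts
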