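"""Multi-coil global B0 shimming.

Given per-coil basis field maps (Hz/A) and a target field map, the shim
currents minimise the quadratic cost

    cost_s = Σ_voxel | B0(r) − Σᵢ cᵢ · basisᵢ(r) |²

over the brain mask, subject to per-coil limits |cᵢ| ≤ 4 A and a total
current budget Σᵢ|cᵢ| ≤ 50 A.  The absolute values are linearised by
current splitting cᵢ = cᵢ⁺ − cᵢ⁻ (cᵢ± ∈ [0, 4]), turning the problem into
a smooth convex QP solved with SLSQP; the zero-current point is always
feasible, so the residual never exceeds the unshimmed field.

A global frequency offset is *not* a shim channel: the mask-mean of the
target is removed before solving (and reported), since coil fields cannot
and need not cancel it.

The synthetic 16-channel array places coils on a cylinder around the head;
each basis is the z-field of a magnetic point dipole at the coil centre,
oriented along the (radial) coil normal — a harmonic field inside the FOV,
like a measured coil map.

Cost functions are evaluated on a 2 mm working grid: maps simulated at
finer resolution are block-mean downsampled first.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy.optimize import minimize

from .volume import Grid, VoxelVolume, center_affine

__all__ = [
    "ShimSystem", "ShimReport", "generate_coil_basis",
    "downsample_for_shim", "downsample_mask", "solve_shim_currents",
    "evaluate_shim",
]

PER_COIL_LIMIT_A = 4.0
TOTAL_LIMIT_A = 50.0


@dataclass
class ShimSystem:
    """Multi-coil shim array: basis maps (Hz/A) and current limits (A)."""

    basis: np.ndarray             # (n_coils, nx, ny, nz)
    affine: np.ndarray
    per_coil_limit: float = PER_COIL_LIMIT_A
    total_limit: float = TOTAL_LIMIT_A
    coil_positions: np.ndarray | None = None
    currents: np.ndarray | None = None

    def __post_init__(self):
        self.basis = np.asarray(self.basis, dtype=float)
        if self.basis.ndim != 4:
            raise ValueError("basis must be (n_coils, nx, ny, nz)")

    @property
    def n_coils(self) -> int:
        return self.basis.shape[0]

    @property
    def grid(self) -> Grid:
        return Grid(tuple(self.basis.shape[1:]), self.affine)

    def shim_field(self, currents: np.ndarray) -> np.ndarray:
        return np.tensordot(np.asarray(currents, dtype=float), self.basis, axes=1)

    def check_currents(self, currents: np.ndarray, atol: float = 1e-6):
        c = np.asarray(currents, dtype=float)
        if np.any(np.abs(c) > self.per_coil_limit + atol):
            raise ValueError("per-coil current limit exceeded")
        if np.sum(np.abs(c)) > self.total_limit + atol:
            raise ValueError("total current limit exceeded")


def generate_coil_basis(
    grid: Grid,
    n_coils: int = 16,
    cylinder_radius_mm: float = 160.0,
    ring_z_mm: tuple = (-25.0, 35.0),
    dipole_scale: float = 2.5e7,
    head_radius_mm: float = 90.0,
) -> ShimSystem:
    """Synthetic cylindrical shim array (deterministic given its parameters).

    ``dipole_scale`` (Hz·mm³/A) sets the basis amplitude; with the defaults
    each coil produces fields of a few Hz/A over a head-sized FOV.
    """
    import warnings

    if n_coils < 1:
        raise ValueError("need at least one coil")
    n_rings = len(ring_z_mm)
    per_ring = int(np.ceil(n_coils / n_rings))
    x, y, z = grid.world_coords()
    X, Y, Z = np.broadcast_arrays(x, y, z)

    if cylinder_radius_mm < head_radius_mm:
        warnings.warn("shim coils lie inside the head region", RuntimeWarning)

    positions, bases = [], []
    idx = 0
    for zr in ring_z_mm:
        for j in range(per_ring):
            if idx >= n_coils:
                break
            # stagger alternate rings by half a coil spacing
            phi = 2 * np.pi * (j + 0.5 * (idx // per_ring)) / per_ring
            cx = cylinder_radius_mm * np.cos(phi)
            cy = cylinder_radius_mm * np.sin(phi)
            pos = np.array([cx, cy, zr])
            normal = np.array([-np.cos(phi), -np.sin(phi), 0.0])  # inward
            dx, dy, dz = X - cx, Y - cy, Z - zr
            d = np.sqrt(dx**2 + dy**2 + dz**2)
            d = np.maximum(d, 1.0)
            # z-component of a point dipole with moment along the coil normal
            mdotu = (normal[0] * dx + normal[1] * dy + normal[2] * dz) / d
            bz = dipole_scale * (3.0 * mdotu * (dz / d) - normal[2]) / d**3
            positions.append(pos)
            bases.append(bz)
            idx += 1
    return ShimSystem(
        basis=np.stack(bases), affine=grid.affine.copy(),
        coil_positions=np.array(positions),
    )


def _block_reduce(data: np.ndarray, weights: np.ndarray, factor: int):
    shape = data.shape
    trim = [int(n // factor * factor) for n in shape]
    # average trailing partial blocks over their valid voxels by padding
    # with zero weight up to a full block
    pad = [(0, (factor - n % factor) % factor) for n in shape]
    d = np.pad(data * weights, pad)
    w = np.pad(weights, pad)
    new = [s // factor for s in d.shape]
    d = d.reshape(new[0], factor, new[1], factor, new[2], factor)
    w = w.reshape(new[0], factor, new[1], factor, new[2], factor)
    dsum = d.sum(axis=(1, 3, 5))
    wsum = w.sum(axis=(1, 3, 5))
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(wsum > 0, dsum / np.maximum(wsum, 1e-300), 0.0)
    return out, wsum


def downsample_for_shim(vol: VoxelVolume, factor: int) -> VoxelVolume:
    """Block-mean pooling by an integer factor; invalid voxels are excluded
    from block means and blocks with no valid voxel are flagged invalid."""
    if factor < 1 or int(factor) != factor:
        raise ValueError("factor must be a positive integer")
    factor = int(factor)
    if factor == 1:
        return vol.copy()
    weights = vol.valid_mask().astype(float)
    out, wsum = _block_reduce(np.asarray(vol.data, dtype=float), weights, factor)
    new_aff = vol.affine.copy()
    new_aff[:3, :3] *= factor
    # block centre sits (factor−1)/2 voxels beyond the first voxel centre
    new_aff[:3, 3] += vol.affine[:3, :3] @ np.full(3, (factor - 1) / 2.0)
    return VoxelVolume(out, new_aff, vol.units, valid=wsum > 0)


def downsample_mask(mask: np.ndarray, factor: int, frac: float = 0.5) -> np.ndarray:
    """Mask counterpart of :func:`downsample_for_shim`: a coarse voxel is in
    the mask when at least ``frac`` of its block is."""
    if factor == 1:
        return mask.astype(bool)
    out, _ = _block_reduce(mask.astype(float), np.ones(mask.shape), int(factor))
    return out >= frac


@dataclass
class ShimReport:
    """Outcome of a shim solve or cross-evaluation."""

    currents: np.ndarray
    cost: float
    offset_hz: float
    sigma_before_hz: float | None = None
    sigma_after_hz: float | None = None

    @property
    def sigma_reduction_pct(self) -> float:
        return 100.0 * (1.0 - self.sigma_after_hz / self.sigma_before_hz)


def solve_shim_currents(
    target_fm: VoxelVolume, brain_mask: np.ndarray, system: ShimSystem
) -> ShimReport:
    """Constrained least-squares shim-current solve (see module docstring)."""
    if tuple(target_fm.data.shape) != system.grid.shape:
        raise ValueError("target map must live on the shim grid")
    ok = brain_mask & target_fm.valid_mask()
    if not np.any(ok):
        raise ValueError("no valid voxels inside the shim mask")
    A = system.basis[:, ok].T                       # (n_vox, n_coils)
    offset = float(np.mean(target_fm.data[ok]))
    b = target_fm.data[ok].astype(float) - offset
    # the global frequency offset is a free nuisance term, not a coil
    # channel: project constants out of the coil responses as well, so the
    # solve is the joint minimisation over (currents, offset)
    A = A - A.mean(axis=0, keepdims=True)

    n = system.n_coils
    G = A.T @ A
    h = A.T @ b
    bb = float(b @ b)
    scale = bb if bb > 0 else 1.0      # objective normalised to O(1)
    S = np.hstack([np.eye(n), -np.eye(n)])          # c = S u

    def fun(u):
        c = S @ u
        return float(c @ G @ c - 2.0 * h @ c + bb) / scale

    def jac(u):
        c = S @ u
        return 2.0 * S.T @ (G @ c - h) / scale

    cons = [{
        "type": "ineq",
        "fun": lambda u: system.total_limit - np.sum(u),
        "jac": lambda u: -np.ones_like(u),
    }]
    bounds = [(0.0, system.per_coil_limit)] * (2 * n)

    # warm start: unconstrained least squares projected into the feasible box
    c0, *_ = np.linalg.lstsq(A, b, rcond=None)
    c0 = np.clip(c0, -system.per_coil_limit, system.per_coil_limit)
    total0 = np.sum(np.abs(c0))
    if total0 > system.total_limit:
        c0 *= system.total_limit / total0
    u0 = np.concatenate([np.clip(c0, 0, None), np.clip(-c0, 0, None)])

    best = None
    for start in (u0, np.zeros(2 * n)):
        res = minimize(
            fun, start, jac=jac, bounds=bounds, constraints=cons,
            method="SLSQP", options=dict(maxiter=1000, ftol=1e-14),
        )
        if np.sum(res.x) <= system.total_limit + 1e-6 and (
            best is None or res.fun < best.fun
        ):
            best = res
    if best is None:
        raise RuntimeError("shim QP failed: no feasible solver result")
    currents = S @ best.x
    # the warm start itself is feasible; never return anything worse
    if fun(u0) < best.fun:
        currents = c0
    # tiny constraint violations from the solver tolerance are clipped
    currents = np.clip(currents, -system.per_coil_limit, system.per_coil_limit)
    system.currents = currents
    resid = b - A @ currents
    return ShimReport(
        currents=currents, cost=float(resid @ resid), offset_hz=offset,
        sigma_before_hz=float(np.std(b)), sigma_after_hz=float(np.std(resid)),
    )


def evaluate_shim(
    measured_fm: VoxelVolume,
    currents: np.ndarray,
    system: ShimSystem,
    brain_mask: np.ndarray,
) -> ShimReport:
    """Apply ``currents`` (e.g. solved on a *predicted* map) to the
    *measured* map and report Vol.σB0 before/after."""
    system.check_currents(currents)
    ok = brain_mask & measured_fm.valid_mask()
    if not np.any(ok):
        raise ValueError("no valid voxels inside the mask")
    shim = system.shim_field(currents)
    resid = measured_fm.data[ok] - shim[ok]
    before = float(np.std(measured_fm.data[ok]))
    after = float(np.std(resid))
    return ShimReport(
        currents=np.asarray(currents, dtype=float),
        cost=float(np.sum((resid - np.mean(resid)) ** 2)),
        offset_hz=float(np.mean(measured_fm.data[ok])),
        sigma_before_hz=before, sigma_after_hz=after,
    )
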