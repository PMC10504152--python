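"""Decomposition of a measured reference field map into its sources.

The total off-resonance field is modelled as a superposition

    ΔB0 = B_SH + Bχ + B_k + Bχ′ + B0_shift ,

where B_SH is the static scanner shim field, Bχ the head-susceptibility
field, B_k a linear phase-error field along the first phase-encoding axis,
Bχ′ the far field of susceptibility sources below the FOV (modelled as one
axial point dipole) and B0_shift a constant frequency offset.  This module
recovers each term from measured dual-echo complex data:

* :func:`field_map_from_echoes` — standard phase-difference field mapping,
  f = ∠(S₁* S₂) / (2π ΔTE), with a magnitude validity threshold.
* :func:`estimate_ky_shift` — the gradient-imperfection term shows up as a
  shift Δk_n = −a·t_n of the k-space centre along k_y, proportional to the
  echo time.  After demodulating the known fields the shift is read off as
  the first moment of the k-space energy along k_y, computed through the
  shift theorem as the phase of the lag-1 spatial autocorrelation along y
  (exact for a pure linear phase ramp, independent of object structure).
  The slope ``a`` is fitted through the origin and re-expressed as the
  equivalent linear field B_k (Hz), zero at the FOV centre.
* :func:`fit_lower_body_dipole` — Eq.-style simplex fit of (P, r_d) and the
  constant offset B0_shift to B_diff = measured − B_SH − Bχ − B_k over the
  brain mask (RMSE cost), seeded by a coarse position grid search in which
  (P, B0_shift) are solved in closed form.
* :func:`compute_smr` — the simple-model residual, i.e. what the 3-class
  susceptibility model cannot explain.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize

from .forward import DipoleSource, point_dipole_field
from .volume import Grid, VoxelVolume

__all__ = [
    "EchoPair",
    "PhaseErrorModel",
    "DecompositionResult",
    "field_map_from_echoes",
    "compute_field_map",
    "estimate_ky_shift",
    "fit_lower_body_dipole",
    "compute_smr",
    "decompose_reference",
]


@dataclass
class EchoPair:
    """Dual-echo complex GRE volumes with their echo times (s)."""

    echo1: np.ndarray
    echo2: np.ndarray
    te1: float
    te2: float
    affine: np.ndarray

    def __post_init__(self):
        self.echo1 = np.asarray(self.echo1)
        self.echo2 = np.asarray(self.echo2)
        if self.echo1.shape != self.echo2.shape:
            raise ValueError("echoes must share one grid")
        if not self.te2 > self.te1:
            raise ValueError("TE2 must exceed TE1")
        self.affine = np.asarray(self.affine, dtype=float)

    @property
    def delta_te(self) -> float:
        return self.te2 - self.te1

    @property
    def grid(self) -> Grid:
        return Grid(tuple(self.echo1.shape), self.affine)


@dataclass
class PhaseErrorModel:
    """Linear k-space shift model Δk_n = −a·t_n and its field equivalent.

    ``slope`` is in k-space indices per second; ``bk`` is the corresponding
    linear field (Hz) along the first-PE (y) axis, zero at the FOV centre.
    """

    slope: float
    shifts: tuple          # measured Δk per echo (k-space indices)
    bk: VoxelVolume


def _bk_from_slope(slope: float, grid: Grid) -> VoxelVolume:
    ny = grid.shape[1]
    y_idx = np.arange(ny, dtype=float) - (ny - 1) / 2.0
    data = np.broadcast_to((-slope / ny) * y_idx[None, :, None], grid.shape).copy()
    return VoxelVolume(data, grid.affine.copy(), units="Hz")


def field_map_from_echoes(echoes: EchoPair, mag_threshold: float = 0.05) -> VoxelVolume:
    """Phase-difference field map in Hz.

    Voxels whose magnitude (geometric mean over the two echoes) falls below
    ``mag_threshold`` times the robust (99th-percentile) maximum are flagged
    invalid.  Fields beyond ±1/(2·ΔTE) alias to the principal value.
    """
    if echoes.delta_te <= 0:
        raise ValueError("TE2 must exceed TE1")
    prod = np.conj(echoes.echo1) * echoes.echo2
    fm = np.angle(prod) / (2.0 * np.pi * echoes.delta_te)
    mag = np.sqrt(np.abs(prod))
    robust_max = np.percentile(mag, 99)
    if robust_max <= 0:
        raise ValueError("signal-free echoes: cannot compute a field map")
    valid = mag >= mag_threshold * robust_max
    return VoxelVolume(fm, echoes.affine.copy(), units="Hz", valid=valid)


# spec-facing alias
compute_field_map = field_map_from_echoes


def _centroid_shift(sig: np.ndarray) -> float:
    """k_y centre-of-energy shift (in k-space indices) of a complex volume.

    By the Fourier shift theorem a centre shift Δk along k_y multiplies the
    image by exp(i·2π·Δk·y/N); the phase of the lag-1 autocorrelation along
    y therefore equals 2πΔk/N, weighted by the k-space energy.
    """
    corr = np.sum(np.conj(sig[:, :-1, :]) * sig[:, 1:, :])
    if np.abs(corr) == 0:
        raise ValueError("signal-free input: cannot estimate a k-space shift")
    return sig.shape[1] * np.angle(corr) / (2.0 * np.pi)


def estimate_ky_shift(echoes: EchoPair, demod_field: VoxelVolume) -> PhaseErrorModel:
    """Estimate the phase-error slope ``a`` (Δk_n = −a·t_n) and its field.

    ``demod_field`` holds the known fields (shim + head susceptibility, Hz)
    whose phase is removed before measuring the residual k-space shift.
    """
    shifts = []
    for sig, te in ((echoes.echo1, echoes.te1), (echoes.echo2, echoes.te2)):
        demod = sig * np.exp(-2j * np.pi * demod_field.data * te)
        shifts.append(_centroid_shift(demod))
    times = np.array([echoes.te1, echoes.te2])
    dk = np.array(shifts)
    # least squares through the origin: Δk = −a t
    slope = -float(np.sum(times * dk) / np.sum(times**2))
    return PhaseErrorModel(slope=slope, shifts=tuple(shifts),
                           bk=_bk_from_slope(slope, echoes.grid))


# --------------------------------------------------------------------------
# lower-body dipole + B0 shift
# --------------------------------------------------------------------------

def _dipole_profile(coords, position):
    dx = coords[0] - position[0]
    dy = coords[1] - position[1]
    dz = coords[2] - position[2]
    d2 = dx**2 + dy**2 + dz**2
    d = np.sqrt(d2)
    return (3.0 * (dz / d) ** 2 - 1.0) / (d * d2)


def fit_lower_body_dipole(
    b_diff: VoxelVolume,
    brain_mask: np.ndarray,
    init: DipoleSource | None = None,
    grid_search: bool = True,
    maxiter: int = 4000,
):
    """Fit (P, r_d, B0_shift) of an axial point dipole to B_diff over the brain.

    Cost is the RMSE between B_diff and P·g(r; r_d) + B0_shift on the brain
    mask.  A coarse 5×5×5 grid of candidate positions (closed-form P and
    offset at each) seeds a Nelder–Mead simplex refinement over all five
    parameters.  Returns ``(DipoleSource, b0_shift, info)`` where ``info``
    carries the final cost and a convergence flag.
    """
    grid = b_diff.grid
    if not np.all(np.isfinite(b_diff.data[brain_mask])):
        raise ValueError("B_diff contains non-finite values inside the mask")
    x, y, z = grid.world_coords()
    X, Y, Z = np.broadcast_arrays(x, y, z)
    coords = (X[brain_mask], Y[brain_mask], Z[brain_mask])
    b = b_diff.data[brain_mask].astype(float)
    n = b.size
    if n == 0:
        raise ValueError("empty brain mask")

    def closed_form(position):
        g = _dipole_profile(coords, position)
        A = np.column_stack([g, np.ones(n)])
        sol, *_ = np.linalg.lstsq(A, b, rcond=None)
        resid = b - A @ sol
        return sol[0], sol[1], float(np.sqrt(np.mean(resid**2)))

    fov = np.asarray(grid.shape) * grid.voxel_size
    if init is None:
        init = DipoleSource(0.0, (0.0, 0.0, -(fov[2] / 2.0 + 100.0)))

    best_pos = np.asarray(init.position, dtype=float)
    best_P, best_s, best_cost = closed_form(best_pos)
    if grid_search:
        span = 120.0  # mm half-extent of the candidate cube
        offs = np.linspace(-span, span, 5)
        for ox in offs:
            for oy in offs:
                for oz in offs:
                    pos = np.asarray(init.position) + np.array([ox, oy, oz])
                    P, s, c = closed_form(pos)
                    if c < best_cost:
                        best_pos, best_P, best_s, best_cost = pos, P, s, c

    p_scale = max(abs(best_P), 1e3)

    def cost(params):
        P = params[0] * p_scale
        pos = params[1:4]
        s = params[4]
        g = _dipole_profile(coords, pos)
        return float(np.sqrt(np.mean((b - P * g - s) ** 2)))

    x0 = np.array([best_P / p_scale, *best_pos, best_s])
    res = minimize(
        cost, x0, method="Nelder-Mead",
        options=dict(xatol=1e-10, fatol=1e-12, maxiter=maxiter, adaptive=True),
    )
    if not res.success:
        warnings.warn("dipole fit did not converge; returning best-so-far",
                      RuntimeWarning)
    P = res.x[0] * p_scale
    position = tuple(res.x[1:4])
    b0_shift = float(res.x[4])
    info = {"cost": float(res.fun), "converged": bool(res.success),
            "n_iter": int(res.nit)}
    return DipoleSource(P, position), b0_shift, info


@dataclass
class DecompositionResult:
    """All recovered terms of the reference-position field decomposition."""

    measured: VoxelVolume
    b_sh: VoxelVolume
    b_chi: VoxelVolume
    b_k: VoxelVolume
    b_chi_prime: VoxelVolume
    b0_shift: float
    brain_mask: np.ndarray
    phase_error: PhaseErrorModel | None = None
    dipole: DipoleSource | None = None
    fit_info: dict | None = None

    def simulated(self) -> VoxelVolume:
        """B_SH + Bχ + B_k + Bχ′ + B0_shift (Hz)."""
        return self.b_sh + self.b_chi + self.b_k + self.b_chi_prime + self.b0_shift

    def b_diff(self) -> VoxelVolume:
        return self.measured - self.b_sh - self.b_chi - self.b_k

    def smr(self) -> VoxelVolume:
        return compute_smr(self)


def compute_smr(result: DecompositionResult) -> VoxelVolume:
    """Simple-model residual: measured − all modelled terms, brain-masked."""
    resid = result.measured - result.simulated()
    data = np.where(result.brain_mask, resid.data, 0.0)
    valid = result.brain_mask & resid.valid_mask()
    return VoxelVolume(data, resid.affine, units="Hz", valid=valid)


def decompose_reference(
    echoes: EchoPair,
    b_sh: VoxelVolume,
    b_chi: VoxelVolume,
    brain_mask: np.ndarray,
    dipole_init: DipoleSource | None = None,
) -> DecompositionResult:
    """Run the full reference-position decomposition.

    ``b_chi`` is the forward-simulated field of the (3-class) susceptibility
    model; the remaining terms (B_k slope, dipole, B0 shift) are estimated
    from the data.
    """
    measured = field_map_from_echoes(echoes)
    pe = estimate_ky_shift(echoes, b_sh + b_chi)
    b_diff = measured - b_sh - b_chi - pe.bk
    dipole, b0_shift, info = fit_lower_body_dipole(b_diff, brain_mask,
                                                   init=dipole_init)
    b_chi_prime = point_dipole_field(dipole, measured.grid)
    return DecompositionResult(
        measured=measured, b_sh=b_sh, b_chi=b_chi, b_k=pe.bk,
        b_chi_prime=b_chi_prime, b0_shift=b0_shift, brain_mask=brain_mask,
        phase_error=pe, dipole=dipole, fit_info=info,
    )
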