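"""Forward synthesis of B0 field components.

Three field sources are synthesised here:

* ``susceptibility_to_field`` — the Fourier (k-space) dipole approximation of
  the field induced by an arbitrary susceptibility distribution χ(r).  In
  k-space the unit dipole response along B0 (z) with the Lorentz-sphere
  correction is

      D(k) = 1/3 − k_z² / (k_x² + k_y² + k_z²),

  so that  Bχ(r) = f0·10⁻⁶ · F⁻¹{ D(k) · F{χ}(k) }  with χ in ppm and the
  output in Hz.  D is singular at k = 0; the DC term is set to zero, which
  makes the synthesised field mean-free over the padded computational volume
  (any physical constant offset is absorbed by the B0-shift term fitted
  downstream).  The χ map is zero-padded (default factor 3 per axis) before
  the FFT so the periodic images of the dipole response do not fold back
  into the field of view.

* ``sh_shim_field`` — the static scanner shim field as a real solid-harmonic
  expansion up to 2nd order.

* ``point_dipole_field`` — the far field of an axially (z-) oriented magnetic
  point dipole, used to model susceptibility sources below the imaging
  volume (lungs/torso):

      B(r) = P/|r−r_d|³ · (3·((r−r_d)·ẑ / |r−r_d|)² − 1)

  with P in Hz·mm³ and positions in mm, so the result is in Hz.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .volume import Grid, VoxelVolume

__all__ = [
    "DEFAULT_F0",
    "SH_BASIS_NAMES",
    "SHCoefficients",
    "DipoleSource",
    "dipole_kernel",
    "susceptibility_to_field",
    "sh_shim_field",
    "point_dipole_field",
]

#: default Larmor frequency (Hz), 3 T
DEFAULT_F0 = 123.2e6

#: order of the real solid-harmonic shim basis (scanner mm coordinates)
SH_BASIS_NAMES = ("1", "x", "y", "z", "2z2-x2-y2", "zx", "zy", "x2-y2", "xy")


@dataclass(frozen=True)
class SHCoefficients:
    """Spherical-harmonic shim coefficients up to 2nd order.

    Units: order 0 in Hz, order 1 in Hz/mm, order 2 in Hz/mm², matching the
    unnormalised basis ``SH_BASIS_NAMES`` evaluated at world mm coordinates.
    """

    values: tuple

    def __post_init__(self):
        vals = tuple(float(v) for v in self.values)
        if len(vals) != 9:
            raise ValueError("expected 9 SH coefficients (orders 0..2)")
        if not np.all(np.isfinite(vals)):
            raise ValueError("SH coefficients must be finite")
        object.__setattr__(self, "values", vals)

    @classmethod
    def zeros(cls) -> "SHCoefficients":
        return cls((0.0,) * 9)


@dataclass(frozen=True)
class DipoleSource:
    """Axial point dipole: strength P (Hz·mm³) at world position r_d (mm)."""

    P: float
    position: tuple

    def __post_init__(self):
        pos = tuple(float(v) for v in self.position)
        if len(pos) != 3 or not np.all(np.isfinite(pos)) or not np.isfinite(self.P):
            raise ValueError("dipole strength/position must be three finite numbers")
        object.__setattr__(self, "position", pos)


def dipole_kernel(shape, voxel_size) -> np.ndarray:
    """Unit dipole response D(k) = 1/3 − k_z²/k² on the FFT frequency lattice.

    ``voxel_size`` (mm per axis) sets the frequency spacing per axis; the
    kernel itself is dimensionless.  D(0) is set to 0 (mean-free field).
    """
    vs = np.broadcast_to(np.asarray(voxel_size, float), (3,))
    kx, ky, kz = (
        np.fft.fftfreq(n, d=d).astype(float) for n, d in zip(shape, vs)
    )
    kx = kx[:, None, None]
    ky = ky[None, :, None]
    kz = kz[None, None, :]
    k2 = kx**2 + ky**2 + kz**2
    with np.errstate(divide="ignore", invalid="ignore"):
        kern = 1.0 / 3.0 - kz**2 / k2
    kern[0, 0, 0] = 0.0
    return kern


def _pad_centered(arr: np.ndarray, pad_factor: int) -> tuple[np.ndarray, tuple]:
    if pad_factor == 1:
        return arr, tuple(slice(0, n) for n in arr.shape)
    pads, crops = [], []
    for n in arr.shape:
        total = n * (pad_factor - 1)
        before = total // 2
        pads.append((before, total - before))
        crops.append(slice(before, before + n))
    return np.pad(arr, pads), tuple(crops)


def susceptibility_to_field(
    chi: VoxelVolume, pad_factor: int = 3, f0: float = DEFAULT_F0
) -> VoxelVolume:
    """Field (Hz) induced by a susceptibility map (ppm) via the k-space
    dipole approximation.  See module docstring for conventions."""
    if chi.units != "ppm":
        raise ValueError("susceptibility map must carry units 'ppm'")
    if not np.all(np.isfinite(chi.data)):
        raise ValueError("susceptibility map contains non-finite values")
    if pad_factor < 1 or int(pad_factor) != pad_factor:
        raise ValueError("pad_factor must be an integer >= 1")

    padded, crops = _pad_centered(np.asarray(chi.data, dtype=float), int(pad_factor))
    # χ and the kernel are real and the kernel is even, so a real-input FFT
    # yields the exact real field (no imaginary residue to discard)
    kern = dipole_kernel(padded.shape, chi.voxel_size)
    kern_half = kern[..., : padded.shape[2] // 2 + 1]
    spec = np.fft.rfftn(padded)
    field = np.fft.irfftn(kern_half * spec, s=padded.shape, axes=(0, 1, 2))
    out = (f0 * 1e-6) * field[crops]
    return chi.like(out, units="Hz")


def sh_shim_field(coeffs: SHCoefficients, grid: Grid) -> VoxelVolume:
    """Evaluate the 2nd-order real solid-harmonic shim field on ``grid`` (Hz)."""
    x, y, z = grid.world_coords()
    c = coeffs.values
    field = (
        c[0]
        + c[1] * x
        + c[2] * y
        + c[3] * z
        + c[4] * (2 * z**2 - x**2 - y**2)
        + c[5] * z * x
        + c[6] * z * y
        + c[7] * (x**2 - y**2)
        + c[8] * x * y
    )
    field = np.broadcast_to(field, grid.shape).copy()
    return VoxelVolume(field, grid.affine.copy(), units="Hz")


def point_dipole_field(src: DipoleSource, grid: Grid) -> VoxelVolume:
    """Axial point-dipole field (Hz) on ``grid``; see module docstring.

    Distances are clipped at half the smallest voxel size so a source placed
    on (or numerically at) a grid point stays finite.
    """
    x, y, z = grid.world_coords()
    dx = x - src.position[0]
    dy = y - src.position[1]
    dz = z - src.position[2]
    dist = np.sqrt(dx**2 + dy**2 + dz**2)
    dist = np.maximum(dist, 0.5 * float(np.min(grid.voxel_size)))
    cos2 = (dz / dist) ** 2
    field = src.P / dist**3 * (3.0 * cos2 - 1.0)
    field = np.broadcast_to(field, grid.shape).copy()
    return VoxelVolume(field, grid.affine.copy(), units="Hz")
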