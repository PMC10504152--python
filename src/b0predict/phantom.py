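"""Digital head phantom and simulated MR measurements.

The phantom emulates every input the field-prediction pipeline consumes:

* a head-shaped body (ellipsoid + neck cylinder) with a skull shell, a brain
  compartment and air cavities (frontal sinus, nasal cavity, ear canals),
  each carrying a true susceptibility (ppm);
* a proton-density UTE-like magnitude image whose −log histogram is bimodal
  (soft-tissue peak at small values, air/noise peak at large values);
* dual-echo complex GRE volumes whose phase encodes the total simulated
  field plus a configurable linear phase-error ramp along the first
  phase-encoding (y) axis;
* scanner-frame field components: 2nd-order SH shim field, the phase-error
  field B_k, an out-of-FOV point-dipole perturbation, and a constant B0
  offset.

The constant offset mimics the scanner frequency adjustment: the mean total
field over the brain at the reference position is driven to
``b0_shift_extra`` (Hz), i.e. the recorded B0-shift truth is
``b0_shift_extra`` minus the brain mean of the other components.

All geometry is analytic, so :func:`apply_motion` regenerates the moved
phantom exactly (no resampling): shapes are evaluated at inverse-transformed
coordinates.  Scanner-frame components (shim, phase error, lower-body
dipole, B0 shift) stay fixed under motion.

Dynamic range: at 3 T with the default echo times, tissue voxels adjacent
to air cavities exceed the ±1/(2·ΔTE) phase-difference limit and wrap, just
as in a real acquisition.  ``consistency_mask`` marks the body voxels whose
true field is inside that limit; the brain lies entirely inside it for the
default geometry.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field as dc_field, replace

import numpy as np

from .decompose import EchoPair, field_map_from_echoes
from .forward import (
    DEFAULT_F0,
    DipoleSource,
    SHCoefficients,
    point_dipole_field,
    sh_shim_field,
    susceptibility_to_field,
)
from .transforms import RigidTransform
from .volume import Grid, VoxelVolume, center_affine

__all__ = [
    "AIR", "SOFT", "BONE", "BRAIN", "CLASS_NAMES",
    "LITERATURE_CHI", "PhantomSpec", "PhantomTruth",
    "generate_phantom", "apply_motion",
]

# tissue class labels
AIR, SOFT, BONE, BRAIN = 0, 1, 2, 3
CLASS_NAMES = {AIR: "air", SOFT: "soft", BONE: "bone", BRAIN: "brain"}

#: literature susceptibilities (ppm): air is the reference
LITERATURE_CHI = {"air": 0.0, "bone": -11.4, "soft": -9.6, "brain": -9.6}


@dataclass(frozen=True)
class PhantomSpec:
    """Full parameterisation of a phantom realisation (deterministic per seed)."""

    grid_shape: tuple = (64, 64, 64)
    voxel_size: float = 2.0            # mm, isotropic
    f0: float = DEFAULT_F0             # Hz
    pad_factor: int = 3

    # geometry (head frame, mm)
    head_center: tuple = (0.0, 0.0, 6.0)
    head_semiaxes: tuple = (40.0, 50.0, 54.0)
    skull_thickness: float = 4.0
    brain_center: tuple = (0.0, 5.0, 16.0)
    brain_semiaxes: tuple = (22.0, 26.0, 26.0)
    #: air cavities: ((cx, cy, cz), radius) in mm, head frame
    cavities: tuple = (
        ((0.0, -32.0, 36.0), 5.0),     # frontal sinus
        ((0.0, -36.0, -6.0), 5.0),     # nasal cavity
        ((31.0, 4.0, -8.0), 4.0),      # ear canal R
        ((-31.0, 4.0, -8.0), 4.0),     # ear canal L
    )
    neck_radius: float = 24.0
    neck_center_y: float = 6.0
    #: posterior neck bulge used when motion deforms the soft tissue
    bulge_center: tuple = (0.0, 30.0, -44.0)
    bulge_semiaxes: tuple = (16.0, 12.0, 14.0)

    # true susceptibility per class (ppm)
    chi: dict = dc_field(default_factory=lambda: dict(LITERATURE_CHI))

    # UTE model: −log-intensity mean/SD per class (soft small, air large)
    ute_neglog_mean: dict = dc_field(
        default_factory=lambda: {"soft": 0.30, "brain": 0.30, "bone": 1.30, "air": 3.20}
    )
    ute_neglog_sd: dict = dc_field(
        default_factory=lambda: {"soft": 0.10, "brain": 0.10, "bone": 0.18, "air": 0.35}
    )

    # dual-echo GRE model
    gre_magnitude: dict = dc_field(
        default_factory=lambda: {"soft": 1.0, "brain": 1.0, "bone": 0.35, "air": 0.02}
    )
    te1: float = 2.68e-3               # s
    te2: float = 7.49e-3               # s
    phase_slope: float = 150.0         # a, k-space indices per second (Eq. 3 slope)
    noise_sd: float = 0.0              # complex-noise SD per channel (magnitude units)

    # scanner-frame components
    sh_coeffs: tuple = (2.0, 0.06, -0.05, 0.08, -1.5e-3, 8e-4, -1.0e-3, 9e-4, -6e-4)
    dipole_P: float = 6.0e7            # Hz·mm³
    dipole_position: tuple = (5.0, -10.0, -230.0)
    b0_shift_extra: float = 5.0        # Hz, brain-mean field after frequency adjust

    seed: int = 0

    def __post_init__(self):
        shape = tuple(int(n) for n in self.grid_shape)
        if len(shape) != 3 or min(shape) < 32:
            raise ValueError("grid_shape must be three axes of at least 32 voxels")
        if not (self.te2 > self.te1 > 0):
            raise ValueError("echo times must satisfy TE2 > TE1 > 0")
        if self.voxel_size <= 0:
            raise ValueError("voxel_size must be positive")
        for table in (self.chi, self.ute_neglog_mean, self.ute_neglog_sd,
                      self.gre_magnitude):
            missing = set(CLASS_NAMES.values()) - set(table)
            if missing:
                raise ValueError(f"parameter table missing classes: {sorted(missing)}")
        object.__setattr__(self, "grid_shape", shape)

    @property
    def grid(self) -> Grid:
        return Grid(self.grid_shape, center_affine(self.grid_shape, self.voxel_size))

    @classmethod
    def small(cls, seed: int = 0, **overrides) -> "PhantomSpec":
        """Compact 48³ / 2 mm profile for fast tests and seeded sweeps."""
        kw = dict(
            grid_shape=(48, 48, 48),
            head_center=(0.0, 0.0, 3.0),
            head_semiaxes=(29.0, 35.0, 38.0),
            skull_thickness=4.0,
            brain_center=(0.0, 4.0, 12.0),
            brain_semiaxes=(16.0, 19.0, 19.0),
            cavities=(
                ((0.0, -24.0, 28.0), 4.0),
                ((0.0, -26.0, -6.0), 4.0),
                ((22.5, 3.0, -8.0), 3.0),
                ((-22.5, 3.0, -8.0), 3.0),
            ),
            neck_radius=17.0,
            neck_center_y=4.0,
            bulge_center=(0.0, 21.0, -34.0),
            bulge_semiaxes=(12.0, 9.0, 10.0),
            seed=seed,
        )
        kw.update(overrides)
        return cls(**kw)

    @classmethod
    def highres(cls, seed: int = 0, **overrides) -> "PhantomSpec":
        """128³ / 1.5 mm profile for high-resolution runs."""
        kw = dict(grid_shape=(128, 128, 128), voxel_size=1.5, seed=seed)
        kw.update(overrides)
        return cls(**kw)


@dataclass
class PhantomTruth:
    """Ground-truth state of a phantom at one head pose."""

    spec: PhantomSpec
    pose: np.ndarray                    # 4x4 world map, head frame → scanner
    deformed: bool
    labels: np.ndarray                  # int8 class volume
    chi: VoxelVolume                    # ppm
    brain_mask: np.ndarray
    body_mask: np.ndarray
    components: dict                    # name → VoxelVolume (Hz)
    field: VoxelVolume                  # total simulated field (Hz)
    ute: VoxelVolume                    # UTE-like magnitude
    echo1: np.ndarray                   # complex
    echo2: np.ndarray

    @property
    def grid(self) -> Grid:
        return self.spec.grid

    @property
    def echoes(self) -> EchoPair:
        return EchoPair(self.echo1, self.echo2, self.spec.te1, self.spec.te2,
                        self.grid.affine)

    def measured_field_map(self, mag_threshold: float = 0.05) -> VoxelVolume:
        """Field map recomputed from the simulated echoes (Hz)."""
        return field_map_from_echoes(self.echoes, mag_threshold=mag_threshold)

    def consistency_mask(self) -> np.ndarray:
        """Body voxels whose true field is inside the phase-difference
        dynamic range ±1/(2·ΔTE) (no wrapping)."""
        limit = 0.5 / (self.spec.te2 - self.spec.te1)
        return self.body_mask & (np.abs(self.field.data) < 0.999 * limit)


# --------------------------------------------------------------------------
# geometry rasterisation
# --------------------------------------------------------------------------

def _ellipsoid(px, py, pz, center, semiaxes) -> np.ndarray:
    return (
        ((px - center[0]) / semiaxes[0]) ** 2
        + ((py - center[1]) / semiaxes[1]) ** 2
        + ((pz - center[2]) / semiaxes[2]) ** 2
    ) <= 1.0


def _head_frame_coords(grid: Grid, pose: np.ndarray):
    x, y, z = grid.world_coords()
    X, Y, Z = np.broadcast_arrays(x, y, z)
    R = pose[:3, :3]
    t = pose[:3, 3]
    # head-frame position p with r = R p + t  ⇒  p = Rᵀ (r − t)
    px = R[0, 0] * (X - t[0]) + R[1, 0] * (Y - t[1]) + R[2, 0] * (Z - t[2])
    py = R[0, 1] * (X - t[0]) + R[1, 1] * (Y - t[1]) + R[2, 1] * (Z - t[2])
    pz = R[0, 2] * (X - t[0]) + R[1, 2] * (Y - t[1]) + R[2, 2] * (Z - t[2])
    return px, py, pz


def _rasterize_labels(spec: PhantomSpec, pose: np.ndarray, deformed: bool) -> np.ndarray:
    grid = spec.grid
    px, py, pz = _head_frame_coords(grid, pose)

    head = _ellipsoid(px, py, pz, spec.head_center, spec.head_semiaxes)
    neck = (
        np.sqrt(px**2 + (py - spec.neck_center_y) ** 2) <= spec.neck_radius
    ) & (pz <= spec.head_center[2])
    body = head | neck
    if deformed:
        body = body | _ellipsoid(px, py, pz, spec.bulge_center, spec.bulge_semiaxes)

    inner_axes = tuple(a - spec.skull_thickness for a in spec.head_semiaxes)
    if min(inner_axes) <= 0:
        raise ValueError("skull shell: thickness exceeds head semi-axes")
    inner = _ellipsoid(px, py, pz, spec.head_center, inner_axes)
    skull = head & ~inner

    brain = _ellipsoid(px, py, pz, spec.brain_center, spec.brain_semiaxes)

    labels = np.zeros(grid.shape, dtype=np.int8)  # AIR
    labels[body] = SOFT
    labels[skull] = BONE
    labels[brain & inner] = BRAIN
    for center, radius in spec.cavities:
        if radius <= 0:
            continue
        cav = _ellipsoid(px, py, pz, center, (radius,) * 3)
        labels[cav & head] = AIR
    return labels


def _check_geometry_fits(spec: PhantomSpec):
    grid = spec.grid
    x, y, z = grid.world_coords()
    lo = np.array([x.min(), y.min(), z.min()])
    hi = np.array([x.max(), y.max(), z.max()])
    c = np.asarray(spec.head_center)
    a = np.asarray(spec.head_semiaxes)
    # the neck is allowed to run off the inferior face; the head is not
    if np.any(c - a < lo - 1e-9) or np.any(c[:2] + a[:2] > hi[:2] + 1e-9) or (
        c[2] + a[2] > hi[2] + 1e-9
    ):
        raise ValueError("phantom geometry does not fit inside the grid: head ellipsoid")
    for center, radius in spec.cavities:
        c_arr = np.asarray(center, dtype=float)
        if np.any(c_arr - radius < lo - 1e-9) or np.any(c_arr + radius > hi + 1e-9):
            raise ValueError(
                f"phantom geometry does not fit inside the grid: cavity at {center}"
            )
    bc = np.asarray(spec.brain_center)
    ba = np.asarray(spec.brain_semiaxes)
    if np.any(bc - ba < lo) or np.any(bc + ba > hi):
        raise ValueError("phantom geometry does not fit inside the grid: brain ellipsoid")


# --------------------------------------------------------------------------
# measurement simulation
# --------------------------------------------------------------------------

def _class_table_volume(labels: np.ndarray, table: dict) -> np.ndarray:
    lut = np.zeros(max(CLASS_NAMES) + 1, dtype=float)
    for lab, name in CLASS_NAMES.items():
        lut[lab] = table[name]
    return lut[labels]


def _noise_seed(spec: PhantomSpec, pose: np.ndarray, deformed: bool) -> int:
    if not deformed and np.allclose(pose, np.eye(4), atol=1e-12):
        return spec.seed
    key = np.round(np.asarray(pose, dtype=float), 9).tobytes() + bytes([deformed])
    return int((spec.seed * 1000003 + zlib.crc32(key)) % (2**31 - 1))


def _simulate(spec: PhantomSpec, pose: np.ndarray, deformed: bool) -> PhantomTruth:
    grid = spec.grid
    labels = _rasterize_labels(spec, pose, deformed)
    brain_mask = labels == BRAIN
    body_mask = labels != AIR

    chi_data = _class_table_volume(labels, spec.chi)
    chi = VoxelVolume(chi_data, grid.affine.copy(), units="ppm")

    b_chi = susceptibility_to_field(chi, pad_factor=spec.pad_factor, f0=spec.f0)
    b_sh = sh_shim_field(SHCoefficients(spec.sh_coeffs), grid)
    b_dip = point_dipole_field(DipoleSource(spec.dipole_P, spec.dipole_position), grid)

    # phase-error field: linear along the first PE (y) axis, zero at centre
    ny = grid.shape[1]
    y_idx = np.arange(ny, dtype=float) - (ny - 1) / 2.0
    bk_data = np.broadcast_to(
        (-spec.phase_slope / ny) * y_idx[None, :, None], grid.shape
    ).copy()
    b_k = VoxelVolume(bk_data, grid.affine.copy(), units="Hz")

    # frequency adjustment: brain-mean of the total field → b0_shift_extra.
    # The reference-pose brain mask defines the adjustment; under motion the
    # scanner-frame constant is carried over unchanged, so recompute it from
    # the reference (identity-pose) geometry.
    if not deformed and np.allclose(pose, np.eye(4), atol=1e-12):
        ref_brain = brain_mask
        ref_static = b_sh.data + b_chi.data + b_dip.data
    else:
        ref_labels = _rasterize_labels(spec, np.eye(4), False)
        ref_brain = ref_labels == BRAIN
        ref_chi = VoxelVolume(_class_table_volume(ref_labels, spec.chi),
                              grid.affine.copy(), units="ppm")
        ref_static = (
            b_sh.data
            + susceptibility_to_field(ref_chi, pad_factor=spec.pad_factor,
                                      f0=spec.f0).data
            + b_dip.data
        )
    shift_value = spec.b0_shift_extra - float(np.mean(ref_static[ref_brain]))
    b0_shift = VoxelVolume(np.full(grid.shape, shift_value), grid.affine.copy(),
                           units="Hz")

    total = b_sh + b_chi + b_k + b_dip + b0_shift

    rng = np.random.default_rng(_noise_seed(spec, pose, deformed))

    # UTE-like magnitude: per-class Gaussian in −log intensity
    neglog = (
        _class_table_volume(labels, spec.ute_neglog_mean)
        + _class_table_volume(labels, spec.ute_neglog_sd)
        * rng.standard_normal(grid.shape)
    )
    ute = VoxelVolume(np.exp(-neglog), grid.affine.copy(), units="1")

    # dual-echo complex GRE
    mag = _class_table_volume(labels, spec.gre_magnitude)
    echoes = []
    for te in (spec.te1, spec.te2):
        phase = 2.0 * np.pi * total.data * te
        sig = mag * np.exp(1j * phase)
        if spec.noise_sd > 0:
            sig = sig + spec.noise_sd * (
                rng.standard_normal(grid.shape) + 1j * rng.standard_normal(grid.shape)
            )
        echoes.append(sig)

    components = {
        "B_SH": b_sh,
        "B_chi": b_chi,
        "B_k": b_k,
        "B_chi_prime": b_dip,
        "B0_shift": b0_shift,
    }
    return PhantomTruth(
        spec=spec, pose=np.asarray(pose, dtype=float), deformed=deformed,
        labels=labels, chi=chi, brain_mask=brain_mask, body_mask=body_mask,
        components=components, field=total, ute=ute,
        echo1=echoes[0], echo2=echoes[1],
    )


def generate_phantom(spec: PhantomSpec) -> PhantomTruth:
    """Generate the reference-pose phantom (deterministic per spec/seed)."""
    _check_geometry_fits(spec)
    return _simulate(spec, np.eye(4), deformed=False)


def apply_motion(
    truth: PhantomTruth, transform: RigidTransform, deform_neck: bool = False
) -> PhantomTruth:
    """Phantom ground truth after rigid head motion (optionally with a
    posterior neck-bulge soft-tissue deformation).

    The analytic geometry is re-rasterised at the new pose (exact, no
    interpolation); scanner-frame components are carried over unchanged.
    """
    new_pose = transform.matrix() @ truth.pose
    if transform.is_identity and truth.deformed == deform_neck:
        return truth
    moved = _simulate(truth.spec, new_pose, deform_neck or truth.deformed)
    ref_body = int(truth.body_mask.sum())
    if moved.body_mask.sum() < 0.5 * ref_body:
        raise ValueError("transform moves the head mostly outside the grid")
    return moved
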