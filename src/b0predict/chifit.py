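"""Per-(tissue-bin, VOI) susceptibility fitting.

The field induced by a susceptibility map is linear in χ, so fitting one χ
value per (intensity bin, volume-of-interest) pair is a bound-constrained
*linear* least-squares problem once the unit-response field of each pair
(the field inside the brain produced by χ = 1 ppm on that pair's voxels)
has been precomputed.  The fit minimises the RMSE between the modelled
multi-class field Bχ_m and

    B_diff_m = B_measured − B_SH − Bχ′ − B_k − B0_shift

over the brain mask, with all fitted values bounded to [−14, 1] ppm and
initialised on a linear ramp over [−12, 0] ppm matched to the bins (higher
−log(UTE) signal → higher, i.e. more air-like, susceptibility).  Classes
with fixed literature values (brain, clear soft tissue, clear air) are not
fitted; their field contribution is subtracted from the target first.

Pairs with fewer than ``min_voxels`` voxels are merged into the nearest
populated bin of the same VOI before fitting (single-voxel classes are
noise-dominated).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import lsq_linear

from .forward import DEFAULT_F0, susceptibility_to_field
from .segmentation import BIN0, L_AIR, L_BRAIN, L_SOFT, LITERATURE_CHI_PPM, \
    SegmentationModel
from .volume import Grid, VoxelVolume

__all__ = [
    "VOIPartition", "DesignBasis", "ChiFitResult",
    "build_design_basis", "fit_susceptibilities", "compute_mmr",
    "octant_vois",
]

CHI_BOUNDS = (-14.0, 1.0)       # ppm
INIT_RANGE = (-12.0, 0.0)       # ppm, linear ramp over the bins


@dataclass
class VOIPartition:
    """Integer VOI label per voxel; 0 marks voxels never fitted."""

    labels: np.ndarray
    names: dict

    def __post_init__(self):
        self.labels = np.asarray(self.labels)

    @property
    def voi_ids(self) -> list:
        return sorted(int(v) for v in np.unique(self.labels) if v != 0)


def octant_vois(grid: Grid, n_vois: int = 8) -> VOIPartition:
    """Axis-aligned box VOIs: the eight world-coordinate octants (or a
    single whole-volume VOI for ``n_vois = 1``)."""
    if n_vois == 1:
        labels = np.ones(grid.shape, dtype=np.int16)
        return VOIPartition(labels, {1: "whole volume"})
    if n_vois != 8:
        raise ValueError("octant partition supports 1 or 8 VOIs")
    x, y, z = grid.world_coords()
    X, Y, Z = np.broadcast_arrays(x, y, z)
    labels = (
        1 + (X >= 0).astype(np.int16)
        + 2 * (Y >= 0).astype(np.int16)
        + 4 * (Z >= 0).astype(np.int16)
    )
    names = {i + 1: f"octant {i + 1}" for i in range(8)}
    return VOIPartition(labels.astype(np.int16), names)


@dataclass
class DesignBasis:
    """Unit-response design for the pair fit.

    ``matrix`` has one column per fitted (bin, VOI) pair: the field (Hz)
    inside the brain mask produced by χ = 1 ppm on that pair's voxels.
    ``fixed_field`` is the brain-masked field of all fixed-χ voxels.
    """

    pairs: list                   # (bin_label, voi_id)
    matrix: np.ndarray            # (n_mask_voxels, n_pairs)
    voxel_sets: list              # boolean volumes, one per pair
    fixed_field: np.ndarray       # (n_mask_voxels,)
    fixed_chi_map: VoxelVolume    # ppm, fixed classes only
    brain_mask: np.ndarray
    grid: Grid
    pad_factor: int
    f0: float


def _merge_small_pairs(labels, vois, fitted_bins, min_voxels):
    """Reassign bins of under-populated (bin, VOI) pairs to the nearest
    populated bin in the same VOI.  Returns an adjusted label volume."""
    out = labels.copy()
    for voi in np.unique(vois.labels):
        if voi == 0:
            continue
        in_voi = vois.labels == voi
        counts = {
            b: int(np.sum(in_voi & (labels == b))) for b in fitted_bins
        }
        big = [b for b, c in counts.items() if c >= min_voxels]
        small = [b for b, c in counts.items() if 0 < c < min_voxels]
        for b in small:
            if not big:
                continue  # nothing to merge into; pair stays and is fitted
            target = min(big, key=lambda t: abs(t - b))
            out[in_voi & (labels == b)] = target
    return out


def build_design_basis(
    model: SegmentationModel,
    vois: VOIPartition,
    brain_mask: np.ndarray,
    pad_factor: int = 3,
    f0: float = DEFAULT_F0,
    min_voxels: int = 5,
) -> DesignBasis:
    """Precompute the per-(bin, VOI) unit-response fields inside the brain."""
    if model.mode != "multi_class":
        raise ValueError("design basis requires a multi-class segmentation")
    grid = Grid(tuple(model.labels.shape), model.affine)

    fitted_bins = sorted(
        int(l) for l in np.unique(model.labels) if l >= BIN0
    )
    labels = _merge_small_pairs(model.labels, vois, fitted_bins, min_voxels)

    # fixed-χ classes: brain, clear soft tissue, clear air
    fixed = np.zeros(grid.shape, dtype=float)
    fixed[labels == L_BRAIN] = LITERATURE_CHI_PPM["brain"]
    fixed[labels == L_SOFT] = LITERATURE_CHI_PPM["soft"]
    fixed[labels == L_AIR] = LITERATURE_CHI_PPM["air"]
    fixed_vol = VoxelVolume(fixed, grid.affine.copy(), units="ppm")
    fixed_field = susceptibility_to_field(fixed_vol, pad_factor, f0).data[brain_mask]

    pairs, cols, voxel_sets = [], [], []
    for b in sorted(int(l) for l in np.unique(labels) if l >= BIN0):
        for voi in vois.voi_ids:
            vox = (labels == b) & (vois.labels == voi) & ~brain_mask
            if not np.any(vox):
                continue
            unit = VoxelVolume(vox.astype(float), grid.affine.copy(), units="ppm")
            field = susceptibility_to_field(unit, pad_factor, f0)
            pairs.append((b, voi))
            cols.append(field.data[brain_mask])
            voxel_sets.append(vox)

    matrix = (
        np.column_stack(cols) if cols else np.zeros((int(brain_mask.sum()), 0))
    )
    return DesignBasis(
        pairs=pairs, matrix=matrix, voxel_sets=voxel_sets,
        fixed_field=fixed_field, fixed_chi_map=fixed_vol,
        brain_mask=brain_mask, grid=grid, pad_factor=pad_factor, f0=f0,
    )


@dataclass
class ChiFitResult:
    """Fitted multi-class susceptibility model and its residual field."""

    pair_chi: dict                # (bin, VOI) → ppm
    chi_map: VoxelVolume          # ppm, fixed + fitted voxels
    b_chi_m: VoxelVolume          # Hz, field of the fitted model
    cost_trace: list              # RMSE (Hz) at init and after the solve
    active_bounds: list           # pairs pinned at a bound
    non_identifiable: list        # pairs flagged by the rank check

    @property
    def cost(self) -> float:
        return self.cost_trace[-1]


def _bin_init_values(pairs) -> np.ndarray:
    """Linear χ ramp over [−12, 0] ppm matched to the bin indices
    (higher bin = higher −log signal = more air-like = higher χ)."""
    bins = np.array([b for b, _ in pairs], dtype=float)
    lo_b, hi_b = bins.min(), bins.max()
    if hi_b == lo_b:
        frac = np.full(bins.shape, 0.5)
    else:
        frac = (bins - lo_b) / (hi_b - lo_b)
    return INIT_RANGE[0] + frac * (INIT_RANGE[1] - INIT_RANGE[0])


def fit_susceptibilities(
    b_diff_m: VoxelVolume,
    brain_mask: np.ndarray,
    basis: DesignBasis,
    init: np.ndarray | None = None,
    bounds: tuple = CHI_BOUNDS,
) -> ChiFitResult:
    """Bound-constrained linear least-squares fit of the pair χ values."""
    if not np.array_equal(brain_mask, basis.brain_mask):
        raise ValueError("brain mask does not match the design basis")
    target = b_diff_m.data[brain_mask].astype(float) - basis.fixed_field
    A = basis.matrix
    n_pairs = A.shape[1]
    n = target.size

    if init is None:
        init = _bin_init_values(basis.pairs) if n_pairs else np.zeros(0)
    init = np.clip(np.asarray(init, dtype=float), bounds[0], bounds[1])

    cost_init = float(np.sqrt(np.mean((target - A @ init) ** 2))) if n else 0.0

    non_identifiable = []
    if n_pairs:
        rank = np.linalg.matrix_rank(A)
        if rank < n_pairs:
            # flag the pairs whose column adds no new rank (minimum-norm
            # behaviour is provided by the solver itself)
            _, R = np.linalg.qr(A)
            diag = np.abs(np.diag(R))
            thresh = diag.max() * max(A.shape) * np.finfo(float).eps
            non_identifiable = [
                basis.pairs[i] for i in range(n_pairs) if diag[i] < thresh
            ]
        res = lsq_linear(A, target, bounds=bounds, method="bvls",
                         tol=1e-12, max_iter=200)
        chi = res.x
        cost_fit = float(np.sqrt(np.mean((target - A @ chi) ** 2)))
        if cost_fit > cost_init:      # guaranteed not to regress on the init
            chi, cost_fit = init, cost_init
    else:
        chi, cost_fit = init, cost_init

    pair_chi = {p: float(c) for p, c in zip(basis.pairs, chi)}
    tol = 1e-9
    active = [p for p, c in pair_chi.items()
              if abs(c - bounds[0]) < tol or abs(c - bounds[1]) < tol]

    chi_map = basis.fixed_chi_map.data.copy()
    for vox, c in zip(basis.voxel_sets, chi):
        chi_map[vox] = c
    chi_vol = VoxelVolume(chi_map, basis.grid.affine.copy(), units="ppm")
    b_chi_m = susceptibility_to_field(chi_vol, basis.pad_factor, basis.f0)

    return ChiFitResult(
        pair_chi=pair_chi, chi_map=chi_vol, b_chi_m=b_chi_m,
        cost_trace=[cost_init, cost_fit], active_bounds=active,
        non_identifiable=non_identifiable,
    )


def compute_mmr(
    measured: VoxelVolume, simulated: VoxelVolume, brain_mask: np.ndarray
) -> VoxelVolume:
    """Multi-model residual: measured − simulated, brain-masked (Hz)."""
    resid = measured - simulated
    data = np.where(brain_mask, resid.data, 0.0)
    valid = brain_mask & resid.valid_mask()
    return VoxelVolume(data, resid.affine, units="Hz", valid=valid)
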