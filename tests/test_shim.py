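"""Multi-coil shim: basis generation, downsampling, the constrained QP."""

import numpy as np
import pytest

from b0predict.shim import (
    ShimSystem,
    downsample_for_shim,
    downsample_mask,
    evaluate_shim,
    generate_coil_basis,
    solve_shim_currents,
)
from b0predict.volume import Grid, VoxelVolume, center_affine


@pytest.fixture(scope="module")
def grid():
    return Grid((24, 24, 24), center_affine((24, 24, 24), 4.0))


@pytest.fixture(scope="module")
def system(grid):
    return generate_coil_basis(grid)


@pytest.fixture(scope="module")
def full_mask(grid):
    return np.ones(grid.shape, bool)


# ------------------------------------------------------------------- basis

def test_coil_count_and_determinism(grid, system):
    assert system.n_coils == 16
    again = generate_coil_basis(grid)
    assert np.array_equal(again.basis, system.basis)


def test_mirrored_coils_are_mirror_symmetric(grid):
    """Coils at azimuth φ and φ+π produce fields related by (x,y)→(−x,−y)."""
    sys8 = generate_coil_basis(grid, n_coils=8, ring_z_mm=(0.0,))
    b0 = sys8.basis[0]
    b4 = sys8.basis[4]          # opposite coil on the same ring
    assert np.allclose(b4, b0[::-1, ::-1, :], atol=1e-12)


def test_basis_scales_linearly_with_dipole_strength(grid):
    a = generate_coil_basis(grid, dipole_scale=1e7)
    b = generate_coil_basis(grid, dipole_scale=2e7)
    assert np.allclose(b.basis, 2.0 * a.basis)


def test_coil_fields_are_harmonic_inside_fov(system):
    """Sources sit outside the FOV, so each basis is discretely harmonic."""
    for c in range(0, system.n_coils, 5):
        f = system.basis[c]
        lap = (
            np.diff(f, 2, axis=0)[:, 1:-1, 1:-1]
            + np.diff(f, 2, axis=1)[1:-1, :, 1:-1]
            + np.diff(f, 2, axis=2)[1:-1, 1:-1, :]
        )
        assert np.max(np.abs(lap)) < 1e-3 * np.max(np.abs(f))


def test_coil_inside_head_warns(grid):
    with pytest.warns(RuntimeWarning):
        generate_coil_basis(grid, cylinder_radius_mm=50.0)


# ------------------------------------------------------------- downsampling

def test_downsample_block_mean_arithmetic():
    aff = center_affine((2, 2, 2), 1.0)
    vol = VoxelVolume(np.arange(1.0, 9.0).reshape(2, 2, 2), aff, "Hz")
    out = downsample_for_shim(vol, 2)
    assert out.data.shape == (1, 1, 1)
    assert np.isclose(out.data[0, 0, 0], 4.5)
    assert np.allclose(out.grid.voxel_size, 2.0)


def test_downsample_factor_one_is_identity(grid):
    vol = VoxelVolume(np.random.default_rng(0).normal(size=grid.shape),
                      grid.affine, "Hz")
    out = downsample_for_shim(vol, 1)
    assert np.array_equal(out.data, vol.data)


def test_downsample_constant_volume_stays_constant():
    aff = center_affine((6, 6, 6), 1.0)
    vol = VoxelVolume(np.full((6, 6, 6), 2.5), aff, "Hz")
    assert np.allclose(downsample_for_shim(vol, 3).data, 2.5)


def test_downsample_excludes_invalid_voxels():
    aff = center_affine((2, 2, 2), 1.0)
    valid = np.ones((2, 2, 2), bool)
    valid[0, 0, 0] = False
    vol = VoxelVolume(np.arange(1.0, 9.0).reshape(2, 2, 2), aff, "Hz",
                      valid=valid)
    out = downsample_for_shim(vol, 2)
    assert np.isclose(out.data[0, 0, 0], np.mean(np.arange(2.0, 9.0)))


def test_downsample_block_centres_keep_world_positions():
    aff = center_affine((4, 4, 4), 1.0)
    vol = VoxelVolume(np.zeros((4, 4, 4)), aff, "Hz")
    out = downsample_for_shim(vol, 2)
    x, _, _ = out.grid.world_coords()
    assert np.allclose(np.sort(np.unique(x)), [-1.0, 1.0])


# --------------------------------------------------------------------- QP

def test_zero_target_gives_zero_currents(grid, system, full_mask):
    target = VoxelVolume(np.zeros(grid.shape), grid.affine, "Hz")
    rep = solve_shim_currents(target, full_mask, system)
    assert np.allclose(rep.currents, 0.0, atol=1e-9)
    assert rep.cost < 1e-12


def test_in_span_target_currents_recovered(grid, system, full_mask):
    rng = np.random.default_rng(0)
    c_true = rng.uniform(-2.0, 2.0, system.n_coils)
    c_true *= min(1.0, 20.0 / np.sum(np.abs(c_true)))
    target = VoxelVolume(system.shim_field(c_true), grid.affine, "Hz")
    rep = solve_shim_currents(target, full_mask, system)
    assert np.max(np.abs(rep.currents - c_true)) < 1e-3
    assert rep.sigma_after_hz < 1e-3


def test_per_coil_limit_clamps_against_closed_form(grid, full_mask):
    """Single-coil system whose unconstrained optimum is 10 A: the 1-D
    closed form clip(⟨a,b⟩/⟨a,a⟩, ±4) demands exactly 4 A."""
    sys16 = generate_coil_basis(grid)
    one = ShimSystem(basis=sys16.basis[:1], affine=grid.affine)
    target = VoxelVolume(10.0 * one.basis[0], grid.affine, "Hz")
    a = one.basis[0].ravel() - one.basis[0].mean()
    b = target.data.ravel() - target.data.mean()
    closed = np.clip(a @ b / (a @ a), -4.0, 4.0)
    assert np.isclose(closed, 4.0)
    rep = solve_shim_currents(target, full_mask, one)
    assert np.isclose(rep.currents[0], 4.0, atol=1e-6)


def test_residual_never_exceeds_preshim_sigma(grid, system, full_mask):
    rng = np.random.default_rng(1)
    target = VoxelVolume(rng.normal(0, 20, grid.shape), grid.affine, "Hz")
    rep = solve_shim_currents(target, full_mask, system)
    assert rep.sigma_after_hz <= rep.sigma_before_hz + 1e-9


def test_relaxing_limits_never_increases_cost(grid, full_mask):
    base = generate_coil_basis(grid)
    target = VoxelVolume(base.shim_field(np.full(16, 3.0)), grid.affine, "Hz")
    costs = []
    for lim in (1.0, 2.0, 4.0):
        s = ShimSystem(basis=base.basis, affine=grid.affine, per_coil_limit=lim)
        costs.append(solve_shim_currents(target, full_mask, s).cost)
    assert costs[0] >= costs[1] >= costs[2] - 1e-9
    # and tightening the total budget can only hurt
    tight = ShimSystem(basis=base.basis, affine=grid.affine, total_limit=10.0)
    loose = ShimSystem(basis=base.basis, affine=grid.affine, total_limit=50.0)
    assert solve_shim_currents(target, full_mask, tight).cost >= \
        solve_shim_currents(target, full_mask, loose).cost - 1e-9


def test_total_current_constraint_respected(grid, full_mask):
    base = generate_coil_basis(grid)
    s = ShimSystem(basis=base.basis, affine=grid.affine, total_limit=8.0)
    target = VoxelVolume(base.shim_field(np.full(16, 3.0)), grid.affine, "Hz")
    rep = solve_shim_currents(target, full_mask, s)
    assert np.sum(np.abs(rep.currents)) <= 8.0 + 1e-6


# -------------------------------------------------------------- evaluation

def test_zero_currents_leave_target_unchanged(grid, system, full_mask):
    rng = np.random.default_rng(2)
    fm = VoxelVolume(rng.normal(0, 15, grid.shape), grid.affine, "Hz")
    rep = evaluate_shim(fm, np.zeros(system.n_coils), system, full_mask)
    assert np.isclose(rep.sigma_after_hz, rep.sigma_before_hz)


def test_evaluate_rejects_out_of_limit_currents(grid, system, full_mask):
    fm = VoxelVolume(np.zeros(grid.shape), grid.affine, "Hz")
    with pytest.raises(ValueError):
        evaluate_shim(fm, np.full(16, 5.0), system, full_mask)


def test_downsample_mask_majority_rule():
    mask = np.zeros((4, 4, 4), bool)
    mask[:2, :2, :2] = True       # one full coarse block
    mask[2, 2, 2] = True          # 1/8 of another block
    out = downsample_mask(mask, 2)
    assert out[0, 0, 0] and not out[1, 1, 1]
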