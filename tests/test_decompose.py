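"""Field-map decomposition: phase mapping, k-space shift, dipole fit, SMR."""

import numpy as np
import pytest

from b0predict.decompose import (
    EchoPair,
    estimate_ky_shift,
    field_map_from_echoes,
    fit_lower_body_dipole,
)
from b0predict.forward import DipoleSource, point_dipole_field
from b0predict.volume import Grid, VoxelVolume, center_affine

TE1, TE2 = 2.68e-3, 7.49e-3
DTE = TE2 - TE1


def _echoes(phase1, phase2, mag=1.0, shape=(8, 8, 8)):
    aff = center_affine(shape, 2.0)
    e1 = np.full(shape, mag) * np.exp(1j * np.full(shape, phase1))
    e2 = np.full(shape, mag) * np.exp(1j * np.full(shape, phase2))
    return EchoPair(e1, e2, TE1, TE2, aff)


# ---------------------------------------------------------------- field map

def test_identical_phases_give_zero_field():
    fm = field_map_from_echoes(_echoes(0.7, 0.7))
    assert np.allclose(fm.data, 0.0)


def test_quarter_cycle_phase_difference():
    # Δφ = π/2 over ΔTE = 4.81 ms ⇒ (π/2)/(2π·0.00481) ≈ 51.98 Hz
    fm = field_map_from_echoes(_echoes(0.0, np.pi / 2))
    assert np.allclose(fm.data, (np.pi / 2) / (2 * np.pi * DTE))
    assert np.allclose(fm.data, 51.975, atol=0.01)


def test_field_beyond_dynamic_range_wraps_negative():
    f_true = 0.5 / DTE + 5.0
    fm = field_map_from_echoes(_echoes(0.0, 2 * np.pi * f_true * DTE))
    assert np.all(fm.data < 0)


def test_equal_echo_times_rejected():
    with pytest.raises(ValueError):
        EchoPair(np.ones((4, 4, 4), complex), np.ones((4, 4, 4), complex),
                 TE1, TE1, np.eye(4))


def test_low_magnitude_voxels_flagged_invalid():
    ep = _echoes(0.0, 0.3)
    ep.echo1[0, 0, 0] = ep.echo2[0, 0, 0] = 1e-6
    fm = field_map_from_echoes(ep)
    assert not fm.valid[0, 0, 0]
    assert fm.valid[4, 4, 4]


# ------------------------------------------------------------ k-space shift

def _ramp_echoes(a, mag, shape=(32, 32, 32)):
    aff = center_affine(shape, 2.0)
    ny = shape[1]
    y = np.arange(ny) - (ny - 1) / 2
    out = []
    for te in (TE1, TE2):
        ramp = 2 * np.pi * (-a * te) * y[None, :, None] / ny
        out.append(mag * np.exp(1j * np.broadcast_to(ramp, shape)))
    return EchoPair(out[0], out[1], TE1, TE2, aff)


def _zero_field(shape=(32, 32, 32)):
    return VoxelVolume(np.zeros(shape), center_affine(shape, 2.0), "Hz")


def test_no_ramp_gives_zero_slope():
    rng = np.random.default_rng(0)
    mag = np.abs(rng.normal(1.0, 0.1, (32, 32, 32)))
    pe = estimate_ky_shift(_ramp_echoes(0.0, mag), _zero_field())
    assert abs(pe.slope) < 1e-10
    assert np.allclose(pe.bk.data, 0.0)


def test_known_ramp_slope_recovered_within_1pct():
    rng = np.random.default_rng(1)
    mag = np.abs(rng.normal(1.0, 0.2, (32, 32, 32)))
    pe = estimate_ky_shift(_ramp_echoes(200.0, mag), _zero_field())
    assert abs(pe.slope - 200.0) < 2.0
    np.testing.assert_allclose(pe.shifts, (-200.0 * TE1, -200.0 * TE2), rtol=0.01)


def test_slope_invariant_under_global_magnitude_scaling():
    rng = np.random.default_rng(2)
    mag = np.abs(rng.normal(1.0, 0.2, (32, 32, 32)))
    ep = _ramp_echoes(120.0, mag)
    scaled = EchoPair(7.5 * ep.echo1, 7.5 * ep.echo2, TE1, TE2, ep.affine)
    a1 = estimate_ky_shift(ep, _zero_field()).slope
    a2 = estimate_ky_shift(scaled, _zero_field()).slope
    assert np.isclose(a1, a2)


def test_signal_free_input_rejected():
    ep = _ramp_echoes(50.0, np.zeros((32, 32, 32)))
    with pytest.raises(ValueError, match="signal-free"):
        estimate_ky_shift(ep, _zero_field())


def test_bk_field_is_linear_in_y_and_zero_at_center(truth, spec):
    bk = truth.components["B_k"].data
    assert np.allclose(bk[:, :, :] - bk[:1, :, :1], 0.0)  # varies along y only
    ny = spec.grid_shape[1]
    center = 0.5 * (bk[:, ny // 2 - 1, :] + bk[:, ny // 2, :])
    assert np.allclose(center, 0.0, atol=1e-12)


# -------------------------------------------------------------- dipole fit

def _mask(shape=(32, 32, 32), lo=8, hi=24):
    m = np.zeros(shape, bool)
    m[lo:hi, lo:hi, lo:hi] = True
    return m


def test_constant_field_fits_as_pure_offset():
    g = Grid((32,) * 3, center_affine((32,) * 3, 2.0))
    c = 11.0
    vol = VoxelVolume(np.full(g.shape, c), g.affine, "Hz")
    src, shift, info = fit_lower_body_dipole(vol, _mask(), grid_search=False)
    field = point_dipole_field(src, g).data
    assert np.max(np.abs(field[_mask()])) < 1e-3 * abs(c)
    assert abs(shift - c) < 1e-3


def test_generative_dipole_recovery():
    g = Grid((32,) * 3, center_affine((32,) * 3, 2.0))
    true = DipoleSource(4.0e7, (6.0, -12.0, -180.0))
    b = point_dipole_field(true, g) + 3.0
    init = DipoleSource(0.0, (2.0, -6.0, -174.0))  # within 5 voxels of truth
    src, shift, info = fit_lower_body_dipole(b, _mask(), init=init,
                                             grid_search=False)
    assert abs(src.P - true.P) < 0.02 * true.P
    assert np.max(np.abs(np.array(src.position) - true.position)) < 2.0  # 1 voxel
    assert abs(shift - 3.0) < 1e-3
    norm = np.sqrt(np.mean(b.data[_mask()] ** 2))
    assert info["cost"] < 1e-6 * norm


def test_cost_vanishes_at_true_parameters():
    g = Grid((32,) * 3, center_affine((32,) * 3, 2.0))
    true = DipoleSource(4.0e7, (6.0, -12.0, -180.0))
    b = point_dipole_field(true, g) + 3.0
    m = _mask()
    resid = b.data[m] - point_dipole_field(true, g).data[m] - 3.0
    assert np.sqrt(np.mean(resid**2)) < 1e-9


def test_dipole_fit_translation_equivariance():
    g = Grid((32,) * 3, center_affine((32,) * 3, 2.0))
    delta = np.array([4.0, -6.0, 10.0])
    base = DipoleSource(4.0e7, (6.0, -12.0, -180.0))
    shifted = DipoleSource(4.0e7, tuple(np.array(base.position) + delta))
    m = _mask()
    for true in (base, shifted):
        b = point_dipole_field(true, g)
        init = DipoleSource(0.0, tuple(np.array(true.position) + 3.0))
        src, _, _ = fit_lower_body_dipole(b, m, init=init, grid_search=False)
        assert np.allclose(src.position, true.position, atol=0.5)


# --------------------------------------------------------------------- SMR

def test_reconstruction_identity_is_exact(ref_decomp, truth):
    """B_SH + Bχ + B_k + Bχ′ + B0_shift + SMR equals the measured map
    exactly inside the brain (definition of the residual)."""
    recon = ref_decomp.simulated() + ref_decomp.smr()
    m = truth.brain_mask
    assert np.allclose(recon.data[m], ref_decomp.measured.data[m],
                       rtol=0, atol=1e-9)


def test_smr_zero_for_perfect_component_knowledge(truth_decomp, truth):
    smr = truth_decomp.smr()
    assert np.allclose(smr.data[truth.brain_mask], 0.0, atol=1e-9)


def test_smr_invariant_under_global_offset(truth, truth_decomp):
    """Adding a constant to the measured map is absorbed by the refitted
    B0 shift: the residual is unchanged."""
    from b0predict.decompose import fit_lower_body_dipole as fit

    m = truth.brain_mask
    b_diff = truth_decomp.b_diff()
    src0, s0, _ = fit(b_diff, m)
    src1, s1, _ = fit(b_diff + 25.0, m)
    assert np.allclose(src1.position, src0.position, atol=0.5)
    assert abs((s1 - s0) - 25.0) < 1e-3


def test_chi_model_errors_show_up_as_smr(truth, spec, truth_decomp):
    """A deliberately mis-set 3-class χ leaves a nonzero residual."""
    import b0predict as bp
    from b0predict.decompose import DecompositionResult

    wrong_chi = truth.chi.like(truth.chi.data * 0.7)
    wrong_field = bp.susceptibility_to_field(wrong_chi, spec.pad_factor, spec.f0)
    wrong = DecompositionResult(
        measured=truth_decomp.measured, b_sh=truth_decomp.b_sh,
        b_chi=wrong_field, b_k=truth_decomp.b_k,
        b_chi_prime=truth_decomp.b_chi_prime, b0_shift=truth_decomp.b0_shift,
        brain_mask=truth.brain_mask,
    )
    rmse = np.sqrt(np.mean(wrong.smr().data[truth.brain_mask] ** 2))
    assert rmse > 1.0
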