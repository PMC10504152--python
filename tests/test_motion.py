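"""Rigid transport, prediction strategies and their scoring."""

import numpy as np
import pytest

import b0predict as bp
from b0predict.motion import (
    body_mask_from_magnitude,
    predict_combined_fm,
    predict_simulated_fm,
    predict_transformed_fm,
    score_prediction,
    transform_volume,
    update_geometry_mask,
)
from b0predict.chifit import compute_mmr
from b0predict.volume import VoxelVolume, center_affine


def _smooth_volume(shape=(24, 24, 24)):
    aff = center_affine(shape, 2.0)
    g = bp.Grid(shape, aff)
    x, y, z = g.world_coords()
    data = np.broadcast_to(
        np.sin(x / 11.0) + np.cos(y / 7.0) * np.sin(z / 9.0), shape
    ).copy()
    return VoxelVolume(data, aff, "Hz")


# ---------------------------------------------------------------- transport

def test_identity_transform_is_exact():
    vol = _smooth_volume()
    out = transform_volume(vol, bp.RigidTransform(), "continuous")
    assert np.array_equal(out.data, vol.data)


def test_integer_voxel_translation_is_exact_shift():
    vol = _smooth_volume()
    out = transform_volume(vol, bp.RigidTransform((0, 0, 0), (0, 0, 4.0)),
                           "continuous")
    # +4 mm = +2 voxels along z: out[k] = in[k − 2]
    assert np.allclose(out.data[:, :, 2:][out.valid[:, :, 2:]],
                       vol.data[:, :, :-2][out.valid[:, :, 2:]], atol=1e-9)
    assert not np.any(out.valid[:, :, :1])


def test_round_trip_error_bounded_by_interpolation_modulus():
    vol = _smooth_volume()
    t = np.array([1.0, 0.5, 0.0])
    T = bp.RigidTransform((0, 0, 9.0), tuple(t))
    # exact inverse of a single-axis rotation + translation in this convention
    Tinv = bp.RigidTransform((0, 0, -9.0),
                             tuple(-(bp.RigidTransform((0, 0, -9.0))
                                     .rotation_matrix() @ t)))
    assert np.allclose(Tinv.matrix() @ T.matrix(), np.eye(4), atol=1e-12)
    there = transform_volume(vol, T, "continuous")
    back = transform_volume(there, Tinv, "continuous")
    ok = back.valid
    err = np.max(np.abs(back.data[ok] - vol.data[ok]))
    # smooth field, 2 mm lattice: second-order interpolation error ≪ range
    assert err < 0.05 * np.ptp(vol.data)


def test_label_transport_preserves_label_values(truth):
    lab = VoxelVolume(truth.labels.astype(np.int16), truth.grid.affine, "1")
    out = transform_volume(lab, bp.RigidTransform((0, 6.0, 0)), "label")
    assert set(np.unique(out.data)).issubset(set(np.unique(truth.labels)))


# -------------------------------------------------------------- strategies

def test_transformed_fm_identity_reproduces_measured(truth_decomp):
    rep = predict_transformed_fm(truth_decomp, bp.RigidTransform())
    assert np.allclose(rep.predicted.data, truth_decomp.measured.data, atol=1e-9)


def test_simulated_fm_identity_matches_reference_simulation(truth, truth_decomp, spec):
    rep = predict_simulated_fm(truth_decomp, truth.chi, bp.RigidTransform(),
                               pad_factor=spec.pad_factor, f0=spec.f0)
    ref_sim = truth_decomp.simulated()
    assert np.allclose(rep.predicted.data, ref_sim.data, atol=1e-9)


def test_simulated_fm_rigid_self_consistency():
    """Rigid-only, noiseless, default (64³ / 2 mm) resolution: predicting
    with the true susceptibility model agrees with the moved phantom's
    measured map to better than 1 Hz (generator/predictor self-consistency;
    the only error source is nearest-neighbour transport of χ)."""
    from b0predict.decompose import DecompositionResult

    spec = bp.PhantomSpec(seed=4)
    truth = bp.generate_phantom(spec)
    ref = DecompositionResult(
        measured=truth.measured_field_map(),
        b_sh=truth.components["B_SH"], b_chi=truth.components["B_chi"],
        b_k=truth.components["B_k"], b_chi_prime=truth.components["B_chi_prime"],
        b0_shift=float(truth.components["B0_shift"].data[0, 0, 0]),
        brain_mask=truth.brain_mask,
    )
    T = bp.RigidTransform((0, 0, 5.0))
    moved = bp.apply_motion(truth, T)
    rep = predict_simulated_fm(ref, truth.chi, T,
                               pad_factor=spec.pad_factor, f0=spec.f0)
    scored = score_prediction(rep, moved.measured_field_map(), moved.brain_mask)
    assert scored.rmse_hz < 1.0


def test_combined_fm_identity_is_exact(truth, truth_decomp, spec):
    measured = truth_decomp.measured
    sim = predict_simulated_fm(truth_decomp, truth.chi, bp.RigidTransform(),
                               pad_factor=spec.pad_factor, f0=spec.f0)
    mmr = compute_mmr(measured, sim.predicted, truth.brain_mask)
    rep = predict_combined_fm(truth_decomp, truth.chi, mmr, bp.RigidTransform(),
                              pad_factor=spec.pad_factor, f0=spec.f0)
    scored = score_prediction(rep, measured, truth.brain_mask)
    assert scored.rmse_hz < 1e-9


def test_zero_mmr_makes_combined_equal_simulated(truth, truth_decomp, spec):
    zero = VoxelVolume(np.zeros(truth.grid.shape), truth.grid.affine, "Hz")
    T = bp.RigidTransform((0, 0, 4.0))
    sim = predict_simulated_fm(truth_decomp, truth.chi, T,
                               pad_factor=spec.pad_factor, f0=spec.f0)
    com = predict_combined_fm(truth_decomp, truth.chi, zero, T,
                              pad_factor=spec.pad_factor, f0=spec.f0)
    ok = com.predicted.valid_mask()
    assert np.allclose(com.predicted.data[ok], sim.predicted.data[ok], atol=1e-9)


# -------------------------------------------------------------- mask update

def test_mask_update_noop_for_transported_mask(truth):
    chi = truth.chi.copy()
    body = truth.body_mask
    out = update_geometry_mask(chi, body, truth.brain_mask)
    assert np.array_equal(out.data, chi.data)


def test_mask_update_adds_soft_tissue_in_bulge(truth):
    chi = truth.chi.copy()
    bulge = truth.body_mask.copy()
    bulge[10:14, 30:34, 2:6] = True          # posterior-inferior extension
    added = bulge & ~truth.body_mask
    out = update_geometry_mask(chi, bulge, truth.brain_mask)
    assert np.all(out.data[added] == -9.6)
    unchanged = truth.body_mask & bulge
    assert np.array_equal(out.data[unchanged], chi.data[unchanged])


def test_mask_update_shrink_only_removes_tissue(truth):
    from scipy import ndimage

    chi = truth.chi.copy()
    shrunk = ndimage.binary_erosion(truth.body_mask, iterations=2)
    out = update_geometry_mask(chi, shrunk, truth.brain_mask)
    assert np.all(out.data[~shrunk] == 0.0)
    # no voxel gains tissue: the shrunk mask lies inside the old body
    gained = (chi.data == 0.0) & (out.data != 0.0)
    assert not np.any(gained)


def test_empty_mask_rejected(truth):
    with pytest.raises(ValueError):
        update_geometry_mask(truth.chi, np.zeros(truth.grid.shape, bool))


def test_body_mask_from_magnitude_recovers_phantom_outline(truth):
    mag = VoxelVolume(np.abs(truth.echo1), truth.grid.affine, "1")
    mask = body_mask_from_magnitude(mag)
    overlap = np.sum(mask & truth.body_mask) / truth.body_mask.sum()
    assert overlap > 0.95


# ------------------------------------------------------------------ scoring

def test_score_arithmetic():
    aff = center_affine((2, 1, 1), 1.0)
    meas = VoxelVolume(np.array([1.0, 2.0]).reshape(2, 1, 1), aff, "Hz")
    pred = VoxelVolume(np.array([1.0, 4.0]).reshape(2, 1, 1), aff, "Hz")
    rep = score_prediction(pred, meas, np.ones((2, 1, 1), bool))
    assert np.isclose(rep.rmse_hz, np.sqrt(2.0))


def test_constant_offset_shifts_rmse_not_sigma(truth_decomp, truth):
    meas = truth_decomp.measured
    pred = meas + 3.0
    rep = score_prediction(pred, meas, truth.brain_mask)
    assert np.isclose(rep.rmse_hz, 3.0)
    assert np.isclose(rep.sigma_predicted_hz, rep.sigma_measured_hz)


def test_empty_mask_scoring_rejected(truth_decomp, truth):
    with pytest.raises(ValueError):
        score_prediction(truth_decomp.measured, truth_decomp.measured,
                         np.zeros(truth.grid.shape, bool))
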