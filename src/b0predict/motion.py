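"""Field-map prediction at new head positions.

Three strategies predict the field after rigid head motion T:

* transformed FM — transport the measured reference map (minus the static
  shim field, which does not move with the head):
  ``predicted = T(measured − B_SH) + B_SH``;
* simulated FM — transport the fitted susceptibility model, re-run the
  forward calculation, and add back the scanner-frame terms:
  ``predicted = B_SH + forward(T(χ)) + B_k + Bχ′ + B0_shift``;
* combined FM — simulated FM plus the transported multi-model residual:
  ``predicted = simulated + T(MMR)``.  At the identity transform this
  reproduces the measured reference map by construction.

For large motion the rigidly transported susceptibility model can disagree
with the true body outline (soft tissue deforms at the neck); an updated
body mask derived from the magnitude image at the new position corrects the
model: voxels outside the new mask become air, newly covered non-brain
voxels become soft tissue.

Continuous maps are transported with trilinear interpolation, labels/masks
with nearest neighbour; voxels transported from outside the support are
air (χ = 0) or flagged invalid (field maps).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .chifit import ChiFitResult, compute_mmr
from .decompose import DecompositionResult
from .forward import susceptibility_to_field
from .segmentation import LITERATURE_CHI_PPM
from .transforms import RigidTransform
from .volume import VoxelVolume

__all__ = [
    "PredictionReport", "transform_volume", "body_mask_from_magnitude",
    "update_geometry_mask", "predict_transformed_fm", "predict_simulated_fm",
    "predict_combined_fm", "score_prediction",
]


@dataclass
class PredictionReport:
    """Predicted field map and its agreement with a measured map."""

    strategy: str
    predicted: VoxelVolume
    rmse_hz: float | None = None
    sigma_measured_hz: float | None = None
    sigma_predicted_hz: float | None = None


def _index_matrix(vol: VoxelVolume, transform: RigidTransform) -> tuple:
    """Voxel-index map for resampling the moved object onto the same grid:
    the moved volume is v'(r) = v(T⁻¹ r)."""
    A = vol.affine
    M = np.linalg.inv(A) @ transform.inverse_matrix() @ A
    return M[:3, :3], M[:3, 3]


def transform_volume(
    vol: VoxelVolume, transform: RigidTransform, kind: str = "continuous"
) -> VoxelVolume:
    """Rigidly transport a volume and resample it on its own grid.

    ``kind``: "continuous" (trilinear, out-of-support → invalid),
    "label" or "mask" (nearest neighbour, out-of-support → 0).
    """
    if kind not in ("continuous", "label", "mask"):
        raise ValueError(f"unknown volume kind {kind!r}")
    if transform.is_identity:
        return vol.copy()
    matrix, offset = _index_matrix(vol, transform)
    order = 1 if kind == "continuous" else 0
    data = ndimage.affine_transform(
        np.asarray(vol.data, dtype=float), matrix, offset=offset,
        order=order, mode="constant", cval=0.0, prefilter=False,
    )
    inside = ndimage.affine_transform(
        np.ones(vol.data.shape), matrix, offset=offset,
        order=order, mode="constant", cval=0.0, prefilter=False,
    ) > (0.999 if order == 0 else 0.999)
    valid = ndimage.affine_transform(
        vol.valid_mask().astype(float), matrix, offset=offset,
        order=order, mode="constant", cval=0.0, prefilter=False,
    ) > 0.999
    valid &= inside
    if kind in ("label", "mask"):
        data = data.astype(vol.data.dtype)
        return VoxelVolume(data, vol.affine.copy(), vol.units, valid=valid)
    return VoxelVolume(data, vol.affine.copy(), vol.units, valid=valid)


def body_mask_from_magnitude(
    magnitude: VoxelVolume, threshold: float = 0.10, closing_radius: int = 2
) -> np.ndarray:
    """Body outline from a magnitude image: threshold at ``threshold`` of the
    robust (99th-percentile) maximum, keep the largest connected component,
    morphologically close with a ball of ``closing_radius`` voxels."""
    mag = np.abs(np.asarray(magnitude.data, dtype=float))
    robust = np.percentile(mag, 99)
    mask = mag >= threshold * robust
    lab, n = ndimage.label(mask)
    if n == 0:
        raise ValueError("magnitude image contains no above-threshold voxels")
    sizes = ndimage.sum_labels(np.ones_like(lab), lab, index=np.arange(1, n + 1))
    mask = lab == (1 + int(np.argmax(sizes)))
    if closing_radius > 0:
        r = closing_radius
        zz, yy, xx = np.mgrid[-r:r + 1, -r:r + 1, -r:r + 1]
        ball = (xx**2 + yy**2 + zz**2) <= r**2
        mask = ndimage.binary_closing(mask, structure=ball)
    return mask


def update_geometry_mask(
    chi_transformed: VoxelVolume,
    new_body_mask: np.ndarray,
    brain_mask: np.ndarray | None = None,
    soft_chi: float = LITERATURE_CHI_PPM["soft"],
) -> VoxelVolume:
    """Reconcile a rigidly transported χ map with the observed body outline.

    Voxels outside the new mask become air (0 ppm); voxels inside the mask
    that were air (and are not brain) take soft-tissue χ; everything else is
    unchanged.
    """
    if not np.any(new_body_mask):
        raise ValueError("empty body mask")
    chi = chi_transformed.data.copy()
    chi[~new_body_mask] = 0.0
    gained = new_body_mask & (chi_transformed.data == 0.0)
    if brain_mask is not None:
        gained &= ~brain_mask
    chi[gained] = soft_chi
    return chi_transformed.like(chi)


def predict_transformed_fm(
    ref: DecompositionResult, transform: RigidTransform
) -> PredictionReport:
    """Transport the measured reference map (shim field held fixed)."""
    if ref.b_sh is None:
        raise ValueError("reference decomposition is missing B_SH")
    moved = transform_volume(ref.measured - ref.b_sh, transform, "continuous")
    predicted = moved + ref.b_sh
    return PredictionReport(strategy="transformed", predicted=predicted)


def predict_simulated_fm(
    ref: DecompositionResult,
    chi_model: VoxelVolume,
    transform: RigidTransform,
    mask_update: np.ndarray | None = None,
    pad_factor: int = 3,
    f0: float | None = None,
    brain_mask_moved: np.ndarray | None = None,
) -> PredictionReport:
    """Re-simulate the field with the transported susceptibility model.

    ``chi_model`` is the fitted (or 3-class) χ map at the reference
    position; scanner-frame terms (B_SH, B_k, Bχ′, B0_shift) are carried
    over unchanged.  ``mask_update`` optionally supplies the body outline
    observed at the new position.
    """
    from .forward import DEFAULT_F0
    f0 = DEFAULT_F0 if f0 is None else f0
    chi_t = transform_volume(chi_model, transform, "label")
    if mask_update is not None:
        chi_t = update_geometry_mask(chi_t, mask_update, brain_mask_moved)
    b_chi = susceptibility_to_field(
        VoxelVolume(np.asarray(chi_t.data, dtype=float), chi_t.affine, "ppm"),
        pad_factor, f0,
    )
    predicted = ref.b_sh + b_chi + ref.b_k + ref.b_chi_prime + ref.b0_shift
    return PredictionReport(strategy="simulated", predicted=predicted)


def predict_combined_fm(
    ref: DecompositionResult,
    chi_model: VoxelVolume,
    mmr: VoxelVolume,
    transform: RigidTransform,
    mask_update: np.ndarray | None = None,
    pad_factor: int = 3,
    f0: float | None = None,
    brain_mask_moved: np.ndarray | None = None,
) -> PredictionReport:
    """Simulated FM plus the transported multi-model residual."""
    sim = predict_simulated_fm(
        ref, chi_model, transform, mask_update=mask_update,
        pad_factor=pad_factor, f0=f0, brain_mask_moved=brain_mask_moved,
    )
    mmr_t = transform_volume(mmr, transform, "continuous")
    predicted = sim.predicted + mmr_t
    return PredictionReport(strategy="combined", predicted=predicted)


def score_prediction(
    predicted: VoxelVolume | PredictionReport,
    measured: VoxelVolume,
    brain_mask: np.ndarray,
) -> PredictionReport:
    """RMSE and volume homogeneity (Vol.σB0) over the brain mask.

    Invalid voxels of either map are excluded from both metrics.
    """
    if isinstance(predicted, PredictionReport):
        report, pred = predicted, predicted.predicted
    else:
        report, pred = PredictionReport("custom", predicted), predicted
    if not pred.grid.same_as(measured.grid):
        raise ValueError("grid mismatch between predicted and measured maps")
    if not np.any(brain_mask):
        raise ValueError("empty brain mask")
    ok = brain_mask & pred.valid_mask() & measured.valid_mask()
    if not np.any(ok):
        raise ValueError("no jointly valid voxels inside the brain mask")
    diff = pred.data[ok] - measured.data[ok]
    report.rmse_hz = float(np.sqrt(np.mean(diff**2)))
    report.sigma_measured_hz = float(np.std(measured.data[ok]))
    report.sigma_predicted_hz = float(np.std(pred.data[ok]))
    return report
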