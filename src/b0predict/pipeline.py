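"""End-to-end orchestration of the field-prediction workflow.

``run_pipeline`` chains every stage on a seeded digital phantom:

1. simulate the phantom (reference + moved positions),
2. segment the UTE-like image (3-class and multi-class models),
3. forward-simulate the 3-class susceptibility field,
4. decompose the measured reference field map (B_k slope, lower-body
   dipole, B0 shift, SMR),
5. fit the per-(bin, VOI) susceptibility model and form the MMR,
6. predict the field at the moved position by the transformed / simulated /
   combined strategies (with optional body-mask update) and score each,
7. solve shim currents on each predicted map and cross-evaluate them on the
   measured map at the moved position.

Every intermediate volume is written with units metadata; the run report is
a JSON file of metrics (RMSE, Vol.σB0, cost traces, currents) and the log
records stage timings and seeds.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field as dc_field
from pathlib import Path

import numpy as np

from . import __version__
from .chifit import build_design_basis, compute_mmr, fit_susceptibilities, octant_vois
from .decompose import decompose_reference
from .forward import susceptibility_to_field
from .io import save_yaml, write_volume
from .motion import (
    body_mask_from_magnitude,
    predict_combined_fm,
    predict_simulated_fm,
    predict_transformed_fm,
    score_prediction,
    transform_volume,
)
from .phantom import PhantomSpec, apply_motion, generate_phantom
from .segmentation import (
    assign_literature_chi,
    fit_histogram_peaks,
    neg_log_transform,
    segment_multi_class,
    segment_three_class,
)
from .shim import (
    downsample_for_shim,
    downsample_mask,
    evaluate_shim,
    generate_coil_basis,
    solve_shim_currents,
)
from .transforms import RigidTransform
from .volume import VoxelVolume

__all__ = ["RunConfig", "run_pipeline"]

log = logging.getLogger("b0predict")


@dataclass
class RunConfig:
    """Configuration of a phantom pipeline run (round-trips through YAML)."""

    out_dir: str
    seed: int = 0
    profile: str = "default"            # "small" | "default" | "highres"
    rotations_deg: tuple = (6.0, 0.0, 0.0)
    translations_mm: tuple = (0.0, 2.0, 0.0)
    deform_neck: bool = True
    mask_update: bool = True
    strategies: tuple = ("transformed", "simulated", "combined")
    pad_factor: int = 3
    noise_sd: float = 0.0
    fit_chi: bool = True
    shim_downsample: int = 1
    write_volumes: bool = True

    def to_yaml(self, path) -> Path:
        return save_yaml(asdict(self), path)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        from .io import load_yaml

        raw = load_yaml(path)
        for key in ("rotations_deg", "translations_mm", "strategies"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def phantom_spec(self) -> PhantomSpec:
        if self.profile == "small":
            return PhantomSpec.small(seed=self.seed, noise_sd=self.noise_sd,
                                     pad_factor=self.pad_factor)
        if self.profile == "highres":
            return PhantomSpec.highres(seed=self.seed, noise_sd=self.noise_sd,
                                       pad_factor=self.pad_factor)
        return PhantomSpec(seed=self.seed, noise_sd=self.noise_sd,
                           pad_factor=self.pad_factor)


def _stage(name):
    log.info("stage %s", name)
    return time.perf_counter()


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full workflow; returns (and writes) the run report."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"version": __version__, "seed": config.seed,
                    "profile": config.profile, "stages": {}}
    t_all = time.perf_counter()

    def emit(vol, name):
        if config.write_volumes:
            write_volume(vol, out / f"{name}.nii.gz")

    try:
        # ------------------------------------------------------ 1. phantom
        t = _stage("simulate")
        spec = config.phantom_spec()
        truth = generate_phantom(spec)
        transform = RigidTransform(config.rotations_deg, config.translations_mm)
        moved = apply_motion(truth, transform, deform_neck=config.deform_neck)
        measured_ref = truth.measured_field_map()
        measured_moved = moved.measured_field_map()
        emit(truth.ute, "ute")
        emit(measured_ref, "fm_measured_ref")
        emit(measured_moved, "fm_measured_moved")
        report["stages"]["simulate"] = {"seconds": time.perf_counter() - t}

        # -------------------------------------------------- 2. segmentation
        t = _stage("segment")
        x = neg_log_transform(truth.ute)
        fit = fit_histogram_peaks(x)
        seg3 = segment_three_class(x, fit)
        segm = segment_multi_class(x, fit, truth.brain_mask)
        chi3 = assign_literature_chi(seg3)
        report["stages"]["segment"] = {
            "seconds": time.perf_counter() - t,
            "center_soft": fit.center_soft, "center_noise": fit.center_noise,
            "bone_interval": list(fit.bone_interval),
        }

        # ------------------------------------------------------- 3. forward
        t = _stage("forward")
        b_chi3 = susceptibility_to_field(chi3.chi_map(), config.pad_factor, spec.f0)
        emit(b_chi3, "b_chi_three_class")
        report["stages"]["forward"] = {"seconds": time.perf_counter() - t}

        # ----------------------------------------------------- 4. decompose
        t = _stage("decompose")
        ref = decompose_reference(
            truth.echoes, truth.components["B_SH"], b_chi3, truth.brain_mask
        )
        smr = ref.smr()
        emit(smr, "smr")
        report["stages"]["decompose"] = {
            "seconds": time.perf_counter() - t,
            "phase_slope": ref.phase_error.slope,
            "dipole_P": ref.dipole.P,
            "dipole_position": list(ref.dipole.position),
            "b0_shift_hz": ref.b0_shift,
            "fit_cost_hz": ref.fit_info["cost"],
            "smr_rmse_hz": float(np.sqrt(np.mean(smr.data[truth.brain_mask] ** 2))),
        }

        # -------------------------------------------------------- 5. chifit
        t = _stage("fit-chi")
        if config.fit_chi:
            vois = octant_vois(truth.grid, 8)
            basis = build_design_basis(
                segm, vois, truth.brain_mask, config.pad_factor, spec.f0
            )
            b_diff_m = (
                ref.measured - ref.b_sh - ref.b_chi_prime - ref.b_k - ref.b0_shift
            )
            chifit = fit_susceptibilities(b_diff_m, truth.brain_mask, basis)
            chi_model = chifit.chi_map
            simulated_ref = (
                ref.b_sh + chifit.b_chi_m + ref.b_k + ref.b_chi_prime + ref.b0_shift
            )
            report["stages"]["fit_chi"] = {
                "seconds": time.perf_counter() - t,
                "n_pairs": len(chifit.pair_chi),
                "cost_trace_hz": chifit.cost_trace,
                "active_bounds": len(chifit.active_bounds),
            }
            emit(chifit.chi_map, "chi_fitted")
        else:
            chi_model = chi3.chi_map()
            simulated_ref = ref.simulated()
            report["stages"]["fit_chi"] = {"seconds": 0.0, "skipped": True}
        mmr = compute_mmr(ref.measured, simulated_ref, truth.brain_mask)
        emit(mmr, "mmr")

        # --------------------------------------------------- 6. predictions
        t = _stage("predict")
        mask_update = (
            body_mask_from_magnitude(
                VoxelVolume(np.abs(moved.echo1), truth.grid.affine.copy())
            )
            if config.mask_update
            else None
        )
        brain_moved = transform_volume(
            VoxelVolume(truth.brain_mask.astype(np.uint8),
                        truth.grid.affine.copy()),
            transform, "mask",
        ).data.astype(bool)
        predictions = {}
        if "transformed" in config.strategies:
            predictions["transformed"] = predict_transformed_fm(ref, transform)
        if "simulated" in config.strategies:
            predictions["simulated"] = predict_simulated_fm(
                ref, chi_model, transform, mask_update=mask_update,
                pad_factor=config.pad_factor, f0=spec.f0,
                brain_mask_moved=brain_moved,
            )
        if "combined" in config.strategies:
            predictions["combined"] = predict_combined_fm(
                ref, chi_model, mmr, transform, mask_update=mask_update,
                pad_factor=config.pad_factor, f0=spec.f0,
                brain_mask_moved=brain_moved,
            )
        report["predictions"] = {}
        for name, pred in predictions.items():
            scored = score_prediction(pred, measured_moved, moved.brain_mask)
            emit(pred.predicted, f"fm_predicted_{name}")
            report["predictions"][name] = {
                "rmse_hz": scored.rmse_hz,
                "sigma_measured_hz": scored.sigma_measured_hz,
                "sigma_predicted_hz": scored.sigma_predicted_hz,
            }
        report["stages"]["predict"] = {"seconds": time.perf_counter() - t}

        # ---------------------------------------------------------- 7. shim
        t = _stage("shim")
        factor = config.shim_downsample
        target_meas = downsample_for_shim(measured_moved, factor)
        mask_ds = downsample_mask(moved.brain_mask, factor)
        system = generate_coil_basis(target_meas.grid)
        baseline = solve_shim_currents(target_meas, mask_ds, system)
        base_eval = evaluate_shim(target_meas, baseline.currents, system, mask_ds)
        report["shim"] = {
            "baseline": {
                "currents_a": baseline.currents.tolist(),
                "sigma_before_hz": base_eval.sigma_before_hz,
                "sigma_after_hz": base_eval.sigma_after_hz,
                "reduction_pct": base_eval.sigma_reduction_pct,
            }
        }
        for name, pred in predictions.items():
            target_pred = downsample_for_shim(pred.predicted, factor)
            solved = solve_shim_currents(target_pred, mask_ds, system)
            crossed = evaluate_shim(target_meas, solved.currents, system, mask_ds)
            report["shim"][name] = {
                "currents_a": solved.currents.tolist(),
                "sigma_after_hz": crossed.sigma_after_hz,
                "reduction_pct": crossed.sigma_reduction_pct,
            }
        report["stages"]["shim"] = {"seconds": time.perf_counter() - t}
    except Exception as exc:
        report["error"] = {"stage": _last_stage(report), "message": str(exc)}
        (out / "report.json").write_text(json.dumps(report, indent=1))
        raise

    report["total_seconds"] = time.perf_counter() - t_all
    (out / "report.json").write_text(json.dumps(report, indent=1))
    config.to_yaml(out / "config.yaml")
    return report


def _last_stage(report: dict) -> str:
    stages = list(report.get("stages", {}))
    return stages[-1] if stages else "simulate"
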