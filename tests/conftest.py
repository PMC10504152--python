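"""Shared fixtures: one seeded compact phantom and its derived products.

The expensive stages (phantom simulation, multi-class design basis) are
session-scoped so every test file works on the same deterministic head.
"""

from __future__ import annotations

import numpy as np
import pytest

import b0predict as bp
from b0predict.chifit import build_design_basis, octant_vois
from b0predict.segmentation import (
    assign_literature_chi,
    fit_histogram_peaks,
    neg_log_transform,
    segment_multi_class,
    segment_three_class,
)

SEED = 42


@pytest.fixture(scope="session")
def spec():
    return bp.PhantomSpec.small(seed=SEED)


@pytest.fixture(scope="session")
def truth(spec):
    return bp.generate_phantom(spec)


@pytest.fixture(scope="session")
def neglog(truth):
    return neg_log_transform(truth.ute)


@pytest.fixture(scope="session")
def hist_fit(neglog):
    return fit_histogram_peaks(neglog)


@pytest.fixture(scope="session")
def seg3(neglog, hist_fit):
    return segment_three_class(neglog, hist_fit)


@pytest.fixture(scope="session")
def chi3(seg3):
    return assign_literature_chi(seg3)


@pytest.fixture(scope="session")
def b_chi3(chi3, spec):
    return bp.susceptibility_to_field(chi3.chi_map(), spec.pad_factor, spec.f0)


@pytest.fixture(scope="session")
def ref_decomp(truth, b_chi3):
    return bp.decompose_reference(
        truth.echoes, truth.components["B_SH"], b_chi3, truth.brain_mask
    )


@pytest.fixture(scope="session")
def seg_multi(neglog, hist_fit, truth):
    return segment_multi_class(neglog, hist_fit, truth.brain_mask)


@pytest.fixture(scope="session")
def vois8(truth):
    return octant_vois(truth.grid, 8)


@pytest.fixture(scope="session")
def multi_basis(seg_multi, vois8, truth, spec):
    return build_design_basis(
        seg_multi, vois8, truth.brain_mask, spec.pad_factor, spec.f0
    )


@pytest.fixture(scope="session")
def truth_decomp(truth):
    """Decomposition assembled from the phantom's exact components."""
    from b0predict.decompose import DecompositionResult

    return DecompositionResult(
        measured=truth.measured_field_map(),
        b_sh=truth.components["B_SH"],
        b_chi=truth.components["B_chi"],
        b_k=truth.components["B_k"],
        b_chi_prime=truth.components["B_chi_prime"],
        b0_shift=float(truth.components["B0_shift"].data[0, 0, 0]),
        brain_mask=truth.brain_mask,
    )
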