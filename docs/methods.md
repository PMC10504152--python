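# Methods

This note records the model, the numerical choices, and what the synthetic
phantom does and does not establish.

## Field decomposition

The off-resonance field over the head is treated as the superposition
`ΔB0 = B_SH + Bχ + B_k + Bχ′ + B0_shift`. Chemical-shift contributions are
deliberately outside the model: all brain tissue is treated as water-like,
so fat-shifted voxels would appear in the residual maps.

**B_SH.** Real solid harmonics up to 2nd order, evaluated at scanner-frame
world coordinates in mm: basis `{1, x, y, z, 2z²−x²−y², zx, zy, x²−y², xy}`
with coefficient units Hz, Hz/mm and Hz/mm². The basis is unnormalised and
documented here precisely because vendor conventions differ; coefficients
from a scanner must be converted to this convention by the caller. Each
order-2 term is (discretely) harmonic, which the tests verify via a
second-difference Laplacian.

**Bχ (Fourier dipole approximation).** In k-space the z-field response of a
unit susceptibility distribution, including the Lorentz-sphere correction,
is `D(k) = 1/3 − k_z²/k²`. The field is `f0·10⁻⁶·F⁻¹{D·F{χ}}` with χ in ppm
and f0 the Larmor frequency (default 123.2 MHz, i.e. 3 T; configurable).
Numerical choices:

* `D(0) = 0`. The kernel is singular at k = 0; setting the DC term to zero
  makes the synthesised field mean-free over the padded volume. Any
  physical constant is indistinguishable from the scanner frequency offset
  and is absorbed by the fitted `B0_shift`.
* Zero-padding by an integer factor (default 3 per axis, centred) before
  the FFT. The DFT is periodic, so without padding the dipole tails of the
  head alias into the opposite side of the volume; the tests show the
  analytic-sphere error decreasing monotonically over pad ∈ {1, 2, 3}.
* Frequency lattice `k_i = n_i/(N_i·Δ_i)` per axis, so voxel anisotropy
  enters only through the frequency spacing; the kernel is dimensionless.
* Real-input FFTs (`rfftn`/`irfftn`): χ is real and D is even, so the field
  is exactly real by construction.

Accuracy anchors (recomputed by `scripts/acceptance.py`): for a uniform
sphere of Δχ = 9.6 ppm (radius 8 voxels on a 64³, 1 mm grid, pad 3) the
external on-axis field matches `(Δχ/3)(a/r)³(3cos²θ−1)f0·10⁻⁶` to ~1.7% at
r ≥ 2a, and the interior — whose true value under the Lorentz-corrected
kernel is exactly zero — is flat to ~0.3% of the Δχ·f0 scale. On a 16³
random χ map the FFT route equals a direct-space periodic convolution with
the lattice impulse response to ~10⁻¹⁵ relative.

**B_k.** Gradient/eddy imperfections during the dual-echo acquisition shift
the k-space centre along the first phase-encoding axis (y) in proportion to
echo time, `Δk_n = −a·t_n` with zero intercept (no shift at t = 0). The
shift of each demodulated echo is measured as the phase of the lag-1
spatial autocorrelation along y, which by the shift theorem is the
k-space-energy-weighted mean phase increment — exact for a pure linear
ramp irrespective of object structure, which is why it meets a 1% slope
tolerance where sub-sample peak interpolation on the k-space profile would
not. The slope is fitted through the origin over both echoes, and re-emitted
as the linear field `B_k(y) = −a·(y_idx − y_c)/N_y` Hz, zero at the FOV
centre. Known fields (shim + head susceptibility) are demodulated first; the
residual lower-body gradient leaves a sub-percent bias that the dipole fit
largely absorbs.

**Bχ′ + B0_shift.** One axial point dipole `P/|d|³·(3(d·ẑ/|d|)²−1)` with P
in Hz·mm³ (distances in mm — the unit convention of this package) plus a
constant offset, fitted to `B_diff = measured − B_SH − Bχ − B_k` over the
brain mask by RMSE. Because a far dipole trades off strength against depth,
the Nelder–Mead simplex refinement is seeded by a coarse 5×5×5 position
grid (half-extent 120 mm, centred 100 mm inferior to the FOV) at which
(P, offset) are solved in closed form. The dipole singularity is clipped at
half a voxel. On noiseless generative fields the recovery is exact to
optimizer tolerance (≪ 2% in P, ≪ 1 voxel in position).

**Residual maps.** `SMR = measured − (all five terms)` with the 3-class
susceptibility model; `MMR` is the same with the fitted multi-class model.
Both are identities by definition; their RMSE measures what the
susceptibility model cannot explain. With the exact phantom χ the SMR RMSE
is ~0.02 Hz (0.1% of Vol.σB0), limited by the B_k/dipole estimator
cross-talk described above.

## Segmentation

The UTE-like image is normalised as `x = −log(I/I_max)` after flooring
intensities at the 0.01 percentile of nonzero voxels (avoids log 0; the
floor is a choice, not physics). The histogram (256 bins, 5-bin moving
average) is scanned for its two dominant modes; a candidate peak is
accepted only if it carries at least 5% of the maximum count and is
separated from already-accepted peaks by ≥ 10 bins *and* by a valley deeper
than half the lower peak — without the valley rule, Poisson shoulders of
the broad air peak can masquerade as a second mode. Each peak is fitted by
least squares with a Gaussian over ± half the inter-peak distance;
FWHM = 2√(2 ln 2)·σ. Soft tissue is the *left* peak by position, never by
height.

Thresholds: bone occupies `[c_soft + 1.4·FWHM_soft, c_noise −
1.4·FWHM_noise]`; the multi-class model bins non-brain voxels over
`[c_soft − 1.4·FWHM_soft, c_noise]` with width 0.1 (below-interval → soft,
above-interval → air). Brain-mask voxels are fixed at soft-tissue χ
(−9.6 ppm); literature values are air 0 (reference), bone −11.4, soft
−9.6 ppm. Intermediate tissues without a printed literature value (muscle
in the neck) are treated as soft tissue.

## Susceptibility fitting

Because Bχ is linear in χ, fitting one value per (intensity bin, VOI) pair
is posed as *bounded linear least squares* over precomputed unit-response
fields (1 ppm on each pair's voxels, evaluated inside the brain mask),
rather than a generic nonlinear search — same optimum, deterministic, and
orders of magnitude faster. Bounds [−14, 1] ppm; initial values on a linear
ramp over [−12, 0] ppm matched to the bins (more air-like intensity →
higher χ). Fixed classes (brain, clear soft tissue, clear air) contribute a
constant field that is subtracted from the target first. Pairs with fewer
than 5 voxels are merged into the nearest populated bin of the same VOI
(single-voxel classes are noise-dominated). Rank deficiency is flagged; the
BVLS solver provides minimum-norm behaviour. The reported cost trace
(initial, final) is non-increasing by construction, and the fit never
returns a solution worse than its initialisation.

VOIs for phantoms are the eight world-coordinate octants (axis-aligned
boxes); anatomical VOI drawing is out of scope. The nested-model property —
8 VOIs strictly beat 1 VOI whenever the true χ of a bin differs between
regions — is asserted in the tests.

## Motion prediction

Rigid transforms use intrinsic rotations `R = R_x·R_y·R_z` about the
scanner axes through the volume centre, then translation; external 6-DOF
estimates must be converted to this convention. χ maps and masks are
transported with nearest-neighbour interpolation (no invented interface
susceptibilities), continuous maps trilinearly; voxels transported from
outside the support become air (χ) or invalid (field maps).

Strategies: *transformed FM* `T(measured − B_SH) + B_SH` (the shim field
does not move with the head); *simulated FM* `B_SH + forward(T(χ)) + B_k +
Bχ′ + B0_shift` (scanner-frame terms carried over unchanged, including the
reference B0_shift — the frequency adjust is not re-run after motion);
*combined FM* adds `T(MMR)` and therefore equals the measured map exactly
at the identity transform. For large motion the transported model is
reconciled with a body mask computed from the new-position magnitude image
(threshold 10% of the robust maximum, largest connected component,
morphological closing with a 2-voxel ball): voxels leaving the mask become
air, newly covered non-brain voxels become soft tissue.

Scoring: RMSE and Vol.σB0 (SD) over the brain mask, excluding invalid
voxels of either map.

## Shimming

The 16-coil array solve minimises `Σ_mask (B0 − Σ c_i·basis_i)²` subject to
|c_i| ≤ 4 A and Σ|c_i| ≤ 50 A (the total limit is read as a sum of
magnitudes). The absolute values are linearised by current splitting
`c = c⁺ − c⁻`, giving a smooth convex QP solved by SLSQP with an analytic
gradient, the objective normalised by ‖b‖² and warm-started from the
box-projected unconstrained solution; the zero-current point is always
feasible, so the residual SD can never exceed the unshimmed SD, and the
returned solution is never worse than the warm start. The global frequency
offset is *not* a shim channel: constants are projected out of both the
target and the coil responses (the joint optimum over currents and offset),
and the removed offset is reported.

The synthetic array places 16 radially-oriented point-dipole coils on two
staggered 8-coil rings (radius 160 mm) around the head — harmonic inside
the FOV like measured coil maps, deterministic given its parameters. Cost
evaluation uses a 2 mm working grid; finer maps are block-mean downsampled
with invalid-voxel exclusion. Cross-evaluation applies currents solved on a
*predicted* map to the *measured* map, mirroring the situation where no
field map can be acquired after motion.

## The phantom, and what the tests do (and do not) show

The phantom is analytic geometry (head ellipsoid, skull shell, brain
ellipsoid, four spherical cavities, neck cylinder, optional posterior neck
bulge) rasterised on a seeded grid. Default profiles: 64³ at 2 mm, a 48³ at
2 mm compact profile used for test sweeps, and 128³ at 1.5 mm for
high-resolution runs — desk-scale choices; sub-millimetre sampling is
supported but not the default. Measurements are simulated forward:
per-class Gaussian −log-intensities for the UTE image (bimodal by
construction), complex dual-echo GRE signal whose phase carries the total
field plus the B_k ramp, circular Gaussian noise, echo times 2.68/7.49 ms.
The constant field component mimics the frequency adjustment by driving the
reference brain-mean field to a small set-point (5 Hz), exactly as a
scanner would; under motion that constant is carried over unchanged.

At 3 T with these echo times, tissue next to air cavities exceeds the
±1/(2·ΔTE) ≈ ±104 Hz phase-difference range and wraps — as in vivo. No
spatial unwrapping is attempted; the default geometry keeps the entire
brain well inside the unwrapped range (|field| ≲ 45 Hz, Vol.σB0 ≈ 17 Hz,
comparable to measured heads), and the zero-noise additivity invariant is
asserted on the ~84% of body voxels below the aliasing limit.

Moved phantoms are re-rasterised analytically at the new pose (exact ground
truth, no resampling); the neck deformation is a posterior bulge whose
magnitude is a free design parameter, not an estimate of any in-vivo
effect. What the phantom does **not** emulate: anatomical detail (no
atlas), partial-volume mixing beyond rasterisation, receive-coil or RF
effects, physiological noise/drift, chemical shift, eddy currents beyond
the linear B_k term, and non-rigid motion beyond the single bulge. Passing
tests therefore demonstrate the *self-consistency and numerical
correctness* of the pipeline and the relative ordering of the prediction
strategies under controlled geometry changes — not in-vivo accuracy.

## Known limitations

* The dipole (P, r_d) pair is weakly identifiable from a shallow FOV; only
  its field over the brain is well determined. Reported parameters should
  be read as an effective source.
* The B_k estimator measures a single global k_y shift; shifts along the
  partition axis, if present, fold into the residual maps.
* Susceptibility fitting is per-(bin, VOI), not voxel-wise; intra-bin
  variation lands in the MMR.
* Whether the scanner re-estimates the frequency offset after motion is
  site-dependent; this package carries the reference value forward.
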