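"""Threshold-based tissue segmentation of a UTE-like magnitude image.

Short-T2 (UTE) proton-density images show bone at intermediate intensity
between bright soft tissue and dark air, so the head can be segmented by
thresholds on x = −log(I/I_max): the histogram of x is bimodal with a
soft-tissue peak at small x and an air/noise peak at large x, and bone
spreads in between.  Two models are built:

* a 3-class model (air / bone / soft tissue) with the bone interval
  [center_soft + 1.4·FWHM_soft, center_noise − 1.4·FWHM_noise];
* a multi-class model in which voxels outside the brain mask are binned by
  x over [center_soft − 1.4·FWHM_soft, center_noise] with bin width 0.1
  (voxels below the interval count as soft tissue, above it as air), while
  brain-mask voxels form one fixed class.

Literature susceptibilities (ppm): air 0 (reference), bone −11.4, soft
tissue −9.6; the brain class takes the soft-tissue value.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .volume import VoxelVolume

__all__ = [
    "HistogramFit", "SegmentationModel", "SusceptibilityModel",
    "neg_log_transform", "fit_histogram_peaks",
    "segment_three_class", "segment_multi_class", "assign_literature_chi",
    "LITERATURE_CHI_PPM", "BIN_WIDTH", "FWHM_FACTOR",
]

LITERATURE_CHI_PPM = {"air": 0.0, "bone": -11.4, "soft": -9.6, "brain": -9.6}
BIN_WIDTH = 0.1          # multi-class bin width in −log-intensity units
FWHM_FACTOR = 1.4        # threshold distance from each peak centre

GAUSS_TO_FWHM = 2.0 * np.sqrt(2.0 * np.log(2.0))   # 2.3548·σ

# three-class label codes; multi-class bins start at BIN0
L_AIR, L_SOFT, L_BONE, L_BRAIN = 0, 1, 2, 3
BIN0 = 10


@dataclass
class HistogramFit:
    """Two-Gaussian fit of the −log(UTE) histogram."""

    center_soft: float
    fwhm_soft: float
    center_noise: float
    fwhm_noise: float
    bin_edges: np.ndarray
    counts: np.ndarray

    def __post_init__(self):
        if not (self.center_soft < self.center_noise):
            raise ValueError("soft-tissue peak must lie left of the noise peak")
        if self.fwhm_soft <= 0 or self.fwhm_noise <= 0:
            raise ValueError("peak FWHM must be positive")

    @property
    def bone_interval(self) -> tuple[float, float]:
        return (
            self.center_soft + FWHM_FACTOR * self.fwhm_soft,
            self.center_noise - FWHM_FACTOR * self.fwhm_noise,
        )

    @property
    def multi_interval(self) -> tuple[float, float]:
        return (self.center_soft - FWHM_FACTOR * self.fwhm_soft, self.center_noise)


@dataclass
class SegmentationModel:
    """Label volume plus the class table that interprets it."""

    mode: str                     # "three_class" | "multi_class"
    labels: np.ndarray
    affine: np.ndarray
    classes: dict                 # label → description
    bone_interval: tuple | None = None
    bin_edges: np.ndarray | None = None   # multi-class bin edges in x

    def class_counts(self) -> dict:
        labs, counts = np.unique(self.labels, return_counts=True)
        return {int(l): int(c) for l, c in zip(labs, counts)}


@dataclass
class SusceptibilityModel:
    """Label volume + per-class χ (ppm) + body mask."""

    labels: np.ndarray
    chi_per_class: dict           # label → ppm
    affine: np.ndarray
    body_mask: np.ndarray

    def chi_map(self) -> VoxelVolume:
        out = np.zeros(self.labels.shape, dtype=float)
        for lab, chi in self.chi_per_class.items():
            out[self.labels == lab] = chi
        return VoxelVolume(out, self.affine.copy(), units="ppm")


def neg_log_transform(ute: VoxelVolume, floor_percentile: float = 0.01) -> VoxelVolume:
    """x = −log(I / I_max), with intensities floored at the
    ``floor_percentile`` percentile of the nonzero voxels to avoid log(0)."""
    data = np.asarray(ute.data, dtype=float)
    nonzero = data[data > 0]
    if nonzero.size == 0:
        raise ValueError("all-zero image: cannot take a logarithm")
    floor = np.percentile(nonzero, floor_percentile)
    clipped = np.clip(data, floor, None)
    x = -np.log(clipped / clipped.max())
    return ute.like(x, units="1")


def _gauss(x, amp, mu, sigma):
    return amp * np.exp(-((x - mu) ** 2) / (2.0 * sigma**2))


def fit_histogram_peaks(
    x: VoxelVolume, nbins: int = 256, min_separation_bins: int = 10
) -> HistogramFit:
    """Locate and Gaussian-fit the soft-tissue and noise peaks of the
    −log-intensity histogram.

    The histogram is lightly smoothed (5-bin moving average); the two
    highest local maxima separated by at least ``min_separation_bins`` are
    taken as peaks (the left one is soft tissue, by position not height) and
    each is fitted by least squares over ± half the inter-peak distance.
    """
    data = np.asarray(x.data, dtype=float).ravel()
    counts, edges = np.histogram(data, bins=nbins)
    centers = 0.5 * (edges[:-1] + edges[1:])
    smooth = np.convolve(counts.astype(float), np.ones(5) / 5.0, mode="same")

    interior = smooth[1:-1]
    is_max = (interior >= smooth[:-2]) & (interior >= smooth[2:]) & (interior > 0)
    peak_idx = np.nonzero(is_max)[0] + 1
    # a genuine tissue peak carries real mass; drop noise blips in the tails
    peak_idx = peak_idx[smooth[peak_idx] >= 0.05 * smooth.max()]
    peak_idx = peak_idx[np.argsort(smooth[peak_idx])[::-1]]

    # accept a second peak only if a genuine valley separates it from every
    # already-accepted peak (guards against shoulders of one broad mode)
    chosen: list[int] = []
    for idx in peak_idx:
        ok = all(abs(idx - c) >= min_separation_bins for c in chosen)
        for c in chosen:
            lo_i, hi_i = sorted((int(idx), c))
            valley = smooth[lo_i : hi_i + 1].min()
            if valley > 0.5 * min(smooth[idx], smooth[c]):
                ok = False
        if ok:
            chosen.append(int(idx))
        if len(chosen) == 2:
            break
    if len(chosen) < 2:
        raise ValueError("histogram not bimodal: fewer than two separated peaks")
    chosen.sort()
    half_dist = (chosen[1] - chosen[0]) // 2

    fits = []
    for idx in chosen:
        lo = max(0, idx - half_dist)
        hi = min(nbins, idx + half_dist + 1)
        xs, ys = centers[lo:hi], smooth[lo:hi]
        sigma0 = max((centers[1] - centers[0]) * 2, np.std(xs) / 2)
        try:
            popt, _ = curve_fit(
                _gauss, xs, ys, p0=(smooth[idx], centers[idx], sigma0),
                maxfev=10000,
            )
        except RuntimeError as exc:   # pragma: no cover - degenerate histograms
            raise ValueError(f"Gaussian peak fit failed: {exc}") from exc
        fits.append((popt[1], abs(popt[2]) * GAUSS_TO_FWHM))

    (mu_s, fwhm_s), (mu_n, fwhm_n) = fits
    return HistogramFit(
        center_soft=float(mu_s), fwhm_soft=float(fwhm_s),
        center_noise=float(mu_n), fwhm_noise=float(fwhm_n),
        bin_edges=edges, counts=counts,
    )


def segment_three_class(x: VoxelVolume, fit: HistogramFit) -> SegmentationModel:
    """Air / bone / soft-tissue labels from the bone intensity interval."""
    lo, hi = fit.bone_interval
    if not lo < hi:
        raise ValueError(
            "bone interval is inverted: soft-tissue and noise peaks overlap"
        )
    data = x.data
    labels = np.full(data.shape, L_BONE, dtype=np.int16)
    labels[data < lo] = L_SOFT
    labels[data > hi] = L_AIR
    return SegmentationModel(
        mode="three_class", labels=labels, affine=x.affine.copy(),
        classes={L_AIR: "air", L_SOFT: "soft", L_BONE: "bone"},
        bone_interval=(lo, hi),
    )


def segment_multi_class(
    x: VoxelVolume, fit: HistogramFit, brain_mask: np.ndarray
) -> SegmentationModel:
    """Multiple-segment model: brain fixed, non-brain voxels binned by x.

    Bins of width 0.1 tile [center_soft − 1.4·FWHM_soft, center_noise];
    voxels below the interval are soft tissue, above it air.
    """
    if not np.any(brain_mask):
        warnings.warn("empty brain mask: every voxel will be intensity-binned",
                      RuntimeWarning)
    lo, hi = fit.multi_interval
    n_bins = int(np.ceil((hi - lo) / BIN_WIDTH - 1e-9))
    edges = lo + BIN_WIDTH * np.arange(n_bins + 1)

    data = x.data
    labels = np.full(data.shape, L_SOFT, dtype=np.int16)
    bin_idx = np.floor((data - lo) / BIN_WIDTH).astype(int)
    in_interval = (data >= lo) & (bin_idx < n_bins)
    labels[in_interval] = BIN0 + bin_idx[in_interval]
    labels[data >= edges[-1]] = L_AIR
    labels[brain_mask] = L_BRAIN

    classes = {L_AIR: "air", L_SOFT: "soft", L_BRAIN: "brain"}
    for b in range(n_bins):
        classes[BIN0 + b] = f"bin[{edges[b]:.2f},{edges[b + 1]:.2f})"
    return SegmentationModel(
        mode="multi_class", labels=labels, affine=x.affine.copy(),
        classes=classes, bin_edges=edges,
    )


def assign_literature_chi(model: SegmentationModel) -> SusceptibilityModel:
    """Literature χ values (ppm) for a 3-class model (brain allowed too)."""
    chi = {}
    for lab, name in model.classes.items():
        if name not in LITERATURE_CHI_PPM:
            raise ValueError(f"no literature susceptibility for class {name!r}")
        chi[lab] = LITERATURE_CHI_PPM[name]
    body = np.isin(model.labels, [l for l, n in model.classes.items() if n != "air"])
    return SusceptibilityModel(
        labels=model.labels.copy(), chi_per_class=chi,
        affine=model.affine.copy(), body_mask=body,
    )
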