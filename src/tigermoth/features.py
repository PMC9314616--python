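"""Colour, pattern (granularity), luminance and allometry metrics.

Turns calibrated multichannel specimen images with ROI masks into the
feature set used for genotype discrimination:

* per-ROI mean reflectance in the uv/sw/mw/lw camera channels and ROI
  area in pixels;
* a granularity spectrum — the energy of the long-wave (luminance)
  channel in a geometric series of spatial-frequency band-pass filters
  (default scales 2 px to 100 px in steps of x1.414) — summarised as
  pattern dominance (maxPower), diversity (propPower), marking size
  (maxFreq) and pattern contrast;
* a 20-band luminance histogram over the 0-65535 dynamic range;
* allometric area ratios FW/AB, FW/TH, FW/HW, TH/AB;

plus a greedy |r| >= threshold correlation filter over the resulting
feature table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .specimen import CHANNELS, ROI_NAMES, MultichannelSpecimen

__all__ = [
    "GranularitySpectrum",
    "calibrate_reflectance",
    "roi_colour_means",
    "granularity_bands",
    "granularity_spectrum",
    "pattern_summaries",
    "luminance_band_histogram",
    "allometric_ratios",
    "build_feature_table",
    "drop_correlated_features",
    "RATIO_PAIRS",
]

#: Allometric ratios computed from ROI areas (numerator, denominator).
RATIO_PAIRS = (("FW", "AB"), ("FW", "TH"), ("FW", "HW"), ("TH", "AB"))


def calibrate_reflectance(raw: np.ndarray, dark_std_response: float,
                          bright_std_response: float) -> np.ndarray:
    """Map raw camera responses to reflectance via two grey standards.

    The affine map sends the dark standard's response to 0.07 and the
    bright standard's to 0.93 (standards reflecting 7% and 93% across
    the camera's spectral range); output is clipped to [0, 1].
    """
    dark, bright = float(dark_std_response), float(bright_std_response)
    if bright <= dark:
        raise ValueError("bright standard response must exceed dark standard response")
    out = 0.07 + (np.asarray(raw, dtype=float) - dark) * (0.93 - 0.07) / (bright - dark)
    return np.clip(out, 0.0, 1.0)


def roi_colour_means(spec: MultichannelSpecimen, roi: str) -> tuple[dict[str, float], int]:
    """Mean reflectance per channel over one ROI, plus its area in pixels."""
    sel = spec.roi_pixels(roi)
    area = int(sel.sum())
    if area == 0:
        raise ValueError(f"specimen {spec.id}: ROI {roi} is empty")
    means = {c: float(spec.channels[c][sel].mean()) for c in CHANNELS}
    return means, area


def granularity_bands(start: float = 2.0, end: float = 100.0,
                      factor: float = 1.414) -> np.ndarray:
    """Geometric series of band scales s_k = start * factor**k with s_k <= end."""
    if start < 1 or factor <= 1:
        raise ValueError("need start >= 1 and factor > 1")
    scales = []
    s = float(start)
    while s <= end * (1 + 1e-12):
        scales.append(s)
        s *= factor
    return np.asarray(scales)


@dataclass
class GranularitySpectrum:
    """Band-pass energy of one ROI at a geometric series of spatial scales."""

    scales: np.ndarray
    energies: np.ndarray

    def __post_init__(self) -> None:
        self.scales = np.asarray(self.scales, dtype=float)
        self.energies = np.asarray(self.energies, dtype=float)
        if self.scales.ndim != 1 or self.scales.shape != self.energies.shape:
            raise ValueError("scales and energies must be matching 1-D arrays")
        if np.any(np.diff(self.scales) <= 0):
            raise ValueError("scales must be strictly increasing")
        if np.any(self.energies < -1e-12):
            raise ValueError("energies must be non-negative")


def bandpass_filters(shape: tuple[int, int], scales: np.ndarray,
                     factor: float | None = None) -> np.ndarray:
    """Radial log-frequency band-pass filters, one per scale.

    A band at scale ``s`` passes Fourier components of wavelength ``s``
    px at unit gain and crossfades to zero at the adjacent band centres
    with a raised-cosine (Hann) profile in log-frequency, so adjacent
    bands partition energy smoothly and the DC component is always
    excluded.  Returns an array ``(n_bands, h, w)`` of gains on the
    unshifted FFT grid.
    """
    h, w = shape
    fy = np.fft.fftfreq(h)[:, None]
    fx = np.fft.fftfreq(w)[None, :]
    r = np.hypot(fy, fx)
    scales = np.asarray(scales, dtype=float)
    if factor is None:
        factor = scales[1] / scales[0] if len(scales) > 1 else 1.414
    delta = np.log(factor)
    with np.errstate(divide="ignore"):
        logr = np.where(r > 0, np.log(r), -np.inf)
    H = np.zeros((len(scales), h, w))
    for k, s in enumerate(scales):
        d = logr - np.log(1.0 / s)
        inside = np.abs(d) < delta
        H[k][inside] = np.cos(0.5 * np.pi * d[inside] / delta) ** 2
    return H


def granularity_spectrum(spec: MultichannelSpecimen, roi: str,
                         scales: np.ndarray | None = None,
                         channel: str = "lw") -> GranularitySpectrum:
    """Granularity spectrum of one ROI.

    The luminance (default long-wave) channel is cropped to the ROI
    bounding box with non-ROI pixels replaced by the ROI mean (so the
    mask edge contributes no spurious energy), band-pass filtered in the
    Fourier domain at each scale, and each band's energy taken as the
    standard deviation of the filtered values over the ROI pixels.
    """
    if scales is None:
        scales = granularity_bands()
    sel = spec.roi_pixels(roi)
    if not sel.any():
        raise ValueError(f"specimen {spec.id}: ROI {roi} is empty")
    rows = np.flatnonzero(sel.any(axis=1))
    cols = np.flatnonzero(sel.any(axis=0))
    box = (slice(rows[0], rows[-1] + 1), slice(cols[0], cols[-1] + 1))
    img = np.array(spec.channels[channel][box], dtype=float)
    inroi = sel[box]
    mean = img[inroi].mean()
    img[~inroi] = mean
    if min(img.shape) < 2 * scales[-1]:
        warnings.warn(
            f"ROI {roi} bounding box {img.shape} is smaller than twice the largest "
            f"band scale {scales[-1]:.0f}px; large-scale energies are unreliable",
            stacklevel=2,
        )
    H = bandpass_filters(img.shape, scales)
    F = np.fft.fft2(img)
    energies = np.empty(len(scales))
    for k in range(len(scales)):
        filtered = np.fft.ifft2(F * H[k]).real
        energies[k] = filtered[inroi].std()
    return GranularitySpectrum(scales, energies)


def pattern_summaries(gs: GranularitySpectrum) -> dict:
    """Summarise a granularity spectrum.

    dominance (maxPower) is the peak band energy; diversity (propPower)
    the peak energy divided by the summed energy; marking size (maxFreq)
    the scale of the peak band (ties broken toward the smallest scale
    and flagged); pattern contrast the root of the summed squared
    energies.  An all-zero spectrum gets diversity 0 with a flag.
    """
    if len(gs.energies) == 0:
        raise ValueError("empty granularity spectrum")
    flags = []
    e = gs.energies
    total = e.sum()
    peak = int(np.argmax(e))  # argmax takes the first (smallest-scale) maximum
    if np.sum(np.isclose(e, e[peak])) > 1:
        flags.append("marking_size_tie")
    if total <= 0:
        diversity = 0.0
        flags.append("zero_spectrum")
    else:
        diversity = float(e[peak] / total)
    return dict(
        dominance=float(e[peak]),
        diversity=diversity,
        marking_size=float(gs.scales[peak]),
        pattern_contrast=float(np.sqrt(np.sum(e**2))),
        flags=flags,
    )


def luminance_band_histogram(spec: MultichannelSpecimen, roi: str,
                             n_bands: int = 20, max_value: float = 65535.0) -> np.ndarray:
    """Proportion of ROI pixels in each of ``n_bands`` equal luminance bands.

    Luminance is the long-wave channel rescaled to [0, ``max_value``]
    (the dynamic-range anchor of a 16-bit-per-channel TIFF); the last
    band includes its right edge.  Proportions sum to 1.
    """
    sel = spec.roi_pixels(roi)
    if not sel.any():
        raise ValueError(f"specimen {spec.id}: ROI {roi} is empty")
    lum = spec.channels["lw"][sel] * max_value
    counts, _ = np.histogram(lum, bins=np.linspace(0.0, max_value, n_bands + 1))
    return counts / counts.sum()


def allometric_ratios(areas: dict[str, float]) -> dict[str, float]:
    """Area ratios FW/AB, FW/TH, FW/HW and TH/AB from per-ROI pixel areas."""
    for roi in ROI_NAMES:
        if areas.get(roi, 0) <= 0:
            raise ValueError(f"ROI {roi} has non-positive area")
    return {f"{a}_{b}": float(areas[a]) / float(areas[b]) for a, b in RATIO_PAIRS}


def build_feature_table(cohort: list[MultichannelSpecimen],
                        scales: np.ndarray | None = None,
                        include_luminance: bool = False) -> pd.DataFrame:
    """Feature table: one row per specimen, columns named ``ROI_metric``.

    Per ROI: area, the four channel means, and the four pattern
    summaries; plus the four allometric ratios.  The 20-band luminance
    histogram is computed on request (``include_luminance``) but is not
    part of the default discriminant feature set.  Per-specimen failures
    are caught and flagged in a ``failed`` column rather than aborting
    the cohort.
    """
    if scales is None:
        scales = granularity_bands()
    rows = []
    for spec in cohort:
        row: dict = {"id": spec.id}
        for k, v in spec.meta.items():
            if np.isscalar(v):
                row[k] = v
        try:
            areas = {}
            for roi in ROI_NAMES:
                means, area = roi_colour_means(spec, roi)
                areas[roi] = area
                row[f"{roi}_area"] = area
                for ch in CHANNELS:
                    row[f"{roi}_{ch}"] = means[ch]
                summ = pattern_summaries(granularity_spectrum(spec, roi, scales))
                row[f"{roi}_pattern_dominance"] = summ["dominance"]
                row[f"{roi}_pattern_diversity"] = summ["diversity"]
                row[f"{roi}_marking_size"] = summ["marking_size"]
                row[f"{roi}_pattern_contrast"] = summ["pattern_contrast"]
                if include_luminance:
                    props = luminance_band_histogram(spec, roi)
                    for b, p in enumerate(props):
                        row[f"{roi}_lum_{b:02d}"] = p
            for name, val in allometric_ratios(areas).items():
                row[f"ratio_{name}"] = val
            row["failed"] = False
        except ValueError as err:
            row["failed"] = True
            row["failure"] = str(err)
        rows.append(row)
    return pd.DataFrame(rows)


def drop_correlated_features(table: pd.DataFrame, threshold: float = 0.9
                             ) -> tuple[list[str], list[dict]]:
    """Greedy correlation filter over numeric feature columns.

    Zero-variance columns are dropped first.  Then, while any pair of
    remaining columns has ``|r| >= threshold``, the member of the
    worst-correlated pair with the larger mean absolute correlation to
    all other remaining columns is dropped (ties broken toward the
    later column, so the order is deterministic).  Returns the retained
    column list and a report of drops with reasons.
    """
    if len(table) < 2:
        raise ValueError("need at least two rows to estimate correlations")
    num = table.select_dtypes(include=[np.number])
    report: list[dict] = []
    keep = []
    for c in num.columns:
        if num[c].std(ddof=0) == 0:
            report.append(dict(column=c, reason="zero variance", partner=None))
        else:
            keep.append(c)
    while len(keep) > 1:
        corr = num[keep].corr().abs().to_numpy()
        np.fill_diagonal(corr, 0.0)
        i, j = np.unravel_index(np.argmax(corr), corr.shape)
        if corr[i, j] < threshold:
            break
        mean_i = corr[i].mean()
        mean_j = corr[j].mean()
        drop_idx = j if (mean_j > mean_i or np.isclose(mean_i, mean_j)) else i
        other_idx = i if drop_idx == j else j
        report.append(dict(column=keep[drop_idx], reason=f"|r|={corr[i, j]:.3f}>= {threshold}",
                           partner=keep[other_idx]))
        keep.pop(drop_idx)
    return keep, report
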