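"""Perforant-pathway synaptic relative immunointensity ratio (RIR).

Synapses of the entorhinal→dentate perforant pathway terminate in the outer
molecular layer of the dentate gyrus; the inner molecular layer is
relatively spared in Alzheimer's disease. The RIR compares synaptophysin
staining of the two layers on an 8-bit intensity scale, normalized per
slide to a blank (unstained) region:

    RIR = (outer − blank) / (inner − blank)

Both numerator and denominator are negative in stained sections (staining
darkens pixels below the blank level), so the ratio is positive, equals 1
for symmetric staining, and falls toward 0 as outer-layer synapses are
preferentially lost.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from npq.roi import ROIPolygon
from npq.stain import RGBImage


@dataclass(frozen=True)
class RIRMeasurement:
    """Mean 8-bit pixel intensities of the three measured regions."""

    outer_mean_intensity: float
    inner_mean_intensity: float
    blank_mean_intensity: float

    def __post_init__(self):
        for v in (self.outer_mean_intensity, self.inner_mean_intensity,
                  self.blank_mean_intensity):
            if not 0 <= v <= 255:
                raise ValueError("mean intensities must lie in [0, 255]")


def compute_rir(m: RIRMeasurement) -> float:
    """(outer − blank) / (inner − blank).

    Raises when inner equals blank (no inner-layer staining: ratio
    undefined).
    """
    denom = m.inner_mean_intensity - m.blank_mean_intensity
    if denom == 0:
        raise ValueError("inner layer equals blank: RIR undefined")
    return (m.outer_mean_intensity - m.blank_mean_intensity) / denom


def _mean_gray(image: RGBImage, roi: ROIPolygon) -> float:
    # unweighted channel mean, matching a plain 8-bit grayscale conversion
    mask = roi.mask(image.shape)
    if not mask.any():
        raise ValueError("ROI contains no pixels")
    return float(image.pixels[mask].mean())


def measure_rir(
    image: RGBImage,
    outer: ROIPolygon,
    inner: ROIPolygon,
    blank: ROIPolygon,
) -> float:
    """Measure the RIR from an image and three region annotations.

    Mean grayscale intensities are taken over each ROI; the blank region
    normalizes out slide-level illumination and background staining.
    """
    m = RIRMeasurement(
        outer_mean_intensity=_mean_gray(image, outer),
        inner_mean_intensity=_mean_gray(image, inner),
        blank_mean_intensity=_mean_gray(image, blank),
    )
    return compute_rir(m)
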