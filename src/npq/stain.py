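"""Brightfield color deconvolution and DAB positive-area quantification.

Brightfield IHC slides carry two chromogens — a blue hematoxylin
counterstain and the brown DAB reaction product — whose absorbances add in
optical-density (OD) space (Beer–Lambert). Each stain absorbs the three RGB
channels in a characteristic ratio, so the per-pixel OD vector is a linear
mixture of per-stain unit "color vectors" and the stain amounts are
recovered by inverting the 3×3 mixing matrix (color deconvolution). A third
"residual" vector completes the basis and absorbs off-model signal.

The default color vectors are the measured values for this staining
protocol: hematoxylin (0.67, 0.66, 0.339), DAB (0.311, 0.522, 0.794),
residual (0.02, 0.999, 0.02), each normalized to unit length.

The pTau burden metric is the classic positive-pixel statistic
``OD × %Positive``: average positive optical density multiplied by the
percent of ROI pixels whose DAB pseudo-intensity falls below an upper
positive threshold (default 200 on the 8-bit scale — stained pixels are
*darker*, i.e. lower intensity, than the cutoff).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from npq.roi import ROIPolygon

# 8-bit scanner conventions: incident light 255, floor to avoid log(0),
# OD ceiling attained by a fully dark pixel (intensity clamped to 1).
I0 = 255.0
EPS_INTENSITY = 1.0
OD_MAX = float(np.log10(I0))  # ≈ 2.4065

DEFAULT_HEMATOXYLIN = (0.67, 0.66, 0.339)
DEFAULT_DAB = (0.311, 0.522, 0.794)
DEFAULT_RESIDUAL = (0.02, 0.999, 0.02)


@dataclass(frozen=True)
class RGBImage:
    """Calibrated 8-bit RGB brightfield image.

    Parameters
    ----------
    pixels : (H, W, 3) array
        Intensities on the 0–255 scale (float or integer).
    pixel_size_um : float
        Physical pixel size in µm/pixel; slides here were scanned at 20x
        (0.5 µm/pixel).
    """

    pixels: np.ndarray
    pixel_size_um: float = 0.5

    def __post_init__(self):
        p = np.asarray(self.pixels, dtype=float)
        if p.ndim != 3 or p.shape[2] != 3:
            raise ValueError("pixels must be H×W×3")
        if p.min() < 0 or p.max() > 255:
            raise ValueError("intensities must lie in [0, 255]")
        if not self.pixel_size_um > 0:
            raise ValueError("pixel_size_um must be positive")
        object.__setattr__(self, "pixels", p)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]


@dataclass(frozen=True)
class StainModel:
    """Three RGB optical-density color vectors and their inversion matrix.

    Vectors are stored normalized to unit length. The rows of
    :attr:`matrix` are (hematoxylin, DAB, residual); deconvolution solves
    ``od = concentrations @ matrix`` per pixel.
    """

    hematoxylin: np.ndarray = field(default=DEFAULT_HEMATOXYLIN)
    dab: np.ndarray = field(default=DEFAULT_DAB)
    residual: np.ndarray = field(default=DEFAULT_RESIDUAL)

    def __post_init__(self):
        for name in ("hematoxylin", "dab", "residual"):
            v = np.asarray(getattr(self, name), dtype=float)
            norm = np.linalg.norm(v)
            if v.shape != (3,) or norm == 0:
                raise ValueError(f"{name} vector must be a nonzero RGB triple")
            object.__setattr__(self, name, v / norm)

    @property
    def matrix(self) -> np.ndarray:
        return np.stack([self.hematoxylin, self.dab, self.residual])

    @property
    def inverse(self) -> np.ndarray:
        m = self.matrix
        if abs(np.linalg.det(m)) < 1e-10:
            raise ValueError(
                "singular stain matrix: vectors "
                f"hematoxylin={tuple(np.round(self.hematoxylin, 4))}, "
                f"dab={tuple(np.round(self.dab, 4))}, "
                f"residual={tuple(np.round(self.residual, 4))} "
                "are linearly dependent")
        return np.linalg.inv(m)

    @property
    def channels(self) -> tuple[str, str, str]:
        return ("hematoxylin", "dab", "residual")


@dataclass(frozen=True)
class ODImage:
    """Per-channel optical-density maps with channel labels."""

    od: np.ndarray  # H×W×C
    channels: tuple[str, ...]

    def __post_init__(self):
        if self.od.shape[-1] != len(self.channels):
            raise ValueError("channel labels must match OD map count")

    def channel(self, name: str) -> np.ndarray:
        return self.od[..., self.channels.index(name)]


@dataclass(frozen=True)
class AreaAnalysisParams:
    """Positive-pixel parameters; the calibrated upper threshold is 200."""

    upper_positive_intensity_threshold: float = 200.0


@dataclass(frozen=True)
class AreaAnalysisResult:
    """OD × %Positive burden metric for one ROI."""

    percent_positive: float
    avg_positive_od: float

    @property
    def od_weighted_metric(self) -> float:
        return self.avg_positive_od * self.percent_positive


def intensity_to_od(intensity: np.ndarray) -> np.ndarray:
    """Beer–Lambert OD of 8-bit intensities: −log10(max(I, ε)/255)."""
    i = np.maximum(np.asarray(intensity, dtype=float), EPS_INTENSITY)
    return np.minimum(-np.log10(i / I0), OD_MAX)


def rgb_to_od(image: RGBImage) -> ODImage:
    """Convert an RGB image to per-channel optical density.

    OD = −log10(max(I, ε)/255) per channel, clamped to ``OD_MAX``; a blank
    (255) pixel maps to OD 0 and OD decreases monotonically with intensity.
    """
    return ODImage(intensity_to_od(image.pixels), ("red", "green", "blue"))


def deconvolve(od: ODImage, model: StainModel | None = None) -> ODImage:
    """Unmix RGB optical density into per-stain OD maps.

    Solves the 3-stain linear system per pixel; negative unmixed
    concentrations (off-model pixels) are clipped to zero.

    Raises
    ------
    ValueError
        If the stain matrix is singular (names the offending vectors).
    """
    model = model or StainModel()
    conc = od.od @ model.inverse
    return ODImage(np.maximum(conc, 0.0), model.channels)


def stain_to_intensity(stain_od_map: np.ndarray) -> np.ndarray:
    """Map a single stain OD map back to a 0–255 pseudo-intensity.

    ``intensity = 255 × 10^(−OD)``: the inverse of the OD transform
    restricted to one channel, so stained (high-OD) pixels are dark.
    """
    return I0 * np.power(10.0, -np.asarray(stain_od_map, dtype=float))


def area_analysis(
    dab_intensity_map: np.ndarray,
    roi: ROIPolygon,
    params: AreaAnalysisParams | None = None,
    exclusion_mask: np.ndarray | None = None,
) -> AreaAnalysisResult:
    """Positive-area analysis of the DAB channel inside an ROI.

    A pixel is positive when its DAB pseudo-intensity is *below* the upper
    positive threshold — i.e. the stain is darker than the cutoff. Returns
    percent positive, the mean OD over positive pixels, and their product
    (the OD × %Positive burden metric).

    ``exclusion_mask`` marks pixels (pigment artifacts etc.) removed from
    the ROI before analysis.
    """
    params = params or AreaAnalysisParams()
    mask = roi.mask(dab_intensity_map.shape)
    if exclusion_mask is not None:
        mask &= ~exclusion_mask
    n_total = int(mask.sum())
    if n_total == 0:
        raise ValueError("ROI contains no pixels")
    intensities = dab_intensity_map[mask]
    positive = intensities < params.upper_positive_intensity_threshold
    n_pos = int(positive.sum())
    percent = 100.0 * n_pos / n_total
    avg_od = float(intensity_to_od(intensities[positive]).mean()) if n_pos else 0.0
    return AreaAnalysisResult(percent_positive=percent, avg_positive_od=avg_od)


def tau_subtype_ratio(
    hippocampus_metric: float, mfg_metric: float, ratio_cutoff: float = 1.5
) -> str:
    """Classify tau regional distribution by the hippocampus/MFG OD ratio.

    Cases whose hippocampal tau burden exceeds the middle-frontal-gyrus
    burden by more than ``ratio_cutoff`` (strict) are labeled
    ``"limbic-predominant"``; otherwise ``"not limbic-predominant"``.
    """
    if hippocampus_metric < 0 or mfg_metric < 0:
        raise ValueError("burden metrics must be non-negative")
    if mfg_metric == 0:
        raise ValueError("MFG metric is zero: hippocampus/MFG ratio undefined")
    ratio = hippocampus_metric / mfg_metric
    return "limbic-predominant" if ratio > ratio_cutoff else "not limbic-predominant"
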