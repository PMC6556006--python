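"""Synthetic-data generators with planted ground truth.

Every generator is a pure function of its parameters and seed, and emits
the exact structures consumed by the analysis modules:

* :func:`render_ihc_image` — Beer–Lambert-composited hematoxylin+DAB
  brightfield images with planted inclusions (disks, ellipses, fibers) of
  known size, shape, and stain OD, optional fusing bridges for
  declustering fixtures, and a ground-truth object table.
* :func:`render_rir_fixture` — a dentate-gyrus-like image with planted
  outer/inner molecular-layer staining densities and the three ROIs the
  RIR measurement needs.
* :func:`simulate_cohort` — an autopsy cohort with planted resistant,
  resilient, and AD-dementia-pool cases (each satisfying its selection
  predicate by construction), decoy cases violating exactly one criterion
  each, and filler cases.
* :func:`simulate_progeny` — multinomial progeny genotype counts from a
  transgene-cross model with genotype-specific viability.

The image noise model is additive Gaussian on intensity (default SD 2
intensity units, a scanner shot-noise stand-in), applied after stain
compositing and clipped to [0, 255].
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from npq.cohort import CaseRecord
from npq.roi import ROIPolygon
from npq.segregation import CrossModel, ProgenyCounts, expected_proportions
from npq.stain import I0, RGBImage, StainModel

FIBER_WIDTH_UM = 1.5  # rasterized fiber width; guarantees roundness < 0.25


# ---------------------------------------------------------------------------
# IHC image rendering

@dataclass(frozen=True)
class PlantedObject:
    """One planted inclusion: center (x, y) in px, shape, area, DAB OD."""

    center: tuple[float, float]
    shape: str = "disk"          # disk | ellipse | fiber
    area_um2: float = 50.0
    dab_od: float = 0.3
    aspect: float = 3.0          # major/minor ratio for ellipses
    angle_deg: float = 0.0


@dataclass(frozen=True)
class Bridge:
    """A stained strip fusing two planted objects (declustering fixtures)."""

    a: int                       # indices into the object list
    b: int
    dab_od: float
    width_um: float = 2.0


@dataclass(frozen=True)
class ImageSimParams:
    seed: int
    shape: tuple[int, int] = (512, 512)
    pixel_size_um: float = 0.5
    background_hematoxylin_od: float = 0.3
    noise_sd: float = 2.0
    objects: tuple[PlantedObject, ...] = ()
    bridges: tuple[Bridge, ...] = ()
    stain_model: StainModel = field(default_factory=StainModel)


def _object_mask(obj: PlantedObject, shape: tuple[int, int],
                 pixel_size_um: float) -> np.ndarray:
    h, w = shape
    ys, xs = np.mgrid[0:h, 0:w]
    cx, cy = obj.center
    dx, dy = xs - cx, ys - cy
    theta = np.deg2rad(obj.angle_deg)
    u = dx * np.cos(theta) + dy * np.sin(theta)   # along major axis
    v = -dx * np.sin(theta) + dy * np.cos(theta)
    area_px = obj.area_um2 / pixel_size_um**2
    if obj.shape == "disk":
        r = np.sqrt(area_px / np.pi)
        return dx**2 + dy**2 <= r**2
    if obj.shape == "ellipse":
        b = np.sqrt(area_px / (np.pi * obj.aspect))
        a = obj.aspect * b
        return (u / a) ** 2 + (v / b) ** 2 <= 1.0
    if obj.shape == "fiber":
        width = FIBER_WIDTH_UM / pixel_size_um
        length = area_px / width
        along = np.clip(u, -length / 2, length / 2)
        return (u - along) ** 2 + v**2 <= (width / 2) ** 2
    raise ValueError(f"unknown planted shape {obj.shape!r}")


def _bridge_mask(bridge: Bridge, objs: Sequence[PlantedObject],
                 shape: tuple[int, int], pixel_size_um: float) -> np.ndarray:
    h, w = shape
    ys, xs = np.mgrid[0:h, 0:w]
    p0 = np.asarray(objs[bridge.a].center, float)
    p1 = np.asarray(objs[bridge.b].center, float)
    d = p1 - p0
    length = np.hypot(*d)
    if length == 0:
        raise ValueError("bridge endpoints coincide")
    t = np.clip(((xs - p0[0]) * d[0] + (ys - p0[1]) * d[1]) / length**2, 0, 1)
    px, py = p0[0] + t * d[0], p0[1] + t * d[1]
    half = bridge.width_um / pixel_size_um / 2
    return (xs - px) ** 2 + (ys - py) ** 2 <= half**2


def render_ihc_image(params: ImageSimParams) -> tuple[RGBImage, pd.DataFrame]:
    """Render a brightfield IHC image with planted ground truth.

    RGB intensity per channel c is ``255 · 10^(−(OD_hem·v_hem[c] +
    OD_dab·v_dab[c]))`` with the normalized stain vectors, plus Gaussian
    intensity noise, clipped to [0, 255]. Objects may not overlap unless a
    bridge between them is declared (the ground truth would otherwise be
    ambiguous). Returns the image and a table of every planted object's
    shape class, true area, and stain OD.
    """
    rng = np.random.default_rng(params.seed)
    h, w = params.shape
    masks = [_object_mask(o, params.shape, params.pixel_size_um)
             for o in params.objects]
    bridged = {frozenset((br.a, br.b)) for br in params.bridges}
    for i in range(len(masks)):
        for j in range(i + 1, len(masks)):
            if (masks[i] & masks[j]).any() and frozenset((i, j)) not in bridged:
                raise ValueError(
                    f"planted objects {i} and {j} overlap without a declared "
                    "bridge: ground truth would be ambiguous")
    od_dab = np.zeros((h, w))
    for br in params.bridges:
        bm = _bridge_mask(br, params.objects, params.shape, params.pixel_size_um)
        od_dab[bm] = br.dab_od
    for o, m in zip(params.objects, masks):
        od_dab[m] = o.dab_od
    od_hem = np.full((h, w), params.background_hematoxylin_od)
    sm = params.stain_model
    od_rgb = (od_hem[..., None] * sm.hematoxylin[None, None, :]
              + od_dab[..., None] * sm.dab[None, None, :])
    pixels = I0 * np.power(10.0, -od_rgb)
    if params.noise_sd > 0:
        pixels = pixels + rng.normal(0.0, params.noise_sd, pixels.shape)
    image = RGBImage(np.clip(pixels, 0, 255), params.pixel_size_um)
    truth = pd.DataFrame([
        {
            "object_id": i,
            "shape": o.shape,
            "center_x": o.center[0],
            "center_y": o.center[1],
            "area_um2": o.area_um2,
            "rasterized_area_um2": float(m.sum()) * params.pixel_size_um**2,
            "dab_od": o.dab_od,
            "dab_intensity": I0 * 10.0 ** (-o.dab_od),
        }
        for i, (o, m) in enumerate(zip(params.objects, masks))
    ])
    return image, truth


def scatter_centers(n: int, shape: tuple[int, int], min_separation_px: float,
                    seed: int, margin_px: float = 20.0) -> list[tuple[float, float]]:
    """Random object centers with a minimum pairwise separation (dart throwing)."""
    rng = np.random.default_rng(seed)
    centers: list[tuple[float, float]] = []
    h, w = shape
    for _ in range(100000):
        if len(centers) == n:
            break
        c = (float(rng.uniform(margin_px, w - margin_px)),
             float(rng.uniform(margin_px, h - margin_px)))
        if all(np.hypot(c[0] - x, c[1] - y) >= min_separation_px
               for x, y in centers):
            centers.append(c)
    if len(centers) < n:
        raise ValueError("could not place objects at the requested separation")
    return centers


def render_rir_fixture(
    outer_od: float,
    inner_od: float,
    seed: int,
    shape: tuple[int, int] = (120, 240),
    noise_sd: float = 0.0,
) -> tuple[RGBImage, ROIPolygon, ROIPolygon, ROIPolygon]:
    """Dentate-gyrus-like fixture: outer/inner stained bands plus blank.

    Plants uniform synaptophysin (DAB) OD ``outer_od`` and ``inner_od`` in
    two horizontal bands and leaves a blank band unstained; returns the
    image and the three band ROIs. The planted outer/inner OD ratio is the
    quantity the RIR should recover (to within Beer–Lambert nonlinearity,
    negligible at low OD).
    """
    rng = np.random.default_rng(seed)
    h, w = shape
    od_dab = np.zeros((h, w))
    third = h // 3
    od_dab[:third, :] = outer_od
    od_dab[third:2 * third, :] = inner_od
    sm = StainModel()
    pixels = I0 * np.power(10.0, -(od_dab[..., None] * sm.dab[None, None, :]))
    if noise_sd > 0:
        pixels = pixels + rng.normal(0.0, noise_sd, pixels.shape)
    image = RGBImage(np.clip(pixels, 0, 255))
    pad = 2
    outer_roi = ROIPolygon.rectangle(pad, pad, w - pad, third - pad)
    inner_roi = ROIPolygon.rectangle(pad, third + pad, w - pad, 2 * third - pad)
    blank_roi = ROIPolygon.rectangle(pad, 2 * third + pad, w - pad, h - pad)
    return image, outer_roi, inner_roi, blank_roi


# ---------------------------------------------------------------------------
# Cohort simulation

@dataclass(frozen=True)
class CohortSimParams:
    """Planted structure of the synthetic autopsy cohort.

    Defaults mirror the source study's structure: 684 autopsies screened,
    14 resistant and 7 resilient cases planted, and a pool of same-sex
    severe-ADNC dementia candidates large enough for one-to-one matching.
    """

    seed: int
    n_cases: int = 684
    n_resistant: int = 14
    n_resilient: int = 7
    n_pool: int = 80
    late_prevalence_pool: float = 13 / 14
    late_prevalence_resistant: float = 2 / 14
    n_decoys: int = 8

    def __post_init__(self):
        planted = (self.n_resistant + self.n_resilient + self.n_pool
                   + self.n_decoys)
        if planted > self.n_cases:
            raise ValueError("planted groups exceed total cohort size")


def _death_date(rng, year: int) -> dt.date:
    return dt.date(year, int(rng.integers(1, 13)), int(rng.integers(1, 29)))


def _casi_history(rng, death: dt.date, latency_years: float,
                  demented: bool, n_visits: int = 5):
    """Biennial CASI visits ending ``latency_years`` before death.

    Non-demented trajectories are stable around 90; demented ones decline
    linearly and cross the ≤85 evaluation threshold at the last recorded
    visit (after which testing stops in the source protocol).
    """
    last = death - dt.timedelta(days=round(latency_years * 365.25))
    dates = [last - dt.timedelta(days=round(730.5 * k))
             for k in range(n_visits - 1, -1, -1)]
    if demented:
        scores = np.linspace(93, 83, n_visits) + rng.normal(0, 1.0, n_visits)
        scores[-1] = min(scores[-1], 84.0)
    else:
        scores = 90 + rng.normal(0, 3.0, n_visits)
    return [(d, float(np.clip(s, 0, 100))) for d, s in zip(dates, scores)]


def _vascular(rng, severe: bool) -> dict:
    shift = 1 if severe else 0
    return dict(
        n_microinfarcts=int(rng.poisson(1.5 if severe else 1.0)),
        n_macroinfarcts=int(rng.poisson(0.8 if severe else 0.2)),
        caa_severity=int(np.clip(rng.poisson(1.0 + 0.4 * shift), 0, 3)),
        arteriolosclerosis=int(np.clip(rng.poisson(2.0 + 0.5 * shift), 0, 3)),
        atherosclerosis=int(np.clip(rng.poisson(1.9 + 0.35 * shift), 0, 3)),
    )


def _late_stage(rng, prevalence: float) -> str:
    if rng.random() < prevalence:
        return str(rng.choice(["amygdala", "hippocampal", "neocortical"],
                              p=[0.2, 0.4, 0.4]))
    return "none"


def simulate_cohort(params: CohortSimParams
                    ) -> tuple[list[CaseRecord], pd.DataFrame]:
    """Generate a cohort with planted selection structure.

    Returns the case records and a planted-label table (``case_id``,
    ``planted_group`` ∈ resistant / resilient / pool / decoy_* / filler).
    Every planted resistant/resilient/pool case satisfies its predicate by
    construction; each decoy violates exactly one criterion; fillers are
    non-demented with stale CASI (latency > 2 y) or demented without severe
    ADNC, so neither predicate can fire on them.
    """
    rng = np.random.default_rng(params.seed)
    cases: list[CaseRecord] = []
    labels: list[tuple[str, str]] = []
    counter = 0

    def _new_id() -> str:
        nonlocal counter
        counter += 1
        return f"C{counter:04d}"

    def _base(sex, age, demented, latency, braak, cerad, severe_path, late_prev):
        year = int(rng.integers(1995, 2017))
        death = _death_date(rng, year)
        return CaseRecord(
            case_id=_new_id(), sex=sex, age_at_death=round(float(age), 1),
            year_of_death=year, pmi_hours=round(float(rng.uniform(2, 30)), 1),
            dementia_status=demented,
            casi_history=_casi_history(rng, death, latency, demented),
            death_date=death, braak_stage=braak, cerad_score=cerad,
            thal_phase=int(np.clip(cerad + rng.integers(0, 3), 0, 5)),
            lbd_distribution=str(rng.choice(
                ["none", "brainstem", "limbic-amygdala", "neocortical"],
                p=[0.6, 0.15, 0.15, 0.1])),
            late_nc_stage=_late_stage(rng, late_prev),
            brain_weight_g=round(float(rng.normal(
                1115 if severe_path else 1228, 80)), 0),
            apoe_genotype=str(rng.choice(
                ["e3/e3", "e3/e4", "e2/e3"],
                p=[0.45, 0.45, 0.1] if severe_path else [0.75, 0.1, 0.15])),
            education_years=round(float(rng.normal(14.5, 3.0)), 1),
            **_vascular(rng, severe_path),
        )

    # planted resistant: non-demented, recent CASI, Braak ≤ III, CERAD none,
    # age ≥ 85 — sex split 8F/6M as in the source cohort
    for i in range(params.n_resistant):
        sex = "F" if i < round(params.n_resistant * 8 / 14) else "M"
        c = _base(sex, np.clip(rng.normal(94.7, 3.8), 85.0, 105.0), False,
                  rng.uniform(0.25, 1.8), int(rng.integers(0, 4)), 0,
                  False, params.late_prevalence_resistant)
        cases.append(c)
        labels.append((c.case_id, "resistant"))

    # planted resilient: non-demented, recent CASI, Braak VI, CERAD frequent
    for i in range(params.n_resilient):
        sex = "F" if i < round(params.n_resilient * 5 / 7) else "M"
        c = _base(sex, np.clip(rng.normal(85.2, 6.1), 66.0, 102.0), False,
                  rng.uniform(0.17, 1.6), 6, 3, True, 0.0)
        cases.append(c)
        labels.append((c.case_id, "resilient"))

    # AD-dementia matching pool: demented, Braak VI, CERAD frequent
    for i in range(params.n_pool):
        sex = "F" if i < params.n_pool // 2 else "M"
        c = _base(sex, np.clip(rng.normal(88.0, 5.5), 66.0, 105.0), True,
                  rng.uniform(2.5, 6.0), 6, 3, True,
                  params.late_prevalence_pool)
        cases.append(c)
        labels.append((c.case_id, "pool"))

    # decoys: each violates exactly one criterion of its target predicate
    decoy_specs = [
        ("decoy_resistant_young",
         dict(age=80.0, demented=False, latency=1.0, braak=2, cerad=0)),
        ("decoy_resistant_braak",
         dict(age=90.0, demented=False, latency=1.0, braak=4, cerad=0)),
        ("decoy_resistant_cerad",
         dict(age=90.0, demented=False, latency=1.0, braak=2, cerad=1)),
        ("decoy_resistant_stale_casi",
         dict(age=90.0, demented=False, latency=2.5, braak=2, cerad=0)),
        ("decoy_resistant_demented",
         dict(age=90.0, demented=True, latency=1.0, braak=2, cerad=0)),
        ("decoy_resilient_braak",
         dict(age=86.0, demented=False, latency=1.0, braak=5, cerad=3)),
        ("decoy_resilient_cerad",
         dict(age=86.0, demented=False, latency=1.0, braak=6, cerad=2)),
        ("decoy_resilient_stale_casi",
         dict(age=86.0, demented=False, latency=2.6, braak=6, cerad=3)),
    ]
    for name, kw in decoy_specs[: params.n_decoys]:
        c = _base(str(rng.choice(["F", "M"])), kw["age"], kw["demented"],
                  kw["latency"], kw["braak"], kw["cerad"], False, 0.1)
        cases.append(c)
        labels.append((c.case_id, name))

    # fillers: structurally unable to satisfy either predicate
    n_fillers = params.n_cases - len(cases)
    for _ in range(n_fillers):
        if rng.random() < 0.5:
            # non-demented with stale CASI
            c = _base(str(rng.choice(["F", "M"])),
                      np.clip(rng.normal(86, 7), 65, 105), False,
                      rng.uniform(2.1, 8.0), int(rng.integers(0, 7)),
                      int(rng.integers(0, 4)), False, 0.05)
        else:
            # demented without severe ADNC (keeps the matching pool planted)
            braak = int(rng.integers(0, 6))
            cerad = int(rng.integers(0, 4)) if braak < 6 else int(rng.integers(0, 3))
            c = _base(str(rng.choice(["F", "M"])),
                      np.clip(rng.normal(86, 7), 65, 105), True,
                      rng.uniform(2.5, 7.0), braak, cerad, True, 0.5)
        cases.append(c)
        labels.append((c.case_id, "filler"))

    label_df = pd.DataFrame(labels, columns=["case_id", "planted_group"])
    return cases, label_df


# ---------------------------------------------------------------------------
# Transgene-cross progeny

def simulate_progeny(model: CrossModel, n: int, seed: int) -> ProgenyCounts:
    """Multinomial progeny genotype counts under the cross model."""
    if n <= 0:
        raise ValueError("n must be positive")
    rng = np.random.default_rng(seed)
    p = expected_proportions(model)
    counts = rng.multinomial(n, p)
    return ProgenyCounts(tuple(int(c) for c in counts))
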