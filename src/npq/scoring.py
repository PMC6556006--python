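"""Semi-quantitative pathology scales and the summary neuropathology score.

The summary score condenses four axes of neurodegenerative and vascular
pathology into a single 0–15 descriptive metric:

* ADNC subscore (0–6): Braak neurofibrillary-tangle stage expressed as a
  number, divided by 2, plus the CERAD neuritic-plaque score (0–3).
* µVBI subscore (0–3): number of chronic microinfarcts on standardized
  screening sections, capped at 3.
* LBD subscore (0–3): extent of Lewy body disease — brainstem 1,
  limbic/amygdala 2, neocortical 3.
* LATE-NC subscore (0–3): pTDP-43 distribution — amygdala-only 1,
  hippocampal 2, neocortical (beyond medial temporal) 3.

Regional burden scales bin field counts: pTau tangles per 10x field
(0 / <3 / 3–10 / >10 → 0–3), Aβ plaques per 10x field
(0 / <5 / 5–20 / >20 → 0–3), and combined pTDP-43 inclusions/neurites per
20x field (0 / 1–2 / 3–5 / 6–10 / 11–15 / 16–20 / >20 → 0–6; the published
scale lists 15 in two adjacent bins, resolved here to the lower bin).
Fractional counts (densities) are floored before binning.
"""

from __future__ import annotations

from dataclasses import dataclass

from npq.cohort import CaseRecord, LBD_LEVELS, LATE_LEVELS


@dataclass(frozen=True)
class SummaryScore:
    adnc_subscore: float
    uvbi_subscore: int
    lbd_subscore: int
    late_subscore: int

    @property
    def total(self) -> float:
        return (self.adnc_subscore + self.uvbi_subscore
                + self.lbd_subscore + self.late_subscore)


def adnc_subscore(braak: float, cerad: int) -> float:
    """(Braak stage / 2) + CERAD score; maximum 6 (half-integers allowed)."""
    if not 0 <= braak <= 6:
        raise ValueError("Braak stage must be 0–6")
    if not 0 <= cerad <= 3:
        raise ValueError("CERAD score must be 0–3")
    return braak / 2 + cerad


def uvbi_subscore(n_microinfarcts: int) -> int:
    """Microinfarct count capped at 3 (≥3 microinfarcts score 3)."""
    if n_microinfarcts < 0:
        raise ValueError("microinfarct count must be non-negative")
    return min(int(n_microinfarcts), 3)


def lbd_subscore(distribution: str) -> int:
    """Lewy body extent: none 0, brainstem 1, limbic/amygdala 2, neocortical 3."""
    try:
        return LBD_LEVELS.index(distribution)
    except ValueError:
        raise ValueError(f"unknown LBD distribution {distribution!r}") from None


def late_subscore(stage: str) -> int:
    """LATE-NC stage: none 0, amygdala 1, hippocampal 2, neocortical 3."""
    try:
        return LATE_LEVELS.index(stage)
    except ValueError:
        raise ValueError(f"unknown LATE-NC stage {stage!r}") from None


def summary_score(case: CaseRecord) -> SummaryScore:
    """Sum of ADNC, µVBI, LBD, and LATE-NC subscores (0–15)."""
    if case.braak_stage is None or case.cerad_score is None:
        raise ValueError(f"case {case.case_id}: Braak/CERAD staging missing")
    return SummaryScore(
        adnc_subscore=adnc_subscore(case.braak_stage, case.cerad_score),
        uvbi_subscore=uvbi_subscore(case.n_microinfarcts),
        lbd_subscore=lbd_subscore(case.lbd_distribution),
        late_subscore=late_subscore(case.late_nc_stage),
    )


def _binned(count: float, edges: list[int], name: str) -> int:
    # edges[i] = first count belonging to score i+1; lower bin wins at edges
    if count < 0:
        raise ValueError(f"{name} count must be non-negative")
    c = int(count)  # densities floored before binning
    score = 0
    for i, e in enumerate(edges):
        if c >= e:
            score = i + 1
    return score


def bin_ptau(tangles_per_10x: float) -> int:
    """pTau tangle score: 0 none, 1 rare (<3), 2 numerous (3–10), 3 (>10)."""
    return _binned(tangles_per_10x, [1, 3, 11], "tangle")


def bin_abeta(plaques_per_10x: float) -> int:
    """Aβ plaque score: 0 none, 1 rare (<5), 2 numerous (5–20), 3 (>20)."""
    return _binned(plaques_per_10x, [1, 5, 21], "plaque")


def bin_ptdp(count_per_20x: float) -> int:
    """pTDP-43 density score 0–6 per 20x field.

    0 none, 1 = 1–2, 2 = 3–5, 3 = 6–10, 4 = 11–15, 5 = 16–20, 6 = >20.
    """
    return _binned(count_per_20x, [1, 3, 6, 11, 16, 21], "inclusion/neurite")
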