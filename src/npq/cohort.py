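"""Resistant/resilient case selection and one-to-one dementia matching.

Implements the cohort workflow of a community-based autopsy series:

* **Resistant** cases escaped Alzheimer's pathology — non-demented (last
  CASI cognitive test within two years of death), Braak stage III or lower,
  CERAD none, and age 85 or older at death.
* **Resilient** cases escaped dementia despite severe AD neuropathologic
  change — non-demented with Braak stage VI and CERAD frequent.
* Each index case is matched one-to-one, without replacement, to a same-sex
  demented case with severe ADNC (Braak VI, CERAD frequent); candidates are
  ranked by |Δ age at death|, then |Δ year of death|, then |Δ post-mortem
  interval|, with a final tie broken by smallest case id.

CASI is the Cognitive Abilities Screening Instrument (0–100); a score ≤ 85
triggers dementia evaluation in the source study, so non-demented status is
only credible when the last test is recent — hence the two-year latency
rule.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from typing import Optional, Sequence

import pandas as pd

DAYS_PER_YEAR = 365.25

LBD_LEVELS = ("none", "brainstem", "limbic-amygdala", "neocortical")
LATE_LEVELS = ("none", "amygdala", "hippocampal", "neocortical")


@dataclass
class CaseRecord:
    """One autopsy case: demographics, cognition, and pathology staging."""

    case_id: str
    sex: str
    age_at_death: float
    year_of_death: int
    pmi_hours: float
    dementia_status: bool
    casi_history: list[tuple[dt.date, float]] = field(default_factory=list)
    death_date: Optional[dt.date] = None
    braak_stage: Optional[int] = None       # 0, I–VI encoded 0–6
    cerad_score: Optional[int] = None       # none/sparse/moderate/frequent 0–3
    thal_phase: Optional[int] = None        # 0–5
    lbd_distribution: str = "none"
    late_nc_stage: str = "none"
    n_microinfarcts: int = 0
    n_macroinfarcts: int = 0
    caa_severity: int = 0
    arteriolosclerosis: int = 0
    atherosclerosis: int = 0
    brain_weight_g: Optional[float] = None
    apoe_genotype: Optional[str] = None
    education_years: Optional[float] = None

    def __post_init__(self):
        if self.braak_stage is not None and not 0 <= self.braak_stage <= 6:
            raise ValueError("braak_stage must be 0–6")
        if self.cerad_score is not None and not 0 <= self.cerad_score <= 3:
            raise ValueError("cerad_score must be 0–3")
        for d, s in self.casi_history:
            if not 0 <= s <= 100:
                raise ValueError("CASI scores range from 0 to 100")
        if self.lbd_distribution not in LBD_LEVELS:
            raise ValueError(f"unknown LBD distribution {self.lbd_distribution!r}")
        if self.late_nc_stage not in LATE_LEVELS:
            raise ValueError(f"unknown LATE-NC stage {self.late_nc_stage!r}")


@dataclass(frozen=True)
class MatchingPolicy:
    """Eligibility and ranking rules for index→dementia matching."""

    require_same_sex: bool = True
    pool_braak: int = 6
    pool_cerad: int = 3
    without_replacement: bool = True


def casi_latency(case: CaseRecord) -> float:
    """Years between the last CASI administration and death (365.25-d years)."""
    if not case.casi_history:
        raise ValueError(f"case {case.case_id}: no CASI history")
    if case.death_date is None:
        raise ValueError(f"case {case.case_id}: death date missing")
    last = max(d for d, _ in case.casi_history)
    days = (case.death_date - last).days
    if days < 0:
        raise ValueError(f"case {case.case_id}: CASI dated after death")
    return days / DAYS_PER_YEAR


def _require_staging(case: CaseRecord) -> None:
    if case.braak_stage is None or case.cerad_score is None:
        raise ValueError(f"case {case.case_id}: Braak/CERAD staging missing")


def classify_resistant(case: CaseRecord, max_casi_latency_years: float = 2.0) -> bool:
    """Non-demented, recent CASI, Braak ≤ III, CERAD none, age ≥ 85."""
    _require_staging(case)
    return (
        not case.dementia_status
        and casi_latency(case) <= max_casi_latency_years
        and case.braak_stage <= 3
        and case.cerad_score == 0
        and case.age_at_death >= 85
    )


def classify_resilient(case: CaseRecord, max_casi_latency_years: float = 2.0) -> bool:
    """Non-demented, recent CASI, with severe ADNC (Braak VI, CERAD frequent)."""
    _require_staging(case)
    return (
        not case.dementia_status
        and casi_latency(case) <= max_casi_latency_years
        and case.braak_stage == 6
        and case.cerad_score == 3
    )


def select_group(cases: Sequence[CaseRecord], group: str) -> list[CaseRecord]:
    """All cases of a cohort satisfying the named selection predicate."""
    pred = {"resistant": classify_resistant, "resilient": classify_resilient}[group]
    return [c for c in cases if pred(c)]


def eligible_pool(cases: Sequence[CaseRecord],
                  policy: MatchingPolicy | None = None) -> list[CaseRecord]:
    """Demented cases with severe ADNC, eligible as matching candidates."""
    policy = policy or MatchingPolicy()
    out = []
    for c in cases:
        _require_staging(c)
        if (c.dementia_status and c.braak_stage == policy.pool_braak
                and c.cerad_score == policy.pool_cerad):
            out.append(c)
    return out


def match_cases(
    index_cases: Sequence[CaseRecord],
    pool: Sequence[CaseRecord],
    policy: MatchingPolicy | None = None,
) -> list[tuple[CaseRecord, CaseRecord]]:
    """Greedy one-to-one matching of index cases to the dementia pool.

    Index cases are processed in ascending case-id order. For each, the
    same-sex unused pool members are ranked lexicographically by
    (|Δ age at death|, |Δ year of death|, |Δ PMI|, case id) and the minimum
    is taken and removed from the pool. Deterministic for any storage order
    of the inputs.
    """
    policy = policy or MatchingPolicy()
    for c in pool:
        _require_staging(c)
        if not (c.dementia_status and c.braak_stage == policy.pool_braak
                and c.cerad_score == policy.pool_cerad):
            raise ValueError(
                f"pool case {c.case_id} does not satisfy the pool criteria "
                "(demented, Braak VI, CERAD frequent)")
    available = list(pool)
    pairs: list[tuple[CaseRecord, CaseRecord]] = []
    for index in sorted(index_cases, key=lambda c: c.case_id):
        eligible = [c for c in available
                    if not policy.require_same_sex or c.sex == index.sex]
        if not eligible:
            raise ValueError(f"no eligible match remains for case {index.case_id}")
        best = min(eligible, key=lambda c: (
            abs(c.age_at_death - index.age_at_death),
            abs(c.year_of_death - index.year_of_death),
            abs(c.pmi_hours - index.pmi_hours),
            c.case_id,
        ))
        pairs.append((index, best))
        if policy.without_replacement:
            available.remove(best)
    return pairs


# ---------------------------------------------------------------------------
# Tabular I/O: cohort CSV (one row per case) + long-format CASI CSV

_CSV_FIELDS = [
    "case_id", "sex", "age_at_death", "year_of_death", "pmi_hours",
    "dementia_status", "death_date", "braak_stage", "cerad_score",
    "thal_phase", "lbd_distribution", "late_nc_stage", "n_microinfarcts",
    "n_macroinfarcts", "caa_severity", "arteriolosclerosis",
    "atherosclerosis", "brain_weight_g", "apoe_genotype", "education_years",
]


def cases_to_frame(cases: Sequence[CaseRecord]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Serialize cases to (cohort table, long-format CASI table)."""
    rows = []
    casi_rows = []
    for c in cases:
        row = {f: getattr(c, f) for f in _CSV_FIELDS}
        row["death_date"] = c.death_date.isoformat() if c.death_date else ""
        rows.append(row)
        for d, s in c.casi_history:
            casi_rows.append({"case_id": c.case_id, "date": d.isoformat(), "casi": s})
    return (pd.DataFrame(rows, columns=_CSV_FIELDS),
            pd.DataFrame(casi_rows, columns=["case_id", "date", "casi"]))


def frame_to_cases(cohort: pd.DataFrame, casi: pd.DataFrame) -> list[CaseRecord]:
    """Parse a cohort table and companion CASI table into case records."""
    hist: dict[str, list[tuple[dt.date, float]]] = {}
    for _, r in casi.iterrows():
        hist.setdefault(str(r["case_id"]), []).append(
            (dt.date.fromisoformat(str(r["date"])), float(r["casi"])))
    cases = []
    for _, r in cohort.iterrows():
        cid = str(r["case_id"])

        def _opt(key, cast):
            v = r.get(key)
            return None if pd.isna(v) else cast(v)

        cases.append(CaseRecord(
            case_id=cid,
            sex=str(r["sex"]),
            age_at_death=float(r["age_at_death"]),
            year_of_death=int(r["year_of_death"]),
            pmi_hours=float(r["pmi_hours"]),
            dementia_status=str(r["dementia_status"]).lower() in ("true", "1"),
            casi_history=sorted(hist.get(cid, [])),
            death_date=(dt.date.fromisoformat(str(r["death_date"]))
                        if str(r.get("death_date", "")) not in ("", "nan") else None),
            braak_stage=_opt("braak_stage", int),
            cerad_score=_opt("cerad_score", int),
            thal_phase=_opt("thal_phase", int),
            lbd_distribution=str(r.get("lbd_distribution", "none")),
            late_nc_stage=str(r.get("late_nc_stage", "none")),
            n_microinfarcts=int(r.get("n_microinfarcts", 0)),
            n_macroinfarcts=int(r.get("n_macroinfarcts", 0)),
            caa_severity=int(r.get("caa_severity", 0)),
            arteriolosclerosis=int(r.get("arteriolosclerosis", 0)),
            atherosclerosis=int(r.get("atherosclerosis", 0)),
            brain_weight_g=_opt("brain_weight_g", float),
            apoe_genotype=_opt("apoe_genotype", str),
            education_years=_opt("education_years", float),
        ))
    return cases
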