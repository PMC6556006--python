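"""Mendelian segregation analysis of transgene crosses.

A parent homozygous for one chromosomally integrated transgene and
heterozygous for a second segregates the second transgene among progeny in
the Mendelian 25% (+/+), 50% (+/−), 25% (−/−) ratio. Synthetic lethality —
here, joint toxicity of human tau and TDP-43 transgenes — depresses the
viability of the double-homozygote class, skewing the observed genotype
counts away from that expectation; the departure is tested by chi-square
goodness of fit against the *pre-selection* Mendelian ratios.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from npq.stats import ChiSquareResult, chi_square_goodness_of_fit

MENDELIAN_SINGLE_LOCUS = (0.25, 0.50, 0.25)  # (+/+, +/−, −/−)
GENOTYPES = ("+/+", "+/-", "-/-")


@dataclass(frozen=True)
class CrossModel:
    """Segregation of one heterozygous transgene with per-genotype viability.

    ``viabilities`` are relative survival probabilities in [0, 1] for the
    (+/+, +/−, −/−) classes; all 1 is the neutral (fully Mendelian) model,
    and a near-zero first entry models synthetic lethality of the
    transgene homozygote on the sensitized (tau-homozygous) background.
    """

    mendelian_ratios: tuple[float, float, float] = MENDELIAN_SINGLE_LOCUS
    viabilities: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self):
        r = np.asarray(self.mendelian_ratios, dtype=float)
        v = np.asarray(self.viabilities, dtype=float)
        if not np.isclose(r.sum(), 1.0) or (r < 0).any():
            raise ValueError("mendelian ratios must be non-negative and sum to 1")
        if (v < 0).any() or (v > 1).any():
            raise ValueError("viabilities must lie in [0, 1]")

    def collapse_presence(self) -> "CrossModel":
        """Two-class variant (transgene present vs absent, ¾ : ¼).

        Matches a blind-scoring protocol that records only whether progeny
        carry the transgene. Presence classes pool (+/+, +/−); the pooled
        viability is the ratio-weighted mean of the two classes.
        """
        r = np.asarray(self.mendelian_ratios)
        v = np.asarray(self.viabilities)
        present = r[0] + r[1]
        v_present = (r[0] * v[0] + r[1] * v[1]) / present if present > 0 else 0.0
        return CrossModel((present, r[2], 0.0), (v_present, v[2], 0.0))


@dataclass(frozen=True)
class ProgenyCounts:
    """Observed progeny genotype counts for (+/+, +/−, −/−)."""

    counts: tuple[int, int, int]

    def __post_init__(self):
        if any(c < 0 for c in self.counts):
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return int(sum(self.counts))


def expected_proportions(model: CrossModel) -> np.ndarray:
    """Genotype proportions among surviving progeny.

    Proportional to mendelian ratio × viability, renormalized; with all
    viabilities 1 this is exactly (0.25, 0.50, 0.25).
    """
    w = np.asarray(model.mendelian_ratios) * np.asarray(model.viabilities)
    total = w.sum()
    if total == 0:
        raise ValueError("all genotype classes have zero expected survival")
    return w / total


def segregation_test(counts: ProgenyCounts, model: CrossModel | None = None
                     ) -> ChiSquareResult:
    """χ² test of observed genotype counts against Mendelian expectation.

    The comparison uses the model's pre-selection Mendelian ratios (not the
    viability-adjusted proportions): the question is whether the observed
    progeny depart from neutral single-locus assortment.
    """
    model = model or CrossModel()
    if counts.total == 0:
        raise ValueError("no progeny scored")
    return chi_square_goodness_of_fit(counts.counts, model.mendelian_ratios)
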