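"""Quantitative-parasitology summaries of host surveys.

Standard definitions: prevalence = infected / examined hosts; mean intensity
= worms per *infected* host (undefined when none is infected); mean
abundance = worms per examined host, so abundance = prevalence × intensity.
Arithmetic is exact (rational) internally; published accounts round to one
decimal, so :func:`display_round` rounds half-up to one decimal for
comparison with printed values (11/8 → 1.4).
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from fractions import Fraction
from typing import Iterable, Optional

from .reference import SurveyRecord

__all__ = ["InfectionSummary", "summarize_infection", "pool_surveys", "display_round"]


@dataclass(frozen=True)
class InfectionSummary:
    n_examined: int
    n_infected: int
    prevalence: Fraction
    mean_intensity: Optional[Fraction]  # None when no host is infected
    mean_abundance: Fraction

    @property
    def prevalence_display(self) -> float:
        return display_round(self.prevalence)

    @property
    def mean_intensity_display(self) -> Optional[float]:
        return None if self.mean_intensity is None else display_round(self.mean_intensity)

    @property
    def mean_abundance_display(self) -> float:
        return display_round(self.mean_abundance)


def display_round(value: Fraction | float, digits: int = 1) -> float:
    """Round half-up to ``digits`` decimals, the convention of the accounts."""
    if isinstance(value, Fraction):
        dec = Decimal(value.numerator) / Decimal(value.denominator)
    else:
        dec = Decimal(repr(float(value)))
    quantum = Decimal(1).scaleb(-digits)
    return float(dec.quantize(quantum, rounding=ROUND_HALF_UP))


def summarize_infection(survey: SurveyRecord) -> InfectionSummary:
    """Exact infection parameters of one survey record.

    Requires resolved per-host worm counts; a record whose counts were
    published only as a range cannot be summarized and raises ``ValueError``
    (its reported figures are on the record itself).
    """
    if survey.n_examined == 0:
        raise ValueError("cannot summarize a survey with zero hosts examined")
    counts = survey.worm_counts_per_infected_host
    if counts is None:
        raise ValueError(
            f"survey ({survey.host_species}, {survey.locality}) has unresolved "
            "worm counts; only reported figures are available"
        )
    n_inf = len(counts)
    total = sum(counts)
    prevalence = Fraction(n_inf, survey.n_examined)
    intensity = Fraction(total, n_inf) if n_inf else None
    abundance = Fraction(total, survey.n_examined)
    return InfectionSummary(survey.n_examined, n_inf, prevalence, intensity, abundance)


def pool_surveys(surveys: Iterable[SurveyRecord]) -> InfectionSummary:
    """Pooled summary; prevalence is examined-weighted across surveys."""
    n_examined = 0
    counts: list[int] = []
    for s in surveys:
        if s.worm_counts_per_infected_host is None:
            raise ValueError("cannot pool a survey with unresolved worm counts")
        n_examined += s.n_examined
        counts.extend(s.worm_counts_per_infected_host)
    pooled = SurveyRecord(
        host_species="(pooled)", locality="(pooled)", country="",
        n_examined=n_examined, worm_counts_per_infected_host=counts,
    )
    return summarize_infection(pooled)
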