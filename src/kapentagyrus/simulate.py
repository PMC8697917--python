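"""Synthetic specimens and surveys with the statistical structure of the
published summary tables.

The tables publish, per species and parameter, only (min, mean, max, n).  The
generator treats each parameter as a truncated normal on [min, max] whose
standard deviation follows the range rule sd = f·(max − min) (f = 0.25 by
default) and whose *truncated* mean equals the printed mean — the latent
location is moment-matched numerically, since plain truncation at asymmetric
bounds would bias the realized mean off the printed value.  A per-specimen
latent size factor induces a Gaussian-copula correlation ρ between all
length parameters of one worm, emulating allometry (no covariance data are
published, so ρ is a free knob, default 0.5).  Single-value cells are
reproduced verbatim.  Missingness is applied after sampling, hook pair VII
being the hardest structure to measure and therefore missing most often.

Surveys are simulated as independent Bernoulli infections with zero-truncated
Poisson worm counts on infected hosts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
from scipy import optimize, stats

from .morphometry import (
    HOOK_PAIRS,
    AnchorMeasurements,
    BarMeasurements,
    HookMeasurements,
    McoMeasurements,
    SpecimenRecord,
)
from .reference import (
    MEASUREMENT_NAMES,
    ParamSummary,
    SpeciesProfile,
    SurveyRecord,
    normalize_host,
)

__all__ = ["SimulationConfig", "simulate_specimens", "simulate_column", "simulate_survey"]

DEFAULT_MISSING_RATE = 0.05
HOOK_VII_MISSING_RATE = 0.5


@dataclass
class SimulationConfig:
    """Study conditions for specimen simulation.

    ``missing_rates`` overrides the per-parameter missingness probability
    (default 0.05 everywhere except hook pair VII at 0.5).  ``sd_rule`` is
    the fraction f in sd = f·(max − min).  Values are always truncated to
    the printed [min, max] (``boundary_policy``)."""

    species: List[str]
    n_per_species: int = 50
    seed: int = 0
    sd_rule: float = 0.25
    latent_size_correlation: float = 0.5
    missing_rates: Dict[str, float] = field(default_factory=dict)
    boundary_policy: str = "truncate"

    def __post_init__(self) -> None:
        if self.n_per_species < 1:
            raise ValueError("n_per_species must be >= 1")
        if not (0.0 <= self.latent_size_correlation < 1.0):
            raise ValueError("latent_size_correlation must be in [0, 1)")
        if not (0.0 < self.sd_rule):
            raise ValueError("sd_rule must be positive")
        if self.boundary_policy != "truncate":
            raise ValueError("only the 'truncate' boundary policy is supported")
        for name, rate in self.missing_rates.items():
            if not (0.0 <= rate <= 1.0):
                raise ValueError(f"missing rate for {name} must be in [0, 1]")

    def missing_rate(self, parameter: str) -> float:
        if parameter in self.missing_rates:
            return self.missing_rates[parameter]
        return HOOK_VII_MISSING_RATE if parameter == "hVII" else DEFAULT_MISSING_RATE


def _matched_loc(summary: ParamSummary, sd: float) -> float:
    """Latent normal location whose [min, max]-truncated mean is the printed mean."""
    lo, hi, target = summary.min, summary.max, summary.working_mean
    # a truncated mean cannot sit arbitrarily close to a bound; clamp the
    # target just inside the attainable range (distorts only near-degenerate
    # cells whose printed mean coincides with an endpoint)
    margin = 0.03 * (hi - lo)
    target = min(max(target, lo + margin), hi - margin)

    def gap(loc: float) -> float:
        a, b = (lo - loc) / sd, (hi - loc) / sd
        return stats.truncnorm.mean(a, b, loc=loc, scale=sd) - target

    lower, upper = lo - 12 * sd, hi + 12 * sd
    return float(optimize.brentq(gap, lower, upper, xtol=1e-10))


def _sample_parameter(
    summary: ParamSummary, n: int, sd_rule: float, copula_u: np.ndarray
) -> np.ndarray:
    """Truncated-normal draws through the Gaussian copula scores ``copula_u``."""
    if summary.min is None or summary.max is None or summary.working_mean is None:
        raise ValueError("summary lacks both mean and range")
    if summary.min == summary.max:
        return np.full(n, summary.min)
    sd = sd_rule * (summary.max - summary.min)
    loc = _matched_loc(summary, sd)
    a, b = (summary.min - loc) / sd, (summary.max - loc) / sd
    p = stats.norm.cdf(copula_u)
    # keep strictly inside (0, 1) so the ppf never lands exactly on a bound
    p = np.clip(p, 1e-12, 1.0 - 1e-12)
    return stats.truncnorm.ppf(p, a, b, loc=loc, scale=sd)


def simulate_column(
    profile: SpeciesProfile,
    host: str,
    n: int,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> List[SpecimenRecord]:
    """``n`` specimens from one measurement column of one species."""
    host = normalize_host(host)
    col = profile.columns[host]
    rho = config.latent_size_correlation
    latent = rng.standard_normal(n)

    sampled: Dict[str, np.ndarray] = {}
    absent: List[str] = []
    for name in MEASUREMENT_NAMES:
        summary = col.get(name)
        if summary is None or summary.working_mean is None:
            absent.append(name)
            continue
        noise = rng.standard_normal(n)
        u = np.sqrt(rho) * latent + np.sqrt(1.0 - rho) * noise
        sampled[name] = _sample_parameter(summary, n, config.sd_rule, u)
    if absent:
        warnings.warn(
            f"{profile.species_name} [{host}]: parameters without published "
            f"summaries emitted missing: {', '.join(absent)}",
            stacklevel=2,
        )

    missing_mask: Dict[str, np.ndarray] = {
        name: rng.random(n) < config.missing_rate(name) for name in sampled
    }

    records: List[SpecimenRecord] = []
    tag = profile.species_name.split()[-1]
    for i in range(n):

        def value(name: str) -> Optional[float]:
            if name not in sampled or missing_mask[name][i]:
                return None
            return float(sampled[name][i])

        hooks = {p: v for p in HOOK_PAIRS if (v := value(f"h{p}")) is not None}
        records.append(
            SpecimenRecord(
                specimen_id=f"sim-{tag}-{host.split()[-1]}-{i:04d}",
                species_label=profile.species_name,
                host_species=host,
                locality="simulated",
                country="",
                dorsal_anchor=AnchorMeasurements(
                    value("da_total"), value("da_ltn"), value("da_inner"),
                    value("da_outer"), value("da_point"),
                ),
                ventral_anchor=AnchorMeasurements(
                    value("va_total"), value("va_ltn"), value("va_inner"),
                    value("va_outer"), value("va_point"),
                ),
                dorsal_bar=BarMeasurements(value("db_len"), value("db_width")),
                ventral_bar=BarMeasurements(value("vb_len"), value("vb_width")),
                hooks=HookMeasurements(hooks),
                mco=McoMeasurements(
                    value("mco_tube"), value("mco_ap"), profile.ap_loop_side
                ),
                broad_inner_roots=profile.broad_inner_roots,
            )
        )
    return records


def simulate_specimens(
    config: SimulationConfig, profiles: Sequence[SpeciesProfile]
) -> List[SpecimenRecord]:
    """Simulated specimens for every requested species.

    ``n_per_species`` specimens are drawn from each measurement column of
    each requested species (so a species with two host-specific columns
    contributes twice that many).  Fully reproducible from ``config.seed``.
    """
    by_name = {p.species_name: p for p in profiles}
    missing = [s for s in config.species if s not in by_name]
    if missing:
        raise ValueError(f"no profile for requested species: {missing}")
    rng = np.random.default_rng(config.seed)
    records: List[SpecimenRecord] = []
    for species in config.species:
        profile = by_name[species]
        for host in profile.columns:
            records.extend(
                simulate_column(profile, host, config.n_per_species, config, rng)
            )
    return records


def simulate_survey(
    prevalence: float,
    intensity_lambda: float,
    n_hosts: int,
    seed: int = 0,
    host_species: str = "simulated host",
    locality: str = "simulated",
) -> SurveyRecord:
    """One survey: Bernoulli infections, zero-truncated Poisson worm counts.

    As λ → 0⁺ every infected host carries exactly one worm (the truncation
    limit); prevalence 0 yields an uninfected survey.
    """
    if n_hosts < 1:
        raise ValueError("n_hosts must be >= 1")
    if not (0.0 <= prevalence <= 1.0):
        raise ValueError("prevalence must lie in [0, 1]")
    if intensity_lambda <= 0:
        raise ValueError("intensity_lambda must be positive")
    rng = np.random.default_rng(seed)
    infected = rng.random(n_hosts) < prevalence
    n_inf = int(infected.sum())
    # inverse-CDF draw conditional on count >= 1
    u = rng.random(n_inf)
    p0 = np.exp(-intensity_lambda)
    counts = stats.poisson.ppf(p0 + u * (1.0 - p0), intensity_lambda)
    counts = np.maximum(counts, 1).astype(int)
    return SurveyRecord(
        host_species=host_species,
        locality=locality,
        country="",
        n_examined=n_hosts,
        worm_counts_per_infected_host=[int(c) for c in counts],
    )
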