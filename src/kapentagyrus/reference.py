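"""Embedded quantitative reference data: species profiles and host surveys.

The package ships, as versioned JSON fixtures, the per-species morphometric
summary columns (range, average and number of structures measured for each
parameter) for the eleven newly delineated species plus *K. pellonulae*, and
the host-survey rows (lots examined, locality, country) with worm counts per
infected host attached wherever the per-host distribution is fixed by the
published infection accounts.

*K. chochamandai* carries two host-specific measurement columns (ex
*Microthrissa moeruensis*, the type host, and ex *Potamothrissa
acutirostris*); all other profiles carry one.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Dict, List, Optional

from .morphometry import (
    HOOK_PAIRS,
    AnchorMeasurements,
    BarMeasurements,
    HookMeasurements,
    McoMeasurements,
    SpecimenRecord,
)

__all__ = [
    "PARAMETER_NAMES",
    "PROPORTION_PARAMETERS",
    "ParamSummary",
    "SpeciesProfile",
    "SurveyRecord",
    "builtin_profiles",
    "builtin_surveys",
    "host_registry",
    "normalize_host",
    "mean_specimen",
    "profile_mean_records",
    "check_proportion_consistency",
]

#: The 23 direct measurements of a specimen, in CSV column order.
MEASUREMENT_NAMES = (
    "da_total", "da_ltn", "da_inner", "da_outer", "da_point",
    "va_total", "va_ltn", "va_inner", "va_outer", "va_point",
    "db_len", "db_width", "vb_len", "vb_width",
    "hI", "hII", "hIII", "hIV", "hV", "hVI", "hVII",
    "mco_tube", "mco_ap",
)

#: Printed proportion rows: (ratio name, numerator, denominator).
PROPORTION_PARAMETERS = (
    ("da_root_ratio", "da_inner", "da_outer"),
    ("da_inner_over_hI", "da_inner", "hI"),
    ("va_root_ratio", "va_inner", "va_outer"),
    ("va_inner_over_hI", "va_inner", "hI"),
)

PARAMETER_NAMES = MEASUREMENT_NAMES + tuple(p[0] for p in PROPORTION_PARAMETERS) + ("hook_avg",)

# Spelling variants across the survey table, the taxonomic accounts and the
# printed key; the survey-table form is canonical for localities, the full
# binomial for hosts.
HOST_ALIASES = {
    "Odaxothrissa ansorgi": "Odaxothrissa ansorgii",
    "Potamothrisssa acutirostris": "Potamothrissa acutirostris",
}
LOCALITY_ALIASES = {
    "Manianga": "Manyanga",
    "Aboumé": "Aboun, Noya River",
}


def normalize_host(name: str) -> str:
    return HOST_ALIASES.get(name.strip(), name.strip())


@dataclass(frozen=True)
class ParamSummary:
    """Printed (min, mean, max, n) summary for one parameter; parts may be absent."""

    min: Optional[float] = None
    mean: Optional[float] = None
    max: Optional[float] = None
    n: Optional[int] = None

    def __post_init__(self) -> None:
        vals = [v for v in (self.min, self.mean, self.max) if v is not None]
        if vals != sorted(vals):
            raise ValueError(f"summary must satisfy min <= mean <= max: {self}")
        if self.n is not None and self.n < 1:
            raise ValueError("n must be >= 1")

    @property
    def working_mean(self) -> Optional[float]:
        """The printed mean; for range-only cells the midpoint (imputed)."""
        if self.mean is not None:
            return self.mean
        if self.min is not None and self.max is not None:
            return 0.5 * (self.min + self.max)
        return None

    @property
    def mean_imputed(self) -> bool:
        return self.mean is None and self.min is not None and self.max is not None

    @property
    def spread(self) -> Optional[float]:
        if self.min is None or self.max is None:
            return None
        return self.max - self.min


@dataclass
class SpeciesProfile:
    """One species: host list, AP loop side and per-parameter summaries.

    ``columns`` maps host name to a full summary column; ``summaries``
    exposes the type-host column, which is what single-column callers want.
    """

    species_name: str
    host_species: List[str]
    type_host: str
    columns: Dict[str, Dict[str, ParamSummary]]
    ap_loop_side: str = "unknown"
    is_new_species: bool = True
    broad_inner_roots: Optional[bool] = None

    def __post_init__(self) -> None:
        for host, col in self.columns.items():
            for name in col:
                if name not in PARAMETER_NAMES:
                    raise ValueError(
                        f"{self.species_name} [{host}]: unknown parameter {name!r}"
                    )

    @property
    def summaries(self) -> Dict[str, ParamSummary]:
        return self.columns[self.type_host]

    def summary(self, parameter: str, host: Optional[str] = None) -> Optional[ParamSummary]:
        col = self.columns.get(normalize_host(host) if host else self.type_host)
        if col is None:
            return None
        return col.get(parameter)


@dataclass
class SurveyRecord:
    """One host-survey row: lot examined at a locality, with worm counts.

    ``worm_counts_per_infected_host`` is ``None`` when the published account
    gives only a range or pooled figure; then ``n_infected_reported`` and
    (possibly) ``reported_mean_intensity`` carry what was stated.
    """

    host_species: str
    locality: str
    country: str
    n_examined: int
    worm_counts_per_infected_host: Optional[List[int]] = None
    parasite_species: Optional[str] = None
    n_infected_reported: Optional[int] = None
    reported_mean_intensity: Optional[float] = None
    row_id: Optional[int] = None
    notes: List[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.n_examined < 0:
            raise ValueError("n_examined must be non-negative")
        counts = self.worm_counts_per_infected_host
        if counts is not None:
            if any(c < 1 for c in counts):
                raise ValueError("worm counts must be >= 1")
            if len(counts) > self.n_examined:
                raise ValueError("more infected hosts than hosts examined")
        if (
            self.n_infected_reported is not None
            and self.n_infected_reported > self.n_examined
        ):
            raise ValueError("n_infected_reported exceeds n_examined")

    @property
    def n_infected(self) -> Optional[int]:
        if self.worm_counts_per_infected_host is not None:
            return len(self.worm_counts_per_infected_host)
        return self.n_infected_reported


def _load_json(name: str) -> dict:
    with resources.files("kapentagyrus.data").joinpath(name).open("r", encoding="utf-8") as fh:
        return json.load(fh)


def builtin_profiles() -> List[SpeciesProfile]:
    """The 12 embedded species profiles (11 new species + *K. pellonulae*)."""
    raw = _load_json("profiles.json")
    profiles: List[SpeciesProfile] = []
    for entry in raw["profiles"]:
        columns = {
            host: {
                name: ParamSummary(
                    min=cell[0], mean=cell[1], max=cell[2],
                    n=None if cell[3] is None else int(cell[3]),
                )
                for name, cell in col.items()
            }
            for host, col in entry["columns"].items()
        }
        profiles.append(
            SpeciesProfile(
                species_name=entry["species"],
                host_species=list(entry["hosts"]),
                type_host=entry["type_host"],
                columns=columns,
                ap_loop_side=entry["ap_loop_side"],
                is_new_species=entry["is_new_species"],
                broad_inner_roots=entry.get("broad_inner_roots"),
            )
        )
    names = [p.species_name for p in profiles]
    if len(set(names)) != len(names):
        raise ValueError("duplicate species names in embedded profiles")
    return profiles


def builtin_surveys() -> List[SurveyRecord]:
    """One :class:`SurveyRecord` per embedded host-survey row (30 rows)."""
    raw = _load_json("surveys.json")
    records: List[SurveyRecord] = []
    for entry in raw["surveys"]:
        records.append(
            SurveyRecord(
                host_species=normalize_host(entry["host"]),
                locality=entry["locality"],
                country=entry["country"],
                n_examined=entry["n_examined"],
                worm_counts_per_infected_host=(
                    None if entry["worm_counts"] is None else list(entry["worm_counts"])
                ),
                parasite_species=entry.get("parasite"),
                n_infected_reported=entry.get("n_infected"),
                reported_mean_intensity=entry.get("reported_mean_intensity"),
                row_id=entry.get("row_id"),
                notes=list(entry.get("notes", [])),
            )
        )
    return records


def host_registry(profiles: Optional[List[SpeciesProfile]] = None) -> Dict[str, List[str]]:
    """Species → recorded host list, including the two Lake Tanganyika species
    (whose morphometric profiles are published elsewhere and not embedded)."""
    registry = {
        "Kapentagyrus limnotrissae": ["Limnothrissa miodon"],
        "Kapentagyrus tanganicanus": ["Limnothrissa miodon", "Stolothrissa tanganicae"],
    }
    for p in profiles if profiles is not None else builtin_profiles():
        registry[p.species_name] = list(p.host_species)
    return registry


def mean_specimen(
    profile: SpeciesProfile, host: Optional[str] = None, specimen_id: Optional[str] = None
) -> SpecimenRecord:
    """A synthetic specimen carrying the working means of one profile column.

    Used to route species through the identification key and to export the
    fixture CSV; parameters absent from the column stay missing.
    """
    host = normalize_host(host) if host else profile.type_host
    col = profile.columns[host]

    def m(name: str) -> Optional[float]:
        s = col.get(name)
        return None if s is None else s.working_mean

    hooks = {
        pair: v for pair in HOOK_PAIRS if (v := m(f"h{pair}")) is not None
    }
    rec = SpecimenRecord(
        specimen_id=specimen_id or f"{profile.species_name} mean ex {host}",
        species_label=profile.species_name,
        host_species=host,
        locality="",
        country="",
        dorsal_anchor=AnchorMeasurements(
            m("da_total"), m("da_ltn"), m("da_inner"), m("da_outer"), m("da_point")
        ),
        ventral_anchor=AnchorMeasurements(
            m("va_total"), m("va_ltn"), m("va_inner"), m("va_outer"), m("va_point")
        ),
        dorsal_bar=BarMeasurements(m("db_len"), m("db_width")),
        ventral_bar=BarMeasurements(m("vb_len"), m("vb_width")),
        hooks=HookMeasurements(hooks),
        mco=McoMeasurements(m("mco_tube"), m("mco_ap"), profile.ap_loop_side),
        broad_inner_roots=profile.broad_inner_roots,
    )
    rec.validate()
    return rec


def profile_mean_records(
    profiles: Optional[List[SpeciesProfile]] = None,
) -> List[SpecimenRecord]:
    """Mean specimens for every profile column (13 records: 12 profiles, with
    *K. chochamandai* contributing one record per host column)."""
    out = []
    for p in profiles if profiles is not None else builtin_profiles():
        for host in p.columns:
            out.append(mean_specimen(p, host))
    return out


def check_proportion_consistency(
    profiles: Optional[List[SpeciesProfile]] = None, rel_tol: float = 0.35
) -> List[str]:
    """Cross-check printed proportion rows against the ratio of length means.

    The printed proportions average per-specimen ratios, so they need not
    equal the ratio of the printed means; gross disagreements (beyond
    ``rel_tol`` relative difference) are returned as messages, not raised.
    """
    issues: List[str] = []
    for p in profiles if profiles is not None else builtin_profiles():
        for host, col in p.columns.items():
            for ratio_name, num_name, den_name in PROPORTION_PARAMETERS:
                ratio = col.get(ratio_name)
                num, den = col.get(num_name), col.get(den_name)
                if ratio is None or num is None or den is None:
                    continue
                if None in (ratio.working_mean, num.working_mean, den.working_mean):
                    continue
                implied = num.working_mean / den.working_mean
                printed = ratio.working_mean
                if not math.isclose(implied, printed, rel_tol=rel_tol):
                    issues.append(
                        f"{p.species_name} [{host}] {ratio_name}: printed mean "
                        f"{printed:g} vs ratio of means {implied:.2f}"
                    )
    return issues
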