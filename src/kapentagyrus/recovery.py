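"""Parameter-recovery study: can the key re-identify simulated specimens?

For each measurement column of each species, specimens are simulated from the
published summaries (no missingness) and routed through the key with host
information.  A species column is *decision-path eligible* when the printed
ranges alone decide every couplet on its path — the whole range lies strictly
on one side of every threshold (printed proportion rows are used for ratio
conditions where available, interval arithmetic on the operand ranges
otherwise) and no decision parameter is absent from the column.  For eligible
columns near-perfect recovery is expected; ineligible columns are reported
with the reason (range straddling a threshold, a missing decision parameter,
or a couplet at which the key contradicts the species description).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .key import KeyCouplet, KeyLead, build_printed_key, identify
from .reference import SpeciesProfile, host_registry
from .simulate import SimulationConfig, simulate_column

__all__ = ["column_eligibility", "run_recovery", "RecoveryReport"]

_RATIO_OPERANDS = {
    "da_root_ratio": ("da_inner", "da_outer"),
    "va_root_ratio": ("va_inner", "va_outer"),
    "da_inner_over_hI": ("da_inner", "hI"),
    "va_inner_over_hI": ("va_inner", "hI"),
    "da_ltn_over_hI": ("da_ltn", "hI"),
    "db_len_over_hI": ("db_len", "hI"),
}


def _interval(col, subject: str) -> Optional[Tuple[float, float]]:
    s = col.get(subject)
    if s is not None and s.min is not None and s.max is not None:
        return (s.min, s.max)
    if subject in _RATIO_OPERANDS:
        num_name, den_name = _RATIO_OPERANDS[subject]
        num, den = col.get(num_name), col.get(den_name)
        if num and den and None not in (num.min, num.max, den.min, den.max):
            return (num.min / den.max, num.max / den.min)
    return None


def _interval_compare(lo: float, hi: float, comparator: str, t: float) -> Optional[bool]:
    """Decide ``value comparator t`` for a value supported on [lo, hi].

    For a non-degenerate interval the boundary carries no probability mass;
    a point value exactly on a strict threshold is undecided, as in the key.
    """
    if lo == hi:
        v = lo
        if comparator == "<":
            return True if v < t else (False if v > t else None)
        if comparator == ">":
            return True if v > t else (False if v < t else None)
        if comparator == "<=":
            return v <= t
        return v >= t
    if comparator == "<":
        return True if hi <= t else (False if lo >= t else None)
    if comparator == ">":
        return True if lo >= t else (False if hi <= t else None)
    if comparator == "<=":
        return True if hi <= t else (False if lo >= t else None)
    return True if lo >= t else (False if hi <= t else None)  # >=


def _lead_interval_eval(lead: KeyLead, profile: SpeciesProfile, host: str) -> Optional[bool]:
    col = profile.columns[host]
    result: Optional[bool] = True
    for cond in lead.conditions:
        if cond.kind in ("measurement", "ratio"):
            iv = _interval(col, cond.subject)
            value = None if iv is None else _interval_compare(iv[0], iv[1], cond.comparator, cond.threshold)
        elif cond.kind == "categorical":
            side = profile.ap_loop_side
            value = None if side == "unknown" else side in cond.threshold
        elif cond.kind == "boolean":
            value = profile.broad_inner_roots
        else:  # host
            value = host in cond.threshold
        if value is None and cond.optional:
            continue
        if value is False:
            return False
        if value is None:
            result = None
    return result


def column_eligibility(
    profile: SpeciesProfile, host: str, key: Optional[Sequence[KeyCouplet]] = None
) -> Tuple[bool, str]:
    """(eligible, reason).  Eligible means the printed ranges route this
    column to its own terminal with every couplet decided outright."""
    key = list(key) if key is not None else build_printed_key()
    by_id = {c.couplet_id: c for c in key}
    cid = 1
    while True:
        couplet = by_id[cid]
        a = _lead_interval_eval(couplet.lead_a, profile, host)
        b = (not a if a is not None else None) if couplet.lead_b.complement \
            else _lead_interval_eval(couplet.lead_b, profile, host)
        if a is True and b is False:
            lead = couplet.lead_a
        elif b is True and a is False:
            lead = couplet.lead_b
        elif a is False and b is False:
            return False, f"key contradiction at couplet {cid}"
        else:
            return False, f"printed ranges do not decide couplet {cid}"
        if lead.goto is not None:
            cid = lead.goto
            continue
        terminal = {t.species for t in lead.terminals}
        if terminal == {profile.species_name}:
            return True, "printed ranges decide every couplet on the path"
        return False, f"printed ranges route to {sorted(terminal)} at couplet {cid}"


@dataclass
class RecoveryReport:
    confusion: pd.DataFrame  # generating column × assigned outcome (counts)
    accuracy: Dict[str, float]  # column label → fraction sole-and-correct
    eligibility: Dict[str, Tuple[bool, str]]
    n_per_column: int
    seed: int
    exempt: List[str] = field(default_factory=list)

    @property
    def eligible_accuracy(self) -> Dict[str, float]:
        return {k: v for k, v in self.accuracy.items() if self.eligibility[k][0]}


def run_recovery(
    profiles: Sequence[SpeciesProfile],
    n_per_column: int = 1000,
    seed: int = 0,
    use_host: bool = True,
    config: Optional[SimulationConfig] = None,
) -> RecoveryReport:
    """Simulate, identify, and tabulate a confusion matrix.

    Simulation uses no missingness (the study asks what the key can do when
    every structure is measurable).  ``accuracy`` counts a specimen as
    recovered only when the generating species is the *sole* candidate.
    """
    key = build_printed_key()
    registry = host_registry(list(profiles))
    rng = np.random.default_rng(seed)
    zero_missing = {name: 0.0 for name in ("hVII",)}

    counts: Dict[str, Dict[str, int]] = {}
    accuracy: Dict[str, float] = {}
    eligibility: Dict[str, Tuple[bool, str]] = {}
    exempt: List[str] = []
    for profile in profiles:
        for host in profile.columns:
            label = (
                profile.species_name
                if len(profile.columns) == 1
                else f"{profile.species_name} ex {host}"
            )
            eligibility[label] = column_eligibility(profile, host, key)
            if not eligibility[label][0]:
                exempt.append(label)
            cfg = config or SimulationConfig(
                species=[profile.species_name],
                n_per_species=n_per_column,
                seed=seed,
            )
            cfg_local = SimulationConfig(
                species=cfg.species,
                n_per_species=n_per_column,
                seed=cfg.seed,
                sd_rule=cfg.sd_rule,
                latent_size_correlation=cfg.latent_size_correlation,
                missing_rates={**{n: 0.0 for n in _all_parameters()}, **zero_missing},
            )
            records = simulate_column(profile, host, n_per_column, cfg_local, rng)
            row: Dict[str, int] = {}
            correct = 0
            for rec in records:
                result = identify(rec, use_host=use_host, key=key, registry=registry)
                if len(result.candidates) == 1:
                    assigned = next(iter(result.candidates))
                else:
                    assigned = "(ambiguous)"
                row[assigned] = row.get(assigned, 0) + 1
                if assigned == profile.species_name:
                    correct += 1
            counts[label] = row
            accuracy[label] = correct / n_per_column

    confusion = (
        pd.DataFrame.from_dict(counts, orient="index").fillna(0).astype(int).sort_index()
    )
    confusion = confusion[sorted(confusion.columns)]
    return RecoveryReport(
        confusion=confusion,
        accuracy=accuracy,
        eligibility=eligibility,
        n_per_column=n_per_column,
        seed=seed,
        exempt=exempt,
    )


def _all_parameters():
    from .reference import MEASUREMENT_NAMES

    return MEASUREMENT_NAMES
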