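"""Measurement scheme for *Kapentagyrus* sclerites and derived diagnostic ratios.

The unit of observation is a single worm (a :class:`SpecimenRecord`) carrying
up to 21 haptoral and 2 genital length measurements in micrometres: five per
anchor (dorsal and ventral), branch length and maximum width per transversal
bar (dorsal and ventral), the lengths of the seven marginal hook pairs
(pairs I–V ventral, VI–VII dorsal), and the axial lengths of the copulatory
tube and accessory piece of the male copulatory organ (MCO).

Missing values are first-class: any field may be ``None``, and every derived
quantity propagates missingness rather than zero-filling.  All lengths are in
µm throughout; there is no unit-conversion layer.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields
from typing import Dict, Iterator, Optional, Tuple

__all__ = [
    "HOOK_PAIRS",
    "AnchorMeasurements",
    "HookMeasurements",
    "BarMeasurements",
    "McoMeasurements",
    "SpecimenRecord",
    "FeatureVector",
    "ValidationError",
    "compute_features",
]

HOOK_PAIRS: Tuple[str, ...] = ("I", "II", "III", "IV", "V", "VI", "VII")


class ValidationError(ValueError):
    """A measurement violates a type invariant; the message names the field."""


def _check_positive(value: Optional[float], name: str) -> None:
    if value is None:
        return
    if not math.isfinite(value) or value <= 0:
        raise ValidationError(f"{name} must be a positive finite length in µm, got {value!r}")


@dataclass
class AnchorMeasurements:
    """The five standard anchor lengths (µm); any field may be missing.

    ``total_length`` runs from the tip of the inner root to the anchor point,
    ``length_to_notch`` to the notch between the two roots.
    """

    total_length: Optional[float] = None
    length_to_notch: Optional[float] = None
    inner_root_length: Optional[float] = None
    outer_root_length: Optional[float] = None
    point_length: Optional[float] = None

    def validate(self, prefix: str = "anchor") -> None:
        for f in fields(self):
            _check_positive(getattr(self, f.name), f"{prefix}.{f.name}")
        if (
            self.total_length is not None
            and self.length_to_notch is not None
            and self.length_to_notch > self.total_length
        ):
            raise ValidationError(
                f"{prefix}.length_to_notch ({self.length_to_notch}) exceeds "
                f"total_length ({self.total_length})"
            )
        if (
            self.total_length is not None
            and self.point_length is not None
            and self.point_length >= self.total_length
        ):
            raise ValidationError(
                f"{prefix}.point_length ({self.point_length}) must be smaller "
                f"than total_length ({self.total_length})"
            )

    def scaled(self, c: float) -> "AnchorMeasurements":
        return AnchorMeasurements(
            *(None if v is None else v * c for v in (
                self.total_length, self.length_to_notch, self.inner_root_length,
                self.outer_root_length, self.point_length))
        )


@dataclass
class HookMeasurements:
    """Lengths (µm) of the marginal hook pairs, keyed by Roman label I–VII."""

    length_by_pair: Dict[str, float] = field(default_factory=dict)

    def validate(self, prefix: str = "hooks") -> None:
        for pair, value in self.length_by_pair.items():
            if pair not in HOOK_PAIRS:
                raise ValidationError(f"{prefix}: unknown hook pair label {pair!r}")
            _check_positive(value, f"{prefix}[{pair}]")

    def get(self, pair: str) -> Optional[float]:
        return self.length_by_pair.get(pair)

    def scaled(self, c: float) -> "HookMeasurements":
        return HookMeasurements({p: v * c for p, v in self.length_by_pair.items()})


@dataclass
class BarMeasurements:
    """Transversal bar: branch length and maximum branch width (µm)."""

    branch_length: Optional[float] = None
    branch_max_width: Optional[float] = None

    def validate(self, prefix: str = "bar") -> None:
        _check_positive(self.branch_length, f"{prefix}.branch_length")
        _check_positive(self.branch_max_width, f"{prefix}.branch_max_width")
        if (
            self.branch_length is not None
            and self.branch_max_width is not None
            and self.branch_max_width >= self.branch_length
        ):
            raise ValidationError(
                f"{prefix}.branch_max_width ({self.branch_max_width}) must be "
                f"smaller than branch_length ({self.branch_length})"
            )

    def scaled(self, c: float) -> "BarMeasurements":
        return BarMeasurements(
            None if self.branch_length is None else self.branch_length * c,
            None if self.branch_max_width is None else self.branch_max_width * c,
        )


@dataclass
class McoMeasurements:
    """Male copulatory organ: tube and accessory-piece axial lengths (µm).

    ``ap_loop_side`` records from which side the accessory piece loops around
    the copulatory tube — a categorical diagnostic character.
    """

    copulatory_tube_axial_length: Optional[float] = None
    accessory_piece_axial_length: Optional[float] = None
    ap_loop_side: str = "unknown"
    heel_present: Optional[bool] = None

    def validate(self, prefix: str = "mco") -> None:
        _check_positive(self.copulatory_tube_axial_length, f"{prefix}.copulatory_tube_axial_length")
        _check_positive(self.accessory_piece_axial_length, f"{prefix}.accessory_piece_axial_length")
        if self.ap_loop_side not in ("left", "right", "unknown"):
            raise ValidationError(
                f"{prefix}.ap_loop_side must be 'left', 'right' or 'unknown', "
                f"got {self.ap_loop_side!r}"
            )

    def scaled(self, c: float) -> "McoMeasurements":
        return McoMeasurements(
            None if self.copulatory_tube_axial_length is None
            else self.copulatory_tube_axial_length * c,
            None if self.accessory_piece_axial_length is None
            else self.accessory_piece_axial_length * c,
            self.ap_loop_side,
            self.heel_present,
        )


@dataclass
class SpecimenRecord:
    """One worm: full measurement set plus host and locality metadata.

    ``broad_inner_roots`` is the optional qualitative character used by the
    first couplet of the identification key ("broad inner anchor roots"); it
    has no numeric definition, so it is carried as an optional boolean.
    """

    specimen_id: str
    locality: str = ""
    country: str = ""
    species_label: Optional[str] = None
    host_species: Optional[str] = None
    dorsal_anchor: AnchorMeasurements = field(default_factory=AnchorMeasurements)
    ventral_anchor: AnchorMeasurements = field(default_factory=AnchorMeasurements)
    dorsal_bar: BarMeasurements = field(default_factory=BarMeasurements)
    ventral_bar: BarMeasurements = field(default_factory=BarMeasurements)
    hooks: HookMeasurements = field(default_factory=HookMeasurements)
    mco: McoMeasurements = field(default_factory=McoMeasurements)
    broad_inner_roots: Optional[bool] = None

    def validate(self) -> None:
        if not self.specimen_id:
            raise ValidationError("specimen_id must be non-empty")
        self.dorsal_anchor.validate("dorsal_anchor")
        self.ventral_anchor.validate("ventral_anchor")
        self.dorsal_bar.validate("dorsal_bar")
        self.ventral_bar.validate("ventral_bar")
        self.hooks.validate("hooks")
        self.mco.validate("mco")

    def scaled(self, c: float) -> "SpecimenRecord":
        """All lengths multiplied by ``c`` (> 0); metadata unchanged."""
        if c <= 0:
            raise ValueError("scale factor must be positive")
        return SpecimenRecord(
            specimen_id=self.specimen_id,
            locality=self.locality,
            country=self.country,
            species_label=self.species_label,
            host_species=self.host_species,
            dorsal_anchor=self.dorsal_anchor.scaled(c),
            ventral_anchor=self.ventral_anchor.scaled(c),
            dorsal_bar=self.dorsal_bar.scaled(c),
            ventral_bar=self.ventral_bar.scaled(c),
            hooks=self.hooks.scaled(c),
            mco=self.mco.scaled(c),
            broad_inner_roots=self.broad_inner_roots,
        )

    def measurements(self) -> Dict[str, Optional[float]]:
        """Flat mapping of the 23 numeric fields under the CSV column names."""
        out: Dict[str, Optional[float]] = {
            "da_total": self.dorsal_anchor.total_length,
            "da_ltn": self.dorsal_anchor.length_to_notch,
            "da_inner": self.dorsal_anchor.inner_root_length,
            "da_outer": self.dorsal_anchor.outer_root_length,
            "da_point": self.dorsal_anchor.point_length,
            "va_total": self.ventral_anchor.total_length,
            "va_ltn": self.ventral_anchor.length_to_notch,
            "va_inner": self.ventral_anchor.inner_root_length,
            "va_outer": self.ventral_anchor.outer_root_length,
            "va_point": self.ventral_anchor.point_length,
            "db_len": self.dorsal_bar.branch_length,
            "db_width": self.dorsal_bar.branch_max_width,
            "vb_len": self.ventral_bar.branch_length,
            "vb_width": self.ventral_bar.branch_max_width,
        }
        for pair in HOOK_PAIRS:
            out[f"h{pair}"] = self.hooks.get(pair)
        out["mco_tube"] = self.mco.copulatory_tube_axial_length
        out["mco_ap"] = self.mco.accessory_piece_axial_length
        return out


@dataclass(frozen=True)
class FeatureVector:
    """Per-specimen diagnostic ratios; ``None`` whenever an operand is missing.

    These are the proportions the genus diagnosis relies on: inner/outer root
    length per anchor, inner root length relative to the first hook pair, and
    — used by the Lake Tanganyika couplet of the key — dorsal length-to-notch
    and dorsal bar branch length relative to the first hook pair.
    """

    dorsal_root_ratio: Optional[float] = None
    ventral_root_ratio: Optional[float] = None
    dorsal_inner_root_over_hook1: Optional[float] = None
    ventral_inner_root_over_hook1: Optional[float] = None
    ltn_dorsal_over_hook1: Optional[float] = None
    dorsal_bar_branch_over_hook1: Optional[float] = None

    def as_dict(self) -> Dict[str, Optional[float]]:
        return {
            "da_root_ratio": self.dorsal_root_ratio,
            "va_root_ratio": self.ventral_root_ratio,
            "da_inner_over_hI": self.dorsal_inner_root_over_hook1,
            "va_inner_over_hI": self.ventral_inner_root_over_hook1,
            "da_ltn_over_hI": self.ltn_dorsal_over_hook1,
            "db_len_over_hI": self.dorsal_bar_branch_over_hook1,
        }

    def __iter__(self) -> Iterator[Optional[float]]:
        return iter(self.as_dict().values())


def _ratio(num: Optional[float], den: Optional[float]) -> Optional[float]:
    if num is None or den is None:
        return None
    return num / den


def compute_features(record: SpecimenRecord) -> FeatureVector:
    """Diagnostic ratios of one specimen.

    The record is validated first (a non-positive measurement raises
    :class:`ValidationError` naming the field).  Each ratio is either a
    positive finite number or ``None``; a missing operand never becomes zero.
    Ratios are per-specimen quantities: summaries over samples should average
    these ratios, not divide averaged lengths.
    """
    record.validate()
    h1 = record.hooks.get("I")
    return FeatureVector(
        dorsal_root_ratio=_ratio(
            record.dorsal_anchor.inner_root_length, record.dorsal_anchor.outer_root_length
        ),
        ventral_root_ratio=_ratio(
            record.ventral_anchor.inner_root_length, record.ventral_anchor.outer_root_length
        ),
        dorsal_inner_root_over_hook1=_ratio(record.dorsal_anchor.inner_root_length, h1),
        ventral_inner_root_over_hook1=_ratio(record.ventral_anchor.inner_root_length, h1),
        ltn_dorsal_over_hook1=_ratio(record.dorsal_anchor.length_to_notch, h1),
        dorsal_bar_branch_over_hook1=_ratio(record.dorsal_bar.branch_length, h1),
    )
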