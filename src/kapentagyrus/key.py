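"""The dichotomous identification key as an executable, traceable decision tree.

The printed key separates the fourteen known species of *Kapentagyrus* in 13
couplets.  Each couplet offers two leads; a lead is a conjunction of atomic
conditions over anchor/hook measurements, diagnostic ratios, the side from
which the accessory piece loops the copulatory tube, or the host identity,
and either forwards to another couplet or names terminal species.

Evaluation is three-valued: a condition over a missing operand — or a strict
comparison that lands exactly on its threshold, which the key leaves
undefined — is *undecided*.  A lead is followed alone only when it is the
single lead not known to be false; otherwise both leads are explored, the
candidate sets are unioned, and a note records why.  When both leads are
definitely false the key itself is contradictory at that couplet for that
specimen; this genuinely happens (see couplet 11) and is reported, never
silently repaired.

Two modes exist: ``strict`` evaluates the key exactly as printed;
``annotated`` routes identically but additionally warns at couplets where
the printed key is known to conflict with the species descriptions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, List, Optional, Sequence, Set, Tuple, Union

from .morphometry import SpecimenRecord, compute_features
from .reference import host_registry, normalize_host

__all__ = [
    "AtomicCondition",
    "KeyLead",
    "KeyCouplet",
    "KeyNote",
    "KeyResult",
    "UnknownHostError",
    "build_printed_key",
    "identify",
    "validate_key",
    "ValidationRow",
    "key_to_json",
    "format_trace",
]

_TANGANYIKA_HOSTS = frozenset({"Limnothrissa miodon", "Stolothrissa tanganicae"})
_NON_TANGANYIKA_HOSTS = frozenset(
    {
        "Nannothrissa parva",
        "Pellonula leonensis",
        "Potamothrissa acutirostris",
        "Microthrissa congica",
        "Microthrissa moeruensis",
        "Microthrissa royauxi",
    }
)
_ODAX_HOSTS = frozenset(
    {"Odaxothrissa ansorgii", "Odaxothrissa mento", "Odaxothrissa losera"}
)


class UnknownHostError(ValueError):
    """Raised when host-aware identification meets a host not in the registry."""


@dataclass(frozen=True)
class AtomicCondition:
    """One clause of a lead.

    kind ∈ {measurement, ratio, categorical, host, boolean}; ``comparator``
    is one of <, <=, >, >= for numeric kinds and ``in`` for categorical/host.
    ``optional`` marks clauses that are skipped (not undecided) when their
    operand is unavailable — used for the qualitative "broad inner anchor
    roots" character and for the host gloss of couplet 1, so that the
    quantitative conditions alone decide when that information is absent.
    """

    kind: str
    subject: str
    comparator: str
    threshold: Union[float, FrozenSet[str]]
    optional: bool = False

    def __post_init__(self) -> None:
        numeric = self.kind in ("measurement", "ratio")
        if numeric and self.comparator not in ("<", "<=", ">", ">="):
            raise ValueError(f"bad comparator {self.comparator!r} for {self.kind}")
        if numeric and not isinstance(self.threshold, (int, float)):
            raise ValueError("numeric condition needs a numeric threshold")
        if numeric and self.threshold <= 0:
            raise ValueError("numeric thresholds are positive lengths/ratios")
        if self.kind in ("categorical", "host") and self.comparator != "in":
            raise ValueError(f"{self.kind} condition uses the 'in' comparator")

    def describe(self) -> str:
        if self.kind in ("measurement", "ratio"):
            return f"{self.subject} {self.comparator} {self.threshold:g}"
        if self.kind == "boolean":
            return f"{self.subject}"
        return f"{self.subject} in {{{', '.join(sorted(self.threshold))}}}"

    def evaluate(self, ctx: "EvalContext") -> Optional[bool]:
        """True / False / None (undecided); None also flags boundary hits."""
        if self.kind in ("measurement", "ratio"):
            value = ctx.numeric(self.subject)
            if value is None:
                return None
            if self.comparator == "<":
                return True if value < self.threshold else (False if value > self.threshold else None)
            if self.comparator == ">":
                return True if value > self.threshold else (False if value < self.threshold else None)
            if self.comparator == "<=":
                return value <= self.threshold
            return value >= self.threshold
        if self.kind == "categorical":
            value = ctx.categorical(self.subject)
            if value is None or value == "unknown":
                return None
            return value in self.threshold
        if self.kind == "boolean":
            value = ctx.boolean(self.subject)
            return value  # None when unrecorded; 'optional' handles the skip
        # host
        if not ctx.use_host or ctx.host is None:
            return None
        return ctx.host in self.threshold


@dataclass
class EvalContext:
    """Flattened view of one specimen for condition evaluation."""

    values: Dict[str, Optional[float]]
    ap_loop_side: str
    broad_inner_roots: Optional[bool]
    host: Optional[str]
    use_host: bool

    @classmethod
    def from_record(cls, record: SpecimenRecord, use_host: bool) -> "EvalContext":
        values = dict(record.measurements())
        values.update(compute_features(record).as_dict())
        host = normalize_host(record.host_species) if record.host_species else None
        return cls(values, record.mco.ap_loop_side, record.broad_inner_roots, host, use_host)

    def numeric(self, subject: str) -> Optional[float]:
        return self.values.get(subject)

    def categorical(self, subject: str) -> Optional[str]:
        if subject == "ap_loop_side":
            return self.ap_loop_side
        return None

    def boolean(self, subject: str) -> Optional[bool]:
        if subject == "broad_inner_roots":
            return self.broad_inner_roots
        return None


@dataclass(frozen=True)
class Terminal:
    species: str
    hosts: Tuple[str, ...]


@dataclass
class KeyLead:
    """One lead of a couplet: a conjunction and where it sends the user.

    ``complement`` marks the printed "Anchors different" alternative, whose
    truth value is defined as the negation of the sister lead.
    """

    conditions: List[AtomicCondition]
    goto: Optional[int] = None
    terminals: List[Terminal] = field(default_factory=list)
    complement: bool = False

    def evaluate(self, ctx: EvalContext) -> Optional[bool]:
        result: Optional[bool] = True
        for cond in self.conditions:
            value = cond.evaluate(ctx)
            if value is None and cond.optional:
                continue
            if value is False:
                return False
            if value is None:
                result = None
        return result

    def describe(self) -> str:
        if self.complement:
            return "anchors different (complement of the first lead)"
        return " and ".join(c.describe() for c in self.conditions) or "(no conditions)"


@dataclass
class KeyCouplet:
    couplet_id: int
    lead_a: KeyLead
    lead_b: KeyLead
    annotation: Optional[str] = None  # emitted in annotated mode


@dataclass(frozen=True)
class KeyNote:
    couplet_id: int
    kind: str  # missing_or_boundary | both_leads | contradiction | host_filter | annotation
    message: str

    def __str__(self) -> str:
        return f"[couplet {self.couplet_id}] {self.message}"


@dataclass
class KeyResult:
    candidates: Set[str]
    path: List[Tuple[int, str]]  # (couplet_id, 'a' | 'b' | 'both')
    ambiguous: bool
    notes: List[KeyNote]


def _m(subject: str, comparator: str, threshold: float, optional: bool = False) -> AtomicCondition:
    return AtomicCondition("measurement", subject, comparator, threshold, optional)


def _r(subject: str, comparator: str, threshold: float) -> AtomicCondition:
    return AtomicCondition("ratio", subject, comparator, threshold)


def _hosts(hosts: FrozenSet[str], optional: bool = False) -> AtomicCondition:
    return AtomicCondition("host", "host", "in", hosts, optional)


def build_printed_key() -> List[KeyCouplet]:
    """The printed 13-couplet key, verified acyclic with 14 reachable terminals."""
    t = Terminal
    couplets = [
        KeyCouplet(
            1,
            KeyLead(
                [
                    _m("va_ltn", ">", 24.0),
                    AtomicCondition("boolean", "broad_inner_roots", ">", 1.0, optional=True),
                    _m("da_total", ">", 31.0),
                    _hosts(_ODAX_HOSTS, optional=True),
                ],
                goto=2,
            ),
            KeyLead([], goto=4, complement=True),
            annotation=(
                "the quantitative conditions of this couplet are also met by the mean "
                "measurements of K. verbisti, which does not infect Odaxothrissa"
            ),
        ),
        KeyCouplet(
            2,
            KeyLead(
                [_m("va_total", ">", 40.0), _m("va_inner", ">", 22.0)],
                terminals=[t("Kapentagyrus sefcae", ("Odaxothrissa losera",))],
            ),
            KeyLead([_m("va_total", "<", 40.0), _m("va_inner", "<", 22.0)], goto=3),
        ),
        KeyCouplet(
            3,
            KeyLead(
                [_m("da_inner", ">", 18.0), _m("da_outer", ">", 7.0)],
                terminals=[t("Kapentagyrus marispastoris", ("Odaxothrissa mento",))],
            ),
            KeyLead(
                [_m("da_inner", "<", 18.0), _m("da_outer", "<", 7.0)],
                terminals=[t("Kapentagyrus voreli", ("Odaxothrissa ansorgii",))],
            ),
        ),
        KeyCouplet(
            4,
            KeyLead([_hosts(_TANGANYIKA_HOSTS)], goto=5),
            KeyLead([_hosts(_NON_TANGANYIKA_HOSTS)], goto=6),
        ),
        KeyCouplet(
            5,
            KeyLead(
                [
                    _r("va_root_ratio", ">", 2.6),
                    _r("da_ltn_over_hI", "<", 1.2),
                    _r("db_len_over_hI", "<", 1.5),
                ],
                terminals=[t("Kapentagyrus limnotrissae", ("Limnothrissa miodon",))],
            ),
            KeyLead(
                [
                    _r("va_root_ratio", "<", 2.6),
                    _r("da_ltn_over_hI", ">", 1.2),
                    _r("db_len_over_hI", ">", 1.5),
                ],
                terminals=[
                    t(
                        "Kapentagyrus tanganicanus",
                        ("Limnothrissa miodon", "Stolothrissa tanganicae"),
                    )
                ],
            ),
        ),
        KeyCouplet(
            6,
            KeyLead([_hosts(frozenset({"Pellonula leonensis"}))], goto=7),
            KeyLead(
                [_hosts(_NON_TANGANYIKA_HOSTS - {"Pellonula leonensis"})], goto=10
            ),
        ),
        KeyCouplet(
            7,
            KeyLead(
                [_m("da_total", ">=", 40.0), _m("va_total", ">=", 40.0)],
                terminals=[t("Kapentagyrus pellonulae", ("Pellonula leonensis",))],
            ),
            KeyLead([_m("da_total", "<", 40.0), _m("va_total", "<", 40.0)], goto=8),
        ),
        KeyCouplet(
            8,
            KeyLead(
                [_m("da_total", ">=", 35.0), _m("da_total", "<", 40.0)],
                terminals=[t("Kapentagyrus verbisti", ("Pellonula leonensis",))],
            ),
            KeyLead([_m("da_total", "<", 35.0)], goto=9),
        ),
        KeyCouplet(
            9,
            KeyLead(
                [_m("va_ltn", "<", 19.0)],
                terminals=[t("Kapentagyrus hahni", ("Pellonula leonensis",))],
            ),
            KeyLead(
                [_m("va_ltn", ">=", 19.0)],
                terminals=[t("Kapentagyrus hugei", ("Pellonula leonensis",))],
            ),
        ),
        KeyCouplet(
            10,
            KeyLead([_r("da_inner_over_hI", ">", 1.0)], goto=11),
            KeyLead([_r("da_inner_over_hI", "<", 1.0)], goto=13),
            annotation=(
                "the table means of K. boegeri put it on the '< 1' lead although the "
                "key resolves K. boegeri under couplet 12"
            ),
        ),
        KeyCouplet(
            11,
            KeyLead(
                [
                    AtomicCondition("categorical", "ap_loop_side", "in", frozenset({"right"})),
                    _m("hVI", "<", 15.0),
                    _m("hVII", "<", 15.0),
                ],
                terminals=[t("Kapentagyrus rochetteae", ("Microthrissa royauxi",))],
            ),
            KeyLead(
                [
                    AtomicCondition("categorical", "ap_loop_side", "in", frozenset({"left"})),
                    _m("hVI", ">", 15.0),
                    _m("hVII", ">", 15.0),
                ],
                goto=12,
            ),
            annotation=(
                "the printed key sends accessory-piece-right specimens to K. rochetteae, "
                "but the species accounts describe the loop of K. rochetteae from the "
                "left and of K. bisthoveni from the right"
            ),
        ),
        KeyCouplet(
            12,
            KeyLead(
                [_m("da_inner", "<", 12.0)],
                terminals=[t("Kapentagyrus boegeri", ("Microthrissa congica",))],
            ),
            KeyLead(
                [_m("da_inner", ">=", 12.0)],
                terminals=[t("Kapentagyrus bisthoveni", ("Microthrissa congica",))],
            ),
        ),
        KeyCouplet(
            13,
            KeyLead(
                [_m("va_ltn", "<", 19.0)],
                terminals=[t("Kapentagyrus parisellei", ("Nannothrissa parva",))],
            ),
            KeyLead(
                [_m("va_ltn", ">", 19.0)],
                terminals=[
                    t(
                        "Kapentagyrus chochamandai",
                        ("Microthrissa moeruensis", "Potamothrissa acutirostris"),
                    )
                ],
            ),
            annotation=(
                "the single K. chochamandai specimen ex P. acutirostris has a ventral "
                "length to notch of 18.5 µm, conflicting with the '> 19 µm' lead"
            ),
        ),
    ]
    _assert_structure(couplets)
    return couplets


def _assert_structure(couplets: Sequence[KeyCouplet]) -> None:
    by_id = {c.couplet_id: c for c in couplets}
    if len(by_id) != len(couplets):
        raise ValueError("duplicate couplet ids")
    reachable: Set[int] = set()
    terminals: Set[str] = set()

    def visit(cid: int, stack: Tuple[int, ...]) -> None:
        if cid in stack:
            raise ValueError(f"cycle through couplet {cid}")
        if cid not in by_id:
            raise ValueError(f"goto target {cid} does not exist")
        reachable.add(cid)
        for lead in (by_id[cid].lead_a, by_id[cid].lead_b):
            if lead.goto is not None:
                visit(lead.goto, stack + (cid,))
            for term in lead.terminals:
                terminals.add(term.species)

    visit(1, ())
    if reachable != set(by_id):
        raise ValueError(f"unreachable couplets: {set(by_id) - reachable}")
    if len(terminals) != 14:
        raise ValueError(f"expected 14 terminal species, found {len(terminals)}")


def key_terminals(key: Sequence[KeyCouplet]) -> List[Terminal]:
    out = []
    for couplet in key:
        for lead in (couplet.lead_a, couplet.lead_b):
            out.extend(lead.terminals)
    return out


def identify(
    record: SpecimenRecord,
    use_host: bool = True,
    key: Optional[Sequence[KeyCouplet]] = None,
    mode: str = "strict",
    registry: Optional[Dict[str, List[str]]] = None,
) -> KeyResult:
    """Route one specimen through the key.

    Deterministic and pure: identical record and key give an identical
    result.  With ``use_host`` (the default, since two couplets are purely
    host-based) host conditions participate and, at the end, candidate
    species never recorded from the specimen's host are filtered out when at
    least one consistent candidate remains.  A host name absent from the
    registry raises :class:`UnknownHostError` listing the known hosts.
    """
    if mode not in ("strict", "annotated"):
        raise ValueError("mode must be 'strict' or 'annotated'")
    key = list(key) if key is not None else build_printed_key()
    registry = registry if registry is not None else host_registry()
    known_hosts = sorted({h for hosts in registry.values() for h in hosts})

    host = normalize_host(record.host_species) if record.host_species else None
    if use_host and host is not None and host not in known_hosts:
        raise UnknownHostError(
            f"host {host!r} is not in the registry; known hosts: {', '.join(known_hosts)}"
        )

    ctx = EvalContext.from_record(record, use_host)
    by_id = {c.couplet_id: c for c in key}
    candidates: Set[str] = set()
    path: List[Tuple[int, str]] = []
    notes: List[KeyNote] = []
    had_both_step = False
    seen_annotations: Set[int] = set()

    def follow(lead: KeyLead) -> None:
        if lead.goto is not None:
            walk(lead.goto)
        for term in lead.terminals:
            candidates.add(term.species)

    def walk(cid: int) -> None:
        nonlocal had_both_step
        couplet = by_id[cid]
        if mode == "annotated" and couplet.annotation and cid not in seen_annotations:
            seen_annotations.add(cid)
            notes.append(KeyNote(cid, "annotation", couplet.annotation))
        a = couplet.lead_a.evaluate(ctx)
        b = (not a if a is not None else None) if couplet.lead_b.complement else couplet.lead_b.evaluate(ctx)
        if a is not False and b is False:
            path.append((cid, "a"))
            follow(couplet.lead_a)
        elif b is not False and a is False:
            path.append((cid, "b"))
            follow(couplet.lead_b)
        else:
            path.append((cid, "both"))
            had_both_step = True
            if a is False and b is False:
                notes.append(
                    KeyNote(
                        cid,
                        "contradiction",
                        "neither lead is satisfied; the key is inconsistent for this "
                        "specimen here — both leads explored",
                    )
                )
            elif a is True and b is True:
                notes.append(
                    KeyNote(cid, "both_leads", "both leads satisfied; both explored")
                )
            else:
                notes.append(
                    KeyNote(
                        cid,
                        "missing_or_boundary",
                        "undecidable (missing operand or boundary equality); both leads explored",
                    )
                )
            follow(couplet.lead_a)
            follow(couplet.lead_b)

    walk(1)

    if use_host and host is not None and len(candidates) > 1:
        consistent = {s for s in candidates if host in registry.get(s, [])}
        if consistent and consistent != candidates:
            notes.append(
                KeyNote(
                    0,
                    "host_filter",
                    f"dropped {sorted(candidates - consistent)} — not recorded from {host}",
                )
            )
            candidates = consistent

    ambiguous = len(candidates) > 1 or had_both_step
    return KeyResult(candidates=candidates, path=path, ambiguous=ambiguous, notes=notes)


@dataclass
class ValidationRow:
    """Outcome of routing one profile column's mean specimen through the key."""

    species: str
    host: str
    candidates: Set[str]
    path: List[Tuple[int, str]]
    outcome: str  # match | match_with_missing_data | inconsistency
    notes: List[KeyNote]

    @property
    def matched(self) -> bool:
        return self.outcome != "inconsistency"


def validate_key(
    profiles,
    use_host: bool = True,
    key: Optional[Sequence[KeyCouplet]] = None,
    mode: str = "strict",
) -> Dict[str, List[ValidationRow]]:
    """Route every profile column's mean specimen; report matches and conflicts.

    Returns a mapping species → rows (one row per measurement column, so
    *K. chochamandai* has two).  A row is an ``inconsistency`` when the
    species is not among the candidates, or when routing hit a couplet at
    which neither lead was satisfied despite complete operands — the two ways
    the printed key disagrees with the measurement tables.  Ambiguity caused
    purely by measurements absent from the published column is reported as
    ``match_with_missing_data``.
    """
    from .reference import mean_specimen  # local import to avoid cycle at module load

    key = list(key) if key is not None else build_printed_key()
    registry = host_registry(profiles)
    report: Dict[str, List[ValidationRow]] = {}
    for profile in profiles:
        rows = []
        for host in profile.columns:
            record = mean_specimen(profile, host)
            result = identify(record, use_host=use_host, key=key, mode=mode, registry=registry)
            contradiction = any(n.kind == "contradiction" for n in result.notes)
            if profile.species_name not in result.candidates or contradiction:
                outcome = "inconsistency"
            elif result.candidates == {profile.species_name} and not result.ambiguous:
                outcome = "match"
            else:
                outcome = "match_with_missing_data"
            rows.append(
                ValidationRow(
                    species=profile.species_name,
                    host=host,
                    candidates=result.candidates,
                    path=result.path,
                    outcome=outcome,
                    notes=result.notes,
                )
            )
        report[profile.species_name] = rows
    return report


def key_to_json(key: Sequence[KeyCouplet]) -> str:
    """Serialize a key to JSON (couplets, leads, conditions, terminals)."""

    def cond(c: AtomicCondition) -> dict:
        threshold = sorted(c.threshold) if isinstance(c.threshold, frozenset) else c.threshold
        return {
            "kind": c.kind,
            "subject": c.subject,
            "comparator": c.comparator,
            "threshold": threshold,
            "optional": c.optional,
        }

    def lead(l: KeyLead) -> dict:
        return {
            "conditions": [cond(c) for c in l.conditions],
            "goto": l.goto,
            "terminals": [{"species": t.species, "hosts": list(t.hosts)} for t in l.terminals],
            "complement": l.complement,
        }

    return json.dumps(
        [
            {
                "couplet": c.couplet_id,
                "lead_a": lead(c.lead_a),
                "lead_b": lead(c.lead_b),
                "annotation": c.annotation,
            }
            for c in key
        ],
        indent=2,
    )


def format_trace(result: KeyResult) -> str:
    """Human-readable indented couplet path of one identification."""
    lines = []
    for depth, (cid, lead) in enumerate(result.path):
        lines.append("  " * depth + f"couplet {cid}: lead {lead}")
    lines.append(
        "candidates: " + ", ".join(sorted(result.candidates))
        + ("  (ambiguous)" if result.ambiguous else "")
    )
    for note in result.notes:
        lines.append(f"note: {note}")
    return "\n".join(lines)
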