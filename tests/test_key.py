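import pytest

from kapentagyrus.key import (
    UnknownHostError,
    build_printed_key,
    identify,
    key_terminals,
    key_to_json,
    validate_key,
)
from kapentagyrus.morphometry import (
    AnchorMeasurements,
    HookMeasurements,
    McoMeasurements,
    SpecimenRecord,
)
from kapentagyrus.reference import mean_specimen
from kapentagyrus.simulate import SimulationConfig, simulate_column

import numpy as np


class TestStructure:
    def test_thirteen_couplets_fourteen_terminals(self, printed_key):
        assert len(printed_key) == 13
        assert len({t.species for t in key_terminals(printed_key)}) == 14

    def test_terminals_span_eleven_hosts(self, printed_key):
        hosts = {h for t in key_terminals(printed_key) for h in t.hosts}
        assert len(hosts) == 11

    def test_couplet_nine_separates_hahni_from_hugei(self, printed_key):
        nine = next(c for c in printed_key if c.couplet_id == 9)
        assert nine.lead_a.terminals[0].species == "Kapentagyrus hahni"
        assert nine.lead_a.conditions[0].describe() == "va_ltn < 19"
        assert nine.lead_b.terminals[0].species == "Kapentagyrus hugei"

    def test_shared_species_terminal_keeps_both_hosts(self, printed_key):
        cho = next(
            t for t in key_terminals(printed_key)
            if t.species == "Kapentagyrus chochamandai"
        )
        assert set(cho.hosts) == {"Microthrissa moeruensis", "Potamothrissa acutirostris"}

    def test_serializes_to_json(self, printed_key):
        import json

        payload = json.loads(key_to_json(printed_key))
        assert len(payload) == 13
        assert payload[0]["couplet"] == 1


class TestIdentify:
    def test_sefcae_mean_routes_in_two_couplets(self, profiles_by_epithet, printed_key):
        rec = mean_specimen(profiles_by_epithet["sefcae"])
        result = identify(rec, key=printed_key)
        assert result.candidates == {"Kapentagyrus sefcae"}
        assert [c for c, _ in result.path] == [1, 2]
        assert not result.ambiguous

    def test_verbisti_mean_routes_via_host(self, profiles_by_epithet, printed_key):
        rec = mean_specimen(profiles_by_epithet["verbisti"])
        result = identify(rec, key=printed_key)
        assert result.candidates == {"Kapentagyrus verbisti"}
        assert [c for c, _ in result.path] == [1, 4, 6, 7, 8]

    def test_all_measurements_missing_yields_every_terminal(self, printed_key):
        rec = SpecimenRecord(specimen_id="empty")
        result = identify(rec, use_host=False, key=printed_key)
        assert result.ambiguous
        assert len(result.candidates) == 14

    def test_boundary_equality_is_undecided(self, printed_key):
        """A ventral length-to-notch of exactly 19 µm leaves couplet 9 open."""
        rec = SpecimenRecord(
            specimen_id="edge",
            host_species="Pellonula leonensis",
            dorsal_anchor=AnchorMeasurements(total_length=28.0),
            ventral_anchor=AnchorMeasurements(total_length=27.0, length_to_notch=19.0),
        )
        result = identify(rec, key=printed_key)
        assert result.candidates == {"Kapentagyrus hahni", "Kapentagyrus hugei"}
        assert (9, "both") in result.path
        assert result.ambiguous

    def test_unknown_host_raises_with_registry(self, printed_key):
        rec = SpecimenRecord(specimen_id="x", host_species="Pellonula vorax")
        with pytest.raises(UnknownHostError, match="Pellonula leonensis"):
            identify(rec, key=printed_key)

    def test_host_free_mode_never_errors_on_any_host(self, printed_key):
        rec = SpecimenRecord(specimen_id="x", host_species="Pellonula vorax")
        result = identify(rec, use_host=False, key=printed_key)
        assert result.candidates

    def test_determinism(self, profiles_by_epithet, printed_key):
        rec = mean_specimen(profiles_by_epithet["rochetteae"])
        r1 = identify(rec, key=printed_key)
        r2 = identify(rec, key=printed_key)
        assert r1.candidates == r2.candidates and r1.path == r2.path

    def test_annotated_mode_warns_at_conflicting_couplets(
        self, profiles_by_epithet, printed_key
    ):
        rec = mean_specimen(profiles_by_epithet["rochetteae"])
        strict = identify(rec, key=printed_key, mode="strict")
        annotated = identify(rec, key=printed_key, mode="annotated")
        assert annotated.candidates == strict.candidates  # same routing
        assert any(n.kind == "annotation" and n.couplet_id == 11 for n in annotated.notes)
        assert not any(n.kind == "annotation" for n in strict.notes)


class TestHostConsistency:
    """With host information and complete data, candidates stay within the
    species recorded from that host (the two couplet-11 species are rescued
    by the registry filter; species flagged as key/table conflicts whose
    terminal is plain wrong are exercised in the validation tests)."""

    @pytest.mark.parametrize(
        "epithet",
        ["voreli", "marispastoris", "hugei", "verbisti", "parisellei",
         "pellonulae", "chochamandai", "bisthoveni", "rochetteae"],
    )
    def test_candidates_subset_of_host_species(
        self, profiles, profiles_by_epithet, epithet, printed_key
    ):
        from kapentagyrus.reference import MEASUREMENT_NAMES, host_registry

        registry = host_registry(profiles)
        profile = profiles_by_epithet[epithet]
        host = profile.type_host
        rng = np.random.default_rng(11)
        cfg = SimulationConfig(
            species=[profile.species_name], n_per_species=1, seed=11,
            missing_rates={n: 0.0 for n in MEASUREMENT_NAMES},
        )
        records = simulate_column(profile, host, 30, cfg, rng)
        col = profile.columns[host]
        for rec in records:
            # ratios are computed from independently sampled operands, so a
            # tail specimen can fall outside the printed proportion ranges
            # and legitimately misroute; the invariant concerns specimens
            # consistent with the published proportions
            from kapentagyrus.morphometry import compute_features

            fv = compute_features(rec).as_dict()
            consistent = all(
                col[name].min - 1e-9 <= value <= col[name].max + 1e-9
                for name, value in fv.items()
                if value is not None and name in col
            )
            if not consistent:
                continue
            result = identify(rec, use_host=True, key=printed_key, registry=registry)
            assert result.candidates <= set(
                s for s, hosts in registry.items() if host in hosts
            ), rec.specimen_id


class TestMonotoneInformation:
    @pytest.mark.parametrize("epithet", ["voreli", "hugei", "chochamandai", "parisellei"])
    @pytest.mark.parametrize("drop", ["va_ltn", "da_total", "hI", "va_inner"])
    def test_removing_a_measurement_never_shrinks_candidates(
        self, profiles_by_epithet, printed_key, epithet, drop
    ):
        """Adding information never enlarges the candidate set — equivalently,
        removing a measurement never shrinks it.  Scoped to routings free of
        the key's internal contradictions (where monotonicity cannot hold)."""
        from kapentagyrus.reference import MEASUREMENT_NAMES

        profile = profiles_by_epithet[epithet]
        rng = np.random.default_rng(5)
        cfg = SimulationConfig(
            species=[profile.species_name], n_per_species=1, seed=5,
            missing_rates={n: 0.0 for n in MEASUREMENT_NAMES},
        )
        records = simulate_column(profile, profile.type_host, 10, cfg, rng)
        for rec in records:
            full = identify(rec, use_host=False, key=printed_key)
            if any(n.kind == "contradiction" for n in full.notes):
                continue
            reduced = _without(rec, drop)
            partial = identify(reduced, use_host=False, key=printed_key)
            assert full.candidates <= partial.candidates


def _without(rec: SpecimenRecord, field: str) -> SpecimenRecord:
    import copy

    out = copy.deepcopy(rec)
    if field == "va_ltn":
        out.ventral_anchor.length_to_notch = None
    elif field == "da_total":
        out.dorsal_anchor.total_length = None
    elif field == "hI":
        out.hooks.length_by_pair.pop("I", None)
    elif field == "va_inner":
        out.ventral_anchor.inner_root_length = None
    return out


class TestValidateKey:
    def test_report_covers_all_twelve_profiles(self, profiles):
        report = validate_key(profiles)
        assert len(report) == 12
        assert sum(len(rows) for rows in report.values()) == 13

    def test_parisellei_mean_matches_terminal(self, profiles):
        rows = validate_key(profiles)["Kapentagyrus parisellei"]
        assert rows[0].outcome == "match"
        assert rows[0].candidates == {"Kapentagyrus parisellei"}
        assert rows[0].path[-1] == (13, "a")

    def test_boegeri_routed_down_the_low_ratio_branch(self, profiles):
        """The table means of K. boegeri give a dorsal inner-root/hook-I ratio
        below 1, so the key misroutes it — a documented key/table conflict."""
        rows = validate_key(profiles)["Kapentagyrus boegeri"]
        assert rows[0].outcome == "inconsistency"
        assert (10, "b") in rows[0].path
        assert "Kapentagyrus boegeri" not in rows[0].candidates

    def test_exceptions_are_exactly_the_documented_conflicts(self, profiles):
        report = validate_key(profiles)
        flagged = {
            (species, row.host)
            for species, rows in report.items()
            for row in rows
            if row.outcome == "inconsistency"
        }
        assert flagged == {
            ("Kapentagyrus boegeri", "Microthrissa congica"),
            ("Kapentagyrus bisthoveni", "Microthrissa congica"),
            ("Kapentagyrus rochetteae", "Microthrissa royauxi"),
            ("Kapentagyrus chochamandai", "Potamothrissa acutirostris"),
        }

    def test_no_silent_mismatches_elsewhere(self, profiles):
        report = validate_key(profiles)
        for species, rows in report.items():
            for row in rows:
                if row.outcome == "inconsistency":
                    continue
                assert species in row.candidates
                if row.outcome == "match_with_missing_data":
                    # ambiguity must be traceable to missing measurements
                    assert any(n.kind == "missing_or_boundary" for n in row.notes)
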