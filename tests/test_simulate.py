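import numpy as np
import pytest

from kapentagyrus.parasitology import summarize_infection
from kapentagyrus.reference import MEASUREMENT_NAMES
from kapentagyrus.simulate import (
    SimulationConfig,
    simulate_specimens,
    simulate_survey,
)

NO_MISSING = {n: 0.0 for n in MEASUREMENT_NAMES}


class TestSpecimens:
    def test_values_stay_inside_printed_ranges(self, profiles, profiles_by_epithet):
        cfg = SimulationConfig(
            species=["Kapentagyrus sefcae"], n_per_species=100, seed=8,
            missing_rates=NO_MISSING,
        )
        records = simulate_specimens(cfg, profiles)
        col = profiles_by_epithet["sefcae"].summaries
        for rec in records:
            for name, value in rec.measurements().items():
                if value is None or name not in col:
                    continue
                s = col[name]
                assert s.min - 1e-9 <= value <= s.max + 1e-9, (name, value)

    def test_truncated_mean_matches_printed_mean(self, profiles):
        """CLT check at n = 2000: the sample mean of the ventral anchor total
        of K. sefcae lands within 0.2 µm of the printed 45.1."""
        cfg = SimulationConfig(
            species=["Kapentagyrus sefcae"], n_per_species=2000, seed=17,
            missing_rates=NO_MISSING,
        )
        records = simulate_specimens(cfg, profiles)
        values = np.array([r.ventral_anchor.total_length for r in records])
        assert abs(values.mean() - 45.1) < 0.2

    def test_single_value_cells_reproduced_verbatim(self, profiles):
        cfg = SimulationConfig(
            species=["Kapentagyrus marispastoris"], n_per_species=20, seed=3,
            missing_rates=NO_MISSING,
        )
        records = simulate_specimens(cfg, profiles)
        assert {r.dorsal_anchor.total_length for r in records} == {38.1}

    def test_forced_hook_seven_missingness(self, profiles):
        cfg = SimulationConfig(
            species=["Kapentagyrus sefcae"], n_per_species=30, seed=4,
            missing_rates={**NO_MISSING, "hVII": 1.0},
        )
        records = simulate_specimens(cfg, profiles)
        assert all(r.hooks.get("VII") is None for r in records)

    def test_default_hook_seven_missing_most_often(self, profiles):
        cfg = SimulationConfig(species=["Kapentagyrus sefcae"], n_per_species=400, seed=5)
        records = simulate_specimens(cfg, profiles)
        h7_missing = np.mean([r.hooks.get("VII") is None for r in records])
        h1_missing = np.mean([r.hooks.get("I") is None for r in records])
        assert 0.4 < h7_missing < 0.6
        assert h1_missing < 0.15

    def test_reproducible_from_seed(self, profiles):
        cfg = SimulationConfig(species=["Kapentagyrus hugei"], n_per_species=15, seed=99)
        a = simulate_specimens(cfg, profiles)
        b = simulate_specimens(cfg, profiles)
        assert [r.measurements() for r in a] == [r.measurements() for r in b]

    def test_unsampleable_parameters_emitted_missing_with_warning(
        self, profiles, profiles_by_epithet
    ):
        cfg = SimulationConfig(
            species=["Kapentagyrus hahni"], n_per_species=5, seed=1,
            missing_rates=NO_MISSING,
        )
        with pytest.warns(UserWarning, match="without published summaries"):
            records = simulate_specimens(cfg, profiles)
        assert all(r.dorsal_anchor.total_length is None for r in records)
        assert all(r.ventral_anchor.total_length is not None for r in records)

    def test_latent_correlation_induces_positive_association(self, profiles):
        def corr(rho):
            cfg = SimulationConfig(
                species=["Kapentagyrus sefcae"], n_per_species=800, seed=13,
                latent_size_correlation=rho, missing_rates=NO_MISSING,
            )
            records = simulate_specimens(cfg, profiles)
            x = np.array([r.ventral_anchor.total_length for r in records])
            y = np.array([r.dorsal_anchor.total_length for r in records])
            return np.corrcoef(x, y)[0, 1]

        assert corr(0.8) > 0.5
        assert abs(corr(0.0)) < 0.15

    def test_unknown_species_rejected(self, profiles):
        cfg = SimulationConfig(species=["Kapentagyrus nullius"], n_per_species=5, seed=1)
        with pytest.raises(ValueError, match="nullius"):
            simulate_specimens(cfg, profiles)

    @pytest.mark.parametrize("kwargs", [
        {"n_per_species": 0}, {"latent_size_correlation": 1.0}, {"sd_rule": 0.0},
        {"boundary_policy": "clip"}, {"missing_rates": {"hI": 1.5}},
    ])
    def test_invalid_configuration_rejected(self, kwargs):
        base = dict(species=["Kapentagyrus sefcae"], n_per_species=5, seed=0)
        base.update(kwargs)
        with pytest.raises(ValueError):
            SimulationConfig(**base)


class TestSurveys:
    def test_zero_prevalence_means_no_worms(self):
        record = simulate_survey(0.0, 2.0, 50, seed=1)
        assert record.worm_counts_per_infected_host == []

    def test_truncation_limit_gives_single_worms(self):
        record = simulate_survey(1.0, 1e-9, 200, seed=2)
        assert len(record.worm_counts_per_infected_host) == 200
        assert set(record.worm_counts_per_infected_host) == {1}

    def test_prevalence_recovered_at_large_n(self):
        record = simulate_survey(0.5, 2.0, 10_000, seed=3)
        summary = summarize_infection(record)
        assert abs(float(summary.prevalence) - 0.5) < 0.02

    def test_intensity_matches_zero_truncated_poisson_mean(self):
        lam = 2.0
        record = simulate_survey(1.0, lam, 20_000, seed=4)
        summary = summarize_infection(record)
        expected = lam / (1.0 - np.exp(-lam))
        assert float(summary.mean_intensity) == pytest.approx(expected, abs=0.05)

    def test_zero_hosts_rejected(self):
        with pytest.raises(ValueError, match="n_hosts"):
            simulate_survey(0.5, 2.0, 0)

    def test_reproducible_from_seed(self):
        a = simulate_survey(0.4, 1.5, 100, seed=9)
        b = simulate_survey(0.4, 1.5, 100, seed=9)
        assert a.worm_counts_per_infected_host == b.worm_counts_per_infected_host
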