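import numpy as np
import pandas as pd
import pytest

from kapentagyrus.ordination import (
    prepare_matrix,
    records_to_frame,
    run_nmds,
    run_pca,
    separation_statistic,
)
from kapentagyrus.reference import MEASUREMENT_NAMES
from kapentagyrus.simulate import SimulationConfig, simulate_specimens

NO_MISSING = {n: 0.0 for n in MEASUREMENT_NAMES}


def frame(n_rows, n_cols, seed=0, missing=()):
    rng = np.random.default_rng(seed)
    df = pd.DataFrame(
        rng.normal(20, 3, size=(n_rows, n_cols)),
        columns=[f"p{i}" for i in range(n_cols)],
        index=[f"s{i}" for i in range(n_rows)],
    )
    for r, c in missing:
        df.iloc[r, c] = np.nan
    return df


class TestPrepare:
    def test_hook_seven_always_excluded(self, profiles):
        cfg = SimulationConfig(
            species=["Kapentagyrus sefcae"], n_per_species=10, seed=1,
            missing_rates=NO_MISSING,
        )
        matrix = prepare_matrix(simulate_specimens(cfg, profiles))
        assert "hVII" not in matrix.data.columns
        assert "hVII" in matrix.dropped_cols
        assert matrix.data.shape[1] == 20

    def test_specimen_over_threshold_dropped(self):
        df = frame(10, 20)
        df.iloc[0, :15] = np.nan  # 75% missing
        matrix = prepare_matrix(df, missing_threshold=0.5)
        assert "s0" in matrix.dropped_rows
        assert matrix.data.shape[0] == 9

    def test_complete_matrix_passes_through(self):
        df = frame(8, 6)
        matrix = prepare_matrix(df)
        pd.testing.assert_frame_equal(matrix.data, df)
        assert not matrix.imputed_cells

    def test_zero_threshold_drops_anything_touched(self):
        df = frame(10, 5, missing=[(2, 1)])
        matrix = prepare_matrix(df, missing_threshold=0.0)
        # the column goes first (drop order is columns, then rows)
        assert matrix.dropped_cols == ["p1"]
        assert matrix.data.shape == (10, 4)

    def test_residual_missing_cells_mean_imputed_and_logged(self):
        df = frame(10, 8, missing=[(3, 2)])
        matrix = prepare_matrix(df, missing_threshold=0.5)
        assert len(matrix.imputed_cells) == 1
        row, col, value = matrix.imputed_cells[0]
        assert (row, col) == ("s3", "p2")
        assert value == pytest.approx(df["p2"].dropna().mean())

    def test_too_few_specimens_rejected(self):
        with pytest.raises(ValueError, match="at least 3"):
            prepare_matrix(frame(2, 5))


class TestPCA:
    def test_rank_one_data_loads_entirely_on_axis_one(self):
        base = np.arange(1.0, 13.0)
        df = pd.DataFrame({"a": base, "b": 2 * base, "c": 0.5 * base + 1})
        result = run_pca(prepare_matrix(df))
        assert result.explained_variance_pct[0] == pytest.approx(100.0, abs=1e-8)

    def test_explained_variance_non_increasing_and_sums_to_100(self):
        result = run_pca(prepare_matrix(frame(40, 8, seed=3)))
        pct = result.explained_variance_pct
        assert np.all(np.diff(pct) <= 1e-9)
        assert pct.sum() == pytest.approx(100.0)

    def test_null_spectrum_is_flat(self):
        """20 independent standard-normal columns at n = 2000: every axis
        near 5%, inside the Marchenko-Pastur support (4.05%–6.05%) plus a
        finite-sample margin."""
        rng = np.random.default_rng(2024)
        df = pd.DataFrame(
            rng.standard_normal((2000, 20)), columns=[f"c{i}" for i in range(20)]
        )
        pct = run_pca(prepare_matrix(df)).explained_variance_pct
        assert pct.max() < 6.6
        assert pct.min() > 3.6

    def test_affine_rescaling_invariance(self):
        df = frame(25, 6, seed=9)
        base = run_pca(prepare_matrix(df))
        rescaled = df.copy()
        rescaled["p0"] = rescaled["p0"] * 7.0 + 100.0
        rescaled["p3"] = rescaled["p3"] * 0.01 - 5.0
        again = run_pca(prepare_matrix(rescaled))
        np.testing.assert_allclose(base.scores.to_numpy(), again.scores.to_numpy(), atol=1e-8)

    def test_zero_variance_column_dropped_with_warning(self):
        df = frame(10, 4)
        df["p2"] = 3.14
        with pytest.warns(UserWarning, match="zero-variance"):
            result = run_pca(prepare_matrix(df))
        assert "p2" in result.dropped_cols

    def test_sign_convention_deterministic(self):
        df = frame(20, 5, seed=4)
        a = run_pca(prepare_matrix(df))
        b = run_pca(prepare_matrix(df))
        np.testing.assert_array_equal(a.scores.to_numpy(), b.scores.to_numpy())
        for axis in a.loadings.columns:
            top = a.loadings[axis].abs().idxmax()
            assert a.loadings.loc[top, axis] > 0


class TestNMDS:
    def test_perfect_two_dimensional_configuration_has_zero_stress(self):
        result = run_nmds(prepare_matrix(frame(14, 2, seed=6)), k=2, seed=0)
        assert result.stress < 1e-6

    def test_duplicated_specimens_coincide(self):
        df = frame(6, 4, seed=8)
        df = pd.concat([df, df.rename(index=lambda s: s + "_dup")])
        result = run_nmds(prepare_matrix(df), k=2, seed=0)
        for s in [f"s{i}" for i in range(6)]:
            d = np.linalg.norm(
                result.scores.loc[s].to_numpy() - result.scores.loc[s + "_dup"].to_numpy()
            )
            assert d < 1e-3

    def test_stress_non_increasing_in_k(self):
        df = frame(15, 8, seed=10)
        matrix = prepare_matrix(df)
        stresses = [run_nmds(matrix, k=k, seed=3).stress for k in (1, 2, 3)]
        assert stresses[0] >= stresses[1] - 1e-9
        assert stresses[1] >= stresses[2] - 1e-9

    def test_k_must_be_below_specimen_count(self):
        with pytest.raises(ValueError, match="smaller than"):
            run_nmds(prepare_matrix(frame(4, 3)), k=4)

    def test_disjoint_species_separate(self, profiles):
        """Two species with disjoint printed ranges: at least 95% of
        between/within distance comparisons favour between."""
        cfg = SimulationConfig(
            species=["Kapentagyrus sefcae", "Kapentagyrus parisellei"],
            n_per_species=25, seed=21, missing_rates=NO_MISSING,
        )
        records = simulate_specimens(cfg, profiles)
        matrix = prepare_matrix(records)
        result = run_nmds(matrix, k=2, seed=21)
        assert separation_statistic(result.scores, matrix.labels) >= 0.95


def test_records_to_frame_has_haptoral_columns(profiles):
    cfg = SimulationConfig(species=["Kapentagyrus hugei"], n_per_species=5, seed=2)
    records = simulate_specimens(cfg, profiles)
    df = records_to_frame(records)
    assert df.shape == (5, 21)
    assert list(df.columns)[:2] == ["da_total", "da_ltn"]
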