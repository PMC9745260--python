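import numpy as np
import pandas as pd
import pytest

from rguc_kit.aflp_io import BandMatrix, ClimateStack
from rguc_kit.geneclim import (
    TurnoverModel,
    fit_turnover,
    map_groups,
    scenario_average,
    transform,
    transform_stack,
    vif_filter,
)


class TestVifFilter:
    def test_duplicated_layer_dropped(self):
        rng = np.random.default_rng(0)
        a = rng.random(30)
        df = pd.DataFrame({"a": a, "dup": a * 2 + 1, "b": rng.random(30)})
        kept = vif_filter(df)
        assert "b" in kept and len(kept) == 2
        assert ("a" in kept) != ("dup" in kept)

    def test_independent_layers_all_retained(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame(rng.random((200, 4)), columns=list("abcd"))
        assert vif_filter(df) == list("abcd")

    def test_planted_collinear_blocks(self):
        rng = np.random.default_rng(2)
        base1, base2 = rng.random(100), rng.random(100)
        df = pd.DataFrame({
            "b1": base1,
            "b1_copy1": base1 + rng.normal(0, 0.01, 100),
            "b1_copy2": -base1 + rng.normal(0, 0.01, 100),
            "b2": base2,
            "b2_copy": 3 * base2 + rng.normal(0, 0.01, 100),
            "free": rng.random(100),
        })
        kept = vif_filter(df)
        assert "free" in kept
        assert sum(c.startswith("b1") for c in kept) == 1
        assert sum(c.startswith("b2") for c in kept) == 1

    def test_all_constant_rejected(self):
        df = pd.DataFrame({"a": np.ones(20), "b": np.ones(20)})
        with pytest.raises(ValueError, match="degenerate"):
            vif_filter(df)


def _step_dataset(seed=0, n_pops=8, n_per_pop=10):
    """Band determined by a hard threshold on predictor A; B is noise."""
    rng = np.random.default_rng(seed)
    a_vals = np.linspace(0, 1, n_pops)
    pred = pd.DataFrame({
        "population": [str(i) for i in range(n_pops)],
        "A": a_vals,
        "B": rng.random(n_pops),
    })
    pops, rows = [], []
    for i in range(n_pops):
        for _ in range(n_per_pop):
            pops.append(str(i))
            signal = int(a_vals[i] > 0.5)
            noise = int(rng.random() < 0.5)
            rows.append([signal, noise])
    values = np.array(rows)
    bm = BandMatrix(values, [f"i{k}" for k in range(len(pops))],
                    ["sig", "noise"], pops)
    return bm, pred


class TestFitTurnover:
    def test_planted_step_signal_ranks_first(self):
        bm, pred = _step_dataset(seed=3)
        model = fit_turnover(bm, pred, n_trees=100, seed=1)
        assert model.importance.idxmax() == "A"
        assert "sig" in model.retained_loci

    def test_constant_predictor_zero_importance(self):
        bm, pred = _step_dataset(seed=4)
        pred["C"] = 1.0
        model = fit_turnover(bm, pred, n_trees=100, seed=1)
        assert model.importance["C"] == 0.0

    def test_monomorphic_locus_skipped(self):
        bm, pred = _step_dataset(seed=5)
        values = np.hstack([bm.values, np.ones((bm.n_individuals, 1), dtype=int)])
        bm2 = BandMatrix(values, bm.individual_ids, [*bm.locus_ids, "mono"], bm.populations)
        model = fit_turnover(bm2, pred, n_trees=50, seed=1)
        assert "mono" not in model.loci.index

    def test_cumulative_functions_monotone_and_scaled(self):
        bm, pred = _step_dataset(seed=6)
        model = fit_turnover(bm, pred, n_trees=100, seed=2)
        for p in model.predictors:
            cum = model.cumulative[p]
            assert (np.diff(cum) >= 0).all()
            assert cum[-1] == pytest.approx(model.importance[p], abs=1e-12)


def _toy_model():
    """Hand-built turnover model: one predictor, known step positions."""
    edges = np.linspace(0.0, 10.0, 201)
    cum = np.zeros(200)
    cum[40:] = 0.3   # jump at x=2.0
    cum[120:] = 1.0  # jump at x=6.0
    cum *= 0.5  # total importance 0.5
    return TurnoverModel(
        predictors=["A"],
        importance=pd.Series({"A": 0.5}),
        bin_edges={"A": edges},
        cumulative={"A": cum},
        loci=pd.DataFrame({"oob_error": [0.1], "null_error": [0.5], "retained": [True]},
                          index=["L1"]),
    )


class TestTransform:
    def test_step_function_evaluation(self):
        model = _toy_model()
        out = transform(model, pd.DataFrame({"A": [-5.0, 1.0, 3.0, 7.0, 42.0]}))
        np.testing.assert_allclose(out["A"], [0.0, 0.0, 0.15, 0.5, 0.5], atol=1e-12)

    def test_monotone_in_input(self):
        model = _toy_model()
        xs = np.linspace(-1, 11, 200)
        t = transform(model, pd.DataFrame({"A": xs}))["A"].to_numpy()
        assert (np.diff(t) >= 0).all()

    def test_missing_layer_rejected(self):
        with pytest.raises(ValueError, match="missing predictor"):
            transform(_toy_model(), pd.DataFrame({"B": [1.0]}))


def _regime_stack():
    """Three climate regimes in distinct thirds of the grid."""
    nrow, ncol = 12, 12
    a = np.zeros((nrow, ncol))
    a[:, 4:8] = 5.0
    a[:, 8:] = 10.0
    return ClimateStack({"A": a, "B": a * 0.5 + 1}, 0.0, 0.0, 1.0)


class TestMapGroups:
    def _fit(self, seed=0):
        rng = np.random.default_rng(seed)
        # populations in three regimes with regime-determined bands
        pops = [str(i) for i in range(6)]
        pred = pd.DataFrame({
            "population": pops,
            "A": [0.0, 0.0, 5.0, 5.0, 10.0, 10.0],
            "B": [1.0, 1.0, 3.5, 3.5, 6.0, 6.0],
        })
        values, labels = [], []
        for i, p in enumerate(pops):
            regime = i // 2
            for _ in range(8):
                labels.append(p)
                values.append([int(regime >= 1), int(regime >= 2),
                               int(rng.random() < 0.5)])
        bm = BandMatrix(np.array(values), [f"i{k}" for k in range(len(labels))],
                        ["r1", "r2", "noise"], labels)
        model = fit_turnover(bm, pred, n_trees=80, seed=seed)
        return model, pred

    def test_recovers_three_regimes(self):
        model, pred = self._fit(seed=1)
        stack = _regime_stack()
        gmap = map_groups(model, pred, stack, n_groups=3, n_axes=2)
        groups = gmap.groups
        # each third of the grid is internally homogeneous and distinct
        thirds = [groups[:, :4], groups[:, 4:8], groups[:, 8:]]
        ids = [np.unique(t) for t in thirds]
        assert all(len(u) == 1 for u in ids)
        assert len({u[0] for u in ids}) == 3

    def test_population_cells_inherit_population_group(self):
        model, pred = self._fit(seed=2)
        stack = _regime_stack()
        gmap = map_groups(model, pred, stack, n_groups=3, n_axes=2)
        # population 0 sits in the first regime (A=0) -> its group covers col 0
        g0 = int(gmap.population_table.set_index("population").loc["0", "group"])
        assert gmap.groups[0, 0] == g0

    def test_too_many_groups_rejected(self):
        model, pred = self._fit(seed=3)
        with pytest.raises(ValueError, match="n_groups"):
            map_groups(model, pred, _regime_stack(), n_groups=7)

    def test_indistinct_populations_rejected(self):
        model, pred = self._fit(seed=4)
        pred_flat = pred.copy()
        pred_flat["A"] = 5.0
        pred_flat["B"] = 3.5
        with pytest.raises(ValueError, match="do not separate"):
            map_groups(model, pred_flat, _regime_stack(), n_groups=3, n_axes=2)


class TestScenarioAverage:
    def test_identical_stack_reproduces_map(self):
        model, pred = TestMapGroups()._fit(seed=5)
        stack = _regime_stack()
        gmap = map_groups(model, pred, stack, n_groups=3, n_axes=2)
        fut = scenario_average([stack, stack], model, gmap)
        np.testing.assert_array_equal(fut.groups, gmap.groups)

    def test_average_is_arithmetic_mean(self):
        model, pred = TestMapGroups()._fit(seed=6)
        s1 = _regime_stack()
        shifted = {k: v + 1.0 for k, v in s1.layers.items()}
        s2 = ClimateStack(shifted, s1.xllcorner, s1.yllcorner, s1.cellsize)
        gmap = map_groups(model, pred, s1, n_groups=3, n_axes=2)
        fut = scenario_average([s1, s2], model, gmap)
        t1 = transform_stack(model, s1)[model.predictors].to_numpy()
        t2 = transform_stack(model, s2)[model.predictors].to_numpy()
        expected = gmap.pca.transform((t1 + t2) / 2)
        got = fut.pixel_scores[[f"pc{i+1}" for i in range(expected.shape[1])]].to_numpy()
        np.testing.assert_allclose(got, expected, atol=1e-10)

    def test_grid_mismatch_rejected(self):
        model, pred = TestMapGroups()._fit(seed=7)
        s1 = _regime_stack()
        s2 = ClimateStack({"A": np.zeros((5, 5)), "B": np.zeros((5, 5))}, 0, 0, 1.0)
        gmap = map_groups(model, pred, s1, n_groups=3, n_axes=2)
        with pytest.raises(ValueError, match="geometry"):
            scenario_average([s1, s2], model, gmap)

    def test_warming_shift_moves_pixels_toward_warm_group(self):
        model, pred = TestMapGroups()._fit(seed=8)
        stack = _regime_stack()
        gmap = map_groups(model, pred, stack, n_groups=3, n_axes=2)
        warm_group = int(gmap.population_table.set_index("population").loc["4", "group"])
        warmed = ClimateStack({k: v + 5.0 for k, v in stack.layers.items()},
                              stack.xllcorner, stack.yllcorner, stack.cellsize)
        fut = scenario_average([warmed], model, gmap)
        assert (fut.groups == warm_group).sum() > (gmap.groups == warm_group).sum()
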