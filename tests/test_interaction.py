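"""Effectorness scaling and the per-gene interaction model."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from sklearn.base import clone

from effectorness import (
    CellSimConfig,
    EffectornessCytokineModel,
    EffectornessScaler,
    classify_genes,
    draw_gene_effects,
    effectorness_from_pseudotime,
    fit_interaction_model,
    scale_pseudotime,
    simulate_effectorness_cells,
    unify_effectorness,
)


class TestScalePseudotime:
    def test_min_max_example(self):
        np.testing.assert_allclose(scale_pseudotime([2.0, 5.0, 8.0]), [0.0, 0.5, 1.0])

    def test_identity_on_unit_range(self):
        np.testing.assert_allclose(scale_pseudotime([0.0, 1.0]), [0.0, 1.0])

    def test_rank_order_preserved_on_random_vectors(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            t = rng.gamma(2.0, 5.0, size=rng.integers(3, 50))
            if t.max() == t.min():
                continue
            rho = stats.spearmanr(t, scale_pseudotime(t)).statistic
            assert rho == pytest.approx(1.0)

    def test_constant_pseudotime_is_an_error(self):
        with pytest.raises(ValueError, match="constant"):
            scale_pseudotime([3.0, 3.0, 3.0])

    def test_single_cell_is_an_error(self):
        with pytest.raises(ValueError, match="two cells"):
            scale_pseudotime([1.0])


class TestUnifyEffectorness:
    def test_concatenation_is_a_no_op_on_values(self):
        a, b = np.array([0.0, 1.0]), np.array([0.0, 0.5, 1.0])
        out = unify_effectorness({"Th0": a, "Th2": b})
        np.testing.assert_array_equal(out, [0.0, 1.0, 0.0, 0.5, 1.0])

    def test_combined_column_spans_unit_interval(self):
        out = unify_effectorness({"A": [0.0, 0.3, 1.0], "B": [0.0, 1.0]})
        assert out.min() == 0.0 and out.max() == 1.0

    def test_missing_condition_values_is_an_error(self):
        with pytest.raises(ValueError, match="Th2"):
            unify_effectorness({"Th0": [0.0, 1.0], "Th2": []})

    def test_scaling_then_unifying_preserves_within_condition_ranks(self):
        rng = np.random.default_rng(1)
        obs = pd.DataFrame(
            {
                "condition": rng.choice(["Th0", "Th2", "Th17"], size=200),
                "pseudotime": rng.gamma(2.0, 3.0, size=200),
            }
        )
        eff = effectorness_from_pseudotime(obs)
        for cond, sub in obs.groupby("condition"):
            rho = stats.spearmanr(sub["pseudotime"], eff.loc[sub.index]).statistic
            assert rho == pytest.approx(1.0)
            assert eff.loc[sub.index].min() == 0.0 and eff.loc[sub.index].max() == 1.0


class TestEffectornessScaler:
    def test_fit_transform_matches_function(self):
        rng = np.random.default_rng(2)
        obs = pd.DataFrame(
            {
                "condition": rng.choice(["Th0", "Th2"], size=50),
                "pseudotime": rng.uniform(0, 20, size=50),
            }
        )
        scaler = EffectornessScaler().fit(obs)
        np.testing.assert_allclose(
            scaler.transform(obs), effectorness_from_pseudotime(obs), atol=1e-12
        )

    def test_unseen_condition_rejected(self):
        obs = pd.DataFrame({"condition": ["A"] * 3, "pseudotime": [1.0, 2.0, 3.0]})
        scaler = EffectornessScaler().fit(obs)
        with pytest.raises(ValueError, match="not seen"):
            scaler.transform(pd.DataFrame({"condition": ["B"], "pseudotime": [1.0]}))

    def test_sklearn_clone_roundtrip(self):
        scaler = EffectornessScaler(pseudotime_col="pt")
        assert clone(scaler).get_params()["pseudotime_col"] == "pt"


def _noiseless_cells(n=400, seed=0):
    rng = np.random.default_rng(seed)
    e = rng.uniform(0, 1, n)
    cond = rng.choice(["Th0", "Th2", "Th17", "iTreg"], size=n)
    return e, cond


class TestFitInteractionModel:
    def test_noiseless_shared_slope(self):
        e, cond = _noiseless_cells()
        x = pd.DataFrame({"g": 1.0 + 0.5 * e})
        fits = fit_interaction_model(x, e, cond)
        assert fits["alpha"].iloc[0] == pytest.approx(1.0, abs=1e-10)
        assert fits["beta"].iloc[0] == pytest.approx(0.5, abs=1e-10)
        for c in ("Th2", "Th17", "iTreg"):
            assert fits[f"gamma_{c}"].iloc[0] == pytest.approx(0.0, abs=1e-10)
            assert fits[f"delta_{c}"].iloc[0] == pytest.approx(0.0, abs=1e-10)

    def test_noiseless_condition_and_interaction_terms(self):
        e, cond = _noiseless_cells(seed=1)
        th17 = (cond == "Th17").astype(float)
        x = pd.DataFrame({"g": 1.0 + 0.5 * e + 1.0 * th17 + 0.7 * e * th17})
        fits = fit_interaction_model(x, e, cond)
        assert fits["gamma_Th17"].iloc[0] == pytest.approx(1.0, abs=1e-10)
        assert fits["delta_Th17"].iloc[0] == pytest.approx(0.7, abs=1e-10)
        assert fits["gamma_Th2"].iloc[0] == pytest.approx(0.0, abs=1e-10)

    def test_zero_expression_cells_are_omitted(self):
        e, cond = _noiseless_cells(seed=2)
        y = 2.0 + 1.0 * e
        y[e < 0.3] = 0.0  # censored cells must not drag the fit down
        fits = fit_interaction_model(pd.DataFrame({"g": y}), e, cond)
        assert fits["beta"].iloc[0] == pytest.approx(1.0, abs=1e-10)
        assert fits["n_cells_used"].iloc[0] == int((e >= 0.3).sum())

    def test_single_condition_gene_reported_unfit(self):
        e, cond = _noiseless_cells(seed=3)
        y = np.where(cond == "Th17", 2.0 + e, 0.0)
        fits = fit_interaction_model(pd.DataFrame({"g": y}), e, cond)
        assert not fits["fitted"].iloc[0]
        assert "reference" in fits["reason"].iloc[0]

    def test_reference_only_gene_reported_unfit(self):
        e, cond = _noiseless_cells(seed=4)
        y = np.where(cond == "Th0", 2.0 + e, 0.0)
        fits = fit_interaction_model(pd.DataFrame({"g": y}), e, cond)
        assert not fits["fitted"].iloc[0]
        assert "single condition" in fits["reason"].iloc[0]

    def test_rmse_decreases_with_cell_count(self):
        effects = draw_gene_effects(30, random_state=5)
        rmses = []
        for n in (200, 2000, 20000):
            adata = simulate_effectorness_cells(
                CellSimConfig(n_cells=n, n_genes=30, effects=effects, dropout=False, seed=6)
            )
            fits = fit_interaction_model(
                pd.DataFrame(adata.X, columns=adata.var_names),
                adata.obs["effectorness"],
                adata.obs["condition"],
            )
            err = fits["beta"] - effects["beta"].to_numpy()
            rmses.append(np.sqrt((err**2).mean()))
        assert rmses[0] > rmses[1] > rmses[2]


def _fits_frame(rows):
    """Hand-built fit table for classification tests."""
    conditions = ["Th0", "Th2", "Th17", "iTreg"]
    cols = {}
    for name in ["beta"] + [f"gamma_{c}" for c in conditions[1:]] + [
        f"delta_{c}" for c in conditions[1:]
    ]:
        cols[name] = [r.get(name, 0.0) for r in rows]
        cols[f"q_{name}"] = [r.get(f"q_{name}", 1.0) for r in rows]
    frame = pd.DataFrame(cols, index=[r["gene"] for r in rows])
    frame["alpha"] = 1.0
    frame["fitted"] = [r.get("fitted", True) for r in rows]
    frame.attrs["conditions"] = conditions
    return frame


class TestClassifyGenes:
    def test_group_assignment_rules(self):
        fits = _fits_frame(
            [
                {"gene": "eff_only", "beta": 1.0, "q_beta": 0.01},
                {"gene": "cyto_only", "gamma_Th17": 1.0, "q_gamma_Th17": 0.01},
                {
                    "gene": "indep",
                    "beta": 1.0,
                    "q_beta": 0.01,
                    "gamma_Th2": 1.0,
                    "q_gamma_Th2": 0.02,
                },
                {
                    "gene": "inter_specific",
                    "q_beta": 0.2,
                    "delta_Th17": 1.0,
                    "q_delta_Th17": 0.01,
                },
                {
                    "gene": "inter_ubiq",
                    "beta": 1.0,
                    "q_beta": 0.01,
                    "delta_Th2": 1.0,
                    "q_delta_Th2": 0.01,
                },
                {"gene": "nothing"},
                {"gene": "broken", "fitted": False},
            ]
        )
        out = classify_genes(fits)
        assert out.loc["eff_only", "mechanism"] == "effectorness_only"
        assert out.loc["cyto_only", "mechanism"] == "cytokine_only"
        assert out.loc["indep", "mechanism"] == "independent"
        assert out.loc["inter_specific", "mechanism"] == "interaction_cytokine_specific"
        assert out.loc["inter_ubiq", "mechanism"] == "interaction_ubiquitous"
        assert out.loc["nothing", "mechanism"] == "null"
        assert out.loc["broken", "mechanism"] == "unfit"

    def test_strong_effect_flags_require_significance_and_magnitude(self):
        fits = _fits_frame(
            [
                {"gene": "strong", "beta": 0.9, "q_beta": 0.01},
                {"gene": "weak", "beta": 0.3, "q_beta": 0.01},
                {"gene": "big_but_ns", "beta": 0.9, "q_beta": 0.5},
                {
                    "gene": "strong_delta",
                    "q_beta": 0.9,
                    "delta_iTreg": -0.8,
                    "q_delta_iTreg": 0.001,
                },
            ]
        )
        out = classify_genes(fits)
        assert out.loc["strong", "strong_beta"]
        assert not out.loc["weak", "strong_beta"]
        assert not out.loc["big_but_ns", "strong_beta"]
        assert out.loc["strong_delta", "strong_delta_iTreg"]


class TestEffectornessCytokineModel:
    def test_fit_on_anndata_with_pseudotime_fallback(self):
        adata = simulate_effectorness_cells(CellSimConfig(n_cells=500, n_genes=20, seed=7))
        obs_no_eff = adata.obs.drop(columns=["effectorness"])
        adata2 = adata.copy()
        adata2.obs = obs_no_eff
        model = EffectornessCytokineModel().fit(adata2)
        assert model.fits_["fitted"].all()
        assert model.conditions_[0] == "Th0"

    def test_classes_match_truth_on_clean_simulation(self):
        adata = simulate_effectorness_cells(
            CellSimConfig(n_cells=3000, n_genes=100, dropout=False, seed=8)
        )
        model = EffectornessCytokineModel().fit(adata)
        acc = (model.classes_["mechanism"] == adata.var["mechanism"]).mean()
        assert acc >= 0.9

    def test_sklearn_clone_roundtrip(self):
        model = EffectornessCytokineModel(q_sig=0.01, beta_strong=0.4)
        params = clone(model).get_params()
        assert params["q_sig"] == 0.01 and params["beta_strong"] == 0.4
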