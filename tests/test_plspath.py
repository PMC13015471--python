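"""PLS path modeling: engine, bootstrap, mediation/moderation, diagnostics."""

import numpy as np
import pandas as pd
import pytest

from stimnet import plspath as pls


def zscore(x):
    x = np.asarray(x, float)
    return (x - x.mean()) / x.std()


def closed_form_standardized_ols(X, y):
    """Standardized regression coefficients via the correlation-matrix
    normal equations: beta = R_xx^{-1} r_xy."""
    Z = np.column_stack([zscore(c) for c in X.T])
    zy = zscore(y)
    n = len(y)
    Rxx = Z.T @ Z / n
    rxy = Z.T @ zy / n
    return np.linalg.solve(Rxx, rxy)


@pytest.fixture(scope="module")
def ols_data():
    rng = np.random.default_rng(21)
    n = 120
    x1 = rng.standard_normal(n)
    x2 = 0.4 * x1 + rng.standard_normal(n)
    y = 0.5 * x1 - 0.3 * x2 + rng.standard_normal(n)
    return pd.DataFrame({"x1": x1, "x2": x2, "y": y})


class TestSpec:
    def test_cyclic_graph_rejected(self):
        with pytest.raises(ValueError):
            pls.PathModelSpec(blocks={"a": ["u"], "b": ["v"]},
                              paths=[("a", "b"), ("b", "a")])

    def test_indicator_in_two_blocks_rejected(self):
        with pytest.raises(ValueError):
            pls.PathModelSpec(blocks={"a": ["u"], "b": ["u"]}, paths=[("a", "b")])

    def test_unknown_latent_rejected(self):
        with pytest.raises(ValueError):
            pls.PathModelSpec(blocks={"a": ["u"]}, paths=[("a", "zzz")])

    def test_yaml_round_trip(self, tmp_path):
        p = tmp_path / "model.yaml"
        p.write_text(
            "blocks:\n  a: [u, v]\n  b: [w]\npaths:\n  - [a, b]\n"
            "moderations: []\nn_boot: 100\n"
        )
        spec = pls.PathModelSpec.from_yaml(p)
        assert spec.blocks == {"a": ["u", "v"], "b": ["w"]}
        assert spec.paths == [("a", "b")]


class TestPreprocess:
    def test_zero_replacement_and_log(self):
        df = pd.DataFrame({"sc": [0.0, 1.0, np.e]})
        out = pls.preprocess_indicators(df, log_columns=["sc"])
        # pre-standardization values {ln 1, ln 1, 1} = {0, 0, 1}
        want = zscore(np.array([0.0, 0.0, 1.0]))
        # preprocess uses sample sd; rescale the oracle accordingly
        want = want * np.std([0.0, 0.0, 1.0]) / np.std([0.0, 0.0, 1.0], ddof=1)
        assert np.allclose(out["sc"].to_numpy(), want)

    def test_standardized_moments(self):
        rng = np.random.default_rng(4)
        df = pd.DataFrame({"a": rng.gamma(2, 1, 50), "b": rng.normal(3, 2, 50)})
        out = pls.preprocess_indicators(df, log_columns=["a"])
        for col in out:
            assert out[col].mean() == pytest.approx(0.0, abs=1e-12)
            assert out[col].std(ddof=1) == pytest.approx(1.0)

    def test_unflagged_column_only_standardized(self):
        df = pd.DataFrame({"a": [1.0, 2.0, 4.0]})
        out = pls.preprocess_indicators(df)
        x = df["a"].to_numpy()
        assert np.allclose(out["a"], (x - x.mean()) / x.std(ddof=1))

    def test_all_zero_flagged_column_rejected(self):
        with pytest.raises(ValueError):
            pls.preprocess_indicators(pd.DataFrame({"sc": [0.0, 0.0]}),
                                      log_columns=["sc"])


class TestFit:
    def test_single_indicator_matches_closed_form_ols(self, ols_data):
        spec = pls.PathModelSpec(
            blocks={"X1": ["x1"], "X2": ["x2"], "Y": ["y"]},
            paths=[("X1", "Y"), ("X2", "Y")],
        )
        fit = pls.fit_pls(spec, ols_data)
        want = closed_form_standardized_ols(
            ols_data[["x1", "x2"]].to_numpy(), ols_data["y"].to_numpy()
        )
        assert fit.paths[("X1", "Y")] == pytest.approx(want[0], abs=1e-6)
        assert fit.paths[("X2", "Y")] == pytest.approx(want[1], abs=1e-6)

    def test_scores_standardized_and_loadings_bounded(self, ols_data):
        spec = pls.PathModelSpec(blocks={"X": ["x1", "x2"], "Y": ["y"]},
                                 paths=[("X", "Y")])
        fit = pls.fit_pls(spec, ols_data)
        for latent, score in fit.scores.items():
            assert score.mean() == pytest.approx(0.0, abs=1e-10)
            assert score.std() == pytest.approx(1.0, abs=1e-10)
            assert np.all(np.abs(fit.loadings[latent]) <= 1.0 + 1e-9)

    def test_duplicated_indicators_saturated_case(self):
        rng = np.random.default_rng(5)
        x = rng.standard_normal(60)
        y = 0.6 * x + 0.8 * rng.standard_normal(60)
        df = pd.DataFrame({"x1": x, "x2": x.copy(), "y1": y, "y2": y.copy()})
        spec = pls.PathModelSpec(blocks={"X": ["x1", "x2"], "Y": ["y1", "y2"]},
                                 paths=[("X", "Y")])
        fit = pls.fit_pls(spec, df)
        assert fit.paths[("X", "Y")] == pytest.approx(np.corrcoef(x, y)[0, 1], abs=1e-9)

    def test_reflective_parameter_recovery(self):
        """Planted structural beta=0.5 with 3-indicator reflective blocks is
        recovered to within 0.1 on average."""
        rng = np.random.default_rng(6)
        betas = []
        for _ in range(100):
            n = 200
            xi = rng.standard_normal(n)
            eta = 0.5 * xi + np.sqrt(1 - 0.25) * rng.standard_normal(n)
            lam = 0.85
            mk = lambda f: np.column_stack(
                [lam * f + np.sqrt(1 - lam**2) * rng.standard_normal(n)
                 for _ in range(3)]
            )
            X, Y = mk(xi), mk(eta)
            df = pd.DataFrame(np.hstack([X, Y]),
                              columns=["x1", "x2", "x3", "y1", "y2", "y3"])
            spec = pls.PathModelSpec(
                blocks={"X": ["x1", "x2", "x3"], "Y": ["y1", "y2", "y3"]},
                paths=[("X", "Y")],
            )
            betas.append(pls.fit_pls(spec, df).paths[("X", "Y")])
        assert abs(np.mean(betas) - 0.5) < 0.1

    def test_r2_matches_ols_definition(self, ols_data):
        spec = pls.PathModelSpec(blocks={"X1": ["x1"], "Y": ["y"]},
                                 paths=[("X1", "Y")])
        fit = pls.fit_pls(spec, ols_data)
        r = np.corrcoef(ols_data["x1"], ols_data["y"])[0, 1]
        assert fit.r2["Y"] == pytest.approx(r**2, abs=1e-9)

    def test_too_few_observations_rejected(self):
        df = pd.DataFrame(np.random.default_rng(0).standard_normal((3, 4)),
                          columns=list("abcd"))
        spec = pls.PathModelSpec(blocks={"A": ["a", "b", "c"], "B": ["d"]},
                                 paths=[("A", "B")])
        with pytest.raises(ValueError):
            pls.fit_pls(spec, df.iloc[:3])


class TestBootstrap:
    def test_seed_determinism(self, ols_data):
        spec = pls.PathModelSpec(blocks={"X1": ["x1"], "Y": ["y"]},
                                 paths=[("X1", "Y")])
        a = pls.bootstrap_inference(spec, ols_data, n_boot=50, seed=3)
        b = pls.bootstrap_inference(spec, ols_data, n_boot=50, seed=3)
        assert np.array_equal(a.path_draws, b.path_draws)
        assert a.path_table.equals(b.path_table)

    def test_strong_effect_significant(self, ols_data):
        spec = pls.PathModelSpec(blocks={"X1": ["x1"], "X2": ["x2"], "Y": ["y"]},
                                 paths=[("X1", "Y"), ("X2", "Y")])
        boot = pls.bootstrap_inference(spec, ols_data, n_boot=300, seed=4)
        assert boot.path_row("X1", "Y").p < 0.01

    def test_percentile_ci_brackets_estimate(self, ols_data):
        spec = pls.PathModelSpec(blocks={"X1": ["x1"], "Y": ["y"]},
                                 paths=[("X1", "Y")])
        boot = pls.bootstrap_inference(spec, ols_data, n_boot=300, seed=5)
        row = boot.path_row("X1", "Y")
        assert row.ci_low < row.beta < row.ci_high


class TestModeration:
    def make_data(self, interaction, seed, n=100):
        rng = np.random.default_rng(seed)
        x = rng.standard_normal(n)
        m = (rng.random(n) < 0.5).astype(float)
        y = 0.3 * x + 0.2 * m + interaction * x * (m - 0.5) + rng.standard_normal(n)
        return pd.DataFrame({"x": x, "m": m, "y": y})

    def spec(self, n_boot=200, seed=0):
        return pls.PathModelSpec(
            blocks={"X": ["x"], "M": ["m"], "Y": ["y"]},
            paths=[("X", "Y"), ("M", "Y")],
            moderations=[("M", "X", "Y")],
            n_boot=n_boot, seed=seed,
        )

    def test_interaction_term_recovered(self):
        df = self.make_data(interaction=1.0, seed=7, n=300)
        boot = pls.bootstrap_inference(self.spec(seed=7), df)
        assert boot.path_row("M*X", "Y").p < 0.05

    def test_interaction_standardized(self):
        df = self.make_data(interaction=0.5, seed=8)
        fit = pls.fit_pls(self.spec(), df)
        inter = fit.scores["M"] * fit.scores["X"]
        assert np.std(inter) > 0  # standardization applied inside regression
        assert ("M*X", "Y") in fit.paths

    def test_moderation_beta_accessor(self):
        df = self.make_data(interaction=0.8, seed=9)
        fit = pls.fit_pls(self.spec(), df)
        assert pls.moderation_beta(fit, "M", "X", "Y") == fit.paths[("M*X", "Y")]


class TestMediation:
    def published_table_fit(self):
        """Fit object with the path coefficients of a WMP mediation table."""
        spec = pls.PathModelSpec(
            blocks={"wmp": ["w"], "sc": ["s"], "memory": ["d"]},
            paths=[("wmp", "sc"), ("sc", "memory"), ("wmp", "memory")],
        )
        fit = pls.PathModelFit(
            spec=spec, weights={}, loadings={}, scores={},
            paths={("wmp", "sc"): -0.302, ("sc", "memory"): 0.493,
                   ("wmp", "memory"): -0.343 - (-0.302 * 0.493)},
            r2={}, sse={}, n_obs=61, n_iter=1,
        )
        return fit

    def test_indirect_effect_product(self):
        med = pls.mediation(self.published_table_fit(), "wmp", "sc", "memory")
        assert med.indirect == pytest.approx(-0.149, abs=5e-4)

    def test_proportion_mediated(self):
        med = pls.mediation(self.published_table_fit(), "wmp", "sc", "memory")
        assert med.total == pytest.approx(-0.343)
        assert med.proportion_mediated * 100 == pytest.approx(43.0, abs=1.0)

    def test_zero_a_path(self):
        fit = self.published_table_fit()
        fit.paths[("wmp", "sc")] = 0.0
        med = pls.mediation(fit, "wmp", "sc", "memory")
        assert med.indirect == 0.0
        assert med.proportion_mediated == 0.0

    def test_inconsistent_signs_flagged(self):
        fit = self.published_table_fit()
        fit.paths[("wmp", "memory")] = 0.5  # direct opposes indirect, dominates
        med = pls.mediation(fit, "wmp", "sc", "memory")
        assert med.flagged
        assert np.isnan(med.proportion_mediated)

    def test_bootstrap_indirect_inference(self):
        rng = np.random.default_rng(10)
        n = 150
        w = rng.standard_normal(n)
        s = -0.5 * w + rng.standard_normal(n)
        d = 0.5 * s - 0.1 * w + rng.standard_normal(n)
        df = pd.DataFrame({"w": w, "s": s, "d": d})
        spec = pls.PathModelSpec(
            blocks={"wmp": ["w"], "sc": ["s"], "memory": ["d"]},
            paths=[("wmp", "sc"), ("sc", "memory"), ("wmp", "memory")],
        )
        boot = pls.bootstrap_inference(spec, df, n_boot=300, seed=11)
        med = pls.mediation(boot.fit, "wmp", "sc", "memory", boot)
        assert med.indirect_p < 0.05
        assert med.indirect_ci[0] < med.indirect < med.indirect_ci[1]


class TestQuality:
    def test_perfect_block_ave_one(self):
        x = np.random.default_rng(12).standard_normal(80)
        df = pd.DataFrame({"a1": x, "a2": x.copy(), "b": x + np.random.default_rng(13).standard_normal(80)})
        spec = pls.PathModelSpec(blocks={"A": ["a1", "a2"], "B": ["b"]},
                                 paths=[("A", "B")])
        fit = pls.fit_pls(spec, df)
        q = pls.quality_diagnostics(fit, df)
        assert q.ave["A"] == pytest.approx(1.0, abs=1e-9)
        assert q.ave["B"] == 1.0
        assert all(0.0 <= v <= 1.0 + 1e-9 for v in q.ave.values())

    def test_independent_blocks_htmt_near_zero(self):
        rng = np.random.default_rng(14)
        n = 2000
        f1, f2 = rng.standard_normal((2, n))
        mk = lambda f: np.column_stack(
            [0.8 * f + 0.6 * rng.standard_normal(n) for _ in range(3)]
        )
        df = pd.DataFrame(np.hstack([mk(f1), mk(f2)]),
                          columns=["a1", "a2", "a3", "b1", "b2", "b3"])
        spec = pls.PathModelSpec(blocks={"A": ["a1", "a2", "a3"],
                                         "B": ["b1", "b2", "b3"]},
                                 paths=[("A", "B")])
        fit = pls.fit_pls(spec, df)
        q = pls.quality_diagnostics(fit, df)
        assert q.htmt.loc["A", "B"] < 0.1

    def test_same_factor_blocks_htmt_near_one(self):
        rng = np.random.default_rng(15)
        n = 2000
        f = rng.standard_normal(n)
        mk = lambda: np.column_stack(
            [0.9 * f + np.sqrt(1 - 0.81) * rng.standard_normal(n) for _ in range(3)]
        )
        df = pd.DataFrame(np.hstack([mk(), mk()]),
                          columns=["a1", "a2", "a3", "b1", "b2", "b3"])
        spec = pls.PathModelSpec(blocks={"A": ["a1", "a2", "a3"],
                                         "B": ["b1", "b2", "b3"]},
                                 paths=[("A", "B")])
        fit = pls.fit_pls(spec, df)
        q = pls.quality_diagnostics(fit, df)
        assert q.htmt.loc["A", "B"] > 0.9


class TestBIC:
    def two_latent_fit(self, noise_sd, seed=16, n=61):
        rng = np.random.default_rng(seed)
        x = rng.standard_normal(n)
        y = 0.6 * x + noise_sd * rng.standard_normal(n)
        df = pd.DataFrame({"x": x, "y": y})
        spec = pls.PathModelSpec(blocks={"X": ["x"], "Y": ["y"]},
                                 paths=[("X", "Y")])
        return pls.fit_pls(spec, df)

    def test_identical_models_delta_zero(self):
        f = self.two_latent_fit(1.0)
        assert pls.model_bic(f, "Y") - pls.model_bic(f, "Y") == 0.0

    def test_bic_decreases_with_r2_at_fixed_k(self):
        hi = self.two_latent_fit(noise_sd=0.3)
        lo = self.two_latent_fit(noise_sd=2.0)
        assert pls.model_bic(hi, "Y") < pls.model_bic(lo, "Y")

    def test_null_predictor_penalized(self):
        """Adding a predictor with true beta=0 at n=61 worsens BIC in most
        replicates."""
        rng = np.random.default_rng(17)
        favored = 0
        n_rep = 50
        for i in range(n_rep):
            n = 61
            x = rng.standard_normal(n)
            z = rng.standard_normal(n)  # irrelevant
            y = 0.5 * x + rng.standard_normal(n)
            df = pd.DataFrame({"x": x, "z": z, "y": y})
            small = pls.fit_pls(
                pls.PathModelSpec(blocks={"X": ["x"], "Y": ["y"]},
                                  paths=[("X", "Y")]), df[["x", "y"]])
            big = pls.fit_pls(
                pls.PathModelSpec(blocks={"X": ["x"], "Z": ["z"], "Y": ["y"]},
                                  paths=[("X", "Y"), ("Z", "Y")]), df)
            if pls.model_bic(small, "Y") < pls.model_bic(big, "Y"):
                favored += 1
        assert favored >= 0.8 * n_rep
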