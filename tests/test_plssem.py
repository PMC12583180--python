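"""PLS path modeling: VIF, fitting, quality metrics, effects, bootstrap."""

import numpy as np
import pandas as pd
import pytest

from vegdyn.plssem import (PLSModelSpec, bootstrap_significance,
                           effects_decomposition, fit_pls_sem, model_quality,
                           vif)
from vegdyn.synthetic import generate_pls_dataset


class TestVIF:
    def test_orthogonal_variables_vif_one(self, rng):
        n = 4000
        df = pd.DataFrame({"a": rng.normal(size=n), "b": rng.normal(size=n)})
        out = vif(df, ["a", "b"])
        assert out["a"] == pytest.approx(1.0, abs=0.01)

    def test_perfect_collinearity_infinite(self, rng):
        x = rng.normal(size=50)
        df = pd.DataFrame({"a": x, "b": 2 * x + 1})
        with pytest.warns(UserWarning, match="collinearity"):
            out = vif(df, ["a", "b"])
        assert np.isinf(out["a"])

    def test_equicorrelated_triplet_closed_form(self, rng):
        # pairwise correlation 0.5 -> R^2 = 1/3 -> VIF = 1.5
        n = 200000
        chol = np.linalg.cholesky(0.5 * np.ones((3, 3)) + 0.5 * np.eye(3))
        data = rng.standard_normal((n, 3)) @ chol.T
        out = vif(pd.DataFrame(data, columns=list("abc")), list("abc"))
        for v in out.values():
            assert v == pytest.approx(1.5, abs=0.03)

    def test_constant_column_rejected(self):
        df = pd.DataFrame({"a": [1.0, 1.0, 1.0, 1.0, 1.0], "b": [1, 2, 3, 4, 5]})
        with pytest.raises(ValueError, match="constant"):
            vif(df, ["a", "b"])


class TestSpec:
    def test_cycle_rejected(self):
        with pytest.raises(ValueError, match="cycle"):
            PLSModelSpec(blocks={"A": ["a"], "B": ["b"]},
                         inner_paths=[("A", "B"), ("B", "A")])

    def test_duplicate_indicator_rejected(self):
        with pytest.raises(ValueError, match="appears"):
            PLSModelSpec(blocks={"A": ["x"], "B": ["x"]}, inner_paths=[])


class TestFit:
    def test_single_indicator_block_score_is_standardized_indicator(self, rng):
        x = rng.normal(2.0, 3.0, 300)
        df = pd.DataFrame({"x": x})
        spec = PLSModelSpec(blocks={"A": ["x"]}, inner_paths=[])
        fit = fit_pls_sem(df, spec)
        assert fit.loadings["x"] == pytest.approx(1.0)
        z = (x - x.mean()) / x.std(ddof=1)
        assert np.allclose(fit.latent_scores["A"], z, atol=1e-10)

    def test_two_single_indicator_latents_path_equals_correlation(self, rng):
        n = 500
        a = rng.normal(size=n)
        b = 0.6 * a + 0.8 * rng.normal(size=n)
        df = pd.DataFrame({"xa": a, "xb": b})
        spec = PLSModelSpec(blocks={"A": ["xa"], "B": ["xb"]},
                            inner_paths=[("A", "B")])
        fit = fit_pls_sem(df, spec)
        r = np.corrcoef(a, b)[0, 1]
        assert fit.path_coefficients[("A", "B")] == pytest.approx(r, abs=1e-10)
        assert fit.r_squared["B"] == pytest.approx(r ** 2, abs=1e-10)

    def test_latent_scores_standardized(self, rng):
        paths = {("L1", "L2"): 0.5}
        data, _ = generate_pls_dataset(paths, {"L1": 2, "L2": 2}, n=400, seed=5)
        spec = PLSModelSpec(
            blocks={k: [f"{k}_x1", f"{k}_x2"] for k in ("L1", "L2")},
            inner_paths=list(paths))
        fit = fit_pls_sem(data, spec)
        scores = fit.latent_scores.to_numpy()
        assert np.allclose(scores.mean(axis=0), 0.0, atol=1e-10)
        assert np.allclose(scores.std(axis=0, ddof=1), 1.0, atol=1e-10)

    @pytest.mark.parametrize("scheme", ["centroid", "factor", "path"])
    def test_parameter_recovery_four_blocks(self, scheme):
        paths = {("L1", "L2"): 0.5, ("L1", "L3"): -0.4, ("L2", "L4"): 0.3}
        blocks = {f"L{i}": 2 for i in range(1, 5)}
        data, truth = generate_pls_dataset(paths, blocks, loading=0.8,
                                           n=2000, seed=11)
        spec = PLSModelSpec(
            blocks={k: [f"{k}_x1", f"{k}_x2"] for k in blocks},
            inner_paths=list(paths), scheme=scheme)
        fit = fit_pls_sem(data, spec)
        assert fit.converged
        for edge, coef in paths.items():
            assert fit.path_coefficients[edge] == pytest.approx(coef, abs=0.05)
        for ind, lam in truth["loadings"].items():
            assert fit.loadings[ind] == pytest.approx(lam, abs=0.05)

    def test_listwise_deletion_counted(self, rng):
        df = pd.DataFrame({"xa": rng.normal(size=50), "xb": rng.normal(size=50)})
        df.loc[3, "xa"] = np.nan
        spec = PLSModelSpec(blocks={"A": ["xa"], "B": ["xb"]},
                            inner_paths=[("A", "B")])
        fit = fit_pls_sem(df, spec)
        assert fit.n_dropped == 1 and fit.n_obs == 49


class TestQuality:
    def test_gof_direct_substitution(self):
        # communalities {0.5, 0.7}, R2 {0.6, 0.4} -> GOF = sqrt(0.6 * 0.5)
        gof = np.sqrt(np.mean([0.5, 0.7]) * np.mean([0.6, 0.4]))
        assert gof == pytest.approx(0.5477, abs=1e-4)

    def test_quality_table_bands(self, rng):
        paths = {("L1", "L2"): 0.68}
        data, _ = generate_pls_dataset(paths, {"L1": 1, "L2": 1}, n=3000, seed=7)
        spec = PLSModelSpec(blocks={"L1": ["L1_x1"], "L2": ["L2_x1"]},
                            inner_paths=list(paths))
        fit = fit_pls_sem(data, spec)
        q = model_quality(fit)
        r2_row = q[(q.metric == "R2") & (q.name == "L2")]
        # R2 ~ 0.46 -> moderate explanatory power band
        assert "Moderate" in r2_row["assessment"].item()
        ave_rows = q[q.metric == "AVE"]
        assert np.allclose(ave_rows["value"], 1.0)     # single indicators

    def test_all_unit_loadings_give_unit_ave(self, rng):
        x = rng.normal(size=200)
        df = pd.DataFrame({"x": x, "y": 0.9 * x + 0.1 * rng.normal(size=200)})
        spec = PLSModelSpec(blocks={"A": ["x"], "B": ["y"]},
                            inner_paths=[("A", "B")])
        fit = fit_pls_sem(df, spec)
        assert fit.ave["A"] == pytest.approx(1.0)


class TestEffects:
    def _fit_with_paths(self, coefs):
        """Build a fit whose inner coefficients are exactly `coefs`."""
        paths = dict(coefs)
        latents = sorted({l for e in paths for l in e})
        blocks = {l: 1 for l in latents}
        data, _ = generate_pls_dataset(paths, blocks, n=200, seed=3)
        spec = PLSModelSpec(blocks={l: [f"{l}_x1"] for l in latents},
                            inner_paths=list(paths))
        fit = fit_pls_sem(data, spec)
        fit.path_coefficients = dict(paths)       # exact coefficients
        return fit

    def test_chain_indirect_product(self):
        fit = self._fit_with_paths({("A", "B"): 0.5, ("B", "C"): 0.4})
        eff = effects_decomposition(fit).set_index(["source", "target"])
        row = eff.loc[("A", "C")]
        assert row["direct"] == 0.0
        assert row["indirect"] == pytest.approx(0.2)
        assert row["total"] == pytest.approx(0.2)

    def test_total_equals_direct_plus_indirect_exactly(self, rng):
        fit = self._fit_with_paths({("A", "B"): 0.3, ("A", "C"): -0.2,
                                    ("B", "C"): 0.6, ("C", "D"): 0.5,
                                    ("A", "D"): 0.1})
        eff = effects_decomposition(fit)
        assert np.allclose(eff["total"], eff["direct"] + eff["indirect"],
                           atol=1e-15)

    def test_matches_bruteforce_path_enumeration(self, rng):
        # random DAG on 6 latents with topological order L0..L5
        names = [f"N{i}" for i in range(6)]
        coefs = {}
        for i in range(6):
            for j in range(i + 1, 6):
                if rng.random() < 0.5:
                    coefs[(names[i], names[j])] = round(float(
                        rng.uniform(-0.4, 0.4)), 3)
        if not coefs:
            coefs[("N0", "N1")] = 0.2
        fit = self._fit_with_paths(coefs)
        eff = effects_decomposition(fit).set_index(["source", "target"])

        def brute_total(src, dst):
            total = 0.0
            stack = [(src, 1.0)]
            while stack:
                node, prod = stack.pop()
                for (s, d), c in coefs.items():
                    if s == node:
                        if d == dst:
                            total += prod * c
                        else:
                            stack.append((d, prod * c))
            return total

        for src in names:
            for dst in names:
                if src == dst:
                    continue
                expected = brute_total(src, dst)
                if (src, dst) in eff.index:
                    assert eff.loc[(src, dst), "total"] == pytest.approx(
                        expected, abs=1e-12)
                else:
                    assert expected == pytest.approx(0.0, abs=1e-12)

    def test_additivity_of_published_effect_row(self):
        # topography on FVC: direct -0.02, indirect -0.44 -> total -0.46
        assert -0.02 + -0.44 == pytest.approx(-0.46)


class TestBootstrap:
    def _spec_and_data(self, coef, n, seed):
        paths = {("A", "B"): coef} if coef else {}
        blocks = {"A": 1, "B": 1}
        if coef:
            data, _ = generate_pls_dataset(paths, blocks, n=n, seed=seed)
        else:
            rng = np.random.default_rng(seed)
            data = pd.DataFrame({"A_x1": rng.normal(size=n),
                                 "B_x1": rng.normal(size=n)})
        spec = PLSModelSpec(blocks={"A": ["A_x1"], "B": ["B_x1"]},
                            inner_paths=[("A", "B")])
        return data, spec

    def test_deterministic_under_seed(self):
        data, spec = self._spec_and_data(0.5, 200, 4)
        a = bootstrap_significance(data, spec, n_boot=100, seed=9)
        b = bootstrap_significance(data, spec, n_boot=100, seed=9)
        pd.testing.assert_frame_equal(a, b)

    def test_strong_path_significant(self):
        data, spec = self._spec_and_data(0.6, 500, 8)
        out = bootstrap_significance(data, spec, n_boot=200, seed=2)
        assert out["p_value"].item() < 0.001

    def test_minimum_resamples_enforced(self):
        data, spec = self._spec_and_data(0.5, 100, 1)
        with pytest.raises(ValueError, match="n_boot"):
            bootstrap_significance(data, spec, n_boot=50, seed=0)
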