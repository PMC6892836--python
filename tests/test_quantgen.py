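"""Variance components, heritability, and genetic correlation estimators."""

import numpy as np
import pandas as pd
import pytest

from spectrait import (
    SimulationConfig,
    generate_experiment,
    genetic_correlation,
    heritability,
    screen_indices,
    variance_components,
    water_content,
)
from spectrait.quantgen import DesignError, VarianceComponents


class TestWaterContent:
    def test_fresh_basis_arithmetic(self):
        assert water_content(8.0, 2.0) == pytest.approx(75.0)

    def test_both_bases_at_fw_twice_dw(self):
        assert water_content(4.0, 2.0, basis="fresh") == pytest.approx(50.0)
        assert water_content(4.0, 2.0, basis="dry") == pytest.approx(100.0)

    def test_rejects_dw_at_least_fw(self):
        with pytest.raises(ValueError):
            water_content(2.0, 2.0)

    def test_realistic_biomass_range_is_fresh_basis(self):
        # field biomass water contents of 58-79% require the fresh-basis
        # convention; on a dry basis the same FW/DW ratios exceed 100%
        for fw_over_dw in (2.5, 3.5, 4.5):
            wc = water_content(fw_over_dw, 1.0, basis="fresh")
            assert 55.0 < wc < 80.0
            assert water_content(fw_over_dw, 1.0, basis="dry") > 100.0


def _brute_force_components(frame, r, e):
    """Independent ANOVA oracle: explicit sums over pandas groupbys."""
    grand = frame["y"].mean()
    g_means = frame.groupby("g")["y"].mean()
    cell_means = frame.groupby(["g", "env"])["y"].mean()
    env_means = frame.groupby("env")["y"].mean()
    ss_g = r * e * ((g_means - grand) ** 2).sum()
    ss_ge = r * sum(
        (cell_means[gi, ei] - g_means[gi] - env_means[ei] + grand) ** 2
        for gi, ei in cell_means.index
    )
    ss_err = sum(
        (row["y"] - cell_means[row["g"], row["env"]]) ** 2 for _, row in frame.iterrows()
    )
    n_g, n_e = len(g_means), len(env_means)
    ms_g = ss_g / (n_g - 1)
    ms_ge = ss_ge / ((n_g - 1) * (n_e - 1))
    ms_err = ss_err / (n_g * n_e * (r - 1))
    return (ms_g - ms_ge) / (r * e), (ms_ge - ms_err) / r, ms_err


class TestVarianceComponents:
    def test_matches_bruteforce_anova_oracle(self):
        rng = np.random.default_rng(0)
        g_lab = np.repeat([f"g{i}" for i in range(3)], 4)
        env = np.tile(np.repeat(["e1", "e2"], 2), 3)
        y = rng.normal(10, 2, size=12)
        vc = variance_components(y, g_lab, env)
        frame = pd.DataFrame({"g": g_lab, "env": env, "y": y})
        sg, sge, se = _brute_force_components(frame, r=2, e=2)
        assert vc.sigma2_e == pytest.approx(se, abs=1e-10)
        assert vc.sigma2_ge == pytest.approx(max(sge, 0.0), abs=1e-10)
        assert vc.sigma2_g == pytest.approx(max(sg, 0.0), abs=1e-10)

    def test_noiseless_no_gxe_gives_h2_one(self):
        g_eff = {"g0": -1.0, "g1": 0.0, "g2": 1.0}
        rows = [
            (g, env, 5.0 + eff)
            for g, eff in g_eff.items()
            for env in ("e1", "e2")
            for _ in range(3)
        ]
        g_lab, env, y = map(np.array, zip(*rows))
        vc = variance_components(y.astype(float), g_lab, env)
        assert vc.sigma2_ge == pytest.approx(0.0, abs=1e-12)
        assert vc.sigma2_e == pytest.approx(0.0, abs=1e-12)
        assert heritability(vc).h2 == pytest.approx(1.0)

    def test_unbalanced_layout_rejected(self):
        g_lab = np.array(["a", "a", "b", "b", "b"])
        env = np.array(["e1", "e2", "e1", "e2", "e2"])
        with pytest.raises(DesignError):
            variance_components(np.arange(5.0), g_lab, env)

    def test_parameter_recovery_200_genotypes(self):
        cfg = SimulationConfig(
            n_genotypes=200,
            treatments=("LM",),
            var_components={t: (0.04, 0.01, 0.01) for t in ("DW", "WC", "GY")},
            seed=42,
        )
        exp = generate_experiment(cfg, with_spectra=False)
        tr = exp.traits
        env = (tr["treatment"] + ":" + tr["year"]).to_numpy()
        vc = variance_components(tr["DW"].to_numpy(), tr["genotype"].to_numpy(), env)
        assert vc.sigma2_g == pytest.approx(0.04, rel=0.15)
        assert vc.sigma2_ge == pytest.approx(0.01, rel=0.15)
        assert vc.sigma2_e == pytest.approx(0.01, rel=0.15)


class TestHeritability:
    def test_printed_formula_arithmetic(self):
        vc = VarianceComponents(sigma2_g=1.0, sigma2_ge=1.0, sigma2_e=1.0, e=2, r=3)
        assert vc.sigma2_p == pytest.approx(1 + 0.5 + 1 / 6)
        assert heritability(vc).h2 == pytest.approx(0.6)

    def test_pure_genetic_variance_gives_one(self):
        vc = VarianceComponents(sigma2_g=1.0, sigma2_ge=0.0, sigma2_e=0.0, e=2, r=3)
        assert heritability(vc).h2 == pytest.approx(1.0)

    def test_phenotypic_variance_identity_randomized(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            sg, sge, se = rng.uniform(0, 5, size=3)
            e, r = rng.integers(2, 6), rng.integers(2, 5)
            vc = VarianceComponents(sigma2_g=sg, sigma2_ge=sge, sigma2_e=se, e=int(e), r=int(r))
            assert vc.sigma2_p == pytest.approx(sg + sge / e + se / (r * e), abs=1e-12)

    def test_affine_invariance(self):
        rng = np.random.default_rng(2)
        g_lab = np.repeat([f"g{i}" for i in range(10)], 6)
        env = np.tile(np.repeat(["e1", "e2"], 3), 10)
        y = rng.normal(0, 1, 60)
        h_raw = heritability(variance_components(y, g_lab, env)).h2
        h_scaled = heritability(variance_components(7.3 * y + 11, g_lab, env)).h2
        assert h_raw == pytest.approx(h_scaled, rel=1e-10)


class TestGeneticCorrelation:
    @staticmethod
    def _layout(rng, n_g=20):
        g_lab = np.repeat([f"g{i}" for i in range(n_g)], 6)
        env = np.tile(np.repeat(["e1", "e2"], 3), n_g)
        y = rng.normal(0, 1, 6 * n_g) + np.repeat(rng.normal(0, 1, n_g), 6)
        return g_lab, env, y

    def test_self_correlation_is_one(self):
        rng = np.random.default_rng(3)
        g_lab, env, y = self._layout(rng)
        est = genetic_correlation(y, y, g_lab, env)
        assert est.rg == pytest.approx(1.0)

    def test_affine_transform_gives_one(self):
        rng = np.random.default_rng(4)
        g_lab, env, y = self._layout(rng)
        est = genetic_correlation(y, 2.5 * y + 3.0, g_lab, env)
        assert est.rg == pytest.approx(1.0)

    def test_planted_correlation_recovered(self):
        cfg = SimulationConfig(n_genotypes=200, treatments=("LM",), seed=5)
        exp = generate_experiment(cfg, with_spectra=False)
        tr = exp.traits
        env = (tr["treatment"] + ":" + tr["year"]).to_numpy()
        est = genetic_correlation(
            tr["DW"].to_numpy(), tr["GY"].to_numpy(), tr["genotype"].to_numpy(), env
        )
        assert est.rg == pytest.approx(0.8, abs=0.1)

    def test_permuting_genotypes_destroys_rg(self):
        cfg = SimulationConfig(n_genotypes=100, treatments=("LM",), seed=6)
        exp = generate_experiment(cfg, with_spectra=False)
        tr = exp.traits
        env = (tr["treatment"] + ":" + tr["year"]).to_numpy()
        # shuffle which genotype produced which GY genotype-block; the
        # planted rg(DW, GY) = 0.8 must collapse to sampling noise
        blocks = tr.groupby("genotype", sort=False)
        gy = tr["GY"].to_numpy()
        starts = {g: idx.to_numpy() for g, idx in blocks.groups.items()}
        keys = list(starts)
        null_rg = []
        for perm_seed in range(5):
            order = np.random.default_rng(perm_seed).permutation(len(keys))
            gy_new = np.empty_like(gy)
            for k, g in enumerate(keys):
                gy_new[starts[g]] = gy[starts[keys[order[k]]]]
            est = genetic_correlation(
                tr["DW"].to_numpy(), gy_new, tr["genotype"].to_numpy(), env
            )
            null_rg.append(abs(est.rg))
        assert np.median(null_rg) < 0.15


class TestScreening:
    def test_shape_and_constructed_proxy(self, default_experiment):
        exp = default_experiment
        tr = exp.traits
        table = pd.DataFrame(
            {
                "proxy_GY": 0.1 * tr["GY"].to_numpy() + 2.0,
                "noise": np.random.default_rng(8).normal(size=len(tr)),
            },
            index=pd.Index(tr["plot_id"], name="plot_id"),
        )
        out = screen_indices(table, tr, scope="FL+LM")
        h2_rows = out[out["trait"] == ""]
        rg_rows = out[out["trait"] != ""]
        assert len(h2_rows) == 2 + 3  # two indices + three traits
        assert len(rg_rows) == 2 * 3
        rg_proxy = rg_rows.query("variable == 'proxy_GY' and trait == 'GY'")["rg"].iloc[0]
        assert rg_proxy == pytest.approx(1.0, abs=1e-6)
        h2_gy = h2_rows.query("variable == 'GY'")["H2"].iloc[0]
        h2_proxy = h2_rows.query("variable == 'proxy_GY'")["H2"].iloc[0]
        assert h2_proxy == pytest.approx(h2_gy, abs=1e-6)
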