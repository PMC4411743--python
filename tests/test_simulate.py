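"""Cohort simulator: determinism, Hardy-Weinberg, architecture tracking."""

import numpy as np
import pytest
from scipy import stats

from gxekit.grm import build_ge_matrix, compute_grm
from gxekit.grps import compute_grps, match_alleles
from gxekit.reml import fit_univariate
from gxekit.simulate import (
    SimulationConfig,
    simulate_cohort,
    simulate_discovery,
    simulate_genotypes,
)


class TestSimulateGenotypes:
    def test_deterministic_under_seed(self):
        a, fa = simulate_genotypes(30, 40, seed=7)
        b, fb = simulate_genotypes(30, 40, seed=7)
        np.testing.assert_array_equal(a.dosages, b.dosages)
        np.testing.assert_array_equal(fa, fb)
        c, _ = simulate_genotypes(30, 40, seed=8)
        assert not np.array_equal(a.dosages, c.dosages)

    def test_fixed_half_frequency(self):
        geno, freqs = simulate_genotypes(4000, 5, maf_range=(0.5, 0.5), seed=1)
        np.testing.assert_array_equal(freqs, 0.5)
        assert abs(geno.dosages.mean() - 1.0) < 0.03

    def test_hwe_proportions(self):
        geno, _ = simulate_genotypes(10000, 1, freqs=np.array([0.2]), seed=2)
        counts = np.bincount(geno.dosages[:, 0].astype(int), minlength=3)
        expected = 10000 * np.array([0.64, 0.32, 0.04])
        p = stats.chisquare(counts, expected).pvalue
        assert p > 0.001

    def test_invalid_sizes(self):
        with pytest.raises(ValueError):
            simulate_genotypes(0, 5)


class TestSimulateCohort:
    def test_realized_variances_match_configuration(self):
        cfg = SimulationConfig(n=500, m=400, var_g=0.3, var_ge=0.2, var_e=0.5, seed=3)
        cohort = simulate_cohort(cfg)
        assert cohort.realized["var_g"] == pytest.approx(0.3, abs=1e-9)
        assert cohort.realized["var_ge"] == pytest.approx(0.2, abs=1e-9)
        assert cohort.realized["var_e"] == pytest.approx(0.5, abs=1e-9)
        # components mutually near-orthogonal by construction
        assert abs(np.corrcoef(cohort.g, cohort.ge)[0, 1]) < 0.2

    def test_binary_case_fraction(self):
        cfg = SimulationConfig(
            n=5000, m=200, var_g=0.3, var_ge=0.0, var_e=0.7,
            trait="binary", disease_prevalence=0.1, seed=4,
        )
        cohort = simulate_cohort(cfg)
        frac = cohort.phenotype.values.mean()
        tol = 4 * np.sqrt(0.1 * 0.9 / 5000)
        assert abs(frac - 0.1) < tol

    def test_pure_noise_cohort(self):
        cfg = SimulationConfig(n=400, m=100, var_g=0.0, var_ge=0.0, var_e=1.0, seed=5)
        cohort = simulate_cohort(cfg)
        assert cohort.liability.var() == pytest.approx(1.0, abs=1e-9)
        assert (cohort.allelic_effects == 0).all()

    def test_interaction_covariance_respects_environment_mask(self):
        # same-environment pairs share interaction effects; across
        # environments the interaction deviations are independent draws
        cfg = SimulationConfig(n=200, m=150, var_g=0.0, var_ge=1.0, var_e=0.0, seed=6)
        cohort = simulate_cohort(cfg)
        e = cohort.env.values
        eff = cohort.allelic_interaction_effects
        assert set(eff) == {0.0, 1.0}
        d = cohort.genotypes.dosages
        for lev in (0.0, 1.0):
            mask = e == lev
            # within a level, ge equals the level's own allelic burden
            # (up to the centring constant absorbed by the intercept)
            resid = cohort.ge[mask] - d[mask] @ eff[lev]
            assert resid.std() < 1e-9

    def test_ascertainment_hits_target_fraction(self):
        cfg = SimulationConfig(
            n=4000, m=100, var_g=0.3, var_ge=0.0, var_e=0.7, trait="binary",
            disease_prevalence=0.1, ascertain_case_fraction=0.5, seed=7,
        )
        cohort = simulate_cohort(cfg)
        frac = cohort.phenotype.values.mean()
        assert frac == pytest.approx(0.5, abs=0.02)

    def test_continuous_environment_and_amplification_modes(self):
        c1 = simulate_cohort(SimulationConfig(n=300, m=100, env_kind="continuous", seed=8))
        assert c1.env.kind == "continuous"
        assert "slope" in c1.allelic_interaction_effects
        c2 = simulate_cohort(
            SimulationConfig(n=300, m=100, interaction_mode="amplification", seed=9)
        )
        # amplified effects are proportional to the main effects
        top = c2.allelic_interaction_effects[1.0]
        ratio = top[c2.allelic_effects != 0] / c2.allelic_effects[c2.allelic_effects != 0]
        np.testing.assert_allclose(ratio, ratio[0])

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            simulate_cohort(SimulationConfig(var_g=-0.1))
        with pytest.raises(ValueError, match="prevalence"):
            simulate_cohort(SimulationConfig(env_prevalence=1.5))
        with pytest.raises(ValueError, match="maf_range"):
            simulate_cohort(SimulationConfig(maf_range=(0.0, 0.6)))
        with pytest.raises(ValueError, match="positive"):
            simulate_cohort(SimulationConfig(var_g=0, var_ge=0, var_e=0))


class TestSimulateDiscovery:
    def test_estimated_betas_track_truth(self):
        cfg = SimulationConfig(n=200, m=50, var_g=0.5, var_ge=0.0, var_e=0.5, seed=10)
        cohort = simulate_cohort(cfg)
        ss = simulate_discovery(cohort, 50000, seed=11)
        r = np.corrcoef(ss.frame["beta"], cohort.allelic_effects)[0, 1]
        assert r > 0.95

    def test_null_effects_give_null_scores(self):
        cfg = SimulationConfig(n=500, m=80, var_g=0.0, var_ge=0.0, var_e=1.0, seed=12)
        cohort = simulate_cohort(cfg)
        ss = simulate_discovery(cohort, 2000, seed=13)
        assert abs(ss.frame["beta"].mean()) < 0.02
        matched, _ = match_alleles(cohort.genotypes, ss)
        scores = compute_grps(cohort.genotypes, matched).scores[:, 0]
        r = np.corrcoef(scores, cohort.phenotype.values)[0, 1]
        assert abs(r) < 0.15

    def test_overlapping_ids_rejected(self):
        cfg = SimulationConfig(n=100, m=50, seed=14)
        cohort = simulate_cohort(cfg)
        fake_target = cohort.genotypes.samples.copy()
        fake_target["fid"] = [f"D{i + 1}" for i in range(len(fake_target))]
        fake_target["iid"] = fake_target["fid"]
        with pytest.raises(ValueError, match="disjoint"):
            simulate_discovery(cohort, 200, seed=15, target_ids=fake_target)


def test_null_interaction_recovers_near_zero_component():
    cfg = SimulationConfig(n=600, m=800, var_g=0.4, var_ge=0.0, var_e=0.6, seed=16)
    cohort = simulate_cohort(cfg)
    grm = compute_grm(cohort.genotypes)
    ge = build_ge_matrix(grm, cohort.env)
    X = np.column_stack([np.ones(cfg.n), cohort.env.values])
    fit = fit_univariate(cohort.phenotype.values, [grm, ge], X=X, names=["g", "ge"])
    assert fit.estimates[1] < 0.12
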