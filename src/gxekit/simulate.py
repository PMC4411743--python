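"""Synthetic cohorts with known genetic, environmental and interaction
architecture.

The generative model mirrors the variance decomposition the estimators
target: a polygenic genetic value g = Σ z_i β_i over standardised dosages,
an interaction deviation ge whose covariance structure matches the
environment-masked relationship matrix, and Gaussian noise.  For binary or
categorical exposures the interaction deviation is built from an
*independent* effect-size vector per environment level, so that
Cov(ge_j, ge_k) = σ²_ge A_jk exactly when e_j = e_k and 0 otherwise — the
structure the interaction relationship matrix encodes.  For continuous
exposures the reaction-norm product form (Σ z_i γ_i)·z_e is used.  An
"amplification" mode (γ proportional to β) generates pure scale effects
for phenotype-transformation experiments.

Each realised component is rescaled to hit its configured variance exactly,
so estimator-recovery experiments measure estimation error, not simulation
Monte-Carlo error.  Binary traits arise by thresholding the liability at
the normal quantile implied by the configured prevalence.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .containers import (
    EnvironmentVector,
    GenotypeMatrix,
    PhenotypeVector,
    SummaryStats,
)

__all__ = [
    "SimulationConfig",
    "SimulatedCohort",
    "simulate_genotypes",
    "simulate_cohort",
    "simulate_discovery",
]


@dataclass
class SimulationConfig:
    """Cohort architecture: sizes, variance components and exposure model.

    Variances are on the liability/phenotype scale and need not sum to 1;
    the liability threshold for binary traits uses their sum as the total
    variance.
    """

    n: int = 1000
    m: int = 1000
    maf_range: tuple = (0.05, 0.5)
    var_g: float = 0.3
    var_ge: float = 0.2
    var_e: float = 0.5
    env_kind: str = "binary"  # binary | categorical | continuous
    env_prevalence: float = 0.5  # P(exposed) for binary E
    env_levels: int = 2  # categorical E only
    env_beta: float = 0.0  # fixed main effect of (centred) E on y
    trait: str = "quantitative"  # quantitative | binary
    disease_prevalence: float = 0.1
    ascertain_case_fraction: float | None = None
    interaction_mode: str = "independent"  # independent | amplification
    seed: int = 0

    def validate(self) -> None:
        if min(self.var_g, self.var_ge, self.var_e) < 0:
            raise ValueError("variance components must be non-negative")
        if self.var_g + self.var_ge + self.var_e <= 0:
            raise ValueError("at least one variance component must be positive")
        if not (0 < self.env_prevalence < 1):
            raise ValueError("environment prevalence must lie in (0, 1)")
        if not (0 < self.disease_prevalence < 1):
            raise ValueError("disease prevalence must lie in (0, 1)")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must be within (0, 0.5]")
        if self.trait not in ("quantitative", "binary"):
            raise ValueError(f"unknown trait kind {self.trait!r}")
        if self.env_kind not in ("binary", "categorical", "continuous"):
            raise ValueError(f"unknown environment kind {self.env_kind!r}")
        if self.interaction_mode not in ("independent", "amplification"):
            raise ValueError(f"unknown interaction mode {self.interaction_mode!r}")
        if self.interaction_mode == "amplification" and self.var_g == 0 and self.var_ge > 0:
            raise ValueError("amplification mode requires a genetic main component")


@dataclass
class SimulatedCohort:
    genotypes: GenotypeMatrix
    env: EnvironmentVector
    phenotype: PhenotypeVector
    liability: np.ndarray
    g: np.ndarray
    ge: np.ndarray
    noise: np.ndarray
    allelic_effects: np.ndarray  # per-dosage main effects
    allelic_interaction_effects: dict  # env level -> per-dosage effects
    variant_freqs: np.ndarray  # generating allele frequencies of A1
    realized: dict = field(default_factory=dict)
    config: SimulationConfig | None = None


def simulate_genotypes(
    n: int,
    m: int,
    maf_range: tuple = (0.05, 0.5),
    seed: int | np.random.Generator = 0,
    sample_prefix: str = "T",
    freqs: np.ndarray | None = None,
) -> tuple[GenotypeMatrix, np.ndarray]:
    """Draw unlinked Hardy–Weinberg genotypes.

    Allele frequencies are drawn uniformly in ``maf_range`` (or taken from
    ``freqs``), and each dosage is two independent allele draws.  Returns
    the matrix and the generating frequencies.
    """
    if n < 1 or m < 1:
        raise ValueError("n and m must be at least 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if freqs is None:
        lo, hi = maf_range
        freqs = rng.uniform(lo, hi, size=m)
    dosages = rng.binomial(2, freqs, size=(n, m)).astype(float)
    variants = pd.DataFrame(
        {
            "id": [f"snp{i + 1}" for i in range(m)],
            "chrom": "1",
            "pos": np.arange(1, m + 1) * 1000,
            "a1": "A",
            "a2": "G",
        }
    )
    samples = pd.DataFrame(
        {
            "fid": [f"{sample_prefix}{i + 1}" for i in range(n)],
            "iid": [f"{sample_prefix}{i + 1}" for i in range(n)],
        }
    )
    return GenotypeMatrix(dosages=dosages, variants=variants, samples=samples), freqs


def _standardize_columns(d: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    mu = d.mean(axis=0)
    sd = d.std(axis=0)
    ok = sd > 0
    z = np.zeros_like(d)
    z[:, ok] = (d[:, ok] - mu[ok]) / sd[ok]
    return z, sd, ok


def _scaled_component(raw: np.ndarray, target_var: float, label: str) -> tuple[np.ndarray, float]:
    """Rescale a raw draw to hit the target variance exactly."""
    if target_var == 0:
        return np.zeros_like(raw), 0.0
    sd = raw.std()
    if sd == 0:
        raise ValueError(f"degenerate draw for the {label} component (zero variance)")
    scale = np.sqrt(target_var) / sd
    return raw * scale, scale


def _draw_environment(cfg: SimulationConfig, n: int, rng) -> np.ndarray:
    if cfg.env_kind == "binary":
        e = rng.binomial(1, cfg.env_prevalence, size=n).astype(float)
        if np.unique(e).size < 2:  # tiny-n guard: force both groups present
            e[: max(1, n // 2)] = 1.0 - e[0]
        return e
    if cfg.env_kind == "categorical":
        return rng.integers(0, cfg.env_levels, size=n).astype(float)
    return rng.normal(size=n)


def simulate_cohort(config: SimulationConfig) -> SimulatedCohort:
    """Generate a cohort from the y = g + ge + ε architecture."""
    cfg = config
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    genotypes, freqs = simulate_genotypes(
        cfg.n, cfg.m, cfg.maf_range, seed=rng, sample_prefix="T"
    )
    z, sd_x, ok = _standardize_columns(genotypes.dosages)
    n, m = z.shape

    e = _draw_environment(cfg, n, rng)

    # main polygenic component
    beta = rng.normal(size=m)
    g_raw = z @ beta / np.sqrt(m)
    g, scale_g = _scaled_component(g_raw, cfg.var_g, "genetic")
    allelic = np.zeros(m)
    allelic[ok] = beta[ok] * scale_g / np.sqrt(m) / sd_x[ok]

    # interaction component
    allelic_int: dict = {}
    if cfg.var_ge > 0:
        if cfg.interaction_mode == "amplification":
            if cfg.env_kind == "continuous":
                mod = (e - e.mean()) / e.std()
            else:
                top = np.max(e)
                mod = (e == top).astype(float)
            ge_raw = g_raw * mod
            ge, scale_ge = _scaled_component(ge_raw, cfg.var_ge, "interaction")
            for lev in np.unique(e):
                allelic_int[float(lev)] = (
                    allelic / max(scale_g, 1e-300) * scale_ge * (1.0 if lev == np.max(e) else 0.0)
                    if cfg.env_kind != "continuous"
                    else allelic / max(scale_g, 1e-300) * scale_ge
                )
        elif cfg.env_kind == "continuous":
            gamma = rng.normal(size=m)
            z_e = (e - e.mean()) / e.std()
            ge_raw = (z @ gamma / np.sqrt(m)) * z_e
            ge, scale_ge = _scaled_component(ge_raw, cfg.var_ge, "interaction")
            eff = np.zeros(m)
            eff[ok] = gamma[ok] * scale_ge / np.sqrt(m) / sd_x[ok]
            allelic_int["slope"] = eff
        else:
            levels = np.unique(e)
            gammas = rng.normal(size=(m, levels.size))
            u = z @ gammas / np.sqrt(m)  # n x L
            idx = np.searchsorted(levels, e)
            ge_raw = u[np.arange(n), idx]
            ge, scale_ge = _scaled_component(ge_raw, cfg.var_ge, "interaction")
            for L, lev in enumerate(levels):
                eff = np.zeros(m)
                eff[ok] = gammas[ok, L] * scale_ge / np.sqrt(m) / sd_x[ok]
                allelic_int[float(lev)] = eff
    else:
        ge = np.zeros(n)

    noise, _ = _scaled_component(rng.normal(size=n), cfg.var_e, "residual")

    liability = g + ge + noise
    if cfg.env_beta != 0.0:
        liability = liability + cfg.env_beta * (e - e.mean())

    if cfg.trait == "binary":
        total = cfg.var_g + cfg.var_ge + cfg.var_e
        threshold = stats.norm.ppf(1 - cfg.disease_prevalence) * np.sqrt(total)
        y = (liability > threshold).astype(float)
        kind = "binary"
    else:
        y = liability.copy()
        kind = "continuous"

    samples = genotypes.samples
    env_vec = EnvironmentVector(
        frame=pd.DataFrame({"fid": samples["fid"], "iid": samples["iid"], "value": e}),
        kind="binary" if cfg.env_kind == "binary" else
        ("ordinal" if cfg.env_kind == "categorical" else "continuous"),
    )
    pheno_vec = PhenotypeVector(
        frame=pd.DataFrame({"fid": samples["fid"], "iid": samples["iid"], "value": y}),
        kind=kind,
    )
    cohort = SimulatedCohort(
        genotypes=genotypes,
        env=env_vec,
        phenotype=pheno_vec,
        liability=liability,
        g=g,
        ge=ge,
        noise=noise,
        allelic_effects=allelic,
        allelic_interaction_effects=allelic_int,
        variant_freqs=freqs,
        realized={
            "var_g": float(g.var()),
            "var_ge": float(ge.var()),
            "var_e": float(noise.var()),
            "case_fraction": float(y.mean()) if cfg.trait == "binary" else np.nan,
        },
        config=cfg,
    )
    if cfg.ascertain_case_fraction is not None:
        cohort = _ascertain(cohort, cfg.ascertain_case_fraction, rng)
    return cohort


def _ascertain(cohort: SimulatedCohort, case_fraction: float, rng) -> SimulatedCohort:
    """Case-control ascertainment: keep all cases, thin controls."""
    if cohort.config.trait != "binary":
        raise ValueError("ascertainment applies to binary traits only")
    y = cohort.phenotype.values
    cases = np.where(y == 1)[0]
    controls = np.where(y == 0)[0]
    n_controls = int(round(cases.size * (1 - case_fraction) / case_fraction))
    if n_controls > controls.size:
        n_controls = controls.size
    keep = np.sort(np.concatenate([cases, rng.choice(controls, n_controls, replace=False)]))
    gt = cohort.genotypes
    sub = GenotypeMatrix(
        dosages=gt.dosages[keep],
        variants=gt.variants,
        samples=gt.samples.iloc[keep].reset_index(drop=True),
    )
    return SimulatedCohort(
        genotypes=sub,
        env=EnvironmentVector(cohort.env.frame.iloc[keep].reset_index(drop=True), cohort.env.kind),
        phenotype=PhenotypeVector(
            cohort.phenotype.frame.iloc[keep].reset_index(drop=True), cohort.phenotype.kind
        ),
        liability=cohort.liability[keep],
        g=cohort.g[keep],
        ge=cohort.ge[keep],
        noise=cohort.noise[keep],
        allelic_effects=cohort.allelic_effects,
        allelic_interaction_effects=cohort.allelic_interaction_effects,
        variant_freqs=cohort.variant_freqs,
        realized=dict(cohort.realized, ascertained_case_fraction=float(np.mean(cohort.phenotype.values[keep]))),
        config=cohort.config,
    )


def simulate_discovery(
    cohort: SimulatedCohort,
    n_discovery: int,
    seed: int,
    target_ids: pd.DataFrame | None = None,
) -> SummaryStats:
    """Simulate an independent discovery GWAS sharing the cohort's true
    effects, and return per-variant marginal regression estimates.

    The discovery cohort is generated at the same allele frequencies with
    the same allelic main and interaction effects (its own environment
    draw — a discovery GWAS is typically ignorant of the exposure), and
    each variant is regressed marginally on the phenotype.  Discovery
    sample ids carry a ``D`` prefix; any overlap with ``target_ids``
    (default: the cohort itself) raises, enforcing the no-overlap rule for
    out-of-sample scoring.
    """
    cfg = cohort.config
    rng = np.random.default_rng(seed)
    geno, _ = simulate_genotypes(
        n_discovery, cfg.m, cfg.maf_range, seed=rng, sample_prefix="D", freqs=cohort.variant_freqs
    )
    if target_ids is None:
        target_ids = cohort.genotypes.samples
    overlap = pd.merge(geno.samples, target_ids, on=["fid", "iid"], how="inner")
    if len(overlap):
        raise ValueError(
            f"{len(overlap)} discovery sample(s) overlap the target sample; "
            "discovery and target cohorts must be disjoint"
        )
    d = geno.dosages
    e = _draw_environment(cfg, n_discovery, rng)
    g = d @ cohort.allelic_effects
    ge = np.zeros(n_discovery)
    eff = cohort.allelic_interaction_effects
    if eff:
        if "slope" in eff:
            z_e = (e - e.mean()) / e.std()
            ge = (d @ eff["slope"]) * z_e
        else:
            for lev, vec in eff.items():
                mask = e == lev
                ge[mask] = d[mask] @ vec
    noise = rng.normal(0, np.sqrt(cfg.var_e), size=n_discovery)
    liability = g + ge + noise
    if cfg.trait == "binary":
        total = cfg.var_g + cfg.var_ge + cfg.var_e
        y = (liability > stats.norm.ppf(1 - cfg.disease_prevalence) * np.sqrt(total)).astype(float)
    else:
        y = liability

    xc = d - d.mean(axis=0)
    yc = y - y.mean()
    var_x = (xc**2).sum(axis=0)
    var_x[var_x == 0] = np.nan
    beta_hat = (xc.T @ yc) / var_x
    beta_hat = np.nan_to_num(beta_hat, nan=0.0)
    v = cohort.genotypes.variants
    frame = pd.DataFrame(
        {
            "id": v["id"],
            "effect_allele": v["a1"],
            "other_allele": v["a2"],
            "beta": beta_hat,
        }
    )
    return SummaryStats(frame=frame)
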