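"""SNP-derived relationship matrices: genetic (A_g) and interaction (A_ge).

The genetic matrix follows the standard GREML estimator: with dosages x_ij,
in-sample allele frequencies p_i and per-pair counts m_jk of loci observed
in both individuals,

    A_jk = (1 / m_jk) * sum_i (x_ij - 2 p_i)(x_ik - 2 p_i) / (2 p_i (1 - p_i))

The interaction matrix encodes that interaction effects are shared only
within an environment: for binary or categorical exposures
A_ge[j, k] = A_g[j, k] when e_j = e_k and 0 otherwise (the diagonal is
always retained — an individual shares its own environment); for a
continuous exposure the reaction-norm form A_ge = A_g ∘ z zᵀ is used with z
the standardised exposure.
"""

from __future__ import annotations

import numpy as np

from .containers import EnvironmentVector, GenotypeMatrix, Grm


def compute_grm(
    genotypes: GenotypeMatrix,
    maf_min: float = 0.01,
    max_relatedness: float | None = None,
) -> Grm:
    """Estimate the genetic relationship matrix from allele dosages.

    Parameters
    ----------
    genotypes:
        Hard-call dosage matrix; missing genotypes are handled by per-pair
        denominators (a locus contributes to A_jk only when observed in
        both j and k).
    maf_min:
        Variants with minor allele frequency below this (or monomorphic
        variants) are excluded. The default 0.01 avoids near-degenerate
        2p(1-p) denominators.
    max_relatedness:
        If given, raise if any off-diagonal entry exceeds it (relatedness
        pruning guard; off by default — the model assumes individuals not
        related in the classical sense).

    Returns
    -------
    Grm with kind ``genetic`` and per-pair SNP counts.
    """
    d = genotypes.dosages
    n = d.shape[0]
    if n < 2:
        raise ValueError("at least two samples are required")
    all_missing = np.isnan(d).all(axis=1)
    if all_missing.any():
        bad = genotypes.samples.iloc[int(np.where(all_missing)[0][0])]
        raise ValueError(f"sample {bad['fid']}/{bad['iid']} has no observed genotypes")
    p = genotypes.a1_frequency()
    maf = np.minimum(p, 1 - p)
    keep = (maf >= maf_min) & (maf > 0)
    if not keep.any():
        raise ValueError(
            "no variant passes the MAF filter (all monomorphic or below maf_min)"
        )
    d = d[:, keep]
    p = p[keep]

    obs = ~np.isnan(d)
    z = (d - 2 * p) / np.sqrt(2 * p * (1 - p))
    z[~obs] = 0.0
    num = z @ z.T
    counts = obs.astype(np.float64) @ obs.astype(np.float64).T
    if (counts == 0).any():
        j, k = np.argwhere(counts == 0)[0]
        raise ValueError(f"samples {j} and {k} share no observed variants")
    values = num / counts
    values = (values + values.T) / 2  # enforce exact symmetry
    if max_relatedness is not None:
        off = values[~np.eye(n, dtype=bool)]
        if (off > max_relatedness).any():
            raise ValueError(
                f"off-diagonal relatedness exceeds {max_relatedness}; "
                "prune related samples before fitting"
            )
    return Grm(
        values=values,
        ids=genotypes.sample_ids(),
        n_snps=counts,
        kind="genetic",
    )


def build_ge_matrix(grm: Grm, env: EnvironmentVector, env_kind: str | None = None) -> Grm:
    """Construct the interaction relationship matrix A_ge from A_g and an
    environmental exposure.

    ``env_kind`` overrides the kind declared on ``env`` (``binary``,
    ``ordinal``/``categorical`` -> same-level masking; ``continuous`` ->
    A_g ∘ zzᵀ with z standardised).
    """
    kind = env_kind or env.kind
    if kind == "categorical":
        kind = "ordinal"
    e = env.align_to(grm.ids)
    missing = np.isnan(e)
    if missing.any():
        rows = grm.ids[missing]
        ids = [f"{r.fid}/{r.iid}" for r in rows.itertuples()]
        raise ValueError(f"environment missing for sample(s): {ids[:5]}")
    if np.unique(e).size < 2:
        raise ValueError(
            "environment is constant: the interaction matrix would equal A_g"
        )

    if kind in ("binary", "ordinal"):
        same = e[:, None] == e[None, :]
        values = np.where(same, grm.values, 0.0)
    elif kind == "continuous":
        z = (e - e.mean()) / e.std()
        values = grm.values * np.outer(z, z)
    else:
        raise ValueError(f"unknown environment kind {kind!r}")
    return Grm(values=values, ids=grm.ids.copy(), n_snps=grm.n_snps.copy(), kind="interaction")


def scale_to_unit_diagonal(grm: Grm) -> Grm:
    """Rescale a relationship matrix so its mean diagonal is 1 (optional
    pre-fitting normalisation; off by default in the REML drivers)."""
    scale = np.mean(np.diag(grm.values))
    if scale <= 0:
        raise ValueError("mean diagonal is not positive; cannot rescale")
    return Grm(
        values=grm.values / scale,
        ids=grm.ids.copy(),
        n_snps=grm.n_snps.copy(),
        kind=grm.kind,
    )
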