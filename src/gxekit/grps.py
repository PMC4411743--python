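"""Genomic risk profile scores (GRPS).

A GRPS is the number of risk alleles an individual carries, weighted by
discovery-sample effect sizes and averaged over the loci scored:

    score_i = ( Σ_j x_ij β_j ) / (# non-missing loci for i)

Construction is two-step: (1) match discovery effect alleles to target
genotype alleles — flipping the sign when the effect allele is the target's
A2 and resolving strand via complement, with strand-ambiguous (A/T, C/G)
pairs optionally dropped; (2) average the effect-weighted allele counts,
optionally within named SNP partitions (e.g. by functional annotation or
physical position).  The discovery and target samples must be disjoint:
scoring a cohort with weights estimated from overlapping individuals
inflates association.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .containers import GenotypeMatrix, RiskScoreSet, SummaryStats

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


def _complement(allele: str) -> str:
    return "".join(_COMPLEMENT.get(b, "N") for b in allele.upper()[::-1])


def _is_ambiguous(a: str, b: str) -> bool:
    return {a.upper(), b.upper()} in ({"A", "T"}, {"C", "G"})


def match_alleles(
    genotypes: GenotypeMatrix,
    sumstats: SummaryStats,
    drop_ambiguous: bool = True,
) -> tuple[pd.DataFrame, dict]:
    """Match discovery effect sizes to target genotype alleles.

    Returns
    -------
    matched : DataFrame
        Columns ``id``, ``col`` (column index into the dosage matrix),
        ``weight`` (effect size applied to the A1 dosage; negated for
        flipped matches) and ``category``.
    report : dict
        Counts per matching category, including exclusions.
    """
    if genotypes.n_variants == 0 or len(sumstats) == 0:
        raise ValueError("empty genotype matrix or summary statistics")
    variants = genotypes.variants.reset_index(drop=True)
    variants = variants.assign(col=np.arange(len(variants)))
    merged = variants.merge(sumstats.frame, on="id", how="inner")
    report = {
        "direct": 0,
        "flipped": 0,
        "strand_direct": 0,
        "strand_flipped": 0,
        "ambiguous_excluded": 0,
        "mismatch_excluded": 0,
        "not_in_target": int(len(sumstats) - len(merged)),
    }
    rows = []
    for rec in merged.itertuples():
        a1, a2 = rec.a1.upper(), rec.a2.upper()
        ea, oa = rec.effect_allele.upper(), rec.other_allele.upper()
        if drop_ambiguous and _is_ambiguous(a1, a2):
            report["ambiguous_excluded"] += 1
            continue
        if (ea, oa) == (a1, a2):
            cat, w = "direct", rec.beta
        elif (ea, oa) == (a2, a1):
            cat, w = "flipped", -rec.beta
        elif (_complement(ea), _complement(oa)) == (a1, a2):
            cat, w = "strand_direct", rec.beta
        elif (_complement(ea), _complement(oa)) == (a2, a1):
            cat, w = "strand_flipped", -rec.beta
        else:
            report["mismatch_excluded"] += 1
            continue
        report[cat] += 1
        rows.append((rec.id, rec.col, w, cat))
    if not rows:
        raise ValueError("no variants could be matched between target and summary statistics")
    matched = pd.DataFrame(rows, columns=["id", "col", "weight", "category"])
    return matched, report


def compute_grps(
    genotypes: GenotypeMatrix,
    matched: pd.DataFrame,
    partitions: dict | None = None,
    standardize: bool = False,
    impute_missing: bool = False,
) -> RiskScoreSet:
    """Average effect-weighted risk-allele counts per individual.

    Parameters
    ----------
    matched:
        Output of :func:`match_alleles`.
    partitions:
        Mapping of partition name to variant ids; default a single ``all``
        partition over every matched variant.  Ids absent from the matched
        set are ignored; an empty partition raises.
    standardize:
        Z-score each score column (the raw average is kept otherwise;
        downstream interaction tests are invariant to this affine choice).
    impute_missing:
        Replace missing dosages by twice the in-sample allele frequency
        instead of excluding the locus from numerator and denominator.
    """
    if matched.empty:
        raise ValueError("no matched effects supplied")
    if partitions is None:
        partitions = {"all": list(matched["id"])}
    d = genotypes.dosages
    n = d.shape[0]
    freq = genotypes.a1_frequency()
    names = list(partitions)
    scores = np.full((n, len(names)), np.nan)
    n_loci = np.zeros((n, len(names)), dtype=int)
    by_id = matched.set_index("id")
    for j, name in enumerate(names):
        ids = [i for i in partitions[name] if i in by_id.index]
        if not ids:
            raise ValueError(f"partition {name!r} contains no matched variants")
        cols = by_id.loc[ids, "col"].to_numpy(dtype=int)
        w = by_id.loc[ids, "weight"].to_numpy(dtype=float)
        sub = d[:, cols]
        obs = ~np.isnan(sub)
        if impute_missing:
            sub = np.where(obs, sub, 2 * freq[cols])
            num = sub @ w
            cnt = np.full(n, len(ids))
        else:
            filled = np.where(obs, sub, 0.0)
            num = filled @ w
            cnt = obs.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            col_scores = np.where(cnt > 0, num / np.maximum(cnt, 1), np.nan)
        if (cnt == 0).any():
            warnings.warn(
                f"{int((cnt == 0).sum())} individual(s) have no scorable locus in "
                f"partition {name!r}; score set to missing",
                stacklevel=2,
            )
        scores[:, j] = col_scores
        n_loci[:, j] = cnt
    if standardize:
        mu = np.nanmean(scores, axis=0)
        sd = np.nanstd(scores, axis=0)
        sd[sd == 0] = 1.0
        scores = (scores - mu) / sd
    return RiskScoreSet(
        samples=genotypes.sample_ids(),
        scores=scores,
        n_loci=n_loci,
        partitions=names,
    )


def warn_on_sample_overlap(
    target_samples: pd.DataFrame, discovery_samples: pd.DataFrame
) -> int:
    """Warn when target and discovery cohorts share individuals.

    Overlap leaks the target phenotype into the score weights and inflates
    the apparent association.  Returns the number of overlapping ids.
    """
    overlap = pd.merge(
        target_samples[["fid", "iid"]],
        discovery_samples[["fid", "iid"]],
        on=["fid", "iid"],
        how="inner",
    )
    if len(overlap):
        warnings.warn(
            f"{len(overlap)} individual(s) appear in both the discovery and the "
            "target sample; out-of-sample scores will be inflated",
            stacklevel=2,
        )
    return len(overlap)


class GenomicRiskScorer(BaseEstimator, TransformerMixin):
    """Transformer building GRPS columns from genotypes.

    ``fit`` matches the supplied summary statistics to the target variant
    set (storing ``matched_`` and ``match_report_``); ``transform`` scores
    a genotype matrix with the matched weights.
    """

    def __init__(
        self,
        sumstats: SummaryStats = None,
        partitions: dict | None = None,
        drop_ambiguous: bool = True,
        standardize: bool = False,
        impute_missing: bool = False,
    ):
        self.sumstats = sumstats
        self.partitions = partitions
        self.drop_ambiguous = drop_ambiguous
        self.standardize = standardize
        self.impute_missing = impute_missing

    def fit(self, genotypes: GenotypeMatrix, y=None):
        if self.sumstats is None:
            raise ValueError("sumstats must be provided")
        self.matched_, self.match_report_ = match_alleles(
            genotypes, self.sumstats, drop_ambiguous=self.drop_ambiguous
        )
        return self

    def transform(self, genotypes: GenotypeMatrix) -> RiskScoreSet:
        if not hasattr(self, "matched_"):
            raise ValueError("scorer is not fitted")
        return compute_grps(
            genotypes,
            self.matched_,
            partitions=self.partitions,
            standardize=self.standardize,
            impute_missing=self.impute_missing,
        )
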