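"""Risk-profile score construction: allele matching and weighted averaging."""

import numpy as np
import pandas as pd
import pytest

from gxekit.containers import SummaryStats
from gxekit.grps import (
    GenomicRiskScorer,
    compute_grps,
    match_alleles,
    warn_on_sample_overlap,
)

from conftest import make_genotypes


def sumstats(rows):
    return SummaryStats(
        frame=pd.DataFrame(rows, columns=["id", "effect_allele", "other_allele", "beta"])
    )


class TestMatchAlleles:
    @pytest.mark.parametrize(
        "ea,oa,a1,a2,category,sign",
        [
            ("A", "G", "A", "G", "direct", 1.0),
            ("G", "A", "A", "G", "flipped", -1.0),
            ("T", "C", "A", "G", "strand_direct", 1.0),  # complement of T/C is A/G
            ("C", "T", "A", "G", "strand_flipped", -1.0),
        ],
    )
    def test_match_categories(self, ea, oa, a1, a2, category, sign):
        gm = make_genotypes([[1], [2]], a1=a1, a2=a2)
        matched, report = match_alleles(gm, sumstats([("snp1", ea, oa, 0.3)]))
        assert report[category] == 1
        assert matched["weight"].iloc[0] == pytest.approx(sign * 0.3)

    def test_ambiguous_excluded_and_counted(self):
        gm = make_genotypes([[1]], a1="A", a2="T")
        with pytest.raises(ValueError, match="no variants"):
            match_alleles(gm, sumstats([("snp1", "A", "T", 0.3)]), drop_ambiguous=True)
        gm2 = make_genotypes([[1, 1]], a1="A", a2="T")
        gm2.variants.loc[1, ["a1", "a2"]] = ["C", "A"]
        matched, report = match_alleles(
            gm2, sumstats([("snp1", "A", "T", 0.3), ("snp2", "C", "A", 0.1)])
        )
        assert report["ambiguous_excluded"] == 1
        assert list(matched["id"]) == ["snp2"]

    def test_mismatch_excluded(self):
        gm = make_genotypes([[1]], a1="A", a2="G")
        with pytest.raises(ValueError):
            match_alleles(gm, sumstats([("snp1", "A", "C", 0.3)]))

    def test_flip_equivalent_to_complemented_dosage(self, rng):
        # scoring A1 dosage with -beta == scoring (2 - x) with +beta, up to
        # a constant that the average turns into -beta per locus
        d = rng.binomial(2, 0.4, size=(30, 5)).astype(float)
        gm = make_genotypes(d, a1="A", a2="G")
        beta = rng.normal(size=5)
        flipped = sumstats(
            [(f"snp{i + 1}", "G", "A", beta[i]) for i in range(5)]
        )
        matched, _ = match_alleles(gm, flipped)
        scores = compute_grps(gm, matched).scores[:, 0]
        direct = ((2 - d) @ beta) / 5  # score the A2 counts directly
        np.testing.assert_allclose(scores, direct - 2 * beta.sum() / 5, atol=1e-12)


class TestComputeGrps:
    def test_hand_worked_average(self):
        gm = make_genotypes([[1, 2]])
        matched, _ = match_alleles(
            gm, sumstats([("snp1", "A", "G", 0.5), ("snp2", "A", "G", -0.25)])
        )
        scores = compute_grps(gm, matched)
        assert scores.scores[0, 0] == pytest.approx((0.5 * 1 - 0.25 * 2) / 2)
        assert scores.scores[0, 0] == pytest.approx(0.0)
        assert scores.n_loci[0, 0] == 2

    def test_all_reference_individual_scores_zero(self):
        gm = make_genotypes([[0, 0, 0], [1, 2, 0]])
        matched, _ = match_alleles(
            gm, sumstats([(f"snp{i}", "A", "G", b) for i, b in [(1, 0.2), (2, -0.4), (3, 1.0)]])
        )
        assert compute_grps(gm, matched).scores[0, 0] == 0.0

    def test_linear_in_weights(self, rng):
        d = rng.binomial(2, 0.3, size=(20, 8)).astype(float)
        gm = make_genotypes(d)
        base = [(f"snp{i + 1}", "A", "G", w) for i, w in enumerate(rng.normal(size=8))]
        doubled = [(i, e, o, 2 * w) for i, e, o, w in base]
        m1, _ = match_alleles(gm, sumstats(base))
        m2, _ = match_alleles(gm, sumstats(doubled))
        s1 = compute_grps(gm, m1).scores
        s2 = compute_grps(gm, m2).scores
        np.testing.assert_allclose(s2, 2 * s1)

    def test_missing_locus_drops_from_both_sides(self):
        gm = make_genotypes([[2, np.nan], [2, 2]])
        matched, _ = match_alleles(
            gm, sumstats([("snp1", "A", "G", 0.5), ("snp2", "A", "G", 0.5)])
        )
        res = compute_grps(gm, matched)
        assert res.scores[0, 0] == pytest.approx(1.0)  # (0.5*2)/1
        assert res.n_loci[0, 0] == 1
        assert res.scores[1, 0] == pytest.approx(1.0)  # (0.5*2 + 0.5*2)/2
        imputed = compute_grps(gm, matched, impute_missing=True)
        assert imputed.n_loci[0, 0] == 2
        # imputed dosage is 2 * freq(snp2) = 2
        assert imputed.scores[0, 0] == pytest.approx(1.0)

    def test_partitions(self, rng):
        d = rng.binomial(2, 0.3, size=(10, 4)).astype(float)
        gm = make_genotypes(d)
        w = rng.normal(size=4)
        matched, _ = match_alleles(
            gm, sumstats([(f"snp{i + 1}", "A", "G", w[i]) for i in range(4)])
        )
        parts = {"first": ["snp1", "snp2"], "rest": ["snp3", "snp4"]}
        res = compute_grps(gm, matched, partitions=parts)
        assert res.partitions == ["first", "rest"]
        np.testing.assert_allclose(res.scores[:, 0], d[:, :2] @ w[:2] / 2)
        with pytest.raises(ValueError, match="no matched"):
            compute_grps(gm, matched, partitions={"empty": ["nope"]})

    def test_standardize_columns(self, rng):
        d = rng.binomial(2, 0.3, size=(50, 6)).astype(float)
        gm = make_genotypes(d)
        matched, _ = match_alleles(
            gm, sumstats([(f"snp{i + 1}", "A", "G", 0.1 * (i + 1)) for i in range(6)])
        )
        z = compute_grps(gm, matched, standardize=True).scores[:, 0]
        assert abs(z.mean()) < 1e-12 and z.std() == pytest.approx(1.0)


def test_overlap_warning():
    a = pd.DataFrame({"fid": ["F1", "F2"], "iid": ["I1", "I2"]})
    b = pd.DataFrame({"fid": ["F2", "F3"], "iid": ["I2", "I3"]})
    with pytest.warns(UserWarning, match="discovery"):
        assert warn_on_sample_overlap(a, b) == 1


def test_scorer_transformer_matches_functions(rng):
    d = rng.binomial(2, 0.3, size=(15, 5)).astype(float)
    gm = make_genotypes(d)
    ss = sumstats([(f"snp{i + 1}", "A", "G", w) for i, w in enumerate(rng.normal(size=5))])
    scorer = GenomicRiskScorer(sumstats=ss).fit(gm)
    via_class = scorer.transform(gm).scores
    matched, _ = match_alleles(gm, ss)
    via_fn = compute_grps(gm, matched).scores
    np.testing.assert_array_equal(via_class, via_fn)
    assert scorer.get_params()["drop_ambiguous"] is True
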