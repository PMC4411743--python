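"""In-memory containers shared across the toolkit.

Genotypes are held as an ``n x m`` float array of counts of the A1 allele
(0, 1, 2 or NaN for missing) together with pandas frames of variant and
sample metadata, mirroring how PLINK lays out .bed/.bim/.fam.  Relationship
matrices carry their sample ids and per-pair SNP counts so they can be
round-tripped through the GCTA binary format without loss.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

VARIANT_COLUMNS = ["id", "chrom", "pos", "a1", "a2"]
SAMPLE_COLUMNS = ["fid", "iid"]


@dataclass
class GenotypeMatrix:
    """Hard-call allele dosages with variant and sample metadata.

    Parameters
    ----------
    dosages:
        ``n x m`` array of counts of the A1 allele per individual per
        variant; values in {0, 1, 2} or NaN for missing.
    variants:
        Frame with columns ``id, chrom, pos, a1, a2`` (one row per variant).
    samples:
        Frame with columns ``fid, iid`` (one row per individual).
    """

    dosages: np.ndarray
    variants: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=np.float64)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be a 2-D array")
        n, m = self.dosages.shape
        if len(self.samples) != n:
            raise ValueError(
                f"sample table has {len(self.samples)} rows but dosage matrix has {n}"
            )
        if len(self.variants) != m:
            raise ValueError(
                f"variant table has {len(self.variants)} rows but dosage matrix has {m} columns"
            )
        vals = self.dosages[~np.isnan(self.dosages)]
        if vals.size and not np.isin(vals, (0.0, 1.0, 2.0)).all():
            raise ValueError("non-missing dosages must be 0, 1 or 2")
        ids = self.variants["id"]
        if ids.duplicated().any():
            dupes = ids[ids.duplicated()].unique()[:5]
            raise ValueError(f"duplicate variant ids: {list(dupes)}")
        bad = self.variants["a1"] == self.variants["a2"]
        if bad.any():
            raise ValueError(
                f"variant(s) with identical alleles: {list(self.variants.loc[bad, 'id'][:5])}"
            )

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    def maf(self) -> np.ndarray:
        """Missing-aware minor allele frequency per variant (A1 or A2,
        whichever is rarer; in [0, 0.5])."""
        p = np.nanmean(self.dosages, axis=0) / 2.0
        return np.minimum(p, 1.0 - p)

    def a1_frequency(self) -> np.ndarray:
        """Missing-aware in-sample frequency of the A1 allele."""
        return np.nanmean(self.dosages, axis=0) / 2.0

    def sample_ids(self) -> pd.DataFrame:
        return self.samples[SAMPLE_COLUMNS].copy()


@dataclass
class Grm:
    """Symmetric SNP-derived relationship matrix (genetic or interaction)."""

    values: np.ndarray
    ids: pd.DataFrame
    n_snps: np.ndarray
    kind: str = "genetic"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        n = self.values.shape[0]
        if self.values.shape != (n, n):
            raise ValueError("GRM must be square")
        if len(self.ids) != n:
            raise ValueError(f"GRM has {n} rows but {len(self.ids)} ids")
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise ValueError("GRM must be symmetric")
        self.n_snps = np.asarray(self.n_snps)
        if self.n_snps.shape != (n, n):
            raise ValueError("per-pair SNP count matrix must match GRM shape")
        if self.kind not in ("genetic", "interaction"):
            raise ValueError(f"unknown GRM kind: {self.kind!r}")

    @property
    def n(self) -> int:
        return self.values.shape[0]


@dataclass
class SampleVector:
    """Per-sample values keyed by (FID, IID): a phenotype or environment.

    ``kind`` declares the measurement scale: ``binary`` (0/1), ``ordinal``
    (small integer codes) or ``continuous``.  NaN marks missing.
    """

    frame: pd.DataFrame  # columns fid, iid, value
    kind: str = "continuous"

    def __post_init__(self) -> None:
        if self.kind not in ("binary", "ordinal", "continuous"):
            raise ValueError(f"unknown kind: {self.kind!r}")
        missing = [c for c in ("fid", "iid", "value") if c not in self.frame.columns]
        if missing:
            raise ValueError(f"sample vector frame missing columns {missing}")
        self.frame = self.frame.copy()
        self.frame["value"] = pd.to_numeric(self.frame["value"], errors="coerce")
        if self.kind == "binary":
            vals = self.frame["value"].dropna()
            if not vals.isin((0.0, 1.0)).all():
                bad = sorted(set(vals[~vals.isin((0.0, 1.0))]))[:5]
                raise ValueError(f"binary vector contains values other than 0/1: {bad}")

    @property
    def values(self) -> np.ndarray:
        return self.frame["value"].to_numpy(dtype=float)

    def align_to(self, samples: pd.DataFrame) -> np.ndarray:
        """Values reordered to a genotype sample table; NaN where absent.

        The join keys on (FID, IID) and the output order follows ``samples``.
        """
        keyed = self.frame.set_index(["fid", "iid"])["value"]
        idx = pd.MultiIndex.from_frame(samples[SAMPLE_COLUMNS])
        return keyed.reindex(idx).to_numpy(dtype=float)


# Backwards-friendly aliases matching the two roles a SampleVector plays.
PhenotypeVector = SampleVector
EnvironmentVector = SampleVector


@dataclass
class SummaryStats:
    """Discovery-sample per-variant effect sizes keyed by effect allele.

    ``frame`` columns: ``id`` (variant), ``effect_allele``, ``other_allele``,
    ``beta`` (log-odds ratio or regression coefficient on the effect-allele
    count).  Odds ratios are log-transformed on input by the readers.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        need = ["id", "effect_allele", "other_allele", "beta"]
        missing = [c for c in need if c not in self.frame.columns]
        if missing:
            raise ValueError(f"summary statistics missing columns {missing}")
        dup = self.frame["id"].duplicated()
        if dup.any():
            raise ValueError(
                f"duplicate variant id in summary statistics: {self.frame.loc[dup, 'id'].iloc[0]!r}"
            )
        if not np.isfinite(self.frame["beta"].to_numpy(dtype=float)).all():
            raise ValueError("non-finite effect size in summary statistics")

    def __len__(self) -> int:
        return len(self.frame)


@dataclass
class RiskScoreSet:
    """Per-individual genomic risk profile scores, one column per partition."""

    samples: pd.DataFrame
    scores: np.ndarray  # n x p, NaN where no locus was scorable
    n_loci: np.ndarray  # n x p integer counts of loci entering each score
    partitions: list = field(default_factory=lambda: ["all"])

    def __post_init__(self) -> None:
        self.scores = np.atleast_2d(np.asarray(self.scores, dtype=float))
        self.n_loci = np.atleast_2d(np.asarray(self.n_loci))
        n, p = self.scores.shape
        if len(self.samples) != n or self.n_loci.shape != (n, p):
            raise ValueError("score matrix, loci counts and sample table disagree in shape")
        if len(self.partitions) != p:
            raise ValueError("one partition name required per score column")

    def to_frame(self) -> pd.DataFrame:
        """Long-format FID IID PARTITION SCORE N_LOCI table."""
        rows = []
        for j, name in enumerate(self.partitions):
            part = self.samples[SAMPLE_COLUMNS].copy()
            part["partition"] = name
            part["score"] = self.scores[:, j]
            part["n_loci"] = self.n_loci[:, j]
            rows.append(part)
        return pd.concat(rows, ignore_index=True)
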