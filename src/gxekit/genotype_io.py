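"""Readers and writers for the on-disk formats the toolkit touches.

Supported formats
-----------------
* PLINK 1 binary genotypes (``.bed``/``.bim``/``.fam``), SNP-major only.
  The 2-bit code follows the PLINK 1.9 convention: ``00`` = homozygous A1
  (dosage 2), ``01`` = missing, ``10`` = heterozygous (dosage 1), ``11`` =
  homozygous A2 (dosage 0), packed little-endian four genotypes per byte.
* GCTA binary relationship matrices (``.grm.bin``/``.grm.N.bin``/``.grm.id``):
  the lower triangle including the diagonal, row-major over pairs, 4-byte
  little-endian floats.
* Whitespace/tab-delimited tables: GWAS summary statistics (header with
  columns ``SNP A1 A2 BETA`` or ``OR``), phenotype/environment files
  (``FID IID VALUE``, no header) and SNP partition files
  (``PARTITION SNP``, no header).

All sample joins key on (FID, IID); read/write round-trips are bit-exact
for ``.bed`` and exact at float32 precision for ``.grm.bin``.
"""

from __future__ import annotations

import io
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import Grm, GenotypeMatrix, SampleVector, SummaryStats

_BED_MAGIC = b"\x6c\x1b"
_SNP_MAJOR = b"\x01"

# dosage of A1 for 2-bit codes 00, 01, 10, 11
_CODE_TO_DOSAGE = np.array([2.0, np.nan, 1.0, 0.0])

# byte -> four 2-bit codes, least-significant pair first
_BYTE_TO_CODES = np.array(
    [[(b >> s) & 0b11 for s in (0, 2, 4, 6)] for b in range(256)], dtype=np.uint8
)


class PlinkFormatError(ValueError):
    """Malformed or unsupported PLINK binary file."""


def read_plink(prefix: str | Path) -> GenotypeMatrix:
    """Read a PLINK ``.bed``/``.bim``/``.fam`` fileset.

    Parameters
    ----------
    prefix:
        Path without extension; ``prefix.bed``, ``prefix.bim`` and
        ``prefix.fam`` must all exist.

    Returns
    -------
    GenotypeMatrix
        Dosages count copies of A1 (the fifth .bim column), matching PLINK
        scoring semantics.
    """
    prefix = Path(prefix)
    fam = pd.read_csv(
        Path(str(prefix) + ".fam"),
        sep=r"\s+",
        header=None,
        names=["fid", "iid", "pid", "mid", "sex", "pheno"],
        dtype={"fid": str, "iid": str},
    )
    bim = pd.read_csv(
        Path(str(prefix) + ".bim"),
        sep=r"\s+",
        header=None,
        names=["chrom", "id", "cm", "pos", "a1", "a2"],
        dtype={"chrom": str, "id": str, "a1": str, "a2": str},
    )
    n, m = len(fam), len(bim)
    raw = Path(str(prefix) + ".bed").read_bytes()
    if raw[:2] != _BED_MAGIC:
        raise PlinkFormatError(
            f"{prefix}.bed: bad magic bytes {raw[:2]!r} (expected {_BED_MAGIC!r})"
        )
    if raw[2:3] != _SNP_MAJOR:
        raise PlinkFormatError(
            f"{prefix}.bed: sample-major (or unknown) mode byte {raw[2:3]!r} is unsupported"
        )
    bytes_per_variant = (n + 3) // 4
    body = np.frombuffer(raw, dtype=np.uint8, offset=3)
    if body.size != m * bytes_per_variant:
        raise PlinkFormatError(
            f"{prefix}.bed: expected {m * bytes_per_variant} data bytes for "
            f"{n} samples x {m} variants, found {body.size}"
        )
    codes = _BYTE_TO_CODES[body.reshape(m, bytes_per_variant)].reshape(m, -1)[:, :n]
    dosages = _CODE_TO_DOSAGE[codes].T  # n x m
    variants = bim[["id", "chrom", "pos", "a1", "a2"]].copy()
    samples = fam[["fid", "iid"]].copy()
    return GenotypeMatrix(dosages=dosages, variants=variants, samples=samples)


def write_plink(genotypes: GenotypeMatrix, prefix: str | Path) -> None:
    """Write a GenotypeMatrix as a PLINK SNP-major ``.bed``/``.bim``/``.fam``."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    n, m = genotypes.dosages.shape
    d = genotypes.dosages
    codes = np.full(d.shape, 1, dtype=np.uint8)  # missing
    codes[d == 2.0] = 0b00
    codes[d == 1.0] = 0b10
    codes[d == 0.0] = 0b11
    pad = (-n) % 4
    if pad:
        codes = np.concatenate([codes, np.zeros((pad, m), dtype=np.uint8)], axis=0)
    quads = codes.T.reshape(m, -1, 4)  # variant-major groups of four samples
    packed = (
        quads[:, :, 0]
        | (quads[:, :, 1] << 2)
        | (quads[:, :, 2] << 4)
        | (quads[:, :, 3] << 6)
    ).astype(np.uint8)
    with open(Path(str(prefix) + ".bed"), "wb") as fh:
        fh.write(_BED_MAGIC + _SNP_MAJOR)
        fh.write(packed.tobytes())

    v = genotypes.variants
    bim = pd.DataFrame(
        {
            "chrom": v["chrom"],
            "id": v["id"],
            "cm": 0,
            "pos": v["pos"],
            "a1": v["a1"],
            "a2": v["a2"],
        }
    )
    bim.to_csv(Path(str(prefix) + ".bim"), sep="\t", header=False, index=False)
    s = genotypes.samples
    fam = pd.DataFrame(
        {"fid": s["fid"], "iid": s["iid"], "pid": 0, "mid": 0, "sex": 0, "pheno": -9}
    )
    fam.to_csv(Path(str(prefix) + ".fam"), sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# delimited tables
# ---------------------------------------------------------------------------

_SCHEMAS = ("sumstats", "phenotype", "environment", "partition")


def read_table(path: str | Path, schema: str, kind: str = "continuous"):
    """Read a whitespace/tab-delimited table of a known schema.

    Parameters
    ----------
    path:
        File to read.
    schema:
        One of ``sumstats`` (header: SNP A1 A2 BETA|OR), ``phenotype`` /
        ``environment`` (no header: FID IID VALUE; ``NA`` marks missing),
        ``partition`` (no header: PARTITION SNP).
    kind:
        Measurement scale for phenotype/environment files (``binary``,
        ``ordinal`` or ``continuous``); binary files are validated to 0/1.

    Returns
    -------
    SummaryStats, SampleVector or dict mapping partition name -> list of
    variant ids, according to ``schema``.
    """
    if schema not in _SCHEMAS:
        raise ValueError(f"unknown table schema {schema!r}; expected one of {_SCHEMAS}")
    path = Path(path)
    text = path.read_text()
    if not text.strip():
        raise ValueError(f"{path}: empty file")

    if schema == "sumstats":
        return _read_sumstats(path, text)
    if schema == "partition":
        frame = pd.read_csv(
            io.StringIO(text), sep=r"\s+", header=None, names=["partition", "id"], dtype=str
        )
        return {
            name: list(group["id"]) for name, group in frame.groupby("partition", sort=False)
        }

    frame = pd.read_csv(
        io.StringIO(text),
        sep=r"\s+",
        header=None,
        names=["fid", "iid", "value"],
        dtype={"fid": str, "iid": str},
        na_values=["NA", "na", "NaN", "-9"],
    )
    if frame["value"].isna().all():
        raise ValueError(f"{path}: no parseable values")
    raw = pd.read_csv(
        io.StringIO(text), sep=r"\s+", header=None, names=["fid", "iid", "value"], dtype=str
    )
    parsed = pd.to_numeric(raw["value"], errors="coerce")
    bad = parsed.isna() & ~raw["value"].isin(["NA", "na", "NaN", "-9"]) & raw["value"].notna()
    if bad.any():
        lines = [i + 1 for i in raw.index[bad][:5]]
        raise ValueError(f"{path}: unparseable value(s) at line(s) {lines}")
    return SampleVector(frame=frame, kind=kind)


def _read_sumstats(path: Path, text: str) -> SummaryStats:
    frame = pd.read_csv(io.StringIO(text), sep=r"\s+", dtype={0: str})
    frame.columns = [c.upper() for c in frame.columns]
    for col in ("SNP", "A1", "A2"):
        if col not in frame.columns:
            raise ValueError(f"{path}: summary statistics lack required column {col}")
    if "BETA" in frame.columns:
        beta = frame["BETA"].astype(float)
    elif "OR" in frame.columns:
        orr = frame["OR"].astype(float)
        if (orr <= 0).any():
            raise ValueError(f"{path}: non-positive odds ratio cannot be log-transformed")
        beta = np.log(orr)
    else:
        raise ValueError(f"{path}: summary statistics need a BETA or OR column")
    dup = frame["SNP"].duplicated()
    if dup.any():
        raise ValueError(
            f"{path}: duplicate variant id {frame.loc[dup, 'SNP'].iloc[0]!r} in summary statistics"
        )
    out = pd.DataFrame(
        {
            "id": frame["SNP"].astype(str),
            "effect_allele": frame["A1"].astype(str).str.upper(),
            "other_allele": frame["A2"].astype(str).str.upper(),
            "beta": beta,
        }
    )
    return SummaryStats(frame=out)


def write_sumstats(stats: SummaryStats, path: str | Path) -> None:
    out = pd.DataFrame(
        {
            "SNP": stats.frame["id"],
            "A1": stats.frame["effect_allele"],
            "A2": stats.frame["other_allele"],
            "BETA": stats.frame["beta"],
        }
    )
    out.to_csv(path, sep="\t", index=False, float_format="%.6g")


def write_sample_vector(vec: SampleVector, path: str | Path) -> None:
    frame = vec.frame[["fid", "iid", "value"]].copy()
    frame.to_csv(path, sep="\t", header=False, index=False, na_rep="NA", float_format="%.6g")


# ---------------------------------------------------------------------------
# GCTA binary GRM triplets
# ---------------------------------------------------------------------------


def write_grm(grm: Grm, prefix: str | Path) -> None:
    """Write a Grm as GCTA's ``.grm.bin``/``.grm.N.bin``/``.grm.id`` triplet."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    n = grm.n
    rows, cols = np.tril_indices(n)
    tri = grm.values[rows, cols].astype("<f4")
    tri_n = grm.n_snps[rows, cols].astype("<f4")
    Path(str(prefix) + ".grm.bin").write_bytes(tri.tobytes())
    Path(str(prefix) + ".grm.N.bin").write_bytes(tri_n.tobytes())
    grm.ids[["fid", "iid"]].to_csv(
        str(prefix) + ".grm.id", sep="\t", header=False, index=False
    )


def read_grm(prefix: str | Path, kind: str = "genetic") -> Grm:
    """Read a GCTA binary GRM triplet; exact inverse of :func:`write_grm`
    up to float32 precision."""
    prefix = Path(prefix)
    ids = pd.read_csv(
        str(prefix) + ".grm.id",
        sep=r"\s+",
        header=None,
        names=["fid", "iid"],
        dtype=str,
    )
    n = len(ids)
    expected = n * (n + 1) // 2
    tri = np.frombuffer(Path(str(prefix) + ".grm.bin").read_bytes(), dtype="<f4")
    if tri.size != expected:
        raise ValueError(
            f"{prefix}.grm.bin holds {tri.size} pair values but {prefix}.grm.id lists "
            f"{n} samples (expected a triangle of {expected})"
        )
    tri_n = np.frombuffer(Path(str(prefix) + ".grm.N.bin").read_bytes(), dtype="<f4")
    if tri_n.size != expected:
        raise ValueError(f"{prefix}.grm.N.bin length does not match the id count")
    values = np.zeros((n, n))
    counts = np.zeros((n, n))
    rows, cols = np.tril_indices(n)
    values[rows, cols] = tri
    values[cols, rows] = tri
    counts[rows, cols] = tri_n
    counts[cols, rows] = tri_n
    return Grm(values=values, ids=ids, n_snps=counts, kind=kind)
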