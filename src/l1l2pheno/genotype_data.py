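"""Genotype and phenotype containers, file I/O, encoding and imputation.

Genotypes are held as a samples x SNPs numeric matrix under one of four
encodings.  The working encoding for the regression pipeline is the additive
{0, 1, 2} code: the number of copies of the non-reference (minor) allele a
sample carries at a locus, with the reference allele taken as the major
allele observed in the data unless declared.  Missing calls are tracked in a
boolean mask and filled by random draws from the per-locus genotype-class
frequencies before any model fitting.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "EncodingScheme",
    "SnpRecord",
    "GenotypeMatrix",
    "PhenotypeVector",
    "GenotypeDataError",
    "GenotypeParseError",
    "read_genotypes",
    "write_genotypes",
    "read_genotype_tsv",
    "write_genotype_tsv",
    "read_phenotypes",
    "encode",
    "impute_missing",
    "missingness_report",
]

MISSING_ALLELE = "0"


class GenotypeDataError(ValueError):
    """Structural or content problem in genotype/phenotype data."""


class GenotypeParseError(GenotypeDataError):
    """Malformed input file; message names the offending line."""


class EncodingScheme(enum.Enum):
    """Numeric representation of a genotype call.

    additive_012
        Count of non-reference alleles (0 = reference homozygote,
        1 = heterozygote, 2 = alternate homozygote).
    centered_101
        Additive code shifted to {-1, 0, 1}.
    onehot_3col
        Indicator triple (hom-ref, het, hom-alt); three columns per SNP.
    class_frequency
        Each call replaced by the observed relative frequency of its
        genotype class at that locus.
    """

    additive_012 = "additive_012"
    centered_101 = "centered_101"
    onehot_3col = "onehot_3col"
    class_frequency = "class_frequency"


@dataclass(frozen=True)
class SnpRecord:
    """Map entry for one SNP: name, chromosome label, 1-based bp position."""

    name: str
    chromosome: str
    position_bp: int

    def __post_init__(self) -> None:
        if self.position_bp < 0:
            raise GenotypeDataError(
                f"SNP {self.name}: negative position {self.position_bp}"
            )


@dataclass
class GenotypeMatrix:
    """Samples x SNPs numeric genotype matrix with map metadata.

    ``values[i, j]`` is the encoded genotype of sample i at SNP j;
    ``missing_mask`` is True where the call was missing (the value there is
    a placeholder, conventionally 0, until :func:`impute_missing` runs).
    """

    values: np.ndarray
    missing_mask: np.ndarray
    snps: list[SnpRecord]
    sample_ids: list[str]
    family_ids: list[str]
    encoding: EncodingScheme = EncodingScheme.additive_012

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
        n, p = self.values.shape
        if self.missing_mask.shape != (n, p):
            raise GenotypeDataError("missing_mask shape differs from values")
        if len(self.sample_ids) != n or len(self.family_ids) != n:
            raise GenotypeDataError("sample/family id count differs from rows")
        # one SnpRecord per column; onehot_3col triples both (suffixed names)
        if len(self.snps) != p:
            raise GenotypeDataError("snp record count inconsistent with columns")
        names = [s.name for s in self.snps]
        if len(set(names)) != len(names):
            raise GenotypeDataError("duplicate SNP names")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    @property
    def snp_names(self) -> list[str]:
        return [s.name for s in self.snps]

    def copy(self) -> "GenotypeMatrix":
        return replace(
            self,
            values=self.values.copy(),
            missing_mask=self.missing_mask.copy(),
            snps=list(self.snps),
            sample_ids=list(self.sample_ids),
            family_ids=list(self.family_ids),
        )


@dataclass
class PhenotypeVector:
    """One real-valued trait aligned to a GenotypeMatrix's samples."""

    values: np.ndarray
    trait_name: str
    sample_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise GenotypeDataError("phenotype values must be 1-D")
        if not np.all(np.isfinite(self.values)):
            raise GenotypeDataError(f"non-finite phenotype values in {self.trait_name}")
        if self.sample_ids and len(self.sample_ids) != self.values.size:
            raise GenotypeDataError("sample_ids length differs from values")


# ---------------------------------------------------------------------------
# PLINK-style .ped/.map I/O


def _read_map(map_path) -> list[SnpRecord]:
    records: list[SnpRecord] = []
    with open(map_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) < 4:
                raise GenotypeParseError(f"{map_path}: line {lineno}: expected 4 fields")
            chrom, name, _cm, pos = parts[:4]
            try:
                records.append(SnpRecord(name=name, chromosome=chrom, position_bp=int(pos)))
            except ValueError as exc:
                raise GenotypeParseError(f"{map_path}: line {lineno}: bad position {pos!r}") from exc
    return records


def read_genotypes(ped_path, map_path) -> GenotypeMatrix:
    """Read a whitespace-delimited .ped/.map pair into additive encoding.

    The .ped columns are family, individual, father, mother, sex, phenotype
    followed by two allele codes per SNP; allele code "0" marks a missing
    call (either allele missing masks the genotype).  The reference allele
    at each locus is the major allele among called genotypes.
    """
    snps = _read_map(map_path)
    p = len(snps)
    sample_ids: list[str] = []
    family_ids: list[str] = []
    allele_rows: list[list[str]] = []
    with open(ped_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) != 6 + 2 * p:
                raise GenotypeParseError(
                    f"{ped_path}: line {lineno}: expected {6 + 2 * p} fields, got {len(parts)}"
                )
            family_ids.append(parts[0])
            sample_ids.append(parts[1])
            allele_rows.append(parts[6:])
    if not allele_rows:
        raise GenotypeParseError(f"{ped_path}: no samples")

    n = len(allele_rows)
    alleles = np.array(allele_rows, dtype=object).reshape(n, p, 2)
    values = np.zeros((n, p))
    mask = np.zeros((n, p), dtype=bool)
    for j in range(p):
        aj = alleles[:, j, :]
        miss = (aj == MISSING_ALLELE).any(axis=1)
        mask[:, j] = miss
        called = aj[~miss].ravel()
        classes, counts = np.unique(called, return_counts=True) if called.size else ([], [])
        if len(classes) > 2:
            raise GenotypeDataError(
                f"SNP {snps[j].name}: more than two alleles {sorted(classes)}"
            )
        if len(classes) == 0:
            continue
        # major allele = reference; dosage counts the other (minor) allele
        ref = classes[int(np.argmax(counts))]
        values[~miss, j] = (aj[~miss] != ref).sum(axis=1)
    return GenotypeMatrix(values, mask, snps, sample_ids, family_ids, EncodingScheme.additive_012)


def write_genotypes(g: GenotypeMatrix, ped_path, map_path) -> None:
    """Write additive-encoded genotypes as a .ped/.map pair.

    Allele letters are synthesized as A (reference) / B (alternate);
    masked calls are written as "0 0".
    """
    if g.encoding is not EncodingScheme.additive_012:
        raise GenotypeDataError("ped output requires additive encoding")
    with open(map_path, "w") as fh:
        for s in g.snps:
            fh.write(f"{s.chromosome}\t{s.name}\t0\t{s.position_bp}\n")
    pair = {0: "A A", 1: "A B", 2: "B B"}
    with open(ped_path, "w") as fh:
        for i, (fid, sid) in enumerate(zip(g.family_ids, g.sample_ids)):
            calls = [
                "0 0" if g.missing_mask[i, j] else pair[int(round(g.values[i, j]))]
                for j in range(g.n_snps)
            ]
            fh.write(" ".join([fid, sid, "0", "0", "0", "-9"] + calls) + "\n")


# ---------------------------------------------------------------------------
# TSV dialect


def read_genotype_tsv(path, snps: list[SnpRecord] | None = None) -> GenotypeMatrix:
    """Read the TSV dialect: header of SNP names; rows sample_id, family_id,
    then codes in {0, 1, 2, NA}."""
    df = pd.read_csv(path, sep="\t", dtype={0: str, 1: str})
    sample_ids = df.iloc[:, 0].tolist()
    family_ids = df.iloc[:, 1].tolist()
    codes = df.iloc[:, 2:].apply(pd.to_numeric, errors="coerce").to_numpy(dtype=float)
    mask = np.isnan(codes)
    codes = np.where(mask, 0.0, codes)
    bad = ~mask & ~np.isin(codes, [0.0, 1.0, 2.0])
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise GenotypeParseError(f"{path}: row {i + 2}: invalid code in column {j + 3}")
    names = df.columns[2:].tolist()
    if snps is None:
        snps = [SnpRecord(name=nm, chromosome="0", position_bp=0) for nm in names]
    elif [s.name for s in snps] != names:
        raise GenotypeDataError("SNP map does not match TSV header")
    return GenotypeMatrix(codes, mask, snps, sample_ids, family_ids, EncodingScheme.additive_012)


def write_genotype_tsv(g: GenotypeMatrix, path) -> None:
    if g.encoding is not EncodingScheme.additive_012:
        raise GenotypeDataError("TSV output requires additive encoding")
    vals = g.values.astype(object)
    vals[g.missing_mask] = "NA"
    df = pd.DataFrame(vals, columns=g.snp_names)
    df.insert(0, "family_id", g.family_ids)
    df.insert(0, "sample_id", g.sample_ids)
    out = df.copy()
    for c in g.snp_names:
        out[c] = out[c].map(lambda v: v if v == "NA" else str(int(v)))
    out.to_csv(path, sep="\t", index=False)


def read_phenotypes(path, trait: str) -> PhenotypeVector:
    """Read one trait column from a phenotype TSV (sample_id, family_id, traits...)."""
    df = pd.read_csv(path, sep="\t", dtype={0: str, 1: str})
    if trait not in df.columns:
        raise GenotypeDataError(f"trait {trait!r} not among columns {list(df.columns[2:])}")
    return PhenotypeVector(
        values=df[trait].to_numpy(dtype=float),
        trait_name=trait,
        sample_ids=df.iloc[:, 0].tolist(),
    )


# ---------------------------------------------------------------------------
# Encoding


def encode(g: GenotypeMatrix, scheme: EncodingScheme) -> GenotypeMatrix:
    """Re-encode an additive {0,1,2} matrix under another scheme.

    class_frequency replaces each call by the relative frequency of its
    genotype class at that locus among called samples; onehot_3col expands
    each SNP into an indicator triple (hom-ref, het, hom-alt) and suffixes
    the SNP names accordingly.  Masked entries stay masked (value 0).
    """
    if g.encoding is not EncodingScheme.additive_012:
        raise GenotypeDataError("encode() expects an additive-encoded input")
    vals = g.values
    mask = g.missing_mask
    if scheme is EncodingScheme.additive_012:
        return g.copy()
    if scheme is EncodingScheme.centered_101:
        out = np.where(mask, 0.0, vals - 1.0)
        return replace(g.copy(), values=out, encoding=scheme)
    if scheme is EncodingScheme.class_frequency:
        out = np.zeros_like(vals)
        for j in range(g.n_snps):
            called = ~mask[:, j]
            col = vals[called, j]
            if col.size == 0:
                continue
            freqs = {c: np.mean(col == c) for c in (0.0, 1.0, 2.0)}
            out[called, j] = [freqs[v] for v in col]
        return replace(g.copy(), values=out, encoding=scheme)
    if scheme is EncodingScheme.onehot_3col:
        n, p = vals.shape
        out = np.zeros((n, 3 * p))
        outmask = np.repeat(mask, 3, axis=1)
        for c in (0, 1, 2):
            out[:, c::3] = (~mask) & (vals == c)
        snps3 = [
            SnpRecord(f"{s.name}__{tag}", s.chromosome, s.position_bp)
            for s in g.snps
            for tag in ("homref", "het", "homalt")
        ]
        return GenotypeMatrix(out, outmask, snps3, list(g.sample_ids), list(g.family_ids), scheme)
    raise GenotypeDataError(f"unknown encoding scheme {scheme!r}")


# ---------------------------------------------------------------------------
# Imputation and missingness


def impute_missing(g: GenotypeMatrix, seed: int) -> GenotypeMatrix:
    """Fill masked calls by draws from per-locus genotype-class frequencies.

    Each masked entry at SNP j is replaced by a draw from {0, 1, 2} with
    probabilities equal to the relative frequencies of the three genotype
    classes among called samples at j.  One seeded stream is consumed in
    SNP (column) order, so adding samples does not reshuffle draws at
    unrelated loci.  Deterministic given ``seed``.
    """
    if g.encoding is not EncodingScheme.additive_012:
        raise GenotypeDataError("imputation requires additive encoding")
    rng = np.random.default_rng(seed)
    out = g.copy()
    for j in range(g.n_snps):
        miss = out.missing_mask[:, j]
        if not miss.any():
            continue
        col = out.values[~miss, j]
        if col.size == 0:
            raise GenotypeDataError(f"SNP {g.snps[j].name}: all calls missing, cannot impute")
        probs = np.array([np.mean(col == c) for c in (0.0, 1.0, 2.0)])
        out.values[miss, j] = rng.choice([0.0, 1.0, 2.0], size=int(miss.sum()), p=probs)
        out.missing_mask[:, j] = False
    return out


def missingness_report(g: GenotypeMatrix, thresholds: tuple[float, ...] = (0.01, 0.02, 0.05)) -> dict:
    """Overall and per-SNP missing-call fractions, plus threshold exceedance counts."""
    per_snp = g.missing_mask.mean(axis=0)
    return {
        "overall_fraction": float(g.missing_mask.mean()),
        "per_snp_fraction": per_snp,
        "max_per_snp": float(per_snp.max()) if per_snp.size else 0.0,
        "n_exceeding": {t: int((per_snp > t).sum()) for t in thresholds},
    }
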