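"""Family-structured synthetic cohorts with LD blocks and additive traits.

The simulator emulates the statistical structure of a heterogeneous-stock
mapping population at desk scale: samples come in multi-member families
(so interfamily train/test splits matter), SNPs lie in linkage blocks along
chromosomes (so correlated columns surround each causal variant), a sparse
set of SNPs carries additive effects, and a small fraction of calls is
missing at random.

Family model: each family has two founders; every founder haplotype is
drawn block-wise — one Bernoulli(maf) seed allele per LD block carried by
the block's first SNP, copied across the rest of the block with a small
per-SNP flip probability — and offspring receive one haplotype per parent
per chromosome (no within-chromosome recombination).  Two LD shapes are
available: ``ld_mode="seed"`` flips every copy independently from the seed
(roughly constant correlation ~(1-2f) across the block), while
``ld_mode="chain"`` flips each SNP from its left neighbour, giving a
geometric decay of correlation with within-block distance ~(1-2f)^k.  The
trait is y = X beta + eps with the noise variance set so that
Var(X beta) / Var(y) equals the requested heritability h^2.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .genotype_data import (
    EncodingScheme,
    GenotypeMatrix,
    PhenotypeVector,
    SnpRecord,
)

__all__ = ["CohortSpec", "TrueModel", "simulate_cohort", "realized_ld", "shuffle_phenotype"]


@dataclass(frozen=True)
class CohortSpec:
    """Generator settings.

    Defaults mirror the structure of the motivating mouse dataset at a
    size a workstation handles: 120 families of 5 sibs (600 samples),
    2000 SNPs in 10-SNP LD blocks over 5 chromosomes, 20 causal SNPs at
    h^2 = 0.3, and a 0.14% missing-call rate.
    """

    n_families: int = 120
    samples_per_family: int = 5
    n_snps: int = 2000
    n_chromosomes: int = 5
    snp_spacing_bp: int = 100_000
    ld_block_size: int = 10
    within_block_flip_prob: float = 0.05
    maf_range: tuple[float, float] = (0.1, 0.5)
    n_causal: int = 20
    effect_size_range: tuple[float, float] = (0.5, 1.0)
    heritability: float = 0.3
    missing_rate: float = 0.0014
    ld_mode: str = "seed"  # "seed": flat block correlation; "chain": geometric decay
    seed: int = 0

    def __post_init__(self) -> None:
        if self.ld_mode not in ("seed", "chain"):
            raise ValueError("ld_mode must be 'seed' or 'chain'")
        if not (0.0 < self.heritability < 1.0):
            raise ValueError("heritability must lie strictly in (0, 1)")
        if not (0.0 <= self.within_block_flip_prob < 0.5):
            raise ValueError("flip probability must be in [0, 0.5)")
        if self.n_causal > self.n_snps:
            raise ValueError("n_causal exceeds n_snps")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")
        if self.n_families < 1 or self.samples_per_family < 1 or self.n_snps < 1:
            raise ValueError("cohort dimensions must be positive")


@dataclass
class TrueModel:
    """Ground truth behind a simulated cohort."""

    causal_indices: np.ndarray
    beta: np.ndarray                    # length n_snps, nonzero exactly at causal_indices
    realized_heritability: float
    block_of_snp: np.ndarray            # LD-block id per SNP
    causal_blocks: np.ndarray

    def to_json(self) -> str:
        return json.dumps(
            {
                "causal_indices": self.causal_indices.tolist(),
                "beta_on_causal": self.beta[self.causal_indices].tolist(),
                "realized_heritability": self.realized_heritability,
                "causal_blocks": self.causal_blocks.tolist(),
            },
            indent=1,
        )


def _founder_haplotypes(rng, n_hap, blocks, maf_of_block, flip_prob, ld_mode):
    """n_hap x n_snps binary haplotypes with block-copy-with-flips LD.

    The first SNP of each block carries the seed allele exactly; later
    SNPs are noisy copies — of the seed ("seed" mode, flat correlation)
    or of their left neighbour ("chain" mode, geometric decay).
    """
    n_snps = blocks.size
    hap = np.empty((n_hap, n_snps), dtype=np.int8)
    for b in np.unique(blocks):
        cols = np.flatnonzero(blocks == b)
        seed_allele = (rng.random(n_hap) < maf_of_block[b]).astype(np.int8)
        flips = (rng.random((n_hap, cols.size)) < flip_prob).astype(np.int8)
        flips[:, 0] = 0
        if ld_mode == "seed":
            block = seed_allele[:, None] ^ flips
        else:  # chain: cumulative XOR of flips along the block
            block = seed_allele[:, None] ^ (np.cumsum(flips, axis=1) % 2).astype(np.int8)
        hap[:, cols] = block
    return hap


def simulate_cohort(spec: CohortSpec) -> tuple[GenotypeMatrix, PhenotypeVector, TrueModel]:
    """Generate one cohort; fully determined by ``spec`` (including its seed)."""
    rng = np.random.default_rng(spec.seed)
    n = spec.n_families * spec.samples_per_family
    p = spec.n_snps

    # map: SNPs split as evenly as possible over chromosomes, evenly spaced
    chrom_of = np.array_split(np.arange(p), spec.n_chromosomes)
    snps: list[SnpRecord] = []
    chrom_id = np.empty(p, dtype=int)
    for c, idx in enumerate(chrom_of, start=1):
        for k, j in enumerate(idx):
            snps.append(SnpRecord(f"snp{j:05d}", str(c), (k + 1) * spec.snp_spacing_bp))
            chrom_id[j] = c

    # LD blocks never straddle a chromosome boundary
    blocks = np.empty(p, dtype=int)
    next_block = 0
    for idx in chrom_of:
        for start in range(0, idx.size, spec.ld_block_size):
            blocks[idx[start : start + spec.ld_block_size]] = next_block
            next_block += 1
    n_blocks = next_block
    maf_of_block = rng.uniform(*spec.maf_range, size=n_blocks)

    # genotypes: two founders per family, offspring by Mendelian transmission
    geno = np.empty((n, p), dtype=np.int8)
    family_ids: list[str] = []
    sample_ids: list[str] = []
    row = 0
    for f in range(spec.n_families):
        founders = _founder_haplotypes(
            rng, 4, blocks, maf_of_block, spec.within_block_flip_prob, spec.ld_mode
        )  # rows 0,1 = parent A; rows 2,3 = parent B
        for c_ix in range(spec.samples_per_family):
            pickA = rng.integers(0, 2, size=spec.n_chromosomes)
            pickB = rng.integers(0, 2, size=spec.n_chromosomes)
            hapA = np.empty(p, dtype=np.int8)
            hapB = np.empty(p, dtype=np.int8)
            for c, idx in enumerate(chrom_of):
                hapA[idx] = founders[pickA[c], idx]
                hapB[idx] = founders[2 + pickB[c], idx]
            geno[row] = hapA + hapB
            family_ids.append(f"fam{f:04d}")
            sample_ids.append(f"fam{f:04d}_s{c_ix}")
            row += 1

    # causal SNPs: one per chosen block (the block's first SNP), +/- uniform effects
    causal_blocks = rng.choice(n_blocks, size=spec.n_causal, replace=False)
    causal = np.array(sorted(int(np.flatnonzero(blocks == b)[0]) for b in causal_blocks))
    beta = np.zeros(p)
    mags = rng.uniform(*spec.effect_size_range, size=spec.n_causal)
    signs = rng.choice([-1.0, 1.0], size=spec.n_causal)
    beta[causal] = mags * signs

    g_score = geno[:, causal].astype(float) @ beta[causal]
    var_g = float(np.var(g_score))
    if var_g == 0:
        raise ValueError("degenerate cohort: causal SNPs carry no variance")
    sigma2 = var_g * (1.0 - spec.heritability) / spec.heritability
    y = g_score + rng.normal(0.0, np.sqrt(sigma2), size=n)
    realized_h2 = var_g / float(np.var(y))

    mask = rng.random((n, p)) < spec.missing_rate
    values = geno.astype(float)
    values[mask] = 0.0

    g = GenotypeMatrix(values, mask, snps, sample_ids, family_ids, EncodingScheme.additive_012)
    ph = PhenotypeVector(y, trait_name="sim_trait", sample_ids=sample_ids)
    truth = TrueModel(
        causal_indices=causal,
        beta=beta,
        realized_heritability=realized_h2,
        block_of_snp=blocks,
        causal_blocks=np.sort(causal_blocks),
    )
    return g, ph, truth


def realized_ld(g: GenotypeMatrix, truth: TrueModel) -> dict:
    """Within-block vs cross-block genotype correlation diagnostics.

    Returns the mean |Pearson correlation| between each block seed (first
    SNP of the block) and the other members of its block, pooled over
    blocks, alongside a cross-block null from random SNP pairs.
    """
    vals = g.values
    blocks = truth.block_of_snp
    rng = np.random.default_rng(0)
    within: list[float] = []
    for b in np.unique(blocks):
        cols = np.flatnonzero(blocks == b)
        if cols.size < 2:
            continue
        seed_col = vals[:, cols[0]]
        if seed_col.std() == 0:
            continue
        for j in cols[1:]:
            other = vals[:, j]
            if other.std() == 0:
                continue
            within.append(abs(float(np.corrcoef(seed_col, other)[0, 1])))
    cross: list[float] = []
    for _ in range(500):
        a, b = rng.integers(0, g.n_snps, size=2)
        if blocks[a] == blocks[b]:
            continue
        ca, cb = vals[:, a], vals[:, b]
        if ca.std() == 0 or cb.std() == 0:
            continue
        cross.append(abs(float(np.corrcoef(ca, cb)[0, 1])))
    return {
        "within_block_mean_abs_corr": float(np.mean(within)) if within else float("nan"),
        "cross_block_mean_abs_corr": float(np.mean(cross)) if cross else float("nan"),
        "n_within_pairs": len(within),
        "n_cross_pairs": len(cross),
    }


def shuffle_phenotype(ph: PhenotypeVector, seed: int) -> PhenotypeVector:
    """Uniform random permutation of trait values; sample alignment kept.

    Breaking the genotype-phenotype link while preserving the trait's
    marginal distribution gives the negative control for the pipeline: any
    residual predictive accuracy reflects chance association.
    """
    rng = np.random.default_rng(seed)
    perm = rng.permutation(ph.values.size)
    return PhenotypeVector(
        values=ph.values[perm],
        trait_name=f"{ph.trait_name}_shuffled",
        sample_ids=list(ph.sample_ids),
    )
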