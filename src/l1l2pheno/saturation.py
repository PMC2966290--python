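"""Marker-panel saturation: recover SNPs in LD with top-ranked markers.

Sparse selection keeps one representative per group of correlated SNPs and
discards the rest, even when they tag the same locus.  Saturation walks
back from the selected panel: a SNP is *top-ranked* when its |weight| falls
in the top percentile of the nonzero weights in enough resamplings, and
every other SNP whose genotype column has |Pearson correlation| above a
threshold with a top-ranked SNP is reported as *top-correlated*, together
with the correlation, the base-pair distance when both sit on the same
chromosome, and the regression weight the model assigned it (0 when it was
eliminated).  Raising the correlation threshold concentrates the recovered
SNPs around their reference marker, so the pooled distance distribution is
a direct readout of the local LD structure the panel spans.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotype_data import GenotypeMatrix

__all__ = [
    "TopRankedSet",
    "CorrelatedSnp",
    "SaturationResult",
    "find_top_ranked",
    "find_top_correlated",
    "distance_summary",
    "threshold_sweep",
    "write_table",
    "write_bed",
]


@dataclass
class TopRankedSet:
    """SNPs whose |weight| reached the top percentile in >= min_runs resamplings."""

    members: dict              # snp name -> {"n_qualifying": int, "mean_abs_weight": float}
    percentile: float
    min_runs: int
    n_resamplings: int

    @property
    def names(self) -> list[str]:
        return sorted(self.members)


@dataclass(frozen=True)
class CorrelatedSnp:
    name: str
    correlation: float
    same_chromosome: bool
    distance_bp: int | None
    weight: float


@dataclass
class SaturationResult:
    """Per top-ranked SNP: the top-correlated SNPs above the threshold."""

    threshold: float
    by_top_snp: dict = field(default_factory=dict)  # name -> list[CorrelatedSnp]

    def all_correlated_names(self) -> set:
        return {c.name for lst in self.by_top_snp.values() for c in lst}


def _percentile_cut(abs_w: np.ndarray, percentile: float) -> float | None:
    """|weight| cut marking the top ``percentile`` % of nonzero weights.

    The cut is the value of the ceil(percentile% * m)-th largest nonzero
    |weight|; None when the vector has no nonzero entries.
    """
    nz = abs_w[abs_w > 0]
    if nz.size == 0:
        return None
    k = max(1, math.ceil(percentile / 100.0 * nz.size))
    return float(np.sort(nz)[::-1][k - 1])


def find_top_ranked(
    weight_vectors: list[np.ndarray],
    snp_names: list[str],
    percentile: float = 10.0,
    min_runs: int = 14,
    dense: bool = False,
) -> TopRankedSet:
    """Collect SNPs in the top weight percentile of >= min_runs resamplings.

    For sparse weight vectors the percentile is taken over the NONZERO
    |weights| of each resampling (over all weights the cut would be zero
    and everything would qualify); set ``dense=True`` for dense baselines
    such as linear-SVR weights, where all p weights enter the percentile.
    """
    if not weight_vectors:
        raise ValueError("need at least one weight vector")
    if not (0.0 < percentile < 100.0):
        raise ValueError("percentile must lie in (0, 100)")
    if min_runs > len(weight_vectors):
        raise ValueError("min_runs exceeds the number of resamplings")
    p = len(snp_names)
    counts = np.zeros(p, dtype=int)
    weight_sum = np.zeros(p)
    for w in weight_vectors:
        w = np.asarray(w, dtype=float)
        if w.size != p:
            raise ValueError("weight vector length differs from SNP count")
        aw = np.abs(w)
        if dense:
            k = max(1, math.ceil(percentile / 100.0 * p))
            cut = float(np.sort(aw)[::-1][k - 1])
            qual = aw >= cut
        else:
            cut = _percentile_cut(aw, percentile)
            qual = np.zeros(p, dtype=bool) if cut is None else (aw >= cut) & (aw > 0)
        counts += qual
        weight_sum += np.where(qual, aw, 0.0)
    members = {
        snp_names[j]: {
            "n_qualifying": int(counts[j]),
            "mean_abs_weight": float(weight_sum[j] / counts[j]),
        }
        for j in np.flatnonzero(counts >= min_runs)
    }
    return TopRankedSet(members, percentile, min_runs, len(weight_vectors))


def find_top_correlated(
    g: GenotypeMatrix,
    top: TopRankedSet,
    threshold: float,
    weights: np.ndarray | None = None,
) -> SaturationResult:
    """List every SNP correlated above ``threshold`` with each top-ranked SNP.

    ``weights`` (one per SNP, e.g. mean debiased weights over resamplings)
    annotate the recovered SNPs; zero means the model eliminated them.
    Zero-variance genotype columns have undefined correlation and are
    skipped with a warning.
    """
    if not (0.0 < threshold <= 1.0):
        raise ValueError("threshold must lie in (0, 1]")
    if g.missing_mask.any():
        raise ValueError("impute genotypes before computing correlations")
    vals = g.values
    names = g.snp_names
    name_ix = {nm: j for j, nm in enumerate(names)}
    sd = vals.std(axis=0)
    degenerate = np.flatnonzero(sd == 0)
    if degenerate.size:
        warnings.warn(
            f"{degenerate.size} zero-variance SNP columns skipped (undefined correlation)"
        )
    if weights is None:
        weights = np.zeros(len(names))
    weights = np.asarray(weights, dtype=float)

    centered = vals - vals.mean(axis=0)
    safe_sd = np.where(sd == 0, 1.0, sd)
    result = SaturationResult(threshold=threshold)
    for nm in top.names:
        t = name_ix[nm]
        if sd[t] == 0:
            continue
        corr = (centered.T @ centered[:, t]) / (vals.shape[0] * safe_sd * sd[t])
        corr[degenerate] = 0.0
        hits = np.flatnonzero((np.abs(corr) >= threshold) & (np.arange(len(names)) != t))
        rec_t = g.snps[t]
        out = []
        for s in hits:
            rec_s = g.snps[s]
            same = rec_s.chromosome == rec_t.chromosome
            out.append(
                CorrelatedSnp(
                    name=names[s],
                    correlation=float(corr[s]),
                    same_chromosome=same,
                    distance_bp=abs(rec_s.position_bp - rec_t.position_bp) if same else None,
                    weight=float(weights[s]),
                )
            )
        result.by_top_snp[nm] = out
    return result


def distance_summary(r: SaturationResult, min_correlated: int = 0) -> pd.DataFrame:
    """Per-top-SNP count and same-chromosome distance statistics.

    ``min_correlated`` filters to top-ranked SNPs with at least that many
    top-correlated SNPs (the published tables use 5).  Cross-chromosome
    pairs count toward n but not toward distances.
    """
    rows = []
    for nm in sorted(r.by_top_snp):
        lst = r.by_top_snp[nm]
        if len(lst) < min_correlated:
            continue
        d = [c.distance_bp for c in lst if c.same_chromosome]
        rows.append(
            {
                "snp": nm,
                "n": len(lst),
                "mean_distance_bp": float(np.mean(d)) if d else float("nan"),
                "min_distance_bp": int(np.min(d)) if d else pd.NA,
                "max_distance_bp": int(np.max(d)) if d else pd.NA,
            }
        )
    return pd.DataFrame(rows, columns=["snp", "n", "mean_distance_bp", "min_distance_bp", "max_distance_bp"])


def threshold_sweep(
    g: GenotypeMatrix,
    top: TopRankedSet,
    thresholds: tuple[float, ...] = (0.6, 0.7, 0.8, 0.9),
    weights: np.ndarray | None = None,
) -> pd.DataFrame:
    """Pooled distance and weight distributions across a threshold sweep.

    One row per (threshold, top SNP, correlated SNP); the pooled median of
    same-chromosome distances per threshold is the quantity whose decrease
    with rising threshold signals that recovered SNPs cluster around their
    reference marker.
    """
    rows = []
    for thr in thresholds:
        res = find_top_correlated(g, top, thr, weights)
        for nm, lst in res.by_top_snp.items():
            for c in lst:
                rows.append(
                    {
                        "threshold": thr,
                        "top_snp": nm,
                        "snp": c.name,
                        "correlation": c.correlation,
                        "same_chromosome": c.same_chromosome,
                        "distance_bp": c.distance_bp if c.same_chromosome else pd.NA,
                        "weight": c.weight,
                    }
                )
    return pd.DataFrame(
        rows,
        columns=["threshold", "top_snp", "snp", "correlation", "same_chromosome", "distance_bp", "weight"],
    )


def write_table(r: SaturationResult, path, min_correlated: int = 5, snp_chromosome: dict | None = None) -> None:
    """Write the per-top-SNP distance summary as TSV."""
    df = distance_summary(r, min_correlated=min_correlated)
    if snp_chromosome:
        df.insert(1, "chromosome", [snp_chromosome.get(nm, "NA") for nm in df["snp"]])
    df.to_csv(path, sep="\t", index=False)


def write_bed(g: GenotypeMatrix, top: TopRankedSet, r: SaturationResult, path) -> None:
    """Genome-track BED of top-ranked plus top-correlated SNP positions."""
    byname = {s.name: s for s in g.snps}
    rows = []
    for nm in top.names:
        s = byname[nm]
        rows.append((s.chromosome, s.position_bp - 1, s.position_bp, nm, "top_ranked"))
    for nm in sorted(r.all_correlated_names() - set(top.names)):
        s = byname[nm]
        rows.append((s.chromosome, s.position_bp - 1, s.position_bp, nm, "top_correlated"))
    rows.sort(key=lambda t: (t[0], t[1]))
    with open(path, "w") as fh:
        for chrom, start, end, nm, kind in rows:
            fh.write(f"{chrom}\t{max(start, 0)}\t{end}\t{nm}\t0\t+\t{kind}\n")
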