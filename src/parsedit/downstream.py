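"""Region-set enrichment arithmetic, translation efficiency, and contrasts.

Enrichment of point features (editing sites, DES, Alu elements...) between
two region sets is the density ratio fold = (n1/size1) / (n2/size2) with a
Fisher exact p on the site-versus-base table.  Translation efficiency (TE) is
the ribosome-footprint to mRNA normalized-count ratio per gene; its
knockdown/control ratio TER satisfies the identity

    TER = TE_kd / TE_control = FC_ribo / FC_rna

which holds exactly for any per-library normalization.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats


class AnalysisError(ValueError):
    pass


@dataclass
class EnrichmentResult:
    fold: float
    p: float
    n1: int
    size1: int
    n2: int
    size2: int
    infinite: bool = False


def region_enrichment(n1: int, size1: int, n2: int, size2: int) -> EnrichmentResult:
    """Density-ratio enrichment of features between two region sets.

    fold = (n1/size1)/(n2/size2); p from the two-sided Fisher exact test on
    [[n1, size1-n1], [n2, size2-n2]] (feature bases vs non-feature bases).
    """
    if size1 <= 0 or size2 <= 0:
        raise AnalysisError(f"region sizes must be positive: {size1}, {size2}")
    if n2 == 0:
        return EnrichmentResult(float("inf"), float("nan"), n1, size1, n2, size2, infinite=True)
    fold = (n1 / size1) / (n2 / size2)
    p = float(stats.fisher_exact([[n1, size1 - n1], [n2, size2 - n2]])[1])
    return EnrichmentResult(fold=fold, p=p, n1=n1, size1=size1, n2=n2, size2=size2)


@dataclass
class RegionSet:
    """Named set of stranded 0-based half-open intervals, merged on demand."""

    name: str
    intervals: list[tuple[str, int, int]]

    def merged(self) -> dict[str, list[tuple[int, int]]]:
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for chrom, start, end in self.intervals:
            by_chrom.setdefault(chrom, []).append((start, end))
        out = {}
        for chrom, ivals in by_chrom.items():
            ivals.sort()
            merged: list[list[int]] = []
            for s, e in ivals:
                if merged and s <= merged[-1][1]:
                    merged[-1][1] = max(merged[-1][1], e)
                else:
                    merged.append([s, e])
            out[chrom] = [(s, e) for s, e in merged]
        return out

    @property
    def total_size(self) -> int:
        return sum(e - s for ivals in self.merged().values() for s, e in ivals)


def count_features_in_regions(
    features: list[tuple[str, int] | tuple[str, int, int]], regions: RegionSet
) -> int:
    """Count feature occurrences overlapping the merged regions.

    Point features (chrom, pos) are counted per occurrence (duplicates count
    twice); interval features (chrom, start, end) count once each if they
    overlap any region.  Half-open convention: a point at a region's end
    coordinate is outside it.
    """
    trees = {
        chrom: IntervalTree.from_tuples(ivals)
        for chrom, ivals in regions.merged().items()
        if ivals
    }
    n = 0
    for f in features:
        if len(f) == 2:
            chrom, pos = f
            if chrom in trees and trees[chrom].overlaps_point(pos):
                n += 1
        elif len(f) == 3:
            chrom, start, end = f
            if chrom in trees and trees[chrom].overlap(start, end):
                n += 1
        else:
            raise AnalysisError(f"bad feature {f!r}")
    return n


def _normalize(counts: pd.Series, normalizer: str, paired: pd.Series | None = None) -> pd.Series:
    if normalizer == "total":
        return counts / counts.sum()
    if normalizer == "median-of-ratios":
        if paired is None:
            raise AnalysisError("median-of-ratios needs the partner library")
        both = (counts > 0) & (paired > 0)
        geo = np.sqrt(counts[both] * paired[both])
        size_factor = float(np.median(counts[both] / geo))
        return counts / size_factor
    raise AnalysisError(f"unknown normalizer {normalizer!r}")


def fold_change(
    counts_kd: pd.Series, counts_control: pd.Series, normalizer: str = "total"
) -> pd.Series:
    """Library-size-normalized knockdown/control count ratio per gene.

    ``normalizer="total"`` scales each library to its total; ``"median-of-
    ratios"`` uses size factors from the median ratio to the per-gene
    geometric mean (the standard differential-expression scaling).  Genes
    with zero control signal get NaN (undefined) fold change.
    """
    counts_kd, counts_control = counts_kd.align(counts_control, join="inner")
    if counts_kd.sum() <= 0 or counts_control.sum() <= 0:
        raise AnalysisError("library totals must be positive")
    nk = _normalize(counts_kd, normalizer, counts_control)
    nc = _normalize(counts_control, normalizer, counts_kd)
    with np.errstate(divide="ignore", invalid="ignore"):
        fc = nk / nc
    return fc.where(nc > 0)


@dataclass
class TranslationTable:
    table: pd.DataFrame  # TE_control, TE_kd, FC_rna, FC_ribo, TER
    n_filtered: int


def translation_efficiency(
    ribo: pd.DataFrame, rna: pd.DataFrame, min_reads: float = 100, normalizer: str = "total"
) -> TranslationTable:
    """Per-gene TE and TER from Ribo-seq and RNA-seq count tables.

    Both tables need ``control`` and ``kd`` columns indexed by gene.  Genes
    with strictly more than ``min_reads`` total reads in BOTH assays are
    retained.  TER = TE_kd / TE_control, and equals FC_ribo / FC_rna to
    numerical precision by construction.
    """
    genes = ribo.index.intersection(rna.index)
    ribo, rna = ribo.loc[genes], rna.loc[genes]
    keep = (ribo[["control", "kd"]].sum(axis=1) > min_reads) & (
        rna[["control", "kd"]].sum(axis=1) > min_reads
    )
    n_filtered = int((~keep).sum())
    ribo, rna = ribo[keep], rna[keep]
    if ribo.empty:
        raise AnalysisError("no genes pass the coverage filter")

    nr = {c: _normalize(ribo[c], normalizer, ribo["control" if c == "kd" else "kd"]) for c in ("control", "kd")}
    nm = {c: _normalize(rna[c], normalizer, rna["control" if c == "kd" else "kd"]) for c in ("control", "kd")}
    out = pd.DataFrame(index=ribo.index)
    with np.errstate(divide="ignore", invalid="ignore"):
        out["TE_control"] = nr["control"] / nm["control"]
        out["TE_kd"] = nr["kd"] / nm["kd"]
        out["FC_ribo"] = nr["kd"] / nr["control"]
        out["FC_rna"] = nm["kd"] / nm["control"]
        out["TER"] = out["TE_kd"] / out["TE_control"]
    return TranslationTable(table=out, n_filtered=n_filtered)


def rank_overlap_enrichment(
    ranked_genes: list[str], feature_set: set[str], background_set: set[str], top_n: int = 1000
) -> EnrichmentResult:
    """Enrichment of a feature set among the top of a ranked list.

    fold = (fraction of the feature set inside the top ``top_n``) over the
    same fraction for the background set, with a Fisher exact p on the
    in-top/out-of-top by feature/background 2x2 table.
    """
    if top_n > len(ranked_genes):
        raise AnalysisError(f"top_n={top_n} exceeds list length {len(ranked_genes)}")
    universe = set(ranked_genes)
    if not (feature_set <= universe and background_set <= universe):
        raise AnalysisError("ranked list must contain every feature/background gene")
    top = set(ranked_genes[:top_n])
    a = len(top & feature_set)
    b = len(top & background_set)
    if len(feature_set) == 0 or len(background_set) == 0:
        raise AnalysisError("empty feature or background set")
    table = [[a, len(feature_set) - a], [b, len(background_set) - b]]
    p = float(stats.fisher_exact(table)[1])
    if b == 0:
        return EnrichmentResult(float("inf"), p, a, len(feature_set), b, len(background_set), infinite=True)
    fold = (a / len(feature_set)) / (b / len(background_set))
    return EnrichmentResult(fold, p, a, len(feature_set), b, len(background_set))


@dataclass
class UpDownContrast:
    frac_up_a: float
    frac_down_a: float
    frac_up_b: float
    frac_down_b: float
    fisher_p: float


def updown_contrast(
    set_a: set[str],
    set_b: set[str],
    fc: dict[str, float],
    significant: set[str] | None = None,
) -> UpDownContrast:
    """Fractions of up- (FC > 1) and down-regulated genes in two gene sets
    and a Fisher exact test of the up/down split between them.  When a
    significance mask is given, only genes in it count as changed."""
    if not set_a or not set_b:
        raise AnalysisError("gene sets must be non-empty")

    def split(genes):
        up = down = 0
        total = 0
        for g in genes:
            if g not in fc or np.isnan(fc[g]):
                continue
            total += 1
            if significant is not None and g not in significant:
                continue
            if fc[g] > 1:
                up += 1
            elif fc[g] < 1:
                down += 1
        if total == 0:
            raise AnalysisError("no genes with fold changes in a set")
        return up, down, total

    up_a, down_a, n_a = split(set_a)
    up_b, down_b, n_b = split(set_b)
    p = float(stats.fisher_exact([[up_a, down_a], [up_b, down_b]])[1])
    return UpDownContrast(
        frac_up_a=up_a / n_a,
        frac_down_a=down_a / n_a,
        frac_up_b=up_b / n_b,
        frac_down_b=down_b / n_b,
        fisher_p=p,
    )
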