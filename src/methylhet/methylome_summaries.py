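"""Genome-scale methylation summaries.

Global methylation level, fixed-width (default 5 kb) tiling with a
coverage-based eligibility rule, the per-sample coefficient of variation
(CV) over eligible tiles used as an interindividual-heterogeneity score, a
TSS→TES metagene profile, and a region-wise two-group comparison on
user-supplied regions (rank-sum with Benjamini–Hochberg correction).

A tile's methylation is the unweighted mean of per-CpG betas inside it and
is reported only when the tile's mean per-CpG read depth exceeds the depth
threshold (strictly more than ten reads by default).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .epiread_core import BetaTrack, CpGReference

DEFAULT_TILE_WIDTH = 5000
DEFAULT_DEPTH_THRESHOLD = 10  # eligibility requires depth strictly above this


@dataclass(frozen=True)
class SampleCV:
    """Coefficient of variation of eligible-tile methylation for one sample."""

    sample_id: str
    cv: float
    n_eligible_tiles: int


@dataclass
class MetageneProfile:
    """Mean methylation across upstream flank, scaled gene body, downstream flank."""

    values: np.ndarray  # length n_flank_bins + n_body_bins + n_flank_bins
    gene_counts: np.ndarray  # genes contributing to each bin
    n_flank_bins: int
    n_body_bins: int
    flank_bp: int
    n_genes_used: int
    n_genes_skipped: int


# ---------------------------------------------------------------------------
# Tiling and CV
# ---------------------------------------------------------------------------

def tile_methylation(
    track: BetaTrack,
    ref: CpGReference,
    tile_width: int = DEFAULT_TILE_WIDTH,
    depth_threshold: float = DEFAULT_DEPTH_THRESHOLD,
    depth_rule: str = "mean",
) -> pd.DataFrame:
    """Partition each contig into half-open fixed-width tiles and average betas.

    Tile methylation is the unweighted mean of the defined per-CpG betas in
    the tile. Depth is the mean read depth over the tile's CpGs
    (``depth_rule="mean"``) or the minimum (``"each"``: every CpG must pass).
    A tile is eligible iff it contains at least one CpG and its depth is
    strictly greater than ``depth_threshold``.
    """
    if depth_rule not in ("mean", "each"):
        raise ValueError("depth_rule must be 'mean' or 'each'")
    rows = []
    for contig in ref.contigs():
        length = ref.contig_lengths[contig]
        pos = ref.positions[contig]
        beta = track.beta(contig)
        depth = track.total[contig]
        n_tiles = max(1, math.ceil(length / tile_width)) if length > 0 else 0
        tile_of_cpg = pos // tile_width
        for t in range(n_tiles):
            start = t * tile_width
            end = min(length, start + tile_width)
            mask = tile_of_cpg == t
            n_cpgs = int(mask.sum())
            if n_cpgs == 0:
                rows.append((contig, start, end, 0, math.nan, math.nan, False))
                continue
            d = depth[mask]
            tile_depth = float(d.mean()) if depth_rule == "mean" else float(d.min())
            b = beta[mask]
            b = b[~np.isnan(b)]
            meth = float(b.mean()) if b.size else math.nan
            eligible = bool(tile_depth > depth_threshold and b.size > 0)
            rows.append((contig, start, end, n_cpgs, tile_depth, meth, eligible))
    return pd.DataFrame(
        rows,
        columns=["contig", "start", "end", "n_cpgs", "mean_depth", "methylation", "eligible"],
    )


def sample_cv(tiles: pd.DataFrame, sample_id: str = "") -> SampleCV:
    """sd/mean (sample sd, n−1) of methylation over eligible tiles.

    Undefined (NaN) with fewer than two eligible tiles or a zero mean.
    """
    vals = tiles.loc[tiles["eligible"], "methylation"].to_numpy(dtype=float)
    vals = vals[~np.isnan(vals)]
    if vals.size < 2 or vals.mean() == 0:
        return SampleCV(sample_id=sample_id, cv=math.nan, n_eligible_tiles=int(vals.size))
    return SampleCV(
        sample_id=sample_id,
        cv=float(vals.std(ddof=1) / vals.mean()),
        n_eligible_tiles=int(vals.size),
    )


def global_methylation(track: BetaTrack, weighted: bool = False) -> float:
    """Mean CpG methylation over covered CpGs.

    Unweighted mean of betas by default; ``weighted=True`` pools calls
    (total methylated / total called) instead. NaN with no coverage.
    """
    if weighted:
        meth = sum(int(track.meth[c].sum()) for c in track.contigs())
        total = sum(int(track.total[c].sum()) for c in track.contigs())
        return meth / total if total else math.nan
    betas = np.concatenate([track.beta(c) for c in track.contigs()]) if track.contigs() else np.array([])
    betas = betas[~np.isnan(betas)]
    return float(betas.mean()) if betas.size else math.nan


# ---------------------------------------------------------------------------
# Metagene profile
# ---------------------------------------------------------------------------

def read_bed(path, names=("contig", "start", "end", "name", "score", "strand")) -> pd.DataFrame:
    """Read a headerless BED-style TSV, keeping whichever columns exist."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df.columns = list(names[: df.shape[1]])
    return df


def metagene_profile(
    track: BetaTrack,
    ref: CpGReference,
    genes: pd.DataFrame,
    flank_bp: int = 2000,
    n_body_bins: int = 100,
    n_flank_bins: int = 20,
) -> MetageneProfile:
    """Average methylation across scaled gene bodies with fixed flanks.

    Genes need ``contig``, ``start``, ``end`` and (optionally) ``strand``
    columns; half-open coordinates. Flank bins cover fixed bp windows around
    TSS/TES; body bins are length-scaled. Minus-strand genes are flipped so
    every profile reads TSS→TES. Genes shorter than ``n_body_bins`` bp are
    skipped and counted. Each gene contributes its per-bin mean; the profile
    is the unweighted mean across genes with data in the bin.
    """
    if genes.empty:
        raise ValueError("empty gene set")
    n_bins = 2 * n_flank_bins + n_body_bins
    acc = np.zeros(n_bins)
    counts = np.zeros(n_bins, dtype=np.int64)
    used = skipped = 0
    for gene in genes.itertuples(index=False):
        contig = gene.contig
        if contig not in ref.positions:
            skipped += 1
            continue
        gstart, gend = int(gene.start), int(gene.end)
        if gend - gstart < n_body_bins:
            skipped += 1
            continue
        strand = getattr(gene, "strand", "+")
        pos = ref.positions[contig]
        beta = track.beta(contig)
        lo = np.searchsorted(pos, gstart - flank_bp)
        hi = np.searchsorted(pos, gend + flank_bp)
        if hi <= lo:
            skipped += 1
            continue
        gene_sum = np.zeros(n_bins)
        gene_n = np.zeros(n_bins, dtype=np.int64)
        for p, b in zip(pos[lo:hi], beta[lo:hi]):
            if np.isnan(b):
                continue
            if p < gstart:  # upstream in genome coordinates
                frac = (p - (gstart - flank_bp)) / flank_bp
                bin_idx = min(n_flank_bins - 1, int(frac * n_flank_bins))
            elif p >= gend:
                frac = (p - gend) / flank_bp
                bin_idx = 2 * n_flank_bins + n_body_bins - n_flank_bins + min(
                    n_flank_bins - 1, int(frac * n_flank_bins)
                )
            else:
                frac = (p - gstart) / (gend - gstart)
                bin_idx = n_flank_bins + min(n_body_bins - 1, int(frac * n_body_bins))
            gene_sum[bin_idx] += b
            gene_n[bin_idx] += 1
        if strand == "-":
            gene_sum = gene_sum[::-1]
            gene_n = gene_n[::-1]
        has = gene_n > 0
        acc[has] += gene_sum[has] / gene_n[has]
        counts[has] += 1
        used += 1
    with np.errstate(invalid="ignore", divide="ignore"):
        values = np.where(counts > 0, acc / np.maximum(counts, 1), np.nan)
    return MetageneProfile(
        values=values,
        gene_counts=counts,
        n_flank_bins=n_flank_bins,
        n_body_bins=n_body_bins,
        flank_bp=flank_bp,
        n_genes_used=used,
        n_genes_skipped=skipped,
    )


# ---------------------------------------------------------------------------
# Region-wise two-group comparison
# ---------------------------------------------------------------------------

def region_group_comparison(
    region_means: pd.DataFrame,
    groups: pd.Series | dict,
    exact_max_n: int = 8,
) -> pd.DataFrame:
    """Two-group rank-sum test per region with BH correction.

    ``region_means`` is regions × samples (one row per region, one column per
    sample); ``groups`` maps each sample to one of exactly two labels, each
    with at least two samples. The Mann–Whitney U statistic is reported for
    the first (alphabetically lower) group; the p-value is exact when both
    groups have at most ``exact_max_n`` samples and tie-corrected normal
    otherwise. ``q`` is the Benjamini–Hochberg adjusted p across regions.
    """
    groups = pd.Series(groups)
    labels = sorted(groups.unique())
    if len(labels) != 2:
        raise ValueError(f"need exactly two groups, got {labels}")
    a_ids = groups.index[groups == labels[0]]
    b_ids = groups.index[groups == labels[1]]
    if len(a_ids) < 2 or len(b_ids) < 2:
        raise ValueError("each group needs at least two samples")
    method = "exact" if max(len(a_ids), len(b_ids)) <= exact_max_n else "asymptotic"
    rows = []
    for region, row in region_means.iterrows():
        a = row[a_ids].to_numpy(dtype=float)
        b = row[b_ids].to_numpy(dtype=float)
        mean_diff = float(a.mean() - b.mean())
        use = method
        if method == "exact" and (
            len(np.unique(np.concatenate([a, b]))) < len(a) + len(b)
        ):
            use = "asymptotic"  # exact method does not handle ties
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method=use)
        rows.append((region, mean_diff, float(res.statistic), float(res.pvalue)))
    out = pd.DataFrame(rows, columns=["region", "mean_diff", "U", "p"]).set_index("region")
    out["q"] = multipletests(out["p"], method="fdr_bh")[1] if len(out) else []
    return out
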