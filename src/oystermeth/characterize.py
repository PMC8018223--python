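"""Methylome characterization.

Metagene profiling (scale-regions style: fixed-width flank bins, gene body
scaled to a common bin count), gene-body methylation rate (GBMR, the
unweighted mean of per-site CpG fractions over the annotated gene span),
rank-based low/mid/high gene classification, RPKM normalisation and the
methylation-by-expression-rank curve, and Ward clustering of samples on
1 - Pearson correlation distance.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .calling import MethylationCallSet, UnitedMatrix
from .synthetic import GeneSet


# ---------------------------------------------------------------------------
# metagene profile
# ---------------------------------------------------------------------------

def metagene_profile(callsets, gene_set: GeneSet, flank: int = 3000,
                     body_bins: int = 60, flank_bin_bp: int = 100) -> pd.DataFrame:
    """Average methylation across genes on a common TSS-to-TES axis.

    Each CpG within a gene or its ``flank`` is assigned, after strand-aware
    coordinate reversal for minus-strand genes, to one of
    ``flank//flank_bin_bp`` upstream bins, ``body_bins`` proportionally
    scaled body bins, or the downstream bins.  Per-bin site fractions are
    averaged within each gene, then across genes; bins a gene does not cover
    are simply absent from its average.
    """
    if isinstance(callsets, MethylationCallSet):
        callsets = [callsets]
    n_flank_bins = flank // flank_bin_bp
    total_bins = 2 * n_flank_bins + body_bins
    sums = np.zeros(total_bins)
    counts = np.zeros(total_bins, dtype=int)
    site_tallies = np.zeros(total_bins, dtype=int)
    n_skipped = 0

    frames = []
    for cs in callsets:
        df = cs.data
        frames.append(df[df["context"] == "CpG"])
    sites = pd.concat(frames, ignore_index=True)

    for g in gene_set.genes.itertuples(index=False):
        sub = sites[
            (sites["scaffold"] == g.scaffold)
            & (sites["pos"] >= g.start - flank)
            & (sites["pos"] <= g.end + flank)
        ]
        if len(sub) == 0:
            n_skipped += 1
            continue
        pos = sub["pos"].to_numpy()
        frac = sub["fraction"].to_numpy()
        if g.strand == "+":
            rel = pos - g.start
        else:
            rel = g.end - pos  # reversed axis so TSS is at 0
        length = g.end - g.start + 1
        bins = np.empty(len(rel), dtype=int)
        up = rel < 0
        down = rel >= length
        body = ~up & ~down
        bins[up] = (rel[up] + flank) // flank_bin_bp
        bins[body] = n_flank_bins + np.minimum(
            (rel[body] * body_bins) // length, body_bins - 1
        )
        bins[down] = (
            n_flank_bins + body_bins + (rel[down] - length) // flank_bin_bp
        )
        per_bin = pd.Series(frac).groupby(bins).mean()
        sums[per_bin.index] += per_bin.to_numpy()
        counts[per_bin.index] += 1
        site_tallies += np.bincount(bins, minlength=total_bins)

    with np.errstate(invalid="ignore"):
        mean_frac = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    region = (
        ["upstream"] * n_flank_bins
        + ["body"] * body_bins
        + ["downstream"] * n_flank_bins
    )
    out = pd.DataFrame(
        {
            "bin": np.arange(total_bins),
            "region": region,
            "mean_fraction": mean_frac,
            "n_genes": counts,
            "n_sites": site_tallies,
        }
    )
    out.attrs["n_genes_skipped"] = n_skipped
    return out


# ---------------------------------------------------------------------------
# gene body methylation and classification
# ---------------------------------------------------------------------------

def gene_body_methylation(callset: MethylationCallSet, gene_set: GeneSet) -> pd.DataFrame:
    """Per-gene mean CpG methylation fraction (bedtools map -o mean semantics).

    Every CpG overlapping the annotated span contributes with equal weight;
    a CpG under two overlapping genes contributes to both.  Genes with no
    covered CpG get NaN and are excluded from ranking downstream.
    """
    df = callset.data
    cpg = df[df["context"] == "CpG"]
    gbmr = np.full(len(gene_set), np.nan)
    n_sites = np.zeros(len(gene_set), dtype=int)
    for i, g in enumerate(gene_set.genes.itertuples(index=False)):
        sub = cpg[
            (cpg["scaffold"] == g.scaffold)
            & (cpg["pos"] >= g.start)
            & (cpg["pos"] <= g.end)
        ]
        if len(sub):
            gbmr[i] = sub["fraction"].mean()
            n_sites[i] = len(sub)
    return pd.DataFrame(
        {
            "gene_id": gene_set.genes["gene_id"].to_numpy(),
            "gbmr": gbmr,
            "n_sites": n_sites,
        }
    )


def classify_genes_by_rank(gene_meth: pd.DataFrame, low_cut: float = 0.2,
                           high_cut: float = 0.5) -> pd.DataFrame:
    """Rank genes by GBMR and split into low / mid / high classes.

    ``rank_fraction`` is the fractional midrank (rank - 0.5)/n with average
    ranks for ties; genes at or below ``low_cut`` are 'low', at or above
    ``high_cut`` 'high', in between 'mid'.  Genes without a GBMR are left
    unclassified (empty class).
    """
    out = gene_meth.copy()
    valid = out["gbmr"].notna()
    vals = out.loc[valid, "gbmr"].to_numpy()
    if valid.sum() < 2:
        raise ValueError("need at least two ranked genes")
    ranks = stats.rankdata(vals, method="average")
    rank_fraction = (ranks - 0.5) / len(vals)
    out["rank_fraction"] = np.nan
    out.loc[valid, "rank_fraction"] = rank_fraction
    cls = np.full(len(out), "", dtype=object)
    if np.all(vals == vals[0]):
        warnings.warn("all gene methylation rates tied; classifying all as mid")
        cls[np.flatnonzero(valid)] = "mid"
    else:
        v_idx = np.flatnonzero(valid)
        cls[v_idx] = "mid"
        cls[v_idx[rank_fraction <= low_cut]] = "low"
        cls[v_idx[rank_fraction >= high_cut]] = "high"
    out["meth_class"] = cls
    return out


def rpkm(counts, gene_length_bp, total_mapped_reads) -> np.ndarray:
    """Reads per kilobase per million mapped reads: 1e9 * c / (L * N)."""
    counts = np.asarray(counts, dtype=float)
    L = np.asarray(gene_length_bp, dtype=float)
    if np.any(L <= 0):
        raise ValueError("gene length must be positive")
    if total_mapped_reads <= 0:
        raise ValueError("library size must be positive")
    return 1e9 * counts / (L * total_mapped_reads)


def methylation_by_expression_rank(gene_meth: pd.DataFrame, expression: pd.DataFrame,
                                   n_bins: int = 10) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Mean GBMR per expression bin.

    Returns (rank_curve, fixed_bins): the rank curve uses ``n_bins``
    equal-count bins of RPKM rank; the fixed table always reports the
    <100, 100-1000 and >1000 RPKM bands.
    """
    merged = gene_meth.merge(expression, on="gene_id").dropna(subset=["gbmr", "rpkm"])
    if len(merged) == 0:
        raise ValueError("no overlapping gene ids between methylation and expression")
    n_bins = min(n_bins, len(merged))
    ranks = stats.rankdata(merged["rpkm"], method="average") / len(merged)
    bin_idx = np.minimum((ranks * n_bins).astype(int), n_bins - 1)
    curve = (
        merged.assign(bin=bin_idx)
        .groupby("bin")
        .agg(mean_gbmr=("gbmr", "mean"), mean_rpkm=("rpkm", "mean"), n=("gbmr", "size"))
        .reset_index()
    )
    bands = pd.cut(
        merged["rpkm"], [-np.inf, 100, 1000, np.inf], labels=["<100", "100-1000", ">1000"]
    )
    fixed = (
        merged.assign(band=bands)
        .groupby("band", observed=False)
        .agg(mean_gbmr=("gbmr", "mean"), n=("gbmr", "size"))
        .reset_index()
    )
    return curve, fixed


# ---------------------------------------------------------------------------
# sample clustering
# ---------------------------------------------------------------------------

def cluster_samples(united: UnitedMatrix):
    """Ward clustering of samples on 1 - Pearson correlation of site fractions.

    Returns (linkage_matrix, leaf_labels) with leaves in dendrogram order.
    Raises if any sample has a constant methylation profile (undefined
    correlation).
    """
    if len(united.samples) < 3:
        raise ValueError("need at least three samples to cluster")
    if len(united) < 2:
        raise ValueError("need at least two shared sites")
    mat = np.vstack([united.fractions(s) for s in united.samples])
    sd = mat.std(axis=1)
    for sid, s in zip(united.samples, sd):
        if s == 0:
            raise ValueError(f"sample {sid!r} has a constant profile; correlation undefined")
    corr = np.corrcoef(mat)
    dist = 1.0 - corr
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)
    Z = hierarchy.linkage(squareform(dist, checks=False), method="ward")
    order = hierarchy.leaves_list(Z)
    labels = [united.samples[i] for i in order]
    return Z, labels


def linkage_to_newick(Z: np.ndarray, labels) -> str:
    """Dendrogram as a Newick string with branch lengths from merge heights."""
    n = len(labels)
    heights = {i: 0.0 for i in range(n)}

    def build(node: int) -> str:
        if node < n:
            return labels[node]
        a, b, h, _ = Z[node - n]
        a, b = int(a), int(b)
        heights[node] = h
        left = f"{build(a)}:{h - heights[a]:.6g}"
        right = f"{build(b)}:{h - heights[b]:.6g}"
        return f"({left},{right})"

    return build(2 * n - 2) + ";"


def first_split(Z: np.ndarray, labels) -> tuple[set, set]:
    """The two sample sets separated by the root of the dendrogram."""
    n = len(labels)

    def leaves(node: int) -> set:
        if node < n:
            return {labels[node]}
        a, b, _, _ = Z[node - n]
        return leaves(int(a)) | leaves(int(b))

    a, b, _, _ = Z[-1]
    return leaves(int(a)), leaves(int(b))
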