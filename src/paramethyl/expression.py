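"""Expression-pattern classes and positional candidate triage.

Differentially expressed genes are grouped by average-linkage
hierarchical clustering on 1 - Pearson correlation of their (log2,
library-normalised, per-gene median-centred) profiles, cutting the tree
where merges fall below a correlation threshold (0.7 by default).
Clusters are then labelled by the sign pattern of their genotype means
relative to wild type: down in sulf and sulf/+ (I), down in sulf only
(II), up in both (III), up in sulf only (IV), anything else "other".

The positional filter intersects three criteria to shortlist candidate
genes for the silenced locus: significantly differentially expressed,
down-regulated in sulf (positive wt-over-sulf log2 fold-change), and
located on the target chromosome upstream of (at or before) the S-locus
boundary coordinate; candidates are ranked by fold-change so the most
repressed gene tops the list.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

logger = logging.getLogger(__name__)

FLAT_CLUSTER = "flat"

CATEGORY_PATTERNS = {
    # (sign of sulf/+ - wt, sign of sulf - wt) -> class
    (-1, -1): "I",
    (0, -1): "II",
    (1, 1): "III",
    (0, 1): "IV",
}


@dataclass
class ExpressionSet:
    """Log2 normalised, per-gene median-centred expression with genotypes."""

    values: pd.DataFrame  # genes x samples
    genotype: pd.Series  # sample -> {wt, sulf/+, sulf}

    def __post_init__(self):
        missing = set(self.values.columns) - set(self.genotype.index)
        if missing:
            raise ValueError(f"samples without genotype label: {sorted(missing)}")


def prepare_matrix(
    counts: pd.DataFrame, lib_sizes: pd.Series | None = None, genotype: pd.Series | None = None
) -> ExpressionSet:
    """Library-normalise, log2-transform and median-centre a count matrix.

    Counts-per-million scaling by library size (column totals by default),
    then log2(x + 1), then subtraction of each gene's median so profiles
    compare shape rather than magnitude.
    """
    if (counts < 0).any().any():
        raise ValueError("counts must be non-negative")
    sizes = counts.sum(axis=0).astype(float) if lib_sizes is None else lib_sizes.astype(float)
    if (sizes <= 0).any():
        raise ValueError("library sizes must be > 0")
    cpm = counts.div(sizes, axis=1) * 1e6
    log2 = np.log2(cpm + 1.0)
    centred = log2.sub(log2.median(axis=1), axis=0)
    if genotype is None:
        genotype = pd.Series("wt", index=counts.columns, name="genotype")
    return ExpressionSet(values=centred, genotype=genotype)


def median_center(values: pd.DataFrame) -> pd.DataFrame:
    """Per-gene median centring of an already-log2 matrix."""
    return values.sub(values.median(axis=1), axis=0)


def correlation_cluster(values: pd.DataFrame, r_threshold: float = 0.7) -> pd.Series:
    """Average-linkage correlation clustering with a threshold cut.

    Distance is 1 - Pearson r across samples; the tree is cut so that
    merges with correlation >= r_threshold stay together.  Zero-variance
    (flat) genes cannot enter a correlation and each becomes its own
    singleton cluster labelled ``flat:<gene>``.  Input order does not
    matter: genes are sorted lexicographically before clustering.

    Returns a Series gene -> cluster label (strings).
    """
    if len(values) < 1:
        return pd.Series(dtype=object, name="cluster")
    values = values.sort_index(kind="stable")
    sd = values.std(axis=1, ddof=0)
    flat = sd == 0
    labels = pd.Series(index=values.index, dtype=object, name="cluster")
    for gene in values.index[flat]:
        labels[gene] = f"{FLAT_CLUSTER}:{gene}"
    active = values.loc[~flat]
    if len(active) == 1:
        labels[active.index[0]] = "c1"
        return labels
    if len(active) == 0:
        return labels
    corr = np.corrcoef(active.to_numpy())
    dist = np.clip(1.0 - corr, 0.0, 2.0)
    np.fill_diagonal(dist, 0.0)
    z = linkage(squareform(dist, checks=False), method="average")
    assignment = fcluster(z, t=1.0 - r_threshold, criterion="distance")
    for gene, k in zip(active.index, assignment):
        labels[gene] = f"c{k}"
    return labels


def cluster_genotype_means(
    values: pd.DataFrame, genotype: pd.Series, clusters: pd.Series
) -> pd.DataFrame:
    """Mean expression per (cluster, genotype)."""
    geno_means = values.T.groupby(genotype).mean().T  # genes x genotypes
    return geno_means.groupby(clusters).mean()


def assign_categories(
    cluster_means: pd.DataFrame, min_effect: float = 0.5
) -> pd.Series:
    """Label clusters I-IV / other from their genotype mean differences.

    The two axes are (sulf/+ - wt) and (sulf - wt); a difference smaller
    in magnitude than ``min_effect`` (log2 units) counts as unchanged.
    """
    for g in ("wt", "sulf/+", "sulf"):
        if g not in cluster_means.columns:
            raise ValueError(f"missing genotype mean for {g!r}")

    def sgn(x: float) -> int:
        if x >= min_effect:
            return 1
        if x <= -min_effect:
            return -1
        return 0

    out = {}
    for cluster, row in cluster_means.iterrows():
        key = (sgn(row["sulf/+"] - row["wt"]), sgn(row["sulf"] - row["wt"]))
        out[cluster] = CATEGORY_PATTERNS.get(key, "other")
    return pd.Series(out, name="category")


def categorize(
    eset: ExpressionSet, r_threshold: float = 0.7, min_effect: float = 0.5
) -> pd.DataFrame:
    """Cluster genes and label each with its cluster's expression class."""
    clusters = correlation_cluster(eset.values, r_threshold=r_threshold)
    means = cluster_genotype_means(eset.values, eset.genotype, clusters)
    categories = assign_categories(means, min_effect=min_effect)
    return pd.DataFrame(
        {"gene": clusters.index, "cluster": clusters.to_numpy(),
         "category": categories.reindex(clusters.to_numpy()).to_numpy()}
    )


def positional_candidate_filter(
    de: pd.DataFrame,
    annotation: pd.DataFrame,
    boundary: int,
    chrom: str = "2",
    padj_max: float = 0.05,
) -> pd.DataFrame:
    """Shortlist sulf-down-regulated genes upstream of the S locus.

    Keeps genes with adjusted p < padj_max, positive wt-over-sulf log2
    fold-change (down in sulf), on ``chrom`` with gene end at or before
    ``boundary`` (inclusive).  Genes missing from the annotation are
    logged and dropped.  Result is sorted by descending fold-change.
    """
    merged = de.merge(annotation, on="gene", how="left", validate="one_to_one")
    missing = merged["chrom"].isna()
    if missing.any():
        logger.warning(
            "%d DE genes missing from annotation, excluded: %s",
            int(missing.sum()),
            ", ".join(merged.loc[missing, "gene"].head(5)),
        )
        merged = merged.loc[~missing]
    keep = (
        (merged["padj"] < padj_max)
        & (merged["log2fc"] > 0)
        & (merged["chrom"].astype(str) == str(chrom))
        & (merged["end"] <= boundary)
    )
    out = merged.loc[keep].sort_values(
        ["log2fc", "gene"], ascending=[False, True], kind="stable"
    )
    return out.reset_index(drop=True)
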