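"""Alpha- and beta-diversity.

Alpha: Faith's phylogenetic diversity (rooted, includes the path to the
root), OTU richness, Shannon entropy (log2 by default) and Pielou evenness.
Beta: Bray-Curtis, unweighted UniFrac and weighted UniFrac
(non-normalized by default). Faith's PD, UniFrac and the underlying tree
handling are delegated to scikit-bio.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from skbio import TreeNode
from skbio.diversity import alpha_diversity as _skbio_alpha
from skbio.diversity import beta_diversity as _skbio_beta
from skbio.stats.distance import DistanceMatrix

from .data_model import OtuTable, ValidationError, check_tree_coverage

ALPHA_INDICES = ["faith_pd", "otu_richness", "shannon", "pielou_e"]


def shannon_entropy(counts: np.ndarray, base: float = 2.0) -> float:
    """Shannon entropy H = -sum p log p over taxa with positive counts."""
    x = np.asarray(counts, dtype=float)
    x = x[x > 0]
    if x.size == 0:
        raise ValidationError("Shannon entropy of an empty sample")
    p = x / x.sum()
    return float(-(p * (np.log(p) / np.log(base))).sum())


def alpha_diversity(table: OtuTable, tree: TreeNode,
                    shannon_base: float = 2.0) -> pd.DataFrame:
    """Per-sample alpha-diversity table (faith_pd, otu_richness, shannon, pielou_e).

    ``pielou_e = H / log(richness)`` in the same base; it is reported as NaN
    for single-taxon samples (log richness = 0).
    """
    check_tree_coverage(table, tree)
    totals = table.sample_totals()
    if (totals == 0).any():
        zero = table.sample_ids[int(np.argmax(totals == 0))]
        raise ValidationError(f"sample {zero!r} has zero total count")
    counts_sm = table.counts.T  # samples x taxa for skbio
    faith = _skbio_alpha("faith_pd", counts_sm, ids=table.sample_ids,
                         taxa=table.taxon_ids, tree=tree)
    richness = (table.counts > 0).sum(axis=0)
    shannon = np.array([shannon_entropy(table.counts[:, j], shannon_base)
                        for j in range(table.n_samples)])
    with np.errstate(divide="ignore", invalid="ignore"):
        log_rich = np.log(richness) / np.log(shannon_base)
        pielou = np.where(richness > 1, shannon / log_rich, np.nan)
    return pd.DataFrame(
        {"faith_pd": faith.to_numpy(), "otu_richness": richness,
         "shannon": shannon, "pielou_e": pielou},
        index=pd.Index(table.sample_ids, name="sample_id"),
    )


def bray_curtis(table: OtuTable) -> DistanceMatrix:
    """Bray-Curtis dissimilarity: BC = 1 - 2 sum min(x, y) / (sum x + sum y)."""
    totals = table.sample_totals()
    if (totals == 0).any():
        zero = table.sample_ids[int(np.argmax(totals == 0))]
        raise ValidationError(
            f"Bray-Curtis undefined: sample {zero!r} is all-zero"
        )
    return _skbio_beta("braycurtis", table.counts.T.astype(float),
                       ids=table.sample_ids)


def unweighted_unifrac(table: OtuTable, tree: TreeNode) -> DistanceMatrix:
    """Unweighted UniFrac: unique branch length / total branch length in the union."""
    check_tree_coverage(table, tree)
    return _skbio_beta("unweighted_unifrac", table.counts.T,
                       ids=table.sample_ids, taxa=table.taxon_ids, tree=tree)


def weighted_unifrac(table: OtuTable, tree: TreeNode,
                     normalized: bool = False) -> DistanceMatrix:
    """Weighted UniFrac: sum_b l_b |P_b(i) - P_b(j)| over branches.

    ``P_b`` is the relative abundance of the subtree below branch ``b``.
    The default is the raw (non-normalized) variant; ``normalized=True``
    divides by the abundance-weighted tree depth, bounding values in [0, 1].
    """
    check_tree_coverage(table, tree)
    return _skbio_beta("weighted_unifrac", table.counts.T,
                       ids=table.sample_ids, taxa=table.taxon_ids, tree=tree,
                       normalized=normalized)
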