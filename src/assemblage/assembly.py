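"""Community assembly null models and process classification.

The inference proceeds in two steps per sample pair:

1. **Phylogenetic turnover.** betaMNTD is the abundance-weighted mean
   patristic distance from each taxon in one community to its nearest
   relative in the other. betaNTI standardizes the observed betaMNTD against
   a null distribution obtained by shuffling taxon labels across the tips of
   the phylogeny (the regional-pool tip shuffle). |betaNTI| > 2 indicates
   selection: heterogeneous (> +2) or homogeneous (< -2).

2. **Compositional turnover.** For pairs not resolved by selection, the
   Raup-Crick metric on Bray-Curtis dissimilarity (RCbray) compares observed
   turnover with a null that preserves each sample's richness and read total,
   drawing membership with probability proportional to regional occupancy
   and filling abundance proportionally to regional relative abundance.
   RCbray > +0.95 indicates dispersal limitation, < -0.95 homogenizing
   dispersal, and values in between leave the pair "undominated".
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from skbio import TreeNode
from skbio.stats.distance import DistanceMatrix

from .data_model import OtuTable, ValidationError, check_tree_coverage

logger = logging.getLogger("assemblage")

PROCESS_LABELS = [
    "heterogeneous selection",
    "homogeneous selection",
    "dispersal limitation",
    "homogenizing dispersal",
    "undominated",
]


@dataclass
class PairwiseNullResult:
    """Observed statistic + null summary for every sample pair.

    ``observed``, ``null_mean``, ``null_sd`` and ``score`` are square
    symmetric arrays over ``sample_ids``. For betaNTI the score is
    (obs - null mean) / null SD; pairs with null SD = 0 carry NaN and are
    flagged in ``degenerate``. For RCbray the score is the rescaled
    empirical CDF position in [-1, 1].
    """

    sample_ids: list[str]
    statistic_name: str
    observed: np.ndarray
    null_mean: np.ndarray
    null_sd: np.ndarray
    score: np.ndarray
    n_null: int
    seed: int | None = None
    degenerate: np.ndarray = field(default=None, repr=False)

    def score_matrix(self) -> DistanceMatrix:
        """Score as a DistanceMatrix-like DataFrame (may contain NaN)."""
        return pd.DataFrame(self.score, index=self.sample_ids,
                            columns=self.sample_ids)

    def to_long(self) -> pd.DataFrame:
        """Long format: one row per unordered sample pair."""
        rows = []
        n = len(self.sample_ids)
        for i in range(n):
            for j in range(i + 1, n):
                rows.append({
                    "sample_i": self.sample_ids[i],
                    "sample_j": self.sample_ids[j],
                    "observed": self.observed[i, j],
                    "null_mean": self.null_mean[i, j],
                    "null_sd": self.null_sd[i, j],
                    self.statistic_name: self.score[i, j],
                })
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# betaMNTD / betaNTI
# ---------------------------------------------------------------------------

def patristic_distances(tree: TreeNode, taxon_ids: list[str]) -> np.ndarray:
    """Tip-to-tip patristic distance matrix ordered like ``taxon_ids``."""
    dm = tree.tip_tip_distances(endpoints=list(taxon_ids))
    return dm.filter(list(taxon_ids)).data


def _abundance_weights(table: OtuTable, weighted: bool) -> np.ndarray:
    """Taxon weight matrix F (taxa x samples): relative abundance or 1/richness."""
    totals = table.sample_totals()
    if (totals == 0).any():
        zero = table.sample_ids[int(np.argmax(totals == 0))]
        raise ValidationError(f"sample {zero!r} is empty")
    if weighted:
        return table.counts / totals.astype(float)
    presence = (table.counts > 0)
    richness = presence.sum(axis=0).astype(float)
    return presence / richness


def _bmntd_from_dmin(F: np.ndarray, dmin: np.ndarray) -> np.ndarray:
    """betaMNTD for all pairs given per-sample nearest-taxon distances.

    ``dmin[k, j]`` = distance from taxon k to its nearest taxon present in
    sample j. Returns the symmetric n x n matrix
    0.5 * (sum_k F[k,i] dmin[k,j] + sum_k F[k,j] dmin[k,i]).
    """
    M = F.T @ dmin
    return 0.5 * (M + M.T)


def _dmin_matrix(D: np.ndarray, present: list[np.ndarray]) -> np.ndarray:
    """dmin[k, j] = min over taxa present in sample j of D[k, l]."""
    n_taxa = D.shape[0]
    dmin = np.empty((n_taxa, len(present)))
    for j, idx in enumerate(present):
        dmin[:, j] = D[:, idx].min(axis=1)
    return dmin


def beta_mntd(table: OtuTable, tree: TreeNode,
              weighted: bool = True) -> DistanceMatrix:
    """Between-community mean nearest taxon distance (betaMNTD)."""
    check_tree_coverage(table, tree)
    D = patristic_distances(tree, table.taxon_ids)
    F = _abundance_weights(table, weighted)
    present = [np.flatnonzero(table.counts[:, j] > 0)
               for j in range(table.n_samples)]
    bm = _bmntd_from_dmin(F, _dmin_matrix(D, present))
    bm = (bm + bm.T) / 2
    np.fill_diagonal(bm, 0.0)
    return DistanceMatrix(bm, ids=table.sample_ids)


def beta_nti(table: OtuTable, tree: TreeNode, weighted: bool = True,
             n_null: int = 999, seed=None) -> PairwiseNullResult:
    """betaNTI: standardized betaMNTD under tip-shuffle nulls.

    Each null replicate permutes the taxon-to-tip assignment across the whole
    regional pool (every taxon in the table); the same shuffle is reused for
    all sample pairs within a replicate. betaNTI = (obs - null mean) / null
    SD; pairs with a zero null SD are reported as NaN and flagged.
    """
    if n_null < 99:
        raise ValueError(f"n_null must be >= 99, got {n_null}")
    check_tree_coverage(table, tree)
    D = patristic_distances(tree, table.taxon_ids)
    F = _abundance_weights(table, weighted)
    present = [np.flatnonzero(table.counts[:, j] > 0)
               for j in range(table.n_samples)]
    obs = _bmntd_from_dmin(F, _dmin_matrix(D, present))

    rng = np.random.default_rng(seed)
    n_taxa = table.n_taxa
    total = np.zeros_like(obs)
    total_sq = np.zeros_like(obs)
    for _ in range(n_null):
        perm = rng.permutation(n_taxa)
        # shuffling tip labels == relabeling the patristic distance matrix
        Dp = D[np.ix_(perm, perm)]
        bm = _bmntd_from_dmin(F, _dmin_matrix(Dp, present))
        total += bm
        total_sq += bm ** 2
    mean = total / n_null
    var = total_sq / n_null - mean ** 2
    sd = np.sqrt(np.clip(var, 0, None))
    degenerate = sd <= 1e-12
    with np.errstate(divide="ignore", invalid="ignore"):
        score = np.where(degenerate, np.nan, (obs - mean) / sd)
    np.fill_diagonal(score, 0.0)
    np.fill_diagonal(degenerate, False)
    if degenerate.any():
        logger.warning("betaNTI: %d pairs with zero null SD flagged",
                       int(degenerate.sum() // 2))
    return PairwiseNullResult(list(table.sample_ids), "bNTI", obs, mean, sd,
                              score, n_null, seed, degenerate)


# ---------------------------------------------------------------------------
# Raup-Crick on Bray-Curtis
# ---------------------------------------------------------------------------

def _null_community_draw(rng, n_taxa: int, richness: int, total: int,
                         p_occ: np.ndarray, p_ab: np.ndarray) -> np.ndarray:
    """One null community preserving richness and total reads."""
    members = rng.choice(n_taxa, size=richness, replace=False, p=p_occ)
    col = np.zeros(n_taxa)
    col[members] = 1.0
    if total > richness:
        w = p_ab[members]
        w_sum = w.sum()
        if w_sum <= 0:
            w = np.full(len(members), 1.0 / len(members))
        else:
            w = w / w_sum
        col[members] += rng.multinomial(total - richness, w)
    return col


def raup_crick_bray(table: OtuTable, n_null: int = 999,
                    seed=None) -> PairwiseNullResult:
    """Raup-Crick metric on Bray-Curtis dissimilarity (RCbray in [-1, 1]).

    Null communities preserve each sample's observed richness and read
    total: membership is drawn without replacement with probability
    proportional to regional occupancy, then the remaining reads are assigned
    by multinomial sampling proportional to regional relative abundance.
    One null community is drawn per sample per replicate and Bray-Curtis is
    evaluated for all pairs within the replicate.
    RCbray = 2 * [#(null < obs) + 0.5 #(null = obs)] / n_null - 1.
    """
    if n_null < 99:
        raise ValueError(f"n_null must be >= 99, got {n_null}")
    counts = table.counts
    richness = (counts > 0).sum(axis=0)
    if (richness == 0).any():
        zero = table.sample_ids[int(np.argmax(richness == 0))]
        raise ValidationError(f"sample {zero!r} has zero richness")
    totals = table.sample_totals()
    occupancy = (counts > 0).sum(axis=1).astype(float)
    p_occ = occupancy / occupancy.sum()
    regional = counts.sum(axis=1).astype(float)
    p_ab = regional / regional.sum()

    obs_sq = squareform(pdist(counts.T.astype(float), metric="braycurtis"))
    n = table.n_samples
    rng = np.random.default_rng(seed)
    n_taxa = table.n_taxa
    less = np.zeros((n, n))
    equal = np.zeros((n, n))
    null_sum = np.zeros((n, n))
    null_sq = np.zeros((n, n))
    eps = 1e-12
    for _ in range(n_null):
        null = np.empty((n, n_taxa))
        for j in range(n):
            null[j] = _null_community_draw(rng, n_taxa, int(richness[j]),
                                           int(totals[j]), p_occ, p_ab)
        bc = squareform(pdist(null, metric="braycurtis"))
        less += bc < obs_sq - eps
        equal += np.abs(bc - obs_sq) <= eps
        null_sum += bc
        null_sq += bc ** 2
    rc = 2.0 * (less + 0.5 * equal) / n_null - 1.0
    rc = np.clip(rc, -1.0, 1.0)
    np.fill_diagonal(rc, 0.0)
    mean = null_sum / n_null
    var = null_sq / n_null - mean ** 2
    sd = np.sqrt(np.clip(var, 0, None))
    return PairwiseNullResult(list(table.sample_ids), "RCbray", obs_sq, mean,
                              sd, rc, n_null, seed)


# ---------------------------------------------------------------------------
# Process classification
# ---------------------------------------------------------------------------

def classify_pair(bnti: float, rc: float, bnti_threshold: float = 2.0,
                  rc_threshold: float = 0.95) -> str:
    """Five-way process call for one pair from its betaNTI and RCbray."""
    if bnti > bnti_threshold:
        return "heterogeneous selection"
    if bnti < -bnti_threshold:
        return "homogeneous selection"
    if rc > rc_threshold:
        return "dispersal limitation"
    if rc < -rc_threshold:
        return "homogenizing dispersal"
    return "undominated"


def classify_processes(bnti: PairwiseNullResult,
                       rc: PairwiseNullResult,
                       bnti_threshold: float = 2.0,
                       rc_threshold: float = 0.95) -> pd.DataFrame:
    """Per-pair process labels from matched betaNTI and RCbray results.

    Pairs with a missing betaNTI (degenerate null) are excluded and counted
    in the log.
    """
    if bnti.sample_ids != rc.sample_ids:
        raise ValidationError("betaNTI and RCbray cover different samples")
    ids = bnti.sample_ids
    n = len(ids)
    rows = []
    skipped = 0
    for i in range(n):
        for j in range(i + 1, n):
            b = bnti.score[i, j]
            r = rc.score[i, j]
            if not np.isfinite(b):
                skipped += 1
                continue
            rows.append({"sample_i": ids[i], "sample_j": ids[j],
                         "bNTI": b, "RCbray": r,
                         "process": classify_pair(b, r, bnti_threshold,
                                                  rc_threshold)})
    if skipped:
        logger.warning("classify_processes: skipped %d pairs with missing "
                       "betaNTI", skipped)
    return pd.DataFrame(rows)


def summarize_processes(labels: pd.DataFrame, metadata: pd.DataFrame,
                        month_col: str = "month") -> pd.DataFrame:
    """Per-stratum process percentages.

    Strata are within-month ("May") and between-month pairs ("May-Aug"),
    derived from the month of each sample in the pair. Percentages over the
    five process classes sum to 100 per stratum; empty strata are omitted.
    """
    month = metadata[month_col]
    missing = (set(labels["sample_i"]) | set(labels["sample_j"])) \
        - set(month.index)
    if missing:
        raise ValidationError(f"samples without month labels: "
                              f"{sorted(missing)[:5]}")
    m_i = labels["sample_i"].map(month)
    m_j = labels["sample_j"].map(month)
    strata = np.where(m_i == m_j, m_i,
                      ["-".join(sorted([a, b])) for a, b in zip(m_i, m_j)])
    out = []
    for stratum in pd.unique(strata):
        sub = labels.loc[strata == stratum, "process"]
        n_pairs = len(sub)
        pct = {proc: 100.0 * (sub == proc).sum() / n_pairs
               for proc in PROCESS_LABELS}
        out.append({"stratum": stratum, "n_pairs": n_pairs, **pct})
    return pd.DataFrame(out).set_index("stratum")
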