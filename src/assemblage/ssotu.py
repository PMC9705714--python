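"""Seasonal-specific OTU detection and co-occurrence networks.

ssOTUs are taxa flagged independently by two tests that must agree on the
season: a correlation-based indicator analysis (point-biserial r with a
permutation p-value) and a negative-binomial GLM likelihood-ratio test
(BH-adjusted) on TMM-normalized counts. The co-occurrence network links OTUs
with Spearman rho > 0.7 at p < 0.001, and modules come from greedy
modularity optimization; module cumulative abundance is regressed on
environmental variables by OLS.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

from .data_model import OtuTable, ValidationError

logger = logging.getLogger("assemblage")


# ---------------------------------------------------------------------------
# TMM normalization and CPM
# ---------------------------------------------------------------------------

def tmm_factors(table: OtuTable, logratio_trim: float = 0.3,
                sum_trim: float = 0.05) -> pd.Series:
    """Trimmed-mean-of-M normalization factors (geometric mean 1).

    The reference is the sample whose 75th-percentile count fraction is
    closest to the mean across samples. Per sample, log2 ratios (M) and
    average log2 abundances (A) against the reference are computed over taxa
    present in both; M is trimmed by ``logratio_trim`` and A by ``sum_trim``
    from each tail, and the factor is 2 to the precision-weighted trimmed
    mean of M.
    """
    counts = table.counts.astype(float)
    if table.n_samples < 2:
        raise ValidationError("TMM needs at least 2 samples")
    lib = counts.sum(axis=0)
    q75 = np.array([np.quantile(counts[:, j] / lib[j], 0.75)
                    for j in range(table.n_samples)])
    ref = int(np.argmin(np.abs(q75 - q75.mean())))
    yr, nr = counts[:, ref], lib[ref]
    factors = np.ones(table.n_samples)
    for j in range(table.n_samples):
        if j == ref:
            continue
        y, n = counts[:, j], lib[j]
        both = (y > 0) & (yr > 0)
        if not both.any():
            raise ValidationError(
                f"sample {table.sample_ids[j]!r} shares no taxa with the "
                f"TMM reference")
        p, pr = y[both] / n, yr[both] / nr
        m = np.log2(p / pr)
        a = 0.5 * np.log2(p * pr)
        w = (n - y[both]) / (n * y[both]) + (nr - yr[both]) / (nr * yr[both])
        keep = _double_trim(m, a, logratio_trim, sum_trim)
        if keep.sum() == 0 or np.abs(m[keep]).max() < 1e-6:
            factors[j] = 1.0
            continue
        inv_w = 1.0 / w[keep]
        factors[j] = 2.0 ** (np.sum(m[keep] * inv_w) / np.sum(inv_w))
    factors /= np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=table.sample_ids, name="tmm_factor")


def _double_trim(m: np.ndarray, a: np.ndarray, m_trim: float,
                 a_trim: float) -> np.ndarray:
    n = len(m)
    rank_m = stats.rankdata(m)
    rank_a = stats.rankdata(a)
    keep_m = (rank_m > n * m_trim) & (rank_m <= n * (1 - m_trim))
    keep_a = (rank_a > n * a_trim) & (rank_a <= n * (1 - a_trim))
    return keep_m & keep_a


def cpm(table: OtuTable, factors: pd.Series | None = None) -> pd.DataFrame:
    """Counts per million over the effective (TMM-scaled) library size."""
    counts = table.counts.astype(float)
    lib = counts.sum(axis=0)
    if factors is None:
        f = np.ones(table.n_samples)
    else:
        f = factors.loc[table.sample_ids].to_numpy(float)
    eff = lib * f
    if (eff <= 0).any():
        raise ValidationError("zero effective library size")
    return pd.DataFrame(counts / eff * 1e6, index=table.taxon_ids,
                        columns=table.sample_ids)


# ---------------------------------------------------------------------------
# Negative-binomial likelihood-ratio test
# ---------------------------------------------------------------------------

def _nb_loglik(y: np.ndarray, mu: np.ndarray, alpha: float) -> np.ndarray:
    """NB2 log-likelihood per observation (size r = 1/alpha)."""
    r = 1.0 / alpha
    mu = np.clip(mu, 1e-10, None)
    return (gammaln(y + r) - gammaln(r) - gammaln(y + 1)
            + r * np.log(r / (r + mu)) + y * np.log(mu / (r + mu)))


def _fit_group_means(Y: np.ndarray, offsets: np.ndarray, groups: np.ndarray,
                     alpha: float, max_iter: int = 50):
    """Per-OTU, per-group NB mean fit with log link and fixed dispersion.

    Returns (loglik per OTU, beta per OTU x group, Fisher info per OTU x group).
    ``Y`` is OTUs x samples; ``offsets`` = effective library sizes.
    """
    labels = np.unique(groups)
    n_otu = Y.shape[0]
    ll = np.zeros(n_otu)
    betas = np.zeros((n_otu, len(labels)))
    infos = np.zeros((n_otu, len(labels)))
    r = 1.0 / alpha
    for gi, lab in enumerate(labels):
        cols = groups == lab
        y = Y[:, cols]
        s = offsets[cols]
        # Newton iteration on the group log-mean, vectorized over OTUs
        b = np.log(np.clip(y.sum(axis=1), 0.5, None) / s.sum())
        for _ in range(max_iter):
            mu = s[None, :] * np.exp(b)[:, None]
            score = ((y - mu) * r / (r + mu)).sum(axis=1)
            info = (r * mu * (r + y) / (r + mu) ** 2).sum(axis=1)
            step = score / np.clip(info, 1e-12, None)
            step = np.clip(step, -5, 5)
            b = b + step
            if np.abs(step).max() < 1e-10:
                break
        mu = s[None, :] * np.exp(b)[:, None]
        ll += _nb_loglik(y, mu, alpha).sum(axis=1)
        betas[:, gi] = b
        # Fisher working weights for the Cox-Reid adjustment
        infos[:, gi] = (mu / (1 + alpha * mu)).sum(axis=1)
    return ll, betas, infos, labels


def estimate_common_dispersion(Y: np.ndarray, offsets: np.ndarray,
                               groups: np.ndarray) -> float:
    """Common NB dispersion by adjusted profile likelihood across OTUs.

    Maximizes sum over OTUs of [group-model log-likelihood minus the
    Cox-Reid adjustment 0.5 log det(X'WX)] over the dispersion alpha.
    """
    from scipy.optimize import minimize_scalar

    def neg_apl(log_alpha: float) -> float:
        alpha = float(np.exp(log_alpha))
        ll, _, infos, _ = _fit_group_means(Y, offsets, groups, alpha)
        cr = 0.5 * np.log(np.clip(infos, 1e-12, None)).sum(axis=1)
        return -(ll - cr).sum()

    res = minimize_scalar(neg_apl, bounds=(np.log(1e-4), np.log(10.0)),
                          method="bounded",
                          options={"xatol": 1e-3})
    return float(np.exp(res.x))


def nb_lrt(table: OtuTable, grouping, factors: pd.Series | None = None,
           dispersion: str | float = "common") -> pd.DataFrame:
    """Per-OTU negative-binomial likelihood-ratio test for a group effect.

    Full model: one mean per group (log link, offset = log effective library
    size); reduced model: a single intercept. LRT = 2 (ll_full - ll_reduced)
    with a chi-square reference on (groups - 1) df; BH adjustment across
    OTUs. ``dispersion`` is "common" (adjusted-profile-likelihood estimate
    shared across OTUs, the default), "per-otu" (per-OTU MLE), or a fixed
    float. All-zero OTUs are excluded with a note.
    """
    g = _grouping_for_table(table, grouping)
    labels, counts_per = np.unique(g, return_counts=True)
    if len(labels) < 2 or (counts_per < 2).any():
        raise ValidationError("need >= 2 groups with >= 2 samples each")
    lib = table.sample_totals().astype(float)
    f = (factors.loc[table.sample_ids].to_numpy(float)
         if factors is not None else np.ones(table.n_samples))
    offsets = lib * f

    nonzero = table.taxon_totals() > 0
    if (~nonzero).any():
        logger.info("nb_lrt: excluded %d all-zero OTUs", int((~nonzero).sum()))
    Y = table.counts[nonzero].astype(float)
    otus = [t for t, k in zip(table.taxon_ids, nonzero) if k]

    if dispersion == "common":
        alpha = estimate_common_dispersion(Y, offsets, g)
        alphas = np.full(len(otus), alpha)
    elif dispersion == "per-otu":
        alphas = np.array([_per_otu_alpha(Y[i:i + 1], offsets, g)
                           for i in range(len(otus))])
    else:
        alphas = np.full(len(otus), float(dispersion))

    df = len(labels) - 1
    rows = []
    # group alphas to reuse the vectorized fitter
    for alpha in np.unique(alphas):
        mask = alphas == alpha
        Ys = Y[mask]
        ll_full, betas, _, labs = _fit_group_means(Ys, offsets, g, alpha)
        ll_red, _, _, _ = _fit_group_means(Ys, offsets,
                                           np.zeros(len(g), dtype=int), alpha)
        lrt = np.clip(2.0 * (ll_full - ll_red), 0.0, None)
        pvals = stats.chi2.sf(lrt, df)
        best = labs[np.argmax(betas, axis=1)]
        for i, otu in enumerate(np.array(otus)[mask]):
            rows.append({"otu": otu, "lrt": lrt[i], "p": pvals[i],
                         "max_group": best[i], "dispersion": alpha})
    out = pd.DataFrame(rows).set_index("otu").loc[otus]
    from statsmodels.stats.multitest import multipletests
    out["p_adj"] = multipletests(out["p"].to_numpy(), method="fdr_bh")[1]
    return out


def _per_otu_alpha(y_row: np.ndarray, offsets: np.ndarray,
                   groups: np.ndarray) -> float:
    from scipy.optimize import minimize_scalar

    def neg_ll(log_alpha):
        alpha = float(np.exp(log_alpha))
        ll, _, _, _ = _fit_group_means(y_row, offsets, groups, alpha)
        return -ll.sum()

    res = minimize_scalar(neg_ll, bounds=(np.log(1e-4), np.log(10.0)),
                          method="bounded", options={"xatol": 1e-3})
    return float(np.exp(res.x))


def _grouping_for_table(table: OtuTable, grouping) -> np.ndarray:
    if isinstance(grouping, pd.Series):
        return grouping.loc[table.sample_ids].to_numpy()
    g = np.asarray(grouping)
    if len(g) != table.n_samples:
        raise ValidationError("grouping length does not match table samples")
    return g


# ---------------------------------------------------------------------------
# Indicator analysis
# ---------------------------------------------------------------------------

def indicator_analysis(abundance: pd.DataFrame, grouping, n_perm: int = 999,
                       seed=None) -> pd.DataFrame:
    """Point-biserial indicator analysis (multipatt-style, single groups).

    ``abundance`` is OTUs x samples (e.g. CPM). Per OTU the point-biserial
    correlation with each group's membership indicator is computed; the best
    group is the argmax. The permutation p-value compares the observed best
    correlation with the max-over-groups statistic under label shuffles.
    Constant OTUs are excluded.
    """
    if isinstance(grouping, pd.Series):
        g = grouping.loc[abundance.columns].to_numpy()
    else:
        g = np.asarray(grouping)
    labels = np.unique(g)
    if len(labels) < 2:
        raise ValidationError("need at least 2 groups")
    X = abundance.to_numpy(float)
    keep = X.std(axis=1) > 0
    if (~keep).any():
        logger.info("indicator_analysis: excluded %d constant OTUs",
                    int((~keep).sum()))
    X = X[keep]
    otus = abundance.index[keep]
    Xs = _standardize_rows(X)
    Z = np.column_stack([(g == lab).astype(float) for lab in labels])
    n = len(g)

    def corr(Zm: np.ndarray) -> np.ndarray:
        Zs = (Zm - Zm.mean(axis=0)) / Zm.std(axis=0)
        return Xs @ Zs / n

    R = corr(Z)
    best_idx = np.argmax(R, axis=1)
    best_r = R[np.arange(len(otus)), best_idx]
    # season-assignment ties (two groups at the max) are flagged
    sorted_r = np.sort(R, axis=1)
    tied = np.isclose(sorted_r[:, -1], sorted_r[:, -2])

    rng = np.random.default_rng(seed)
    exceed = np.zeros(len(otus))
    for _ in range(n_perm):
        Rp = corr(Z[rng.permutation(n)])
        exceed += Rp.max(axis=1) >= best_r
    p = (exceed + 1) / (n_perm + 1)
    return pd.DataFrame(
        {"r": best_r, "best_group": labels[best_idx], "p": p, "tied": tied},
        index=pd.Index(otus, name="otu"),
    )


def _standardize_rows(X: np.ndarray) -> np.ndarray:
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, keepdims=True)
    return (X - mu) / sd


# ---------------------------------------------------------------------------
# ssOTU calling
# ---------------------------------------------------------------------------

def call_ssotus(indicator: pd.DataFrame, lrt: pd.DataFrame,
                alpha_ind: float = 0.05,
                alpha_lrt: float = 0.05) -> pd.DataFrame:
    """Intersect indicator and NB-LRT calls into the ssOTU table.

    An OTU is an ssOTU iff the indicator permutation p <= ``alpha_ind``, the
    BH-adjusted LRT p <= ``alpha_lrt``, the two tests assign the same season,
    and the indicator best group is untied. Disagreements are logged.
    """
    merged = indicator.join(lrt, how="inner", lsuffix="_ind", rsuffix="_lrt")
    sig = ((merged["p_ind"] <= alpha_ind)
           & (merged["p_adj"] <= alpha_lrt)
           & ~merged["tied"])
    agree = merged["best_group"] == merged["max_group"]
    n_disagree = int((sig & ~agree).sum())
    if n_disagree:
        logger.info("call_ssotus: %d significant OTUs rejected for "
                    "disagreeing season assignments", n_disagree)
    merged["is_ssotu"] = sig & agree
    merged["season"] = merged["best_group"].where(merged["is_ssotu"])
    if not merged["is_ssotu"].any():
        logger.warning("call_ssotus: empty ssOTU set")
    return merged[["r", "p_ind", "best_group", "lrt", "p_lrt", "p_adj",
                   "max_group", "is_ssotu", "season"]]


# ---------------------------------------------------------------------------
# Co-occurrence network and modules
# ---------------------------------------------------------------------------

@dataclass
class CooccurrenceNetwork:
    graph: nx.Graph
    edges: pd.DataFrame
    modules: pd.Series | None = None
    modularity: float | None = None
    params: dict = field(default_factory=dict)


def build_network(abundance: pd.DataFrame, rho_min: float = 0.7,
                  p_max: float = 0.001) -> CooccurrenceNetwork:
    """Spearman co-occurrence network over OTUs.

    Edge iff rho > ``rho_min`` (strict; only positive associations) AND the
    two-tailed p-value (t approximation, mid-rank ties) < ``p_max`` (strict).
    Isolated nodes are retained.
    """
    if abundance.shape[1] < 3:
        raise ValidationError("need at least 3 samples for Spearman p-values")
    otus = list(abundance.index)
    rho, p = stats.spearmanr(abundance.to_numpy(float), axis=1)
    if np.ndim(rho) == 0:  # scipy returns scalars for exactly two variables
        rho = np.array([[1.0, rho], [rho, 1.0]])
        p = np.array([[0.0, p], [p, 0.0]])
    G = nx.Graph()
    G.add_nodes_from(otus)
    rows = []
    n = len(otus)
    for i in range(n):
        for j in range(i + 1, n):
            if rho[i, j] > rho_min and p[i, j] < p_max:
                G.add_edge(otus[i], otus[j], rho=float(rho[i, j]),
                           p=float(p[i, j]))
                rows.append({"otu_i": otus[i], "otu_j": otus[j],
                             "rho": rho[i, j], "p": p[i, j]})
    edges = pd.DataFrame(rows, columns=["otu_i", "otu_j", "rho", "p"])
    return CooccurrenceNetwork(G, edges,
                               params={"rho_min": rho_min, "p_max": p_max})


def detect_modules(network: CooccurrenceNetwork) -> CooccurrenceNetwork:
    """Greedy modularity modules on the unweighted edge set.

    Nodes are processed in sorted-id order so ties break deterministically.
    An edgeless network puts every node in its own module with Q = 0.
    Module ids are assigned by decreasing module size.
    """
    G = nx.Graph()
    G.add_nodes_from(sorted(network.graph.nodes))
    G.add_edges_from(sorted(map(tuple, map(sorted, network.graph.edges))))
    if G.number_of_edges() == 0:
        modules = pd.Series({node: i for i, node in enumerate(sorted(G))},
                            name="module")
        network.modules, network.modularity = modules, 0.0
        return network
    communities = nx.community.greedy_modularity_communities(G)
    communities = sorted((sorted(c) for c in communities),
                         key=lambda c: (-len(c), c[0]))
    q = nx.community.modularity(G, communities)
    assign = {}
    for mid, members in enumerate(communities):
        for node in members:
            assign[node] = mid
    network.modules = pd.Series(assign, name="module").sort_index()
    network.modularity = float(q)
    return network


def module_env_regression(network: CooccurrenceNetwork,
                          abundance: pd.DataFrame, metadata: pd.DataFrame,
                          variables: list[str],
                          min_module_size: int = 2) -> pd.DataFrame:
    """OLS of module cumulative abundance on each environmental variable.

    Per module x variable: slope, R-squared and the two-tailed p-value on
    the slope. Constant variables are skipped.
    """
    if network.modules is None:
        raise ValidationError("run detect_modules first")
    meta = metadata.loc[abundance.columns]
    rows = []
    for mid in sorted(network.modules.unique()):
        members = network.modules.index[network.modules == mid]
        members = [m for m in members if m in abundance.index]
        if len(members) < min_module_size:
            continue
        total = abundance.loc[members].sum(axis=0).to_numpy(float)
        for var in variables:
            y = meta[var].to_numpy(float)
            if np.std(y) == 0:
                continue
            res = stats.linregress(y, total)
            rows.append({"module": mid, "variable": var,
                         "slope": res.slope, "r2": res.rvalue ** 2,
                         "p": res.pvalue, "n_otus": len(members)})
    return pd.DataFrame(rows)


def write_graphml(network: CooccurrenceNetwork, path) -> None:
    G = network.graph.copy()
    if network.modules is not None:
        nx.set_node_attributes(G, network.modules.to_dict(), "module")
    nx.write_graphml(G, str(path))
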