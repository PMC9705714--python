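"""Ordination and permutation inference on distance matrices.

PCA of environmental variables, PCoA, ANOSIM, PERMANOVA, simple/partial
Mantel tests, PCNM spatial eigenfunctions, forward selection on db-RDA,
variance partitioning (env / linear trend / PCNM), per-group significance
letters and alpha-diversity ~ environment correlations.

All permutation engines take an explicit ``seed`` and report
``p = (# permuted >= observed + 1) / (n_perm + 1)``, so p-values are bounded
below by ``1/(n_perm+1)``. Mantel-family tests are one-tailed for positive
association by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import squareform
from scipy.stats import rankdata
from skbio.stats.distance import DistanceMatrix

from .data_model import ValidationError


# ---------------------------------------------------------------------------
# Result containers
# ---------------------------------------------------------------------------

@dataclass
class OrdinationResult:
    """Sample coordinates + eigenvalues from PCA or PCoA."""

    coordinates: pd.DataFrame            # samples x axes
    eigenvalues: np.ndarray              # sorted descending
    proportion_explained: np.ndarray
    loadings: pd.DataFrame | None = None  # variables x axes (PCA only)
    negative_eigenvalues: np.ndarray = field(
        default_factory=lambda: np.array([]))


@dataclass
class PermutationTestResult:
    statistic_name: str
    statistic: float
    n_perm: int
    p_value: float
    seed: int | None = None
    extra: dict = field(default_factory=dict)


@dataclass
class VpaResult:
    """Adjusted-R2 variance partitioning over three explanatory sets.

    ``fractions`` holds the raw algebraic decomposition (pure env/trend/pcnm,
    pairwise joints, triple joint, residual); negative values are retained.
    ``displayed`` truncates negatives to 0 (the raw value is what sums
    exactly). ``set_p_values`` are conditional Monte-Carlo p-values per set,
    testing each set with the others partialled out.
    """

    fractions: dict
    displayed: dict
    set_p_values: dict
    selected: dict
    full_adj_r2: float
    testable: bool
    n_perm: int
    seed: int | None = None


# ---------------------------------------------------------------------------
# Ordination
# ---------------------------------------------------------------------------

def pca_environment(metadata: pd.DataFrame,
                    variables: list[str]) -> OrdinationResult:
    """PCA on the correlation matrix of z-scored environmental variables."""
    X = metadata[variables].to_numpy(float)
    if X.shape[0] < 3:
        raise ValidationError("PCA needs at least 3 samples")
    sd = X.std(axis=0, ddof=1)
    if (sd == 0).any():
        raise ValidationError(
            f"constant variable {variables[int(np.argmax(sd == 0))]!r}")
    Z = (X - X.mean(axis=0)) / sd
    corr = np.corrcoef(Z, rowvar=False)
    evals, evecs = np.linalg.eigh(corr)
    order = np.argsort(evals)[::-1]
    evals, evecs = np.clip(evals[order], 0, None), evecs[:, order]
    scores = Z @ evecs
    axes = [f"PC{i+1}" for i in range(len(evals))]
    return OrdinationResult(
        coordinates=pd.DataFrame(scores, index=metadata.index, columns=axes),
        eigenvalues=evals,
        proportion_explained=evals / evals.sum(),
        loadings=pd.DataFrame(evecs, index=variables, columns=axes),
    )


def pcoa(dm: DistanceMatrix) -> OrdinationResult:
    """Principal coordinates analysis (Gower centering + eigendecomposition).

    Negative eigenvalues are reported separately, never silently corrected.
    """
    coords, pos, neg = _pcoa_decompose(dm.data)
    axes = [f"PCo{i+1}" for i in range(coords.shape[1])]
    denom = pos.sum() + np.abs(neg).sum()
    return OrdinationResult(
        coordinates=pd.DataFrame(coords, index=list(dm.ids), columns=axes),
        eigenvalues=pos,
        proportion_explained=pos / denom if denom > 0 else pos,
        negative_eigenvalues=neg,
    )


def _pcoa_decompose(d: np.ndarray):
    """Return (coordinates for positive eigenvalues, pos eigvals, neg eigvals)."""
    n = d.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (d ** 2) @ J
    B = (B + B.T) / 2
    evals, evecs = np.linalg.eigh(B)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    tol = max(np.abs(evals).max(), 1.0) * 1e-10
    pos_mask = evals > tol
    neg = evals[evals < -tol]
    pos = evals[pos_mask]
    coords = evecs[:, pos_mask] * np.sqrt(pos)
    return coords, pos, neg


def pcoa_embedding(dm: DistanceMatrix) -> np.ndarray:
    """Sample coordinates on the positive-eigenvalue PCoA axes.

    This is the response matrix used by distance-based RDA; negative
    eigenvalues are discarded (their count is available via :func:`pcoa`).
    """
    coords, _, _ = _pcoa_decompose(dm.data)
    return coords


# ---------------------------------------------------------------------------
# ANOSIM / PERMANOVA
# ---------------------------------------------------------------------------

def _check_grouping(grouping: np.ndarray, min_per_group: int = 2) -> None:
    labels, counts = np.unique(grouping, return_counts=True)
    if len(labels) < 2:
        raise ValidationError("need at least 2 groups")
    if (counts < min_per_group).any():
        small = labels[counts < min_per_group][0]
        raise ValidationError(f"group {small!r} has fewer than "
                              f"{min_per_group} samples")


def anosim(dm: DistanceMatrix, grouping, n_perm: int = 999,
           seed=None) -> PermutationTestResult:
    """ANOSIM R = (mean between-group rank - mean within-group rank) / (n(n-1)/4)."""
    g = _grouping_array(dm, grouping)
    _check_grouping(g)
    n = len(g)
    ranks = rankdata(squareform(dm.data, checks=False))
    iu, ju = np.triu_indices(n, k=1)
    denom = n * (n - 1) / 4.0

    def stat(labels):
        within = labels[iu] == labels[ju]
        return (ranks[~within].mean() - ranks[within].mean()) / denom

    obs = stat(g)
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        exceed += stat(rng.permutation(g)) >= obs
    p = (exceed + 1) / (n_perm + 1)
    return PermutationTestResult("ANOSIM R", float(obs), n_perm, float(p),
                                 seed)


def permanova(dm: DistanceMatrix, grouping, n_perm: int = 999,
              seed=None) -> PermutationTestResult:
    """PERMANOVA pseudo-F from among/within sums of squared distances.

    Returns F as the statistic with ``R2 = SS_among / SS_total`` in ``extra``.
    """
    g = _grouping_array(dm, grouping)
    _check_grouping(g)
    n = len(g)
    d2 = dm.data.astype(float) ** 2
    ss_total = d2[np.triu_indices(n, k=1)].sum() / n
    labels = np.unique(g)
    a = len(labels)

    def ss_within(gv):
        ssw = 0.0
        for lab in labels:
            mask = gv == lab
            ng = mask.sum()
            if ng > 1:
                sub = d2[np.ix_(mask, mask)]
                ssw += sub[np.triu_indices(ng, k=1)].sum() / ng
        return ssw

    def f_stat(gv):
        ssw = ss_within(gv)
        ssa = ss_total - ssw
        if ssw <= 0:
            return np.inf, ssa
        return (ssa / (a - 1)) / (ssw / (n - a)), ssa

    obs_f, obs_ssa = f_stat(g)
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        f_p, _ = f_stat(rng.permutation(g))
        exceed += f_p >= obs_f
    p = (exceed + 1) / (n_perm + 1)
    return PermutationTestResult(
        "PERMANOVA pseudo-F", float(obs_f), n_perm, float(p), seed,
        extra={"R2": float(obs_ssa / ss_total) if ss_total > 0 else 0.0},
    )


def _grouping_array(dm: DistanceMatrix, grouping) -> np.ndarray:
    if isinstance(grouping, pd.Series):
        return grouping.loc[list(dm.ids)].to_numpy()
    g = np.asarray(grouping)
    if len(g) != len(dm.ids):
        raise ValidationError("grouping length does not match distance matrix")
    return g


# ---------------------------------------------------------------------------
# Mantel tests
# ---------------------------------------------------------------------------

def _aligned_square(d1: DistanceMatrix, d2: DistanceMatrix) -> np.ndarray:
    if set(d1.ids) != set(d2.ids):
        raise ValidationError("distance matrices have mismatched ids")
    return d2.filter(list(d1.ids)).data


def _rank_square(sq: np.ndarray) -> np.ndarray:
    """Rank-transform the off-diagonal entries, keeping the square layout."""
    cond = rankdata(squareform(sq, checks=False))
    out = squareform(cond)
    return out


def _pearson_condensed(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc ** 2).sum() * (yc ** 2).sum())
    if denom == 0:
        return np.nan
    return float((xc * yc).sum() / denom)


def mantel(d1: DistanceMatrix, d2: DistanceMatrix,
           method: str = "spearman", n_perm: int = 999, seed=None,
           alternative: str = "greater") -> PermutationTestResult:
    """Mantel correlation between two distance matrices.

    ``method='spearman'`` rank-transforms the off-diagonal entries first.
    Permutation shuffles rows/columns of ``d2`` simultaneously; the default
    alternative is one-tailed positive.
    """
    if len(d1.ids) < 4:
        raise ValidationError("Mantel test needs at least 4 samples")
    x_sq = d1.data.astype(float)
    y_sq = _aligned_square(d1, d2).astype(float)
    if method == "spearman":
        x_sq, y_sq = _rank_square(x_sq), _rank_square(y_sq)
    elif method != "pearson":
        raise ValueError(f"unknown method {method!r}")
    x = squareform(x_sq, checks=False)
    obs = _pearson_condensed(x, squareform(y_sq, checks=False))
    rng = np.random.default_rng(seed)
    n = x_sq.shape[0]
    exceed = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        r = _pearson_condensed(
            x, squareform(y_sq[np.ix_(perm, perm)], checks=False))
        exceed += _tail_exceeds(r, obs, alternative)
    p = (exceed + 1) / (n_perm + 1)
    return PermutationTestResult(f"Mantel r ({method})", obs, n_perm,
                                 float(p), seed)


def _tail_exceeds(r_perm: float, r_obs: float, alternative: str) -> bool:
    if alternative == "greater":
        return r_perm >= r_obs
    if alternative == "two-sided":
        return abs(r_perm) >= abs(r_obs)
    raise ValueError(f"unknown alternative {alternative!r}")


def _partial_r(r12: float, r13: float, r23: float) -> float:
    denom = np.sqrt(max((1 - r13 ** 2) * (1 - r23 ** 2), 0.0))
    num = r12 - r13 * r23
    if denom < 1e-12:
        if abs(num) < 1e-10:
            # d2 coincides with the control: nothing left to correlate
            return 0.0
        raise ValidationError("degenerate partial correlation: |r| = 1 "
                              "between a matrix and the control")
    return num / denom


def partial_mantel(d1: DistanceMatrix, d2: DistanceMatrix,
                   d_control: DistanceMatrix, method: str = "spearman",
                   n_perm: int = 999, seed=None,
                   alternative: str = "greater") -> PermutationTestResult:
    """Partial Mantel r(d1, d2 | d_control), permuting ``d2``."""
    if len(d1.ids) < 4:
        raise ValidationError("partial Mantel test needs at least 4 samples")
    x_sq = d1.data.astype(float)
    y_sq = _aligned_square(d1, d2).astype(float)
    z_sq = _aligned_square(d1, d_control).astype(float)
    if method == "spearman":
        x_sq, y_sq, z_sq = (_rank_square(m) for m in (x_sq, y_sq, z_sq))
    elif method != "pearson":
        raise ValueError(f"unknown method {method!r}")
    x = squareform(x_sq, checks=False)
    z = squareform(z_sq, checks=False)
    r13 = _pearson_condensed(x, z)

    def partial_stat(y_square):
        y = squareform(y_square, checks=False)
        r12 = _pearson_condensed(x, y)
        r23 = _pearson_condensed(y, z)
        return _partial_r(r12, r13, r23)

    obs = partial_stat(y_sq)
    rng = np.random.default_rng(seed)
    n = x_sq.shape[0]
    exceed = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        exceed += _tail_exceeds(partial_stat(y_sq[np.ix_(perm, perm)]),
                                obs, alternative)
    p = (exceed + 1) / (n_perm + 1)
    return PermutationTestResult(f"partial Mantel r ({method})", float(obs),
                                 n_perm, float(p), seed)


def temporal_control_matrix(metadata: pd.DataFrame,
                            month_col: str = "month") -> DistanceMatrix:
    """Binary temporal distance: 0 = same sampling month, 1 = different."""
    if metadata[month_col].isna().any():
        bad = metadata.index[metadata[month_col].isna()][0]
        raise ValidationError(f"missing month label for sample {bad!r}")
    months = metadata[month_col].to_numpy()
    d = (months[:, None] != months[None, :]).astype(float)
    return DistanceMatrix(d, ids=list(map(str, metadata.index)))


# ---------------------------------------------------------------------------
# PCNM
# ---------------------------------------------------------------------------

def pcnm_vectors(geo: DistanceMatrix) -> pd.DataFrame:
    """Spatial eigenfunctions from a truncated geographic distance matrix.

    Distances above the truncation threshold ``t`` (the largest edge of the
    minimum spanning tree) are replaced by ``4t``; the positive-eigenvalue
    PCoA axes of the truncated matrix are returned as predictors.
    """
    from scipy.sparse.csgraph import minimum_spanning_tree

    d = geo.data.astype(float)
    if np.allclose(d, 0):
        raise ValidationError("all samples at one location; PCNM undefined")
    mst = minimum_spanning_tree(d).toarray()
    t = mst[mst > 0].max()
    d_trunc = np.where(d > t, 4 * t, d)
    np.fill_diagonal(d_trunc, 0.0)
    coords, _, _ = _pcoa_decompose(d_trunc)
    cols = [f"PCNM{i+1}" for i in range(coords.shape[1])]
    return pd.DataFrame(coords, index=list(geo.ids), columns=cols)


# ---------------------------------------------------------------------------
# db-RDA, forward selection, variance partitioning
# ---------------------------------------------------------------------------

def _as_response(response) -> np.ndarray:
    if isinstance(response, DistanceMatrix):
        return pcoa_embedding(response)
    return np.asarray(response, dtype=float)


def _rda_r2(Y: np.ndarray, X: np.ndarray) -> tuple[float, int]:
    """R2 of the multivariate regression of centered Y on centered X.

    Returns (R2, rank of centered X)."""
    Yc = Y - Y.mean(axis=0)
    Xc = X - X.mean(axis=0)
    sst = (Yc ** 2).sum()
    if sst == 0:
        raise ValidationError("response has zero variance")
    if Xc.size == 0:
        return 0.0, 0
    beta, _, rank, _ = np.linalg.lstsq(Xc, Yc, rcond=None)
    fitted = Xc @ beta
    return float((fitted ** 2).sum() / sst), int(rank)


def adjusted_r2(r2: float, n: int, p: int) -> float:
    """Ezekiel adjustment: 1 - (1 - R2)(n - 1)/(n - 1 - p)."""
    if n - 1 - p <= 0:
        raise ValidationError(f"{p} predictors with only {n} samples")
    return 1 - (1 - r2) * (n - 1) / (n - 1 - p)


@dataclass
class ForwardSelectionResult:
    selected: list[str]
    adj_r2_path: list[float]
    p_values: list[float]
    global_adj_r2: float
    global_p: float = np.nan


def forward_select(response, candidates: pd.DataFrame, alpha: float = 0.05,
                   n_perm: int = 999, seed=None) -> ForwardSelectionResult:
    """Double-stopping forward selection on distance-based RDA.

    The model with every candidate is tested first by free permutation of the
    response rows; if it is not significant at ``alpha`` nothing is selected.
    Otherwise candidates enter one at a time by largest R2 gain, each gated by
    a permutation test of its partial F (p <= ``alpha``) and by the global
    ceiling: the cumulative adjusted R2 may not exceed the full-candidate
    model's adjusted R2 (differences within 10% of the global residual
    fraction are treated as ties, since the Ezekiel adjustment of noise
    predictors is zero-mean random at that scale). An empty selection is a
    legal outcome.
    """
    Y = _as_response(response)
    n = Y.shape[0]
    if candidates.shape[0] != n:
        raise ValidationError("candidate rows do not match response samples")
    X_all = candidates.to_numpy(float)
    r2_all, rank_all = _rda_r2(Y, X_all)
    global_adj = adjusted_r2(r2_all, n, rank_all)
    rng = np.random.default_rng(seed)

    # global pre-test: select nothing when the full model is not significant
    f_global = _partial_f(Y, 0.0, r2_all, 0, rank_all, n)
    exceed = 0
    for _ in range(n_perm):
        Yp = Y[rng.permutation(n)]
        r2p, rkp = _rda_r2(Yp, X_all)
        exceed += _partial_f(Yp, 0.0, r2p, 0, rkp, n) >= f_global
    global_p = (exceed + 1) / (n_perm + 1)
    if global_p > alpha:
        return ForwardSelectionResult([], [], [], global_adj, float(global_p))

    ceiling = global_adj + 0.1 * max(1.0 - global_adj, 0.0)
    selected: list[str] = []
    adj_path: list[float] = []
    p_values: list[float] = []
    remaining = list(candidates.columns)
    r2_cur, rank_cur = 0.0, 0
    while remaining:
        gains = []
        for name in remaining:
            cols = selected + [name]
            r2_new, rank_new = _rda_r2(Y, candidates[cols].to_numpy(float))
            gains.append((r2_new - r2_cur, r2_new, rank_new, name))
        gain, r2_new, rank_new, best = max(gains, key=lambda t: t[0])
        if gain <= 1e-10 or rank_new == rank_cur:
            break  # no candidate adds information (collinearity guard)
        adj_new = adjusted_r2(r2_new, n, rank_new)
        if adj_new > ceiling:
            break
        # permutation test of the partial F for adding `best`
        X_new = candidates[selected + [best]].to_numpy(float)
        f_obs = _partial_f(Y, r2_cur, r2_new, rank_cur, rank_new, n)
        exceed = 0
        for _ in range(n_perm):
            Yp = Y[rng.permutation(n)]
            r2_c, _ = _rda_r2(Yp, candidates[selected].to_numpy(float)) \
                if selected else (0.0, 0)
            r2_n, rk_n = _rda_r2(Yp, X_new)
            exceed += _partial_f(Yp, r2_c, r2_n, rank_cur, rk_n, n) >= f_obs
        p = (exceed + 1) / (n_perm + 1)
        if p > alpha:
            break
        selected.append(best)
        remaining.remove(best)
        adj_path.append(adj_new)
        p_values.append(float(p))
        r2_cur, rank_cur = r2_new, rank_new
    return ForwardSelectionResult(selected, adj_path, p_values, global_adj,
                                  float(global_p))


def _partial_f(Y, r2_reduced, r2_full, rank_reduced, rank_full, n) -> float:
    df1 = max(rank_full - rank_reduced, 1)
    df2 = n - 1 - rank_full
    if df2 <= 0 or r2_full >= 1:
        return np.inf
    return ((r2_full - r2_reduced) / df1) / ((1 - r2_full) / df2)


_VPA_KEYS = ["env", "trend", "pcnm", "env_trend", "env_pcnm",
             "trend_pcnm", "env_trend_pcnm"]


def variance_partition(response, env: pd.DataFrame | None,
                       trend: pd.DataFrame | None,
                       pcnm: pd.DataFrame | None,
                       n_perm: int = 999, seed=None) -> VpaResult:
    """Partition db-RDA adjusted R2 among env, linear-trend and PCNM sets.

    The seven fractions (three pure, three pairwise joints, one triple joint)
    are obtained algebraically from the adjusted R2 of the seven set
    combinations; they sum exactly to the full-model adjusted R2, with the
    residual making up the rest. Negative fractions are kept in ``fractions``
    and shown as 0 in ``displayed``. Per-set p-values test each set
    conditionally on the other two by freely permuting samples.
    """
    Y = _as_response(response)
    n = Y.shape[0]
    sets = {"E": env, "T": trend, "P": pcnm}
    nonempty = {k: v for k, v in sets.items()
                if v is not None and v.shape[1] > 0}
    if not nonempty:
        return VpaResult({}, {}, {}, {k: [] for k in ("env", "trend", "pcnm")},
                         np.nan, False, n_perm, seed)
    for k, v in nonempty.items():
        if v.shape[1] > n - 1:
            raise ValidationError(f"set {k!r} has more columns than n-1")

    def combo_x(keys: str) -> np.ndarray:
        mats = [nonempty[k].to_numpy(float) for k in keys if k in nonempty]
        if not mats:
            return np.empty((n, 0))
        return np.column_stack(mats)

    def adj(keys: str) -> float:
        X = combo_x(keys)
        if X.shape[1] == 0:
            return 0.0
        r2, rank = _rda_r2(Y, X)
        return adjusted_r2(r2, n, rank)

    rE, rT, rP = adj("E"), adj("T"), adj("P")
    rET, rEP, rTP = adj("ET"), adj("EP"), adj("TP")
    rETP = adj("ETP")
    a = rETP - rTP                       # pure env
    b = rETP - rEP                       # pure trend
    c = rETP - rET                       # pure pcnm
    d = rEP + rTP - rETP - rP            # env & trend joint
    e = rET + rTP - rETP - rT            # env & pcnm joint
    f = rET + rEP - rETP - rE            # trend & pcnm joint
    g = rETP - a - b - c - d - e - f     # triple joint
    fractions = dict(zip(_VPA_KEYS, [a, b, c, d, e, f, g]))
    fractions["residual"] = 1 - rETP
    displayed = {k: (max(v, 0.0) if k != "residual" else v)
                 for k, v in fractions.items()}

    rng = np.random.default_rng(seed)
    set_p: dict[str, float] = {}
    name_of = {"E": "env", "T": "trend", "P": "pcnm"}
    for key in "ETP":
        if key not in nonempty:
            continue
        others = "".join(k for k in "ETP" if k != key and k in nonempty)
        X_full = combo_x("ETP")
        X_red = combo_x(others)
        r2_full, rank_full = _rda_r2(Y, X_full)
        r2_red, rank_red = (_rda_r2(Y, X_red) if X_red.shape[1] else (0.0, 0))
        f_obs = _partial_f(Y, r2_red, r2_full, rank_red, rank_full, n)
        exceed = 0
        for _ in range(n_perm):
            Yp = Y[rng.permutation(n)]
            r2f, rkf = _rda_r2(Yp, X_full)
            r2r, rkr = (_rda_r2(Yp, X_red) if X_red.shape[1] else (0.0, 0))
            exceed += _partial_f(Yp, r2r, r2f, rkr, rkf, n) >= f_obs
        set_p[name_of[key]] = (exceed + 1) / (n_perm + 1)

    selected = {name_of[k]: (list(sets[k].columns) if k in nonempty else [])
                for k in "ETP"}
    return VpaResult(fractions, displayed, set_p, selected, rETP, True,
                     n_perm, seed)


# ---------------------------------------------------------------------------
# Group comparisons and correlations
# ---------------------------------------------------------------------------

def group_difference_letters(values, grouping, alpha: float = 0.05,
                             method: str = "welch") -> pd.DataFrame:
    """Per-group mean +- SD with compact letter display.

    Groups sharing a letter are not significantly different at ``alpha``
    under all pairwise Welch t-tests (default) or Duncan's multiple range
    test. Groups are ordered by descending mean.
    """
    from scipy import stats

    v = np.asarray(values, dtype=float)
    g = np.asarray(grouping)
    labels, counts = np.unique(g, return_counts=True)
    if len(labels) < 2:
        raise ValidationError("need at least 2 groups")
    if (counts < 2).any():
        raise ValidationError(
            f"group {labels[counts < 2][0]!r} has fewer than 2 samples")
    means = np.array([v[g == lab].mean() for lab in labels])
    sds = np.array([v[g == lab].std(ddof=1) for lab in labels])
    order = np.argsort(means)[::-1]
    labels, means, sds, counts = (labels[order], means[order], sds[order],
                                  counts[order])
    k = len(labels)
    pmat = np.ones((k, k))
    if method == "welch":
        for i in range(k):
            for j in range(i + 1, k):
                xi, xj = v[g == labels[i]], v[g == labels[j]]
                if xi.std(ddof=1) == 0 and xj.std(ddof=1) == 0:
                    p = 1.0 if xi.mean() == xj.mean() else 0.0
                else:
                    p = stats.ttest_ind(xi, xj, equal_var=False).pvalue
                pmat[i, j] = pmat[j, i] = p
    elif method == "duncan":
        pmat = _duncan_pmatrix(v, g, labels, alpha)
    else:
        raise ValueError(f"unknown method {method!r}")

    letters = _compact_letters(pmat, alpha)
    return pd.DataFrame(
        {"mean": means, "sd": sds, "n": counts, "letters": letters},
        index=pd.Index(labels, name="group"),
    )


def _duncan_pmatrix(v, g, labels, alpha):
    """Pairwise significance under Duncan's multiple range test.

    Returns a pseudo p-matrix holding 0 where the range test rejects at the
    protection level 1-(1-alpha)^(p-1) and 1 otherwise (means sorted
    descending, p = span between the pair).
    """
    from scipy.stats import studentized_range

    k = len(labels)
    ns = np.array([np.sum(g == lab) for lab in labels])
    means = np.array([v[g == lab].mean() for lab in labels])
    df_err = len(v) - k
    mse = sum(((v[g == lab] - v[g == lab].mean()) ** 2).sum()
              for lab in labels) / df_err
    n_h = k / (1.0 / ns).sum()  # harmonic mean group size
    pmat = np.ones((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            span = j - i + 1
            level = 1 - (1 - alpha) ** (span - 1)
            crit = studentized_range.ppf(1 - level, span, df_err)
            lsr = crit * np.sqrt(mse / n_h)
            if abs(means[i] - means[j]) > lsr:
                pmat[i, j] = pmat[j, i] = 0.0
    return pmat


def _compact_letters(pmat: np.ndarray, alpha: float) -> list[str]:
    """Letters via the underlining method on mean-sorted groups."""
    k = pmat.shape[0]
    ranges = []
    for i in range(k):
        j = i
        while j + 1 < k and all(pmat[a, j + 1] > alpha for a in range(i, j + 1)):
            j += 1
        ranges.append((i, j))
    # drop ranges contained in an earlier, wider one
    kept = []
    for r in ranges:
        if not any(o[0] <= r[0] and r[1] <= o[1] for o in kept):
            kept.append(r)
    letters = ["" for _ in range(k)]
    for idx, (lo, hi) in enumerate(kept):
        ch = chr(ord("a") + idx)
        for i in range(lo, hi + 1):
            letters[i] += ch
    return letters


def alpha_env_correlation(alpha_table: pd.DataFrame, metadata: pd.DataFrame,
                          variables: list[str]) -> pd.DataFrame:
    """Pearson r (two-tailed p) between each alpha index and each variable.

    Constant variables yield NaN entries rather than an error.
    """
    from scipy import stats

    meta = metadata.loc[alpha_table.index]
    rows = []
    for idx_name in alpha_table.columns:
        x = alpha_table[idx_name].to_numpy(float)
        for var in variables:
            y = meta[var].to_numpy(float)
            ok = np.isfinite(x) & np.isfinite(y)
            if ok.sum() < 3 or np.std(x[ok]) == 0 or np.std(y[ok]) == 0:
                r, p = np.nan, np.nan
            else:
                r, p = stats.pearsonr(x[ok], y[ok])
            rows.append({"index": idx_name, "variable": var,
                         "r": r, "p": p})
    return pd.DataFrame(rows).set_index(["index", "variable"])
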