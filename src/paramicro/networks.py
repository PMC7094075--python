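"""Compositional co-association networks and their comparison.

Two inference routes are provided. SparCC estimates linear (Pearson-like)
correlations between the unobserved absolute abundances underlying
compositional count data: log-ratio variances T_ij = var(log x_i/x_j) are
estimated by averaging over Dirichlet resamples of the observed counts,
component ("basis") variances are solved from the sparsity approximation
t_i = sum_j T_ij ~ (D-1) w_i + sum_{j!=i} w_j, and strongly correlated
pairs are iteratively excluded from that system. Edges are thresholded on
effect size and a bootstrap pseudo-p-value.

The second route is neighborhood selection (MB): an L1-penalized
regression of each clr-transformed feature on all others over a geometric
penalty path, with the penalty chosen by stability selection (StARS) over
subsamples; the final graph is the union (OR rule) of neighborhoods.

Networks are summarized by degree, betweenness centrality, edge density
and Freeman betweenness centralization, and compared between communities
by a bootstrap of mean node centrality followed by a two-sample
Kolmogorov-Smirnov test.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import lasso_path

from .core_io import FeatureTable

logger = logging.getLogger("paramicro")


# ---------------------------------------------------------------------------
# containers


@dataclasses.dataclass
class CoAssociationNetwork:
    """Undirected signed network over feature nodes.

    edges is a tuple of (u, v, weight) with each unordered pair listed
    once and no self loops; weight carries the sign of the association.
    node_attrs (optional) holds per-node annotation such as mean clr
    abundance and phylum.
    """

    node_ids: tuple
    edges: tuple
    method: str = ""
    params: dict = dataclasses.field(default_factory=dict)
    node_attrs: pd.DataFrame | None = None

    def __post_init__(self):
        self.node_ids = tuple(self.node_ids)
        nodes = set(self.node_ids)
        seen = set()
        norm = []
        for u, v, w in self.edges:
            if u == v:
                raise ValueError(f"self edge on {u!r}")
            if u not in nodes or v not in nodes:
                raise ValueError(f"edge endpoint not in node set: ({u!r}, {v!r})")
            key = (u, v) if u <= v else (v, u)
            if key in seen:
                raise ValueError(f"duplicate edge {key}")
            seen.add(key)
            norm.append((key[0], key[1], float(w)))
        self.edges = tuple(norm)

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.node_ids)
        for u, v, w in self.edges:
            g.add_edge(u, v, weight=w, sign="+" if w >= 0 else "-")
        if self.node_attrs is not None:
            for col in self.node_attrs.columns:
                nx.set_node_attributes(g, self.node_attrs[col].to_dict(), name=col)
        return g


@dataclasses.dataclass(frozen=True)
class NetworkStats:
    degree: pd.Series
    betweenness: pd.Series
    edge_density: float
    betweenness_centralization: float


@dataclasses.dataclass(frozen=True)
class BootstrapKSResult:
    statistic: float
    pvalue: float
    k: int
    n_reps: int
    seed: int | None


@dataclasses.dataclass(frozen=True)
class SparccResult:
    correlations: np.ndarray
    feature_ids: tuple
    flagged: tuple  # features whose basis variance was non-positive


# ---------------------------------------------------------------------------
# SparCC


def _variation_matrix(log_fracs: np.ndarray) -> np.ndarray:
    """T_ij = var(log f_i / log f_j) from per-sample log fractions (D x n)."""
    c = np.cov(log_fracs)
    v = np.diag(c)
    return v[:, None] + v[None, :] - 2.0 * c


def _basis_variances(T: np.ndarray, excluded: np.ndarray) -> np.ndarray:
    """Solve the sparsity-approximation linear system for component variances.

    With S_i the non-excluded partners of i, sum_{j in S_i} T_ij =
    |S_i| w_i + sum_{j in S_i} w_j; excluded pairs drop out of both sides.
    """
    active = ~excluded
    np.fill_diagonal(active, False)
    t = (T * active).sum(axis=1)
    m = active.astype(float)
    np.fill_diagonal(m, active.sum(axis=1))
    try:
        return np.linalg.solve(m, t)
    except np.linalg.LinAlgError:
        return np.linalg.lstsq(m, t, rcond=None)[0]


def _rho_from_basis(T: np.ndarray, omega: np.ndarray) -> np.ndarray:
    bad = omega <= 0
    om = np.where(bad, np.nan, omega)
    with np.errstate(invalid="ignore"):
        rho = (om[:, None] + om[None, :] - T) / (2.0 * np.sqrt(np.outer(om, om)))
        rho = np.clip(rho, -1.0, 1.0)
    np.fill_diagonal(rho, 1.0)
    rho[bad, :] = np.nan
    rho[:, bad] = np.nan
    np.fill_diagonal(rho, 1.0)
    return rho


def _sparcc_once(
    counts: np.ndarray,
    rng: np.random.Generator,
    exclusion_threshold: float,
    exclusion_rounds: int,
) -> np.ndarray:
    d = counts.shape[0]
    g = rng.standard_gamma(counts + 1.0)
    fracs = g / g.sum(axis=0, keepdims=True)
    T = _variation_matrix(np.log(fracs))
    excluded = np.zeros((d, d), dtype=bool)
    omega = _basis_variances(T, excluded)
    rho = _rho_from_basis(T, omega)
    if d >= 4:
        for _ in range(exclusion_rounds):
            cand = np.abs(np.where(np.isnan(rho), 0.0, rho))
            cand[excluded] = 0.0
            np.fill_diagonal(cand, 0.0)
            i, j = np.unravel_index(np.argmax(cand), cand.shape)
            if cand[i, j] <= exclusion_threshold:
                break
            excluded[i, j] = excluded[j, i] = True
            omega = _basis_variances(T, excluded)
            rho = _rho_from_basis(T, omega)
    return rho


def sparcc_correlations(
    counts: FeatureTable | np.ndarray,
    inner_iterations: int = 20,
    exclusion_threshold: float = 0.1,
    exclusion_rounds: int = 10,
    seed: int | None = None,
) -> SparccResult:
    """SparCC correlation matrix of a count table.

    Each inner iteration resamples fractions from a per-sample Dirichlet
    posterior (counts + 1) and re-estimates correlations; the reported
    matrix is the element-wise median over iterations. Features whose
    basis variance is non-positive in every iteration are flagged and
    their rows/columns set to NaN.
    """
    if isinstance(counts, FeatureTable):
        ids, mat = counts.feature_ids, counts.counts.astype(float)
    else:
        mat = np.asarray(counts, dtype=float)
        ids = tuple(f"F{i}" for i in range(mat.shape[0]))
    d, n = mat.shape
    if d < 3:
        raise ValueError("SparCC needs at least 3 features")
    if n < 3:
        raise ValueError("SparCC needs at least 3 samples")
    rng = np.random.default_rng(seed)
    draws = [
        _sparcc_once(mat, rng, exclusion_threshold, exclusion_rounds)
        for _ in range(inner_iterations)
    ]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        rho = np.nanmedian(np.stack(draws), axis=0)
    np.fill_diagonal(rho, 1.0)
    off = ~np.eye(d, dtype=bool)
    flagged = tuple(
        ids[i] for i in range(d) if np.all(np.isnan(rho[i][off[i]]))
    )
    return SparccResult(rho, tuple(ids), flagged)


def sparcc_pvalues(
    counts: FeatureTable | np.ndarray,
    n_bootstrap: int = 100,
    seed: int | None = None,
    **sparcc_kwargs,
) -> np.ndarray:
    """Two-sided bootstrap pseudo-p-values for every SparCC correlation.

    Samples are resampled with replacement n_bootstrap times; for each
    pair, p = 2 * min(#{rho_b <= 0}, #{rho_b >= 0}) / B, floored at 1/B
    and capped at 1.
    """
    if isinstance(counts, FeatureTable):
        mat = counts.counts.astype(float)
    else:
        mat = np.asarray(counts, dtype=float)
    d, n = mat.shape
    if n_bootstrap < 20:
        logger.warning("n_bootstrap=%d gives a coarse p-value grid", n_bootstrap)
    ss = np.random.SeedSequence(seed)
    resample_rng = np.random.default_rng(ss.spawn(1)[0])
    child_seeds = ss.spawn(n_bootstrap)
    neg = np.zeros((d, d))
    pos = np.zeros((d, d))
    valid = np.zeros((d, d))
    for b in range(n_bootstrap):
        idx = resample_rng.integers(0, n, size=n)
        rho_b = sparcc_correlations(
            mat[:, idx], seed=child_seeds[b].generate_state(1)[0] % (2**31), **sparcc_kwargs
        ).correlations
        ok = ~np.isnan(rho_b)
        neg += ok & (rho_b <= 0)
        pos += ok & (rho_b >= 0)
        valid += ok
    with np.errstate(invalid="ignore", divide="ignore"):
        p = 2.0 * np.minimum(neg, pos) / valid
        p = np.clip(p, 1.0 / n_bootstrap, 1.0)
    p[valid == 0] = np.nan
    np.fill_diagonal(p, np.nan)
    return p


def threshold_edges(
    rho: np.ndarray,
    p: np.ndarray,
    feature_ids,
    min_abs_corr: float = 0.6,
    alpha: float = 0.05,
    node_attrs: pd.DataFrame | None = None,
    params: dict | None = None,
) -> CoAssociationNetwork:
    """Edges where |rho| > min_abs_corr AND p < alpha (both strict).

    Isolated nodes are kept in the node set; NaN entries never qualify.
    """
    ids = tuple(feature_ids)
    d = len(ids)
    rho = np.asarray(rho, float)
    p = np.asarray(p, float)
    if rho.shape != (d, d) or p.shape != (d, d):
        raise ValueError("rho/p must be square and match the feature ids")
    edges = []
    for i in range(d):
        for j in range(i + 1, d):
            if np.isnan(rho[i, j]) or np.isnan(p[i, j]):
                continue
            if abs(rho[i, j]) > min_abs_corr and p[i, j] < alpha:
                edges.append((ids[i], ids[j], rho[i, j]))
    prm = {"min_abs_corr": min_abs_corr, "alpha": alpha}
    if params:
        prm.update(params)
    return CoAssociationNetwork(ids, tuple(edges), "sparcc", prm, node_attrs)


# ---------------------------------------------------------------------------
# neighborhood selection + StARS


def _standardize(x: np.ndarray) -> np.ndarray:
    mu = x.mean(axis=0, keepdims=True)
    sd = x.std(axis=0, keepdims=True)
    return (x - mu) / sd


def _neighborhood_coefs(x_std: np.ndarray, lambdas: np.ndarray) -> np.ndarray:
    """Lasso coefficients for every node regression over the penalty path.

    Returns B with shape (nlambda, p, p); B[l, j, k] is the coefficient
    of feature k in the regression of feature j at penalty lambdas[l].
    """
    n, p = x_std.shape
    out = np.zeros((len(lambdas), p, p))
    cols = np.arange(p)
    for j in range(p):
        others = cols[cols != j]
        _, coefs, _ = lasso_path(x_std[:, others], x_std[:, j], alphas=lambdas)
        out[:, j, others] = coefs.T
    return out


def mb_stars_network(
    data: np.ndarray,
    feature_ids=None,
    nlambda: int = 100,
    min_lambda_ratio: float = 0.002,
    n_subsamples: int = 30,
    instability_threshold: float = 0.05,
    subsample_frac: float = 0.8,
    seed: int | None = None,
    node_attrs: pd.DataFrame | None = None,
) -> CoAssociationNetwork:
    """Meinshausen-Buhlmann neighborhood selection with StARS penalty choice.

    `data` is samples x features of clr-transformed abundances. The
    penalty path is geometric from lambda_max (the largest absolute
    off-diagonal empirical correlation) down by min_lambda_ratio. For
    each of n_subsamples subsamples of size floor(subsample_frac * n)
    the OR-rule graph is recorded along the path; per-pair instability
    2*theta*(1-theta) is averaged over pairs and monotonized by a running
    supremum along the densifying path, and the densest penalty whose
    monotonized instability stays at or below the threshold is selected.
    Edge weight is the mean of the two directed lasso coefficients at the
    selected penalty on the full data.
    """
    x = np.asarray(data, dtype=float)
    n, p = x.shape
    if n < 4:
        raise ValueError("need at least 4 samples")
    ids = tuple(feature_ids) if feature_ids is not None else tuple(f"F{i}" for i in range(p))
    sd = x.std(axis=0)
    keep = sd > 0
    if not keep.all():
        logger.warning("dropping %d constant features before MB inference", (~keep).sum())
        x = x[:, keep]
        ids = tuple(i for i, k in zip(ids, keep) if k)
        p = x.shape[1]
    if p < 2:
        raise ValueError("need at least 2 varying features")

    xs = _standardize(x)
    corr = (xs.T @ xs) / n
    lam_max = float(np.max(np.abs(corr - np.eye(p))))
    lam_max = max(lam_max, 1e-3)
    lambdas = np.geomspace(lam_max, lam_max * min_lambda_ratio, nlambda)

    rng = np.random.default_rng(seed)
    m = int(np.floor(subsample_frac * n))
    theta = np.zeros((nlambda, p, p))
    for _ in range(n_subsamples):
        idx = rng.choice(n, size=m, replace=False)
        sub = _standardize(x[idx])
        b = _neighborhood_coefs(sub, lambdas)
        adj = (b != 0) | (b.transpose(0, 2, 1) != 0)
        theta += adj
    theta /= n_subsamples
    xi = 2.0 * theta * (1.0 - theta)
    iu = np.triu_indices(p, 1)
    instability = xi[:, iu[0], iu[1]].mean(axis=1) if len(iu[0]) else np.zeros(nlambda)
    mono = np.maximum.accumulate(instability)
    ok = np.flatnonzero(mono <= instability_threshold)
    opt = int(ok[-1]) if len(ok) else 0

    b_full = _neighborhood_coefs(_standardize(x), lambdas[: opt + 1])[opt]
    adj = (b_full != 0) | (b_full.T != 0)
    weights = (b_full + b_full.T) / 2.0
    edges = [
        (ids[i], ids[j], weights[i, j]) for i, j in zip(*np.where(np.triu(adj, 1)))
    ]
    params = {
        "method": "mb",
        "nlambda": nlambda,
        "min_lambda_ratio": min_lambda_ratio,
        "n_subsamples": n_subsamples,
        "instability_threshold": instability_threshold,
        "lambda_selected": float(lambdas[opt]),
        "lambda_index": opt,
        "instability_path": instability.tolist(),
    }
    return CoAssociationNetwork(ids, tuple(edges), "mb_stars", params, node_attrs)


# ---------------------------------------------------------------------------
# statistics and comparison


def network_stats(net: CoAssociationNetwork) -> NetworkStats:
    """Degree, betweenness, edge density and betweenness centralization.

    Centrality is computed on the unweighted, sign-ignored graph; each
    unordered pair is counted once and path endpoints are excluded.
    Freeman centralization uses the star graph as the maximizer:
    C_B = sum_i(b_max - b_i) / ((V-1)^2 (V-2) / 2), defined 0 for V < 3.
    """
    g = nx.Graph()
    g.add_nodes_from(net.node_ids)
    g.add_edges_from((u, v) for u, v, _ in net.edges)
    v = g.number_of_nodes()
    degree = pd.Series(dict(g.degree()), dtype=float).reindex(list(net.node_ids))
    btw = pd.Series(nx.betweenness_centrality(g, normalized=False)).reindex(
        list(net.node_ids)
    )
    density = 2.0 * g.number_of_edges() / (v * (v - 1)) if v > 1 else 0.0
    if v < 3:
        centralization = 0.0
    else:
        centralization = float((btw.max() - btw).sum() / ((v - 1) ** 2 * (v - 2) / 2.0))
    return NetworkStats(degree, btw, float(density), centralization)


def bootstrap_centrality_ks(
    values_a: np.ndarray,
    values_b: np.ndarray,
    k: int = 50,
    n_reps: int = 10000,
    seed: int | None = None,
) -> BootstrapKSResult:
    """Compare two node-centrality distributions via bootstrap means.

    For each network, n_reps means of k values drawn with replacement are
    formed (k stays fixed even when a network has fewer than k nodes);
    the distributions of means are compared with a two-sample
    Kolmogorov-Smirnov test (asymptotic p-value).
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("centrality vectors must be non-empty")
    rng = np.random.default_rng(seed)
    means_a = a[rng.integers(0, a.size, size=(n_reps, k))].mean(axis=1)
    means_b = b[rng.integers(0, b.size, size=(n_reps, k))].mean(axis=1)
    res = stats.ks_2samp(means_a, means_b, method="asymp")
    return BootstrapKSResult(float(res.statistic), float(res.pvalue), k, n_reps, seed)
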