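"""Synthetic paired host-parasite microbiome datasets with ground truth.

The generator emulates the field design the analysis targets: seven plant
community types (parasite leaf/root, infected-host leaf, directly
parasitized root, uninfected root of infected host, uninfected-host leaf
and root) plus soil, sampled at 4 sites x 3 replicates (12 samples per
type). Counts are sparse, overdispersed and have log-normal library
sizes; taxa live on a simulated phylogeny whose pseudo-phyla and
pseudo-orders are monophyletic clades.

Host-parasite congruence is tunable. Compositional turnover across
specimens is modelled as two latent modes: fixed direction vectors in
log-abundance space, concentrated on a designated abundant driver clade,
whose per-specimen scalar coordinates drive community shifts (an
infection-associated clade bloom that waxes and wanes across excavated
units). The directly parasitized host root carries these coordinates
fully; the parasite organs of the same specimen receive them scaled by
kappa plus an independent sqrt(1 - kappa^2) remainder, so per-type
variance does not depend on kappa and kappa = 0 gives an exchangeable
protest null. The driver concentration gives the leave-one-out
attribution statistic a known answer. A co-association graph can be
planted in the residual covariance for network-inference ground truth.
"""

from __future__ import annotations

import dataclasses
import itertools

import numpy as np
import pandas as pd
from skbio import TreeNode

from .core_io import AnalysisBundle, COMMUNITY_TYPES, FeatureTable, TAXONOMY_RANKS


# ---------------------------------------------------------------------------
# tree + taxonomy


def _random_subtree(leaves: list[TreeNode], rng: np.random.Generator, scale: float) -> TreeNode:
    """Random bifurcating join of the given nodes (Yule-like topology)."""
    nodes = list(leaves)
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        parent = TreeNode(length=float(rng.exponential(scale)), children=[a, b])
        nodes.append(parent)
    return nodes[0]


def _partition(n: int, k: int) -> list[int]:
    base, extra = divmod(n, k)
    return [base + (1 if i < extra else 0) for i in range(k)]


def simulate_tree_taxonomy(
    n_taxa: int,
    n_phyla: int = 4,
    orders_per_phylum: int = 2,
    seed: int | None = None,
    branch_scale: float = 0.1,
) -> tuple[TreeNode, pd.DataFrame]:
    """Random rooted tree plus a nested taxonomy of monophyletic clades.

    Taxa are partitioned evenly into pseudo-phyla and, within each
    phylum, into pseudo-orders; each order and phylum is a clade of the
    tree by construction. Branch lengths are exponential (mean
    branch_scale, in substitutions/site).
    """
    if n_taxa < n_phyla * orders_per_phylum:
        raise ValueError("need at least one taxon per (phylum, order) cell")
    rng = np.random.default_rng(seed)
    names = [f"ASV{i + 1:04d}" for i in range(n_taxa)]
    rows = {}
    phylum_trees = []
    it = iter(names)
    for p, n_in_p in enumerate(_partition(n_taxa, n_phyla), start=1):
        phylum = f"P{p}"
        order_trees = []
        for o, n_in_o in enumerate(_partition(n_in_p, orders_per_phylum), start=1):
            order = f"{phylum}_O{o}"
            leaf_names = list(itertools.islice(it, n_in_o))
            for i, nm in enumerate(leaf_names):
                rows[nm] = {
                    "phylum": phylum,
                    "class": f"{phylum}_C1",
                    "order": order,
                    "family": f"{order}_F1",
                    "genus": f"{order}_G{i % 3 + 1}",
                }
            leaves = [
                TreeNode(name=nm, length=float(rng.exponential(branch_scale)))
                for nm in leaf_names
            ]
            sub = _random_subtree(leaves, rng, branch_scale)
            if sub.length is None:
                sub.length = float(rng.exponential(branch_scale))
            order_trees.append(sub)
        sub = (
            order_trees[0]
            if len(order_trees) == 1
            else _random_subtree(order_trees, rng, branch_scale)
        )
        if sub.length is None:
            sub.length = float(rng.exponential(branch_scale))
        phylum_trees.append(sub)
    root = (
        phylum_trees[0]
        if len(phylum_trees) == 1
        else _random_subtree(phylum_trees, rng, branch_scale)
    )
    root.length = None
    taxonomy = pd.DataFrame.from_dict(rows, orient="index").rename_axis("feature_id")
    taxonomy = taxonomy[list(TAXONOMY_RANKS)].loc[names]
    return root, taxonomy


# ---------------------------------------------------------------------------
# parameters


DEFAULT_COMMUNITY_TYPES = ("PL", "PR", "IL", "IIR", "IUR", "UL", "UR", "SOIL")

#: weight of the shared specimen signal per community type: the directly
#: parasitized host root carries it fully, the parasite organs receive it
#: scaled by kappa, everything else has independent specimen effects.
_SHARED_WEIGHT = {"IIR": 1.0, "PR": "kappa", "PL": "kappa"}


@dataclasses.dataclass(frozen=True)
class SimulationParams:
    """Knobs of the paired-community generator.

    kappa in [0, 1] is the host-parasite congruence strength;
    driver_clade_fraction is the share of the specimen-signal variance
    carried by the driver clade, and driver_baseline_boost keeps that
    clade abundant in every community type (a rare clade cannot carry an
    abundance-weighted signal). Standard deviations are on the latent
    log-abundance scale. Site effects are deliberately weak relative to
    specimen effects so that the protest permutation null is exchangeable
    at kappa = 0.
    """

    n_taxa: int = 120
    n_phyla: int = 4
    orders_per_phylum: int = 2
    n_sites: int = 4
    reps_per_site: int = 3
    community_types: tuple = DEFAULT_COMMUNITY_TYPES
    kappa: float = 0.5
    driver_clade_fraction: float = 0.8
    driver_baseline_boost: float = 1.5
    n_shared_modes: int = 2
    baseline_sd: float = 2.0
    site_sd: float = 0.25
    shared_sd: float = 1.8
    noise_sd: float = 0.6
    overdispersion: float = 0.3
    library_size_log_mean: float = float(np.log(10_000))
    library_size_log_sd: float = 0.5
    true_graph: object = None  # None | "chain" | ("erdos", p) | edge list
    graph_strength: float = 0.35
    seed: int | None = None

    def __post_init__(self):
        if not 0.0 <= self.kappa <= 1.0:
            raise ValueError("kappa must be in [0, 1]")
        if not 0.0 < self.driver_clade_fraction <= 1.0:
            raise ValueError("driver_clade_fraction must be in (0, 1]")


@dataclasses.dataclass
class SyntheticDataset:
    bundle: AnalysisBundle
    params: SimulationParams
    driver_phylum: str
    driver_order: str
    driver_features: tuple
    true_edges: tuple


# ---------------------------------------------------------------------------
# graphs and covariances


def _resolve_graph(spec, n_taxa: int, rng: np.random.Generator) -> list[tuple[int, int]]:
    if spec is None:
        return []
    if spec == "chain":
        return [(i, i + 1) for i in range(n_taxa - 1)]
    if isinstance(spec, tuple) and len(spec) == 2 and spec[0] == "erdos":
        p = float(spec[1])
        edges = [
            (i, j)
            for i in range(n_taxa)
            for j in range(i + 1, n_taxa)
            if rng.random() < p
        ]
        return edges
    return [tuple(e) for e in spec]


def graph_covariance(edges, n: int, strength: float = 0.35) -> np.ndarray:
    """Correlation matrix whose inverse has the sparsity pattern of `edges`.

    Builds precision I + strength * A, shrinking strength if needed to
    keep the matrix positive definite, inverts, and rescales to unit
    diagonal.
    """
    a = np.zeros((n, n))
    for i, j in edges:
        a[i, j] = a[j, i] = 1.0
    if not edges:
        return np.eye(n)
    lam_min = np.linalg.eigvalsh(a).min()
    s = strength
    if 1.0 + s * lam_min < 0.05:
        s = 0.95 / abs(lam_min)
    omega = np.eye(n) + s * a
    sigma = np.linalg.inv(omega)
    d = 1.0 / np.sqrt(np.diag(sigma))
    return sigma * np.outer(d, d)


def gaussian_graph_data(
    edges, n_features: int, n_samples: int, strength: float = 0.35, seed: int | None = None
) -> np.ndarray:
    """Zero-mean Gaussian samples (n_samples x n_features) whose precision
    matrix has the given edge pattern; for structure-recovery checks."""
    rng = np.random.default_rng(seed)
    sigma = graph_covariance(edges, n_features, strength)
    chol = np.linalg.cholesky(sigma)
    return rng.standard_normal((n_samples, n_features)) @ chol.T


# ---------------------------------------------------------------------------
# paired communities


def _clade_loading(n_taxa: int, driver_idx: np.ndarray, fraction: float) -> np.ndarray:
    """Per-taxon loading of the specimen signal.

    Driver taxa load 1; the rest load so the driver clade carries
    `fraction` of the total signal variance.
    """
    m = np.zeros(n_taxa)
    m[driver_idx] = 1.0
    n_d = len(driver_idx)
    n_o = n_taxa - n_d
    if n_o > 0 and fraction < 1.0:
        m[m == 0] = np.sqrt((1.0 - fraction) / fraction * n_d / n_o)
    return m


def simulate_paired_communities(params: SimulationParams) -> SyntheticDataset:
    """Simulate the full paired design with known ground truth.

    Latent per-sample log-abundance = community-type baseline + site
    effect + specimen signal + (graph-structured) noise. The specimen
    signal lives in n_shared_modes fixed directions concentrated on the
    driver clade; its scalar coordinates in the parasite organs equal
    kappa times the host-root coordinates of the same excavated unit
    plus an independent sqrt(1 - kappa^2) remainder. Counts are
    multinomial with log-normal library sizes. Deterministic given
    params.seed.
    """
    rng = np.random.default_rng(params.seed)
    tree, taxonomy = simulate_tree_taxonomy(
        params.n_taxa,
        params.n_phyla,
        params.orders_per_phylum,
        seed=int(rng.integers(2**31)),
    )
    feature_ids = tuple(taxonomy.index)
    n_taxa = params.n_taxa

    driver_order = taxonomy["order"].iloc[0]
    driver_phylum = taxonomy["phylum"].iloc[0]
    driver_idx = np.flatnonzero((taxonomy["order"] == driver_order).to_numpy())
    loading = _clade_loading(n_taxa, driver_idx, params.driver_clade_fraction)

    # fixed compositional modes of specimen-level turnover; RMS-1 scaled so
    # shared_sd is the per-taxon signal scale on the driver clade
    n_modes = params.n_shared_modes
    modes = np.empty((n_modes, n_taxa))
    for k in range(n_modes):
        raw = loading * rng.standard_normal(n_taxa)
        modes[k] = raw / np.sqrt(np.mean(raw[driver_idx] ** 2))
    mode_scale = params.shared_sd / np.sqrt(n_modes)

    edge_idx = _resolve_graph(params.true_graph, n_taxa, rng)
    if edge_idx:
        chol = np.linalg.cholesky(graph_covariance(edge_idx, n_taxa, params.graph_strength))
    else:
        chol = None
    true_edges = tuple((feature_ids[i], feature_ids[j]) for i, j in edge_idx)

    sites = [f"s{i + 1}" for i in range(params.n_sites)]
    reps = list(range(1, params.reps_per_site + 1))
    noise_total = float(np.sqrt(params.noise_sd**2 + params.overdispersion**2))

    # Per-type baselines, except that the driver clade's baseline is drawn
    # once and shared across community types (boosted so the clade stays
    # abundant everywhere): a clade whose typical abundance differed wildly
    # between host and parasite could not visibly couple their turnover.
    driver_base = 0.5 * params.baseline_sd * rng.standard_normal(
        len(driver_idx)
    ) + params.driver_baseline_boost
    baselines = {}
    for ct in params.community_types:
        b = params.baseline_sd * rng.standard_normal(n_taxa)
        b[driver_idx] = driver_base
        baselines[ct] = b
    site_eff = {
        (ct, s): params.site_sd * rng.standard_normal(n_taxa)
        for ct in params.community_types
        for s in sites
    }
    # host-root specimen coordinates per excavated unit
    shared_coord = {(s, r): rng.standard_normal(n_modes) for s in sites for r in reps}

    sample_ids, columns, meta_rows = [], [], []
    for ct in params.community_types:
        species, organ = COMMUNITY_TYPES[ct]
        w = _SHARED_WEIGHT.get(ct, 0.0)
        kappa_c = params.kappa if w == "kappa" else float(w)
        patch = "i" if ct in ("PL", "PR", "IL", "IIR", "IUR") else (
            "s" if ct == "SOIL" else "u"
        )
        for s in sites:
            for r in reps:
                own = rng.standard_normal(n_modes)
                coord = kappa_c * shared_coord[(s, r)] + np.sqrt(1 - kappa_c**2) * own
                spec_eff = mode_scale * (coord @ modes)
                if chol is not None:
                    eps = noise_total * (chol @ rng.standard_normal(n_taxa))
                else:
                    eps = noise_total * rng.standard_normal(n_taxa)
                lam = baselines[ct] + site_eff[(ct, s)] + spec_eff + eps
                p = np.exp(lam - lam.max())
                p /= p.sum()
                lib = int(
                    np.round(
                        rng.lognormal(
                            params.library_size_log_mean, params.library_size_log_sd
                        )
                    )
                )
                lib = max(lib, 1)
                columns.append(rng.multinomial(lib, p))
                sid = f"{ct}.{s}.r{r}"
                sample_ids.append(sid)
                meta_rows.append(
                    {
                        "sample_id": sid,
                        "species": species,
                        "organ": organ,
                        "community_type": ct,
                        "site_id": s,
                        "replicate": r,
                        "specimen_id": f"{s}r{r}{patch}",
                        "total_usable_reads": int(columns[-1].sum()),
                    }
                )

    counts = np.column_stack(columns)
    table = FeatureTable(feature_ids, tuple(sample_ids), counts)
    metadata = pd.DataFrame(meta_rows).set_index("sample_id")
    bundle = AnalysisBundle(table, metadata, taxonomy, tree)
    return SyntheticDataset(
        bundle,
        params,
        driver_phylum,
        driver_order,
        tuple(taxonomy.index[driver_idx]),
        true_edges,
    )


# ---------------------------------------------------------------------------
# simple nulls and planted structures


def simulate_null_counts(
    n_taxa: int,
    n_samples: int,
    seed: int | None = None,
    baseline_sd: float = 2.0,
    noise_sd: float = 1.0,
    library_size_log_mean: float = float(np.log(10_000)),
    library_size_log_sd: float = 0.5,
) -> FeatureTable:
    """Counts from independent log-normal latents: no true co-associations."""
    if n_taxa < 2 or n_samples < 2:
        raise ValueError("need at least 2 taxa and 2 samples")
    rng = np.random.default_rng(seed)
    base = baseline_sd * rng.standard_normal(n_taxa)
    lam = base[:, None] + noise_sd * rng.standard_normal((n_taxa, n_samples))
    cols = []
    for j in range(n_samples):
        p = np.exp(lam[:, j] - lam[:, j].max())
        p /= p.sum()
        lib = max(1, int(np.round(rng.lognormal(library_size_log_mean, library_size_log_sd))))
        cols.append(rng.multinomial(lib, p))
    ids = tuple(f"ASV{i + 1:04d}" for i in range(n_taxa))
    sids = tuple(f"N{j + 1:03d}" for j in range(n_samples))
    return FeatureTable(ids, sids, np.column_stack(cols))


def simulate_correlated_pair_counts(
    n_taxa: int = 32,
    n_samples: int = 200,
    rho: float = 0.9,
    seed: int | None = None,
    latent_sd: float = 1.0,
    baseline_sd: float = 1.0,
    library_size_log_mean: float = float(np.log(20_000)),
    library_size_log_sd: float = 0.3,
) -> FeatureTable:
    """Null counts with one planted correlated pair (features 0 and 1).

    The first two taxa share latent log-abundance correlation `rho`;
    all others are independent. Used to verify correlation recovery.
    """
    rng = np.random.default_rng(seed)
    base = baseline_sd * rng.standard_normal(n_taxa)
    z = rng.standard_normal((n_taxa, n_samples))
    z[1] = rho * z[0] + np.sqrt(1 - rho**2) * z[1]
    lam = base[:, None] + latent_sd * z
    cols = []
    for j in range(n_samples):
        p = np.exp(lam[:, j] - lam[:, j].max())
        p /= p.sum()
        lib = max(1, int(np.round(rng.lognormal(library_size_log_mean, library_size_log_sd))))
        cols.append(rng.multinomial(lib, p))
    ids = tuple(f"ASV{i + 1:04d}" for i in range(n_taxa))
    sids = tuple(f"S{j + 1:03d}" for j in range(n_samples))
    return FeatureTable(ids, sids, np.column_stack(cols))
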