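"""Procrustes congruence between paired ordinations and its clade attribution.

Two community types sampled from the same specimens (e.g. parasite roots
and the host roots they attach to) are compared by symmetric Procrustes
analysis of their PCoA scores: both configurations are centered and
scaled to unit sum of squares, and the best rotation/reflection aligning
them yields the correlation-like statistic t0 in [0, 1] (1 = perfect
congruence). Significance comes from a permutation test (protest).

The leave-one-out procedure attributes congruence to taxonomy: all
features of one clade are removed from the parasite table, distances and
ordination are recomputed for the parasite side only (host scores stay
frozen), and delta_t = t_excluded - t0 measures that clade's
contribution -- negative delta_t means the clade drives congruence.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .core_io import FeatureTable, TAXONOMY_RANKS, UNASSIGNED
from .ordination import pcoa, weighted_unifrac


@dataclasses.dataclass(frozen=True)
class ProcrustesResult:
    t0: float
    m12_squared: float
    rotation: np.ndarray
    permutation_p: float | None = None
    n_permutations: int = 0


def _center_scale(m: np.ndarray) -> np.ndarray:
    m = np.asarray(m, dtype=float)
    m = m - m.mean(axis=0, keepdims=True)
    ss = np.sqrt((m**2).sum())
    if ss == 0:
        raise ValueError("configuration has zero spread")
    return m / ss


def procrustes_fit(X: np.ndarray, Y: np.ndarray) -> ProcrustesResult:
    """Symmetric Procrustes fit of two paired score matrices.

    Both inputs are centered and scaled to unit total sum of squares;
    reflections are allowed. t0 equals the sum of singular values of
    X'Y and m12^2 = 1 - t0^2 is the residual after optimal rotation
    and symmetric scaling.
    """
    X, Y = np.asarray(X, float), np.asarray(Y, float)
    if X.shape[0] != Y.shape[0]:
        raise ValueError(f"row mismatch: {X.shape[0]} vs {Y.shape[0]}")
    if X.shape[0] < 3:
        raise ValueError("need at least 3 paired rows")
    if X.shape[1] < 2 or Y.shape[1] < 2:
        raise ValueError("need at least 2 score columns per configuration")
    Xc, Yc = _center_scale(X), _center_scale(Y)
    u, s, vt = np.linalg.svd(Xc.T @ Yc)
    t0 = float(np.clip(s.sum(), 0.0, 1.0))
    rotation = (u @ vt).T  # maps Y-space onto X-space
    return ProcrustesResult(t0, 1.0 - t0**2, rotation)


def protest(
    X: np.ndarray,
    Y: np.ndarray,
    n_permutations: int = 999,
    seed: int | None = None,
) -> ProcrustesResult:
    """Procrustes permutation test.

    Permutes the row pairing of Y n_permutations times; the p-value is
    (#{t_perm >= t0} + 1) / (n_permutations + 1), so it is never zero.
    """
    base = procrustes_fit(X, Y)
    Xc, Yc = _center_scale(np.asarray(X, float)), _center_scale(np.asarray(Y, float))
    rng = np.random.default_rng(seed)
    n = Xc.shape[0]
    hits = 0
    for _ in range(n_permutations):
        perm = rng.permutation(n)
        s = np.linalg.svd(Xc.T @ Yc[perm], compute_uv=False)
        if min(s.sum(), 1.0) >= base.t0 - 1e-12:
            hits += 1
    p = (hits + 1) / (n_permutations + 1)
    return ProcrustesResult(base.t0, base.m12_squared, base.rotation, p, n_permutations)


def paired_sample_ids(
    metadata: pd.DataFrame, type_a: str, type_b: str
) -> tuple[list, list]:
    """Sample ids of two community types paired by (site, replicate).

    Samples of one excavated unit share a specimen id; across patches of
    the same site the pairing falls back to the site/replicate design, so
    any two community types with complete designs yield n_site x n_rep
    pairs, in deterministic sorted order.
    """
    out = []
    for ct in (type_a, type_b):
        sub = metadata[metadata["community_type"] == ct]
        key = list(zip(sub["site_id"].astype(str), sub["replicate"].astype(int)))
        if len(set(key)) != len(key):
            raise ValueError(f"community type {ct!r} has duplicate (site, replicate) keys")
        out.append(dict(zip(key, sub.index)))
    shared = sorted(set(out[0]) & set(out[1]))
    if not shared:
        raise ValueError(f"no shared (site, replicate) keys between {type_a} and {type_b}")
    return [out[0][k] for k in shared], [out[1][k] for k in shared]


@dataclasses.dataclass(frozen=True)
class LeaveOneOutRecord:
    rank: str
    clade: str
    n_features_excluded: int
    t_excluded: float | None
    delta_t: float | None
    skipped: bool = False
    note: str = ""


def _clade_features(table: FeatureTable, taxonomy: pd.DataFrame, rank: str) -> dict:
    """clade name -> feature ids of the table assigned to it (unassigned dropped)."""
    if rank not in TAXONOMY_RANKS:
        raise KeyError(f"unknown taxonomic rank {rank!r}")
    tax = taxonomy.loc[list(table.feature_ids), rank]
    clades: dict[str, list] = {}
    for fid, clade in tax.items():
        if clade == UNASSIGNED:
            continue
        clades.setdefault(str(clade), []).append(fid)
    return clades


def _loo_over(
    clades: dict,
    rank: str,
    table: FeatureTable,
    tree,
    host_scores: np.ndarray,
    t0_baseline: float,
    axes: int,
    normalized: bool,
) -> list[LeaveOneOutRecord]:
    records = []
    for clade in sorted(clades):
        feats = clades[clade]
        sub = table.drop_features(feats)
        if sub.n_features == 0 or np.any(sub.sample_totals() == 0):
            records.append(
                LeaveOneOutRecord(
                    rank, clade, len(feats), None, None, True,
                    "exclusion empties at least one sample",
                )
            )
            continue
        ordn = pcoa(weighted_unifrac(sub, tree, normalized=normalized))
        if ordn.n_axes < axes:
            records.append(
                LeaveOneOutRecord(
                    rank, clade, len(feats), None, None, True,
                    f"fewer than {axes} positive ordination axes after exclusion",
                )
            )
            continue
        t_excl = procrustes_fit(host_scores, ordn.axes(axes)).t0
        records.append(
            LeaveOneOutRecord(rank, clade, len(feats), t_excl, t_excl - t0_baseline)
        )
    return records


def leave_one_out(
    parasite_table: FeatureTable,
    taxonomy: pd.DataFrame,
    tree,
    host_scores: np.ndarray,
    t0_baseline: float,
    rank: str = "phylum",
    axes: int = 2,
    normalized: bool = True,
) -> list[LeaveOneOutRecord]:
    """Recompute congruence after excluding each clade at `rank` in turn.

    The parasite table's samples must be ordered to pair the rows of
    host_scores (see paired_sample_ids). The host ordination is never
    recomputed; only the parasite distances/PCoA change. Clades whose
    exclusion empties a parasite sample are flagged and skipped.
    """
    if host_scores.shape[0] != parasite_table.n_samples:
        raise ValueError("host_scores rows must pair the parasite table's samples")
    clades = _clade_features(parasite_table, taxonomy, rank)
    return _loo_over(
        clades, rank, parasite_table, tree, host_scores, t0_baseline, axes, normalized
    )


def drill_down(
    records: list[LeaveOneOutRecord],
    parasite_table: FeatureTable,
    taxonomy: pd.DataFrame,
    tree,
    host_scores: np.ndarray,
    t0_baseline: float,
    top_k: int = 3,
    axes: int = 2,
    normalized: bool = True,
) -> list[LeaveOneOutRecord]:
    """Leave-one-out at order rank within the top_k phyla by |delta_t|."""
    if top_k <= 0:
        return []
    # clades whose wholesale exclusion was infeasible (it emptied samples)
    # are exactly the ones worth drilling into, so they rank first
    blocked = [r for r in records if r.skipped]
    scored = sorted(
        (r for r in records if not r.skipped and r.delta_t is not None),
        key=lambda r: abs(r.delta_t),
        reverse=True,
    )
    top_phyla = {r.clade for r in (blocked + scored)[:top_k]}
    orders = _clade_features(parasite_table, taxonomy, "order")
    tax = taxonomy.loc[list(parasite_table.feature_ids)]
    keep = {}
    for order_name, feats in orders.items():
        phyla = set(tax.loc[feats, "phylum"])
        if phyla & top_phyla:
            keep[order_name] = feats
    return _loo_over(
        keep, "order", parasite_table, tree, host_scores, t0_baseline, axes, normalized
    )


def records_to_frame(records: list[LeaveOneOutRecord]) -> pd.DataFrame:
    return pd.DataFrame([dataclasses.asdict(r) for r in records])
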