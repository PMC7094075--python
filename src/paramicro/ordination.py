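"""Weighted UniFrac distances and principal coordinates analysis.

Weighted UniFrac compares two communities on a shared rooted phylogeny:
each branch contributes its length times the absolute difference in the
proportion of reads descending from it. The normalized variant divides by
the abundance-weighted total branch length, bounding distances in [0, 1]
and removing dependence on overall tree depth. Proportions are computed
from relative abundances, so the metric is library-size independent.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from skbio import DistanceMatrix, TreeNode

from .core_io import FeatureTable, ValidationError


def _branch_profile(table: FeatureTable, tree: TreeNode) -> tuple[np.ndarray, np.ndarray]:
    """Per-branch descendant proportions.

    Returns (lengths, P) where P[b, s] is the fraction of sample s's reads
    descending through branch b. One row per non-root node.
    """
    totals = table.sample_totals().astype(float)
    if np.any(totals == 0):
        j = int(np.flatnonzero(totals == 0)[0])
        raise ValidationError(f"sample {table.sample_ids[j]!r} has zero total reads")
    props = table.counts / totals[None, :]
    feat_idx = {f: i for i, f in enumerate(table.feature_ids)}

    n_s = table.n_samples
    lengths, rows = [], []
    node_prop: dict[int, np.ndarray] = {}
    for node in tree.postorder(include_self=True):
        if node.is_tip():
            i = feat_idx.get(node.name)
            p = props[i] if i is not None else np.zeros(n_s)
        else:
            p = np.zeros(n_s)
            for c in node.children:
                p = p + node_prop.pop(id(c))
        node_prop[id(node)] = p
        if node.parent is not None:
            lengths.append(node.length or 0.0)
            rows.append(p)
    return np.asarray(lengths), np.asarray(rows)


def weighted_unifrac(
    table: FeatureTable, tree: TreeNode, normalized: bool = True
) -> DistanceMatrix:
    """Pairwise weighted UniFrac distances between the table's samples."""
    missing = set(table.feature_ids) - {t.name for t in tree.tips()}
    if missing:
        raise ValidationError(f"table features absent from tree: {sorted(missing)[:5]}")
    lengths, prof = _branch_profile(table, tree)
    n = table.n_samples
    dm = np.zeros((n, n))
    for i in range(n):
        diff = np.abs(prof[:, i : i + 1] - prof[:, i + 1 :])
        raw = lengths @ diff
        if normalized:
            denom = lengths @ (prof[:, i : i + 1] + prof[:, i + 1 :])
            with np.errstate(invalid="ignore", divide="ignore"):
                raw = np.where(denom > 0, raw / denom, 0.0)
        dm[i, i + 1 :] = raw
    dm = dm + dm.T
    return DistanceMatrix(dm, ids=list(table.sample_ids))


@dataclasses.dataclass(frozen=True)
class Ordination:
    """PCoA result: sample scores on the positive-eigenvalue axes.

    eigenvalues holds the full descending spectrum (negative values
    included, for diagnostics); scores has one column per positive
    eigenvalue and column sums of squares equal to the eigenvalue.
    proportion_explained is relative to the sum of positive eigenvalues.
    """

    sample_ids: tuple
    scores: np.ndarray
    eigenvalues: np.ndarray
    proportion_explained: np.ndarray

    @property
    def n_axes(self) -> int:
        return self.scores.shape[1]

    def axes(self, k: int) -> np.ndarray:
        """First k axes of the sample scores (error if fewer are positive)."""
        if k > self.n_axes:
            raise ValueError(f"only {self.n_axes} positive axes available, asked for {k}")
        return self.scores[:, :k]


def pcoa(dm: DistanceMatrix, eps: float = 1e-10) -> Ordination:
    """Classical (metric) multidimensional scaling of a distance matrix.

    Double-centers -D^2/2, eigendecomposes, and keeps the axes whose
    eigenvalues exceed eps times the largest. Negative-eigenvalue axes are
    recorded in the spectrum but excluded from the scores; no Lingoes or
    Cailliez correction is applied.
    """
    d = np.asarray(dm.data, dtype=float)
    if not np.allclose(d, d.T, atol=1e-8):
        raise ValidationError("distance matrix is not symmetric")
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d**2) @ j
    evals, evecs = np.linalg.eigh((b + b.T) / 2)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    pos = evals > eps * max(evals.max(), 1.0)
    scores = evecs[:, pos] * np.sqrt(evals[pos])[None, :]
    pos_sum = evals[pos].sum()
    prop = evals[pos] / pos_sum if pos_sum > 0 else np.zeros(pos.sum())
    return Ordination(tuple(dm.ids), scores, evals, prop)
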