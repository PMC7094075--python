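"""Per-sample alpha diversity: richness, inverse Simpson, evenness, Faith's PD."""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from skbio import TreeNode

from .core_io import FeatureTable


@dataclasses.dataclass(frozen=True)
class AlphaDiversityRecord:
    """Diversity of one sample.

    richness -- number of features with at least one read.
    inverse_simpson -- 1 / sum(p_i^2); ranges from 1 (single dominant
        feature) to richness (perfectly even).
    evenness -- inverse_simpson / richness, in (0, 1].
    faith_pd -- total branch length of the minimal subtree spanning the
        observed features (and the root, by the study's convention);
        None when no tree was supplied.
    """

    richness: int
    inverse_simpson: float
    evenness: float
    faith_pd: float | None = None


def alpha_diversity(sample_counts: np.ndarray) -> AlphaDiversityRecord:
    x = np.asarray(sample_counts, dtype=float)
    if np.any(x < 0):
        raise ValueError("counts must be non-negative")
    total = x.sum()
    if total == 0:
        raise ValueError("all-zero sample has no diversity")
    richness = int((x > 0).sum())
    p = x / total
    inv_simpson = 1.0 / float((p**2).sum())
    return AlphaDiversityRecord(richness, inv_simpson, inv_simpson / richness)


def faith_pd(
    sample_counts: np.ndarray,
    feature_ids,
    tree: TreeNode,
    include_root: bool = True,
) -> float:
    """Faith's phylogenetic diversity of one sample.

    Sums the branch lengths of the minimal subtree connecting the present
    tips; with include_root (the default, matching the convention of the
    community-phylogenetics tooling this mirrors) the subtree is anchored
    at the tree root, so a single present tip contributes its full
    root-to-tip path.
    """
    x = np.asarray(sample_counts, dtype=float)
    present = {f for f, c in zip(feature_ids, x) if c > 0}
    if not present:
        return 0.0
    tips = {t.name for t in tree.tips()}
    missing = present - tips
    if missing:
        raise KeyError(f"features not in tree: {sorted(missing)[:5]}")

    # bottom-up: a branch counts if any present tip lies below it
    pd_total = 0.0
    has_present: dict[int, bool] = {}
    spanning: list[TreeNode] = []
    for node in tree.postorder(include_self=True):
        if node.is_tip():
            hit = node.name in present
        else:
            hit = any(has_present[id(c)] for c in node.children)
        has_present[id(node)] = hit
        if hit and node.parent is not None:
            pd_total += node.length or 0.0
            spanning.append(node)
    if not include_root:
        # walk down from the root while the present tips lie in a single child
        node = tree
        while True:
            hot = [c for c in node.children if has_present[id(c)]]
            if len(hot) != 1 or hot[0].is_tip():
                break
            node = hot[0]
            pd_total -= node.length or 0.0
    return pd_total


def alpha_diversity_table(table: FeatureTable, tree: TreeNode | None = None) -> pd.DataFrame:
    """All alpha metrics for every sample of a feature table."""
    rows = {}
    for j, sid in enumerate(table.sample_ids):
        rec = alpha_diversity(table.counts[:, j])
        pd_val = (
            faith_pd(table.counts[:, j], table.feature_ids, tree) if tree is not None else np.nan
        )
        rows[sid] = {
            "richness": rec.richness,
            "inverse_simpson": rec.inverse_simpson,
            "evenness": rec.evenness,
            "faith_pd": pd_val,
        }
    return pd.DataFrame.from_dict(rows, orient="index").rename_axis("sample_id")
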