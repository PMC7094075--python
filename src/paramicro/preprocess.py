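"""Filtering and normalization of feature tables.

Implements the study-wide prevalence/abundance filter, proportional
(relative-abundance) normalization, rarefaction, the centered log-ratio
transform used for network displays, and the per-community node filter
applied before network inference.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np

from .core_io import FeatureTable, ValidationError


@dataclasses.dataclass(frozen=True)
class PrevalenceFilterResult:
    table: FeatureTable
    retained_read_fraction: float
    n_features_dropped: int


def filter_prevalence(
    table: FeatureTable, min_samples: int = 5, min_reads: int = 25
) -> PrevalenceFilterResult:
    """Keep features with >= min_reads counts in >= min_samples samples.

    Thresholds are inclusive. Samples are never dropped. The retained
    read fraction (retained reads / total reads) is reported alongside.
    """
    if min_samples < 1 or min_reads < 1:
        raise ValueError("thresholds must be >= 1")
    if table.n_features == 0 or table.n_samples == 0:
        raise ValidationError("cannot filter an empty table")
    hits = (table.counts >= min_reads).sum(axis=1)
    keep = hits >= min_samples
    total = table.counts.sum()
    retained = table.counts[keep].sum()
    out = FeatureTable(
        tuple(f for f, k in zip(table.feature_ids, keep) if k),
        table.sample_ids,
        table.counts[keep],
    )
    frac = float(retained / total) if total > 0 else 0.0
    return PrevalenceFilterResult(out, frac, int((~keep).sum()))


def relative_abundance(table: FeatureTable) -> np.ndarray:
    """Per-sample proportions; columns sum to 1."""
    totals = table.sample_totals()
    if np.any(totals == 0):
        j = int(np.flatnonzero(totals == 0)[0])
        raise ValidationError(f"sample {table.sample_ids[j]!r} has zero total reads")
    return table.counts / totals[None, :]


@dataclasses.dataclass(frozen=True)
class RarefyResult:
    table: FeatureTable
    dropped_samples: tuple


def rarefy(table: FeatureTable, depth: int = 1000, seed: int | None = None) -> RarefyResult:
    """Subsample each sample to `depth` reads without replacement.

    Samples with fewer than `depth` total reads are dropped and reported.
    Draws are multivariate hypergeometric, so every retained column sums
    to exactly `depth`.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    rng = np.random.default_rng(seed)
    totals = table.sample_totals()
    keep_ids, cols = [], []
    dropped = []
    for j, sid in enumerate(table.sample_ids):
        if totals[j] < depth:
            dropped.append(sid)
            continue
        keep_ids.append(sid)
        if totals[j] == depth:
            cols.append(table.counts[:, j])
        else:
            cols.append(rng.multivariate_hypergeometric(table.counts[:, j], depth))
    counts = (
        np.column_stack(cols) if cols else np.zeros((table.n_features, 0), dtype=np.int64)
    )
    return RarefyResult(
        FeatureTable(table.feature_ids, tuple(keep_ids), counts), tuple(dropped)
    )


def clr_transform(table: FeatureTable, pseudocount: float = 1.0) -> np.ndarray:
    """Centered log-ratio transform of counts, per sample.

    log(x + pseudocount) minus the per-sample mean of the logs; each
    column of the result sums to zero.
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    logs = np.log(table.counts + pseudocount)
    return logs - logs.mean(axis=0, keepdims=True)


def clr_from_matrix(counts: np.ndarray, pseudocount: float = 1.0) -> np.ndarray:
    """clr of a raw features x samples count matrix (no FeatureTable needed)."""
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    logs = np.log(np.asarray(counts, dtype=float) + pseudocount)
    return logs - logs.mean(axis=0, keepdims=True)


def filter_network_nodes(
    table: FeatureTable, min_reads: int = 10, min_sample_frac: float = 0.5
) -> FeatureTable:
    """Node filter applied per community type before network inference.

    Keeps features with >= min_reads in at least ceil(min_sample_frac * n)
    samples. The caller is expected to pass a single community type's
    samples; the filter itself is community-agnostic.
    """
    if table.n_features == 0 or table.n_samples == 0:
        raise ValidationError("cannot filter an empty table")
    need = math.ceil(min_sample_frac * table.n_samples)
    hits = (table.counts >= min_reads).sum(axis=1)
    keep = hits >= need
    return FeatureTable(
        tuple(f for f, k in zip(table.feature_ids, keep) if k),
        table.sample_ids,
        table.counts[keep],
    )
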