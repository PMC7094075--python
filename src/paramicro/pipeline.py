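"""End-to-end orchestration of the paired host-parasite analysis.

One call runs: prevalence filtering -> alpha diversity -> weighted
UniFrac + PCoA -> the Procrustes congruence grid over community-type
pairs -> leave-one-out clade attribution (phylum rank, then drill-down to
orders) -> per-community co-association networks with statistics and
pairwise bootstrap-KS comparisons. Every stage writes plain TSV; a JSON
manifest records every threshold and derived sub-seed so a rerun with the
same config is byte-identical.
"""

from __future__ import annotations

import dataclasses
import itertools
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .congruence import (
    drill_down,
    leave_one_out,
    paired_sample_ids,
    procrustes_fit,
    protest,
    records_to_frame,
)
from .core_io import AnalysisBundle, write_distance_matrix, write_network
from .diversity import alpha_diversity_table
from .networks import (
    bootstrap_centrality_ks,
    network_stats,
    sparcc_correlations,
    sparcc_pvalues,
    threshold_edges,
)
from .ordination import pcoa, weighted_unifrac
from .preprocess import clr_from_matrix, filter_network_nodes, filter_prevalence

logger = logging.getLogger("paramicro")


class StageError(RuntimeError):
    """A pipeline stage failed; earlier outputs are kept on disk."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclasses.dataclass(frozen=True)
class StudyConfig:
    """All thresholds of the study, with the published values as defaults."""

    min_samples: int = 5
    min_reads: int = 25
    node_min_reads: int = 10
    node_min_sample_frac: float = 0.5
    min_abs_corr: float = 0.6
    alpha: float = 0.05
    n_permutations: int = 999
    sparcc_inner_iterations: int = 20
    sparcc_bootstrap: int = 100
    ks_k: int = 50
    ks_reps: int = 10000
    axes: int = 2
    procrustes_pairs: tuple | None = None  # None -> all pairs of present types
    loo_comparisons: tuple = (("PR", "IIR"), ("PL", "IIR"))
    loo_top_k: int = 3
    network_communities: tuple | None = None  # None -> all with enough nodes
    seed: int = 0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = [list(x) if isinstance(x, tuple) else x for x in v]
        return d


def _sub_seeds(master: int, names: list[str]) -> dict:
    children = np.random.SeedSequence(master).spawn(len(names))
    return {nm: int(c.generate_state(1)[0] % (2**31)) for nm, c in zip(names, children)}


def _bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (an extension over the raw
    permutation p-values the study reports)."""
    p = np.asarray(p, float)
    n = len(p)
    order = np.argsort(p)
    ranked = p[order] * n / (np.arange(n) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.clip(ranked, 0, 1)
    return out


def run_study(bundle: AnalysisBundle, config: StudyConfig, out_dir) -> dict:
    """Run the full analysis and return the report (also written to disk)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _sub_seeds(config.seed, ["protest", "sparcc", "sparcc_boot", "ks"])
    report: dict = {"config": config.to_dict(), "seeds": seeds, "stages": {}}

    # --- filtering ---------------------------------------------------
    try:
        filt = filter_prevalence(bundle.table, config.min_samples, config.min_reads)
        table = filt.table
        report["stages"]["filter"] = {
            "n_features_in": bundle.table.n_features,
            "n_features_retained": table.n_features,
            "retained_read_fraction": filt.retained_read_fraction,
        }
    except Exception as e:  # noqa: BLE001
        raise StageError("filter", e) from e

    md = bundle.metadata
    taxonomy = bundle.taxonomy.loc[list(table.feature_ids)]

    # --- alpha diversity ---------------------------------------------
    try:
        alpha = alpha_diversity_table(table, bundle.tree)
        alpha.to_csv(out / "alpha_diversity.tsv", sep="\t")
        report["stages"]["alpha"] = {"path": "alpha_diversity.tsv"}
    except Exception as e:  # noqa: BLE001
        raise StageError("alpha", e) from e

    # --- global beta diversity ---------------------------------------
    try:
        dm_all = weighted_unifrac(table, bundle.tree)
        write_distance_matrix(dm_all, out / "weighted_unifrac.tsv")
        ord_all = pcoa(dm_all)
        k = min(3, ord_all.n_axes)
        pd.DataFrame(
            ord_all.scores[:, :k],
            index=list(ord_all.sample_ids),
            columns=[f"PCoA{i + 1}" for i in range(k)],
        ).to_csv(out / "pcoa_scores.tsv", sep="\t", index_label="sample_id")
        report["stages"]["beta"] = {
            "proportion_explained": ord_all.proportion_explained[:k].tolist()
        }
    except Exception as e:  # noqa: BLE001
        raise StageError("beta", e) from e

    # --- per-community ordinations ------------------------------------
    types = [ct for ct in md["community_type"].unique()]
    ords: dict = {}
    for ct in types:
        ids = list(md.index[md["community_type"] == ct])
        if len(ids) < 3:
            logger.info("skipping ordination for %s: fewer than 3 samples", ct)
            continue
        sub = table.select_samples(ids)
        if np.any(sub.sample_totals() == 0):
            logger.info("skipping ordination for %s: empty sample after filtering", ct)
            continue
        ords[ct] = pcoa(weighted_unifrac(sub, bundle.tree))

    # --- Procrustes grid ----------------------------------------------
    try:
        pairs = (
            [tuple(p) for p in config.procrustes_pairs]
            if config.procrustes_pairs is not None
            else list(itertools.combinations(sorted(ords), 2))
        )
        rows = []
        rng_seed = seeds["protest"]
        for i, (a, b) in enumerate(pairs):
            if a not in ords or b not in ords:
                logger.info("skipping pair %s:%s (no ordination)", a, b)
                continue
            ids_a, ids_b = paired_sample_ids(md, a, b)
            if len(ids_a) < 3:
                logger.info("skipping pair %s:%s (<3 paired samples)", a, b)
                continue
            if ords[a].n_axes < config.axes or ords[b].n_axes < config.axes:
                logger.info("skipping pair %s:%s (degenerate ordination)", a, b)
                continue
            pos_a = [ords[a].sample_ids.index(s) for s in ids_a]
            pos_b = [ords[b].sample_ids.index(s) for s in ids_b]
            xa = ords[a].axes(config.axes)[pos_a]
            xb = ords[b].axes(config.axes)[pos_b]
            res = protest(xa, xb, config.n_permutations, seed=rng_seed + i)
            rows.append(
                {
                    "type_a": a,
                    "type_b": b,
                    "n_pairs": len(ids_a),
                    "t0": res.t0,
                    "m12_squared": res.m12_squared,
                    "p_perm": res.permutation_p,
                }
            )
        grid = pd.DataFrame(rows)
        if len(grid):
            grid["p_bh"] = _bh_adjust(grid["p_perm"].to_numpy())
        grid.to_csv(out / "procrustes_grid.tsv", sep="\t", index=False)
        report["stages"]["procrustes"] = {
            "n_pairs": len(grid),
            "grid": grid.to_dict(orient="records"),
        }
    except Exception as e:  # noqa: BLE001
        raise StageError("procrustes", e) from e

    # --- leave-one-out attribution ------------------------------------
    try:
        loo_frames = []
        for para_ct, host_ct in config.loo_comparisons:
            if para_ct not in ords or host_ct not in ords:
                logger.info("skipping leave-one-out %s:%s", para_ct, host_ct)
                continue
            if ords[para_ct].n_axes < config.axes or ords[host_ct].n_axes < config.axes:
                continue
            ids_p, ids_h = paired_sample_ids(md, para_ct, host_ct)
            pos_h = [ords[host_ct].sample_ids.index(s) for s in ids_h]
            host_scores = ords[host_ct].axes(config.axes)[pos_h]
            para_table = table.select_samples(ids_p)
            base_ord = pcoa(weighted_unifrac(para_table, bundle.tree))
            t0 = procrustes_fit(host_scores, base_ord.axes(config.axes)).t0
            recs = leave_one_out(
                para_table, taxonomy, bundle.tree, host_scores, t0,
                rank="phylum", axes=config.axes,
            )
            drill = drill_down(
                recs, para_table, taxonomy, bundle.tree, host_scores, t0,
                top_k=config.loo_top_k, axes=config.axes,
            )
            df = records_to_frame(recs + drill)
            df.insert(0, "comparison", f"{para_ct}:{host_ct}")
            df.insert(1, "t0_baseline", t0)
            loo_frames.append(df)
        if loo_frames:
            loo_all = pd.concat(loo_frames, ignore_index=True)
            loo_all.to_csv(out / "leave_one_out.tsv", sep="\t", index=False)
            report["stages"]["leave_one_out"] = {"n_records": len(loo_all)}
    except Exception as e:  # noqa: BLE001
        raise StageError("leave_one_out", e) from e

    # --- networks ------------------------------------------------------
    try:
        net_types = (
            list(config.network_communities)
            if config.network_communities is not None
            else [ct for ct in sorted(types) if ct != "SOIL"]
        )
        stats_rows, betweenness = {}, {}
        for ct in net_types:
            ids = list(md.index[md["community_type"] == ct])
            if len(ids) < 3:
                continue
            sub = filter_network_nodes(
                table.select_samples(ids), config.node_min_reads, config.node_min_sample_frac
            )
            if sub.n_features < 4:
                logger.info("skipping network for %s: %d nodes", ct, sub.n_features)
                continue
            rho = sparcc_correlations(
                sub,
                inner_iterations=config.sparcc_inner_iterations,
                seed=seeds["sparcc"],
            ).correlations
            pmat = sparcc_pvalues(
                sub,
                n_bootstrap=config.sparcc_bootstrap,
                seed=seeds["sparcc_boot"],
                inner_iterations=config.sparcc_inner_iterations,
            )
            clr = clr_from_matrix(sub.counts)
            attrs = pd.DataFrame(
                {
                    "mean_clr": clr.mean(axis=1),
                    "phylum": taxonomy.loc[list(sub.feature_ids), "phylum"].to_numpy(),
                },
                index=list(sub.feature_ids),
            )
            net = threshold_edges(
                rho, pmat, sub.feature_ids, config.min_abs_corr, config.alpha, attrs
            )
            write_network(net, out / f"network_{ct}.tsv", "edge-tsv")
            write_network(net, out / f"network_{ct}.graphml", "graphml")
            st = network_stats(net)
            stats_rows[ct] = {
                "n_nodes": net.n_nodes,
                "n_edges": net.n_edges,
                "edge_density": st.edge_density,
                "betweenness_centralization": st.betweenness_centralization,
                "mean_degree": float(st.degree.mean()),
                "mean_betweenness": float(st.betweenness.mean()),
            }
            betweenness[ct] = st.betweenness.to_numpy()
        if stats_rows:
            pd.DataFrame.from_dict(stats_rows, orient="index").rename_axis(
                "community_type"
            ).to_csv(out / "network_stats.tsv", sep="\t")
        ks_rows = []
        for i, (a, b) in enumerate(itertools.combinations(sorted(betweenness), 2)):
            res = bootstrap_centrality_ks(
                betweenness[a], betweenness[b], config.ks_k, config.ks_reps,
                seed=seeds["ks"] + i,
            )
            ks_rows.append(
                {"type_a": a, "type_b": b, "ks_D": res.statistic, "ks_p": res.pvalue}
            )
        if ks_rows:
            pd.DataFrame(ks_rows).to_csv(out / "network_ks.tsv", sep="\t", index=False)
        report["stages"]["networks"] = {"stats": stats_rows, "ks": ks_rows}
    except Exception as e:  # noqa: BLE001
        raise StageError("networks", e) from e

    with open(out / "manifest.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return report
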