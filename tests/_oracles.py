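"""Independent brute-force oracles used to validate the fast implementations.

Each oracle computes the same quantity as the library by explicit
enumeration, with no code shared with the implementation under test.
"""

import itertools

import networkx as nx
import numpy as np


def brute_unifrac(table, tree, normalized=True):
    """Weighted UniFrac by explicit enumeration of every branch's tip set."""
    props = table.counts / table.counts.sum(axis=0, keepdims=True)
    prop_of = dict(zip(table.feature_ids, props))
    branches = []
    for node in tree.traverse(include_self=False):
        if node.is_tip():
            tip_set = {node.name}
        else:
            tip_set = {t.name for t in node.tips()}
        branches.append((node.length or 0.0, tip_set))
    n = table.n_samples
    dm = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        raw = denom = 0.0
        for length, tips in branches:
            pi = sum(prop_of[t][i] for t in tips if t in prop_of)
            pj = sum(prop_of[t][j] for t in tips if t in prop_of)
            raw += length * abs(pi - pj)
            denom += length * (pi + pj)
        d = raw / denom if (normalized and denom > 0) else (raw if not normalized else 0.0)
        dm[i, j] = dm[j, i] = d
    return dm


def brute_faith_pd(present_tips, tree):
    """Faith's PD as the union of every present tip's root path."""
    spanning = set()
    for tip in tree.tips():
        if tip.name in present_tips:
            node = tip
            while node.parent is not None:
                spanning.add(id(node))
                node = node.parent
    total = 0.0
    for node in tree.traverse(include_self=False):
        if id(node) in spanning:
            total += node.length or 0.0
    return total


def brute_betweenness(g: nx.Graph) -> dict:
    """Betweenness by exhaustive path enumeration (small graphs only)."""
    btw = {v: 0.0 for v in g.nodes}
    for s, t in itertools.combinations(list(g.nodes), 2):
        paths = list(nx.all_simple_paths(g, s, t))
        if not paths:
            continue
        shortest = min(len(p) for p in paths)
        sp = [p for p in paths if len(p) == shortest]
        for p in sp:
            for v in p[1:-1]:
                btw[v] += 1.0 / len(sp)
    return btw


def brute_ks(a, b) -> float:
    """Two-sample KS statistic by scanning every observed point."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    pts = np.concatenate([a, b])
    return max(abs((a <= x).mean() - (b <= x).mean()) for x in pts)


def f1_edges(found, truth) -> float:
    found = {tuple(sorted(e)) for e in found}
    truth = {tuple(sorted(e)) for e in truth}
    if not found and not truth:
        return 1.0
    tp = len(found & truth)
    prec = tp / len(found) if found else 0.0
    rec = tp / len(truth) if truth else 0.0
    return 2 * prec * rec / (prec + rec) if prec + rec else 0.0
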