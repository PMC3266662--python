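"""Metabolic-network analysis: homology-based model transfer, reporter
metabolites, and enriched-path detection on the gene projection graph.

The network is a bipartite graph of gene and metabolite nodes. Gene nodes
carry correlation p-values (one-sided, per tail), transformed to z-scores
by z = Phi^-1(1 - p).

Reporter metabolites score each metabolite by the collective extremeness of
its neighboring genes: Z_raw = sum_i z_i / sqrt(k) over the k adjacent
genes, background-corrected against the mean and SD of the same statistic
over random size-k gene draws, with p = 1 - Phi(Z_corrected).

Enriched paths are maximum-score simple paths of fixed length k in the
gene projection graph (genes adjacent when they share a metabolite), found
with the color-coding randomized dynamic program: each of n_colorings
trials assigns k random colors and keeps the best "colorful" path (all
colors distinct), which finds the true optimum with probability
>= 1 - (1 - k!/k^k)^n_colorings. Path significance is an empirical p-value
from shuffling node weights over nodes (and edge weights over edges) with
the add-one estimator; overlapping significant paths are merged by gene-set
union.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

_P_FLOOR = 1e-15


class NetworkError(ValueError):
    """Invalid input to the network analysis."""


# ---------------------------------------------------------------------------
# Bidirectional-best-hit model transfer


@dataclass
class BBHResult:
    mapping: pd.DataFrame  # columns source, target, score_fwd, score_rev
    reactions: dict[str, list[str]]  # target gene -> transferred reaction ids


def _best_hits(scores: pd.DataFrame) -> dict[str, str]:
    """Unique best hit per query; ties are skipped with a warning."""
    best: dict[str, str] = {}
    for query, sub in scores.groupby("query"):
        top = sub["bitscore"].max()
        winners = sub.loc[sub["bitscore"] == top, "subject"].unique()
        if len(winners) > 1:
            logger.warning("query %s has tied best hits; skipped", query)
            continue
        best[str(query)] = str(winners[0])
    return best


def bbh_transfer(
    score_table: pd.DataFrame,
    reactions: Mapping[str, Sequence[str]],
    cutoff: float = 50.0,
    require_both: bool = False,
) -> BBHResult:
    """Transfer reactions from source-species genes to reciprocal best hits.

    A source/target gene pair is mapped iff each is the other's unique best
    hit and the bit score exceeds *cutoff* in at least one direction
    (``require_both=True`` demands both). Reactions of mapped source genes
    are copied onto the target gene. The mapping is an injective partial
    matching by construction.
    """
    required = {"query", "subject", "bitscore"}
    if not required <= set(score_table.columns):
        raise NetworkError(f"score table must have columns {sorted(required)}")
    best = _best_hits(score_table)
    pair_score = {
        (str(q), str(s)): float(b)
        for q, s, b in score_table[["query", "subject", "bitscore"]].itertuples(
            index=False
        )
    }
    rows = []
    out_reactions: dict[str, list[str]] = {}
    for source in sorted(reactions):
        target = best.get(source)
        if target is None or best.get(target) != source:
            continue
        fwd = pair_score.get((source, target), float("-inf"))
        rev = pair_score.get((target, source), float("-inf"))
        passed = (fwd > cutoff and rev > cutoff) if require_both else (
            fwd > cutoff or rev > cutoff
        )
        if not passed:
            continue
        rows.append(
            {"source": source, "target": target, "score_fwd": fwd, "score_rev": rev}
        )
        out_reactions[target] = list(reactions[source])
    mapping = pd.DataFrame(rows, columns=["source", "target", "score_fwd", "score_rev"])
    return BBHResult(mapping=mapping, reactions=out_reactions)


def bidirectional_scores(mapping: pd.DataFrame) -> dict[str, float]:
    """Per target gene, the product of its two directional bit scores."""
    return {
        str(t): float(f) * float(r)
        for t, f, r in mapping[["target", "score_fwd", "score_rev"]].itertuples(
            index=False
        )
    }


# ---------------------------------------------------------------------------
# Reporter metabolites


def reporter_metabolites(
    edges: pd.DataFrame,
    gene_pvalues: pd.Series,
    n_background: int = 1000,
    seed: int = 0,
    p_cut: float = 0.05,
    min_genes: int = 2,
    filtered: bool = True,
) -> pd.DataFrame:
    """Background-corrected reporter-metabolite scores.

    *edges* has columns gene_id, metabolite_id. Genes without a p-value are
    excluded from a metabolite's neighborhood (and from k). Returns a
    DataFrame with columns metabolite_id, k, z_raw, z_corrected, p,
    significant; with ``filtered=True`` only rows at p < p_cut and
    k >= min_genes are kept.
    """
    pvals = gene_pvalues.dropna()
    if (pvals <= 0).any() or (pvals > 1).any():
        raise NetworkError("gene p-values must lie in (0, 1]")
    z = pd.Series(
        stats.norm.isf(np.clip(pvals.to_numpy(dtype=float), _P_FLOOR, 1.0)),
        index=pvals.index,
    )
    neighbor_z: dict[str, np.ndarray] = {}
    for met, sub in edges.groupby("metabolite_id"):
        genes = sub["gene_id"].unique()
        zz = z.reindex(genes).dropna().to_numpy()
        if len(zz):
            neighbor_z[str(met)] = zz
    if not neighbor_z:
        return pd.DataFrame(
            columns=["metabolite_id", "k", "z_raw", "z_corrected", "p", "significant"]
        )
    all_z = z.to_numpy()
    rng = np.random.default_rng(seed)
    mu_sd: dict[int, tuple[float, float]] = {}
    ks = sorted({len(v) for v in neighbor_z.values()})
    for k in ks:
        draws = rng.choice(all_z, size=(n_background, k), replace=True)
        bg = draws.sum(axis=1) / np.sqrt(k)
        sd = float(bg.std(ddof=0))
        # degenerate backgrounds (all gene p equal) would divide by ~0
        mu_sd[k] = (float(bg.mean()), sd if sd > 1e-9 else 1.0)
    rows = []
    for met in sorted(neighbor_z):
        zz = neighbor_z[met]
        k = len(zz)
        z_raw = float(zz.sum() / np.sqrt(k))
        mu, sd = mu_sd[k]
        z_corr = (z_raw - mu) / sd
        p = float(stats.norm.sf(z_corr))
        rows.append(
            {
                "metabolite_id": met,
                "k": k,
                "z_raw": z_raw,
                "z_corrected": z_corr,
                "p": max(p, _P_FLOOR),
                "significant": p < p_cut and k >= min_genes,
            }
        )
    table = pd.DataFrame(rows).sort_values("p", kind="mergesort").reset_index(drop=True)
    if filtered:
        table = table[table["significant"]].reset_index(drop=True)
    return table


# ---------------------------------------------------------------------------
# Gene projection graph


def gene_projection(
    edges: pd.DataFrame, gene_scores: Mapping[str, float] | None = None
) -> nx.Graph:
    """Project the bipartite network onto genes.

    Genes are adjacent when they share at least one metabolite. The edge
    weight is the product of the two genes' bidirectional-hit scores (see
    :func:`bidirectional_scores`), rescaled into (0, 1] by the maximum
    product; genes without a score receive the smallest observed score
    (weight 1 everywhere when no scores are given). Shared metabolites are
    recorded on the edge.
    """
    graph = nx.Graph()
    by_met = edges.groupby("metabolite_id")["gene_id"].unique()
    genes = sorted(edges["gene_id"].unique())
    graph.add_nodes_from(genes)
    if gene_scores:
        floor = min(gene_scores.values())
        score = {g: float(gene_scores.get(g, floor)) for g in genes}
    else:
        score = {g: 1.0 for g in genes}
    for met, gg in by_met.items():
        for u, v in itertools.combinations(sorted(gg), 2):
            if graph.has_edge(u, v):
                graph[u][v]["metabolites"].add(met)
            else:
                graph.add_edge(u, v, metabolites={met}, raw=score[u] * score[v])
    if graph.number_of_edges():
        top = max(d["raw"] for _, _, d in graph.edges(data=True))
        for _, _, d in graph.edges(data=True):
            d["weight"] = d.pop("raw") / top
    return graph


# ---------------------------------------------------------------------------
# Path search


@dataclass
class PathSearch:
    path: tuple[str, ...]
    score: float


def _path_score(
    path: Sequence[int], node_scores: np.ndarray, log_w: dict | None, lam: float
) -> float:
    s = float(node_scores[list(path)].sum())
    if lam and log_w is not None:
        s += lam * sum(
            log_w[(min(a, b), max(a, b))] for a, b in zip(path[:-1], path[1:])
        )
    return s


def enumerate_simple_paths(adj: list[list[int]], k: int) -> list[tuple[int, ...]]:
    """All simple paths with exactly k nodes, each undirected path once
    (canonical orientation: first node index < last node index)."""
    n = len(adj)
    paths: list[tuple[int, ...]] = []

    def extend(path: list[int], visited: set[int]) -> None:
        if len(path) == k:
            if path[0] <= path[-1]:
                paths.append(tuple(path))
            return
        for nxt in adj[path[-1]]:
            if nxt not in visited:
                visited.add(nxt)
                path.append(nxt)
                extend(path, visited)
                path.pop()
                visited.remove(nxt)

    for start in range(n):
        extend([start], {start})
    return paths


def _colorful_best_path(
    adj: list[list[int]],
    node_scores: np.ndarray,
    colors: np.ndarray,
    k: int,
    log_w: dict | None = None,
    lam: float = 0.0,
) -> tuple[float, tuple[int, ...]] | None:
    """Best simple path of k nodes whose colors are pairwise distinct.

    Dynamic program over (end node, used color set) states; the color set
    bound makes every returned path simple.
    """
    # state: (node, colorset) -> (score, path tuple)
    table: dict[tuple[int, int], tuple[float, tuple[int, ...]]] = {}
    for v in range(len(adj)):
        table[(v, 1 << colors[v])] = (float(node_scores[v]), (v,))
    for _ in range(k - 1):
        nxt_table: dict[tuple[int, int], tuple[float, tuple[int, ...]]] = {}
        for (v, cset), (score, path) in table.items():
            for u in adj[v]:
                cu = 1 << colors[u]
                if cset & cu:
                    continue
                s = score + float(node_scores[u])
                if lam and log_w is not None:
                    s += lam * log_w[(min(u, v), max(u, v))]
                key = (u, cset | cu)
                if key not in nxt_table or s > nxt_table[key][0]:
                    nxt_table[key] = (s, path + (u,))
        table = nxt_table
        if not table:
            return None
    best = max(table.values(), key=lambda t: t[0], default=None)
    return best


def color_coding_best_path(
    graph: nx.Graph,
    node_scores: Mapping[str, float],
    k: int,
    n_colorings: int = 300,
    seed: int | np.random.Generator = 0,
    lam: float = 0.0,
) -> PathSearch | None:
    """Highest-scoring simple path of k nodes by color coding."""
    nodes, adj, scores, log_w = _graph_arrays(graph, node_scores)
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    best: tuple[float, tuple[int, ...]] | None = None
    for _ in range(n_colorings):
        colors = rng.integers(0, k, size=len(nodes))
        res = _colorful_best_path(adj, scores, colors, k, log_w, lam)
        if res is not None and (best is None or res[0] > best[0]):
            best = res
    if best is None:
        return None
    return PathSearch(path=tuple(nodes[i] for i in best[1]), score=best[0])


def _graph_arrays(graph: nx.Graph, node_scores: Mapping[str, float]):
    nodes = sorted(graph.nodes)
    index = {g: i for i, g in enumerate(nodes)}
    adj: list[list[int]] = [[] for _ in nodes]
    log_w: dict[tuple[int, int], float] = {}
    for u, v, d in graph.edges(data=True):
        iu, iv = index[u], index[v]
        adj[iu].append(iv)
        adj[iv].append(iu)
        log_w[(min(iu, iv), max(iu, iv))] = float(
            np.log(max(d.get("weight", 1.0), 1e-300))
        )
    scores = np.array([float(node_scores[g]) for g in nodes])
    return nodes, adj, scores, log_w


# ---------------------------------------------------------------------------
# EMPath


@dataclass
class PathResult:
    gene_ids: tuple[str, ...]
    k: int
    score: float
    p: float


@dataclass
class MergedPath:
    gene_ids: tuple[str, ...]  # union of member path genes, sorted
    p: float  # smallest member p
    members: list[PathResult] = field(default_factory=list)


@dataclass
class EmpathResult:
    paths: list[PathResult]  # best path per length k, with empirical p
    merged: list[MergedPath]  # significant paths merged by gene-set overlap


def node_scores_from_pvalues(pvalues: Mapping[str, float]) -> dict[str, float]:
    """z = Phi^-1(1 - p) node scores from one-sided correlation p-values."""
    return {
        g: float(stats.norm.isf(np.clip(p, _P_FLOOR, 1.0 - _P_FLOOR)))
        for g, p in pvalues.items()
    }


def empath(
    graph: nx.Graph,
    node_pvalues: Mapping[str, float],
    k_min: int = 3,
    k_max: int = 12,
    n_shuffle: int = 10_000,
    n_colorings: int = 300,
    seed: int = 0,
    p_cut: float = 0.025,
    lam: float = 0.0,
    method: str = "auto",
    max_enumeration: int = 200_000,
) -> EmpathResult:
    """Enriched-path detection with shuffle-null significance.

    For each path length k in [k_min, k_max] the maximum-score simple path
    is sought; its empirical p-value is the add-one fraction of
    weight-shuffled replicates (node weights permuted over nodes, edge
    weights over edges) whose best score reaches the observed one.
    Significant paths (p < p_cut) are merged by gene-set union into the
    final reported paths.

    method: 'enumerate' scores every simple path exactly (and vectorizes
    the shuffle null), 'color_coding' uses the randomized DP throughout,
    'auto' enumerates when the path count stays below *max_enumeration*.
    """
    if k_min < 2:
        raise NetworkError("k_min must be >= 2")
    if graph.number_of_nodes() == 0:
        return EmpathResult(paths=[], merged=[])
    k_max = min(k_max, graph.number_of_nodes())
    rng = np.random.default_rng(seed)
    nodes, adj, _, log_w = _graph_arrays(graph, {g: 0.0 for g in graph.nodes})
    scores_map = node_scores_from_pvalues(
        {g: node_pvalues[g] for g in graph.nodes}
    )
    scores = np.array([scores_map[g] for g in nodes])
    results: list[PathResult] = []
    for k in range(k_min, k_max + 1):
        paths = None
        use_enum = method == "enumerate"
        if method == "auto":
            paths = enumerate_simple_paths(adj, k)
            use_enum = len(paths) <= max_enumeration
            if not use_enum:
                paths = None
        elif use_enum:
            paths = enumerate_simple_paths(adj, k)
        if use_enum:
            if not paths:
                continue
            obs_score, obs_path = _best_by_enumeration(paths, scores, log_w, lam)
            null = _null_best_scores_enum(paths, scores, log_w, lam, n_shuffle, rng)
        else:
            found = color_coding_best_path(graph, scores_map, k, n_colorings, rng, lam)
            if found is None:
                continue
            obs_score, obs_path = found.score, tuple(nodes.index(g) for g in found.path)
            null = np.empty(n_shuffle)
            for i in range(n_shuffle):
                perm = rng.permutation(scores)
                shuffled = {g: perm[j] for j, g in enumerate(nodes)}
                res = color_coding_best_path(graph, shuffled, k, n_colorings, rng, lam)
                null[i] = res.score if res is not None else -np.inf
        p = (1 + int((null >= obs_score - 1e-12).sum())) / (1 + n_shuffle)
        results.append(
            PathResult(
                gene_ids=tuple(nodes[i] for i in obs_path),
                k=k,
                score=float(obs_score),
                p=float(p),
            )
        )
    merged = merge_significant_paths([r for r in results if r.p < p_cut])
    return EmpathResult(paths=results, merged=merged)


def _best_by_enumeration(paths, scores, log_w, lam):
    mat = np.array(paths)
    totals = scores[mat].sum(axis=1)
    if lam:
        totals = totals + lam * np.array(
            [
                sum(log_w[(min(a, b), max(a, b))] for a, b in zip(p[:-1], p[1:]))
                for p in paths
            ]
        )
    i = int(np.argmax(totals))
    return float(totals[i]), paths[i]


def _null_best_scores_enum(paths, scores, log_w, lam, n_shuffle, rng):
    mat = np.array(paths)
    if lam:
        # edge weights are shuffled over edges; with lam != 0 recompute per draw
        keys = list({e for p in paths for e in zip(p[:-1], p[1:])})
    null = np.empty(n_shuffle)
    for i in range(n_shuffle):
        perm = rng.permutation(scores)
        totals = perm[mat].sum(axis=1)
        if lam:
            vals = rng.permutation([log_w[(min(a, b), max(a, b))] for a, b in keys])
            lw = dict(zip(((min(a, b), max(a, b)) for a, b in keys), vals))
            totals = totals + lam * np.array(
                [sum(lw[(min(a, b), max(a, b))] for a, b in zip(p[:-1], p[1:])) for p in paths]
            )
        null[i] = totals.max()
    return null


def merge_significant_paths(paths: list[PathResult]) -> list[MergedPath]:
    """Union-merge paths whose gene sets overlap (transitively)."""
    if not paths:
        return []
    overlap = nx.Graph()
    overlap.add_nodes_from(range(len(paths)))
    for i, j in itertools.combinations(range(len(paths)), 2):
        if set(paths[i].gene_ids) & set(paths[j].gene_ids):
            overlap.add_edge(i, j)
    merged = []
    for comp in nx.connected_components(overlap):
        members = [paths[i] for i in sorted(comp)]
        genes = sorted(set().union(*(m.gene_ids for m in members)))
        merged.append(
            MergedPath(
                gene_ids=tuple(genes),
                p=min(m.p for m in members),
                members=members,
            )
        )
    merged.sort(key=lambda m: m.p)
    return merged
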