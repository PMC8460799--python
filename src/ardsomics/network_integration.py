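"""Multi-omic integration over a protein-protein interaction network.

Two integration routes produce candidate ARDS-mortality gene sets:

* the *network* route runs an edge-weighted dense module search on the
  PPI graph, with node weights the normal quantiles of gene-association
  p-values and edge weights the Fisher-z standardized change in gene
  co-expression between non-survivors and survivors; the top 0.1% of
  size-normalized modules are pooled and intersected with differential
  methylation (any probe raw p < 0.05);
* the *overlap* route intersects per-omic gene lists at a loosened raw
  p < 0.05 threshold across the gene-based GWAS, RNA-seq differential
  expression, and gene-level methylation (minimum probe p).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ModuleSearchParams",
    "Module",
    "WeightedPpiNetwork",
    "CandidateGeneSet",
    "node_weights",
    "edge_weights",
    "build_network",
    "module_score",
    "dense_module_search",
    "normalize_module_scores",
    "select_top_modules",
    "methylation_filter",
    "gene_level_methylation_p",
    "overlap_gene_approach",
]

P_CLAMP = 1e-16


@dataclass
class ModuleSearchParams:
    """Tunables of the greedy edge-weighted dense module search."""

    lam: float = 0.5          # edge/node score mix in [0, 1]
    expansion_rate: float = 0.1   # r: require S_new >= S_old * (1 + r)
    neighbor_depth: int = 1
    top_fraction: float = 0.001
    n_random_norm: int = 100  # random size-matched modules per size
    seed: int = 0


@dataclass
class Module:
    genes: list  # insertion order
    score_raw: float
    seed_gene: str
    score_norm: float = math.nan


@dataclass
class WeightedPpiNetwork:
    """PPI graph restricted to scored genes, with node and edge weights."""

    graph: nx.Graph
    node_z: dict = field(default_factory=dict)
    edge_z: dict = field(default_factory=dict)  # (a, b) sorted tuple -> z

    def get_edge_z(self, a, b) -> float:
        return self.edge_z.get((a, b) if a < b else (b, a), 0.0)


@dataclass
class CandidateGeneSet:
    genes: list
    provenance: str  # "network" or "overlap"
    evidence: pd.DataFrame | None = None


def node_weights(gene_p: dict) -> dict:
    """Gene-association p-values to node z-weights, z = Phi^-1(1 - p)."""
    out = {}
    for gene, p in gene_p.items():
        p = min(max(float(p), P_CLAMP), 1.0 - P_CLAMP)
        out[gene] = float(stats.norm.isf(p))
    return out


def edge_weights(expr: pd.DataFrame, groups: pd.Series, edges) -> dict:
    """Differential co-expression edge weights.

    For each edge (i, j): the within-group Pearson correlations are
    Fisher-z transformed and their absolute standardized difference,
    ``|atanh(r1) - atanh(r0)| / sqrt(1/(n1-3) + 1/(n0-3))``, is the edge
    weight.  Edges touching a gene constant within a group get weight 0
    with a warning.
    """
    g = groups.loc[expr.columns].to_numpy()
    n1 = int((g == 1).sum())
    n0 = int((g == 0).sum())
    if min(n0, n1) < 4:
        raise ValueError("need at least 4 subjects per group for edge weights")
    x = expr.to_numpy(dtype=float)
    gene_idx = {gene: i for i, gene in enumerate(expr.index)}
    scale = math.sqrt(1.0 / (n1 - 3) + 1.0 / (n0 - 3))

    def _corr_matrix(cols):
        sub = x[:, cols]
        sd = sub.std(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            r = np.corrcoef(sub)
        return np.atleast_2d(r), sd

    r1, sd1 = _corr_matrix(g == 1)
    r0, sd0 = _corr_matrix(g == 0)
    out = {}
    warned = False
    for a, b in edges:
        if a not in gene_idx or b not in gene_idx:
            continue
        i, j = gene_idx[a], gene_idx[b]
        if sd1[i] == 0 or sd1[j] == 0 or sd0[i] == 0 or sd0[j] == 0:
            if not warned:
                warnings.warn("constant gene within a group; edge weight set to 0",
                              stacklevel=2)
                warned = True
            z = 0.0
        else:
            c1 = np.clip(r1[i, j], -0.999999, 0.999999)
            c0 = np.clip(r0[i, j], -0.999999, 0.999999)
            z = abs(math.atanh(c1) - math.atanh(c0)) / scale
        out[(a, b) if a < b else (b, a)] = float(z)
    return out


def build_network(ppi_edges: pd.DataFrame, gene_p: dict, expr: pd.DataFrame,
                  groups: pd.Series) -> WeightedPpiNetwork:
    """Assemble the weighted network from PPI edges, association p, expression.

    Only genes present in both the association results and the
    expression matrix are retained (and only PPI edges between them).
    """
    usable = set(gene_p) & set(expr.index)
    edges = [(a, b) for a, b in ppi_edges[["gene_a", "gene_b"]].itertuples(index=False)
             if a in usable and b in usable and a != b]
    graph = nx.Graph()
    graph.add_nodes_from(sorted(usable))
    graph.add_edges_from(edges)
    nz = node_weights({g: gene_p[g] for g in usable})
    ez = edge_weights(expr.loc[sorted(usable)], groups, edges)
    return WeightedPpiNetwork(graph=graph, node_z=nz, edge_z=ez)


def module_score(genes, network: WeightedPpiNetwork, lam: float = 0.5) -> float:
    """Combined module score.

    ``S = (1 - lam) * sum(node_z) / sqrt(k) + lam * sum(edge_z) / sqrt(max(m, 1))``
    over the module's k genes and m induced edges.
    """
    genes = list(genes)
    k = len(genes)
    if k == 0:
        raise ValueError("empty module")
    node_sum = sum(network.node_z.get(g, 0.0) for g in genes)
    gene_set = set(genes)
    edge_sum = 0.0
    m = 0
    for i, a in enumerate(genes):
        for b in network.graph.neighbors(a):
            if b in gene_set and a < b:
                edge_sum += network.get_edge_z(a, b)
                m += 1
    return ((1.0 - lam) * node_sum / math.sqrt(k)
            + lam * edge_sum / math.sqrt(max(m, 1)))


def _grow_module(seed_gene: str, network: WeightedPpiNetwork,
                 params: ModuleSearchParams) -> Module:
    """Greedy expansion from one seed node.

    At each step every candidate within ``neighbor_depth`` of the module
    that touches it by an edge is scored; the best is added if
    ``S_new >= S_old * (1 + r)``.  Ties break by higher node z, then
    lexicographic gene id.
    """
    lam = params.lam
    adj = network.graph.adj
    members = [seed_gene]
    member_set = {seed_gene}
    node_sum = network.node_z.get(seed_gene, 0.0)
    edge_sum = 0.0
    m_edges = 0
    score = module_score(members, network, lam)
    while True:
        # nodes within depth d of the module
        frontier = set()
        seen = set(member_set)
        layer = member_set
        for _ in range(params.neighbor_depth):
            nxt = set()
            for u in layer:
                for v in adj[u]:
                    if v not in seen:
                        nxt.add(v)
            seen |= nxt
            frontier |= nxt
            layer = nxt
        best = None  # (score, node_z, -ord) for max
        for v in frontier:
            links = [u for u in adj[v] if u in member_set]
            if not links:
                continue  # keep the induced subgraph connected
            add_edge = sum(network.get_edge_z(v, u) for u in links)
            k_new = len(members) + 1
            m_new = m_edges + len(links)
            s_new = ((1.0 - lam) * (node_sum + network.node_z.get(v, 0.0))
                     / math.sqrt(k_new)
                     + lam * (edge_sum + add_edge) / math.sqrt(max(m_new, 1)))
            key = (s_new, network.node_z.get(v, 0.0), v)
            if best is None or (key[0], key[1]) > (best[0], best[1]) or (
                    (key[0], key[1]) == (best[0], best[1]) and v < best[2]):
                best = (s_new, key[1], v, add_edge, len(links))
        if best is None:
            break
        s_new, _, v, add_edge, n_links = best
        # require a relative improvement of at least r (S_old * (1 + r) for
        # positive scores; |S_old|-scaled for non-positive ones)
        required = score + params.expansion_rate * abs(score)
        if s_new < required or s_new <= score:
            break
        members.append(v)
        member_set.add(v)
        node_sum += network.node_z.get(v, 0.0)
        edge_sum += add_edge
        m_edges += n_links
        score = s_new
    return Module(genes=members, score_raw=score, seed_gene=seed_gene)


def dense_module_search(network: WeightedPpiNetwork,
                        params: ModuleSearchParams | None = None) -> list:
    """One greedily grown module per seed node, with normalized scores.

    Deterministic given the network and parameters: expansion tie-breaks
    are total, and the size-matched random-module normalization is
    seeded from ``params.seed``.
    """
    if params is None:
        params = ModuleSearchParams()
    if network.graph.number_of_nodes() == 0:
        raise ValueError("empty network")
    modules = [_grow_module(g, network, params)
               for g in sorted(network.graph.nodes)]
    normalize_module_scores(modules, network, params)
    return modules


def _random_connected_module(network: WeightedPpiNetwork, size: int,
                             rng: np.random.Generator) -> list:
    """Uniform-ish random connected subgraph by randomized neighbor growth."""
    nodes = network._node_list  # cached below
    adj = network.graph.adj
    for _ in range(20):  # retry if stuck in a small component
        start = nodes[rng.integers(len(nodes))]
        members = [start]
        member_set = {start}
        frontier = [v for v in adj[start]]
        while len(members) < size and frontier:
            v = frontier.pop(rng.integers(len(frontier)))
            if v in member_set:
                continue
            members.append(v)
            member_set.add(v)
            frontier.extend(u for u in adj[v] if u not in member_set)
        if len(members) == size:
            return members
    return members  # degenerate small component; best effort


def normalize_module_scores(modules: list, network: WeightedPpiNetwork,
                            params: ModuleSearchParams) -> None:
    """Attach size-matched normalized scores in place.

    For each distinct module size k, ``n_random_norm`` random connected
    modules of size k are scored; ``score_norm = (S - mu_k) / sigma_k``.
    """
    rng = np.random.default_rng(params.seed)
    network._node_list = sorted(network.graph.nodes)
    null_by_size = {}
    for size in sorted({len(m.genes) for m in modules}):
        draws = np.array([
            module_score(_random_connected_module(network, size, rng),
                         network, params.lam)
            for _ in range(params.n_random_norm)])
        mu = float(draws.mean())
        sigma = float(draws.std(ddof=1))
        null_by_size[size] = (mu, sigma if sigma > 0 else 1.0)
    for mod in modules:
        mu, sigma = null_by_size[len(mod.genes)]
        mod.score_norm = (mod.score_raw - mu) / sigma


def select_top_modules(modules: list, top_fraction: float = 0.001,
                       use_raw: bool = False):
    """Keep the top fraction of modules and pool their genes.

    Modules are ranked by normalized score (raw score with
    ``use_raw=True``); ``ceil(top_fraction * N)`` modules are retained.
    Returns ``(gene_list, kept_modules)``.
    """
    if not modules:
        return [], []
    key = (lambda m: (-m.score_raw, m.seed_gene)) if use_raw else (
        lambda m: (-m.score_norm, -m.score_raw, m.seed_gene))
    ranked = sorted(modules, key=key)
    n_keep = int(math.ceil(top_fraction * len(ranked)))
    kept = ranked[:n_keep]
    genes = sorted(set().union(*(set(m.genes) for m in kept)))
    return genes, kept


def gene_level_methylation_p(dm_results: pd.DataFrame) -> pd.Series:
    """Gene-level methylation p as the minimum probe raw p per gene."""
    return dm_results.groupby("gene_id")["p_raw"].min()


def methylation_filter(genes, dm_results: pd.DataFrame,
                       p_max: float = 0.05) -> CandidateGeneSet:
    """Keep genes with any differentially methylated probe (raw p < p_max).

    ``dm_results`` must carry ``gene_id`` and ``p_raw`` columns (one row
    per probe).  Genes without any mapped probe are dropped with a
    warning.  The evidence table lists, per input gene, its best probe p
    and whether it qualified.
    """
    by_gene = dm_results.groupby("gene_id")["p_raw"].min()
    rows = []
    kept = []
    for gene in genes:
        if gene in by_gene.index:
            best = float(by_gene[gene])
            qualifies = best < p_max
            if qualifies:
                kept.append(gene)
            rows.append({"gene": gene, "min_probe_p": best, "methylated": qualifies})
        else:
            warnings.warn(f"{gene}: no methylation probes mapped; dropped",
                          stacklevel=2)
            rows.append({"gene": gene, "min_probe_p": np.nan, "methylated": False})
    return CandidateGeneSet(genes=sorted(kept), provenance="network",
                            evidence=pd.DataFrame(rows))


def overlap_gene_approach(gene_lists: dict, p_max: float = 0.05) -> CandidateGeneSet:
    """Loosened-threshold intersection across omic gene lists.

    ``gene_lists`` maps omic name -> {gene: raw p}.  A gene is kept when
    its p is strictly below ``p_max`` in every omic.
    """
    if not gene_lists:
        raise ValueError("no gene lists supplied")
    sets = []
    for omic, mapping in gene_lists.items():
        sets.append({g for g, p in mapping.items() if p < p_max})
    genes = sorted(set.intersection(*sets))
    evid = pd.DataFrame({
        omic: pd.Series({g: mapping.get(g, np.nan) for g in genes})
        for omic, mapping in gene_lists.items()
    })
    return CandidateGeneSet(genes=genes, provenance="overlap", evidence=evid)
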