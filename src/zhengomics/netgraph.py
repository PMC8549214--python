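"""Graph analytics: label propagation and integrated subnetwork extraction.

Gene prioritisation uses Zhou-style label propagation with symmetric
normalisation: F = alpha*S*F + (1-alpha)*Y with S = D^(-1/2) W D^(-1/2),
iterated to a fixed point that equals (1-alpha)(I - alpha*S)^(-1) Y.  Seeded
genes (e.g. differential proteins) diffuse score mass to functionally
associated neighbours; the top-scoring non-seeds augment the seed list for
PPI-network construction.  Metabolite-gene subnetworks are induced on
matched seeds plus "bridge" nodes adjacent to at least two seeds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import scipy.sparse as sp

logger = logging.getLogger(__name__)


@dataclass
class PropagationResult:
    scores: dict            # node -> score (>= 0)
    seeds: set
    alpha: float
    tol: float
    iterations: int
    converged: bool


def _normalized_adjacency(g: nx.Graph, nodes: list) -> sp.csr_matrix:
    w = nx.to_scipy_sparse_array(g, nodelist=nodes, weight="weight", format="csr")
    deg = np.asarray(w.sum(axis=1)).ravel()
    with np.errstate(divide="ignore"):
        dinv = 1.0 / np.sqrt(deg)
    dinv[~np.isfinite(dinv)] = 0.0
    d = sp.diags(dinv)
    return d @ w @ d


def label_propagate(
    g: nx.Graph,
    seeds,
    alpha: float = 0.5,
    tol: float = 1e-9,
    max_iter: int = 1000,
) -> PropagationResult:
    """Propagate seed labels over the network.

    Iterates F <- alpha*S*F + (1-alpha)*Y until the sup-norm change drops
    below ``tol``.  Nodes in components containing no seed keep score 0; an
    isolated seed keeps exactly (1-alpha).
    """
    seeds = set(seeds)
    if not seeds <= set(g.nodes):
        raise ValueError("seeds must be nodes of the network")
    if not (0 <= alpha < 1):
        raise ValueError("alpha must be in [0, 1)")
    nodes = sorted(g.nodes)
    y = np.array([1.0 if n in seeds else 0.0 for n in nodes])
    if alpha == 0:
        return PropagationResult(dict(zip(nodes, y)), seeds, alpha, tol, 0, True)
    s = _normalized_adjacency(g, nodes)
    f = y.copy()
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        f_new = alpha * (s @ f) + (1 - alpha) * y
        if np.max(np.abs(f_new - f)) < tol:
            f = f_new
            converged = True
            break
        f = f_new
    if not converged:
        logger.warning("label propagation did not converge in %d iterations", max_iter)
    return PropagationResult(dict(zip(nodes, f)), seeds, alpha, tol, it, converged)


def closed_form_propagate(g: nx.Graph, seeds, alpha: float = 0.5) -> dict:
    """Direct linear-solve fixed point (1-alpha)(I - alpha*S)^(-1) Y.

    Dense; intended for small networks and as an independent check of the
    iterative solver.
    """
    seeds = set(seeds)
    nodes = sorted(g.nodes)
    y = np.array([1.0 if n in seeds else 0.0 for n in nodes])
    s = _normalized_adjacency(g, nodes).toarray()
    f = np.linalg.solve(np.eye(len(nodes)) - alpha * s, (1 - alpha) * y)
    return dict(zip(nodes, f))


def expand_top_k(
    g: nx.Graph, result: PropagationResult, k: int = 10
) -> tuple[list, nx.Graph]:
    """Seeds plus the k top-scoring non-seed nodes, with induced subgraph.

    Ties break by (score descending, node id ascending) so the expansion is
    reproducible.
    """
    if not result.converged:
        raise ValueError("propagation did not converge")
    non_seeds = [(n, s) for n, s in result.scores.items() if n not in result.seeds and s > 0]
    if k > len(non_seeds):
        logger.warning("only %d scorable non-seeds available (k=%d)", len(non_seeds), k)
    ranked = sorted(non_seeds, key=lambda ns: (-ns[1], ns[0]))
    chosen = [n for n, _ in ranked[:k]]
    nodes = sorted(result.seeds) + chosen
    return nodes, g.subgraph(nodes).copy()


def extract_metabolite_gene_network(
    g: nx.Graph,
    seed_mets,
    seed_genes,
    signature_targets=None,
    include_degree1: bool = False,
) -> nx.Graph:
    """Integrated subnetwork on matched seeds and bridge nodes.

    Keeps (i) seed metabolites/genes present in the graph and (ii) non-seed
    nodes adjacent to >= 2 matched seeds ("bridges"; >= 1 with
    ``include_degree1``).  Matched seeds left without any edge in the
    induced subgraph are dropped.  Node attribute ``origin`` records
    DM / DP / signature / bridge provenance.
    """
    seed_mets, seed_genes = set(seed_mets), set(seed_genes)
    sig = set(signature_targets or ())
    all_seeds = seed_mets | seed_genes | sig
    matched = all_seeds & set(g.nodes)
    unmatched = all_seeds - matched
    if unmatched:
        logger.info("%d seed ids not present in the network", len(unmatched))
    if not matched:
        logger.warning("no seed matched the network; returning empty graph")
        return nx.Graph()

    min_links = 1 if include_degree1 else 2
    bridges = {
        n
        for n in g.nodes
        if n not in matched and sum(1 for nb in g.neighbors(n) if nb in matched) >= min_links
    }
    sub = g.subgraph(matched | bridges).copy()
    sub.remove_nodes_from([n for n in matched if sub.degree(n) == 0])
    for n in sub.nodes:
        if n in seed_mets:
            origin = "DM"
        elif n in seed_genes:
            origin = "DP"
        elif n in sig:
            origin = "signature"
        else:
            origin = "bridge"
        sub.nodes[n]["origin"] = origin
    return sub
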