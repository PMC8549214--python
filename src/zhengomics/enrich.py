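"""Over-representation analysis and kappa-based annotation clustering.

ORA tests a query list against named annotation sets inside a universe
using the hypergeometric upper tail: with N universe items, K term members,
n query items and k overlaps, p = P(X >= k).  Joint queries (genes +
metabolites) run the same single test on the combined namespace.  Term
redundancy is summarised DAVID-style: pairwise Cohen's kappa between term
membership profiles, greedy seed-and-merge clustering, and a cluster
enrichment score of -log10(geometric mean of member p-values).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

# "High" classification stringency surrogate: minimum kappa for a
# similarity link, minimum number of linked partners for a cluster seed,
# and the shared-membership fraction at which two groups merge.
STRINGENCY_PRESETS = {
    "high": {"kappa": 0.85, "m0": 3, "linkage": 0.5},
    "medium": {"kappa": 0.50, "m0": 3, "linkage": 0.5},
    "low": {"kappa": 0.35, "m0": 2, "linkage": 0.5},
}


def percentage(k_mapped: int, n_input: int) -> float:
    """Report percentage 100*k/n rounded to 2 decimals."""
    if n_input <= 0:
        raise ValueError("input list must be non-empty")
    if k_mapped > n_input:
        raise ValueError("mapped count exceeds input size")
    return round(100.0 * k_mapped / n_input, 2)


def ora(query, sets: dict[str, set], universe) -> pd.DataFrame:
    """Hypergeometric over-representation of ``query`` in each annotation set.

    Rows carry term, k (overlap), K (term size in universe), n (query size
    in universe), N (universe size), p (upper tail), q (BH across the
    tested terms) and the report percentage 100*k/|query|; sorted by
    (p ascending, term ascending).
    """
    universe = set(universe)
    query = set(query)
    n_input = len(query)
    eff_query = query & universe
    if not eff_query:
        raise ValueError("query has no members in the universe")
    n = len(eff_query)
    big_n = len(universe)
    rows = []
    for term in sorted(sets):
        members = set(sets[term]) & universe
        big_k = len(members)
        k = len(eff_query & members)
        p = float(stats.hypergeom.sf(k - 1, big_n, big_k, n))
        rows.append((term, k, big_k, n, big_n, p, percentage(k, n_input)))
    out = pd.DataFrame(rows, columns=["term", "k", "K", "n", "N", "p", "percentage"])
    out["q"] = multipletests(out["p"].to_numpy(), method="fdr_bh")[1]
    out = out.sort_values(["p", "term"], kind="mergesort").reset_index(drop=True)
    return out[["term", "k", "K", "n", "N", "p", "q", "percentage"]]


def joint_ora(genes, mets, joint_sets: dict[str, set], joint_universe) -> pd.DataFrame:
    """Single combined-query hypergeometric test per mixed gene+metabolite term.

    Gene and metabolite id namespaces must be disjoint; the query is their
    union over the joint universe.
    """
    genes, mets = set(genes), set(mets)
    if genes & mets:
        raise ValueError(f"gene/metabolite namespaces collide: {sorted(genes & mets)[:5]}")
    return ora(genes | mets, joint_sets, joint_universe)


# ---------------------------------------------------------------------------
# kappa clustering
# ---------------------------------------------------------------------------

def kappa_matrix(items, annotations: dict[str, set]) -> pd.DataFrame:
    """Pairwise Cohen's kappa between term membership profiles over ``items``.

    Each term defines a binary profile over the item set; kappa is computed
    from the 2x2 agreement table.  Degenerate pairs (expected agreement 1)
    get kappa 0 with a warning; the diagonal is 1.
    """
    items = sorted(set(items))
    terms = sorted(annotations)
    if len(terms) < 2:
        raise ValueError("need at least 2 terms")
    profiles = np.array([[1 if it in annotations[t] else 0 for it in items] for t in terms])
    n_terms = len(terms)
    kap = np.eye(n_terms)
    n_items = len(items)
    for i in range(n_terms):
        for j in range(i + 1, n_terms):
            a, b = profiles[i], profiles[j]
            po = float((a == b).mean())
            pa, pb = a.mean(), b.mean()
            pe = pa * pb + (1 - pa) * (1 - pb)
            if pe == 1.0:
                logger.warning("degenerate term pair (%s, %s); kappa set to 0", terms[i], terms[j])
                k = 0.0
            else:
                k = (po - pe) / (1 - pe)
            kap[i, j] = kap[j, i] = k
    _ = n_items
    return pd.DataFrame(kap, index=terms, columns=terms)


@dataclass
class TermCluster:
    members: list
    score: float      # -log10(geometric mean of member p-values)
    rank: int


def cluster_terms(
    enrichment: pd.DataFrame,
    kappa: pd.DataFrame,
    stringency: str = "high",
) -> list[TermCluster]:
    """Greedy seed-and-merge clustering of enriched terms.

    A term seeds a group when it has >= m0 partners at kappa >= the
    stringency threshold; its group is the term plus those partners.
    Groups merge while any pair shares >= the linkage fraction of the
    smaller group.  Terms in no merged group become singletons.  Cluster
    enrichment score = -log10(geometric mean of member p-values); clusters
    are ranked by score descending.
    """
    preset = STRINGENCY_PRESETS[stringency]
    pvals = dict(zip(enrichment["term"], enrichment["p"]))
    terms = [t for t in kappa.index if t in pvals]

    groups: list[set] = []
    for t in terms:
        partners = {u for u in terms if u != t and kappa.loc[t, u] >= preset["kappa"]}
        if len(partners) >= preset["m0"]:
            groups.append({t} | partners)

    merged = True
    while merged:
        merged = False
        for i in range(len(groups)):
            for j in range(i + 1, len(groups)):
                shared = len(groups[i] & groups[j])
                if shared and shared / min(len(groups[i]), len(groups[j])) >= preset["linkage"]:
                    groups[i] |= groups[j]
                    del groups[j]
                    merged = True
                    break
            if merged:
                break

    clustered = set().union(*groups) if groups else set()
    for t in terms:
        if t not in clustered:
            groups.append({t})

    clusters = []
    for g in groups:
        members = sorted(g)
        logp = np.log10([max(pvals[m], 1e-300) for m in members])
        clusters.append(TermCluster(members, float(-logp.mean()), 0))
    clusters.sort(key=lambda c: (-c.score, c.members[0]))
    for rank, c in enumerate(clusters, start=1):
        c.rank = rank
    return clusters


# ---------------------------------------------------------------------------
# cross-view consistency
# ---------------------------------------------------------------------------

def cross_view_consistency(hits: dict[str, dict[str, set]]) -> pd.DataFrame:
    """Membership of significant pathway terms across analysis views.

    ``hits`` maps syndrome -> view -> set of significant terms, with views
    from {proteomics, metabolomics, integrated}.  Rows are (syndrome, term)
    with one boolean column per view, a ``flag`` ("consistent" when a term
    is hit by all supplied views of the syndrome, "<view>-only" when by
    exactly one), and ``shared_between_syndromes`` marking terms hit in
    more than one syndrome.
    """
    views = sorted({v for per_syn in hits.values() for v in per_syn})
    syn_terms = {
        syn: set().union(*per_syn.values()) if per_syn else set() for syn, per_syn in hits.items()
    }
    rows = []
    for syn in sorted(hits):
        for term in sorted(syn_terms[syn]):
            member = {v: term in hits[syn].get(v, set()) for v in views}
            n_hit = sum(member.values())
            if n_hit == len(views):
                flag = "consistent"
            elif n_hit == 1:
                only = next(v for v, m in member.items() if m)
                flag = f"{only}-only"
            else:
                flag = "partial"
            shared = sum(term in terms for terms in syn_terms.values()) > 1
            rows.append({"syndrome": syn, "term": term, **member, "flag": flag,
                         "shared_between_syndromes": shared})
    return pd.DataFrame(rows)
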