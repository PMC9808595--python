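"""Over-representation analysis and PPI hub scoring.

Annotations (GMT gene sets) and the interaction network (two-column edge
list) are user-supplied files: database-version-dependent term content is
explicitly out of reproducibility scope. The hypergeometric upper-tail test
follows the clusterProfiler convention; hub scores are plain degree or
Maximal Clique Centrality (cytoHubba's MCC: sum of (|C|-1)! over maximal
cliques C containing the node).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import networkx as nx
import pandas as pd
from scipy import stats

from pbscreen.enrichment import bh_adjust
from pbscreen.errors import ParseError, ValidationError


@dataclass
class GeneSet:
    term_id: str
    term_name: str
    genes: set[str]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValidationError(f"gene set {self.term_id} is empty")


@dataclass
class OraRecord:
    term_id: str
    term_name: str
    k: int  # DEGs in term
    K: int  # universe genes in term
    n: int  # DEG count
    N: int  # universe size
    p: float
    adj_p: float = 1.0


def read_gmt(path) -> list[GeneSet]:
    """Standard GMT: term_id <tab> description <tab> gene1 <tab> gene2 ..."""
    sets = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError(f"{path}:{lineno}: GMT line has < 3 fields")
            sets.append(GeneSet(parts[0], parts[1], set(g for g in parts[2:] if g)))
    return sets


def write_gmt(gene_sets: list[GeneSet], path) -> None:
    with open(path, "w") as fh:
        for gs in gene_sets:
            fh.write("\t".join([gs.term_id, gs.term_name, *sorted(gs.genes)]) + "\n")


def ora_test(
    deg_set: set[str], universe: set[str], gene_sets: list[GeneSet]
) -> list[OraRecord]:
    """Hypergeometric over-representation of the DEG list in each term.

    p = P(X >= k) for X ~ Hypergeometric(N, K, n), with N the universe
    size, K the term's genes in the universe, n the DEG count. Terms with
    no universe genes are skipped; an empty DEG list gives an empty result.
    BH adjustment runs across the tested terms.
    """
    deg = set(deg_set)
    uni = set(universe)
    if not deg <= uni:
        raise ValidationError("DEG set must be a subset of the universe")
    if not deg:
        return []
    n = len(deg)
    big_n = len(uni)
    records = []
    for gs in gene_sets:
        term = gs.genes & uni
        if not term:
            continue
        k = len(deg & term)
        p = float(stats.hypergeom.sf(k - 1, big_n, len(term), n))
        records.append(
            OraRecord(gs.term_id, gs.term_name, k, len(term), n, big_n, min(p, 1.0))
        )
    if records:
        adj = bh_adjust([r.p for r in records])
        for r, a in zip(records, adj):
            r.adj_p = float(a)
    return sorted(records, key=lambda r: (r.p, r.term_id))


def read_edge_list(path) -> nx.Graph:
    """Two-column TSV of undirected edges; self-loops and duplicates dropped."""
    g = nx.Graph()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ParseError(f"{path}:{lineno}: edge line has < 2 fields")
            a, b = parts[0], parts[1]
            if a != b:
                g.add_edge(a, b)
    return g


def extract_subnetwork(graph: nx.Graph, gene_set: set[str]) -> nx.Graph:
    """Induced subgraph on the genes present in the network."""
    return graph.subgraph(set(gene_set) & set(graph.nodes)).copy()


def hub_scores(graph: nx.Graph, method: str = "MCC") -> pd.Series:
    """Per-node hub score, ranked descending with gene-id tie-break.

    ``degree`` counts neighbors; ``MCC`` sums (|C|-1)! over the maximal
    cliques containing each node (Bron–Kerbosch enumeration). An isolated
    node scores 0 under both.
    """
    if method not in ("degree", "MCC"):
        raise ValidationError(f"unknown hub method {method!r}")
    if method == "degree":
        scores = {v: graph.degree(v) for v in graph.nodes}
    else:
        scores = {v: 0 for v in graph.nodes}
        for clique in nx.find_cliques(graph):
            if len(clique) < 2:
                continue  # an isolated node's trivial clique scores nothing
            contrib = math.factorial(len(clique) - 1)
            for v in clique:
                scores[v] += contrib
    s = pd.Series(scores, dtype=float)
    return s.sort_index().sort_values(ascending=False, kind="stable")


def ora_to_frame(records: list[OraRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "term_id": [r.term_id for r in records],
            "term_name": [r.term_name for r in records],
            "k": [r.k for r in records],
            "K": [r.K for r in records],
            "n": [r.n for r in records],
            "N": [r.N for r in records],
            "p": [r.p for r in records],
            "adj_p": [r.adj_p for r in records],
        }
    )
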