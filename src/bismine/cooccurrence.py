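"""Gene cooccurrence network over metagenome samples.

For each unordered pair of roster genes, the hit count of the lower of the
two genes in each sample is added to a running total; the resulting edge
weight counts how often the pair "occurred together" across all samples.
Node weight is a gene's total hit count.  Edge weights therefore never
exceed either endpoint's node weight.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import networkx as nx
import numpy as np
import pandas as pd


def pair_weight(counts_a, counts_b) -> int:
    """Sum over samples of the smaller of the two genes' hit counts."""
    a = np.asarray(counts_a)
    b = np.asarray(counts_b)
    if a.shape != b.shape:
        raise ValueError(f"count vectors differ in length: {a.shape} vs {b.shape}")
    if (a < 0).any() or (b < 0).any():
        raise ValueError("counts must be non-negative")
    return int(np.minimum(a, b).sum())


@dataclass
class CooccurrenceNetwork:
    """Node totals and symmetric min-count edge weights for the roster."""

    nodes: dict[str, int]
    edges: dict[tuple[str, str], int]  # keys are sorted (a, b) pairs, a < b

    def weight(self, a: str, b: str) -> int:
        if a == b:
            raise ValueError("no self-edges in a cooccurrence network")
        return self.edges[tuple(sorted((a, b)))]

    def to_networkx(self, drop_zero: bool = True) -> nx.Graph:
        g = nx.Graph()
        for gene, total in self.nodes.items():
            g.add_node(gene, total_hits=total)
        for (a, b), w in self.edges.items():
            if w > 0 or not drop_zero:
                g.add_edge(a, b, weight=w)
        return g

    def edge_frame(self) -> pd.DataFrame:
        rows = [
            {"gene_a": a, "gene_b": b, "weight": w}
            for (a, b), w in sorted(self.edges.items())
        ]
        return pd.DataFrame(rows)

    def node_frame(self) -> pd.DataFrame:
        rows = [{"gene": g, "total_hits": n} for g, n in sorted(self.nodes.items())]
        return pd.DataFrame(rows)


def build_network(count_matrix: pd.DataFrame) -> CooccurrenceNetwork:
    """Cooccurrence network from a samples x genes count matrix.

    All unordered gene pairs are defined (zero-weight edges may be dropped
    only on export).
    """
    values = count_matrix.to_numpy()
    if values.size and ((values < 0).any() or not np.issubdtype(values.dtype, np.number)):
        raise ValueError("count matrix must be non-negative numeric")
    genes = list(count_matrix.columns)
    nodes = {g: int(count_matrix[g].sum()) for g in genes}
    edges = {
        (a, b) if a < b else (b, a): pair_weight(count_matrix[a], count_matrix[b])
        for a, b in combinations(genes, 2)
    }
    return CooccurrenceNetwork(nodes=nodes, edges=edges)
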