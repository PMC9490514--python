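"""Compound–target and protein–protein interaction network construction,
and the three node centralities used for hub screening.

Conventions (frozen, matching common interactome-analysis practice):

* shortest paths are unweighted — interaction scores are used only for
  edge thresholding, never as path lengths;
* degree is the plain neighbor count;
* betweenness is the unnormalized shortest-path betweenness over
  unordered node pairs, endpoints excluded;
* closeness of node ``v`` is ``r(v) / sum of distances to reachable
  nodes``, with ``r(v)`` the number of nodes reachable from ``v`` —
  i.e. the reciprocal mean distance within v's connected component;
  an isolated node has closeness 0.

STRING-style edge lists come in two dialects: combined scores in
[0, 1] or in [0, 1000].  If any score in a file exceeds 1 the whole
file is read as the 0–1000 dialect and divided by 1000.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import pandas as pd

from .io_model import FormatError

__all__ = [
    "BipartiteNetwork",
    "PPINetwork",
    "UnknownNodeError",
    "build_ct_network",
    "read_string_edges",
    "build_ppi_network",
    "compute_centralities",
    "write_centrality_table",
    "write_graphml",
]

#: default STRING combined-score threshold ("high confidence")
DEFAULT_MIN_SCORE = 0.7

#: fixed compound-degree cutoff echoed in the degree report
DEGREE_FLAG_FLOOR = 7


class UnknownNodeError(ValueError):
    """A link references a compound or target absent from the node lists."""


@dataclass
class BipartiteNetwork:
    """Undirected compound–target network with a degree report.

    ``flagged_targets`` / ``flagged_compounds`` list the nodes whose
    degree is at least ``max(7, ceil(2 x median degree))`` of their node
    class — the high-degree flag used to call out promiscuous targets
    and broadly acting compounds.  It is a report, not a filter.
    """

    graph: nx.Graph
    compounds: tuple[str, ...]
    targets: tuple[str, ...]
    flagged_targets: tuple[str, ...]
    flagged_compounds: tuple[str, ...]
    target_flag_threshold: float
    compound_flag_threshold: float

    def degree(self, node: str) -> int:
        return self.graph.degree(node)

    def target_degrees(self) -> dict[str, int]:
        return {t: self.graph.degree(t) for t in self.targets}

    def compound_degrees(self) -> dict[str, int]:
        return {c: self.graph.degree(c) for c in self.compounds}


def _median(values: Sequence[float]) -> float:
    s = sorted(values)
    n = len(s)
    if n == 0:
        return 0.0
    mid = n // 2
    return float(s[mid]) if n % 2 else (s[mid - 1] + s[mid]) / 2.0


def _flag_threshold(degrees: Sequence[int]) -> float:
    return max(DEGREE_FLAG_FLOOR, math.ceil(2 * _median(degrees)))


def build_ct_network(
    compounds: Iterable[str],
    targets: Iterable[str],
    links: Iterable[tuple[str, str]],
) -> BipartiteNetwork:
    """Build the deduplicated bipartite compound–target graph.

    ``links`` are (compound_id, target_symbol) pairs; duplicates
    collapse to a single edge.  Links referencing unknown nodes raise
    :class:`UnknownNodeError` listing every offender.
    """
    comp = tuple(dict.fromkeys(compounds))
    targ = tuple(dict.fromkeys(targets))
    cset, tset = set(comp), set(targ)
    if cset & tset:
        raise UnknownNodeError(
            f"compound and target namespaces overlap: {sorted(cset & tset)}"
        )
    g = nx.Graph()
    g.add_nodes_from(comp, bipartite="compound")
    g.add_nodes_from(targ, bipartite="target")
    offenders = []
    for c, t in links:
        if c not in cset or t not in tset:
            offenders.append((c, t))
            continue
        g.add_edge(c, t)
    if offenders:
        raise UnknownNodeError(f"links reference unknown nodes: {offenders}")

    tdeg = [g.degree(t) for t in targ]
    cdeg = [g.degree(c) for c in comp]
    t_thr = _flag_threshold(tdeg)
    c_thr = _flag_threshold(cdeg)
    return BipartiteNetwork(
        graph=g,
        compounds=comp,
        targets=targ,
        flagged_targets=tuple(t for t in targ if g.degree(t) >= t_thr),
        flagged_compounds=tuple(c for c in comp if g.degree(c) >= c_thr),
        target_flag_threshold=t_thr,
        compound_flag_threshold=c_thr,
    )


@dataclass
class PPINetwork:
    """Simple undirected gene graph with combined scores in [0, 1].

    Nodes from the candidate list that survive no edge are kept as
    declared isolated nodes.
    """

    graph: nx.Graph
    min_score: float

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()


def read_string_edges(path: str | Path) -> list[tuple[str, str, float]]:
    """Parse a STRING-dialect TSV (protein1, protein2, combined_score).

    Auto-detects the score dialect: if any score exceeds 1 the file is
    taken to be on the 0–1000 scale and every score is divided by 1000.
    A score outside both ranges raises :class:`FormatError` with its
    line number.
    """
    rows: list[tuple[str, str, float]] = []
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    if not lines:
        return rows
    start = 0
    head = lines[0].replace("\t", " ").lower().split()
    if head[:2] == ["protein1", "protein2"]:
        start = 1
    for i, line in enumerate(lines[start:], start=start + 1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t") if "\t" in line else line.split()
        if len(parts) < 3:
            raise FormatError(f"{path}: line {i}: expected 3 columns, got {len(parts)}")
        try:
            score = float(parts[2])
        except ValueError:
            raise FormatError(f"{path}: line {i}: non-numeric score {parts[2]!r}") from None
        rows.append((parts[0].strip().upper(), parts[1].strip().upper(), score))

    if any(s > 1 for _, _, s in rows):
        # 0-1000 dialect
        for j, (a, b, s) in enumerate(rows):
            if not (0 <= s <= 1000):
                raise FormatError(
                    f"{path}: line {j + start + 1}: score {s} outside [0,1] and [0,1000]"
                )
            rows[j] = (a, b, s / 1000.0)
    else:
        for j, (a, b, s) in enumerate(rows):
            if not (0 <= s <= 1):
                raise FormatError(
                    f"{path}: line {j + start + 1}: score {s} outside [0,1] and [0,1000]"
                )
    return rows


def build_ppi_network(
    edges: Iterable[tuple[str, str, float]],
    min_score: float = DEFAULT_MIN_SCORE,
    candidates: Iterable[str] = (),
) -> PPINetwork:
    """Threshold, deduplicate and assemble the PPI graph.

    Edges with score below ``min_score`` are removed (inclusive: a score
    equal to the threshold is kept), self-loops dropped, and a pair seen
    twice keeps its maximum score.  ``candidates`` not present in any
    surviving edge are retained as isolated nodes.
    """
    best: dict[frozenset[str], float] = {}
    for a, b, s in edges:
        if a == b:
            continue
        key = frozenset((a, b))
        if s > best.get(key, -1.0):
            best[key] = s
    g = nx.Graph()
    g.add_nodes_from(dict.fromkeys(candidates))
    for key, s in best.items():
        if s >= min_score:
            a, b = sorted(key)
            g.add_edge(a, b, score=s)
    return PPINetwork(graph=g, min_score=min_score)


def compute_centralities(net: PPINetwork | nx.Graph) -> pd.DataFrame:
    """Degree, closeness and betweenness for every node.

    Returns a DataFrame indexed by node (sorted) with columns
    ``degree``, ``closeness``, ``betweenness``; empty graph gives an
    empty table.
    """
    g = net.graph if isinstance(net, PPINetwork) else net
    nodes = sorted(g.nodes)
    if not nodes:
        return pd.DataFrame(columns=["degree", "closeness", "betweenness"])
    deg = dict(g.degree())
    clo = nx.closeness_centrality(g, wf_improved=False)
    btw = nx.betweenness_centrality(g, normalized=False)
    return pd.DataFrame(
        {
            "degree": [deg[n] for n in nodes],
            "closeness": [clo[n] for n in nodes],
            "betweenness": [btw[n] for n in nodes],
        },
        index=pd.Index(nodes, name="node"),
    )


def write_centrality_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", lineterminator="\n")


def write_graphml(net: PPINetwork | BipartiteNetwork | nx.Graph, path: str | Path) -> None:
    """Cytoscape-importable GraphML export."""
    g = net.graph if hasattr(net, "graph") else net
    nx.write_graphml(g, path)
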