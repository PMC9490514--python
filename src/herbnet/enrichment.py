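"""Over-representation analysis and the compound–core-target–pathway network.

Enrichment is the classic one-sided hypergeometric (Fisher) test: for a
query of ``n`` genes drawn from a background universe of ``N`` genes,
and a gene set containing ``K`` background genes, the p-value of an
observed overlap ``k`` is ``P(X >= k)`` with
``X ~ Hypergeometric(N, K, n)``.  Benjamini–Hochberg step-up FDR is
appended across all tested terms.

The background universe is explicit, supplied by the caller (typically
the full candidate-target universe rather than the genome) — never an
implicit genome-wide default.

The compound–core-target–pathway (C-T-P) network is the tripartite
mechanism summary: compounds link to the core targets they act on, and
core targets link to the pathways that contain them; each pathway's
weight is the count (and percentage) of core targets it covers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd
from scipy.stats import hypergeom

from .io_model import FormatError, TargetSet

__all__ = [
    "GeneSet",
    "GeneSetCollection",
    "read_gmt",
    "write_gmt",
    "fisher_enrichment",
    "bh_adjust",
    "CTPNetwork",
    "build_ctp_network",
    "round_half_up",
]


@dataclass(frozen=True)
class GeneSet:
    term_id: str
    name: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"gene set {self.term_id!r} is empty")


class GeneSetCollection:
    """Named gene sets (GMT-style), keyed by term id."""

    def __init__(self, sets: Iterable[GeneSet]):
        self._sets: dict[str, GeneSet] = {}
        for gs in sets:
            if gs.term_id in self._sets:
                raise ValueError(f"duplicate term id {gs.term_id!r}")
            self._sets[gs.term_id] = gs

    def __len__(self) -> int:
        return len(self._sets)

    def __iter__(self):
        return iter(self._sets.values())

    def __getitem__(self, term_id: str) -> GeneSet:
        return self._sets[term_id]

    def __contains__(self, term_id: str) -> bool:
        return term_id in self._sets

    def restrict(self, term_ids: Iterable[str]) -> "GeneSetCollection":
        return GeneSetCollection(self._sets[t] for t in term_ids)


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT file (term, description, member genes...)."""
    sets = []
    for i, line in enumerate(Path(path).read_text(encoding="utf-8").splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise FormatError(f"{path}: line {i}: GMT row needs term, description, >=1 member")
        members = [m.strip().upper() for m in parts[2:] if m.strip()]
        if not members:
            raise FormatError(f"{path}: line {i}: gene set {parts[0]!r} has no members")
        sets.append(GeneSet(term_id=parts[0], name=parts[1], members=frozenset(members)))
    return GeneSetCollection(sets)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    lines = [
        "\t".join([gs.term_id, gs.name, *sorted(gs.members)]) for gs in collection
    ]
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8", newline="\n")


def bh_adjust(p_values: Sequence[float]) -> list[float]:
    """Benjamini–Hochberg step-up FDR; input order preserved.

    Each adjusted value is ``min over j >= rank of p_(j) * m / j``,
    capped at 1.  Raises on any p outside (0, 1].
    """
    m = len(p_values)
    for p in p_values:
        if not (0.0 < p <= 1.0):
            raise ValueError(f"p-value {p} outside (0, 1]")
    order = sorted(range(m), key=lambda i: p_values[i])
    adjusted = [0.0] * m
    running_min = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        running_min = min(running_min, p_values[i] * m / rank_from_top)
        adjusted[i] = running_min
    return adjusted


def fisher_enrichment(
    query: TargetSet,
    collection: GeneSetCollection,
    background: TargetSet,
) -> pd.DataFrame:
    """Hypergeometric over-representation test per gene set.

    Query genes outside the background are reported (``clipped``
    attribute on the result) and excluded from ``n``; terms with no
    members in the background are skipped (``skipped_terms`` attribute).
    Rows are sorted by p-value then term id; BH FDR is appended.
    """
    if not background.symbols:
        raise ValueError("empty background universe")
    bg = background.symbols
    clipped = sorted(query.symbols - bg)
    q = query.symbols & bg
    n, N = len(q), len(bg)

    rows = []
    skipped = []
    for gs in collection:
        members = gs.members & bg
        K = len(members)
        if K == 0:
            skipped.append(gs.term_id)
            continue
        k = len(q & members)
        # upper tail P(X >= k); survival function is P(X > k-1)
        p = float(hypergeom.sf(k - 1, N, K, n))
        p = min(max(p, math.ulp(0.0)), 1.0)
        rows.append((gs.term_id, gs.name, k, K, n, N, p))

    rows.sort(key=lambda r: (r[6], r[0]))
    df = pd.DataFrame(
        rows, columns=["term", "name", "k", "K", "n", "N", "p_value"]
    )
    df["fdr"] = bh_adjust(df["p_value"].tolist()) if len(df) else []
    df.attrs["clipped"] = clipped
    df.attrs["skipped_terms"] = skipped
    return df


def round_half_up(value: float, ndigits: int = 1) -> float:
    """Decimal half-up rounding (5 rounds away from zero), as printed tables do."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class CTPNetwork:
    """Tripartite compound → core-target → pathway mechanism network."""

    graph: nx.Graph
    pathway_table: pd.DataFrame  # pathway, n_core_targets, pct_core_targets
    n_compounds: int
    n_targets: int
    n_pathways: int

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()


def build_ctp_network(
    compound_links: Mapping[str, Iterable[str]] | Iterable[tuple[str, str]],
    core: TargetSet,
    pathways: GeneSetCollection,
) -> CTPNetwork:
    """Assemble the C-T-P network and the per-pathway coverage table.

    ``compound_links`` are compound → target links (mapping or edge
    pairs); only links to core targets become edges, and compounds with
    no core link are left out of the network.  Every supplied pathway is
    kept, even with zero core members (visible, not dropped).  The
    coverage percentage is ``count / |core| * 100`` rounded half-up to
    one decimal; pathways are ranked by count descending, ties by name.
    """
    if len(pathways) == 0:
        raise ValueError("no pathways supplied")
    if isinstance(compound_links, Mapping):
        pairs = [(c, t) for c, ts in compound_links.items() for t in ts]
    else:
        pairs = list(compound_links)

    g = nx.Graph()
    for t in core.symbols:
        g.add_node(t, kind="target")
    for c, t in pairs:
        if t in core.symbols:
            g.add_node(c, kind="compound")
            g.add_edge(c, t)

    rows = []
    for gs in pathways:
        covered = gs.members & core.symbols
        node = f"pathway:{gs.term_id}"
        g.add_node(node, kind="pathway", name=gs.name)
        for t in covered:
            g.add_edge(node, t)
        pct = round_half_up(100.0 * len(covered) / len(core), 1) if len(core) else 0.0
        rows.append((gs.name, len(covered), pct))

    rows.sort(key=lambda r: (-r[1], r[0]))
    table = pd.DataFrame(rows, columns=["pathway", "n_core_targets", "pct_core_targets"])
    kinds = nx.get_node_attributes(g, "kind")
    return CTPNetwork(
        graph=g,
        pathway_table=table,
        n_compounds=sum(1 for v in kinds.values() if v == "compound"),
        n_targets=sum(1 for v in kinds.values() if v == "target"),
        n_pathways=sum(1 for v in kinds.values() if v == "pathway"),
    )
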