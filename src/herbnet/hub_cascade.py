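"""Three-stage median-centrality hub screening of a PPI network.

Stage 1 (hubs): keep nodes whose degree, closeness and betweenness are
each strictly greater than the corresponding median over all nodes of
the network (isolated nodes included in the medians).

Stage 2 (major hubs): re-run the same filter on the subgraph induced by
the stage-1 hubs, with all three centralities recomputed on that
subgraph.

Stage 3 (core targets): keep major hubs whose degree in the
compound–target network is at least ``min_compound_degree`` (default 7,
i.e. nodes affected by fewer than seven compounds are excluded).

The median rule is conjunctive by default — all three centralities must
exceed their medians — which is the aggressive reduction used in hub
screening; a disjunctive (any-of-three) variant is available as a
switch.  On a vertex-transitive graph (e.g. any cycle) nothing is
strictly greater than the median, so every tier is empty.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

from .io_model import TargetSet
from .network_build import BipartiteNetwork, PPINetwork, compute_centralities

__all__ = ["HubCascadeResult", "median_filter", "run_cascade"]

CENTRALITY_COLUMNS = ("degree", "closeness", "betweenness")


@dataclass
class HubCascadeResult:
    """The three nested tiers plus the thresholds actually applied."""

    stage1_hubs: TargetSet
    stage2_major_hubs: TargetSet
    stage3_core_targets: TargetSet
    stage1_medians: dict[str, float]
    stage2_medians: dict[str, float]
    min_compound_degree: int
    excluded_at_stage3: list[dict] = field(default_factory=list)
    conjunctive: bool = True

    def to_json(self, path: str | Path) -> None:
        payload = {
            "stage1_hubs": sorted(self.stage1_hubs.symbols),
            "stage2_major_hubs": sorted(self.stage2_major_hubs.symbols),
            "stage3_core_targets": sorted(self.stage3_core_targets.symbols),
            "stage1_medians": self.stage1_medians,
            "stage2_medians": self.stage2_medians,
            "min_compound_degree": self.min_compound_degree,
            "conjunctive": self.conjunctive,
            "excluded_at_stage3": self.excluded_at_stage3,
        }
        Path(path).write_text(
            json.dumps(payload, indent=2) + "\n", encoding="utf-8", newline="\n"
        )


def median_filter(
    net: PPINetwork,
    conjunctive: bool = True,
    label: str = "hubs",
) -> tuple[TargetSet, dict[str, float]]:
    """Keep nodes whose centralities strictly exceed the network medians.

    Medians are computed over *all* nodes of the input network,
    isolated nodes included.  With ``conjunctive`` (default) a node
    must beat all three medians; otherwise any one suffices.
    """
    table = compute_centralities(net)
    if table.empty:
        return TargetSet(label, ()), {c: 0.0 for c in CENTRALITY_COLUMNS}
    medians = {c: float(table[c].median()) for c in CENTRALITY_COLUMNS}
    exceeds = {c: table[c] > medians[c] for c in CENTRALITY_COLUMNS}
    if conjunctive:
        mask = exceeds["degree"] & exceeds["closeness"] & exceeds["betweenness"]
    else:
        mask = exceeds["degree"] | exceeds["closeness"] | exceeds["betweenness"]
    return TargetSet(label, table.index[mask]), medians


def run_cascade(
    ppi: PPINetwork,
    ct: BipartiteNetwork,
    min_compound_degree: int = 7,
    conjunctive: bool = True,
) -> HubCascadeResult:
    """Run the full hub → major-hub → core-target cascade.

    The PPI and compound–target networks must share the target
    namespace; a major hub absent from the compound–target network has
    compound-degree 0 and is excluded at stage 3 with an audit entry.
    """
    stage1, med1 = median_filter(ppi, conjunctive=conjunctive, label="hubs")

    sub = PPINetwork(
        graph=ppi.graph.subgraph(stage1.symbols).copy(), min_score=ppi.min_score
    )
    stage2, med2 = median_filter(sub, conjunctive=conjunctive, label="major_hubs")

    ct_targets = set(ct.targets)
    core: list[str] = []
    excluded: list[dict] = []
    for t in sorted(stage2.symbols):
        if t not in ct_targets:
            excluded.append(
                {"target": t, "compound_degree": 0, "reason": "absent from compound-target network"}
            )
            continue
        d = ct.graph.degree(t)
        if d >= min_compound_degree:
            core.append(t)
        else:
            excluded.append(
                {
                    "target": t,
                    "compound_degree": int(d),
                    "reason": f"affected by fewer than {min_compound_degree} compounds",
                }
            )
    return HubCascadeResult(
        stage1_hubs=stage1,
        stage2_major_hubs=stage2,
        stage3_core_targets=TargetSet("core_targets", core),
        stage1_medians=med1,
        stage2_medians=med2,
        min_compound_degree=min_compound_degree,
        excluded_at_stage3=excluded,
        conjunctive=conjunctive,
    )
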