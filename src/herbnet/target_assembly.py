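"""Target assembly: per-database score filtering, merging, and the
herb ∩ disease intersection that defines the candidate-target set.

Each source database reports interactions on its own scale, so each has
its own cutoff and direction: BindingDB keeps affinities of at most
10,000 nM, SwissTargetPrediction keeps prediction scores of at least
0.5, STITCH at least 0.4, BATMAN at least 20 and DisGeNET at least 0.2;
TTD, CTD, OMIM and DrugBank records carry no numeric cutoff and are
always kept.  All comparisons are boundary-inclusive.

Merging keeps per-symbol provenance (which databases and compounds
contributed each target) so compound→target links survive into the
network stages.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .io_model import TargetRecord, TargetSet

__all__ = [
    "DatabaseCutoffConfig",
    "UnknownDatabaseError",
    "MergedTargets",
    "VennResult",
    "filter_database_records",
    "merge_target_sets",
    "intersect_targets",
]


class UnknownDatabaseError(ValueError):
    """A record's source database is not in the cutoff configuration."""


@dataclass(frozen=True)
class DatabaseCutoffConfig:
    """Per-database score cutoffs (all inclusive at the boundary).

    ``max`` direction: keep score <= cutoff (binding affinity in nM,
    smaller = stronger).  ``min`` direction: keep score >= cutoff.
    Databases absent from both maps have no numeric cutoff.
    """

    bindingdb_max_affinity_nm: float = 10_000.0
    swisstarget_min_score: float = 0.5
    stitch_min_score: float = 0.4
    batman_min_score: float = 20.0
    disgenet_min_score: float = 0.2
    no_cutoff_dbs: frozenset[str] = frozenset({"ttd", "ctd", "omim", "drugbank"})

    def keeps(self, record: TargetRecord) -> bool:
        db = record.source_db
        if db == "bindingdb":
            return record.score is not None and record.score <= self.bindingdb_max_affinity_nm
        if db == "swisstarget":
            return record.score is not None and record.score >= self.swisstarget_min_score
        if db == "stitch":
            return record.score is not None and record.score >= self.stitch_min_score
        if db == "batman":
            return record.score is not None and record.score >= self.batman_min_score
        if db == "disgenet":
            return record.score is not None and record.score >= self.disgenet_min_score
        if db in self.no_cutoff_dbs:
            return True
        raise UnknownDatabaseError(f"no cutoff rule for database {db!r}")


def filter_database_records(
    records: Sequence[TargetRecord],
    cfg: DatabaseCutoffConfig | None = None,
) -> list[TargetRecord]:
    """Keep each record iff its score satisfies its database's cutoff.

    Pure per-record predicate: output order is input order restricted.
    Records from a no-cutoff database are always kept; a record from a
    scored database with no score does not satisfy the cutoff.
    """
    cfg = cfg or DatabaseCutoffConfig()
    return [r for r in records if cfg.keeps(r)]


@dataclass(frozen=True)
class MergedTargets:
    """Union of target sets with per-symbol provenance."""

    targets: TargetSet
    sources: dict[str, tuple[str, ...]]  # symbol -> sorted source labels
    compound_ids: dict[str, tuple[str, ...]] = field(default_factory=dict)


def merge_target_sets(
    per_db: Sequence[TargetSet],
    records: Iterable[TargetRecord] = (),
    label: str = "merged",
) -> MergedTargets:
    """Union the per-database sets, retaining source provenance.

    ``records`` may supply the underlying scored rows so that
    compound→target links (compound_id provenance) are carried along
    for later degree counts.
    """
    union: set[str] = set()
    sources: dict[str, set[str]] = {}
    compounds: dict[str, set[str]] = {}
    for ts in per_db:
        for s in ts.symbols:
            union.add(s)
            sources.setdefault(s, set()).add(ts.label)
    for r in records:
        if r.compound_id is not None:
            compounds.setdefault(r.symbol, set()).add(r.compound_id)
    return MergedTargets(
        targets=TargetSet(label, union),
        sources={s: tuple(sorted(v)) for s, v in sources.items()},
        compound_ids={s: tuple(sorted(v)) for s, v in compounds.items()},
    )


@dataclass(frozen=True)
class VennResult:
    """Herb ∩ disease intersection plus the two difference sizes."""

    common: TargetSet
    n_herb_only: int
    n_disease_only: int
    warning: str | None = None

    @property
    def n_common(self) -> int:
        return len(self.common)


def intersect_targets(herb: TargetSet, disease: TargetSet) -> VennResult:
    """Exact set intersection of herb and disease targets (Venn counts kept).

    An empty input set is a warning, not an error; the intersection is
    then empty.
    """
    warning = None
    if not herb.symbols or not disease.symbols:
        warning = "empty herb or disease target set; intersection is empty"
    common = herb.symbols & disease.symbols
    return VennResult(
        common=TargetSet(f"{herb.label}&{disease.label}", common),
        n_herb_only=len(herb.symbols - disease.symbols),
        n_disease_only=len(disease.symbols - herb.symbols),
        warning=warning,
    )
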