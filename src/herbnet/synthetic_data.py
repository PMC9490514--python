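"""Seeded generators emulating every input the pipeline consumes.

Each generator is a pure function of the configuration (seed included):
repeated calls produce identical objects, and the save helpers write
byte-identical files.  Ground truth is always recorded next to the data
so tests compare pipeline output to what was planted, never to
re-derived values.

What is emulated, and the planted structure:

* **Compound bundle** — an LC-MS-style compound table whose descriptor
  blocks are drawn so that a known subset passes the 2-of-5
  drug-likeness + OB >= 0.55 screen (flavonoid-like blocks pass all
  five rule sets; heavy glycoside-like blocks fail them all and carry
  low OB scores), plus a literature keep-list and a no-target drop
  list.  Defaults mirror a realistic screen: 62 identified compounds,
  34 passing, 13 literature-kept, 1 dropped for lacking targets → 46
  retained.
* **Network bundle** — per-database target exports with scores
  straddling each database's cutoff (plus decoy symbols that fail it),
  herb and disease symbol lists with a planted intersection, a
  STRING-dialect PPI edge list with a planted three-tier topology
  (a dense core clique wired into a shell ring, with a sparse halo
  hanging off the shell), compound→target links wiring every core
  target to at least seven retained compounds, and a GMT whose terms
  cover the core at configured fractions.  The hub cascade recovers
  the planted core from this construction.
* **Animal study** — per-animal fasting biochemistry for
  normal-control / diabetic-control / treated groups (group means
  patterned on a high-fat-diet + streptozotocin rat model: NC glucose
  ≈ 90 vs DC ≈ 344 mg/dl) and qPCR Ct values engineered so that
  planted fold changes are recoverable by the 2^-ddCt method.

One RNG stream per generator, seeded from ``cfg.seed`` plus a fixed
per-generator offset, so adding a generator never perturbs the others.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .io_model import (
    CompoundRecord,
    DescriptorBlock,
    TargetRecord,
    TargetSet,
    write_compound_table,
    write_symbol_list,
    write_target_table,
)
from .enrichment import GeneSet, GeneSetCollection, write_gmt

__all__ = [
    "SyntheticConfig",
    "CompoundBundle",
    "NetworkBundle",
    "AnimalStudy",
    "generate_compound_bundle",
    "generate_network_bundle",
    "generate_docking_matrix",
    "generate_animal_study",
]

# fixed per-generator seed offsets (documented contract)
_OFFSET_COMPOUNDS = 101
_OFFSET_NETWORK = 202
_OFFSET_DOCKING = 303
_OFFSET_ANIMALS = 404


class SyntheticConfigError(ValueError):
    """Infeasible generator configuration."""


@dataclass(frozen=True)
class SyntheticConfig:
    """Knobs for all generators; defaults are the study conditions."""

    seed: int = 0

    # compound bundle
    n_compounds: int = 62
    frac_ob_pass: float = 34 / 62  # fraction drawn to pass the screen
    n_literature_keep: int = 13    # rescued from the failing side
    n_drop_no_targets: int = 1     # dropped from the passing side

    # network bundle: planted three-tier PPI
    n_core: int = 8
    n_shell: int = 22
    n_halo: int = 30
    planted_overlap: int | None = None  # defaults to n_core+n_shell+n_halo
    shell_core_links: int = 2      # core attachments per shell node
    halo_shell_links: int = 1      # shell attachments per halo node (0 => isolated halo)
    n_herb_extra: int = 190        # herb-only targets (union 250 by default)
    n_disease_extra: int = 60
    ppi_score_range: tuple[float, float] = (0.72, 0.98)
    ppi_decoy_score_range: tuple[float, float] = (0.15, 0.69)
    core_compound_degree: tuple[int, int] = (8, 12)   # >= 7 by construction
    noncore_compound_degree: tuple[int, int] = (1, 6)  # < 7 by construction

    # gene sets
    n_pathways: int = 15
    pathway_core_coverage: tuple[float, ...] = tuple(
        0.9 - 0.05 * i for i in range(15)
    )
    pathway_filler_genes: int = 10

    # docking grid
    n_docking_compounds: int = 21
    n_docking_proteins: int = 11
    docking_score_range: tuple[float, float] = (-11.0, -3.0)

    # animal study (means patterned on an HFD+STZ rat model)
    n_per_group: int = 7
    group_means: dict = field(
        default_factory=lambda: {
            "NC": {"fasting_glucose": 89.71, "fasting_insulin": 11.51, "triglycerides": 66.0},
            "DC": {"fasting_glucose": 343.86, "fasting_insulin": 6.31, "triglycerides": 155.0},
            "ETH100": {"fasting_glucose": 193.86, "fasting_insulin": 7.70, "triglycerides": 96.0},
        }
    )
    group_sds: dict = field(
        default_factory=lambda: {
            "fasting_glucose": 11.0,
            "fasting_insulin": 1.6,
            "triglycerides": 9.0,
        }
    )
    #: planted fold changes per gene per group, relative to the calibrator NC
    gene_folds: dict = field(
        default_factory=lambda: {
            "IL1B": {"NC": 1.0, "DC": 3.0, "ETH100": 1.6},
            "PIK3R1": {"NC": 1.0, "DC": 0.4, "ETH100": 0.75},
        }
    )
    ct_reference_mean: float = 15.0
    ct_noise_sd: float = 0.2
    calibrator_group: str = "NC"

    @property
    def n_tier_nodes(self) -> int:
        if self.planted_overlap is not None:
            return self.planted_overlap
        return self.n_core + self.n_shell + self.n_halo


def _rng(cfg: SyntheticConfig, offset: int) -> np.random.Generator:
    return np.random.default_rng(cfg.seed + offset)


# ---------------------------------------------------------------------------
# compound bundle
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CompoundBundle:
    """Compound table + override lists + recorded ground truth."""

    compounds: tuple[CompoundRecord, ...]
    keep_list: frozenset[str]
    drop_no_target_list: frozenset[str]
    ground_truth_retained: frozenset[str]

    def save(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_compound_table(self.compounds, out / "compounds.tsv")
        write_symbol_list(sorted(self.keep_list), out / "keep_list.txt")
        write_symbol_list(sorted(self.drop_no_target_list), out / "drop_no_targets.txt")
        write_symbol_list(sorted(self.ground_truth_retained), out / "ground_truth_retained.txt")


def _passing_block(rng: np.random.Generator) -> DescriptorBlock:
    """Flavonoid-like descriptors that satisfy all five rule sets."""
    return DescriptorBlock(
        mw=float(np.round(rng.uniform(210, 470), 2)),
        mlogp=float(np.round(rng.uniform(0.0, 3.0), 2)),
        wlogp=float(np.round(rng.uniform(0.5, 4.0), 2)),
        xlogp=float(np.round(rng.uniform(0.0, 4.5), 2)),
        hba=float(rng.integers(3, 10)),
        hbd=float(rng.integers(0, 5)),
        rotb=float(rng.integers(0, 9)),
        tpsa=float(np.round(rng.uniform(40, 130), 2)),
        molar_refractivity=float(np.round(rng.uniform(50, 120), 2)),
        heavy_atoms=float(rng.integers(20, 34)),
        carbons=float(rng.integers(10, 26)),
        heteroatoms=float(rng.integers(3, 10)),
        rings=float(rng.integers(1, 5)),
    )


def _failing_block(rng: np.random.Generator) -> DescriptorBlock:
    """Heavy glycoside-like descriptors that fail every rule set."""
    return DescriptorBlock(
        mw=float(np.round(rng.uniform(620, 900), 2)),
        mlogp=float(np.round(rng.uniform(-3.5, -1.0), 2)),
        wlogp=float(np.round(rng.uniform(6.0, 8.0), 2)),
        xlogp=float(np.round(rng.uniform(5.5, 8.0), 2)),
        hba=float(rng.integers(12, 19)),
        hbd=float(rng.integers(7, 12)),
        rotb=float(rng.integers(16, 22)),
        tpsa=float(np.round(rng.uniform(170, 280), 2)),
        molar_refractivity=float(np.round(rng.uniform(140, 220), 2)),
        heavy_atoms=float(rng.integers(75, 95)),
        carbons=float(rng.integers(27, 40)),
        heteroatoms=float(rng.integers(12, 20)),
        rings=float(rng.integers(8, 11)),
    )


def generate_compound_bundle(cfg: SyntheticConfig | None = None) -> CompoundBundle:
    """Compound table with a planted pass/fail split and override lists."""
    cfg = cfg or SyntheticConfig()
    if not (0.0 <= cfg.frac_ob_pass <= 1.0):
        raise SyntheticConfigError(f"frac_ob_pass {cfg.frac_ob_pass} outside [0, 1]")
    n = cfg.n_compounds
    n_pass = int(round(cfg.frac_ob_pass * n))
    n_fail = n - n_pass
    if cfg.n_literature_keep > n_fail:
        raise SyntheticConfigError(
            f"n_literature_keep {cfg.n_literature_keep} exceeds failing compounds {n_fail}"
        )
    if cfg.n_drop_no_targets > n_pass:
        raise SyntheticConfigError(
            f"n_drop_no_targets {cfg.n_drop_no_targets} exceeds passing compounds {n_pass}"
        )
    rng = _rng(cfg, _OFFSET_COMPOUNDS)
    width = len(str(n))
    ids = [f"C{i + 1:0{width}d}" for i in range(n)]
    pass_mask = np.zeros(n, dtype=bool)
    pass_mask[rng.choice(n, size=n_pass, replace=False)] = True

    records = []
    for i, cid in enumerate(ids):
        if pass_mask[i]:
            desc = _passing_block(rng)
            ob = float(rng.choice([0.55, 0.56, 0.85]))
        else:
            desc = _failing_block(rng)
            ob = float(rng.choice([0.11, 0.17]))
        records.append(
            CompoundRecord(
                compound_id=cid,
                name=f"phytochem-{cid}",
                ob_score=ob,
                descriptors=desc,
                rt_min=float(np.round(rng.uniform(1.0, 15.0), 3)),
            )
        )

    failing_ids = [ids[i] for i in range(n) if not pass_mask[i]]
    passing_ids = [ids[i] for i in range(n) if pass_mask[i]]
    keep = rng.choice(failing_ids, size=cfg.n_literature_keep, replace=False) if cfg.n_literature_keep else []
    drop = rng.choice(passing_ids, size=cfg.n_drop_no_targets, replace=False) if cfg.n_drop_no_targets else []
    keep_set = frozenset(str(x) for x in keep)
    drop_set = frozenset(str(x) for x in drop)
    retained = frozenset((set(passing_ids) - drop_set) | keep_set)
    return CompoundBundle(
        compounds=tuple(records),
        keep_list=keep_set,
        drop_no_target_list=drop_set,
        ground_truth_retained=retained,
    )


# ---------------------------------------------------------------------------
# network bundle
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class NetworkBundle:
    """All network-stage inputs with the planted ground truth alongside."""

    herb_targets: TargetSet
    disease_targets: TargetSet
    planted_common: TargetSet
    planted_core: TargetSet
    planted_shell: TargetSet
    planted_halo: TargetSet
    ppi_edges: tuple[tuple[str, str, float], ...]
    ct_links: tuple[tuple[str, str], ...]
    compound_ids: tuple[str, ...]
    database_records: tuple[TargetRecord, ...]
    pathways: GeneSetCollection

    def save(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_symbol_list(sorted(self.herb_targets.symbols), out / "herb_targets.txt")
        write_symbol_list(sorted(self.disease_targets.symbols), out / "disease_targets.txt")
        write_target_table(self.database_records, out / "database_records.tsv")
        lines = ["protein1\tprotein2\tcombined_score"]
        lines += [f"{a}\t{b}\t{s}" for a, b, s in self.ppi_edges]
        (out / "ppi_edges.tsv").write_text("\n".join(lines) + "\n", encoding="utf-8", newline="\n")
        lines = ["compound_id\tsymbol"]
        lines += [f"{c}\t{t}" for c, t in self.ct_links]
        (out / "ct_links.tsv").write_text("\n".join(lines) + "\n", encoding="utf-8", newline="\n")
        write_gmt(self.pathways, out / "pathways.gmt")
        truth = {
            "planted_common": sorted(self.planted_common.symbols),
            "planted_core": sorted(self.planted_core.symbols),
            "planted_shell": sorted(self.planted_shell.symbols),
            "planted_halo": sorted(self.planted_halo.symbols),
        }
        (out / "ground_truth_network.json").write_text(
            json.dumps(truth, indent=2) + "\n", encoding="utf-8", newline="\n"
        )


def _tier_symbols(prefix: str, count: int, start: int, width: int) -> list[str]:
    return [f"{prefix}{i:0{width}d}" for i in range(start, start + count)]


def generate_network_bundle(
    cfg: SyntheticConfig | None = None,
    compound_ids: tuple[str, ...] | None = None,
) -> NetworkBundle:
    """Per-database exports, herb/disease lists, PPI, compound links and GMT.

    The planted intersection of the herb and disease lists is exactly
    the tier nodes (core + shell + halo); those nodes form the PPI
    candidate set.  Core nodes form a clique and are wired to at least
    seven retained compounds; shell and halo nodes stay below that.
    """
    cfg = cfg or SyntheticConfig()
    if cfg.planted_overlap is not None:
        n_halo = cfg.planted_overlap - cfg.n_core - cfg.n_shell
        if n_halo < 0:
            raise SyntheticConfigError(
                "planted_overlap smaller than n_core + n_shell"
            )
    else:
        n_halo = cfg.n_halo
    if cfg.n_core < 3:
        raise SyntheticConfigError("n_core must be >= 3 to form a meaningful clique")
    if cfg.n_shell < cfg.n_core:
        raise SyntheticConfigError("n_shell must be >= n_core")
    n_tier = cfg.n_core + cfg.n_shell + n_halo
    overlap = cfg.planted_overlap if cfg.planted_overlap is not None else n_tier
    n_herb = overlap + cfg.n_herb_extra
    n_disease = overlap + cfg.n_disease_extra
    if overlap > min(n_herb, n_disease):
        raise SyntheticConfigError("planted overlap exceeds a list size")

    rng = _rng(cfg, _OFFSET_NETWORK)
    if compound_ids is None:
        compound_ids = tuple(sorted(generate_compound_bundle(cfg).ground_truth_retained))
    lo, hi = cfg.core_compound_degree
    if lo < 7:
        raise SyntheticConfigError("core compound degree must plant >= 7 links")
    if len(compound_ids) < hi:
        raise SyntheticConfigError("not enough retained compounds to wire the core")

    width = len(str(n_tier + cfg.n_herb_extra + cfg.n_disease_extra)) + 1
    core = _tier_symbols("GC", cfg.n_core, 1, width)
    shell = _tier_symbols("GS", cfg.n_shell, 1, width)
    halo = _tier_symbols("GH", n_halo, 1, width)
    tier_nodes = core + shell + halo
    herb_only = _tier_symbols("HB", cfg.n_herb_extra, 1, width)
    disease_only = _tier_symbols("DZ", cfg.n_disease_extra, 1, width)

    # --- PPI edges (scores already on the 0-1 scale) -----------------------
    def score() -> float:
        return float(np.round(rng.uniform(*cfg.ppi_score_range), 3))

    edges: list[tuple[str, str, float]] = []
    for i in range(len(core)):
        for j in range(i + 1, len(core)):
            edges.append((core[i], core[j], score()))
    # each shell node attaches to shell_core_links distinct cores, spread
    # round-robin so no core is starved, with a seeded rotation
    rot = int(rng.integers(0, cfg.n_core))
    for si, s in enumerate(shell):
        for k in range(cfg.shell_core_links):
            c = core[(si * cfg.shell_core_links + k + rot) % cfg.n_core]
            edges.append((s, c, score()))
    # shell ring keeps shell betweenness strictly positive
    for si in range(len(shell)):
        edges.append((shell[si], shell[(si + 1) % len(shell)], score()))
    # halo nodes hang off the shell (0 links => isolated halo)
    for hi_, h in enumerate(halo):
        for k in range(cfg.halo_shell_links):
            s = shell[(hi_ + k) % len(shell)]
            edges.append((h, s, score()))
    # sub-threshold decoy edges that the 0.7 cutoff must remove
    decoys = rng.choice(len(tier_nodes), size=(max(4, n_tier // 3), 2))
    for a, b in decoys:
        if a != b:
            edges.append(
                (
                    tier_nodes[int(a)],
                    tier_nodes[int(b)],
                    float(np.round(rng.uniform(*cfg.ppi_decoy_score_range), 3)),
                )
            )

    # --- compound-target links --------------------------------------------
    ct_links: list[tuple[str, str]] = []
    n_comp = len(compound_ids)
    for t in core:
        k = int(rng.integers(lo, hi + 1))
        for ci in rng.choice(n_comp, size=min(k, n_comp), replace=False):
            ct_links.append((compound_ids[int(ci)], t))
    nlo, nhi = cfg.noncore_compound_degree
    for t in shell + halo:
        k = int(rng.integers(nlo, nhi + 1))
        for ci in rng.choice(n_comp, size=k, replace=False):
            ct_links.append((compound_ids[int(ci)], t))

    # --- per-database exports ---------------------------------------------
    herb_set = tier_nodes + herb_only
    disease_set = tier_nodes + disease_only
    records: list[TargetRecord] = []
    herb_dbs = ["bindingdb", "swisstarget", "stitch", "ttd", "ctd", "batman"]
    passing_score = {
        "bindingdb": lambda: float(np.round(rng.uniform(10, 10_000), 1)),
        "swisstarget": lambda: float(np.round(rng.uniform(0.5, 1.0), 3)),
        "stitch": lambda: float(np.round(rng.uniform(0.4, 0.99), 3)),
        "batman": lambda: float(np.round(rng.uniform(20, 95), 1)),
        "ttd": lambda: None,
        "ctd": lambda: None,
    }
    failing_score = {
        "bindingdb": lambda: float(np.round(rng.uniform(10_001, 90_000), 1)),
        "swisstarget": lambda: float(np.round(rng.uniform(0.01, 0.499), 3)),
        "stitch": lambda: float(np.round(rng.uniform(0.01, 0.399), 3)),
        "batman": lambda: float(np.round(rng.uniform(1, 19.9), 1)),
    }
    for si, sym in enumerate(herb_set):
        dbs = rng.choice(len(herb_dbs), size=int(rng.integers(1, 4)), replace=False)
        for di in dbs:
            db = herb_dbs[int(di)]
            records.append(
                TargetRecord(
                    symbol=sym,
                    source_db=db,
                    score=passing_score[db](),
                    compound_id=compound_ids[int(rng.integers(0, n_comp))],
                )
            )
    # decoy herb records that every cutoff rejects
    scored_dbs = ["bindingdb", "swisstarget", "stitch", "batman"]
    for i in range(30):
        db = scored_dbs[int(rng.integers(0, 4))]
        records.append(
            TargetRecord(
                symbol=f"XF{i:03d}",
                source_db=db,
                score=failing_score[db](),
                compound_id=compound_ids[int(rng.integers(0, n_comp))],
            )
        )
    disease_dbs = ["omim", "disgenet", "ttd", "drugbank"]
    for sym in disease_set:
        db = disease_dbs[int(rng.integers(0, 4))]
        records.append(
            TargetRecord(
                symbol=sym,
                source_db=db,
                score=float(np.round(rng.uniform(0.2, 1.0), 3)) if db == "disgenet" else None,
            )
        )
    for i in range(10):
        records.append(
            TargetRecord(
                symbol=f"XD{i:03d}",
                source_db="disgenet",
                score=float(np.round(rng.uniform(0.01, 0.199), 3)),
            )
        )

    # --- gene sets ---------------------------------------------------------
    coverage = cfg.pathway_core_coverage[: cfg.n_pathways]
    if len(coverage) < cfg.n_pathways:
        raise SyntheticConfigError("pathway_core_coverage shorter than n_pathways")
    sets = []
    fillers = shell + halo + herb_only
    for pi, frac in enumerate(coverage):
        n_cov = max(1, int(round(frac * cfg.n_core)))
        cov = [core[int(i)] for i in rng.choice(cfg.n_core, size=n_cov, replace=False)]
        fill = [
            fillers[int(i)]
            for i in rng.choice(len(fillers), size=cfg.pathway_filler_genes, replace=False)
        ]
        sets.append(
            GeneSet(
                term_id=f"P{pi + 1:02d}",
                name=f"synthetic pathway {pi + 1:02d}",
                members=frozenset(cov + fill),
            )
        )

    return NetworkBundle(
        herb_targets=TargetSet("herb", herb_set),
        disease_targets=TargetSet("disease", disease_set),
        planted_common=TargetSet("common", tier_nodes),
        planted_core=TargetSet("core", core),
        planted_shell=TargetSet("shell", shell),
        planted_halo=TargetSet("halo", halo),
        ppi_edges=tuple(edges),
        ct_links=tuple(sorted(set(ct_links))),
        compound_ids=tuple(compound_ids),
        database_records=tuple(records),
        pathways=GeneSetCollection(sets),
    )


# ---------------------------------------------------------------------------
# docking grid
# ---------------------------------------------------------------------------


def generate_docking_matrix(cfg: SyntheticConfig | None = None):
    """Compound x protein grid of binding energies (kcal/mol)."""
    import pandas as pd

    cfg = cfg or SyntheticConfig()
    rng = _rng(cfg, _OFFSET_DOCKING)
    lo, hi = cfg.docking_score_range
    scores = np.round(rng.uniform(lo, hi, size=(cfg.n_docking_compounds, cfg.n_docking_proteins)), 2)
    return pd.DataFrame(
        scores,
        index=[f"C{i + 1:02d}" for i in range(cfg.n_docking_compounds)],
        columns=[f"PROT{j + 1:02d}" for j in range(cfg.n_docking_proteins)],
    )


# ---------------------------------------------------------------------------
# animal study
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AnimalStudy:
    """Per-animal table plus the planted means and fold changes."""

    table: "object"  # pandas DataFrame (wide: ct_<gene> columns + ct_18s)
    planted_means: dict
    planted_folds: dict
    calibrator_group: str

    def save(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.table.to_csv(out / "animals.tsv", sep="\t", index=False, lineterminator="\n")
        truth = {
            "planted_means": self.planted_means,
            "planted_folds": self.planted_folds,
            "calibrator_group": self.calibrator_group,
        }
        (out / "ground_truth_animals.json").write_text(
            json.dumps(truth, indent=2) + "\n", encoding="utf-8", newline="\n"
        )


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float, size: int) -> np.ndarray:
    """Normal draws redrawn until positive (means are far from zero)."""
    if mean <= 0:
        raise SyntheticConfigError(f"analyte mean must be positive, got {mean}")
    if sd < 0:
        raise SyntheticConfigError(f"analyte SD must be >= 0, got {sd}")
    vals = rng.normal(mean, sd, size=size)
    for _ in range(100):
        bad = vals <= 0
        if not bad.any():
            return vals
        vals[bad] = rng.normal(mean, sd, size=int(bad.sum()))
    raise SyntheticConfigError("could not draw positive analyte values")


def generate_animal_study(cfg: SyntheticConfig | None = None):
    """Animal biochemistry + Ct table with planted group means and folds."""
    import pandas as pd

    cfg = cfg or SyntheticConfig()
    rng = _rng(cfg, _OFFSET_ANIMALS)
    rows = []
    genes = sorted(cfg.gene_folds)
    for group in cfg.group_means:
        means = cfg.group_means[group]
        analytes = {
            name: _truncated_normal(rng, means[name], cfg.group_sds[name], cfg.n_per_group)
            for name in ("fasting_glucose", "fasting_insulin", "triglycerides")
        }
        ct_ref = rng.normal(cfg.ct_reference_mean, cfg.ct_noise_sd, cfg.n_per_group)
        ct_genes = {}
        for gene in genes:
            fold = cfg.gene_folds[gene].get(group, 1.0)
            # dCt planted so 2^-ddCt relative to the calibrator equals `fold`
            # (calibrator baseline dCt = 5 cycles above the reference)
            dct = 5.0 - np.log2(fold)
            ct_genes[gene] = ct_ref + dct + rng.normal(0.0, cfg.ct_noise_sd, cfg.n_per_group)
        for i in range(cfg.n_per_group):
            row = {
                "animal_id": f"{group}-{i + 1}",
                "group": group,
                "fasting_glucose": float(np.round(analytes["fasting_glucose"][i], 2)),
                "fasting_insulin": float(np.round(analytes["fasting_insulin"][i], 2)),
                "triglycerides": float(np.round(analytes["triglycerides"][i], 2)),
                "ct_18s": float(np.round(ct_ref[i], 4)),
            }
            for gene in genes:
                row[f"ct_{gene}"] = float(np.round(ct_genes[gene][i], 4))
            rows.append(row)
    table = pd.DataFrame(rows)
    return AnimalStudy(
        table=table,
        planted_means={g: dict(m) for g, m in cfg.group_means.items()},
        planted_folds={g: dict(f) for g, f in cfg.gene_folds.items()},
        calibrator_group=cfg.calibrator_group,
    )
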