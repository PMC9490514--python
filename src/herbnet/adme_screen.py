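"""Drug-likeness and oral-bioavailability screening of candidate compounds.

A compound is retained for network analysis when it passes at least two
of the five published drug-likeness rule sets (Lipinski, Ghose, Veber,
Egan, Muegge) *and* has an oral-bioavailability score of at least 0.55.
Two override lists modify the verdict: a literature keep-list rescues
compounds with known bioactivity despite poor predicted pharmacokinetics,
and a drop list removes compounds that have no biological targets.

The rule-set thresholds are the SwissADME definitions, frozen here:

* Lipinski (pass = at most one violation):
  mw <= 500, MLOGP <= 4.15, N+O acceptors <= 10, NH+OH donors <= 5
* Ghose: 160 <= mw <= 480, -0.4 <= WLOGP <= 5.6,
  40 <= molar refractivity <= 130, 20 <= heavy atoms <= 70
* Veber: rotatable bonds <= 10, TPSA <= 140
* Egan: WLOGP <= 5.88, TPSA <= 131.6
* Muegge: 200 <= mw <= 600, -2 <= XLOGP <= 5, TPSA <= 150, rings <= 7,
  carbons > 4, heteroatoms > 1, rotatable bonds <= 15,
  acceptors <= 10, donors <= 5

A rule set that needs an absent descriptor fails with a logged reason
(conservative, reproducible).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from .io_model import CompoundRecord, DescriptorBlock

__all__ = [
    "FILTER_NAMES",
    "OB_THRESHOLD",
    "DruglikenessVerdict",
    "ConfigurationError",
    "evaluate_druglikeness",
    "screen_compounds",
    "write_verdict_table",
]

FILTER_NAMES = ("lipinski", "ghose", "veber", "egan", "muegge")

#: inclusive oral-bioavailability cutoff ("0.55 or more")
OB_THRESHOLD = 0.55


class ConfigurationError(ValueError):
    """Invalid screening configuration (e.g. overlapping override lists)."""


@dataclass(frozen=True)
class DruglikenessVerdict:
    """Screening outcome for one compound.

    ``retained`` is true iff the compound is literature-kept, or passes
    the OB cutoff and >= 2 rule sets and is not dropped for lacking
    targets.
    """

    compound_id: str
    filter_flags: dict[str, bool]
    n_filters_passed: int
    ob_pass: bool
    retained: bool
    override: str = "none"  # none | literature_keep | drop_no_targets
    notes: tuple[str, ...] = field(default_factory=tuple)


def _required_missing(d: DescriptorBlock, names: Iterable[str]) -> list[str]:
    return [n for n in names if getattr(d, n) is None]


def evaluate_druglikeness(d: DescriptorBlock) -> tuple[dict[str, bool], int, list[str]]:
    """Evaluate the five rule sets on a descriptor block.

    Returns ``(flags, n_passed, notes)`` where *notes* records every
    rule set failed because of an absent descriptor.
    """
    flags: dict[str, bool] = {}
    notes: list[str] = []

    # Lipinski: tolerant rule, <= 1 violation of the four bounds
    missing = _required_missing(d, ("mw", "mlogp", "hba", "hbd"))
    if missing:
        flags["lipinski"] = False
        notes.append(f"lipinski: missing descriptor(s) {', '.join(missing)}")
    else:
        violations = sum(
            [d.mw > 500, d.mlogp > 4.15, d.hba > 10, d.hbd > 5]
        )
        flags["lipinski"] = violations <= 1

    missing = _required_missing(d, ("mw", "wlogp", "molar_refractivity", "heavy_atoms"))
    if missing:
        flags["ghose"] = False
        notes.append(f"ghose: missing descriptor(s) {', '.join(missing)}")
    else:
        flags["ghose"] = (
            160 <= d.mw <= 480
            and -0.4 <= d.wlogp <= 5.6
            and 40 <= d.molar_refractivity <= 130
            and 20 <= d.heavy_atoms <= 70
        )

    missing = _required_missing(d, ("rotb", "tpsa"))
    if missing:
        flags["veber"] = False
        notes.append(f"veber: missing descriptor(s) {', '.join(missing)}")
    else:
        flags["veber"] = d.rotb <= 10 and d.tpsa <= 140

    missing = _required_missing(d, ("wlogp", "tpsa"))
    if missing:
        flags["egan"] = False
        notes.append(f"egan: missing descriptor(s) {', '.join(missing)}")
    else:
        flags["egan"] = d.wlogp <= 5.88 and d.tpsa <= 131.6

    missing = _required_missing(
        d, ("mw", "xlogp", "tpsa", "rings", "carbons", "heteroatoms", "rotb", "hba", "hbd")
    )
    if missing:
        flags["muegge"] = False
        notes.append(f"muegge: missing descriptor(s) {', '.join(missing)}")
    else:
        flags["muegge"] = (
            200 <= d.mw <= 600
            and -2 <= d.xlogp <= 5
            and d.tpsa <= 150
            and d.rings <= 7
            and d.carbons > 4
            and d.heteroatoms > 1
            and d.rotb <= 15
            and d.hba <= 10
            and d.hbd <= 5
        )

    return flags, sum(flags.values()), notes


def screen_compounds(
    compounds: Sequence[CompoundRecord],
    keep_list: Iterable[str] = (),
    drop_no_target_list: Iterable[str] = (),
    ob_threshold: float = OB_THRESHOLD,
    min_filters: int = 2,
) -> list[DruglikenessVerdict]:
    """Screen compounds with the 2-of-5 + OB rule plus override lists.

    ``keep_list`` holds compound ids retained on literature evidence
    regardless of the rules; ``drop_no_target_list`` holds ids excluded
    because no biological target is known.  The two lists must be
    disjoint.  Input order is preserved.
    """
    keep = set(keep_list)
    drop = set(drop_no_target_list)
    overlap = keep & drop
    if overlap:
        raise ConfigurationError(
            f"keep_list and drop_no_target_list overlap: {sorted(overlap)}"
        )

    verdicts: list[DruglikenessVerdict] = []
    for c in compounds:
        flags, n_passed, notes = evaluate_druglikeness(c.descriptors)
        ob_pass = c.ob_score >= ob_threshold
        if c.compound_id in keep:
            override = "literature_keep"
        elif c.compound_id in drop:
            override = "drop_no_targets"
        else:
            override = "none"
        retained = (override == "literature_keep") or (
            ob_pass and n_passed >= min_filters and override != "drop_no_targets"
        )
        verdicts.append(
            DruglikenessVerdict(
                compound_id=c.compound_id,
                filter_flags=flags,
                n_filters_passed=n_passed,
                ob_pass=ob_pass,
                retained=retained,
                override=override,
                notes=tuple(notes),
            )
        )
    return verdicts


def write_verdict_table(verdicts: Sequence[DruglikenessVerdict], path: str | Path) -> None:
    """One row per compound, one column per rule set, plus the verdict."""
    cols = ["compound_id", *FILTER_NAMES, "n_filters_passed", "ob_pass", "retained", "override"]
    lines = ["\t".join(cols)]
    for v in verdicts:
        row = [v.compound_id]
        row += [str(int(v.filter_flags[f])) for f in FILTER_NAMES]
        row += [str(v.n_filters_passed), str(int(v.ob_pass)), str(int(v.retained)), v.override]
        lines.append("\t".join(row))
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8", newline="\n")
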