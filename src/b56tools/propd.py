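"""Proteomic peptide phage display (ProP-PD) count processing.

A selection experiment yields, per bait, a table of displayed peptides with
next-generation sequencing counts.  Processing follows three steps: a count
cutoff separates confident binders from noise; peptides enriched against
most baits are removed as promiscuous background binders; and below-cutoff
peptides that contain a consensus docking window are rescued back into the
ligand set.  Set overlaps between baits summarise shared specificity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import FormatError, ParameterError
from .motif import B56_CONSENSUS, MotifPattern, find_motif_windows
from .sequences import ProteinRecord, strip_phospho

ABOVE_CUTOFF = "above_cutoff"
RESCUED = "rescued"


@dataclass
class LigandSet:
    """Retained peptides for one bait with per-peptide provenance."""

    bait: str
    provenance: dict[str, str] = field(default_factory=dict)

    @property
    def peptides(self) -> set[str]:
        return set(self.provenance)

    def add(self, peptide: str, how: str) -> None:
        if peptide in self.provenance:
            return  # first provenance wins; above_cutoff is assigned first
        self.provenance[peptide] = how


def _validate_counts(table: pd.DataFrame) -> None:
    for col in ("peptide", "bait", "count"):
        if col not in table.columns:
            raise FormatError(f"count table missing column {col!r}")
    if (table["count"] < 0).any():
        raise FormatError("negative sequencing counts in input")


def _passes(count: int, cutoff: int, mode: str) -> bool:
    if mode == "gt":
        return count > cutoff
    if mode == "ge":
        return count >= cutoff
    raise ParameterError(f"cutoff mode must be 'gt' or 'ge', got {mode!r}")


def apply_count_cutoff(
    table: pd.DataFrame, cutoff: int = 1, mode: str = "gt"
) -> dict[str, LigandSet]:
    """Per-bait ligand sets of peptides passing the sequencing-count cutoff.

    With the default strict mode, retained peptides have count > cutoff
    (a "cutoff=1" with at least one read per observed peptide would
    otherwise retain everything).
    """
    if cutoff < 0:
        raise ParameterError("cutoff must be >= 0")
    _validate_counts(table)
    out: dict[str, LigandSet] = {}
    for bait, grp in table.groupby("bait"):
        ls = LigandSet(bait=str(bait))
        for _, row in grp.iterrows():
            if _passes(int(row["count"]), cutoff, mode):
                ls.add(str(row["peptide"]), ABOVE_CUTOFF)
        out[str(bait)] = ls
    return out


def filter_promiscuous(
    table: pd.DataFrame,
    cutoff: int = 1,
    mode: str = "gt",
    max_bait_fraction: float = 0.5,
) -> tuple[pd.DataFrame, list[str]]:
    """Drop peptides enriched in more than ``max_bait_fraction`` of baits.

    Promiscuity is judged within the supplied baits: a peptide is removed if
    it passes the cutoff in strictly more than ``max_bait_fraction`` of the
    baits present in the table.  Returns the filtered table and the removed
    peptides.
    """
    _validate_counts(table)
    baits = table["bait"].unique()
    if len(baits) < 2:
        raise ParameterError("promiscuity filtering needs >= 2 baits")
    passing = table[[_passes(int(c), cutoff, mode) for c in table["count"]]]
    n_baits_passing = passing.groupby("peptide")["bait"].nunique()
    removed = sorted(
        n_baits_passing[n_baits_passing > max_bait_fraction * len(baits)].index
    )
    keep = ~table["peptide"].isin(removed)
    return table[keep].reset_index(drop=True), removed


def rescue_motif_matches(
    below_cutoff: Iterable[str], pattern: MotifPattern = B56_CONSENSUS
) -> set[str]:
    """Below-cutoff peptides containing at least one consensus window."""
    return {p for p in below_cutoff if find_motif_windows(p, pattern)}


def build_ligand_sets(
    table: pd.DataFrame,
    pattern: MotifPattern = B56_CONSENSUS,
    cutoff: int = 1,
    mode: str = "gt",
    max_bait_fraction: float = 0.5,
    drop_promiscuous: bool = True,
) -> tuple[dict[str, LigandSet], list[str]]:
    """Full processing: promiscuity filter, cutoff, motif rescue.

    Returns per-bait ligand sets (provenance ``above_cutoff`` or
    ``rescued``) and the list of promiscuous peptides removed.
    """
    _validate_counts(table)
    removed: list[str] = []
    if drop_promiscuous and table["bait"].nunique() >= 2:
        table, removed = filter_promiscuous(table, cutoff, mode, max_bait_fraction)
    sets = apply_count_cutoff(table, cutoff, mode)
    for bait, grp in table.groupby("bait"):
        ls = sets[str(bait)]
        below = [
            str(r["peptide"])
            for _, r in grp.iterrows()
            if not _passes(int(r["count"]), cutoff, mode)
        ]
        for pep in rescue_motif_matches(below, pattern):
            ls.add(pep, RESCUED)
    return sets, removed


def map_peptides(
    peptides: Iterable[str], proteome: Sequence[ProteinRecord]
) -> pd.DataFrame:
    """Exact-match placements of peptides in a proteome (1-based starts).

    Phospho marks are stripped before matching; all occurrences are
    reported; absent peptides contribute no rows.
    """
    rows = []
    for pep in peptides:
        plain = strip_phospho(pep)
        for rec in proteome:
            start = rec.sequence.find(plain)
            while start != -1:
                rows.append({"peptide": pep, "protein": rec.id, "start": start + 1})
                start = rec.sequence.find(plain, start + 1)
    return pd.DataFrame(rows, columns=["peptide", "protein", "start"])


def overlap_sets(sets: Mapping[str, set[str]]) -> dict[tuple[str, ...], int]:
    """Cardinality of every exclusive intersection region (Venn regions).

    Keys are sorted tuples of bait names; the value for ``(a, b)`` counts
    elements in exactly ``{a, b}`` and no other set.  Region counts are
    disjoint and sum to the size of the union.
    """
    names = sorted(sets)
    regions: dict[tuple[str, ...], int] = {}
    for k in range(1, len(names) + 1):
        for combo in combinations(names, k):
            inside = set.intersection(*(sets[n] for n in combo)) if combo else set()
            outside = set().union(*(sets[n] for n in names if n not in combo), set())
            regions[combo] = len(inside - outside)
    return regions
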