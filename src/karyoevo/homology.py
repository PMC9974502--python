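"""Macrosynteny homology mapping from ortholog abundance.

For each outgroup (amphioxus-like) chromosome — or, once cephalochordate
fusions have been resolved, each ancestral linkage group — this module counts
where its orthologs land in an ingroup genome and converts the counts into a
relative-abundance profile.  The chromosomes that absorb at least a minimum
fraction of the placed orthologs are assigned as homologs, labelled A, B, C,
D in descending abundance.  Under two rounds of whole-genome duplication and
no later rearrangement the expected signature is a clean 1:4 relationship;
fusions redistribute the same signal over shared chromosomes and are picked
up downstream by :mod:`karyoevo.history`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd

from .errors import KaryoevoError
from .tables import SLOT_LABELS, GenePositionTable, OrthoGroupTable


@dataclass
class HomologyProfile:
    """Ortholog counts of one outgroup unit over ingroup chromosomes."""

    unit: str
    counts: dict[str, int]

    @property
    def n_placed(self) -> int:
        return int(sum(self.counts.values()))

    @property
    def abundance(self) -> dict[str, float]:
        """Fraction of this unit's placed orthologs per ingroup chromosome."""
        total = self.n_placed
        if total == 0:
            return {}
        return {chrom: n / total for chrom, n in self.counts.items()}


@dataclass(frozen=True)
class SlotAssignment:
    label: str
    chromosome: str
    count: int
    abundance: float


@dataclass
class HomologyAssignment:
    """Assigned homologous chromosomes (up to four slots) for one unit."""

    unit: str
    slots: list[SlotAssignment]
    residue: float
    n_placed: int
    low_confidence: bool = False

    def slot_of(self) -> dict[str, str]:
        """chromosome -> slot label."""
        return {s.chromosome: s.label for s in self.slots}

    def chromosomes(self) -> set[str]:
        return {s.chromosome for s in self.slots}


#: outgroup unit -> assignment
HomologyMap = dict[str, HomologyAssignment]


def placed_ortholog_frame(orthogroups: OrthoGroupTable,
                          outgroup_positions: GenePositionTable,
                          ingroup_positions: GenePositionTable,
                          outgroup: str, ingroup: str
                          ) -> tuple[pd.DataFrame, dict[str, int]]:
    """Join orthogroups with both position tables.

    Returns a frame with one row per (orthogroup, outgroup chromosome,
    ingroup gene) combination — columns ``group, out_chrom, n_out, in_gene,
    in_chrom`` — restricted to groups with at least one placed gene on each
    side, plus a skip report counting genes without a chromosome assignment.
    """
    for sp in (outgroup, ingroup):
        if sp not in orthogroups.species:
            raise KaryoevoError(f"species {sp!r} absent from orthogroup table")
    long = orthogroups.to_long()
    skip = {}

    out_rows = long[long["species"] == outgroup][["group", "gene"]]
    out_chrom = outgroup_positions.chrom_of()
    placed = out_rows["gene"].map(out_chrom)
    skip[outgroup] = int(placed.isna().sum())
    out_rows = out_rows.assign(out_chrom=placed).dropna(subset=["out_chrom"])
    # number of outgroup genes per (group, chromosome): the per-pair weight
    out_units = (out_rows.groupby(["group", "out_chrom"], sort=True)
                 .size().rename("n_out").reset_index())

    in_rows = long[long["species"] == ingroup][["group", "gene"]]
    in_chrom = ingroup_positions.chrom_of()
    placed = in_rows["gene"].map(in_chrom)
    skip[ingroup] = int(placed.isna().sum())
    in_rows = (in_rows.assign(in_chrom=placed).dropna(subset=["in_chrom"])
               .rename(columns={"gene": "in_gene"}))

    frame = out_units.merge(in_rows, on="group", how="inner")
    return frame, skip


def build_profiles(orthogroups: OrthoGroupTable,
                   outgroup_positions: GenePositionTable,
                   ingroup_positions: GenePositionTable,
                   outgroup: str, ingroup: str,
                   weight_mode: str = "per_gene",
                   unit_assignment: Mapping[tuple[str, str], str] | None = None,
                   ) -> tuple[dict[str, HomologyProfile], dict[str, int]]:
    """Count ortholog placements per outgroup unit and ingroup chromosome.

    ``weight_mode`` controls multi-member orthogroups: ``per_gene`` adds one
    count per ingroup gene (default; avoids quadratic inflation from large
    families), ``per_pair`` adds one count per (outgroup gene, ingroup gene)
    pair.  ``unit_assignment`` optionally remaps each (group, outgroup
    chromosome) to an ancestral-linkage-group id, so that profiles can be
    built per ALG once cephalochordate fusions are resolved.

    Returns the profiles keyed by unit plus a skip report of genes that had
    no chromosome assignment.
    """
    if weight_mode not in ("per_gene", "per_pair"):
        raise KaryoevoError(f"unknown weight_mode {weight_mode!r}")
    frame, skip = placed_ortholog_frame(
        orthogroups, outgroup_positions, ingroup_positions, outgroup, ingroup)
    if frame.empty:
        if sum(skip.values()):
            raise KaryoevoError(
                "no orthologs could be placed on chromosomes "
                f"(skipped: {skip}); check that the species labels match "
                "the position tables")
        return {}, skip
    weight = frame["n_out"] if weight_mode == "per_pair" else 1
    unit = frame["out_chrom"]
    if unit_assignment is not None:
        keys = list(zip(frame["group"], frame["out_chrom"]))
        unit = pd.Series([unit_assignment.get(k, k[1]) for k in keys],
                         index=frame.index)
    counts = (frame.assign(unit=unit, w=weight)
              .groupby(["unit", "in_chrom"], sort=True)["w"].sum())
    profiles: dict[str, HomologyProfile] = {}
    for (u, chrom), n in counts.items():
        profiles.setdefault(u, HomologyProfile(u, {})).counts[chrom] = int(n)
    return profiles, skip


def assign_homologs(profile: HomologyProfile, max_homologs: int = 4,
                    min_fraction: float = 0.05,
                    min_placed: int = 10) -> HomologyAssignment:
    """Pick up to ``max_homologs`` chromosomes with abundance >= ``min_fraction``.

    Slots are ordered by descending abundance with a lexicographic tie-break
    on chromosome name; units with fewer than ``min_placed`` placed orthologs
    are flagged low-confidence rather than dropped.
    """
    if profile.n_placed == 0:
        raise KaryoevoError(f"unit {profile.unit!r} has no placed orthologs")
    abundance = profile.abundance
    ranked = sorted(abundance.items(), key=lambda kv: (-kv[1], kv[0]))
    slots = []
    for label, (chrom, frac) in zip(SLOT_LABELS, ranked[:max_homologs]):
        if frac < min_fraction:
            break
        slots.append(SlotAssignment(label, chrom, profile.counts[chrom], frac))
    residue = 1.0 - sum(s.abundance for s in slots)
    return HomologyAssignment(
        unit=profile.unit, slots=slots, residue=residue,
        n_placed=profile.n_placed,
        low_confidence=profile.n_placed < min_placed)


def build_homology_map(profiles: Mapping[str, HomologyProfile],
                       max_homologs: int = 4, min_fraction: float = 0.05,
                       min_placed: int = 10) -> HomologyMap:
    return {unit: assign_homologs(prof, max_homologs=max_homologs,
                                  min_fraction=min_fraction,
                                  min_placed=min_placed)
            for unit, prof in sorted(profiles.items())}


def write_homology_map(homology_map: HomologyMap, path: str | Path) -> None:
    """TSV: outgroup unit, slot, ingroup chromosome, count, abundance."""
    with Path(path).open("w", encoding="utf-8", newline="\n") as fh:
        fh.write("unit\tslot\tingroup_chrom\tcount\tabundance\n")
        for unit in sorted(homology_map):
            for s in homology_map[unit].slots:
                fh.write(f"{unit}\t{s.label}\t{s.chromosome}\t{s.count}\t"
                         f"{s.abundance:.6f}\n")
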