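"""Ohnolog-group extraction and cross-species ohnology transfer.

Ohnologs are paralogs retained from whole-genome duplication.  Given the
homology map (which ingroup chromosomes descend from each outgroup
chromosome or ancestral linkage group), each orthogroup is restricted to the
ingroup genes lying on the assigned homologous chromosomes; genes are
labelled by slot (A-D) according to the chromosome they sit on, and groups
occupying at least ``min_slots`` distinct slots are kept.  Ohnology labels
can then be transferred to a second species through pairwise orthologs, the
route by which new human ohnologs were identified from chicken.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .errors import KaryoevoError
from .homology import HomologyMap
from .tables import (GenePositionTable, OhnologDatasetRecord, OrthoGroupTable,
                     OrthologPairMap)


@dataclass
class OhnologGroup:
    """One orthogroup restricted to genes on homologous chromosomes.

    ``anchor`` is the outgroup chromosome (or ALG id) the group is counted
    under; ``members`` maps slot labels to the ingroup genes on that slot's
    chromosome.  Multiple genes on one slot chromosome are tandem duplicates
    and count as a single occupied slot.
    """

    group_id: str
    anchor: str
    anchor_genes: tuple[str, ...]
    species: str
    members: dict[str, tuple[str, ...]]

    @property
    def n_members(self) -> int:
        """Number of distinct occupied slots (homologous chromosomes)."""
        return sum(1 for genes in self.members.values() if genes)

    def genes(self) -> set[str]:
        return {g for genes in self.members.values() for g in genes}


@dataclass
class ExtractionReport:
    n_source_groups: int = 0
    n_excluded_genes: int = 0
    n_dropped_few_slots: int = 0
    skipped_units: set[str] = field(default_factory=set)


def extract_ohnolog_groups(orthogroups: OrthoGroupTable,
                           homology_map: HomologyMap,
                           outgroup_positions: GenePositionTable,
                           ingroup_positions: GenePositionTable,
                           outgroup: str, ingroup: str,
                           min_slots: int = 2,
                           unit_assignment: Mapping[tuple[str, str], str] | None = None,
                           ) -> tuple[list[OhnologGroup], ExtractionReport]:
    """Extract ohnolog groups from each qualifying orthogroup.

    Orthogroups whose outgroup genes span several outgroup chromosomes are
    split, one anchor per chromosome, so each anchor's bookkeeping stays per
    outgroup chromosome.  Ingroup genes on chromosomes not assigned to the
    anchor are excluded and tallied in the report; groups occupying fewer
    than ``min_slots`` distinct slots are dropped.
    """
    out_chrom = outgroup_positions.chrom_of()
    in_chrom = ingroup_positions.chrom_of()
    report = ExtractionReport()
    groups: list[OhnologGroup] = []
    for gid, row in orthogroups:
        anchors: dict[str, list[str]] = {}
        for g in row[outgroup]:
            chrom = out_chrom.get(g)
            if chrom is not None:
                anchors.setdefault(chrom, []).append(g)
        if not anchors or not row[ingroup]:
            continue
        report.n_source_groups += 1
        multi = len(anchors) > 1
        for chrom in sorted(anchors):
            unit = (unit_assignment.get((gid, chrom), chrom)
                    if unit_assignment is not None else chrom)
            assignment = homology_map.get(unit)
            if assignment is None:
                report.skipped_units.add(unit)
                continue
            slot_of = assignment.slot_of()
            members: dict[str, list[str]] = {}
            for g in row[ingroup]:
                label = slot_of.get(in_chrom.get(g))
                if label is None:
                    report.n_excluded_genes += 1
                else:
                    members.setdefault(label, []).append(g)
            group = OhnologGroup(
                group_id=f"{gid}:{unit}" if multi else gid,
                anchor=unit, anchor_genes=tuple(anchors[chrom]),
                species=ingroup,
                members={label: tuple(v)
                         for label, v in sorted(members.items())})
            if group.n_members >= min_slots:
                groups.append(group)
            else:
                report.n_dropped_few_slots += 1
    return groups, report


def count_groups(groups: Iterable[OhnologGroup], min_slots: int) -> int:
    """Number of groups occupying at least ``min_slots`` distinct slots."""
    return sum(1 for g in groups if g.n_members >= min_slots)


def transfer_ohnology(groups: Sequence[OhnologGroup],
                      pairs: OrthologPairMap,
                      target_positions: GenePositionTable,
                      target_map: HomologyMap,
                      ) -> tuple[list[OhnologGroup], list[str]]:
    """Project ohnolog groups onto a second species via pairwise orthologs.

    Every source member is replaced by its target-species orthologs; each
    target gene is slot-labelled through the target species' homology map
    for the same anchor.  Genes with no ortholog (or landing off the
    assigned chromosomes) drop out; the returned gene list contains all
    distinct transferred genes, the candidates for newly identified
    ohnologs in the target species.
    """
    targets = pairs.targets_of()
    chrom_of = target_positions.chrom_of()
    transferred: list[OhnologGroup] = []
    all_genes: set[str] = set()
    for group in groups:
        assignment = target_map.get(group.anchor)
        if assignment is None:
            continue
        slot_of = assignment.slot_of()
        members: dict[str, set[str]] = {}
        for genes in group.members.values():
            for g in genes:
                for tg in targets.get(g, ()):
                    label = slot_of.get(chrom_of.get(tg))
                    if label is not None:
                        members.setdefault(label, set()).add(tg)
        if not members:
            continue
        out = OhnologGroup(
            group_id=group.group_id, anchor=group.anchor,
            anchor_genes=group.anchor_genes,
            species=pairs.species_b,
            members={label: tuple(sorted(v))
                     for label, v in sorted(members.items())})
        transferred.append(out)
        all_genes.update(out.genes())
    return transferred, sorted(all_genes)


def to_dataset_records(groups_by_species: Mapping[str, Sequence[OhnologGroup]],
                       new_genes: Mapping[str, Iterable[str]] | None = None,
                       ) -> list[OhnologDatasetRecord]:
    """Merge per-species ohnolog groups into row-per-group dataset records.

    Groups from different species are aligned on (group id, anchor); novelty
    flags mark the given genes in their species' ``new`` column.
    """
    new_sets = {sp: set(genes) for sp, genes in (new_genes or {}).items()}
    keys: list[tuple[str, str]] = []
    index: dict[tuple[str, str], dict[str, dict[str, tuple[str, ...]]]] = {}
    for sp, groups in groups_by_species.items():
        for g in groups:
            key = (g.group_id, g.anchor)
            if key not in index:
                index[key] = {}
                keys.append(key)
            index[key][sp] = dict(g.members)
    records = []
    for gid, anchor in keys:
        members = {sp: index[(gid, anchor)].get(sp, {})
                   for sp in groups_by_species}
        new = {}
        for sp, flagged in new_sets.items():
            genes = {g for slot in members.get(sp, {}).values() for g in slot}
            hits = tuple(sorted(genes & flagged))
            if hits:
                new[sp] = hits
        records.append(OhnologDatasetRecord(
            group=gid, anchor=anchor, members=members, new=new))
    return records


def groups_to_orthogroup_table(groups: Sequence[OhnologGroup],
                               outgroup: str) -> OrthoGroupTable:
    """Re-express ohnolog groups as an orthogroup table (anchor genes plus
    slot members), the inverse view used for idempotence checks."""
    if not groups:
        raise KaryoevoError("no groups to convert")
    species = [outgroup, groups[0].species]
    table = {}
    for g in groups:
        table[g.group_id] = {
            outgroup: list(g.anchor_genes),
            g.species: [gene for genes in g.members.values() for gene in genes],
        }
    return OrthoGroupTable(species, table)
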