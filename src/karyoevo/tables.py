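"""Readers and writers for the exchange formats used across the pipeline.

The central formats are deliberately plain text:

* orthogroup tables in the OrthoFinder ``Orthogroups.tsv`` dialect (one row
  per orthogroup, one column per species, gene ids joined by ``", "``),
* BED-like gene position tables (chrom, start, end, gene_id; 0-based
  half-open),
* two-column ortholog pair maps,
* a row-per-group ohnolog dataset (TSV or XLSX) mirroring the layout of the
  published supplementary table: one column of amphioxus (Bb) anchor
  chromosomes and comma-joined member lists per species and homologous
  chromosome slot A-D.

All writers emit UTF-8 with Unix newlines, and every reader/writer pair
round-trips byte-identically on the canonical dialect.
"""

from __future__ import annotations

import csv
import io
import string
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import TableFormatError

_CELL_DELIM = ", "
SLOT_LABELS = string.ascii_uppercase


# ---------------------------------------------------------------------------
# Orthogroup tables
# ---------------------------------------------------------------------------

class OrthoGroupTable:
    """An orthogroup table: group id -> per-species gene lists.

    Gene ids are opaque tokens, unique within a species across the whole
    table; the species set is fixed by the header.
    """

    def __init__(self, species: Sequence[str],
                 groups: Mapping[str, Mapping[str, Sequence[str]]]):
        self.species = list(species)
        if not self.species:
            raise TableFormatError("orthogroup table needs at least one species")
        self.groups: dict[str, dict[str, tuple[str, ...]]] = {}
        seen: dict[str, set[str]] = {sp: set() for sp in self.species}
        for gid, members in groups.items():
            if gid in self.groups:
                raise TableFormatError(f"duplicate orthogroup id {gid!r}")
            row = {}
            for sp in self.species:
                genes = tuple(members.get(sp, ()))
                for g in genes:
                    if g in seen[sp]:
                        raise TableFormatError(
                            f"gene {g!r} occurs twice for species {sp!r}")
                    seen[sp].add(g)
                row[sp] = genes
            self.groups[gid] = row
        self._long: pd.DataFrame | None = None

    # -- basic container behaviour -----------------------------------------
    def __len__(self) -> int:
        return len(self.groups)

    def __iter__(self):
        return iter(self.groups.items())

    def members(self, group_id: str, species: str) -> tuple[str, ...]:
        return self.groups[group_id][species]

    def genes(self, species: str) -> list[str]:
        return [g for row in self.groups.values() for g in row[species]]

    def to_long(self) -> pd.DataFrame:
        """Flatten to a (group, species, gene) frame; cached."""
        if self._long is None:
            recs = [(gid, sp, g)
                    for gid, row in self.groups.items()
                    for sp in self.species
                    for g in row[sp]]
            self._long = pd.DataFrame(recs, columns=["group", "species", "gene"])
        return self._long

    # -- I/O ---------------------------------------------------------------
    @classmethod
    def read(cls, path: str | Path) -> "OrthoGroupTable":
        path = Path(path)
        with path.open(encoding="utf-8", newline="") as fh:
            reader = csv.reader(fh, delimiter="\t")
            try:
                header = next(reader)
            except StopIteration:
                raise TableFormatError(f"{path}: empty file, no header")
            if len(header) < 2:
                raise TableFormatError(
                    f"{path}: header names no species (columns: {header})")
            species = header[1:]
            groups: dict[str, dict[str, list[str]]] = {}
            for lineno, row in enumerate(reader, start=2):
                if not row:
                    continue
                if len(row) != len(header):
                    raise TableFormatError(
                        f"{path}: line {lineno}: expected {len(header)} "
                        f"columns, found {len(row)}")
                gid = row[0]
                if gid in groups:
                    raise TableFormatError(
                        f"{path}: line {lineno}: duplicate orthogroup id {gid!r}")
                groups[gid] = {
                    sp: _parse_cell(cell) for sp, cell in zip(species, row[1:])
                }
        return cls(species, groups)

    def write(self, path: str | Path) -> None:
        path = Path(path)
        with path.open("w", encoding="utf-8", newline="\n") as fh:
            fh.write("\t".join(["Orthogroup"] + self.species) + "\n")
            for gid, row in self.groups.items():
                cells = [_CELL_DELIM.join(row[sp]) for sp in self.species]
                fh.write("\t".join([gid] + cells) + "\n")


def _parse_cell(cell: str) -> list[str]:
    cell = cell.strip()
    if not cell:
        return []
    return [tok.strip() for tok in cell.split(",") if tok.strip()]


# ---------------------------------------------------------------------------
# Gene position tables
# ---------------------------------------------------------------------------

@dataclass
class GenePositionTable:
    """Per-species gene placements in BED-like coordinates (0-based half-open)."""

    species: str
    df: pd.DataFrame  # columns: chrom, start, end, gene_id

    COLUMNS = ("chrom", "start", "end", "gene_id")

    def __post_init__(self):
        df = self.df.reset_index(drop=True)
        if list(df.columns[:4]) != list(self.COLUMNS):
            df = df.iloc[:, :4].set_axis(list(self.COLUMNS), axis=1)
        if len(df):
            if (df["start"] >= df["end"]).any():
                bad = df[df["start"] >= df["end"]].iloc[0]
                raise TableFormatError(
                    f"{self.species}: gene {bad['gene_id']!r} has start >= end "
                    f"({bad['start']} >= {bad['end']})")
            if (df["start"] < 0).any():
                raise TableFormatError(f"{self.species}: negative coordinate")
            dup = df["gene_id"].duplicated()
            if dup.any():
                raise TableFormatError(
                    f"{self.species}: duplicate gene id "
                    f"{df.loc[dup, 'gene_id'].iloc[0]!r}")
        self.df = df

    def __len__(self) -> int:
        return len(self.df)

    def chrom_of(self) -> dict[str, str]:
        """gene_id -> chromosome mapping."""
        return dict(zip(self.df["gene_id"], self.df["chrom"]))

    @classmethod
    def read(cls, path: str | Path, species: str) -> "GenePositionTable":
        path = Path(path)
        try:
            raw = pd.read_csv(path, sep="\t", header=None, dtype=str,
                              comment="#")
        except pd.errors.EmptyDataError:
            return cls(species, pd.DataFrame(columns=list(cls.COLUMNS)))
        if raw.shape[1] < 4:
            raise TableFormatError(
                f"{path}: expected >=4 tab-separated columns, found {raw.shape[1]}")
        df = raw.iloc[:, :4].set_axis(list(cls.COLUMNS), axis=1)
        for col in ("start", "end"):
            vals = pd.to_numeric(df[col], errors="coerce")
            if vals.isna().any():
                bad = df.loc[vals.isna(), col].iloc[0]
                raise TableFormatError(
                    f"{path}: non-integer {col} coordinate {bad!r}")
            if (vals % 1 != 0).any():
                raise TableFormatError(f"{path}: non-integer {col} coordinate")
            df[col] = vals.astype(int)
        return cls(species, df)

    def write(self, path: str | Path) -> None:
        path = Path(path)
        with path.open("w", encoding="utf-8", newline="\n") as fh:
            for rec in self.df.itertuples(index=False):
                fh.write(f"{rec.chrom}\t{rec.start}\t{rec.end}\t{rec.gene_id}\n")


# ---------------------------------------------------------------------------
# Ortholog pair maps
# ---------------------------------------------------------------------------

@dataclass
class OrthologPairMap:
    """Pairwise (possibly many-to-many) orthologs between two species."""

    species_a: str
    species_b: str
    pairs: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self):
        seen = set()
        for p in self.pairs:
            if p in seen:
                raise TableFormatError(f"duplicate ortholog pair {p!r}")
            seen.add(p)

    def __len__(self) -> int:
        return len(self.pairs)

    def targets_of(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for a, b in self.pairs:
            out.setdefault(a, []).append(b)
        return out

    @classmethod
    def from_orthogroups(cls, table: OrthoGroupTable, species_a: str,
                         species_b: str) -> "OrthologPairMap":
        """All within-orthogroup cross pairs between the two species.

        This mirrors extracting pairwise orthologous relationships from
        clustering output: every (gene_a, gene_b) combination inside one
        orthogroup is a candidate ortholog pair.
        """
        pairs = [(a, b)
                 for _, row in table
                 for a in row[species_a]
                 for b in row[species_b]]
        return cls(species_a, species_b, pairs)

    @classmethod
    def read(cls, path: str | Path, species_a: str,
             species_b: str) -> "OrthologPairMap":
        path = Path(path)
        pairs: list[tuple[str, str]] = []
        with path.open(encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) < 2:
                    raise TableFormatError(
                        f"{path}: line {lineno}: expected 2 columns")
                pairs.append((parts[0], parts[1]))
        return cls(species_a, species_b, pairs)

    def write(self, path: str | Path) -> None:
        with Path(path).open("w", encoding="utf-8", newline="\n") as fh:
            for a, b in self.pairs:
                fh.write(f"{a}\t{b}\n")


# ---------------------------------------------------------------------------
# Ohnolog dataset (supplementary-table layout)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OhnologColumns:
    """Column mapping for the row-per-group ohnolog dataset.

    The published supplementary spreadsheet's exact headers vary between
    exports, so the reader is driven by this mapping rather than hard-coded
    names.  ``member_pattern`` expands to one column per (species, slot),
    e.g. ``chicken_A``; ``new_pattern`` to one optional novelty column per
    species, e.g. ``new_in_human``.
    """

    group: str = "group"
    anchor: str = "bb_chromosome"
    species: tuple[str, ...] = ("chicken", "human")
    slots: tuple[str, ...] = ("A", "B", "C", "D")
    member_pattern: str = "{species}_{slot}"
    new_pattern: str = "new_in_{species}"

    def member_column(self, species: str, slot: str) -> str:
        return self.member_pattern.format(species=species, slot=slot)

    def new_column(self, species: str) -> str:
        return self.new_pattern.format(species=species)


@dataclass
class OhnologDatasetRecord:
    """One ohnolog group row: anchor chromosome plus per-species slot members."""

    group: str
    anchor: str
    members: dict[str, dict[str, tuple[str, ...]]]
    new: dict[str, tuple[str, ...]] = field(default_factory=dict)

    def n_slots(self, species: str) -> int:
        return sum(1 for genes in self.members.get(species, {}).values() if genes)

    def n_members(self, species: str) -> int:
        return sum(len(genes) for genes in self.members.get(species, {}).values())


def read_ohnolog_dataset(path: str | Path,
                         columns: OhnologColumns | None = None
                         ) -> list[OhnologDatasetRecord]:
    """Read a row-per-group ohnolog dataset from TSV or XLSX.

    Raises :class:`TableFormatError` naming any expected column that is
    missing.  Novelty columns are optional.
    """
    columns = columns or OhnologColumns()
    path = Path(path)
    if path.suffix.lower() in (".xlsx", ".xls"):
        df = pd.read_excel(path, dtype=str)
    else:
        try:
            df = pd.read_csv(path, sep="\t", dtype=str)
        except pd.errors.EmptyDataError:
            return []
    df = df.fillna("")
    required = [columns.group, columns.anchor] + [
        columns.member_column(sp, slot)
        for sp in columns.species for slot in columns.slots]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise TableFormatError(
            f"{path}: missing expected columns: {', '.join(missing)}")
    records = []
    for row in df.itertuples(index=False):
        row = dict(zip(df.columns, row))
        members = {
            sp: {slot: tuple(_parse_cell(row[columns.member_column(sp, slot)]))
                 for slot in columns.slots}
            for sp in columns.species}
        new = {}
        for sp in columns.species:
            col = columns.new_column(sp)
            if col in df.columns:
                genes = tuple(_parse_cell(row[col]))
                if genes:
                    new[sp] = genes
        records.append(OhnologDatasetRecord(
            group=row[columns.group], anchor=row[columns.anchor],
            members=members, new=new))
    return records


def write_ohnolog_dataset(records: Iterable[OhnologDatasetRecord],
                          path: str | Path,
                          columns: OhnologColumns | None = None) -> None:
    """Write dataset records as TSV or XLSX (chosen by file suffix)."""
    columns = columns or OhnologColumns()
    records = list(records)
    header = [columns.group, columns.anchor]
    header += [columns.member_column(sp, slot)
               for sp in columns.species for slot in columns.slots]
    novelty_species = [sp for sp in columns.species
                       if any(rec.new.get(sp) for rec in records)]
    header += [columns.new_column(sp) for sp in novelty_species]
    rows = []
    for rec in records:
        row = [rec.group, rec.anchor]
        for sp in columns.species:
            for slot in columns.slots:
                row.append(_CELL_DELIM.join(rec.members.get(sp, {}).get(slot, ())))
        for sp in novelty_species:
            row.append(_CELL_DELIM.join(rec.new.get(sp, ())))
        rows.append(row)
    path = Path(path)
    df = pd.DataFrame(rows, columns=header)
    if path.suffix.lower() in (".xlsx", ".xls"):
        df.to_excel(path, index=False)
    else:
        buf = io.StringIO()
        df.to_csv(buf, sep="\t", index=False, lineterminator="\n")
        path.write_text(buf.getvalue(), encoding="utf-8")


def count_groups_with_min_slots(records: Iterable[OhnologDatasetRecord],
                                species: str, min_slots: int = 3) -> int:
    """Groups whose members occupy at least ``min_slots`` distinct homologous
    chromosomes (slots) in ``species``."""
    return sum(1 for rec in records if rec.n_slots(species) >= min_slots)


def count_new_members(records: Iterable[OhnologDatasetRecord],
                      species: str) -> int:
    """Total number of novelty-flagged genes for ``species``, deduplicated."""
    genes = {g for rec in records for g in rec.new.get(species, ())}
    return len(genes)
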