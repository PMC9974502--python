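"""Forward simulator of chordate-to-vertebrate karyotype evolution.

The generative model mirrors the inferred history of vertebrate chromosomes:
an ancestral genome of ``N0`` chromosomes with ``G`` genes each evolves along
a fixed tree.  The outgroup (amphioxus-like) branch experiences only
chromosome fusions; the vertebrate stem applies an ordered sequence of
fusions and two whole-genome duplications (1R and 2R), after which each
ancestral gene has up to four copies residing on the four 2R-derived
chromosome copies.  Two extant ingroup species are emitted from the same
post-2R genome with independent gene loss: each post-WGD gene copy survives
with probability ``p`` (optionally modulated per chromosome copy to model
asymmetric sequence loss), conditioned by default on at least one surviving
copy per orthogroup and species.  Optional translocation noise moves a small
fraction of surviving genes to random chromosomes.

The simulator emits the same table formats the inference modules consume
(orthogroup table, per-species gene positions) plus a :class:`TruthLog`
holding the complete ground truth, so every inference stage can be tested
against a known history without external data.

By default fusion partners are drawn uniformly among chromosome pairs that
share no ancestral linkage content and whose ancestral-unit combination has
not occurred before anywhere in the history.  Abundance-based fusion
inference identifies fusions as novel combinations of ancestral units, so
self-fusions and repeated combinations are unidentifiable in principle; the
default therefore generates identifiable histories (as the reconstructed
vertebrate history itself is).  Set ``allow_homologous_fusion=True`` for
fully uniform partner choice.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigurationError
from .history import (EventHistory, FUSION, WGD, NODE_ROOT, NODE_JAWED,
                      EPOCH_CEPH, EPOCH_PRE1R, EPOCH_POST1R, EPOCH_POST2R,
                      EPOCH_LINEAGE, apply_events, vertebrate_stem_history)
from .tables import GenePositionTable, OrthoGroupTable

#: default stem event sequence: six fusions, 1R, nine fusions, 2R, five fusions
DEFAULT_STEM_EVENTS = ((FUSION,) * 6 + (WGD,) + (FUSION,) * 9 + (WGD,)
                       + (FUSION,) * 5)

_PREFIXES = {"amphioxus": "bb", "chicken": "gg", "human": "hs",
             "zebrafinch": "tg", "gar": "lo"}

_GENE_LEN = 1_000
_GENE_SPACING = 2_000


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one simulated history.

    Defaults reproduce the inferred vertebrate history: a 23-chromosome
    chordate ancestor, three fusions on the cephalochordate branch, six
    pre-1R stem fusions, 1R, nine post-1R fusions, 2R, five post-2R fusions
    (45 jawed-vertebrate chromosomes), and five further fusions on the
    chicken (bird-stem) branch, with per-copy retention probability 0.9.
    """

    n_ancestral_chromosomes: int = 23
    genes_per_chromosome: int = 100
    outgroup: str = "amphioxus"
    ingroups: tuple[str, ...] = ("chicken", "human")
    outgroup_fusions: int = 3
    stem_events: tuple[str, ...] = DEFAULT_STEM_EVENTS
    lineage_events: Mapping[str, tuple[str, ...]] = field(
        default_factory=lambda: {"chicken": (FUSION,) * 5})
    retention_prob: float = 0.9
    asymmetry_sd: float = 0.0
    translocation_rate: float = 0.0
    min_one_copy: bool = True
    allow_homologous_fusion: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.n_ancestral_chromosomes < 1:
            raise ConfigurationError("need at least one ancestral chromosome")
        if self.genes_per_chromosome < 1:
            raise ConfigurationError("need at least one gene per chromosome")
        if not 0.0 <= self.retention_prob <= 1.0:
            raise ConfigurationError("retention_prob must lie in [0, 1]")
        if not 0.0 <= self.translocation_rate <= 1.0:
            raise ConfigurationError("translocation_rate must lie in [0, 1]")
        if self.asymmetry_sd < 0:
            raise ConfigurationError("asymmetry_sd must be >= 0")
        if self.outgroup in self.ingroups:
            raise ConfigurationError("outgroup cannot also be an ingroup")
        if len(set(self.ingroups)) != len(self.ingroups):
            raise ConfigurationError("duplicate ingroup species names")
        for sp in self.lineage_events:
            if sp not in self.ingroups:
                raise ConfigurationError(
                    f"lineage events given for unknown species {sp!r}")
        # dry-run the count arithmetic so infeasible event lists fail early
        apply_events(self.n_ancestral_chromosomes,
                     (FUSION,) * self.outgroup_fusions)
        jawed = apply_events(self.n_ancestral_chromosomes, self.stem_events)
        for sp, events in self.lineage_events.items():
            apply_events(jawed, tuple(events))

    @property
    def n_wgd(self) -> int:
        return sum(1 for ev in self.stem_events if ev == WGD)

    # -- serialisation -----------------------------------------------------
    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        data["stem_events"] = list(self.stem_events)
        data["ingroups"] = list(self.ingroups)
        data["lineage_events"] = {sp: list(ev)
                                  for sp, ev in self.lineage_events.items()}
        Path(path).write_text(yaml.safe_dump(data, sort_keys=True),
                              encoding="utf-8")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        data = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        return cls.from_dict(data)

    @classmethod
    def from_dict(cls, data: Mapping) -> "SimulationConfig":
        data = dict(data)
        if "stem_events" in data:
            data["stem_events"] = tuple(data["stem_events"])
        if "ingroups" in data:
            data["ingroups"] = tuple(data["ingroups"])
        if "lineage_events" in data:
            data["lineage_events"] = {sp: tuple(ev) for sp, ev
                                      in data["lineage_events"].items()}
        return cls(**data)


# ---------------------------------------------------------------------------
# internal genome representation: blocks of G co-travelling genes
# ---------------------------------------------------------------------------

@dataclass
class _Block:
    alg: int                  # ancestral chromosome index
    lineage: tuple[int, ...]  # WGD side choices, e.g. (0, 1) after 2R
    weight: float = 1.0       # per-chromosome-copy retention multiplier


@dataclass
class _Chrom:
    cid: int
    blocks: list[_Block]

    def alg_set(self) -> frozenset[int]:
        return frozenset(b.alg for b in self.blocks)


class _FusionSampler:
    """Seeded fusion-partner choice with the identifiability constraint."""

    def __init__(self, rng: np.random.Generator, allow_homologous: bool):
        self.rng = rng
        self.allow_homologous = allow_homologous
        self.used_pairs: set[frozenset[int]] = set()

    def pick(self, genome: list[_Chrom]) -> tuple[int, int]:
        candidates = []
        for i, j in itertools.combinations(range(len(genome)), 2):
            a, b = genome[i].alg_set(), genome[j].alg_set()
            if not self.allow_homologous:
                if a & b:
                    continue
                if any(frozenset((x, y)) in self.used_pairs
                       for x in a for y in b):
                    continue
            candidates.append((i, j))
        if not candidates:
            raise ConfigurationError(
                "no admissible fusion partners left; relax the event list or "
                "set allow_homologous_fusion=True")
        return candidates[int(self.rng.integers(len(candidates)))]

    def record(self, a: frozenset[int], b: frozenset[int]) -> None:
        for x in a:
            for y in b:
                self.used_pairs.add(frozenset((x, y)))


def _fuse(genome: list[_Chrom], i: int, j: int, next_id: int) -> _Chrom:
    hi, lo = max(i, j), min(i, j)
    right = genome.pop(hi)
    left = genome.pop(lo)
    merged = _Chrom(next_id, left.blocks + right.blocks)
    genome.append(merged)
    return merged


def _wgd(genome: list[_Chrom], next_id: int) -> tuple[list[_Chrom], int]:
    new = []
    for chrom in genome:
        for side in (0, 1):
            new.append(_Chrom(next_id, [
                _Block(b.alg, b.lineage + (side,), b.weight)
                for b in chrom.blocks]))
            next_id += 1
    return new, next_id


# ---------------------------------------------------------------------------
# truth log
# ---------------------------------------------------------------------------

@dataclass
class TruthLog:
    """Complete ground truth of one simulated history.

    ``genes`` has one row per emitted gene: species, gene_id, orthogroup,
    alg (true ancestral chromosome), copy (WGD lineage tag, empty for
    single-copy genes), chromosome (final name) and translocated flag.
    ``fusions`` lists every fusion event with its epoch and the ancestral
    units carried by the two fusing chromosomes.  ``quartets`` maps each ALG
    to the ordered tuple of extant chromosomes carrying its 2R copies, per
    species; ``retention_probs`` holds the effective per-copy retention
    probabilities in the same order.
    """

    genes: pd.DataFrame
    fusions: list[dict]
    quartets: dict[str, dict[str, tuple[str, ...]]]
    retention_probs: dict[str, dict[str, tuple[float, ...]]]
    n_empty_orthogroups: dict[str, int]

    def fusion_epoch_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for rec in self.fusions:
            counts[rec["epoch"]] = counts.get(rec["epoch"], 0) + 1
        return counts

    def alg_of_outgroup_chrom(self) -> dict[str, set[str]]:
        """Extant outgroup chromosome -> set of true ALG ids it carries."""
        sub = self.genes[self.genes["copy"] == ""]
        return {chrom: set(g["alg"]) for chrom, g in sub.groupby("chromosome")}

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        self.genes.to_csv(outdir / "truth_genes.tsv", sep="\t", index=False,
                          lineterminator="\n")
        rows = [{"epoch": rec["epoch"], "branch": rec["branch"],
                 "left_units": ",".join(sorted(rec["left"])),
                 "right_units": ",".join(sorted(rec["right"]))}
                for rec in self.fusions]
        pd.DataFrame(rows, columns=["epoch", "branch", "left_units",
                                    "right_units"]).to_csv(
            outdir / "truth_fusions.tsv", sep="\t", index=False,
            lineterminator="\n")


@dataclass
class SimulationResult:
    config: SimulationConfig
    history: EventHistory
    orthogroups: OrthoGroupTable
    positions: dict[str, GenePositionTable]
    truth: TruthLog

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.config.to_yaml(outdir / "config.yaml")
        self.orthogroups.write(outdir / "Orthogroups.tsv")
        for sp, table in self.positions.items():
            table.write(outdir / f"{sp}.genes.bed")
        self.truth.write(outdir)
        with (outdir / "node_counts.tsv").open("w", encoding="utf-8",
                                               newline="\n") as fh:
            fh.write("node\tchromosomes\n")
            for node, count in self.history.nodes.items():
                fh.write(f"{node}\t{count}\n")


# ---------------------------------------------------------------------------
# main entry point
# ---------------------------------------------------------------------------

def simulate_history(config: SimulationConfig) -> SimulationResult:
    """Run the forward model; identical config (incl. seed) gives identical
    output."""
    rng = np.random.default_rng(config.seed)
    n0 = config.n_ancestral_chromosomes
    alg_ids = [f"ALG{i + 1:02d}" for i in range(n0)]
    sampler = _FusionSampler(rng, config.allow_homologous_fusion)
    fusions: list[dict] = []
    next_id = n0

    ancestral = [_Chrom(i, [_Block(i, ())]) for i in range(n0)]

    def run_branch(genome: list[_Chrom], events: Sequence[str], branch: str,
                   nid: int, wgd_offset: int = 0) -> tuple[list[_Chrom], int]:
        genome = [_Chrom(c.cid, list(c.blocks)) for c in genome]
        n_wgd = wgd_offset
        for ev in events:
            if ev == FUSION:
                i, j = sampler.pick(genome)
                a, b = genome[i].alg_set(), genome[j].alg_set()
                if branch == "stem":
                    epoch = (EPOCH_PRE1R, EPOCH_POST1R,
                             EPOCH_POST2R)[min(n_wgd, 2)]
                elif branch == "outgroup":
                    epoch = EPOCH_CEPH
                else:
                    epoch = EPOCH_LINEAGE
                fusions.append({
                    "epoch": epoch, "branch": branch,
                    "left": {alg_ids[x] for x in a},
                    "right": {alg_ids[x] for x in b}})
                sampler.record(a, b)
                _fuse(genome, i, j, nid)
                nid += 1
            elif ev == WGD:
                genome, nid = _wgd(genome, nid)
                n_wgd += 1
                if config.asymmetry_sd > 0:
                    for chrom in genome:
                        w = float(rng.lognormal(0.0, config.asymmetry_sd))
                        for block in chrom.blocks:
                            block.weight = w
            else:
                raise ConfigurationError(f"unknown event {ev!r}")
        return genome, nid

    outgroup_genome, next_id = run_branch(
        ancestral, (FUSION,) * config.outgroup_fusions, "outgroup", next_id)
    jawed_genome, next_id = run_branch(
        ancestral, config.stem_events, "stem", next_id)

    species_genomes: dict[str, list[_Chrom]] = {config.outgroup: outgroup_genome}
    for sp in config.ingroups:
        genome, next_id = run_branch(
            jawed_genome, tuple(config.lineage_events.get(sp, ())), sp,
            next_id, wgd_offset=config.n_wgd)
        species_genomes[sp] = genome

    gene_rows = []
    og_members: dict[int, dict[str, list[str]]] = {}
    quartets: dict[str, dict[str, tuple[str, ...]]] = {}
    retention: dict[str, dict[str, tuple[float, ...]]] = {}
    n_empty: dict[str, int] = {}
    positions: dict[str, GenePositionTable] = {}

    species_order = [config.outgroup] + list(config.ingroups)
    for sp in species_order:
        rows, quart, probs, empties, postab = _emit_species(
            sp, species_genomes[sp], config, alg_ids, rng,
            is_outgroup=(sp == config.outgroup))
        gene_rows.extend(rows)
        quartets[sp] = quart
        retention[sp] = probs
        n_empty[sp] = empties
        positions[sp] = postab
        for row in rows:
            og_members.setdefault(row["og_serial"], {}).setdefault(
                sp, []).append(row["gene_id"])

    n_genes = config.genes_per_chromosome
    groups = {}
    for serial in range(n0 * n_genes):
        members = og_members.get(serial, {})
        groups[f"OG{serial:07d}"] = {sp: members.get(sp, [])
                                     for sp in species_order}
    orthogroups = OrthoGroupTable(species_order, groups)

    genes = pd.DataFrame(
        [{"species": r["species"], "gene_id": r["gene_id"],
          "orthogroup": f"OG{r['og_serial']:07d}", "alg": r["alg"],
          "copy": r["copy"], "chromosome": r["chromosome"],
          "translocated": r["translocated"]} for r in gene_rows],
        columns=["species", "gene_id", "orthogroup", "alg", "copy",
                 "chromosome", "translocated"])

    truth = TruthLog(genes=genes, fusions=fusions, quartets=quartets,
                     retention_probs=retention, n_empty_orthogroups=n_empty)
    history = _build_history(config, species_genomes)
    return SimulationResult(config=config, history=history,
                            orthogroups=orthogroups, positions=positions,
                            truth=truth)


def _emit_species(species: str, genome: list[_Chrom],
                  config: SimulationConfig, alg_ids: list[str],
                  rng: np.random.Generator, is_outgroup: bool):
    n_genes = config.genes_per_chromosome
    prefix = _PREFIXES.get(species, species[:2])
    order = sorted(genome, key=lambda c: (-len(c.blocks), c.cid))
    chrom_name = {c.cid: f"chr{i + 1}" for i, c in enumerate(order)}
    chrom_rank = {c.cid: i for i, c in enumerate(order)}
    all_chroms = [chrom_name[c.cid] for c in order]

    # group the blocks of each ancestral chromosome: its extant copies
    copies: dict[int, list[tuple[_Chrom, _Block]]] = {}
    for chrom in genome:
        for block in chrom.blocks:
            copies.setdefault(block.alg, []).append((chrom, block))
    for alg in copies:
        copies[alg].sort(key=lambda cb: cb[1].lineage)

    quartets = {}
    probs_out = {}
    records = []
    n_empty = 0
    for alg_idx in range(config.n_ancestral_chromosomes):
        blocks = copies.get(alg_idx, [])
        if not blocks:
            continue
        k = len(blocks)
        if k == 1 or is_outgroup:
            probs = [1.0] * k
        else:
            probs = [min(1.0, config.retention_prob * b.weight)
                     for _, b in blocks]
        quartets[alg_ids[alg_idx]] = tuple(chrom_name[c.cid]
                                           for c, _ in blocks)
        probs_out[alg_ids[alg_idx]] = tuple(probs)
        kept, empties = _sample_retention(probs, n_genes,
                                          config.min_one_copy, rng)
        n_empty += empties
        for g in range(n_genes):
            serial = alg_idx * n_genes + g
            for ci, (chrom, block) in enumerate(blocks):
                if kept[g, ci]:
                    records.append({
                        "species": species, "og_serial": serial,
                        "alg": alg_ids[alg_idx],
                        "copy": ".".join(map(str, block.lineage)),
                        "chromosome": chrom_name[chrom.cid],
                        "translocated": False})

    if config.translocation_rate > 0 and len(all_chroms) > 1:
        moves = rng.random(len(records)) < config.translocation_rate
        for idx in np.flatnonzero(moves):
            rec = records[idx]
            others = [c for c in all_chroms if c != rec["chromosome"]]
            rec["chromosome"] = others[int(rng.integers(len(others)))]
            rec["translocated"] = True

    # stable order: chromosome rank, then emission order; then name genes
    rank = {name: i for i, name in enumerate(all_chroms)}
    records.sort(key=lambda r: rank[r["chromosome"]])
    pos_rows = []
    counter: dict[str, int] = {}
    for i, rec in enumerate(records):
        rec["gene_id"] = f"{prefix}{i + 1:06d}"
        idx = counter.get(rec["chromosome"], 0)
        counter[rec["chromosome"]] = idx + 1
        pos_rows.append((rec["chromosome"], idx * _GENE_SPACING,
                         idx * _GENE_SPACING + _GENE_LEN, rec["gene_id"]))
    postab = GenePositionTable(species, pd.DataFrame(
        pos_rows, columns=list(GenePositionTable.COLUMNS)))
    return records, quartets, probs_out, n_empty, postab


def _sample_retention(probs: Sequence[float], n_genes: int,
                      min_one_copy: bool, rng: np.random.Generator
                      ) -> tuple[np.ndarray, int]:
    """Sample an (n_genes, k) retention matrix from the joint per-copy
    Bernoulli distribution, optionally conditioned on >=1 surviving copy."""
    k = len(probs)
    p = np.asarray(probs, dtype=float)
    if k == 1 and p[0] >= 1.0:
        return np.ones((n_genes, 1), dtype=bool), 0
    patterns = np.array(list(itertools.product((0, 1), repeat=k)), dtype=bool)
    pattern_p = np.prod(np.where(patterns, p, 1.0 - p), axis=1)
    if min_one_copy:
        pattern_p = pattern_p.copy()
        pattern_p[0] = 0.0  # the all-lost pattern comes first
        total = pattern_p.sum()
        if total <= 0:
            raise ConfigurationError(
                "retention_prob leaves no surviving pattern; cannot condition "
                "on a minimum of one copy")
        pattern_p /= total
    idx = np.searchsorted(np.cumsum(pattern_p), rng.random(n_genes),
                          side="right")
    idx = np.clip(idx, 0, len(pattern_p) - 1)
    kept = patterns[idx]
    n_empty = 0 if min_one_copy else int((~kept.any(axis=1)).sum())
    return kept, n_empty


def _build_history(config: SimulationConfig,
                   species_genomes: Mapping[str, list[_Chrom]]) -> EventHistory:
    events = list(config.stem_events)
    if config.n_wgd == 2:
        first = events.index(WGD)
        second = events.index(WGD, first + 1)
        if all(ev == FUSION for ev in events[:first] + events[first + 1:second]
               + events[second + 1:]):
            lineage = {sp: sum(1 for ev in config.lineage_events.get(sp, ())
                               if ev == FUSION)
                       for sp in config.ingroups}
            h = vertebrate_stem_history(
                root_count=config.n_ancestral_chromosomes,
                pre_1r_fusions=first,
                post_1r_fusions=second - first - 1,
                post_2r_fusions=len(events) - second - 1,
                outgroup_fusions=config.outgroup_fusions,
                outgroup=config.outgroup,
                lineage_fusions=lineage)
            h.validate()
            return h
    # generic fallback for non-canonical stems
    h = EventHistory()
    h.add_node(NODE_ROOT, config.n_ancestral_chromosomes)
    h.add_node(config.outgroup, len(species_genomes[config.outgroup]))
    h.add_branch(NODE_ROOT, config.outgroup,
                 (FUSION,) * config.outgroup_fusions)
    h.add_node(NODE_JAWED)
    h.add_branch(NODE_ROOT, NODE_JAWED, config.stem_events)
    for sp in config.ingroups:
        h.add_node(sp)
        h.add_branch(NODE_JAWED, sp,
                     tuple(config.lineage_events.get(sp, ())))
    h.propagate()
    return h
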