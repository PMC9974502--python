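"""End-to-end pipeline wiring: simulate (optional) -> homology -> ohnologs ->
history, with a machine-readable summary.

The pipeline is configured by a YAML mapping (see ``PipelineConfig``); all
randomness flows from a single seed, and re-running an identical
configuration produces a byte-identical summary.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import yaml

from . import __version__
from .errors import ConfigurationError, KaryoevoError
from .history import (assign_epochs, detect_fused_chromosomes,
                      detect_outgroup_fusions, epoch_counts, reconstruct_algs,
                      reconstruct_history)
from .homology import build_homology_map, build_profiles, write_homology_map
from .ohnologs import (count_groups, extract_ohnolog_groups,
                       to_dataset_records, transfer_ohnology)
from .simulate import SimulationConfig, simulate_history
from .tables import (GenePositionTable, OrthoGroupTable, OrthologPairMap,
                     write_ohnolog_dataset)

DEFAULT_THRESHOLDS = {
    "min_fraction": 0.05,     # homolog slot assignment
    "max_homologs": 4,
    "min_placed": 10,
    "min_slots": 2,           # ohnolog group retention
    "fusion_min_fraction": 0.10,
}


@dataclass
class PipelineConfig:
    """Validated pipeline configuration.

    Either ``simulate`` (a :class:`SimulationConfig` field mapping) or
    ``inputs`` (paths to an orthogroup table and per-species position
    tables) must be provided.  ``species`` names the outgroup, the analysis
    ingroup, and optionally a transfer target.
    """

    seed: int = 0
    simulate: Mapping[str, Any] | None = None
    inputs: Mapping[str, Any] | None = None
    species: Mapping[str, str] = field(default_factory=dict)
    thresholds: Mapping[str, Any] = field(default_factory=dict)

    def __post_init__(self):
        if self.simulate is None and self.inputs is None:
            raise ConfigurationError(
                "config needs either a 'simulate' or an 'inputs' section")
        bad = set(self.thresholds) - set(DEFAULT_THRESHOLDS)
        if bad:
            raise ConfigurationError(f"unknown thresholds: {sorted(bad)}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        known = {"seed", "simulate", "inputs", "species", "thresholds"}
        bad = set(data) - known
        if bad:
            raise ConfigurationError(f"unknown config keys: {sorted(bad)}")
        return cls(**data)


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> dict:
    """Execute the pipeline stages in order, writing every stage output plus
    ``summary.json`` under ``outdir``; returns the summary dict.

    A failure in any stage raises :class:`KaryoevoError` naming the stage.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    thresholds = {**DEFAULT_THRESHOLDS, **dict(config.thresholds)}
    summary: dict[str, Any] = {
        "version": __version__,
        "seed": config.seed,
        "thresholds": thresholds,
    }

    # -- stage: inputs (simulate or load) ----------------------------------
    stage = "simulate" if config.simulate else "load-inputs"
    try:
        if config.simulate:
            sim_cfg = SimulationConfig.from_dict(
                {**dict(config.simulate), "seed": config.seed})
            sim = simulate_history(sim_cfg)
            sim.write(outdir / "simulation")
            orthogroups = sim.orthogroups
            positions = sim.positions
            outgroup = config.species.get("outgroup", sim_cfg.outgroup)
            ingroup = config.species.get("ingroup", sim_cfg.ingroups[0])
            transfer = config.species.get(
                "transfer",
                sim_cfg.ingroups[1] if len(sim_cfg.ingroups) > 1 else None)
            summary["true_fusion_epochs"] = sim.truth.fusion_epoch_counts()
        else:
            inputs = dict(config.inputs or {})
            og_path = Path(inputs.get("orthogroups", ""))
            if not og_path.is_file():
                raise ConfigurationError(
                    f"orthogroup table not found: {og_path}")
            orthogroups = OrthoGroupTable.read(og_path)
            positions = {}
            for sp, p in dict(inputs.get("positions", {})).items():
                p = Path(p)
                if not p.is_file():
                    raise ConfigurationError(
                        f"position table for {sp!r} not found: {p}")
                positions[sp] = GenePositionTable.read(p, sp)
            try:
                outgroup = config.species["outgroup"]
                ingroup = config.species["ingroup"]
            except KeyError as exc:
                raise ConfigurationError(
                    f"species role {exc} missing from config") from exc
            transfer = config.species.get("transfer")
        for sp in filter(None, (outgroup, ingroup, transfer)):
            if sp not in positions:
                raise ConfigurationError(
                    f"no position table for species {sp!r}")
        summary["species"] = {"outgroup": outgroup, "ingroup": ingroup,
                              "transfer": transfer}
        summary["n_orthogroups"] = len(orthogroups)
    except KaryoevoError as exc:
        raise KaryoevoError(f"stage {stage}: {exc}") from exc

    # -- stage: homology ----------------------------------------------------
    stage = "homology"
    try:
        algs, assignment = reconstruct_algs(
            orthogroups, positions[outgroup], positions[ingroup],
            outgroup, ingroup)
        ceph_calls = detect_outgroup_fusions(algs)
        profiles, skip = build_profiles(
            orthogroups, positions[outgroup], positions[ingroup],
            outgroup, ingroup, unit_assignment=assignment)
        homology_map = build_homology_map(
            profiles, max_homologs=thresholds["max_homologs"],
            min_fraction=thresholds["min_fraction"],
            min_placed=thresholds["min_placed"])
        write_homology_map(homology_map, outdir / "homology_map.tsv")
        summary["n_algs"] = len(algs)
        summary["skipped_unplaced_genes"] = skip
        summary["slot_counts"] = {
            unit: len(homology_map[unit].slots) for unit in sorted(homology_map)}
    except KaryoevoError as exc:
        raise KaryoevoError(f"stage {stage}: {exc}") from exc

    # -- stage: ohnologs ----------------------------------------------------
    stage = "ohnologs"
    try:
        groups, report = extract_ohnolog_groups(
            orthogroups, homology_map, positions[outgroup],
            positions[ingroup], outgroup, ingroup,
            min_slots=thresholds["min_slots"], unit_assignment=assignment)
        summary["ohnolog_groups"] = {
            "total": len(groups),
            "min_slots_3": count_groups(groups, 3),
            "min_slots_4": count_groups(groups, 4),
            "excluded_genes": report.n_excluded_genes,
        }
        by_species = {ingroup: groups}
        new_genes = {}
        if transfer:
            pairs = OrthologPairMap.from_orthogroups(
                orthogroups, ingroup, transfer)
            t_profiles, _ = build_profiles(
                orthogroups, positions[outgroup], positions[transfer],
                outgroup, transfer, unit_assignment=assignment)
            t_map = build_homology_map(
                t_profiles, max_homologs=thresholds["max_homologs"],
                min_fraction=thresholds["min_fraction"],
                min_placed=thresholds["min_placed"])
            t_groups, t_genes = transfer_ohnology(
                groups, pairs, positions[transfer], t_map)
            by_species[transfer] = t_groups
            new_genes[transfer] = t_genes
            summary["ohnolog_groups"]["transferred"] = len(t_groups)
            summary["ohnolog_groups"]["transferred_genes"] = len(t_genes)
        records = to_dataset_records(by_species, new_genes)
        write_ohnolog_dataset(records, outdir / "ohnolog_groups.tsv")
    except KaryoevoError as exc:
        raise KaryoevoError(f"stage {stage}: {exc}") from exc

    # -- stage: history ------------------------------------------------------
    stage = "history"
    try:
        candidates = detect_fused_chromosomes(
            homology_map, profiles,
            min_fraction=thresholds["fusion_min_fraction"])
        events = assign_epochs(candidates, profiles,
                               min_fraction=thresholds["fusion_min_fraction"])
        all_calls = ceph_calls + events
        counts = epoch_counts(all_calls)
        summary["fusion_epochs"] = counts
        n_ingroup = positions[ingroup].df["chrom"].nunique()
        history = reconstruct_history(
            all_calls, n_extant_ingroup=n_ingroup, outgroup=outgroup)
        summary["node_counts"] = {n: c for n, c in history.nodes.items()}
        with (outdir / "fusion_events.tsv").open(
                "w", encoding="utf-8", newline="\n") as fh:
            fh.write("epoch\tunits\tchromosomes\tambiguous\n")
            for call in all_calls:
                fh.write(f"{call.epoch}\t{','.join(sorted(call.units))}\t"
                         f"{','.join(sorted(call.chromosomes))}\t"
                         f"{int(call.ambiguous)}\n")
        (outdir / "history.txt").write_text(history.render() + "\n",
                                            encoding="utf-8")
    except KaryoevoError as exc:
        raise KaryoevoError(f"stage {stage}: {exc}") from exc

    (outdir / "summary.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True) + "\n",
        encoding="utf-8")
    return summary
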