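"""Shared helpers for the test suite."""

from collections import Counter
from types import SimpleNamespace

from karyoevo.history import (assign_epochs, detect_fused_chromosomes,
                              detect_outgroup_fusions, epoch_counts,
                              reconstruct_algs)
from karyoevo.homology import build_homology_map, build_profiles


def run_inference(result, ingroup, **thresholds):
    """Run the ALG -> homology -> fusion-epoch chain on one simulation."""
    outgroup = result.config.outgroup
    pos_out = result.positions[outgroup]
    pos_in = result.positions[ingroup]
    algs, assignment = reconstruct_algs(result.orthogroups, pos_out, pos_in,
                                        outgroup, ingroup)
    ceph = detect_outgroup_fusions(algs)
    profiles, skip = build_profiles(result.orthogroups, pos_out, pos_in,
                                    outgroup, ingroup,
                                    unit_assignment=assignment)
    hmap = build_homology_map(profiles, **thresholds)
    candidates = detect_fused_chromosomes(hmap, profiles)
    events = assign_epochs(candidates, profiles)
    return SimpleNamespace(
        algs=algs, assignment=assignment, ceph=ceph, profiles=profiles,
        hmap=hmap, candidates=candidates, events=events,
        counts=epoch_counts(ceph + events), calls=ceph + events)


def unit_of_alg(result, assignment):
    """Map each true ALG id to the inferred homology unit it was assigned to
    (majority vote over the ALG's orthogroups)."""
    genes = result.truth.genes
    outgroup = result.config.outgroup
    og2alg = dict(genes[genes["species"] == outgroup]
                  [["orthogroup", "alg"]].values)
    tally: dict[str, Counter] = {}
    for (group, _chrom), unit in assignment.items():
        tally.setdefault(og2alg[group], Counter())[unit] += 1
    return {alg: counter.most_common(1)[0][0]
            for alg, counter in tally.items()}


def true_ohnolog_genes(result, species, min_chromosomes=2):
    """Genes whose orthogroup retained copies on >= min_chromosomes distinct
    chromosomes in ``species`` (the ground-truth ohnolog membership)."""
    genes = result.truth.genes
    sub = genes[genes["species"] == species]
    per_og = sub.groupby("orthogroup")["chromosome"].nunique()
    keep = per_og[per_og >= min_chromosomes].index
    return set(sub[sub["orthogroup"].isin(keep)]["gene_id"])
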