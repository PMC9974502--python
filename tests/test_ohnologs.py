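"""Ohnolog extraction, counting, transfer, and their invariants."""

import pandas as pd
import pytest

from _util import run_inference, true_ohnolog_genes, unit_of_alg
from karyoevo.homology import HomologyAssignment, SlotAssignment
from karyoevo.ohnologs import (OhnologGroup, count_groups,
                               extract_ohnolog_groups,
                               groups_to_orthogroup_table, to_dataset_records,
                               transfer_ohnology)
from karyoevo.tables import (GenePositionTable, OrthoGroupTable,
                             OrthologPairMap, read_ohnolog_dataset,
                             write_ohnolog_dataset)


def _positions(species, placements):
    rows = [(chrom, i * 1000, i * 1000 + 500, gene)
            for i, (gene, chrom) in enumerate(placements.items())]
    return GenePositionTable(species, pd.DataFrame(
        rows, columns=list(GenePositionTable.COLUMNS)))


def _map(unit, chrom_by_slot, n_placed=100):
    n = len(chrom_by_slot)
    slots = [SlotAssignment(label, chrom, n_placed // n, 1.0 / n)
             for label, chrom in chrom_by_slot.items()]
    return {unit: HomologyAssignment(unit, slots, 0.0, n_placed)}


@pytest.fixture
def two_slot_fixture():
    og = OrthoGroupTable(["out", "in"], {
        "OG1": {"out": ["o1"], "in": ["g_a", "g_c", "g_off"]},
        "OG2": {"out": ["o2"], "in": ["g_solo"]}})
    pos_out = _positions("out", {"o1": "bb1", "o2": "bb1"})
    pos_in = _positions("in", {"g_a": "chr1", "g_c": "chr3",
                               "g_off": "chr9", "g_solo": "chr1"})
    hmap = _map("bb1", {"A": "chr1", "B": "chr2", "C": "chr3", "D": "chr4"})
    return og, pos_out, pos_in, hmap


def test_direct_membership(two_slot_fixture):
    """Ingroup genes on slots A and C only give a two-member group; genes on
    unassigned chromosomes are excluded and tallied."""
    og, pos_out, pos_in, hmap = two_slot_fixture
    groups, report = extract_ohnolog_groups(og, hmap, pos_out, pos_in,
                                            "out", "in", min_slots=2)
    assert len(groups) == 1
    grp = groups[0]
    assert grp.group_id == "OG1"
    assert grp.members == {"A": ("g_a",), "C": ("g_c",)}
    assert grp.n_members == 2
    assert report.n_excluded_genes == 1
    assert report.n_dropped_few_slots == 1  # OG2 occupies one slot


def test_multi_anchor_orthogroups_are_split():
    og = OrthoGroupTable(["out", "in"], {
        "OG1": {"out": ["o1", "o2"], "in": ["g1", "g2", "g3", "g4"]}})
    pos_out = _positions("out", {"o1": "bb1", "o2": "bb2"})
    pos_in = _positions("in", {"g1": "chr1", "g2": "chr2",
                               "g3": "chr5", "g4": "chr6"})
    hmap = {**_map("bb1", {"A": "chr1", "B": "chr2"}),
            **_map("bb2", {"A": "chr5", "B": "chr6"})}
    groups, _ = extract_ohnolog_groups(og, hmap, pos_out, pos_in,
                                       "out", "in", min_slots=2)
    assert sorted(g.group_id for g in groups) == ["OG1:bb1", "OG1:bb2"]
    assert all(g.n_members == 2 for g in groups)


def test_count_groups_and_monotonicity(two_slot_fixture):
    assert count_groups([], 3) == 0
    sizes = [{"A": ("x1",), "B": ("x2",)},
             {"A": ("y1",), "B": ("y2",), "C": ("y3",)},
             {"A": ("z1",), "B": ("z2",), "C": ("z3",), "D": ("z4",)}]
    groups = [OhnologGroup(f"G{i}", "bb1", ("o",), "in", m)
              for i, m in enumerate(sizes)]
    assert count_groups(groups, 3) == 2
    counts = [count_groups(groups, k) for k in range(1, 6)]
    assert counts == sorted(counts, reverse=True)  # non-increasing


def test_tandem_duplicates_count_one_slot():
    grp = OhnologGroup("G", "bb1", ("o",), "in",
                       {"A": ("g1", "g2", "g3"), "B": ("g4",)})
    assert grp.n_members == 2


def test_lossless_oracle_groups_match_truth(lossless_sim):
    """Without loss, extracted groups reproduce the true ohnolog partition:
    per orthogroup, genes grouped by chromosome over the true quartet."""
    res = lossless_sim
    inf = run_inference(res, "chicken")
    groups, _ = extract_ohnolog_groups(
        res.orthogroups, inf.hmap, res.positions["amphioxus"],
        res.positions["chicken"], "amphioxus", "chicken",
        min_slots=2, unit_assignment=inf.assignment)
    genes = res.truth.genes
    sub = genes[genes["species"] == "chicken"]
    truth = {og: {chrom: frozenset(g["gene_id"])
                  for chrom, g in grp.groupby("chromosome")}
             for og, grp in sub.groupby("orthogroup")}
    assert len(groups) == len(truth)
    for grp in groups:
        slot_chrom = {s.label: s.chromosome
                      for s in inf.hmap[grp.anchor].slots}
        got = {slot_chrom[label]: frozenset(genes_)
               for label, genes_ in grp.members.items()}
        assert got == truth[grp.group_id], grp.group_id


def test_subset_property_and_independent_recount(lossy_sim):
    """Every member is drawn from its source orthogroup, and count_groups
    agrees with a brute-force scan."""
    res = lossy_sim
    inf = run_inference(res, "chicken")
    groups, _ = extract_ohnolog_groups(
        res.orthogroups, inf.hmap, res.positions["amphioxus"],
        res.positions["chicken"], "amphioxus", "chicken",
        min_slots=2, unit_assignment=inf.assignment)
    for grp in groups:
        source = set(res.orthogroups.members(grp.group_id, "chicken"))
        assert grp.genes() <= source
    # independent tally: recount qualifying groups by scanning membership
    brute = sum(1 for grp in groups
                if len([1 for v in grp.members.values() if v]) >= 3)
    assert count_groups(groups, 3) == brute


def test_extraction_idempotence(two_slot_fixture):
    """Extracting from already-extracted groups changes nothing."""
    og, pos_out, pos_in, hmap = two_slot_fixture
    groups, _ = extract_ohnolog_groups(og, hmap, pos_out, pos_in,
                                       "out", "in", min_slots=2)
    table2 = groups_to_orthogroup_table(groups, "out")
    groups2, _ = extract_ohnolog_groups(table2, hmap, pos_out, pos_in,
                                        "out", "in", min_slots=2)
    assert [(g.group_id, g.members) for g in groups2] == \
           [(g.group_id, g.members) for g in groups]


def test_transfer_empty_pair_map(two_slot_fixture):
    og, pos_out, pos_in, hmap = two_slot_fixture
    groups, _ = extract_ohnolog_groups(og, hmap, pos_out, pos_in,
                                       "out", "in", min_slots=2)
    out, genes = transfer_ohnology(
        groups, OrthologPairMap("in", "tgt", []),
        _positions("tgt", {"t1": "c1"}), _map("bb1", {"A": "c1"}))
    assert out == [] and genes == []


def test_transfer_hand_fixture():
    """Two groups with known 1:1 pairs project onto the expected target
    slots; a gene without an ortholog drops out."""
    groups = [
        OhnologGroup("G1", "bb1", ("o1",), "in",
                     {"A": ("g1",), "B": ("g2",)}),
        OhnologGroup("G2", "bb2", ("o2",), "in",
                     {"A": ("g3",), "C": ("g4",)}),
    ]
    pairs = OrthologPairMap("in", "tgt", [("g1", "t1"), ("g2", "t2"),
                                          ("g3", "t3")])
    pos = _positions("tgt", {"t1": "c1", "t2": "c2", "t3": "c5"})
    tmap = {**_map("bb1", {"A": "c1", "B": "c2"}),
            **_map("bb2", {"A": "c5", "B": "c6"})}
    out, genes = transfer_ohnology(groups, pairs, pos, tmap)
    assert [(g.group_id, g.members) for g in out] == [
        ("G1", {"A": ("t1",), "B": ("t2",)}),
        ("G2", {"A": ("t3",)})]
    assert genes == ["t1", "t2", "t3"]


def test_transfer_simulation_oracle(lossy_sim):
    """Transferred slot labels place every 1:1-orthologous gene on its true
    chromosome in the second species."""
    res = lossy_sim
    inf_c = run_inference(res, "chicken")
    groups, _ = extract_ohnolog_groups(
        res.orthogroups, inf_c.hmap, res.positions["amphioxus"],
        res.positions["chicken"], "amphioxus", "chicken",
        min_slots=2, unit_assignment=inf_c.assignment)
    pairs = OrthologPairMap.from_orthogroups(res.orthogroups,
                                             "chicken", "human")
    inf_h = run_inference(res, "human")
    # align human map keys with the chicken-side anchors via true ALGs
    m_c = {v: k for k, v in unit_of_alg(res, inf_c.assignment).items()}
    m_h = unit_of_alg(res, inf_h.assignment)
    hmap_aligned = {anchor: inf_h.hmap[m_h[alg]]
                    for anchor, alg in m_c.items()}
    out, genes = transfer_ohnology(groups, pairs, res.positions["human"],
                                   hmap_aligned)
    truth = res.truth.genes
    hum = truth[truth["species"] == "human"].set_index("gene_id")
    assert len(out) > 0
    for grp in out:
        slot_chrom = {s.label: s.chromosome
                      for s in hmap_aligned[grp.anchor].slots}
        for label, members in grp.members.items():
            for gene in members:
                assert hum.loc[gene, "chromosome"] == slot_chrom[label]


def test_dataset_records_round_trip(tmp_path, two_slot_fixture):
    og, pos_out, pos_in, hmap = two_slot_fixture
    groups, _ = extract_ohnolog_groups(og, hmap, pos_out, pos_in,
                                       "out", "in", min_slots=2)
    records = to_dataset_records({"in": groups}, {"in": ["g_c"]})
    from karyoevo.tables import OhnologColumns
    cols = OhnologColumns(species=("in",))
    path = tmp_path / "ds.tsv"
    write_ohnolog_dataset(records, path, cols)
    back = read_ohnolog_dataset(path, cols)
    assert len(back) == len(records)
    assert back[0].members["in"] == {
        "A": ("g_a",), "B": (), "C": ("g_c",), "D": ()}
    assert back[0].new == {"in": ("g_c",)}
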