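"""Karyotype event histories and fusion-epoch inference.

Two halves live here.

The first is pure bookkeeping: :class:`EventHistory` holds a species tree
whose branches carry ordered fusion/WGD events, with the invariant that a
child's chromosome count equals the parent's after applying the events in
order (fusion: -1, WGD: x2).  :func:`chromosome_count_trajectory` walks a
root-to-node path and reports the count at every node, which is how the
chordate -> pre-1R -> post-1R -> post-2R -> jawed-vertebrate -> bird series
(23 -> 17 -> 34 -> 25 -> 50 -> 45 -> 40) is reproduced.

The second half infers fusions from a homology map.  An ingroup chromosome
that absorbs a substantial fraction of the orthologs of two or more distinct
ancestral linkage groups (ALGs) is called fused, and the epoch of each fusion
follows from how many of the four 2R-derived chromosome copies share the ALG
combination:

* present in all four copies  -> the fusion predates 1R (pre-1R),
* present in exactly the two copies descending from one 1R product -> post-1R,
* present in a single copy -> post-2R,
* present in three copies -> ambiguous; assigned pre-1R (the single-event
  parsimony reading) and flagged.

Fusions on the outgroup's own branch (cephalochordate lineage) are instead
detected by splitting each outgroup chromosome into ancestral units: genes of
two ancestral chromosomes that fused in the outgroup map to two disjoint
quartets of ingroup chromosomes, so the orthogroup co-membership graph over
ingroup chromosomes falls apart into two connected components.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import networkx as nx

from .errors import ConfigurationError, ReconstructionError
from .homology import HomologyMap, HomologyProfile, placed_ortholog_frame
from .tables import GenePositionTable, OrthoGroupTable

FUSION = "fusion"
WGD = "wgd"

EPOCH_CEPH = "cephalochordate"
EPOCH_PRE1R = "pre-1R"
EPOCH_POST1R = "post-1R"
EPOCH_POST2R = "post-2R"
EPOCH_LINEAGE = "lineage"
EPOCHS = (EPOCH_CEPH, EPOCH_PRE1R, EPOCH_POST1R, EPOCH_POST2R, EPOCH_LINEAGE)

# canonical node names for the two-WGD vertebrate stem
NODE_ROOT = "chordate-ancestor"
NODE_PRE1R = "pre-1R"
NODE_POST1R = "post-1R"
NODE_PRE2R = "pre-2R"
NODE_POST2R = "post-2R"
NODE_JAWED = "jawed-vertebrate-ancestor"
STEM_PATH = (NODE_ROOT, NODE_PRE1R, NODE_POST1R, NODE_PRE2R, NODE_POST2R,
             NODE_JAWED)


# ---------------------------------------------------------------------------
# Event history
# ---------------------------------------------------------------------------

def apply_events(count: int, events: Sequence[str]) -> int:
    """Apply ordered fusion/WGD events to a chromosome count."""
    for ev in events:
        if ev == FUSION:
            if count < 2:
                raise ConfigurationError(
                    f"fusion requires >=2 chromosomes, have {count}")
            count -= 1
        elif ev == WGD:
            count *= 2
        else:
            raise ConfigurationError(f"unknown event {ev!r}")
    return count


class EventHistory:
    """A rooted tree of named nodes with per-branch ordered event lists."""

    def __init__(self):
        self.nodes: dict[str, int | None] = {}
        self.branches: dict[tuple[str, str], list[str]] = {}
        self._parent: dict[str, str] = {}

    def add_node(self, name: str, count: int | None = None) -> None:
        if name in self.nodes:
            raise ConfigurationError(f"node {name!r} already exists")
        self.nodes[name] = count

    def add_branch(self, parent: str, child: str,
                   events: Sequence[str] = ()) -> None:
        for n in (parent, child):
            if n not in self.nodes:
                raise ConfigurationError(f"unknown node {n!r}")
        if child in self._parent:
            raise ConfigurationError(f"node {child!r} already has a parent")
        self.branches[(parent, child)] = list(events)
        self._parent[child] = parent

    def parent(self, node: str) -> str | None:
        return self._parent.get(node)

    def root(self) -> str:
        roots = [n for n in self.nodes if n not in self._parent]
        if len(roots) != 1:
            raise ConfigurationError(f"expected one root, found {roots}")
        return roots[0]

    def count(self, node: str) -> int:
        c = self.nodes[node]
        if c is None:
            raise ConfigurationError(f"node {node!r} has no chromosome count")
        return c

    def propagate(self) -> None:
        """Fill missing child counts by applying events from the root down."""
        order = [self.root()]
        children = {}
        for (p, c) in self.branches:
            children.setdefault(p, []).append(c)
        i = 0
        while i < len(order):
            node = order[i]
            for child in children.get(node, []):
                derived = apply_events(self.count(node),
                                       self.branches[(node, child)])
                if self.nodes[child] is None:
                    self.nodes[child] = derived
                elif self.nodes[child] != derived:
                    raise ConfigurationError(
                        f"node {child!r}: stored count {self.nodes[child]} "
                        f"inconsistent with derived {derived}")
                order.append(child)
            i += 1

    def validate(self) -> None:
        """Re-check the count invariant on every branch independently."""
        for (p, c), events in self.branches.items():
            derived = apply_events(self.count(p), events)
            if derived != self.count(c):
                raise ConfigurationError(
                    f"branch {p!r}->{c!r}: count {self.count(c)} != "
                    f"{derived} from events")
            if self.count(c) < 1:
                raise ConfigurationError(f"node {c!r} has count < 1")

    def trajectory(self, path: Sequence[str]) -> list[tuple[str, int]]:
        """Ordered (node, count) list along a root-to-node walk.

        Pure arithmetic: each step applies the branch's events to the
        running count.
        """
        if not path:
            return []
        for node in path:
            if node not in self.nodes:
                raise ConfigurationError(f"unknown node {node!r}")
        count = self.count(path[0])
        out = [(path[0], count)]
        for parent, child in zip(path, path[1:]):
            if (parent, child) not in self.branches:
                raise ConfigurationError(
                    f"{parent!r} -> {child!r} is not a branch of the tree")
            count = apply_events(count, self.branches[(parent, child)])
            out.append((child, count))
        return out

    def render(self) -> str:
        """Text rendering of the tree with counts and per-branch events."""
        lines = []

        def walk(node, depth):
            lines.append("  " * depth + f"{node} [{self.nodes[node]}]")
            for (p, c), events in self.branches.items():
                if p == node:
                    tag = ",".join(events) if events else "-"
                    lines.append("  " * (depth + 1) + f"|({tag})")
                    walk(c, depth + 1)

        walk(self.root(), 0)
        return "\n".join(lines)


def chromosome_count_trajectory(history: EventHistory,
                                path: Sequence[str]) -> list[tuple[str, int]]:
    """Module-level alias for :meth:`EventHistory.trajectory`."""
    return history.trajectory(path)


def vertebrate_stem_history(root_count: int = 23,
                            pre_1r_fusions: int = 6,
                            post_1r_fusions: int = 9,
                            post_2r_fusions: int = 5,
                            outgroup_fusions: int = 3,
                            outgroup: str = "amphioxus",
                            lineage_fusions: Mapping[str, int] | None = None,
                            ) -> EventHistory:
    """Canonical chordate -> jawed-vertebrate history with two WGDs.

    ``lineage_fusions`` adds leaf branches below the jawed-vertebrate
    ancestor, e.g. ``{"bird-ancestor": 5}``.
    """
    h = EventHistory()
    h.add_node(NODE_ROOT, root_count)
    for node in STEM_PATH[1:]:
        h.add_node(node)
    h.add_node(outgroup)
    h.add_branch(NODE_ROOT, NODE_PRE1R, [FUSION] * pre_1r_fusions)
    h.add_branch(NODE_PRE1R, NODE_POST1R, [WGD])
    h.add_branch(NODE_POST1R, NODE_PRE2R, [FUSION] * post_1r_fusions)
    h.add_branch(NODE_PRE2R, NODE_POST2R, [WGD])
    h.add_branch(NODE_POST2R, NODE_JAWED, [FUSION] * post_2r_fusions)
    h.add_branch(NODE_ROOT, outgroup, [FUSION] * outgroup_fusions)
    for leaf, n in (lineage_fusions or {}).items():
        h.add_node(leaf)
        h.add_branch(NODE_JAWED, leaf, [FUSION] * n)
    h.propagate()
    return h


# ---------------------------------------------------------------------------
# Ancestral linkage groups and cephalochordate fusions
# ---------------------------------------------------------------------------

@dataclass
class AncestralLinkageGroup:
    """A reconstructed chordate-ancestor chromosome unit.

    Identified as one connected component of the orthogroup co-membership
    graph over ingroup chromosomes, restricted to the orthogroups anchored on
    one outgroup chromosome.  An unfused outgroup chromosome yields exactly
    one ALG; a fused one yields one per ancestral unit.
    """

    alg_id: str
    outgroup_chromosome: str
    ingroup_chromosomes: frozenset[str]
    orthogroups: tuple[str, ...]

    @property
    def n_orthogroups(self) -> int:
        return len(self.orthogroups)


@dataclass
class FusionCall:
    """One inferred fusion event (or, before epoch assignment, a candidate
    fused chromosome)."""

    units: frozenset[str]
    chromosomes: frozenset[str]
    epoch: str | None = None
    contributions: dict[str, float] = field(default_factory=dict)
    ambiguous: bool = False
    note: str = ""


def reconstruct_algs(orthogroups: OrthoGroupTable,
                     outgroup_positions: GenePositionTable,
                     ingroup_positions: GenePositionTable,
                     outgroup: str, ingroup: str,
                     min_edge_weight: int = 2,
                     min_chrom_genes: int = 3,
                     ) -> tuple[list[AncestralLinkageGroup],
                                dict[tuple[str, str], str]]:
    """Partition each outgroup chromosome into ancestral linkage groups.

    Returns the ALG list plus an assignment of each (orthogroup, outgroup
    chromosome) anchor to its ALG id, suitable for
    :func:`karyoevo.homology.build_profiles`.

    ``min_chrom_genes`` drops ingroup chromosomes that receive fewer placed
    orthologs than this from the outgroup chromosome (translocation noise);
    ``min_edge_weight`` is the minimum number of co-membership orthogroups
    needed to connect two ingroup chromosomes.
    """
    frame, _ = placed_ortholog_frame(
        orthogroups, outgroup_positions, ingroup_positions, outgroup, ingroup)
    algs: list[AncestralLinkageGroup] = []
    assignment: dict[tuple[str, str], str] = {}
    if frame.empty:
        return algs, assignment
    for out_chrom, sub in frame.groupby("out_chrom", sort=True):
        chrom_counts = sub.groupby("in_chrom")["in_gene"].count()
        kept = set(chrom_counts[chrom_counts >= min_chrom_genes].index)
        g = nx.Graph()
        g.add_nodes_from(kept)
        group_chroms = (sub[sub["in_chrom"].isin(kept)]
                        .groupby("group")["in_chrom"].agg(lambda s: set(s)))
        edge_weight: dict[tuple[str, str], int] = {}
        for chroms in group_chroms:
            for a, b in combinations(sorted(chroms), 2):
                edge_weight[(a, b)] = edge_weight.get((a, b), 0) + 1
        for (a, b), w in edge_weight.items():
            if w >= min_edge_weight:
                g.add_edge(a, b)
        comps = sorted(nx.connected_components(g),
                       key=lambda c: (-sum(chrom_counts.get(x, 0) for x in c),
                                      min(c)))
        if not comps:
            continue
        ids = ([str(out_chrom)] if len(comps) == 1 else
               [f"{out_chrom}:{i + 1}" for i in range(len(comps))])
        comp_of = {chrom: i for i, comp in enumerate(comps) for chrom in comp}
        member_groups: list[list[str]] = [[] for _ in comps]
        for group, chroms in group_chroms.items():
            votes = [0] * len(comps)
            for chrom in chroms:
                if chrom in comp_of:
                    votes[comp_of[chrom]] += 1
            if max(votes, default=0) == 0:
                continue
            idx = votes.index(max(votes))
            member_groups[idx].append(group)
            assignment[(group, str(out_chrom))] = ids[idx]
        for i, comp in enumerate(comps):
            algs.append(AncestralLinkageGroup(
                alg_id=ids[i], outgroup_chromosome=str(out_chrom),
                ingroup_chromosomes=frozenset(comp),
                orthogroups=tuple(sorted(member_groups[i]))))
    return algs, assignment


def detect_outgroup_fusions(algs: Iterable[AncestralLinkageGroup]
                            ) -> list[FusionCall]:
    """Cephalochordate-lineage fusions: outgroup chromosomes spanning >=2 ALGs.

    An outgroup chromosome split into k ancestral units implies k-1 fusion
    events on the outgroup's own branch.
    """
    by_chrom: dict[str, list[AncestralLinkageGroup]] = {}
    for alg in algs:
        by_chrom.setdefault(alg.outgroup_chromosome, []).append(alg)
    calls = []
    for chrom in sorted(by_chrom):
        units = sorted(a.alg_id for a in by_chrom[chrom])
        for extra in units[1:]:
            calls.append(FusionCall(
                units=frozenset([units[0], extra]) if len(units) == 2
                else frozenset(units),
                chromosomes=frozenset([chrom]),
                epoch=EPOCH_CEPH,
                note="" if len(units) == 2 else
                "one of several units joined on this chromosome"))
    return calls


# ---------------------------------------------------------------------------
# Ingroup fusion detection and epoch assignment
# ---------------------------------------------------------------------------

def detect_fused_chromosomes(homology_map: HomologyMap,
                             profiles: Mapping[str, HomologyProfile],
                             min_fraction: float = 0.10) -> list[FusionCall]:
    """Candidate fused ingroup chromosomes.

    A chromosome that receives at least ``min_fraction`` of the placed
    orthologs of two or more distinct units is called fused; contributions
    are recorded per unit.
    """
    contrib: dict[str, dict[str, float]] = {}
    for unit, prof in sorted(profiles.items()):
        for chrom, frac in prof.abundance.items():
            if frac >= min_fraction:
                contrib.setdefault(chrom, {})[unit] = frac
    calls = []
    for chrom in sorted(contrib):
        units = contrib[chrom]
        if len(units) >= 2:
            calls.append(FusionCall(
                units=frozenset(units), chromosomes=frozenset([chrom]),
                contributions=dict(sorted(units.items()))))
    return calls


def _significant_chromosomes(profiles: Mapping[str, HomologyProfile],
                             min_fraction: float) -> dict[str, set[str]]:
    return {unit: {c for c, f in prof.abundance.items() if f >= min_fraction}
            for unit, prof in profiles.items()}


def assign_epochs(candidates: Sequence[FusionCall],
                  profiles: Mapping[str, HomologyProfile],
                  min_fraction: float = 0.10) -> list[FusionCall]:
    """Resolve candidate fused chromosomes into epoch-labelled fusion events.

    The sharing rule operates on pairs of units: the number of distinct
    ingroup chromosomes jointly carrying both units decides the epoch (4:
    pre-1R, 2: post-1R, 1: post-2R; 3: ambiguous, assigned pre-1R and
    flagged).  Chains of fusions are collapsed by parsimony: pre-1R events
    are counted as (component size - 1) over the graph of >=3-copy pairs;
    post-1R events are grouped by identical two-chromosome support sets,
    counting one event per extra pre-1R unit joined; post-2R events are
    counted per fused chromosome as one event per extra merged unit group.
    """
    sig = _significant_chromosomes(profiles, min_fraction)
    units = sorted(sig)
    shared: dict[tuple[str, str], frozenset[str]] = {}
    for u, v in combinations(units, 2):
        s = sig[u] & sig[v]
        if s:
            shared[(u, v)] = frozenset(s)

    # pre-1R: pairs sharing >=3 of the four 2R copies
    pre_graph = nx.Graph()
    pre_graph.add_nodes_from(units)
    for (u, v), s in shared.items():
        if len(s) >= 3:
            pre_graph.add_edge(u, v, n_shared=len(s))
    unit_of: dict[str, int] = {}
    events: list[FusionCall] = []
    for i, comp in enumerate(sorted(nx.connected_components(pre_graph),
                                    key=min)):
        comp = sorted(comp)
        for u in comp:
            unit_of[u] = i
        if len(comp) < 2:
            continue
        tree = nx.minimum_spanning_tree(pre_graph.subgraph(comp))
        for u, v in sorted(tree.edges()):
            n = pre_graph[u][v]["n_shared"]
            events.append(FusionCall(
                units=frozenset([u, v]), chromosomes=shared[_key(u, v)],
                epoch=EPOCH_PRE1R, ambiguous=n == 3,
                note="shared by 3 of 4 copies" if n == 3 else ""))

    # post-1R: two-copy pairs across distinct pre-1R units, grouped by their
    # supporting chromosome pair (the two 2R copies of one 1R product)
    support: dict[frozenset[str], list[tuple[str, str]]] = {}
    for (u, v), s in shared.items():
        if len(s) == 2 and unit_of[u] != unit_of[v]:
            support.setdefault(s, []).append((u, v))
    for s in sorted(support, key=sorted):
        pre_units: dict[int, list[str]] = {}
        for u, v in support[s]:
            pre_units.setdefault(unit_of[u], []).append(u)
            pre_units.setdefault(unit_of[v], []).append(v)
        reps = sorted(min(v) for v in pre_units.values())
        for extra in reps[1:]:
            events.append(FusionCall(
                units=frozenset([reps[0], extra]) if len(reps) == 2
                else frozenset(reps),
                chromosomes=s, epoch=EPOCH_POST1R,
                note="" if len(reps) == 2 else
                "one of several 1R units joined in this product"))

    # post-2R: per candidate chromosome, units not already joined by an
    # earlier epoch form separate classes; each extra class is one event
    for cand in candidates:
        chrom = next(iter(cand.chromosomes))
        cg = nx.Graph()
        cg.add_nodes_from(cand.units)
        for u, v in combinations(sorted(cand.units), 2):
            s = shared.get(_key(u, v))
            if s is not None and len(s) >= 2:
                cg.add_edge(u, v)
        classes = sorted(nx.connected_components(cg), key=min)
        for cls in classes[1:]:
            events.append(FusionCall(
                units=frozenset(classes[0]) | frozenset(cls),
                chromosomes=frozenset([chrom]), epoch=EPOCH_POST2R,
                contributions={u: cand.contributions.get(u, 0.0)
                               for u in sorted(cand.units)}))
    return events


def _key(u: str, v: str) -> tuple[str, str]:
    return (u, v) if u < v else (v, u)


def epoch_counts(calls: Iterable[FusionCall]) -> dict[str, int]:
    counts = {epoch: 0 for epoch in EPOCHS}
    for call in calls:
        if call.epoch is None:
            continue
        key = call.epoch if call.epoch in counts else EPOCH_LINEAGE
        counts[key] += 1
    return counts


# ---------------------------------------------------------------------------
# History reconstruction
# ---------------------------------------------------------------------------

def reconstruct_history(calls: Sequence[FusionCall],
                        n_extant_ingroup: int | None = None,
                        n_pre1r_groups: int | None = None,
                        n_extant_outgroup: int | None = None,
                        outgroup: str = "amphioxus",
                        ) -> EventHistory:
    """Build the full chordate -> jawed-vertebrate event history by reversing
    the epoch-labelled fusion calls under a fusion + two-WGD model.

    Anchoring works from either end: ``n_extant_ingroup`` is the chromosome
    count at the jawed-vertebrate ancestor level (post-2R fusions applied),
    ``n_pre1r_groups`` the number of pre-1R linkage groups.  At least one
    must be given; when both are given they must agree.  Implied non-integer
    or non-positive counts raise :class:`ReconstructionError`, signalling
    inconsistent calls.
    """
    counts = epoch_counts(calls)
    f_ceph = counts[EPOCH_CEPH]
    f_pre = counts[EPOCH_PRE1R]
    f_post1 = counts[EPOCH_POST1R]
    f_post2 = counts[EPOCH_POST2R]

    if n_pre1r_groups is not None:
        pre1r = n_pre1r_groups
        post1r = 2 * pre1r
        pre2r = post1r - f_post1
        post2r = 2 * pre2r
        jawed = post2r - f_post2
        if n_extant_ingroup is not None and jawed != n_extant_ingroup:
            raise ReconstructionError(
                f"extant ingroup count {n_extant_ingroup} inconsistent with "
                f"{jawed} implied by {n_pre1r_groups} pre-1R groups")
    elif n_extant_ingroup is not None:
        jawed = n_extant_ingroup
        post2r = jawed + f_post2
        if post2r % 2:
            raise ReconstructionError(
                f"post-2R count {post2r} is odd; cannot reverse a WGD")
        pre2r = post2r // 2
        post1r = pre2r + f_post1
        if post1r % 2:
            raise ReconstructionError(
                f"post-1R count {post1r} is odd; cannot reverse a WGD")
        pre1r = post1r // 2
    else:
        raise ReconstructionError(
            "need n_extant_ingroup or n_pre1r_groups to anchor the history")

    root = pre1r + f_pre
    outgroup_count = root - f_ceph
    for name, value in (("pre-1R", pre1r), ("pre-2R", pre2r),
                        ("jawed-vertebrate", jawed), ("root", root),
                        ("outgroup", outgroup_count)):
        if value < 1:
            raise ReconstructionError(
                f"implied {name} chromosome count {value} < 1; "
                "fusion calls are inconsistent")
    if n_extant_outgroup is not None and outgroup_count != n_extant_outgroup:
        raise ReconstructionError(
            f"extant outgroup count {n_extant_outgroup} inconsistent with "
            f"implied {outgroup_count}")

    history = vertebrate_stem_history(
        root_count=root, pre_1r_fusions=f_pre, post_1r_fusions=f_post1,
        post_2r_fusions=f_post2, outgroup_fusions=f_ceph, outgroup=outgroup)
    history.validate()
    return history
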