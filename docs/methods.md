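# Methods

## Model

The package treats karyotype evolution as a sequence of two event types on a
fixed chordate tree: chromosome **fusions** (two chromosomes join; count −1)
and **whole-genome duplications** (every chromosome doubles; count ×2).  The
canonical tree has a chordate root, an outgroup (cephalochordate) branch
carrying only fusions, a vertebrate stem carrying fusions interleaved with
the two duplications (1R, 2R), and ingroup lineage branches below the
jawed-vertebrate ancestor.  Fissions are not modelled: the inferred
vertebrate history contains none, and the abundance signature used here
cannot distinguish a fission from assembly splitting.

Gene content is modelled at the level of ancestral genes: each of the
`N0 × G` ancestral genes defines one orthogroup.  After the two
duplications each gene has four copies, one per 2R-derived chromosome copy.
Copies survive independently with probability `p`, optionally multiplied by
a per-chromosome factor (see *Asymmetric loss*), and by default conditioned
on at least one surviving copy per orthogroup and species — the ohnolog
bookkeeping presumes orthogroups survive, and unconditioned loss would
change every expected count.  Two ingroup species are emitted from the same
post-2R genome with independent loss so that ohnology transfer through
pairwise orthologs can be exercised; divergence-time realism is a non-goal.

## Inference

**Homology profiles.**  For each outgroup chromosome the orthologs placed
in the ingroup are tallied per ingroup chromosome; the abundance `r_c` is
the fraction of that unit's placed orthologs on chromosome `c`.  Slots A–D
are the up-to-four chromosomes with `r_c ≥ min_fraction` (default 0.05),
ordered by abundance with a lexicographic tie-break.  Multi-member
orthogroups contribute one count per ingroup gene by default (`per_gene`);
a `per_pair` mode weighting by outgroup gene count is available because the
counting basis genuinely is an open choice.  Units with fewer than 10
placed orthologs are flagged low-confidence rather than dropped.

**Ancestral linkage groups.**  Fusions on the outgroup's own branch are
resolved first: for each outgroup chromosome, a graph over ingroup
chromosomes is built whose edges are orthogroups with members on both
chromosomes (edge support ≥ 2 groups; chromosomes receiving < 3 placed
orthologs are treated as translocation noise).  Connected components are
the ancestral units (ALGs); an outgroup chromosome spanning `k ≥ 2`
components records `k − 1` cephalochordate fusions.  Downstream profiles
are then rebuilt per ALG.

**Fusion epochs.**  An ingroup chromosome receiving at least
`fusion_min_fraction` (default 0.10) of the placed orthologs of two or more
ALGs is a fused candidate.  For each ALG pair, the number of distinct
chromosomes jointly carrying both decides the epoch: 4 → pre-1R,
2 → post-1R, 1 → post-2R.  A 3-of-4 pattern is contradictory; it is
assigned pre-1R (the single-event parsimony reading) and flagged
ambiguous.  Fusion chains are collapsed by parsimony: pre-1R events are
counted as (component size − 1) over the ≥3-copy pair graph; post-1R pairs
are grouped by their two supporting chromosomes (the 2R copies of one 1R
product), one event per additional pre-1R unit joined; post-2R events are
counted per chromosome as one event per additional unit group not already
merged at an earlier epoch.  For single pairwise fusions this reduces
exactly to the sharing rule above.  With one ingroup species,
lineage-private fusions are indistinguishable from post-2R fusions and are
folded into that tally; placing them on a specific branch requires either a
second ingroup comparison or a user-supplied branch annotation
(`lineage_fusions` in the history builders).

**Count reconstruction.**  Epoch-labelled calls are reversed from either
anchor — the extant (jawed-ancestor-level) chromosome count or the number
of pre-1R linkage groups: post-2R count = extant + post-2R fusions, halve,
add post-1R fusions, halve, add stem fusions to reach the root; the
outgroup count is the root minus cephalochordate fusions.  Odd counts at a
halving step or non-positive implied counts raise an error, signalling
inconsistent calls.  The resulting event history re-verifies the count
invariant on every branch independently.

## Asymmetric loss

Asymmetric sequence loss — one member of a duplicated pair losing far more
genes — is modelled by a per-chromosome retention multiplier drawn once per
chromosome after each WGD (log-normal with spread `asymmetry_sd`, default
0.0 = symmetric), shared by both ingroup species and capped so the
effective per-copy probability stays in [0, 1].  The truth log records the
effective probabilities so tests can compare observed per-copy retention
against exact enumeration of the conditioned joint distribution.

## Identifiable fusion histories

Fusion partners are drawn uniformly at random among admissible chromosome
pairs of the evolving genome, seeded.  By default two constraints apply:
partners may not share ancestral content (no fusion of homologous copies),
and the ALG combination created must not already occur elsewhere in the
history.  Abundance-based inference identifies a fusion as a *novel*
combination of ancestral units, so histories violating these constraints
are unidentifiable in principle by this method class — and the
reconstructed vertebrate history contains no such event.  The default
therefore generates histories on which exact recovery is a meaningful
benchmark; `allow_homologous_fusion=True` restores fully uniform sampling
for robustness experiments.

## Synthetic data: what it does and does not emulate

The generator reproduces the features the inference actually consumes:
orthogroup membership across species, chromosome assignment of every gene,
fusion/WGD structure, per-copy retention with optional asymmetry, optional
uniform translocation noise, and a second ingroup species for transfer.
It does **not** emulate sequence evolution, gene order or synteny-block
structure within chromosomes (positions are evenly spaced intervals and
only chromosome membership is used), tandem-duplication dynamics,
orthology-inference error (orthogroups are exact by construction), or
lineage-specific gene family expansion.  Passing tests therefore show the
statistical machinery is correct under the stated generative model, not
that orthology calls on real genomes are error-free.

## Parameters and defaults

| parameter | default | meaning |
| --- | --- | --- |
| `n_ancestral_chromosomes` | 23 | chordate ancestor karyotype |
| `genes_per_chromosome` | 100 | orthogroups per ancestral chromosome |
| `outgroup_fusions` | 3 | cephalochordate-branch fusions |
| `stem_events` | 6×fusion, 1R, 9×fusion, 2R, 5×fusion | vertebrate stem |
| `lineage_events` | chicken: 5×fusion | bird-stem fusions |
| `retention_prob` | 0.9 | per post-WGD copy survival |
| `asymmetry_sd` | 0.0 | log-normal spread of per-chromosome loss bias |
| `translocation_rate` | 0.0 | per-gene uniform relocation probability |
| `min_fraction` | 0.05 | slot-assignment abundance floor |
| `max_homologs` | 4 | slot count, forced by 2R |
| `fusion_min_fraction` | 0.10 | fusion-contribution evidence floor |
| `min_slots` | 2 | slots required to keep an ohnolog group |

The two abundance floors are not stated by the source analyses; 5%
suppresses translocation noise in slot assignment while keeping genuine
quarter-shares (~25%) comfortably above threshold, and 10% plays the same
role for fusion evidence where shares of a fused chromosome are ~12–50%.
Both are exposed on the CLI.  `max_homologs = 4` follows from two
duplications.  Whether an ohnolog group requires three *genes* or three
*distinct chromosomes* is read here as distinct chromosomes (slots), the
interpretation consistent with the A–D chromosome bookkeeping; the
`min_slots` parameter makes the alternative reading a one-line sensitivity
check.

## Numerical and degenerate-case choices

Retention is sampled by exact enumeration of the 2^k per-copy patterns
(k = copies per gene), zeroing the all-lost pattern when conditioning; this
makes the simulator's law identical to the enumeration oracle used in
tests.  `retention_prob = 0` with conditioning enabled has no surviving
pattern and is rejected; with conditioning disabled, emptied orthogroups
are counted and reported.  Ties in slot ordering break lexicographically.
Chromosomes with zero trans contacts yield undefined (NaN) enrichment
pairs rather than infinities; all-zero expression rows are excluded from
tau with a warning.  The trans-contact expectation uses trans-only
marginals (`T_a` excludes intra-chromosomal contacts); the conservation
rescaling `Σ E = Σ O` holds by construction either way, which is why the
alternative (cis-inclusive) marginal is not separately implemented.

## Problem sizes

Default test and acceptance runs use `N0 = 23`, `G = 100` (2,300
orthogroups, ~9,200 genes per ingroup species) and ten replicate seeds for
stochastic recovery checks; the retention-statistics check uses 10,000
four-copy orthogroups.  These sizes put standard errors well below the
effect sizes being checked while keeping a full suite run around ten
seconds.

## Known limitations

* Self-fusions and repeated ALG combinations are invisible to the
  abundance signature (see *Identifiable fusion histories*).
* Epoch assignment presumes exactly two WGDs; other ploidy histories would
  need a generalised sharing rule.
* Novelty of transferred ohnologs is relative to the pipeline's own input;
  comparison against an external ohnolog catalogue is a documented
  post-step, not part of the package.
* The supplementary-dataset reader is layout-driven (column mapping); it
  has been validated against synthetic exports in the same layout, not
  against the published spreadsheet itself, which must be downloaded
  separately.
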