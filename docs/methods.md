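# Methods

## Reconciliation model

The core inference is parsimony-based gene-tree/species-tree
reconciliation. Both trees are rooted and strictly binary (polytomies
are rejected by default; an optional deterministic resolution ladderizes
children by their smallest leaf label). The LCA mapping is computed
bottom-up; pairwise species-tree LCAs use depth-walking on a precomputed
parent/depth index. A node is a duplication iff its mapping equals the
mapping of *at least one* child — the standard criterion; requiring both
children would miss duplications followed by asymmetric sorting.

**Lineage decomposition.** The set `D` of duplication nodes mapping to
the species root is a connected crown containing the gene root (if any
node of `D` had a root-mapped *speciation* ancestor, that speciation's
children would both map below the root, contradicting mapping
monotonicity). Lineage roots are the gene root when it is not in `D`,
plus every non-`D` node whose parent is in `D`; the leaves therefore
partition exactly, and lineage ids are assigned in pre-order
(`lineage_1`, `lineage_2`, …). This operationalizes the verbal rules
used in comparative studies of the family — "clade containing copies
from all main groups", "retained by a single species implies ancestral
presence and loss elsewhere" — as a single criterion, and it reproduces
all six lineages of the canonical fixture, including the two
single-species ones.

**Dollo losses.** Per lineage, presence is forced at the species root
(single origin at the reference ancestor — the reading under which a
single-species lineage implies losses everywhere else). The present set
is then the union of root paths of retaining species; each edge from a
present node to an absent child is one loss, which is the minimum
conditional on root presence (each maximal absent subtree needs at least
one loss, and this assignment uses exactly one). Because forcing the
root is a modelling choice, the unconstrained minimum (origin at the
MRCA of retaining species) is computed alongside and reported in the
lineage table as `n_losses_unconstrained`.

**Pseudogenes** are excluded from the gene tree and all lineage counts
(the published per-species totals count putatively functional genes);
the pipeline drops leaves annotated as pseudogenes unless
`include_pseudogenes` is set.

## Annotation stage

A candidate gene model is *functional* iff it has exactly two exons, a
phase-0 intron (exon lengths divisible by 3), exon 1 encoding 37–64 aa
(start codon included), exon 2 encoding 340 ± 10 aa, an intact ORF
(ATG start, no internal stop, terminal stop), and both the family
signature and the active-site motif in the exon-2 translation. It is a
*pseudogene* iff the ORF is disrupted (missing start, internal stop, or
frameshift-length CDS) but the signature still matches the exon-2 region
translated in at least one of the three forward frames — frameshifted
copies keep a recognizable signature in a shifted frame. Anything else
is *rejected*, with reason codes enumerating every failed check.

Parameter defaults and rationale:

| parameter | default | why |
|---|---|---|
| `exon1_aa_min/max` | 37 / 64 | observed range of the variable first exon |
| `exon2_aa_target` | 340 | canonical conserved second exon |
| `exon2_aa_tolerance` | 10 aa | strict equality would reject real paralogs with small indels |
| `signature_pattern` | `GC[FY]AGGT` | catalytic-cysteine-containing family motif |
| `active_site_pattern` | `GFGPG` | the GFGPG active-site loop |

The motif defaults are placeholders of the right character, not curated
alignments: the published figures shade the regions without printing
residues, so the patterns are configuration, and all tests plant the
generator's own motifs rather than relying on the defaults.

Tandem names are `<chromosome>-T<k>` by ascending start coordinate
(chromosome 5′→3′ orientation regardless of gene strand); pseudogenes
keep their index and gain the `ps` suffix. Tied start coordinates are an
error, not silently broken — there is no published tie rule.

Coordinates are 1-based inclusive (GFF3 dialect); splicing concatenates
exons in transcription order with reverse-complementation on the minus
strand, which makes classification strand-invariant by construction
(verified by a mirror-genome test).

## Birth–death simulator

Each of `k` root copies evolves independently down the dated species
tree; on a branch of length `t` a copy duplicates at rate λ and dies at
rate μ (competing exponentials), and at speciations every copy enters
both child branches. Duplications are bifurcations at the event time;
whole-genome duplications are not a separate event class, because the
reconciliation stage is mechanism-agnostic. Extinct subtrees are pruned,
unary nodes suppressed. Surviving root copies are joined in a ladder at
the root age, so the joins are root-mapped duplications by construction
and the decomposition's recovered lineage count can be compared directly
with the true number of surviving copies: recovery never exceeds truth,
and is exact whenever every surviving copy has extant members on both
sides of the species-root bipartition (copies confined to one side can
coalesce with a neighbour below the root, causing undercounts — the
honest failure mode of the parsimony criterion).

Total extinctions are reported as empty replicates, never resampled, so
expectation checks against `E[n(t)] = k·e^{(λ−μ)t}` stay unbiased. One
root seed spawns per-replicate RNG streams (`numpy` `SeedSequence`), so
replicate `i` is reproducible independently of the others.

## Canonical fixture

The fixture encodes the published 12-species CHS study as data: an
ultrametric species tree with root age 107 my and the Fabales crown at
75 my (inside the published 57–97 my window; the other internal ages are
not printed anywhere and are fixed once to internally consistent
values — no result depends on them), and a 70-leaf gene tree in which
six lineages (yellow 1 copy, blue 4, red 4, green 10, brown 9, pink 42)
hang off a backbone ladder of five root-mapped duplications. Copy counts
that the published text leaves open are fixed to the unique values
consistent with the printed totals (e.g. medic 14 + 2 pink copies plus
1 green = 17). The backbone ladder order among lineages is arbitrary —
any order keeps the five joins root-mapped — and is frozen for
reproducibility. Gene models are laid out on chromosomes matching the
published chromosome occupancy (soybean's 15 genes on 7 chromosomes;
single chromosomes for thale cress, lyrate rockcress, castor bean), with
2 + 2 + 3 pseudogenes in barrel medic, *Lotus japonicus*, and field
mustard.

The sequence generator fabricates each locus from its gene model:
deterministic random codons (stop-free), planted signature and
active-site motifs at fixed exon-2 offsets, `GT…AG` intron, and one of
three planted disruptions per pseudogene (internal stop, 1-bp
frameshift, missing start), cycling by pseudogene index. What this does
**not** emulate: real sequence homology between paralogs (filler codons
are i.i.d.), non-phase-0 introns, sequencing/assembly noise, and real
motif variation. Passing the closed-loop tests therefore shows the
classifier implements its definition faithfully on clean input, not that
the default motifs would recover genes from a real genome.

## Validation design

Three independent oracles back the reconciliation core: (i) an LCA
oracle that picks the smallest species-tree clade containing a node's
species set by exhaustive scan; (ii) event labels recomputed from that
oracle mapping; (iii) a Dollo oracle enumerating all presence/absence
labellings of the species-tree internal nodes. Equivalence is checked
exhaustively on **every** species-labelled rooted binary gene-tree shape
with ≤ 8 leaves over a 4-species tree — 429,459 trees, enumerated
canonically so each distinct shape is checked once (leaf identity beyond
the species label cannot affect any of the three computations) — and on
500 simulated gene trees. Simulator calibration uses 2000 replicates for
the closed-form mean checks (3 Monte-Carlo standard errors) and 500
replicates for the recovery properties; these sizes keep the whole suite
within a few minutes while leaving the Monte-Carlo bands narrow.

## Known limitations

- The decomposition is parsimony-based: lineages that never left both
  sides of the root bipartition are undercounted (quantified by the
  recovery experiment); no likelihood model of duplication/loss is fit.
- Dollo's single-origin assumption ignores horizontal transfer and
  convergent re-gain, both reasonable exclusions for plant nuclear gene
  families at this scale.
- Weakly supported gene-tree nodes are taken at face value; no
  rearrangement of low-support branches is attempted.
- Duplication-node ages are not estimated; the Fabales window quoted for
  the fixture is a calibration read off the species tree, not a result.
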