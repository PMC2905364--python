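# Methods

This note records the model implemented by `gigatree`, the numerical and
design choices made where the procedure was genuinely open, what the
synthetic-data generator does and does not emulate, and the known
limitations. Empirical rates quoted here are the ones computed by the test
suite and `scripts/acceptance.py`; nothing below states a number those runs
do not themselves produce.

## The inference procedure

Inputs are an aligned protein family (FASTA, `-` gaps), a rooted species
tree (newick; multifurcations allowed; branch lengths ignored), and a
sequence→species mapping (default: the suffix after the final `_` of each
id; a two-column TSV overrides it).

**Preprocessing.** Sequences are weighted with position-based
(Henikoff-style) weights: each column splits one unit equally among the
residue types present, each type's share equally among the sequences
carrying it. Gapped sequences receive nothing from a column, so heavily
gapped (fragmentary) sequences are down-weighted rather than inflated as a
rare "type" — the latter convention would push a single 60%-truncated
sequence over the trim threshold and delete its columns for the whole
family. Columns whose weighted gap fraction exceeds `gap_threshold` (default
0.15) are removed. Ambiguity codes (`X B Z J U O *`) are treated as gaps
everywhere. Pairwise distances are raw p-distances over pairwise-complete
kept columns (gaps never count as mismatches); they are computed once and
never updated. Group-to-group distance is the minimum over inter-group
pairs, and the site count `n` attached to a group distance is that of the
minimizing pair.

**Agglomeration.** All sequence pairs are visited once, in ascending
(p, id-pair) order — ties break lexicographically so runs are fully
deterministic. Pairs inside one OS are skipped; a pair whose operation is
refused is never revisited. Merged OS topology is always the species-tree
restriction over the members' species; no distance information shapes the
inside of an OS. Duplication placement ("immediately prior to the MRCA") is
encoded as the species-tree node below the founding edge; a duplication
above the species-tree root lives on a virtual pre-root edge.

Decisions taken where the rule system is silent:

* **Equal-MRCA joins** assign mutual FCEs to both OS's; at assembly a mutual
  pair becomes one duplication node (rootward-most of the two placements if
  revisions made them differ).
* **Both OS's already dated**: no rule applies; the pair is skipped, and the
  OS's meet, if ever, only through their sibling links or at the unresolved
  root.
* **Revision orientation.** The revision inequality is implemented as
  *the joining group must be significantly closer to the dated group than to
  that group's sibling*: `d2 − d1 > m(σ1+σ2)` with `d1` = joining↔dated,
  `d2` = joining↔sibling. The multiplier is `ortholog_sd_multiplier` (1.5)
  when the joining group shares no species with the sibling (the competing
  hypothesis implies no duplication) and `paralog_sd_multiplier` (0.5)
  otherwise. `GigaConfig.revision_literal_sign` flips the margin's sign for
  comparison studies. A saturated distance (p ≥ 19/20) makes the evidence
  fail conservatively. A successful revision moves the placement rootward to
  the merged MRCA — never leafward.
* **Sibling cycles.** Because an OS pair can be visited by several sequence
  pairs at different stages, sibling links could form cycles (a founds on b,
  b on c, c on a). A join that would make an OS transitively its own founder
  is refused and logged (`sibling-cycle`); the two-cycle of a mutual pair is
  the only allowed loop. Assembly still carries a defensive cycle check.
* **Fragment test.** Expected ancestral sites are the columns where more
  than half of the merged group's members *excluding the candidate* carry a
  residue. Excluding the candidate matters: in a two-singleton merge (a
  fragment's usual first contact) the all-members vote reduces to the
  intersection of the two sequences' sites, which a fragment covers by
  construction and so could never be flagged. A candidate is exempt once its
  OS holds `fragment_exempt_os_size` (3) other sequences. Quarantined
  fragments are re-inserted after the main pass in ascending order of their
  best distance to a non-fragment, one merge-or-join attempt each (without
  the fragment test); failures are reported as discarded.
* **Assembly.** Founded OS's are grafted onto their sibling's subtree at the
  MRCA of the sibling members lying inside the placement's clade, rootward
  placements first so nested duplications stack oldest-above. Grafts with
  identical sibling and placement extend one multifurcating duplication
  node. Components never connected by any event are children of an
  unresolved multifurcating root.

**Post-inference.** Ancestral states: post-order strict majority over child
states per site ('X' excluded from the denominator, gaps countable but
emitted as 'X'); ties are broken by the node's sibling subtree (leaf-
majority, so the result is traversal-order independent) when it matches a
child state, else 'X'; the root has no outgroup. Branch lengths: p between
adjacent node sequences over sites where both are residues — restricted,
for edges leaving a duplication node, to sites aligned in all of that node's
leaf descendants (the rate-heterogeneity guard) — then Jukes–Cantor
corrected with s = 20. Saturated branches are capped at
`max_branch_length` (10.0) and flagged; zero comparable sites give length 0
with a warning.

## Parameters

| name | default | meaning |
| --- | --- | --- |
| `gap_threshold` | 0.15 | max weighted gap fraction for a kept column |
| `fragment_coverage` | 0.5 | max expected-site coverage that still flags a fragment |
| `fragment_exempt_os_size` | 3 | other-sequence count that exempts a candidate |
| `ortholog_sd_multiplier` | 1.5 | revision stringency, no-duplication alternative |
| `paralog_sd_multiplier` | 0.5 | revision stringency, duplication alternative |
| `alphabet_states` | 20 | s in the Jukes–Cantor forms (4 recovers the nucleotide form) |
| `max_branch_length` | 10.0 | substitutions/site cap for saturated branches |

## The synthetic-data generator

One ancestral gene evolves down an ultrametric species tree (random
coalescent-style topologies with exponential waiting times, height
normalized to 1; user trees get unit-edge heights). Per edge and per gene
lineage: loss with probability `loss_probability`; a Poisson
(`duplication_rate`) number of duplications, each copy founded at the top of
the edge; substitutions per site with probability
`substitution_rate × (edge time span)` under a uniform 20-state exchange
model, so clock-like divergence has a closed form for calibration. The
founded copy evolves its founding edge at `post_duplication_multiplier`
(1.5) times the rate, emulating post-duplication acceleration — this is
also what lets the revision rule see accelerated paralogs in simulations.
Fragments are planted by gapping the trailing fraction of a sequence.
Defaults: 300 sites, substitution rate 0.4 per unit height, no losses, no
duplications unless asked.

Not emulated: indels and alignment error (alignments are gap-free except
planted fragments), among-site rate variation, non-uniform exchange
matrices, horizontal transfer, incomplete lineage sorting. Passing the
synthetic checks therefore demonstrates the correctness of the rule system
and its bookkeeping under the stated model — not performance on real
alignments, where alignment quality is known to dominate.

## Evaluation protocols and problem sizes

* *Congruence*: 200 duplication-free clock families on random 10–20-leaf
  trees; the inferred tree must equal the species-tree restriction (RF 0).
* *Placement recovery*: 100 families, one duplication planted on the
  **longest internal edge** of an 8–13-leaf tree, no loss, 300 sites.
  The longest edge is used deliberately: coalescent trees contain internal
  edges of near-zero duration, where a planted duplication is statistically
  indistinguishable from the adjacent speciation at any finite sequence
  length; planting on an identifiable edge makes the protocol measure the
  dating logic rather than distance noise. Recovery must be exact, 100/100.
* *Dating bias*: a fixed fixture with a duplication above a three-species
  clade and the second copy deleted in one species. The inferred date must
  fall at the most recent consistent edge — deliberately more recent than
  the truth. This is the documented cost of deletion parsimony.
* *Genomic proof*: on all runs above plus 50 runs driven by arbitrary random
  distance matrices, every join event must record a species overlap and
  every duplication node must cover two genes of one species.
* *Fragments*: 50 12-taxon families with one 60%-truncated sequence; the
  fragment must always be quarantined and the topology over full-length
  sequences must match the fragment-free run.
* *Robustness*: 100 clock-like duplication-free 12-taxon families; drop 3
  random species and re-run; the restricted topology must be unchanged in
  ≥ 99/100 (distance ties are the only expected failure mode). On families
  *with* duplications this property does not hold in general — deleting
  taxa removes the gene-content witnesses that date duplications — which is
  a real property of content-based dating, not an implementation artifact;
  see limitations.
* *Determinism*: 20 fixtures run twice through the CLI; tree, event log,
  ortholog table and manifest must be byte-identical.
* *Closed forms*: `jc_distance` and `jc_stddev` agree with direct
  evaluations over a (p, n) grid to 1e-12.

These sizes run the whole suite in well under a minute on one CPU;
`scripts/acceptance.py` re-runs them from a user seed.

## Known limitations

* Gene content outweighs sequence signal by design: duplications adjacent to
  short species-tree edges are dated to the nearest consistent edge, and
  losses near a duplication make the inferred date too recent (the bias
  protocol above reproduces this on purpose).
* When two copy lineages assign each other mutual FCEs, more distant
  orthologs can fail the revision test (equidistant to both copies) and end
  up attached at the unresolved root rather than inside an OS.
* With duplications present, the result depends on the visiting order of
  pairs, so adding or removing taxa can change the restricted topology;
  order-independence is guaranteed only for duplication-free inputs.
* The species tree is trusted absolutely; genuine gene-tree/species-tree
  incongruence (e.g. incomplete lineage sorting, horizontal transfer) is
  outside the model, and the output is then the best vertical-inheritance
  null hypothesis rather than the true history.
* Ancestral states and branch lengths are fast approximations meant for
  annotation and relative comparison; for publication-grade branch lengths
  refit the fixed topology with a maximum-likelihood tool.
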