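# gigatree

Species-tree-constrained agglomerative gene-tree inference, in the style of
the GIGA algorithm: build a gene family's phylogeny from nothing more than a
raw pairwise sequence-distance matrix, a trusted rooted species tree, and the
knowledge of which genome each sequence came from.

## Who this is for

Phylogenomics pipelines that need gene trees — and the orthologs read off
them — for many families at once, where a reliable species tree and complete
genome annotations are available. Instead of estimating the topology from
sequence data alone (slow, and fragile under lineage-specific rate shifts),
the inference treats genome-derived information as hard constraints and uses
sequences only to reveal common ancestry.

## The model

A gene tree is viewed as a set of **orthologous subtrees (OS's)** — maximal
groups of genes related only by speciation events, at most one gene per
species — joined together by **founding copy events (FCEs)**: the gene
duplications that created each new OS, each dated onto an edge of the
species tree.

Distances are raw p-distances: for sequences *i, j*,
`p = (# differing amino acids at shared homologous sites) / n`, computed on
an alignment trimmed of columns where more than 15% of the (Henikoff-
weighted) sequences are gapped. Distances are computed once and never
averaged or updated; the distance between two groups is the minimum over
inter-group sequence pairs.

Every sequence starts as its own OS. Walking sequence pairs in ascending
distance order, each pair proposes one operation on the two OS's containing
it:

1. **Merge (Rule 1)** — if the union has at most one gene per species, the
   OS's are merged and the merged topology is *the species-tree restriction*
   over the member species: orthologous sequences are always arranged
   congruently with the species tree, regardless of join order.
2. **Duplication join (Rules 2–3)** — if the union holds two genes from one
   species (genomic proof of duplication, the "witness of non-orthology"),
   the OS's stay separate and are related by a duplication. The OS with the
   more recent species-tree MRCA is founded on the other, the event placed
   *immediately prior to its MRCA* — the placement implying the fewest
   independent gene losses (deletion parsimony).
3. **Revision (Rule 4)** — a merge that would deepen an already-dated FCE is
   allowed only with significant distance evidence. With `d1` the distance
   of the joining group to the dated group, `d2` its distance to the dated
   group's sibling, and `σ` the Jukes–Cantor standard deviations
   `σ = sqrt(p(1−p) / (n (1 − (s/(s−1))p)²))` (s = 20 amino-acid states),
   the merge requires `d2 − d1 > m(σ1+σ2)`, with m = 1.5 when the competing
   hypothesis implies no duplication and m = 0.5 otherwise. The FCE is then
   revised rootward.
4. **Fragment quarantine (Rule 5)** — a merge-driving sequence covering at
   most 50% of the sites expected in its subtree's ancestor is quarantined
   and re-inserted afterwards with a single merge-or-join attempt.

After assembly, ancestral sequences are reconstructed by a local majority
rule with outgroup tie-breaking, and branch lengths are Jukes–Cantor
corrected p-distances between adjacent node sequences,
`d = −((s−1)/s) ln(1 − (s/(s−1)) p)`, with sites below a duplication
restricted to those aligned in all of its descendants.

See `docs/methods.md` for every numerical choice and limitation.

## Worked example

A six-sequence methylenetetrahydrofolate-reductase-style family with two
fungal paralog groups (MET13/met9 and MET12/met11), UniProt-style ids:

```bash
giga infer --alignment family.fasta --species-tree species.nwk \
  --out-tree tree.nwk --out-events events.tsv --out-orthologs orthologs.tsv
# 6 leaves, 1 duplications, 0 discarded fragments
```

with `species.nwk` =
`(((HUMAN,MOUSE)euarchonta,(YEAST,SCHPO)fungi)opisthokonta,DICDI)root;`.
The inferred tree (`tree.nwk`, NHX annotations: `D=Y` duplication, `D=N`
speciation at species-tree node `S`):

```
((MTHFR_HUMAN:0.000000,Mthfr_MOUSE:0.019058):0.000000[&&NHX:D=N:S=euarchonta],
 ((MET12_YEAST:0.000000,met11_SCHPO:0.000000):0.208867[&&NHX:D=N:S=fungi],
  (MET13_YEAST:0.000000,met9_SCHPO:0.019813):0.378962[&&NHX:D=N:S=fungi]
 ):0.000000[&&NHX:D=Y:S=fungi])[&&NHX:D=N:S=opisthokonta];
```

Both fungal pairs sit under one duplication node dated `S=fungi`: the event
happened on the species-tree edge just above the fungal common ancestor, the
most deletion-parsimonious placement given that only fungi carry two copies.
The event log (`events.tsv`) is the explainability artifact — every decision
with its driving pair and distance:

```
step  action       seq1         seq2         os1  os2  distance  detail
1     merge        MTHFR_HUMAN  Mthfr_MOUSE  2    3    0.018868  no-fce
2     merge        MET12_YEAST  met11_SCHPO  4    5    0.037736  no-fce
3     merge        MET13_YEAST  met9_SCHPO   0    1    0.056604  no-fce
4     merge        MTHFR_HUMAN  met11_SCHPO  2    4    0.830189  no-fce
7     join         MET12_YEAST  MET13_YEAST  0    2    0.886792  fce@fungi;overlap=SCHPO,YEAST
9     refuse-join  MET13_YEAST  met11_SCHPO  0    2    0.886792  span-exceeds-dated-os
```

`orthologs.tsv` lists the 11 leaf pairs whose MRCA is a speciation node;
note MET13_YEAST–met11_SCHPO is *not* among them (their MRCA is the
duplication), while each fungal gene is orthologous to the human and mouse
genes.

The same inference is available as an estimator:

```python
from gigatree import GigaTreeEstimator
est = GigaTreeEstimator(species_tree="((HUMAN,MOUSE),YEAST);")
est.fit([("A_HUMAN", "ACDEF..."), ("B_MOUSE", "ACDEV..."), ("C_YEAST", "ACWEV...")])
est.tree_.to_newick(); est.ortholog_pairs_
```

`giga simulate` generates families with known event histories along a
species tree, and `giga compare` computes the Robinson–Foulds distance,
ortholog-pair difference, or the clean-vs-full robustness comparison between
two trees.

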