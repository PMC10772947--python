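# allophase

Dual-evidence subgenome phasing for allopolyploid genomes.

Allopolyploids carry chromosome sets (subgenomes) inherited from two or
more distinct progenitor species.  Sorting a polyploid's chromosomes by
parental origin — *subgenome phasing* — is the entry point to
subgenome-aware phylogenetics, but it is hard precisely when it matters
most: when the diploid progenitors are extinct or unsampled.  `allophase`
implements the two complementary phasing strategies used in that setting,
as one toolkit with shared data structures, plus the validation machinery
needed to trust (or distrust) the result:

* **k-mer channel** — lineage-specific repeats accumulated before
  hybridisation leave *differential k-mer signatures*.  The channel
  counts canonical k-mers per chromosome, keeps those differentially
  abundant within homoeologous chromosome groups, clusters chromosomes on
  them (k-means, with heatmap linkage and PCA exports), and scans
  fixed-step windows for runs enriched in another subgenome's k-mers —
  candidate homoeologous exchanges (HEs), scored with an exact binomial
  tail.
* **synteny/Ks/phylogeny channel** — gene-anchor synteny against an
  outgroup (built-in seed-and-count protein hits, or external 12-column
  hit tables), NG86 synonymous-rate estimates per anchor
  (Ks = −¾ ln(1 − 4/3·pₛ)), Ks-coloured dot plots, karyotype projection
  onto outgroup chromosomes, complementarity assignment of translocated
  segments, per-homoeologous-group neighbour-joining gene trees, and a
  quartet-consensus species/subgenome tree with per-branch supports
  (q1, q2, q3), gene-tree concordance percentages and coalescent-unit
  branch lengths −ln(1.5(1−q1)).  Group labels are iterated until every
  chromosome of a subgenome occupies the same phylogenetic position.
* **evaluation** — random-sorting negative control (labels reshuffled
  within homoeologous groups), channel-vs-channel discrepancy reports,
  best-hit percentages against candidate progenitors, fractionation
  profiles, and classification of each subgenome pair as **absolutely**
  phased (progenitor identity resolved) or only **relatively** phased
  (topologically equivalent sisters, named arbitrarily).
* **simulator** — a ground-truthed allopolyploid generator: diploid
  progenitors diverge from one ancestor along a declared species tree
  (JC-like per-site substitutions), receive lineage-specific intergenic
  repeat bursts, merge (nested mergers allowed, e.g. AABB + DD → AABBDD)
  with gene fractionation, and optionally suffer balanced/unbalanced HEs
  and large-scale translocations.  Five presets mirror classic complex
  scenarios: wheat-like [[A,D],B], oat-like [[A,D],C], poppy-like
  [D,[C,[B,A]]], a U's-triangle trio of tetraploids, and a
  strawberry-like octoploid [V,[I,[T1,T2]]] with a sister pair that is
  only relatively phaseable.

The two channels fail differently, by design: balanced (reciprocal,
synteny-preserving) HEs are invisible to the synteny channel but flagged
by k-mer window enrichment, while exchanges in regions sparse in
differential signatures are invisible to k-mers but recovered by synteny
complementarity.  The toolkit reproduces both asymmetries on simulated
ground truth.

## Worked example

Simulate a wheat-like complex (tetraploid TT = AABB, hexaploid
TA = AABBDD, plus an outgroup), then phase it with both channels:

```
$ allophase simulate --preset wheat --seed 1 --out-dir sim
$ allophase kmer-phase --genome sim/TA.genome.fasta --groups sim/groups.json \
      --n-subgenomes 3 --seed 1 --out-prefix TA
$ allophase phase --dir sim --out-prefix wheat
```

`TA.assignment.tsv` (k-mer channel; cluster names are arbitrary ints):

```
species chromosome  start  end    label  evidence
TA      1A          0      15050  0      kmer
TA      1B          0      14450  1      kmer
TA      1D          0      15650  2      kmer
```

`wheat.consensus.nwk` and `wheat.supports.tsv` (phylogeny channel):

```
(OUTGROUP,(((TA|1,TT|1),TA|3),(TA|2,TT|2)));

branch_side                q1     q2     q3     concordance  length
OUTGROUP,TA|2,TT|2         1.000  0.000  0.000  100.0        10.000
OUTGROUP,TA|2,TA|3,TT|2    1.000  0.000  0.000  100.0        10.000
OUTGROUP,TA|1,TA|3,TT|1    1.000  0.000  0.000  100.0        10.000
```

Reading: subgenome 3 (the D-like lineage, present only in the hexaploid)
is sister to the pair of 1-labelled columns (the A-like copies of both
species); the 2-labelled pair (B-like) is outside; every branch is
resolved by 100 % of gene trees (q1 = 1, branch length capped at 10
coalescent units).  `wheat.decisions.tsv` classifies every subgenome pair
as `absolute` — e.g. pair 1/3 because those lineages occur in different
species sets, pair 1/2 because swapping them changes the consensus
topology.  On the strawberry-like preset the same command instead reports
the T1/T2 sister pair as `relative`: their positions are equivalent and
no non-phylogenetic evidence separates them.

The same steps are available as library calls
(`allophase.pipeline.run_kmer_channel` / `run_synteny_channel`), which is
how the test-suite and the benchmark studies drive them.

## Inputs for real data

FASTA assemblies/proteomes/CDS, the 7-column tab-separated gene
coordinate table (chromosome, gene id, start, end, strand, order rank,
original id; 1-based inclusive on disk), optional precomputed 12-column
protein hit tables, optional externally computed gene trees (newick), an
outgroup genome and a homoeologous-chromosome grouping.  See
`docs/methods.md` for the model, parameter defaults and limitations.
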