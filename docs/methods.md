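# Methods

This note documents the models and procedures implemented in `allophase`,
the parameters that matter, the numerical conventions, and what the
simulation-based tests do and do not demonstrate about real data.

## Problem setting

An allopolyploid's chromosomes descend from two or more progenitor
lineages.  Phasing assigns each chromosome (or chromosome segment, since
homoeologous exchanges and translocations move material between
subgenomes) to its source lineage.  When progenitor genomes are
unavailable, two kinds of within-polyploid evidence remain: repeat
(k-mer) signatures laid down in each lineage before hybridisation, and
the similarity/synteny/phylogeny structure of the retained homoeologous
genes relative to an outgroup.  `allophase` implements both, keeps their
outputs in a common segment-level assignment table, and measures their
agreement.

A subgenome pair is **absolutely** phased when evidence fixes which
lineage is which; sisters occupying topologically equivalent positions
with no further evidence can only be **relatively** phased — their names
are arbitrary, which is harmless for the subgenome phylogeny itself but
fatal for naming progenitors.  `classify_phasing` formalises this: a pair
(X, Y) is relative iff exchanging X and Y in every species column is an
automorphism of the consensus topology and no distinguishing evidence tag
(`ks`, `kmer`, `complementarity`, `override`; configurable) attaches to
either label.  Note the species-complex structure matters: in a single
[[A,D],B] genome A and D are exchangeable, but with a tetraploid relative
carrying A and B only, the asymmetry of species membership makes every
pair absolute.

## k-mer channel

Canonical k-mers (lexicographic minimum of a k-mer and its reverse
complement; k odd so no k-mer is its own reverse complement) are counted
per chromosome with a 2-bit rolling encoding.  A k-mer is *differential*
if, in more than half of the homoeologous groups, its most abundant
member chromosome exceeds `min_fold` times the next member (counts per
Mb), and its total count is at least `min_freq`.  The majority rule keeps
one exchanged or aberrant group from vetoing a lineage signature.
Chromosomes are clustered on the standardised differential-count matrix
by seeded k-means into `n_subgenomes` clusters; a hierarchical linkage
and a 2-component PCA projection are exported for visual verification.

Window scan: for each window (default `window`=2 kb, `step`=1 kb at
preset scale; 100 kb/50 kb would be ordinary at genome scale) and each
subgenome, the observed count of that subgenome's specific k-mers is
compared with expectation = genome-wide density of those k-mers × window
positions, via a one-sided binomial tail.  A window is *enriched* for the
argmax-ratio label when the tail probability is below `alpha` (0.01) and
the ratio exceeds 1.  Runs of at least `min_consecutive` (3) windows
enriched for the same non-assigned subgenome merge into exchange
candidates.  Because expectation is the genome-wide density, enrichment
of a chromosome's own label is common (its own density is roughly
`n_subgenomes`-fold the genome-wide value) and deliberately not treated
as an exchange signal; calibration is therefore stated for *discordant*
significant windows, which on exchange-free genomes stay well below the
nominal threshold.  A consequence worth knowing: on a two-subgenome
genome the expected enrichment ratio over true exchanges is only ~2, so
single windows can miss the score threshold; on three or more subgenomes
the signal is proportionally stronger.

For closely related subgenome pairs, `rerun_subset` re-selects
differential k-mers over just that pair's chromosomes, recovering
pair-specific k-mers that the full contrast discards.

## Synteny / Ks / phylogeny channel

**Hits.**  The built-in scorer counts shared amino-acid 5-mers
(`min_score` 4 shared words, `top_n` 2 subjects per query).  It exists so
the pipeline is self-contained on simulated data; for real genomes,
externally computed 12-column hit tables are first-class inputs.

**Chaining.**  Anchors (hits mapped to gene-order ranks) are chained per
chromosome pair into maximal strictly monotone runs, forward and
reverse, with consecutive anchors at most `max_gap` (25) ranks apart on
both axes; chains are extracted by repeated longest-chain dynamic
programming (each hit used once), dropping chains below `min_anchors`
(5).  Ties are broken deterministically (forward before reverse; then
the chain minimising the anchor-index sequence read from its last anchor
backwards), and the implementation is property-tested against an
exhaustive enumeration oracle under the same convention.

**Ks.**  NG86 counting: per codon, synonymous site fractions from the
three single-base neighbours (changes to stop codons count as
nonsynonymous, so S + N = 3 × codons); codons differing at 2–3 positions
average their synonymous/nonsynonymous difference counts over minimal
mutational pathways, excluding pathways through stop codons (all
pathways are used if every one is blocked).  Jukes–Cantor correction
Ks = −¾ ln(1 − 4/3·pₛ), undefined (saturated) for pₛ ≥ ¾.  Other
estimators are out of scope.  Blocks carry the median of their finite
anchor Ks values; all-saturated blocks are flagged.

**Orthology filtering.**  `filter_orthologous` keeps, per overlapping
block region, the `multiplicity` blocks with lowest median Ks (then most
anchors) — multiplicity being the expected subgenome copy number — or
applies a plain Ks cutoff; a per-block override file replaces manual
out-paralog curation and is idempotent.  The simulated complexes contain
no out-paralogy, so the channel driver applies no region filter by
default (a `ks_cut` option is exposed).

**Karyotype and complementarity.**  Orthologous blocks against the
outgroup partition each polyploid chromosome into segments labelled by
outgroup chromosome (adjacent same-label segments merged, boundaries at
rank midpoints, one-gene resolution).  A minority segment whose outgroup
label differs from its host chromosome's is a translocation candidate;
it is assigned the subgenome of the same-species chromosome whose own
coverage of that outgroup chromosome misses exactly the span the segment
supplies — the two jointly reconstituting one outgroup chromosome.
Ambiguous or partnerless segments stay unassigned with a warning.

**Gene trees and consensus.**  Per outgroup gene, the syntenic orthologs
of the group's member chromosomes (equal-length CDS; rows with fewer
than `min_taxa` = 4 present tips, or length mismatches, are skipped)
give pairwise Jukes–Cantor distances and a neighbour-joining tree
(scikit-bio), tips named species|chromosome.  The species/subgenome
consensus maximises total quartet agreement with the gene trees —
exhaustive over all unrooted topologies for ≤ 8 labels (cached
per-leaf-count resolution tables make this a vectorised gather), greedy
stepwise addition above; topology ties are logged and broken by the
lexicographically smallest canonical newick.  Each internal branch
carries q1/q2/q3 (normalised frequencies of the three resolutions of the
quartets spanning the branch), the percentage of gene trees containing
the branch's restricted bipartition, and a coalescent-unit length
−ln(1.5(1−q1)), floored at 0 and capped at 10 when q1 → 1.

**Iteration.**  Starting from arbitrary per-group labels, the loop
alternates (a) consensus over current species|label columns and (b) per
group, the member relabelling (exhaustive over per-species permutations)
maximising that group's quartet agreement with the consensus, keeping
current labels on ties (so the fixed point is idempotent) and flagging
tied groups.  Convergence is declared when no group changes;
`max_rounds` (10) guards non-convergence.  Afterwards, labels are
harmonised across species: columns joined by a consensus clade
containing at most one column per species share a lineage name.  For
topologically equivalent sisters the per-group tie-break is arbitrary,
exactly as relative phasing implies; accuracy metrics therefore treat
declared relative pairs as interchangeable.

## Evaluation

`random_sort` permutes labels uniformly within each homoeologous group
(preserving each group's label multiset, renaming control labels to
integers).  Draws in which every group applies the same per-species
bijection — a mere renaming, producing no artificial exchanges — are
redrawn; with the ~7 groups of a real genome this rejection is a no-op.
`concordance` reports per-branch gene-tree agreement with any reference
topology; `best_hit_fraction` reports the percentage of each subgenome's
proteins whose best hit lies in each candidate progenitor (ties counted
as ambiguous and excluded; percentages over all proteins and over hit
proteins are both emitted); `compare_assignments` matches two tables'
arbitrary label sets by bp-weighted Hungarian assignment and reports
agreement on the finest common segmentation; `fractionation_profile`
gives sliding-window retained-gene fractions per subgenome column.

## Simulator

All randomness flows from one integer seed; identical configuration and
seed give byte-identical output.  Defaults (also the conditions of the
benchmark studies): 3 chromosomes per haploid set, 28 genes per
chromosome, 300 bp genes (100 sense codons, no internal stops), 200 bp
intergenic gaps, per-branch substitution proportion 0.05, one 50 bp
lineage-specific repeat copy per intergenic gap, fractionation 0.05 per
merger, post-merger divergence 0.01.  Substitutions are i.i.d. per site
and uniform over the three alternative bases (so pairwise expectations
compose in closed form: p ⊕ q = p + q − 4/3·pq); a substitution that
would create a stop codon is redirected to a non-stop alternative, which
perturbs expectations only at second order.  Repeats are inserted
intergenically only, so gene-based synteny is untouched; one copy per
gap (uniform position within the gap) rather than a Poisson scatter, so
every preset-scale window over an exchanged span carries signal.  The
small post-merger divergence exists because exact byte-identity between
a polyploid's subgenome and its parent (Ks = 0 everywhere) is degenerate
for hit ranking and dot-plot ordering.  Divergence is specified directly
as a substitution proportion; no molecular-clock mapping from divergence
times is attempted.

Exchange events: *balanced* — reciprocal swap of equal-gene-count spans
(outgroup synteny preserved; invisible to the synteny channel);
*unbalanced* — receiver span overwritten with a copy of the donor span;
*translocation* — donor span moved to the receiver's end, leaving a
complementary gap.  Overlapping events on one span are rejected.
`strip_repeats` removes the repeat insertions from a span to emulate
signature-sparse regions.

**What passing tests show, and what they do not.**  The generator has no
TE families, nesting or decay, no indels in genes, no recombination, no
missing or misassembled sequence, and clean 1:1 orthology.  Recovery at
100 % under these conditions demonstrates the algorithms' correctness
and their designed failure asymmetries (balanced exchanges vs sparse
signatures), not expected field accuracy on real assemblies, where
alignment quality, paralogy and assembly errors dominate.

## Benchmark studies and problem sizes

The studies behind `scripts/acceptance.py` and the end-to-end tests use
the preset scale above: five scenarios × 20 seeds (exchange-free, both
channels, paired random-sort control), 20 balanced-exchange runs on the
oat-like scenario (8-gene terminal swaps, 500 bp scan step), and 10
translocation runs on the U's-triangle scenario with and without
stripped repeats.  Oracle comparisons: 500 random 30-codon pairs for
NG86 (counts to 1e-9; rates compared away from the pₛ ≥ 0.74 saturation
boundary, where the JC transform amplifies last-bit differences without
bound), 200 random anchor sets (≤ 12 anchors) for chaining, 200 random
gene-tree collections over 5–6 labels for the quartet consensus.

## Known limitations

* Built-in gene trees are JC + neighbour-joining; external
  maximum-likelihood trees can be ingested per group instead.
* Quartet supports are plain frequencies; no local posterior
  probabilities are computed.
* Per-block or sliding-window phylogenies for exchange verification are
  not implemented; the k-mer channel's window scan covers that role.
* The consensus search is exhaustive only to 8 labels (greedy above,
  hard limit 12); larger complexes should be phased per sub-problem.
* Balanced exchanges approaching half a chromosome can flip a whole
  chromosome's phylogenetic label rather than appear as a segment error
  — an inherent property of chromosome-level phylogeny, not a bug the
  toolkit can detect from synteny alone.
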