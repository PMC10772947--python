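"""End-to-end channel drivers composing the module operations.

Two independent evidence channels produce an :class:`AssignmentTable`
each: the k-mer channel (per species) and the synteny/Ks/phylogeny channel
(joint over the whole species complex, anchored on the outgroup).  Helper
functions score either channel against simulator ground truth and run the
random-sorting negative control.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .evaluation import per_species_label_map, random_sort
from .io_formats import GenomeComplex
from .kmer_phasing import (DifferentialKmerSet, ExchangeCandidate,
                           WindowEnrichment, call_exchanges, cluster_subgenomes,
                           count_kmers, relabel_kmers, scan_windows,
                           select_differential)
from .phylo import (OUTGROUP_TIP, AssignmentTable, ConsensusTree, GeneTree,
                    IterationResult, KaryotypeSegment, assign_complementarity,
                    build_gene_trees, build_ortholog_table, classify_phasing,
                    consensus_from_counts, gene_tree_from_newick,
                    group_homoeologs, iterate_assignment, map_karyotype,
                    quartet_counts)
from .synteny import (chain_synteny, compute_block_ks, compute_hits,
                      filter_orthologous, integrate_blocks)
from .synthetic import GroundTruth


def truth_table(truth: GroundTruth, gc: GenomeComplex) -> AssignmentTable:
    """Ground truth as an assignment table (labels = source lineages)."""
    table = AssignmentTable()
    from .phylo import AssignmentRow
    for seg in truth.segments:
        table.rows.append(AssignmentRow(
            truth.species_id, seg.chromosome, seg.start, seg.end,
            seg.subgenome, "override"))
    table.rows.sort(key=lambda r: (r.species, r.chromosome, r.start))
    return table


# ==========================================================================
# k-mer channel
# ==========================================================================

@dataclass
class KmerChannelResult:
    species: str
    cluster_labels: dict
    diffset: DifferentialKmerSet
    windows: list
    candidates: list
    table: AssignmentTable


def run_kmer_channel(gc: GenomeComplex, groups: list[list[str]],
                     n_subgenomes: int, k: int = 13, seed: int = 0,
                     min_fold: float = 2.0, min_freq: int = 10,
                     window: int = 2000, step: int = 1000,
                     alpha: float = 0.01, min_consecutive: int = 3,
                     ) -> KmerChannelResult:
    """Differential-k-mer phasing of one assembly plus exchange calling."""
    matrix = count_kmers(gc.chromosomes, k)
    diffset = select_differential(matrix, groups, min_fold, min_freq)
    labels, _ = cluster_subgenomes(diffset, n_subgenomes, seed)
    relabel_kmers(diffset, labels)
    windows = scan_windows(gc.chromosomes, diffset, window, step, alpha)
    candidates = call_exchanges(windows, labels, min_consecutive)
    table = AssignmentTable.from_labels(
        gc.species_id, gc.chromosome_lengths(),
        {c: str(l) for c, l in labels.items()}, "kmer")
    for cand in candidates:
        table.set_span(gc.species_id, cand.chromosome, cand.start, cand.end,
                       str(cand.enriched_label), "kmer")
    return KmerChannelResult(species=gc.species_id, cluster_labels=labels,
                             diffset=diffset, windows=windows,
                             candidates=candidates, table=table)


# ==========================================================================
# synteny / Ks / phylogeny channel
# ==========================================================================

@dataclass
class SyntenyChannelResult:
    table: AssignmentTable
    segments: list
    groups: list
    blocks_by_species: dict
    group_trees: dict                 # outgroup chromosome -> list[GeneTree]
    group_members: dict               # group -> species -> [chromosomes]
    iteration: IterationResult
    consensus: ConsensusTree
    decisions: list
    ortholog_table: pd.DataFrame


def run_synteny_channel(complexes: dict[str, GenomeComplex],
                        outgroup: GenomeComplex,
                        min_anchors: int = 5, max_gap: int = 25,
                        top_n: int = 2, min_taxa: int = 4,
                        max_rounds: int = 10, ks_cut: float | None = None,
                        external_trees: dict | None = None,
                        ) -> SyntenyChannelResult:
    """Outgroup-anchored synteny phasing of a whole species complex.

    Per species: built-in protein hits vs the outgroup, chaining, NG86 Ks,
    optional out-paralog removal by Ks cutoff, karyotype projection.
    Jointly: homoeologous groups, complementarity assignment of
    translocated segments, per-group NJ gene trees (or ``external_trees``:
    group -> list of newick), and the iterate-until-consistent
    quartet-consensus loop.
    """
    blocks_by_species: dict[str, list] = {}
    segments: list[KaryotypeSegment] = []
    ploidies: dict[str, int] = {}
    sequences: dict[str, str] = dict(outgroup.cds)
    positions: dict[str, tuple[str, int]] = {
        g.gene_id: (g.chromosome, g.start) for g in outgroup.genes}
    for sp in sorted(complexes):
        gc = complexes[sp]
        sequences.update(gc.cds)
        positions.update({g.gene_id: (g.chromosome, g.start) for g in gc.genes})
        hits = compute_hits(gc.proteins, outgroup.proteins, top_n=top_n)
        blocks = chain_synteny(hits, gc.gene_orders(), outgroup.gene_orders(),
                               min_anchors=min_anchors, max_gap=max_gap,
                               block_prefix=f"{sp}.b")
        ks_map = compute_block_ks(blocks, gc.cds, outgroup.cds)
        blocks = integrate_blocks(blocks, ks_map)
        if ks_cut is not None:
            blocks = filter_orthologous(blocks, mode="ks_cut", ks_cut=ks_cut)
        blocks_by_species[sp] = blocks
        ploidies[sp] = max(1, round(len(gc.chromosomes) / len(outgroup.chromosomes)))
        segments.extend(map_karyotype(blocks, gc, min_anchors=min_anchors,
                                      species=sp))
    groups = group_homoeologs(segments, ploidies)

    # chromosome-level membership: a chromosome sits in the group of its
    # highest-support segment; translocated minority segments are handled
    # by complementarity, not by group membership
    major: dict[tuple[str, str], str | None] = {}
    per_chrom: dict[tuple[str, str], list[KaryotypeSegment]] = {}
    for seg in segments:
        per_chrom.setdefault((seg.species, seg.chromosome), []).append(seg)
    for key, segs in per_chrom.items():
        labelled = [s for s in segs if s.outgroup_chromosome is not None]
        major[key] = max(labelled, key=lambda s: s.support).outgroup_chromosome \
            if labelled else None
    group_members: dict[str, dict[str, list[str]]] = {}
    for (sp, chrom), g in sorted(major.items()):
        if g is not None:
            group_members.setdefault(g, {}).setdefault(sp, []).append(chrom)

    ortho = build_ortholog_table(blocks_by_species, outgroup)
    group_trees: dict[str, list[GeneTree]] = {}
    for g in sorted(group_members):
        if external_trees is not None and g in external_trees:
            group_trees[g] = [gene_tree_from_newick(nwk)
                              for nwk in external_trees[g]]
            continue
        rows = ortho[ortho["outgroup_chromosome"] == g]
        cols = [f"{sp}|{c}" for sp, chroms in group_members[g].items()
                for c in chroms if f"{sp}|{c}" in ortho.columns]
        sub = rows[cols].copy()
        sub[OUTGROUP_TIP] = list(rows.index)
        group_trees[g] = build_gene_trees(sub, sequences, OUTGROUP_TIP,
                                          min_taxa=min_taxa)
    group_trees = {g: ts for g, ts in group_trees.items() if ts}
    members_used = {g: group_members[g] for g in group_trees}
    iteration = iterate_assignment(group_trees, members_used,
                                   max_rounds=max_rounds)

    # harmonise label names across species (columns sharing a lineage clade
    # in the consensus get one name), then recompute the consensus with
    # gene-tree concordance under the final names
    from .phylo import harmonize_labels
    col_rename = harmonize_labels(iteration.consensus)
    mapping = {(sp, chrom): col_rename.get(f"{sp}|{lab}", str(lab))
               for (sp, chrom), lab in iteration.mapping.items()}
    tipmap = {f"{sp}|{c}": f"{sp}|{l}" for (sp, c), l in mapping.items()}
    renamed_trees = [t.renamed(tipmap)
                     for ts in group_trees.values() for t in ts]
    labels = sorted(set().union(*(t.taxa for t in renamed_trees)))
    consensus = consensus_from_counts(quartet_counts(renamed_trees), labels,
                                      OUTGROUP_TIP, trees=renamed_trees)
    iteration.mapping = mapping
    iteration.consensus = consensus

    table = AssignmentTable()
    from .phylo import AssignmentRow
    for sp in sorted(complexes):
        lengths = complexes[sp].chromosome_lengths()
        for chrom in sorted(complexes[sp].chromosomes):
            label = mapping.get((sp, chrom))
            table.rows.append(AssignmentRow(
                sp, chrom, 0, lengths[chrom],
                label if label is not None else "unassigned", "phylogeny"))
    out_counts: dict[str, int] = {}
    for gr in outgroup.genes:
        out_counts[gr.chromosome] = out_counts.get(gr.chromosome, 0) + 1
    table = assign_complementarity(segments, table, out_counts)

    evidence_tags: dict[str, set] = {}
    for r in table.rows:
        evidence_tags.setdefault(str(r.label), set()).add(r.evidence)
    decisions = classify_phasing(iteration.consensus, evidence_tags)
    return SyntenyChannelResult(
        table=table, segments=segments, groups=groups,
        blocks_by_species=blocks_by_species, group_trees=group_trees,
        group_members=members_used, iteration=iteration,
        consensus=consensus, decisions=decisions,
        ortholog_table=ortho)


# ==========================================================================
# scoring helpers
# ==========================================================================

def combined_truth(truths: dict[str, GroundTruth],
                   complexes: dict[str, GenomeComplex]) -> AssignmentTable:
    table = AssignmentTable()
    for sp in sorted(truths):
        table.rows.extend(truth_table(truths[sp], complexes[sp]).rows)
    return table


def consensus_topology_matches(result: SyntenyChannelResult,
                               truth: AssignmentTable,
                               expected_newick: str,
                               outgroup_tip: str = OUTGROUP_TIP) -> bool:
    """Compare the channel consensus (arbitrary labels) with the generating
    topology: rename predicted labels to true lineages via per-species
    maximum-agreement matching, then compare unrooted bipartition sets."""
    maps = per_species_label_map(truth, result.table)
    rename = {}
    for col in result.consensus.labels:
        if col == outgroup_tip:
            continue
        sp, lab = col.split("|", 1)
        true_lab = maps.get(sp, {}).get(str(lab), str(lab))
        rename[col] = f"{sp}|{true_lab}"
    labels = set(rename.get(l, l) for l in result.consensus.labels)

    def normalise(side: frozenset, universe: set) -> frozenset:
        return side if outgroup_tip not in side else frozenset(universe - side)

    pred_bips = {normalise(frozenset(rename.get(t, t) for t in side), labels)
                 for side in result.consensus.topology.bipartition_sets()}
    exp_tree = gene_tree_from_newick(expected_newick)
    exp_bips = {normalise(side, set(exp_tree.taxa))
                for side in exp_tree.bipartitions}
    return exp_tree.taxa == frozenset(labels) and pred_bips == exp_bips


def control_metrics(result: SyntenyChannelResult, seed: int = 0) -> dict:
    """Concordance and mean quartet support under the true assignment vs
    the random-sorting control (same gene trees, shuffled labels)."""
    groups_list = [[(sp, c) for sp, chroms in members.items() for c in chroms]
                   for g, members in sorted(result.group_members.items())]
    control_table, shuffled = random_sort(result.table, groups_list, seed=seed)

    def consensus_for(mapping: dict) -> ConsensusTree:
        tipmap = {f"{sp}|{c}": f"{sp}|{l}" for (sp, c), l in mapping.items()}
        renamed = [t.renamed(tipmap) for ts in result.group_trees.values()
                   for t in ts]
        labels = sorted(set().union(*(t.taxa for t in renamed)))
        return consensus_from_counts(quartet_counts(renamed), labels,
                                     OUTGROUP_TIP, trees=renamed)

    true_cons = result.consensus
    ctrl_cons = consensus_for(shuffled)
    return {
        "true_concordance": true_cons.mean_concordance,
        "control_concordance": ctrl_cons.mean_concordance,
        "true_mean_q1": true_cons.mean_q1,
        "control_mean_q1": ctrl_cons.mean_q1,
        "true_mean_branch_length": float(np.mean([e.length for e in true_cons.edges]))
        if true_cons.edges else 0.0,
        "control_mean_branch_length": float(np.mean([e.length for e in ctrl_cons.edges]))
        if ctrl_cons.edges else 0.0,
        "control_table": control_table,
    }
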