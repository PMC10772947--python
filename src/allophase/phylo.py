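"""Karyotype projection, complementarity assignment, gene trees, quartet
consensus and the iterate-until-consistent subgenome assignment loop.

The phylogenetic channel proceeds outgroup-first: orthologous synteny
against the outgroup partitions each polyploid chromosome into karyotype
segments; segments sharing an outgroup chromosome form homoeologous
groups; per outgroup gene a neighbour-joining tree over the group's
chromosome copies is built; a quartet-consensus species/subgenome topology
is computed; and group members are relabelled until chromosomes occupying
the same phylogenetic position share a label (a fixed point of the loop).

Quartet supports: each internal branch of the consensus carries the
normalised frequencies (q1, q2, q3) of the three resolutions of its
surrounding quartets among the gene trees, a gene-tree concordance
percentage, and a coalescent-unit branch length -ln(1.5 (1 - q1)).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from functools import lru_cache
from itertools import combinations, permutations, product
from math import log

import numpy as np
import pandas as pd

OUTGROUP_TIP = "OUTGROUP"
_MAX_BRANCH = 10.0
_MAX_DIST = 5.0


# ==========================================================================
# gene trees
# ==========================================================================

@dataclass
class GeneTree:
    """Unrooted topology summarised as internal-edge bipartitions."""

    taxa: frozenset
    bipartitions: list            # list[frozenset]: one side per internal edge
    newick: str = ""

    def renamed(self, mapping: dict) -> "GeneTree":
        f = lambda t: mapping.get(t, t)
        return GeneTree(
            taxa=frozenset(f(t) for t in self.taxa),
            bipartitions=[frozenset(f(t) for t in b) for b in self.bipartitions],
            newick=self.newick)


def _jc_distance(a: str, b: str) -> float:
    diffs = sum(1 for x, y in zip(a, b) if x != y)
    p = diffs / len(a)
    if p >= 0.7495:
        return _MAX_DIST
    return -0.75 * log(1.0 - (4.0 / 3.0) * p)


def _bipartitions_from_skbio(tree, taxa: frozenset) -> list:
    bips = []
    for node in tree.postorder(include_self=False):
        if node.is_tip():
            continue
        side = frozenset(t.name for t in node.tips())
        if 2 <= len(side) <= len(taxa) - 2:
            bips.append(side)
    return bips


def nj_tree(sequences: dict[str, str]) -> GeneTree:
    """Neighbour-joining on pairwise JC distances (gap-free, equal length)."""
    from skbio import DistanceMatrix
    from skbio.tree import nj
    ids = sorted(sequences)
    n = len(ids)
    dm = np.zeros((n, n))
    for i, j in combinations(range(n), 2):
        d = _jc_distance(sequences[ids[i]], sequences[ids[j]])
        dm[i, j] = dm[j, i] = d
    tree = nj(DistanceMatrix(dm, ids))
    taxa = frozenset(ids)
    return GeneTree(taxa=taxa,
                    bipartitions=_bipartitions_from_skbio(tree, taxa),
                    newick=str(tree).strip())


def gene_tree_from_newick(newick: str) -> GeneTree:
    """Ingest an externally computed tree (topology only)."""
    from .io_formats import read_tree_string
    t = read_tree_string(newick)
    taxa = frozenset(l.taxon.label for l in t.leaf_node_iter())
    bips = []
    for node in t.preorder_node_iter():
        if node.parent_node is None or node.is_leaf():
            continue
        side = frozenset(l.taxon.label for l in node.leaf_iter())
        if 2 <= len(side) <= len(taxa) - 2:
            bips.append(side)
    return GeneTree(taxa=taxa, bipartitions=bips, newick=newick)


def build_gene_trees(matrix: pd.DataFrame, sequences: dict[str, str],
                     outgroup_column: str, min_taxa: int = 4,
                     ) -> list[GeneTree]:
    """One NJ tree per matrix row with >= ``min_taxa`` present cells
    (outgroup required).  Rows with unequal sequence lengths are skipped."""
    trees: list[GeneTree] = []
    skipped = 0
    for _, row in matrix.iterrows():
        cells = {col: row[col] for col in matrix.columns
                 if isinstance(row[col], str) and row[col]}
        if outgroup_column not in cells or len(cells) < min_taxa:
            continue
        seqs = {}
        ok = True
        for col, gid in cells.items():
            if gid not in sequences:
                ok = False
                break
            seqs[col] = sequences[gid]
        if not ok:
            skipped += 1
            continue
        lengths = {len(s) for s in seqs.values()}
        if len(lengths) != 1:
            skipped += 1
            continue
        trees.append(nj_tree(seqs))
    if skipped:
        warnings.warn(f"skipped {skipped} rows (missing/mismatched sequences)")
    return trees


# ==========================================================================
# quartets and topologies
# ==========================================================================

def quartet_resolution(bipartitions: list, quartet: tuple) -> int | None:
    """Resolution index of a sorted 4-tuple: 0 = q0q1|q2q3, 1 = q0q2|q1q3,
    2 = q0q3|q1q2; None if unresolved."""
    qs = set(quartet)
    for side in bipartitions:
        inter = qs & side
        if len(inter) == 2:
            if quartet[0] in inter:
                other = (inter - {quartet[0]}).pop()
                return {quartet[1]: 0, quartet[2]: 1, quartet[3]: 2}[other]
            other_pair = qs - inter
            first = quartet[0]
            mate = (other_pair - {first}).pop()
            return {quartet[1]: 0, quartet[2]: 1, quartet[3]: 2}[mate]
    return None


def quartet_counts(trees: list[GeneTree]) -> dict[tuple, np.ndarray]:
    """Aggregate resolution counts per sorted taxon quartet."""
    counts: dict[tuple, np.ndarray] = {}
    for t in trees:
        taxa = sorted(t.taxa)
        for quartet in combinations(taxa, 4):
            r = quartet_resolution(t.bipartitions, quartet)
            if r is None:
                continue
            if quartet not in counts:
                counts[quartet] = np.zeros(3)
            counts[quartet][r] += 1
    return counts


@lru_cache(maxsize=32)
def _enumerate_edge_lists(n: int) -> tuple:
    """All unrooted binary topologies over leaves 0..n-1 as edge tuples.

    Leaves are 0..n-1, internal nodes n and up; generated by stepwise
    addition, which yields each labelled topology exactly once."""
    if n < 3:
        raise ValueError("need >= 3 leaves")
    base = (((0, n), (1, n), (2, n)),)
    trees = base
    next_internal = n + 1
    for leaf in range(3, n):
        new_trees = []
        for edges in trees:
            for i, (u, v) in enumerate(edges):
                mid = next_internal
                new_edges = edges[:i] + edges[i + 1:] + (
                    (u, mid), (v, mid), (leaf, mid))
                new_trees.append(new_edges)
        trees = tuple(new_trees)
        next_internal += 1
    return trees


def _edge_bip_masks(edges: tuple, n: int) -> list[tuple]:
    """(leaf bitmask, edge) per edge; mask = leaves on the child side."""
    adj: dict[int, list[int]] = {}
    for u, v in edges:
        adj.setdefault(u, []).append(v)
        adj.setdefault(v, []).append(u)

    def side_mask(u, v):  # leaves reachable from u without crossing v
        stack, seen, mask = [u], {u, v}, 0
        while stack:
            x = stack.pop()
            if x < n:
                mask |= 1 << x
            for y in adj[x]:
                if y not in seen:
                    seen.add(y)
                    stack.append(y)
        return mask

    return [(side_mask(u, v), (u, v)) for u, v in edges], adj


def _mask_resolution(masks: list[int], quartet: tuple[int, int, int, int]) -> int:
    a, b, c, d = quartet
    qmask = (1 << a) | (1 << b) | (1 << c) | (1 << d)
    for m in masks:
        inter = m & qmask
        cnt = bin(inter).count("1")
        if cnt == 2:
            if inter & (1 << a):
                if inter & (1 << b):
                    return 0
                if inter & (1 << c):
                    return 1
                return 2
            # complement contains a
            if not inter & (1 << b):
                return 0
            if not inter & (1 << c):
                return 1
            return 2
    return 0  # binary trees over the full leaf set always resolve


@dataclass
class Topology:
    labels: tuple
    edges: tuple
    adjacency: dict = field(repr=False)
    bip_masks: list = field(repr=False)

    def bipartition_sets(self) -> list[frozenset]:
        n = len(self.labels)
        out = []
        for m, _ in self.bip_masks:
            side = frozenset(self.labels[i] for i in range(n) if m >> i & 1)
            if 2 <= len(side) <= n - 2:
                out.append(side)
        return out


def _make_topology(labels: tuple, edges: tuple) -> Topology:
    masks, adj = _edge_bip_masks(edges, len(labels))
    return Topology(labels=labels, edges=edges, adjacency=adj, bip_masks=masks)


def canonical_newick(topology: Topology, root_label: str,
                     rename: dict | None = None) -> str:
    """Deterministic newick string: rooted at ``root_label``'s pendant edge,
    children sorted lexicographically; the canonical form of a topology."""
    labels = topology.labels
    name = {i: (rename.get(labels[i], labels[i]) if rename else labels[i])
            for i in range(len(labels))}
    root_leaf = labels.index(root_label)
    adj = topology.adjacency

    def fmt(u, parent):
        if u < len(labels):
            return name[u]
        parts = sorted(fmt(v, u) for v in adj[u] if v != parent)
        return "(" + ",".join(parts) + ")"

    inner = adj[root_leaf][0]
    return f"({name[root_leaf]},{fmt(inner, root_leaf)});"


@dataclass
class EdgeSupport:
    side: frozenset               # labels on one side of the branch
    q1: float
    q2: float
    q3: float
    concordance: float | None     # percent of gene trees agreeing; None if n/a
    length: float                 # coalescent units, -ln(1.5(1-q1))


@dataclass
class ConsensusTree:
    labels: tuple
    topology: Topology
    edges: list[EdgeSupport]
    score: float
    newick: str
    tied: bool = False

    @property
    def mean_q1(self) -> float:
        return float(np.mean([e.q1 for e in self.edges])) if self.edges else 1.0

    @property
    def mean_concordance(self) -> float | None:
        vals = [e.concordance for e in self.edges if e.concordance is not None]
        return float(np.mean(vals)) if vals else None

    def annotated_newick(self) -> str:
        """Newick with [q1,q2,q3,concordance] comments per internal branch
        is approximated by a side-table; the plain topology string is
        returned here and branch annotations live in ``edges``."""
        return self.newick


@lru_cache(maxsize=8)
def _topology_tables(n: int) -> tuple:
    """(edge lists, quartet index map, resolution matrix) for n leaves.

    resolution matrix: topologies x quartets, entry = resolution index of
    that (sorted) leaf-index quartet in that topology.  Computed once per
    leaf count; consensus scoring is then a vectorised gather.
    """
    edge_lists = _enumerate_edge_lists(n)
    quartets = list(combinations(range(n), 4))
    qindex = {q: i for i, q in enumerate(quartets)}
    res = np.zeros((len(edge_lists), len(quartets)), dtype=np.int8)
    for ti, edges in enumerate(edge_lists):
        masks = [m for m, _ in _edge_bip_masks(edges, n)[0]]
        for qi, q in enumerate(quartets):
            res[ti, qi] = _mask_resolution(masks, q)
    return edge_lists, qindex, res


def _score_topologies(counts: dict[tuple, np.ndarray], labels: tuple,
                      ) -> tuple[tuple, float, bool]:
    """Best edge-list by total quartet agreement; exhaustive for <= 8
    labels, greedy stepwise addition above."""
    n = len(labels)
    idx = {l: i for i, l in enumerate(labels)}
    iquartets = []
    vecs = []
    for q, v in counts.items():
        if all(l in idx for l in q):
            iq = tuple(sorted(idx[l] for l in q))
            iquartets.append(iq)
            vecs.append(v)
    if not iquartets:
        raise ValueError("no quartet information over the requested labels")
    varr = np.array(vecs)

    def score_edges(edges):
        masks = [m for m, _ in _edge_bip_masks(edges, n)[0]]
        s = 0.0
        for qi, iq in enumerate(iquartets):
            r = _mask_resolution(masks, iq)
            s += varr[qi][r]
        return s

    if n <= 8:
        edge_lists, qindex, res = _topology_tables(n)
        cmat = np.zeros((len(qindex), 3))
        for iq, v in zip(iquartets, varr):
            cmat[qindex[iq]] += v
        scores = cmat[np.arange(len(qindex))[None, :], res].sum(axis=1)
        best_score = float(scores.max())
        tied_idx = np.nonzero(scores >= best_score - 1e-12)[0]
        tied = len(tied_idx) > 1
        if not tied:
            best_edges = edge_lists[int(tied_idx[0])]
        else:
            best_edges = min(
                (edge_lists[int(i)] for i in tied_idx),
                key=lambda e: canonical_newick(_make_topology(labels, e),
                                               labels[0]))
        return best_edges, best_score, tied
    # greedy stepwise addition
    edges = ((0, n), (1, n), (2, n))
    next_internal = n + 1
    for leaf in range(3, n):
        best, best_s = None, -1.0
        for i, (u, v) in enumerate(edges):
            mid = next_internal
            cand = edges[:i] + edges[i + 1:] + ((u, mid), (v, mid), (leaf, mid))
            s = score_edges(cand)
            if s > best_s:
                best, best_s = cand, s
        edges = best
        next_internal += 1
    return edges, score_edges(edges), False


def consensus_from_counts(counts: dict[tuple, np.ndarray], labels: list,
                          outgroup: str, trees: list[GeneTree] | None = None,
                          ) -> ConsensusTree:
    """Quartet-consensus topology with per-branch supports.

    ``counts`` maps sorted label quartets to resolution count vectors (as
    from :func:`quartet_counts`); ``trees`` (optional) adds per-branch
    gene-tree concordance percentages.
    """
    labels = tuple(sorted(labels))
    if len(labels) < 4:
        raise ValueError("need at least 4 labels (including the outgroup)")
    edges, score, tied = _score_topologies(counts, labels)
    if tied:
        warnings.warn("quartet-consensus tie; lexicographically smallest "
                      "canonical newick chosen")
    topo = _make_topology(labels, edges)
    n = len(labels)
    adj = topo.adjacency
    supports: list[EdgeSupport] = []

    def leafset(u, parent):
        stack, seen, out = [u], {u, parent}, []
        while stack:
            x = stack.pop()
            if x < n:
                out.append(x)
            for y in adj[x]:
                if y not in seen:
                    seen.add(y)
                    stack.append(y)
        return out

    for (u, v) in topo.edges:
        if u < n or v < n:
            continue  # pendant edges carry no quartet around them
        nu = [w for w in adj[u] if w != v]
        nv = [w for w in adj[v] if w != u]
        A, B = (leafset(w, u) for w in nu)
        C, D = (leafset(w, v) for w in nv)
        tally = np.zeros(3)
        for a, b, c, d in product(A, B, C, D):
            q = tuple(sorted((a, b, c, d)))
            lq = tuple(labels[i] for i in q)
            if lq not in counts:
                continue
            vec = counts[lq]
            # which resolution index corresponds to the species-tree pairing
            # {a,b}|{c,d} under the sorted order of q?
            pair = {a, b}
            if q[0] in pair:
                mate = (pair - {q[0]}).pop()
            else:
                mate = ({c, d} - {q[0]}).pop() if q[0] in {c, d} else None
            if mate is None:
                continue
            species_idx = {q[1]: 0, q[2]: 1, q[3]: 2}[mate]
            order = [species_idx] + [i for i in range(3) if i != species_idx]
            tally += vec[order]
        total = tally.sum()
        q1, q2, q3 = (tally / total) if total > 0 else (np.array([1.0, 0.0, 0.0]))
        side = frozenset(labels[i] for i in (A + B))
        conc = None
        if trees is not None:
            agree = denom = 0
            for t in trees:
                restricted = side & t.taxa
                other = t.taxa - restricted
                if len(restricted) < 2 or len(other) < 2:
                    continue
                denom += 1
                if any(b == restricted or b == other for b in t.bipartitions):
                    agree += 1
            conc = 100.0 * agree / denom if denom else None
        if q1 >= 1.0 - 1e-12:
            length = _MAX_BRANCH
        else:
            length = max(0.0, -log(1.5 * (1.0 - q1)))
        supports.append(EdgeSupport(side=side, q1=float(q1), q2=float(q2),
                                    q3=float(q3), concordance=conc,
                                    length=min(length, _MAX_BRANCH)))
    nwk = canonical_newick(topo, outgroup if outgroup in labels else labels[0])
    return ConsensusTree(labels=labels, topology=topo, edges=supports,
                         score=score, newick=nwk, tied=tied)


def consensus_tree(gene_trees: list[GeneTree], labels: list | None = None,
                   outgroup: str = OUTGROUP_TIP) -> ConsensusTree:
    """Quartet-consensus species/subgenome tree from gene trees."""
    if not gene_trees:
        raise ValueError("no gene trees supplied")
    if labels is None:
        labels = sorted(set().union(*(t.taxa for t in gene_trees)))
    if len(labels) > 12:
        raise ValueError("more than 12 labels; reduce the label set")
    counts = quartet_counts(gene_trees)
    return consensus_from_counts(counts, labels, outgroup, trees=gene_trees)


# ==========================================================================
# assignment table
# ==========================================================================

EVIDENCE_KINDS = ("ks", "phylogeny", "kmer", "complementarity", "random", "override")


@dataclass
class AssignmentRow:
    species: str
    chromosome: str
    start: int
    end: int
    label: object
    evidence: str


class AssignmentTable:
    """Per-chromosome-segment subgenome labels with evidence tags.

    Rows tile each chromosome in base coordinates (0-based half-open); the
    central mutable object of the pipeline.
    """

    def __init__(self, rows: list[AssignmentRow] | None = None):
        self.rows: list[AssignmentRow] = rows or []

    @classmethod
    def from_labels(cls, species: str, chrom_lengths: dict[str, int],
                    labels: dict[str, object], evidence: str) -> "AssignmentTable":
        rows = [AssignmentRow(species, c, 0, chrom_lengths[c], labels[c], evidence)
                for c in sorted(labels)]
        return cls(rows)

    def copy(self) -> "AssignmentTable":
        return AssignmentTable([AssignmentRow(**vars(r)) for r in self.rows])

    def chromosomes(self, species: str | None = None) -> set:
        return {(r.species, r.chromosome) for r in self.rows
                if species is None or r.species == species}

    def set_span(self, species: str, chromosome: str, start: int, end: int,
                 label: object, evidence: str) -> None:
        """Overwrite [start, end) on one chromosome, splitting rows."""
        new_rows = []
        for r in self.rows:
            if r.species != species or r.chromosome != chromosome \
                    or r.end <= start or end <= r.start:
                new_rows.append(r)
                continue
            if r.start < start:
                new_rows.append(AssignmentRow(r.species, r.chromosome,
                                              r.start, start, r.label, r.evidence))
            if end < r.end:
                new_rows.append(AssignmentRow(r.species, r.chromosome,
                                              end, r.end, r.label, r.evidence))
        new_rows.append(AssignmentRow(species, chromosome, start, end,
                                      label, evidence))
        self.rows = sorted(new_rows, key=lambda r: (r.species, r.chromosome, r.start))

    def label_at(self, species: str, chromosome: str, pos: int):
        for r in self.rows:
            if r.species == species and r.chromosome == chromosome \
                    and r.start <= pos < r.end:
                return r.label
        return None

    def majority_label(self, species: str, chromosome: str):
        best: dict[object, int] = {}
        for r in self.rows:
            if r.species == species and r.chromosome == chromosome:
                best[r.label] = best.get(r.label, 0) + (r.end - r.start)
        return max(sorted(best, key=str), key=lambda l: best[l]) if best else None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(r) for r in self.rows])

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "AssignmentTable":
        df = pd.read_csv(path, sep="\t", dtype={"label": str})
        return cls([AssignmentRow(r.species, r.chromosome, int(r.start),
                                  int(r.end), r.label, r.evidence)
                    for r in df.itertuples()])


# ==========================================================================
# karyotype mapping
# ==========================================================================

@dataclass
class KaryotypeSegment:
    species: str
    chromosome: str
    start_rank: int           # gene-order ranks, 1-based half-open [start, end)
    end_rank: int
    start: int                # base coordinates
    end: int
    outgroup_chromosome: str | None
    support: int
    subject_span: tuple[int, int]  # rank span on the outgroup chromosome


def map_karyotype(blocks, polyploid, min_anchors: int = 5,
                  species: str | None = None) -> list[KaryotypeSegment]:
    """Partition polyploid chromosomes into outgroup-labelled segments.

    ``blocks`` must be polyploid-vs-outgroup orthologous synteny with the
    polyploid on the query side.  Adjacent same-label segments merge;
    boundaries between different labels fall at the rank midpoint; a
    chromosome without anchors yields one unassigned segment.
    """
    sp = species or polyploid.species_id
    genes_by_chrom: dict[str, list] = {}
    for g in polyploid.genes:
        genes_by_chrom.setdefault(g.chromosome, []).append(g)
    for gl in genes_by_chrom.values():
        gl.sort(key=lambda g: g.order)
    chrom_lengths = polyploid.chromosome_lengths()
    by_chrom: dict[str, list] = {}
    for b in blocks:
        if b.score >= min_anchors:
            by_chrom.setdefault(b.query_chromosome, []).append(b)
    segments: list[KaryotypeSegment] = []
    for chrom in sorted(polyploid.chromosomes):
        genes = genes_by_chrom.get(chrom, [])
        n = len(genes)

        def rank_to_base(rank_boundary: int) -> int:
            # boundary before gene with order == rank_boundary
            if rank_boundary <= 1:
                return 0
            if rank_boundary > n:
                return chrom_lengths[chrom]
            prev_end = genes[rank_boundary - 2].end
            nxt_start = genes[rank_boundary - 1].start
            return (prev_end + nxt_start) // 2

        blks = sorted(by_chrom.get(chrom, []), key=lambda b: b.query_span)
        if not blks:
            warnings.warn(f"chromosome {chrom} has no orthologous anchors; "
                          "left unassigned")
            segments.append(KaryotypeSegment(
                sp, chrom, 1, n + 1, 0, chrom_lengths[chrom],
                None, 0, (0, 0)))
            continue
        merged: list[dict] = []
        for b in blks:
            if merged and merged[-1]["label"] == b.subject_chromosome:
                merged[-1]["end_rank"] = max(merged[-1]["end_rank"], b.query_span[1])
                merged[-1]["support"] += b.score
                s0, s1 = merged[-1]["sspan"]
                merged[-1]["sspan"] = (min(s0, b.subject_span[0]),
                                       max(s1, b.subject_span[1]))
            else:
                merged.append(dict(label=b.subject_chromosome,
                                   start_rank=b.query_span[0],
                                   end_rank=b.query_span[1],
                                   support=b.score, sspan=b.subject_span))
        # stretch boundaries: midpoints between neighbours, chromosome ends outside
        bounds = [1]
        for prev, nxt in zip(merged, merged[1:]):
            bounds.append((prev["end_rank"] + nxt["start_rank"] + 1) // 2)
        bounds.append(n + 1)
        for i, m in enumerate(merged):
            lo, hi = bounds[i], bounds[i + 1]
            segments.append(KaryotypeSegment(
                sp, chrom, lo, hi, rank_to_base(lo), rank_to_base(hi),
                m["label"], m["support"], m["sspan"]))
    return segments


# ==========================================================================
# homoeologous groups
# ==========================================================================

@dataclass
class HomoeologGroup:
    outgroup_chromosome: str
    members: list            # (species, chromosome, KaryotypeSegment)
    flagged: bool = False
    message: str = ""


def group_homoeologs(segments: list[KaryotypeSegment],
                     ploidies: dict[str, int]) -> list[HomoeologGroup]:
    """One group per outgroup chromosome; member counts checked against the
    declared number of subgenome copies per species (mismatches flagged,
    not fatal)."""
    by_out: dict[str, list] = {}
    for seg in segments:
        if seg.outgroup_chromosome is None:
            continue
        by_out.setdefault(seg.outgroup_chromosome, []).append(
            (seg.species, seg.chromosome, seg))
    groups = []
    for out_chrom in sorted(by_out):
        members = by_out[out_chrom]
        counts: dict[str, set] = {}
        for sp, chrom, _ in members:
            counts.setdefault(sp, set()).add(chrom)
        flagged = False
        msgs = []
        for sp, expected in ploidies.items():
            got = len(counts.get(sp, set()))
            if got != expected:
                flagged = True
                msgs.append(f"{sp}: {got} members, expected {expected}")
        groups.append(HomoeologGroup(out_chrom, members, flagged,
                                     "; ".join(msgs)))
    return groups


# ==========================================================================
# complementarity assignment of translocations
# ==========================================================================

def assign_complementarity(segments: list[KaryotypeSegment],
                           table: AssignmentTable,
                           outgroup_gene_counts: dict[str, int],
                           ) -> AssignmentTable:
    """Label translocated segments by synteny complementarity.

    A minor segment mapping to outgroup chromosome X is assigned the
    subgenome of the chromosome (same species) whose own coverage of X
    misses exactly the span the segment supplies — the two jointly
    reconstituting one intact outgroup chromosome.  Ambiguous or
    partner-less segments stay unassigned with a warning.
    """
    table = table.copy()
    # major outgroup label per chromosome (largest support)
    major: dict[tuple[str, str], str] = {}
    per_chrom: dict[tuple[str, str], list[KaryotypeSegment]] = {}
    for seg in segments:
        per_chrom.setdefault((seg.species, seg.chromosome), []).append(seg)
    for key, segs in per_chrom.items():
        labelled = [s for s in segs if s.outgroup_chromosome is not None]
        if labelled:
            major[key] = max(labelled, key=lambda s: s.support).outgroup_chromosome
    for seg in segments:
        if seg.outgroup_chromosome is None:
            continue
        key = (seg.species, seg.chromosome)
        if major.get(key) == seg.outgroup_chromosome:
            continue
        # translocated segment: find complementary partner
        target = seg.outgroup_chromosome
        n_out = outgroup_gene_counts.get(target, 0)
        scores: list[tuple[int, tuple[str, str]]] = []
        for other_key, m in major.items():
            if m != target or other_key == key or other_key[0] != seg.species:
                continue
            covered: set[int] = set()
            for s in per_chrom[other_key]:
                if s.outgroup_chromosome == target:
                    covered.update(range(s.subject_span[0], s.subject_span[1]))
            uncovered = set(range(1, n_out + 1)) - covered
            overlap = len(uncovered & set(range(seg.subject_span[0],
                                                seg.subject_span[1])))
            scores.append((overlap, other_key))
        scores.sort(key=lambda t: (-t[0], t[1]))
        if not scores or scores[0][0] == 0:
            warnings.warn(f"no complementary partner for segment on "
                          f"{seg.chromosome} [{seg.start},{seg.end})")
            continue
        if len(scores) > 1 and scores[0][0] == scores[1][0]:
            warnings.warn(f"ambiguous complementary partners for segment on "
                          f"{seg.chromosome}; left unassigned")
            continue
        partner = scores[0][1]
        label = table.majority_label(partner[0], partner[1])
        if label is None:
            continue
        table.set_span(seg.species, seg.chromosome, seg.start, seg.end,
                       label, "complementarity")
    return table


# ==========================================================================
# ortholog table / hierarchical gene matrix
# ==========================================================================

def build_ortholog_table(blocks_by_species: dict[str, list], outgroup,
                         ) -> pd.DataFrame:
    """Rows: outgroup genes in chromosomal order; columns: one per
    (species, polyploid chromosome); cells: syntenic ortholog gene ids.
    Label-independent precursor of the hierarchical gene matrix."""
    out_genes = sorted(outgroup.genes, key=lambda g: (g.chromosome, g.order))
    index = [g.gene_id for g in out_genes]
    data: dict[str, dict[str, str]] = {}
    best_score: dict[tuple[str, str], int] = {}
    for sp, blocks in sorted(blocks_by_species.items()):
        for b in blocks:
            col = f"{sp}|{b.query_chromosome}"
            data.setdefault(col, {})
            for a in b.anchors:
                key = (col, a.subject_gene)
                if key in best_score and best_score[key] >= b.score:
                    continue
                best_score[key] = b.score
                data[col][a.subject_gene] = a.query_gene
    frame = pd.DataFrame(index=index, columns=sorted(data))
    for col, cells in data.items():
        for out_gene, gid in cells.items():
            if out_gene in frame.index:
                frame.at[out_gene, col] = gid
    frame["outgroup_chromosome"] = [g.chromosome for g in out_genes]
    return frame


def build_gene_matrix(ortholog_table: pd.DataFrame, table: AssignmentTable,
                      gene_positions: dict[str, tuple[str, int]],
                      ) -> pd.DataFrame:
    """Hierarchical gene matrix: columns (species|subgenome label), rows
    outgroup genes.  Each cell takes the syntenic ortholog from the
    chromosome segment assigned to that column's subgenome; conflicts keep
    the first-seen (higher-score) gene and are logged."""
    cols = [c for c in ortholog_table.columns if c != "outgroup_chromosome"]
    out = {}
    conflicts = 0
    for col in cols:
        sp, chrom = col.split("|", 1)
        for out_gene, gid in ortholog_table[col].dropna().items():
            pos = gene_positions.get(gid)
            if pos is None:
                continue
            label = table.label_at(sp, chrom, pos[1])
            if label is None:
                continue
            tcol = f"{sp}|{label}"
            out.setdefault(tcol, {})
            if out_gene in out[tcol]:
                conflicts += 1
                continue
            out[tcol][out_gene] = gid
    if conflicts:
        warnings.warn(f"{conflicts} gene-matrix cell conflicts resolved by "
                      "first-come (higher block score)")
    frame = pd.DataFrame(index=ortholog_table.index, columns=sorted(out))
    for col, cells in out.items():
        for og, gid in cells.items():
            frame.at[og, col] = gid
    frame.insert(0, "outgroup_gene", list(ortholog_table.index))
    frame["outgroup_chromosome"] = ortholog_table["outgroup_chromosome"].values
    return frame


# ==========================================================================
# the iterate-until-consistent loop
# ==========================================================================

@dataclass
class IterationResult:
    mapping: dict                 # (species, chromosome) -> label
    consensus: ConsensusTree      # over species|label columns + outgroup
    group_consensus: dict         # outgroup chromosome -> ConsensusTree
    rounds: int
    converged: bool
    flagged_groups: list = field(default_factory=list)


def _rename_counts(qcounts: dict[tuple, np.ndarray], tipmap: dict,
                   ) -> dict[tuple, np.ndarray]:
    """Rename quartet keys through ``tipmap`` and permute resolution
    indices accordingly (index i-1 pairs the sorted quartet's first element
    with its (i+1)-th element)."""
    out: dict[tuple, np.ndarray] = {}
    for q, vec in qcounts.items():
        rename = {t: tipmap.get(t, t) for t in q}
        new_q = tuple(sorted(rename[t] for t in q))
        pos = {t: i for i, t in enumerate(new_q)}
        new_vec = np.zeros(3)
        for old_idx in range(1, 4):
            pair = {rename[q[0]], rename[q[old_idx]]}
            if new_q[0] in pair:
                mate = (pair - {new_q[0]}).pop()
            else:
                comp = set(new_q) - pair
                mate = (comp - {new_q[0]}).pop()
            new_vec[pos[mate] - 1] += vec[old_idx - 1]
        if new_q in out:
            out[new_q] += new_vec
        else:
            out[new_q] = new_vec
    return out


def _candidate_mappings(members_by_species: dict[str, list],
                        current: dict) -> list[dict]:
    """All per-species relabelings of a group's members (bijections over the
    labels those members currently hold)."""
    per_species = []
    for sp in sorted(members_by_species):
        chroms = sorted(members_by_species[sp])
        labels = sorted((current[(sp, c)] for c in chroms), key=str)
        opts = [dict(zip(((sp, c) for c in chroms), perm))
                for perm in sorted(set(permutations(labels)))]
        per_species.append(opts)
    out = []
    for combo in product(*per_species):
        m: dict = {}
        for d in combo:
            m.update(d)
        out.append(m)
    return out


def iterate_assignment(group_trees: dict[str, list[GeneTree]],
                       group_members: dict[str, dict[str, list[str]]],
                       initial: dict | None = None,
                       outgroup: str = OUTGROUP_TIP,
                       max_rounds: int = 10) -> IterationResult:
    """Relabel homoeologous-group members until chromosomes occupying the
    same phylogenetic position share a subgenome label.

    ``group_trees``: per outgroup chromosome, gene trees whose tips are
    "species|chromosome" plus the outgroup tip.  ``group_members``: per
    group, species -> member chromosome list.  The loop alternates between
    a quartet-consensus over current (species|label) columns and, per
    group, the member relabelling maximising agreement with it; ties keep
    the current labels (idempotence at the fixed point) and are flagged.
    """
    # per-species label alphabet sized by the widest group
    ploidy: dict[str, int] = {}
    for members in group_members.values():
        for sp, chroms in members.items():
            ploidy[sp] = max(ploidy.get(sp, 0), len(chroms))
    mapping: dict = {}
    if initial is not None:
        mapping.update(initial)
    else:
        for g in sorted(group_members):
            for sp, chroms in sorted(group_members[g].items()):
                for i, c in enumerate(sorted(chroms)):
                    mapping[(sp, c)] = str(i + 1)
    qcounts_by_group = {g: quartet_counts(ts) for g, ts in group_trees.items()}
    all_cols = sorted({f"{sp}|{l}" for (sp, _), l in mapping.items()}) + [outgroup]
    flagged: list[str] = []
    rounds = 0
    converged = False

    def tipmap_for(local: dict) -> dict:
        return {f"{sp}|{c}": f"{sp}|{l}" for (sp, c), l in local.items()}

    consensus = None
    for rounds in range(1, max_rounds + 1):
        label_counts: dict[tuple, np.ndarray] = {}
        tm = tipmap_for(mapping)
        for g, qc in qcounts_by_group.items():
            for q, vec in _rename_counts(qc, tm).items():
                if q in label_counts:
                    label_counts[q] += vec
                else:
                    label_counts[q] = vec.copy()
        consensus = consensus_from_counts(label_counts, all_cols, outgroup)
        tstar_res = {tuple(sorted(q)): _mask_resolution(
            [m for m, _ in consensus.topology.bip_masks],
            tuple(sorted(consensus.labels.index(l) for l in q)))
            for q in combinations(consensus.labels, 4)}

        def agreement(group: str, local: dict) -> float:
            tm_local = tipmap_for(local)
            renamed = _rename_counts(qcounts_by_group[group], tm_local)
            s = 0.0
            for q, vec in renamed.items():
                if q in tstar_res:
                    s += vec[tstar_res[q]]
            return s

        changed = False
        round_flags = []
        for g in sorted(group_members):
            members = group_members[g]
            current_local = {(sp, c): mapping[(sp, c)]
                             for sp, chroms in members.items() for c in chroms}
            best_local, best_s = current_local, agreement(g, current_local)
            tie = False
            for cand in _candidate_mappings(members, mapping):
                s = agreement(g, cand)
                if s > best_s + 1e-9:
                    best_local, best_s, tie = cand, s, False
                elif abs(s - best_s) <= 1e-9 and cand != best_local:
                    tie = True
            if best_local != current_local:
                mapping.update(best_local)
                changed = True
            if tie:
                round_flags.append(g)
        flagged = round_flags
        if not changed:
            converged = True
            break

    # final consensus + per-group consensus with final labels
    tm = tipmap_for(mapping)
    label_counts = {}
    renamed_trees: list[GeneTree] = []
    for g, ts in group_trees.items():
        renamed_trees.extend(t.renamed(tm) for t in ts)
    counts = quartet_counts(renamed_trees)
    consensus = consensus_from_counts(counts, all_cols, outgroup,
                                      trees=renamed_trees)
    group_consensus = {}
    for g, ts in group_trees.items():
        rts = [t.renamed(tm) for t in ts]
        labels = sorted(set().union(*(t.taxa for t in rts)))
        if len(labels) >= 4:
            group_consensus[g] = consensus_from_counts(
                quartet_counts(rts), labels, outgroup, trees=rts)
    return IterationResult(mapping=mapping, consensus=consensus,
                           group_consensus=group_consensus, rounds=rounds,
                           converged=converged, flagged_groups=flagged)


# ==========================================================================
# cross-species label harmonisation
# ==========================================================================

def harmonize_labels(consensus: ConsensusTree,
                     outgroup: str = OUTGROUP_TIP) -> dict:
    """Give columns of different species that represent the same progenitor
    lineage a shared subgenome name.

    Columns joined by a consensus clade containing at most one column per
    species form one lineage; remaining columns stay singletons.  Returns
    column -> harmonised label ("1", "2", ... in deterministic order).
    """
    cols = [l for l in consensus.labels if l != outgroup]
    universe = set(consensus.labels)
    clades = []
    for side in consensus.topology.bipartition_sets():
        clade = side if outgroup not in side else frozenset(universe - side)
        clade = frozenset(clade - {outgroup})
        species = [c.split("|", 1)[0] for c in clade]
        if len(clade) >= 2 and len(species) == len(set(species)):
            clades.append(clade)
    clades.sort(key=lambda c: (-len(c), sorted(c)))
    component: dict[str, int] = {}
    comps: list[frozenset] = []
    for clade in clades:
        if all(c not in component for c in clade):
            for c in clade:
                component[c] = len(comps)
            comps.append(clade)
    for c in cols:
        if c not in component:
            component[c] = len(comps)
            comps.append(frozenset({c}))
    order = sorted(range(len(comps)), key=lambda i: sorted(comps[i])[0])
    rank = {ci: str(i + 1) for i, ci in enumerate(order)}
    return {c: rank[component[c]] for c in cols}


# ==========================================================================
# absolute vs relative phasing
# ==========================================================================

@dataclass
class PhasingDecision:
    pair: tuple
    classification: str        # "absolute" | "relative"
    justification: str


DISTINGUISHING_EVIDENCE = frozenset({"ks", "kmer", "complementarity", "override"})


def classify_phasing(consensus: ConsensusTree,
                     evidence_tags: dict | None = None,
                     outgroup: str = OUTGROUP_TIP,
                     distinguishing=DISTINGUISHING_EVIDENCE,
                     ) -> list[PhasingDecision]:
    """Mark each subgenome-label pair "relative" or "absolute".

    A pair (X, Y) is relative iff swapping X and Y across every species
    column is an automorphism of the consensus topology (their positions
    are phylogenetically equivalent) and no non-phylogenetic evidence
    (``distinguishing`` tags in ``evidence_tags``) separates them.
    """
    evidence_tags = evidence_tags or {}
    cols = [l for l in consensus.labels if l != outgroup]
    by_label: dict[str, list[str]] = {}
    for c in cols:
        sp, lab = c.split("|", 1)
        by_label.setdefault(lab, []).append(sp)
    base_labels = sorted(by_label)
    root = outgroup if outgroup in consensus.labels else consensus.labels[0]
    base_newick = canonical_newick(consensus.topology, root)
    decisions = []
    for x, y in combinations(base_labels, 2):
        if sorted(by_label[x]) != sorted(by_label[y]):
            decisions.append(PhasingDecision(
                (x, y), "absolute",
                f"{x} and {y} occur in different species sets; positions "
                "not exchangeable"))
            continue
        rename = {}
        for sp in by_label[x]:
            rename[f"{sp}|{x}"] = f"{sp}|{y}"
            rename[f"{sp}|{y}"] = f"{sp}|{x}"
        swapped = canonical_newick(consensus.topology, root, rename=rename)
        if swapped != base_newick:
            decisions.append(PhasingDecision(
                (x, y), "absolute",
                f"swapping {x}/{y} changes the consensus topology"))
            continue
        ev = (evidence_tags.get(x, set()) | evidence_tags.get(y, set())) \
            & set(distinguishing)
        if ev:
            decisions.append(PhasingDecision(
                (x, y), "absolute",
                f"positions equivalent but {sorted(ev)} evidence separates them"))
        else:
            decisions.append(PhasingDecision(
                (x, y), "relative",
                f"{x} and {y} are topologically equivalent sisters with no "
                "non-phylogenetic evidence separating them"))
    return decisions
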