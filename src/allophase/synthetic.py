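"""Ground-truthed allopolyploid genome simulator.

Generates diploid progenitors from a shared ancestor along a declared
species tree (i.i.d. per-site substitutions, uniform over the three
alternative bases — JC-like, so closed-form expectations exist for tests),
adds lineage-specific repeat bursts into intergenic space only (gene-based
synteny stays intact), merges progenitors into (possibly nested)
allopolyploids with gene fractionation, and injects balanced/unbalanced
homoeologous exchanges and large-scale translocations.  Every surviving
gene's source lineage is tracked, so downstream phasing can be scored
against ground truth.

Coding sequences never contain internal stop codons: ancestral genes are
sampled from the 61 sense codons and a substitution that would create a
stop is redirected to a non-stop alternative base (the per-site mutation
probability is unchanged; only the conditional choice of the alternative
differs, which perturbs expectations only at second order).
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np

from .io_formats import GeneRecord, GenomeComplex, read_tree_string
from .ks import CODON_TABLE, STOP_CODONS

_SENSE_CODONS = sorted(c for c in CODON_TABLE if c not in STOP_CODONS)
_COMP = str.maketrans("ACGT", "TGCA")


class SimulationError(ValueError):
    pass


class ConflictError(SimulationError):
    """Two exchange events touched the same span."""


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


# --------------------------------------------------------------------------
# configuration
# --------------------------------------------------------------------------

@dataclass
class SimulationConfig:
    seed: int = 0
    n_chromosomes: int = 3
    genes_per_chromosome: int = 28
    gene_length: int = 300            # bases, multiple of 3
    intergenic_length: int = 200      # bases per gap
    divergence: float = 0.05          # per-branch substitution proportion
    repeat_motif_length: int = 50
    repeats_per_gap: int = 1          # lineage-specific copies per intergenic gap
    fractionation_rate: float = 0.05  # per-gene loss probability at each merger
    polyploid_divergence: float = 0.01  # extra divergence applied after each merger
    species_tree: str = "(((A,D),B),Out);"
    outgroup_label: str = "Out"

    def validate(self) -> None:
        if self.gene_length % 3 != 0:
            raise SimulationError("gene_length must be a multiple of 3")
        if not (0.0 <= self.divergence <= 0.3):
            raise SimulationError("divergence must lie in [0, 0.3]")
        if not (0.0 <= self.fractionation_rate < 1.0):
            raise SimulationError("fractionation_rate must lie in [0, 1)")
        # JC back-transform must not saturate on the deepest leaf-to-leaf path
        tree = read_tree_string(self.species_tree)
        depth = max(sum(1 for _ in leaf.ancestor_iter())
                    for leaf in tree.leaf_node_iter())
        p = 0.0
        for _ in range(2 * (depth + 1)):
            p = p + self.divergence - (4.0 / 3.0) * p * self.divergence
        if p >= 0.7495:
            raise SimulationError(
                "divergence saturates the JC correction on the deepest path")


# --------------------------------------------------------------------------
# internal genome representation
# --------------------------------------------------------------------------
# A gap is a list of [kind, seq] pieces, kind "bg" (background intergenic)
# or "rep" (inserted repeat copy); genes carry their CDS in coding
# orientation.  A chromosome with n genes has n+1 gaps.

@dataclass
class SimGene:
    anc: tuple[str, int]       # ancestral identity: (group, gene index)
    lineage: str               # true source progenitor lineage
    provenance: str            # native | balanced_he | unbalanced_he | translocation
    cds: str
    strand: str
    gene_id: str


@dataclass
class SimChromosome:
    group: str                 # homoeologous group, e.g. "1"
    subgenome: str             # host subgenome label, e.g. "A"
    name: str                  # rendered id, e.g. "1A"
    genes: list[SimGene]
    gaps: list[list[list]]     # list of gaps; gap = list of [kind, seq]


@dataclass
class SimGenome:
    species_id: str
    chromosomes: list[SimChromosome]
    ploidy_label: str = ""

    def chromosome(self, name: str) -> SimChromosome:
        for c in self.chromosomes:
            if c.name == name:
                return c
        raise KeyError(f"no chromosome {name} in {self.species_id}")


# --------------------------------------------------------------------------
# ground truth
# --------------------------------------------------------------------------

@dataclass
class TruthSegment:
    chromosome: str
    start_gene: int            # gene-order span, 0-based half-open
    end_gene: int
    start: int                 # base span, 0-based half-open
    end: int
    subgenome: str             # true source lineage
    provenance: str


@dataclass
class GroundTruth:
    species_id: str
    segments: list[TruthSegment]
    species_tree: str
    chromosome_labels: dict[str, str] = field(default_factory=dict)  # majority lineage

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("chromosome\tstart_gene\tend_gene\tstart\tend"
                     "\tsubgenome\tprovenance\n")
            for s in self.segments:
                fh.write(f"{s.chromosome}\t{s.start_gene}\t{s.end_gene}\t{s.start}"
                         f"\t{s.end}\t{s.subgenome}\t{s.provenance}\n")


# --------------------------------------------------------------------------
# mutation machinery
# --------------------------------------------------------------------------

_B2I = {"A": 0, "C": 1, "G": 2, "T": 3}
_I2B = "ACGT"


def _mutate_noncoding(seq: str, d: float, rng: np.random.Generator) -> str:
    if d <= 0 or not seq:
        return seq
    codes = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    lut = np.full(256, 255, dtype=np.uint8)
    for b, i in _B2I.items():
        lut[ord(b)] = i
    idx = lut[codes]
    mask = (rng.random(len(seq)) < d) & (idx != 255)
    n_mut = int(mask.sum())
    if n_mut:
        shift = rng.integers(1, 4, size=n_mut).astype(np.uint8)
        new_idx = (idx[mask] + shift) % 4
        out = codes.copy()
        enc = np.frombuffer("ACGT".encode(), dtype=np.uint8)
        out[np.nonzero(mask)[0]] = enc[new_idx]
        return out.tobytes().decode()
    return seq


def _mutate_cds(cds: str, d: float, rng: np.random.Generator) -> str:
    """Per-site substitutions that never create a stop codon."""
    if d <= 0:
        return cds
    seq = list(cds)
    hit = np.nonzero(rng.random(len(seq)) < d)[0]
    for pos in hit:
        codon_start = 3 * (pos // 3)
        codon = seq[codon_start:codon_start + 3]
        within = pos - codon_start
        orig = seq[pos]
        alts = []
        for b in "ACGT":
            if b == orig:
                continue
            trial = codon.copy()
            trial[within] = b
            if "".join(trial) not in STOP_CODONS:
                alts.append(b)
        if not alts:
            continue
        seq[pos] = alts[int(rng.integers(0, len(alts)))]
    return "".join(seq)


def _mutate_genome(sim: SimGenome, d: float, rng: np.random.Generator) -> None:
    for chrom in sim.chromosomes:
        for gene in chrom.genes:
            gene.cds = _mutate_cds(gene.cds, d, rng)
        for gap in chrom.gaps:
            for piece in gap:
                piece[1] = _mutate_noncoding(piece[1], d, rng)


def expected_pairwise_difference(d: float, n_branches: int) -> float:
    """Closed-form expected per-site difference between two sequences
    separated by ``n_branches`` branches of per-branch substitution
    proportion ``d`` (JC-like composition)."""
    p = 0.0
    for _ in range(n_branches):
        p = p + d - (4.0 / 3.0) * p * d
    return p


# --------------------------------------------------------------------------
# progenitor simulation
# --------------------------------------------------------------------------

def _random_cds(n_codons: int, rng: np.random.Generator) -> str:
    idx = rng.integers(0, len(_SENSE_CODONS), size=n_codons)
    return "".join(_SENSE_CODONS[i] for i in idx)


def _random_seq(n: int, rng: np.random.Generator) -> str:
    return "".join(_I2B[i] for i in rng.integers(0, 4, size=n))


def _ancestor_genome(cfg: SimulationConfig, rng: np.random.Generator) -> SimGenome:
    chroms = []
    for c in range(cfg.n_chromosomes):
        group = str(c + 1)
        genes = [SimGene(
            anc=(group, i), lineage="ancestor", provenance="native",
            cds=_random_cds(cfg.gene_length // 3, rng),
            strand="+" if rng.random() < 0.5 else "-",
            gene_id=f"anc_{group}_{i}")
            for i in range(cfg.genes_per_chromosome)]
        gaps = [[["bg", _random_seq(cfg.intergenic_length, rng)]]
                for _ in range(cfg.genes_per_chromosome + 1)]
        chroms.append(SimChromosome(group=group, subgenome="ancestor",
                                    name=f"{group}anc", genes=genes, gaps=gaps))
    return SimGenome(species_id="ancestor", chromosomes=chroms)


def _insert_repeats(sim: SimGenome, motif: str, per_gap: int,
                    rng: np.random.Generator) -> None:
    for chrom in sim.chromosomes:
        for gap in chrom.gaps:
            for _ in range(per_gap):
                total = sum(len(p[1]) for p in gap)
                pos = int(rng.integers(0, total + 1))
                # locate the piece containing pos and split it
                acc = 0
                for i, piece in enumerate(gap):
                    if acc + len(piece[1]) >= pos:
                        off = pos - acc
                        kind, seq = piece
                        gap[i:i + 1] = [[kind, seq[:off]], ["rep", motif],
                                        [kind, seq[off:]]]
                        break
                    acc += len(piece[1])


def simulate_progenitors(cfg: SimulationConfig,
                         ) -> tuple[dict[str, SimGenome], SimGenome]:
    """Evolve diploid progenitors (and the outgroup) from one ancestor.

    Returns (progenitors keyed by leaf label, outgroup genome).  All leaves
    descend from the same ancestral gene order, so orthologs share perfect
    synteny; each leaf then receives its own repeat motif inserted into
    every intergenic gap.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    ancestor = _ancestor_genome(cfg, rng)
    tree = read_tree_string(cfg.species_tree)
    leaves: dict[str, SimGenome] = {}

    def descend(node, genome: SimGenome):
        for child in node.child_nodes():
            g = copy.deepcopy(genome)
            _mutate_genome(g, cfg.divergence, rng)
            if child.is_leaf():
                label = child.taxon.label
                g.species_id = label
                for i, chrom in enumerate(g.chromosomes):
                    chrom.subgenome = label
                    chrom.name = f"{chrom.group}{label}"
                    for gene in chrom.genes:
                        gene.lineage = label
                        gene.gene_id = f"{label}_{gene.anc[0]}_{gene.anc[1]}"
                g.ploidy_label = label * 2
                leaves[label] = g
            else:
                descend(child, g)

    descend(tree.seed_node, ancestor)
    for label in sorted(leaves):
        motif = _random_seq(cfg.repeat_motif_length, rng)
        if cfg.repeats_per_gap > 0:
            _insert_repeats(leaves[label], motif, cfg.repeats_per_gap, rng)
    if cfg.outgroup_label not in leaves:
        raise SimulationError(
            f"species tree has no outgroup leaf {cfg.outgroup_label!r}")
    outgroup = leaves.pop(cfg.outgroup_label)
    return leaves, outgroup


# --------------------------------------------------------------------------
# polyploid assembly
# --------------------------------------------------------------------------

def simulate_allopolyploid(parents: list[SimGenome], species_id: str,
                           fractionation_rate: float, seed: int,
                           extra_divergence: float = 0.0) -> SimGenome:
    """Merge parent genomes (diploid or polyploid) into one allopolyploid.

    Each parent contributes one renamed copy of every chromosome; genes are
    then independently deleted with ``fractionation_rate``, and the whole
    merged genome optionally receives ``extra_divergence`` of post-merger
    substitutions.  Nested merges emulate e.g. AABB + DD -> AABBDD.
    """
    rng = np.random.default_rng(seed)
    chroms: list[SimChromosome] = []
    seen_subgenomes: list[str] = []
    for parent in parents:
        for chrom in parent.chromosomes:
            c = copy.deepcopy(chrom)
            for gene in c.genes:
                gene.gene_id = f"{species_id}|{c.name}|{gene.anc[0]}_{gene.anc[1]}"
            chroms.append(c)
        for sg in sorted({c.subgenome for c in parent.chromosomes}):
            seen_subgenomes.append(sg)
    if len(set(c.name for c in chroms)) != len(chroms):
        raise SimulationError("parents contribute clashing chromosome names")
    sim = SimGenome(species_id=species_id, chromosomes=chroms,
                    ploidy_label="".join(s * 2 for s in sorted(set(seen_subgenomes))))
    if fractionation_rate > 0:
        for chrom in sim.chromosomes:
            keep = rng.random(len(chrom.genes)) >= fractionation_rate
            new_genes, new_gaps = [], []
            pending = []
            for i, gene in enumerate(chrom.genes):
                if keep[i]:
                    new_gaps.append(sum(pending, []) + chrom.gaps[i])
                    pending = []
                    new_genes.append(gene)
                else:
                    pending.append(chrom.gaps[i])
            new_gaps.append(sum(pending, []) + chrom.gaps[-1])
            chrom.genes, chrom.gaps = new_genes, new_gaps
    if extra_divergence > 0:
        _mutate_genome(sim, extra_divergence, rng)
    return sim


# --------------------------------------------------------------------------
# exchange events
# --------------------------------------------------------------------------

@dataclass
class ExchangeEvent:
    kind: str                  # balanced | unbalanced | translocation
    donor_chromosome: str
    receiver_chromosome: str
    span: tuple[int, int]      # gene-order interval on the donor, half-open
    receiver_span: tuple[int, int] | None = None  # defaults to ``span``;
    # balanced events require equal gene counts on both sides


def _check_overlap(sim: SimGenome, chrom: str, span: tuple[int, int]) -> None:
    if not hasattr(sim, "_exchanged_spans"):
        sim._exchanged_spans = {}
    reg = sim._exchanged_spans
    for s, e in reg.get(chrom, []):
        if span[0] < e and s < span[1]:
            raise ConflictError(
                f"overlapping exchange events on {chrom} spans {span} and {(s, e)}")
    reg.setdefault(chrom, []).append(span)


def inject_exchange(sim: SimGenome, event: ExchangeEvent,
                    seed: int = 0) -> SimGenome:
    """Apply one exchange event in place (also returns the genome).

    balanced: reciprocal swap of equal-gene-count spans — outgroup synteny
    is preserved, so the event is invisible to synteny-based phasing.
    unbalanced: the receiver span is overwritten with a copy of the donor
    span.  translocation: the donor span moves to the end of the receiver,
    leaving a complementary gap on the donor.
    """
    donor = sim.chromosome(event.donor_chromosome)
    receiver = sim.chromosome(event.receiver_chromosome)
    lin_d = _majority_lineage(donor)
    lin_r = _majority_lineage(receiver)
    if lin_d == lin_r:
        raise SimulationError(
            "exchange chromosomes must belong to distinct true subgenomes")
    i, j = event.span
    ri, rj = event.receiver_span if event.receiver_span is not None else event.span
    if not (0 <= i < j <= len(donor.genes)):
        raise SimulationError(f"span {event.span} outside {donor.name} bounds")
    if event.kind in ("balanced", "unbalanced") and rj > len(receiver.genes):
        raise SimulationError(
            f"span {(ri, rj)} outside {receiver.name} bounds")
    if event.kind == "balanced" and (j - i) != (rj - ri):
        raise SimulationError("balanced exchange requires equal gene counts")
    _check_overlap(sim, donor.name, (i, j))
    if event.kind != "translocation":
        _check_overlap(sim, receiver.name, (ri, rj))

    if event.kind == "balanced":
        dg, rg = donor.genes[i:j], receiver.genes[ri:rj]
        donor.genes[i:j], receiver.genes[ri:rj] = rg, dg
        dgap, rgap = donor.gaps[i:j], receiver.gaps[ri:rj]
        donor.gaps[i:j], receiver.gaps[ri:rj] = rgap, dgap
        for g in donor.genes[i:j] + receiver.genes[ri:rj]:
            g.provenance = "balanced_he"
    elif event.kind == "unbalanced":
        moved = copy.deepcopy(donor.genes[i:j])
        for g in moved:
            g.gene_id += "@he"
            g.provenance = "unbalanced_he"
        receiver.genes[ri:rj] = moved
        receiver.gaps[ri:rj] = copy.deepcopy(donor.gaps[i:j])
    elif event.kind == "translocation":
        moved_genes = donor.genes[i:j]
        moved_gaps = donor.gaps[i:j]
        for g in moved_genes:
            g.provenance = "translocation"
        del donor.genes[i:j]
        del donor.gaps[i:j]
        n = len(receiver.genes)
        receiver.genes.extend(moved_genes)
        receiver.gaps = receiver.gaps[:n + 1] + moved_gaps
        # gap count: n+1 existing + m moved == new gene count + 1
    else:
        raise SimulationError(f"unknown exchange kind {event.kind!r}")
    return sim


def strip_repeats(sim: SimGenome, chromosome: str, span: tuple[int, int]) -> None:
    """Remove lineage-specific repeat insertions from the gaps of a
    gene-order span (emulates a region sparse in differential signatures)."""
    chrom = sim.chromosome(chromosome)
    i, j = span
    for gap in chrom.gaps[i:j + 1]:
        gap[:] = [p for p in gap if p[0] != "rep"] or [["bg", ""]]


def _majority_lineage(chrom: SimChromosome) -> str:
    counts: dict[str, int] = {}
    for g in chrom.genes:
        counts[g.lineage] = counts.get(g.lineage, 0) + 1
    return max(sorted(counts), key=lambda k: counts[k]) if counts else chrom.subgenome


# --------------------------------------------------------------------------
# rendering
# --------------------------------------------------------------------------

_TRANSLATE = {c: aa for c, aa in CODON_TABLE.items()}


def _translate(cds: str) -> str:
    return "".join(_TRANSLATE.get(cds[i:i + 3], "X") for i in range(0, len(cds), 3))


def render(sim: SimGenome, species_tree: str = "") -> tuple[GenomeComplex, GroundTruth]:
    """Materialise a structured genome into sequences + annotations + truth."""
    gc = GenomeComplex(species_id=sim.species_id, ploidy_label=sim.ploidy_label)
    segments: list[TruthSegment] = []
    chrom_labels: dict[str, str] = {}
    for chrom in sim.chromosomes:
        parts: list[str] = []
        pos = 0
        gene_bounds: list[tuple[int, int]] = []
        for idx, gene in enumerate(chrom.genes):
            gap_seq = "".join(p[1] for p in chrom.gaps[idx])
            parts.append(gap_seq)
            pos += len(gap_seq)
            gseq = gene.cds if gene.strand == "+" else revcomp(gene.cds)
            parts.append(gseq)
            gene_bounds.append((pos, pos + len(gseq)))
            pos += len(gseq)
        tail = "".join(p[1] for p in chrom.gaps[len(chrom.genes)])
        parts.append(tail)
        gc.chromosomes[chrom.name] = "".join(parts)
        for idx, gene in enumerate(chrom.genes):
            s, e = gene_bounds[idx]
            gc.genes.append(GeneRecord(
                chromosome=chrom.name, gene_id=gene.gene_id,
                start=s, end=e, strand=gene.strand, order=idx + 1,
                original_id=f"{gene.anc[0]}_{gene.anc[1]}"))
            gc.cds[gene.gene_id] = gene.cds
            gc.proteins[gene.gene_id] = _translate(gene.cds)
        # truth segments: run-length encode by (lineage, provenance)
        run_start = 0
        for idx in range(1, len(chrom.genes) + 1):
            if (idx == len(chrom.genes)
                    or (chrom.genes[idx].lineage, chrom.genes[idx].provenance)
                    != (chrom.genes[run_start].lineage, chrom.genes[run_start].provenance)):
                g0, g1 = chrom.genes[run_start], chrom.genes[idx - 1]
                segments.append(TruthSegment(
                    chromosome=chrom.name, start_gene=run_start, end_gene=idx,
                    start=gene_bounds[run_start][0] if run_start == 0 else gene_bounds[run_start][0],
                    end=gene_bounds[idx - 1][1],
                    subgenome=g0.lineage, provenance=g0.provenance))
                run_start = idx
        chrom_labels[chrom.name] = _majority_lineage(chrom)
    # extend first/last truth segments to the chromosome ends
    by_chrom: dict[str, list[TruthSegment]] = {}
    for s in segments:
        by_chrom.setdefault(s.chromosome, []).append(s)
    for chrom_name, segs in by_chrom.items():
        segs.sort(key=lambda s: s.start)
        segs[0].start = 0
        segs[-1].end = len(gc.chromosomes[chrom_name])
        for a, b in zip(segs, segs[1:]):
            mid = (a.end + b.start) // 2
            a.end = mid
            b.start = mid
    truth = GroundTruth(species_id=sim.species_id, segments=segments,
                        species_tree=species_tree, chromosome_labels=chrom_labels)
    gc.validate()
    return gc, truth
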