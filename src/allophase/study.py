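"""Benchmark studies exercising the whole toolkit on simulated complexes.

These routines drive the five preset scenarios end to end and measure the
properties the package is designed around: ground-truth recovery by both
evidence channels, topology recovery, the balanced-exchange discrepancy
between channels, the sparse-signature blind spot of the k-mer channel,
the random-sorting negative control, enrichment-score calibration, and
oracle equivalence of the three core algorithmic primitives.
"""

from __future__ import annotations

import random
import warnings
from dataclasses import dataclass, field

import numpy as np

from .evaluation import compare_assignments, label_accuracy
from .phylo import AssignmentTable
from .pipeline import (combined_truth, consensus_topology_matches,
                       control_metrics, run_kmer_channel, run_synteny_channel,
                       truth_table)
from .presets import RELATIVE_PAIRS, build_preset, expected_column_topology
from .synthetic import ExchangeEvent, inject_exchange, render, strip_repeats


def _spawn_seed(base: int, i: int, salt: int = 0) -> int:
    return (base * 100003 + 1009 * salt + i) % (2 ** 31)


# --------------------------------------------------------------------------
# preset recovery study (exchange-free)
# --------------------------------------------------------------------------

@dataclass
class PresetRun:
    preset: str
    seed: int
    kmer_accuracy: float
    synteny_accuracy: float
    topology_match: bool
    decisions_ok: bool
    control: dict
    n_windows: int
    n_discordant_significant: int
    n_chromosomes: int


def run_preset_once(preset: str, seed: int, alpha: float = 0.01) -> PresetRun:
    bundle = build_preset(preset, seed=seed)
    rel = RELATIVE_PAIRS[preset]
    truth_all = combined_truth(bundle.truths, bundle.complexes)

    # k-mer channel, per species
    kmer_accs = []
    n_windows = n_disc = 0
    for sp, gc in sorted(bundle.complexes.items()):
        res = run_kmer_channel(gc, bundle.groups[sp], bundle.ploidies[sp],
                               seed=seed, alpha=alpha)
        tt = truth_table(bundle.truths[sp], gc)
        kmer_accs.append((label_accuracy(res.table, tt, rel),
                          sum(len(c) for c in gc.chromosomes.values())))
        assigned = {c: l for c, l in res.cluster_labels.items()}
        for w in res.windows:
            n_windows += 1
            if w.enriched_label is not None \
                    and w.enriched_label != assigned[w.chromosome]:
                n_disc += 1
    kmer_acc = sum(a * w for a, w in kmer_accs) / sum(w for _, w in kmer_accs)

    # synteny / phylogeny channel, joint
    syn = run_synteny_channel(bundle.complexes, bundle.outgroup)
    syn_acc = label_accuracy(syn.table, truth_all, rel)
    topo_ok = consensus_topology_matches(
        syn, truth_all, expected_column_topology(preset))
    decisions_ok = _decisions_match_truth(syn, truth_all, rel)
    ctrl = control_metrics(syn, seed=seed)
    ctrl.pop("control_table")
    return PresetRun(
        preset=preset, seed=seed, kmer_accuracy=kmer_acc,
        synteny_accuracy=syn_acc, topology_match=topo_ok,
        decisions_ok=decisions_ok, control=ctrl, n_windows=n_windows,
        n_discordant_significant=n_disc,
        n_chromosomes=sum(len(gc.chromosomes)
                          for gc in bundle.complexes.values()))


def _decisions_match_truth(syn, truth_all: AssignmentTable,
                           relative_pairs) -> bool:
    """The channel must call exactly the declared sister pairs 'relative'
    (after renaming its arbitrary labels to true lineages)."""
    from .evaluation import per_species_label_map
    maps = per_species_label_map(truth_all, syn.table)
    # base label -> true lineage; consistent across species or the pair
    # cannot be judged
    expected_rel = {frozenset(map(str, p)) for p in relative_pairs}
    for d in syn.decisions:
        x, y = d.pair
        true_x = {m[str(x)] for m in maps.values() if str(x) in m}
        true_y = {m[str(y)] for m in maps.values() if str(y) in m}
        if len(true_x) != 1 or len(true_y) != 1:
            return False
        key = frozenset({true_x.pop(), true_y.pop()})
        if (d.classification == "relative") != (key in expected_rel):
            return False
    return True


@dataclass
class PresetStudy:
    runs: list = field(default_factory=list)

    def kmer_accuracy(self, preset: str) -> float:
        rs = [r for r in self.runs if r.preset == preset]
        return float(np.mean([r.kmer_accuracy for r in rs]))

    def synteny_accuracy(self, preset: str) -> float:
        rs = [r for r in self.runs if r.preset == preset]
        return float(np.mean([r.synteny_accuracy for r in rs]))

    def topology_matches(self, preset: str) -> int:
        return sum(r.topology_match for r in self.runs if r.preset == preset)

    def decisions_ok(self, preset: str) -> int:
        return sum(r.decisions_ok for r in self.runs if r.preset == preset)

    def control_separations(self) -> tuple[int, int, int]:
        """(concordance separations, q1 separations, total paired runs)."""
        conc = q1 = 0
        for r in self.runs:
            c = r.control
            conc += (c["true_concordance"] or 0) > (c["control_concordance"] or 0)
            q1 += c["true_mean_q1"] > c["control_mean_q1"]
        return conc, q1, len(self.runs)

    def branch_length_separations(self) -> int:
        return sum(r.control["true_mean_branch_length"]
                   > r.control["control_mean_branch_length"]
                   for r in self.runs)

    def discordant_window_fraction(self) -> float:
        disc = sum(r.n_discordant_significant for r in self.runs)
        tot = sum(r.n_windows for r in self.runs)
        return disc / tot if tot else 0.0


def run_preset_study(presets=None, n_seeds: int = 20, base_seed: int = 0,
                     ) -> PresetStudy:
    presets = presets or ["wheat", "oat", "poppy", "u_triangle", "strawberry"]
    study = PresetStudy()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for preset in presets:
            for i in range(n_seeds):
                study.runs.append(
                    run_preset_once(preset, _spawn_seed(base_seed, i)))
    return study


# --------------------------------------------------------------------------
# balanced-exchange discrepancy study (oat-like scenario)
# --------------------------------------------------------------------------

@dataclass
class BalancedHERun:
    seed: int
    kmer_flags_both: bool        # candidates on both partner chromosomes
    synteny_misses: bool         # synteny channel labels the spans wrongly
    localized: bool              # disagreement confined to the swapped spans


def run_balanced_he_once(seed: int, span_genes: int = 8,
                         window: int = 2000, step: int = 500) -> BalancedHERun:
    bundle = build_preset("oat", seed=seed)
    sim = bundle.sims["AS"]
    donor, receiver = "1C", "1D"
    nd = len(sim.chromosome(donor).genes)
    nr = len(sim.chromosome(receiver).genes)
    inject_exchange(sim, ExchangeEvent(
        "balanced", donor, receiver,
        (nd - span_genes, nd), (nr - span_genes, nr)))
    gc, truth = render(sim, bundle.config.species_tree)
    bundle.complexes["AS"] = gc
    bundle.truths["AS"] = truth
    tt = truth_table(truth, gc)

    kres = run_kmer_channel(gc, bundle.groups["AS"], 3, seed=seed,
                            window=window, step=step)
    flagged = {c.chromosome for c in kres.candidates}
    kmer_flags_both = donor in flagged and receiver in flagged

    syn = run_synteny_channel(bundle.complexes, bundle.outgroup)
    syn_sp = AssignmentTable([r for r in syn.table.rows if r.species == "AS"])
    syn_acc = label_accuracy(syn_sp, tt)
    synteny_misses = syn_acc < 1.0

    rep = compare_assignments(syn_sp, kres.table)
    bad = rep.segments[~rep.segments.agree]
    true_spans = {(s.chromosome, s.start, s.end) for s in truth.segments
                  if s.provenance == "balanced_he"}
    localized = not bad.empty
    for row in bad.itertuples():
        inside = any(row.chromosome == c
                     and row.start >= s - window and row.end <= e + window
                     for c, s, e in true_spans)
        localized = localized and inside
    # every swapped span must be hit by at least one disagreement
    for c, s, e in true_spans:
        hit = any(row.chromosome == c and row.end > s and row.start < e
                  for row in bad.itertuples())
        localized = localized and hit
    return BalancedHERun(seed=seed, kmer_flags_both=kmer_flags_both,
                         synteny_misses=synteny_misses, localized=localized)


def run_balanced_he_study(n_seeds: int = 20, base_seed: int = 0,
                          ) -> list[BalancedHERun]:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return [run_balanced_he_once(_spawn_seed(base_seed, i, salt=1))
                for i in range(n_seeds)]


# --------------------------------------------------------------------------
# sparse-signature blind spot study (Brassica-like scenario)
# --------------------------------------------------------------------------

@dataclass
class BlindspotRun:
    seed: int
    kmer_suppressed: bool        # no k-mer candidate over the moved span
    kmer_detects_without_strip: bool
    synteny_correct: bool        # complementarity assigns the span right


def run_blindspot_once(seed: int, span_genes: int = 10) -> BlindspotRun:
    def make(stripped: bool):
        bundle = build_preset("u_triangle", seed=seed)
        sim = bundle.sims["BC"]
        donor, receiver = "1B", "2C"
        n = len(sim.chromosome(donor).genes)
        span = (n - span_genes, n)
        if stripped:
            strip_repeats(sim, donor, span)
        inject_exchange(sim, ExchangeEvent("translocation", donor, receiver,
                                           span))
        gc, truth = render(sim, bundle.config.species_tree)
        bundle.complexes["BC"] = gc
        bundle.truths["BC"] = truth
        return bundle, gc, truth

    bundle, gc, truth = make(stripped=True)
    moved = [s for s in truth.segments if s.provenance == "translocation"]
    kres = run_kmer_channel(gc, bundle.groups["BC"], 2, seed=seed)

    def covers_moved(cands):
        return any(c.chromosome == s.chromosome
                   and c.end > s.start and c.start < s.end
                   for c in cands for s in moved)

    suppressed = not covers_moved(kres.candidates)
    syn = run_synteny_channel(bundle.complexes, bundle.outgroup)
    syn_sp = AssignmentTable([r for r in syn.table.rows if r.species == "BC"])
    tt = truth_table(truth, gc)
    # correct = the moved span carries the donor's label over (nearly) its
    # whole length — block boundaries have one-gene resolution — and the
    # genome-wide assignment is right
    donor_label = syn_sp.majority_label("BC", "1B")
    covered = 0
    for s in moved:
        for r in syn_sp.rows:
            if r.chromosome == s.chromosome and r.label == donor_label:
                covered += max(0, min(r.end, s.end) - max(r.start, s.start))
    span_len = sum(s.end - s.start for s in moved)
    synteny_correct = (covered >= 0.8 * span_len
                       and label_accuracy(syn_sp, tt) >= 0.98)

    bundle2, gc2, truth2 = make(stripped=False)
    kres2 = run_kmer_channel(gc2, bundle2.groups["BC"], 2, seed=seed)
    moved = [s for s in truth2.segments if s.provenance == "translocation"]
    detects = covers_moved(kres2.candidates)
    return BlindspotRun(seed=seed, kmer_suppressed=suppressed,
                        kmer_detects_without_strip=detects,
                        synteny_correct=synteny_correct)


def run_blindspot_study(n_seeds: int = 10, base_seed: int = 0,
                        ) -> list[BlindspotRun]:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return [run_blindspot_once(_spawn_seed(base_seed, i, salt=2))
                for i in range(n_seeds)]


# --------------------------------------------------------------------------
# oracle-equivalence studies
# --------------------------------------------------------------------------

def ks_oracle_study(n_pairs: int = 500, n_codons: int = 30, seed: int = 0,
                    ) -> dict:
    from .ks import compute_ks
    from .reference import GENETIC_CODE, ng86_reference_counts
    sense = sorted(c for c, a in GENETIC_CODE.items() if a != "*")
    r = random.Random(seed)
    max_diff = 0.0
    n_saturated = 0
    for _ in range(n_pairs):
        a = "".join(r.choice(sense) for _ in range(n_codons))
        b = "".join(r.choice(sense) for _ in range(n_codons))
        est = compute_ks(a, b)
        ref = ng86_reference_counts(a, b)
        for attr in ("S", "N", "Sd", "Nd", "ps", "pn"):
            max_diff = max(max_diff, abs(getattr(est, attr) - ref[attr]))
        # rates compared away from the saturation boundary, where the JC
        # transform amplifies last-bit differences without bound
        for mine, theirs, p in ((est.Ks, ref["Ks"], est.ps),
                                (est.Ka, ref["Ka"], est.pn)):
            if p <= 0.74:
                max_diff = max(max_diff, abs(mine - theirs))
            else:
                n_saturated += 1
    hand = compute_ks("AAA" * 9, "AAA" * 8 + "AAG").Ks
    return {"max_abs_diff": max_diff, "n_pairs": n_pairs,
            "n_saturated": n_saturated, "hand_example_ks": hand}


def chain_oracle_study(n_instances: int = 200, seed: int = 0) -> dict:
    from .io_formats import HitRecord
    from .reference import maximal_chains_reference
    from .synteny import chain_synteny
    r = random.Random(seed)
    agree = 0
    for _ in range(n_instances):
        n = r.randint(4, 12)
        coords = set()
        while len(coords) < n:
            coords.add((r.randint(1, 18), r.randint(1, 18)))
        anchors = sorted(coords)
        max_gap = r.choice([3, 5, 10, 25])
        min_anchors = r.choice([2, 3])
        hits = [HitRecord(f"q{q}_{s}", f"s{q}_{s}", 90.0, 100, 0, 0, 1, 100,
                          1, 100, 0.0, 10.0) for q, s in anchors]
        oq = {f"q{q}_{s}": ("qc", q) for q, s in anchors}
        os_ = {f"s{q}_{s}": ("sc", s) for q, s in anchors}
        blocks = chain_synteny(hits, oq, os_, min_anchors=min_anchors,
                               max_gap=max_gap)
        got = [[(oq[a.query_gene][1], os_[a.subject_gene][1])
                for a in b.anchors] for b in blocks]
        expected = maximal_chains_reference(anchors, max_gap, min_anchors)
        agree += got == expected
    return {"agreement_fraction": agree / n_instances,
            "n_instances": n_instances}


def consensus_oracle_study(n_instances: int = 200, seed: int = 0) -> dict:
    from .phylo import consensus_tree, gene_tree_from_newick
    from .reference import (_canonical_str, all_unrooted_newicks,
                            quartet_consensus_reference)
    labels5 = ["A", "B", "C", "D", "E"]
    labels6 = ["A", "B", "C", "D", "E", "F"]
    r = random.Random(seed)
    agree = 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for i in range(n_instances):
            labels = labels5 if i % 2 == 0 else labels6
            cands = all_unrooted_newicks(labels)
            nwks = [r.choice(cands) for _ in range(r.randint(3, 9))]
            trees = [gene_tree_from_newick(n) for n in nwks]
            cons = consensus_tree(trees, labels=labels, outgroup=labels[0])
            ref_nwk, ref_score = quartet_consensus_reference(nwks, labels)
            same_score = abs(cons.score - ref_score) < 1e-9
            same_top = cons.tied or _canonical_str(cons.newick) == ref_nwk
            agree += same_score and same_top
        # the worked example: 5 of 7 trees resolve the A+D pairing
        trees = [gene_tree_from_newick("((A,D),(B,Out));")] * 5 + \
                [gene_tree_from_newick("((A,B),(D,Out));")] * 2
        cons = consensus_tree(trees, outgroup="Out")
    return {"agreement_fraction": agree / n_instances,
            "n_instances": n_instances,
            "worked_example_q1": cons.edges[0].q1}
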