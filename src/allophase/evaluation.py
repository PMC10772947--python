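"""Validation machinery: random-sorting negative control, concordance
metrics, best-hit percentages, method-discrepancy reports, fractionation
profiles, and ground-truth scoring.

Subgenome names are arbitrary, so every comparison first matches the two
label sets by maximum agreement (Hungarian assignment on a base-pair
weighted confusion matrix).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .phylo import AssignmentRow, AssignmentTable, ConsensusTree, GeneTree
from .synteny import compute_hits


# --------------------------------------------------------------------------
# random-sorting negative control
# --------------------------------------------------------------------------

def random_sort(table: AssignmentTable, groups: list[list[tuple[str, str]]],
                seed: int = 0) -> tuple[AssignmentTable, dict]:
    """Permute chromosome labels uniformly within each homoeologous group.

    Produces extensive artificial exchanges while preserving each group's
    label multiset.  Control labels are renamed to integers ("1", "2", ...)
    to make their arbitrariness visible.  Returns (control table,
    (species, chromosome) -> control label).
    """
    rng = np.random.default_rng(seed)
    majors: dict[tuple[str, str], object] = {}
    for g in groups:
        for sp, chrom in g:
            lab = table.majority_label(sp, chrom)
            if lab is None:
                raise ValueError(f"group member {sp}:{chrom} has no assignment")
            majors[(sp, chrom)] = lab
    all_labels = sorted({str(l) for l in majors.values()})
    to_int = {l: str(i + 1) for i, l in enumerate(all_labels)}
    # a draw is only a control when it actually mixes lineages: a shuffle
    # in which every group applies the same per-species label bijection
    # (identity included) is a mere renaming, produces no artificial
    # exchanges, and is redrawn
    multi = [g for g in groups
             if any(len({str(majors[(sp, c)]) for sp2, c in g if sp2 == sp}) > 1
                    for sp in {m[0] for m in g})]
    can_vary = len(multi) >= 2
    shuffled: dict[tuple[str, str], str] = {}
    for _ in range(1000):
        shuffled = {}
        group_maps: list[dict] = []
        for g in groups:
            by_species: dict[str, list[tuple[str, str]]] = {}
            for sp, chrom in g:
                by_species.setdefault(sp, []).append((sp, chrom))
            gmap: dict[tuple[str, str], str] = {}
            for sp in sorted(by_species):
                members = sorted(by_species[sp], key=lambda t: t[1])
                labels = [majors[m] for m in members]
                perm = rng.permutation(len(labels))
                for m, i in zip(members, perm):
                    shuffled[m] = to_int[str(labels[i])]
                    gmap[(sp, str(majors[m]))] = shuffled[m]
            group_maps.append(gmap)
        merged: dict[tuple[str, str], str] = {}
        consistent = True
        for gmap in group_maps:
            for key, new in gmap.items():
                if merged.setdefault(key, new) != new:
                    consistent = False
        if not consistent or not can_vary:
            break
    chrom_ends: dict[tuple[str, str], int] = {}
    for r in table.rows:
        key = (r.species, r.chromosome)
        chrom_ends[key] = max(chrom_ends.get(key, 0), r.end)
    rows = [AssignmentRow(sp, chrom, 0, chrom_ends[(sp, chrom)],
                          shuffled[(sp, chrom)], "random")
            for (sp, chrom) in sorted(shuffled)]
    return AssignmentTable(rows), shuffled


# --------------------------------------------------------------------------
# concordance
# --------------------------------------------------------------------------

def concordance(gene_trees: list[GeneTree], reference: ConsensusTree,
                max_missing: int | None = None) -> dict:
    """Per-branch percentage of gene trees resolving each internal branch
    of the reference identically; invariant to gene-tree order and to the
    reference's rooting (bipartitions only)."""
    results = {}
    excluded = 0
    for edge in reference.edges:
        side = edge.side
        agree = denom = 0
        for t in gene_trees:
            if max_missing is not None and \
                    len(set(reference.labels) - t.taxa) > max_missing:
                excluded += 1
                continue
            restricted = side & t.taxa
            other = t.taxa - restricted
            if len(restricted) < 2 or len(other) < 2:
                continue
            denom += 1
            if any(b == restricted or b == other for b in t.bipartitions):
                agree += 1
        results[side] = 100.0 * agree / denom if denom else None
    vals = [v for v in results.values() if v is not None]
    return {"per_branch": results,
            "overall": float(np.mean(vals)) if vals else None,
            "excluded_trees": excluded}


# --------------------------------------------------------------------------
# best-hit quantification
# --------------------------------------------------------------------------

@dataclass
class BestHitReport:
    percent_of_all: pd.DataFrame      # subgenome x progenitor, denominator = all proteins
    percent_of_hit: pd.DataFrame      # denominator = proteins with any hit
    ambiguous: dict = field(default_factory=dict)  # subgenome -> tie count


def best_hit_fraction(subgenome_proteins: dict[object, dict[str, str]],
                      progenitor_proteomes: dict[str, dict[str, str]],
                      ) -> BestHitReport:
    """Percent of each subgenome's proteins whose best hit (by score) lies
    in each candidate progenitor; ties are counted as ambiguous and
    excluded from the percentages."""
    progs = sorted(progenitor_proteomes)
    pooled: dict[str, str] = {}
    owner: dict[str, str] = {}
    for p in progs:
        if not progenitor_proteomes[p]:
            raise ValueError(f"empty proteome for progenitor {p}")
        for gid, seq in progenitor_proteomes[p].items():
            key = f"{p}::{gid}"
            pooled[key] = seq
            owner[key] = p
    rows_all, rows_hit, ambiguous = {}, {}, {}
    for sub in sorted(subgenome_proteins, key=str):
        prots = subgenome_proteins[sub]
        if not prots:
            raise ValueError(f"empty proteome for subgenome {sub}")
        hits = compute_hits(prots, pooled, top_n=len(pooled))
        by_query: dict[str, list] = {}
        for h in hits:
            by_query.setdefault(h.query_gene, []).append(h)
        counts = {p: 0 for p in progs}
        ties = 0
        n_hit = 0
        for q, hs in by_query.items():
            best = max(h.bitscore for h in hs)
            best_owners = {owner[h.subject_gene] for h in hs
                           if h.bitscore == best}
            n_hit += 1
            if len(best_owners) > 1:
                ties += 1
                continue
            counts[best_owners.pop()] += 1
        n_all = len(prots)
        unamb = max(1, n_hit - ties)
        rows_all[sub] = {p: 100.0 * counts[p] / n_all for p in progs}
        rows_hit[sub] = {p: 100.0 * counts[p] / unamb for p in progs}
        ambiguous[sub] = ties
        if ties and ties == n_hit:
            warnings.warn(f"all hits ambiguous for subgenome {sub}")
    return BestHitReport(
        percent_of_all=pd.DataFrame(rows_all).T[progs],
        percent_of_hit=pd.DataFrame(rows_hit).T[progs],
        ambiguous=ambiguous)


# --------------------------------------------------------------------------
# label matching and assignment comparison
# --------------------------------------------------------------------------

def _overlap_matrix(a: AssignmentTable, b: AssignmentTable,
                    ) -> tuple[pd.DataFrame, list]:
    """Base-pair overlap between a-labels and b-labels on the finest common
    segmentation; also returns the segment list
    (species, chrom, start, end, label_a, label_b)."""
    chroms_a = a.chromosomes()
    chroms_b = b.chromosomes()
    if chroms_a != chroms_b:
        raise ValueError("assignment tables cover different chromosome sets")
    segments = []
    weights: dict[tuple, float] = {}
    rows_by_chrom_a: dict[tuple, list[AssignmentRow]] = {}
    rows_by_chrom_b: dict[tuple, list[AssignmentRow]] = {}
    for r in a.rows:
        rows_by_chrom_a.setdefault((r.species, r.chromosome), []).append(r)
    for r in b.rows:
        rows_by_chrom_b.setdefault((r.species, r.chromosome), []).append(r)
    for key in sorted(chroms_a):
        ra = sorted(rows_by_chrom_a[key], key=lambda r: r.start)
        rb = sorted(rows_by_chrom_b[key], key=lambda r: r.start)
        bounds = sorted({r.start for r in ra} | {r.end for r in ra}
                        | {r.start for r in rb} | {r.end for r in rb})
        for s, e in zip(bounds, bounds[1:]):
            mid = (s + e) // 2
            la = next((r.label for r in ra if r.start <= mid < r.end), None)
            lb = next((r.label for r in rb if r.start <= mid < r.end), None)
            if la is None or lb is None:
                continue
            segments.append((key[0], key[1], s, e, la, lb))
            weights[(str(la), str(lb))] = weights.get((str(la), str(lb)), 0) + (e - s)
    la_set = sorted({k[0] for k in weights})
    lb_set = sorted({k[1] for k in weights})
    mat = pd.DataFrame(0.0, index=la_set, columns=lb_set)
    for (la, lb), w in weights.items():
        mat.at[la, lb] = w
    return mat, segments


def match_labels(a: AssignmentTable, b: AssignmentTable) -> dict:
    """Maximum-agreement mapping of b's labels onto a's (Hungarian on the
    bp-weighted confusion matrix)."""
    mat, _ = _overlap_matrix(a, b)
    cost = -mat.to_numpy()
    n = max(cost.shape)
    padded = np.zeros((n, n))
    padded[:cost.shape[0], :cost.shape[1]] = cost
    ri, ci = linear_sum_assignment(padded)
    mapping = {}
    for i, j in zip(ri, ci):
        if i < len(mat.index) and j < len(mat.columns):
            mapping[mat.columns[j]] = mat.index[i]
    return mapping


@dataclass
class DiscrepancyReport:
    segments: pd.DataFrame      # finest common segmentation with agree flag
    percent_agreement: float    # bp-weighted
    label_mapping: dict


def compare_assignments(table_a: AssignmentTable, table_b: AssignmentTable,
                        ) -> DiscrepancyReport:
    """Segment-level agreement between two assignments after matching their
    (arbitrary) label sets by maximum agreement."""
    mapping = match_labels(table_a, table_b)
    _, segments = _overlap_matrix(table_a, table_b)
    recs = []
    agree_bp = total_bp = 0
    for sp, chrom, s, e, la, lb in segments:
        lb_mapped = mapping.get(str(lb), str(lb))
        ok = str(la) == lb_mapped
        agree_bp += (e - s) if ok else 0
        total_bp += e - s
        recs.append(dict(species=sp, chromosome=chrom, start=s, end=e,
                         label_a=str(la), label_b=str(lb),
                         label_b_mapped=lb_mapped, agree=ok))
    pct = 100.0 * agree_bp / total_bp if total_bp else 100.0
    return DiscrepancyReport(segments=pd.DataFrame(recs),
                             percent_agreement=pct, label_mapping=mapping)


def _restrict(table: AssignmentTable, species: str) -> AssignmentTable:
    return AssignmentTable([r for r in table.rows if r.species == species])


def per_species_label_map(truth: AssignmentTable, predicted: AssignmentTable,
                          ) -> dict[str, dict[str, str]]:
    """Per species, the maximum-agreement mapping predicted label -> true
    label.  Channel labels are arbitrary and only meaningful within one
    species, so matching never crosses species."""
    out: dict[str, dict[str, str]] = {}
    for sp in sorted({r.species for r in truth.rows}):
        out[sp] = match_labels(_restrict(truth, sp), _restrict(predicted, sp))
    return out


def label_accuracy(predicted: AssignmentTable, truth: AssignmentTable,
                   relative_pairs: list[tuple] = ()) -> float:
    """Fraction of base pairs whose matched predicted label equals the true
    label (per-species maximum-agreement matching); labels inside a
    declared "relative" sister pair are counted as interchangeable — their
    identities are arbitrary by construction."""
    maps = per_species_label_map(truth, predicted)
    equiv: dict[str, frozenset] = {}
    for x, y in relative_pairs:
        equiv[str(x)] = equiv[str(y)] = frozenset({str(x), str(y)})
    ok_bp = total_bp = 0
    for sp, mapping in maps.items():
        _, segments = _overlap_matrix(_restrict(truth, sp),
                                      _restrict(predicted, sp))
        for _, chrom, s, e, lt, lp in segments:
            lp_mapped = mapping.get(str(lp), str(lp))
            lt = str(lt)
            good = lp_mapped == lt or (lt in equiv and lp_mapped in equiv[lt])
            ok_bp += (e - s) if good else 0
            total_bp += e - s
    return ok_bp / total_bp if total_bp else 1.0


# --------------------------------------------------------------------------
# fractionation profile
# --------------------------------------------------------------------------

@dataclass
class FractionationProfile:
    frame: pd.DataFrame     # rows: window start index; columns: subgenome columns

    def column_means(self) -> pd.Series:
        return self.frame.mean(axis=0)


def fractionation_profile(gene_matrix: pd.DataFrame, window_genes: int = 50,
                          step_genes: int = 10) -> FractionationProfile:
    """Sliding-window retained-gene fraction per subgenome column along the
    outgroup gene order."""
    if window_genes < 1:
        raise ValueError("window_genes must be >= 1")
    if step_genes < 1:
        raise ValueError("step_genes must be >= 1")
    cols = [c for c in gene_matrix.columns
            if c not in ("outgroup_gene", "outgroup_chromosome")]
    present = gene_matrix[cols].notna().to_numpy()
    n = present.shape[0]
    starts = list(range(0, max(1, n - window_genes + 1), step_genes))
    data = {c: [] for c in cols}
    for s in starts:
        w = present[s:s + window_genes]
        for j, c in enumerate(cols):
            data[c].append(float(w[:, j].mean()))
    return FractionationProfile(pd.DataFrame(data, index=starts))
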