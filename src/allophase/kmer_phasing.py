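"""Differential-k-mer subgenome phasing and window-based exchange calling.

The channel works purely from the assembly plus a homoeologous-chromosome
grouping: count canonical k-mers per chromosome, keep k-mers that are
strongly enriched in one homoeolog per group (the differential set),
cluster chromosomes on those counts (k-means) to obtain provisional
subgenome labels, then scan fixed-step windows for runs of k-mers specific
to a *different* subgenome — candidate homoeologous exchanges.

Significance of a window's enrichment is a one-sided binomial tail against
the subgenome's genome-wide specific-k-mer density; exactly computable and
oracle-checkable, deliberately not a named test framework.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.stats import binom

_COMP = str.maketrans("ACGT", "TGCA")


class KmerError(ValueError):
    pass


class GroupingError(ValueError):
    pass


def canonical(kmer: str) -> str:
    rc = kmer.translate(_COMP)[::-1]
    return kmer if kmer <= rc else rc


# --------------------------------------------------------------------------
# 2-bit k-mer machinery (A=0 < C=1 < G=2 < T=3, so numeric order equals
# lexicographic order and min(code, rc_code) is the canonical form)
# --------------------------------------------------------------------------

_ENC_LUT = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate("ACGT"):
    _ENC_LUT[ord(_b)] = _i
    _ENC_LUT[ord(_b.lower())] = _i


def _canonical_codes(seq: str, k: int) -> tuple[np.ndarray, np.ndarray]:
    """(canonical 2-bit codes, validity mask) for every k-mer position."""
    codes = _ENC_LUT[np.frombuffer(seq.encode(), dtype=np.uint8)].astype(np.int64)
    n = len(codes) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=bool)
    fwd = np.zeros(n, dtype=np.int64)
    rev = np.zeros(n, dtype=np.int64)
    ok = np.ones(n, dtype=bool)
    for j in range(k):
        c = codes[j:n + j]
        ok &= c >= 0
        cc = np.where(c >= 0, c, 0)
        fwd = (fwd << 2) | cc
        rev = rev | ((3 - cc) << (2 * j))
    return np.minimum(fwd, rev), ok


def encode_kmer(kmer: str) -> int:
    """Canonical 2-bit integer code of a k-mer string."""
    canon = canonical(kmer.upper())
    code = 0
    for ch in canon:
        code = (code << 2) | int(_ENC_LUT[ord(ch)])
    return code


def decode_kmer(code: int, k: int) -> str:
    out = []
    for _ in range(k):
        out.append("ACGT"[code & 3])
        code >>= 2
    return "".join(reversed(out))


# --------------------------------------------------------------------------
# counting
# --------------------------------------------------------------------------

@dataclass
class KmerMatrix:
    """Per-chromosome canonical k-mer counts (keys are 2-bit codes)."""

    k: int
    counts: dict[str, dict[int, int]]          # chromosome -> code -> count
    chromosome_lengths: dict[str, int]

    def total(self, kmer: str | int) -> int:
        code = encode_kmer(kmer) if isinstance(kmer, str) else kmer
        return sum(c.get(code, 0) for c in self.counts.values())

    def string_counts(self, chromosome: str) -> dict[str, int]:
        return {decode_kmer(code, self.k): n
                for code, n in self.counts[chromosome].items()}

    @property
    def kmers(self) -> list[str]:
        codes = set()
        for c in self.counts.values():
            codes.update(c)
        return [decode_kmer(code, self.k) for code in sorted(codes)]


def count_kmers(chromosomes: dict[str, str], k: int) -> KmerMatrix:
    """Canonical k-mer counts per chromosome.

    ``k`` must be odd (even k makes a k-mer its own reverse complement,
    breaking canonicality) and at most 31.  Positions containing ambiguous
    bases are skipped.
    """
    if k % 2 == 0:
        raise KmerError(f"k must be odd, got {k}")
    if not (3 <= k <= 31):
        raise KmerError(f"k must lie in [3, 31], got {k}")
    counts: dict[str, dict[int, int]] = {}
    for chrom, seq in chromosomes.items():
        canon, ok = _canonical_codes(seq, k)
        vals, cnts = np.unique(canon[ok], return_counts=True)
        counts[chrom] = {int(v): int(c) for v, c in zip(vals, cnts)}
    return KmerMatrix(k=k, counts=counts,
                      chromosome_lengths={c: len(s) for c, s in chromosomes.items()})


# --------------------------------------------------------------------------
# differential selection
# --------------------------------------------------------------------------

@dataclass
class DifferentialKmerSet:
    k: int
    frame: pd.DataFrame                        # index: chromosome, columns: k-mers (raw counts)
    chromosome_lengths: dict[str, int]
    fold: dict[str, float] = field(default_factory=dict)   # per-k-mer min fold across groups
    labels: dict[str, object] = field(default_factory=dict)  # k-mer -> subgenome label

    @property
    def kmers(self) -> list[str]:
        return list(self.frame.columns)

    def normalized(self) -> pd.DataFrame:
        """Counts per megabase of chromosome."""
        scale = pd.Series({c: 1e6 / max(1, l)
                           for c, l in self.chromosome_lengths.items()})
        return self.frame.mul(scale.reindex(self.frame.index), axis=0)


def select_differential(matrix: KmerMatrix, homoeolog_groups: list[list[str]],
                        min_fold: float = 2.0, min_freq: int = 10,
                        ) -> DifferentialKmerSet:
    """Keep k-mers differentially abundant within homoeologous groups.

    Abundances are normalised per megabase.  A k-mer is retained when its
    best member exceeds ``min_fold`` times the next-best member in a
    majority of groups, and its total raw count is at least ``min_freq``.
    """
    for g in homoeolog_groups:
        if len(g) < 2:
            raise GroupingError(f"homoeolog group {g} has fewer than 2 members")
        for chrom in g:
            if chrom not in matrix.counts:
                raise GroupingError(f"unknown chromosome {chrom} in grouping")
    grouped = [c for g in homoeolog_groups for c in g]
    totals: dict[int, int] = {}
    for chrom in grouped:
        for km, n in matrix.counts[chrom].items():
            totals[km] = totals.get(km, 0) + n
    candidates = [km for km, n in totals.items() if n >= min_freq]
    norm_factor = {c: 1e6 / max(1, matrix.chromosome_lengths[c]) for c in grouped}
    eps = 1e-9
    kept: list[int] = []
    folds: dict[str, float] = {}
    need = len(homoeolog_groups) / 2.0
    for km in candidates:
        ok = 0
        min_fold_seen = float("inf")
        for g in homoeolog_groups:
            vals = sorted((matrix.counts[c].get(km, 0) * norm_factor[c] for c in g),
                          reverse=True)
            m1, m2 = vals[0], vals[1]
            fold = m1 / max(m2, eps)
            if m1 > 0 and fold >= min_fold:
                ok += 1
                min_fold_seen = min(min_fold_seen, fold)
        if ok > need:
            kept.append(km)
            folds[decode_kmer(km, matrix.k)] = min_fold_seen
    kept.sort()
    data = {decode_kmer(km, matrix.k): [matrix.counts[c].get(km, 0) for c in grouped]
            for km in kept}
    frame = pd.DataFrame(data, index=grouped, dtype=float)
    return DifferentialKmerSet(
        k=matrix.k, frame=frame,
        chromosome_lengths={c: matrix.chromosome_lengths[c] for c in grouped},
        fold=folds)


# --------------------------------------------------------------------------
# clustering / projection
# --------------------------------------------------------------------------

def _standardized(diffset: DifferentialKmerSet) -> np.ndarray:
    norm = diffset.normalized().to_numpy()
    mu = norm.mean(axis=0)
    sd = norm.std(axis=0)
    sd[sd == 0] = 1.0
    return (norm - mu) / sd


def cluster_subgenomes(diffset: DifferentialKmerSet, n_subgenomes: int,
                       seed: int = 0) -> tuple[dict[str, int], np.ndarray]:
    """Seeded k-means over standardised per-Mb counts.

    Returns (chromosome -> integer cluster label, hierarchical linkage for
    heatmap export).  Labels are arbitrary integers; name harmonisation
    happens downstream.  Also annotates the diffset: each k-mer is labelled
    with the cluster in which it is most abundant.
    """
    from sklearn.cluster import KMeans
    chroms = list(diffset.frame.index)
    if n_subgenomes < 2:
        raise KmerError("n_subgenomes must be >= 2")
    if len(chroms) < n_subgenomes:
        raise KmerError(
            f"{len(chroms)} chromosomes cannot form {n_subgenomes} clusters")
    X = _standardized(diffset)
    if np.allclose(X, X[0]):
        warnings.warn("all chromosomes identical on the differential set; "
                      "degenerate clustering")
        labels = {c: 0 for c in chroms}
        lk = linkage(np.zeros((len(chroms), 1)), method="average") \
            if len(chroms) > 1 else np.empty((0, 4))
        return labels, lk
    km = KMeans(n_clusters=n_subgenomes, random_state=seed, n_init=10)
    assigned = km.fit_predict(X)
    labels = {c: int(l) for c, l in zip(chroms, assigned)}
    lk = linkage(X, method="average")
    norm = diffset.normalized()
    for kmer in diffset.kmers:
        by_cluster: dict[int, float] = {}
        for c in chroms:
            by_cluster.setdefault(labels[c], 0.0)
            by_cluster[labels[c]] += norm.at[c, kmer]
        diffset.labels[kmer] = max(sorted(by_cluster), key=lambda l: by_cluster[l])
    return labels, lk


def project_pca(diffset: DifferentialKmerSet) -> pd.DataFrame:
    """First two principal components of the standardised count matrix."""
    from sklearn.decomposition import PCA
    chroms = list(diffset.frame.index)
    if len(chroms) < 3:
        raise KmerError("PCA projection requires at least 3 chromosomes")
    X = _standardized(diffset)
    if np.allclose(X, 0):
        warnings.warn("constant matrix: zero-variance PCA projection")
        return pd.DataFrame(np.zeros((len(chroms), 2)), index=chroms,
                            columns=["pc1", "pc2"])
    p = PCA(n_components=2, random_state=0)
    coords = p.fit_transform(X)
    return pd.DataFrame(coords, index=chroms, columns=["pc1", "pc2"])


# --------------------------------------------------------------------------
# window enrichment scan
# --------------------------------------------------------------------------

@dataclass
class WindowEnrichment:
    chromosome: str
    start: int
    end: int
    counts: dict                 # subgenome label -> specific-k-mer count in window
    expected: dict               # label -> expected count under uniform density
    ratio: dict                  # label -> observed / expected
    score: dict                  # label -> one-sided binomial tail probability
    enriched_label: object       # argmax-ratio label if significant, else None


def relabel_kmers(diffset: DifferentialKmerSet,
                  chromosome_labels: dict[str, object]) -> None:
    """Re-annotate k-mer labels with caller-supplied subgenome names."""
    norm = diffset.normalized()
    for kmer in diffset.kmers:
        by_label: dict[object, float] = {}
        for c in diffset.frame.index:
            lab = chromosome_labels[c]
            by_label[lab] = by_label.get(lab, 0.0) + norm.at[c, kmer]
        diffset.labels[kmer] = max(sorted(by_label, key=str),
                                   key=lambda l: by_label[l])


def scan_windows(chromosomes: dict[str, str], diffset: DifferentialKmerSet,
                 window: int, step: int, alpha: float = 0.01,
                 ) -> list[WindowEnrichment]:
    """Per-window counts of subgenome-specific k-mers with binomial scores.

    Expected counts use each label's genome-wide specific-k-mer density;
    a window is called enriched for the argmax-ratio label when its
    binomial tail probability is below ``alpha`` and the ratio exceeds 1.
    """
    if not (window >= step > 0):
        raise KmerError("require window >= step > 0")
    k = diffset.k
    label_of = dict(diffset.labels)
    labels = sorted({v for v in label_of.values() if v is not None}, key=str)
    if not labels:
        raise KmerError("differential set carries no k-mer labels; cluster first")
    lab_idx = {l: i for i, l in enumerate(labels)}
    code_list = sorted((encode_kmer(km), lab_idx[lab])
                       for km, lab in label_of.items() if lab is not None)
    code_arr = np.array([c for c, _ in code_list], dtype=np.int64)
    code_lab = np.array([l for _, l in code_list], dtype=np.int64)
    # per-chromosome per-position label hits
    per_chrom: dict[str, np.ndarray] = {}
    genome_positions = 0
    genome_hits = np.zeros(len(labels))
    for chrom, seq in chromosomes.items():
        canon, ok = _canonical_codes(seq, k)
        pos = np.searchsorted(code_arr, canon)
        pos_clip = np.minimum(pos, len(code_arr) - 1)
        hit = ok & (code_arr[pos_clip] == canon)
        arr = np.where(hit, code_lab[pos_clip], -1).astype(np.int8)
        per_chrom[chrom] = arr
        genome_positions += len(arr)
        for li in range(len(labels)):
            genome_hits[li] += int((arr == li).sum())
    density = genome_hits / max(1, genome_positions)
    out: list[WindowEnrichment] = []
    for chrom, seq in chromosomes.items():
        arr = per_chrom[chrom]
        L = len(seq)
        starts = list(range(0, max(1, L - window + 1), step)) if L > window \
            else [0]
        # cumulative hit counts per label for O(1) window sums
        cums = [np.concatenate([[0], np.cumsum(arr == li)]) for li in range(len(labels))]
        obs = np.zeros((len(starts), len(labels)), dtype=int)
        bounds = []
        for wi, s in enumerate(starts):
            e = min(L, s + window)
            npos_w = max(0, min(len(arr), e - k + 1) - s)
            bounds.append((s, e, npos_w))
            for li in range(len(labels)):
                lo, hi = s, min(len(arr), max(s, e - k + 1))
                obs[wi, li] = cums[li][hi] - cums[li][lo]
        for wi, (s, e, npos_w) in enumerate(bounds):
            counts = {}
            expected = {}
            ratio = {}
            score = {}
            for li, lab in enumerate(labels):
                o = int(obs[wi, li])
                exp = density[li] * npos_w
                counts[lab] = o
                expected[lab] = exp
                ratio[lab] = o / exp if exp > 0 else (float("inf") if o > 0 else 0.0)
                score[lab] = float(binom.sf(o - 1, max(1, npos_w), density[li])) \
                    if o > 0 else 1.0
            enriched = None
            if counts:
                best = max(labels, key=lambda l: (ratio[l], str(l)))
                if ratio[best] > 1.0 and score[best] < alpha:
                    enriched = best
            out.append(WindowEnrichment(
                chromosome=chrom, start=s, end=e, counts=counts,
                expected=expected, ratio=ratio, score=score,
                enriched_label=enriched))
    return out


# --------------------------------------------------------------------------
# exchange candidates
# --------------------------------------------------------------------------

@dataclass
class ExchangeCandidate:
    chromosome: str
    start: int
    end: int
    enriched_label: object
    assigned_label: object
    n_windows: int
    mean_enrichment: float


def call_exchanges(windows: list[WindowEnrichment],
                   assignment: dict[str, object],
                   min_consecutive: int = 3) -> list[ExchangeCandidate]:
    """Merge runs of discordantly enriched windows into exchange candidates.

    A candidate is a maximal run of >= ``min_consecutive`` consecutive
    windows on one chromosome, all significantly enriched for the same
    label, which differs from the chromosome's assigned subgenome.
    Overlapping windows merge into one span.
    """
    by_chrom: dict[str, list[WindowEnrichment]] = {}
    for w in windows:
        if w.chromosome not in assignment:
            raise KeyError(f"assignment missing chromosome {w.chromosome}")
        by_chrom.setdefault(w.chromosome, []).append(w)
    out: list[ExchangeCandidate] = []
    for chrom in sorted(by_chrom):
        ws = sorted(by_chrom[chrom], key=lambda w: w.start)
        own = assignment[chrom]
        run: list[WindowEnrichment] = []

        def flush():
            if len(run) >= min_consecutive:
                lab = run[0].enriched_label
                out.append(ExchangeCandidate(
                    chromosome=chrom,
                    start=run[0].start, end=run[-1].end,
                    enriched_label=lab, assigned_label=own,
                    n_windows=len(run),
                    mean_enrichment=float(np.mean([w.ratio[lab] for w in run]))))

        for w in ws:
            lab = w.enriched_label
            if lab is not None and lab != own:
                if run and run[-1].enriched_label == lab:
                    run.append(w)
                else:
                    flush()
                    run = [w]
            else:
                flush()
                run = []
        flush()
    return out


# --------------------------------------------------------------------------
# pair re-runs (for closely related subgenomes)
# --------------------------------------------------------------------------

def rerun_subset(matrix: KmerMatrix, homoeolog_groups: list[list[str]],
                 chromosome_labels: dict[str, object],
                 subgenome_pair: tuple, min_fold: float = 2.0,
                 min_freq: int = 10) -> DifferentialKmerSet:
    """Re-select differential k-mers over two subgenomes only.

    Restricting the contrast to a close pair recovers pair-specific k-mers
    that the full run discards because a third, more distant subgenome
    dominates the fold ranking.
    """
    a, b = subgenome_pair
    known = set(chromosome_labels.values())
    for lab in (a, b):
        if lab not in known:
            raise KmerError(f"unknown subgenome label {lab!r}")
    keep = {c for c, l in chromosome_labels.items() if l in (a, b)}
    groups = []
    for g in homoeolog_groups:
        sub = [c for c in g if c in keep]
        if len(sub) >= 2:
            groups.append(sub)
    if not groups:
        raise GroupingError("no homoeolog group retains both pair members")
    sub_matrix = KmerMatrix(
        k=matrix.k,
        counts={c: matrix.counts[c] for g in groups for c in g},
        chromosome_lengths={c: matrix.chromosome_lengths[c]
                            for g in groups for c in g})
    diffset = select_differential(sub_matrix, groups, min_fold, min_freq)
    if not diffset.kmers:
        warnings.warn("pair re-run found no differential k-mers")
    relabel_kmers(diffset, {c: chromosome_labels[c] for c in diffset.frame.index})
    return diffset
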