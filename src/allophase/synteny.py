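"""Gene-anchor synteny: hit generation, chaining, Ks integration, filtering.

A syntenic block is a maximal chain of gene-pair anchors whose gene-order
ranks increase strictly on the query and move strictly monotonically on the
subject (forward or reverse orientation), with consecutive anchors no more
than ``max_gap`` ranks apart on either axis.  Chains are extracted greedily
by repeated longest-chain dynamic programming, each hit used at most once.

The built-in hit scorer is a shared amino-acid 5-mer count (seed-and-count,
no alignment); externally computed 12-column hit tables are first-class
inputs for real data and take precedence over it.
"""

from __future__ import annotations

import statistics
import warnings
from dataclasses import dataclass, field

from .io_formats import HitRecord
from .ks import KsEstimate, KsError, compute_ks


@dataclass
class Anchor:
    query_gene: str
    subject_gene: str
    ks: float | None = None        # None: not yet computed or saturated
    ks_defined: bool = False


@dataclass
class SyntenicBlock:
    block_id: str
    query_chromosome: str
    subject_chromosome: str
    anchors: list[Anchor]
    orientation: str               # "forward" | "reverse"
    query_span: tuple[int, int]    # gene-order ranks, half-open
    subject_span: tuple[int, int]
    median_ks: float | None = None
    saturated: bool = False

    @property
    def score(self) -> int:
        return len(self.anchors)


# --------------------------------------------------------------------------
# built-in hit scorer
# --------------------------------------------------------------------------

def compute_hits(proteins_a: dict[str, str], proteins_b: dict[str, str],
                 top_n: int = 5, word_size: int = 5,
                 min_score: int = 4) -> list[HitRecord]:
    """Score protein pairs by shared amino-acid k-word count.

    For each query the ``top_n`` best subjects with at least ``min_score``
    shared words are reported.  Symmetric on identical inputs up to hit
    direction.  Empty sequences are skipped with a warning.
    """
    index: dict[str, list[str]] = {}
    subj_words: dict[str, set[str]] = {}
    for sid, seq in proteins_b.items():
        if not seq:
            warnings.warn(f"empty protein sequence for {sid}; skipped")
            continue
        words = {seq[i:i + word_size] for i in range(len(seq) - word_size + 1)}
        subj_words[sid] = words
        for w in words:
            index.setdefault(w, []).append(sid)
    hits: list[HitRecord] = []
    for qid, qseq in proteins_a.items():
        if not qseq:
            warnings.warn(f"empty protein sequence for {qid}; skipped")
            continue
        qwords = {qseq[i:i + word_size] for i in range(len(qseq) - word_size + 1)}
        scores: dict[str, int] = {}
        for w in qwords:
            for sid in index.get(w, ()):
                scores[sid] = scores.get(sid, 0) + 1
        ranked = sorted(
            ((s, sid) for sid, s in scores.items() if s >= min_score),
            key=lambda t: (-t[0], t[1]))[:top_n]
        for score, sid in ranked:
            denom = max(1, min(len(qseq), len(proteins_b[sid])) - word_size + 1)
            hits.append(HitRecord(
                query_gene=qid, subject_gene=sid,
                identity=round(100.0 * score / denom, 2),
                length=min(len(qseq), len(proteins_b[sid])),
                mismatches=0, gapopens=0,
                qstart=1, qend=len(qseq), sstart=1, send=len(proteins_b[sid]),
                evalue=0.0, bitscore=float(score)))
    return hits


# --------------------------------------------------------------------------
# chaining
# --------------------------------------------------------------------------

def _longest_chain(points: list[tuple[int, int, int]], max_gap: int,
                   reverse: bool) -> list[int]:
    """Longest strictly-monotone chain over (q, s, original-index) points.

    Consecutive anchors must satisfy 1 <= dq <= max_gap and
    1 <= |ds| <= max_gap with ds > 0 (forward) or ds < 0 (reverse).
    Deterministic: on ties the earliest predecessor in (q, s) order wins.
    """
    pts = sorted(points, key=lambda p: (p[0], p[1]))
    n = len(pts)
    best = [1] * n
    prev = [-1] * n
    for i in range(n):
        qi, si = pts[i][0], pts[i][1]
        for j in range(i):
            qj, sj = pts[j][0], pts[j][1]
            dq = qi - qj
            ds = si - sj if not reverse else sj - si
            if 1 <= dq <= max_gap and 1 <= ds <= max_gap:
                if best[j] + 1 > best[i]:
                    best[i] = best[j] + 1
                    prev[i] = j
    if n == 0:
        return []
    end = max(range(n), key=lambda i: (best[i], -i))
    chain = []
    while end != -1:
        chain.append(pts[end][2])
        end = prev[end]
    chain.reverse()
    return chain


def chain_synteny(hits: list[HitRecord],
                  gene_orders_q: dict[str, tuple[str, int]],
                  gene_orders_s: dict[str, tuple[str, int]],
                  min_anchors: int = 5, max_gap: int = 25,
                  block_prefix: str = "b") -> list[SyntenicBlock]:
    """Chain hits into syntenic blocks, per chromosome pair.

    ``gene_orders_*`` map gene id to (chromosome, order rank).  Hits whose
    genes are absent from the order tables raise ``KeyError`` naming the
    gene.  Each hit is used in at most one block; blocks shorter than
    ``min_anchors`` are dropped.
    """
    by_pair: dict[tuple[str, str], list[tuple[int, int, HitRecord]]] = {}
    for h in hits:
        if h.query_gene not in gene_orders_q:
            raise KeyError(f"gene {h.query_gene} absent from query order table")
        if h.subject_gene not in gene_orders_s:
            raise KeyError(f"gene {h.subject_gene} absent from subject order table")
        qc, qr = gene_orders_q[h.query_gene]
        sc, sr = gene_orders_s[h.subject_gene]
        by_pair.setdefault((qc, sc), []).append((qr, sr, h))
    blocks: list[SyntenicBlock] = []
    counter = 0
    for (qc, sc) in sorted(by_pair):
        pool = by_pair[(qc, sc)]
        while True:
            points = [(q, s, i) for i, (q, s, _) in enumerate(pool)]
            fwd = _longest_chain(points, max_gap, reverse=False)
            rev = _longest_chain(points, max_gap, reverse=True)
            chain, orient = (fwd, "forward") if len(fwd) >= len(rev) else (rev, "reverse")
            if len(chain) < min_anchors:
                break
            counter += 1
            chosen = [pool[i] for i in chain]
            qranks = [q for q, _, _ in chosen]
            sranks = [s for _, s, _ in chosen]
            blocks.append(SyntenicBlock(
                block_id=f"{block_prefix}{counter}",
                query_chromosome=qc, subject_chromosome=sc,
                anchors=[Anchor(h.query_gene, h.subject_gene) for _, _, h in chosen],
                orientation=orient,
                query_span=(min(qranks), max(qranks) + 1),
                subject_span=(min(sranks), max(sranks) + 1)))
            used = set(chain)
            pool = [p for i, p in enumerate(pool) if i not in used]
    return blocks


# --------------------------------------------------------------------------
# Ks integration
# --------------------------------------------------------------------------

def compute_block_ks(blocks: list[SyntenicBlock], cds_q: dict[str, str],
                     cds_s: dict[str, str]) -> dict[tuple[str, str], KsEstimate | None]:
    """Ks estimate per anchor pair; None where the pair cannot be aligned
    codon-wise (length mismatch / internal stop)."""
    out: dict[tuple[str, str], KsEstimate | None] = {}
    for blk in blocks:
        for a in blk.anchors:
            key = (a.query_gene, a.subject_gene)
            if key in out:
                continue
            try:
                out[key] = compute_ks(cds_q[a.query_gene], cds_s[a.subject_gene],
                                      a.query_gene, a.subject_gene)
            except KsError:
                out[key] = None
    return out


def integrate_blocks(blocks: list[SyntenicBlock],
                     ks_estimates: dict[tuple[str, str], KsEstimate | None],
                     ) -> list[SyntenicBlock]:
    """Attach per-anchor Ks and the per-block median; flag saturated blocks."""
    missing = []
    for blk in blocks:
        finite = []
        for a in blk.anchors:
            key = (a.query_gene, a.subject_gene)
            if key not in ks_estimates:
                missing.append(key)
                continue
            est = ks_estimates[key]
            if est is not None and est.Ks is not None:
                a.ks = est.Ks
                a.ks_defined = True
                finite.append(est.Ks)
            else:
                a.ks = None
                a.ks_defined = False
        if finite:
            blk.median_ks = statistics.median(finite)
            blk.saturated = False
        else:
            blk.median_ks = None
            blk.saturated = True
    if missing:
        raise KeyError(f"missing Ks estimates for anchor pairs: {missing[:5]}"
                       + ("..." if len(missing) > 5 else ""))
    return blocks


# --------------------------------------------------------------------------
# orthologous filtering
# --------------------------------------------------------------------------

def _read_override(path) -> dict[str, str]:
    actions = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2 or parts[1] not in ("keep", "drop"):
                raise ValueError(f"override line must be '<block_id>\\t(keep|drop)': {line!r}")
            actions[parts[0]] = parts[1]
    return actions


def filter_orthologous(blocks: list[SyntenicBlock], mode: str = "best_per_region",
                       multiplicity: int = 1, ks_cut: float | None = None,
                       region_side: str = "subject",
                       override_path=None) -> list[SyntenicBlock]:
    """Reduce integrated blocks to the orthologous set.

    mode "best_per_region": cluster blocks whose spans on ``region_side``
    overlap (per chromosome on that side) and keep the ``multiplicity``
    blocks with lowest median Ks (then highest anchor count) per cluster —
    the homoeolog multiplicity is the number of subgenome copies expected
    per region.  mode "ks_cut": drop blocks with median Ks above ``ks_cut``
    (saturated blocks always dropped).  The override file replaces the
    manual out-paralog curation step: per-block force keep/drop.
    """
    if mode == "best_per_region":
        if multiplicity < 1:
            raise ValueError("multiplicity must be >= 1")
        if region_side not in ("query", "subject"):
            raise ValueError("region_side must be 'query' or 'subject'")
        chrom_of = (lambda b: b.subject_chromosome) if region_side == "subject" \
            else (lambda b: b.query_chromosome)
        span_of = (lambda b: b.subject_span) if region_side == "subject" \
            else (lambda b: b.query_span)
        kept: list[SyntenicBlock] = []
        by_chrom: dict[str, list[SyntenicBlock]] = {}
        for b in blocks:
            by_chrom.setdefault(chrom_of(b), []).append(b)
        for chrom in sorted(by_chrom):
            group = sorted(by_chrom[chrom], key=lambda b: span_of(b))
            clusters: list[list[SyntenicBlock]] = []
            cur: list[SyntenicBlock] = []
            cur_end = -1
            for b in group:
                s, e = span_of(b)
                if cur and s < cur_end:
                    cur.append(b)
                    cur_end = max(cur_end, e)
                else:
                    if cur:
                        clusters.append(cur)
                    cur, cur_end = [b], e
            if cur:
                clusters.append(cur)
            for cl in clusters:
                ranked = sorted(cl, key=lambda b: (
                    b.median_ks if b.median_ks is not None else float("inf"),
                    -b.score, b.block_id))
                kept.extend(ranked[:multiplicity])
        result = sorted(kept, key=lambda b: b.block_id)
    elif mode == "ks_cut":
        if ks_cut is None:
            raise ValueError("ks_cut mode requires a threshold")
        result = [b for b in blocks
                  if b.median_ks is not None and b.median_ks <= ks_cut]
    else:
        raise ValueError(f"unknown filter mode {mode!r}")

    if override_path is not None:
        actions = _read_override(override_path)
        log = []
        by_id = {b.block_id: b for b in blocks}
        result_ids = {b.block_id for b in result}
        for bid, action in sorted(actions.items()):
            if action == "drop" and bid in result_ids:
                result = [b for b in result if b.block_id != bid]
                result_ids.discard(bid)
                log.append(f"override drop {bid}")
            elif action == "keep" and bid not in result_ids and bid in by_id:
                result.append(by_id[bid])
                result_ids.add(bid)
                log.append(f"override keep {bid}")
        if log:
            warnings.warn("; ".join(log))
        result = sorted(result, key=lambda b: b.block_id)
    return result


# --------------------------------------------------------------------------
# dot-plot export
# --------------------------------------------------------------------------

def export_dotplot(blocks: list[SyntenicBlock],
                   gene_orders_q: dict[str, tuple[str, int]],
                   gene_orders_s: dict[str, tuple[str, int]],
                   path, plot_path=None) -> None:
    """Write one TSV row per anchor (ranks + Ks + block id); optionally a
    Ks-coloured scatter image."""
    rows = []
    with open(path, "w") as fh:
        fh.write("query_chrom\tquery_rank\tsubject_chrom\tsubject_rank\tks\tblock_id\n")
        for blk in blocks:
            for a in blk.anchors:
                qr = gene_orders_q[a.query_gene][1]
                sr = gene_orders_s[a.subject_gene][1]
                ks = "" if a.ks is None else f"{a.ks:.4f}"
                fh.write(f"{blk.query_chromosome}\t{qr}\t{blk.subject_chromosome}"
                         f"\t{sr}\t{ks}\t{blk.block_id}\n")
                rows.append((qr, sr, a.ks))
    if plot_path is not None:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
        fig, ax = plt.subplots(figsize=(5, 5))
        xs = [r[0] for r in rows]
        ys = [r[1] for r in rows]
        cs = [r[2] if r[2] is not None else float("nan") for r in rows]
        sc = ax.scatter(xs, ys, c=cs, s=6, cmap="viridis")
        fig.colorbar(sc, label="Ks")
        ax.set_xlabel("query gene rank")
        ax.set_ylabel("subject gene rank")
        fig.tight_layout()
        fig.savefig(plot_path, dpi=120)
        plt.close(fig)
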