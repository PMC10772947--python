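"""Independent brute-force reference implementations used for
cross-validation of the optimised operations.

Everything here is deliberately naive — exhaustive enumeration and direct
recursion with no shared code paths or lookup tables — so agreement with
the main implementations is informative.  Only suitable for tiny inputs.
"""

from __future__ import annotations

from itertools import combinations, permutations
from math import log

# standard genetic code, built independently of allophase.ks
_BASES = "TCAG"
_AA = ("FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIMMTTTTNNKKSSRRVVVVAAAADDEEGGGG")
GENETIC_CODE = {}
_i = 0
for _b1 in _BASES:
    for _b2 in _BASES:
        for _b3 in _BASES:
            GENETIC_CODE[_b1 + _b2 + _b3] = _AA[_i]
            _i += 1


def ng86_reference_counts(cds_a: str, cds_b: str) -> dict:
    """NG86 site/difference counts and rates by direct per-codon pathway
    enumeration (no caching, no lookup tables)."""
    assert len(cds_a) == len(cds_b) and len(cds_a) % 3 == 0
    S = N = Sd = Nd = 0.0
    for i in range(0, len(cds_a), 3):
        ca, cb = cds_a[i:i + 3], cds_b[i:i + 3]
        if GENETIC_CODE[ca] == "*" or GENETIC_CODE[cb] == "*":
            continue
        # site counts
        for codon in (ca, cb):
            syn = 0
            for pos in range(3):
                for base in "ACGT":
                    if base == codon[pos]:
                        continue
                    mut = codon[:pos] + base + codon[pos + 1:]
                    if GENETIC_CODE[mut] == GENETIC_CODE[codon]:
                        syn += 1
            S += syn / 6.0           # averaged over the two codons
            N += (9 - syn) / 6.0
        # difference counts via pathway enumeration
        positions = [p for p in range(3) if ca[p] != cb[p]]
        if not positions:
            continue
        results = []
        for order in permutations(positions):
            cur, sd, nd, blocked = ca, 0, 0, False
            for pos in order:
                nxt = cur[:pos] + cb[pos] + cur[pos + 1:]
                if GENETIC_CODE[nxt] == "*" and nxt != cb:
                    blocked = True
                if GENETIC_CODE[nxt] == GENETIC_CODE[cur]:
                    sd += 1
                else:
                    nd += 1
                cur = nxt
            results.append((blocked, sd, nd))
        open_paths = [r for r in results if not r[0]] or results
        Sd += sum(r[1] for r in open_paths) / len(open_paths)
        Nd += sum(r[2] for r in open_paths) / len(open_paths)

    def jc(p):
        return None if p >= 0.75 else -0.75 * log(1 - 4 * p / 3)

    ps = Sd / S if S > 0 else 0.0
    pn = Nd / N if N > 0 else 0.0
    return {"S": S, "N": N, "Sd": Sd, "Nd": Nd, "ps": ps, "pn": pn,
            "Ks": jc(ps), "Ka": jc(pn)}


def maximal_chains_reference(anchors: list[tuple[int, int]], max_gap: int,
                             min_anchors: int) -> list[list[tuple[int, int]]]:
    """Iterated extraction of globally longest strictly-monotone chains by
    exhaustive depth-first enumeration of every valid chain.

    A chain is valid when consecutive (by query) anchors satisfy
    1 <= dq <= max_gap and 1 <= |ds| <= max_gap with a consistent sign of
    ds.  Ties are resolved by (longest, forward before reverse, smallest
    index tuple read from the last anchor backwards) — a fixed convention.
    Only usable for ~12 anchors or fewer.
    """
    chains_out: list[list[tuple[int, int]]] = []
    pool = sorted(anchors)

    def best_chain(pool_sorted):
        candidates: list[tuple[int, int, tuple]] = []  # (-len, orient, rev idx)

        def extend(idx_chain, sign):
            last = pool_sorted[idx_chain[-1]]
            extended = False
            for ci, cand in enumerate(pool_sorted):
                dq = cand[0] - last[0]
                ds = cand[1] - last[1]
                if 1 <= dq <= max_gap and 1 <= sign * ds <= max_gap:
                    extend(idx_chain + [ci], sign)
                    extended = True
            candidates.append((-len(idx_chain), 0 if sign == 1 else 1,
                               tuple(reversed(idx_chain))))

        for orient, sign in ((0, 1), (1, -1)):
            for start in range(len(pool_sorted)):
                extend([start], sign)
        if not candidates:
            return []
        best = min(candidates)
        return [pool_sorted[i] for i in reversed(best[2])]

    while True:
        best = best_chain(pool)
        if len(best) < min_anchors:
            break
        chains_out.append(best)
        remaining = list(best)
        new_pool = []
        for p in pool:
            if remaining and p == remaining[0]:
                remaining.pop(0)
            else:
                new_pool.append(p)
        pool = new_pool
    return chains_out


def _newick_quartet(nwk: str, quartet: tuple) -> int | None:
    """Resolution of a 4-taxon subset in a newick string by splitting on
    top-level commas recursively (independent of the tree classes)."""

    def parse(s):
        if not s.startswith("("):
            return s
        inner = s[1:-1]
        depth = 0
        parts, cur = [], ""
        for ch in inner:
            if ch == "(":
                depth += 1
            if ch == ")":
                depth -= 1
            if ch == "," and depth == 0:
                parts.append(cur)
                cur = ""
            else:
                cur += ch
        parts.append(cur)
        return [parse(p) for p in parts]

    def leaves(t):
        if isinstance(t, str):
            return [t]
        out = []
        for c in t:
            out.extend(leaves(c))
        return out

    def clades(t, acc):
        if isinstance(t, str):
            return
        acc.append(frozenset(leaves(t)))
        for c in t:
            clades(c, acc)

    tree = parse(nwk.rstrip(";").strip())
    acc: list[frozenset] = []
    clades(tree, acc)
    qs = set(quartet)
    for clade in acc:
        inter = set(clade & qs)
        if len(inter) == 2:
            a = quartet[0]
            if a in inter:
                other = (inter - {a}).pop()
            else:
                other = (qs - inter - {a}).pop()
            return {quartet[1]: 0, quartet[2]: 1, quartet[3]: 2}[other]
    return None


def all_unrooted_newicks(labels: list[str]) -> list[str]:
    """Every unrooted binary topology over the labels, via the bijection
    with rooted binary trees over all labels but the first (root the
    unrooted tree at the first label's pendant edge)."""
    labels = list(labels)
    first, rest = labels[0], labels[1:]
    if len(labels) < 4:
        return ["(" + ",".join(labels) + ");"]

    def grow(struct, leaf):
        # insert leaf on every edge of the rooted struct, incl. above root
        results = [[struct, leaf]]
        if not isinstance(struct, str):
            for i, child in enumerate(struct):
                for sub in grow(child, leaf):
                    results.append(struct[:i] + [sub] + struct[i + 1:])
        return results

    structs = [[rest[0], rest[1]]]
    for leaf in rest[2:]:
        structs = [s2 for s in structs for s2 in grow(s, leaf)]

    def fmt(t):
        if isinstance(t, str):
            return t
        return "(" + ",".join(fmt(c) for c in t) + ")"

    return [f"({first},{fmt(s)});" for s in structs]


def quartet_consensus_reference(gene_tree_newicks: list[str],
                                labels: list[str]) -> tuple[str, float]:
    """Best topology by exhaustive enumeration + direct quartet scoring.

    Returns (winning newick, score).  Ties are broken by the smallest
    newick string after canonical child sorting.
    """
    quartets = list(combinations(sorted(labels), 4))
    counts = {q: [0, 0, 0] for q in quartets}
    for nwk in gene_tree_newicks:
        for q in quartets:
            r = _newick_quartet(nwk, q)
            if r is not None:
                counts[q][r] += 1
    best_nwk, best_score = None, -1.0
    for cand in all_unrooted_newicks(sorted(labels)):
        s = 0.0
        for q in quartets:
            r = _newick_quartet(cand, q)
            if r is not None:
                s += counts[q][r]
        key = _canonical_str(cand)
        if s > best_score or (s == best_score and key < _canonical_str(best_nwk)):
            best_nwk, best_score = cand, s
    return _canonical_str(best_nwk), best_score


def _canonical_str(nwk: str) -> str:
    """Canonical rooted-newick string: children sorted recursively."""

    def parse(s):
        if not s.startswith("("):
            return s
        inner = s[1:-1]
        depth = 0
        parts, cur = [], ""
        for ch in inner:
            if ch == "(":
                depth += 1
            if ch == ")":
                depth -= 1
            if ch == "," and depth == 0:
                parts.append(cur)
                cur = ""
            else:
                cur += ch
        parts.append(cur)
        return [parse(p) for p in parts]

    def fmt(t):
        if isinstance(t, str):
            return t
        return "(" + ",".join(sorted(fmt(c) for c in t)) + ")"

    return fmt(parse(nwk.rstrip(";").strip())) + ";"
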