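"""Synonymous/nonsynonymous substitution rates between coding sequences.

Implements the Nei–Gojobori (NG86) counting method with Jukes–Cantor
correction.  Synonymous site fractions come from the three single-base
neighbours of each codon (changes into stop codons count as nonsynonymous,
so S + N always equals 3 x aligned codons).  Codons differing at more than
one position are resolved by averaging the synonymous/nonsynonymous
difference counts over all minimal mutational pathways, excluding pathways
that pass through a stop codon (if every pathway is blocked, all are used).

Ks/Ka are reported as ``None`` when the JC correction saturates
(proportion of differences >= 3/4).
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from itertools import permutations
from math import log

BASES = "TCAG"

# standard genetic code, indexed by codon string
CODON_TABLE = {
    t1 + t2 + t3: aa
    for t1, row in zip(
        BASES,
        [
            "FFLLSSSSYY**CC*W",
            "LLLLPPPPHHQQRRRR",
            "IIMMTTTTNNKKSSRR",
            "VVVVAAAADDEEGGGG",
        ],
    )
    for t2, quad in zip(BASES, [row[i:i + 4] for i in range(0, 16, 4)])
    for t3, aa in zip(BASES, quad)
}

STOP_CODONS = frozenset(c for c, aa in CODON_TABLE.items() if aa == "*")


class KsError(ValueError):
    """Invalid input to the substitution-rate computation."""


@dataclass
class KsEstimate:
    """NG86 counts and JC-corrected rates for one aligned CDS pair."""

    query_gene: str
    subject_gene: str
    S: float       # synonymous sites (average of the two sequences)
    N: float       # nonsynonymous sites
    Sd: float      # observed synonymous differences
    Nd: float      # observed nonsynonymous differences
    ps: float
    pn: float
    Ks: float | None
    Ka: float | None

    @property
    def saturated(self) -> bool:
        return self.Ks is None


def _syn_site_fraction(codon: str) -> float:
    """Fraction of the 9 possible single-base changes that are synonymous."""
    if codon in STOP_CODONS:
        raise KsError(f"stop codon {codon} has no site counts")
    aa = CODON_TABLE[codon]
    syn = 0
    for pos in range(3):
        for b in "ACGT":
            if b == codon[pos]:
                continue
            alt = codon[:pos] + b + codon[pos + 1:]
            if CODON_TABLE[alt] == aa:
                syn += 1
    return syn / 3.0


_SYN_SITES = {c: _syn_site_fraction(c) for c in CODON_TABLE if c not in STOP_CODONS}


@lru_cache(maxsize=None)
def _pair_differences(c1: str, c2: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) differences between two codons.

    Averaged over minimal mutational pathways; pathways through stop codons
    are excluded unless that leaves none.
    """
    diff_pos = [i for i in range(3) if c1[i] != c2[i]]
    if not diff_pos:
        return 0.0, 0.0
    paths = []
    for order in permutations(diff_pos):
        cur = c1
        sd = nd = 0
        blocked = False
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1:]
            if nxt in STOP_CODONS and nxt != c2:
                blocked = True
            if CODON_TABLE[cur] == CODON_TABLE[nxt]:
                sd += 1
            else:
                nd += 1
            cur = nxt
        paths.append((blocked, sd, nd))
    usable = [p for p in paths if not p[0]] or paths
    sd = sum(p[1] for p in usable) / len(usable)
    nd = sum(p[2] for p in usable) / len(usable)
    return sd, nd


def _jc_correct(p: float) -> float | None:
    if p >= 0.75:
        return None
    return -0.75 * log(1.0 - (4.0 / 3.0) * p)


def compute_ks(cds_a: str, cds_b: str,
               query_gene: str = "a", subject_gene: str = "b") -> KsEstimate:
    """NG86 Ks/Ka for an aligned, gap-free, in-frame CDS pair.

    Sequences must be equal length, a multiple of 3, and free of internal
    stop codons.  Codons containing ambiguous bases are skipped.
    """
    a, b = cds_a.upper(), cds_b.upper()
    if len(a) != len(b):
        raise KsError(f"length mismatch: {len(a)} vs {len(b)}")
    if len(a) % 3 != 0:
        raise KsError(f"length {len(a)} not a multiple of 3")
    S = N = Sd = Nd = 0.0
    n_codons = len(a) // 3
    for i in range(n_codons):
        ca, cb = a[3 * i:3 * i + 3], b[3 * i:3 * i + 3]
        if any(ch not in "ACGT" for ch in ca + cb):
            continue
        for c, name in ((ca, query_gene), (cb, subject_gene)):
            if c in STOP_CODONS and i < n_codons - 1:
                raise KsError(f"internal stop codon in {name} at codon {i + 1}")
        if ca in STOP_CODONS or cb in STOP_CODONS:
            continue  # terminal stop: excluded from counting
        S += (_SYN_SITES[ca] + _SYN_SITES[cb]) / 2.0
        N += 3.0 - (_SYN_SITES[ca] + _SYN_SITES[cb]) / 2.0
        sd, nd = _pair_differences(ca, cb)
        Sd += sd
        Nd += nd
    ps = Sd / S if S > 0 else 0.0
    pn = Nd / N if N > 0 else 0.0
    return KsEstimate(
        query_gene=query_gene, subject_gene=subject_gene,
        S=S, N=N, Sd=Sd, Nd=Nd, ps=ps, pn=pn,
        Ks=_jc_correct(ps), Ka=_jc_correct(pn))
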