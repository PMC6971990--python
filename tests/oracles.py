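"""Independent brute-force oracles used by the test suite and the
acceptance script.

These re-derive expected results by a different route than the package:
the event enumerator works on per-base exon-membership arrays rather than
exon tuples, translation goes through Biopython, BH correction and the
hypergeometric tail are written out from their textbook definitions.
"""

from __future__ import annotations

import math
from typing import Optional

from Bio.Seq import Seq

# splice-chain code table, re-typed independently from its published form
ORACLE_CODES = {
    "1^2-,0": "IR",
    "1-2^,0": "ES",
    "1-,2-": "A3SS",
    "1^,2^": "A5SS",
    "1^2-3^4-,0": "IR1+IR2",
    "1^3-,2^4-": "A5SS_or_A3SS",
    "1^2-,3^4-": "IR1_or_IR2",
    "1^4-,2^3-": "A5SS+A3SS",
    "1-2^3-4^,0": "ES1+ES2",
    "1-2^,3-4^": "MXE",
    "1^6-,2^3-4^5-": "A5SS+ES+A3SS",
}


def _membership(exons, lo, hi):
    """Boolean exon-membership array over [lo, hi)."""
    arr = [False] * (hi - lo)
    for s, e in exons:
        for p in range(max(s, lo), min(e, hi)):
            arr[p - lo] = True
    return arr


def _sites_from_membership(exons, strand, lo, hi):
    """(position, kind) internal splice sites strictly inside (lo, hi),
    derived from membership flips of the per-base array."""
    span_lo, span_hi = exons[0][0], exons[-1][1]
    arr = _membership(exons, span_lo, span_hi)
    sites = []
    for i in range(1, len(arr)):
        pos = span_lo + i
        if not (lo < pos < hi):
            continue
        if arr[i - 1] and not arr[i]:       # exon -> intron boundary
            kind = "donor" if strand == "+" else "acceptor"
            sites.append((pos, kind))
        elif not arr[i - 1] and arr[i]:     # intron -> exon boundary
            kind = "acceptor" if strand == "+" else "donor"
            sites.append((pos, kind))
    return sites


def oracle_pair_events(t1, t2):
    """Events between two isoforms: list of dicts with code, type and
    anchors, derived from per-base membership arrays."""
    strand = t1.strand
    lo = max(t1.exons[0][0], t2.exons[0][0])
    hi = min(t1.exons[-1][1], t2.exons[-1][1])
    if lo >= hi:
        return []
    s1 = _sites_from_membership(t1.exons, strand, lo, hi)
    s2 = _sites_from_membership(t2.exons, strand, lo, hi)
    set1, set2 = set(s1), set(s2)
    common = set1 & set2

    def exonic(exons, pos):
        return any(s <= pos < e for s, e in exons)

    if strand == "+":
        left_in, right_in = lo, hi - 1
    else:
        left_in, right_in = hi - 1, lo
    left_ok = exonic(t1.exons, left_in) and exonic(t2.exons, left_in)
    right_ok = exonic(t1.exons, right_in) and exonic(t2.exons, right_in)

    def tx_key(site):
        pos, kind = site
        return (pos if strand == "+" else -pos, kind)

    merged = sorted(set1 | set2, key=tx_key)
    events = []
    run: list = []
    prev: Optional[tuple] = None

    def emit(nxt):
        if not run:
            return
        if prev is None and not left_ok:
            return
        if nxt is None and not right_ok:
            return
        order = {s: i + 1 for i, s in enumerate(sorted(run, key=tx_key))}
        chains = []
        for sset in (set1, set2):
            own = sorted((s for s in run if s in sset), key=tx_key)
            if not own:
                chains.append((math.inf, "0"))
            else:
                txt = "".join(
                    f"{order[s]}{'^' if s[1] == 'donor' else '-'}" for s in own
                )
                chains.append((order[own[0]], txt))
        chains.sort()
        code = ",".join(c for _, c in chains)
        events.append({
            "code": code,
            "type": ORACLE_CODES.get(code, "complex"),
            "anchor_left": prev[0] if prev else None,
            "anchor_right": nxt[0] if nxt else None,
        })

    for site in merged:
        if site in common:
            emit(site)
            run.clear()
            prev = site
        else:
            run.append(site)
    emit(None)
    return events


def oracle_translate(cdna: str, start: int):
    """(protein, stop transcript-coordinate or None) via Biopython."""
    tail = cdna[start:]
    tail = tail[: len(tail) - len(tail) % 3]
    aa = str(Seq(tail).translate())
    if "*" in aa:
        idx = aa.index("*")
        return aa[:idx], start + 3 * idx
    return aa, None


def oracle_bh(pvalues):
    """Benjamini-Hochberg q-values from the step-up definition."""
    n = len(pvalues)
    order = sorted(range(n), key=lambda i: pvalues[i])
    q = [0.0] * n
    running = 1.0
    for rank in range(n - 1, -1, -1):
        i = order[rank]
        running = min(running, pvalues[i] * n / (rank + 1))
        q[i] = running
    return q


def oracle_hypergeom_tail(k: int, big_n: int, big_k: int, n: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n), by direct summation."""
    denom = math.comb(big_n, n)
    total = 0
    for i in range(k, min(big_k, n) + 1):
        total += math.comb(big_k, i) * math.comb(big_n - big_k, n - i)
    return total / denom


def oracle_pearson(x, y) -> float:
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    num = sum((a - mx) * (b - my) for a, b in zip(x, y))
    den = math.sqrt(sum((a - mx) ** 2 for a in x)
                    * sum((b - my) ** 2 for b in y))
    return num / den
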